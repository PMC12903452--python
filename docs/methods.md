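# Methods

`perturbmap` implements the statistical pipeline for pooled CRISPRi screens
with single-cell RNA-seq readout across multiple donors: guide assignment,
quality control and normalization, trans-effect estimation against a
control-cell model, co-regulation networks, a donor-heritability test with a
constrained permutation null, off-target screening, and bootstrap power
analysis. Everything is exercised on synthetic screens with known ground
truth. This note records the models, the defaults, and the numerical
decisions.

## Synthetic screens (`perturbmap.simulate`)

The generator emulates a multi-donor iPSC CRISPRi screen. Donors each
contribute two replicate cell lines (the paired design the permutation test
requires). Cells carry one guide from a library of `n_targets x
guides_per_target` targeting guides plus `n_nontargeting` (default 40)
non-targeting controls; additional cells per line are "unassigned" controls
with zero guide-capture UMIs.

UMI counts are negative binomial (Gamma–Poisson) with gene-specific means
`depth_c * exp(b_g + effects)` and a common dispersion `theta` (default 10).
Per-gene baseline log-means are Normal(location, scale) (default (1, 1));
per-cell depth is log-normal (log-SD 0.25). All injected effects are
natural-log fold changes acting multiplicatively on the NB mean, which makes
them commensurate with differences of log1p-normalized expression — up to a
pseudocount/Jensen correction of order `(e^{-lfc} - 1) / (2 mu)` for a gene
of raw mean `mu`. For this reason target genes are mapped to the first
`n_targets` gene indices and given boosted baselines, and recovery analyses
use well-expressed genes (baseline log-mean around 2.3): the real screens
likewise restricted to genes with mean log-normalized expression above 0.1,
where the correction is negligible.

Injected signal: an on-target LFC (default -0.5) for the cell's guide
target; sparse trans effects from a (target, gene) -> LFC map; optional
donor modulation of selected trans effects, `lfc + gamma_{t,g,donor}` with
`gamma ~ N(0, donor_trans_sd)` drawn once per (target, gene, donor),
centered across donors, and shared by the donor's two replicate lines —
exactly the structure the donor-permutation test is designed to detect; and
optional donor offsets on baseline expression for a `heritable_baseline_
fraction` of genes ("heritable" baseline expression, for the control-cell
heritability test). Cell lines have no expression effects of their own
beyond their donor; mitochondrial fraction and library size are drawn
independently of perturbation status.

Guide capture: each cell receives `Poisson(true_guide_umi_mean)` UMIs
(floored at 1; default mean 10) for its true guide plus
`Poisson(ambient_guide_rate)` (default 1) ambient UMIs scattered over other
guides. With these defaults the top-guide relative abundance has a cluster
near 10/11 ≈ 0.91 and a point mass at 1.0 (zero-ambient cells); the
distributional family of real guide-capture noise is unknown, so this
Poisson-ambient model is a configurable stand-in. What a green test on this
world does **not** establish: robustness to cell-type heterogeneity, ambient
RNA contamination of the expression matrix, doublets, or guide-capture
overdispersion beyond Poisson.

Determinism: one `seed` drives named `SeedSequence` substreams; identical
configurations give bit-identical outputs.

## Guide assignment

A cell's relative abundance is `top-guide UMIs / total guide UMIs` (ties
broken lexicographically). Assignment requires at least 3 top-guide UMIs and
a relative abundance at or above the inlet threshold. The threshold is
detected per inlet as the deepest valley of a Gaussian KDE (absolute
bandwidth 0.02, 501-point grid) between the two highest modes inside the
window [0.5, 1.0]; window edges count as modes when density rises toward
them. Fallback is 0.75 (the reference screens' median inlet threshold) when there are
fewer than 100 cells, the abundances are near-constant, or no interior
valley exists. Note that on the default synthetic world the detector
separates the 0.91 cluster from the 1.0 point mass (threshold ≈ 0.95), which
is faithful to the rule but assigns conservatively; analyses that need fixed
behavior pass an explicit threshold (the pipeline's
`assignment_threshold`). Unassigned cells join the control set downstream.

## QC and normalization

Cells pass QC when total UMIs clear a per-inlet minimum (supplied, not
auto-detected — reproducibility over heuristics), detected features ≥ 2,000
and mitochondrial fraction ≤ 10% (defaults; synthetic runs scale them).
Normalization is `ln(1 + count / total * 10^4)` — natural log, pseudocount
1, so downstream LFCs are natural-log differences. Expressed genes have mean
normalized expression > 0.1. Cell-cycle S/G2M module scores use
expression-binned background gene sets (24 bins, 100 controls per bin, fixed
seed; scanpy's implementation) and the phase call is the argmax of (S, G2M,
0).

## Trans-effect estimation

Per expressed gene, ordinary least squares on control cells (unassigned +
non-targeting carriers) with covariates: intercept, cell line, inlet
(one-hot, first level reference), mitochondrial fraction, S and G2M scores,
total UMIs. Collinear columns are dropped greedily in column order (the
intercept always survives) and logged. Residual SD uses denominator
`n - rank`.

A cell's perturbation-effect profile is observed minus predicted expression
(knockdown therefore negative). Effects average within guides (≥ 5 cells),
targets (≥ 10) or target x line pairings (≥ 10); the z-test uses
`se = residual_sd / sqrt(n_cells)` with a two-sided normal p-value, and
Benjamini–Hochberg adjustment runs across the whole family the run defines,
significance at adjusted p < 0.1. The cis-variant effect replaces the
cell-line term with the donor's allele dosage and reports the dosage
coefficient.

The z-test leans on the CLT for the mean of `n_cells` per-cell residuals and
on the control pool being large (residual-SD noise and the prediction-error
inflation `1 + p/n_controls` are ignored); calibration is verified on a null
screen with >= 10^4 tests.

## Co-regulation

Pearson correlation of target LFC profiles across expressed genes
(co-regulating targets) or of gene response profiles across targets
(co-regulated genes); missing entries pairwise-excluded with a minimum
overlap of 20 features, zero-variance profiles flagged missing. Edges at
|r| strictly greater than 0.2.

## Donor heritability

For each candidate pair — significant in at least one line (adjusted
p < 0.1, |LFC| > 0.1) and not off-target-flagged — the per-cell effects of
the target's cells are fitted by REML with fixed effects (intercept,
normalized target-gene expression as an efficacy proxy; dropped and logged
for unexpressed targets) and independent random intercepts for guide, line
and donor. The donor statistic is `LRT = 2(l_full - l_no_donor)`, clipped at
0; both models share the fixed effects so the REML ratio is well-defined,
and permutation inference avoids the boundary-chi-square problem entirely.

The LMM is implemented in-package (`perturbmap.lmm`): the residual variance
profiles out, the Woodbury identity reduces every likelihood evaluation to
dense algebra in the number of factor levels (independent of cell count),
and Nelder–Mead optimizes the log variance ratios from two starts. An
analytic gradient (envelope theorem) with L-BFGS-B serves the permutation
loop. The implementation is cross-checked against statsmodels' MixedLM in
the tests; on crossed designs our optimizer reaches equal or better optima.

Permutation null: donor labels are permuted across lines such that both
lines of every donor land in different donors — the unlabeled perfect
pairings of the 2n lines avoiding every original pair (544 for n = 5;
labels are irrelevant to a variance component). Pairings are enumerated
exhaustively (sampled without replacement above the 10^4 cap), evaluated in
seeded random order with early stopping after 10 exceedances, and

    p_emp = max(10, S + 1) / (min(P, 10^4) + 1),   clipped at 1,

so p_emp is floored at 10/(P+1). The floor is conservative, but the
derangement constraint introduces genuine negative dependence — when the
observed pairing's lines are coincidentally similar, every admissible null
pairing is forbidden from using exactly those pairs, which suppresses the
null distribution — and in simulation the two effects nearly cancel: the
type-I error at alpha = 0.05 is about 0.075 in a pure Gaussian null world.
The test should be treated as approximately calibrated, not conservative.
The reduced (donor-free) likelihood is permutation-invariant and computed
once; permuted full models are assembled from line-level aggregates of the
base cross-products, so no per-cell work happens in the loop. Two numerical
safeguards matter here: warm starts for permuted fits are floored at a
variance ratio of 0.05 (a gradient search started in the flat gamma ≈ 0
region terminates immediately and would systematically underestimate null
statistics), and exceedances are counted with a 1e-6 tie tolerance so that
boundary fits on both sides compare as equal. Without these, null worlds
with all variance components at zero reject far above the nominal rate.

Control-cell heritability uses the same machinery on normalized expression
with randoms line and donor only. Classification of a donor-significant pair
(adjusted p < 0.1): expression heritable in controls (control adjusted
p < 0.1) resolves to *loss* (post-knockdown heritability gone, adjusted
p ≥ 0.1) or *maintenance*; no evidence in controls (p > 0.9) resolves to
*gain* (heritability appears after knockdown) or *no-gain*; anything between
is *unclassified*. The post-knockdown test applies the same LMM to perturbed
cells' normalized expression of the response gene — the source procedure is
described narratively, and this re-test is our formalization of it.
Direction comes from the per-line LFC signs; when exactly one donor's lines
are up and the rest are not, that donor is reported as the carrier.
Variance decomposition reports REML components plus the variance of the
fitted fixed-effect contribution, normalized to sum to 1.

## Off-target screen

Protospacers (20 nt) are Hamming-scanned against both strands of
user-supplied TSS-centred sequence windows (FASTA with
`gene|chrom|start|end|strand` headers, 0-based half-open; the TSS is the
window centre). Flags: exact match within 1 kb of another gene's TSS
(`proximity`), at most 2 mismatches within 1 kb (`mismatch<=2` — "fewer
than 3 nt mismatches"), and, for a designated focus gene, an exact match of
the 9-nt PAM-proximal seed within 2 kb (`seed9`). PAM sequences are not
modeled; non-ACGT characters never match and are warned about. A guide
never flags its intended target. Flagged (target, gene) pairs are annotated
or excluded from heritability candidates; cross-mapping exclusions are
accepted as a user-supplied list, never computed.

## Power analysis

For a target's assigned cells, effects are re-estimated on bootstrap
resamples (with replacement) of 5, 10, 25, 50, 100, 250, 500 and 1000 cells,
25 replicates each, through the same summarization code path as the main
pipeline; the control model is not refit (controls are untouched by the
resampling). Summaries: SD of the LFC across replicates (expected to scale
as cells^-1/2) and detection rate at BH-adjusted p < 0.1, with BH applied
within each (size, replicate) family. Seeding spawns one stream per
(size, replicate) so the grid is order-independent.

## Pipeline and I/O

`run_pipeline` wires the stages (simulate -> assign -> QC -> effects ->
co-regulation -> heritability -> power, as toggled) from a single
`PipelineConfig` whose defaults are the reference thresholds; unknown keys
are rejected, the effective configuration is serialized next to the
outputs, and every table carries the package version and a SHA-256 config
hash in `#`-comment headers. Counts travel as MatrixMarket + features/
barcodes TSV (10x layout, genes x cells, 1-based); guide UMIs as long-form
TSV; truth as JSON. Readers validate MTX entry counts and reject duplicate
barcodes; expression/guide barcode sets are reconciled by intersection with
logged drop counts.

## Known limitations

- The donor-permutation test needs at least 4 donors for p_emp ever to drop
  below 1 (with n < 4 donors the admissible permutation count is below the
  early-stop floor of 10); 5 donors give a floor of 10/545 ≈ 0.018.
- With only 5 donors, the realized spread of donor modulations varies
  widely around `donor_trans_sd`; individual planted effects can be
  undetectable by bad luck, which is why power guarantees are stated over
  many pairs.
- The z-test treats the control fit as fixed; with small control pools it
  is slightly anti-conservative (inflation ~ p/n_controls, untested below
  ~1,000 controls).
- Guide-capture noise is Poisson-ambient by assumption; inlet thresholds on
  other noise families are unvalidated.
- Cross-mapping between homologous transcripts is not detected.
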