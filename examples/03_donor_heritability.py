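"""Test whether a trans effect differs between donors (heritability).

A 5-donor screen (two replicate lines each) with one donor-modulated trans
effect. The donor contribution to the per-cell effect is tested with a REML
likelihood ratio against a permutation null that reassigns lines to donors
while keeping the line structure — 544 admissible relabelings for 5 donors.
"""

import numpy as np
import pandas as pd

from perturbmap import SimConfig, generate_dataset
from perturbmap.heritability import (
    LmmSpec,
    enumerate_donor_permutations,
    lrt_donor,
    permutation_pvalue,
    variance_decomposition,
)
from perturbmap.simulate import DonorDesign
from perturbmap.effects import fit_control_model, per_cell_effects
from perturbmap.qc import lognormalize

sim = SimConfig(
    n_donors=5, cells_per_line_per_guide=17, n_genes=60, n_targets=2,
    guides_per_target=3, n_nontargeting=10, baseline_logmean_dist=(2.3, 0.4),
    trans_effect_matrix={(0, 10): 0.5, (1, 20): 0.5},
    donor_modulated_pairs=[(0, 10)], donor_trans_sd=0.6, seed=2,
)
adata, _, library, truth = generate_dataset(sim)
lognormalize(adata)
adata.obs["s_score"] = 0.0
adata.obs["g2m_score"] = 0.0

# effects vs control cells, using the true guide labels for brevity
adata.obs["guide"] = adata.obs_names.map(truth.guide_of_cell)
controls = truth.control_cells
fit = fit_control_model(adata, controls)
design = DonorDesign(dict(truth.design))
perms = enumerate_donor_permutations(design)
print(f"{len(perms)} admissible donor relabelings for 5 paired lines")

for target, gene, label in [("gene0000", "gene0010", "donor-modulated"),
                            ("gene0001", "gene0020", "uniform")]:
    cells = [c for c in adata.obs_names
             if truth.guide_of_cell[c].startswith(target + "_")]
    prof = per_cell_effects(adata, cells, fit)
    obs = adata.obs.loc[cells]
    spec = LmmSpec(
        y=prof[gene].to_numpy(),
        fixed=np.asarray(adata[cells, [target]].layers["lognorm"].todense()).ravel(),
        guide=obs["guide"].to_numpy(),
        line=obs["cell_line"].to_numpy(),
        donor=obs["donor"].to_numpy(),
    )
    lrt = lrt_donor(spec)
    S, P, p = permutation_pvalue(lrt, spec, perms, seed=1)
    print(f"\n{target} -> {gene} ({label} trans effect):")
    print(f"  donor LRT {lrt:.2f}; {S} of {P} null stats as strong; p_emp {p:.4f}")
    fr = variance_decomposition(
        spec.y, {"guide": spec.guide, "line": spec.line, "donor": spec.donor},
        fixed=spec.fixed,
    )
    print("  variance shares:", {k: round(v, 3) for k, v in fr.items()})

print("\nA small p_emp (floor 10/545 = 0.018) means the effect size differs"
      " consistently between donors — a heritable trans effect.")
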