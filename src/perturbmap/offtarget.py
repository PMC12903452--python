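"""Off-target screening of guides by TSS proximity and protospacer similarity.

A guide is flagged for a gene when its 20-nt protospacer matches, on either
strand, a sequence near that gene's transcription start site: an exact match
within 1 kb (rule ``proximity``), a 1-2-mismatch match within 1 kb (rule
``mismatch<=2``), or — for a designated focus gene — an exact match of the
9-nt PAM-proximal seed within 2 kb (rule ``seed9``). Windows of TSS-proximal
sequence are supplied as FASTA with ``gene|chrom|start|end|strand`` headers
(0-based half-open coordinates, TSS at the window center), so no genome
index is required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "TssWindow",
    "OffTargetFlag",
    "read_windows_fasta",
    "find_offtargets",
    "seed_match",
    "annotate_effects",
    "flagged_pairs",
]

logger = logging.getLogger(__name__)


@dataclass
class TssWindow:
    gene: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    seq: str

    @property
    def tss(self) -> int:
        return self.start + (self.end - self.start) // 2


@dataclass(frozen=True)
class OffTargetFlag:
    guide: str
    flagged_gene: str
    rule: str  # proximity | mismatch<=2 | seed9
    mismatches: int
    distance_to_tss: int


def read_windows_fasta(path) -> list[TssWindow]:
    """Parse TSS-proximal windows from FASTA with pipe-delimited headers."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) != 5:
            raise ValueError(f"window header {rec.id!r} is not gene|chrom|start|end|strand")
        gene, chrom, start, end, strand = fields
        out.append(TssWindow(gene, chrom, int(start), int(end), strand, str(rec.seq).upper()))
    return out


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_matches(spacer: str, window: TssWindow, max_mismatches: int):
    """Yield (genomic_start_of_protospacer, mismatches, strand) hits.

    Both strands are scanned with a Hamming distance at every offset.
    Non-ACGT characters never match (counted as mismatches) and trigger a
    warning once per window.
    """
    L = len(spacer)
    W = len(window.seq)
    if W < L:
        logger.warning("window for %s shorter than protospacer: skipped", window.gene)
        return
    if set(window.seq) - set("ACGT"):
        logger.warning("window for %s contains ambiguity codes; they never match", window.gene)
    enc = _encode(window.seq)
    views = np.lib.stride_tricks.sliding_window_view(enc, L)
    for strand_label, query in (("+", spacer), ("-", str(Seq(spacer).reverse_complement()))):
        mm = (views != _encode(query)).sum(axis=1)
        for off in np.nonzero(mm <= max_mismatches)[0]:
            # genomic coordinate of the protospacer 5' end in guide orientation
            if strand_label == "+":
                gstart = window.start + int(off)
            else:
                gstart = window.start + int(off) + L - 1
            yield gstart, int(mm[off]), strand_label


def find_offtargets(
    library: pd.DataFrame,
    windows: list[TssWindow],
    max_mismatches: int = 2,
    window_bp: int = 1000,
) -> list[OffTargetFlag]:
    """Flag guides matching within ``window_bp`` of another gene's TSS.

    Exact matches are reported under rule ``proximity`` and 1-2-mismatch
    matches under ``mismatch<=2``; the best (fewest-mismatch) hit per
    (guide, gene) is kept. A guide never flags its own intended target.
    """
    flags: dict[tuple[str, str], OffTargetFlag] = {}
    for _, g in library.iterrows():
        for w in windows:
            if not g.is_control and w.gene == g.target:
                continue
            for gstart, mm, _ in _best_matches(g.sequence, w, max_mismatches):
                dist = abs(gstart - w.tss)
                if dist > window_bp:
                    continue
                rule = "proximity" if mm == 0 else f"mismatch<={max_mismatches}"
                key = (g.guide_id, w.gene)
                prev = flags.get(key)
                if prev is None or (mm, dist) < (prev.mismatches, prev.distance_to_tss):
                    flags[key] = OffTargetFlag(g.guide_id, w.gene, rule, mm, dist)
    return sorted(flags.values(), key=lambda f: (f.guide, f.flagged_gene))


def seed_match(
    library: pd.DataFrame,
    windows: list[TssWindow],
    focus_gene: str,
    seed_len: int = 9,
    window_bp: int = 2000,
) -> list[OffTargetFlag]:
    """Flag guides whose PAM-proximal seed occurs exactly near a focus TSS.

    The seed is the last ``seed_len`` nt of the protospacer (adjacent to the
    PAM); only exact matches within ``window_bp`` of the focus gene's TSS
    count.
    """
    focus = [w for w in windows if w.gene == focus_gene]
    if not focus:
        raise ValueError(f"no window supplied for focus gene {focus_gene!r}")
    flags: dict[tuple[str, str], OffTargetFlag] = {}
    for _, g in library.iterrows():
        if not g.is_control and g.target == focus_gene:
            continue
        seed = g.sequence[-seed_len:]
        for w in focus:
            for gstart, mm, _ in _best_matches(seed, w, 0):
                dist = abs(gstart - w.tss)
                if dist > window_bp:
                    continue
                key = (g.guide_id, w.gene)
                prev = flags.get(key)
                if prev is None or dist < prev.distance_to_tss:
                    flags[key] = OffTargetFlag(g.guide_id, w.gene, "seed9", 0, dist)
    return sorted(flags.values(), key=lambda f: (f.guide, f.flagged_gene))


def annotate_effects(
    effects: pd.DataFrame,
    flags: list[OffTargetFlag],
    library: pd.DataFrame,
    mode: str = "annotate",
) -> pd.DataFrame:
    """Mark (or drop) effect rows explainable by off-target activity.

    A row matches a flag when its gene equals the flagged gene and its unit
    is the flagging guide (guide level) or the guide's target (target and
    target x line levels). ``mode='exclude'`` drops matched rows, which is
    how candidate pairs for the heritability test are cleaned.
    """
    if mode not in ("annotate", "exclude"):
        raise ValueError("mode must be 'annotate' or 'exclude'")
    target_of_guide = dict(zip(library.guide_id, library.target))
    out = effects.copy()
    out["offtarget_flagged"] = False
    out["offtarget_rule"] = ""
    unit_target = out["unit"].astype(str).str.split("|", n=1).str[0]
    for f in flags:
        tgt = target_of_guide.get(f.guide)
        hit = (out["gene"] == f.flagged_gene) & (
            (out["unit"] == f.guide) | (unit_target == tgt)
        )
        out.loc[hit, "offtarget_flagged"] = True
        out.loc[hit & (out["offtarget_rule"] == ""), "offtarget_rule"] = f.rule
    if mode == "exclude":
        return out[~out["offtarget_flagged"]].drop(
            columns=["offtarget_flagged", "offtarget_rule"]
        )
    return out


def flagged_pairs(flags: list[OffTargetFlag], library: pd.DataFrame) -> set[tuple[str, str]]:
    """(target, gene) pairs affected by any flag, for candidate filtering."""
    target_of_guide = dict(zip(library.guide_id, library.target))
    return {
        (target_of_guide[f.guide], f.flagged_gene)
        for f in flags
        if f.guide in target_of_guide
    }
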