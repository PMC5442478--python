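"""Promoter chromatin-state classification over three histone marks.

Promoters (TSS +- 500 bp) are classified per condition into eight classes by
which of H3K4me3, H3K9ac and H3K27me3 are carried by nucleosomes inside the
promoter: each single mark, each pair, all three, or none.  A mark is
"present" when at least one retained nucleosome call for that mark (called
from the mark's reads with the standard caller and kept only if its
occupancy over the 147-bp footprint exceeds 1 RPKM) has its midpoint inside
the promoter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import GeneAnnotation, ReadTable, rpkm
from .nucmap import EXCLUSION, MIN_COUNT, SIGMA, call_nucleosomes, reads_to_dyads

MARKS = ("H3K4me3", "H3K9ac", "H3K27me3")
RPKM_CUTOFF = 1.0
FOOTPRINT = 147

#: The eight promoter classes, canonical order (singles, pairs, triple, none).
STATE_CLASSES = (
    "H3K4me3",
    "H3K9ac",
    "H3K27me3",
    "H3K4me3/H3K9ac",
    "H3K4me3/H3K27me3",
    "H3K9ac/H3K27me3",
    "H3K4me3/H3K9ac/H3K27me3",
    "none",
)


def state_name(marks_present) -> str:
    """Canonical class name for a set of present marks."""
    present = [m for m in MARKS if m in set(marks_present)]
    return "/".join(present) if present else "none"


def hm_nucleosomes(
    reads: ReadTable,
    chrom_lengths: dict[str, int] | None = None,
    sigma: float = SIGMA,
    exclusion: int = EXCLUSION,
    min_count: int = MIN_COUNT,
    rpkm_cutoff: float = RPKM_CUTOFF,
) -> pd.DataFrame:
    """Call nucleosomes carrying a histone mark and filter by occupancy.

    The mark's reads go through the standard dyad shift and caller; each
    call's occupancy is its read count as RPKM over the 147-bp footprint
    (denominator: the mark sample's total mapped reads) and calls at or
    below ``rpkm_cutoff`` are discarded.
    """
    dyads = reads_to_dyads(reads)
    calls = call_nucleosomes(dyads, chrom_lengths, sigma, exclusion, min_count)
    if calls.empty:
        return calls.assign(rpkm=pd.Series(dtype=float))
    total = reads.total_mapped
    calls = calls.assign(
        rpkm=[rpkm(c, FOOTPRINT, total) for c in calls["read_count"]]
    )
    return calls[calls["rpkm"] > rpkm_cutoff].reset_index(drop=True)


def classify_promoter(promoter_row, mark_calls: dict[str, pd.DataFrame]) -> str:
    """Class of one promoter interval given per-mark retained call sets."""
    present = []
    for mark, calls in mark_calls.items():
        sel = calls[
            (calls["chrom"] == promoter_row.chrom)
            & (calls["midpoint"] >= promoter_row.start)
            & (calls["midpoint"] < promoter_row.end)
        ]
        if len(sel):
            present.append(mark)
    return state_name(present)


def classify_promoters(
    annotation: GeneAnnotation, mark_calls: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-gene promoter state; columns ``gene_id, state``."""
    promoters = annotation.promoters()
    states = [classify_promoter(row, mark_calls) for row in promoters.itertuples()]
    return pd.DataFrame({"gene_id": promoters["gene_id"], "state": states})


def state_transitions(states_a: pd.DataFrame, states_b: pd.DataFrame) -> pd.DataFrame:
    """8x8 transition count matrix between condition-A and condition-B states.

    Row = class in A, column = class in B; margins therefore equal the
    per-condition class counts.  Raises if the two gene universes differ.
    """
    if set(states_a["gene_id"]) != set(states_b["gene_id"]):
        raise ValueError("state tables cover different gene sets")
    merged = states_a.merge(states_b, on="gene_id", suffixes=("_a", "_b"))
    mat = pd.crosstab(merged["state_a"], merged["state_b"])
    mat = mat.reindex(index=STATE_CLASSES, columns=STATE_CLASSES, fill_value=0)
    mat.index.name = "state_a"
    mat.columns.name = "state_b"
    return mat


def promoter_occupancy(
    reads: ReadTable, annotation: GeneAnnotation
) -> pd.DataFrame:
    """Per-gene RPKM occupancy of one mark's reads in the promoter window."""
    dyads = reads_to_dyads(reads)
    promoters = annotation.promoters()
    total = reads.total_mapped
    rows = []
    for row in promoters.itertuples():
        count = dyads.count_in(row.chrom, int(row.start), int(row.end))
        occ = rpkm(count, int(row.end) - int(row.start), total) if total else 0.0
        rows.append((row.gene_id, count, occ))
    return pd.DataFrame(rows, columns=["gene_id", "count", "occupancy"])


def promoter_hm_fold_change(
    occ_a: pd.DataFrame, occ_b: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """log2 of the condition-B / condition-A promoter occupancy ratio.

    A pseudocount (RPKM units) keeps the ratio finite at zero occupancy;
    two zero occupancies give exactly 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    merged = occ_a.merge(occ_b, on="gene_id", suffixes=("_a", "_b"))
    fc = (merged["occupancy_b"] + pseudocount) / (merged["occupancy_a"] + pseudocount)
    return pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "occupancy_a": merged["occupancy_a"],
            "occupancy_b": merged["occupancy_b"],
            "fold_change": fc,
            "log2_ratio": np.log2(fc),
        }
    )
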