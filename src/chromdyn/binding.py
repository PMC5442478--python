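"""TF peak calling and comparison of binding-site sets between conditions.

Peaks are enriched regions that additionally pass a fold-enrichment
threshold over the local background (default p < 1e-4 and fold >= 10, with
a 250-bp window matching the sheared-fragment size).  Two conditions' peak
sets are partitioned into condition-specific and common peaks, and peak
sets are intersected with region sets (e.g. CRRs) to quantify co-location.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import GenomeSpec, ReadTable
from .diffsig import PCUT_TF, call_enriched_regions
from .nucmap import _in_any_interval

TF_WINDOW = 250
TF_MIN_FOLD = 10.0


def call_tf_peaks(
    tf_reads: ReadTable,
    control: ReadTable,
    genome: GenomeSpec,
    pcut: float = PCUT_TF,
    min_fold: float = TF_MIN_FOLD,
    window: int = TF_WINDOW,
    step: int = 50,
) -> pd.DataFrame:
    """Call TF binding peaks passing both p-value and fold thresholds.

    Fold is the best window's treatment count over its Poisson rate; peaks
    with fold >= ``min_fold`` (inclusive) are kept.
    """
    regions = call_enriched_regions(tf_reads, control, genome, pcut, window, step)
    if regions.empty:
        return regions
    return regions[regions["fold"] >= min_fold].reset_index(drop=True)


def compare_peak_sets(
    peaks_a: pd.DataFrame, peaks_b: pd.DataFrame, min_overlap: int = 1
) -> dict[str, pd.DataFrame | int]:
    """Partition two peak sets into condition-specific and common peaks.

    A peak is *common* when it overlaps any peak of the other set by at
    least ``min_overlap`` bp; every peak lands in exactly one class per
    side.  Returns the per-side partitions plus the headline common count
    (pairs counted from the A side).
    """
    common_a = _overlaps_any(peaks_a, peaks_b, min_overlap)
    common_b = _overlaps_any(peaks_b, peaks_a, min_overlap)
    return {
        "a_specific": peaks_a[~common_a].reset_index(drop=True),
        "b_specific": peaks_b[~common_b].reset_index(drop=True),
        "a_common": peaks_a[common_a].reset_index(drop=True),
        "b_common": peaks_b[common_b].reset_index(drop=True),
        "n_common": int(common_a.sum()),
    }


def _overlaps_any(peaks: pd.DataFrame, others: pd.DataFrame, min_overlap: int) -> np.ndarray:
    out = np.zeros(len(peaks), dtype=bool)
    for chrom, group in others.groupby("chrom"):
        mask = (peaks["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = group["start"].to_numpy(np.int64)
        ends = group["end"].to_numpy(np.int64)
        p_start = peaks.loc[mask, "start"].to_numpy(np.int64)
        p_end = peaks.loc[mask, "end"].to_numpy(np.int64)
        hit = np.zeros(len(p_start), dtype=bool)
        for s, e in zip(starts.tolist(), ends.tolist()):
            hit |= np.minimum(p_end, e) - np.maximum(p_start, s) >= min_overlap
        out[np.flatnonzero(mask)] = hit
    return out


def peaks_vs_regions(
    peaks: pd.DataFrame, regions: pd.DataFrame, genome: GenomeSpec
) -> dict[str, float]:
    """Fraction of peaks inside a region set and its fold over expectation.

    A peak counts as inside when its midpoint falls in a region; the
    expected fraction under uniform placement is the regions' share of the
    genome, and fold = observed / expected.
    """
    coverage = int((regions["end"] - regions["start"]).sum()) if len(regions) else 0
    expected = coverage / genome.total_length
    if len(peaks) == 0:
        return {"fraction": 0.0, "expected": expected, "fold": float("nan")}
    mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy(np.int64)
    n_in = 0
    for chrom, group in regions.groupby("chrom"):
        mask = (peaks["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        inside = _in_any_interval(
            mid[mask], group["start"].to_numpy(np.int64), group["end"].to_numpy(np.int64)
        )
        n_in += int(inside.sum())
    fraction = n_in / len(peaks)
    fold = fraction / expected if expected > 0 else float("inf") if fraction else float("nan")
    return {"fraction": fraction, "expected": expected, "fold": fold}
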