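"""Nucleosome calling and positioning dynamics.

Single-end reads are shifted 73 bp interior to their 5' end to estimate the
nucleosome dyad (the centre of the 147 bp of wrapped DNA).  Dyad counts are
smoothed with a Gaussian kernel (sigma 20 bp) and nucleosomes are called
greedily under a 147-bp exclusion zone, so that two called midpoints on a
chromosome are never closer than the physical footprint allows.  Calls are
then filtered by supporting read count, given a positional fuzziness (the
population SD of their supporting dyad coordinates), assigned to a genomic
compartment, and compared between two conditions to label each nucleosome
fixed / shift / gain / loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneAnnotation, GenomeSpec, ReadTable, rpkm

DYAD_SHIFT = 73          # bp from the 5' read end to the dyad (147/2, rounded down)
EXCLUSION = 147          # bp minimum distance between called midpoints
SIGMA = 20.0             # bp Gaussian smoothing bandwidth
MIN_COUNT = 6            # minimum supporting reads for a reported call
SUPPORT_HALFWIDTH = 73   # dyads within +-73 bp of a midpoint support the call
GAINLOSS_DIST = 107      # bp midpoint distance at or beyond which a pair is gain/loss

GENOMIC_CLASSES = ("promoter", "genic", "intergenic")
DYNAMICS_LABELS = ("fixed", "shift", "gain", "loss")


@dataclass
class DyadMap:
    """Sparse per-base dyad counts per chromosome.

    ``dyads`` maps chrom -> (positions sorted ascending, counts); positions
    are distinct.  ``n_clipped`` counts reads whose shifted dyad fell off
    the chromosome and was clipped to its bounds.
    """

    dyads: dict[str, tuple[np.ndarray, np.ndarray]]
    total_dyads: int
    n_clipped: int = 0

    def chrom_positions(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self.dyads.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Total dyads in half-open [start, end)."""
        pos, cnt = self.chrom_positions(chrom)
        lo, hi = np.searchsorted(pos, (start, end))
        return int(cnt[lo:hi].sum())


def reads_to_dyads(
    reads: ReadTable,
    shift: int = DYAD_SHIFT,
    genome: GenomeSpec | None = None,
) -> DyadMap:
    """Shift each read ``shift`` bp interior to its 5' end to its dyad.

    ``+`` strand: dyad = start + shift; ``-`` strand: dyad = (end-1) - shift.
    With a genome given, dyads outside the chromosome are clipped to its
    bounds and tallied in ``n_clipped``.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_clipped = 0
    total = 0
    for chrom, df in reads.by_chrom().items():
        start = df["start"].to_numpy(np.int64)
        end = df["end"].to_numpy(np.int64)
        fwd = (df["strand"] == "+").to_numpy()
        dyad = np.where(fwd, start + shift, end - 1 - shift)
        upper = genome.chrom_lengths[chrom] - 1 if genome is not None else None
        if upper is not None:
            clipped = (dyad < 0) | (dyad > upper)
            n_clipped += int(clipped.sum())
            dyad = np.clip(dyad, 0, upper)
        else:
            dyad = np.maximum(dyad, 0)
        pos, cnt = np.unique(dyad, return_counts=True)
        out[chrom] = (pos.astype(np.int64), cnt.astype(np.int64))
        total += len(df)
    return DyadMap(out, total_dyads=total, n_clipped=n_clipped)


def _gaussian_kernel(sigma: float) -> np.ndarray:
    # Radius at which exp(-r^2 / 2 sigma^2) underflows to exactly 0.0, so
    # truncation is invisible at double precision and the smoothed signal
    # equals the full per-base sum bit for bit.
    radius = int(math.ceil(sigma * math.sqrt(2.0 * 746.0)))
    x = np.arange(-radius, radius + 1, dtype=float)
    return np.exp(-(x * x) / (2.0 * sigma * sigma))


def smoothed_signal(pos: np.ndarray, cnt: np.ndarray, length: int, sigma: float) -> np.ndarray:
    """Gaussian-smoothed dyad density s(x) = sum_d count(d) exp(-(x-d)^2/2s^2).

    Contributions are accumulated in ascending dyad order so the result is
    reproducible and matches a direct per-base summation exactly.
    """
    kernel = _gaussian_kernel(sigma)
    radius = len(kernel) // 2
    s = np.zeros(length, dtype=float)
    for p, c in zip(pos.tolist(), cnt.tolist()):
        lo = max(0, p - radius)
        hi = min(length, p + radius + 1)
        if lo >= hi:
            continue
        s[lo:hi] += c * kernel[lo - p + radius : hi - p + radius]
    return s


def _greedy_select(s: np.ndarray, exclusion: int) -> np.ndarray:
    """Greedy peak picking: repeatedly take the highest remaining position
    (leftmost on ties) and suppress everything within < exclusion bp."""
    candidates = np.flatnonzero(s > 0)
    if candidates.size == 0:
        return candidates
    order = np.lexsort((candidates, -s[candidates]))
    blocked = np.zeros(len(s), dtype=bool)
    picked = []
    for pos in candidates[order]:
        if blocked[pos]:
            continue
        picked.append(pos)
        lo = max(0, pos - exclusion + 1)
        blocked[lo : pos + exclusion] = True
    return np.sort(np.asarray(picked, dtype=np.int64))


def compute_fuzziness(coords: np.ndarray, counts: np.ndarray | None = None) -> float:
    """Positional fuzziness: population SD of supporting dyad coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("fuzziness of an empty coordinate set is undefined")
    if counts is None:
        counts = np.ones_like(coords)
    counts = np.asarray(counts, dtype=float)
    mean = np.average(coords, weights=counts)
    var = np.average((coords - mean) ** 2, weights=counts)
    return float(math.sqrt(max(var, 0.0)))


def call_nucleosomes(
    dyad_map: DyadMap,
    chrom_lengths: dict[str, int] | None = None,
    sigma: float = SIGMA,
    exclusion: int = EXCLUSION,
    min_count: int = MIN_COUNT,
    support_halfwidth: int = SUPPORT_HALFWIDTH,
) -> pd.DataFrame:
    """Call nucleosomes from a dyad map.

    Returns a DataFrame with columns ``chrom, midpoint, read_count,
    fuzziness`` sorted by (chrom, midpoint).  A call's supporting dyads are
    those within ``+-support_halfwidth`` bp of its midpoint; calls with
    fewer than ``min_count`` supporting reads are dropped.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if exclusion < 1:
        raise ValueError("exclusion must be >= 1")
    rows = []
    for chrom in sorted(dyad_map.dyads):
        pos, cnt = dyad_map.dyads[chrom]
        if pos.size == 0:
            continue
        if chrom_lengths is not None and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            length = int(pos[-1]) + int(math.ceil(4 * sigma)) + 1
        s = smoothed_signal(pos, cnt, length, sigma)
        midpoints = _greedy_select(s, exclusion)
        if midpoints.size == 0:
            continue
        lo = np.searchsorted(pos, midpoints - support_halfwidth)
        hi = np.searchsorted(pos, midpoints + support_halfwidth + 1)
        for m, a, b in zip(midpoints.tolist(), lo.tolist(), hi.tolist()):
            n_reads = int(cnt[a:b].sum())
            if n_reads < min_count:
                continue
            fuzz = compute_fuzziness(pos[a:b], cnt[a:b])
            rows.append((chrom, m, n_reads, fuzz))
    calls = pd.DataFrame(rows, columns=["chrom", "midpoint", "read_count", "fuzziness"])
    return calls.sort_values(["chrom", "midpoint"], kind="mergesort").reset_index(drop=True)


def annotate_calls(calls: pd.DataFrame, annotation: GeneAnnotation) -> pd.DataFrame:
    """Assign each call to promoter / genic / intergenic by its midpoint.

    Promoter wins over genic on overlap; calls on chromosomes absent from
    the annotation are intergenic.
    """
    calls = calls.copy()
    classes = np.full(len(calls), "intergenic", dtype=object)
    promoters = annotation.promoters()
    bodies = annotation.gene_bodies()
    for label, regions in (("genic", bodies), ("promoter", promoters)):
        for chrom, group in regions.groupby("chrom"):
            mask = (calls["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            mid = calls.loc[mask, "midpoint"].to_numpy()
            inside = _in_any_interval(
                mid, group["start"].to_numpy(np.int64), group["end"].to_numpy(np.int64)
            )
            idx = np.flatnonzero(mask)[inside]
            classes[idx] = label
    calls["genomic_class"] = classes
    return calls


def _in_any_interval(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: point falls in any half-open [start, end) interval."""
    if starts.size == 0:
        return np.zeros(points.shape, dtype=bool)
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    # merge overlapping intervals so a single searchsorted test suffices
    m_starts, m_ends = [], []
    for s, e in zip(starts.tolist(), ends.tolist()):
        if m_ends and s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    m_starts = np.asarray(m_starts)
    m_ends = np.asarray(m_ends)
    idx = np.searchsorted(m_starts, points, side="right") - 1
    ok = idx >= 0
    ok[ok] &= points[ok] < m_ends[idx[ok]]
    return ok


def window_occupancy(
    dyad_map: DyadMap, genome: GenomeSpec, window: int = 10_000
) -> pd.DataFrame:
    """RPKM-normalised dyad count per non-overlapping genomic window."""
    if window <= 0:
        raise ValueError("window must be positive")
    total = dyad_map.total_dyads
    rows = []
    for chrom, length in genome.chrom_lengths.items():
        pos, cnt = dyad_map.chrom_positions(chrom)
        n_windows = int(math.ceil(length / window))
        if pos.size:
            counts = np.bincount(pos // window, weights=cnt, minlength=n_windows)
        else:
            counts = np.zeros(n_windows)
        for i in range(n_windows):
            start = i * window
            end = min(start + window, length)
            occ = rpkm(float(counts[i]), end - start, total) if total else 0.0
            rows.append((chrom, start, end, float(counts[i]), occ))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "rpkm"])


def classify_dynamics(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    gainloss_dist: int = GAINLOSS_DIST,
    fixed_tol: int = 0,
) -> pd.DataFrame:
    """Label every nucleosome in either condition fixed / shift / gain / loss.

    Matching is symmetric nearest-neighbour on midpoints within a
    chromosome.  A pair at distance <= ``fixed_tol`` (default exact
    equality) is one *fixed* nucleosome; a call whose nearest partner is at
    >= ``gainloss_dist`` bp (or absent) is a *loss* if it is condition-A
    only or a *gain* if condition-B only; everything else *shifts*.

    Returns one row per nucleosome entity: columns ``chrom, midpoint,
    condition, label, partner_dist`` (condition "AB" for fixed pairs;
    partner_dist is NaN where no partner exists).
    """
    rows = []
    chroms = sorted(set(calls_a["chrom"]).union(calls_b["chrom"]))
    for chrom in chroms:
        mid_a = np.sort(calls_a.loc[calls_a["chrom"] == chrom, "midpoint"].to_numpy(np.int64))
        mid_b = np.sort(calls_b.loc[calls_b["chrom"] == chrom, "midpoint"].to_numpy(np.int64))
        dist_a = _nearest_distance(mid_a, mid_b)
        dist_b = _nearest_distance(mid_b, mid_a)
        fixed_a = (dist_a <= fixed_tol) if mid_b.size else np.zeros(mid_a.shape, bool)
        fixed_b = (dist_b <= fixed_tol) if mid_a.size else np.zeros(mid_b.shape, bool)
        for m, d, fx in zip(mid_a.tolist(), dist_a.tolist(), fixed_a.tolist()):
            if fx:
                rows.append((chrom, m, "AB", "fixed", d))
            elif not np.isfinite(d) or d >= gainloss_dist:
                rows.append((chrom, m, "A", "loss", d))
            else:
                rows.append((chrom, m, "A", "shift", d))
        for m, d, fx in zip(mid_b.tolist(), dist_b.tolist(), fixed_b.tolist()):
            if fx:
                continue  # the pair is already recorded from the A side
            if not np.isfinite(d) or d >= gainloss_dist:
                rows.append((chrom, m, "B", "gain", d))
            else:
                rows.append((chrom, m, "B", "shift", d))
    return pd.DataFrame(
        rows, columns=["chrom", "midpoint", "condition", "label", "partner_dist"]
    )


def _nearest_distance(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    if query.size == 0:
        return np.empty(0, dtype=float)
    if ref.size == 0:
        return np.full(query.shape, np.inf)
    idx = np.searchsorted(ref, query)
    left = np.clip(idx - 1, 0, len(ref) - 1)
    right = np.clip(idx, 0, len(ref) - 1)
    return np.minimum(np.abs(query - ref[left]), np.abs(query - ref[right])).astype(float)


def dynamics_summary(labels: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per dynamics label (entities, not call rows)."""
    counts = labels["label"].value_counts().reindex(DYNAMICS_LABELS, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {"count": counts, "fraction": counts / total if total else 0.0}
    ).rename_axis("label")


def eviction_overlap(
    evicted: pd.DataFrame,
    other: pd.DataFrame,
    max_dist: int,
    annotation: GeneAnnotation | None = None,
    tss_flank: int = 2000,
) -> dict[str, float]:
    """Fraction of evicted calls with a partner call nearby.

    Reports the fraction of ``evicted`` midpoints with an ``other`` midpoint
    within ``max_dist`` bp, and (when an annotation is given) the fraction
    of each set lying within ``+-tss_flank`` of a TSS.
    """
    n_near = 0
    for chrom in evicted["chrom"].unique():
        mids = np.sort(evicted.loc[evicted["chrom"] == chrom, "midpoint"].to_numpy(np.int64))
        ref = np.sort(other.loc[other["chrom"] == chrom, "midpoint"].to_numpy(np.int64))
        d = _nearest_distance(mids, ref)
        n_near += int((d <= max_dist).sum())
    out = {"overlap_fraction": n_near / len(evicted) if len(evicted) else 0.0}
    if annotation is not None:
        for name, calls in (("evicted", evicted), ("other", other)):
            n_tss = 0
            for chrom, group in annotation.genes.groupby("chrom"):
                mids = calls.loc[calls["chrom"] == chrom, "midpoint"].to_numpy(np.int64)
                tss = np.sort(group["tss"].to_numpy(np.int64))
                if mids.size:
                    d = _nearest_distance(np.sort(mids), tss)
                    n_tss += int((d <= tss_flank).sum())
            out[f"{name}_tss_fraction"] = n_tss / len(calls) if len(calls) else 0.0
    return out


def calls_to_bed(calls: pd.DataFrame, halfwidth: int = SUPPORT_HALFWIDTH) -> pd.DataFrame:
    """Calls as BED-style intervals midpoint +- halfwidth, score=read_count."""
    return pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": np.maximum(calls["midpoint"] - halfwidth, 0),
            "end": calls["midpoint"] + halfwidth + 1,
            "score": calls["read_count"],
            "strand": "+",
        }
    )
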