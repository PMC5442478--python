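"""TSS-anchored occupancy profiles and NDR (nucleosome depletion region) metrics.

The composite profile aggregates nucleosome positions (the midpoint of each
read extended to the 147-bp nucleosome footprint) by strand-oriented
distance to the TSS over all genes, normalises per million mapped reads,
bins at 10 bp and smooths with a 5-bin moving average.  The NDR metric is
the RPKM-normalised dyad count in the strand-oriented window -150..+50 bp
of the TSS, whose occupancy anti-correlates with expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionTable, GeneAnnotation, ReadTable, rpkm
from .nucmap import DYAD_SHIFT, DyadMap, reads_to_dyads

NDR_WINDOW = (-150, 50)   # strand-oriented bp relative to TSS, half-open
PROFILE_FLANK = 2000
PROFILE_BIN = 10
PROFILE_SMOOTH = 5
HEATMAP_WINDOW = (-300, 1000)
DISPLAY_WIDTH = 127       # nucleosome width used when painting heat-map rows


def _oriented_offsets(positions: np.ndarray, tss: int, strand: str) -> np.ndarray:
    d = positions - tss
    return d if strand == "+" else -d


def composite_profile(
    reads: ReadTable,
    annotation: GeneAnnotation,
    flank: int = PROFILE_FLANK,
    bin_size: int = PROFILE_BIN,
    smooth_bins: int = PROFILE_SMOOTH,
) -> pd.DataFrame:
    """Composite nucleosome-position profile around the TSS.

    Each read is reduced to the midpoint of its 147-bp extension (the dyad
    estimate), accumulated at its strand-oriented distance to every gene's
    TSS within ``+-flank``, normalised per million mapped reads, binned and
    smoothed.  Returns columns ``offset`` (bin centre) , ``occupancy``
    (smoothed) and ``raw`` (binned, unsmoothed).
    """
    dyads = reads_to_dyads(reads, DYAD_SHIFT)
    per_base = np.zeros(2 * flank + 1, dtype=float)
    n_valid = 0
    for gene in annotation.genes.itertuples():
        pos, cnt = dyads.chrom_positions(gene.chrom)
        if pos.size == 0:
            n_valid += 1
            continue
        lo, hi = np.searchsorted(pos, (gene.tss - flank, gene.tss + flank + 1))
        off = _oriented_offsets(pos[lo:hi], int(gene.tss), gene.strand)
        np.add.at(per_base, off + flank, cnt[lo:hi])
        n_valid += 1
    if n_valid == 0:
        raise ValueError("no genes with valid flanks")
    if reads.total_mapped == 0:
        raise ValueError("empty read table")
    per_base *= 1e6 / reads.total_mapped
    n_bins = (2 * flank) // bin_size
    binned = per_base[: n_bins * bin_size].reshape(n_bins, bin_size).sum(axis=1)
    smoothed = moving_average(binned, smooth_bins)
    centers = -flank + bin_size * np.arange(n_bins) + bin_size / 2
    return pd.DataFrame({"offset": centers, "occupancy": smoothed, "raw": binned})


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks at the edges (no padding)."""
    values = np.asarray(values, dtype=float)
    half = window // 2
    cum = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cum[hi] - cum[lo]) / (hi - lo)


def heatmap_matrix(
    calls: pd.DataFrame,
    annotation: GeneAnnotation,
    window: tuple[int, int] = HEATMAP_WINDOW,
    display_width: int = DISPLAY_WIDTH,
    order_key=None,
) -> pd.DataFrame:
    """Per-gene occupancy rows around the TSS from called nucleosomes.

    Each call paints a ``display_width``-bp interval centred on its
    midpoint; rows are genes (strand-oriented), columns the offsets
    ``window[0]..window[1]-1``.  ``order_key``: optional gene_id -> sort key.
    """
    lo_w, hi_w = window
    if hi_w <= lo_w:
        raise ValueError("invalid window")
    width = hi_w - lo_w
    half = display_width // 2
    by_chrom = {c: g.sort_values("midpoint") for c, g in calls.groupby("chrom")}
    rows = np.zeros((len(annotation.genes), width), dtype=float)
    gene_ids = annotation.genes["gene_id"].tolist()
    for i, gene in enumerate(annotation.genes.itertuples()):
        group = by_chrom.get(gene.chrom)
        if group is None:
            continue
        mids = group["midpoint"].to_numpy(np.int64)
        off = _oriented_offsets(mids, int(gene.tss), gene.strand)
        for o in off[(off >= lo_w - half) & (off < hi_w + half)]:
            a = max(int(o) - half - lo_w, 0)
            b = min(int(o) + half + 1 - lo_w, width)
            rows[i, a:b] = 1.0
    mat = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"),
                       columns=np.arange(lo_w, hi_w))
    if order_key is not None:
        mat = mat.loc[sorted(gene_ids, key=order_key)]
    return mat


def ndr_occupancy(
    dyad_map: DyadMap,
    annotation: GeneAnnotation,
    window: tuple[int, int] = NDR_WINDOW,
) -> pd.DataFrame:
    """RPKM-normalised dyad occupancy of the NDR window per gene.

    The window is strand-oriented and half-open: offsets ``d`` with
    ``window[0] <= d < window[1]`` downstream-positive.
    """
    lo_w, hi_w = window
    length = hi_w - lo_w
    total = dyad_map.total_dyads
    rows = []
    for gene in annotation.genes.itertuples():
        tss = int(gene.tss)
        if gene.strand == "+":
            start, end = tss + lo_w, tss + hi_w
        else:
            # offsets d in [lo_w, hi_w) map to positions tss - d
            start, end = tss - hi_w + 1, tss - lo_w + 1
        count = dyad_map.count_in(gene.chrom, start, end)
        occ = rpkm(count, length, total) if total > 0 else 0.0
        rows.append((gene.gene_id, count, occ))
    return pd.DataFrame(rows, columns=["gene_id", "count", "occupancy"])


def ndr_formation_genes(
    metric_a: pd.DataFrame,
    metric_b: pd.DataFrame,
    occ_high: float,
    occ_low: float,
) -> list[str]:
    """Genes whose NDR is occupied in condition A and depleted in B.

    A gene qualifies when its condition-A occupancy is at least ``occ_high``
    and its condition-B occupancy is at most ``occ_low``.
    """
    if not occ_high > occ_low >= 0:
        raise ValueError("need occ_high > occ_low >= 0")
    merged = metric_a.merge(metric_b, on="gene_id", suffixes=("_a", "_b"))
    keep = (merged["occupancy_a"] >= occ_high) & (merged["occupancy_b"] <= occ_low)
    return merged.loc[keep, "gene_id"].tolist()


def default_ndr_thresholds(
    metric_a: pd.DataFrame, metric_b: pd.DataFrame, q_high: float = 60, q_low: float = 20
) -> tuple[float, float]:
    """Percentile stand-in thresholds (60th of A, 20th of B).

    Only meaningful when condition-A occupancies are not majority-zero;
    recovery experiments with a known planted amplitude should threshold at
    half that amplitude instead.
    """
    return (
        float(np.percentile(metric_a["occupancy"], q_high)),
        float(np.percentile(metric_b["occupancy"], q_low)),
    )


def expression_correlation(
    metric: pd.DataFrame, expression: ExpressionTable, column: str = "expr_a"
) -> tuple[float, float]:
    """Spearman rank correlation of NDR occupancy against expression."""
    merged = metric.merge(expression.table, on="gene_id")
    if len(merged) < 3:
        raise ValueError("need at least 3 genes")
    occ = merged["occupancy"].to_numpy()
    expr = merged[column].to_numpy()
    if np.all(occ == occ[0]) or np.all(expr == expr[0]):
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(occ, expr)
    return float(rho), float(p)
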