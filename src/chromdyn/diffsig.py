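"""Differential chromatin signal: HMI, ROC predictiveness, enriched regions
and chromatin remodeling regions (CRRs).

The Histone Modification Index of a gene is

    HMI = log2(fold change of promoter H3K9ac, B/A)
        - log2(fold change of promoter H3K27me3, B/A)

so positive values mean acetylation gain dominates methylation gain and
predict activation.  Genes are stratified at HMI <= -1 / >= +1.

Differential enrichment is called with a simplified sliding-window scan:
windows are scored by the exact upper-tail Poisson probability of the
treatment count under a local rate estimated from the control sample
(scaled to treatment depth) floored at the genome-wide treatment rate.
This intentionally reproduces the *differential design* (which condition is
treatment, the p-value cutoffs) rather than any particular peak caller's
internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneAnnotation, GenomeSpec, ReadTable, rpkm
from .nucmap import _in_any_interval, reads_to_dyads

HMI_LOW = -1.0
HMI_HIGH = 1.0
PCUT_HM = 1e-5
PCUT_TF = 1e-4
HM_WINDOW = 1000
HM_STEP = 100


def compute_hmi(
    occ_k9ac: pd.DataFrame,
    occ_k27me3: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """HMI per gene from promoter occupancy tables of the two marks.

    Inputs carry columns ``gene_id, occupancy_a, occupancy_b`` (RPKM) for
    H3K9ac and H3K27me3.  Returns ``gene_id, fc_k9ac, fc_k27me3, hmi,
    stratum`` with strata ``low`` (HMI <= -1), ``high`` (HMI >= +1), else
    ``mid``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    merged = occ_k9ac.merge(occ_k27me3, on="gene_id", suffixes=("_k9", "_k27"))
    fc9 = (merged["occupancy_b_k9"] + pseudocount) / (merged["occupancy_a_k9"] + pseudocount)
    fc27 = (merged["occupancy_b_k27"] + pseudocount) / (merged["occupancy_a_k27"] + pseudocount)
    hmi = np.log2(fc9) - np.log2(fc27)
    stratum = np.where(hmi <= HMI_LOW, "low", np.where(hmi >= HMI_HIGH, "high", "mid"))
    return pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "fc_k9ac": fc9,
            "fc_k27me3": fc27,
            "hmi": hmi,
            "stratum": stratum,
        }
    )


def hmi_expression_association(hmi: pd.DataFrame, expression) -> pd.DataFrame:
    """Median expression change per HMI stratum with rank-sum tests vs mid.

    Returns one row per stratum with ``n, median_log2_fc, p_value`` where
    the p-value is a two-sided Mann-Whitney test of that stratum's log2
    expression changes against the mid stratum (NaN for mid itself, for an
    empty stratum, or when the test is degenerate).
    """
    table = expression.table if hasattr(expression, "table") else expression
    merged = hmi.merge(table, on="gene_id")
    mid = merged.loc[merged["stratum"] == "mid", "log2_fc"].to_numpy()
    rows = []
    for stratum in ("low", "mid", "high"):
        vals = merged.loc[merged["stratum"] == stratum, "log2_fc"].to_numpy()
        p = math.nan
        if stratum != "mid" and len(vals) >= 2 and len(mid) >= 2:
            pooled = np.concatenate([vals, mid])
            if not np.all(pooled == pooled[0]):
                p = float(stats.mannwhitneyu(vals, mid, alternative="two-sided").pvalue)
        med = float(np.median(vals)) if len(vals) else math.nan
        rows.append((stratum, len(vals), med, p))
    return pd.DataFrame(rows, columns=["stratum", "n", "median_log2_fc", "p_value"])


@dataclass
class ROCCurve:
    """Threshold sweep of a score against binary labels."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC of a continuous score for binary labels, positives = True.

    Scores are sorted descending and every distinct value used as a
    threshold (ties grouped); a gene is called positive when its score
    exceeds or equals the threshold.  AUC by the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    distinct = np.flatnonzero(np.diff(s, append=-np.inf))  # last index of each tie group
    tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp[distinct] / n_neg])
    thresholds = np.concatenate([[np.inf], s[distinct]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds, tpr, fpr, auc)


def poisson_sf(count: int, lam: float) -> float:
    """P(X >= count) for X ~ Poisson(lam)."""
    if count <= 0:
        return 1.0
    return float(stats.poisson.sf(count - 1, lam))


def _window_counts(positions: np.ndarray, starts: np.ndarray, width: int) -> np.ndarray:
    lo = np.searchsorted(positions, starts)
    hi = np.searchsorted(positions, starts + width)
    return (hi - lo).astype(np.int64)


def _read_midpoints(reads: ReadTable) -> dict[str, np.ndarray]:
    out = {}
    for chrom, df in reads.by_chrom().items():
        mids = (df["start"].to_numpy(np.int64) + df["end"].to_numpy(np.int64)) // 2
        out[chrom] = np.sort(mids)
    return out


def call_enriched_regions(
    treat: ReadTable,
    control: ReadTable,
    genome: GenomeSpec,
    pcut: float = PCUT_HM,
    window: int = HM_WINDOW,
    step: int = HM_STEP,
) -> pd.DataFrame:
    """Sliding-window differential enrichment of treatment over control.

    Windows of ``window`` bp every ``step`` bp are scored by the exact
    Poisson upper tail of the treatment read count given
    ``lambda = max(genome-wide treatment rate x window,
    control window count x depth ratio)``.  Windows with p < ``pcut`` are
    merged when gapped by at most ``step`` bp.  Returns ``chrom, start,
    end, count, p_value, score, fold`` (score = -log10 of the best window
    p; fold = best window count / its lambda).
    """
    if treat.total_mapped == 0:
        raise ValueError("empty treatment sample")
    t_mids = _read_midpoints(treat)
    c_mids = _read_midpoints(control)
    depth_ratio = (
        treat.total_mapped / control.total_mapped if control.total_mapped else 0.0
    )
    genome_rate = treat.total_mapped / genome.total_length
    rows = []
    for chrom, length in genome.chrom_lengths.items():
        tp = t_mids.get(chrom, np.empty(0, np.int64))
        cp = c_mids.get(chrom, np.empty(0, np.int64))
        starts = np.arange(0, max(length - window, 0) + 1, step, dtype=np.int64)
        if starts.size == 0:
            starts = np.array([0], dtype=np.int64)
        t_counts = _window_counts(tp, starts, window)
        c_counts = _window_counts(cp, starts, window)
        lam = np.maximum(genome_rate * window, c_counts * depth_ratio)
        pvals = stats.poisson.sf(t_counts - 1, lam)
        pvals = np.where(t_counts <= 0, 1.0, pvals)
        sig = np.flatnonzero(pvals < pcut)
        for group in _merge_window_groups(starts[sig], window, step):
            idx = sig[(starts[sig] >= group[0]) & (starts[sig] <= group[1] - window)]
            best = idx[np.argmin(pvals[idx])]
            p_best = float(pvals[best])
            fold = float(t_counts[best] / lam[best]) if lam[best] > 0 else math.inf
            count = int(
                _window_counts(tp, np.array([group[0]]), group[1] - group[0])[0]
            )
            score = -math.log10(p_best) if p_best > 0 else math.inf
            rows.append((chrom, group[0], group[1], count, p_best, score, fold))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "count", "p_value", "score", "fold"]
    )


def _merge_window_groups(starts: np.ndarray, window: int, step: int):
    """Merge significant windows into regions when gapped <= step bp."""
    if starts.size == 0:
        return
    cur_start = int(starts[0])
    cur_end = cur_start + window
    for s in starts[1:].tolist():
        if s - cur_end <= step:
            cur_end = s + window
        else:
            yield (cur_start, cur_end)
            cur_start, cur_end = s, s + window
    yield (cur_start, cur_end)


def region_rpkm(regions: pd.DataFrame, reads: ReadTable) -> np.ndarray:
    """RPKM occupancy of each region in its own mark's read sample."""
    mids = _read_midpoints(reads)
    total = reads.total_mapped
    out = np.zeros(len(regions))
    for i, row in enumerate(regions.itertuples()):
        pos = mids.get(row.chrom, np.empty(0, np.int64))
        lo, hi = np.searchsorted(pos, (row.start, row.end))
        out[i] = rpkm(int(hi - lo), int(row.end - row.start), total) if total else 0.0
    return out


def build_crrs(
    k9ac_up: pd.DataFrame,
    k27me3_down: pd.DataFrame,
    k9ac_reads: ReadTable,
    k27me3_reads: ReadTable,
    rpkm_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Chromatin remodeling regions: filtered union of the two region sets.

    Regions with significant H3K9ac gain and regions with significant
    H3K27me3 loss are each filtered to occupancy > ``rpkm_cutoff`` of their
    own mark (measured in the mark's treatment sample), then unioned with
    interval merging.  Returns merged ``chrom, start, end, length``.
    """
    kept = []
    for regions, reads in ((k9ac_up, k9ac_reads), (k27me3_down, k27me3_reads)):
        if len(regions) == 0:
            continue
        occ = region_rpkm(regions, reads)
        kept.append(regions.loc[occ > rpkm_cutoff, ["chrom", "start", "end"]])
    if not kept:
        return pd.DataFrame(columns=["chrom", "start", "end", "length"])
    merged = merge_intervals(pd.concat(kept, ignore_index=True))
    merged["length"] = merged["end"] - merged["start"]
    return merged


def merge_intervals(regions: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent half-open intervals per chromosome."""
    rows = []
    for chrom, group in regions.groupby("chrom"):
        group = group.sort_values("start")
        cur_s = cur_e = None
        for row in group.itertuples():
            if cur_s is None:
                cur_s, cur_e = int(row.start), int(row.end)
            elif row.start <= cur_e:
                cur_e = max(cur_e, int(row.end))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(row.start), int(row.end)
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def genome_compartments(annotation: GeneAnnotation, genome: GenomeSpec) -> dict[str, pd.DataFrame]:
    """Partition the genome into promoter / genic / intergenic intervals.

    Promoters take precedence over gene bodies; intergenic is the rest.
    """
    promoters = merge_intervals(annotation.promoters()[["chrom", "start", "end"]])
    bodies = merge_intervals(annotation.gene_bodies()[["chrom", "start", "end"]])
    genic_rows, inter_rows = [], []
    for chrom, length in genome.chrom_lengths.items():
        prom = promoters[promoters["chrom"] == chrom]
        body = bodies[bodies["chrom"] == chrom]
        prom_iv = list(zip(prom["start"], prom["end"]))
        body_iv = list(zip(body["start"], body["end"]))
        genic = _subtract(body_iv, prom_iv)
        genic_rows += [(chrom, s, e) for s, e in genic]
        non_inter = sorted(prom_iv + genic)
        inter = _subtract([(0, length)], non_inter)
        inter_rows += [(chrom, s, e) for s, e in inter]
    return {
        "promoter": promoters,
        "genic": pd.DataFrame(genic_rows, columns=["chrom", "start", "end"]),
        "intergenic": pd.DataFrame(inter_rows, columns=["chrom", "start", "end"]),
    }


def _subtract(base: list[tuple[int, int]], minus: list[tuple[int, int]]):
    """Interval difference base \\ minus; both lists of half-open tuples."""
    out = []
    minus = sorted(minus)
    for s, e in sorted(base):
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, min(ms, e)))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def region_enrichment(
    regions: pd.DataFrame, annotation: GeneAnnotation, genome: GenomeSpec
) -> pd.DataFrame:
    """Region density per genomic compartment, normalised per Mb.

    Each region is assigned to promoter / genic / intergenic by its
    midpoint; the count is divided by the compartment's total length.
    """
    compartments = genome_compartments(annotation, genome)
    mid = ((regions["start"] + regions["end"]) // 2).to_numpy(np.int64)
    rows = []
    for name, ivs in compartments.items():
        total_len = int((ivs["end"] - ivs["start"]).sum())
        n = 0
        for chrom, group in ivs.groupby("chrom"):
            mask = (regions["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            inside = _in_any_interval(
                mid[mask],
                group["start"].to_numpy(np.int64),
                group["end"].to_numpy(np.int64),
            )
            n += int(inside.sum())
        per_mb = n / (total_len / 1e6) if total_len else 0.0
        rows.append((name, n, total_len, per_mb))
    return pd.DataFrame(rows, columns=["compartment", "n_regions", "length", "per_mb"])


def signal_fold_profile(
    centers: pd.DataFrame,
    reads_a: ReadTable,
    reads_b: ReadTable,
    flank: int = 2000,
    bin_size: int = 100,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-bin log2 fold change of depth-normalised signal around centers.

    ``centers``: DataFrame with ``chrom, pos``.  Signal per condition is
    the read-midpoint count per bin per million mapped reads summed over
    all centers; the profile is log2((B + pc) / (A + pc)).
    """
    if len(centers) == 0:
        raise ValueError("no centers given")
    n_bins = (2 * flank) // bin_size
    prof = {}
    for name, reads in (("a", reads_a), ("b", reads_b)):
        mids = _read_midpoints(reads)
        acc = np.zeros(n_bins)
        for row in centers.itertuples():
            pos = mids.get(row.chrom, np.empty(0, np.int64))
            lo, hi = np.searchsorted(pos, (row.pos - flank, row.pos + flank))
            off = pos[lo:hi] - (row.pos - flank)
            np.add.at(acc, np.minimum(off // bin_size, n_bins - 1), 1)
        scale = 1e6 / reads.total_mapped if reads.total_mapped else 0.0
        prof[name] = acc * scale
    offsets = -flank + bin_size * np.arange(n_bins) + bin_size / 2
    log2fc = np.log2((prof["b"] + pseudocount) / (prof["a"] + pseudocount))
    return pd.DataFrame(
        {"offset": offsets, "signal_a": prof["a"], "signal_b": prof["b"], "log2_fc": log2fc}
    )
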