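"""Two-condition synthetic chromatin datasets with machine-readable truth.

The generator lays out a genome of evenly pitched genes on alternating
strands, each with the canonical promoter nucleosome architecture: a -1
nucleosome upstream, a nucleosome depletion region (NDR) spanning -150..+50
bp of the TSS, and a phased +1/+2/... array at 180-bp spacing running into
the gene body; intergenic space carries phased arrays too.  A configurable
fraction of genes has the NDR *occupied* by a nucleosome in condition A and
depleted in condition B (NDR formation upon differentiation).

Reads are emitted the way the assays produce them:

* nucleosome (MNase-style) reads: per true dyad, a Poisson number of 49-bp
  single-end reads whose 5' end sits 73 bp outside a jittered dyad
  (jitter SD = the per-condition positional fuzziness), so the standard
  dyad shift recovers the jittered dyad exactly;
* histone-mark reads: same emission, restricted to promoter nucleosomes of
  genes carrying the mark in that condition (nucleosome-resolution ChIP);
* TF and control reads: a ~250-bp sheared-fragment model, reads taken from
  either fragment end;
* every sample gets a uniform background read rate.

Expression couples to the chromatin truth: occupied NDRs depress a gene's
expression level, and promoter H3K9ac gain / H3K27me3 loss raise the
expression change, plus Gaussian noise.

Each sample draws from its own RNG stream keyed by (master seed, sample
name), so adding a sample never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionTable,
    GeneAnnotation,
    GenomeSpec,
    ReadTable,
    write_bed,
    write_expression_tsv,
    write_genes_tsv,
)
from .chromstate import MARKS, state_name

READ_LENGTH = 49
FRAGMENT_LENGTH = 250
NDR_DYAD_OFFSET = -50     # dyad of the NDR-filling nucleosome, TSS-relative
UPSTREAM_DYADS = (-590, -410, -230)
FIRST_DOWNSTREAM = 130    # +1 nucleosome dyad


@dataclass
class MarkConfig:
    """Promoter presence/turnover model for one histone mark."""

    p_present_a: float = 0.5
    p_gain: float = 0.1    # absent in A -> present in B
    p_loss: float = 0.1    # present in A -> absent in B
    coverage: float = 20.0  # mean reads per marked promoter nucleosome


def default_mark_configs() -> dict[str, MarkConfig]:
    return {
        "H3K4me3": MarkConfig(p_present_a=0.6, p_gain=0.10, p_loss=0.10),
        "H3K9ac": MarkConfig(p_present_a=0.40, p_gain=0.20, p_loss=0.10),
        "H3K27me3": MarkConfig(p_present_a=0.40, p_gain=0.10, p_loss=0.20),
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset."""

    n_genes: int = 400
    gene_pitch: int = 6000       # bp between successive TSSs
    gene_length: int = 2000
    margin: int = 5000           # chromosome edge clearance
    spacing: int = 180           # dyad spacing of phased arrays
    fuzziness_sd: float = 10.0   # per-nucleosome dyad jitter, bp
    fuzziness_sd_b: float | None = None  # condition B override
    coverage: float = 30.0       # mean reads per nucleosome
    ndr_gene_fraction: float = 0.2
    shift_fraction: float = 0.05  # intergenic nucleosomes repositioned in B
    shift_bp: int = 30  # keeps 180-bp arrays sterically valid (>=147 bp apart)
    mark_configs: dict[str, MarkConfig] = field(default_factory=default_mark_configs)
    bg_rate: float = 0.002       # background reads per bp (nucleosome samples)
    mark_bg_rate: float = 0.0005
    n_tf_sites_a: int = 60
    n_tf_sites_b: int = 40
    n_tf_common: int = 10
    tf_site_coverage: float = 50.0
    tf_bg_rate: float = 0.0005
    control_rate: float = 0.002
    expression_coupling: float = 2.0   # log2 units per net activating mark change
    ndr_penalty: float = 1.5           # log2 expression drop when the NDR is occupied
    noise_sd: float = 0.7              # SD of the log2 expression change noise
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if not 0 <= self.ndr_gene_fraction <= 1:
            raise ValueError("ndr_gene_fraction must be in [0, 1]")
        for name, val in (
            ("coverage", self.coverage),
            ("bg_rate", self.bg_rate),
            ("mark_bg_rate", self.mark_bg_rate),
            ("tf_bg_rate", self.tf_bg_rate),
            ("control_rate", self.control_rate),
            ("fuzziness_sd", self.fuzziness_sd),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        arch_span = max(abs(UPSTREAM_DYADS[0]), self.gene_length) + 600
        if self.gene_pitch < 2 * arch_span // 2 + 700:
            raise ValueError("genes too dense for the promoter architecture")
        if self.margin < 700:
            raise ValueError("margin must leave room for read emission")

    @property
    def chrom_length(self) -> int:
        return 2 * self.margin + self.n_genes * self.gene_pitch

    def fuzziness(self, condition: str) -> float:
        if condition == "B" and self.fuzziness_sd_b is not None:
            return self.fuzziness_sd_b
        return self.fuzziness_sd


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    dyads: dict[str, dict[str, np.ndarray]]       # condition -> chrom -> positions
    ndr_genes: list[str]
    states: pd.DataFrame                          # gene_id, per-mark booleans, state_a/b
    tf_sites: dict[str, pd.DataFrame]             # condition -> chrom,pos
    expression: pd.DataFrame                      # gene_id, log2_fc, components


@dataclass
class SimResult:
    genome: GenomeSpec
    annotation: GeneAnnotation
    expression: ExpressionTable
    reads: dict[str, ReadTable]
    truth: GroundTruth
    config: SimConfig


def _rng(seed: int, sample: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(sample.encode()) & 0x7FFFFFFF])


def _gene_layout(cfg: SimConfig) -> GeneAnnotation:
    rows = []
    for i in range(cfg.n_genes):
        anchor = cfg.margin + i * cfg.gene_pitch + cfg.gene_pitch // 2
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss, tes = anchor, anchor + cfg.gene_length - 1
        else:
            tss, tes = anchor, anchor - cfg.gene_length + 1
        rows.append((f"gene{i:05d}", "chr1", strand, tss, tes))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])
    )


def _gene_rel_dyads(cfg: SimConfig) -> np.ndarray:
    downstream = np.arange(FIRST_DOWNSTREAM, cfg.gene_length, cfg.spacing)
    return np.concatenate([np.array(UPSTREAM_DYADS), downstream])


def _true_dyads(cfg: SimConfig, annotation: GeneAnnotation, rng: np.random.Generator):
    """Per-condition true dyad positions plus the NDR gene set."""
    rel = _gene_rel_dyads(cfg)
    n_ndr = int(round(cfg.ndr_gene_fraction * cfg.n_genes))
    ndr_idx = rng.choice(cfg.n_genes, size=n_ndr, replace=False)
    ndr_mask = np.zeros(cfg.n_genes, dtype=bool)
    ndr_mask[ndr_idx] = True

    gene_dyads = {}
    covered = []
    genes = annotation.genes
    for i, gene in enumerate(genes.itertuples()):
        sign = 1 if gene.strand == "+" else -1
        pos = gene.tss + sign * rel
        gene_dyads[i] = np.sort(pos)
        lo = gene.tss + sign * UPSTREAM_DYADS[0]
        hi = gene.tss + sign * (cfg.gene_length - 1)
        covered.append((min(lo, hi) - 90, max(lo, hi) + 90))

    # intergenic phased arrays in the gaps between gene architectures
    inter = []
    prev_end = 90
    for s, e in sorted(covered) + [(cfg.chrom_length - 90, cfg.chrom_length)]:
        gap_start, gap_end = prev_end, s
        if gap_end - gap_start >= cfg.spacing:
            inter.append(
                np.arange(
                    gap_start + cfg.spacing // 2,
                    gap_end - cfg.spacing // 2 + 1,
                    cfg.spacing,
                )
            )
        prev_end = max(prev_end, e)
    inter_dyads = np.concatenate(inter) if inter else np.empty(0, np.int64)
    shifted = rng.random(len(inter_dyads)) < cfg.shift_fraction

    dyads = {}
    for condition in ("A", "B"):
        parts = []
        for i in range(cfg.n_genes):
            d = gene_dyads[i]
            if ndr_mask[i] and condition == "A":
                gene = genes.iloc[i]
                sign = 1 if gene["strand"] == "+" else -1
                d = np.append(d, gene["tss"] + sign * NDR_DYAD_OFFSET)
            parts.append(d)
        inter_c = inter_dyads.copy()
        if condition == "B":
            inter_c[shifted] += cfg.shift_bp
        parts.append(inter_c)
        dyads[condition] = {"chr1": np.sort(np.concatenate(parts)).astype(np.int64)}
    ndr_genes = genes.loc[ndr_mask, "gene_id"].tolist()
    return dyads, ndr_genes


def _emit_dyad_reads(
    dyads: np.ndarray,
    coverage: float,
    fuzz_sd: float,
    chrom_length: int,
    rng: np.random.Generator,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Dyad-centred 49-bp single-end reads; the 73-bp shift recovers the dyad."""
    n_reads = rng.poisson(coverage, size=len(dyads))
    centers = np.repeat(dyads, n_reads).astype(np.int64)
    if fuzz_sd > 0:
        centers = centers + np.rint(rng.normal(0, fuzz_sd, size=len(centers))).astype(np.int64)
    centers = np.clip(centers, 80, chrom_length - 81)
    fwd = rng.random(len(centers)) < 0.5
    start = np.where(fwd, centers - 73, centers + 74 - READ_LENGTH)
    end = start + READ_LENGTH
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": np.where(fwd, "+", "-"),
        }
    )


def _emit_background(
    rate: float, chrom_length: int, rng: np.random.Generator, chrom: str = "chr1"
) -> pd.DataFrame:
    n = rng.poisson(rate * chrom_length)
    centers = rng.integers(80, chrom_length - 81, size=n)
    fwd = rng.random(n) < 0.5
    start = np.where(fwd, centers - 73, centers + 74 - READ_LENGTH)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + READ_LENGTH,
            "strand": np.where(fwd, "+", "-"),
        }
    )


def _emit_fragment_reads(
    centers: np.ndarray,
    reads_per_center,
    chrom_length: int,
    rng: np.random.Generator,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Sheared-fragment model: read from either end of a ~250-bp fragment."""
    n_reads = np.asarray(reads_per_center)
    pos = np.repeat(centers, n_reads).astype(np.int64)
    frag_start = pos - rng.integers(0, FRAGMENT_LENGTH, size=len(pos))
    fwd = rng.random(len(pos)) < 0.5
    start = np.where(fwd, frag_start, frag_start + FRAGMENT_LENGTH - READ_LENGTH)
    start = np.clip(start, 0, chrom_length - READ_LENGTH)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + READ_LENGTH,
            "strand": np.where(fwd, "+", "-"),
        }
    )


def _mark_states(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene mark presence in both conditions and the 8-class names."""
    n = cfg.n_genes
    data = {"gene_id": [f"gene{i:05d}" for i in range(n)]}
    for mark in MARKS:
        mc = cfg.mark_configs[mark]
        in_a = rng.random(n) < mc.p_present_a
        gain = rng.random(n) < mc.p_gain
        loss = rng.random(n) < mc.p_loss
        in_b = np.where(in_a, ~loss, gain)
        data[f"{mark}_a"] = in_a
        data[f"{mark}_b"] = in_b
    df = pd.DataFrame(data)
    for cond in ("a", "b"):
        df[f"state_{cond}"] = [
            state_name([m for m in MARKS if row[f"{m}_{cond}"]])
            for _, row in df.iterrows()
        ]
    return df


def _promoter_mark_dyads(
    cfg: SimConfig, annotation: GeneAnnotation, gene_mask: np.ndarray, ndr_occupied: np.ndarray
) -> np.ndarray:
    """True dyads inside the +-500 promoter of each selected gene."""
    rel = _gene_rel_dyads(cfg)
    rel_prom = rel[np.abs(rel) <= 500]
    parts = []
    for i, gene in enumerate(annotation.genes.itertuples()):
        if not gene_mask[i]:
            continue
        sign = 1 if gene.strand == "+" else -1
        d = gene.tss + sign * rel_prom
        if ndr_occupied[i]:
            d = np.append(d, gene.tss + sign * NDR_DYAD_OFFSET)
        parts.append(d)
    return np.sort(np.concatenate(parts)).astype(np.int64) if parts else np.empty(0, np.int64)


def _tf_sites(cfg: SimConfig, annotation: GeneAnnotation, rng: np.random.Generator):
    """Planted binding sites: specific per condition plus a shared set."""
    n_total = cfg.n_tf_sites_a + cfg.n_tf_sites_b + cfg.n_tf_common
    length = cfg.chrom_length
    # place sites on a jittered grid, keeping >= 1 kb apart
    grid = np.linspace(2000, length - 2000, n_total).astype(np.int64)
    jitter = rng.integers(-400, 401, size=n_total)
    pos = grid + jitter
    rng.shuffle(pos)
    a_only = pos[: cfg.n_tf_sites_a]
    b_only = pos[cfg.n_tf_sites_a : cfg.n_tf_sites_a + cfg.n_tf_sites_b]
    common = pos[cfg.n_tf_sites_a + cfg.n_tf_sites_b :]
    sites = {
        "A": pd.DataFrame({"chrom": "chr1", "pos": np.sort(np.concatenate([a_only, common]))}),
        "B": pd.DataFrame({"chrom": "chr1", "pos": np.sort(np.concatenate([b_only, common]))}),
    }
    return sites


def _expression(
    cfg: SimConfig,
    states: pd.DataFrame,
    ndr_genes: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = cfg.n_genes
    ndr_occ_a = states["gene_id"].isin(ndr_genes).to_numpy()
    base = rng.normal(5.0, 1.5, size=n)
    noise = rng.normal(0, cfg.noise_sd / np.sqrt(2), size=(2, n))
    k9a = states["H3K9ac_a"].to_numpy(float)
    k9b = states["H3K9ac_b"].to_numpy(float)
    k27a = states["H3K27me3_a"].to_numpy(float)
    k27b = states["H3K27me3_b"].to_numpy(float)
    log2_a = base - cfg.ndr_penalty * ndr_occ_a + cfg.expression_coupling * (k9a - k27a) + noise[0]
    log2_b = base + cfg.expression_coupling * (k9b - k27b) + noise[1]
    return pd.DataFrame(
        {
            "gene_id": states["gene_id"],
            "log2_expr_a": log2_a,
            "log2_expr_b": log2_b,
            "log2_fc": log2_b - log2_a,
        }
    )


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Generate the full two-condition dataset with ground truth."""
    cfg.validate()
    annotation = _gene_layout(cfg)
    genome = GenomeSpec({"chr1": cfg.chrom_length})
    dyads, ndr_genes = _true_dyads(cfg, annotation, _rng(cfg.seed, "layout"))
    states = _mark_states(cfg, _rng(cfg.seed, "states"))
    tf_sites = _tf_sites(cfg, annotation, _rng(cfg.seed, "tf_sites"))
    expr_truth = _expression(cfg, states, ndr_genes, _rng(cfg.seed, "expression"))

    reads: dict[str, ReadTable] = {}
    length = cfg.chrom_length
    for condition in ("A", "B"):
        sample = f"nuc_{condition}"
        rng = _rng(cfg.seed, sample)
        df = _emit_dyad_reads(
            dyads[condition]["chr1"], cfg.coverage, cfg.fuzziness(condition), length, rng
        )
        bg = _emit_background(cfg.bg_rate, length, rng)
        reads[sample] = ReadTable(pd.concat([df, bg], ignore_index=True))

    ndr_occupied_a = annotation.genes["gene_id"].isin(ndr_genes).to_numpy()
    no_ndr = np.zeros(cfg.n_genes, dtype=bool)
    for mark in MARKS:
        mc = cfg.mark_configs[mark]
        for condition in ("A", "B"):
            sample = f"{mark}_{condition}"
            rng = _rng(cfg.seed, sample)
            mask = states[f"{mark}_{condition.lower()}"].to_numpy()
            target = _promoter_mark_dyads(
                cfg, annotation, mask, ndr_occupied_a if condition == "A" else no_ndr
            )
            df = _emit_dyad_reads(
                target, mc.coverage, cfg.fuzziness(condition), length, rng
            )
            bg = _emit_background(cfg.mark_bg_rate, length, rng)
            reads[sample] = ReadTable(pd.concat([df, bg], ignore_index=True))

    for condition in ("A", "B"):
        sample = f"tf_{condition}"
        rng = _rng(cfg.seed, sample)
        sites = tf_sites[condition]["pos"].to_numpy(np.int64)
        n_per = rng.poisson(cfg.tf_site_coverage, size=len(sites))
        df = _emit_fragment_reads(sites, n_per, length, rng)
        n_bg = rng.poisson(cfg.tf_bg_rate * length)
        bg_centers = rng.integers(300, length - 300, size=n_bg)
        bg = _emit_fragment_reads(bg_centers, np.ones(n_bg, int), length, rng)
        reads[sample] = ReadTable(pd.concat([df, bg], ignore_index=True))

        sample = f"control_{condition}"
        rng = _rng(cfg.seed, sample)
        n_ctrl = rng.poisson(cfg.control_rate * length)
        centers = rng.integers(300, length - 300, size=n_ctrl)
        reads[sample] = ReadTable(
            _emit_fragment_reads(centers, np.ones(n_ctrl, int), length, rng)
        )

    # H2A.Z marks the eviction-prone promoter nucleosomes (-1, NDR, +1)
    rng = _rng(cfg.seed, "h2az_A")
    rel = np.array([UPSTREAM_DYADS[-1], FIRST_DOWNSTREAM])
    parts = []
    for i, gene in enumerate(annotation.genes.itertuples()):
        sign = 1 if gene.strand == "+" else -1
        d = gene.tss + sign * rel
        if ndr_occupied_a[i]:
            d = np.append(d, gene.tss + sign * NDR_DYAD_OFFSET)
        parts.append(d)
    h2az_dyads = np.sort(np.concatenate(parts)).astype(np.int64)
    df = _emit_dyad_reads(h2az_dyads, cfg.coverage, cfg.fuzziness("A"), length, rng)
    bg = _emit_background(cfg.mark_bg_rate, length, rng)
    reads["h2az_A"] = ReadTable(pd.concat([df, bg], ignore_index=True))

    expr_a = np.power(2.0, expr_truth["log2_expr_a"].to_numpy())
    expr_b = np.power(2.0, expr_truth["log2_expr_b"].to_numpy())
    log2_fc = expr_truth["log2_fc"].to_numpy()
    deg = np.where(log2_fc >= 1, "up", np.where(log2_fc <= -1, "down", "none"))
    expression = ExpressionTable(
        pd.DataFrame(
            {
                "gene_id": expr_truth["gene_id"],
                "expr_a": expr_a,
                "expr_b": expr_b,
                "log2_fc": log2_fc,
                "deg_label": deg,
            }
        )
    )

    truth = GroundTruth(
        dyads=dyads,
        ndr_genes=ndr_genes,
        states=states,
        tf_sites=tf_sites,
        expression=expr_truth,
    )
    return SimResult(genome, annotation, expression, reads, truth, cfg)


def simulate_hmi_experiment(
    n_genes: int = 300,
    coupling: float = 2.0,
    noise_sd: float = 0.7,
    enriched_rpkm: float = 30.0,
    background_rpkm: float = 1.0,
    occ_noise_sd: float = 0.4,
    mark_configs: dict[str, MarkConfig] | None = None,
    seed: int = 0,
):
    """Occupancy-level HMI experiment (no read emission).

    Draws per-gene promoter states, lognormal promoter occupancies for
    H3K9ac and H3K27me3 around state-dependent means, and expression
    changes coupled to the net activating mark change.  Returns
    ``(occ_k9ac, occ_k27me3, ExpressionTable, states)`` with the occupancy
    tables in the layout :func:`chromdyn.diffsig.compute_hmi` expects.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        expression_coupling=coupling,
        noise_sd=noise_sd,
        ndr_gene_fraction=0.0,
        seed=seed,
    )
    if mark_configs is not None:
        cfg.mark_configs = mark_configs
    states = _mark_states(cfg, _rng(seed, "hmi_states"))
    rng = _rng(seed, "hmi_occupancy")
    occ = {}
    for mark in ("H3K9ac", "H3K27me3"):
        tabs = {}
        for cond in ("a", "b"):
            mean = np.where(states[f"{mark}_{cond}"], enriched_rpkm, background_rpkm)
            tabs[cond] = mean * rng.lognormal(0.0, occ_noise_sd, size=n_genes)
        occ[mark] = pd.DataFrame(
            {
                "gene_id": states["gene_id"],
                "occupancy_a": tabs["a"],
                "occupancy_b": tabs["b"],
            }
        )
    expr_truth = _expression(cfg, states, [], _rng(seed, "hmi_expression"))
    log2_fc = expr_truth["log2_fc"].to_numpy()
    deg = np.where(log2_fc >= 1, "up", np.where(log2_fc <= -1, "down", "none"))
    expression = ExpressionTable(
        pd.DataFrame(
            {
                "gene_id": states["gene_id"],
                "expr_a": np.power(2.0, expr_truth["log2_expr_a"]),
                "expr_b": np.power(2.0, expr_truth["log2_expr_b"]),
                "log2_fc": log2_fc,
                "deg_label": deg,
            }
        )
    )
    return occ["H3K9ac"], occ["H3K27me3"], expression, states


def truth_report(result: SimResult, outdir) -> None:
    """Write every ground-truth component plus inputs to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    for sample, table in result.reads.items():
        write_bed(table, outdir / f"{sample}.bed")
    write_genes_tsv(result.annotation, outdir / "genes.tsv")
    write_expression_tsv(result.expression, outdir / "expression.tsv")
    for condition, per_chrom in result.truth.dyads.items():
        rows = []
        for chrom, pos in per_chrom.items():
            for p in pos.tolist():
                rows.append(f"{chrom}\t{p}\t{p + 1}\t.\t0\t+")
        (truth_dir / f"dyads_{condition}.bed").write_text(
            "\n".join(rows) + ("\n" if rows else "")
        )
    (truth_dir / "ndr_genes.txt").write_text(
        "\n".join(result.truth.ndr_genes) + ("\n" if result.truth.ndr_genes else "")
    )
    result.truth.states.to_csv(truth_dir / "promoter_states.tsv", sep="\t", index=False)
    for condition, sites in result.truth.tf_sites.items():
        rows = [
            f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t.\t0\t+" for r in sites.itertuples()
        ]
        (truth_dir / f"tf_sites_{condition}.bed").write_text(
            "\n".join(rows) + ("\n" if rows else "")
        )
    result.truth.expression.to_csv(truth_dir / "expression_truth.tsv", sep="\t", index=False)
    manifest = dataclasses.asdict(result.config)
    manifest["mark_configs"] = {
        m: dataclasses.asdict(c) for m, c in result.config.mark_configs.items()
    }
    manifest["genome"] = result.genome.chrom_lengths
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
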