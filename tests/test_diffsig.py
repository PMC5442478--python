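import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from chromdyn.core_io import ExpressionTable, GenomeSpec, ReadTable
from chromdyn.diffsig import (
    build_crrs,
    call_enriched_regions,
    compute_hmi,
    genome_compartments,
    hmi_expression_association,
    merge_intervals,
    poisson_sf,
    region_enrichment,
    roc_curve,
    signal_fold_profile,
)
from chromdyn.simulate import simulate_hmi_experiment
from oracles import poisson_upper_tail


def occ_table(values_a, values_b):
    n = len(values_a)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "occupancy_a": values_a,
            "occupancy_b": values_b,
        }
    )


def uniform_reads(rng, n, length, chrom="chr1"):
    start = rng.integers(0, length - 49, size=n)
    return ReadTable.from_arrays([chrom] * n, start, start + 49, ["+"] * n)


class TestComputeHmi:
    def test_arithmetic_and_stratum(self):
        # fc_k9ac = 4, fc_k27me3 = 1 -> HMI = 2, high stratum
        k9 = occ_table([100.0], [400.0])
        k27 = occ_table([100.0], [100.0])
        out = compute_hmi(k9, k27, pseudocount=1e-9)
        assert out["hmi"].iloc[0] == pytest.approx(2.0, abs=1e-6)
        assert out["stratum"].iloc[0] == "high"

    def test_equal_fold_changes_mid(self):
        k9 = occ_table([10.0], [20.0])
        k27 = occ_table([5.0], [10.0])
        out = compute_hmi(k9, k27)
        assert out["hmi"].iloc[0] == pytest.approx(0.0, abs=0.05)
        assert out["stratum"].iloc[0] == "mid"

    def test_boundary_inclusive(self):
        k9 = occ_table([1.5], [3.5])  # (3.5+.5)/(1.5+.5) = 2 -> hmi exactly 1
        k27 = occ_table([1.5], [1.5])
        out = compute_hmi(k9, k27)
        assert out["hmi"].iloc[0] == pytest.approx(1.0)
        assert out["stratum"].iloc[0] == "high"

    @given(
        occ=st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 100, allow_nan=False),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_antisymmetric_under_condition_swap(self, occ):
        a9, b9, a27, b27 = map(list, zip(*occ))
        fwd = compute_hmi(occ_table(a9, b9), occ_table(a27, b27))
        rev = compute_hmi(occ_table(b9, a9), occ_table(b27, a27))
        np.testing.assert_allclose(fwd["hmi"], -rev["hmi"], atol=1e-12)


class TestHmiExpressionAssociation:
    def mk_expr(self, log2_fc):
        n = len(log2_fc)
        return ExpressionTable(
            pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n)],
                    "expr_a": 1.0,
                    "expr_b": 1.0,
                    "log2_fc": log2_fc,
                    "deg_label": "none",
                }
            )
        )

    def test_coupled_simulation_orders_strata(self):
        occ9, occ27, expr, _ = simulate_hmi_experiment(n_genes=600, coupling=2.0, seed=3)
        hmi = compute_hmi(occ9, occ27)
        assoc = hmi_expression_association(hmi, expr).set_index("stratum")
        assert (
            assoc.loc["high", "median_log2_fc"]
            > assoc.loc["mid", "median_log2_fc"]
            > assoc.loc["low", "median_log2_fc"]
        )
        assert assoc.loc["high", "p_value"] < 0.05
        assert assoc.loc["low", "p_value"] < 0.05

    def test_degenerate_identical_changes_flagged(self):
        rng = np.random.default_rng(4)
        hmi = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(30)],
                "hmi": rng.normal(0, 2, 30),
                "stratum": ["high"] * 10 + ["mid"] * 10 + ["low"] * 10,
            }
        )
        assoc = hmi_expression_association(hmi, self.mk_expr([1.0] * 30))
        assert assoc["p_value"].isna().all()

    def test_empty_stratum_skipped(self):
        hmi = pd.DataFrame(
            {"gene_id": ["g0", "g1", "g2", "g3"], "hmi": [0.1, 0.0, -0.1, 0.2],
             "stratum": ["mid"] * 4}
        )
        assoc = hmi_expression_association(hmi, self.mk_expr([0.5, -0.5, 0.2, 0.1]))
        assert assoc.set_index("stratum").loc["high", "n"] == 0


class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert curve.auc == 1.0

    def test_constant_scores_diagonal(self):
        curve = roc_curve([1.0, 1.0, 1.0, 1.0], [True, False, True, False])
        assert curve.auc == 0.5
        assert curve.tpr.tolist() == [0.0, 1.0]

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        curve = roc_curve(scores, labels)
        assert curve.tpr[0] == 0.0 and curve.fpr[0] == 0.0
        assert curve.tpr[-1] == 1.0 and curve.fpr[-1] == 1.0
        assert (np.diff(curve.tpr) >= 0).all() and (np.diff(curve.fpr) >= 0).all()

    def test_matches_sklearn_auc(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(6)
        scores = np.round(rng.normal(size=500), 1)  # coarse grid -> many ties
        labels = rng.random(500) < 0.3
        curve = roc_curve(scores, labels)
        assert curve.auc == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
        )

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.random(300)
        labels = rng.random(300) < 0.5
        base = roc_curve(scores, labels).auc
        assert roc_curve(np.exp(5 * scores), labels).auc == pytest.approx(base)
        assert roc_curve(np.log(scores + 1e-9), labels).auc == pytest.approx(base)

    def test_binormal_auc_closed_form(self):
        rng = np.random.default_rng(8)
        n = 5000
        scores = np.concatenate([rng.normal(2, 1, n), rng.normal(0, 1, n)])
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        expected = stats.norm.cdf(2 / np.sqrt(2))
        assert roc_curve(scores, labels).auc == pytest.approx(expected, abs=0.02)

    def test_label_permutation_near_half(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=2000)
        labels = rng.permutation([True] * 1000 + [False] * 1000)
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.05)


class TestPoissonTail:
    def test_worked_example_exact_tail(self):
        # count 10, lambda 2: sum_{k>=10} e^-2 2^k / k!
        expected = poisson_upper_tail(10, 2.0)
        assert poisson_sf(10, 2.0) == pytest.approx(expected, abs=1e-12)

    def test_matches_summation_oracle_over_grid(self):
        rng = np.random.default_rng(10)
        for _ in range(300):
            k = int(rng.integers(1, 201))
            lam = float(rng.uniform(0.1, 150))
            assert poisson_sf(k, lam) == pytest.approx(
                poisson_upper_tail(k, lam), abs=1e-12
            )

    def test_zero_count_is_one(self):
        assert poisson_sf(0, 5.0) == 1.0


class TestCallEnrichedRegions:
    def test_treat_equals_control_no_regions(self):
        rng = np.random.default_rng(11)
        genome = GenomeSpec({"chr1": 200_000})
        reads = uniform_reads(rng, 5_000, 200_000)
        out = call_enriched_regions(reads, reads, genome, pcut=1e-5)
        assert len(out) == 0

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(12)
        genome = GenomeSpec({"chr1": 500_000})
        bg = uniform_reads(rng, 10_000, 500_000)
        extra_start = rng.integers(250_000, 252_000, size=400)
        extra = ReadTable.from_arrays(
            ["chr1"] * 400, extra_start, extra_start + 49, ["+"] * 400
        )
        treat = bg.concat(extra)
        control = uniform_reads(rng, 10_000, 500_000)
        out = call_enriched_regions(treat, control, genome, pcut=1e-5)
        assert len(out) >= 1
        assert ((out["start"] < 252_100) & (out["end"] > 250_000)).any()

    def test_empty_treatment_rejected(self):
        genome = GenomeSpec({"chr1": 1_000})
        with pytest.raises(ValueError):
            call_enriched_regions(ReadTable.empty(), ReadTable.empty(), genome)


class TestBuildCrrs:
    def regions(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def reads_in(self, start, end, n, total_extra=0):
        rng = np.random.default_rng(13)
        pos = rng.integers(start, end - 49, size=n)
        chroms, starts = ["chr1"] * n, list(pos)
        for i in range(total_extra):
            chroms.append("chr1")
            starts.append(900_000 + 200 * i)
        starts = np.asarray(starts)
        return ReadTable.from_arrays(chroms, starts, starts + 49, ["+"] * len(starts))

    def test_low_occupancy_region_dropped(self):
        k9_up = self.regions([("chr1", 1_000, 3_000)])
        # 1 read in 2 kb with a 625k-read library -> RPKM 0.8, under the cutoff
        k9_reads = self.reads_in(1_000, 3_000, 1, total_extra=624_999)
        crrs = build_crrs(k9_up, self.regions([]), k9_reads, ReadTable.empty())
        assert len(crrs) == 0

    def test_disjoint_surviving_sets_union(self):
        k9_up = self.regions([("chr1", i * 10_000, i * 10_000 + 2_000) for i in range(3)])
        k27_down = self.regions(
            [("chr1", 100_000 + i * 10_000, 102_000 + i * 10_000) for i in range(4)]
        )
        k9_reads = self.reads_in(0, 30_000, 3_000)
        k27_reads = self.reads_in(100_000, 140_000, 3_000)
        crrs = build_crrs(k9_up, k27_down, k9_reads, k27_reads)
        assert len(crrs) == 7

    def test_overlapping_regions_merged(self):
        shared = self.regions([("chr1", 1_000, 3_000)])
        overlapping = self.regions([("chr1", 2_000, 4_000)])
        reads = self.reads_in(1_000, 4_000, 1_000)
        crrs = build_crrs(shared, overlapping, reads, reads)
        assert len(crrs) == 1
        assert crrs.iloc[0]["start"] == 1_000 and crrs.iloc[0]["end"] == 4_000

    def test_union_idempotent(self):
        regions = self.regions([("chr1", 0, 1_000), ("chr1", 5_000, 6_000)])
        reads = self.reads_in(0, 6_000, 500)
        once = build_crrs(regions, self.regions([]), reads, ReadTable.empty())
        twice = build_crrs(
            once[["chrom", "start", "end"]], self.regions([]), reads, ReadTable.empty()
        )
        pd.testing.assert_frame_equal(once, twice)


class TestMergeIntervals:
    @given(
        ivs=st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 100)),
            min_size=0,
            max_size=20,
        )
    )
    def test_output_non_overlapping_and_covers_input(self, ivs):
        df = pd.DataFrame(
            [("chr1", s, s + w) for s, w in ivs], columns=["chrom", "start", "end"]
        )
        merged = merge_intervals(df)
        ends = merged["end"].to_numpy()
        starts = merged["start"].to_numpy()
        assert (starts[1:] > ends[:-1]).all()  # disjoint, sorted
        assert (merged["end"] - merged["start"]).sum() >= 0
        # every input point is covered
        for s, w in ivs:
            assert ((starts <= s) & (ends >= s + w)).any()


class TestRegionEnrichment:
    def test_compartments_partition_genome(self, two_gene_annotation, small_genome):
        comps = genome_compartments(two_gene_annotation, small_genome)
        total = sum(int((c["end"] - c["start"]).sum()) for c in comps.values())
        assert total == small_genome.total_length

    def test_all_regions_in_promoters(self, two_gene_annotation, small_genome):
        regions = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [9_800, 29_800], "end": [10_000, 30_000]}
        )
        enr = region_enrichment(regions, two_gene_annotation, small_genome).set_index(
            "compartment"
        )
        assert enr.loc["promoter", "n_regions"] == 2
        assert enr.loc["intergenic", "per_mb"] == 0.0

    def test_density_arithmetic(self, two_gene_annotation, small_genome):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [9_900], "end": [10_100]})
        enr = region_enrichment(regions, two_gene_annotation, small_genome).set_index(
            "compartment"
        )
        prom_len = enr.loc["promoter", "length"]
        assert enr.loc["promoter", "per_mb"] == pytest.approx(1 / (prom_len / 1e6))

    def test_uniform_regions_similar_density(self, two_gene_annotation, small_genome):
        rng = np.random.default_rng(14)
        start = rng.integers(0, 49_000, size=4_000)
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": start, "end": start + 10}
        )
        enr = region_enrichment(regions, two_gene_annotation, small_genome).set_index(
            "compartment"
        )
        # chr1 density ~ 4000/50kb; compare promoter vs genic vs intergenic on chr1
        chr1_len = 50_000
        densities = []
        for comp in ("promoter", "genic"):
            frac = enr.loc[comp, "length"]
            densities.append(enr.loc[comp, "n_regions"] / frac)
        ratio = densities[0] / densities[1]
        assert 0.7 < ratio < 1.4


class TestSignalFoldProfile:
    def test_identical_samples_zero_profile(self):
        rng = np.random.default_rng(15)
        reads = uniform_reads(rng, 2_000, 100_000)
        centers = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [20_000, 50_000, 80_000]})
        prof = signal_fold_profile(centers, reads, reads)
        assert np.allclose(prof["log2_fc"], 0.0)

    def test_planted_central_enrichment(self):
        rng = np.random.default_rng(16)
        length = 200_000
        centers_pos = np.array([50_000, 100_000, 150_000])
        base = uniform_reads(rng, 5_000, length)
        extra_pos = np.concatenate([rng.integers(c - 150, c + 150, 400) for c in centers_pos])
        extra = ReadTable.from_arrays(
            ["chr1"] * len(extra_pos), extra_pos, extra_pos + 49, ["+"] * len(extra_pos)
        )
        reads_b = base.concat(extra)
        centers = pd.DataFrame({"chrom": "chr1", "pos": centers_pos})
        prof = signal_fold_profile(centers, base, reads_b, flank=2_000, bin_size=100)
        central = prof.loc[np.abs(prof["offset"]) < 200, "log2_fc"].mean()
        flank_sig = prof.loc[np.abs(prof["offset"]) > 1_500, "log2_fc"].mean()
        assert central > 1.0
        assert abs(flank_sig) < 0.4

    def test_empty_centers_rejected(self):
        with pytest.raises(ValueError):
            signal_fold_profile(
                pd.DataFrame(columns=["chrom", "pos"]),
                ReadTable.empty(),
                ReadTable.empty(),
            )
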