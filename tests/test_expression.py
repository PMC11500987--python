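import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csslkit.expression import (
    EmptyGeneSetError,
    GeneOrigin,
    InsufficientReplicatesError,
    ZeroTotalSampleError,
    call_deg,
    call_deg_table,
    classify_gene_locus,
    classify_gene_origin,
    donor_haplotype_share_percent,
    expression_capacity,
    normalize_counts,
    proportion_with_donor_haplotype,
    size_factors,
)
from csslkit.formats_io import GeneModel, RunConfig, HOM_REF, HOM_ALT
from csslkit.ssd_core import SubstitutionSegment

from conftest import make_variant_table


def seg(chrom, start, end, line="L1"):
    return SubstitutionSegment(line, chrom, start, end, 0.95, 5, 0, 0)


class TestNormalizeCounts:
    def test_identical_samples_unchanged(self):
        raw = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]}, index=list("xyz"))
        out = normalize_counts(raw)
        pd.testing.assert_frame_equal(out, raw.astype(float))

    def test_double_depth_sample_rescaled(self):
        raw = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]}, index=list("xyz"))
        out = normalize_counts(raw)
        np.testing.assert_allclose(out["a"] / out["b"], 1.0)

    def test_matches_textbook_recomputation(self):
        """Independent median-of-ratios recomputation on a random matrix."""
        rng = np.random.default_rng(8)
        raw = pd.DataFrame(
            rng.poisson(50, size=(50, 4)) + 1,
            index=[f"g{i}" for i in range(50)],
            columns=list("abcd"),
        )
        factors = size_factors(raw)
        # textbook: per-sample median of count / geometric-mean-profile
        log_counts = np.log(raw.to_numpy())
        ref = log_counts.mean(axis=1)
        expected = np.exp(np.median(log_counts - ref[:, None], axis=0))
        np.testing.assert_allclose(factors.to_numpy(), expected, rtol=1e-12)

    def test_all_zero_gene_retained(self):
        raw = pd.DataFrame({"a": [10, 0, 5], "b": [12, 0, 6]}, index=list("xyz"))
        out = normalize_counts(raw)
        assert (out.loc["y"] == 0).all() and list(out.index) == list("xyz")

    def test_zero_total_sample_raises(self):
        raw = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ZeroTotalSampleError):
            normalize_counts(raw)


class TestGeneLocus:
    def test_inside_segment_is_cis(self):
        g = GeneModel("g1", "chr1", 150, 180)
        assert classify_gene_locus(g, [seg("chr1", 100, 200)]) == "cis"

    def test_one_bp_overlap_is_cis(self):
        g = GeneModel("g1", "chr1", 199, 250)
        assert classify_gene_locus(g, [seg("chr1", 100, 200)]) == "cis"

    def test_touching_boundary_is_trans(self):
        g = GeneModel("g1", "chr1", 200, 250)
        assert classify_gene_locus(g, [seg("chr1", 100, 200)]) == "trans"

    def test_other_chromosome_is_trans(self):
        g = GeneModel("g1", "chr2", 150, 180)
        assert classify_gene_locus(g, [seg("chr1", 100, 200)]) == "trans"

    def test_origin_categories(self):
        inside = GeneModel("g1", "chr1", 150, 180)
        outside = GeneModel("g2", "chr1", 900, 950)
        segments = [seg("chr1", 100, 200)]
        assert classify_gene_origin(inside, segments, {"g1": "GH_g1"}) is GeneOrigin.GB_ORTHOLOG
        assert classify_gene_origin(inside, segments, {}) is GeneOrigin.GB_NOVEL
        assert classify_gene_origin(outside, segments, {}) is GeneOrigin.GH_NATIVE


class TestCallDeg:
    def test_novel_gene_expression_rule_boundary(self):
        low = call_deg("g", GeneOrigin.GB_NOVEL, [0.5, 0.5, 0.5], [])
        at = call_deg("g", GeneOrigin.GB_NOVEL, [1.0, 1.0, 1.0], [])
        assert not low.is_deg and at.is_deg  # threshold is >= 1
        assert low.p_value is None and at.p_value is None

    def test_ortholog_fold_change_and_test(self):
        """means 63 vs 3 with pseudocount 1 -> log2(64/4) = 4 exactly; the
        p-value must equal the Welch statistic computed from first principles."""
        cssl = np.array([60.0, 63.0, 66.0])
        rec = np.array([2.0, 3.0, 4.0])
        call = call_deg("g", GeneOrigin.GB_ORTHOLOG, cssl, rec)
        assert call.log_fc == pytest.approx(4.0)
        a, b = np.log2(cssl + 1), np.log2(rec + 1)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p_hand = 2 * stats.t.sf(abs(t), df)
        assert call.p_value == pytest.approx(p_hand)
        assert call.is_deg == (abs(call.log_fc) >= 2 and p_hand < 0.05)

    def test_subthreshold_fold_change_not_deg(self):
        rec = np.array([3.0, 3.0, 3.0])
        cssl = np.full(3, (3 + 1) * 2**1.9 - 1)  # lfc exactly 1.9
        call = call_deg("g", GeneOrigin.GH_NATIVE, cssl, rec, locus_class="trans")
        assert call.log_fc == pytest.approx(1.9)
        assert not call.is_deg

    def test_identical_groups_null(self):
        x = np.array([5.0, 7.0, 6.0])
        call = call_deg("g", GeneOrigin.GH_NATIVE, x, x.copy(), locus_class="trans")
        assert call.log_fc == 0.0 and not call.is_deg

    def test_magnitude_change_flag(self):
        call = call_deg(
            "g", GeneOrigin.GB_ORTHOLOG,
            np.array([5000.0, 5100.0, 4900.0]), np.array([0.0, 0.0, 0.1]),
        )
        assert call.is_deg and call.magnitude_change  # |lfc| > 10

    def test_insufficient_replicates_raises(self):
        with pytest.raises(InsufficientReplicatesError):
            call_deg("g", GeneOrigin.GH_NATIVE, [1.0], [1.0, 2.0])

    def test_partition_and_branches(self):
        """Every gene is exactly cis or trans; branch A never has a p-value."""
        genes = [GeneModel(f"g{i}", "chr1", i * 100, i * 100 + 50) for i in range(1, 9)]
        segments = [seg("chr1", 100, 400)]
        rng = np.random.default_rng(0)
        nc = pd.DataFrame(
            rng.poisson(30, size=(8, 6)).astype(float),
            index=[g.gene_id for g in genes],
        )
        table = call_deg_table(
            nc.iloc[:, :3], nc.iloc[:, 3:], genes, segments,
            ortholog_map={"g1": "x", "g2": "x"},
        )
        assert set(table.locus_class) <= {"cis", "trans"}
        assert len(table) == len(genes)
        novel = table[table.origin == "GB_novel"]
        tested = table[table.origin != "GB_novel"]
        assert novel.p_value.isna().all()
        assert tested.p_value.notna().all()


class TestCapacity:
    def test_none_expressed(self):
        nc = pd.Series({"a": 0.0, "b": 0.0})
        assert expression_capacity(nc, ["a", "b"]) == 0.0

    def test_fraction(self):
        nc = pd.Series({"a": 5.0, "b": 2.0, "c": 1.5, "d": 0.5})
        assert expression_capacity(nc, list("abcd")) == 0.75

    def test_threshold_is_strict(self):
        nc = pd.Series({"a": 1.0})
        assert expression_capacity(nc, ["a"], threshold_nc=1.0) == 0.0

    def test_empty_set_raises(self):
        with pytest.raises(EmptyGeneSetError):
            expression_capacity(pd.Series(dtype=float), [])

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(4)
        nc = pd.Series(rng.exponential(2, size=100), index=[f"g{i}" for i in range(100)])
        genes = [f"g{i}" for i in range(0, 100, 3)]
        expected = sum(1 for g in genes if nc[g] > 1.0) / len(genes)
        assert expression_capacity(nc, genes) == pytest.approx(expected)


class TestDonorHaplotypeShare:
    def test_reported_population_share(self):
        assert round(donor_haplotype_share_percent(13_504_713, 19_444_373), 2) == 69.45

    def test_site_membership_matches_oracle(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(np.arange(1, 100_001), size=500, replace=False))
        gts = np.zeros((500, 1), dtype=np.int8)
        table = make_variant_table(pos, gts, ["S"])
        segs = {
            "L1": [seg("chr1", 10_000, 30_000, "L1")],
            "L2": [seg("chr1", 25_000, 40_000, "L2"), seg("chr1", 90_000, 95_000, "L2")],
        }
        got = proportion_with_donor_haplotype(table, segs)
        ivals = [(10_000, 30_000), (25_000, 40_000), (90_000, 95_000)]
        expected = sum(
            1 for p in pos if any(s <= p - 1 < e for s, e in ivals)
        ) / len(pos)
        assert got == pytest.approx(expected)

    def test_no_segments_zero(self):
        table = make_variant_table([100], np.zeros((1, 1), dtype=np.int8), ["S"])
        assert proportion_with_donor_haplotype(table, {}) == 0.0
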