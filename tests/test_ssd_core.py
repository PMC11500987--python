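import math

import numpy as np
import pytest

from csslkit.allele_model import AlleleClass, classify_line
from csslkit.formats_io import RunConfig
from csslkit.ssd_core import (
    EmptyPedigreeError,
    PedigreeMix,
    SubstitutionSegment,
    WindowStat,
    adjust_ambiguous,
    annotate_homology,
    call_segments,
    detect_line,
    expected_substitution_proportion,
    genome_coverage_union,
    observed_substitution_proportion,
    window_scan,
)

from conftest import make_track

R, D, A, M = (
    int(AlleleClass.RECURRENT_LSA),
    int(AlleleClass.DONOR_LSA),
    int(AlleleClass.AMBIGUOUS),
    int(AlleleClass.MISSING),
)


class TestWindowScan:
    def test_pure_donor_window(self):
        track = make_track(np.arange(1, 11) * 100, [D] * 10)
        ws = window_scan(track, 2000, 2000, 1, {"chr1": 2000})
        assert len(ws) == 1 and ws[0].lsp == 1.0 and ws[0].n_donor == 10

    def test_mixed_window_lsp(self):
        track = make_track(np.arange(1, 11) * 100, [D] * 6 + [R] * 4)
        ws = window_scan(track, 2000, 2000, 1, {"chr1": 2000})
        assert ws[0].lsp == pytest.approx(0.6)

    def test_uninformative_window(self):
        track = make_track([100, 200], [A, M])
        ws = window_scan(track, 1000, 1000, 1, {"chr1": 1000})
        assert not ws[0].informative and math.isnan(ws[0].lsp)

    def test_empty_track(self):
        track = make_track([], [])
        assert window_scan(track, 1000, 500, 1) == []

    def test_overlapping_windows_match_brute_force(self):
        """200-kb windows at 50-kb step over 1 Mb vs an independent recount."""
        rng = np.random.default_rng(11)
        pos = np.sort(rng.choice(np.arange(1, 1_000_001), size=400, replace=False))
        classes = rng.choice([R, D, A, M], size=400)
        track = make_track(pos, classes)
        ws = window_scan(track, 200_000, 50_000, 5, {"chr1": 1_000_000})

        for w in ws:
            in_w = (pos >= w.start + 1) & (pos <= w.end)
            assert w.n_donor == int(np.sum(classes[in_w] == D))
            assert w.n_recurrent == int(np.sum(classes[in_w] == R))
            assert w.n_ambiguous == int(np.sum(classes[in_w] == A))
            assert w.n_missing == int(np.sum(classes[in_w] == M))
        # every site is covered by window_size/step = 4 windows (interior)
        assert sum(w.n_donor + w.n_recurrent + w.n_ambiguous + w.n_missing for w in ws) >= 4 * 300


class TestAdjustAmbiguous:
    def mk(self, nr, nd, na, informative=False, lsp=float("nan")):
        return WindowStat("chr1", 0, 1000, nr, nd, na, 0, informative, lsp)

    def test_rescued_window(self):
        out = adjust_ambiguous([self.mk(1, 9, 24)], 0.5, 0.8)
        w = out[0]
        assert w.adjusted and w.informative and w.lsp == pytest.approx(0.9)

    def test_fails_donor_fraction(self):
        out = adjust_ambiguous([self.mk(5, 5, 24)], 0.5, 0.8)
        assert not out[0].adjusted and not out[0].informative

    def test_fails_ambiguous_fraction(self):
        out = adjust_ambiguous([self.mk(1, 9, 1)], 0.5, 0.8)
        assert not out[0].adjusted


class TestCallSegments:
    CFG = RunConfig(window_size_bp=2000, step_bp=1000, min_informative_per_window=3)

    def test_all_recurrent_no_segments(self):
        track = make_track(np.arange(1, 51) * 100, [R] * 50)
        ws = window_scan(track, 2000, 1000, 3, {"chr1": 5000})
        assert call_segments(ws, track, self.CFG) == []

    def test_single_planted_block(self):
        # donor markers at 2001..4000, recurrent elsewhere
        pos = np.arange(1, 101) * 100
        classes = np.where((pos > 2000) & (pos <= 4000), D, R)
        track = make_track(pos, classes)
        ws = window_scan(track, 2000, 1000, 3, {"chr1": 10_000})
        segs = call_segments(ws, track, self.CFG)
        assert len(segs) == 1
        s = segs[0]
        assert s.start == 2100 - 1 and s.end == 4000
        assert s.updated_substitution_proportion == 1.0

    def test_exact_threshold_is_rejected(self):
        # repeating DDDR pattern: marker-wise donor fraction exactly 0.75 < 0.80
        pos = np.arange(1, 81) * 100
        classes = np.array(([D, D, D, R] * 20)[:80])
        track = make_track(pos, classes)
        ws = window_scan(track, 2000, 1000, 3, {"chr1": 8000})
        assert call_segments(ws, track, self.CFG) == []

    def test_two_separated_blocks(self):
        pos = np.arange(1, 201) * 100
        classes = np.where(
            ((pos > 1000) & (pos <= 4000)) | ((pos > 14000) & (pos <= 18000)), D, R
        )
        track = make_track(pos, classes)
        ws = window_scan(track, 2000, 1000, 3, {"chr1": 20_000})
        segs = call_segments(ws, track, self.CFG)
        assert len(segs) == 2
        assert segs[0].end <= 4000 and segs[1].start >= 14000

    def test_homologous_tract_does_not_split_block(self):
        """A parent-identical (all ambiguous) tract inside a donor block."""
        pos = np.arange(1, 101) * 100
        classes = np.where((pos > 4000) & (pos <= 7000), A, D)
        track = make_track(pos, classes)
        ws = window_scan(track, 2000, 1000, 3, {"chr1": 10_000})
        ws = adjust_ambiguous(ws, 0.5, 0.8)
        segs = call_segments(ws, track, self.CFG)
        assert len(segs) == 1
        assert segs[0].start < 4000 and segs[0].end > 7000


class TestDetectOnSimulation:
    def test_planted_blocks_recovered(self, small_sim):
        cfg = RunConfig(window_size_bp=500_000)
        sim_cfg = small_sim.config
        for line_id in small_sim.line_ids:
            track = classify_line(
                small_sim.variants, line_id, sim_cfg.recurrent_id, sim_cfg.donor_id
            )
            segs = detect_line(track, cfg, sim_cfg.chrom_lengths)
            truth = small_sim.truth.donor_intervals[line_id]
            # every called segment overlaps a true donor interval
            for s in segs:
                assert any(
                    c == s.chrom and s.start < e and b < s.end for c, b, e in truth
                )
            # every large truth block is covered by calls
            for c, b, e in truth:
                if e - b < 5 * cfg.window_size_bp:
                    continue
                cov = sum(
                    min(s.end, e) - max(s.start, b)
                    for s in segs
                    if s.chrom == c and s.start < e and b < s.end
                )
                assert cov / (e - b) > 0.8

    def test_determinism(self, small_sim):
        cfg = RunConfig(window_size_bp=500_000)
        sim_cfg = small_sim.config
        line = small_sim.line_ids[0]
        t1 = classify_line(small_sim.variants, line, sim_cfg.recurrent_id, sim_cfg.donor_id)
        t2 = classify_line(small_sim.variants, line, sim_cfg.recurrent_id, sim_cfg.donor_id)
        s1 = detect_line(t1, cfg, sim_cfg.chrom_lengths)
        s2 = detect_line(t2, cfg, sim_cfg.chrom_lengths)
        assert [(s.chrom, s.start, s.end, s.updated_substitution_proportion) for s in s1] == [
            (s.chrom, s.start, s.end, s.updated_substitution_proportion) for s in s2
        ]

    def test_threshold_monotonicity(self, small_sim):
        """Raising the substitution threshold never yields more/longer calls."""
        sim_cfg = small_sim.config
        line = small_sim.line_ids[0]
        track = classify_line(small_sim.variants, line, sim_cfg.recurrent_id, sim_cfg.donor_id)
        prev_len = None
        for thr in (0.5, 0.7, 0.8, 0.9, 0.99):
            cfg = RunConfig(window_size_bp=500_000, lsp_threshold=thr)
            segs = detect_line(track, cfg, sim_cfg.chrom_lengths)
            total = sum(s.length_bp for s in segs)
            if prev_len is not None:
                assert total <= prev_len
            prev_len = total


class TestPedigreeExpectation:
    def test_reported_population_mix(self):
        mix = PedigreeMix([(52, 4), (47, 5)])
        value = expected_substitution_proportion(mix)
        assert math.trunc(value * 1000) / 1000 == 0.023

    @pytest.mark.parametrize("b,expected", [(0, 0.5), (1, 0.25), (4, 0.03125)])
    def test_single_group(self, b, expected):
        assert expected_substitution_proportion(PedigreeMix([(10, b)])) == expected

    def test_strictly_decreasing_in_backcross(self):
        values = [
            expected_substitution_proportion(PedigreeMix([(1, b)])) for b in range(8)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_empty_mix_raises(self):
        with pytest.raises(EmptyPedigreeError):
            PedigreeMix([])


class TestObservedProportion:
    def seg(self, chrom, start, end, line="L1"):
        return SubstitutionSegment(line, chrom, start, end, 0.95, 1, 0, 0)

    def test_reported_population_arithmetic(self):
        segs = [self.seg("chr1", 0, 6_620_380_000)]
        value = observed_substitution_proportion(segs, 99, 2_295_260_000)
        assert round(value, 3) == 0.029

    def test_no_segments(self):
        assert observed_substitution_proportion([], 10, 1000) == 0.0

    def test_whole_genome_single_line(self):
        segs = [self.seg("chr1", 0, 1000)]
        assert observed_substitution_proportion(segs, 4, 1000) == 0.25


class TestGenomeCoverageUnion:
    def seg(self, chrom, start, end, line="L1"):
        return SubstitutionSegment(line, chrom, start, end, 0.95, 1, 0, 0)

    def test_identical_segments_counted_once(self):
        segs = [self.seg("chr1", 0, 100, "L1"), self.seg("chr1", 0, 100, "L2")]
        assert genome_coverage_union(segs, 1000) == pytest.approx(0.1)

    def test_disjoint_additivity(self):
        segs = [self.seg("chr1", 0, 100), self.seg("chr1", 500, 650, "L2")]
        assert genome_coverage_union(segs, 1000) == pytest.approx(0.25)

    def test_matches_bitmask_oracle(self):
        rng = np.random.default_rng(3)
        G = 1_000_000
        segs = []
        mask = np.zeros(G, dtype=bool)
        for i in range(200):
            s = int(rng.integers(0, G - 1))
            e = int(rng.integers(s + 1, min(s + 20_000, G) + 1))
            segs.append(self.seg("chr1", s, e, f"L{i % 7}"))
            mask[s:e] = True
        assert genome_coverage_union(segs, G) == pytest.approx(mask.sum() / G)


class TestAnnotateHomology:
    def seg(self, start, end):
        return SubstitutionSegment("L1", "chr1", start, end, 0.9, 1, 0, 0)

    @pytest.mark.parametrize(
        "start,end,flagged",
        [(150, 180, True), (500, 600, False), (199, 300, True), (200, 300, False)],
    )
    def test_overlap_rule(self, start, end, flagged):
        out = annotate_homology([self.seg(start, end)], [("chr1", 100, 200)])
        assert out[0].homology_flagged is flagged
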