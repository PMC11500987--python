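"""The substitution-segment detector (SSD) and population statistics.

Three steps per line: (1) a sliding-window scan computes the local
substitution proportion (LSP) — the donor fraction of informative sites in
each window; (2) windows dominated by ambiguous sites are rescued when their
few informative sites are predominantly donor-origin, so that
parent-homologous tracts inside a true substitution do not split it; (3)
seed windows with LSP above the threshold are merged, boundaries refined to
the outermost donor-diagnostic markers, and the *updated substitution
proportion* recomputed marker-wise over the refined interval. A segment is
reported only if that marker-wise fraction strictly exceeds the threshold
(default 0.80).

Population-level summaries follow: expected donor proportion from the
backcross pedigree (halving per backcross), observed proportion from the
summed segment lengths, and the pooled genomic union coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .allele_model import AlleleClass, AlleleClassTrack
from .formats_io import CsslkitError, RunConfig, logger


class EmptyPedigreeError(CsslkitError):
    pass


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------


@dataclass
class WindowStat:
    """Counts and LSP for one window (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    n_recurrent: int
    n_donor: int
    n_ambiguous: int
    n_missing: int
    informative: bool
    lsp: float = float("nan")  # undefined iff informative is False
    adjusted: bool = False

    @property
    def n_informative(self) -> int:
        return self.n_recurrent + self.n_donor


def _count_in_windows(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    # site at 1-based pos p lies in [s, e) iff s + 1 <= p <= e
    lo = np.searchsorted(positions, starts + 1, side="left")
    hi = np.searchsorted(positions, ends, side="right")
    return hi - lo


def window_scan(
    track: AlleleClassTrack,
    window_size_bp: int,
    step_bp: int,
    min_informative: int,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Tile each chromosome with sliding windows and count classes per window.

    Windows start at 0 and advance by ``step_bp``; the last window is clipped
    to the chromosome end (``chrom_lengths`` if supplied, else the last
    genotyped position). LSP is defined only where the informative-site count
    reaches ``min_informative``.
    """
    if window_size_bp < step_bp or step_bp <= 0:
        raise ValueError("require window_size_bp >= step_bp > 0")
    if track.n_sites == 0:
        logger.warning("empty track for %s: no windows", track.line_id)
        return []

    out: list[WindowStat] = []
    for chrom in track.chromosomes():
        m = track.chrom == chrom
        pos = track.pos[m]
        cls = track.classes[m]
        chrom_end = int(chrom_lengths[chrom]) if chrom_lengths else int(pos[-1])
        starts = np.arange(0, chrom_end, step_bp, dtype=np.int64)
        ends = np.minimum(starts + window_size_bp, chrom_end)
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]

        counts = {
            k: _count_in_windows(pos[cls == k], starts, ends)
            for k in AlleleClass
        }
        for i in range(len(starts)):
            nr = int(counts[AlleleClass.RECURRENT_LSA][i])
            nd = int(counts[AlleleClass.DONOR_LSA][i])
            na = int(counts[AlleleClass.AMBIGUOUS][i])
            nm = int(counts[AlleleClass.MISSING][i])
            informative = (nr + nd) >= min_informative
            lsp = nd / (nd + nr) if informative else float("nan")
            out.append(WindowStat(chrom, int(starts[i]), int(ends[i]), nr, nd, na, nm, informative, lsp))
    return out


# ---------------------------------------------------------------------------
# ambiguous-region adjustment
# ---------------------------------------------------------------------------


def adjust_ambiguous(
    windows: list[WindowStat],
    ambiguous_frac_min: float = 0.5,
    donor_frac_min: float = 0.8,
) -> list[WindowStat]:
    """Rescue windows dominated by ambiguous sites.

    A window whose ambiguous fraction reaches ``ambiguous_frac_min`` and
    whose informative sites are at least ``donor_frac_min`` donor-origin is
    treated as donor-supporting: its LSP becomes the informative-site donor
    fraction and it counts as informative even below the usual floor, as
    long as it has at least one informative site. Other windows pass through
    unchanged.
    """
    out: list[WindowStat] = []
    for w in windows:
        total = w.n_recurrent + w.n_donor + w.n_ambiguous
        n_info = w.n_recurrent + w.n_donor
        if total > 0 and n_info > 0:
            amb_frac = w.n_ambiguous / total
            donor_frac = w.n_donor / n_info
            if amb_frac >= ambiguous_frac_min and donor_frac >= donor_frac_min:
                out.append(
                    WindowStat(
                        w.chrom, w.start, w.end, w.n_recurrent, w.n_donor,
                        w.n_ambiguous, w.n_missing, informative=True,
                        lsp=donor_frac, adjusted=True,
                    )
                )
                continue
        out.append(w)
    return out


# ---------------------------------------------------------------------------
# segment calling
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionSegment:
    """A called donor-origin interval (0-based half-open) for one line."""

    line_id: str
    chrom: str
    start: int
    end: int
    updated_substitution_proportion: float
    n_markers_donor: int
    n_markers_recurrent: int
    n_markers_ambiguous: int
    homology_flagged: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment must have positive length")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def _marker_counts(pos: np.ndarray, cls: np.ndarray, start: int, end: int) -> tuple[int, int, int]:
    lo = np.searchsorted(pos, start + 1, side="left")
    hi = np.searchsorted(pos, end, side="right")
    sub = cls[lo:hi]
    return (
        int(np.sum(sub == AlleleClass.DONOR_LSA)),
        int(np.sum(sub == AlleleClass.RECURRENT_LSA)),
        int(np.sum(sub == AlleleClass.AMBIGUOUS)),
    )


def call_segments(
    windows: list[WindowStat],
    track: AlleleClassTrack,
    config: RunConfig,
) -> list[SubstitutionSegment]:
    """Merge seed windows into candidate intervals and apply the 80% rule.

    Seeds are informative windows with LSP strictly above
    ``config.lsp_threshold``; seed runs separated by at most
    ``config.merge_gap_windows`` non-seed windows merge into one candidate.
    Windows dominated by ambiguous sites whose informative sites (if any)
    are donor-consistent carry no evidence against a substitution and are
    *neutral*: they do not count toward the merge gap, so a
    parent-homologous tract inside a donor block cannot split the segment.
    Candidate boundaries are trimmed to the outermost donor-diagnostic
    markers, the updated substitution proportion is recomputed marker-wise
    over the trimmed interval, and the segment is kept only if it strictly
    exceeds the threshold.
    """
    thr = config.lsp_threshold
    segments: list[SubstitutionSegment] = []
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)

    for chrom, wlist in by_chrom.items():
        wlist = sorted(wlist, key=lambda w: w.start)
        seed_idx = [
            i for i, w in enumerate(wlist)
            if w.informative and not math.isnan(w.lsp) and w.lsp > thr
        ]
        if not seed_idx:
            continue
        m = track.chrom == chrom
        pos = track.pos[m]
        cls = track.classes[m]

        def is_neutral(w: WindowStat) -> bool:
            total = w.n_recurrent + w.n_donor + w.n_ambiguous
            if total == 0:
                return False
            if w.n_ambiguous / total < config.ambiguous_frac_min:
                return False
            n_info = w.n_recurrent + w.n_donor
            return n_info == 0 or w.n_donor / n_info >= config.donor_frac_min

        # group seed indices; neutral windows do not count toward the gap
        runs: list[tuple[int, int]] = []
        run_start = seed_idx[0]
        prev = seed_idx[0]
        for i in seed_idx[1:]:
            gap = sum(1 for w in wlist[prev + 1 : i] if not is_neutral(w))
            if gap > config.merge_gap_windows:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))

        candidates: list[tuple[int, int]] = []
        for a, b in runs:
            cand_start, cand_end = wlist[a].start, wlist[b].end
            lo = np.searchsorted(pos, cand_start + 1, side="left")
            hi = np.searchsorted(pos, cand_end, side="right")
            donor_pos = pos[lo:hi][cls[lo:hi] == AlleleClass.DONOR_LSA]
            if len(donor_pos) == 0:
                continue
            candidates.append((int(donor_pos[0]) - 1, int(donor_pos[-1])))

        # overlapping windows can yield touching refined candidates: merge
        merged: list[list[int]] = []
        for s, e in sorted(candidates):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])

        for s, e in merged:
            nd, nr, na = _marker_counts(pos, cls, s, e)
            if nd + nr == 0:
                continue
            usp = nd / (nd + nr)
            if usp > thr:
                segments.append(
                    SubstitutionSegment(track.line_id, chrom, s, e, usp, nd, nr, na)
                )

    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def detect_line(
    track: AlleleClassTrack,
    config: RunConfig,
    chrom_lengths: dict[str, int] | None = None,
) -> list[SubstitutionSegment]:
    """Full SSD per line: window scan -> ambiguity adjustment -> calling."""
    windows = window_scan(
        track, config.window_size_bp, config.step_bp,
        config.min_informative_per_window, chrom_lengths,
    )
    windows = adjust_ambiguous(windows, config.ambiguous_frac_min, config.donor_frac_min)
    return call_segments(windows, track, config)


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------


@dataclass
class PedigreeMix:
    """Counts of lines per backcross depth, e.g. [(52, 4), (47, 5)]."""

    groups: list[tuple[int, int]]  # (n_lines, n_backcross)

    def __post_init__(self) -> None:
        if not self.groups:
            raise EmptyPedigreeError("pedigree mix has no groups")
        for n, b in self.groups:
            if n <= 0 or b < 0:
                raise ValueError(f"invalid pedigree group ({n}, {b})")

    @property
    def total_lines(self) -> int:
        return sum(n for n, _ in self.groups)


def expected_substitution_proportion(mix: PedigreeMix) -> float:
    """Expected donor genome fraction of a backcross-derived line mixture.

    The donor contribution halves with every backcross: a line selfed from
    BC_b carries 0.5**(b+1) of the donor genome in expectation; selfing does
    not change the expectation.
    """
    total = mix.total_lines
    return sum(n / total * 0.5 ** (b + 1) for n, b in mix.groups)


def observed_substitution_proportion(
    segments: list[SubstitutionSegment], n_lines: int, genome_size_bp: float
) -> float:
    """Mean per-line donor fraction: summed segment length / lines / genome."""
    if n_lines <= 0:
        raise ValueError("n_lines must be > 0")
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be > 0")
    return sum(s.length_bp for s in segments) / n_lines / genome_size_bp


def merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union of half-open intervals, merged per chromosome."""
    out: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for c in sorted(by_chrom):
        cur_s = cur_e = None
        for s, e in sorted(by_chrom[c]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((c, cur_s, cur_e))
    return out


def genome_coverage_union(
    segments: list[SubstitutionSegment], genome_size_bp: float
) -> float:
    """Fraction of the genome covered by the pooled segment union."""
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be > 0")
    merged = merge_intervals([(s.chrom, s.start, s.end) for s in segments])
    return sum(e - s for _, s, e in merged) / genome_size_bp


def annotate_homology(
    segments: list[SubstitutionSegment],
    mask: list[tuple[str, int, int]],
) -> list[SubstitutionSegment]:
    """Flag segments overlapping a parent-homologous interval mask by >= 1 bp."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for c, s, e in mask:
        trees.setdefault(c, IntervalTree()).addi(s, e)
    out = []
    for seg in segments:
        flagged = bool(trees.get(seg.chrom) and trees[seg.chrom].overlap(seg.start, seg.end))
        out.append(
            SubstitutionSegment(
                seg.line_id, seg.chrom, seg.start, seg.end,
                seg.updated_substitution_proportion, seg.n_markers_donor,
                seg.n_markers_recurrent, seg.n_markers_ambiguous,
                homology_flagged=flagged,
            )
        )
    return out
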