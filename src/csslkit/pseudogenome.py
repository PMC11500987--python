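"""Per-line pseudo-genome construction.

Each CSSL gets an individualized reference: the recurrent-parent genome with
every detected substitution segment replaced by the donor consensus — the
segment's sequence with all donor-allele variants (SNPs and explicit-sequence
indels) applied. Outside the segments the output is byte-identical to the
input reference. A liftover table records the piecewise coordinate shift so
gene models can be remapped onto the new sequence.

Donor alleles are taken directly from the joint parent VCF rather than from
a donor whole-genome assembly; with fully genotyped inbred parents the two
are equivalent, and the VCF route is self-contained.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .formats_io import (
    HOM_ALT,
    CsslkitError,
    GenomeSequence,
    VariantTable,
    logger,
)
from .ssd_core import SubstitutionSegment


class OverlappingVariantError(CsslkitError):
    pass


class ReferenceMismatchError(CsslkitError):
    pass


class SymbolicAltError(CsslkitError):
    pass


class SegmentOutOfBoundsError(CsslkitError):
    pass


@dataclass
class Replacement:
    """One applied segment: recurrent interval, new sequence, indel shift."""

    chrom: str
    start: int
    end: int
    sequence: str
    n_variants: int

    @property
    def net_shift(self) -> int:
        return len(self.sequence) - (self.end - self.start)


@dataclass
class PseudoGenomeSpec:
    """Plan/record of segment replacements for one line."""

    line_id: str
    replacements: list[Replacement] = field(default_factory=list)

    def net_shift(self, chrom: str) -> int:
        return sum(r.net_shift for r in self.replacements if r.chrom == chrom)


@dataclass
class LiftoverTable:
    """Piecewise map between recurrent and pseudo-genome coordinates.

    Stored as sorted breakpoints per chromosome: at old coordinate >=
    ``old_breaks[i]`` the cumulative shift is ``shifts[i]``. Positions whose
    exact image is removed by a deletion map to the deletion point.
    """

    old_breaks: dict[str, list[int]] = field(default_factory=dict)
    shifts: dict[str, list[int]] = field(default_factory=dict)

    def _ensure(self, chrom: str) -> None:
        if chrom not in self.old_breaks:
            self.old_breaks[chrom] = [0]
            self.shifts[chrom] = [0]

    def add_shift(self, chrom: str, old_pos: int, delta: int) -> None:
        """Record that old coordinates >= old_pos shift by an extra delta."""
        self._ensure(chrom)
        self.old_breaks[chrom].append(old_pos)
        self.shifts[chrom].append(self.shifts[chrom][-1] + delta)

    def old_to_new(self, chrom: str, pos: int) -> int:
        self._ensure(chrom)
        i = bisect.bisect_right(self.old_breaks[chrom], pos) - 1
        return pos + self.shifts[chrom][i]

    def new_to_old(self, chrom: str, pos: int) -> int:
        self._ensure(chrom)
        breaks, shifts = self.old_breaks[chrom], self.shifts[chrom]
        # invert the monotone piecewise map
        for i in range(len(breaks) - 1, -1, -1):
            if breaks[i] + shifts[i] <= pos:
                return pos - shifts[i]
        return pos - shifts[0]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\told_pos\tcumulative_shift\n")
            for chrom in self.old_breaks:
                for b, s in zip(self.old_breaks[chrom], self.shifts[chrom]):
                    fh.write(f"{chrom}\t{b}\t{s}\n")


def donor_variant_records(
    variants: VariantTable, donor_id: str, chrom: str, start: int, end: int
) -> list[tuple[int, str, str]]:
    """Extract (0-based offset-in-genome pos, ref, alt) for sites where the
    donor is homozygous ALT, inside the half-open interval."""
    gt = variants.sample_gt(donor_id)
    m = (variants.chrom == chrom) & (gt == HOM_ALT)
    pos0 = variants.pos[m] - 1
    keep = (pos0 >= start) & (pos0 + np.array([len(r) for r in variants.ref[m]]) <= end)
    return [
        (int(p), str(r), str(a))
        for p, r, a in zip(pos0[keep], variants.ref[m][keep], variants.alt[m][keep])
    ]


def consensus_sequence(
    sequence: str,
    variant_records: list[tuple[int, str, str]],
    interval: tuple[int, int],
    chrom: str = "?",
    liftover: LiftoverTable | None = None,
) -> str:
    """Apply donor-allele variants to one interval of a reference sequence.

    ``variant_records`` are (0-based position in genome coordinates, REF,
    ALT). Variants are applied in ascending order with cumulative offset
    tracking; REF spans must not overlap and must match the reference.
    Symbolic ALT alleles (``<DEL>`` etc.) are rejected.
    """
    start, end = interval
    recs = sorted(variant_records)
    pieces: list[str] = []
    cursor = start
    for pos, ref, alt in recs:
        if alt.startswith("<") or "[" in alt or "]" in alt:
            raise SymbolicAltError(f"symbolic ALT {alt!r} at {chrom}:{pos + 1}")
        if pos < cursor:
            raise OverlappingVariantError(
                f"variant REF spans overlap at {chrom}:{pos + 1}"
            )
        if pos + len(ref) > end:
            raise OverlappingVariantError(
                f"variant at {chrom}:{pos + 1} extends past interval end"
            )
        if sequence[pos : pos + len(ref)] != ref:
            raise ReferenceMismatchError(
                f"REF mismatch at {chrom}:{pos + 1}: expected {ref!r}, "
                f"reference has {sequence[pos:pos + len(ref)]!r}"
            )
        pieces.append(sequence[cursor:pos])
        pieces.append(alt)
        cursor = pos + len(ref)
        if liftover is not None and len(alt) != len(ref):
            liftover.add_shift(chrom, cursor, len(alt) - len(ref))
    pieces.append(sequence[cursor:end])
    return "".join(pieces)


def build_pseudogenome(
    reference: dict[str, GenomeSequence],
    variants: VariantTable,
    donor_id: str,
    segments: list[SubstitutionSegment],
) -> tuple[dict[str, GenomeSequence], PseudoGenomeSpec, LiftoverTable]:
    """Substitute donor consensus into the recurrent genome over segments.

    Returns the pseudo-genome, the replacement plan, and an old->new
    coordinate liftover for gene-model remapping. The output is
    byte-identical to the reference outside the segments.
    """
    if not segments:
        line_id = "?"
    else:
        line_id = segments[0].line_id
    spec = PseudoGenomeSpec(line_id)
    lift = LiftoverTable()
    by_chrom: dict[str, list[SubstitutionSegment]] = {}
    for s in segments:
        if s.chrom not in reference:
            raise SegmentOutOfBoundsError(f"unknown chromosome {s.chrom}")
        if s.end > reference[s.chrom].length:
            raise SegmentOutOfBoundsError(
                f"segment {s.chrom}:{s.start}-{s.end} beyond chromosome end "
                f"({reference[s.chrom].length})"
            )
        by_chrom.setdefault(s.chrom, []).append(s)

    out: dict[str, GenomeSequence] = {}
    for chrom, ref_seq in reference.items():
        segs = sorted(by_chrom.get(chrom, []), key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise OverlappingVariantError(
                    f"segments overlap on {chrom}: {a.start}-{a.end} / {b.start}-{b.end}"
                )
        if not segs:
            out[chrom] = GenomeSequence(chrom, ref_seq.sequence)
            continue
        pieces: list[str] = []
        cursor = 0
        for s in segs:
            pieces.append(ref_seq.sequence[cursor : s.start])
            recs = donor_variant_records(variants, donor_id, chrom, s.start, s.end)
            cons = consensus_sequence(
                ref_seq.sequence, recs, (s.start, s.end), chrom, liftover=lift
            )
            pieces.append(cons)
            spec.replacements.append(
                Replacement(chrom, s.start, s.end, cons, len(recs))
            )
            cursor = s.end
        pieces.append(ref_seq.sequence[cursor:])
        out[chrom] = GenomeSequence(chrom, "".join(pieces))
        logger.info(
            "%s %s: %d segment(s) replaced, net length shift %+d bp",
            line_id, chrom, len(segs), spec.net_shift(chrom),
        )
    return out, spec, lift


def lift_gene_interval(
    lift: LiftoverTable, chrom: str, start: int, end: int
) -> tuple[int, int]:
    """Map a gene interval from recurrent to pseudo-genome coordinates."""
    return lift.old_to_new(chrom, start), lift.old_to_new(chrom, end)
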