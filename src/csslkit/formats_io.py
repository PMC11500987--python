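"""Readers/writers for the standard formats the toolkit touches, plus run
configuration and small reporting helpers.

Coordinate conventions
----------------------
* VCF input is 1-based; :class:`VariantTable` keeps VCF positions as loaded.
* All interval arithmetic inside the toolkit is 0-based half-open.
* BED output is 0-based half-open.

A marker at 1-based position ``p`` with reference allele of length ``L``
occupies the half-open interval ``[p - 1, p - 1 + L)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger("csslkit")

# ---------------------------------------------------------------------------
# genotype encoding
# ---------------------------------------------------------------------------

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GT_NAMES = {HOM_REF: "hom-ref", HET: "het", HOM_ALT: "hom-alt", MISSING: "missing"}


class CsslkitError(Exception):
    """Base class for all named errors raised by the toolkit."""


class MissingSampleError(CsslkitError):
    pass


class UnsortedVariantsError(CsslkitError):
    pass


class OverlappingSegmentsError(CsslkitError):
    pass


class InvalidBaselineError(CsslkitError):
    pass


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All tunable thresholds of the segment-detection and expression stages.

    The substitution rule is strict: a candidate interval is reported only if
    its marker-wise donor fraction *exceeds* ``lsp_threshold`` (default 0.80).
    """

    window_size_bp: int = 200_000
    step_bp: int = 50_000
    min_informative_per_window: int = 10
    lsp_threshold: float = 0.80
    ambiguous_frac_min: float = 0.5
    donor_frac_min: float = 0.8
    merge_gap_windows: int = 2
    het_policy: str = "ambiguous"  # or "donor_evidence"
    multiallelic: str = "drop"  # or "split"
    # expression thresholds
    pseudocount: float = 1.0
    lfc_min: float = 2.0
    p_max: float = 0.05
    novel_expressed_min_nc: float = 1.0  # mean NC >= 1 calls a novel gene expressed
    capacity_threshold_nc: float = 1.0  # capacity counts genes with NC > 1
    magnitude_lfc: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.window_size_bp >= self.step_bp > 0):
            raise ValueError("require window_size_bp >= step_bp > 0")
        for name in ("lsp_threshold", "ambiguous_frac_min", "donor_frac_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.het_policy not in ("ambiguous", "donor_evidence"):
            raise ValueError(f"unknown het_policy {self.het_policy!r}")
        if self.multiallelic not in ("drop", "split"):
            raise ValueError(f"unknown multiallelic policy {self.multiallelic!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def updated(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Biallelic variant sites for a set of samples.

    ``pos`` is 1-based as in VCF; ``gt`` is an ``(n_sites, n_samples)`` int8
    matrix in the {HOM_REF, HET, HOM_ALT, MISSING} encoding. Positions are
    strictly increasing within each chromosome.
    """

    chrom: np.ndarray  # dtype object/str
    pos: np.ndarray  # int64, 1-based
    ref: np.ndarray  # dtype object
    alt: np.ndarray  # dtype object
    gt: np.ndarray  # int8 (n_sites, n_samples)
    samples: list[str]

    def __post_init__(self) -> None:
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == n):
            raise ValueError("column length mismatch")
        if self.gt.shape != (n, len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        self._check_sorted()
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    def _check_sorted(self) -> None:
        # non-decreasing per chromosome; ties allowed only for distinct
        # alleles (split multiallelic records share a position)
        for c in dict.fromkeys(self.chrom):
            m = self.chrom == c
            p = self.pos[m]
            if len(p) > 1 and not np.all(np.diff(p) >= 0):
                raise UnsortedVariantsError(f"positions not sorted on {c}")
            keys = list(zip(p, self.ref[m], self.alt[m]))
            if len(set(keys)) != len(keys):
                raise UnsortedVariantsError(f"duplicate variant records on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_gt(self, sample: str) -> np.ndarray:
        if sample not in self._sample_index:
            raise MissingSampleError(f"sample {sample!r} not in table")
        return self.gt[:, self._sample_index[sample]]

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chrom))

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom == chrom

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.chrom[mask], self.pos[mask], self.ref[mask], self.alt[mask],
            self.gt[mask], list(self.samples),
        )


@dataclass
class GenomeSequence:
    """A named chromosome sequence."""

    chrom: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"chromosome {self.chrom} has zero length")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: require start < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

# cyvcf2 gt_types with gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
_GT_FROM_CYVCF2 = {0: HOM_REF, 1: HET, 2: HOM_ALT, 3: MISSING}


def read_variants(
    path: str | Path,
    samples: Sequence[str] | None = None,
    multiallelic: str = "drop",
) -> VariantTable:
    """Load biallelic SNP/indel sites from a VCF (optionally gzipped).

    Multiallelic sites are dropped (default) or split into per-ALT biallelic
    records in which any genotype carrying a different ALT is set missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    available = list(vcf.samples)
    if samples is None:
        samples = available
    missing = [s for s in samples if s not in available]
    if missing:
        raise MissingSampleError(f"samples not in VCF: {missing}")
    idx = np.array([available.index(s) for s in samples])

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gts: list[np.ndarray] = []
    n_multi_dropped = 0
    n_multi_split = 0

    for v in vcf:
        if len(v.ALT) == 0:
            continue
        if len(v.ALT) == 1:
            chroms.append(v.CHROM)
            poss.append(v.POS)
            refs.append(v.REF)
            alts.append(v.ALT[0])
            g = np.array([_GT_FROM_CYVCF2[t] for t in v.gt_types], dtype=np.int8)
            gts.append(g[idx])
        elif multiallelic == "drop":
            n_multi_dropped += 1
        else:  # split
            n_multi_split += 1
            # genotypes per allele: recode against each ALT separately
            raw = v.genotype.array()[:, :2]  # allele indices, -1 missing
            for ai, alt in enumerate(v.ALT, start=1):
                g = np.full(len(available), MISSING, dtype=np.int8)
                valid = (raw >= 0).all(axis=1)
                n_alt = (raw == ai).sum(axis=1)
                other = ((raw != 0) & (raw != ai)).any(axis=1)
                g[valid & (n_alt == 0) & ~other] = HOM_REF
                g[valid & (n_alt == 1) & ~other] = HET
                g[valid & (n_alt == 2)] = HOM_ALT
                chroms.append(v.CHROM)
                poss.append(v.POS)
                refs.append(v.REF)
                alts.append(alt)
                gts.append(g[idx])
    vcf.close()

    if not poss:
        logger.warning("VCF %s contained no usable biallelic sites", path)
        table = VariantTable(
            np.array([], dtype=object), np.array([], dtype=np.int64),
            np.array([], dtype=object), np.array([], dtype=object),
            np.zeros((0, len(samples)), dtype=np.int8), list(samples),
        )
        return table

    chrom_arr = np.array(chroms, dtype=object)
    pos_arr = np.array(poss, dtype=np.int64)
    # split records for one site share a position: keep first occurrence order,
    # but strict sortedness must hold per chromosome
    table = VariantTable(
        chrom_arr, pos_arr, np.array(refs, dtype=object),
        np.array(alts, dtype=object), np.vstack(gts), list(samples),
    )
    logger.info(
        "loaded %d sites x %d samples from %s (multiallelic: %d dropped, %d split)",
        table.n_sites, len(samples), path, n_multi_dropped, n_multi_split,
    )
    return table


def write_variants_vcf(table: VariantTable, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """Emit a minimal sorted VCF 4.2 text file for a VariantTable."""
    gt_strings = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            gts = "\t".join(gt_strings[int(g)] for g in table.gt[i])
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------


def read_genome_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: GenomeSequence(name, str(fa[name][:])) for name in fa.keys()}


def write_genome_fasta(genome: dict[str, GenomeSequence], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for seq in genome.values():
            fh.write(f">{seq.chrom}\n")
            s = seq.sequence
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_gene_models(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Load gene features from a GFF3 file (1-based inclusive -> half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for f in db.features_of_type(feature):
        genes.append(
            GeneModel(f.id, f.seqid, f.start - 1, f.end,
                      f.strand if f.strand in "+-" else "+")
        )
    return genes


def write_gene_models_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tcsslkit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_segments_bed(segments: Sequence, path: str | Path) -> None:
    """Write substitution segments as BED6 (0-based half-open).

    name = line id, score = round(1000 x updated substitution proportion).
    Records are sorted by (chrom, start, line). Overlapping segments for the
    same line violate the upstream merge contract and raise.
    """
    by_line: dict[str, list] = {}
    for s in segments:
        by_line.setdefault(s.line_id, []).append(s)
    for line_id, segs in by_line.items():
        segs = sorted(segs, key=lambda s: (s.chrom, s.start))
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise OverlappingSegmentsError(
                    f"line {line_id}: segments overlap at {a.chrom}:{b.start}"
                )
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start, s.line_id))
    with open(path, "w") as fh:
        for s in ordered:
            score = int(round(1000 * s.updated_substitution_proportion))
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.line_id}\t{score}\t.\n")


def read_intervals_bed(path: str | Path) -> list[tuple[str, int, int, str, float]]:
    """Read a BED file; returns (chrom, start, end, name, score/1000) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.rstrip("\n").split("\t")
            name = p[3] if len(p) > 3 else "."
            score = float(p[4]) / 1000 if len(p) > 4 and p[4] != "." else float("nan")
            out.append((p[0], int(p[1]), int(p[2]), name, score))
    return out


# ---------------------------------------------------------------------------
# small reporting utilities
# ---------------------------------------------------------------------------


def percent_change(value: float, baseline: float) -> float:
    """Signed percentage change of ``value`` relative to ``baseline``."""
    if baseline <= 0:
        raise InvalidBaselineError(f"baseline must be > 0, got {baseline}")
    return 100.0 * (value - baseline) / baseline
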