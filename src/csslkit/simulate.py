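"""Forward simulator for CSSL populations with known truth.

Emulates the breeding design behind a chromosome segment substitution line
panel: two inbred parents (a recurrent background and a divergent donor), an
F1, several generations of backcrossing to the recurrent parent, optional
marker-assisted selection (MAS) that retains donor ancestry over target
intervals, and selfing that fixes residual heterozygosity. Meiosis draws a
Poisson number of crossovers per chromosome with uniform breakpoints (no
interference).

The generator emits parent genome sequences, a joint biallelic variant
table (diagnostic sites where the parents differ, plus uninformative sites
inside parent-shared haplotype tracts), per-line observed genotypes with
configurable error and missingness, the exact donor-origin truth intervals
per line, and expression count matrices with planted cis/trans effects —
everything the detector and the expression stage need, with no external
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CsslkitError,
    GeneModel,
    GenomeSequence,
    VariantTable,
)

RECURRENT = 0
DONOR = 1

Interval = tuple[int, int]
# a haplotype is a list of (start, end, origin) covering [0, L)
Haplotype = list[tuple[int, int, int]]
# a fixed line is a list of (start, end, dosage) with donor dosage 0/1/2
LineState = list[tuple[int, int, int]]


class TooFewMarkersError(CsslkitError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the simulated population.

    Defaults model a 20-line panel on two 50-Mb chromosomes genotyped at 50
    markers/Mb with 1% genotype error and 5% missingness, bred as BC4 with
    four selfing generations — a desk-scale stand-in for a real CSSL panel.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000}
    )
    n_lines: int = 20
    marker_density: float = 50 / 1_000_000  # sites per bp
    divergence: float = 1.0  # fraction of markers diagnostic between parents
    indel_fraction: float = 0.05  # diagnostic variants that are short indels
    shared_tracts_per_chrom: int = 1
    shared_tract_length_bp: int = 3_000_000
    n_backcross: int = 4
    n_self: int = 4
    crossover_rate: float = 2.0  # expected crossovers / chromosome / meiosis
    genotype_error: float = 0.01
    missing_rate: float = 0.05
    mas_target_length_bp: int = 4_000_000  # per-line MAS interval when enabled
    use_mas: bool = True
    het_residual: bool = False
    recurrent_id: str = "REC"
    donor_id: str = "DON"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence", "genotype_error", "missing_rate", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")


@dataclass
class Parents:
    recurrent_genome: dict[str, GenomeSequence]
    donor_genome: dict[str, GenomeSequence]
    variants: VariantTable  # samples [recurrent_id, donor_id]
    shared_tracts: list[tuple[str, int, int]]


@dataclass
class TruthSet:
    """Exact donor-origin intervals (and retained het tracts) per line."""

    donor_intervals: dict[str, list[tuple[str, int, int]]]
    het_intervals: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    parents: Parents
    variants: VariantTable  # parents + all lines
    line_ids: list[str]
    truth: TruthSet
    line_states: dict[str, dict[str, LineState]]
    mas_targets: dict[str, list[tuple[str, int, int]]]


# ---------------------------------------------------------------------------
# parents
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def simulate_parents(config: SimConfig, rng: np.random.Generator) -> Parents:
    """Build the two parental genomes and their joint variant table.

    The donor differs from the recurrent reference at diagnostic marker
    sites (SNPs plus a small fraction of 1-3 bp indels) except inside
    parent-shared tracts, where both parents are identical and the markers
    are uninformative.
    """
    chroms, poss, refs, alts = [], [], [], []
    rec_gt, don_gt = [], []
    rec_genome: dict[str, GenomeSequence] = {}
    don_genome: dict[str, GenomeSequence] = {}
    shared: list[tuple[str, int, int]] = []

    for chrom, L in config.chrom_lengths.items():
        n_markers = int(round(config.marker_density * L))
        if n_markers < 10:
            raise TooFewMarkersError(
                f"{chrom}: density x length gives {n_markers} markers (< 10)"
            )
        seq = _random_sequence(L, rng)
        rec_genome[chrom] = GenomeSequence(chrom, seq)

        # marker positions (0-based): jittered grid, min 8 bp apart so REF
        # spans never overlap, uniform coverage along the chromosome
        spacing = (L - 10) // n_markers
        base = np.arange(n_markers, dtype=np.int64) * spacing + spacing // 2
        half = max(spacing // 2 - 5, 0)
        jitter = rng.integers(-half, half + 1, size=n_markers) if half else 0
        pos0 = np.clip(base + jitter, 0, L - 10)

        tracts = []
        for _ in range(config.shared_tracts_per_chrom):
            tl = min(config.shared_tract_length_bp, L)
            s = int(rng.integers(0, max(L - tl, 1)))
            tracts.append((s, s + tl))
            shared.append((chrom, s, s + tl))
        in_shared = np.zeros(len(pos0), dtype=bool)
        for s, e in tracts:
            in_shared |= (pos0 >= s) & (pos0 < e)
        diagnostic = (rng.random(len(pos0)) < config.divergence) & ~in_shared

        donor_edits: list[tuple[int, str, str]] = []
        for p, diag in zip(pos0, diagnostic):
            p = int(p)
            ref_base = seq[p]
            if not diag:
                # uninformative marker: both parents reference-like
                chroms.append(chrom); poss.append(p + 1)
                refs.append(ref_base); alts.append(_other_base(ref_base, rng))
                rec_gt.append(HOM_REF); don_gt.append(HOM_REF)
                continue
            r = rng.random()
            if r < config.indel_fraction / 2:  # insertion
                ins = "".join(rng.choice(list("ACGT")) for _ in range(int(rng.integers(1, 4))))
                ref, alt = ref_base, ref_base + ins
            elif r < config.indel_fraction:  # deletion of 1-3 bp
                dlen = int(rng.integers(1, 4))
                ref, alt = seq[p : p + dlen + 1], ref_base
            else:  # SNP
                ref, alt = ref_base, _other_base(ref_base, rng)
            chroms.append(chrom); poss.append(p + 1)
            refs.append(ref); alts.append(alt)
            rec_gt.append(HOM_REF); don_gt.append(HOM_ALT)
            donor_edits.append((p, ref, alt))

        # donor chromosome: single-pass piecewise join of edits
        pieces, cursor = [], 0
        for p, ref, alt in sorted(donor_edits):
            pieces.append(seq[cursor:p])
            pieces.append(alt)
            cursor = p + len(ref)
        pieces.append(seq[cursor:])
        don_genome[chrom] = GenomeSequence(chrom, "".join(pieces))

    gt = np.column_stack([
        np.array(rec_gt, dtype=np.int8), np.array(don_gt, dtype=np.int8)
    ])
    variants = VariantTable(
        np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object), np.array(alts, dtype=object),
        gt, [config.recurrent_id, config.donor_id],
    )
    return Parents(rec_genome, don_genome, variants, shared)


# ---------------------------------------------------------------------------
# meiosis and pedigree
# ---------------------------------------------------------------------------


def _hap_slice(hap: Haplotype, start: int, end: int) -> Haplotype:
    out = []
    for s, e, o in hap:
        if e <= start or s >= end:
            continue
        out.append((max(s, start), min(e, end), o))
    return out


def _simplify(hap: Haplotype) -> Haplotype:
    out: Haplotype = []
    for s, e, o in hap:
        if s >= e:
            continue
        if out and out[-1][2] == o and out[-1][1] == s:
            out[-1] = (out[-1][0], e, o)
        else:
            out.append((s, e, o))
    return out


def meiosis(
    hap_a: Haplotype, hap_b: Haplotype, length: int,
    rng: np.random.Generator, mean_crossovers: float,
) -> Haplotype:
    """One gamete: Poisson crossover count, uniform breakpoints, random phase."""
    k = int(rng.poisson(mean_crossovers))
    breaks = sorted(int(b) for b in rng.integers(1, length, size=k)) if k else []
    edges = [0] + breaks + [length]
    current = int(rng.integers(2))
    gamete: Haplotype = []
    for s, e in zip(edges, edges[1:]):
        src = hap_a if current == 0 else hap_b
        gamete.extend(_hap_slice(src, s, e))
        current ^= 1
    return _simplify(gamete)


def _carries_donor(hap: Haplotype, targets: list[Interval]) -> bool:
    for ts, te in targets:
        covered = sum(
            min(e, te) - max(s, ts)
            for s, e, o in hap
            if o == DONOR and s < te and e > ts
        )
        if covered < te - ts:
            return False
    return True


def simulate_pedigree(
    config: SimConfig,
    rng: np.random.Generator,
    mas_targets: dict[str, list[Interval]] | None = None,
) -> tuple[dict[str, LineState], TruthSet]:
    """Breed one line: F1, backcrosses (with MAS), selfing fixation.

    Returns the per-chromosome final state (donor dosage intervals) and its
    truth set. With ``het_residual=False`` (the default) every residual
    heterozygous tract is fixed to one parent as a unit (probability 1/2
    each), emulating >= 4 selfing generations; MAS-targeted tracts fix to
    donor.
    """
    mas_targets = mas_targets or {}
    states: dict[str, LineState] = {}
    donor_ivals: list[tuple[str, int, int]] = []
    het_ivals: list[tuple[str, int, int]] = []

    for chrom, L in config.chrom_lengths.items():
        targets = mas_targets.get(chrom, [])
        hap_r: Haplotype = [(0, L, RECURRENT)]
        gamete: Haplotype = [(0, L, DONOR)]  # donor gamete forming the F1
        # each backcross: meiosis in the current (gamete, recurrent) plant
        for _ in range(config.n_backcross):
            for _attempt in range(200):
                g = meiosis(gamete, hap_r, L, rng, config.crossover_rate)
                if not targets or _carries_donor(g, targets):
                    break
            else:  # MAS fallback: splice donor state over the targets
                g = _force_donor(g, targets)
            gamete = g

        # diploid after final backcross: (gamete, recurrent) -> het where donor
        het_tracts = [(s, e) for s, e, o in gamete if o == DONOR]
        state: LineState = []
        if config.het_residual:
            cursor = 0
            for s, e in het_tracts:
                if s > cursor:
                    state.append((cursor, s, 0))
                state.append((s, e, 1))
                cursor = e
            if cursor < L:
                state.append((cursor, L, 0))
        else:
            cursor = 0
            for s, e in het_tracts:
                if s > cursor:
                    state.append((cursor, s, 0))
                fix_donor = any(s < te and e > ts for ts, te in targets) or rng.random() < 0.5
                state.append((s, e, 2 if fix_donor else 0))
                cursor = e
            if cursor < L:
                state.append((cursor, L, 0))

        # merge adjacent same-dosage runs
        merged: LineState = []
        for s, e, d in state:
            if merged and merged[-1][2] == d and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e, d)
            else:
                merged.append((s, e, d))
        states[chrom] = merged
        donor_ivals.extend((chrom, s, e) for s, e, d in merged if d == 2)
        het_ivals.extend((chrom, s, e) for s, e, d in merged if d == 1)

    truth = TruthSet({"": donor_ivals}, {"": het_ivals})
    return states, truth


def _force_donor(hap: Haplotype, targets: list[Interval]) -> Haplotype:
    out: Haplotype = []
    for s, e, o in hap:
        cur = [(s, e, o)]
        for ts, te in targets:
            nxt = []
            for cs, ce, co in cur:
                if ce <= ts or cs >= te:
                    nxt.append((cs, ce, co))
                    continue
                if cs < ts:
                    nxt.append((cs, ts, co))
                nxt.append((max(cs, ts), min(ce, te), DONOR))
                if ce > te:
                    nxt.append((te, ce, co))
            cur = nxt
        out.extend(cur)
    return _simplify(sorted(out))


# ---------------------------------------------------------------------------
# genotype observation
# ---------------------------------------------------------------------------


def genotype_observe(
    line_states: dict[str, LineState],
    parents: Parents,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observed genotypes for one line over the parent variant table.

    The true genotype follows the donor dosage of the surrounding ancestry
    tract; with probability ``error_rate`` it is replaced by a uniformly
    chosen *different* genotype, and with probability ``missing_rate`` it is
    masked.
    """
    v = parents.variants
    don = v.sample_gt(parents.variants.samples[1])
    gt = np.empty(v.n_sites, dtype=np.int8)
    for chrom, state in line_states.items():
        m = v.chrom == chrom
        pos0 = v.pos[m] - 1
        starts = np.array([s for s, _, _ in state])
        dosages = np.array([d for _, _, d in state], dtype=np.int8)
        idx = np.clip(np.searchsorted(starts, pos0, side="right") - 1, 0, None)
        dose = dosages[idx]
        dg = don[m]
        true = np.where(
            dose == 2, dg,
            np.where((dose == 1) & (dg == HOM_ALT), HET, HOM_REF),
        ).astype(np.int8)
        gt[np.flatnonzero(m)] = true

    if error_rate > 0:
        err = rng.random(v.n_sites) < error_rate
        shift = rng.integers(1, 3, size=v.n_sites)
        gt[err] = ((gt[err] + shift[err]) % 3).astype(np.int8)
    if missing_rate > 0:
        gt[rng.random(v.n_sites) < missing_rate] = MISSING
    return gt


# ---------------------------------------------------------------------------
# whole population
# ---------------------------------------------------------------------------


def _default_mas_targets(config: SimConfig, line_index: int) -> dict[str, list[Interval]]:
    """Tile MAS targets round-robin across the genome so the panel covers it."""
    chroms = list(config.chrom_lengths)
    chrom = chroms[line_index % len(chroms)]
    L = config.chrom_lengths[chrom]
    tl = min(config.mas_target_length_bp, L)
    slot = line_index // len(chroms)
    n_slots = max(L // tl, 1)
    start = (slot % n_slots) * tl
    return {chrom: [(start, min(start + tl, L))]}


def simulate_population(config: SimConfig) -> SimResult:
    """Parents, lines, observed genotypes and exact truth, from one seed."""
    rng = np.random.default_rng(config.seed)
    parents = simulate_parents(config, rng)
    line_ids = [f"L{i + 1:03d}" for i in range(config.n_lines)]

    gts = [parents.variants.gt]
    truth_donor: dict[str, list[tuple[str, int, int]]] = {}
    truth_het: dict[str, list[tuple[str, int, int]]] = {}
    all_states: dict[str, dict[str, LineState]] = {}
    all_targets: dict[str, list[tuple[str, int, int]]] = {}
    for i, line_id in enumerate(line_ids):
        targets = _default_mas_targets(config, i) if config.use_mas else None
        states, truth = simulate_pedigree(config, rng, targets)
        all_states[line_id] = states
        truth_donor[line_id] = truth.donor_intervals[""]
        truth_het[line_id] = truth.het_intervals[""]
        all_targets[line_id] = [
            (c, s, e) for c, ivals in (targets or {}).items() for s, e in ivals
        ]
        gts.append(
            genotype_observe(
                states, parents, config.genotype_error, config.missing_rate, rng
            )[:, None]
        )

    v = parents.variants
    variants = VariantTable(
        v.chrom, v.pos, v.ref, v.alt, np.hstack(gts),
        [config.recurrent_id, config.donor_id] + line_ids,
    )
    return SimResult(
        config, parents, variants, line_ids,
        TruthSet(truth_donor, truth_het), all_states, all_targets,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def make_gene_models(
    chrom_lengths: dict[str, int],
    n_genes: int,
    rng: np.random.Generator,
    gene_length: int = 3_000,
) -> list[GeneModel]:
    """Evenly spaced gene models across the genome."""
    total = sum(chrom_lengths.values())
    genes: list[GeneModel] = []
    i = 0
    for chrom, L in chrom_lengths.items():
        n = max(int(round(n_genes * L / total)), 1)
        spacing = L // (n + 1)
        for k in range(n):
            start = (k + 1) * spacing
            genes.append(
                GeneModel(f"G{i + 1:05d}", chrom, start, min(start + gene_length, L),
                          "+" if rng.random() < 0.5 else "-")
            )
            i += 1
    return genes


def simulate_expression(
    genes: list[GeneModel],
    donor_intervals: list[tuple[str, int, int]],
    rng: np.random.Generator,
    n_replicates: int = 3,
    noise_sd: float = 0.3,
    effect_low: float = 3.0,
    effect_high: float = 6.0,
    cis_effect_prob: float = 1.0,
    trans_fraction: float = 0.05,
    trans_attenuation: float = 0.5,
    baseline_log2_range: tuple[float, float] = (3.0, 10.0),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Count matrices for one line and the recurrent parent with planted
    effects.

    Genes overlapping a donor interval receive a signed cis log2 effect with
    magnitude Uniform(effect_low, effect_high); a random fraction of outside
    genes receive attenuated trans effects; the rest are null. Counts are
    log-normal-Poisson: lambda = 2**(baseline + effect + N(0, noise_sd)).
    """
    gene_ids = [g.gene_id for g in genes]
    mu = rng.uniform(*baseline_log2_range, size=len(genes))
    effects = np.zeros(len(genes))
    labels = np.array(["null"] * len(genes), dtype=object)
    for i, g in enumerate(genes):
        inside = any(
            c == g.chrom and g.start < e and s < g.end
            for c, s, e in donor_intervals
        )
        if inside:
            if rng.random() < cis_effect_prob:
                effects[i] = rng.uniform(effect_low, effect_high) * (1 if rng.random() < 0.5 else -1)
            labels[i] = "cis"
        elif rng.random() < trans_fraction:
            effects[i] = (
                rng.uniform(effect_low, effect_high) * trans_attenuation
                * (1 if rng.random() < 0.5 else -1)
            )
            labels[i] = "trans"

    def draw(shift: np.ndarray) -> np.ndarray:
        log_lam = mu[:, None] + shift[:, None] + rng.normal(0, noise_sd, (len(genes), n_replicates))
        return rng.poisson(np.power(2.0, log_lam)).astype(np.int64)

    cssl = pd.DataFrame(
        draw(effects), index=gene_ids,
        columns=[f"cssl_rep{r + 1}" for r in range(n_replicates)],
    )
    recurrent = pd.DataFrame(
        draw(np.zeros(len(genes))), index=gene_ids,
        columns=[f"rec_rep{r + 1}" for r in range(n_replicates)],
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "log2_effect": effects, "label": labels}
    ).set_index("gene_id")
    return cssl, recurrent, truth
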