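"""Cis/trans gene classification, DEG calling and expression-capacity
summaries for CSSL transcriptomes.

A gene is *cis* for a line if its interval overlaps (>= 1 bp) one of that
line's substitution segments, else *trans*. Genes inside segments are
further split by origin: donor genes with a recurrent-genome orthologue
(GB_ORTHOLOG) versus without (GB_NOVEL); everything outside segments is
native background (GH_NATIVE).

DEG rules follow two branches. Novel donor genes have no orthologue to
compare against, so they are called differentially expressed simply when
expressed in the CSSL (mean normalized count >= 1). All other genes are
tested against the recurrent parent: |log2 fold change| >= 2 on normalized
counts (with a pseudocount) and Welch-test P < 0.05 on log-scale replicate
values. Genes with |log fold change| > 10 are flagged as magnitude changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import CsslkitError, GeneModel, RunConfig, VariantTable
from .ssd_core import SubstitutionSegment, merge_intervals


class ZeroTotalSampleError(CsslkitError):
    pass


class EmptyGeneSetError(CsslkitError):
    pass


class InsufficientReplicatesError(CsslkitError):
    pass


class GeneOrigin(Enum):
    GH_NATIVE = "GH_native"
    GB_ORTHOLOG = "GB_ortholog"
    GB_NOVEL = "GB_novel"


@dataclass
class DEGCall:
    gene_id: str
    locus_class: str  # "cis" | "trans"
    origin: GeneOrigin
    mean_nc_cssl: float
    mean_nc_recurrent: float
    log_fc: float
    p_value: float | None
    is_deg: bool
    magnitude_change: bool


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_counts(raw: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios library-size normalization (genes x samples).

    Size factors are medians of per-gene ratios to the geometric-mean
    reference profile, estimated over genes with no zero count; all genes
    are retained in the output.
    """
    if (raw < 0).any().any():
        raise ValueError("counts must be nonnegative")
    totals = raw.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ZeroTotalSampleError(f"samples with zero total counts: {list(zero.index)}")
    usable = raw[(raw > 0).all(axis=1)]
    if usable.empty:
        raise ZeroTotalSampleError("no gene has nonzero counts in every sample")
    log_geomean = np.log(usable).mean(axis=1)
    factors = np.exp(np.median(np.log(usable).sub(log_geomean, axis=0), axis=0))
    return raw.div(factors, axis=1)


def size_factors(raw: pd.DataFrame) -> pd.Series:
    """The median-of-ratios size factors themselves (one per sample)."""
    normalized = normalize_counts(raw)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (raw.sum(axis=0) / normalized.sum(axis=0)).astype(float)
    return f


# ---------------------------------------------------------------------------
# locus and origin classification
# ---------------------------------------------------------------------------


def classify_gene_locus(gene: GeneModel, segments: list[SubstitutionSegment]) -> str:
    """'cis' iff the gene overlaps any of the line's segments by >= 1 bp."""
    for s in segments:
        if s.chrom == gene.chrom and gene.start < s.end and s.start < gene.end:
            return "cis"
    return "trans"


def classify_gene_origin(
    gene: GeneModel,
    segments: list[SubstitutionSegment],
    ortholog_map: dict[str, str] | None,
) -> GeneOrigin:
    """Origin category; GB_* only inside segments, GB_NOVEL iff unmapped."""
    if classify_gene_locus(gene, segments) == "trans":
        return GeneOrigin.GH_NATIVE
    if ortholog_map is not None and gene.gene_id in ortholog_map:
        return GeneOrigin.GB_ORTHOLOG
    return GeneOrigin.GB_NOVEL


# ---------------------------------------------------------------------------
# DEG calling
# ---------------------------------------------------------------------------


def call_deg(
    gene_id: str,
    origin: GeneOrigin,
    cssl_nc: np.ndarray,
    recurrent_nc: np.ndarray,
    config: RunConfig | None = None,
    locus_class: str = "cis",
) -> DEGCall:
    """Call one gene under the two-branch DEG rule.

    Branch A (GB_NOVEL): expressed (mean NC >= threshold) == DEG; no test,
    no p-value. Branch B (everything else): log2 fold change with
    pseudocount, Welch's unequal-variance t-test on log2(NC + pseudocount)
    replicates, DEG iff |lfc| >= lfc_min and P < p_max. Requires >= 2
    replicates per group for the test branch.
    """
    config = config or RunConfig()
    cssl_nc = np.asarray(cssl_nc, dtype=float)
    recurrent_nc = np.asarray(recurrent_nc, dtype=float)
    mean_c = float(np.mean(cssl_nc))

    if origin is GeneOrigin.GB_NOVEL:
        is_deg = mean_c >= config.novel_expressed_min_nc
        mean_r = float(np.mean(recurrent_nc)) if len(recurrent_nc) else float("nan")
        return DEGCall(gene_id, locus_class, origin, mean_c, mean_r,
                       float("nan"), None, is_deg, False)

    if len(cssl_nc) < 2 or len(recurrent_nc) < 2:
        raise InsufficientReplicatesError(
            f"{gene_id}: the test branch needs >= 2 replicates per group "
            f"(got {len(cssl_nc)} vs {len(recurrent_nc)})"
        )
    c = config.pseudocount
    mean_r = float(np.mean(recurrent_nc))
    log_fc = float(np.log2((mean_c + c) / (mean_r + c)))
    a = np.log2(cssl_nc + c)
    b = np.log2(recurrent_nc + c)
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0
    is_deg = abs(log_fc) >= config.lfc_min and p < config.p_max
    magnitude = abs(log_fc) > config.magnitude_lfc
    return DEGCall(gene_id, locus_class, origin, mean_c, mean_r, log_fc, p, is_deg, magnitude)


def call_deg_table(
    nc_cssl: pd.DataFrame,
    nc_recurrent: pd.DataFrame,
    genes: list[GeneModel],
    segments: list[SubstitutionSegment],
    ortholog_map: dict[str, str] | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Apply the DEG rules to every gene of one line; returns a tidy frame."""
    config = config or RunConfig()
    rows = []
    for g in genes:
        locus = classify_gene_locus(g, segments)
        origin = classify_gene_origin(g, segments, ortholog_map)
        call = call_deg(
            g.gene_id, origin,
            nc_cssl.loc[g.gene_id].to_numpy(),
            nc_recurrent.loc[g.gene_id].to_numpy(),
            config, locus_class=locus,
        )
        rows.append(
            dict(gene_id=call.gene_id, locus_class=call.locus_class,
                 origin=call.origin.value, mean_nc_cssl=call.mean_nc_cssl,
                 mean_nc_recurrent=call.mean_nc_recurrent, log_fc=call.log_fc,
                 p_value=call.p_value, is_deg=call.is_deg,
                 magnitude_change=call.magnitude_change)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# capacity and haplotype-share summaries
# ---------------------------------------------------------------------------


def expression_capacity(
    mean_nc: pd.Series, gene_set: list[str], threshold_nc: float = 1.0
) -> float:
    """Fraction of the gene set with mean normalized count > threshold."""
    if not gene_set:
        raise EmptyGeneSetError("capacity of an empty gene set is undefined")
    values = mean_nc.reindex(gene_set)
    return float((values > threshold_nc).sum() / len(gene_set))


def donor_haplotype_share_percent(n_with_donor: int, n_total: int) -> float:
    """Population share (percent) of variant sites whose donor haplotype is
    present in at least one line, from the two counts."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_with_donor <= n_total:
        raise ValueError("require 0 <= n_with_donor <= n_total")
    return 100.0 * n_with_donor / n_total


def proportion_with_donor_haplotype(
    variants: VariantTable,
    segments_by_line: dict[str, list[SubstitutionSegment]],
) -> float:
    """Fraction of variant sites inside >= 1 line's substitution segments."""
    if variants.n_sites == 0:
        return 0.0
    pooled = [
        (s.chrom, s.start, s.end)
        for segs in segments_by_line.values()
        for s in segs
    ]
    if not pooled:
        return 0.0
    merged = merge_intervals(pooled)
    inside = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in merged:
        by_chrom.setdefault(c, []).append((s, e))
    for chrom, ivals in by_chrom.items():
        pos0 = variants.pos[variants.chrom == chrom] - 1
        starts = np.array([s for s, _ in ivals])
        ends = np.array([e for _, e in ivals])
        i = np.searchsorted(starts, pos0, side="right") - 1
        ok = (i >= 0) & (pos0 < ends[np.clip(i, 0, None)])
        inside += int(ok.sum())
    return inside / variants.n_sites
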