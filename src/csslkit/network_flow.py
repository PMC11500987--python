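"""Cross-network module-flow statistics.

Given gene-to-module assignments from co-expression networks built at
different developmental stages, this module counts how the genes of each
source module redistribute ("flow") over the modules of a second network,
and scores each source module's flow with Shannon's equitability

    E_H(i) = -(1 / ln N_B) * sum_j p_ij ln p_ij

where N_B is the number of modules in the target network and ln N_B the
maximum diversity. Two definitions of p_ij are supported: ``as_printed``
divides n_ij by the *target* module size n_j (the literal equation, whose
row sums need not be 1, so E_H is not guaranteed to stay in [0, 1]);
``row_normalized`` divides by the row sum, under which E_H is 0 exactly
when all genes flow to one module and 1 for a perfectly even spread. The
0 * ln 0 := 0 convention applies throughout. ``row_normalized`` is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import CsslkitError


class NoSharedGenesError(CsslkitError):
    pass


class DegenerateNetworkError(CsslkitError):
    pass


@dataclass
class ModuleAssignment:
    """Gene -> module mapping for one network."""

    network_id: str
    mapping: dict[str, str]

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @property
    def n_modules(self) -> int:
        return len(set(self.mapping.values()))

    @classmethod
    def from_tsv(cls, path, network_id: str | None = None) -> "ModuleAssignment":
        mapping = {}
        with open(path) as fh:
            for ln, line in enumerate(fh):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if ln == 0 and parts[0].lower() in ("gene", "gene_id"):
                    continue
                mapping[parts[0]] = parts[1]
        return cls(network_id or str(path), mapping)


@dataclass
class ModuleFlow:
    """Flow of one source module's genes into the target network."""

    source_network: str
    target_network: str
    source_module: str
    counts: dict[str, int]  # target module -> n_ij
    target_sizes: dict[str, int]  # target module -> n_j (over shared genes)
    n_target_modules: int  # N_B
    n_unassigned: int = 0  # source-module genes absent from the target


def build_flow(a: ModuleAssignment, b: ModuleAssignment) -> list[ModuleFlow]:
    """Count gene flow from every module of A into the modules of B.

    Counts are taken over genes assigned in both networks; source-module
    genes missing from B are tallied separately in ``n_unassigned``.
    """
    shared = set(a.mapping) & set(b.mapping)
    if not shared:
        raise NoSharedGenesError(
            f"no genes shared between {a.network_id} and {b.network_id}"
        )
    target_sizes: dict[str, int] = {}
    for g in shared:
        target_sizes[b.mapping[g]] = target_sizes.get(b.mapping[g], 0) + 1
    n_b = b.n_modules

    flows: list[ModuleFlow] = []
    for mod in sorted(set(a.mapping.values())):
        members = [g for g, m in a.mapping.items() if m == mod]
        counts: dict[str, int] = {}
        missing = 0
        for g in members:
            if g in b.mapping:
                counts[b.mapping[g]] = counts.get(b.mapping[g], 0) + 1
            else:
                missing += 1
        flows.append(
            ModuleFlow(a.network_id, b.network_id, mod, counts,
                       target_sizes, n_b, missing)
        )
    return flows


def equitability(flow: ModuleFlow, mode: str = "row_normalized") -> float:
    """Shannon equitability of one module's flow; see module docstring."""
    if mode not in ("row_normalized", "as_printed"):
        raise ValueError(f"unknown mode {mode!r}")
    if flow.n_target_modules < 2:
        raise DegenerateNetworkError(
            "maximum diversity ln(N_B) undefined for N_B < 2"
        )
    n_ij = np.array([c for c in flow.counts.values() if c > 0], dtype=float)
    if len(n_ij) == 0:
        raise ValueError(f"module {flow.source_module}: no nonzero flow counts")
    if mode == "row_normalized":
        p = n_ij / n_ij.sum()
    else:
        n_j = np.array(
            [flow.target_sizes[m] for m, c in flow.counts.items() if c > 0],
            dtype=float,
        )
        p = n_ij / n_j
    h = -np.sum(p * np.log(p))  # 0*ln0 terms excluded by construction
    return float(h / np.log(flow.n_target_modules))


def flow_pattern(gene_id: str, assignments: list[ModuleAssignment]) -> str:
    """Hyphen-joined module ids across networks in order, 'NA' when absent."""
    if not any(gene_id in a.mapping for a in assignments):
        raise KeyError(f"gene {gene_id!r} absent from every assignment")
    return "-".join(a.mapping.get(gene_id, "NA") for a in assignments)


def screen_key_genes(
    membership: "pd.DataFrame",
    trait_corr: "pd.DataFrame",
    modules_of_interest: list[str],
    mm_min: float = 0.8,
    corr_min: float = 0.5,
) -> list[str]:
    """Genes with strong module membership and strong trait correlation.

    ``membership`` is genes x modules (module-membership scores),
    ``trait_corr`` genes x traits (signed correlations). A gene passes if
    its membership in any module of interest is >= mm_min AND it has
    |correlation| >= corr_min with at least one trait; both inclusive.
    """
    import pandas as pd  # local: keeps module import light

    cols = [m for m in modules_of_interest if m in membership.columns]
    if not cols:
        return []
    strong_mm = (membership[cols] >= mm_min).any(axis=1)
    genes = membership.index[strong_mm]
    corr = trait_corr.reindex(genes)
    strong_corr = (corr.abs() >= corr_min).any(axis=1).fillna(False)
    return sorted(corr.index[strong_corr])
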