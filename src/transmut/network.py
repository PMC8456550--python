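"""Regulator-network inference from TF -> target evidence matrices.

A transcription factor is a first-level regulator of the focal gene when
both DNA-binding evidence and expression-perturbation evidence support the
association; a k-th level regulator has both kinds of evidence on some
(k-1)-level regulator.  Edge direction comes from the expression matrices:
activator-only evidence gives "activates", inhibitor-only "inhibits", and
membership in both matrices means the direction is undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .bsa import GTestResult
from .enrichment import g_test_rxc
from .errors import DataError
from .variants import Mutation


@dataclass
class EvidenceMatrices:
    """Boolean TF x target matrices for binding and expression evidence.

    A TF may appear in both expression matrices, meaning its perturbation
    changes the target's expression in an undetermined direction.
    """

    binding: pd.DataFrame
    expr_activator: pd.DataFrame
    expr_inhibitor: pd.DataFrame

    def __post_init__(self) -> None:
        tfs = set(self.binding.index)
        targets = set(self.binding.columns)
        for name in ("expr_activator", "expr_inhibitor"):
            m = getattr(self, name)
            if set(m.index) != tfs or set(m.columns) != targets:
                raise DataError(f"{name} does not share the binding matrix name spaces")

    @classmethod
    def from_files(cls, binding_path: str, activator_path: str, inhibitor_path: str,
                   sep: str = "\t") -> "EvidenceMatrices":
        """Load 0/1 regulation-matrix exports (first column = TF names,
        header row = target names)."""
        load = lambda p: pd.read_csv(p, sep=sep, index_col=0).astype(bool)
        return cls(load(binding_path), load(activator_path), load(inhibitor_path))

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame) -> "EvidenceMatrices":
        """Build matrices from an edge list with columns tf, target,
        evidence_type in {binding, activator, inhibitor}."""
        tfs = sorted(edges["tf"].unique())
        targets = sorted(edges["target"].unique())
        mats = {
            k: pd.DataFrame(False, index=tfs, columns=targets)
            for k in ("binding", "activator", "inhibitor")
        }
        for _, row in edges.iterrows():
            mats[row["evidence_type"]].loc[row["tf"], row["target"]] = True
        return cls(mats["binding"], mats["activator"], mats["inhibitor"])


@dataclass
class RegulatorNetwork:
    focal_gene: str
    levels: dict[str, int] = field(default_factory=dict)  # TF -> minimum level
    edges: list[tuple[str, str, str]] = field(default_factory=list)  # (tf, target, direction)

    @property
    def level1(self) -> set[str]:
        return {tf for tf, lv in self.levels.items() if lv == 1}

    @property
    def level2(self) -> set[str]:
        return {tf for tf, lv in self.levels.items() if lv == 2}

    def members(self) -> set[str]:
        return set(self.levels)


def _edge_direction(m: EvidenceMatrices, tf: str, target: str) -> str:
    act = bool(m.expr_activator.loc[tf, target])
    inh = bool(m.expr_inhibitor.loc[tf, target])
    if act and inh:
        return "unknown"
    return "activates" if act else "inhibits"


def infer_regulators(
    focal_gene: str,
    matrices: EvidenceMatrices,
    max_level: int = 2,
) -> RegulatorNetwork:
    """Breadth-first regulator inference up to ``max_level``.

    A TF regulates a target when binding AND expression evidence are both
    present.  Levels record the minimum qualifying level; a TF regulating
    itself does not promote itself to a deeper level.
    """
    if focal_gene not in matrices.binding.columns:
        raise DataError(f"focal gene {focal_gene!r} absent from target name space")
    expr = matrices.expr_activator | matrices.expr_inhibitor
    regulates = matrices.binding & expr

    network = RegulatorNetwork(focal_gene=focal_gene)
    frontier = {focal_gene}
    for level in range(1, max_level + 1):
        next_frontier: set[str] = set()
        for target in frontier:
            if target not in regulates.columns:
                continue
            for tf in regulates.index[regulates[target]]:
                if tf == target:  # self-loop: recorded but never promotes
                    network.edges.append((tf, target, _edge_direction(matrices, tf, target)))
                    continue
                network.edges.append((tf, target, _edge_direction(matrices, tf, target)))
                if tf not in network.levels:
                    network.levels[tf] = level
                    next_frontier.add(tf)
        frontier = next_frontier
    network.edges = sorted(set(network.edges))
    return network


@dataclass
class MembershipResult:
    trans_proportion: float
    nonreg_proportion: float
    fold_enrichment: float
    test: GTestResult
    table: pd.DataFrame = field(repr=False, default=None)


def network_membership_test(
    trans_mutations: Sequence[Mutation],
    nonreg_mutations: Sequence[Mutation],
    network: RegulatorNetwork,
) -> MembershipResult:
    """2x2 G-test of mutation set against membership of the mutated gene in
    the inferred regulator set, with the proportion-ratio fold enrichment."""
    members = network.members()

    def split(mutations: Sequence[Mutation]) -> tuple[int, int]:
        inside = sum(1 for m in mutations if m.gene in members)
        return inside, len(mutations) - inside

    t_in, t_out = split(trans_mutations)
    n_in, n_out = split(nonreg_mutations)
    table = pd.DataFrame(
        [[t_in, t_out], [n_in, n_out]],
        index=["trans_regulatory", "non_regulatory"],
        columns=["in_network", "outside"],
    )
    test = g_test_rxc(table)
    p_t = t_in / max(len(trans_mutations), 1)
    p_n = n_in / max(len(nonreg_mutations), 1)
    fold = p_t / p_n if p_n > 0 else float("inf")
    return MembershipResult(
        trans_proportion=p_t, nonreg_proportion=p_n, fold_enrichment=fold,
        test=test, table=table,
    )
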