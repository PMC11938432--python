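"""Evidence-network construction and feasibility rules.

A network has treatments as nodes and trials as edges, built per outcome and
analytic scenario.  Two feasibility rules are enforced: at least two studies
within the scenario must report the outcome at the 52-week time point (and at
an approved dose), and the network used for analysis must be a single
connected component containing the reference treatment.  The shipped
scenarios are all stars around daily somatropin, but nothing here assumes
that for arbitrary inputs; multi-arm trials contribute one edge per arm pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence, Union

import networkx as nx

from .exceptions import FeasibilityError
from .study_data import (
    ANALYSIS_WEEK,
    REFERENCE_TREATMENT,
    Scenario,
    TrialRecord,
)


@dataclass
class EvidenceNetwork:
    """Per-outcome, per-scenario evidence network."""

    outcome: str
    scenario: Scenario
    nodes: tuple[str, ...]
    edges: list[tuple[str, tuple[str, str]]]
    reference: str
    trials: list[TrialRecord] = field(default_factory=list)

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for trial_id, (a, b) in self.edges:
            g.add_edge(a, b, trial=trial_id)
        return g

    @property
    def is_connected(self) -> bool:
        return len(connected_components(self)) == 1

    def to_edgelist_csv(self, path: Union[str, Path]) -> None:
        lines = ["trial_id,treatment_a,treatment_b"]
        lines += [f"{t},{a},{b}" for t, (a, b) in self.edges]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def to_dot(self) -> str:
        """DOT description of the network (one edge per trial contrast)."""
        out = [f'graph "{self.outcome}_{self.scenario.name}" {{']
        for n in self.nodes:
            shape = "doublecircle" if n == self.reference else "circle"
            out.append(f'  "{n}" [shape={shape}];')
        for trial_id, (a, b) in self.edges:
            out.append(f'  "{a}" -- "{b}" [label="{trial_id}"];')
        out.append("}")
        return "\n".join(out)


def build_network(
    trials: Sequence[TrialRecord],
    outcome: str,
    scenario: Scenario,
    reference: str = REFERENCE_TREATMENT,
    require_approved: bool = True,
    min_studies: int = 2,
) -> EvidenceNetwork:
    """Assemble the evidence network for one outcome under one scenario.

    Includes only scenario trials reporting the outcome at the analysis week
    in at least two (approved-dose) arms.  Raises :class:`FeasibilityError`
    naming outcome and scenario when fewer than ``min_studies`` studies
    contribute (two, per the feasibility rule; worked examples that
    deliberately analyse a single published trial lower it to one).
    Deterministic and order-independent: nodes are sorted with the reference
    first, edges sorted by (trial, pair).
    """
    contributing: list[TrialRecord] = []
    edges: list[tuple[str, tuple[str, str]]] = []
    nodes: set[str] = set()
    for rec in sorted(trials, key=lambda r: r.trial_id):
        if rec.trial_id not in scenario.trial_ids or rec.week != ANALYSIS_WEEK:
            continue
        arms = [
            a for a in rec.arms
            if outcome in a.outcomes and (a.approved or not require_approved)
        ]
        if len(arms) < 2:
            continue
        contributing.append(rec)
        treats = sorted(a.treatment for a in arms)
        nodes.update(treats)
        for a, b in combinations(treats, 2):
            edges.append((rec.trial_id, (a, b)))
    if len(contributing) < min_studies:
        raise FeasibilityError(
            f"outcome {outcome!r} under scenario {scenario.name!r}: "
            f"{len(contributing)} contributing studies; at least "
            f"{min_studies} studies must report the outcome at week "
            f"{ANALYSIS_WEEK}"
        )
    ordered = ([reference] if reference in nodes else []) + sorted(
        n for n in nodes if n != reference
    )
    return EvidenceNetwork(
        outcome=outcome,
        scenario=scenario,
        nodes=tuple(ordered),
        edges=sorted(edges),
        reference=reference,
        trials=contributing,
    )


def connected_components(net: EvidenceNetwork) -> list[set[str]]:
    """Partition of the nodes by trial-edge connectivity (largest first)."""
    if not net.nodes:
        return []
    comps = nx.connected_components(net.graph())
    return sorted((set(c) for c in comps), key=lambda c: (-len(c), sorted(c)))
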