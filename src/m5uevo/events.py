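"""Most-parsimonious gain/loss/duplication/pseudogenization/transfer
scenarios for gene families on a rooted species tree, plus the matrix-level
consistency checks (counts, mutual exclusivity, genotype -> phenotype).

Conventions
-----------
* Binary character states: 0 = absent, 1 = present. Pseudogenes count as
  present for parsimony (they witness historical presence) and as absent
  for functional checks.
* Events are annotated on edges, each edge identified by its child node
  label ("loss at 28" = loss on the branch whose child is node 28).
* The root state itself is free: ancestral presence at the root is not an
  event. In the Dollo modes the single primary origin is likewise free;
  only losses (and transfers) are costed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from .datamodel import PhyleticMatrix
from .newick import SpeciesTree, TreeNode

MODES = ("wagner", "dollo", "dollo_with_transfers")


@dataclass(frozen=True)
class CostModel:
    gain_cost: float = 2.0
    loss_cost: float = 1.0
    transfer_cost: float = 2.0
    mode: str = "dollo"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("gain_cost", "loss_cost", "transfer_cost"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Event:
    type: str  # gain | loss | duplication | pseudogenization | transfer
    edge: str  # child-node label of the branch carrying the event
    family: str
    donor: Optional[str] = None
    source_family: Optional[str] = None  # set by type_events for duplications
    cost: float = 0.0
    time: Optional[float] = None  # set by the simulator only


@dataclass
class EventScenario:
    family: str
    cost_model: CostModel
    total_cost: float
    events: list[Event] = field(default_factory=list)
    node_states: dict[str, int] = field(default_factory=dict)

    def loss_edges(self) -> set[str]:
        return {e.edge for e in self.events if e.type == "loss"}

    def transfer_edges(self) -> set[str]:
        return {e.edge for e in self.events if e.type == "transfer"}

    def gain_edges(self) -> set[str]:
        return {e.edge for e in self.events if e.type in ("gain", "duplication")}


def _node_key(tree: SpeciesTree) -> dict[str, int]:
    return {n.label: i for i, n in enumerate(tree.preorder()) if n.label}


def _check_leaf_states(tree: SpeciesTree, leaf_states: dict) -> None:
    leaves = set(tree.leaf_labels)
    missing = leaves - set(leaf_states)
    if missing:
        raise ValueError(f"leaves missing from leaf_states: {sorted(missing)}")
    for label, state in leaf_states.items():
        if label not in leaves:
            raise ValueError(f"leaf {label!r} not in tree")
        if state not in (0, 1):
            raise ValueError(f"leaf state for {label!r} must be 0/1, got {state!r}")


def _events_from_states(
    tree: SpeciesTree, states: dict[str, int], costs: CostModel, family: str,
    transfer_edges: frozenset[str] = frozenset(), donor: Optional[str] = None,
) -> list[Event]:
    events = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        ps, cs = states[node.parent.label], states[node.label]
        if ps == cs:
            continue
        if cs == 1:
            if node.label in transfer_edges:
                events.append(
                    Event("transfer", node.label, family, donor=donor,
                          cost=costs.transfer_cost)
                )
            else:
                gain_cost = costs.gain_cost if costs.mode == "wagner" else 0.0
                events.append(Event("gain", node.label, family, cost=gain_cost))
        else:
            events.append(Event("loss", node.label, family, cost=costs.loss_cost))
    return events


def replay_scenario(tree: SpeciesTree, scenario: EventScenario) -> dict[str, int]:
    """Recompute leaf states by applying scenario events from the root down."""
    by_edge: dict[str, list[Event]] = {}
    for event in scenario.events:
        if event.type in ("gain", "loss", "transfer", "duplication"):
            by_edge.setdefault(event.edge, []).append(event)
    states: dict[str, int] = {}
    for node in tree.preorder():
        if node.parent is None:
            states[node.label] = scenario.node_states[node.label]
            continue
        state = states[node.parent.label]
        for event in by_edge.get(node.label, ()):
            state = 0 if event.type == "loss" else 1
        states[node.label] = state
    return {leaf: states[leaf] for leaf in tree.leaf_labels}


# ---------------------------------------------------------------------------
# Sankoff dynamic programming (binary states)
# ---------------------------------------------------------------------------

def _sankoff_tables(
    tree: SpeciesTree,
    leaf_states: dict[str, int],
    edge_cost: Callable[[int, int], float],
    forced: Optional[dict[str, int]] = None,
):
    """Bottom-up min-cost tables: down[label][s] = cost of the subtree given
    the node has state s (including costs of edges below the node)."""
    forced = forced or {}
    down: dict[str, list[float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            state = leaf_states[node.label]
            costs = [math.inf, math.inf]
            costs[state] = 0.0
        else:
            costs = [0.0, 0.0]
            for s in (0, 1):
                for child in node.children:
                    costs[s] += min(
                        edge_cost(s, cs) + down[child.label][cs] for cs in (0, 1)
                    )
        if node.label in forced:
            keep = forced[node.label]
            costs = [c if s == keep else math.inf for s, c in enumerate(costs)]
        down[node.label] = costs
    return down


def _sankoff_backtrace(
    tree: SpeciesTree,
    down,
    edge_cost: Callable[[int, int], float],
    root_state: Optional[int] = None,
) -> dict[str, int]:
    """Canonical optimal labeling. Ties prefer presence at the root and,
    along edges, prefer keeping the parent state (no event)."""
    states: dict[str, int] = {}
    for node in tree.preorder():
        if node.parent is None:
            if root_state is not None:
                states[node.label] = root_state
            else:
                c0, c1 = down[node.label]
                states[node.label] = 1 if c1 <= c0 else 0
            continue
        ps = states[node.parent.label]
        best_state, best_cost = None, math.inf
        for cs in (ps, 1 - ps):  # tie-break: keep parent state
            cost = edge_cost(ps, cs) + down[node.label][cs]
            if cost < best_cost:
                best_state, best_cost = cs, cost
        states[node.label] = best_state
    return states


def _wagner_edge_cost(costs: CostModel) -> Callable[[int, int], float]:
    def edge_cost(ps: int, cs: int) -> float:
        if ps == cs:
            return 0.0
        return costs.gain_cost if cs == 1 else costs.loss_cost

    return edge_cost


def _scenario_from_states(
    tree, states, costs, family, transfer_edges=frozenset(), donor=None
) -> EventScenario:
    events = _events_from_states(tree, states, costs, family, transfer_edges, donor)
    return EventScenario(
        family=family,
        cost_model=costs,
        total_cost=sum(e.cost for e in events),
        events=events,
        node_states=dict(states),
    )


def _dollo_states(tree: SpeciesTree, leaf_states: dict[str, int]) -> dict[str, int]:
    """Single origin at the MRCA of present leaves; a node is present iff it
    lies in the MRCA subtree and has a present descendant."""
    present_leaves = [l for l, s in leaf_states.items() if s == 1]
    states = {node.label: 0 for node in tree.preorder()}
    if not present_leaves:
        return states
    mrca = tree.mrca(present_leaves)
    has_present: dict[str, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            has_present[node.label] = leaf_states[node.label] == 1
        else:
            has_present[node.label] = any(has_present[c.label] for c in node.children)
    for node in mrca.preorder():
        if has_present[node.label]:
            states[node.label] = 1
    return states


def sankoff_reconstruct(
    tree: SpeciesTree, leaf_states: dict[str, int], costs: CostModel,
    family: str = "family",
) -> EventScenario:
    """Minimum-cost ancestral reconstruction for one binary family.

    ``wagner`` mode is unrestricted Sankoff; ``dollo`` fixes the single
    origin at the MRCA of present leaves and charges losses only;
    ``dollo_with_transfers`` dispatches to :func:`dollo_with_transfers`.
    """
    _check_leaf_states(tree, leaf_states)
    if costs.mode == "wagner":
        edge_cost = _wagner_edge_cost(costs)
        down = _sankoff_tables(tree, leaf_states, edge_cost)
        states = _sankoff_backtrace(tree, down, edge_cost)
        return _scenario_from_states(tree, states, costs, family)
    if costs.mode == "dollo":
        states = _dollo_states(tree, leaf_states)
        return _scenario_from_states(tree, states, costs, family)
    return dollo_with_transfers(tree, leaf_states, costs, family=family)


def enumerate_mprs(
    tree: SpeciesTree,
    leaf_states: dict[str, int],
    costs: CostModel,
    max_scenarios: int = 10_000,
    family: str = "family",
) -> list[EventScenario]:
    """All most-parsimonious scenarios; the canonical scenario is a member.

    In ``dollo`` mode the reconstruction is unique by construction. In
    ``dollo_with_transfers`` mode scenarios for every optimal primary-origin
    placement are returned.
    """
    _check_leaf_states(tree, leaf_states)
    if costs.mode == "dollo":
        return [sankoff_reconstruct(tree, leaf_states, costs, family=family)]
    if costs.mode == "dollo_with_transfers":
        return _enumerate_transfer_origins(tree, leaf_states, costs, family)

    # Exact enumeration of all optimal labelings: assign states in preorder,
    # pruning with the DP tables (cost spent so far + DP lower bound on the
    # unassigned frontier must not exceed the optimum).
    edge_cost = _wagner_edge_cost(costs)
    down = _sankoff_tables(tree, leaf_states, edge_cost)
    best = min(down[tree.root.label])
    nodes = list(tree.preorder())
    labelings: list[dict[str, int]] = []

    def frontier_bound(states: dict[str, int]) -> float:
        bound = 0.0
        for node in nodes:
            if node.label not in states:
                continue
            ps = states[node.label]
            for child in node.children:
                if child.label not in states:
                    bound += min(
                        edge_cost(ps, cs) + down[child.label][cs] for cs in (0, 1)
                    )
        return bound

    def rec(idx: int, states: dict[str, int], spent: float):
        if len(labelings) > max_scenarios:
            raise RuntimeError(f"more than {max_scenarios} most-parsimonious scenarios")
        if idx == len(nodes):
            labelings.append(dict(states))
            return
        node = nodes[idx]
        for s in (0, 1):
            if node.is_leaf and leaf_states[node.label] != s:
                continue
            edge = 0.0 if node.parent is None else edge_cost(states[node.parent.label], s)
            states[node.label] = s
            if spent + edge + frontier_bound(states) <= best + 1e-9:
                rec(idx + 1, states, spent + edge)
            del states[node.label]

    rec(0, {}, 0.0)
    return [_scenario_from_states(tree, st, costs, family) for st in labelings]


# ---------------------------------------------------------------------------
# Dollo with horizontal transfers
# ---------------------------------------------------------------------------

def _transfer_edge_cost(costs: CostModel) -> Callable[[int, int], float]:
    def edge_cost(ps: int, cs: int) -> float:
        if ps == cs:
            return 0.0
        return costs.transfer_cost if cs == 1 else costs.loss_cost

    return edge_cost


def _transfer_solution_for_origin(
    tree: SpeciesTree, leaf_states, costs: CostModel, origin: TreeNode
):
    """Min cost with the primary origin forced at ``origin`` (free), all its
    ancestors absent, and any other 0->1 edge charged as a transfer."""
    edge_cost = _transfer_edge_cost(costs)
    forced = {origin.label: 1}
    node = origin.parent
    while node is not None:
        forced[node.label] = 0
        node = node.parent
    down = _sankoff_tables(tree, leaf_states, edge_cost, forced=forced)
    root_label = tree.root.label
    root_state = forced.get(root_label)
    total = down[root_label][root_state] if root_state is not None else min(down[root_label])
    if origin.parent is not None:
        # the 0->1 edge into the origin was charged transfer_cost by the DP;
        # the primary origin is free, so discount it.
        total -= costs.transfer_cost
    return total, down, forced


def dollo_with_transfers(
    tree: SpeciesTree, leaf_states: dict[str, int], costs: CostModel,
    family: str = "family",
) -> EventScenario:
    """Exact minimum of ``loss_cost * #losses + transfer_cost * #transfers``
    over scenarios with one free primary origin plus transfer re-origins.

    The search is exhaustive over primary-origin placements (every node),
    with a Sankoff DP per placement; ties prefer the origin closest to the
    root in preorder.
    """
    _check_leaf_states(tree, leaf_states)
    if not any(leaf_states.values()):
        states = {n.label: 0 for n in tree.preorder()}
        return _scenario_from_states(tree, states, costs, family)

    best_total, best_origin, best_down, best_forced = math.inf, None, None, None
    for origin in tree.preorder():
        # origins on lineages with no present descendants are never optimal
        total, down, forced = _transfer_solution_for_origin(
            tree, leaf_states, costs, origin
        )
        if total < best_total - 1e-12:
            best_total, best_origin, best_down, best_forced = total, origin, down, forced

    edge_cost = _transfer_edge_cost(costs)
    root_label = tree.root.label
    root_state = best_forced.get(root_label)
    states = _sankoff_backtrace(tree, best_down, edge_cost, root_state=root_state)
    # every 0->1 edge other than the origin's own edge is a transfer
    transfer_edges = set()
    for node in tree.preorder():
        if node.parent is None:
            continue
        if states[node.parent.label] == 0 and states[node.label] == 1:
            if node is not best_origin:
                transfer_edges.add(node.label)
    scenario = _scenario_from_states(
        tree, states, costs, family,
        transfer_edges=frozenset(transfer_edges), donor=best_origin.label,
    )
    return scenario


def _enumerate_transfer_origins(tree, leaf_states, costs, family):
    if not any(leaf_states.values()):
        return [dollo_with_transfers(tree, leaf_states, costs)]
    totals = {}
    for origin in tree.preorder():
        total, _, _ = _transfer_solution_for_origin(tree, leaf_states, costs, origin)
        totals[origin.label] = total
    best = min(totals.values())
    scenarios = []
    edge_cost = _transfer_edge_cost(costs)
    for origin in tree.preorder():
        if totals[origin.label] > best + 1e-12:
            continue
        total, down, forced = _transfer_solution_for_origin(
            tree, leaf_states, costs, origin
        )
        root_state = forced.get(tree.root.label)
        states = _sankoff_backtrace(tree, down, edge_cost, root_state=root_state)
        transfer_edges = {
            node.label
            for node in tree.preorder()
            if node.parent is not None
            and states[node.parent.label] == 0
            and states[node.label] == 1
            and node is not origin
        }
        scenarios.append(
            _scenario_from_states(
                tree, states, costs, family,
                transfer_edges=frozenset(transfer_edges), donor=origin.label,
            )
        )
    return scenarios


# ---------------------------------------------------------------------------
# Event typing across related subfamilies
# ---------------------------------------------------------------------------

def type_events(
    scenarios: dict[str, EventScenario],
    tree: SpeciesTree,
    matrix: Optional[PhyleticMatrix] = None,
    related_families: tuple[str, ...] = ("trmFO", "rlmFO", "trmFO_like"),
) -> dict[str, list[Event]]:
    """Re-type gains as duplications where a sister subfamily already runs in
    the lineage, and append terminal pseudogenization events from the matrix.

    A gain of family B on an edge whose parent node carries sister family A
    becomes a duplication with ``source_family`` A; with several candidate
    sisters the source is reported as ``ambiguous``.
    """
    typed: dict[str, list[Event]] = {}
    for family, scenario in scenarios.items():
        events = []
        for event in scenario.events:
            event = replace(event)
            if event.type == "gain" and family in related_families:
                node = tree.node(event.edge)
                parent_label = node.parent.label if node.parent else node.label
                sisters = [
                    other
                    for other in related_families
                    if other != family
                    and other in scenarios
                    and scenarios[other].node_states.get(parent_label, 0) == 1
                ]
                if sisters:
                    event.type = "duplication"
                    event.source_family = sisters[0] if len(sisters) == 1 else "ambiguous"
            events.append(event)
        if matrix is not None and family in matrix.families:
            for sp in matrix.species:
                cell = matrix.cell(sp, family)
                if cell.status in ("pseudogene", "mixed"):
                    events.append(Event("pseudogenization", sp, family))
        typed[family] = events
    return typed


# ---------------------------------------------------------------------------
# Matrix-level checks
# ---------------------------------------------------------------------------

_OPS = {
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
}


def count_species(
    matrix: PhyleticMatrix,
    families,
    copies: tuple[str, int] = (">=", 1),
    statuses=None,
) -> int:
    """Count species whose total copy number over ``families`` (optionally
    restricted to ``statuses``) satisfies the comparison ``copies``."""
    if isinstance(families, str):
        families = [families]
    for fam in families:
        if fam not in matrix.families:
            raise ValueError(f"unknown family {fam!r}")
    op, value = copies
    if op not in _OPS:
        raise ValueError(f"unknown comparison operator {op!r}")
    if statuses is not None:
        bad = set(statuses) - {"absent", "functional", "pseudogene", "mixed"}
        if bad:
            raise ValueError(f"unknown statuses {sorted(bad)}")
    count = 0
    for sp in matrix.species:
        total = 0
        for fam in families:
            cell = matrix.cell(sp, fam)
            if statuses is None or cell.status in statuses:
                total += cell.copy_count
        if _OPS[op](total, value):
            count += 1
    return count


def mutual_exclusivity(
    matrix: PhyleticMatrix, family_a: str, family_b: str, functional_only: bool = True
) -> dict:
    """Species carrying both families in qualifying status."""
    overlap = []
    for sp in matrix.species:
        cell_a = matrix.cell(sp, family_a)
        cell_b = matrix.cell(sp, family_b)
        if functional_only:
            both = cell_a.has_functional and cell_b.has_functional
        else:
            both = cell_a.present and cell_b.present
        if both:
            overlap.append(sp)
    return {"overlap_count": len(overlap), "species": overlap}


#: site -> families whose functional presence predicts the modification
DEFAULT_GENOTYPE_RULES = {
    "m5U54_tRNA": ("trmFO",),
    "m5U1939_23S": ("rlmD", "rlmFO"),
    "m3U1915_23S": ("rlmH",),
    "m5U747_23S": ("rlmC", "rlmCD"),
}

#: sites where a predicted-but-unmodified outcome is a documented anomaly
#: rather than a pipeline failure (the m3U1915 / RlmH cases).
DOCUMENTED_EXCEPTION_SITES = ("m3U1915_23S",)


@dataclass(frozen=True)
class GenotypePhenotypeVerdict:
    species: str
    site: str
    predicted: str  # present | absent
    observed: str
    verdict: str  # consistent | inconsistent | documented_exception


def genotype_phenotype_check(
    matrix: PhyleticMatrix,
    phenotypes,
    rules=None,
    exception_sites=DOCUMENTED_EXCEPTION_SITES,
) -> list[GenotypePhenotypeVerdict]:
    """Compare predicted modification capacity with assayed phenotypes.

    Records with state ``not_determined`` are skipped. Pseudogenes count as
    absent (nonfunctional).
    """
    rules = rules if rules is not None else DEFAULT_GENOTYPE_RULES
    verdicts = []
    for rec in phenotypes:
        if rec.state == "not_determined" or rec.site not in rules:
            continue
        families = rules[rec.site]
        predicted = (
            "present"
            if any(matrix.cell(rec.species, fam).has_functional for fam in families)
            else "absent"
        )
        if predicted == rec.state:
            verdict = "consistent"
        elif (
            rec.site in exception_sites
            and predicted == "present"
            and rec.state == "absent"
        ):
            verdict = "documented_exception"
        else:
            verdict = "inconsistent"
        verdicts.append(
            GenotypePhenotypeVerdict(rec.species, rec.site, predicted, rec.state, verdict)
        )
    return verdicts
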