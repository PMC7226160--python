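"""Synthetic data generators: gene-content evolution along a tree
(loss / duplication / transfer / pseudogenization as Poisson processes per
active copy) and protein/CDS sequences with planted diagnostic features.

All randomness flows through a single seeded ``numpy.random.Generator``, so
identical seeds give bit-identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import FamilyState, PhyleticMatrix
from .events import Event
from .newick import SpeciesTree

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: codons per amino acid for uniform back-translation
_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}


@dataclass
class SimulationParams:
    loss_rate: float = 0.0
    duplication_rate: float = 0.0
    transfer_rate: float = 0.0
    pseudogenization_rate: float = 0.0
    root_state: FamilyState = field(
        default_factory=lambda: FamilyState(1, "functional")
    )
    seed: int = 0

    def __post_init__(self):
        for name in (
            "loss_rate",
            "duplication_rate",
            "transfer_rate",
            "pseudogenization_rate",
        ):
            rate = getattr(self, name)
            if not np.isfinite(rate) or rate < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {rate}")


@dataclass
class SimulationRun:
    params: SimulationParams
    family: str
    true_events: list[Event]
    leaf_matrix: PhyleticMatrix

    def loss_edges(self) -> set[str]:
        return {e.edge for e in self.true_events if e.type == "loss"}

    def transfer_edges(self) -> set[str]:
        return {e.edge for e in self.true_events if e.type == "transfer"}


def _branch_intervals(tree: SpeciesTree) -> dict[str, tuple[float, float]]:
    """(start, end) depth of every non-root branch; missing lengths are 1."""
    depth = {tree.root.label: 0.0}
    intervals = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        length = node.branch_length if node.branch_length is not None else 1.0
        start = depth[node.parent.label]
        depth[node.label] = start + length
        intervals[node.label] = (start, start + length)
    return intervals


def simulate_gene_content(
    tree: SpeciesTree,
    params: SimulationParams,
    family: str = "simfam",
    rng: Optional[np.random.Generator] = None,
) -> SimulationRun:
    """Evolve copy counts along the tree.

    Per functional copy and unit branch length, losses, duplications,
    transfers and pseudogenizations occur as independent Poisson processes.
    Pseudogene copies are inert (no further events). A transfer inserts one
    functional copy into a uniformly chosen branch alive at the transfer
    time (the donor branch excluded); the transferred copy then evolves
    normally below its insertion point.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    intervals = _branch_intervals(tree)
    total_rate = (
        params.loss_rate
        + params.duplication_rate
        + params.transfer_rate
        + params.pseudogenization_rate
    )
    events: list[Event] = []
    # leaf tallies: label -> [n_functional, n_pseudo]
    leaf_tally = {leaf: [0, 0] for leaf in tree.leaf_labels}
    pending_transfers: list[tuple[str, float]] = []  # (donor edge, time)

    def evolve_branch(label: str, n_functional: int, n_pseudo: int, t_enter: float):
        """Evolve copies along one branch from t_enter to branch end."""
        start, end = intervals[label]
        t_enter = max(t_enter, start)
        nf, np_ = n_functional, n_pseudo
        t = t_enter
        while nf > 0 and total_rate > 0:
            wait = rng.exponential(1.0 / (total_rate * nf))
            t = t + wait
            if t >= end:
                break
            u = rng.uniform(0, total_rate)
            if u < params.loss_rate:
                nf -= 1
                events.append(Event("loss", label, family, cost=0.0, time=t))
            elif u < params.loss_rate + params.duplication_rate:
                nf += 1
                events.append(Event("duplication", label, family, cost=0.0, time=t))
            elif u < params.loss_rate + params.duplication_rate + params.transfer_rate:
                pending_transfers.append((label, t))
            else:
                nf -= 1
                np_ += 1
                events.append(
                    Event("pseudogenization", label, family, cost=0.0, time=t)
                )
        return nf, np_

    def descend(node, n_functional: int, n_pseudo: int, t_enter: float):
        if node.parent is not None:
            n_functional, n_pseudo = evolve_branch(
                node.label, n_functional, n_pseudo, t_enter
            )
        if node.is_leaf:
            leaf_tally[node.label][0] += n_functional
            leaf_tally[node.label][1] += n_pseudo
            return
        for child in node.children:
            descend(child, n_functional, n_pseudo, intervals[child.label][0])

    root_functional, root_pseudo = _split_root_state(params.root_state)
    descend(tree.root, root_functional, root_pseudo, 0.0)

    # resolve transfers breadth-wise; a transferred copy may itself transfer
    guard = 0
    while pending_transfers:
        guard += 1
        if guard > 10_000:
            raise RuntimeError("transfer cascade did not terminate")
        donor, t = pending_transfers.pop(0)
        recipients = [
            label
            for label, (start, end) in intervals.items()
            if start <= t < end and label != donor
        ]
        if not recipients:
            continue
        recipient = recipients[rng.integers(0, len(recipients))]
        events.append(
            Event("transfer", recipient, family, donor=donor, cost=0.0, time=t)
        )
        node = tree.node(recipient)
        nf, np_ = evolve_branch(recipient, 1, 0, t)
        if node.is_leaf:
            leaf_tally[node.label][0] += nf
            leaf_tally[node.label][1] += np_
        else:
            for child in node.children:
                descend(child, nf, np_, intervals[child.label][0])

    events.sort(key=lambda e: (e.time if e.time is not None else 0.0))
    cells = {}
    for leaf, (nf, np_) in leaf_tally.items():
        cells[(leaf, family)] = _tally_state(nf, np_)
    matrix = PhyleticMatrix(tree.leaf_labels, [family], cells)
    return SimulationRun(params, family, events, matrix)


def _split_root_state(state: FamilyState) -> tuple[int, int]:
    """(functional, pseudo) copy counts implied by a root FamilyState."""
    if state.status in ("absent", "functional"):
        return state.copy_count, 0
    if state.status == "pseudogene":
        return 0, state.copy_count
    return state.copy_count - 1, 1  # mixed: at least one of each


def _tally_state(n_functional: int, n_pseudo: int) -> FamilyState:
    total = n_functional + n_pseudo
    if total == 0:
        return FamilyState(0, "absent")
    if n_pseudo == 0:
        return FamilyState(total, "functional")
    if n_functional == 0:
        return FamilyState(total, "pseudogene")
    return FamilyState(total, "mixed")


def replay_gene_content(
    tree: SpeciesTree, root_state: FamilyState, events: list[Event], family: str
) -> PhyleticMatrix:
    """Deterministically re-derive the leaf matrix from a true-event log."""
    by_edge: dict[str, list[Event]] = {}
    for e in events:
        by_edge.setdefault(e.edge, []).append(e)
    for edge_events in by_edge.values():
        edge_events.sort(key=lambda e: e.time if e.time is not None else 0.0)

    nf0, np0 = _split_root_state(root_state)

    tallies: dict[str, tuple[int, int]] = {}

    def apply_edge(label, nf, np_):
        for e in by_edge.get(label, ()):
            if e.type == "loss":
                nf -= 1
            elif e.type == "duplication":
                nf += 1
            elif e.type == "pseudogenization":
                nf -= 1
                np_ += 1
            elif e.type == "transfer":
                nf += 1
        return nf, np_

    def descend(node, nf, np_):
        if node.parent is not None:
            nf, np_ = apply_edge(node.label, nf, np_)
        if node.is_leaf:
            prev = tallies.get(node.label, (0, 0))
            tallies[node.label] = (prev[0] + nf, prev[1] + np_)
            return
        for child in node.children:
            descend(child, nf, np_)

    descend(tree.root, nf0, np0)
    cells = {
        (leaf, family): _tally_state(*tallies.get(leaf, (0, 0)))
        for leaf in tree.leaf_labels
    }
    return PhyleticMatrix(tree.leaf_labels, [family], cells)


# ---------------------------------------------------------------------------
# Protein / CDS simulation
# ---------------------------------------------------------------------------

#: reference-frame landmarks used when planting diagnostics (1-based)
FAD_MOTIF_START = 8
CATALYTIC_POSITIONS = (51, 223)
FOLATE_TRIAD_POSITIONS = (308, 309, 310)
FLAVIN_STACK_POSITION = 343

SUBFAMILIES = ("TrmFO", "RlmFO", "TrmFO_like")


def diagnostic_positions() -> frozenset[int]:
    """1-based positions that noise must never touch."""
    motif = range(FAD_MOTIF_START, FAD_MOTIF_START + 9)
    return frozenset(motif) | frozenset(CATALYTIC_POSITIONS) | frozenset(
        FOLATE_TRIAD_POSITIONS
    ) | {FLAVIN_STACK_POSITION}


def _packaged_reference_sequence() -> str:
    from importlib import resources
    import json

    meta = json.loads(
        resources.files("m5uevo.data").joinpath("reference.json").read_text()
    )
    return meta["reference"]["sequence"]


_TEMPLATE_CACHE: dict[str, str] = {}


def simulate_protein(
    subfamily: str,
    length: int = 443,
    noise: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    with_cds: bool = False,
    pseudogenize: bool = False,
    template: Optional[str] = None,
):
    """Protein with subfamily diagnostics planted at reference-frame
    positions: C/C (TrmFO, RlmFO) or Y/Y (TrmFO_like) at the catalytic
    sites, the FAD motif, the folate triad (H,R,N; H,K,N for TrmFO_like)
    and the flavin-stacking Y.

    The sequence is scaffolded on the packaged alignment reference (or a
    supplied ``template``) so that reference-coordinate mapping is
    well-defined; ``noise`` substitutes non-diagnostic positions only.
    Shorter lengths trim the C-terminus (mirroring the shorter TrmFO_like
    homologs); longer lengths pad it with random residues. Returns the
    protein, or ``(protein, cds)`` when ``with_cds``.
    """
    if subfamily not in SUBFAMILIES:
        raise ValueError(f"unknown subfamily {subfamily!r}")
    if length < 350:
        raise ValueError(f"length must be >= 350 to host position 343, got {length}")
    if not (0 <= noise < 1):
        raise ValueError(f"noise must be in [0, 1), got {noise}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if template is None:
        if "default" not in _TEMPLATE_CACHE:
            _TEMPLATE_CACHE["default"] = _packaged_reference_sequence()
        template = _TEMPLATE_CACHE["default"]
    seq = list(template[:length])
    if length > len(template):
        seq.extend(rng.choice(list(AA_ALPHABET), size=length - len(template)))

    motif = "GAGTAGLEA"  # matches GAGx[A/S]Gx E[A/V]
    seq[FAD_MOTIF_START - 1 : FAD_MOTIF_START - 1 + 9] = list(motif)
    catalytic = "Y" if subfamily == "TrmFO_like" else "C"
    for pos in CATALYTIC_POSITIONS:
        seq[pos - 1] = catalytic
    triad = ("H", "K", "N") if subfamily == "TrmFO_like" else ("H", "R", "N")
    for pos, res in zip(FOLATE_TRIAD_POSITIONS, triad):
        seq[pos - 1] = res
    seq[FLAVIN_STACK_POSITION - 1] = "Y"
    # avoid spurious FAD-motif or stop-like artifacts is unnecessary: the
    # motif scan tolerates extra matches and diagnostics are positional.

    if noise > 0:
        protected = diagnostic_positions()
        for pos in range(1, length + 1):
            if pos in protected:
                continue
            if rng.random() < noise:
                current = seq[pos - 1]
                alternatives = [a for a in AA_ALPHABET if a != current]
                seq[pos - 1] = alternatives[rng.integers(0, len(alternatives))]
    protein = "".join(seq)
    if not with_cds:
        return protein
    codons = [
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein
    ]
    if pseudogenize:
        codons[len(codons) // 2] = "TAA"
    codons.append("TAA")
    return protein, "".join(codons)
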