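"""Core domain types: phyletic matrix cells, gene neighborhoods, phenotypes,
and the annotated alignment reference."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

FAMILIES = (
    "thyA",
    "tdk",
    "trmA",
    "rlmC",
    "rlmD",
    "rlmCD",
    "yfjO",
    "trmFO",
    "rlmFO",
    "trmFO_like",
    "rlmH",
)

STATUSES = ("absent", "functional", "pseudogene", "mixed")

#: Families descending from the flavin/folate-dependent methyltransferase
#: ancestor (COG1206); used for the carrier counts and subfamily typing.
COG1206_FAMILIES = ("trmFO", "rlmFO", "trmFO_like")


@dataclass(frozen=True)
class FamilyState:
    """Copy count plus functional status of one gene family in one genome."""

    copy_count: int = 0
    status: str = "absent"
    member_ids: tuple[str, ...] = ()
    provenance: Optional[str] = None

    def __post_init__(self):
        if self.copy_count < 0:
            raise ValueError(f"negative copy_count {self.copy_count}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.copy_count == 0) != (self.status == "absent"):
            raise ValueError(
                f"copy_count {self.copy_count} inconsistent with status {self.status!r}"
            )
        if self.status == "mixed" and self.copy_count < 2:
            raise ValueError("status 'mixed' requires copy_count >= 2")

    @property
    def has_functional(self) -> bool:
        return self.status in ("functional", "mixed")

    @property
    def present(self) -> bool:
        """Present in any state, pseudogenes included."""
        return self.copy_count > 0


class PhyleticMatrix:
    """Species x family grid of :class:`FamilyState` cells.

    Every (species, family) pair has exactly one cell; missing combinations
    are rejected at construction so downstream counts never silently default.
    """

    def __init__(self, species, families, cells):
        self.species = list(species)
        self.families = list(families)
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species identifiers")
        if len(set(self.families)) != len(self.families):
            raise ValueError("duplicate family identifiers")
        self.cells: dict[tuple[str, str], FamilyState] = dict(cells)
        for sp in self.species:
            for fam in self.families:
                if (sp, fam) not in self.cells:
                    raise ValueError(f"missing cell ({sp}, {fam})")
        extra = set(self.cells) - {
            (sp, fam) for sp in self.species for fam in self.families
        }
        if extra:
            raise ValueError(f"cells outside the species x family grid: {sorted(extra)}")

    def cell(self, species: str, family: str) -> FamilyState:
        if family not in self.families:
            raise KeyError(f"unknown family {family!r}")
        if species not in self.species:
            raise KeyError(f"unknown species {species!r}")
        return self.cells[(species, family)]

    def column(self, family: str) -> dict[str, FamilyState]:
        if family not in self.families:
            raise KeyError(f"unknown family {family!r}")
        return {sp: self.cells[(sp, family)] for sp in self.species}

    def binary_leaf_states(self, family: str, pseudogene_is_present: bool = True):
        """Presence/absence map for one family, for parsimony input.

        Pseudogenes witness historical presence and default to ``present``.
        """
        out = {}
        for sp, state in self.column(family).items():
            if pseudogene_is_present:
                out[sp] = 1 if state.present else 0
            else:
                out[sp] = 1 if state.has_functional else 0
        return out

    def __eq__(self, other):
        return (
            isinstance(other, PhyleticMatrix)
            and self.species == other.species
            and self.families == other.families
            and self.cells == other.cells
        )


@dataclass(frozen=True)
class NeighborGene:
    ortholog_family: str
    strand: str
    offset: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.offset == 0:
            raise ValueError("neighbor offset must be nonzero")


@dataclass
class GeneNeighborhood:
    """Ordered flanking genes around an anchor, offsets in gene ranks."""

    anchor_gene: str
    neighbors: list[NeighborGene] = field(default_factory=list)

    def __post_init__(self):
        offsets = [n.offset for n in self.neighbors]
        if len(set(offsets)) != len(offsets):
            raise ValueError(f"duplicate offsets around anchor {self.anchor_gene}")
        self.neighbors.sort(key=lambda n: n.offset)

    def family_set(self, k: Optional[int] = None) -> frozenset[str]:
        """Ortholog families within +/- k genes (strand and order ignored)."""
        if k is not None and k < 1:
            raise ValueError(f"window k must be >= 1, got {k}")
        return frozenset(
            n.ortholog_family
            for n in self.neighbors
            if k is None or abs(n.offset) <= k
        )


@dataclass(frozen=True)
class ModificationPhenotype:
    species: str
    site: str
    state: str  # present | absent | not_determined

    SITES = ("m5U54_tRNA", "m5U1939_23S", "Cm1920_23S", "m3U1915_23S", "m5U747_23S")

    def __post_init__(self):
        if self.site not in self.SITES:
            raise ValueError(f"unknown modification site {self.site!r}")
        if self.state not in ("present", "absent", "not_determined"):
            raise ValueError(f"unknown phenotype state {self.state!r}")


@dataclass(frozen=True)
class ReferenceAnnotation:
    """1-based landmark positions in the alignment reference protein."""

    reference_id: str
    sequence: str
    catalytic_positions: tuple[int, int] = (51, 223)
    folate_triad_positions: tuple[int, int, int] = (308, 309, 310)
    flavin_stack_position: int = 343
    fad_motif_pattern: str = "GAG[A-Z][AS]G[A-Z]E[AV]"

    def __post_init__(self):
        top = max(
            max(self.catalytic_positions),
            max(self.folate_triad_positions),
            self.flavin_stack_position,
        )
        if len(self.sequence) < top:
            raise ValueError(
                f"reference sequence ({len(self.sequence)} aa) shorter than "
                f"annotated position {top}"
            )
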