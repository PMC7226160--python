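"""File I/O: TSV dialects for phyletic matrices, neighborhoods and
phenotypes; FASTA; and the packaged 39-species reference dataset.

TSV dialects (single header line, tab separated):

* phyletic matrix: ``species  family  copy_count  status  member_ids  provenance``
  (``member_ids`` semicolon-joined, empty allowed)
* neighborhoods: ``anchor  offset  ortholog_family  strand``
* phenotypes: ``species  site  state``
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from Bio import SeqIO

from .datamodel import (
    FamilyState,
    GeneNeighborhood,
    ModificationPhenotype,
    NeighborGene,
    PhyleticMatrix,
    ReferenceAnnotation,
)
from .newick import SpeciesTree, parse_newick, write_newick


class FormatError(ValueError):
    pass


def _rows(path) -> Iterable[tuple[int, dict]]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        for i, row in enumerate(reader, start=2):
            yield i, row


def read_phyletic_tsv(path) -> PhyleticMatrix:
    species: list[str] = []
    families: list[str] = []
    cells = {}
    for lineno, row in _rows(path):
        try:
            sp = row["species"]
            fam = row["family"]
            copy_count = int(row["copy_count"])
            status = row["status"]
            members = tuple(m for m in (row.get("member_ids") or "").split(";") if m)
            provenance = row.get("provenance") or None
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {lineno}: {exc}") from None
        if (sp, fam) in cells:
            raise FormatError(f"{path}: row {lineno}: duplicate cell ({sp}, {fam})")
        try:
            cells[(sp, fam)] = FamilyState(copy_count, status, members, provenance)
        except ValueError as exc:
            raise FormatError(f"{path}: row {lineno}: {exc}") from None
        if sp not in species:
            species.append(sp)
        if fam not in families:
            families.append(fam)
    try:
        return PhyleticMatrix(species, families, cells)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_phyletic_tsv(matrix: PhyleticMatrix, path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["species", "family", "copy_count", "status", "member_ids", "provenance"]
        )
        for sp in matrix.species:
            for fam in matrix.families:
                cell = matrix.cells[(sp, fam)]
                writer.writerow(
                    [
                        sp,
                        fam,
                        cell.copy_count,
                        cell.status,
                        ";".join(cell.member_ids),
                        cell.provenance or "",
                    ]
                )


def read_neighborhoods_tsv(path) -> dict[str, GeneNeighborhood]:
    grouped: dict[str, list[NeighborGene]] = {}
    for lineno, row in _rows(path):
        try:
            anchor = row["anchor"]
            neighbor = NeighborGene(
                ortholog_family=row["ortholog_family"],
                strand=row["strand"],
                offset=int(row["offset"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {lineno}: {exc}") from None
        grouped.setdefault(anchor, []).append(neighbor)
    out = {}
    for anchor, neighbors in grouped.items():
        try:
            out[anchor] = GeneNeighborhood(anchor, neighbors)
        except ValueError as exc:
            raise FormatError(f"{path}: anchor {anchor}: {exc}") from None
    return out


def write_neighborhoods_tsv(neighborhoods: dict[str, GeneNeighborhood], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["anchor", "offset", "ortholog_family", "strand"])
        for anchor in neighborhoods:
            for n in neighborhoods[anchor].neighbors:
                writer.writerow([anchor, n.offset, n.ortholog_family, n.strand])


def read_phenotypes_tsv(path) -> list[ModificationPhenotype]:
    records = []
    seen = set()
    for lineno, row in _rows(path):
        try:
            rec = ModificationPhenotype(row["species"], row["site"], row["state"])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: row {lineno}: {exc}") from None
        if (rec.species, rec.site) in seen:
            raise FormatError(
                f"{path}: row {lineno}: duplicate record ({rec.species}, {rec.site})"
            )
        seen.add((rec.species, rec.site))
        records.append(rec)
    return records


def write_phenotypes_tsv(records: list[ModificationPhenotype], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["species", "site", "state"])
        for rec in records:
            writer.writerow([rec.species, rec.site, rec.state])


def read_fasta(path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_tree(path) -> SpeciesTree:
    with open(path) as handle:
        return parse_newick(handle.read())


def write_tree(tree: SpeciesTree, path) -> None:
    with open(path, "w") as handle:
        handle.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Packaged reference dataset
# ---------------------------------------------------------------------------

#: Internal node labels cited in the curated evolutionary scenario.
CITED_NODE_LABELS = ("2", "3", "12", "19", "27", "28", "33", "34", "36", "37", "38")

GROUP_ROOTS = {"S": "36", "H": "27", "P": "12", "AAP": "3"}
MYCOIDES_ROOT = "33"


@dataclass
class ReferenceDataset:
    tree: SpeciesTree
    matrix: PhyleticMatrix
    neighborhoods: dict[str, GeneNeighborhood]
    phenotypes: list[ModificationPhenotype]
    reference_annotation: ReferenceAnnotation
    metadata: dict

    def group_of(self, species: str) -> str:
        node = self.tree.node(species)
        while node is not None:
            for tag, root_label in GROUP_ROOTS.items():
                if node.label == root_label:
                    return tag
            node = node.parent
        raise KeyError(f"species {species!r} not under any tagged group root")

    def species_in_group(self, tag: str) -> list[str]:
        root = GROUP_ROOTS[tag]
        return sorted(self.tree.leaf_set_under(root))


class IntegrityError(RuntimeError):
    pass


def _data_path(name: str):
    return resources.files("m5uevo.data").joinpath(name)


def load_reference_dataset() -> ReferenceDataset:
    """Load the packaged curated 39-species dataset and verify its anchors."""
    tree = parse_newick(_data_path("species_tree.nwk").read_text())
    matrix = read_phyletic_tsv(_data_path("phyletic_matrix.tsv"))
    neighborhoods = read_neighborhoods_tsv(_data_path("neighborhoods.tsv"))
    phenotypes = read_phenotypes_tsv(_data_path("phenotypes.tsv"))
    meta = json.loads(_data_path("reference.json").read_text())
    annotation = ReferenceAnnotation(
        reference_id=meta["reference"]["id"],
        sequence=meta["reference"]["sequence"],
        catalytic_positions=tuple(meta["reference"]["catalytic_positions"]),
        folate_triad_positions=tuple(meta["reference"]["folate_triad_positions"]),
        flavin_stack_position=meta["reference"]["flavin_stack_position"],
        fad_motif_pattern=meta["reference"]["fad_motif_pattern"],
    )

    # Hard text-anchored integrity checks; a corrupted package fails loudly.
    leaves = set(tree.leaf_labels)
    if len(leaves) != 39:
        raise IntegrityError(f"expected 39 leaves, found {len(leaves)}")
    if leaves != set(matrix.species):
        raise IntegrityError("tree leaf set differs from matrix species set")
    for label in CITED_NODE_LABELS:
        if label not in tree:
            raise IntegrityError(f"missing cited internal node label {label}")
    if any(matrix.cell(sp, "trmA").present for sp in matrix.species):
        raise IntegrityError("trmA must be absent in all species")
    if any(matrix.cell(sp, "rlmC").present for sp in matrix.species):
        raise IntegrityError("rlmC must be absent in all species")
    if matrix.cell("Acholeplasma_laidlawii", "rlmD").copy_count != 4:
        raise IntegrityError("A. laidlawii must carry 4 rlmD homologs")
    lacking_tdk = [sp for sp in matrix.species if not matrix.cell(sp, "tdk").present]
    if lacking_tdk != ["Mycoplasma_bovigenitalium_cl-51080"]:
        raise IntegrityError(f"unexpected tdk-lacking species {lacking_tdk}")

    # Tag group roots so downstream code can restrict counts by group.
    for tag, root_label in GROUP_ROOTS.items():
        node = tree.node(root_label)
        node.group_tag = tag
    for node in tree.node(MYCOIDES_ROOT).preorder():
        node.mycoides_cluster = True

    return ReferenceDataset(tree, matrix, neighborhoods, phenotypes, annotation, meta)
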