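"""Subfamily assignment for flavin/folate-dependent methyltransferase
homologs.

A query protein is globally aligned to the annotated reference, diagnostic
residues are read off at reference-mapped positions, and the decision rules
combine the residue signature with neighborhood-conservation scores:

1. tyrosines at both catalytic positions -> TrmFO_like;
2. cysteines at both positions and a conserved rRNA-enzyme context -> RlmFO;
3. cysteines and a conserved tRNA-enzyme context -> TrmFO;
4. cysteines and a gene-tree clade label -> that label;
5. otherwise ambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .datamodel import ReferenceAnnotation
from .synteny import CONTEXT_THRESHOLD

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
FAD_MOTIF_RE = re.compile("GAG[A-Z][AS]G[A-Z]E[AV]")
STOP_CODONS = {"TAA", "TAG", "TGA"}

GAP_OPEN = -11.0
GAP_EXTEND = -1.0


@dataclass
class PairwiseAlignment:
    query_id: str
    reference_id: str
    aligned_query: str
    aligned_reference: str
    score: float
    #: 1-based reference position -> 1-based query position, or None on gap.
    column_map: dict[int, Optional[int]] = field(default_factory=dict)


@dataclass(frozen=True)
class ResidueSignature:
    residue_at_51: str
    residue_at_223: str
    fad_motif_found: bool
    folate_triad_found: bool
    flavin_stack_Y343: bool


@dataclass
class SubfamilyCall:
    protein_id: str
    subfamily: str
    signature: ResidueSignature
    pseudogene: bool = False
    evidence: list[str] = field(default_factory=list)


def _check_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"{name}: illegal characters {sorted(bad)}")
    return seq


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def global_align(
    query: str, reference: str, query_id: str = "query", reference_id: str = "reference"
) -> PairwiseAlignment:
    """Optimal global alignment (BLOSUM62, affine 11/1).

    Ties are broken deterministically by taking the first alignment in the
    aligner's canonical traceback order.
    """
    query = _check_protein(query, query_id)
    reference = _check_protein(reference, reference_id)
    alignment = _make_aligner().align(query, reference)[0]
    indices = alignment.indices  # rows: query, reference; -1 marks gaps
    column_map: dict[int, Optional[int]] = {}
    aligned_q = []
    aligned_r = []
    for qi, ri in zip(indices[0], indices[1]):
        aligned_q.append(query[qi] if qi >= 0 else "-")
        aligned_r.append(reference[ri] if ri >= 0 else "-")
        if ri >= 0:
            column_map[int(ri) + 1] = int(qi) + 1 if qi >= 0 else None
    return PairwiseAlignment(
        query_id=query_id,
        reference_id=reference_id,
        aligned_query="".join(aligned_q),
        aligned_reference="".join(aligned_r),
        score=float(alignment.score),
        column_map=column_map,
    )


def scan_fad_motif(seq: str) -> list[int]:
    """0-based start offsets of all non-overlapping FAD-pyrophosphate motif
    matches (G,A,G,x,[A/S],G,x,E,[A/V])."""
    return [m.start() for m in FAD_MOTIF_RE.finditer(seq.upper())]


def extract_signature(
    alignment: PairwiseAlignment, annotation: ReferenceAnnotation, query: str
) -> ResidueSignature:
    """Read diagnostic residues at reference-mapped positions.

    A reference position spanned by a deletion in the query reads "deleted".
    """
    if alignment.reference_id != annotation.reference_id:
        raise ValueError(
            f"alignment reference {alignment.reference_id!r} does not match "
            f"annotation {annotation.reference_id!r}"
        )
    query = _check_protein(query, alignment.query_id)
    if alignment.aligned_query.replace("-", "") != query:
        raise ValueError("query sequence does not match the aligned query")

    def residue_at(ref_pos: int) -> str:
        qpos = alignment.column_map.get(ref_pos)
        return query[qpos - 1] if qpos is not None else "deleted"

    pos51, pos223 = annotation.catalytic_positions
    triad = [residue_at(p) for p in annotation.folate_triad_positions]
    triad_ok = (
        triad[0] == "H" and triad[1] in ("R", "K") and triad[2] == "N"
    )
    return ResidueSignature(
        residue_at_51=residue_at(pos51),
        residue_at_223=residue_at(pos223),
        fad_motif_found=bool(re.search(annotation.fad_motif_pattern, query)),
        folate_triad_found=triad_ok,
        flavin_stack_Y343=residue_at(annotation.flavin_stack_position) == "Y",
    )


@dataclass(frozen=True)
class PseudogeneVerdict:
    pseudogene: bool
    reason: Optional[str] = None


def detect_pseudogene(cds: str, reference_protein_length: int) -> PseudogeneVerdict:
    """Flag degraded coding sequences.

    Rules: non-multiple-of-3 length suggests a frameshift; an in-frame stop
    before 80% of the reference length is a premature stop; a CDS shorter
    than 60% of the reference length is a truncation.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError(f"CDS too short ({len(cds)} nt)")
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValueError(f"illegal CDS characters {sorted(bad)}")
    if len(cds) % 3 != 0:
        return PseudogeneVerdict(True, "length_frame")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for codon_index, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if codon_index < 0.8 * reference_protein_length:
                return PseudogeneVerdict(True, "premature_stop")
            break
    if len(cds) < 0.6 * reference_protein_length * 3:
        return PseudogeneVerdict(True, "truncation")
    return PseudogeneVerdict(False, None)


def classify_subfamily(
    signature: ResidueSignature,
    synteny_scores: Optional[dict] = None,
    gene_tree_clade: Optional[str] = None,
    pseudogene: bool = False,
    protein_id: str = "query",
    threshold: float = CONTEXT_THRESHOLD,
) -> SubfamilyCall:
    """Apply the ordered decision rules; ``ambiguous`` is a valid outcome."""
    scores = synteny_scores or {}
    trmfo_ctx = scores.get("trmfo_context")
    rlmfo_ctx = scores.get("rlmfo_context")
    res = (signature.residue_at_51, signature.residue_at_223)
    evidence: list[str] = []
    subfamily = "ambiguous"
    if res == ("Y", "Y"):
        subfamily = "TrmFO_like"
        evidence.append("catalytic_YY")
    elif res == ("C", "C"):
        evidence.append("catalytic_CC")
        if (
            rlmfo_ctx is not None
            and rlmfo_ctx >= threshold
            and (trmfo_ctx is None or rlmfo_ctx >= threshold > trmfo_ctx)
        ):
            subfamily = "RlmFO"
            evidence.append("rlmfo_context")
        elif trmfo_ctx is not None and trmfo_ctx >= threshold:
            subfamily = "TrmFO"
            evidence.append("trmfo_context")
        elif gene_tree_clade in ("TrmFO", "RlmFO", "TrmFO_like"):
            subfamily = gene_tree_clade
            evidence.append("gene_tree_clade")
    if subfamily == "ambiguous":
        evidence.append("rule_fallthrough")
    return SubfamilyCall(
        protein_id=protein_id,
        subfamily=subfamily,
        signature=signature,
        pseudogene=pseudogene,
        evidence=evidence,
    )


def classify_protein(
    protein_id: str,
    sequence: str,
    annotation: ReferenceAnnotation,
    synteny_scores: Optional[dict] = None,
    gene_tree_clade: Optional[str] = None,
    cds: Optional[str] = None,
) -> SubfamilyCall:
    """End-to-end: align, extract signature, optionally check the CDS."""
    alignment = global_align(
        sequence, annotation.sequence, query_id=protein_id,
        reference_id=annotation.reference_id,
    )
    signature = extract_signature(alignment, annotation, sequence.upper())
    pseudo = False
    if cds is not None:
        pseudo = detect_pseudogene(cds, len(annotation.sequence)).pseudogene
    return classify_subfamily(
        signature,
        synteny_scores=synteny_scores,
        gene_tree_clade=gene_tree_clade,
        pseudogene=pseudo,
        protein_id=protein_id,
    )
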