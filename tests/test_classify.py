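import numpy as np
import pytest

from m5uevo import (
    classify_protein,
    classify_subfamily,
    detect_pseudogene,
    extract_signature,
    global_align,
    scan_fad_motif,
    simulate_protein,
)
from m5uevo.classify import ResidueSignature


def _sig(res51, res223, **kw):
    defaults = dict(fad_motif_found=True, folate_triad_found=True, flavin_stack_Y343=True)
    defaults.update(kw)
    return ResidueSignature(res51, res223, **defaults)


# --- motif scan -------------------------------------------------------------

def test_fad_motif_found_at_offset():
    assert scan_fad_motif("K" * 10 + "GAGTAGLEA" + "K" * 5) == [10]


def test_fad_motif_rejects_bad_fifth_position():
    assert scan_fad_motif("K" * 10 + "GAGTTGLEA") == []


def test_fad_motif_empty_on_blank_sequence():
    assert scan_fad_motif("K" * 50) == []


# --- signature extraction ---------------------------------------------------

def test_reference_self_alignment_signature(ref):
    ann = ref.reference_annotation
    aln = global_align(ann.sequence, ann.sequence, reference_id=ann.reference_id)
    sig = extract_signature(aln, ann, ann.sequence)
    assert (sig.residue_at_51, sig.residue_at_223) == ("C", "C")
    assert sig.fad_motif_found and sig.folate_triad_found and sig.flavin_stack_Y343


def test_planted_tyrosines_detected(ref):
    ann = ref.reference_annotation
    query = simulate_protein("TrmFO_like", seed=7)
    aln = global_align(query, ann.sequence, reference_id=ann.reference_id)
    sig = extract_signature(aln, ann, query)
    assert (sig.residue_at_51, sig.residue_at_223) == ("Y", "Y")


def test_deletion_spanning_position_51(ref):
    ann = ref.reference_annotation
    query = ann.sequence[:40] + ann.sequence[60:]  # remove 41..60 inclusive
    aln = global_align(query, ann.sequence, reference_id=ann.reference_id)
    sig = extract_signature(aln, ann, query)
    assert sig.residue_at_51 == "deleted"
    assert sig.residue_at_223 == "C"


def test_signature_invariant_to_flanking_padding(ref):
    ann = ref.reference_annotation
    core = simulate_protein("TrmFO", seed=11)
    rng = np.random.default_rng(12)
    pad5 = "".join(rng.choice(list("KNDE"), size=25))
    pad3 = "".join(rng.choice(list("KNDE"), size=30))
    for query in (core, pad5 + core + pad3):
        aln = global_align(query, ann.sequence, reference_id=ann.reference_id)
        sig = extract_signature(aln, ann, query)
        assert (sig.residue_at_51, sig.residue_at_223) == ("C", "C")
        assert sig.folate_triad_found


def test_reference_mismatch_rejected(ref):
    ann = ref.reference_annotation
    aln = global_align("ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY" * 9, ann.sequence,
                       reference_id="some_other_reference")
    with pytest.raises(ValueError, match="does not match"):
        extract_signature(aln, ann, "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY" * 9)


# --- pseudogene detection ---------------------------------------------------

def test_full_length_cds_with_terminal_stop_is_functional():
    _, cds = simulate_protein("TrmFO", seed=3, with_cds=True)
    verdict = detect_pseudogene(cds, 443)
    assert not verdict.pseudogene


def test_premature_stop():
    cds = "ATG" + "GCT" * 48 + "TAA" + "GCT" * 390
    verdict = detect_pseudogene(cds, 440)
    assert verdict.pseudogene and verdict.reason == "premature_stop"


def test_truncation():
    cds = "ATG" + "GCT" * 219  # half of a 440-codon reference
    verdict = detect_pseudogene(cds, 440)
    assert verdict.pseudogene and verdict.reason == "truncation"


def test_frameshift_suspect():
    verdict = detect_pseudogene("ATGGCTGC", 440)
    assert verdict.pseudogene and verdict.reason == "length_frame"


def test_simulated_pseudogenized_cds_detected():
    _, cds = simulate_protein("RlmFO", seed=5, with_cds=True, pseudogenize=True)
    assert detect_pseudogene(cds, 443).pseudogene


# --- decision rules ---------------------------------------------------------

def test_yy_always_trmfo_like():
    call = classify_subfamily(_sig("Y", "Y"), {"trmfo_context": 0.9, "rlmfo_context": 0.9})
    assert call.subfamily == "TrmFO_like"


def test_cc_with_trmfo_context():
    call = classify_subfamily(_sig("C", "C"), {"trmfo_context": 0.6, "rlmfo_context": 0.1})
    assert call.subfamily == "TrmFO"


def test_cc_with_rlmfo_context():
    call = classify_subfamily(_sig("C", "C"), {"trmfo_context": 0.1, "rlmfo_context": 0.6})
    assert call.subfamily == "RlmFO"


def test_cc_with_clade_fallback():
    call = classify_subfamily(_sig("C", "C"), gene_tree_clade="RlmFO")
    assert call.subfamily == "RlmFO"
    assert "gene_tree_clade" in call.evidence


def test_mixed_residues_fall_through_to_ambiguous():
    call = classify_subfamily(_sig("C", "Y"))
    assert call.subfamily == "ambiguous"


def test_end_to_end_classification(ref):
    ann = ref.reference_annotation
    protein = simulate_protein("TrmFO_like", seed=21)
    call = classify_protein("q1", protein, ann)
    assert call.subfamily == "TrmFO_like"
    protein2, cds2 = simulate_protein("TrmFO", seed=22, with_cds=True, pseudogenize=True)
    call2 = classify_protein(
        "q2", protein2, ann, synteny_scores={"trmfo_context": 0.7}, cds=cds2
    )
    assert call2.subfamily == "TrmFO"
    assert call2.pseudogene
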