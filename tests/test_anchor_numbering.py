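"""Anchored alignment, helix annotation and Ballesteros-Weinstein numbering."""

import pytest

from seventm.seq import (Alignment, AnchorError, GAP, HelixAnnotation,
                         HelixNotFoundError, SequenceRecord, anchor_alignment,
                         annotate_helices, assign_bw)
from seventm.synth import make_gpcr_sequence


def test_anchor_alignment_idempotent_on_registered_input():
    aln = Alignment(rows=[("r1", "AAWAA"), ("r2", "KKWKK")])
    anns = [[HelixAnnotation(4, 2, 4, 3)], [HelixAnnotation(4, 2, 4, 3)]]
    out = anchor_alignment(aln, anns)
    assert [r[1] for r in out.rows] == ["AAWAA", "KKWKK"]


def test_anchor_alignment_shifts_single_gap():
    aln = Alignment(rows=[("r1", "AAWAAA"), ("r2", "WAAAAA")])
    anns = [[HelixAnnotation(4, 3, 4, 3)], [HelixAnnotation(4, 1, 2, 1)]]
    out = anchor_alignment(aln, anns)
    col1 = out.rows[0][1].replace(GAP, " ").index("W")
    col2 = out.rows[1][1].replace(GAP, " ").index("W")
    assert col1 == col2
    for (name, gapped), (_, original) in zip(out.rows, aln.rows):
        assert gapped.replace(GAP, "") == original.replace(GAP, "")


def test_anchor_alignment_on_motif_scaffold_sequences(patterns):
    rec1, t1 = make_gpcr_sequence(seed=11)
    rec2, t2 = make_gpcr_sequence(
        seed=12, inter_motif_lengths=[12] + [30] * 6 + [8])
    width = max(len(rec1), len(rec2))
    aln = Alignment(rows=[(rec1.id, rec1.residues.ljust(width, GAP)),
                          (rec2.id, rec2.residues.ljust(width, GAP))])
    anns = [annotate_helices(rec1, patterns), annotate_helices(rec2, patterns)]
    out = anchor_alignment(aln, anns)
    for h in range(7):
        c1 = out.column_of(0, anns[0][h].anchor)
        c2 = out.column_of(1, anns[1][h].anchor)
        assert c1 == c2, f"helix {h + 1} anchors not in register"
    assert out.ungapped(0) == rec1.residues
    assert out.ungapped(1) == rec2.residues
    again = anchor_alignment(out, anns)
    assert [r[1] for r in again.rows] == [r[1] for r in out.rows]


def test_anchor_alignment_rejects_mismatched_helix_sets():
    aln = Alignment(rows=[("r1", "AAWAA"), ("r2", "KKWKK")])
    anns = [[HelixAnnotation(4, 2, 4, 3)], [HelixAnnotation(5, 2, 4, 3)]]
    with pytest.raises(AnchorError):
        anchor_alignment(aln, anns)


def test_annotate_recovers_generator_anchors(patterns, gpcr_sequence):
    rec, truth = gpcr_sequence
    anns = annotate_helices(rec, patterns)
    assert {a.helix_id: a.anchor for a in anns} == truth.anchors
    spans = sorted((a.start, a.end) for a in anns)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 < s2, "helix spans overlap"


def test_missing_helix_motif_names_the_helix(patterns):
    rec, _ = make_gpcr_sequence(seed=3)
    # excise the helix-4 tryptophan: W only occurs in the h4/h6 motifs here
    mangled = rec.residues.replace("W", "A", 1)
    seq = SequenceRecord("no_h4", mangled)
    with pytest.raises(HelixNotFoundError, match="helix 4"):
        annotate_helices(seq, patterns)


def test_assign_bw_definition_and_bijection(patterns, gpcr_sequence):
    rec, truth = gpcr_sequence
    anns = annotate_helices(rec, patterns)
    bw = assign_bw(anns)
    for ann in anns:
        assert bw.entries[ann.anchor] == (ann.helix_id, 50)
        numbers = [bw.entries[i] for i in range(ann.start, ann.end + 1)]
        assert [n for _, n in numbers] == list(
            range(50 - (ann.anchor - ann.start),
                  50 + (ann.end - ann.anchor) + 1))
    values = list(bw.entries.values())
    assert len(values) == len(set(values)), "BW mapping is not a bijection"
    outside = set(range(1, len(rec) + 1)) - set(bw.entries)
    for ann in anns:
        assert not outside & set(range(ann.start, ann.end + 1))


def test_bw_pairs_on_ffa_like_stand_ins(patterns, ffa_trio):
    """Synthetic FFA-like paralogs: numbering recovers every marker pair.

    The sequences are synthetic stand-ins whose anchors encode the marker
    residue positions reported for the free-fatty-acid receptors (e.g. the
    helix-2 lysine at 2.60 and the anchoring arginines at 5.39/7.35), so
    motif-based annotation must re-derive each printed residue<->index pair.
    """
    records, truth = ffa_trio
    for rec in records:
        bw = assign_bw(annotate_helices(rec, patterns))
        for idx, generic in truth.bw_expectations[rec.id].items():
            assert bw.generic(idx) == generic
    ffa1 = records[0]
    anns = annotate_helices(ffa1, patterns)
    h7 = [a for a in anns if a.helix_id == 7][0]
    assert h7.start <= 258 <= h7.end  # the 7.35 arginine sits inside helix 7
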