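"""Motif grammar parsing and exhaustive matching."""

import itertools

import numpy as np
import pytest

from seventm.seq import (MotifParseError, MotifPattern, MotifToken,
                         SequenceRecord, match_motif, parse_motif)


def tokens_of(text, helix=1):
    return [(t.kind, sorted(t.allowed_residues) if t.kind == "literal"
             else sorted(t.allowed_lengths))
            for t in parse_motif(text, helix).tokens]


@pytest.mark.parametrize("text,expected", [
    ("GX3N", [("literal", ["G"]), ("spacer", [3]), ("literal", ["N"])]),
    ("N(S,H)LX3DX7,8,9P",
     [("literal", ["H", "N", "S"]), ("literal", ["L"]), ("spacer", [3]),
      ("literal", ["D"]), ("spacer", [7, 8, 9]), ("literal", ["P"])]),
    ("W", [("literal", ["W"])]),
    ("FX2CW(Y,F)XP",
     [("literal", ["F"]), ("spacer", [2]), ("literal", ["C"]),
      ("literal", ["F", "W", "Y"]), ("spacer", [1]), ("literal", ["P"])]),
])
def test_parse_tokenizes_grammar(text, expected):
    assert tokens_of(text) == expected


@pytest.mark.parametrize("bad", ["G(", "GX3N)", "B", "gX3N", "(A)X3", "X3G(1)"])
def test_parse_rejects_malformed_patterns(bad):
    with pytest.raises(MotifParseError):
        parse_motif(bad, 1)


def test_parse_anchor_must_be_literal():
    with pytest.raises(ValueError):
        parse_motif("GX3N", 1, anchor_token_index=1)  # spacer cannot anchor


def test_single_literal_match():
    seq = SequenceRecord("s", "AWA")
    hits = match_motif(seq, parse_motif("W", 4))
    assert len(hits) == 1
    assert (hits[0].start, hits[0].anchor_position, hits[0].end) == (2, 2, 2)


def test_fixed_spacer_match():
    seq = SequenceRecord("s", "AGKLMNA")
    (hit,) = match_motif(seq, parse_motif("GX3N", 1))
    assert (hit.start, hit.end) == (2, 6)
    assert hit.spacer_choices == (3,)


def test_search_window_limits_start_positions():
    seq = SequenceRecord("s", "AWAWA")
    pat = parse_motif("W", 4)
    assert len(match_motif(seq, pat)) == 2
    assert len(match_motif(seq, pat, search_window=(1, 3))) == 1
    with pytest.raises(ValueError):
        match_motif(seq, pat, search_window=(0, 3))


def brute_force_matches(seq: SequenceRecord, pattern: MotifPattern):
    """Independent oracle: try every start and every spacer combination."""
    spacer_sets = [sorted(t.allowed_lengths) for t in pattern.tokens
                   if t.kind == "spacer"]
    found = []
    for start0 in range(len(seq.residues)):
        for combo in itertools.product(*spacer_sets):
            pos = start0
            ok = True
            anchor = None
            it = iter(combo)
            for i, tok in enumerate(pattern.tokens):
                if tok.kind == "spacer":
                    pos += next(it)
                else:
                    if pos >= len(seq.residues) or \
                            seq.residues[pos] not in tok.allowed_residues:
                        ok = False
                        break
                    if i == pattern.anchor_token_index:
                        anchor = pos + 1
                    pos += 1
            if ok:
                found.append((start0 + 1, pos, anchor, tuple(combo)))
    return sorted(found)


@pytest.mark.parametrize("seed", range(12))
def test_match_equals_bruteforce_on_random_sequences(seed, patterns):
    rng = np.random.default_rng(seed)
    alphabet = list("GNSHLDPXRYWFCIAEKMQTV".replace("X", ""))
    seq = SequenceRecord(
        "r", "".join(rng.choice(alphabet, size=250)))
    for pattern in patterns:
        got = [(m.start, m.end, m.anchor_position, m.spacer_choices)
               for m in match_motif(seq, pattern)]
        assert sorted(got) == brute_force_matches(seq, pattern)


def test_match_ordering_by_start_then_spacers():
    # W then P at +9 and +10 admits both spacer choices at the same start
    seq = SequenceRecord("s", "W" + "A" * 8 + "PP" + "A" * 3)
    hits = match_motif(seq, parse_motif("WX8,9P", 4))
    assert [(h.start, h.spacer_choices) for h in hits] == [(1, (8,)), (1, (9,))]
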