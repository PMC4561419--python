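"""Canonical class-A GPCR transmembrane-helix motifs and numbering defaults.

The seven motif strings below are the conserved helix fingerprints used to
anchor transmembrane alignments of class-A receptors (``Xn`` = n arbitrary
residues, ``(A,B)`` = alternatives for the preceding letter).  The designated
anchor literal of each motif is the helix's most conserved residue, which
carries the Ballesteros-Weinstein index X.50:

=====  =======================  ==================
helix  motif                    X.50 residue
=====  =======================  ==================
1      GX3N                     N
2      N(S,H)LX3DX7,8,9P        D
3      SX3LX2IX2D(E,H)RY        R (of the D-R-Y triad)
4      WX8,9P                   W
5      FX2PX7Y                  P
6      FX2CW(Y,F)XP             P (of C-W-x-P)
7/8    LX3NX3N(D)PX2YX5,6F      P (of N-P-x-x-Y)
=====  =======================  ==================
"""

from __future__ import annotations

from typing import Optional

MOTIF_STRINGS: dict[int, str] = {
    1: "GX3N",
    2: "N(S,H)LX3DX7,8,9P",
    3: "SX3LX2IX2D(E,H)RY",
    4: "WX8,9P",
    5: "FX2PX7Y",
    6: "FX2CW(Y,F)XP",
    7: "LX3NX3N(D)PX2YX5,6F",
}

#: token index of the X.50 anchor literal within each canonical motif string
CANONICAL_ANCHOR_INDEX: dict[str, int] = {
    MOTIF_STRINGS[1]: 2,
    MOTIF_STRINGS[2]: 3,
    MOTIF_STRINGS[3]: 7,
    MOTIF_STRINGS[4]: 0,
    MOTIF_STRINGS[5]: 2,
    MOTIF_STRINGS[6]: 5,
    MOTIF_STRINGS[7]: 5,
}

#: (upstream, downstream) residues around X.50 delimiting each helix span.
#: Chosen so that the positions commonly indexed in binding-site work
#: (2.58-2.63, 3.30-3.37, 4.54-4.61, 5.35-5.43, 6.51-6.55, 7.35-7.53) fall
#: inside while consecutive helices stay disjoint at typical anchor spacings.
DEFAULT_BOUNDARY_OFFSETS: dict[int, tuple[int, int]] = {
    1: (12, 12),
    2: (12, 13),
    3: (22, 12),
    4: (10, 12),
    5: (17, 10),
    6: (20, 10),
    7: (16, 8),
}


def default_patterns(anchor_overrides: Optional[dict[int, int]] = None):
    """The seven canonical motif patterns, parsed and anchor-annotated."""
    from .seq import parse_motif

    anchor_overrides = anchor_overrides or {}
    return [
        parse_motif(text, helix_id,
                    anchor_overrides.get(helix_id,
                                         CANONICAL_ANCHOR_INDEX[text]))
        for helix_id, text in MOTIF_STRINGS.items()
    ]
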