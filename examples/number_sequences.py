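"""Ballesteros-Weinstein numbering of motif-bearing receptor sequences.

Generates the synthetic FFA-like paralog trio, annotates the seven
transmembrane helices by motif matching, and prints the generic numbers of a
few marker residues.  A generic number X.NN means: helix X, NN positions
relative to that helix's most conserved residue (which is defined as X.50).
"""

from seventm import annotate_helices, assign_bw
from seventm.motifs import default_patterns
from seventm.synth import make_ffa_like_trio

records, truth = make_ffa_like_trio(seed=0)
patterns = default_patterns()

for record in records:
    annotations = annotate_helices(record, patterns)
    bw = assign_bw(annotations)
    anchors = {a.helix_id: a.anchor for a in annotations}
    print(f"{record.id}: {len(record)} residues, helix anchors {anchors}")
    for idx, expected in truth.bw_expectations[record.id].items():
        print(f"  residue {record[idx]}{idx} -> {bw.generic(idx)} "
              f"(generator placed it at {expected})")

# Each marker lands on its literature position: e.g. the FFA1-like lysine 62
# is numbered 2.60 (ten residues past the helix-2 anchor at residue 52).
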