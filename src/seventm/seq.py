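"""Sequence handling for seven-transmembrane (7TM) receptor analysis.

This module implements the sequence side of the pipeline: a small grammar for
the conserved transmembrane-helix motifs of class-A GPCRs, exhaustive motif
matching, global pairwise alignment, motif-anchored alignment adjustment,
helix annotation, Ballesteros-Weinstein (BW) generic numbering and
helix-restricted sequence identity.

Motif grammar
-------------
A motif string is a sequence of

* residue letters (one-letter amino-acid codes), each a *literal* token;
* ``(A,B)`` immediately after a literal, adding alternative residues that
  substitute the preceding letter (``N(S,H)`` matches N, S or H);
* ``Xn`` or ``Xn,m,k`` *spacer* tokens matching exactly n (or n, m or k)
  arbitrary residues; a bare ``X`` is a spacer of length 1.

For example the helix-2 motif ``N(S,H)LX3DX7,8,9P`` tokenizes as
literal{N,S,H}, literal{L}, spacer{3}, literal{D}, spacer{7,8,9}, literal{P}.

Residue indexing is 1-based throughout, matching the residue numbers used in
the structural literature (K62, R258, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

GAP = "-"


class MotifParseError(ValueError):
    """Raised when a motif string does not follow the grammar."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with 1-based residue indexing."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, index_1based: int) -> str:
        if not 1 <= index_1based <= len(self.residues):
            raise IndexError(f"residue index {index_1based} out of range")
        return self.residues[index_1based - 1]


@dataclass(frozen=True)
class MotifToken:
    """One token of a motif pattern: a literal residue set or a spacer."""

    kind: str  # "literal" | "spacer"
    allowed_residues: frozenset[str] = frozenset()
    allowed_lengths: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.kind == "literal":
            if not self.allowed_residues or self.allowed_lengths:
                raise ValueError("literal token needs residues and no lengths")
        elif self.kind == "spacer":
            if not self.allowed_lengths or self.allowed_residues:
                raise ValueError("spacer token needs lengths and no residues")
            if any(n < 0 for n in self.allowed_lengths):
                raise ValueError("spacer lengths must be non-negative")
        else:
            raise ValueError(f"unknown token kind {self.kind!r}")


@dataclass(frozen=True)
class MotifPattern:
    """A tokenized helix motif with a designated X.50 anchor literal.

    ``helix_id`` is 1-8; 7 denotes the combined helix-7/8 motif.
    ``anchor_token_index`` points at the literal token whose matched residue
    carries the generic number X.50.
    """

    helix_id: int
    tokens: tuple[MotifToken, ...]
    anchor_token_index: int
    text: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.helix_id <= 8:
            raise ValueError("helix_id must be in 1..8")
        if not self.tokens:
            raise ValueError("pattern has no tokens")
        if self.tokens[0].kind != "literal" or self.tokens[-1].kind != "literal":
            raise ValueError("first and last motif tokens must be literals")
        if not 0 <= self.anchor_token_index < len(self.tokens):
            raise ValueError("anchor_token_index out of range")
        if self.tokens[self.anchor_token_index].kind != "literal":
            raise ValueError("anchor token must be a literal")


@dataclass(frozen=True)
class MotifMatch:
    """An occurrence of a motif in a sequence (1-based, inclusive)."""

    start: int
    end: int
    anchor_position: int
    spacer_choices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.start <= self.anchor_position <= self.end:
            raise ValueError("anchor must lie within the match")


@dataclass
class Alignment:
    """A gapped multiple alignment; rows are (sequence id, gapped string)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        widths = {len(g) for _, g in self.rows}
        if len(widths) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def ungapped(self, row: int) -> str:
        return self.rows[row][1].replace(GAP, "")

    def column_of(self, row: int, residue_index: int) -> int:
        """1-based alignment column holding the residue_index-th residue."""
        seen = 0
        for col, ch in enumerate(self.rows[row][1], start=1):
            if ch != GAP:
                seen += 1
                if seen == residue_index:
                    return col
        raise IndexError(f"row {row} has fewer than {residue_index} residues")


@dataclass(frozen=True)
class HelixAnnotation:
    """A helix span [start, end] with its X.50 anchor residue (1-based)."""

    helix_id: int
    start: int
    end: int
    anchor: int

    def __post_init__(self) -> None:
        if not self.start <= self.anchor <= self.end:
            raise ValueError(
                f"helix {self.helix_id}: anchor {self.anchor} outside "
                f"[{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class BWMap:
    """Per-residue Ballesteros-Weinstein generic numbers.

    ``entries`` maps a 1-based residue index to ``(helix_id, generic_number)``
    where the helix anchor gets 50 and neighbours are numbered relative to it.
    """

    entries: dict[int, tuple[int, int]] = field(default_factory=dict)

    def generic(self, residue_index: int) -> str:
        helix, number = self.entries[residue_index]
        return f"{helix}.{number}"


# ---------------------------------------------------------------------------
# motif grammar


def parse_motif(pattern_text: str, helix_id: int,
                anchor_token_index: Optional[int] = None) -> MotifPattern:
    """Parse a motif string into a :class:`MotifPattern`.

    ``anchor_token_index`` defaults to the index configured for the helix in
    :mod:`seventm.motifs` when the pattern text is one of the canonical
    motifs, otherwise to the last literal token.
    """
    tokens: list[MotifToken] = []
    i = 0
    n = len(pattern_text)
    while i < n:
        ch = pattern_text[i]
        if ch == "X":
            i += 1
            lengths: list[int] = []
            num = ""
            while i < n and (pattern_text[i].isdigit() or pattern_text[i] == ","):
                if pattern_text[i] == ",":
                    if not num:
                        raise MotifParseError(
                            f"empty spacer length before ',' at position {i} "
                            f"in {pattern_text!r}")
                    # a comma not followed by a digit belongs to an outer
                    # context only in '(..)' groups, which are handled below,
                    # so here it always separates spacer lengths
                    lengths.append(int(num))
                    num = ""
                else:
                    num += pattern_text[i]
                i += 1
            if num:
                lengths.append(int(num))
            if not lengths:
                lengths = [1]
            tokens.append(MotifToken("spacer", allowed_lengths=frozenset(lengths)))
        elif ch == "(":
            close = pattern_text.find(")", i)
            if close < 0:
                raise MotifParseError(f"unclosed '(' at position {i} in {pattern_text!r}")
            if not tokens or tokens[-1].kind != "literal":
                raise MotifParseError(
                    f"'(' at position {i} in {pattern_text!r} does not follow a literal")
            alts = pattern_text[i + 1:close].split(",")
            for alt in alts:
                if len(alt) != 1 or alt not in AMINO_ACIDS:
                    raise MotifParseError(
                        f"bad alternative {alt!r} in {pattern_text!r}")
            prev = tokens.pop()
            tokens.append(MotifToken(
                "literal",
                allowed_residues=prev.allowed_residues | frozenset(alts)))
            i = close + 1
        elif ch in AMINO_ACIDS:
            tokens.append(MotifToken("literal", allowed_residues=frozenset(ch)))
            i += 1
        else:
            raise MotifParseError(
                f"unknown character {ch!r} at position {i} in {pattern_text!r}")
    if not tokens:
        raise MotifParseError("empty motif pattern")
    if anchor_token_index is None:
        anchor_token_index = _default_anchor_index(pattern_text, tokens)
    return MotifPattern(helix_id=helix_id, tokens=tuple(tokens),
                        anchor_token_index=anchor_token_index, text=pattern_text)


def _default_anchor_index(pattern_text: str, tokens: list[MotifToken]) -> int:
    from . import motifs  # local import to avoid a cycle at module load

    idx = motifs.CANONICAL_ANCHOR_INDEX.get(pattern_text)
    if idx is not None:
        return idx
    return max(i for i, t in enumerate(tokens) if t.kind == "literal")


def match_motif(seq: SequenceRecord, pattern: MotifPattern,
                search_window: Optional[tuple[int, int]] = None) -> list[MotifMatch]:
    """Every occurrence of ``pattern`` in ``seq``.

    Returns all distinct (start, spacer_choices) combinations, ordered by
    start position then lexicographically by spacer choices.  The optional
    ``search_window`` (1-based, inclusive) restricts match *start* positions.
    """
    lo, hi = 1, len(seq)
    if search_window is not None:
        lo, hi = search_window
        if lo < 1 or hi > len(seq):
            raise ValueError("search window outside sequence bounds")
    residues = seq.residues
    tokens = pattern.tokens
    matches: list[MotifMatch] = []

    def extend(pos0: int, tok_i: int, spacers: tuple[int, ...],
               anchor_pos: Optional[int]) -> None:
        # pos0 is the 0-based position of the next residue to consume
        if tok_i == len(tokens):
            start0 = pos0 - (sum(spacers) +
                             sum(1 for t in tokens if t.kind == "literal"))
            matches.append(MotifMatch(
                start=start0 + 1, end=pos0, anchor_position=anchor_pos,
                spacer_choices=spacers))
            return
        tok = tokens[tok_i]
        if tok.kind == "literal":
            if pos0 < len(residues) and residues[pos0] in tok.allowed_residues:
                a = anchor_pos
                if tok_i == pattern.anchor_token_index:
                    a = pos0 + 1
                extend(pos0 + 1, tok_i + 1, spacers, a)
        else:
            for n in sorted(tok.allowed_lengths):
                if pos0 + n <= len(residues):
                    extend(pos0 + n, tok_i + 1, spacers + (n,), anchor_pos)

    for start0 in range(lo - 1, hi):
        extend(start0, 0, (), None)
    matches.sort(key=lambda m: (m.start, m.spacer_choices))
    return matches


# ---------------------------------------------------------------------------
# global alignment

#: Gap of length k costs gap_open + (k - 1) * gap_extend.
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


def global_align(a: SequenceRecord, b: SequenceRecord,
                 matrix_name: str = "BLOSUM62",
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> Alignment:
    """Optimal global (Needleman-Wunsch, affine-gap) alignment of two sequences.

    The first residue of a gap costs ``gap_open``, each further residue
    ``gap_extend``.  Ties in the traceback are broken deterministically by the
    aligner's fixed enumeration order.
    """
    matrix = substitution_matrices.load(matrix_name)
    for rec in (a, b):
        bad = set(rec.residues) - set(str(c) for c in matrix.alphabet)
        if bad:
            raise ValueError(
                f"sequence {rec.id!r} has residues absent from {matrix_name}: "
                f"{sorted(bad)}")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    best = next(iter(aligner.align(a.residues, b.residues)))
    ga, gb = str(best[0]), str(best[1])
    return Alignment(rows=[(a.id, ga), (b.id, gb)])


def alignment_score(aln: Alignment, matrix_name: str = "BLOSUM62",
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Score a pairwise alignment under the same affine-gap convention."""
    if len(aln.rows) != 2:
        raise ValueError("scoring needs a pairwise alignment")
    matrix = substitution_matrices.load(matrix_name)
    ga, gb = aln.rows[0][1], aln.rows[1][1]
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(ga, gb):
        if ca == GAP and cb == GAP:
            raise ValueError("all-gap column")
        if ca == GAP:
            score -= gap_open if not in_gap_a else gap_extend
            in_gap_a, in_gap_b = True, False
        elif cb == GAP:
            score -= gap_open if not in_gap_b else gap_extend
            in_gap_b, in_gap_a = True, False
        else:
            score += matrix[ca, cb]
            in_gap_a = in_gap_b = False
    return score


# ---------------------------------------------------------------------------
# anchored alignment

class AnchorError(ValueError):
    """Raised when helix anchors cannot be brought into register."""


def anchor_alignment(aln: Alignment,
                     annotations: Sequence[Sequence[HelixAnnotation]]) -> Alignment:
    """Shift gaps so every helix's X.50 anchors share an alignment column.

    For each helix (in helix order) the target anchor column is the largest
    current anchor column over rows; rows whose anchor sits left of it receive
    gaps immediately before the first residue of that helix, i.e. in the
    preceding loop, never inside the helix.  Rows already in register are left
    untouched, which makes the operation idempotent, and gaps are only ever
    inserted, so removing gaps from any output row reproduces its input
    sequence exactly.
    """
    if len(annotations) != len(aln.rows):
        raise ValueError("one annotation list per alignment row required")
    helix_ids = [tuple(sorted(a.helix_id for a in anns)) for anns in annotations]
    if len(set(helix_ids)) != 1:
        raise AnchorError("rows are annotated with different helix sets")
    by_helix: dict[int, list[HelixAnnotation]] = {}
    for anns in annotations:
        for a in anns:
            by_helix.setdefault(a.helix_id, []).append(a)

    rows = [list(g) for _, g in aln.rows]

    def col_of(row: list[str], residue_index: int) -> int:
        seen = 0
        for col, ch in enumerate(row, start=1):
            if ch != GAP:
                seen += 1
                if seen == residue_index:
                    return col
        raise AnchorError(f"annotation index {residue_index} beyond row length")

    prev_anchor_cols = [0] * len(rows)
    for helix_id in sorted(by_helix):
        anns = by_helix[helix_id]
        anchor_cols = [col_of(rows[r], anns[r].anchor) for r in range(len(rows))]
        target = max(anchor_cols)
        for r, col in enumerate(anchor_cols):
            if col < target:
                insert_at = col_of(rows[r], anns[r].start) - 1  # before helix start
                if insert_at < prev_anchor_cols[r]:
                    raise AnchorError(
                        f"helix {helix_id}: cannot align anchors of row {r} "
                        "without deleting residues")
                rows[r][insert_at:insert_at] = [GAP] * (target - col)
        prev_anchor_cols = [col_of(rows[r], anns[r].anchor) for r in range(len(rows))]

    width = max(len(r) for r in rows)
    for r in rows:
        r.extend([GAP] * (width - len(r)))
    return Alignment(rows=[(aln.rows[i][0], "".join(rows[i]))
                           for i in range(len(rows))])


# ---------------------------------------------------------------------------
# helix annotation and BW numbering

class HelixNotFoundError(ValueError):
    """Raised when a required helix motif has no match in a sequence."""


def annotate_helices(seq: SequenceRecord,
                     patterns: Sequence[MotifPattern],
                     boundary_offsets: Optional[dict[int, tuple[int, int]]] = None,
                     expected_anchor_spacing: Optional[dict[int, int]] = None,
                     ) -> list[HelixAnnotation]:
    """Annotate helix spans by matching each helix motif in order.

    Each motif must match at least once downstream of the previous helix's
    anchor.  Ambiguity (several admissible matches) is resolved by preferring
    the match whose anchor is closest to the expected spacing from the
    previous anchor when ``expected_anchor_spacing`` is given, otherwise the
    earliest match; either way a warning is logged.  Helix boundaries are
    placed at anchor - upstream / anchor + downstream (clipped to the
    sequence; overlaps between consecutive helices are clipped at the
    midpoint with a warning).
    """
    from . import motifs

    if boundary_offsets is None:
        boundary_offsets = motifs.DEFAULT_BOUNDARY_OFFSETS
    annotations: list[HelixAnnotation] = []
    prev_anchor = 0
    for pattern in sorted(patterns, key=lambda p: p.helix_id):
        matches = [m for m in match_motif(seq, pattern)
                   if m.anchor_position > prev_anchor]
        if not matches:
            raise HelixNotFoundError(
                f"no match for helix {pattern.helix_id} motif "
                f"{pattern.text or pattern.tokens} in sequence {seq.id!r}")
        chosen = matches[0]
        if len({(m.start, m.spacer_choices) for m in matches}) > 1:
            if expected_anchor_spacing and pattern.helix_id in expected_anchor_spacing:
                expected = prev_anchor + expected_anchor_spacing[pattern.helix_id]
                chosen = min(matches,
                             key=lambda m: (abs(m.anchor_position - expected),
                                            m.start, m.spacer_choices))
            logger.warning(
                "helix %d motif matches %d times in %s; picked anchor %d",
                pattern.helix_id, len(matches), seq.id, chosen.anchor_position)
        up, down = boundary_offsets.get(pattern.helix_id, (15, 15))
        start = max(1, chosen.anchor_position - up)
        end = min(len(seq), chosen.anchor_position + down)
        annotations.append(HelixAnnotation(
            helix_id=pattern.helix_id, start=start, end=end,
            anchor=chosen.anchor_position))
        prev_anchor = chosen.anchor_position

    # clip any overlap between consecutive helices at the midpoint
    for i in range(len(annotations) - 1):
        a, b = annotations[i], annotations[i + 1]
        if a.end >= b.start:
            mid = (a.anchor + b.anchor) // 2
            logger.warning("helices %d and %d overlap; clipping at %d",
                           a.helix_id, b.helix_id, mid)
            annotations[i] = HelixAnnotation(a.helix_id, a.start,
                                             min(a.end, mid), a.anchor)
            annotations[i + 1] = HelixAnnotation(b.helix_id,
                                                 max(b.start, mid + 1),
                                                 b.end, b.anchor)
    return annotations


def assign_bw(annotations: Sequence[HelixAnnotation]) -> BWMap:
    """Ballesteros-Weinstein numbers for every residue in annotated helices.

    The anchor residue of helix X gets X.50; neighbours are numbered
    consecutively relative to it.  Residues outside annotated helices are
    absent from the map.
    """
    entries: dict[int, tuple[int, int]] = {}
    for ann in annotations:
        for idx in range(ann.start, ann.end + 1):
            if idx in entries:
                raise ValueError(f"residue {idx} annotated twice")
            entries[idx] = (ann.helix_id, 50 + (idx - ann.anchor))
    return BWMap(entries=entries)


# ---------------------------------------------------------------------------
# sequence identity

def tm_identity(aln: Alignment, row_a: int, row_b: int,
                column_ranges: Optional[Sequence[tuple[int, int]]] = None) -> float:
    """Percent identity between two rows over the given column ranges.

    Identity = 100 x (identical-residue columns) / (columns where neither row
    has a gap).  ``column_ranges`` are 1-based inclusive; ``None`` means all
    columns.  Raises when no column is eligible.
    """
    ga, gb = aln.rows[row_a][1], aln.rows[row_b][1]
    if column_ranges is None:
        column_ranges = [(1, aln.width)]
    same = total = 0
    for lo, hi in column_ranges:
        if lo < 1 or hi > aln.width:
            raise ValueError(f"column range ({lo}, {hi}) outside alignment")
        for col in range(lo - 1, hi):
            ca, cb = ga[col], gb[col]
            if ca == GAP or cb == GAP:
                continue
            total += 1
            if ca == cb:
                same += 1
    if total == 0:
        raise ValueError("no gap-free columns in the requested ranges")
    return 100.0 * same / total


def round_half_up(value: float) -> int:
    """Round to nearest integer, halves away from zero (report display)."""
    import math
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def helix_column_ranges(aln: Alignment,
                        annotations: Sequence[Sequence[HelixAnnotation]],
                        ) -> list[tuple[int, int]]:
    """Alignment column ranges spanned by the annotated helices.

    For each helix the range runs from the smallest to the largest alignment
    column any row's helix span occupies, so that every helix residue of every
    row is inside some range.
    """
    by_helix: dict[int, list[tuple[int, int]]] = {}
    for r, anns in enumerate(annotations):
        for a in anns:
            lo = aln.column_of(r, a.start)
            hi = aln.column_of(r, a.end)
            by_helix.setdefault(a.helix_id, []).append((lo, hi))
    ranges = []
    for helix_id in sorted(by_helix):
        spans = by_helix[helix_id]
        ranges.append((min(s for s, _ in spans), max(e for _, e in spans)))
    return ranges


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path) -> list[SequenceRecord]:
    records = [SequenceRecord(id=rec.id, residues=str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i:i + 60] + "\n")


def read_alignment(path, fmt: str = "clustal") -> Alignment:
    """Read a Clustal-style or A2M/FASTA alignment."""
    fmt = {"a2m": "fasta"}.get(fmt, fmt)
    msa = AlignIO.read(str(path), fmt)
    return Alignment(rows=[(rec.id, str(rec.seq).upper().replace(".", GAP))
                           for rec in msa])


def write_alignment(aln: Alignment, path, fmt: str = "clustal") -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord as BioSeqRecord

    fmt = {"a2m": "fasta"}.get(fmt, fmt)
    msa = MultipleSeqAlignment(
        [BioSeqRecord(Seq(g), id=name, description="") for name, g in aln.rows])
    AlignIO.write(msa, str(path), fmt)


def bw_table(seq: SequenceRecord, bw: BWMap):
    """BW map as a DataFrame (residue_index, residue, helix, generic_number)."""
    import pandas as pd

    rows = [(idx, seq[idx], helix, number)
            for idx, (helix, number) in sorted(bw.entries.items())]
    return pd.DataFrame(rows, columns=["residue_index", "residue",
                                       "helix", "generic_number"])
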