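"""Cross-species projection of regulatory lysines through pairwise alignment.

Regulatory acetylation sites characterised in one species (e.g. the human
Hsp70 K77 or aldolase K147) are located in orthologs by global pairwise
alignment: the aligned column of the reference position is resolved to a
residue and coordinate in each target, and classified as

    conserved_K      lysine at the projected column
    conservative_R   arginine (charge-preserving substitution)
    other            any other residue
    gap              the column is a gap in the target

Alignment is Needleman-Wunsch with affine gaps (Gotoh three-state recursion);
a gap run of length L scores ``gap_open + (L-1) * gap_extend``.  Defaults:
BLOSUM62, gap_open=-10, gap_extend=-0.5, end gaps penalized.  Traceback ties
are broken deterministically: substitution > gap in target (up) > gap in
reference (left).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Align import substitution_matrices

__all__ = [
    "PairwiseAlignment",
    "TargetProjection",
    "SiteProjection",
    "global_align",
    "percent_identity",
    "project_site",
    "motif_scan",
]

_NEG_INF = float("-inf")
_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYXBZ")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment; gap character is ``-``."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")

    def column_of_a_position(self, position: int) -> int:
        """Alignment column (0-based) holding 1-based position of sequence A."""
        count = 0
        for col, ch in enumerate(self.aligned_a):
            if ch != "-":
                count += 1
                if count == position:
                    return col
        raise IndexError(f"position {position} beyond sequence A")

    def b_position_at_column(self, col: int) -> int | None:
        """1-based position in B at an alignment column, or None on a gap."""
        if self.aligned_b[col] == "-":
            return None
        return len(self.aligned_b[: col + 1].replace("-", ""))


def _score(matrix, x: str, y: str) -> float:
    try:
        return float(matrix[x, y])
    except (KeyError, IndexError):
        return float(matrix["X", "X"]) if "X" in matrix.alphabet else 0.0


def global_align(
    seq_a: str,
    seq_b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap scoring (Gotoh algorithm)."""
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for seq in (seq_a, seq_b):
        bad = set(seq) - _VALID_AA
        if bad:
            raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    matrix = _BLOSUM62 if matrix_name == "BLOSUM62" \
        else substitution_matrices.load(matrix_name)
    n, m = len(seq_a), len(seq_b)

    # M: a_i aligned to b_j; X: gap in B (consumes a_i); Y: gap in A.
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend

    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        row_m, row_x, row_y = M[i], X[i], Y[i]
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = _score(matrix, ai, seq_b[j - 1])
            row_m[j] = max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1]) + s
            row_x[j] = max(prev_m[j] + gap_open,
                           prev_x[j] + gap_extend,
                           prev_y[j] + gap_open)
            row_y[j] = max(row_m[j - 1] + gap_open,
                           row_y[j - 1] + gap_extend,
                           row_x[j - 1] + gap_open)

    score = max(M[n][m], X[n][m], Y[n][m])

    # traceback; tie-break order: M (diagonal) > X (up) > Y (left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = max((("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m])),
                key=lambda kv: (kv[1], kv[0] == "M", kv[0] == "X"))[0]
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = _score(matrix, seq_a[i - 1], seq_b[j - 1])
            target = M[i][j] - s
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
            if abs(M[i][j] - target) < eps:
                state = "M"
            elif abs(X[i][j] - target) < eps:
                state = "X"
            else:
                state = "Y"
            if i == 0 and j == 0:
                break
        elif state == "X":
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            target = X[i][j]
            i -= 1
            if abs(M[i][j] + gap_open - target) < eps:
                state = "M"
            elif abs(X[i][j] + gap_extend - target) < eps:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            target = Y[i][j]
            j -= 1
            if abs(M[i][j] + gap_open - target) < eps:
                state = "M"
            elif abs(Y[i][j] + gap_extend - target) < eps:
                state = "Y"
            else:
                state = "X"
    return PairwiseAlignment("".join(reversed(out_a)),
                             "".join(reversed(out_b)), score)


def percent_identity(alignment: PairwiseAlignment) -> float:
    """100 x identical columns / columns where either sequence is non-gap."""
    qualifying = 0
    identical = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x == "-" and y == "-":
            continue
        qualifying += 1
        if x == y:
            identical += 1
    if qualifying == 0:
        raise ValueError("alignment has no qualifying columns")
    return 100.0 * identical / qualifying


@dataclass(frozen=True)
class TargetProjection:
    target_id: str
    residue: str | None  # None on a gap
    position: int | None  # 1-based in the target, None on a gap
    classification: str  # conserved_K | conservative_R | other | gap
    acetylated: bool | None = None  # None when no acetylome was provided


@dataclass(frozen=True)
class SiteProjection:
    reference_id: str
    reference_position: int
    targets: dict[str, TargetProjection]


def _classify(residue: str | None) -> str:
    if residue is None:
        return "gap"
    if residue == "K":
        return "conserved_K"
    if residue == "R":
        return "conservative_R"
    return "other"


def project_site(
    reference_id: str,
    reference_seq: str,
    position: int,
    targets: Mapping[str, str],
    alignments: Mapping[str, PairwiseAlignment] | None = None,
    acetylomes: Mapping[str, set[int]] | None = None,
) -> SiteProjection:
    """Project a reference residue position onto each target sequence.

    ``alignments`` may supply pre-computed pairwise alignments (reference as
    sequence A); targets without one are aligned with :func:`global_align`.
    ``acetylomes`` maps target id to its set of acetylated 1-based positions;
    when given, each projected position is flagged as acetylated or not.
    """
    reference_seq = reference_seq.upper()
    if not (1 <= position <= len(reference_seq)):
        raise IndexError(
            f"position {position} outside reference of length {len(reference_seq)}")
    if reference_seq[position - 1] != "K":
        import warnings

        warnings.warn(
            f"reference residue at {position} is "
            f"{reference_seq[position - 1]!r}, not K", stacklevel=2)
    projections: dict[str, TargetProjection] = {}
    for tid, tseq in targets.items():
        aln = (alignments or {}).get(tid) or global_align(reference_seq, tseq)
        col = aln.column_of_a_position(position)
        tpos = aln.b_position_at_column(col)
        residue = None if tpos is None else aln.aligned_b[col]
        acetylated = None
        if acetylomes is not None and tid in acetylomes and tpos is not None:
            acetylated = tpos in acetylomes[tid]
        projections[tid] = TargetProjection(
            target_id=tid, residue=residue, position=tpos,
            classification=_classify(residue), acetylated=acetylated)
    return SiteProjection(reference_id, position, projections)


def motif_scan(
    sequence: str,
    motif: str,
    max_mismatches: int = 0,
) -> list[tuple[int, int, int]]:
    """All occurrences of a motif, 1-based inclusive (start, end, n_mismatch).

    A window matches when its Hamming distance to the motif is at most
    ``max_mismatches``.  A motif longer than the sequence yields no hits.
    """
    sequence, motif = sequence.upper(), motif.upper()
    if not motif:
        raise ValueError("motif must be non-empty")
    hits: list[tuple[int, int, int]] = []
    L = len(motif)
    for start in range(len(sequence) - L + 1):
        window = sequence[start:start + L]
        mism = sum(1 for x, y in zip(window, motif) if x != y)
        if mism <= max_mismatches:
            hits.append((start + 1, start + L, mism))
    return hits
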