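"""Pairwise local alignment and the percent-distance metric.

The homolog-selection stage needs one number per pair of sequences: the
similarity *s*, defined as the number of identically paired residues in a
maximal-scoring Smith-Waterman local alignment divided by the length of the
shorter sequence, and the distance 100(1 - s) percent. The scoring model is
deliberately simple — +1 match, -1 mismatch, -1 per gap position (linear
gaps, opening and extension penalised equally).

The dynamic program is computed row-wise with numpy. Linear gap costs allow
the within-row (left) dependency to be resolved with a running maximum, so
each row is a handful of vectorised operations; the traceback runs in plain
Python over the stored score matrix. Determinism is part of the contract:
among co-optimal end cells the smallest end coordinate in ``a`` wins, then
the smallest in ``b``; during traceback a diagonal step is preferred over a
vertical (gap in ``b``) step, which is preferred over a horizontal step.

``N`` scores as a mismatch against everything, including another ``N``, and
never counts as a match: an ambiguous base should not contribute identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import InputError, NucleotideSequence

NEG_INF = np.iinfo(np.int32).min // 2


@dataclass(frozen=True)
class ScoringModel:
    """Match/mismatch/gap scores for local alignment.

    Defaults are +1/-1/-1/-1. The gap model is linear: because opening and
    extension carry the same penalty, only ``gap_open`` is used per gap
    position, and ``gap_extend`` must equal it.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -1
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise InputError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise InputError("gap penalties must be <= 0")
        if self.gap_open != self.gap_extend:
            raise InputError(
                "linear gap model: gap_open must equal gap_extend"
            )


@dataclass(frozen=True)
class LocalAlignment:
    """Result of a local alignment.

    ``a_span``/``b_span`` are half-open intervals on the two inputs;
    ``matches`` counts identically paired (non-N) residues on the traceback
    path. An all-negative scoring landscape yields the empty alignment with
    score 0, matches 0 and empty spans.
    """

    score: int
    matches: int
    a_span: tuple[int, int]
    b_span: tuple[int, int]
    # aligned rows with '-' for gaps; empty strings for the empty alignment
    a_row: str = ""
    b_row: str = ""

    def __post_init__(self) -> None:
        if self.matches < 0:
            raise ValueError("matches must be non-negative")
        a_len = self.a_span[1] - self.a_span[0]
        b_len = self.b_span[1] - self.b_span[0]
        if self.matches > min(a_len, b_len) and min(a_len, b_len) > 0:
            raise ValueError("matches cannot exceed the shorter span")


def _encode(residues: str) -> np.ndarray:
    # A,C,G,T -> 0..3; N -> 4 (never equal to anything, incl. itself)
    table = np.full(128, 4, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        table[ord(base)] = i
    return table[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def _score_matrix(a: str, b: str, model: ScoringModel) -> np.ndarray:
    """Full Smith-Waterman score matrix H of shape (|a|+1, |b|+1)."""
    ea, eb = _encode(a), _encode(b)
    n, m = len(ea), len(eb)
    gap = model.gap_open
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    # substitution scores per row, vectorised over b
    for i in range(1, n + 1):
        sub = np.where(
            (eb == ea[i - 1]) & (ea[i - 1] != 4), model.match, model.mismatch
        ).astype(np.int32)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + gap
        best = np.maximum(np.maximum(diag, up), 0)
        # resolve left-dependency: H[i,j] = max(best[j], max_{k<j}(best[k] - (j-k)))
        # (chained left gaps collapse because the gap cost is linear)
        j = np.arange(1, m + 1, dtype=np.int32)
        g = -gap  # gap magnitude
        run = np.maximum.accumulate(best + g * j)
        left = np.empty_like(best)
        left[0] = NEG_INF
        left[1:] = run[:-1] - g * j[1:]
        H[i, 1:] = np.maximum(best, np.maximum(left, 0))
    return H


def align_local(
    a: NucleotideSequence,
    b: NucleotideSequence,
    model: ScoringModel | None = None,
) -> LocalAlignment:
    """Maximal-scoring local alignment of ``a`` against ``b``.

    Deterministic: among co-optimal end cells, the lowest end coordinate in
    ``a`` wins, then the lowest in ``b``; the traceback prefers
    diagonal > up > left.
    """
    model = model or ScoringModel()
    if not a.residues or not b.residues:
        raise InputError("cannot align empty sequences")
    H = _score_matrix(a.residues, b.residues, model)
    score = int(H.max())
    if score <= 0:
        return LocalAlignment(score=0, matches=0, a_span=(0, 0), b_span=(0, 0))
    # smallest end-i, then end-j among maxima
    flat = int(np.argmax(H))  # row-major argmax == (lowest i, then lowest j)
    ei, ej = divmod(flat, H.shape[1])

    gap = model.gap_open
    i, j = ei, ej
    matches = 0
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        ca, cb = a.residues[i - 1], b.residues[j - 1]
        is_match = ca == cb and ca != "N"
        sub = model.match if is_match else model.mismatch
        if H[i, j] == H[i - 1, j - 1] + sub:
            matches += is_match
            ra.append(ca)
            rb.append(cb)
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            ra.append(ca)
            rb.append("-")
            i -= 1
        elif H[i, j] == H[i, j - 1] + gap:
            ra.append("-")
            rb.append(cb)
            j -= 1
        else:  # pragma: no cover - DP invariant
            raise AssertionError("inconsistent traceback")
    return LocalAlignment(
        score=score,
        matches=matches,
        a_span=(i, ei),
        b_span=(j, ej),
        a_row="".join(reversed(ra)),
        b_row="".join(reversed(rb)),
    )


def rescore(aln: LocalAlignment, model: ScoringModel | None = None) -> int:
    """Re-score an alignment's traceback rows under the model."""
    model = model or ScoringModel()
    total = 0
    for ca, cb in zip(aln.a_row, aln.b_row):
        if ca == "-" or cb == "-":
            total += model.gap_open
        elif ca == cb and ca != "N":
            total += model.match
        else:
            total += model.mismatch
    return total


def similarity(
    a: NucleotideSequence,
    b: NucleotideSequence,
    model: ScoringModel | None = None,
) -> float:
    """Fraction of matched residues over the shorter sequence length, in [0,1]."""
    aln = align_local(a, b, model)
    return aln.matches / min(len(a), len(b))


def distance_percent(
    a: NucleotideSequence,
    b: NucleotideSequence,
    model: ScoringModel | None = None,
) -> float:
    """Percent distance 100(1 - s); 0 for identical, 100 for unalignable."""
    return 100.0 * (1.0 - similarity(a, b, model))
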