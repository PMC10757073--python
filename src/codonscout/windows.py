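"""Windowing of long queries and coordinate mapping.

Coding-potential scoring scales quadratically with input length, so long
queries are subdivided into overlapping fixed-length windows (default
1000 bp, 300 bp overlap) that are searched and scored independently; the
per-window results are then mapped back onto the query. The overlap is a
multiple of 3 so that a coding region crossing a window boundary keeps its
codon phase in both windows, and the final window is anchored at the query
end rather than left as a short tail, because the scorer loses power on
short blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import InputError, NucleotideSequence


@dataclass(frozen=True)
class WindowingConfig:
    chunk_len: int = 1000
    overlap: int = 300
    long_query_threshold: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.overlap < self.chunk_len):
            raise InputError("require 0 < overlap < chunk_len")
        if self.long_query_threshold < self.chunk_len:
            raise InputError("long_query_threshold must be >= chunk_len")


@dataclass(frozen=True)
class SubQuery:
    """One window of the query: [q_start, q_end) and its residue slice."""

    index: int
    q_start: int
    q_end: int
    residues: str

    def __post_init__(self) -> None:
        if self.q_end - self.q_start != len(self.residues):
            raise InputError("window span does not match residue count")

    def __len__(self) -> int:
        return self.q_end - self.q_start

    def as_sequence(self, query_id: str) -> NucleotideSequence:
        return NucleotideSequence(
            id=f"{query_id}|win{self.index}", residues=self.residues
        )


def is_long_query(query: NucleotideSequence, cfg: WindowingConfig | None = None) -> bool:
    """True iff the query is strictly longer than the threshold."""
    cfg = cfg or WindowingConfig()
    return len(query) > cfg.long_query_threshold


def split_query(
    query: NucleotideSequence, cfg: WindowingConfig | None = None
) -> list[SubQuery]:
    """Overlapping chunk_len windows covering the whole query.

    Windows start at multiples of (chunk_len - overlap) from 0; the final
    window is anchored at the query end (start = L - chunk_len), so every
    position is covered and consecutive windows overlap by at least
    ``overlap``. A query no longer than chunk_len yields a single window
    spanning it.
    """
    cfg = cfg or WindowingConfig()
    L = len(query)
    if L <= cfg.chunk_len:
        return [SubQuery(index=0, q_start=0, q_end=L, residues=query.residues)]
    step = cfg.chunk_len - cfg.overlap
    starts = []
    pos = 0
    while pos + cfg.chunk_len < L:
        starts.append(pos)
        pos += step
    last = L - cfg.chunk_len
    if starts and starts[-1] != last:
        starts.append(last)
    elif not starts:  # pragma: no cover - L > chunk_len guarantees one start
        starts.append(last)
    return [
        SubQuery(
            index=i,
            q_start=s,
            q_end=s + cfg.chunk_len,
            residues=query.residues[s : s + cfg.chunk_len],
        )
        for i, s in enumerate(starts)
    ]


def map_to_query(w: SubQuery, local):
    """Shift a window-local coordinate or half-open interval to query space."""
    if isinstance(local, tuple):
        s, e = local
        if not (0 <= s <= e <= len(w)):
            raise InputError(
                f"interval [{s},{e}) outside window of length {len(w)}"
            )
        return (s + w.q_start, e + w.q_start)
    if not (0 <= local <= len(w)):
        raise InputError(f"coordinate {local} outside window of length {len(w)}")
    return local + w.q_start


def map_from_query(w: SubQuery, q):
    """Inverse of :func:`map_to_query` (query space to window-local)."""
    if isinstance(q, tuple):
        s, e = q
        if not (w.q_start <= s <= e <= w.q_end):
            raise InputError(f"interval [{s},{e}) outside window {w.index}")
        return (s - w.q_start, e - w.q_start)
    if not (w.q_start <= q <= w.q_end):
        raise InputError(f"coordinate {q} outside window {w.index}")
    return q - w.q_start
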