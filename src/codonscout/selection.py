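"""Diversity-constrained selection of representative homologs.

Alignment-based coding-potential scoring is only informative when the
aligned sequences are neither near-identical (no substitution signal) nor
too divergent (unreliable alignment). This module reduces a pool of
candidate homologs to a representative set in three steps:

1. ``band_filter`` keeps candidates whose percent distance to the query lies
   in a closed band (default 10-60 %).
2. ``reduce_cand_min_dist`` runs a density-based clustering, similar in
   spirit to DBSCAN: sequences closer than a threshold (default 10 %) to
   each other are grouped, the member representing the largest
   neighbourhood becomes the centroid and survives, the rest of its
   neighbourhood is discarded. The survivors are pairwise at least the
   threshold apart.
3. ``select_final`` keeps the best 2..16 survivors in order of increasing
   search E-value, i.e. decreasing similarity to the query.

Databases contain many near-identical records (strains, isolates); without
step 2 the selected set would be dominated by them and carry almost no
evolutionary information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from pathlib import Path

from .pairwise import ScoringModel, distance_percent
from .records import InputError, NucleotideSequence, read_fasta, write_fasta


class InsufficientHomologsError(RuntimeError):
    """Fewer representatives than the required minimum survived selection."""

    def __init__(self, found: int, required: int):
        self.found = found
        self.required = required
        super().__init__(
            f"insufficient homologs: found {found}, need at least {required}"
        )


@dataclass(frozen=True)
class Candidate:
    """A full-query-length homolog candidate with its retrieval statistics."""

    sequence: NucleotideSequence
    evalue: float
    dist_to_query: Optional[float] = None
    species: str = ""

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise InputError("E-value must be non-negative")
        if self.dist_to_query is not None and not (
            0.0 <= self.dist_to_query <= 100.0
        ):
            raise InputError("dist_to_query must be a percent in [0, 100]")

    @property
    def id(self) -> str:
        return self.sequence.id


@dataclass(frozen=True)
class DistanceBand:
    """Closed interval of acceptable percent distances to the query."""

    min_dist: float = 10.0
    max_dist: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_dist < self.max_dist <= 100.0):
            raise InputError(
                f"invalid distance band [{self.min_dist}, {self.max_dist}]"
            )

    def __contains__(self, dist: float) -> bool:
        return self.min_dist <= dist <= self.max_dist


@dataclass(frozen=True)
class SelectionLimits:
    """Minimum and maximum number of homologs passed on to alignment."""

    min_n: int = 2
    max_n: int = 16

    def __post_init__(self) -> None:
        if not (2 <= self.min_n <= self.max_n):
            raise InputError("limits must satisfy 2 <= min_n <= max_n")


DistanceFn = Callable[[Candidate, Candidate], float]


def _default_distance(model: ScoringModel | None = None) -> DistanceFn:
    cache: dict[tuple[str, str], float] = {}

    def dist(x: Candidate, y: Candidate) -> float:
        key = (x.id, y.id) if x.id <= y.id else (y.id, x.id)
        if key not in cache:
            cache[key] = distance_percent(x.sequence, y.sequence, model)
        return cache[key]

    return dist


def band_filter(
    cands: Sequence[Candidate], band: DistanceBand | None = None
) -> list[Candidate]:
    """Keep candidates whose distance to the query lies in the closed band."""
    band = band or DistanceBand()
    out = []
    for c in cands:
        if c.dist_to_query is None:
            raise InputError(f"candidate {c.id!r} has no dist_to_query")
        if c.dist_to_query in band:
            out.append(c)
    return out


def neighbourhood(
    s: Candidate,
    pool: Sequence[Candidate],
    clustered: set[str],
    min_pair_dist: float,
    distance: DistanceFn,
) -> list[Candidate]:
    """All unclustered pool members strictly closer than the threshold to s.

    Always includes ``s`` itself (even when ``s`` is already clustered);
    preserves pool order.
    """
    ids = {c.id for c in pool}
    if s.id not in ids:
        raise InputError(f"candidate {s.id!r} is not in the pool")
    out = []
    for sp in pool:
        if sp.id == s.id:
            out.append(sp)
        elif sp.id not in clustered and distance(s, sp) < min_pair_dist:
            out.append(sp)
    return out


def reduce_cand_min_dist(
    pool: Sequence[Candidate],
    min_pair_dist: float = 10.0,
    distance: DistanceFn | None = None,
    model: ScoringModel | None = None,
) -> list[Candidate]:
    """Density-based reduction to representatives >= min_pair_dist apart.

    Iterates over the pool in input order (callers pass E-value order).
    A sequence whose neighbourhood is just itself represents itself. For a
    larger neighbourhood, the member with the largest own neighbourhood
    becomes the centroid (ties keep the incumbent, i.e. the earlier
    sequence); the rest of the winning neighbourhood is deleted and the
    whole neighbourhood is marked clustered. Repeats until every sequence
    is clustered. Returns the survivors in input order.

    ``distance`` may be injected (e.g. a precomputed matrix lookup); the
    default aligns sequences with the pairwise module, caching each pair.
    """
    distance = distance or _default_distance(model)
    pool = list(pool)
    clustered: set[str] = set()
    deleted: set[str] = set()

    while len(clustered) < len(pool):
        progressed = False
        for s in pool:
            if s.id in clustered:
                continue
            N = neighbourhood(s, pool, clustered, min_pair_dist, distance)
            if len(N) == 1:
                clustered.add(s.id)
                progressed = True
                continue
            centroid = s
            for sp in N:
                if sp.id == s.id:
                    continue
                M = neighbourhood(sp, pool, clustered, min_pair_dist, distance)
                if len(M) > len(N):
                    centroid = sp
                    N = M
            clustered.update(c.id for c in N)
            clustered.add(centroid.id)
            deleted.update(c.id for c in N if c.id != centroid.id)
            progressed = True
        if not progressed:  # pragma: no cover - loop invariant
            raise AssertionError("clustering made no progress")
    return [c for c in pool if c.id not in deleted]


def select_final(
    reps: Sequence[Candidate], limits: SelectionLimits | None = None
) -> list[Candidate]:
    """Pick the final homolog set in order of increasing E-value.

    Ties are broken by smaller distance to the query, then id. Raises
    :class:`InsufficientHomologsError` when fewer than ``min_n`` survive.
    """
    limits = limits or SelectionLimits()
    if len(reps) < limits.min_n:
        raise InsufficientHomologsError(len(reps), limits.min_n)
    ordered = sorted(
        reps,
        key=lambda c: (
            c.evalue,
            c.dist_to_query if c.dist_to_query is not None else 101.0,
            c.id,
        ),
    )
    return ordered[: limits.max_n]


# ---------------------------------------------------------------------------
# standalone I/O: FASTA + TSV sidecar (id, species, taxon, evalue,
# dist_to_query) so selection can run outside the pipeline

SIDECAR_COLUMNS = ["id", "species", "taxon", "evalue", "dist_to_query"]


def read_candidates(fasta_path: str | Path, sidecar_path: str | Path) -> list[Candidate]:
    """Load candidates from a FASTA file and its per-record sidecar TSV."""
    import pandas as pd

    seqs = {s.id: s for s in read_fasta(fasta_path)}
    df = pd.read_csv(sidecar_path, sep="\t", dtype=str)
    missing = set(SIDECAR_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"sidecar missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        if row["id"] not in seqs:
            raise InputError(f"sidecar id {row['id']!r} not in FASTA")
        seq = seqs[row["id"]]
        seq = NucleotideSequence(
            id=seq.id,
            residues=seq.residues,
            taxon=str(row["taxon"]) if pd.notna(row["taxon"]) else None,
            species=str(row["species"]) if pd.notna(row["species"]) else None,
        )
        out.append(
            Candidate(
                sequence=seq,
                evalue=float(row["evalue"]),
                dist_to_query=float(row["dist_to_query"]),
                species=str(row["species"]),
            )
        )
    return out


def write_candidates(
    cands: Sequence[Candidate], fasta_path: str | Path, sidecar_path: str | Path
) -> None:
    """Inverse of :func:`read_candidates`."""
    write_fasta([c.sequence for c in cands], fasta_path)
    lines = ["\t".join(SIDECAR_COLUMNS)]
    for c in cands:
        lines.append(
            "\t".join(
                [
                    c.id,
                    c.species or "",
                    c.sequence.taxon or "",
                    f"{c.evalue:.3g}",
                    f"{c.dist_to_query:g}" if c.dist_to_query is not None else "",
                ]
            )
        )
    Path(sidecar_path).write_text("\n".join(lines) + "\n")
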