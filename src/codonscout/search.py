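"""Iterative homology search, hit extension and the temporary custom database.

Retrieval must supply homologs across a band of divergences from a single
query. A blastn-style search with a large word size only finds close
homologs, so the search is iterated up to five times with decreasing word
sizes; to keep the widening searches affordable they are restricted
taxonomically, using the lineage of the best hit of the first (unrestricted)
iteration: iteration 2 stays within its order, 3 within its class, 4 within
its phylum, 5 within its kingdom. An E-value cutoff of 0.01 and a large hit
cap (10,000 by default) apply throughout, the latter because near-identical
hits cannot be skipped server-side and must be collected before the
diversity selection can discard them.

Hits rarely cover the whole query, so each hit is extended to full query
length by projecting the unaligned query flanks onto the subject
("estimated coordinates": a gap-free linear projection, not a
re-alignment), clipped at the subject bounds; minus-strand hits are
reverse-complemented so every candidate reads in query sense.

For long queries a temporary custom database is built first: a sensitive
iterative search keeps the best hit per species (up to 300), each expanded
to five times the query length around the hit to leave room for intron
length differences, and the per-window searches then run against this small
collection in a single pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from io import StringIO
from typing import Iterable, Mapping, Optional, Protocol, Sequence

import pandas as pd

from .pairwise import ScoringModel, distance_percent
from .records import InputError, NucleotideSequence, reverse_complement
from .selection import (
    Candidate,
    DistanceBand,
    SelectionLimits,
    band_filter,
    reduce_cand_min_dist,
)

logger = logging.getLogger(__name__)

RANKS = ("order", "class", "phylum", "kingdom")


class NoHomologsError(RuntimeError):
    """The iterative search exhausted all iterations without a usable hit."""


@dataclass(frozen=True)
class Lineage:
    """Four-rank taxonomic lineage; unknown ranks are empty strings."""

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order_: str = ""

    def __post_init__(self) -> None:
        if not any((self.kingdom, self.phylum, self.class_, self.order_)):
            raise InputError("lineage must name at least one rank")

    def rank(self, name: str) -> str:
        return {
            "kingdom": self.kingdom,
            "phylum": self.phylum,
            "class": self.class_,
            "order": self.order_,
        }[name]


@dataclass(frozen=True)
class TaxonRestriction:
    """Restrict a search to records whose lineage matches *value* at *rank*."""

    rank: str
    value: str

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise InputError(f"unknown rank {self.rank!r}")

    def admits(self, lineage: Lineage) -> bool:
        return lineage.rank(self.rank) == self.value


@dataclass(frozen=True)
class SearchHit:
    """One tabular search hit; all coordinates 0-based half-open, forward strand."""

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    evalue: float
    identity_percent: float
    bitscore: float
    taxon: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"bad strand {self.strand!r}")
        if self.evalue < 0:
            raise InputError("E-value must be non-negative")
        if not (0 <= self.query_start < self.query_end):
            raise InputError("bad query interval")
        if not (0 <= self.subject_start < self.subject_end):
            raise InputError("bad subject interval")


# blastn -outfmt "6 ..." with sstrand and staxids appended
HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "evalue",
    "bitscore",
    "qstart",
    "qend",
    "sstart",
    "send",
    "sstrand",
    "staxids",
]


def parse_hits_tsv(text: str) -> list[SearchHit]:
    """Parse the tab-separated hit dialect (blastn outfmt-6 plus strand/taxid).

    Input coordinates are 1-based inclusive; minus-strand hits have
    sstart > send. Both are normalised to 0-based half-open on the forward
    strand. ``sstrand`` accepts plus/minus or +/-.
    """
    if not text.strip():
        return []
    df = pd.read_csv(
        StringIO(text), sep="\t", names=HIT_COLUMNS, dtype=str, comment="#"
    )
    hits = []
    for _, row in df.iterrows():
        sstart, send = int(row.sstart), int(row.send)
        strand = {"plus": "+", "minus": "-", "+": "+", "-": "-"}.get(
            str(row.sstrand).strip()
        )
        if strand is None:
            raise InputError(f"bad sstrand value {row.sstrand!r}")
        if sstart > send:
            sstart, send = send, sstart
            strand = "-"
        hits.append(
            SearchHit(
                query_id=row.qseqid,
                subject_id=row.sseqid,
                query_start=int(row.qstart) - 1,
                query_end=int(row.qend),
                subject_start=sstart - 1,
                subject_end=send,
                strand=strand,
                evalue=float(row.evalue),
                identity_percent=float(row.pident),
                bitscore=float(row.bitscore),
                taxon=str(row.staxids),
            )
        )
    return hits


def format_hits_tsv(hits: Iterable[SearchHit]) -> str:
    """Serialise hits back to the tabular dialect (1-based, blast strand rules)."""
    lines = []
    for h in hits:
        sstart, send = h.subject_start + 1, h.subject_end
        if h.strand == "-":
            sstart, send = send, sstart
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.identity_percent:.3f}",
                    str(h.query_end - h.query_start),
                    f"{h.evalue:.3g}",
                    f"{h.bitscore:.1f}",
                    str(h.query_start + 1),
                    str(h.query_end),
                    str(sstart),
                    str(send),
                    "plus" if h.strand == "+" else "minus",
                    h.taxon,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# schedule

# (word_size_build_db, word_size_full, tax rank or None), iterations 1..5
_SCHEDULE: tuple[tuple[int, int, Optional[str]], ...] = (
    (14, 18, None),
    (11, 14, "order"),
    (9, 10, "class"),
    (8, 8, "phylum"),
    (7, 7, "kingdom"),
)


@dataclass(frozen=True)
class SearchSchedule:
    """The five-iteration word-size/taxonomic-widening schedule."""

    rows: tuple[tuple[int, int, Optional[str]], ...] = _SCHEDULE

    def __post_init__(self) -> None:
        if len(self.rows) != 5:
            raise InputError("schedule must have exactly 5 iterations")
        for col in (0, 1):
            sizes = [r[col] for r in self.rows]
            if any(b > a for a, b in zip(sizes, sizes[1:])):
                raise InputError("word sizes must be non-increasing")

    def n_iterations(self) -> int:
        return len(self.rows)


def schedule_for(
    iteration: int, mode: str, schedule: SearchSchedule | None = None
) -> tuple[int, Optional[str]]:
    """Word size and taxonomic rank for an iteration, in build_db or full mode."""
    schedule = schedule or SearchSchedule()
    if not 1 <= iteration <= schedule.n_iterations():
        raise InputError(f"iteration {iteration} out of range 1..5")
    build, full, rank = schedule.rows[iteration - 1]
    if mode == "build_db":
        return build, rank
    if mode == "full":
        return full, rank
    raise InputError(f"unknown schedule mode {mode!r}")


# ---------------------------------------------------------------------------
# backend contract


class SearchBackend(Protocol):
    """Minimal surface a homology-search backend must provide.

    ``nt_like`` declares whether records may be transcripts (and hence the
    genomic biomol filter applies); curated genome collections set it False.
    """

    nt_like: bool

    def search(
        self,
        query: NucleotideSequence,
        word_size: int,
        evalue_cutoff: float,
        max_hits: int,
        taxon_restriction: Optional[TaxonRestriction] = None,
    ) -> list[SearchHit]: ...

    def subject_length(self, subject_id: str) -> int: ...

    def fetch(self, subject_id: str, start: int, end: int) -> str: ...


def lineage_of(meta_row: Mapping[str, str]) -> Lineage:
    return Lineage(
        kingdom=meta_row.get("kingdom", ""),
        phylum=meta_row.get("phylum", ""),
        class_=meta_row.get("class", ""),
        order_=meta_row.get("order", ""),
    )


# ---------------------------------------------------------------------------
# operations


def genomic_filter(
    hits: Sequence[SearchHit], metadata: Mapping[str, Mapping[str, str]]
) -> list[SearchHit]:
    """Drop hits whose record is not annotated as genomic (unspliced) DNA.

    Transcript records (mRNA etc.) would reintroduce spliced sequence and
    corrupt codon-level comparison across intron boundaries. Hits with no
    metadata are dropped with a warning.
    """
    out = []
    for h in hits:
        row = metadata.get(h.subject_id)
        if row is None:
            logger.warning("no metadata for %s; hit dropped", h.subject_id)
            continue
        if str(row.get("biomol", "")).lower() == "genomic":
            out.append(h)
    if hits and not out:
        logger.warning("no genomic hits remain after biomol filtering")
    return out


def extend_hit(
    hit: SearchHit,
    query_len: int,
    backend: SearchBackend,
    metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> Candidate:
    """Extend a hit to full query length by projecting the unaligned flanks.

    The left flank (query_start) and right flank (query_len - query_end) are
    added beyond the subject interval — swapped for minus-strand hits, where
    the query's left flank lies to the subject's right — then clipped to the
    subject bounds. Minus-strand extracts are reverse-complemented so all
    candidates are query-sense.
    """
    left = hit.query_start
    right = query_len - hit.query_end
    if hit.strand == "-":
        left, right = right, left
    slen = backend.subject_length(hit.subject_id)
    start = max(0, hit.subject_start - left)
    end = min(slen, hit.subject_end + right)
    residues = backend.fetch(hit.subject_id, start, end)
    if hit.strand == "-":
        residues = reverse_complement(residues)
    row = (metadata or {}).get(hit.subject_id, {})
    seq = NucleotideSequence(
        id=f"{hit.subject_id}:{start}-{end}({hit.strand})",
        residues=residues,
        taxon=str(row.get("taxon", hit.taxon)),
        species=str(row.get("species", "")) or None,
    )
    return Candidate(
        sequence=seq, evalue=hit.evalue, species=seq.species or seq.taxon or seq.id
    )


def dedupe_best_per_species(
    hits: Sequence[SearchHit], metadata: Mapping[str, Mapping[str, str]]
) -> list[SearchHit]:
    """Keep the single best hit per species.

    Best = lowest E-value, ties by highest bitscore, then lexicographic
    subject id. Hits whose species is unknown are keyed by subject id.
    """
    best: dict[str, SearchHit] = {}
    for h in hits:
        row = metadata.get(h.subject_id, {})
        species = str(row.get("species", "")) or h.subject_id
        cur = best.get(species)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (
            cur.evalue,
            -cur.bitscore,
            cur.subject_id,
        ):
            best[species] = h
    return sorted(
        best.values(), key=lambda h: (h.evalue, -h.bitscore, h.subject_id)
    )


@dataclass
class SearchConfig:
    """Operating constants of the retrieval stage."""

    evalue_cutoff: float = 0.01
    max_hits: int = 10_000
    band: DistanceBand = None  # type: ignore[assignment]
    limits: SelectionLimits = None  # type: ignore[assignment]
    min_pair_dist: float = None  # type: ignore[assignment]
    schedule: SearchSchedule = None  # type: ignore[assignment]
    model: ScoringModel = None  # type: ignore[assignment]
    customdb_max_seqs: int = 300
    customdb_expansion: int = 5

    def __post_init__(self) -> None:
        self.band = self.band or DistanceBand()
        self.limits = self.limits or SelectionLimits()
        if self.min_pair_dist is None:
            self.min_pair_dist = self.band.min_dist
        self.schedule = self.schedule or SearchSchedule()
        self.model = self.model or ScoringModel()


def _dedupe_hits(hits: Iterable[SearchHit]) -> list[SearchHit]:
    seen: set[tuple] = set()
    out = []
    for h in hits:
        key = (h.subject_id, h.subject_start, h.subject_end, h.strand)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def iterative_search(
    query: NucleotideSequence,
    backend: SearchBackend,
    metadata: Mapping[str, Mapping[str, str]],
    config: SearchConfig | None = None,
    mode: str = "full",
) -> list[Candidate]:
    """Run the five-iteration search and return clustered representatives.

    Iteration 1 is taxonomically unrestricted; its best hit estimates the
    query's phylogenetic position, and iterations 2-5 are restricted to the
    successively wider ranks of that lineage. After each iteration the
    accumulated hits are biomol-filtered (nt-like backends), extended to
    full query length, distance-annotated, band-filtered and clustered;
    the loop stops early once the representative pool reaches the maximum
    usable set size.
    """
    config = config or SearchConfig()
    ref_lineage: Optional[Lineage] = None
    all_hits: list[SearchHit] = []
    reps: list[Candidate] = []
    any_hits = False

    for iteration in range(1, config.schedule.n_iterations() + 1):
        word_size, rank = schedule_for(iteration, mode, config.schedule)
        tr = None
        if rank is not None and ref_lineage is not None:
            tr = TaxonRestriction(rank=rank, value=ref_lineage.rank(rank))
        hits = backend.search(
            query,
            word_size=word_size,
            evalue_cutoff=config.evalue_cutoff,
            max_hits=config.max_hits,
            taxon_restriction=tr,
        )
        logger.info(
            "iteration %d (word size %d, restriction %s): %d hits",
            iteration,
            word_size,
            tr,
            len(hits),
        )
        any_hits = any_hits or bool(hits)
        if backend.nt_like:
            hits = genomic_filter(hits, metadata)
        all_hits = _dedupe_hits(all_hits + hits)
        if not all_hits:
            continue
        if ref_lineage is None:
            # best hit so far estimates the query's phylogenetic position
            best = min(all_hits, key=lambda h: (h.evalue, -h.bitscore))
            row = metadata.get(best.subject_id)
            if row is not None:
                try:
                    ref_lineage = lineage_of(row)
                except InputError:
                    ref_lineage = None

        deduped = dedupe_best_per_species(all_hits, metadata)
        cands = []
        for h in deduped:
            c = extend_hit(h, len(query), backend, metadata)
            if c.sequence.id == query.id or c.sequence.residues == query.residues:
                # self-hit: distance 0, excluded by the band anyway
                dist = 0.0
            else:
                dist = distance_percent(query, c.sequence, config.model)
            cands.append(replace(c, dist_to_query=dist))
        in_band = band_filter(cands, config.band)
        reps = reduce_cand_min_dist(
            sorted(in_band, key=lambda c: (c.evalue, c.id)),
            config.min_pair_dist,
            model=config.model,
        )
        logger.info(
            "iteration %d: %d candidates, %d in band, %d representatives",
            iteration,
            len(cands),
            len(in_band),
            len(reps),
        )
        if len(reps) >= config.limits.max_n:
            break

    if not any_hits:
        raise NoHomologsError(f"no homologs found for query {query.id!r}")
    return reps


# ---------------------------------------------------------------------------
# custom database


class FastaBackend:
    """In-process search backend over an explicit set of records.

    Satisfies the backend contract by exact-seed matching (longest shared
    substring on either strand found at or above the word size); used both
    as the custom-database container and, with synthetic records, as the
    mock backend for tests. The seeding logic lives in :mod:`.synth` to
    keep this module free of generator code.
    """

    def __init__(
        self,
        records: Sequence[NucleotideSequence],
        metadata: Mapping[str, Mapping[str, str]],
        nt_like: bool = False,
    ):
        if not records:
            raise InputError("backend requires at least one record")
        self.records = {r.id: r for r in records}
        if len(self.records) != len(records):
            raise InputError("duplicate record ids in backend")
        self.metadata = metadata
        self.nt_like = nt_like
        self._cache: dict[tuple, tuple] = {}

    def subject_length(self, subject_id: str) -> int:
        return len(self.records[subject_id])

    def fetch(self, subject_id: str, start: int, end: int) -> str:
        rec = self.records[subject_id]
        if not (0 <= start < end <= len(rec)):
            raise InputError(
                f"range [{start},{end}) outside record {subject_id!r}"
            )
        return rec.residues[start:end]

    def lineage(self, subject_id: str) -> Optional[Lineage]:
        row = self.metadata.get(subject_id)
        if row is None:
            return None
        try:
            return lineage_of(row)
        except InputError:
            return None

    def search(
        self,
        query: NucleotideSequence,
        word_size: int,
        evalue_cutoff: float,
        max_hits: int,
        taxon_restriction: Optional[TaxonRestriction] = None,
    ) -> list[SearchHit]:
        from .synth import seed_hit  # deferred: synth depends on this module

        hits = []
        for rec in self.records.values():
            if taxon_restriction is not None:
                lin = self.lineage(rec.id)
                if lin is None or not taxon_restriction.admits(lin):
                    continue
            key = (query.id, query.residues[:32], len(query), rec.id)
            if key in self._cache:
                hit = self._cache[key]
            else:
                hit = seed_hit(query, rec)
                self._cache[key] = hit
            if hit is None:
                continue
            h = hit.with_word_size(query, rec, word_size)
            if h is not None and h.evalue <= evalue_cutoff:
                hits.append(h)
        hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        return hits[:max_hits]


def build_custom_db(
    query: NucleotideSequence,
    backend: SearchBackend,
    metadata: Mapping[str, Mapping[str, str]],
    config: SearchConfig | None = None,
) -> FastaBackend:
    """Build the temporary query-specific database for the long-query path.

    Runs the sensitive (build-db) word-size schedule, keeps the best hit
    per species without any similarity-based selection, expands each
    retained subject interval symmetrically around the hit midpoint to
    ``customdb_expansion`` times the query length (clipped to the subject),
    and caps the collection at ``customdb_max_seqs`` sequences.
    """
    config = config or SearchConfig()
    all_hits: list[SearchHit] = []
    ref_lineage: Optional[Lineage] = None

    for iteration in range(1, config.schedule.n_iterations() + 1):
        word_size, rank = schedule_for(iteration, "build_db", config.schedule)
        tr = None
        if rank is not None and ref_lineage is not None:
            tr = TaxonRestriction(rank=rank, value=ref_lineage.rank(rank))
        hits = backend.search(
            query,
            word_size=word_size,
            evalue_cutoff=config.evalue_cutoff,
            max_hits=config.max_hits,
            taxon_restriction=tr,
        )
        if backend.nt_like:
            hits = genomic_filter(hits, metadata)
        all_hits = _dedupe_hits(all_hits + hits)
        if all_hits and ref_lineage is None:
            best = min(all_hits, key=lambda h: (h.evalue, -h.bitscore))
            row = metadata.get(best.subject_id)
            if row is not None:
                try:
                    ref_lineage = lineage_of(row)
                except InputError:
                    ref_lineage = None
        if len(dedupe_best_per_species(all_hits, metadata)) >= config.customdb_max_seqs:
            break

    per_species = dedupe_best_per_species(all_hits, metadata)[
        : config.customdb_max_seqs
    ]
    if not per_species:
        raise NoHomologsError(
            f"custom database empty: no hits for query {query.id!r}"
        )

    target_len = config.customdb_expansion * len(query)
    records = []
    meta_out: dict[str, dict] = {}
    for h in per_species:
        slen = backend.subject_length(h.subject_id)
        mid = (h.subject_start + h.subject_end) // 2
        start = max(0, mid - target_len // 2)
        end = min(slen, start + target_len)
        start = max(0, min(start, end - target_len))  # re-anchor if clipped right
        residues = backend.fetch(h.subject_id, start, end)
        row = dict(metadata.get(h.subject_id, {}))
        rec = NucleotideSequence(
            id=f"{h.subject_id}|{start}-{end}",
            residues=residues,
            taxon=str(row.get("taxon", h.taxon)) or None,
            species=str(row.get("species", "")) or None,
        )
        records.append(rec)
        row["id"] = rec.id
        meta_out[rec.id] = row
    return FastaBackend(records, meta_out, nt_like=False)
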