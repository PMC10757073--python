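"""Synthetic data: homolog families, lineages, and a mock search backend.

Everything the pipeline consumes from the outside world can be generated
here deterministically, so every stage is testable offline:

* ``make_family`` derives homologs from a random root sequence at
  controlled percent divergences (substitution-only, so the measured
  pairwise distance tracks the substitution load), assigns species names
  and four-rank lineages spread over the orders/classes/phyla of one
  kingdom, and can embed a stop-free ORF whose divergence is biased to
  wobble (third codon) positions.
* ``seed_hit`` gives the :class:`~codonscout.search.FastaBackend` its
  blastn-like discoverability rule: a subject is found at word size *w*
  iff it shares an exact substring of length >= *w* with the query (on
  either strand); the reported hit is the maximal shared block. The
  E-value is a deterministic, monotonically decreasing function of the
  shared-block length — its only job is ordering, and it is scaled so
  that every seeded hit passes the default 0.01 cutoff.
* ``make_scorer_fixture`` renders well-formed scorer tabular output for
  parser tests.

What this emulates, and what it does not: word-size-dependent
discoverability, taxonomic restriction and strandedness are faithful in
kind; indel processes, rate heterogeneity and realistic E-value
statistics are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pairwise import distance_percent
from .records import (
    InputError,
    NucleotideSequence,
    reverse_complement,
    write_fasta,
    write_metadata,
)
from .scoring import HSS, serialize_scorer_tabular
from .search import FastaBackend, SearchHit

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}

# E-value scale: query_len * 2**(-block_len) * _EVALUE_SCALE keeps every
# seeded hit (block >= 7) under the default 0.01 cutoff while preserving
# the ordering by shared-block length.
_EVALUE_SCALE = 2.0**-30
_EVALUE_FLOOR = 1e-180


# ---------------------------------------------------------------------------
# family generation


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for a synthetic homolog family."""

    root_length: int = 600
    n_homologs: int = 8
    # spread across the 10-60 % band; the matches/min-length metric with
    # cheap linear gaps saturates near ~40 % for unrelated sequences, so
    # targets are kept inside its reachable range
    target_distances: tuple[float, ...] = (12, 16, 20, 24, 28, 32, 36, 40)
    seed: int = 0
    coding: Optional[tuple[int, int]] = None  # (orf_start, orf_len_codons)
    flank_len: int = 0  # random flanks around each homolog body
    kingdom: str = "Metazoa"

    def __post_init__(self) -> None:
        if len(self.target_distances) != self.n_homologs:
            raise InputError("need one target distance per homolog")
        if any(not 0 <= d <= 100 for d in self.target_distances):
            raise InputError("target distances must be percents in [0, 100]")
        if self.coding is not None:
            orf_start, orf_len = self.coding
            if orf_start < 0 or orf_start + 3 * (orf_len + 1) > self.root_length:
                raise InputError("ORF does not fit in the root sequence")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=length))


def random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n_codons - 1) random non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(rng.choice(BASES, size=3))
        if c not in STOPS:
            codons.append(c)
    return "".join(codons) + "TAA"


def mutate_to_distance(
    seq: NucleotideSequence,
    target_pct: float,
    seed: int,
    wobble_only_range: Optional[tuple[int, int]] = None,
) -> NucleotideSequence:
    """Substitute random positions until the measured distance reaches target.

    Positions are drawn without replacement in a seeded random order;
    substitutions go to a different base. After each batch the distance is
    measured with the pairwise module, and mutation stops the first time it
    reaches ``target_pct``. With ``wobble_only_range`` set, positions inside
    [start, end) are only eligible if they are third codon positions
    relative to ``start`` (synonymous-biased divergence for embedded ORFs).
    """
    if not 0 <= target_pct <= 100:
        raise InputError("target_pct must be in [0, 100]")
    if target_pct == 0:
        return NucleotideSequence(
            id=f"{seq.id}_d0", residues=seq.residues, taxon=seq.taxon,
            species=seq.species,
        )
    rng = np.random.default_rng(seed)
    residues = np.array(list(seq.residues))
    n = len(residues)
    eligible = np.arange(n)
    if wobble_only_range is not None:
        s, e = wobble_only_range
        inside = (eligible >= s) & (eligible < e)
        wobble = inside & ((eligible - s) % 3 == 2)
        eligible = eligible[~inside | wobble]
    order = rng.permutation(eligible)
    batch = max(1, round(n * 0.01))
    mutated = 0
    current = NucleotideSequence(id=seq.id, residues=seq.residues)

    while mutated < len(order):
        take = order[mutated : mutated + batch]
        for pos in take:
            old = residues[pos]
            choices = BASES[BASES != old]
            residues[pos] = rng.choice(choices)
        mutated += len(take)
        current = NucleotideSequence(id=seq.id, residues="".join(residues))
        if distance_percent(seq, current) >= target_pct:
            break
    return NucleotideSequence(
        id=f"{seq.id}_d{target_pct:g}",
        residues=current.residues,
        taxon=seq.taxon,
        species=seq.species,
    )


@dataclass
class Family:
    root: NucleotideSequence
    homologs: list[NucleotideSequence]
    metadata: pd.DataFrame  # columns: id, species, taxon, biomol, 4 ranks
    orf: Optional[tuple[int, int]] = None  # [start, end) of ORF in the root

    @property
    def records(self) -> list[NucleotideSequence]:
        return self.homologs

    def metadata_lookup(self) -> dict[str, dict]:
        return {row["id"]: dict(row) for _, row in self.metadata.iterrows()}


def _lineage_for(i: int, kingdom: str) -> dict[str, str]:
    """Spread homologs over the taxonomy: closest share the root's order,
    then sibling orders, classes and phyla of one kingdom."""
    if i < 2:
        phylum, class_, order_ = "Phylum1", "Class1", "Order1"
    elif i < 4:
        phylum, class_, order_ = "Phylum1", "Class1", f"Order{i}"
    elif i < 6:
        phylum, class_, order_ = "Phylum1", f"Class{i}", f"Order{i}"
    else:
        phylum, class_, order_ = "Phylum2", f"Class{i}", f"Order{i}"
    return {
        "kingdom": kingdom,
        "phylum": phylum,
        "class": class_,
        "order": order_,
    }


def make_family(spec: FamilySpec) -> Family:
    """Generate root + homologs at the requested distances with metadata."""
    rng = np.random.default_rng(spec.seed)
    if spec.coding is not None:
        orf_start, orf_len = spec.coding
        orf_nt = random_orf(orf_len, rng)
        before = random_sequence(orf_start, rng)
        after_len = spec.root_length - orf_start - len(orf_nt)
        after = random_sequence(after_len, rng)
        root_res = before + orf_nt + after
        orf_span = (orf_start, orf_start + len(orf_nt))
    else:
        root_res = random_sequence(spec.root_length, rng)
        orf_span = None
    root = NucleotideSequence(id="query", residues=root_res)

    homologs = []
    rows = []
    for i, target in enumerate(spec.target_distances):
        body = mutate_to_distance(
            root,
            target,
            seed=int(rng.integers(0, 2**31 - 1)),
            wobble_only_range=orf_span,
        )
        res = body.residues
        if spec.flank_len:
            res = (
                random_sequence(spec.flank_len, rng)
                + res
                + random_sequence(spec.flank_len, rng)
            )
        rec = NucleotideSequence(
            id=f"hom{i:02d}",
            residues=res,
            taxon=str(1000 + i),
            species=f"Species {i:02d}",
        )
        homologs.append(rec)
        row = {
            "id": rec.id,
            "species": rec.species,
            "taxon": rec.taxon,
            "biomol": "genomic",
        }
        row.update(_lineage_for(i, spec.kingdom))
        rows.append(row)
    meta = pd.DataFrame(
        rows,
        columns=[
            "id",
            "species",
            "taxon",
            "biomol",
            "kingdom",
            "phylum",
            "class",
            "order",
        ],
    )
    return Family(root=root, homologs=homologs, metadata=meta, orf=orf_span)


# ---------------------------------------------------------------------------
# mock backend seeding


def _longest_common_block(a: str, b: str) -> tuple[int, int, int]:
    """(length, a_pos, b_pos) of the longest exact shared substring.

    Computed exactly with a rolling dynamic program; the first (smallest
    a_pos, then b_pos) maximal block wins ties.
    """
    ea = np.frombuffer(a.encode(), dtype=np.uint8)
    eb = np.frombuffer(b.encode(), dtype=np.uint8)
    best_len, best_i, best_j = 0, 0, 0
    prev = np.zeros(len(eb) + 1, dtype=np.int32)
    for i in range(1, len(ea) + 1):
        cur = np.zeros(len(eb) + 1, dtype=np.int32)
        eq = eb == ea[i - 1]
        cur[1:][eq] = prev[:-1][eq] + 1
        m = int(cur.max())
        if m > best_len:
            best_len = m
            j = int(np.argmax(cur))
            best_i, best_j = i - m, j - m
        prev = cur
    return best_len, best_i, best_j


@dataclass(frozen=True)
class SeedMatch:
    """Longest exact shared block between a query and one subject record."""

    block_len: int
    q_pos: int
    s_pos: int  # position in the searched orientation of the subject
    strand: str

    def with_word_size(
        self, query: NucleotideSequence, rec: NucleotideSequence, word_size: int
    ) -> Optional[SearchHit]:
        """Materialise a hit if the shared block reaches the word size."""
        if self.block_len < word_size:
            return None
        L = self.block_len
        if self.strand == "+":
            s_start, s_end = self.s_pos, self.s_pos + L
        else:  # block found on the reverse complement; map to forward strand
            s_start = len(rec) - (self.s_pos + L)
            s_end = len(rec) - self.s_pos
        evalue = max(_EVALUE_FLOOR, len(query) * 2.0**-L * _EVALUE_SCALE)
        return SearchHit(
            query_id=query.id,
            subject_id=rec.id,
            query_start=self.q_pos,
            query_end=self.q_pos + L,
            subject_start=s_start,
            subject_end=s_end,
            strand=self.strand,
            evalue=evalue,
            identity_percent=100.0,
            bitscore=2.0 * L,
            taxon=rec.taxon or "",
        )


def seed_hit(
    query: NucleotideSequence, rec: NucleotideSequence
) -> Optional[SeedMatch]:
    """Best seed match, oriented by overall alignment strength.

    The longest exact shared block decides *discoverability* at a word
    size, but the block alone cannot pick the strand: at in-band
    divergence the true strand's longest block is short (~10 bp) and a
    random block on the other strand can tie it. The local-alignment
    score of the query against each orientation of the subject picks the
    strand instead (ties prefer plus), mirroring how a seeded search
    scores the extended alignment, not the seed.
    """
    from .pairwise import align_local  # local import: synth <-> pairwise

    fwd = _longest_common_block(query.residues, rec.residues)
    rev = _longest_common_block(query.residues, reverse_complement(rec.residues))
    if fwd[0] == 0 and rev[0] == 0:
        return None
    if rev[0] == 0:
        strand = "+"
    elif fwd[0] == 0:
        strand = "-"
    else:
        score_fwd = align_local(query, rec).score
        score_rev = align_local(query, rec.reverse_complement()).score
        strand = "+" if score_fwd >= score_rev else "-"
    block = fwd if strand == "+" else rev
    return SeedMatch(block_len=block[0], q_pos=block[1], s_pos=block[2], strand=strand)


def make_mock_backend(
    records: Sequence[NucleotideSequence],
    metadata: dict[str, dict] | pd.DataFrame,
    nt_like: bool = False,
) -> FastaBackend:
    """A fully offline search backend over explicit records.

    Discoverability follows the exact longest-shared-substring rule of
    :func:`seed_hit`; taxonomic restriction and the biomol filter are
    honoured via the metadata table.
    """
    if isinstance(metadata, pd.DataFrame):
        metadata = {row["id"]: dict(row) for _, row in metadata.iterrows()}
    return FastaBackend(records, metadata, nt_like=nt_like)


# ---------------------------------------------------------------------------
# scorer fixtures


def make_scorer_fixture(
    hss_spec: Sequence[HSS], window_len: Optional[int] = None,
    ref_name: str = "query",
) -> str:
    """Render window-local HSS as the scorer's 11-column tabular text."""
    for h in hss_spec:
        if window_len is not None and h.q_end > window_len:
            raise InputError(
                f"HSS [{h.q_start},{h.q_end}) exceeds window length {window_len}"
            )
    return serialize_scorer_tabular(hss_spec, ref_name=ref_name)


def write_family_fixtures(outdir: str | Path, spec: FamilySpec) -> dict[str, Path]:
    """Write a family as FASTA + metadata TSV (regenerable from the seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fam = make_family(spec)
    query_fa = outdir / "query.fa"
    homologs_fa = outdir / "homologs.fa"
    meta_tsv = outdir / "metadata.tsv"
    write_fasta([fam.root], query_fa)
    write_fasta(fam.homologs, homologs_fa)
    write_metadata(fam.metadata, meta_tsv)
    return {"query": query_fa, "homologs": homologs_fa, "metadata": meta_tsv}
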