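"""Sequence records and tabular metadata I/O.

A :class:`NucleotideSequence` is the universal currency of the pipeline: a
named DNA sequence, optionally annotated with the species and taxon of the
record it was extracted from. Residues are uppercased on ingest so that
softmasked input behaves like unmasked input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InputError(ValueError):
    """Raised when user-supplied data violates a precondition."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over {A,C,G,T,N}.

    Parameters
    ----------
    id:
        Non-empty identifier, unique within any collection it is placed in.
    residues:
        Non-empty string; lowercased input is uppercased, other characters
        are rejected.
    taxon:
        Optional taxon identifier of the source record.
    species:
        Optional species name of the source record.
    """

    id: str
    residues: str
    taxon: Optional[str] = None
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence id must be non-empty")
        if not self.residues:
            raise InputError(f"sequence {self.id!r} has no residues")
        res = self.residues.upper()
        bad = set(res) - VALID_RESIDUES
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(
            id=self.id,
            residues=self.residues.translate(COMPLEMENT)[::-1],
            taxon=self.taxon,
            species=self.species,
        )

    def slice(self, start: int, end: int, suffix: str = "") -> "NucleotideSequence":
        """Extract [start, end) as a new record, id extended by *suffix*."""
        if not (0 <= start < end <= len(self)):
            raise InputError(
                f"slice [{start},{end}) out of bounds for {self.id!r} "
                f"(length {len(self)})"
            )
        return NucleotideSequence(
            id=self.id + suffix,
            residues=self.residues[start:end],
            taxon=self.taxon,
            species=self.species,
        )


def reverse_complement(residues: str) -> str:
    return residues.upper().translate(COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file; ids must be unique."""
    seqs: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append(NucleotideSequence(id=rec.id, residues=str(rec.seq)))
    return seqs


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write records wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


METADATA_COLUMNS = [
    "id",
    "species",
    "taxon",
    "biomol",
    "kingdom",
    "phylum",
    "class",
    "order",
]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-record metadata TSV (id, species, taxon, biomol, 4 ranks)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"metadata table missing columns: {sorted(missing)}")
    return df.set_index("id", drop=False)


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=METADATA_COLUMNS)


def metadata_lookup(df: pd.DataFrame) -> Mapping[str, dict]:
    """Index the metadata frame as {record id -> row dict}."""
    return {row["id"]: dict(row) for _, row in df.iterrows()}
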