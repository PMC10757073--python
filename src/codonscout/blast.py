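"""Local blastn backend: real seeding, in-process sequence serving.

Wraps ``makeblastdb``/``blastn`` over an explicit FASTA record set so the
pipeline can use genuine blastn word-size seeding where the binaries are
installed. Subject sequences are served from memory (the records are given
explicitly), taxonomic restriction is applied to the returned hits via the
metadata table, and the tabular dialect is the same outfmt-6 extension the
rest of the package speaks.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .records import InputError, NucleotideSequence, write_fasta
from .search import (
    SearchHit,
    TaxonRestriction,
    lineage_of,
    parse_hits_tsv,
)


def blast_available() -> bool:
    return shutil.which("blastn") is not None and shutil.which("makeblastdb") is not None


class BlastnLocalBackend:
    """Search backend backed by a temporary local blastn database."""

    def __init__(
        self,
        records: Sequence[NucleotideSequence],
        metadata: Mapping[str, Mapping[str, str]],
        nt_like: bool = False,
    ):
        if not blast_available():
            raise InputError("blastn/makeblastdb not found on PATH")
        if not records:
            raise InputError("backend requires at least one record")
        self.records = {r.id: r for r in records}
        self.metadata = metadata
        self.nt_like = nt_like
        self._tmp = tempfile.TemporaryDirectory(prefix="codonscout_blastdb_")
        fasta = Path(self._tmp.name) / "db.fa"
        write_fasta(records, fasta)
        proc = subprocess.run(
            [
                "makeblastdb",
                "-in",
                str(fasta),
                "-dbtype",
                "nucl",
                "-out",
                str(Path(self._tmp.name) / "db"),
            ],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise InputError(f"makeblastdb failed: {proc.stderr.strip()[:500]}")
        self._db = str(Path(self._tmp.name) / "db")

    def subject_length(self, subject_id: str) -> int:
        return len(self.records[subject_id])

    def fetch(self, subject_id: str, start: int, end: int) -> str:
        rec = self.records[subject_id]
        if not (0 <= start < end <= len(rec)):
            raise InputError(f"range [{start},{end}) outside record {subject_id!r}")
        return rec.residues[start:end]

    def search(
        self,
        query: NucleotideSequence,
        word_size: int,
        evalue_cutoff: float,
        max_hits: int,
        taxon_restriction: Optional[TaxonRestriction] = None,
    ) -> list[SearchHit]:
        with tempfile.NamedTemporaryFile(
            "w", suffix=".fa", dir=self._tmp.name, delete=False
        ) as fh:
            fh.write(f">{query.id}\n{query.residues}\n")
            qpath = fh.name
        proc = subprocess.run(
            [
                "blastn",
                "-query",
                qpath,
                "-db",
                self._db,
                "-word_size",
                str(word_size),
                "-evalue",
                str(evalue_cutoff),
                "-max_target_seqs",
                str(max_hits),
                "-outfmt",
                "6 qseqid sseqid pident length evalue bitscore qstart qend "
                "sstart send sstrand staxids",
            ],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise InputError(f"blastn failed: {proc.stderr.strip()[:500]}")
        hits = parse_hits_tsv(proc.stdout)
        out = []
        for h in hits:
            row = self.metadata.get(h.subject_id)
            if taxon_restriction is not None:
                if row is None:
                    continue
                try:
                    lin = lineage_of(row)
                except InputError:
                    continue
                if not taxon_restriction.admits(lin):
                    continue
            if row is not None and row.get("taxon"):
                h = replace(h, taxon=str(row["taxon"]))
            out.append(h)
        out.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        return out[:max_hits]
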