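"""Adapters for the external aligner and coding-potential scorer.

The multiple alignment and the coding-potential statistics themselves are
external tools; this module owns only the contracts around them: building a
validated MSA block with the query row first, invoking the scorer, and
parsing its tabular output into high-scoring-segment (HSS) records with
normalised coordinates, strands and frames.

Tabular dialect (scorer version 0.3, 11 tab-separated columns)::

    hss_id  strand  frame  length_aa  aln_from  aln_to  ref_name  ref_start  ref_end  score  p

``frame`` is 1..3 on input, coordinates are 1-based inclusive on the
reference (query/window) row. The parser converts to frame 0..2 and
0-based half-open coordinates. ``parse`` and ``serialize`` are exact
inverses so fixtures and exports round-trip.

Stub adapters ship here so the whole pipeline runs and is testable without
any external binary; subprocess adapters for Clustal Omega, MAFFT and
RNAcode are thin wrappers used when the binaries are installed.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Protocol, Sequence

from .records import InputError, NucleotideSequence, write_fasta
from .windows import SubQuery, map_to_query


class ScoringError(RuntimeError):
    """An adapter failed or returned output violating its contract."""


@dataclass(frozen=True)
class MSABlock:
    """An alignment of the query window (first row) with its homologs."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    window: SubQuery

    def __post_init__(self) -> None:
        if len(self.rows) < 3:
            raise ScoringError(
                f"alignment has {len(self.rows)} rows; need the query plus "
                "at least 2 homologs"
            )
        if len(self.ids) != len(self.rows):
            raise ScoringError("ids/rows length mismatch")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ScoringError("alignment rows have unequal lengths")
        ref_ungapped = self.rows[0].replace("-", "")
        if ref_ungapped != self.window.residues:
            raise ScoringError(
                "ungapped reference row does not equal the window residues"
            )

    @property
    def reference_id(self) -> str:
        return self.ids[0]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i : i + 60] + "\n")


@dataclass(frozen=True)
class HSS:
    """One high-scoring (putatively coding) segment.

    ``q_start``/``q_end`` are half-open; window-local straight after
    parsing, query coordinates after :func:`score_window`. ``frame`` is the
    codon phase 0..2 of the start relative to the coordinate origin on the
    segment's strand; after query mapping it is normalised so segments from
    different windows are comparable (see :func:`normalise_frame`).
    """

    strand: str
    frame: int
    length_aa: int
    q_start: int
    q_end: int
    score: float
    p_value: float
    window_index: int | tuple[int, ...] = 0
    hss_id: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"bad strand {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise InputError(f"frame must be 0..2, got {self.frame}")
        if not (0 < self.p_value <= 1.0):
            raise InputError(f"p-value {self.p_value} outside (0, 1]")
        if not (0 <= self.q_start < self.q_end):
            raise InputError("HSS interval must be non-empty")

    def length_nt(self) -> int:
        return self.q_end - self.q_start

    def windows(self) -> tuple[int, ...]:
        w = self.window_index
        return w if isinstance(w, tuple) else (w,)


# ---------------------------------------------------------------------------
# aligner adapters


class Aligner(Protocol):
    def align(self, seqs: Sequence[NucleotideSequence]) -> list[tuple[str, str]]:
        """Return (id, aligned row) pairs for all inputs."""
        ...


class StubAligner:
    """Deterministic gap-free 'alignment': right-pads with gaps.

    Adequate whenever the test inputs are equal-length (the pipeline's
    extended candidates are); keeps the suite independent of any binary.
    """

    def align(self, seqs: Sequence[NucleotideSequence]) -> list[tuple[str, str]]:
        if not seqs:
            raise ScoringError("no sequences to align")
        width = max(len(s) for s in seqs)
        return [(s.id, s.residues.ljust(width, "-")) for s in seqs]


class SubprocessAligner:
    """Thin wrapper over a command-line multiple aligner (FASTA in/out)."""

    def __init__(self, executable: str, args: Sequence[str]):
        self.executable = executable
        self.args = list(args)

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def align(self, seqs: Sequence[NucleotideSequence]) -> list[tuple[str, str]]:
        if not self.available():
            raise ScoringError(f"{self.executable} not found on PATH")
        with tempfile.TemporaryDirectory(prefix="codonscout_aln_") as tmp:
            infile = Path(tmp) / "in.fa"
            write_fasta(seqs, infile)
            cmd = [self.executable] + [
                a.format(infile=str(infile)) for a in self.args
            ]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise ScoringError(
                    f"{self.executable} failed: {proc.stderr.strip()[:500]}"
                )
            out = []
            cur_id, cur = None, []
            for line in proc.stdout.splitlines():
                if line.startswith(">"):
                    if cur_id is not None:
                        out.append((cur_id, "".join(cur)))
                    cur_id, cur = line[1:].split()[0], []
                elif line.strip():
                    cur.append(line.strip().upper())
            if cur_id is not None:
                out.append((cur_id, "".join(cur)))
            return out


def clustal_omega_aligner() -> SubprocessAligner:
    return SubprocessAligner("clustalo", ["-i", "{infile}", "--outfmt=fa"])


def mafft_aligner() -> SubprocessAligner:
    return SubprocessAligner("mafft", ["--auto", "--quiet", "{infile}"])


def build_msa(
    window: SubQuery,
    query_id: str,
    homologs: Sequence[NucleotideSequence],
    aligner: Aligner,
) -> MSABlock:
    """Align the window with its homologs; query row first, validated."""
    if len(homologs) < 2:
        raise ScoringError(
            f"need at least 2 homologs to build an alignment, got {len(homologs)}"
        )
    ref = window.as_sequence(query_id)
    rows = aligner.align([ref] + list(homologs))
    if len(rows) != len(homologs) + 1:
        raise ScoringError(
            f"aligner returned {len(rows)} rows for {len(homologs) + 1} inputs"
        )
    by_id = {sid: row for sid, row in rows}
    if ref.id not in by_id:
        raise ScoringError(f"aligner output lost the query row {ref.id!r}")
    ordered_ids = [ref.id] + [sid for sid, _ in rows if sid != ref.id]
    return MSABlock(
        ids=tuple(ordered_ids),
        rows=tuple(by_id[sid] for sid in ordered_ids),
        window=window,
    )


# ---------------------------------------------------------------------------
# scorer tabular dialect

N_COLUMNS = 11


def parse_scorer_tabular(text: str) -> list[HSS]:
    """Parse the scorer's 11-column tabular output into window-local HSS.

    Empty output (or comment-only output) parses to an empty list. Frames
    1..3 become 0..2; 1-based inclusive reference coordinates become
    0-based half-open.
    """
    out: list[HSS] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != N_COLUMNS:
            raise ScoringError(
                f"line {lineno}: expected {N_COLUMNS} tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            (
                hss_id,
                strand,
                frame,
                length_aa,
                _aln_from,
                _aln_to,
                _ref_name,
                ref_start,
                ref_end,
                score,
                p,
            ) = fields
            hss = HSS(
                strand=strand,
                frame=int(frame) - 1,
                length_aa=int(length_aa),
                q_start=int(ref_start) - 1,
                q_end=int(ref_end),
                score=float(score),
                p_value=float(p),
                hss_id=int(hss_id),
            )
        except (ValueError, InputError) as exc:
            raise ScoringError(f"line {lineno}: {exc}") from exc
        out.append(hss)
    return out


def serialize_scorer_tabular(
    hss_list: Sequence[HSS], ref_name: str = "query"
) -> str:
    """Inverse of :func:`parse_scorer_tabular` (window-local coordinates)."""
    lines = []
    for h in hss_list:
        lines.append(
            "\t".join(
                [
                    str(h.hss_id),
                    h.strand,
                    str(h.frame + 1),
                    str(h.length_aa),
                    str(h.q_start + 1),
                    str(h.q_end),
                    ref_name,
                    str(h.q_start + 1),
                    str(h.q_end),
                    f"{h.score:.2f}",
                    f"{h.p_value:g}",
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# scorer adapters


class Scorer(Protocol):
    def score(self, msa: MSABlock) -> str:
        """Run the coding-potential scorer; return its tabular output."""
        ...


class StubScorer:
    """Replays canned tabular output, optionally per window index."""

    def __init__(self, tabular: str = "", per_window: Optional[dict] = None):
        self.tabular = tabular
        self.per_window = per_window or {}

    def score(self, msa: MSABlock) -> str:
        return self.per_window.get(msa.window.index, self.tabular)


class SubprocessScorer:
    """Wrapper over the RNAcode binary, tabular output, default parameters."""

    def __init__(self, executable: str = "RNAcode"):
        self.executable = executable

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def score(self, msa: MSABlock) -> str:
        if not self.available():
            raise ScoringError(f"{self.executable} not found on PATH")
        with tempfile.TemporaryDirectory(prefix="codonscout_score_") as tmp:
            aln = Path(tmp) / "block.aln"
            # scorer consumes CLUSTAL W formatted alignments
            with open(aln, "w") as fh:
                fh.write("CLUSTAL W\n\n")
                for sid, row in zip(msa.ids, msa.rows):
                    fh.write(f"{sid[:30]:<32}{row}\n")
            proc = subprocess.run(
                [self.executable, "--tabular", str(aln)],
                capture_output=True,
                text=True,
            )
            if proc.returncode != 0:
                raise ScoringError(
                    f"{self.executable} failed: {proc.stderr.strip()[:500]}"
                )
            return proc.stdout


def normalise_frame(h: HSS, query_length: int) -> HSS:
    """Re-express the frame in query space so windows are comparable.

    Plus strand: phase of the segment start from the query start.
    Minus strand: phase of the segment end from the query end (codons are
    read right-to-left on the minus strand).
    """
    if h.strand == "+":
        frame = h.q_start % 3
    else:
        frame = (query_length - h.q_end) % 3
    return replace(h, frame=frame)


def score_window(
    msa: MSABlock,
    scorer: Scorer,
    query_length: int,
) -> list[HSS]:
    """Score one alignment block; return HSS in query coordinates.

    A scorer run that reports no segments is a successful negative result,
    not an error.
    """
    try:
        text = scorer.score(msa)
    except ScoringError:
        raise
    except Exception as exc:  # adapter crashed in an unexpected way
        raise ScoringError(f"scorer adapter failed: {exc}") from exc
    out = []
    for h in parse_scorer_tabular(text):
        if h.q_end > len(msa.window):
            raise ScoringError(
                f"HSS [{h.q_start},{h.q_end}) outside window of length "
                f"{len(msa.window)}"
            )
        q_start, q_end = map_to_query(msa.window, (h.q_start, h.q_end))
        h = replace(
            h, q_start=q_start, q_end=q_end, window_index=msa.window.index
        )
        out.append(normalise_frame(h, query_length))
    return out
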