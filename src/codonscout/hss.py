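"""Post-processing of high-scoring segments across windows.

Four operations collate raw per-window scorer output into final
predictions:

* ``merge_in_frame`` — segments re-detected in the overlap zone of
  adjacent windows (same strand, same query-space codon phase,
  overlapping or abutting) are unioned into one prediction.
* ``resolve_shadows`` — a genuine coding region tends to induce a weaker
  but still significant "shadow" segment on the opposite strand or in
  another frame, a statistical artifact of the genetic code; among
  mutually overlapping segments that disagree in strand or frame only the
  most significant one is kept.
* ``filter_p`` — the display cutoff (default p < 0.05).
* ``translate_hss`` — standard-genetic-code translation for protein FASTA
  export.

Exports are byte-deterministic: TSV (the scorer's fields in query
coordinates, re-ingestable), BED6 (0-based half-open), GFF3 (1-based
inclusive), protein FASTA and a run summary of the applied thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio.Seq import Seq

from .records import InputError, NucleotideSequence, reverse_complement
from .scoring import HSS
from .windows import SubQuery

logger = logging.getLogger(__name__)

GFF_SOURCE = "codonscout"
GFF_TYPE = "CDS_region"


@dataclass
class HSSReport:
    """Final result container: the query, its windows, and the HSS list."""

    query_id: str
    query_length: int
    hss: list[HSS]
    windows: list[SubQuery] = field(default_factory=list)
    filters_applied: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for h in self.hss:
            if not (0 <= h.q_start < h.q_end <= self.query_length):
                raise InputError(
                    f"HSS [{h.q_start},{h.q_end}) outside query of length "
                    f"{self.query_length}"
                )


def filter_p(hss: Sequence[HSS], cutoff: float = 0.05) -> list[HSS]:
    """Keep segments with p-value strictly below the cutoff; order preserved."""
    return [h for h in hss if h.p_value < cutoff]


def _overlap(a: HSS, b: HSS) -> bool:
    return a.q_start < b.q_end and b.q_start < a.q_end


def _same_phase(a: HSS, b: HSS) -> bool:
    return a.strand == b.strand and a.frame == b.frame


def resolve_shadows(hss: Sequence[HSS]) -> list[HSS]:
    """Keep only the best segment in each group of conflicting overlaps.

    Conflicts are overlapping segments that differ in strand or frame.
    Groups are connected components of the conflict graph; within a group
    the lowest p-value wins (ties: higher score, then leftmost start).
    Segments without conflicts pass through untouched. Output in query
    order (start, end, strand, frame).
    """
    items = list(hss)
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _overlap(items[i], items[j]) and not _same_phase(
                items[i], items[j]
            ):
                parent[find(i)] = find(j)

    by_group: dict[int, list[HSS]] = {}
    for i, h in enumerate(items):
        by_group.setdefault(find(i), []).append(h)

    kept = []
    for group in by_group.values():
        best = min(group, key=lambda h: (h.p_value, -h.score, h.q_start, h.q_end))
        kept.append(best)
    return sorted(kept, key=lambda h: (h.q_start, h.q_end, h.strand, h.frame))


def _trim_to_codons(start: int, end: int, anchor: HSS) -> tuple[int, int]:
    """Snap an interval to codon boundaries of the anchor's frame.

    Plus strand codons are anchored at the anchor's start; minus strand
    codons are read right-to-left and anchored at the anchor's end.
    """
    if anchor.strand == "+":
        start += (anchor.q_start - start) % 3
        end -= (end - start) % 3
    else:
        end -= (end - anchor.q_end) % 3
        start += (end - start) % 3
    return start, end


def _merge_members(members: list[HSS]) -> HSS:
    anchor = min(members, key=lambda x: (x.p_value, -x.score, x.q_start))
    start = min(m.q_start for m in members)
    end = max(m.q_end for m in members)
    start, end = _trim_to_codons(start, end, anchor)
    if end <= start:  # degenerate after trimming; fall back to the anchor
        start, end = anchor.q_start, anchor.q_end
        if end - (end - start) % 3 > start:
            end -= (end - start) % 3
    wins = tuple(sorted({w for m in members for w in m.windows()}))
    return HSS(
        strand=anchor.strand,
        frame=anchor.frame,
        length_aa=(end - start) // 3,
        q_start=start,
        q_end=end,
        score=max(m.score for m in members),
        p_value=min(m.p_value for m in members),
        window_index=wins[0] if len(wins) == 1 else wins,
        hss_id=anchor.hss_id,
    )


def merge_in_frame(hss: Sequence[HSS]) -> list[HSS]:
    """Union overlapping-or-abutting segments of equal strand and frame.

    The merged segment takes the minimum p-value and maximum score of its
    members, records all contributing window indices, and is trimmed to
    codon boundaries anchored at its most significant member (singletons
    are codon-trimmed the same way, so every output length is a multiple
    of 3). Output in query order.
    """
    groups: dict[tuple[str, int], list[HSS]] = {}
    for h in hss:
        groups.setdefault((h.strand, h.frame), []).append(h)

    merged: list[HSS] = []
    for members in groups.values():
        members.sort(key=lambda h: (h.q_start, h.q_end))
        run = [members[0]]
        for h in members[1:]:
            if h.q_start <= max(m.q_end for m in run):
                run.append(h)
            else:
                merged.append(_merge_members(run))
                run = [h]
        merged.append(_merge_members(run))
    return sorted(merged, key=lambda h: (h.q_start, h.q_end, h.strand, h.frame))


def translate_hss(query: NucleotideSequence, h: HSS) -> str:
    """Translate the segment with the standard genetic code.

    Minus-strand segments are reverse-complemented first. Internal stop
    codons are rendered '*' and logged as a warning (a real coding region
    should not contain them).
    """
    length = h.q_end - h.q_start
    if length % 3 != 0:
        raise InputError(
            f"HSS length {length} not divisible by 3; merge-normalisation "
            "should have trimmed it"
        )
    nt = query.residues[h.q_start : h.q_end]
    if h.strand == "-":
        nt = reverse_complement(nt)
    protein = str(Seq(nt).translate())
    if "*" in protein[:-1] or (protein.endswith("*") and protein.count("*") > 1):
        logger.warning(
            "internal stop codon(s) in HSS [%d,%d) strand %s of %s",
            h.q_start,
            h.q_end,
            h.strand,
            query.id,
        )
    return protein


# ---------------------------------------------------------------------------
# export

TSV_HEADER = [
    "hss_id",
    "strand",
    "frame",
    "length_aa",
    "q_start",
    "q_end",
    "score",
    "p_value",
    "windows",
]


def hss_to_tsv(report: HSSReport) -> str:
    lines = ["\t".join(TSV_HEADER)]
    for h in report.hss:
        lines.append(
            "\t".join(
                [
                    str(h.hss_id),
                    h.strand,
                    str(h.frame),
                    str(h.length_aa),
                    str(h.q_start),
                    str(h.q_end),
                    f"{h.score:.2f}",
                    f"{h.p_value:g}",
                    ",".join(str(w) for w in h.windows()),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def hss_from_tsv(text: str) -> list[HSS]:
    """Re-ingest the TSV export (inverse of :func:`hss_to_tsv`)."""
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines or lines[0].split("\t") != TSV_HEADER:
        raise InputError("not a codonscout HSS TSV (bad header)")
    out = []
    for line in lines[1:]:
        f = line.split("\t")
        wins = tuple(int(x) for x in f[8].split(",")) if f[8] else (0,)
        out.append(
            HSS(
                hss_id=int(f[0]),
                strand=f[1],
                frame=int(f[2]),
                length_aa=int(f[3]),
                q_start=int(f[4]),
                q_end=int(f[5]),
                score=float(f[6]),
                p_value=float(f[7]),
                window_index=wins[0] if len(wins) == 1 else wins,
            )
        )
    return out


def _hss_name(h: HSS) -> str:
    return f"hss{h.hss_id}_f{h.frame}{h.strand}_p{h.p_value:g}"


def hss_to_bed(report: HSSReport) -> str:
    """BED6: 0-based half-open, score column = scorer score (clamped >= 0)."""
    lines = []
    for h in report.hss:
        lines.append(
            "\t".join(
                [
                    report.query_id,
                    str(h.q_start),
                    str(h.q_end),
                    _hss_name(h),
                    f"{max(h.score, 0):.0f}",
                    h.strand,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def hss_to_gff3(report: HSSReport) -> str:
    """GFF3: 1-based inclusive, phase column carries the frame."""
    lines = ["##gff-version 3"]
    for h in report.hss:
        attrs = (
            f"ID={_hss_name(h)};frame={h.frame};p_value={h.p_value:g};"
            f"windows={','.join(str(w) for w in h.windows())}"
        )
        lines.append(
            "\t".join(
                [
                    report.query_id,
                    GFF_SOURCE,
                    GFF_TYPE,
                    str(h.q_start + 1),
                    str(h.q_end),
                    f"{h.score:.2f}",
                    h.strand,
                    str(h.frame),
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def proteins_to_fasta(query: NucleotideSequence, report: HSSReport) -> str:
    chunks = []
    for h in report.hss:
        protein = translate_hss(query, h)
        chunks.append(f">{query.id}|{_hss_name(h)}\n")
        for i in range(0, len(protein), 60):
            chunks.append(protein[i : i + 60] + "\n")
    return "".join(chunks)


def run_summary(report: HSSReport) -> str:
    lines = [
        f"query_id\t{report.query_id}",
        f"query_length\t{report.query_length}",
        f"n_windows\t{len(report.windows)}",
        f"n_hss\t{len(report.hss)}",
    ]
    for key in sorted(report.filters_applied):
        lines.append(f"{key}\t{report.filters_applied[key]}")
    lines.append("window\tstart\tend")
    for w in report.windows:
        lines.append(f"{w.index}\t{w.q_start}\t{w.q_end}")
    return "\n".join(lines) + "\n"


def export(
    report: HSSReport,
    query: NucleotideSequence,
    outdir: str | Path,
    formats: Sequence[str] = ("tsv", "bed", "gff3", "proteins", "summary"),
) -> dict[str, Path]:
    """Write the selected export formats; returns {format: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    writers = {
        "tsv": ("hss.tsv", lambda: hss_to_tsv(report)),
        "bed": ("hss.bed", lambda: hss_to_bed(report)),
        "gff3": ("hss.gff3", lambda: hss_to_gff3(report)),
        "proteins": ("hss_proteins.fa", lambda: proteins_to_fasta(query, report)),
        "summary": ("run_summary.tsv", lambda: run_summary(report)),
    }
    written = {}
    for fmt in formats:
        if fmt not in writers:
            raise InputError(f"unknown export format {fmt!r}")
        name, render = writers[fmt]
        path = outdir / name
        path.write_text(render())
        written[fmt] = path
    return written


def plot_overview(
    report: HSSReport, path: str | Path
) -> None:  # pragma: no cover - optional visual aid
    """Optional one-panel overview: an arrow per HSS, colored by frame,
    window boundaries as dashed lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 2 + 0.3 * max(1, len(report.hss))))
    colors = {0: "tab:blue", 1: "tab:orange", 2: "tab:green"}
    for i, h in enumerate(report.hss):
        y = i + 1
        dx = h.q_end - h.q_start
        x = h.q_start if h.strand == "+" else h.q_end
        ax.arrow(
            x,
            y,
            dx if h.strand == "+" else -dx,
            0,
            width=0.15,
            head_width=0.3,
            head_length=min(30, dx / 4),
            length_includes_head=True,
            color=colors[h.frame],
        )
    for w in report.windows:
        ax.axvline(w.q_start, ls="--", lw=0.5, color="grey")
        ax.axvline(w.q_end, ls="--", lw=0.5, color="grey")
    ax.set_xlim(0, report.query_length)
    ax.set_ylim(0, len(report.hss) + 1)
    ax.set_xlabel(f"{report.query_id} (bp)")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
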