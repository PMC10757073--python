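"""End-to-end orchestration: retrieval, alignment, scoring, collation.

Two paths share all machinery:

* short query (not longer than the windowing threshold): one iterative
  search against the backend, one alignment, one scorer run;
* long query: a sensitive search first builds a temporary custom database
  of up to 300 per-species regions (5x query length), the query is split
  into overlapping 1000 bp windows, and each window is searched (single
  pass, most specific word size), aligned and scored independently against
  that database; per-window results are mapped back to query coordinates.

Post-processing is merge (same strand and frame across windows), then
shadow resolution (best of conflicting overlaps), then the p < 0.05
display filter. A window that fails to collect enough homologs is skipped
with a warning — the remaining windows still inform the result — but if
every window fails the run fails.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Optional

from .config import RunConfig
from .hss import HSSReport, export, filter_p, merge_in_frame, resolve_shadows
from .pairwise import distance_percent
from .records import NucleotideSequence
from .scoring import Aligner, Scorer, ScoringError, build_msa, score_window
from .search import (
    NoHomologsError,
    SearchBackend,
    build_custom_db,
    dedupe_best_per_species,
    extend_hit,
    iterative_search,
    schedule_for,
)
from .selection import (
    InsufficientHomologsError,
    band_filter,
    reduce_cand_min_dist,
    select_final,
)
from .windows import is_long_query, split_query

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """The run could not produce any scored window."""


def _select_single_pass(
    window_seq: NucleotideSequence,
    backend: SearchBackend,
    metadata: Mapping[str, Mapping[str, str]],
    cfg: RunConfig,
):
    """One-shot selection against a (small) database: search at the most
    specific word size, extend, band-filter, cluster, select."""
    sc = cfg.search_config()
    word_size, _ = schedule_for(1, "full", sc.schedule)
    hits = backend.search(
        window_seq,
        word_size=word_size,
        evalue_cutoff=sc.evalue_cutoff,
        max_hits=sc.max_hits,
        taxon_restriction=None,
    )
    if not hits:
        raise NoHomologsError(f"no hits for {window_seq.id!r}")
    deduped = dedupe_best_per_species(hits, metadata)
    cands = []
    for h in deduped:
        c = extend_hit(h, len(window_seq), backend, metadata)
        dist = distance_percent(window_seq, c.sequence, sc.model)
        cands.append(replace(c, dist_to_query=dist))
    in_band = band_filter(cands, sc.band)
    reps = reduce_cand_min_dist(
        sorted(in_band, key=lambda c: (c.evalue, c.id)),
        sc.min_pair_dist,
        model=sc.model,
    )
    logger.info(
        "%s: %d hits, %d per-species, %d in band, %d representatives",
        window_seq.id,
        len(hits),
        len(deduped),
        len(in_band),
        len(reps),
    )
    return select_final(reps, sc.limits)


def run_pipeline(
    query: NucleotideSequence,
    backend: SearchBackend,
    metadata: Mapping[str, Mapping[str, str]],
    cfg: RunConfig,
    aligner: Aligner,
    scorer: Scorer,
    outdir: Optional[str | Path] = None,
) -> HSSReport:
    """Run the whole pipeline on one query; optionally export files."""
    counts: dict[str, int] = {}
    if is_long_query(query, cfg.windowing):
        windows = split_query(query, cfg.windowing)
        custom_db = build_custom_db(query, backend, metadata, cfg.search_config())
        counts["customdb_seqs"] = len(custom_db.records)
        logger.info(
            "long query (%d bp): %d windows, custom database of %d sequences",
            len(query),
            len(windows),
            len(custom_db.records),
        )
        raw_hss = []
        scored_windows = 0
        for w in windows:
            wseq = w.as_sequence(query.id)
            try:
                selected = _select_single_pass(
                    wseq, custom_db, custom_db.metadata, cfg
                )
                msa = build_msa(
                    w, query.id, [c.sequence for c in selected], aligner
                )
                raw_hss.extend(score_window(msa, scorer, len(query)))
                scored_windows += 1
            except (NoHomologsError, InsufficientHomologsError, ScoringError) as exc:
                logger.warning("window %d skipped: %s", w.index, exc)
        if scored_windows == 0:
            raise PipelineError(
                f"all {len(windows)} windows failed for query {query.id!r}"
            )
        counts["windows_scored"] = scored_windows
    else:
        windows = split_query(query, cfg.windowing)  # single window
        reps = iterative_search(query, backend, metadata, cfg.search_config())
        selected = select_final(reps, cfg.limits)
        counts["representatives"] = len(reps)
        counts["selected"] = len(selected)
        msa = build_msa(
            windows[0], query.id, [c.sequence for c in selected], aligner
        )
        raw_hss = score_window(msa, scorer, len(query))
        counts["windows_scored"] = 1

    counts["hss_raw"] = len(raw_hss)
    merged = merge_in_frame(raw_hss) if raw_hss else []
    counts["hss_merged"] = len(merged)
    resolved = resolve_shadows(merged)
    counts["hss_after_shadow"] = len(resolved)
    final = filter_p(resolved, cfg.p_display_cutoff)
    counts["hss_final"] = len(final)
    logger.info("HSS: %d raw, %d merged, %d after shadow resolution, %d at p < %g",
                len(raw_hss), len(merged), len(resolved), len(final),
                cfg.p_display_cutoff)

    filters = dict(cfg.effective())
    filters.update(counts)
    report = HSSReport(
        query_id=query.id,
        query_length=len(query),
        hss=final,
        windows=windows,
        filters_applied=filters,
    )
    if outdir is not None:
        export(report, query, outdir)
    return report
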