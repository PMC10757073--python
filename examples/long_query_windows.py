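"""Long-query path: windowing, custom database, cross-window merging.

A 2500 bp query is split into four overlapping 1000 bp windows, a
temporary custom database is built from the per-species best hits, each
window is searched and scored independently, and two window-local reports
of the same coding region are merged into a single prediction.
"""

from codonscout import RunConfig, StubAligner, StubScorer, run_pipeline, split_query
from codonscout.scoring import HSS
from codonscout.synth import (
    FamilySpec,
    make_family,
    make_mock_backend,
    make_scorer_fixture,
)

fam = make_family(
    FamilySpec(
        root_length=2500,
        n_homologs=5,
        target_distances=(12, 16, 20, 24, 28),
        seed=23,
        flank_len=400,  # homologs embedded in flanking sequence
    )
)
backend = make_mock_backend(fam.homologs, fam.metadata)

windows = split_query(fam.root)
print("windows:", [(w.index, w.q_start, w.q_end) for w in windows])

# the same coding region reported by adjacent windows 1 and 2, each in
# window-local coordinates inside their 300 bp overlap zone
per_window = {
    1: make_scorer_fixture(
        [HSS(strand="+", frame=0, length_aa=60, q_start=602, q_end=782,
             score=30.0, p_value=0.001)]
    ),
    2: make_scorer_fixture(
        [HSS(strand="+", frame=0, length_aa=60, q_start=4, q_end=184,
             score=28.0, p_value=0.003)]
    ),
}

report = run_pipeline(
    fam.root, backend, fam.metadata_lookup(), RunConfig(),
    StubAligner(), StubScorer("", per_window=per_window),
)
print(f"custom database sequences: {report.filters_applied['customdb_seqs']}")
for h in report.hss:
    print(
        f"merged HSS: query [{h.q_start},{h.q_end}) frame {h.frame} "
        f"p={h.p_value:g} from windows {h.windows()}"
    )
# Both window-local segments describe the same query interval in the same
# codon phase, so they collapse into one prediction spanning the window
# boundary, keeping the smaller p-value.
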