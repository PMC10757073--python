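"""Iterative search: schedule, filtering, extension, custom database."""

from __future__ import annotations

import numpy as np
import pytest

from codonscout.records import InputError, NucleotideSequence as NS, reverse_complement
from codonscout.search import (
    FastaBackend,
    NoHomologsError,
    SearchConfig,
    SearchHit,
    SearchSchedule,
    TaxonRestriction,
    build_custom_db,
    dedupe_best_per_species,
    extend_hit,
    format_hits_tsv,
    genomic_filter,
    iterative_search,
    parse_hits_tsv,
    schedule_for,
)
from codonscout.synth import (
    FamilySpec,
    make_family,
    make_mock_backend,
    random_sequence,
)


def hit(subject="s1", qs=0, qe=100, ss=0, se=100, strand="+", ev=1e-10,
        bits=100.0, taxon=""):
    return SearchHit(
        query_id="q",
        subject_id=subject,
        query_start=qs,
        query_end=qe,
        subject_start=ss,
        subject_end=se,
        strand=strand,
        evalue=ev,
        identity_percent=95.0,
        bitscore=bits,
        taxon=taxon,
    )


class TestSchedule:
    @pytest.mark.parametrize(
        "iteration,mode,expected",
        [
            (1, "full", (18, None)),
            (5, "build_db", (7, "kingdom")),
            (3, "full", (10, "class")),
            (1, "build_db", (14, None)),
            (2, "full", (14, "order")),
            (4, "build_db", (8, "phylum")),
        ],
    )
    def test_word_size_and_rank_table(self, iteration, mode, expected):
        assert schedule_for(iteration, mode) == expected

    def test_out_of_range_iteration_rejected(self):
        for bad in (0, 6):
            with pytest.raises(InputError):
                schedule_for(bad, "full")

    def test_word_sizes_non_increasing(self):
        s = SearchSchedule()
        for col in (0, 1):
            sizes = [r[col] for r in s.rows]
            assert sizes == sorted(sizes, reverse=True)

    def test_increasing_schedule_rejected(self):
        with pytest.raises(InputError):
            SearchSchedule(
                rows=((7, 7, None), (8, 8, "order"), (9, 9, "class"),
                      (10, 10, "phylum"), (11, 11, "kingdom"))
            )


class TestGenomicFilter:
    META = {
        "g1": {"biomol": "genomic"},
        "g2": {"biomol": "Genomic"},
        "m1": {"biomol": "mRNA"},
    }

    def test_retains_only_genomic_case_insensitive(self):
        hits = [hit("g1"), hit("m1"), hit("g2")]
        kept = genomic_filter(hits, self.META)
        assert [h.subject_id for h in kept] == ["g1", "g2"]

    def test_empty_input(self):
        assert genomic_filter([], self.META) == []

    def test_all_transcripts_logs_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert genomic_filter([hit("m1")], self.META) == []
        assert "no genomic hits" in caplog.text

    def test_missing_metadata_drops_hit_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert genomic_filter([hit("unknown")], self.META) == []
        assert "unknown" in caplog.text


class TestHitDialect:
    def test_roundtrip(self):
        hits = [
            hit("s1", qs=5, qe=105, ss=10, se=110, strand="+", taxon="9606"),
            hit("s2", qs=0, qe=50, ss=200, se=250, strand="-", ev=1e-3,
                taxon="10090"),
        ]
        again = parse_hits_tsv(format_hits_tsv(hits))
        assert again == hits

    def test_minus_strand_blast_convention(self):
        # blast reports sstart > send on the minus strand, 1-based inclusive
        line = "q\ts1\t95.000\t100\t1e-20\t180.0\t1\t100\t200\t101\tminus\t77\n"
        (h,) = parse_hits_tsv(line)
        assert h.strand == "-"
        assert (h.subject_start, h.subject_end) == (100, 200)
        assert (h.query_start, h.query_end) == (0, 100)

    def test_empty_text(self):
        assert parse_hits_tsv("") == []


class _SubjectBackend:
    """Minimal backend serving one explicit subject sequence."""

    nt_like = False

    def __init__(self, residues: str):
        self.residues = residues

    def subject_length(self, subject_id):
        return len(self.residues)

    def fetch(self, subject_id, start, end):
        return self.residues[start:end]


class TestExtendHit:
    def test_flank_projection_plus_strand(self):
        subject = random_sequence(1000, np.random.default_rng(0))
        be = _SubjectBackend(subject)
        # hit covers query [100,300) of a 400-length query at subject [400,600)
        c = extend_hit(hit(qs=100, qe=300, ss=400, se=600), 400, be)
        assert c.sequence.residues == subject[300:700]

    def test_full_cover_hit_equals_subject_slice(self):
        subject = random_sequence(500, np.random.default_rng(1))
        be = _SubjectBackend(subject)
        c = extend_hit(hit(qs=0, qe=400, ss=50, se=450), 400, be)
        assert c.sequence.residues == subject[50:450]

    def test_left_clip_at_subject_start(self):
        subject = random_sequence(300, np.random.default_rng(2))
        be = _SubjectBackend(subject)
        c = extend_hit(hit(qs=50, qe=400, ss=0, se=200), 400, be)
        # left flank of 50 requested but subject starts at 0
        assert c.sequence.residues == subject[0:200]

    def test_minus_strand_flanks_swapped_and_revcomped(self):
        subject = random_sequence(1000, np.random.default_rng(3))
        be = _SubjectBackend(subject)
        # minus hit: query left flank (50) extends the subject's right end,
        # query right flank (100) extends the subject's left end
        c = extend_hit(hit(qs=50, qe=300, ss=400, se=600, strand="-"), 400, be)
        assert c.sequence.residues == reverse_complement(subject[300:650])


class TestDedupeBestPerSpecies:
    META = {
        "a1": {"species": "X"},
        "a2": {"species": "X"},
        "a3": {"species": "X"},
        "b1": {"species": "Y"},
    }

    def test_lowest_evalue_wins(self):
        hits = [
            hit("a1", ev=1e-10),
            hit("a2", ev=1e-30),
            hit("a3", ev=1e-5),
        ]
        kept = dedupe_best_per_species(hits, self.META)
        assert [h.subject_id for h in kept] == ["a2"]

    def test_distinct_species_unchanged(self):
        hits = [hit("a1", ev=1e-10), hit("b1", ev=1e-5)]
        assert len(dedupe_best_per_species(hits, self.META)) == 2

    def test_evalue_tie_broken_by_bitscore(self):
        hits = [hit("a1", ev=1e-10, bits=50.0), hit("a2", ev=1e-10, bits=90.0)]
        kept = dedupe_best_per_species(hits, self.META)
        assert [h.subject_id for h in kept] == ["a2"]


class TestIterativeSearch:
    def test_early_stop_with_enough_inband_homologs(self):
        """16 easily discoverable in-band homologs -> one iteration only."""
        fam = make_family(
            FamilySpec(
                n_homologs=18,
                target_distances=tuple(12 + (i % 7) for i in range(18)),
                seed=21,
            )
        )
        calls = []
        be = make_mock_backend(fam.homologs, fam.metadata)
        orig = be.search

        def counting_search(*a, **kw):
            calls.append(kw.get("word_size", a[1] if len(a) > 1 else None))
            return orig(*a, **kw)

        be.search = counting_search
        reps = iterative_search(fam.root, be, fam.metadata_lookup())
        assert len(reps) >= 16
        assert calls == [18]

    def test_all_iterations_then_failure_when_nothing_in_band(self):
        """Near-identical hits only: 5 iterations, then too few homologs."""
        fam = make_family(
            FamilySpec(n_homologs=3, target_distances=(1, 2, 3), seed=5)
        )
        be = make_mock_backend(fam.homologs, fam.metadata)
        calls = []
        orig = be.search

        def counting_search(*a, **kw):
            calls.append(kw["word_size"])
            return orig(*a, **kw)

        be.search = counting_search
        reps = iterative_search(fam.root, be, fam.metadata_lookup())
        assert calls == [18, 14, 10, 8, 7]
        assert reps == []  # everything below the band

    def test_no_hits_at_all_raises(self):
        query = NS("q", random_sequence(200, np.random.default_rng(8)))
        stranger = NS("far", random_sequence(200, np.random.default_rng(9)))
        meta = {"far": {"species": "S", "kingdom": "K", "phylum": "P",
                        "class": "C", "order": "O", "biomol": "genomic"}}
        be = FastaBackend([stranger], meta)
        # random 200-mers share blocks shorter than word size 7 only rarely;
        # force undiscoverability via a high word-size-only schedule
        cfg = SearchConfig(
            schedule=SearchSchedule(
                rows=(
                    (60, 60, None),
                    (60, 60, "order"),
                    (60, 60, "class"),
                    (60, 60, "phylum"),
                    (60, 60, "kingdom"),
                )
            )
        )
        with pytest.raises(NoHomologsError):
            iterative_search(query, be, meta, cfg)

    def test_word_size_gates_discovery_of_distant_homolog(self):
        """A homolog whose longest exact shared word is w is found only
        once the schedule's word size drops to w or below."""
        rng = np.random.default_rng(13)
        query = NS("q", random_sequence(400, rng))
        # subject sharing exactly one 9-mer with the query, otherwise random
        block = query.residues[100:109]
        rest = random_sequence(400, rng)
        subject = NS("distant", rest[:200] + block + rest[200:])
        meta = {
            "distant": {"species": "D", "taxon": "1", "biomol": "genomic",
                        "kingdom": "K", "phylum": "P", "class": "C",
                        "order": "O"}
        }
        be = FastaBackend([subject], meta)
        from codonscout.synth import seed_hit

        sm = seed_hit(query, subject)
        assert sm is not None and sm.block_len == 9
        for w, found in [(18, False), (14, False), (10, False), (9, True), (8, True)]:
            hits = be.search(query, word_size=w, evalue_cutoff=0.01,
                             max_hits=100)
            assert bool(hits) is found, w

    def test_taxon_restriction_honoured(self, family, backend, metadata):
        tr = TaxonRestriction(rank="kingdom", value="OtherKingdom")
        hits = backend.search(
            family.root, word_size=7, evalue_cutoff=0.01, max_hits=100,
            taxon_restriction=tr,
        )
        assert hits == []

    def test_candidate_residues_occur_in_subject(self, family, backend, metadata):
        reps = iterative_search(family.root, backend, metadata)
        for c in reps:
            rec = backend.records[c.sequence.id.split(":")[0]]
            res = c.sequence.residues
            assert res in rec.residues or reverse_complement(res) in rec.residues


class TestBuildCustomDb:
    def _species_meta(self, records):
        return {
            r.id: {
                "id": r.id, "species": f"sp_{r.id}", "taxon": r.id,
                "biomol": "genomic", "kingdom": "K", "phylum": "P",
                "class": "C", "order": "O",
            }
            for r in records
        }

    def test_caps_at_300_species(self):
        rng = np.random.default_rng(17)
        query = NS("q", random_sequence(120, rng))
        # 350 distinct species, every record embeds a query 40-mer
        block = query.residues[40:80]
        records = [
            NS(f"r{i:03d}", random_sequence(30, rng) + block
               + random_sequence(30, rng))
            for i in range(350)
        ]
        db = build_custom_db(query, FastaBackend(records, self._species_meta(records)),
                             self._species_meta(records))
        assert len(db.records) == 300

    def test_expansion_to_five_times_query_length(self):
        rng = np.random.default_rng(18)
        query = NS("q", random_sequence(400, rng))
        block = query.residues[100:180]
        subject = NS(
            "big", random_sequence(4000, rng) + block + random_sequence(4000, rng)
        )
        meta = self._species_meta([subject])
        db = build_custom_db(query, FastaBackend([subject], meta), meta)
        (rec,) = db.records.values()
        assert len(rec) == 2000  # 5 x query length

    def test_short_subject_clipped_to_whole_record(self):
        rng = np.random.default_rng(19)
        query = NS("q", random_sequence(400, rng))
        block = query.residues[100:180]
        subject = NS("small", random_sequence(400, rng) + block
                     + random_sequence(420, rng))
        meta = self._species_meta([subject])
        db = build_custom_db(query, FastaBackend([subject], meta), meta)
        (rec,) = db.records.values()
        assert len(rec) == 900

    def test_empty_database_raises(self):
        rng = np.random.default_rng(20)
        query = NS("q", "A" * 200)
        subject = NS("gggg", "G" * 200)  # no shared word on either strand
        meta = self._species_meta([subject])
        with pytest.raises(NoHomologsError):
            build_custom_db(query, FastaBackend([subject], meta), meta)
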