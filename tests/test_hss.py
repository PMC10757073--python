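"""HSS post-processing: p-filter, shadow resolution, merging, translation,
export round-trips."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from codonscout.hss import (
    HSSReport,
    export,
    filter_p,
    hss_from_tsv,
    hss_to_bed,
    hss_to_gff3,
    hss_to_tsv,
    merge_in_frame,
    proteins_to_fasta,
    resolve_shadows,
    translate_hss,
)
from codonscout.records import InputError, NucleotideSequence as NS
from codonscout.scoring import HSS
from codonscout.synth import FamilySpec, make_family


def hss(start, end, strand="+", frame=None, p=0.001, score=20.0, win=0, hid=0):
    if frame is None:
        frame = start % 3 if strand == "+" else 0
    return HSS(
        strand=strand, frame=frame, length_aa=(end - start) // 3,
        q_start=start, q_end=end, score=score, p_value=p,
        window_index=win, hss_id=hid,
    )


# strategy for fuzzed, codon-sane HSS sets
@st.composite
def hss_sets(draw):
    n = draw(st.integers(0, 8))
    out = []
    for i in range(n):
        start = draw(st.integers(0, 200)) * 3
        length = draw(st.integers(1, 60)) * 3
        strand = draw(st.sampled_from("+-"))
        frame = draw(st.integers(0, 2))
        out.append(
            hss(start + frame, start + frame + length, strand=strand,
                frame=(start + frame) % 3 if strand == "+" else frame,
                p=draw(st.sampled_from([1e-8, 1e-4, 0.003, 0.02, 0.2])),
                score=draw(st.sampled_from([5.0, 20.0, 80.0])),
                hid=i)
        )
    return out


class TestFilterP:
    def test_default_cutoff(self):
        items = [hss(0, 30, p=0.001), hss(30, 60, p=0.04), hss(60, 90, p=0.2)]
        assert [h.p_value for h in filter_p(items)] == [0.001, 0.04]

    def test_cutoff_one_keeps_all(self):
        items = [hss(0, 30, p=0.99), hss(30, 60, p=1.0)]
        assert len(filter_p(items, cutoff=1.01)) == 2

    def test_empty(self):
        assert filter_p([]) == []

    @given(hss_sets())
    def test_idempotent_and_all_below_cutoff(self, items):
        once = filter_p(items)
        assert filter_p(once) == once
        assert all(h.p_value < 0.05 for h in once)


class TestResolveShadows:
    def test_shadow_on_opposite_strand_removed(self):
        real = hss(100, 400, strand="+", p=1e-8)
        shadow = hss(100, 400, strand="-", frame=1, p=0.03)
        assert resolve_shadows([real, shadow]) == [real]

    def test_disjoint_opposite_strands_both_survive(self):
        a = hss(0, 90, strand="+")
        b = hss(300, 390, strand="-", frame=1)
        assert resolve_shadows([a, b]) == sorted(
            [a, b], key=lambda h: h.q_start
        )

    def test_three_mutually_overlapping_frames_keep_one(self):
        items = [
            hss(0, 90, frame=0, p=0.01),
            hss(1, 91, frame=1, p=1e-6),
            hss(2, 92, frame=2, p=0.001),
        ]
        kept = resolve_shadows(items)
        assert len(kept) == 1 and kept[0].p_value == 1e-6

    def test_same_frame_overlaps_untouched(self):
        a, b = hss(0, 90, p=0.01), hss(30, 120, p=0.001)
        assert len(resolve_shadows([a, b])) == 2

    def test_tie_on_p_broken_by_score(self):
        a = hss(0, 90, frame=0, p=0.01, score=10.0)
        b = hss(1, 91, frame=1, p=0.01, score=30.0)
        assert resolve_shadows([a, b]) == [b]

    @given(hss_sets())
    def test_no_conflicting_overlaps_remain(self, items):
        kept = resolve_shadows(items)
        assert set(kept) <= set(items)
        for a, b in itertools.combinations(kept, 2):
            overlap = a.q_start < b.q_end and b.q_start < a.q_end
            if overlap:
                assert (a.strand, a.frame) == (b.strand, b.frame)
        # idempotent
        assert resolve_shadows(kept) == sorted(
            kept, key=lambda h: (h.q_start, h.q_end, h.strand, h.frame)
        )


class TestMergeInFrame:
    def test_overlapping_same_frame_unioned(self):
        a = hss(99, 399, p=1e-6)
        b = hss(249, 699, p=0.001)
        (m,) = merge_in_frame([a, b])
        assert (m.q_start, m.q_end) == (99, 699)
        assert m.p_value == 1e-6 and m.score == 20.0
        assert (m.q_end - m.q_start) % 3 == 0

    def test_same_interval_different_frames_not_merged(self):
        a = hss(99, 399, frame=0, strand="+")
        b = hss(99, 399, frame=1, strand="+")
        assert len(merge_in_frame([a, b])) == 2

    def test_cross_window_fragments_merge(self):
        # same region reported by windows 1 and 2 inside the overlap zone
        a = hss(900, 1200, win=1, p=0.002)
        b = hss(1101, 1401, win=2, p=0.0005)
        (m,) = merge_in_frame([a, b])
        assert (m.q_start, m.q_end) == (900, 1401)
        assert m.windows() == (1, 2)
        assert m.p_value == 0.0005

    def test_abutting_same_frame_merge(self):
        a = hss(99, 198)
        b = hss(198, 300)
        (m,) = merge_in_frame([a, b])
        assert (m.q_start, m.q_end) == (99, 300)

    @given(hss_sets())
    def test_merge_properties(self, items):
        merged = merge_in_frame(items)
        # no same-phase overlaps remain
        for a, b in itertools.combinations(merged, 2):
            if (a.strand, a.frame) == (b.strand, b.frame):
                assert a.q_end <= b.q_start or b.q_end <= a.q_start
        # coverage never decreases (codon-sane inputs trim nothing)
        def covered(hs):
            pts = set()
            for h in hs:
                pts.update(range(h.q_start, h.q_end))
            return pts
        assert covered(items) <= covered(merged)
        # all output lengths are codon multiples
        assert all((h.q_end - h.q_start) % 3 == 0 for h in merged)
        # idempotent
        assert merge_in_frame(merged) == merged


class TestTranslate:
    def test_simple_plus_strand(self):
        q = NS("q", "ATGAAA")
        assert translate_hss(q, hss(0, 6)) == "MK"

    def test_minus_strand_revcomp_first(self):
        q = NS("q", "TTTCAT")
        assert translate_hss(q, hss(0, 6, strand="-")) == "MK"

    def test_length_not_codon_multiple_rejected(self):
        q = NS("q", "ATGAAAC")
        h = HSS(strand="+", frame=0, length_aa=2, q_start=0, q_end=7,
                score=1.0, p_value=0.01)
        with pytest.raises(InputError):
            translate_hss(q, h)

    def test_internal_stop_logged(self, caplog):
        q = NS("q", "ATGTAAAAA")
        with caplog.at_level("WARNING"):
            protein = translate_hss(q, hss(0, 9))
        assert protein == "M*K"
        assert "stop" in caplog.text

    def test_synthetic_54_codon_orf_translates_stop_free(self):
        fam = make_family(FamilySpec(seed=11, n_homologs=0,
                                     target_distances=(), coding=(90, 54)))
        start, end = fam.orf
        # the embedded ORF: ATG + 53 codons + TAA stop
        h = hss(start, end)
        protein = translate_hss(fam.root, h)
        assert len(protein) == 55  # 54 coding codons + terminal stop
        assert protein[0] == "M"
        assert protein[-1] == "*"
        assert "*" not in protein[:-1]


class TestExport:
    def _report(self, items, qlen=900):
        return HSSReport(query_id="q", query_length=qlen, hss=items)

    def test_zero_hss_valid_files(self, tmp_path):
        q = NS("q", "ACGT" * 225)
        files = export(self._report([]), q, tmp_path)
        assert files["tsv"].read_text().startswith("hss_id\t")
        assert files["bed"].read_text() == ""
        assert "##gff-version 3" in files["gff3"].read_text()

    def test_bed_and_gff_coordinate_conventions(self, tmp_path):
        items = [hss(730, 820, p=0.004)]
        rep = self._report(items)
        bed = hss_to_bed(rep).split("\t")
        assert (bed[1], bed[2]) == ("730", "820")
        gff_line = hss_to_gff3(rep).splitlines()[1].split("\t")
        assert (gff_line[3], gff_line[4]) == ("731", "820")
        assert gff_line[1] == "codonscout"

    def test_tsv_roundtrip(self):
        items = [hss(99, 399, p=1e-6, hid=0), hss(500, 620, strand="-",
                 frame=2, p=0.01, hid=1, win=2)]
        rep = self._report(items)
        assert hss_from_tsv(hss_to_tsv(rep)) == items

    def test_protein_fasta_lengths(self):
        rng = np.random.default_rng(2)
        q = NS("q", "".join(rng.choice(list("ACGT"), 900)))
        items = [hss(99, 399)]
        fasta = proteins_to_fasta(q, self._report(items))
        protein = "".join(fasta.splitlines()[1:])
        assert len(protein) == 100

    def test_byte_deterministic(self, tmp_path):
        q = NS("q", "ACGT" * 225)
        items = [hss(99, 399, p=1e-6)]
        a = export(self._report(items), q, tmp_path / "a")
        b = export(self._report(items), q, tmp_path / "b")
        for fmt in a:
            assert a[fmt].read_bytes() == b[fmt].read_bytes()
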