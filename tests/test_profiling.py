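"""Activity profiling: exact matching, counts, A, rankings, composition."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpp.models import Activity, BioactivePeptideEntry, CaseinFraction, ProteinRecord
from bpp.profiling import (
    ActivityProfile,
    AhoCorasick,
    Occurrence,
    aa_composition,
    build_profile,
    filter_occurrences_by_residues,
    find_occurrences,
    fragmentomic_scan,
    frequency_A,
    length_histogram,
    rank_proteins,
)
from conftest import naive_find, naive_profile_occurrences

ACE = Activity.ACE_inhibitor
DPP = Activity.DPP4_inhibitor


def _protein(seq: str, pid: str = "p1", label: str = "") -> ProteinRecord:
    return ProteinRecord(pid, label or pid, CaseinFraction.other, "", seq)


class TestFindOccurrences:
    def test_self_overlapping_matches_all_reported(self):
        occs = find_occurrences("AA", _protein("AAAA"))
        assert [o.start for o in occs] == [1, 2, 3]
        assert all(o.end == o.start + 1 for o in occs)

    def test_single_match_coordinates_are_one_based_inclusive(self):
        (occ,) = find_occurrences("QP", _protein("WIQP"))
        assert (occ.start, occ.end) == (3, 4)

    def test_planted_motif_at_208(self, wiqp_protein):
        (occ,) = find_occurrences("WIQP", wiqp_protein)
        assert (occ.start, occ.end) == (208, 211)

    def test_peptide_longer_than_protein_yields_empty(self):
        assert find_occurrences("AAAAA", _protein("AAA")) == []


class TestBuildProfile:
    def test_activity_filter(self, small_db):
        profile = build_profile(_protein("WIQP"), small_db, ACE)
        assert profile.total == 2  # QP and IQP as ACE entries
        assert profile.counts_by_length == {2: 1, 3: 1}

    def test_repeats_counted(self):
        db = [BioactivePeptideEntry("AA", ACE)]
        assert build_profile(_protein("AAAA"), db, ACE).total == 3

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            build_profile(_protein("AAAA"), [], ACE)

    def test_matches_naive_scan_on_planted_protein(self, wiqp_protein, small_db):
        profile = build_profile(wiqp_protein, small_db, DPP)
        expected = naive_profile_occurrences(wiqp_protein.sequence, small_db, DPP)
        assert {(o.start, o.peptide) for o in profile.occurrences} == expected

    def test_row_order_of_database_is_irrelevant(self, wiqp_protein, small_db):
        forward = build_profile(wiqp_protein, small_db, DPP)
        backward = build_profile(wiqp_protein, list(reversed(small_db)), DPP)
        assert forward.occurrences == backward.occurrences


class TestFrequencyA:
    @pytest.mark.parametrize(
        "total, n, expected",
        [
            (107, 214, 0.5),  # alpha-S1 D ACE arithmetic
            (0, 214, 0.0),
            (129, 209, 129 / 209),  # beta B ACE arithmetic
        ],
    )
    def test_quotient(self, total, n, expected):
        profile = ActivityProfile(
            "x", "x", ACE, n,
            [Occurrence(1, 2, "AA") for _ in range(total)],
        )
        assert frequency_A(profile) == pytest.approx(expected, abs=1e-12)

    def test_requires_positive_length(self):
        profile = ActivityProfile("x", "x", ACE, 0, [])
        with pytest.raises(ValueError):
            frequency_A(profile)


def test_length_histogram_sums_to_total():
    db = [BioactivePeptideEntry("AA", ACE), BioactivePeptideEntry("AAA", ACE)]
    profile = build_profile(_protein("AAAA"), db, ACE)
    hist = length_histogram(profile)
    assert hist == {2: 3, 3: 2}
    assert sum(hist.values()) == profile.total
    assert length_histogram(ActivityProfile("x", "x", ACE, 4, [])) == {}


class TestRanking:
    @staticmethod
    def _profile(label: str, total: int) -> ActivityProfile:
        return ActivityProfile(
            label, label, ACE, 200, [Occurrence(1, 2, "AA")] * total
        )

    def test_descending_by_total(self):
        # ordering mirrors the casein ranking: beta/B (129) above kappa/A (80)
        entries = rank_proteins([self._profile("kappa/A", 80), self._profile("beta/B", 129)])
        assert [(e.protein_label, e.rank) for e in entries] == [
            ("beta/B", 1), ("kappa/A", 2),
        ]

    def test_ties_share_min_rank_alphabetical(self):
        entries = rank_proteins(
            [self._profile("Y", 5), self._profile("X", 5), self._profile("Z", 3)]
        )
        assert [(e.protein_label, e.rank) for e in entries] == [
            ("X", 1), ("Y", 1), ("Z", 3),
        ]

    def test_single_profile_rank_one(self):
        assert rank_proteins([self._profile("only", 7)])[0].rank == 1

    def test_ranking_is_permutation_of_input(self):
        profiles = [self._profile(f"p{i}", i % 4) for i in range(8)]
        entries = rank_proteins(profiles)
        assert sorted(e.protein_label for e in entries) == sorted(
            p.protein_label for p in profiles
        )

    def test_mixed_activities_rejected(self):
        bad = self._profile("q", 1)
        bad.activity = DPP
        with pytest.raises(ValueError):
            rank_proteins([self._profile("p", 1), bad])


class TestComposition:
    def test_simple_percentages(self):
        comp = aa_composition(_protein("PPG"))
        assert comp["P"] == pytest.approx(200 / 3)
        assert comp["G"] == pytest.approx(100 / 3)

    def test_kappa_like_proline_fraction(self):
        # 21 Pro residues in a 190-residue chain display as 11.1 %
        seq = "P" * 21 + "A" * 169
        comp = aa_composition(_protein(seq))
        assert round(comp["P"], 1) == 11.1

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=300))
    @settings(max_examples=50, deadline=None)
    def test_percentages_sum_to_100(self, seq):
        assert sum(aa_composition(_protein(seq)).values()) == pytest.approx(100.0, abs=0.1)


class TestResidueFilter:
    def _profile(self, peptides: list[str]) -> ActivityProfile:
        occs = [Occurrence(1, len(p), p) for p in peptides]
        return ActivityProfile("x", "x", ACE, 50, occs)

    def test_contains_any(self):
        kept = filter_occurrences_by_residues(self._profile(["QP", "IQ"]), {"P"})
        assert [o.peptide for o in kept] == ["QP"]

    def test_c_terminal_proline_rule(self):
        kept = filter_occurrences_by_residues(
            self._profile(["VAP", "GGG"]), {"P"}, mode="c_terminal"
        )
        assert [o.peptide for o in kept] == ["VAP"]

    def test_n_terminal(self):
        kept = filter_occurrences_by_residues(
            self._profile(["VAP", "AVP"]), {"A", "L", "I", "V"}, mode="n_terminal"
        )
        assert len(kept) == 2

    def test_disjoint_residues_empty(self):
        assert filter_occurrences_by_residues(self._profile(["GGG"]), {"W"}) == []

    def test_empty_residue_set_rejected(self):
        with pytest.raises(ValueError):
            filter_occurrences_by_residues(self._profile(["QP"]), set())


class TestFragmentomicScan:
    def test_wiqp_submotifs(self, small_db):
        hits = fragmentomic_scan("WIQP", small_db)
        by_motif: dict[str, set[Activity]] = {}
        for motif, act, _ in hits:
            by_motif.setdefault(motif, set()).add(act)
        assert set(by_motif) == {"WI", "IQ", "QP", "IQP"}
        # QP and IQP carry both activities; WI and IQ only DPP-IV
        assert by_motif["QP"] == {ACE, DPP}
        assert by_motif["IQP"] == {ACE, DPP}
        assert by_motif["WI"] == {DPP}
        assert by_motif["IQ"] == {DPP}
        # the full-length peptide itself is never a submotif
        assert "WIQP" not in by_motif

    def test_starts_are_within_peptide(self, small_db):
        for motif, _, start in fragmentomic_scan("WIQP", small_db):
            assert "WIQP"[start - 1 : start - 1 + len(motif)] == motif

    def test_empty_db(self):
        assert fragmentomic_scan("GG", []) == []

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_equals_bruteforce_substring_enumeration(self, data):
        alphabet = "APGV"
        pep = data.draw(st.text(alphabet=alphabet, min_size=2, max_size=8))
        db = [
            BioactivePeptideEntry(s, ACE)
            for s in data.draw(
                st.sets(st.text(alphabet=alphabet, min_size=2, max_size=4),
                        min_size=0, max_size=10)
            )
        ]
        expected = {
            (pep[i : i + k], ACE)
            for k in range(2, len(pep))
            for i in range(len(pep) - k + 1)
            if any(e.sequence == pep[i : i + k] for e in db)
        }
        assert {(m, a) for m, a, _ in fragmentomic_scan(pep, db)} == expected


class TestMatcherEquivalence:
    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_automaton_equals_naive_oracle(self, data):
        alphabet = "APGVLQ"
        text = data.draw(st.text(alphabet=alphabet, min_size=1, max_size=200))
        patterns = data.draw(
            st.lists(st.text(alphabet=alphabet, min_size=1, max_size=6),
                     min_size=1, max_size=30)
        )
        automaton_hits = set(AhoCorasick(patterns).scan(text))
        naive_hits = {
            (start, pat) for pat in set(patterns) for start in naive_find(pat, text)
        }
        assert automaton_hits == naive_hits

    def test_matching_never_spans_records(self, small_db):
        # profiles are strictly per-record: the cross-boundary motifs that a
        # concatenation would create must not appear in either record's profile
        left = build_profile(_protein("WI"), small_db, DPP)
        right = build_profile(_protein("QP"), small_db, DPP)
        assert {o.peptide for o in left.occurrences} == {"WI"}
        assert {o.peptide for o in right.occurrences} == {"QP"}
        joined = build_profile(_protein("WIQP"), small_db, DPP)
        assert joined.total > left.total + right.total  # IQ, IQP, WIQP span the seam

    def test_self_concatenation_at_least_doubles_total(self, wiqp_protein, small_db):
        single = build_profile(wiqp_protein, small_db, DPP).total
        doubled_protein = _protein(wiqp_protein.sequence * 2, "dbl")
        doubled = build_profile(doubled_protein, small_db, DPP).total
        assert doubled >= 2 * single
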