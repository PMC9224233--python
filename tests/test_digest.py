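"""Digestion and discriminating-peptide selection, checked against
independent oracles (pyteomics cleavage, brute-force substring scans)."""

import pytest
from hypothesis import given, strategies as st
from pyteomics import parser as ptparser

from isomrm.digest import (build_peptide_index, digest, digest_peptide_set,
                           merge_indistinguishable, select_discriminating)
from isomrm.io import EvidenceSet, ProteinRecord

from conftest import AA, random_protein

sequences = st.text(alphabet=AA, min_size=1, max_size=60)


class TestDigest:
    @pytest.mark.parametrize("seq,mc,expected", [
        ("AKGR", 0, {("AK", 1, 2), ("GR", 3, 4)}),
        ("KRA", 0, {("K", 1, 1), ("R", 2, 2), ("A", 3, 3)}),
        ("AKGR", 1, {("AK", 1, 2), ("GR", 3, 4), ("AKGR", 1, 4)}),
        ("MAG", 0, {("MAG", 1, 3)}),
    ])
    def test_cleavage_rule(self, seq, mc, expected):
        frags = {(f.sequence, f.start, f.end) for f in digest(seq, mc)}
        assert frags == expected

    def test_missed_cleavage_count_recorded(self):
        by_seq = {f.sequence: f.missed_cleavages for f in digest("AKGR", 1)}
        assert by_seq == {"AK": 0, "GR": 0, "AKGR": 1}

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            digest("")

    def test_proline_suppression_optional(self):
        assert digest_peptide_set("AKPR") == {"AK", "PR"}
        assert digest_peptide_set("AKPR", suppress_proline=True) == {"AKPR"}

    @given(seq=sequences)
    def test_zero_missed_cleavage_tiles_input(self, seq):
        frags = digest(seq, 0)
        assert "".join(f.sequence for f in frags) == seq
        pos = 1
        for f in frags:
            assert f.start == pos
            assert seq[f.start - 1:f.end] == f.sequence
            pos = f.end + 1
        assert pos == len(seq) + 1

    @given(seq=sequences, mc=st.integers(min_value=0, max_value=2))
    def test_matches_pyteomics_cleavage(self, seq, mc):
        ours = digest_peptide_set(seq, mc)
        oracle = ptparser.cleave(seq, r"(?<=[KR])", missed_cleavages=mc,
                                 min_length=1)
        assert ours == set(oracle)


class TestPeptideIndex:
    def test_identical_sequences_share_all_peptides(self):
        recs = [ProteinRecord("A", "AKGR"), ProteinRecord("B", "AKGR")]
        index = build_peptide_index(recs)
        assert all(parents == {"A", "B"} for parents in index.values())

    def test_point_difference_splits_parents(self):
        recs = [ProteinRecord("A", "AKGR"), ProteinRecord("B", "AKGW")]
        index = build_peptide_index(recs)
        assert index == {"AK": {"A", "B"}, "GR": {"A"}, "GW": {"B"}}

    def test_against_brute_force_on_random_proteins(self, rng):
        recs = [ProteinRecord(f"P{i}", random_protein(rng, int(rng.integers(30, 120))))
                for i in range(10)]
        index = build_peptide_index(recs)
        digests = {r.accession: digest_peptide_set(r.sequence) for r in recs}
        expected = {}
        for acc, peps in digests.items():
            for pep in peps:
                expected.setdefault(pep, set()).add(acc)
        assert index == expected


def _singleton_groups(records):
    index = build_peptide_index(records)
    return merge_indistinguishable(records, index)


class TestMerge:
    def test_duplicated_sequences_merge(self):
        recs = [ProteinRecord("A", "AKGRWPLK"), ProteinRecord("B", "AKGRWPLK")]
        groups = _singleton_groups(recs)
        assert len(groups) == 1
        assert groups[0].members == {"A", "B"}
        assert groups[0].label == "A/B"

    def test_distinct_digests_stay_singletons(self):
        recs = [ProteinRecord("A", "AKGR"), ProteinRecord("B", "AKGW"),
                ProteinRecord("C", "MMKGR")]
        groups = _singleton_groups(recs)
        assert len(groups) == 3

    def test_partition_property(self, rng):
        recs = [ProteinRecord(f"P{i}", random_protein(rng, 50))
                for i in range(8)] + [ProteinRecord("P8", random_protein(rng, 50))]
        groups = _singleton_groups(recs)
        seen = [m for g in groups for m in g.members]
        assert sorted(seen) == sorted(r.accession for r in recs)

    def test_length_filter_can_merge(self):
        # members differ only by a peptide outside the filter window
        recs = [ProteinRecord("A", "AAAGGGK" + "WK"),
                ProteinRecord("B", "AAAGGGK" + "MK")]
        index = build_peptide_index(recs)
        assert len(merge_indistinguishable(recs, index)) == 2
        merged = merge_indistinguishable(recs, index, length_bounds=(6, 30))
        assert len(merged) == 1


class TestSelect:
    def _design(self, family, background, evidence, **kw):
        index = build_peptide_index(list(family) + list(background))
        groups = merge_indistinguishable(family, index)
        return select_discriminating(groups, index,
                                     EvidenceSet(frozenset(evidence)), **kw)

    def test_minimum_two_peptides_rule(self):
        fam = [ProteinRecord("A", "AAAGGGK" + "CCCDDDK"),
               ProteinRecord("B", "AAAGGGK" + "EEEFFFK")]
        # only one discriminating peptide of A in evidence
        groups, drop = self._design(fam, [], {"CCCDDDK"}, min_peptides=2)
        by = {g.label: g for g in groups}
        assert by["A"].selected_peptides == ["CCCDDDK"]
        assert not by["A"].quantifiable
        assert not by["B"].quantifiable
        assert len(drop) == 2

    def test_zero_evidence_group_in_drop_log(self):
        fam = [ProteinRecord("A", "AAAGGGK" + "CCCDDDK")]
        groups, drop = self._design(fam, [], set())
        assert not groups[0].quantifiable
        assert drop and "no discriminating peptide in evidence" in drop[0]

    def test_background_peptide_never_discriminates(self):
        fam = [ProteinRecord("A", "AAAGGGKCCCDDDK")]
        bg = [ProteinRecord("BG", "WWK" + "AAAGGGK")]
        groups, _ = self._design(fam, bg, {"AAAGGGK", "CCCDDDK"})
        assert groups[0].discriminating_peptides == {"CCCDDDK"}

    def test_selection_order_deterministic(self):
        fam = [ProteinRecord("A", "CCCDDDK" + "AAAGGGK" + "AAADDDK")]
        groups, _ = self._design(fam, [], {"CCCDDDK", "AAAGGGK", "AAADDDK"},
                                 min_peptides=1)
        assert groups[0].selected_peptides == ["AAADDDK", "AAAGGGK", "CCCDDDK"]

    def test_min_peptides_must_be_positive(self):
        fam = [ProteinRecord("A", "AAAGGGK")]
        with pytest.raises(ValueError):
            self._design(fam, [], set(), min_peptides=0)

    def test_discriminating_sets_match_brute_force(self, rng):
        fam = [ProteinRecord(f"F{i}", random_protein(rng, 80))
               for i in range(6)]
        bg = [ProteinRecord(f"B{i}", random_protein(rng, 80))
              for i in range(6)]
        index = build_peptide_index(fam + bg)
        groups = merge_indistinguishable(fam, index)
        groups, _ = select_discriminating(
            groups, index, EvidenceSet(frozenset()), length_bounds=None)
        digests = {r.accession: digest_peptide_set(r.sequence)
                   for r in fam + bg}
        for g in groups:
            expected = set()
            for member in g.members:
                for pep in digests[member]:
                    owners = {a for a, d in digests.items() if pep in d}
                    if owners <= g.members:
                        expected.add(pep)
            assert g.discriminating_peptides == expected

    def test_background_growth_never_enlarges_discriminating(self, rng):
        fam = [ProteinRecord(f"F{i}", random_protein(rng, 60))
               for i in range(4)]
        bg = [ProteinRecord(f"B{i}", random_protein(rng, 60))
              for i in range(8)]

        def disc(background):
            index = build_peptide_index(fam + background)
            groups = merge_indistinguishable(fam, index)
            groups, _ = select_discriminating(groups, index,
                                              EvidenceSet(frozenset()),
                                              length_bounds=None)
            return {g.label: g.discriminating_peptides for g in groups}

        small = disc(bg[:3])
        large = disc(bg)
        for label, peps in large.items():
            assert peps <= small[label]
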