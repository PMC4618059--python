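"""Parsimony inference: merging, subsumption, razor counting, acceptance.

The property tests compare the grouping against an independent brute-force
evaluation of maximal-indistinguishable-set grouping on small random
instances and check spectral-count conservation (every accepted spectrum
counted exactly once)."""

import pytest
from hypothesis import given, settings, strategies as st

from pdzpull.inference import (
    accept_proteins,
    build_peptide_map,
    count_by_razor,
    group_by_parsimony,
)
from pdzpull.psm_io import ProteinDatabase

from conftest import make_psm


def psms_for(mapping, copies=1):
    """One PSM per peptide occurrence; accessions from the mapping."""
    out = []
    for peptide, accs in mapping.items():
        for _ in range(copies):
            out.append(make_psm(peptide=peptide, accessions=tuple(sorted(accs))))
    return out


class TestBuildPeptideMap:
    def _db(self):
        db = ProteinDatabase()
        db.entries["A"] = ("A", "MSAMPLEKRTTTTTK")
        db.entries["B"] = ("B", "GGGGGSAMPLEKGGR")
        db.entries["C"] = ("C", "WWWWILKWWWK")
        return db

    def test_unique_peptide_maps_to_one_protein(self):
        db = self._db()
        pmap, _ = build_peptide_map([make_psm(peptide="TTTTTK", accessions=("A",))],
                                    db=db, remap=True)
        assert pmap["TTTTTK"] == frozenset({"A"})

    def test_shared_subsequence_maps_to_both(self):
        db = self._db()
        pmap, _ = build_peptide_map([make_psm(peptide="SAMPLEK", accessions=("A",))],
                                    db=db, remap=True)
        assert pmap["SAMPLEK"] == frozenset({"A", "B"})

    def test_isoleucine_leucine_equivalence(self):
        db = self._db()
        pmap, _ = build_peptide_map([make_psm(peptide="WWLLK", accessions=("C",))],
                                    db=db, remap=True)
        assert "C" in pmap["WWLLK"]  # WWILK in the sequence matches

    def test_unmatched_peptide_keeps_psm_accessions_with_warning(self):
        db = self._db()
        pmap, warnings = build_peptide_map(
            [make_psm(peptide="QQQQQQQ", accessions=("Z",))], db=db, remap=True
        )
        assert pmap["QQQQQQQ"] == frozenset({"Z"})
        assert warnings and "QQQQQQQ" in warnings[0]

    def test_without_remap_accessions_come_from_psms(self):
        pmap, _ = build_peptide_map(
            [make_psm(peptide="SAMPLEK", accessions=("X", "Y"))], remap=False
        )
        assert pmap["SAMPLEK"] == frozenset({"X", "Y"})


class TestParsimonyGrouping:
    def test_identical_peptide_sets_merge(self):
        mapping = {"PEPTIDEA": {"A", "B"}, "PEPTIDEB": {"A", "B"}}
        psms = psms_for(mapping)
        groups = group_by_parsimony(dict_to_frozen(mapping), psms)
        assert len(groups) == 1
        assert groups[0].members == frozenset({"A", "B"})
        assert groups[0].representative == "A"

    def test_subset_protein_is_subsumed(self):
        mapping = {"PEPTIDEA": {"A"}, "PEPTIDEB": {"A", "B"}, "PEPTIDEC": {"A"}}
        groups = group_by_parsimony(dict_to_frozen(mapping), psms_for(mapping))
        assert len(groups) == 1
        assert groups[0].members == frozenset({"A"})
        assert groups[0].subsumed_members == frozenset({"B"})

    def test_shared_peptide_counted_once_for_tiebroken_group(self):
        # A:{p1,p2}, B:{p2,p3}; p2's spectra must be counted exactly once
        mapping = {"PEPTIDEA": {"A"}, "PEPTIDEB": {"A", "B"}, "PEPTIDEC": {"B"}}
        psms = psms_for({"PEPTIDEA": {"A"}, "PEPTIDEC": {"B"}}) + psms_for(
            {"PEPTIDEB": {"A", "B"}}, copies=4
        )
        groups = group_by_parsimony(dict_to_frozen(mapping), psms)
        assert len(groups) == 2
        total = sum(g.spectral_count for g in groups)
        assert total == len(psms)  # conservation
        by_rep = {g.representative: g for g in groups}
        # equal peptide counts -> lexicographically smaller representative wins
        assert by_rep["A"].spectral_count == 1 + 4
        assert by_rep["B"].spectral_count == 1

    def test_idempotent_on_own_output(self):
        mapping = {
            "PEPTIDEA": {"A", "B"}, "PEPTIDEB": {"A", "B"},
            "PEPTIDEC": {"C"}, "PEPTIDED": {"C", "D"},
        }
        psms = psms_for(mapping)
        first = group_by_parsimony(dict_to_frozen(mapping), psms)
        remapped = {}
        for g in first:
            for peptide in g.distinct_peptides:
                remapped.setdefault(peptide, set()).update(g.members)
        second = group_by_parsimony(dict_to_frozen(remapped), psms)
        assert {(g.members, g.distinct_peptides) for g in first} == {
            (g.members, g.distinct_peptides) for g in second
        }


class TestAcceptProteins:
    def test_single_peptide_group_rejected_even_at_full_probability(self):
        mapping = {"PEPTIDEA": {"A"}}
        psms = psms_for(mapping, copies=5)
        groups = group_by_parsimony(dict_to_frozen(mapping), psms)
        assert accept_proteins(groups) == []

    def test_probability_combines_independently_and_boundary_keeps(self):
        mapping = {"PEPTIDEA": {"A"}, "PEPTIDEB": {"A"}}
        psms = [
            make_psm(peptide="PEPTIDEA", accessions=("A",), peptide_probability=0.9),
            make_psm(peptide="PEPTIDEB", accessions=("A",), peptide_probability=0.9),
        ]
        groups = group_by_parsimony(dict_to_frozen(mapping), psms)
        assert groups[0].protein_probability == pytest.approx(0.99)
        assert accept_proteins(groups, min_probability=0.99) == groups

    def test_absent_probabilities_fall_back_to_filter_threshold(self):
        mapping = {"PEPTIDEA": {"A"}, "PEPTIDEB": {"A"}}
        psms = [
            make_psm(peptide="PEPTIDEA", accessions=("A",), peptide_probability=None),
            make_psm(peptide="PEPTIDEB", accessions=("A",), peptide_probability=None),
        ]
        groups = group_by_parsimony(dict_to_frozen(mapping), psms, absent_probability=0.95)
        assert groups[0].protein_probability == pytest.approx(1 - 0.05**2)

    def test_empty_input(self):
        assert accept_proteins([]) == []
        assert group_by_parsimony({}, []) == []


def dict_to_frozen(mapping):
    return {p: frozenset(a) for p, a in mapping.items()}


# --------------------------------------------------------------------------
# brute-force oracle on small instances

PROTEINS = list("ABCDEFGH")
PEPTIDES = [f"PEPTID{c}K" for c in "ABCDEFGHIJKL"]


@st.composite
def small_instance(draw):
    n_prot = draw(st.integers(1, 8))
    n_pep = draw(st.integers(1, 12))
    mapping = {}
    for peptide in PEPTIDES[:n_pep]:
        accs = draw(
            st.sets(st.sampled_from(PROTEINS[:n_prot]), min_size=1, max_size=n_prot)
        )
        mapping[peptide] = frozenset(accs)
    return mapping


def oracle_grouping(mapping):
    """Independent maximal-indistinguishable-set grouping: merge proteins
    with identical peptide sets, drop any protein whose set is a strict
    subset of another protein's set."""
    prot_peps = {}
    for peptide, accs in mapping.items():
        for a in accs:
            prot_peps.setdefault(a, set()).add(peptide)
    surviving = {}
    for a, peps in prot_peps.items():
        if any(peps < other for other in prot_peps.values()):
            continue
        surviving.setdefault(frozenset(peps), set()).add(a)
    return {(frozenset(members), peps) for peps, members in surviving.items()}


@settings(max_examples=300, derandomize=True, deadline=None)
@given(small_instance(), st.integers(1, 3))
def test_grouping_matches_oracle_and_conserves_counts(mapping, copies):
    psms = psms_for(mapping, copies=copies)
    groups = group_by_parsimony(mapping, psms)
    assert {(g.members, g.distinct_peptides) for g in groups} == oracle_grouping(mapping)
    # SC conservation: every accepted spectrum counted exactly once
    assert sum(g.spectral_count for g in groups) == len(psms)
    # every peptide covered by >= 1 surviving group
    covered = set().union(*(g.distinct_peptides for g in groups))
    assert covered == set(mapping)
    # count_by_razor over an arbitrary subset is consistent
    subset = psms[::2]
    assert sum(count_by_razor(groups, subset).values()) == len(subset)
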