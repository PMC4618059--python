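"""Peptide filter: boundary behaviour at every threshold, monotonicity,
exhaustive partition, and agreement with an independent re-statement of the
acceptance rules."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from pdzpull.errors import ConfigError
from pdzpull.filtering import PeptideFilterCriteria, filter_psms, passes_engine

from conftest import make_psm


CRITERIA = PeptideFilterCriteria()


class TestEngineBoundaries:
    @pytest.mark.parametrize("score, expected", [(41.0, True), (40.0, False), (39.9, False)])
    def test_mascot_strictly_greater_than_40(self, score, expected):
        rec = make_psm(mascot_ion_score=score)
        assert passes_engine(rec, CRITERIA, "mascot") is expected

    @pytest.mark.parametrize(
        "charge, xcorr, expected",
        [
            (1, 1.6, True), (1, 1.5, False),
            (2, 2.1, True), (2, 2.0, False),
            (3, 2.3, True), (3, 2.2, False),
            (4, 2.6, True), (4, 2.5, False),
            (6, 2.6, True), (6, 2.5, False),  # >=4 inherits the 2.5 cut
        ],
    )
    def test_xcorr_charge_ladder(self, charge, xcorr, expected):
        rec = make_psm(charge=charge, sequest_xcorr=xcorr, sequest_deltacn=0.2)
        assert passes_engine(rec, CRITERIA, "sequest") is expected

    @pytest.mark.parametrize("deltacn, expected", [(0.11, True), (0.10, False)])
    def test_sequest_needs_deltacn_too(self, deltacn, expected):
        rec = make_psm(charge=2, sequest_xcorr=3.0, sequest_deltacn=deltacn)
        assert passes_engine(rec, CRITERIA, "sequest") is expected

    @pytest.mark.parametrize("score, expected", [(2.1, True), (2.0, False)])
    def test_xtandem_neg_log_e(self, score, expected):
        rec = make_psm(xtandem_neg_log_e=score)
        assert passes_engine(rec, CRITERIA, "xtandem") is expected

    def test_absent_score_gives_no_support(self):
        rec = make_psm(mascot_ion_score=None, sequest_xcorr=None,
                       sequest_deltacn=None, xtandem_neg_log_e=4.0)
        assert not passes_engine(rec, CRITERIA, "mascot")
        assert not passes_engine(rec, CRITERIA, "sequest")
        assert passes_engine(rec, CRITERIA, "xtandem")


class TestFilterPsms:
    def test_single_passing_engine_suffices_under_any_engine(self):
        rec = make_psm(mascot_ion_score=50.0, sequest_xcorr=0.1,
                       sequest_deltacn=0.01, xtandem_neg_log_e=0.0,
                       peptide_probability=None)
        accepted, rejected = filter_psms([rec], CRITERIA)
        assert accepted == [rec] and rejected == []

    def test_low_probability_rejects_despite_engines(self):
        rec = make_psm(peptide_probability=0.10)
        accepted, rejected = filter_psms([rec], CRITERIA)
        assert accepted == []
        assert rejected[0][1] == "probability"

    def test_probability_boundary_is_inclusive(self):
        rec = make_psm(peptide_probability=0.95)
        accepted, _ = filter_psms([rec], CRITERIA)
        assert accepted == [rec]

    def test_empty_input(self):
        accepted, rejected = filter_psms([], CRITERIA)
        assert accepted == [] and rejected == []

    def test_all_present_engines_mode_is_stricter(self):
        rec = make_psm(mascot_ion_score=50.0, sequest_xcorr=0.5,
                       sequest_deltacn=0.01, xtandem_neg_log_e=None)
        strict = dataclasses.replace(CRITERIA, engine_combination="all_present_engines")
        assert filter_psms([rec], CRITERIA).accepted == [rec]
        assert filter_psms([rec], strict).accepted == []

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ConfigError):
            PeptideFilterCriteria(xcorr_min_by_charge={1: 1.5, 2: 2.0})
        with pytest.raises(ConfigError):
            PeptideFilterCriteria(engine_combination="bogus")


def test_criteria_yaml_round_trip(tmp_path):
    criteria = PeptideFilterCriteria(mascot_min=45.0,
                                     xcorr_min_by_charge={1: 1.0, 2: 2.0, 3: 2.5, 4: 3.0})
    path = tmp_path / "criteria.yaml"
    criteria.to_yaml(path)
    assert PeptideFilterCriteria.from_yaml(path) == criteria


# --------------------------------------------------------------------------
# property tests

score_or_none = st.one_of(st.none(), st.floats(0.0, 100.0, allow_nan=False))


@st.composite
def random_psm(draw):
    return make_psm(
        charge=draw(st.integers(1, 6)),
        mascot_ion_score=draw(score_or_none),
        sequest_xcorr=draw(score_or_none.map(lambda v: None if v is None else v / 20)),
        sequest_deltacn=draw(st.one_of(st.none(), st.floats(0.0, 1.0, allow_nan=False))),
        xtandem_neg_log_e=draw(st.one_of(st.none(), st.floats(-2.0, 10.0, allow_nan=False))),
        peptide_probability=draw(st.one_of(st.none(), st.floats(0.0, 1.0, allow_nan=False))),
    )


def _oracle_accepts(rec, criteria) -> bool:
    """Literal re-statement of the acceptance rules, kept independent of
    the implementation's code path."""
    if rec.peptide_probability is not None and rec.peptide_probability < criteria.peptide_probability_min:
        return False
    mascot = rec.mascot_ion_score is not None and rec.mascot_ion_score > 40
    xcorr_cut = {1: 1.5, 2: 2.0, 3: 2.2}.get(rec.charge, 2.5)
    sequest = (
        rec.sequest_xcorr is not None
        and rec.sequest_deltacn is not None
        and rec.sequest_deltacn > 0.10
        and rec.sequest_xcorr > xcorr_cut
    )
    xtandem = rec.xtandem_neg_log_e is not None and rec.xtandem_neg_log_e > 2.0
    return mascot or sequest or xtandem


@settings(max_examples=300, derandomize=True)
@given(st.lists(random_psm(), max_size=30))
def test_filter_agrees_with_brute_force_oracle(records):
    records = [r for r in records if not r.invariant_violations()]
    accepted, rejected = filter_psms(records, CRITERIA)
    assert len(accepted) + len(rejected) == len(records)
    assert set(id(r) for r in accepted) == {
        id(r) for r in records if _oracle_accepts(r, CRITERIA)
    }


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(random_psm(), max_size=20),
    st.floats(0, 80, allow_nan=False),
    st.floats(0, 0.5, allow_nan=False),
    st.floats(0, 8, allow_nan=False),
)
def test_raising_thresholds_never_grows_accepted_set(records, mascot, deltacn, xtandem):
    base = filter_psms(records, CRITERIA).accepted
    raised = PeptideFilterCriteria(
        mascot_min=CRITERIA.mascot_min + mascot,
        deltacn_min=CRITERIA.deltacn_min + deltacn,
        xcorr_min_by_charge={c: v + 0.5 for c, v in CRITERIA.xcorr_min_by_charge.items()},
        xtandem_min_neg_log_e=CRITERIA.xtandem_min_neg_log_e + xtandem,
        peptide_probability_min=min(1.0, CRITERIA.peptide_probability_min + 0.01),
    )
    stricter = filter_psms(records, raised).accepted
    assert {id(r) for r in stricter} <= {id(r) for r in base}
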