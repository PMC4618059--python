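import pytest

from pdzpull.psm_io import PSMRecord

_COUNTER = {"n": 0}


def make_psm(**kwargs) -> PSMRecord:
    """A valid PSM with sensible defaults, any field overridable."""
    _COUNTER["n"] += 1
    defaults = dict(
        sample_id="plus",
        condition="plus",
        construct="none",
        spectrum_id=f"spec{_COUNTER['n']:05d}",
        peptide="SAMPLEK",
        charge=2,
        accessions=("P1",),
        mascot_ion_score=60.0,
        sequest_xcorr=3.0,
        sequest_deltacn=0.25,
        xtandem_neg_log_e=4.0,
        peptide_probability=0.99,
    )
    defaults.update(kwargs)
    return PSMRecord(**defaults)


@pytest.fixture
def psm_factory():
    return make_psm
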