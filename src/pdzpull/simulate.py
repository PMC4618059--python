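"""Synthetic two-condition pull-down and two-fraction validation data.

The generator emulates the statistical structure of spectral-count AP-MS:
per-protein spectrum counts are Poisson with log-normally distributed
protein-level rates (a standard overdispersed count model), abundant
background binders appear in bait and control alike, and specific
interactors are captured essentially only on the bait resin, with a small
nonspecific carryover rate into the control.  Engine scores are drawn from
overlapping correct/incorrect score distributions so the peptide filter has
real work to do, and every protein's ground truth lives in a sidecar table
the pipeline never sees.

Rate model for the pull-down.  A background protein binds nonspecifically
with the same rate ``a_i`` (log-normal) in the '+' and '−' elutions.  A true
interactor is scarce in the lysate: its control rate is a small constant
carryover, and its '+' rate adds specific capture proportional to
``enrichment_factor - 1``::

    minus_rate = carryover
    plus_rate  = carryover + (enrichment_factor - 1) * abundance_i

so ``enrichment_factor = 1`` removes all specific binding (the null: both
conditions are symmetric and true interactors vanish from both elutions),
while the default factor of 20 yields hits that are significant and
essentially exclusive to '+', the regime the hit rule is built for.  The
default carryover of 0.02 makes a true interactor spectrally absent from
the control with probability exp(-0.02) ≈ 0.98.

For the fractionation design, a designated set of PDZ proteins is given a
construct-dependent insoluble-membrane enrichment: the wild-type iM rate is
multiplied by the configured target fold enrichment while the motif-deleted
construct keeps the baseline, and non-designated proteins have equal
expected iM/sM in both constructs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pyteomics import parser as pyt_parser

from .errors import ConfigError
from .psm_io import PSMRecord, ProteinDatabase

# PDZ names drawn first when labelling true interactors; the membrane
# validation proteins lead so the fractionation design always has them.
_PDZ_PRIORITY = ("DLG1", "TJP2", "CSKP", "SCRIB", "TJP1", "MPP5", "SNTA1", "MAGI1")

_RESIDUE_POOL = tuple("ACDEFGHMNQSTVWY")  # no K/R (cleavage sites), no I/L/P


def _default_score_model() -> dict[str, tuple[float, float, float, float]]:
    # engine -> (mu_correct, sd_correct, mu_incorrect, sd_incorrect)
    return {
        "mascot": (60.0, 15.0, 25.0, 10.0),
        "xcorr": (3.0, 0.6, 1.2, 0.5),
        "deltacn": (0.25, 0.08, 0.05, 0.04),
        "xtandem": (4.0, 1.5, 0.8, 0.6),
    }


def _default_target_fe() -> dict[str, float]:
    return {"DLG1": 2.2, "TJP2": 2.2, "CSKP": 1.0, "SCRIB": 1.0, "TJP1": 1.0}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions emulated.

    ``background_abundance`` is the mean of the log-normal over per-protein
    Poisson rates (spectra per protein per sample); ``charge_mix`` is the
    probability vector over charges 1-4.  ``zero_variance`` replaces all
    draws by their expectations (rounded counts, mean scores, deterministic
    peptide choice) for exact debugging.
    """

    seed: int = 0
    n_background: int = 900
    n_true_interactors: int = 25
    pdz_fraction: float = 0.6
    enrichment_factor: float = 20.0
    background_abundance: float = 8.0
    abundance_sigma: float = 1.0
    carryover_rate: float = 0.02
    tryptic_peptide_length: tuple[int, int] = (7, 25)
    peptides_per_protein: tuple[int, int] = (8, 25)
    score_model: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_score_model
    )
    charge_mix: tuple[float, ...] = (0.05, 0.55, 0.30, 0.10)
    incorrect_psm_rate: float = 0.05
    missed_cleavage_rate: float = 0.0
    # fractionation design
    im_base_ratio: float = 1.5
    validation_abundance: float = 60.0
    target_fe: dict[str, float] = field(default_factory=_default_target_fe)
    zero_variance: bool = False

    def __post_init__(self) -> None:
        if self.n_background < 0 or self.n_true_interactors <= 0:
            raise ConfigError("protein counts must be positive")
        if abs(sum(self.charge_mix) - 1.0) > 1e-9:
            raise ConfigError("charge_mix must sum to 1")
        for name in ("enrichment_factor", "background_abundance", "carryover_rate",
                     "im_base_ratio", "validation_abundance"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.incorrect_psm_rate <= 1.0:
            raise ConfigError("incorrect_psm_rate must be in [0, 1]")
        if not 0.0 <= self.pdz_fraction <= 1.0:
            raise ConfigError("pdz_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ProteinTruth:
    accession: str
    role: str  # "true_interactor" | "background"
    is_pdz: bool


@dataclass(frozen=True)
class SimulatedProteome:
    database: ProteinDatabase
    truth: list[ProteinTruth]
    peptides: dict[str, list[str]]  # accession -> tryptic peptides (7-25 aa)


def _pdz_reference_names() -> list[str]:
    from .psm_io import load_pdz_reference

    names = [a.name for a in load_pdz_reference()]
    ordered = [n for n in _PDZ_PRIORITY if n in names]
    ordered += sorted(n for n in names if n not in _PDZ_PRIORITY)
    return ordered


def _random_peptide(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    body = "".join(_RESIDUE_POOL[int(i)] for i in rng.integers(0, len(_RESIDUE_POOL), length - 1))
    terminal = "K" if rng.random() < 0.5 else "R"
    return body + terminal


def simulate_proteome(config: SyntheticConfig) -> SimulatedProteome:
    """Random protein database with known interactor/background labels.

    Sequences are concatenations of fully tryptic peptides (cleavage after
    K/R, never before P; the residue pool excludes internal K/R and P so an
    in-silico digest recovers exactly the designed peptides).
    """
    rng = np.random.default_rng([config.seed, 0])
    n_pdz = round(config.pdz_fraction * config.n_true_interactors)
    pdz_pool = _pdz_reference_names()
    if n_pdz > len(pdz_pool):
        raise ConfigError(
            f"pdz_fraction*n_true_interactors = {n_pdz} exceeds the "
            f"{len(pdz_pool)} names in the PDZ reference"
        )
    names = pdz_pool[:n_pdz]
    names += [f"INT{i:03d}" for i in range(1, config.n_true_interactors - n_pdz + 1)]
    names += [f"BG{i:04d}" for i in range(1, config.n_background + 1)]

    db = ProteinDatabase()
    peptides: dict[str, list[str]] = {}
    truth: list[ProteinTruth] = []
    pdz_set = set(pdz_pool)
    for idx, name in enumerate(names):
        n_pep = int(rng.integers(config.peptides_per_protein[0],
                                 config.peptides_per_protein[1] + 1))
        peps = [_random_peptide(rng, config.tryptic_peptide_length) for _ in range(n_pep)]
        sequence = "".join(peps)
        role = "true_interactor" if idx < config.n_true_interactors else "background"
        db.entries[name] = (f"{name} synthetic {role}", sequence)
        peptides[name] = peps
        truth.append(ProteinTruth(name, role, name in pdz_set))
    return SimulatedProteome(database=db, truth=truth, peptides=peptides)


def in_silico_digest(sequence: str, length_range: tuple[int, int] = (7, 25),
                     missed_cleavages: int = 0) -> list[str]:
    """Tryptic digest (cleave after K/R, not before P) filtered to the
    observable length range, in order of first occurrence."""
    peps = pyt_parser.cleave(
        sequence, pyt_parser.expasy_rules["trypsin"], missed_cleavages=missed_cleavages
    )
    ordered = sorted(peps, key=sequence.find)
    return [p for p in ordered if length_range[0] <= len(p) <= length_range[1]]


# ---------------------------------------------------------------------------
# PSM emission


def _draw_scores(
    rng: np.random.Generator, model: Mapping[str, tuple[float, float, float, float]],
    correct: bool, zero_variance: bool,
) -> dict[str, float]:
    out = {}
    for engine, (mu_c, sd_c, mu_i, sd_i) in model.items():
        mu, sd = (mu_c, sd_c) if correct else (mu_i, sd_i)
        value = mu if zero_variance else float(rng.normal(mu, sd))
        if engine in ("mascot", "xcorr"):
            value = max(0.0, value)
        if engine == "deltacn":
            value = min(1.0, max(0.0, value))
        out[engine] = value
    return out


def _draw_probability(rng: np.random.Generator, correct: bool, zero_variance: bool) -> float:
    if zero_variance:
        return 0.99 if correct else 0.2
    if correct:
        return float(max(0.0, min(1.0, 1.0 - rng.exponential(0.01))))
    return float(rng.uniform(0.0, 0.5))


def _emit_psms(
    rng: np.random.Generator,
    config: SyntheticConfig,
    proteome: SimulatedProteome,
    sample_id: str,
    condition: str,
    construct: str,
    rates: Mapping[str, float],
) -> list[PSMRecord]:
    records: list[PSMRecord] = []
    accessions = list(proteome.database.entries)
    zero_var = config.zero_variance
    counter = 0
    charges = np.array([1, 2, 3, 4])
    mix = np.asarray(config.charge_mix)
    for accession in accessions:
        rate = rates.get(accession, 0.0)
        n = int(round(rate)) if zero_var else int(rng.poisson(rate))
        peps = proteome.peptides[accession]
        for j in range(n):
            counter += 1
            incorrect = (not zero_var) and rng.random() < config.incorrect_psm_rate
            if incorrect:
                victim = accessions[int(rng.integers(0, len(accessions)))]
                vpeps = proteome.peptides[victim]
                src = vpeps[int(rng.integers(0, len(vpeps)))]
                peptide = src[-2::-1] + src[-1]  # pseudo-reversed decoy
                acc_list = (victim,)
            else:
                if zero_var:
                    peptide = peps[j % len(peps)]
                else:
                    peptide = peps[int(rng.integers(0, len(peps)))]
                acc_list = (accession,)
            charge = 2 if zero_var else int(rng.choice(charges, p=mix))
            scores = _draw_scores(rng, config.score_model, not incorrect, zero_var)
            records.append(
                PSMRecord(
                    sample_id=sample_id,
                    condition=condition,
                    construct=construct,
                    spectrum_id=f"{sample_id}.{counter:06d}",
                    peptide=peptide,
                    charge=charge,
                    accessions=acc_list,
                    mascot_ion_score=scores["mascot"],
                    sequest_xcorr=scores["xcorr"],
                    sequest_deltacn=scores["deltacn"],
                    xtandem_neg_log_e=scores["xtandem"],
                    peptide_probability=_draw_probability(rng, not incorrect, zero_var),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Pull-down design ('+' bait resin vs '−' resin alone)


@dataclass(frozen=True)
class PulldownTruth:
    accession: str
    role: str
    is_pdz: bool
    rate_plus: float
    rate_minus: float


@dataclass(frozen=True)
class SimulatedPulldown:
    proteome: SimulatedProteome
    records_plus: list[PSMRecord]
    records_minus: list[PSMRecord]
    truth: list[PulldownTruth]

    def all_records(self) -> list[PSMRecord]:
        return self.records_plus + self.records_minus


def simulate_pulldown(config: SyntheticConfig) -> SimulatedPulldown:
    """Simulate the two-condition pull-down experiment."""
    proteome = simulate_proteome(config)
    rng = np.random.default_rng([config.seed, 1])
    mu = np.log(config.background_abundance) - config.abundance_sigma**2 / 2
    truth: list[PulldownTruth] = []
    rates_plus: dict[str, float] = {}
    rates_minus: dict[str, float] = {}
    for pt in proteome.truth:
        abundance = float(rng.lognormal(mu, config.abundance_sigma))
        if pt.role == "true_interactor":
            r_minus = config.carryover_rate
            r_plus = config.carryover_rate + (config.enrichment_factor - 1.0) * abundance
        else:
            r_minus = abundance
            r_plus = abundance
        rates_plus[pt.accession] = r_plus
        rates_minus[pt.accession] = r_minus
        truth.append(PulldownTruth(pt.accession, pt.role, pt.is_pdz, r_plus, r_minus))
    plus = _emit_psms(rng, config, proteome, "plus", "plus", "none", rates_plus)
    minus = _emit_psms(rng, config, proteome, "minus", "minus", "none", rates_minus)
    return SimulatedPulldown(proteome, plus, minus, truth)


# ---------------------------------------------------------------------------
# Fractionation design (iM/sM x WT/dPDZ)

FRACTION_SAMPLES = ("WT_iM", "WT_sM", "dPDZ_iM", "dPDZ_sM")


@dataclass(frozen=True)
class FractionTruth:
    accession: str
    role: str  # "designated" | "background"
    is_pdz: bool
    target_fe: float
    expected_fe: float  # includes the construct-level nSC normalisation factor


@dataclass(frozen=True)
class SimulatedFractionation:
    proteome: SimulatedProteome
    records: dict[str, list[PSMRecord]]
    truth: list[FractionTruth]

    def all_records(self) -> list[PSMRecord]:
        out: list[PSMRecord] = []
        for s in FRACTION_SAMPLES:
            out.extend(self.records[s])
        return out


def simulate_fractionation(config: SyntheticConfig) -> SimulatedFractionation:
    """Simulate the two-fraction, two-construct validation experiment.

    Designated proteins (the keys of ``config.target_fe`` present in the
    proteome) receive a wild-type-specific iM enrichment equal to their
    target fold enrichment; everything else behaves identically in both
    constructs.  The sidecar records for every protein the exact expected
    pipeline fold enrichment, i.e. the rate-level double ratio multiplied
    by the deterministic normalisation factor arising from nSC totals.
    """
    proteome = simulate_proteome(config)
    rng = np.random.default_rng([config.seed, 2])
    mu = np.log(config.background_abundance) - config.abundance_sigma**2 / 2
    designated = {n: fe for n, fe in config.target_fe.items() if n in proteome.database}
    rates: dict[str, dict[str, float]] = {s: {} for s in FRACTION_SAMPLES}
    for pt in proteome.truth:
        if pt.accession in designated:
            base = config.validation_abundance
            fe = designated[pt.accession]
        else:
            base = float(rng.lognormal(mu, config.abundance_sigma))
            fe = 1.0
        rates["WT_sM"][pt.accession] = base
        rates["dPDZ_sM"][pt.accession] = base
        rates["WT_iM"][pt.accession] = base * config.im_base_ratio * fe
        rates["dPDZ_iM"][pt.accession] = base * config.im_base_ratio

    records = {}
    for sample in FRACTION_SAMPLES:
        construct, condition = sample.split("_")
        records[sample] = _emit_psms(
            rng, config, proteome, sample, condition, construct, rates[sample]
        )

    if config.zero_variance:
        counts = {s: {a: round(r) for a, r in rates[s].items()} for s in FRACTION_SAMPLES}
        # pooled grouping sees the union of round-robin peptide picks, so a
        # protein clears the >=2 distinct-peptide rule iff some sample has
        # at least 2 spectra for it
        kept = {
            a
            for a in proteome.database.entries
            if max(counts[s][a] for s in FRACTION_SAMPLES) >= 2
        }
        eff = {s: {a: c for a, c in counts[s].items() if a in kept} for s in FRACTION_SAMPLES}
    else:
        eff = {s: dict(rates[s]) for s in FRACTION_SAMPLES}
    totals = {s: sum(eff[s].values()) for s in FRACTION_SAMPLES}
    norm = (totals["WT_sM"] / totals["WT_iM"]) * (totals["dPDZ_iM"] / totals["dPDZ_sM"])

    truth: list[FractionTruth] = []
    for pt in proteome.truth:
        a = pt.accession
        if eff["WT_sM"].get(a, 0) and eff["dPDZ_iM"].get(a, 0) and eff["dPDZ_sM"].get(a, 0) and eff["WT_iM"].get(a, 0):
            raw = (eff["WT_iM"][a] / eff["WT_sM"][a]) / (eff["dPDZ_iM"][a] / eff["dPDZ_sM"][a])
            expected = raw * norm
        else:
            expected = float("nan")
        truth.append(
            FractionTruth(
                accession=a,
                role="designated" if a in designated else "background",
                is_pdz=pt.is_pdz,
                target_fe=designated.get(a, 1.0),
                expected_fe=expected,
            )
        )
    return SimulatedFractionation(proteome, records, truth)


# ---------------------------------------------------------------------------
# Sidecar truth files


def write_pulldown_truth(truth: Sequence[PulldownTruth], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["accession", "role", "is_pdz", "rate_plus", "rate_minus"])
        for t in truth:
            w.writerow([t.accession, t.role, int(t.is_pdz), repr(t.rate_plus), repr(t.rate_minus)])


def write_fractionation_truth(truth: Sequence[FractionTruth], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["accession", "role", "is_pdz", "target_fe", "expected_fe"])
        for t in truth:
            w.writerow([t.accession, t.role, int(t.is_pdz), repr(t.target_fe), repr(t.expected_fe)])
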