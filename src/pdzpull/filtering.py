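"""Peptide-level acceptance criteria for PSMs.

A PSM is accepted when its PeptideProphet-style posterior probability (if
present) clears the probability threshold AND at least one search engine
supports it at that engine's acceptance threshold.  Engine thresholds are
strict inequalities ("greater than"): Mascot ion score > 40, Sequest
deltaCn > 0.10 together with a charge-dependent XCorr (> 1.5 / 2.0 / 2.2 /
2.5 for 1+ / 2+ / 3+ / >=4+), and X!Tandem -log10(E) > 2.0.

Note on the probability default: the source protocol text for this class of
pipeline states an acceptance probability of "0.1%", which would accept
essentially every spectrum and is read here as a misprint; the default is
0.95 and the knob is fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal

import yaml

from .errors import ConfigError
from .psm_io import PSMRecord

Engine = Literal["mascot", "sequest", "xtandem"]
ENGINES: tuple[Engine, ...] = ("mascot", "sequest", "xtandem")


def _default_xcorr_map() -> dict[int, float]:
    return {1: 1.5, 2: 2.0, 3: 2.2, 4: 2.5}


@dataclass
class PeptideFilterCriteria:
    """Thresholds of the peptide acceptance filter.

    ``xcorr_min_by_charge`` maps charge state to the minimum XCorr; charges
    above the largest key inherit its threshold (the quadruply-charged value
    by default).  ``engine_combination`` is ``any_engine`` (a single passing
    engine suffices) or ``all_present_engines`` (every engine that scored
    the spectrum must pass).
    """

    mascot_min: float = 40.0
    deltacn_min: float = 0.10
    xcorr_min_by_charge: dict[int, float] = field(default_factory=_default_xcorr_map)
    xtandem_min_neg_log_e: float = 2.0
    peptide_probability_min: float = 0.95
    engine_combination: str = "any_engine"

    def __post_init__(self) -> None:
        for name in ("mascot_min", "deltacn_min", "xtandem_min_neg_log_e"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if set(self.xcorr_min_by_charge) < {1, 2, 3, 4}:
            raise ConfigError("xcorr_min_by_charge must cover charges 1..4")
        if not 0.0 <= self.peptide_probability_min <= 1.0:
            raise ConfigError("peptide_probability_min must be in [0, 1]")
        if self.engine_combination not in {"any_engine", "all_present_engines"}:
            raise ConfigError(f"unknown engine_combination {self.engine_combination!r}")

    def xcorr_min(self, charge: int) -> float:
        if charge in self.xcorr_min_by_charge:
            return self.xcorr_min_by_charge[charge]
        return self.xcorr_min_by_charge[max(self.xcorr_min_by_charge)]

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PeptideFilterCriteria":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "xcorr_min_by_charge" in data:
            data["xcorr_min_by_charge"] = {
                int(k): float(v) for k, v in data["xcorr_min_by_charge"].items()
            }
        return cls(**data)


def passes_engine(record: PSMRecord, criteria: PeptideFilterCriteria, engine: Engine) -> bool:
    """Does this engine's evidence clear its threshold for this spectrum?

    An absent score means the engine did not identify the spectrum and
    offers no support (returns False).  Sequest requires both deltaCn and
    the charge-matched XCorr.
    """
    if engine == "mascot":
        s = record.mascot_ion_score
        return s is not None and s > criteria.mascot_min
    if engine == "sequest":
        if record.sequest_xcorr is None or record.sequest_deltacn is None:
            return False
        return (
            record.sequest_deltacn > criteria.deltacn_min
            and record.sequest_xcorr > criteria.xcorr_min(record.charge)
        )
    if engine == "xtandem":
        s = record.xtandem_neg_log_e
        return s is not None and s > criteria.xtandem_min_neg_log_e
    raise ConfigError(f"unknown engine {engine!r}")


@dataclass(frozen=True)
class FilterResult:
    accepted: list[PSMRecord]
    rejected: list[tuple[PSMRecord, str]]

    def __iter__(self):
        return iter((self.accepted, self.rejected))


def filter_psms(
    records: Iterable[PSMRecord], criteria: PeptideFilterCriteria
) -> FilterResult:
    """Partition records into accepted and rejected (with reasons).

    Acceptance is conjunctive: the probability filter (when a probability is
    present) AND engine support under ``engine_combination``.  The partition
    is exhaustive and order-preserving.
    """
    accepted: list[PSMRecord] = []
    rejected: list[tuple[PSMRecord, str]] = []
    for record in records:
        p = record.peptide_probability
        if p is not None and p < criteria.peptide_probability_min:
            rejected.append((record, "probability"))
            continue
        support = [passes_engine(record, criteria, e) for e in ENGINES]
        present = record.engine_scores_present()
        if criteria.engine_combination == "any_engine":
            ok = any(support)
        else:  # all_present_engines
            present_engines = [
                e
                for e in ENGINES
                if (e == "mascot" and record.mascot_ion_score is not None)
                or (e == "sequest" and record.sequest_xcorr is not None)
                or (e == "xtandem" and record.xtandem_neg_log_e is not None)
            ]
            ok = bool(present_engines) and all(
                passes_engine(record, criteria, e) for e in present_engines
            )
        if ok:
            accepted.append(record)
        else:
            reason = "engine_support" if present else "no_engine_scores"
            rejected.append((record, reason))
    return FilterResult(accepted, rejected)
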