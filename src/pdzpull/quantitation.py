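"""Spectral-count quantitation and bait-vs-control enrichment calls.

The relative quantity of a protein group in a sample is its spectral count
(SC, the number of accepted spectra razor-assigned to it); the normalised
spectral count nSC divides SC by the summed SC of the entire sample, so
nSC sums to 1 within a sample.  Specific binding is scored as the ratio of
nSC in the bait-coupled elution ('+') over the resin-alone control ('−');
because spectral counting is imprecise for scarce proteins, only groups
with SC strictly above ``sc_min`` (default 10) are considered significant.
The default hit rule additionally requires exclusivity (SC = 0 in the
control, i.e. an infinite ratio); a finite ``ratio_min`` mode is available
for more tolerant re-analysis.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ConfigError, NormalizationError


@dataclass(frozen=True)
class SampleQuant:
    """Per-sample SC and nSC over protein-group representatives."""

    sample_id: str
    condition: str
    sc: dict[str, int]
    nsc: dict[str, float]

    def total_sc(self) -> int:
        return sum(self.sc.values())


def compute_nsc(sample_id: str, condition: str, sc: Mapping[str, int]) -> SampleQuant:
    """Normalise spectral counts within one sample.

    Raises NormalizationError when every count is zero (the normalisation
    denominator is undefined).
    """
    total = sum(sc.values())
    if total <= 0:
        raise NormalizationError(
            f"sample {sample_id!r}: all spectral counts are zero; nSC undefined"
        )
    nsc = {rep: count / total for rep, count in sc.items()}
    return SampleQuant(sample_id=sample_id, condition=condition, sc=dict(sc), nsc=nsc)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-group '+' vs '−' quantitation and the hit decision."""

    representative: str
    sc_plus: int
    sc_minus: int
    nsc_plus: float
    nsc_minus: float
    ratio: float  # math.inf when absent from the control
    significant: bool
    exclusive_plus: bool
    hit: bool


def resolve_sc_min(
    default: int, overrides: Mapping[str, int] | None, sample_id: str
) -> int:
    """Per-sample significance cut-off override (e.g. a stricter SC > 20)."""
    value = default if overrides is None else overrides.get(sample_id, default)
    if value <= 0:
        raise ConfigError(f"sc_min must be positive, got {value}")
    return value


def call_enrichment(
    plus: SampleQuant,
    minus: SampleQuant,
    sc_min: int = 10,
    ratio_min: float = math.inf,
) -> list[EnrichmentResult]:
    """Score every group present in either sample against the control.

    A group missing from one sample has SC 0 there.  ``significant`` means
    SC strictly above ``sc_min`` in the '+' sample; ``exclusive_plus`` means
    present in '+' but absent from '−' (infinite ratio).  A hit must be
    significant and either exclusive or, when a finite ``ratio_min`` is
    configured, have ratio >= ratio_min.  Results are sorted by
    (exclusivity, ratio, SC+) descending.
    """
    if sc_min <= 0:
        raise ConfigError(f"sc_min must be positive, got {sc_min}")
    universe = sorted(set(plus.sc) | set(minus.sc))
    results = []
    for rep in universe:
        sc_p = plus.sc.get(rep, 0)
        sc_m = minus.sc.get(rep, 0)
        nsc_p = plus.nsc.get(rep, 0.0)
        nsc_m = minus.nsc.get(rep, 0.0)
        if nsc_m > 0:
            ratio = nsc_p / nsc_m
            exclusive = False
        else:
            ratio = math.inf if sc_p > 0 else 0.0
            exclusive = sc_p > 0
        significant = sc_p > sc_min
        hit = significant and (exclusive or (math.isfinite(ratio_min) and ratio >= ratio_min))
        results.append(
            EnrichmentResult(
                representative=rep,
                sc_plus=sc_p,
                sc_minus=sc_m,
                nsc_plus=nsc_p,
                nsc_minus=nsc_m,
                ratio=ratio,
                significant=significant,
                exclusive_plus=exclusive,
                hit=hit,
            )
        )
    results.sort(key=lambda r: (r.exclusive_plus, r.ratio, r.sc_plus), reverse=True)
    return results


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "representative",
                "sc_plus",
                "sc_minus",
                "nsc_plus",
                "nsc_minus",
                "ratio",
                "significant",
                "exclusive_plus",
                "hit",
            ]
        )
        for r in results:
            w.writerow(
                [
                    r.representative,
                    r.sc_plus,
                    r.sc_minus,
                    format(r.nsc_plus, ".4g"),
                    format(r.nsc_minus, ".4g"),
                    "inf" if math.isinf(r.ratio) else format(r.ratio, ".4g"),
                    int(r.significant),
                    int(r.exclusive_plus),
                    int(r.hit),
                ]
            )
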