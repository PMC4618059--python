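"""Membrane-fraction validation statistics: iM/sM ratios and WT-vs-ΔPDZ
fold enrichment.

For each construct (wild-type bait receptor vs a mutant lacking the
C-terminal PDZ-binding motif) the abundance of a protein in the
detergent-insoluble membrane fraction (iM) relative to the detergent-soluble
fraction (sM) is the ratio of its normalised spectral counts,
``nSC_iM / nSC_sM``.  Proteins confined to one fraction or below the
significance cut-off get a status instead of a number:

* ``only_iM``  — SC > sc_min in iM while SC = 0 in sM;
* ``only_sM``  — symmetric;
* ``not_significant`` — SC < sc_min in both fractions.

The fold enrichment FE = (iM/sM of WT) / (iM/sM of mutant) is defined only
when both constructs have numeric ratios; FE strictly above 2 is taken as
evidence of direct PDZ-motif-dependent association.  Displayed FE is
rounded half-up to one decimal; full precision is kept internally.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

from .quantitation import SampleQuant


class FractionStatus(str, Enum):
    RATIO = "ratio"
    ONLY_IM = "only_iM"
    ONLY_SM = "only_sM"
    NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class FractionRatio:
    """iM/sM outcome for one protein in one construct."""

    name: str
    status: FractionStatus
    value: float | None = None

    @classmethod
    def from_value(cls, name: str, value: float) -> "FractionRatio":
        return cls(name=name, status=FractionStatus.RATIO, value=value)

    def display(self) -> str:
        if self.status is FractionStatus.RATIO:
            return format(self.value, ".4g")
        return {
            FractionStatus.ONLY_IM: "only in iM",
            FractionStatus.ONLY_SM: "only in sM",
            FractionStatus.NOT_SIGNIFICANT: "not significant",
        }[self.status]


def fraction_ratio(
    quant_im: SampleQuant, quant_sm: SampleQuant, sc_min: int = 10
) -> dict[str, FractionRatio]:
    """Per-protein iM/sM ratio-or-status for one construct.

    The status rules above are checked first; remaining proteins get the
    numeric nSC ratio.  A zero denominator (or numerator) surviving the
    status checks falls back to the corresponding exclusive status so the
    result is total.
    """
    out: dict[str, FractionRatio] = {}
    for name in sorted(set(quant_im.sc) | set(quant_sm.sc)):
        sc_i = quant_im.sc.get(name, 0)
        sc_s = quant_sm.sc.get(name, 0)
        if sc_i > sc_min and sc_s == 0:
            out[name] = FractionRatio(name, FractionStatus.ONLY_IM)
        elif sc_s > sc_min and sc_i == 0:
            out[name] = FractionRatio(name, FractionStatus.ONLY_SM)
        elif sc_i < sc_min and sc_s < sc_min:
            out[name] = FractionRatio(name, FractionStatus.NOT_SIGNIFICANT)
        elif quant_sm.nsc.get(name, 0.0) == 0.0:
            out[name] = FractionRatio(name, FractionStatus.ONLY_IM)
        elif quant_im.nsc.get(name, 0.0) == 0.0:
            out[name] = FractionRatio(name, FractionStatus.ONLY_SM)
        else:
            out[name] = FractionRatio.from_value(
                name, quant_im.nsc[name] / quant_sm.nsc[name]
            )
    return out


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FoldEnrichmentRecord:
    """Per-protein validation statistic across constructs."""

    name: str
    ratio_wt: FractionRatio
    ratio_dpdz: FractionRatio
    fold_enrichment: float | None
    display_fe: str

    @property
    def status_wt(self) -> FractionStatus:
        return self.ratio_wt.status

    @property
    def status_dpdz(self) -> FractionStatus:
        return self.ratio_dpdz.status


def fold_enrichment(
    wt: Mapping[str, FractionRatio], dpdz: Mapping[str, FractionRatio]
) -> list[FoldEnrichmentRecord]:
    """Combine per-construct ratios into fold-enrichment records.

    FE = ratio_wt / ratio_dpdz where both are numeric; otherwise FE is
    undefined and displayed as an em dash.  Records are sorted by defined
    FE descending, then name.
    """
    records: list[FoldEnrichmentRecord] = []
    for name in sorted(set(wt) | set(dpdz)):
        rw = wt.get(name, FractionRatio(name, FractionStatus.NOT_SIGNIFICANT))
        rd = dpdz.get(name, FractionRatio(name, FractionStatus.NOT_SIGNIFICANT))
        if rw.status is FractionStatus.RATIO and rd.status is FractionStatus.RATIO:
            fe = rw.value / rd.value
            display = format(round_half_up(fe, 1), ".1f")
        else:
            fe = None
            display = "—"
        records.append(
            FoldEnrichmentRecord(
                name=name, ratio_wt=rw, ratio_dpdz=rd, fold_enrichment=fe, display_fe=display
            )
        )
    records.sort(key=lambda r: (-(r.fold_enrichment if r.fold_enrichment is not None else float("-inf")), r.name))
    return records


def classify_direct_binders(
    records: Sequence[FoldEnrichmentRecord], fe_min: float = 2.0
) -> set[str]:
    """Names with defined fold enrichment strictly above ``fe_min``.

    Proteins with a status (exclusive to one fraction, or not significant)
    in either construct have undefined FE and are excluded.
    """
    return {
        r.name
        for r in records
        if r.fold_enrichment is not None and r.fold_enrichment > fe_min
    }


_STATUS_TOKENS = {
    "only_iM": FractionStatus.ONLY_IM,
    "only_sM": FractionStatus.ONLY_SM,
    "not_significant": FractionStatus.NOT_SIGNIFICANT,
}


def load_printed_fraction_ratios() -> tuple[dict[str, FractionRatio], dict[str, FractionRatio]]:
    """Load the packaged published iM/sM ratio summary of the validation
    experiment (per-protein ratios for the wild-type and motif-deleted
    constructs, with exclusivity/significance statuses where no numeric
    ratio exists).  Returns (wt, mutant) maps ready for fold_enrichment."""
    from importlib import resources

    wt: dict[str, FractionRatio] = {}
    dpdz: dict[str, FractionRatio] = {}
    with resources.as_file(
        resources.files("pdzpull.data").joinpath("membrane_fraction_ratios.tsv")
    ) as p, open(p, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            name = row["name"]
            for column, out in (("wt_im_sm", wt), ("dpdz_im_sm", dpdz)):
                token = row[column]
                if token in _STATUS_TOKENS:
                    out[name] = FractionRatio(name, _STATUS_TOKENS[token])
                else:
                    out[name] = FractionRatio.from_value(name, float(token))
    return wt, dpdz


def write_fold_table(records: Sequence[FoldEnrichmentRecord], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "wt_im_sm", "dpdz_im_sm", "fold_enrichment"])
        for r in records:
            w.writerow([r.name, r.ratio_wt.display(), r.ratio_dpdz.display(), r.display_fe])
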