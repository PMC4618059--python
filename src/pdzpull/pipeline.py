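"""End-to-end orchestration: filter -> infer -> quantify -> annotate
(-> validate), as pure functions over PSM records plus a serialisable
run configuration.

Protein grouping is performed once over the pooled accepted PSMs of all
samples in an experiment, so every sample is quantified on the same group
universe (the arithmetic of cross-sample ratios presumes this); per-sample
spectral counts then come from razor assignment of that sample's spectra.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .annotate import HitSet, annotate_hits
from .errors import PipelineError
from .filtering import PeptideFilterCriteria, filter_psms
from .inference import (
    ProteinGroup,
    accept_proteins,
    build_peptide_map,
    count_by_razor,
    group_by_parsimony,
    write_groups_table,
)
from .psm_io import (
    PSMRecord,
    ProteinDatabase,
    load_pdz_reference,
    read_fasta,
    read_psm_table,
)
from .quantitation import (
    EnrichmentResult,
    SampleQuant,
    call_enrichment,
    compute_nsc,
    resolve_sc_min,
    write_enrichment_table,
)
from .validation import (
    FoldEnrichmentRecord,
    classify_direct_binders,
    fold_enrichment,
    fraction_ratio,
    write_fold_table,
)

logger = logging.getLogger("pdzpull")

ERRATUM_NOTES = (
    "note: the protocol text's peptide acceptance 'greater than 0.1% probability' "
    "is treated as a misprint; default probability threshold is 0.95",
    "note: the significance cut-off 'SC > 10' is applied to raw spectral counts; "
    "the parenthetical 'nSC > 10' conflates SC and nSC (nSC <= 1 by construction)",
)


@dataclass
class PipelineConfig:
    """Structured run configuration; flags of the CLI override these."""

    psm_paths: list[str] = field(default_factory=list)
    fasta_path: str | None = None
    annotation_path: str | None = None
    out_dir: str = "results"
    criteria: PeptideFilterCriteria = field(default_factory=PeptideFilterCriteria)
    remap_peptides: bool = False
    min_peptides: int = 2
    min_protein_probability: float = 0.99
    sc_min: int = 10
    sc_min_overrides: dict[str, int] = field(default_factory=dict)
    ratio_min: float = math.inf
    fe_min: float = 2.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["ratio_min"] = "inf" if math.isinf(self.ratio_min) else self.ratio_min
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "criteria" in data:
            crit = data["criteria"]
            if "xcorr_min_by_charge" in crit:
                crit["xcorr_min_by_charge"] = {
                    int(k): float(v) for k, v in crit["xcorr_min_by_charge"].items()
                }
            data["criteria"] = PeptideFilterCriteria(**crit)
        if data.get("ratio_min") in ("inf", None):
            data["ratio_min"] = math.inf
        return cls(**data)

    def config_hash(self) -> str:
        data = asdict(self)
        data["ratio_min"] = repr(self.ratio_min)
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _infer_shared_groups(
    accepted: Sequence[PSMRecord],
    db: ProteinDatabase | None,
    remap: bool,
    criteria: PeptideFilterCriteria,
    min_peptides: int,
    min_probability: float,
) -> tuple[list[ProteinGroup], list[str]]:
    peptide_map, warnings = build_peptide_map(accepted, db=db, remap=remap)
    groups = group_by_parsimony(
        peptide_map, accepted, absent_probability=criteria.peptide_probability_min
    )
    return accept_proteins(groups, min_peptides, min_probability), warnings


@dataclass(frozen=True)
class PulldownReport:
    """Everything the two-condition analysis produces."""

    n_input: dict[str, int]
    n_accepted: dict[str, int]
    groups: list[ProteinGroup]
    quant_plus: SampleQuant
    quant_minus: SampleQuant
    enrichment: list[EnrichmentResult]
    hitset: HitSet
    pdz_warnings: list[str]

    @property
    def hits(self) -> list[EnrichmentResult]:
        return [r for r in self.enrichment if r.hit]

    def summary(self) -> dict:
        return {
            "n_psms_input": dict(self.n_input),
            "n_psms_accepted": dict(self.n_accepted),
            "n_proteins_identified": len(self.groups),
            "n_hits": len(self.hits),
            "n_pdz_hits": len(self.hitset.pdz_hits),
            "n_nonpdz_hits": len(self.hitset.nonpdz_hits),
        }


def run_pulldown_analysis(
    records: Sequence[PSMRecord],
    criteria: PeptideFilterCriteria | None = None,
    db: ProteinDatabase | None = None,
    remap: bool = False,
    min_peptides: int = 2,
    min_protein_probability: float = 0.99,
    sc_min: int = 10,
    sc_min_overrides: Mapping[str, int] | None = None,
    ratio_min: float = math.inf,
    annotations=None,
) -> PulldownReport:
    """Filter, infer, quantify and annotate a '+'/'−' pull-down experiment.

    ``records`` must contain both conditions (``condition`` column 'plus'
    and 'minus'); a missing control aborts the quantify stage.
    """
    criteria = criteria or PeptideFilterCriteria()
    by_condition: dict[str, list[PSMRecord]] = {"plus": [], "minus": []}
    for r in records:
        if r.condition in by_condition:
            by_condition[r.condition].append(r)
    for condition, recs in by_condition.items():
        if not recs:
            raise PipelineError(
                f"quantify stage: no PSMs with condition {condition!r}; "
                "both the bait ('+') and control ('−') elutions are required"
            )

    accepted_by: dict[str, list[PSMRecord]] = {}
    n_input: dict[str, int] = {}
    n_accepted: dict[str, int] = {}
    for condition, recs in by_condition.items():
        result = filter_psms(recs, criteria)
        accepted_by[condition] = result.accepted
        n_input[condition] = len(recs)
        n_accepted[condition] = len(result.accepted)

    pooled = accepted_by["plus"] + accepted_by["minus"]
    groups, warnings = _infer_shared_groups(
        pooled, db, remap, criteria, min_peptides, min_protein_probability
    )

    sc_plus = count_by_razor(groups, accepted_by["plus"])
    sc_minus = count_by_razor(groups, accepted_by["minus"])
    quant_plus = compute_nsc("plus", "plus", sc_plus)
    quant_minus = compute_nsc("minus", "minus", sc_minus)

    effective_sc_min = resolve_sc_min(sc_min, sc_min_overrides, "plus")
    enrichment = call_enrichment(
        quant_plus, quant_minus, sc_min=effective_sc_min, ratio_min=ratio_min
    )
    annotations = annotations if annotations is not None else load_pdz_reference()
    hitset, pdz_warnings = annotate_hits("plus", enrichment, annotations)
    return PulldownReport(
        n_input=n_input,
        n_accepted=n_accepted,
        groups=groups,
        quant_plus=quant_plus,
        quant_minus=quant_minus,
        enrichment=enrichment,
        hitset=hitset,
        pdz_warnings=pdz_warnings + warnings,
    )


@dataclass(frozen=True)
class ValidationReport:
    """Fraction-validation outcome across constructs."""

    n_input: dict[str, int]
    n_accepted: dict[str, int]
    groups: list[ProteinGroup]
    quants: dict[str, SampleQuant]
    ratios_wt: dict
    ratios_dpdz: dict
    records: list[FoldEnrichmentRecord]
    direct_binders: set[str]

    def summary(self) -> dict:
        return {
            "n_psms_input": dict(self.n_input),
            "n_psms_accepted": dict(self.n_accepted),
            "n_proteins_identified": len(self.groups),
            "n_fold_records": len(self.records),
            "direct_binders": sorted(self.direct_binders),
        }


def run_fraction_validation(
    records: Sequence[PSMRecord],
    criteria: PeptideFilterCriteria | None = None,
    db: ProteinDatabase | None = None,
    remap: bool = False,
    min_peptides: int = 2,
    min_protein_probability: float = 0.99,
    sc_min: int = 10,
    fe_min: float = 2.0,
    restrict_to: set[str] | None = None,
) -> ValidationReport:
    """Compute per-construct iM/sM ratios and WT-vs-mutant fold enrichment.

    ``records`` must carry all four (construct, fraction) samples: WT/iM,
    WT/sM, dPDZ/iM, dPDZ/sM.  ``restrict_to`` optionally narrows the
    reported fold-enrichment records to a name set (e.g. PDZ proteins).
    """
    criteria = criteria or PeptideFilterCriteria()
    cells = {("WT", "iM"), ("WT", "sM"), ("dPDZ", "iM"), ("dPDZ", "sM")}
    by_cell: dict[tuple[str, str], list[PSMRecord]] = {c: [] for c in cells}
    for r in records:
        key = (r.construct, r.condition)
        if key in by_cell:
            by_cell[key].append(r)
    missing = [c for c, recs in by_cell.items() if not recs]
    if missing:
        raise PipelineError(f"validate stage: missing samples for {sorted(missing)}")

    accepted_by: dict[tuple[str, str], list[PSMRecord]] = {}
    n_input: dict[str, int] = {}
    n_accepted: dict[str, int] = {}
    for cell, recs in sorted(by_cell.items()):
        result = filter_psms(recs, criteria)
        accepted_by[cell] = result.accepted
        label = f"{cell[0]}_{cell[1]}"
        n_input[label] = len(recs)
        n_accepted[label] = len(result.accepted)

    pooled = [r for cell in sorted(accepted_by) for r in accepted_by[cell]]
    groups, _ = _infer_shared_groups(
        pooled, db, remap, criteria, min_peptides, min_protein_probability
    )

    quants: dict[str, SampleQuant] = {}
    for cell in sorted(accepted_by):
        label = f"{cell[0]}_{cell[1]}"
        sc = count_by_razor(groups, accepted_by[cell])
        quants[label] = compute_nsc(label, cell[1], sc)

    ratios_wt = fraction_ratio(quants["WT_iM"], quants["WT_sM"], sc_min=sc_min)
    ratios_dpdz = fraction_ratio(quants["dPDZ_iM"], quants["dPDZ_sM"], sc_min=sc_min)
    if restrict_to is not None:
        ratios_wt = {n: v for n, v in ratios_wt.items() if n in restrict_to}
        ratios_dpdz = {n: v for n, v in ratios_dpdz.items() if n in restrict_to}
    records_out = fold_enrichment(ratios_wt, ratios_dpdz)
    binders = classify_direct_binders(records_out, fe_min=fe_min)
    return ValidationReport(
        n_input=n_input,
        n_accepted=n_accepted,
        groups=groups,
        quants=quants,
        ratios_wt=ratios_wt,
        ratios_dpdz=ratios_dpdz,
        records=records_out,
        direct_binders=binders,
    )


def run_all(config: PipelineConfig) -> dict:
    """One-shot run over the PSM tables named in the config.

    Reads every PSM table, splits records into the pull-down design
    (plus/minus conditions) and, when present, the fractionation design
    (iM/sM), runs the corresponding analyses, writes stage reports under
    ``out_dir`` and returns the machine-readable summary.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for note in ERRATUM_NOTES:
        logger.info(note)

    records: list[PSMRecord] = []
    diagnostics = 0
    for path in config.psm_paths:
        if not Path(path).exists():
            raise PipelineError(f"input stage: PSM table not found: {path}")
        result = read_psm_table(path)
        records.extend(result.records)
        diagnostics += len(result.diagnostics)
    if not records:
        raise PipelineError("input stage: no valid PSM records")

    db = read_fasta(config.fasta_path) if config.fasta_path else None
    if config.annotation_path:
        from .psm_io import read_annotation_table

        annotations = read_annotation_table(config.annotation_path)
    else:
        annotations = load_pdz_reference()

    summary: dict = {
        "version": _package_version(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_psm_rows_read": len(records) + diagnostics,
        "n_psm_rows_rejected_on_read": diagnostics,
        "errata": list(ERRATUM_NOTES),
    }

    pulldown_records = [r for r in records if r.condition in ("plus", "minus")]
    if pulldown_records:
        report = run_pulldown_analysis(
            pulldown_records,
            criteria=config.criteria,
            db=db,
            remap=config.remap_peptides,
            min_peptides=config.min_peptides,
            min_protein_probability=config.min_protein_probability,
            sc_min=config.sc_min,
            sc_min_overrides=config.sc_min_overrides,
            ratio_min=config.ratio_min,
            annotations=annotations,
        )
        write_groups_table(report.groups, out_dir / "groups.tsv")
        write_enrichment_table(report.enrichment, out_dir / "enrichment.tsv")
        summary["pulldown"] = report.summary()
        summary["pulldown"]["pdz_hits"] = sorted(report.hitset.pdz_hits)

    fraction_records = [r for r in records if r.condition in ("iM", "sM")]
    if fraction_records:
        vreport = run_fraction_validation(
            fraction_records,
            criteria=config.criteria,
            db=db,
            remap=config.remap_peptides,
            min_peptides=config.min_peptides,
            min_protein_probability=config.min_protein_probability,
            sc_min=config.sc_min,
            fe_min=config.fe_min,
        )
        write_fold_table(vreport.records, out_dir / "fold_enrichment.tsv")
        summary["validation"] = vreport.summary()

    if "pulldown" not in summary and "validation" not in summary:
        raise PipelineError("input stage: records carry no recognised conditions")

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _package_version() -> str:
    from . import __version__

    return __version__
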