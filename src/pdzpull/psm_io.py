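"""Readers and writers for PSM tables, FASTA databases and domain annotations.

The pipeline consumes flat tab-separated PSM reports (one row per identified
spectrum, carrying the scores of every search engine that matched it) rather
than pepXML/mzIdentML; engine reports aggregated by a validation tool are
usually exported in exactly this shape.  All report writers use a fixed
column order, tab separation, and shortest-round-trip float rendering for
record tables so that write -> read is the identity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import DuplicateSpectrumError, FormatError

CONDITIONS = frozenset({"plus", "minus", "iM", "sM"})
CONSTRUCTS = frozenset({"WT", "dPDZ", "none"})
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

ENGINE_SCORE_FIELDS = (
    "mascot_ion_score",
    "sequest_xcorr",
    "sequest_deltacn",
    "xtandem_neg_log_e",
)

MANDATORY_COLUMNS = (
    "sample_id",
    "condition",
    "construct",
    "spectrum_id",
    "peptide",
    "charge",
    "accessions",
)

OPTIONAL_COLUMNS = ENGINE_SCORE_FIELDS + ("peptide_probability", "mod_string")

PSM_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS


@dataclass(frozen=True)
class PSMRecord:
    """One identified MS/MS spectrum: the atomic unit of spectral counting.

    ``accessions`` lists every protein the search engines matched the peptide
    to; modifications are carried in ``mod_string`` as a mass-shift
    annotation, never inside ``peptide``.
    """

    sample_id: str
    condition: str
    construct: str
    spectrum_id: str
    peptide: str
    charge: int
    accessions: tuple[str, ...]
    mascot_ion_score: float | None = None
    sequest_xcorr: float | None = None
    sequest_deltacn: float | None = None
    xtandem_neg_log_e: float | None = None
    peptide_probability: float | None = None
    mod_string: str | None = None

    def engine_scores_present(self) -> tuple[str, ...]:
        return tuple(f for f in ENGINE_SCORE_FIELDS if getattr(self, f) is not None)

    def invariant_violations(self) -> list[str]:
        """Return human-readable descriptions of every violated invariant."""
        issues: list[str] = []
        if self.condition not in CONDITIONS:
            issues.append(f"condition {self.condition!r} not one of {sorted(CONDITIONS)}")
        if self.construct not in CONSTRUCTS:
            issues.append(f"construct {self.construct!r} not one of {sorted(CONSTRUCTS)}")
        if not self.spectrum_id:
            issues.append("empty spectrum_id")
        if len(self.peptide) < 5:
            issues.append(f"peptide {self.peptide!r} shorter than 5 residues")
        bad = set(self.peptide) - STANDARD_RESIDUES
        if bad:
            issues.append(f"peptide contains non-standard residues {sorted(bad)}")
        if self.charge < 1:
            issues.append(f"charge {self.charge} < 1")
        if not self.accessions or any(not a for a in self.accessions):
            issues.append("accessions must be a nonempty list of nonempty tokens")
        if not self.engine_scores_present() and self.peptide_probability is None:
            issues.append("no engine score and no peptide probability present")
        if self.sequest_deltacn is not None and not 0.0 <= self.sequest_deltacn <= 1.0:
            issues.append(f"sequest_deltacn {self.sequest_deltacn} outside [0, 1]")
        if self.peptide_probability is not None and not 0.0 <= self.peptide_probability <= 1.0:
            issues.append(f"peptide_probability {self.peptide_probability} outside [0, 1]")
        for f in ("mascot_ion_score", "sequest_xcorr"):
            v = getattr(self, f)
            if v is not None and v < 0:
                issues.append(f"{f} {v} negative")
        return issues


@dataclass(frozen=True)
class RowDiagnostic:
    """A rejected input row with its 1-based row number and the reason."""

    row: int
    message: str


@dataclass(frozen=True)
class PSMReadResult:
    records: list[PSMRecord]
    diagnostics: list[RowDiagnostic]

    def __iter__(self):
        return iter((self.records, self.diagnostics))


def _parse_float(value: str, column: str, row: int) -> float | None:
    if value is None or value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise FormatError(f"row {row}: column {column!r}: not a number: {value!r}") from exc


def read_psm_table(path: str | Path) -> PSMReadResult:
    """Read a PSM TSV into validated records, in file order.

    Rows violating record invariants are rejected with row-numbered
    diagnostics; nothing is silently dropped
    (``len(records) + len(diagnostics)`` equals the number of data rows).

    Raises
    ------
    FormatError
        If a mandatory column is missing from the header.
    DuplicateSpectrumError
        If two rows share (sample_id, spectrum_id).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for column in MANDATORY_COLUMNS:
            if column not in header:
                raise FormatError(f"{path}: missing mandatory column {column!r}")
        records: list[PSMRecord] = []
        diagnostics: list[RowDiagnostic] = []
        seen: set[tuple[str, str]] = set()
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            try:
                charge = int(row["charge"])
            except ValueError:
                diagnostics.append(RowDiagnostic(i, f"charge not an integer: {row['charge']!r}"))
                continue
            record = PSMRecord(
                sample_id=row["sample_id"],
                condition=row["condition"],
                construct=row["construct"] or "none",
                spectrum_id=row["spectrum_id"],
                peptide=row["peptide"].upper(),
                charge=charge,
                accessions=tuple(a for a in row["accessions"].split(";") if a),
                mascot_ion_score=_parse_float(row.get("mascot_ion_score", ""), "mascot_ion_score", i),
                sequest_xcorr=_parse_float(row.get("sequest_xcorr", ""), "sequest_xcorr", i),
                sequest_deltacn=_parse_float(row.get("sequest_deltacn", ""), "sequest_deltacn", i),
                xtandem_neg_log_e=_parse_float(row.get("xtandem_neg_log_e", ""), "xtandem_neg_log_e", i),
                peptide_probability=_parse_float(
                    row.get("peptide_probability", ""), "peptide_probability", i
                ),
                mod_string=row.get("mod_string") or None,
            )
            issues = record.invariant_violations()
            if issues:
                diagnostics.append(RowDiagnostic(i, "; ".join(issues)))
                continue
            key = (record.sample_id, record.spectrum_id)
            if key in seen:
                raise DuplicateSpectrumError(
                    f"{path}: row {i}: duplicate (sample_id, spectrum_id) = {key}"
                )
            seen.add(key)
            records.append(record)
    return PSMReadResult(records, diagnostics)


def _fmt(value: float | int | str | None) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def write_psm_table(records: Iterable[PSMRecord], path: str | Path) -> None:
    """Write records in the canonical column order; exact read round-trip."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PSM_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.condition,
                    r.construct,
                    r.spectrum_id,
                    r.peptide,
                    r.charge,
                    ";".join(r.accessions),
                    _fmt(r.mascot_ion_score),
                    _fmt(r.sequest_xcorr),
                    _fmt(r.sequest_deltacn),
                    _fmt(r.xtandem_neg_log_e),
                    _fmt(r.peptide_probability),
                    r.mod_string or "",
                ]
            )


# ---------------------------------------------------------------------------
# Protein sequence databases


@dataclass
class ProteinDatabase:
    """Accession -> (description, sequence) map used for peptide remapping."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def sequence(self, accession: str) -> str:
        return self.entries[accession][1]

    def accessions(self) -> list[str]:
        return list(self.entries)


def read_fasta(path: str | Path) -> ProteinDatabase:
    """Read a FASTA protein database.

    The accession is the first whitespace-delimited token of the header;
    sequences are uppercased on read.
    """
    path = Path(path)
    db = ProteinDatabase()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        sequence = str(rec.seq).upper()
        if not sequence:
            raise FormatError(f"{path}: record {accession!r} has an empty sequence")
        if accession in db.entries:
            raise FormatError(f"{path}: duplicate accession {accession!r}")
        db.entries[accession] = (rec.description, sequence)
    if not db.entries:
        raise FormatError(f"{path}: no FASTA records found")
    return db


def write_fasta(db: ProteinDatabase, path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for accession, (description, sequence) in db.entries.items():
            header = description if description else accession
            fh.write(f">{header}\n")
            for i in range(0, len(sequence), width):
                fh.write(sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Domain annotations


@dataclass(frozen=True)
class DomainAnnotation:
    """PDZ membership and domain inventory for one protein name."""

    name: str
    synonyms: tuple[str, ...]
    is_pdz: bool
    n_pdz_domains: int
    other_domains: tuple[tuple[str, int], ...]

    def all_names(self) -> frozenset[str]:
        return frozenset({self.name.upper(), *(s.upper() for s in self.synonyms)})


def _parse_domains(text: str) -> tuple[tuple[str, int], ...]:
    # "DIL:1,RA:2" -> (("DIL", 1), ("RA", 2))
    if not text:
        return ()
    out = []
    for item in text.split(","):
        name, _, count = item.partition(":")
        out.append((name.strip(), int(count) if count else 1))
    return tuple(out)


def read_annotation_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a domain-annotation TSV (columns: name, synonyms, is_pdz,
    n_pdz_domains, other_domains)."""
    path = Path(path)
    annotations: list[DomainAnnotation] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "is_pdz", "n_pdz_domains", "other_domains"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            is_pdz = row["is_pdz"].strip() in {"1", "true", "True"}
            n_pdz = int(row["n_pdz_domains"])
            if is_pdz != (n_pdz >= 1):
                raise FormatError(
                    f"{path}: row {i}: is_pdz={is_pdz} inconsistent with "
                    f"n_pdz_domains={n_pdz}"
                )
            annotations.append(
                DomainAnnotation(
                    name=row["name"],
                    synonyms=tuple(
                        s.strip() for s in (row.get("synonyms") or "").split(",") if s.strip()
                    ),
                    is_pdz=is_pdz,
                    n_pdz_domains=n_pdz,
                    other_domains=_parse_domains(row["other_domains"].strip()),
                )
            )
    return annotations


def load_pdz_reference() -> list[DomainAnnotation]:
    """Load the packaged PDZ-protein reference table.

    The fixture lists the PDZ scaffolds recovered in the bait pull-down
    screens together with the PDZ proteins of the membrane-fraction
    validation experiment, with their domain inventories (SMART-style
    domain names) and synonyms.
    """
    with resources.as_file(
        resources.files("pdzpull.data").joinpath("pdz_domains.tsv")
    ) as p:
        return read_annotation_table(p)


# ---------------------------------------------------------------------------
# Per-protein summary tables (supplementary-style protein lists)


def read_protein_summary(path: str | Path) -> "list[dict]":
    """Read a per-protein summary table (one row per protein, columns
    ``name`` plus any number of per-sample spectral-count columns).

    This is the shape of deposited supplementary protein lists once
    exported to TSV; used by the supplementary-count checks.
    """
    path = Path(path)
    rows: list[dict] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if not reader.fieldnames or "name" not in reader.fieldnames:
            raise FormatError(f"{path}: missing mandatory column 'name'")
        sc_columns = [c for c in reader.fieldnames if c != "name"]
        for row in reader:
            entry: dict = {"name": row["name"]}
            for c in sc_columns:
                entry[c] = float(row[c]) if row[c] not in (None, "") else 0.0
            rows.append(entry)
    return rows
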