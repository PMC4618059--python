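"""Hit annotation (PDZ vs non-PDZ) and cross-sample intersection.

Hits are matched to the domain-annotation reference by uppercase name or
synonym, which lets human and mouse hit lists share one merged namespace.
Unannotated names default to non-PDZ with a warning.  The intersection of
several samples' hit sets is reported as a full Venn decomposition; the
cell common to all samples is the shared interactor "fingerprint".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigError
from .psm_io import DomainAnnotation
from .quantitation import EnrichmentResult


@dataclass(frozen=True)
class HitSet:
    """One sample's hit list partitioned by PDZ membership."""

    sample_id: str
    hits: frozenset[str]
    pdz_hits: frozenset[str]
    nonpdz_hits: frozenset[str]


def _name_index(annotations: Iterable[DomainAnnotation]) -> dict[str, DomainAnnotation]:
    index: dict[str, DomainAnnotation] = {}
    for ann in annotations:
        for name in ann.all_names():
            index.setdefault(name, ann)
    return index


def annotate_hits(
    sample_id: str,
    hits: Sequence[EnrichmentResult] | Sequence[str],
    annotations: Sequence[DomainAnnotation],
) -> tuple[HitSet, list[str]]:
    """Partition a hit list into PDZ and non-PDZ sets.

    ``hits`` may be enrichment results (only rows flagged as hits are used)
    or plain names.  Returns the partition and warnings for names absent
    from the annotation table (these default to non-PDZ).
    """
    names: list[str] = []
    for h in hits:
        if isinstance(h, EnrichmentResult):
            if h.hit:
                names.append(h.representative)
        else:
            names.append(h)
    index = _name_index(annotations)
    warnings: list[str] = []
    pdz: set[str] = set()
    nonpdz: set[str] = set()
    for name in names:
        ann = index.get(name.upper())
        if ann is None:
            warnings.append(f"{name}: not in annotation table; assuming non-PDZ")
            nonpdz.add(name)
        elif ann.is_pdz:
            pdz.add(name)
        else:
            nonpdz.add(name)
    return (
        HitSet(
            sample_id=sample_id,
            hits=frozenset(pdz | nonpdz),
            pdz_hits=frozenset(pdz),
            nonpdz_hits=frozenset(nonpdz),
        ),
        warnings,
    )


def intersect_hitsets(
    hitsets: Sequence[HitSet], which: str = "pdz"
) -> dict[frozenset[str], frozenset[str]]:
    """Full Venn decomposition of hit sets across samples.

    Returns a map from subset signature (the frozenset of sample_ids whose
    hit sets contain the names, and no others) to the names in that cell.
    Empty cells are included so every one of the 2^k - 1 signatures is
    present.  The all-samples cell is the shared fingerprint.
    """
    if len(hitsets) < 2:
        raise ConfigError("intersection needs at least 2 hit sets")
    ids = [h.sample_id for h in hitsets]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"duplicate sample_id in hit sets: {ids}")
    member_sets = {
        h.sample_id: (h.pdz_hits if which == "pdz" else h.hits if which == "all" else h.nonpdz_hits)
        for h in hitsets
    }
    cells: dict[frozenset[str], set[str]] = {}
    for k in range(1, len(ids) + 1):
        for combo in combinations(sorted(ids), k):
            cells[frozenset(combo)] = set()
    for name in set().union(*member_sets.values()):
        signature = frozenset(s for s, members in member_sets.items() if name in members)
        cells[signature].add(name)
    return {sig: frozenset(names) for sig, names in cells.items()}


def fingerprint(cells: dict[frozenset[str], frozenset[str]]) -> frozenset[str]:
    """Names common to every sample (the maximal signature's cell)."""
    return cells[max(cells, key=len)]


def write_venn_table(cells: dict[frozenset[str], frozenset[str]], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["samples", "n", "names"])
        for sig in sorted(cells, key=lambda s: (len(s), sorted(s))):
            w.writerow(
                [";".join(sorted(sig)), len(cells[sig]), ";".join(sorted(cells[sig]))]
            )


def summarise_supplementary(
    rows: Sequence[dict],
    annotations: Sequence[DomainAnnotation],
    sc_columns: Sequence[str] | None = None,
    sc_min: int = 10,
) -> dict:
    """Entity counts for a deposited per-protein summary table.

    Reports the number of distinct protein entries and, for tables carrying
    spectral-count columns, how many PDZ-annotated proteins exceed the
    significance cut-off (SC strictly above ``sc_min``) in at least one of
    the selected columns.
    """
    index = _name_index(annotations)
    names = {r["name"] for r in rows}
    n_pdz_significant = 0
    for r in rows:
        columns = sc_columns if sc_columns is not None else [c for c in r if c != "name"]
        ann = index.get(str(r["name"]).upper())
        if ann is not None and ann.is_pdz and any(r.get(c, 0) > sc_min for c in columns):
            n_pdz_significant += 1
    return {"n_entries": len(names), "n_pdz_significant": n_pdz_significant}
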