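"""Peptide-to-protein mapping and parsimony protein inference.

Proteins whose accepted-peptide sets are identical are indistinguishable by
MS/MS and are merged into one group; a protein whose peptide set is a strict
subset of another's is subsumed into the larger protein's group.  Peptides
shared between distinct surviving groups are assigned for counting by the
razor rule (to the group with more distinct peptides; ties broken by the
lexicographically smallest representative), so that every accepted spectrum
is counted exactly once and total spectral counts are conserved.

Group probability uses the independence approximation
``1 - prod(1 - p_i)`` over the best peptide probability of each distinct
peptide; this is a stand-in for a full protein-probability model and any
monotone combiner preserves the acceptance semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .psm_io import PSMRecord, ProteinDatabase

PeptideProteinMap = dict[str, frozenset[str]]


def _il_collapse(s: str) -> str:
    # isobaric residues: leucine and isoleucine cannot be told apart by MS/MS
    return s.replace("L", "J").replace("I", "J")


@dataclass(frozen=True)
class MapResult:
    peptide_map: PeptideProteinMap
    warnings: list[str]

    def __iter__(self):
        return iter((self.peptide_map, self.warnings))


def build_peptide_map(
    accepted: Sequence[PSMRecord],
    db: ProteinDatabase | None = None,
    remap: bool = False,
) -> MapResult:
    """Map each accepted peptide to its candidate protein accessions.

    With ``remap`` the accession set is recomputed by exact substring search
    of the database (I/L treated as equivalent); a peptide matching no
    database sequence keeps its PSM accessions and produces a warning.
    Without ``remap`` the sets come straight from the PSM rows.
    """
    warnings: list[str] = []
    from_psms: dict[str, set[str]] = {}
    for rec in accepted:
        from_psms.setdefault(rec.peptide, set()).update(rec.accessions)
    if not remap:
        return MapResult({p: frozenset(a) for p, a in from_psms.items()}, warnings)
    if db is None:
        raise ValueError("remap=True requires a protein database")
    collapsed_db = {acc: _il_collapse(db.sequence(acc)) for acc in db.entries}
    peptide_map: PeptideProteinMap = {}
    for peptide, psm_accs in from_psms.items():
        needle = _il_collapse(peptide)
        hits = frozenset(acc for acc, seq in collapsed_db.items() if needle in seq)
        if hits:
            peptide_map[peptide] = hits
        else:
            warnings.append(f"peptide {peptide!r} matches no database sequence; "
                            "keeping PSM accessions")
            peptide_map[peptide] = frozenset(psm_accs)
    return MapResult(peptide_map, warnings)


@dataclass(frozen=True)
class ProteinGroup:
    """A parsimony group of indistinguishable protein accessions.

    ``members`` are the accessions sharing exactly ``distinct_peptides``;
    ``subsumed_members`` are accessions whose peptides are a strict subset
    and were absorbed into this group.  ``spectral_count`` is the number of
    accepted PSMs razor-assigned to the group.
    """

    members: frozenset[str]
    representative: str
    distinct_peptides: frozenset[str]
    spectral_count: int
    protein_probability: float
    subsumed_members: frozenset[str] = frozenset()


def _protein_to_peptides(peptide_map: PeptideProteinMap) -> dict[str, frozenset[str]]:
    prot: dict[str, set[str]] = {}
    for peptide, accs in peptide_map.items():
        for acc in accs:
            prot.setdefault(acc, set()).add(peptide)
    return {a: frozenset(p) for a, p in prot.items()}


def razor_map(groups: Sequence[ProteinGroup]) -> dict[str, str]:
    """Assign every peptide to exactly one group representative.

    The winner is the group with the most distinct peptides containing the
    peptide; ties go to the lexicographically smallest representative.
    """
    by_rep = {g.representative: g for g in groups}
    assignment: dict[str, str] = {}
    for group in groups:
        for peptide in group.distinct_peptides:
            incumbent = assignment.get(peptide)
            if incumbent is None:
                assignment[peptide] = group.representative
                continue
            inc_group = by_rep[incumbent]
            if (len(group.distinct_peptides), _neg_name(group.representative)) > (
                len(inc_group.distinct_peptides),
                _neg_name(incumbent),
            ):
                assignment[peptide] = group.representative
    return assignment


class _neg_name(str):
    """Reverse lexicographic ordering helper (smaller name wins a max)."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def count_by_razor(
    groups: Sequence[ProteinGroup], psms: Iterable[PSMRecord]
) -> dict[str, int]:
    """Spectral count per group representative for an arbitrary PSM subset.

    PSMs whose peptide is not covered by any group are ignored.
    """
    assignment = razor_map(groups)
    counts = {g.representative: 0 for g in groups}
    for rec in psms:
        rep = assignment.get(rec.peptide)
        if rep is not None:
            counts[rep] += 1
    return counts


def group_by_parsimony(
    peptide_map: PeptideProteinMap,
    psms: Sequence[PSMRecord],
    absent_probability: float = 0.95,
) -> list[ProteinGroup]:
    """Collapse proteins into parsimony groups and count spectra.

    Steps: merge proteins with identical accepted-peptide sets; absorb
    proteins whose peptide set is a strict subset of another's (flagged as
    subsumed); razor-assign shared peptides for counting.  Group probability
    is the independence combination of the best peptide probabilities
    (missing probabilities filled with ``absent_probability``, the peptide
    filter's own threshold).
    """
    prot_peps = _protein_to_peptides(peptide_map)

    # (a) merge identical peptide sets
    by_set: dict[frozenset[str], set[str]] = {}
    for acc, peps in prot_peps.items():
        by_set.setdefault(peps, set()).add(acc)

    # (b) subsumption: absorb strict subsets into the maximal set that
    # subsumes them (most peptides; ties -> smallest representative)
    sets = list(by_set)
    subsumed_into: dict[frozenset[str], frozenset[str]] = {}
    for s in sets:
        supersets = [t for t in sets if s < t]
        if supersets:
            target = min(supersets, key=lambda t: (-len(t), min(by_set[t])))
            subsumed_into[s] = target

    surviving = [s for s in sets if s not in subsumed_into]
    groups_draft: list[dict] = []
    for s in surviving:
        absorbed: set[str] = set()
        for sub, target in subsumed_into.items():
            # follow chains: a subset's target may itself have been subsumed
            seen: set[frozenset[str]] = set()
            t = target
            while t in subsumed_into and t not in seen:
                seen.add(t)
                t = subsumed_into[t]
            if t == s:
                absorbed.update(by_set[sub])
        members = frozenset(by_set[s])
        groups_draft.append(
            {
                "members": members,
                "representative": min(members),
                "distinct_peptides": s,
                "subsumed_members": frozenset(absorbed),
            }
        )

    # best probability per peptide across its PSMs
    best_prob: dict[str, float | None] = {}
    for rec in psms:
        if rec.peptide in peptide_map:
            prev = best_prob.get(rec.peptide)
            p = rec.peptide_probability
            if p is not None and (prev is None or p > prev):
                best_prob[rec.peptide] = p
            else:
                best_prob.setdefault(rec.peptide, prev)

    prelim = [
        ProteinGroup(
            members=d["members"],
            representative=d["representative"],
            distinct_peptides=d["distinct_peptides"],
            spectral_count=0,
            protein_probability=0.0,
            subsumed_members=d["subsumed_members"],
        )
        for d in groups_draft
    ]
    counts = count_by_razor(prelim, psms)

    groups: list[ProteinGroup] = []
    for g in prelim:
        prob = 1.0
        for peptide in g.distinct_peptides:
            p = best_prob.get(peptide)
            if p is None:
                p = absent_probability
            prob *= 1.0 - p
        groups.append(
            ProteinGroup(
                members=g.members,
                representative=g.representative,
                distinct_peptides=g.distinct_peptides,
                spectral_count=counts[g.representative],
                protein_probability=1.0 - prob,
                subsumed_members=g.subsumed_members,
            )
        )
    groups.sort(key=lambda g: g.representative)
    return groups


def accept_proteins(
    groups: Sequence[ProteinGroup],
    min_peptides: int = 2,
    min_probability: float = 0.99,
) -> list[ProteinGroup]:
    """Keep groups with at least ``min_peptides`` distinct peptides and a
    combined probability of at least ``min_probability``."""
    return [
        g
        for g in groups
        if len(g.distinct_peptides) >= min_peptides
        and g.protein_probability >= min_probability
    ]


def write_groups_table(groups: Sequence[ProteinGroup], path) -> None:
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "representative",
                "members",
                "n_peptides",
                "spectral_count",
                "protein_probability",
                "subsumed_members",
            ]
        )
        for g in groups:
            w.writerow(
                [
                    g.representative,
                    ";".join(sorted(g.members)),
                    len(g.distinct_peptides),
                    g.spectral_count,
                    format(g.protein_probability, ".4g"),
                    ";".join(sorted(g.subsumed_members)),
                ]
            )
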