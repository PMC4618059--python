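# Methods

## Scope and data model

The pipeline starts from engine-aggregated PSM reports — one row per
identified spectrum carrying the sample label, condition ('+'/'−' for the
pull-down; iM/sM plus WT/ΔPDZ for the fractionation design), peptide,
charge, candidate accessions, and whichever of the Mascot / Sequest /
X!Tandem scores and the posterior probability are available. It does not
perform database searching, spectrum processing, or probability modelling
of the PeptideProphet/ProteinProphet kind; those quantities are consumed as
input (or approximated, below). Input is a flat TSV dialect rather than
pepXML/mzIdentML because engine evidence merged by a validation tool is
naturally row-per-spectrum with all scores side by side; a converter seam
is left open.

Readers reject invalid rows with row-numbered diagnostics and never drop
rows silently: accepted + diagnosed = input. Record tables round-trip
exactly (floats written in shortest round-trip form); derived report
tables are written at 4 significant digits and are not meant to round-trip.

## Peptide filter

Acceptance is conjunctive: probability (when present) AND engine support.
Engine thresholds are strict inequalities, since the protocol wording for
this filter family is "greater than": Mascot ion score > 40; Sequest
requires both ΔCn > 0.10 and the charge-matched XCorr (> 1.5, 2.0, 2.2,
2.5 for 1+, 2+, 3+, ≥4+; charges above 4 inherit the 4+ threshold); X!Tandem
−log₁₀E > 2.0. An absent score means that engine offers no support.
`any_engine` is the default combination — three engines were run precisely
so that one engine's evidence suffices — with `all_present_engines` as a
stricter mode.

The probability threshold defaults to 0.95 with `>=` semantics. Protocol
texts in this family sometimes print "greater than 0.1 % probability",
which would accept nearly everything and is treated as a misprint; the
default is a conventional posterior cut and the knob is fully configurable.
The pipeline log surfaces this erratum whenever defaults are used.

## Protein inference

Peptide → accession sets come from the PSM rows, or are recomputed by exact
substring search of a FASTA database with isoleucine/leucine collapsed
(isobaric residues are indistinguishable by MS/MS). Grouping follows
parsimony: proteins with identical accepted-peptide sets merge into one
group (representative: lexicographically smallest accession); a protein
whose set is a strict subset of another's is absorbed into the subsuming
group and flagged. Only accepted peptides participate — peptides failing
the filter never rescue a protein.

Shared peptides between surviving groups are razor-assigned for counting to
the group with more distinct peptides (ties: smaller representative), so
every accepted spectrum is counted exactly once and total SC is conserved —
a property the downstream ratio arithmetic presumes. Note that with
maximal-indistinguishable-set grouping, mutually overlapping peptide sets
that are not subsets (A:{1,2}, B:{2,3}, C:{1,3}) all survive; a minimum
set cover could be smaller, but is ambiguous under ties and would break the
subset semantics, so it is deliberately not used.

Group probability is the independence approximation 1 − ∏(1 − pᵢ) over each
distinct peptide's best probability, with absent probabilities filled by
the peptide-filter threshold. This is a monotone stand-in for a full
protein-probability model; acceptance semantics (≥ 2 distinct peptides and
probability ≥ 0.99) are preserved under any monotone combiner. The 0.99
boundary is inclusive so that two independent 0.9 peptides sit exactly at
acceptance.

When an experiment has several samples, grouping runs once over the pooled
accepted PSMs and every sample is counted on that shared group universe;
cross-sample ratios are otherwise ill-defined.

## Quantitation and hit calling

nSC divides a group's SC by the summed SC of all accepted groups in that
sample's elution (not the whole experiment). Significance is SC strictly
greater than `sc_min` (default 10) on the raw counts of the bait sample;
the occasional "nSC > 10" phrasing in this literature necessarily refers to
SC, since nSC ≤ 1 by construction — the second erratum surfaced in the log.
Per-sample overrides support stricter cut-offs (e.g. SC > 20) without
changing anything else. The default hit rule is exclusivity (SC = 0 in the
control), matching the observation that genuine bait-specific interactors
are essentially absent from resin-alone controls; `ratio_min` enables a
finite-ratio mode. Whether significance should be assessed before or after
any background subtraction is not decidable from the protocol wording;
it is evaluated directly on the '+' sample.

## Annotation and intersection

Hits are matched to the packaged PDZ reference by uppercase name or
synonym, merging human and mouse namespaces; unknown names default to
non-PDZ with a warning. The reference lists the 26 PDZ scaffolds of the
pull-down screens with their SMART-style domain inventories (e.g. MPDZ with
13 PDZ domains, INADL with 10) plus the three validation-only PDZ proteins
(NEB1, NEB2, PDZD8); users can supply their own TSV. Cross-sample
comparison produces the full 2ᵏ−1-cell Venn decomposition; cells partition
the union of hit sets and the all-samples cell is the shared fingerprint.

## Fraction validation

Per construct, each protein gets the nSC ratio iM/sM, or a status:
`only_iM` (SC > sc_min in iM, SC = 0 in sM), `only_sM` (symmetric),
`not_significant` (SC < sc_min in both). The rules above leave corner
cases uncovered (e.g. SC_iM = 10 with SC_sM = 0 is neither "> 10 exclusive"
nor "< 10 in both", and the nSC ratio would divide by zero); a zero
denominator or numerator surviving the status checks resolves to the
corresponding exclusive status so the map is total.

FE = R_WT / R_ΔPDZ is defined only when both ratios are numeric. Display
rounding is half-up to one decimal (verified consistent with the packaged
reference table's printed column); full precision is kept internally, and
the direct-binder call (FE strictly > 2 by default) uses full precision.
Swapping constructs maps FE → 1/FE exactly. With the same denominator pair,
the double ratio is identical whether built from nSC or raw SC; nSC is
used because that is how per-construct ratios are reported.

## Synthetic data

The generator emulates spectral-count AP-MS at the study's scale: 925
proteins (900 background + 25 true interactors, 60 % of them PDZ-annotated
with names drawn from the packaged reference), per-protein Poisson counts
with log-normal rates (mean 8 spectra/protein, σ = 1 — an overdispersed
count model standard for spectral counting), charges drawn from a 1+–4+
mix, and per-engine scores from overlapping correct/incorrect Gaussians
(e.g. Mascot correct ~ N(60, 15) truncated at 0, incorrect ~ N(25, 10))
with 5 % incorrect PSMs carrying pseudo-reversed decoy peptides and low
posteriors. Proteins are built as concatenations of fully tryptic peptides
(7–25 residues, cleavage after K/R never before P; the residue pool
excludes internal K/R and P) so an in-silico digest recovers the designed
peptides exactly; missed cleavages are off by default (knob provided).

Pull-down rates: background binds identically in both elutions
(rate aᵢ); a true interactor has control rate equal to a small carryover
constant (0.02, so it is spectrally absent from the control with
probability ≈ 0.98) and bait rate carryover + (enrichment_factor − 1)·aᵢ.
This form was chosen over a bare multiplication because it simultaneously
yields (i) a proper null at enrichment_factor 1 — both conditions
symmetric, specific binding gone — (ii) near-exclusive, significant hits at
the default factor 20, and (iii) the high control-absence probability that
the exclusivity hit rule presumes. No single-rate multiplicative model
satisfies all three at once.

Fractionation rates: every protein has sM rate equal to its abundance and
iM rate abundance × 1.5 (a mild baseline insoluble-membrane enrichment)
in both constructs; designated proteins (defaults: DLG1 and TJP2 at target
FE 2.2; CSKP, SCRIB, TJP1 at 1.0; abundance 60 so counts are informative)
have their WT iM rate additionally multiplied by the target FE. The
pipeline's FE estimator carries a construct-level normalisation factor
(ratio of sample totals, ≈ 0.98 under defaults) on top of the rate-level
double ratio; the truth sidecar records the exact expected FE including
that factor. A zero-variance debug mode (counts = rounded rates, mean
scores, round-robin peptide choice, no incorrect PSMs) reproduces the
sidecar FE to machine precision.

Ground truth lives only in the sidecar table, never in the PSM files, so
end-to-end tests cannot leak labels. One seed produces byte-identical
outputs; the proteome, pull-down and fractionation stages use disjoint
seed streams derived from the configured seed.

What the generator does **not** emulate: peptide-level detectability
(length/hydrophobicity biases), shared peptides between homologous
proteins (random sequences essentially never collide, so parsimony is
exercised by dedicated unit and property tests rather than by simulation),
retention-time or intensity structure, and inter-replicate variation
beyond Poisson. Passing recovery tests therefore demonstrates the
correctness of the counting, grouping and ratio arithmetic under a
realistic count model — not robustness to all failure modes of real
lysate data.

## Problem sizes and numerical choices

Recovery experiments use the full default scale (925 proteins, ≈ 18 000
spectra per pull-down) over 10 seeds for the pull-down (hit sensitivity,
false-discovery proportion) and 20 seeds for the fractionation (mean FE at
target 2.2); single-run FE estimates have standard deviation ≈ 0.5 at the
default counts, so targets are assessed on seed-averaged means. nSC sums
are checked to 1e−9; FE equality in zero-variance mode to relative 1e−9.
Ties in razor assignment and representatives are broken lexicographically
for determinism. Degenerate inputs fail loudly: all-zero samples raise a
normalisation error, non-positive cut-offs a configuration error, missing
experimental arms abort with the stage name.

## Known limitations

- Protein probability is an independence approximation, not a calibrated
  posterior; absolute acceptance near the 0.99 boundary depends on it.
- Shared-spectrum handling conserves total SC (each spectrum counted
  once); tools that count shared spectra once per protein will report
  higher absolute SCs for homologous groups.
- Single-run design: no replicate-aware significance model (SAINT-style
  scoring is out of scope), no length normalisation (NSAF), no
  decoy-based FDR.
- The deposited supplementary protein lists of the original screens are
  not packaged; entity-count checks against them require user-supplied
  TSV exports under `data/supplementary/`.
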