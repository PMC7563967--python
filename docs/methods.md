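# Methods

This note documents the models and conventions behind the package: what each
stage computes, the defaults and why, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer would want recorded.

## Quantification

Raw inputs are locus-level small-RNA counts (`mir_id, locus_id, sample_id,
bait, replicate, count`). Because a mature miR can be produced from several
genomic loci, per-miR counts are the **sum** over loci; summing (rather than,
say, taking the maximum locus) preserves per-sample totals, which keeps the
conservation invariants simple and makes locus aggregation commute with tpm
scaling.

tpm here is counts-per-million over the miR table provided:
`tpm = count / sample_total × 1e6`. No length normalization is applied —
mature miRs are nearly uniform in length (~22 nt) — so, despite the name,
this is CPM on the miR fraction. Per-sample tpm sums to 10⁶ to within
floating-point rounding. Whether normalization should run over the miR
fraction only or over all mapped small RNAs is a genuine choice; this package
normalizes over whatever table it is given.

Read-length QC is advisory: the library passes when the modal read length
falls in 21–23 nt (the mature-miR peak of a size-selected library). Modal
ties resolve toward the smaller length. A failing QC never aborts the
pipeline; it is a flag for the analyst.

## Enrichment

Replicate tpm values combine by **geometric mean** of `(tpm + pseudocount)`:
enrichment is a ratio statistic and ratios are multiplicative, so the
geometric mean is the natural center. The pseudocount (default 0.01 tpm)
stabilizes miRs absent from the control eluate; records where the control tpm
is at or below twice the pseudocount are flagged `pseudocount_dominated`
because their ratio is floored by the stabilizer rather than measured.

`enriched` means ratio strictly greater than 1. Summary percentages (fraction
of the universe enriched; breakdown of the enriched set by prediction-vote
count) are rounded half-up to two decimals, matching the usual reporting
style for these fractions.

The shipped breakdown fixture (`enriched_vote_breakdown.tsv`) transcribes the
published per-vote counts for the 352 enriched miRs of the TAP1 screen. The
published counts sum to 351; the remaining miR is recorded here in a six-vote
bucket so the breakdown totals 352. None of the percentage checks depend on
that reconstructed row.

## Prediction consensus

Six tools are consulted (miRWalk, microrna.org, miRDB, TargetScan, RNA22,
RNAhybrid); their outputs are consumed as yes/no tables, never recomputed.
Token parsing is case-insensitive because real tool exports mix "yes" and
"Yes". A miR absent from a tool's table counts as *not predicted* (false)
rather than missing: the consensus vote is a count of positive calls, and an
unreported miR contributes none. The tool set is configurable but defaults to
the six above so the "≥ 4 of 6" threshold stays comparable.

The candidate fixture (`tap1_candidate_mirs.tsv`, 21 rows) is audited on
load: the printed vote count of every row must equal the count recomputed
from its six booleans, and energies must be negative.

## Hybridization model

The duplex scorer is **intermolecular-only** (the RNAhybrid model class): the
miR and a UTR window form an antiparallel duplex; neither strand folds on
itself. A structure is a set of non-crossing base pairs (Watson–Crick or G:U
wobble). Its free energy is

    ΔG = initiation + Σ (stack | loop) over consecutive pairs

where adjacent pairs contribute a nearest-neighbor stack term and separated
pairs contribute a linear loop penalty. The embedded stack table carries the
standard Watson–Crick RNA/RNA nearest-neighbor free energies at 37 °C plus a
representative G:U wobble set, expanded to all 36 ordered pair combinations
by rotational symmetry (reading a stack from the opposite strand must give
the same energy). Loop costs are linear per unpaired nucleotide — bulge
2.0 kcal/mol·nt, internal loop 1.0 kcal/mol·nt, total loop size capped at
10 nt — rather than full Turner loop tables. Duplex initiation is
+4.09 kcal/mol; dangling ends are free.

Consequently the energies are an **independent score**, not a reproduction of
RNAhybrid or Turner-2004 output; published energies in the candidate fixture
are treated as data and consumed by the selection module as-is.

The minimum free energy is found by dynamic programming over "last base pair"
states, O(n·m·L²) for sequence lengths n, m and loop cap L, deterministic,
with traceback for the pairing. When no negative-energy structure exists the
scanner returns a "no stable duplex" sentinel (ΔG = 0, no pairs); because
initiation is positive, a stable duplex needs at least two stacked pairs. The
DP is verified against exhaustive enumeration of all legal pairings in the
test suite.

Site scanning is seed-anchored: seed matches are exact Watson–Crick reverse
complements of miR nt 2–7 (wobble is excluded from seed matching but allowed
in duplex extension; 7-mer matches of nt 2–8 are classified separately). Each
match defines a window of 30 nt of 5′ UTR context plus the seed and 5 nt
downstream — enough for 3′-compensatory pairing of a ~22-nt miR — and the
reported site interval is the UTR span actually paired in the MFE structure.
Sites at or below the energy cutoff (default −5 kcal/mol for scanning;
selection applies its own, stricter threshold) are returned sorted by ΔG, and
a miR's binding energy is the minimum over its sites. Coordinates are 0-based
half-open throughout; DNA input (T) is silently converted to RNA (U).

`delete_site` excises an interval, emulating binding-site deletion mutants of
reporter constructs; tests assert that re-scanning after deletion yields no
surviving site.

## ΔCt arithmetic

Relative expression is `2^−(Ct_target − Ct_reference)` with amplification
efficiency fixed at 2; technical replicates average on the Ct scale (standard
practice — averaging the exponentiated values would bias the geometric
structure of the assay). The miTRAP ratio is `2^−(Ct_eluate − Ct_input)`,
reported per bait so the target bait's fold can be compared against the MS2
control bait's; the input maps to exactly 1. Whether the published
bar-graph ratio additionally divides the target-bait fold by the control-bait
fold is ambiguous in the assay description, so both per-bait folds are
reported and their quotient is left to the caller (criterion (vi) compares
them directly). Ct 40 marks a censored reaction and propagates as a flag
rather than dropping rows.

## Candidate selection

All six criteria use strict inequalities, matching their verbal statements
("higher than 1000", "less than 100", "higher than 50"). Thresholds for the
energy and miTRAP criteria are conventions — the assay logic prescribes only
"high" — with defaults chosen to be consistent with the published
retained/excluded candidates: −20.0 kcal/mol keeps a candidate printed at
−20.3 and drops one at −12.8; the factor-2 miTRAP rule reflects a candidate
excluded for a control-bait fold comparable to its target-bait fold. Both
are prominent, ordinary parameters.

Criteria whose inputs are missing for a miR are *not applicable* and do not
fail it (the shipped fixture has no tpm columns, so a fixture run evaluates
votes, ratio and energy only). The report is lossless — every input miR
appears once, with per-criterion verdicts — and passers are ranked by
enrichment ratio descending, ties broken by more negative energy, then by
miR id. The published candidate narrative includes one miR whose own ratio
(1.3) fails the ratio criterion; the report reproduces the criterion, not the
narrative.

## Validation statistics

Reporter wells normalize firefly to renilla per well, then condition means to
the control condition (control ≡ 1). Densitometry normalizes a band to its
loading control and then to the parental lane (parental ≡ 1). Degranulation
subtracts spontaneous (effector-only) CD107a percentages from the with-target
percentage, floored at 0 — a negative specific signal is not meaningful — and
x-fold changes are computed on the specific signal. TAP1
immunohistochemistry grades tumor-cell positivity into 0%, 1–10%, 11–30% and
>30%, with boundary values assigned to the lower bracket per the printed
notation; low = 0–10%, high = >30%, and intermediate lesions are excluded
from high/low comparisons.

Group comparisons default to **Welch's** unequal-variance two-sided t-test
(the equal-variance pooled test and a Mann–Whitney alternative are available
by flag); paired designs use the paired t-test. The test-suite calibration
check runs 1000 null replicates at n = 10 + 10 and requires the empirical
type-I rate to sit in 0.05 ± 0.02.

## Synthetic data

The generator's defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_mirs | 2693 | miRBase-scale universe of the screen |
| n_enriched | 5 | small planted subset |
| depth_per_sample | 10⁶ | typical small-RNA library scale |
| planted_ratio_range | 60–200 | clearly above the ratio-50 criterion |
| n_replicates | 2 | two biological replicates per bait |
| planted_control_tpm | 30 | planted candidates are rare in the control eluate (tpm < 100), matching the profile of the published candidates (e.g. ratio ≈ 92 from tpm ≈ 9210/100) |
| abundance σ (log) | 1.2 | wide log-normal background abundance |
| two_locus_fraction | 0.15 | exercises multi-locus aggregation |
| Ct noise sd | 0.2 cycles | tight technical replication |
| planted folds | 700×, 50× | the published eluate enrichments of the two lead candidates |
| n_patients | 20 | 10 TAP1-high + 10 TAP1-low |
| patient effect | 1.5 log2 units | detectable but noisy inverse association |

Counts are **multinomial** per sample at fixed depth (not per-miR Poisson):
sequencing conditions on total library size, and exact count conservation
makes the invariants sharp. Control and input share the baseline abundance
vector; the target bait multiplies planted abundances by the drawn ratio.
Expected tpm ratios stored in the truth object account for the resulting
renormalization of the target library.

Sequences: planted UTR intervals are 13 nt — a 6-nt reverse complement of the
miR 3′ region (positions 14–19, drawn GC-only so the compensatory helix is
always worth its internal loop), a 1-nt spacer, and the 6-nt reverse
complement of the seed. Flanking nucleotides are chosen unable to pair the
adjacent miR positions, and the background is rejection-sampled (over the
planted miRs' seeds only, for tractability) until each planted miR's seed
complement occurs exactly once and the scanned MFE interval equals the
planted interval. qPCR tables apply the ΔCt model in reverse with constant
reference Cts. Patients draw group-dependent TAP1 frequencies, CD8 counts
and log-normal miR expression.

What the generator does **not** emulate: read-level artifacts (adapters,
mapping ambiguity, rRNA/tRNA contamination), overdispersion beyond
multinomial sampling, correlated replicates, prediction-tool behavior (votes
are planted directly), hybridization thermodynamics of real UTR context, or
qPCR efficiency ≠ 2. Passing recovery tests therefore demonstrates the
pipeline's arithmetic and its ability to recover a planted signal under the
stated noise model — not performance on real screens.

## Problem sizes in the checked runs

The test suite and the acceptance script run the full 2693-miR universe at
10⁶ reads per sample for recovery checks (about a second), exhaustive
DP-vs-enumeration comparison for all sequence pairs up to 4 nt over {G, U}
plus 150 seeded random pairs up to 10 nt over the full alphabet, and 1000
null replicates for the t-test calibration. These sizes were chosen so every
check completes in seconds while keeping the comparisons exact or tightly
bounded.

## Known limitations

* Duplex energies use linear loop penalties and a reduced wobble set; they
  rank sites sensibly but are not comparable in absolute terms to
  RNAhybrid/Turner values.
* The enrichment model has no dispersion estimation — plain ratios, as the
  assay analysis prescribes; miRs with near-zero control tpm are flagged, not
  shrunk.
* Censored Cts (40) are flagged, not imputed.
* The IHC grading consumes consensus frequencies; no image analysis.
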