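# mitrap

Analysis toolkit for **miTRAP** pull-down screens: prioritizing microRNAs that
bind a bait 3′UTR from small-RNA sequencing of the pull-down eluates, with the
downstream qPCR and wet-lab validation arithmetic.

miTRAP (miRNA trapping by RNA in vitro affinity purification) immobilizes an
MS2-loop-tagged bait RNA — here the 3′UTR of the peptide transporter **TAP1**,
a key HLA class I antigen-processing component — on amylose beads via an
MS2BP–MBP fusion, incubates it with cell lysate, and sequences the small-RNA
fraction of the eluate. miRs that bind the UTR are enriched in the target-bait
eluate relative to an MS2-only control bait. This package implements the
analysis that turns such data into a short, auditable candidate list.

## What it computes

For each miR *i* with per-sample counts $c_{is}$:

* **tpm quantification** — counts are summed over genomic loci (a mature miR
  can be encoded by several) and scaled per sample,
  $\mathrm{tpm}_{is} = 10^6 \, c_{is} / \sum_j c_{js}$ (pure counts-per-million;
  mature miRs are ~22 nt, so no length normalization).
* **Enrichment ratio** — replicate tpm are combined by geometric mean with a
  small pseudocount $\epsilon$, and
  $R_i = (\mathrm{tpm}^{\text{target}}_i + \epsilon)/(\mathrm{tpm}^{\text{control}}_i + \epsilon)$;
  $R_i > 1$ defines *enriched*.
* **Prediction consensus** — yes/no calls from six target-prediction tools
  (miRWalk, microrna.org, miRDB, TargetScan, RNA22, RNAhybrid) are merged into
  a vote matrix; candidates need ≥ 4 votes.
* **Hybridization energy** — seed matches (Watson–Crick complement of miR
  nt 2–7) anchor a nearest-neighbor dynamic program that finds the
  minimum-free-energy intermolecular miR:UTR duplex (stacks incl. G:U wobble,
  linear bulge/internal-loop penalties, duplex initiation), reported in
  kcal/mol.
* **ΔCt arithmetic** — relative expression $2^{-\Delta C_t}$ against RNU6A /
  GAPDH / ACTB, ΔΔCt fold changes between conditions, and the **miTRAP
  ratio**: fold enrichment of a miR in an eluate versus the input lysate
  (input ≡ 1), per bait.
* **Six-criterion candidate filter** — (i) ≥ 4 of 6 tool votes,
  (ii) target-eluate tpm > 1000, (iii) control-eluate tpm < 100,
  (iv) enrichment ratio > 50, (v) duplex energy < −20 kcal/mol,
  (vi) target-bait miTRAP ratio > 2× the control bait's. Criteria with
  missing inputs are reported as not-applicable; passers are ranked by ratio.
* **Validation statistics** — firefly/renilla reporter normalization,
  densitometry A.U., CD107a-degranulation specific signal and x-fold, TAP1
  immunohistochemistry grading (0%, 1–10%, 11–30%, >30%), and Welch/paired
  t-tests for group comparisons (e.g. miR expression in TAP1-high vs
  TAP1-low melanoma lesions).

A synthetic-data module generates every input — multinomial counts with
planted enriched miRs, UTR sequences with planted binding sites, Ct tables
with planted folds, a TAP1-high/low patient cohort and noiseless prediction
votes — together with the planted truth, so the whole pipeline runs and is
testable without any download. A verbatim transcription of the published
21-candidate table from the TAP1 screen ships as a fixture.

## Worked example

Selecting candidates from the shipped TAP1-screen table with the vote, ratio
and energy criteria:

```python
import pandas as pd
from mitrap import load_candidate_fixture, apply_criteria, selection_audit

records = load_candidate_fixture()
table = pd.DataFrame({"mir_id": [r.mir_id for r in records],
                      "ratio": [r.enrichment_ratio for r in records]})
votes = {r.mir_id: r.votes for r in records}
energies = {r.mir_id: r.binding_energy for r in records}

report = apply_criteria(table, votes, energies=energies,
                        criteria=("votes", "ratio", "energy"))
print(report.loc[report["pass_all"]].sort_values("rank")
      [["mir_id", "ratio", "votes", "energy", "rank"]].to_string(index=False))
```

prints

```
        mir_id  ratio  votes  energy  rank
 hsa-miR-21-3p 1036.0      5   -20.3     1
 hsa-miR-22-3p  102.9      5   -21.6     2
hsa-miR-26b-5p   92.1      4   -25.4     3
hsa-miR-26a-5p   74.1      4   -25.1     4
hsa-miR-532-5p   65.5      4   -20.5     5
```

i.e. of the 21 candidates with ≥ 4 votes, six exceed the ratio-50 filter and
five also clear the −20 kcal/mol energy floor. The audit explains every
exclusion with the observed value against its threshold:

```python
audit = selection_audit(report)
audit["hsa-miR-590-3p"]   # ['energy -12.8 >= -20']
audit["hsa-miR-140-3p"]   # ['ratio 1.3 <= 50']
```

The hybridization scorer can be used standalone; here a miR against a 13-nt
site carrying its seed complement plus 3′-compensatory pairing
(ΔG = −14.47 kcal/mol):

```python
import mitrap as mt
duplex = mt.duplex_mfe("UAGCUUAUCAGACGCGGCCGGA", "GGCCGCAUAAGCU")
print(duplex.render("UAGCUUAUCAGACGCGGCCGGA", "GGCCGCAUAAGCU"))
```

```
miR    5'-AGCUUAucagacGCGGCC-3'
          ||||||      ||||||
target 3'-UCGAAUa-----CGCCGG-5'
```

A command-line interface mirrors the library
(`mitrap simulate | tpm | length-qc | enrich | votes | hybridize | qpcr |
select | validate`); `mitrap simulate --seed 5 --outdir out/` writes a full
synthetic study (counts, FASTA, Ct, patient tables, truth JSON).

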