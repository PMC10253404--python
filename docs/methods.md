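# Methods

## The analysis model

A capture experiment compares probe-containing samples against probe-less
(DMSO) negative controls, each in triplicate. The pipeline models one
protein's evidence in one assay with three quantities:

* **r** — fold change: the ratio of grouped protein abundances,
  capture over control. Grouping is the replicate mean by default (a
  `center="median"` switch exists; the underlying convention of "grouped
  abundances" admits either reading).
* **p** — one-way fixed-effects ANOVA p-value across the two groups,
  computed on log2 abundances. LFQ intensities are multiplicative, so the
  log scale is the natural one; a `log_transform=False` switch preserves the
  raw-scale alternative. For two groups the ANOVA is exactly the pooled
  two-sample t-test (F = t²), which the tests verify numerically.
* **detection counts** — in how many capture and control replicates the
  protein was observed at all.

Protein abundance is the sum of intensities of peptides *unique* to the
protein. Peptides that map to more than one accession are excluded from
every protein's sum: the redundancy of transcriptome-derived databases makes
shared peptides common, and strict exclusion is the conservative, testable
reading of "unique peptide intensities". Normalization rescales each sample
column so its total equals the grand mean of column totals; any common
target would do (ratios are preserved, and the operation is idempotent), the
grand mean keeps the output on the scale of the input. Proteins whose best
per-sample unique-peptide count is below two are dropped; the per-sample
maximum (rather than a per-experiment sum) keeps proteins confidently
observed anywhere.

Missing cells are a first-class state, never zero and never imputed.
Absence must propagate because the strongest capture signature in this assay
type is qualitative: present in the capture, never seen in the control.

## The tiered capture call

After a reproducibility filter (detection in ≥ 2 of 3 capture replicates —
the weakest majority rule; configurable), each protein is classified:

1. **highly_significant_absent_control** — zero detected control replicates
   (the literal reading of "not present in the negative control";
   configurable via `max_control_detected`).
2. **highly_significant_enriched** — r and p defined, log2(r) > 2 and
   −log10(p) > 2.5, both strict. The −log is base 10: the 2.5 cut then
   corresponds to p ≈ 0.0032, a meaningful tightening of the p < 0.05 gate,
   whereas a natural log would make the cut weaker than the gate itself.
3. **significant** — p < 0.05.
4. **detected** / **not_detected** otherwise.

The rule is total (every r/p/detection combination maps to exactly one
class) and monotone: raising r or lowering p never demotes. One consequence
documented rather than patched: a protein detected in exactly one control
replicate has a defined r but an undefined p (the ANOVA needs two
observations per group), so it can reach at most *detected*. In the
simulation this is the main sensitivity leak of the highly-significant call
(about 4–5% of true binders at the default settings). Imputation would
remove the leak at the cost of manufacturing evidence; the pipeline declines.

## Probe selectivity

For proteins captured by both quercetin probes and absent from the controls,
capture-vs-control ratios are undefined in both assays; the volcano instead
contrasts the two capture groups directly: lg2_r = log2(mean Q8 abundance) −
log2(mean Q6 abundance) (a difference of logs, so swapping probes negates it
exactly), with the same ANOVA machinery for p (two groups ⇒ pooled t-test).
Comparability across capture samples rests on the global normalization; no
pairwise renormalization is applied. Proteins eligible but absent from all
replicates of one probe are reported in a side table, not forced into the
volcano.

## Annotation screen and enrichment

Candidate classes A (oxidase), B (methyltransferase), C
(glycosyltransferase), D (other) are assigned by case-insensitive substring
match of a configurable keyword vocabulary against the protein description
and GO/InterPro term names, with priority A > B > C on multiple matches.
GO over-representation of a capture set against the detected proteome uses
the hypergeometric upper tail with Benjamini–Hochberg adjustment across
tested terms — the minimal standard choice; no GO-graph propagation to
ancestor terms is attempted. Homologue maps translate local
(transcriptome-database) accessions to a reference proteome; many-to-one
collisions are merged per assay cell, the lower p winning, because redundant
database entries make such collisions inevitable.

## Similarity shortlist

In-package similarity uses optimal Smith–Waterman local alignment with
affine gaps (BLOSUM62; a length-L gap costs open + L·extend, defaults 11/1,
the protein-BLAST convention), computed by Biopython's `PairwiseAligner` and
cross-checked in the tests against an independently written quadratic
dynamic program. Raw Smith–Waterman scores are *not* calibrated to BLAST bit
scores; the tier cuts (high > 500, low ≤ 300) are configuration aimed at
bit-score-scale inputs, and the BLAST-tabular ingestion path (outfmt 6,
bit score as score, e-values carried but never computed) is the fidelity
route when BLAST output exists. The shortlist ranks by capture-class
severity first (absent-from-control, enriched, significant, detected), then
alignment score, then accession — a deterministic total order.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
mass spectra: no retention times, search-engine scores, isotope labels or
PTMs (those live upstream of the pipeline's inputs).

Per protein: a base ln-intensity drawn N(`intensity_location`=14,
`intensity_scale`=1.2) (arbitrary LFQ units); 1 + Poisson(7) theoretical
peptides (mean 8), each offset N(0, `peptide_scale`=0.35) around its
protein. Per sample: binder peptides in capture samples are multiplied by
`enrichment_fold` (16) × per-probe affinity (Q8 1, Q6 0.25, K8 0.0625 — a
4× selectivity ladder) × a method multiplier (O: 1, N:
`method_n_efficiency`=0.5, modelling substantial but reduced capture without
probe activation; the multiplier applies to the whole capture so non-binder
expected ratios equal the method multiplier alone). Replicate noise is
multiplicative log-normal at `cv_replicate`=0.20. Detection is a logistic
left-censoring process on ln-intensity (`detection_midpoint`=12.5,
`detection_slope`=12): censored peptide rows are simply absent, so
missingness is intensity-dependent and monotone, and `midpoint = −inf`
disables censoring entirely.

True binders are drawn `binder_intensity_shift`=−1.8 ln units below the bulk
proteome. This is the biology the probes exploit: the target enzymes are
rare membrane-bound proteins near the detection limit of an unenriched
extract, which is exactly why a large fraction of genuine captures appear
as "absent from the negative control" rather than as finite fold changes.
The shift and the steep detection curve were fixed together, once, by a
forward design study so that the default experiment exhibits both capture
signatures (roughly half of binders absent from controls, half strongly
enriched) with the sensitivity the joint rule can deliver; they were then
frozen. Binder annotations carry a shared "catalytic activity" GO term plus
a category-specific term, giving the enrichment and screening stages a
recoverable signal; the first binders receive sequences point-mutated from a
hydroxylase-like query at 90%/60%/30% identity, giving the shortlist its
score tiers. A `redundancy_rate` (default 0.1) duplicates proteins under
alternative accessions for the redundant-database variant.

What passing recovery tests show — and what they do not: the simulator's
binders are cleanly separated in effect size and share no peptides with
non-binders; real data add ragged protein inference, correlated
contaminants, batch structure and nonspecific bead binders that no logistic
censoring model produces. The studies validate the *machinery* (that the
rule recovers what it is designed to recover, at calibrated false-positive
rates), not the field performance of any particular threshold.

## Problem sizes and numerics

The recovery and null-calibration studies use 25 seeds × 500 proteins,
sizes at which Monte-Carlo error on the reported fractions is ≈ 0.01–0.02
and a full run stays in seconds. Seeds derive from one base seed by a fixed
affine map (kept below 2³¹); every stochastic component receives an explicit
seeded generator, and rerunning any configuration byte-identically
reproduces its report bundle. ANOVA p-values are clamped into (0, 1] (the F
survival function underflows at extreme F); zero-variance and
under-replicated proteins are flagged undefined rather than given a number.
All output tables are TSV with fixed column order and "NA" for missing, so
bundles can be diffed exactly.

## Known limitations

* No multiple-testing correction across proteins in the capture calls (by
  design — the tiered rule is the published convention this pipeline
  re-implements; the GO stage does correct).
* No peptide-level FDR handling, match-between-runs or imputation; the
  pipeline trusts its upstream peptide report.
* Smith–Waterman scores and BLAST bit scores are different scales; shortlist
  tiers on in-package scores need recalibrated cuts.
* The one-control-replicate sensitivity leak described above.
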