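# Methods

## Model

The classifier is a deterministic rule system over a binary 38-feature
space: gene-level mutation indicators for 35 lymphoma-associated genes and
rearrangement indicators for *BCL2*, *BCL6*, and *MYC* (FISH). Each subtype
is defined by a fixed feature set; the six sets are mutually disjoint and
their mutation genes cover the 35-gene panel exactly. Assignment is
nearest-medoid over binary vectors: with each subtype's medoid taken as the
indicator vector of its defining set, ranking samples by normalized overlap
score(s) = |F_s ∩ x| / |F_s| is equivalent to ranking by proximity to the
medoids, because the sets are disjoint. Two special rules sit outside the
scoring: an absolute TP53 priority (any qualifying *TP53* mutation wins
immediately) and the MYC split applied only to EZB-like winners.

Assumptions this encodes:

- A mutated gene is a binary event; variant multiplicity, VAF and mutation
  subtype (beyond the qualification filters) carry no weight.
- Defining features are equally weighted within a subtype. A consequence of
  the normalization is that single-gene subtypes (N1-like, and TP53Mut via
  priority) reach score 1.0 from one hit and outrank any partial match of a
  larger set; this is deliberate and matches the published examples.
- Unknown FISH status is never evidence: it counts as negative both for
  scoring (FBCL2/FBCL6) and for the MYC split.

## Variant qualification

Filters are applied post-annotation; alignment, calling and consequence
annotation are upstream and out of scope. Gates and their comparison
senses (all fixed; only the cut points are configurable):

| Gate | WES/WGS | Targeted panel |
|------|---------|----------------|
| mapping quality | > 30 | > 30 |
| population AF (max across databases) | < 0.001 | < 0.001 |
| VAF | > 0.05 | ≥ 0.05 |
| read depth | > 10 | — |
| consequence class | functional only | functional only |
| dbSNP membership | requires COSMIC | requires COSMIC |
| missense scores | — | SIFT ≤ 0.05 ∧ PolyPhen2_HVAR ≥ 0.447 ∧ CADD > 4 |

The VAF boundary sense differs between the two dialects on purpose; both
are implemented exactly as stated. Functional classes are nonsynonymous
SNV, stopgain, stoploss, frameshift/non-frameshift indel, and splicing;
synonymous variants never qualify.

Decisions taken where the source rules are silent or ambiguous:

- **Missing annotations.** Absent population AF passes (treated as a novel
  variant). Absent SIFT/PolyPhen/CADD in the targeted missense gate fails
  closed by default (`missense_scores_fail_open` flips this). The missense
  gate applies only to nonsynonymous SNVs; truncating variants are exempt.
- **dbSNP/COSMIC clause.** Read as: a variant present in dbSNP survives
  only if it is also in COSMIC; variants not in dbSNP are unaffected
  (`dbsnp_requires_cosmic=False` disables the gate).
- **Cohort-context exclusions** (recurrent artifact frameshifts,
  poor-coverage regions, Sanger-confirmed germline) need external evidence
  the table does not carry; they are exposed as optional variant/gene
  blocklists, default empty.
- **MYD88.** Any qualifying MYD88 mutation counts by default; the
  `myd88_l265p_only` switch restricts to p.L265P via the protein-change
  column for users who prefer the stricter legacy convention.
- Gene symbols are upper-cased and trimmed; no alias resolution (the panel
  is small and fixed; alias maps drift). Coordinates, when present, are
  never used by classification.

## Tie-breaking

Two subtypes can reach the same positive score (e.g. one MCD gene and one
ST2 gene: both 1/8). Policies:

- `nos_on_tie` (default): unresolved ties are conservative NOS calls.
- `precedence`: fixed order N1 > MCD > BN2 > EZB > ST2 (single-gene
  definers first).
- `weighted`: user-supplied per-feature weights re-score the tied subtypes;
  a residual tie falls back to NOS.

No published weighting of features within a subtype exists, so equal
weights are the default everywhere.

## Benchmarking

`cross_tabulate` requires identical sample universes and counts every
sample once; `per_class_metrics` removes samples whose predicted **or**
reference label is excluded (default TP53Mut and its copy-number-aware
reference analog A53 — classes the two schemes define differently), then
computes one-vs-rest sensitivity TP/(TP+FN), specificity TN/(TN+FP) and
precision TP/(TP+FP) per retained class. NOS stays in the confusion matrix
but is excluded from per-class metrics unless `include_nos=True`. A metric
with a zero denominator is reported as NA rather than 0.

The genetic-coherence check compares a subtype's scores between carriers
(≥1 defining feature) and non-carriers with a two-sided Mann–Whitney
rank-sum test — exact for group sizes below 50, tie-corrected normal
approximation above (the score distributions are heavily tied, and the
exact method falls back to the approximation when ties occur). Single-gene
subtypes yield a degenerate two-point distribution, handled without error.
No multiple-testing correction is applied across subtypes by default; a
Benjamini–Hochberg helper is provided.

Pooled response rates are evaluable-weighted means: ORR = Σ responders / Σ
evaluable, CRR likewise, reported to one decimal as percentages.

## Synthetic cohorts

The generator emulates the *inputs* of the pipeline with known ground
truth, not tumor biology:

- **Labels** are drawn i.i.d. from a prevalence map; the default is the
  training-cohort distribution (337 cases: 44 TP53Mut / 37 MCD / 39 BN2 /
  12 N1 / 3 EZB-MYC⁺ / 16 EZB-MYC⁻ / 20 ST2 / 166 NOS), so a default
  cohort classifies ≈51% of samples.
- **Planting**: each classified sample receives `k_planted` (default 2)
  features drawn without replacement from its subtype's defining set,
  capped at the set size so single-gene subtypes receive their one feature;
  fusion features set the FISH status, mutation features emit a variant row
  that passes every gate in both filter dialects (VAF ~ U[0.10, 0.60],
  depth 50–300, MQ 60, population AF 0, damaging missense scores).
  EZB-MYC⁺ samples additionally get a positive *MYC* FISH.
- **Background passengers** occur per panel gene outside the sample's own
  defining set at `background_rate` (default 0.02, a realistic per-gene
  panel mutation rate). Because every panel gene defines *some* subtype,
  background can legitimately re-label a sample — that is the realistic
  default. With `exclusive_background=True` passengers are drawn from a
  fixed off-panel gene list instead (which also exercises the off-panel
  logging path), making 100% recovery provable by construction.
- **Filter-failing decoys**: with probability `noise_fail_rate` per planted
  variant, an additional variant violating exactly one gate (VAF ~
  U[0.005, 0.045] or population AF 0.01 — clearly on the failing side of
  the printed thresholds) is emitted in a gene outside the sample's own
  defining set. Decoys are extra rows rather than replacements of planted
  variants, so a correct ingest filter makes noisy and clean cohorts
  classify identically — the property the tests assert. Decoy and
  FISH-unknown draws use a separate RNG stream derived from the seed, so
  toggling noise does not perturb the planted structure.
- **Not emulated**: mutational signatures, trinucleotide context, clonal
  structure/subclonal VAF distributions, copy number, expression data,
  inter-gene mutation correlations beyond the planted co-occurrence.
  Passing recovery tests therefore demonstrates correctness of filtering
  and assignment logic, not field performance on real tumors.

## Numerical and interface choices

- Scores are exact small-integer ratios in double precision; no tolerance
  is needed anywhere in classification.
- Profiles and cohort outputs are sorted by sample ID, making every
  cohort-level result invariant to input row order.
- Duplicate sample IDs are hard errors (FISH table, cohort classification,
  label tables); corrupt variant rows are skipped with a logged warning
  while a missing required column aborts.
- Subtype definitions are data: YAML overrides are accepted, and the
  shipped defaults are frozen by a SHA-256 checksum printed by
  `lymphplex --version` and asserted in the test suite.
- The sklearn estimator (`LymphPlexClassifier`) performs no estimation in
  `fit` — it validates parameters and records the feature universe and
  class set — so it composes with sklearn pipelines and model selection
  while remaining a fixed rule system.

## Problem sizes

The test suite validates the cascade exhaustively over a reduced 10-feature
universe (2¹⁰ × 2 MYC states) against an independently written oracle, and
uses simulated cohorts of 100–1000 samples (5000 for prevalence
convergence, checked within ±2%). The acceptance script uses 1000-sample
cohorts. These sizes give exact or tightly convergent checks for a
deterministic rule system; recovery on a clean cohort is invariant to n by
construction.

## Known limitations

- No copy-number input: the reference scheme's A53 class and
  copy-number-aware EZB-MYC distinction cannot be reproduced, only
  benchmarked against via label exclusion.
- Gene-symbol matching is exact (after case/whitespace normalization);
  inputs using outdated aliases must be normalized upstream.
- The VCF dialect maps INFO fields via a user-supplied field map and
  assumes one gene/consequence annotation per record; multi-allelic records
  with divergent annotations should be split upstream.
- Composite/double-class outputs are not produced: a sample gets exactly
  one label.
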