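# Methods

This note records the models, rules and numerical choices behind each
stage, the assumptions they rest on, and what the synthetic-data tests do
and do not demonstrate about real data.

## Candidate classification

The classification chain applies, in order: score cutoff → stem-loop
homology → other-small-RNA exclusion → repeat exclusion → read-evidence
validation. The order matters only for the rejection *reason*: each
candidate is labelled with the first rule it fails.

* **Score cutoff** (`score_cutoff`, default 4.0, dimensionless discovery
  score). Discovery tools derive this from a signal-to-noise table (the
  emulated study used the score at a 30:1 ratio); since that table is an
  input we do not recompute, the cutoff is a plain parameter. The
  inequality is strict ("scores above this threshold").
* **Homology threshold** (`evalue`, default 10⁻⁶, boundary included).
  Used identically for the stem-loop, small-RNA-family and genome
  screens. Best-hit ties break by bit score then subject id so annotation
  is deterministic.
* **Repeat rule** (`max_loci`, default 5: > 5 significant loci rejects).
  Distinct loci are counted after merging overlapping hit intervals on
  the same contig and strand, so HSP fragments of one locus are not
  double-counted. A stricter preset (> 50) matches screens aimed only at
  high-copy repeats; both are configuration values.
* **Novel validation** (`min_samples` = 2, `min_arm_reads` = 5 strict,
  `consistency_frac` = 0.9). Arm read counts are pooled across samples —
  the per-sample alternative is stricter but under-determined by the
  workflow being modelled; pooling is the permissive reading and is
  documented here as a deliberate choice. "Consistent 5′-end processing"
  is quantified as the modal read start offset carrying ≥ 90% of an arm's
  reads: strict, but tolerant of the rare off-by-one stacks real
  libraries show. Raising the fraction can only reject more candidates
  (tested as a monotonicity property).
* **Unique matures** are exact string-identity groups (after uppercasing
  and T→U), never alignments: family members sharing a mature sequence
  collapse; one-mismatch variants do not.

## Cluster detection

Two genes co-cluster when on the same contig and strand and separated by
less than `max_gap` = 10 000 nt. The gap is measured edge-to-edge
(`max(0, next.start − prev.end − 1)`), the conservative reading of
"located less than 10 kb apart"; a start-to-start mode is available
because the convention is genuinely ambiguous. Chaining is transitive
against the running maximum end, which makes the sweep identical to
connected components of the all-pairs adjacency graph (verified against a
brute-force union-find oracle on random layouts, including nested
intervals where naive consecutive-gene chaining would differ). Cluster
ids are `contig:strand:first-member-start`; coordinates are 1-based
inclusive (GFF3) everywhere on disk.

## Quantification

Counting is exact-match only: a read increments a unique mature's count
iff the strings are identical, reads < 18 nt (`min_read_len`) are
discarded first, and a read matching a mature carried by several gene
copies counts once, for the unique mature. Mapping with mismatches,
isomiRs and multi-mapping resolution are out of scope. Normalisation
divides by the per-sample total of *matched miRNA* reads (not raw library
size) and multiplies by 10⁴, so columns sum to 10⁴ exactly; the length
boundary keeps ≥ 18 nt. RSD uses the n−1 standard deviation —
conventional at n = 8 samples — and is undefined (NaN) at zero mean. The
enrichment screen smooths zeros by half a read on the count scale
(0.5 × 10⁴ / library total when totals are available, a flat 0.5
otherwise) before forming max-tissue / mean-of-rest ratios; it is a
screening aid, not a test.

## Reference-gene stability

The stability model follows the model-based (NormFinder-type) variance
decomposition. Ct values are linearised as 2^(C − Ct) (C = matrix
maximum; any C cancels downstream, and amplification efficiency is
assumed 100% — efficiency-corrected linearisation would need per-assay
calibration data this module does not model). Internally data return to
log2 scale and are centred per sample on the panel's gene average, which
removes per-sample input and RT effects. For gene *i* in group *g* with
*n_g* samples out of a *k*-gene panel:

* intra-group variance σ²(i,g): the sample variance of the centred
  values, unbiased for the panel centring by
  `k/(k−2) · (s² − Σ_h s²_h / (k(k−1)))` and clamped at ≥ 0 (the standard
  method-of-moments convention); the correction is why the panel needs
  ≥ 3 genes;
* group difference d(i,g): the group mean of the centred values, centred
  across groups per gene;
* inter-group variance τ²(i): `Σ_g d² / (G−1) − mean_g σ²(i,g)/n_g`,
  clamped at ≥ 0 — the subtraction removes the spread that finite group
  sizes alone would produce;
* stability value: `sqrt(τ²(i) + mean_g σ²(i,g)/n_g)`, the standard
  deviation of the error committed when gene *i*'s group level is used as
  the normaliser. Lower is more stable; the value is invariant to global
  Ct shifts and to group relabelling.

This is a re-derivation of the published approach rather than a port of
its code: the shrinkage constants of the original implementation are not
reproduced, but the decomposition, the sampling-error correction and the
qualitative behaviour (zero-variance genes rank first, added noise can
only raise a gene's value in expectation) are, and are what the test
suite pins down.

Two-gene combinations average the group differences — opposite systematic
biases cancel — and combine intra-group variances as the variance of the
average, (σ²_a + σ²_b)/4; all unordered pairs are scored exhaustively.
The pair value is reported alongside the best single gene and is *not*
guaranteed to be smaller.

An important consequence of panel centring is that stability is always
**relative to the candidate panel**: systematic bias in other panel
members leaks into every gene's group-difference estimate. The test toys
are constructed with this in mind (unbiased or cancelling co-members);
with a small panel of mutually biased genes, per-run rankings are
statistically noisy even for a correct implementation, which is why
recovery is asserted as a rate over 200 replicates, with competitors
separated mainly by intra-group noise — the component a 9-group ×
8-sample design estimates with the most degrees of freedom.

External controls with poor amplification efficiency should be excluded
*before* the analysis (the module deliberately has no efficiency model);
they can still be compared descriptively by their raw Ct standard
deviation.

## RT-qPCR differential expression

ΔCt subtracts the geometric mean of the reference-gene Ct values — the
geometric mean of the Ct values themselves, as is conventional in
comparative-Ct workflows; an arithmetic-mean mode exists because Ct is
already log-scale and the choice is debatable. Target-tissue promotion
formalises the visual "non-overlap" inspection: a reference tissue whose
median ΔCt falls below the target group's maximum ΔCt is promoted,
iterated to a fixed point (a median-vs-median rule and `none` are
configurable). With no true signal everything overlaps, so promotion
correctly ends in "no reference group left" — null-hypothesis screening
should therefore disable promotion, as the type-I-rate tests do.

Welch's unequal-variance t-test (hand-coded, verified to 10⁻¹⁰ against an
independent implementation) compares target vs reference ΔCt; with both
groups constant and equal, p = 1 by convention. Significance is strict
`p < α/m` (Bonferroni); for the emulated 76-test battery the threshold is
0.05/76 = 6.6 × 10⁻⁴. The design mirrors the emulated study: all
individuals from target tissues, 4 per reference tissue, giving 20–32
reference samples. ΔΔCt = mean reference ΔCt − mean target ΔCt (positive
when the target is higher expressed) and fold = 2^ΔΔCt at assumed 100%
efficiency. The sequencing-side fold estimate requires nonzero normalised
counts in all samples; the cross-platform correlation is product-moment
on log2 folds by default (raw and rank options exist — the choice of
coefficient is a convention, not a result).

## Synthetic data

The generators emulate the assumed designs: 8 deep-sequenced samples (one
tissue each, one individual) and 9 tissues × 8 individuals for qPCR.
Candidates are planted per class, each negative violating exactly one
rule. Counts are negative binomial (dispersion 5 — mid-range
overdispersion for small-RNA libraries), baseline means log-uniform over
two decades around 200 reads, library-size factors spanning 25-fold
(≥ 5-fold guaranteed), planted enrichment folds of 8× with a 100× subset.
Ct values are Gaussian on the cycle scale — baseline + per-(gene, tissue)
effect N(0, tissue_sd²) + individual noise N(0, noise_sd²) — with planted
DE shifts of 5 cycles (≈ 32-fold) against σ = 0.5 cycles of noise, the
scale of clear tissue enrichment. All outputs are byte-identical under a
fixed seed, and every dataset ships a truth table.

What passing these tests shows: the rules, estimators and decision logic
are implemented correctly and recover planted structure at realistic
noise levels. What they do not show: robustness to features the
generators omit — sequencing error and isomiR smear, adapter artefacts,
chimeric or mis-assembled precursors, qPCR efficiency differences between
assays, plate effects, and non-Gaussian Ct outliers. Conclusions about
real libraries still require the usual QC upstream.

## Problem sizes and determinism

Default test and acceptance problem sizes — 50 candidates, ≤ 200-gene
cluster layouts (200 random layouts against the brute-force oracle),
60-mature count matrices, 6-gene stability panels over 200 replicates,
200-replicate power/type-I runs — are chosen so the full suite and the
acceptance script each complete in well under a minute on one CPU while
keeping Monte-Carlo rates stable to a few percent. All randomness flows
from explicit seeds (the acceptance script derives per-component
sub-seeds from `--seed`); reports use stable column order so repeated
runs diff clean.
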