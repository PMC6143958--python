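# Methods

## Scope and data model

`isopair` analyses *ordered isoform pairs*: for each catalogued event, two
transcripts of one gene whose relative use is androgen-regulated. The
orientation (which transcript is "isoform 1") is fixed by the catalogue and
defines the ratio statistic PSI = iso1/(iso1+iso2). All decisions about
direction (induction, repression, switch) are expressed relative to this
orientation; swapping a pair negates every ratio-level effect, which is
enforced as a test invariant.

The packaged reference tables are versioned TSV transcriptions of the source
study's summary tables: the 73-event catalogue, the gene-level androgen
response lists, the cohort description, the tumour-vs-normal differential
statistics and the Gleason/stage correlation statistics. SHA-256 checksums
of all six files are frozen in the test suite; any edit must be deliberate.

## Quantification

* **TPM** — counts are divided by effective transcript length and scaled to
  1e6 per sample. When effective lengths are unknown, unit lengths are
  acceptable for this package's purposes because only within-pair ratios and
  between-group contrasts of the same isoform are used downstream.
* **PSI** — undefined when both isoforms are zero in a sample; such values
  are recorded as missing and excluded from medians and tests rather than
  forced to an arbitrary 0/0 convention.
* **logit transform** — ratios are compared on log(p/(1−p)) after a
  symmetric clamp of p into [ε, 1−ε], ε = 1e-3 by default (configurable).
  The clamp keeps fully mono-isoform samples finite and preserves ordering.
* **2^-ΔΔCt** — technical replicates are averaged on the Ct scale; ΔCt
  subtracts the mean of three reference genes within a sample; ΔΔCt is
  relative to the mean ΔCt of the control condition, making the control
  geometric mean exactly 1. The estimate is invariant to any constant Ct
  offset applied to a whole sample.
* **Percent inclusion** — 100·inc/(inc+exc) from capillary-electrophoresis
  band intensities; only the ratio formula is implemented.

## Differential statistics

The moderated t-test follows the standard empirical-Bayes variance-shrinkage
construction: per-feature pooled two-group variances s² (d = n₁+n₂−2
residual df, reduced per feature when values are missing) are modelled as
s² ~ s₀²·F(d, d₀). The hyper-parameters are estimated by method of moments
on log s² using digamma/trigamma identities, with d₀ obtained by Newton
inversion of the trigamma function; the posterior variance is the
df-weighted blend and the statistic is referred to a t distribution with
d + d₀ df (normal when d₀ = ∞). d₀ = 0 reproduces the classical pooled t
exactly; the test suite also cross-checks the fit against the Bioconductor
limma implementation via Rscript at 1e-10 tolerance. Precision weighting of
observations (voom-style) is deliberately not implemented: at the scales
this package targets, constant weights capture the statistic's behaviour,
and exact parity with any external pipeline is not a goal.

Isoform abundances are tested on log2(TPM + 0.5) (prior count configurable);
ratios on logit-PSI by the same moderated test, or by a Mann–Whitney U test
(exact null for small tie-free groups, tie-corrected normal approximation
otherwise) selected via `psi_test="mannwhitney"`. Both routes are exposed
because published per-figure and per-table PSI significance in this setting
can come from either; neither is treated as the ground truth of the other.
ΔPSI is always reported as the difference of group medians on the raw PSI
scale. Spearman correlations use average ranks and a two-tailed
t-approximation; constant expression is reported as a degenerate (ρ=0, p=1)
rather than an error, a constant covariate is an error. Benjamini–Hochberg
adjustment is applied separately within each statistic family — isoform 1,
isoform 2, and PSI columns across events, per analysis — matching how the
reference tables are organised.

## Consistency classification

Thresholds: FDR ≤ 0.05, minimum ratio change |ΔPSI| > 0.025 (strict, on the
0–1 scale). Rules, given the expected directions implied by the androgen
effect and the PSI definition:

* **Induction/repression of isoform k** (tumour/normal mode): Consistent
  when isoform k is significant in the expected direction and the PSI
  evidence is not contradictory (contradictory = significant AND |ΔPSI| >
  0.025 AND wrong direction — a significant PSI with negligible magnitude,
  e.g. ΔPSI printed as 0.00, is not a contradiction). Opposite is the
  mirror image. A missing statistic for the expected isoform with the
  partner present yields Inconclusive with an evidence note, never an
  exception.
* **Switch events**: decided by the ratio alone — significant PSI with
  |ΔPSI| above the minimum; the sign picks Consistent vs Opposite.
* **Correlation mode** (Gleason score 6–10 or stage T2a…T4 encoded 1…6 as
  numeric): identical logic with ρ signs in place of fold-change signs and
  the PSI ρ sign in place of ΔPSI (no magnitude gate, since ρ is already a
  scale-free effect size). Additionally a significant PSI correlation alone
  may carry a call when the expected isoform is not significant, flagged
  `partial=True`; this PSI-only route is symmetric (it can produce partial
  Opposite as well as partial Consistent) and is disabled in tumour/normal
  mode.
* **NotAssessed** comes from catalogue comparability (an isoform without a
  reference-annotation transcript id), not from statistics availability.

Counting operations ignore the partial flag. The label set is total and
deterministic, and negating every effect direction provably swaps
Consistent↔Opposite while fixing the other labels (tested).

Known source-table inconsistency: in the published correlation tables the
same evidence pattern — expected isoform not significant, PSI significantly
correlated against the androgen direction — is labelled "Opposite -" in the
stage table (PIK3R1) but "Inconclusive" in the Gleason table (PIK3R1,
RCAN1). No single rule reproduces both; this package applies the symmetric
rule, and its golden tests document exactly those two divergent Gleason
rows. All 73 rows of the tumour/normal table and all rows of the stage
table reproduce exactly; the headline counts (13 tumour-consistent, 6
Gleason-consistent, 3 consistent with both grade and stage) are unaffected.
The cohort-description table is kept verbatim even though its per-level
Gleason/stage marginals sum to more than the stated 497 patients; the
mismatch is surfaced programmatically rather than silently corrected. The
source also alternates between 41 and 42 annotated pairs; the tables carry
41 assessed rows and that number is used throughout.

## Structural event classification

Transcript models are exon chains in 1-based inclusive coordinates (GTF read
via gffutils; BED12 converted from 0-based half-open). Chains are first
mapped into transcription orientation (coordinates negated on the minus
strand), then compared:

1. equal chains → identical;
2. one chain equals the other with two adjacent exons merged → retained
   intron;
3. one internal exon present in exactly one chain with flanks shared →
   cassette exon;
4. differences confined to the 5′ end with a shared downstream chain →
   alternative promoter; the mirror case → alternative 3′ end. When only
   the terminal exons differ and they share the inner splice boundary, a
   shift of ≤ 50 bp (configurable per end) is treated as the same
   promoter/3′ end, because reference annotations routinely disagree at
   that scale;
5. anything combining independent differences (including a promoter change
   plus an internal change) → complex, keeping the classes disjoint.

Classification is symmetric in the argument order and equivariant under
coordinate reflection with strand flip (both tested on randomized
constructed pairs, ≥120 instances per class). Re-deriving the catalogue's
printed event types from its gene-span columns is not attempted: the
catalogue records only whole-isoform spans without strand or exon structure,
so the classifier is validated on constructed and user-supplied models.

## Synthetic cohorts

`simulate_cohort` draws, per event and sample, a pair of negative-binomial
counts (variance m + φm², dispersion φ > 0) whose means split a total
expression level by a logit-linear PSI model: logit(PSI) = logit(baseline) +
group shift + grade slope·(Gleason−6) + stage slope·(stage−1). The group
shift is chosen so the tumour-group PSI equals baseline + ΔPSI_true exactly
on the probability scale. A separate `logfc_total` scales the pair's total
expression in tumours; the implied per-isoform log2 fold changes are stored
as ground truth. Grade and stage marginals default to the reference
cohort's published frequencies, cohort sizes to 497/52. Seeding uses
numpy's PCG64 generator, so identical seeds give identical cohorts across
platforms.

What the generator does *not* emulate: library-size variation between
samples, correlated expression across events, grade/stage correlation
structure, batch effects, or read-level uncertainty in isoform abundance
estimates. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the model's own assumptions, not robustness to
real-data artefacts.

Recovery scenarios used by the tests run a scaled profile — 100 tumours vs
20 normals, ΔPSI = 0.2, dispersion 0.1, baseline PSI 0.4, mean pair
expression 100 counts, one true event among nine nulls — chosen as a
realistic moderately-expressed gene at a cohort size where the test suite
stays fast. Under this profile the pipeline calls the true event Consistent
in ≥95% of 100 seeded replicates, the ΔPSI estimator's Monte-Carlo bias over
500 replicates is below 0.01, and global-null scenarios keep the false-call
rate within two binomial standard errors of the nominal 5%.

## Numerical and degenerate-input choices

Zero-variance features are handled by the variance prior (never a division
error); all-zero samples produce zero TPM with a warning; an empty PSI group
after missing-removal is an error; out-of-range p-values are rejected rather
than clipped; log2FC of exactly 0 with a significant FDR supports neither
direction and falls to Inconclusive. The trigamma inversion uses Newton
iteration from the asymptotic start 0.5 + 1/y with a 1e-10 relative
tolerance.

## Limitations

The per-gene cohort statistics shipped as fixtures are inputs, not outputs:
regenerating them requires the original patient-level expression data, which
this package deliberately does not download. The statistics engine is
instead validated property-wise (classical-t equivalence, enumeration and
rank oracles, null calibration, reference-implementation cross-check) and on
synthetic cohorts with known truth. The structural classifier covers the
catalogue's four-class taxonomy plus complex/identical; finer subclasses
(mutually exclusive exons, alternative donors/acceptors) are out of scope.
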