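# Methods

This note documents the models, numerical choices and limitations behind
`follistage`, in the order data flows through the pipeline.

## DNA-content model and deconvolution

Events are PI-stained granulosa cells on a 1024-channel integrated
fluorescence axis. The model assumes PI linearity: the G1 (2n) population
is Gaussian with mean μ (default channel 200) and CV σ/μ (default 4%),
and the G2 (4n) population is Gaussian at exactly `g2_g1_ratio`·μ
(default 2.0, constrained to [1.8, 2.2]) with the same CV. S-phase cells
are uniform in DNA content between the G1 and G2 means, convolved with
the G1 width, giving the closed-form plateau shape
(Φ((x−μ)/σ) − Φ((x−2μ)/σ))/μ. The sub-G1 (apoptotic) component models
the loss of fragmented DNA during ethanol permeabilization: an
exponential smear rising toward the sub-G1 boundary and truncated at
zero. The boundary sits k·σ below the G1 mean (k = 3 by default): a hard,
auditable cut rather than a fitted changepoint, chosen because "less than
2n content" needs an explicit operational edge.

Fitting is two-level least squares on a 256-bin histogram: an outer
bounded Levenberg–Marquardt search over the shape parameters (μ, σ, the
sub-G1 decay scale τ), with the four component weights solved by
non-negative least squares at each step. Because each component density
integrates to one, the weights are event fractions directly. The initial
G1 mean is the smoothed modal bin — valid whenever G1 is the dominant
population, which holds across the stage range this pipeline targets
(sub-G1 up to ~45%). Fit quality is reported as residual RMS relative to
the modal bin count. A deliberate simplification relative to commercial
cell-cycle software: S-phase is a single broadened-uniform component, not
a polynomial; the output contract (four proportions) is unchanged.

Raw proportions sum to 100 by construction here; an optional emulated
reporting mode (`round_profile`) rounds each proportion independently,
reproducing the sums ≠ 100 that per-phase rounding produces in practice.
`normalize_proportions` divides each phase by the sum and multiplies by
100, then absorbs the floating-point drift into one component (trying
components from largest down) so the reported sum is exactly 100.0, not
just within tolerance. The operation is idempotent and scale-invariant.

## Gating

Debris is removed by FSC/SSC floors; doublets by the peak-to-integrated
fluorescence ratio (two cells transiting together stretch the integrated
signal), with a fixed default threshold of 0.6 — a deliberate choice of a
simple, auditable rule over a fitted discriminant. When more than
`target_events` (default 10,000) survive, a seeded uniform subsample
without replacement brings the count to exactly the target. The gating
report carries per-rule removal counts.

## Staging

On normalized profiles the ranking score x = G2 + S + G1 − subG1 equals
100 − 2·subG1, so ranking by x descending is exactly ranking by apoptotic
fraction ascending. QC removes samples with RIN < 7 first. With k = 7 the
top/bottom k ranks are growing/atretic. The plateau window is the k ranks
centered on the median of the remainder; when the excess is odd the extra
exclusion falls on the growing side. This centering rule is our
resolution of an under-specified step ("intermediate x values"): it is
deterministic, symmetric up to the odd-excess convention, and documented
here so sensitivity analyses can move it. Ties in x break by sample id to
keep runs reproducible. x is computed on normalized proportions by
default; a flag allows raw-proportion scoring for sensitivity analysis.
One caveat: descriptions of plateau-group selection in practice hint at
manual curation beyond pure ranks ("few mitosis and limited atresia");
this implementation is the rank rule only.

## Loop-design differential expression

Each contrast (G–P, P–A, G–A) has four biological replicate sample pairs,
each hybridized on two slides with dye assignments exchanged — 24 slides
total. Background correction is fg − bg floored at 0.5 to keep logs
finite (the background model is a plain local subtraction; nothing
fancier is attempted). Within-array loess of M = log2(R/G) on
A = (log2R + log2G)/2 (span 0.3) removes intensity-dependent dye bias;
the correction is pushed back into the channels symmetrically so that
between-array quantile normalization can run on the single-channel log2
matrix (all 48 channels), after which every channel has the identical
sorted vector and M/A are recomputed.

The per-probe linear model is M_a = μ(stage_red) − μ(stage_green) + d + ε
over slides, with growing pinned at zero and d a gene-independent dye
coefficient. Handling the dye swap inside the model (rather than
pre-averaging mates) preserves degrees of freedom and makes the dye term
testable; after loess the fitted d is ≈ 0, and when the model is fit on
raw M it recovers the injected bias. Residual variances are shrunk toward
a prior by moment matching on log variances (digamma/trigamma inversion
for the prior df d0 and prior variance s0²), giving moderated t
statistics on d0 + df degrees of freedom; d0 → 0 recovers the ordinary t
and d0 → ∞ a z-like statistic. Contrast signs follow the convention that
positive log2FC means up-regulation in the second item of the contrast
name.

DEG selection is strict for fold change (raw FC > 1.5, i.e.
|log2FC| > log2 1.5) and p (< 0.05), inclusive for mean intensity
(A ≥ 7, the Agilent-scale convention for "minimal intensity of 7"). No
multiple-testing correction is applied in the selection rule, mirroring
the raw-p design it reproduces; a BH-FDR column is emitted for users who
want it. The cross-contrast partition classifies genes selected in both
transition contrasts as continuous (same direction) or reversal, the rest
as transition-specific, and additionally reports all pairwise
intersection counts since "shared" can be read against either pairing.

## Between-group analysis

BGA is implemented as PCA of the group-centroid matrix weighted by group
size (between-group ordination in the Culhane style), with individual
data sets projected onto the centroid axes; three groups give at most two
axes. The input is built from green-channel data: within a dye-swap pair
each stage appears in green exactly once, so four replicate pairs per
contrast yield exactly 8 single-channel data sets per stage (24 total).
The separation score is the mean silhouette of the projected data sets
under their stage labels. Note that BGA is supervised: with many probes
and few samples it will separate even noise-only groups, so the
separation score is meaningful only against a permutation baseline (the
test suite checks both directions: ~0 under permuted labels, ≤ 0 for
literally identical groups, high for truly separated ones).

## Enrichment

Fisher over-representation is the exact hypergeometric tail of the
observed overlap given an explicit universe — the universe is a required
input because results change materially between an array-probe and a
genome universe. The activation z-score is unweighted:
z = (consistent − inconsistent)/√overlap with calls at |z| ≥ 2.
Literature-confidence weighting of evidence (as in commercial knowledge
bases) is out of scope; so is any bundled gene-set content. Note the
discrete null: for a regulon of size 10 with random directions,
P(|z| ≥ 2) = 22/1024 ≈ 2.1%, not the Gaussian 4.6% — the test suite
asserts the exact enumeration.

## qPCR

Standard curves are least-squares fits of Cq on log10(input ng) over
five decade dilutions (1e-4…1e-8 ng); efficiency is 10^(−1/slope) − 1 and
a positive slope is rejected as miswired input. Quantities invert the
curve; undetected transcripts stay NaN end-to-end (no zero imputation).
geNORM normalization divides each target quantity by the per-sample
geometric mean of the two reference genes; the pairwise-ratio stability
measure M is reported for audit. Contamination QC runs Bartlett's test on
the marker gene (CYP17A1-like) across stages; on rejection, a sample is
flagged when leave-one-out restores homogeneity and its level exceeds its
group median by a configurable multiple (default 5×).

Stage statistics per gene: Bartlett first; if p < 0.05 the quantities are
transformed with Y = log10(y·10¹²) (the large factor keeps ng-scale
values above one so logs stay positive; base 10 chosen as the convention
of the originating analysis software) and Bartlett is re-run — both
p-values are reported. The transform is applied per gene (not per
contrast); a config switch could move it, the choice is recorded here
because the originating description is ambiguous. One-tailed t tests per
contrast take their direction from a user-supplied prior (typically the
microarray fold-change sign), falling back to the observed direction;
one-way ANOVA, a Newman-Keuls post hoc at α = 0.05 (studentized-range
critical values, harmonic-mean n for unequal groups, standard stepwise
blocking) and a linear-trend post-test (equally spaced contrast
coefficients on the ordered stages, F on 1 and within df) complete the
battery. Newman-Keuls letters exploit the interval structure of the
stepwise procedure on ordered means: homogeneous sets are contiguous
ranks, so letters are maximal runs of mutual non-significance. Genes with
fewer than two detected values in at least two stages are reported
untestable (with detection counts) rather than raising.

## Synthetic data: what it does and does not emulate

The generators are pure functions of (config, seed). Event tables draw
singlet classes multinomially from the stage truth, with default stage
mixes (sub-G1/G1/S/G2 percent) of growing (2, 78, 12, 8), plateau
(10, 80, 6, 4) and atretic (30, 62, 4, 4) — no published per-stage
numeric ranges exist, so these are plausible, well-separated values
chosen once to represent the three states. Debris sits at low scatter;
doublets sum two singlets' integrated fluorescence and take the pair's
peak maximum. Expression arrays put base log2 levels at Normal(9, 1.5)
so the intensity-7 filter is exercised on both sides; configured effects
are applied as transition effects (a G→P effect persists into atresia, a
P→A effect appears at atresia), so each configured contrast is realized
exactly and G–A truth is the sum of the transitions. Biological and
preparation variability is drawn per hybridization (each labeling starts
from a fresh aliquot), which makes slides conditionally independent given
the stage and the loop model correctly specified; per-animal random
effects shared across slides are therefore NOT emulated, and on real data
with strong per-sample effects the moderated test would be
anticonservative (a duplicate-correlation style model would be needed).
qPCR Cq values follow Cq = intercept + slope·log10(quantity) + noise with
log-normal biological scatter and stage-independent reference genes.

Passing tests on this synthetic data therefore demonstrate correctness of
the algorithms under the stated generative assumptions — not robustness
to scanner artifacts, spatial effects, amplification bias, aneuploid DNA
content, or correlated biological replication, none of which are
generated.

## Problem sizes and determinism

Default analysis sizes are the study design sizes: 27 follicles, 10,000
gated events, three contrasts × four replicate dye-swap pairs, 2,000
probes in the acceptance computations (unit tests use smaller matrices
where the property under test allows). Every random draw flows from a
single integer seed per entry point; the pipeline manifest carries a
checksum that is identical across reruns of the same config and seed.
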