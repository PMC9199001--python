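# Methods

## Problem and estimands

Corneal epithelial immune-cell (IC) density for a participant and corneal
region is estimated by averaging per-image densities (count / image area,
cells/mm²) over a set of non-overlapping in vivo confocal microscopy
images. The package treats the average over a full reference set of
n = 16 images (2.56 mm² of quantified tissue at the default 0.16 mm² per
image) as the participant's *true mean* m, and asks two questions:

1. **Sample size.** What is the smallest k such that an estimate from k
   randomly chosen images is within a relative tolerance δ of m with
   confidence level L? Defaults: δ = 0.30, L = 0.95, k searched over
   2..n−1.
2. **Observer selection.** How consistent and how biased are estimates
   from 3 images chosen subjectively by observers, relative to 3 random
   images?

## Mean-ratio enumeration

For each participant, all C(n, k) unordered k-subsets are enumerated
(lexicographic index order, a documented and stable contract) and each
subset mean is divided by m, giving the mean ratio r. Two exact
combinatorial identities are used as continuous self-checks:

* each image appears in C(n−1, k−1) subsets, so the mean of the
  enumerated ratios is exactly 1 per participant and k;
* the population sd (divisor N = C(n, k), since the enumeration is the
  complete population of k-subset estimates, not a sample) equals
  (S/m)·sqrt(1/k − 1/n), the finite-population variance of a
  without-replacement subset mean, with S² the sample variance
  (divisor n−1) of the n densities.

Full enumeration costs 2^16 − 18 subsets per participant-region over
k = 2..15 — negligible. A seeded uniform subsample of combinations is
available for hypothetical n well above 16, off by default.

Participant-regions with m = 0 have undefined ratios and are excluded
with a logged warning. The generator makes them practically impossible;
real very-low-density data could produce them.

## Precision bands and k_min

Ratios are pooled across participants at each k (a per-participant
breakdown is available through the long-format export). The band at level
L is mu ± t·SD of the pooled distribution — a *spread* (tolerance) band,
not a standard-error band: it bounds where a single k-image estimate
falls L of the time, which is exactly what the acceptability criterion
asks. t is the two-sided Student-t quantile with df = (pooled count − 1);
at pooled counts in the thousands this is indistinguishable from the
normal quantile, so the df convention is immaterial. k_min is the
smallest k whose band at the criterion's level lies inside
[1 − δ, 1 + δ]; if none qualifies the result is reported as
"not achieved" rather than extrapolated.

The closed-form route computes the pooled sd as
sqrt(mean over participants of the per-participant exact ratio
variance) — valid because every participant's ratio distribution is
centred at exactly 1 — and reproduces the enumeration's band endpoints to
numerical precision (asserted at 1e−8 in tests, observed ~1e−15). Band
width is strictly decreasing in k whenever at least one participant has
non-constant densities, so the k_min decision is a simple threshold
crossing.

## Intraclass correlation coefficients

Both ICC forms are single-rating, two-way random-effects, computed from
the mean squares of the complete subjects × raters layout without
replication (MS_S between subjects, MS_R between raters, MS_E residual):

* consistency ICC(C,1) = (MS_S − MS_E) / (MS_S + (r−1)·MS_E), CI from the
  exact distribution of F = MS_S/MS_E with (n−1) and (n−1)(r−1) df;
* absolute agreement ICC(A,1) =
  (MS_S − MS_E) / (MS_S + (r−1)·MS_E + (r/n)(MS_R − MS_E)), CI via the
  McGraw & Wong construction with a Satterthwaite-approximated
  denominator df.

Negative estimates are reported as computed, not truncated at zero — a
negative ICC is informative (between-subject spread below residual
noise). All-identical tables raise an explicit degenerate-table error; no
missing-data support is provided because the designs involved are
complete. Qualitative labels follow the conventional bands (poor < 0.50,
moderate < 0.75, good ≤ 0.90, excellent above; boundaries assigned
upward). The implementation is cross-checked in the test suite against
pingouin (estimates to 1e−6) and the ANOVA decomposition against a
statsmodels OLS fit; those libraries are reference oracles only.

## Observer comparison

Each observer's estimate per participant-region is the mean density of
their 3 selected images divided by m. The reference distribution is the
exhaustive pooled k = 3 enumeration (560 combinations × participants).
Bias is tested with the two-sample pooled-variance Student's t-test
(Welch available behind a flag, not default), precision with the variance
ratio F = var(observer)/var(random), two-sided p = 2·min(P(F ≤ f),
P(F ≥ f)); both Bonferroni-adjusted over the observer family (default
m = number of observers, per region). Degenerate cases (zero variance)
are flagged, not computed. Between-observer consistency is ICC(C,1) on
the participants × observers ratio table.

## Synthetic-data generator

The generator defines the study conditions for every downstream test:

| parameter | default | meaning |
| --- | --- | --- |
| n_participants | 20 | healthy adults |
| n_images | 16 | non-overlapping reference images per region |
| image_area | 0.16 mm² | 400 µm × 400 µm field of view |
| central density | 21.7 ± 17.7 cells/mm² | gamma, moment-matched |
| peripheral density | 62.0 ± 26.1 cells/mm² | gamma, moment-matched |
| dispersion | ∞ (Poisson) | negative-binomial size parameter |
| seed | 0 | full reproducibility: (config, seed) ⇒ byte-identical output |

Design choices, made once:

* **Gamma, not lognormal, participant densities**: positive support and
  closed-form moment matching (shape = mean²/sd², scale = sd²/mean);
  only mean ± SD and range are published, which cannot distinguish the
  two. Draws below 1e−6 cells/mm² are redrawn so every participant has a
  usable reference. sd = 0 degenerates to identical participants.
* **Poisson image counts by default** (count ~ with mean d·area). No
  within-participant image-to-image variance is published, so the
  dispersion cannot be calibrated from text; the negative-binomial size
  knob is exposed for sensitivity analysis rather than fixed to a
  pretended estimate. The gap between the package's pure-Poisson
  peripheral k_min (4–5) and the value reported for real data (7)
  suggests real counts are overdispersed.
* **Observer recounts**: binomial thinning (detection probability) plus
  Poisson false positives — the simplest mechanism that can be tuned to
  realistic inter-observer agreement; no claim of perceptual realism.
  The three-observer recount fixture used in the acceptance script pairs
  a perfect reference counter (1.0, 0.0) with two imperfect observers
  (0.85, 0.5) and (0.75, 1.0), chosen so the 100-image-panel ICC(A,1)
  sits near 0.9, the regime reported for experienced human counters.
* **Selection bias**: images drawn without replacement with weight
  ∝ exp(β·z), z the within-participant standardized density (z ≡ 0 when
  the within-participant sd is zero, making selection uniform). β = 0 is
  uniform; β ≈ 2 roughly doubles central estimates. Sampling uses the
  Gumbel-top-k construction, equivalent to sequential weighted draws.
  This is a test fixture for the pipeline, not a cognitive model of how
  observers actually choose.
* Regions are generated independently; no inter-eye or inter-region
  correlation is modelled (none is reported).

What the generator does **not** emulate: spatial structure within images,
overlapping fields of view, cell morphology subtypes, age effects, or
disease. Tests passing on synthetic data therefore validate the
*statistical machinery* (enumeration, bands, ICCs, tests) exactly, but
say nothing about image acquisition or counting practice on real corneas.

## Numerical choices and problem sizes

* Pooled sd convention: population (divisor N) throughout the ratio
  pipeline; sample (ddof = 1) in the two-sample tests, as those are
  samples.
* t df = pooled count − 1; F-test p-values two-sided by doubling the
  smaller tail; Bonferroni p = min(1, m·p).
* Degenerate inputs: zero-variance bands collapse to [1, 1] (every k
  satisfies any criterion); zero-variance test samples are flagged
  degenerate; all-equal ICC tables raise.
* Simulation sizes in the test suite: calibration of the observer tests
  uses 1000 replicate single-region datasets (3 observers each), power
  300 replicates, ICC CI coverage 2000 tables of 30 × 3, parameter
  recovery 10 tables of 500 × 3 per target value. These sizes put
  Monte-Carlo error comfortably below the asserted bands while keeping
  the full suite fast.

## Known limitations

* The variance-equality F-test is used as specified for fidelity to
  standard practice, but its nominal size assumes iid normal samples. The
  pooled 3-image ratio distribution is a heteroscedastic mixture across
  participants (per-participant ratio variance scales like 1/expected
  count, spanning ~30× across the gamma density range) and is
  leptokurtic; with unbiased observers the F-test's realised type-I error
  is ~16–18% rather than 5% under the default central-region conditions.
  The t-test, by contrast, calibrates correctly (~5%) because the
  observer mean averages over participants. Interpret non-significant
  F results cautiously and significant ones more so.
* k_min is conditional on the generator's noise model; with real data the
  pipeline should be run on the actual counts (the CLI accepts any
  conforming CSV).
* The ICC confidence intervals assume the usual normal-theory ANOVA
  model; counts are discrete and skewed, so for very sparse panels the
  stated coverage is approximate.
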