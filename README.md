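# icdensity

How many in vivo confocal microscopy (IVCM) images does it take to measure
corneal epithelial immune-cell (IC) density reliably?

A single IVCM image covers 400 µm × 400 µm (0.16 mm²) of cornea — roughly
0.2% of its surface — and ICs are sparse, so a density estimate from a
handful of images can be badly off for an individual. Clinical studies
nevertheless average anywhere from 3 to 12 images, or let an observer pick
"three representative images" by eye. `icdensity` implements a
subsampling-based answer: given a 16-image non-overlapping reference set
per participant and corneal region (central, peripheral), it determines the
smallest number of randomly selected images whose estimate stays within a
stated tolerance of the full-set mean, and it quantifies how consistent and
how biased observer-chosen image subsets are.

## The method

For each participant, the average density over the full reference set of
n = 16 images is the **true mean** m. For a subset size k, every one of
the C(n, k) unordered image combinations yields an estimate; dividing by
m gives a **mean ratio** r centred exactly at 1. Pooling ratios across
participants, the band

    CI = mu ± t × SD

(mu, SD the pooled ratio mean and standard deviation, t the two-sided
t-quantile at 80/85/90/95% confidence) describes how far a random k-image
estimate strays from the truth. The **minimal sample size** k_min is the
smallest k whose 95% band lies inside [1 − δ, 1 + δ] with δ = 0.30: an
estimate within 30% of the true mean, 95% of the time.

The enumeration has an exact closed-form oracle. The sd of a without-
replacement k-subset mean, divided by m, is

    sd(r) = (S / m) × sqrt(1/k − 1/n)

with S the sample sd of the n image densities — the finite-population
correction. Both routes are implemented and agree to numerical precision;
the package uses this identity as a continuous self-check.

Supporting analyses:

* **Inter-observer agreement** of raw cell counts: single-rating, two-way
  random-effects intraclass correlation, absolute-agreement form ICC(A,1),
  with F-based confidence intervals.
* **"Three representative images"** evaluation: per-observer 3-image ratio
  estimates are tested against the pooled distribution of all 560 random
  3-image combinations (Student's t for bias, F for precision, Bonferroni
  adjustment) and scored for between-observer consistency with ICC(C,1).
* A **seeded synthetic-data generator** reproducing the study geometry
  (20 participants × 2 regions × 16 images; gamma participant densities
  matched to the published summaries, central 21.7 ± 17.7 and peripheral
  62.0 ± 26.1 cells/mm²; Poisson or negative-binomial counting noise;
  imperfect-observer recounts; density-biased image selection), since the
  underlying clinical image counts are not publicly available.

## Worked example

```python
from icdensity import (GeneratorConfig, PrecisionCriterion,
                       generate_counts, sample_size_analysis)

dataset = generate_counts(GeneratorConfig(seed=1))      # 640 image records
result = sample_size_analysis(dataset, "central",
                              PrecisionCriterion(delta=0.30, level=0.95))
print(result.k_min)
```

Running `python examples/02_minimal_sample_size.py` prints:

```
=== central cornea ===
  k =  3: 95% band [0.124, 1.876] from 11200 enumerated combinations
  k =  8: 95% band [0.579, 1.421] from 257400 enumerated combinations
  k = 11: 95% band [0.716, 1.284] from 87360 enumerated combinations
  k_min = 11 (exhaustive enumeration), 11 (closed-form finite-population oracle)

=== peripheral cornea ===
  k =  3: 95% band [0.627, 1.373] from 11200 enumerated combinations
  k =  5: 95% band [0.734, 1.266] from 87360 enumerated combinations
  k =  8: 95% band [0.821, 1.179] from 257400 enumerated combinations
  k_min = 5 (exhaustive enumeration), 5 (closed-form finite-population oracle)
```

Three central images give estimates anywhere between 12% and 188% of the
truth; eleven are needed before the 95% band fits inside ±30%. The denser
peripheral cornea reaches the same precision with five. Under this pure-
Poisson generator the central k_min typically lands at 11–12, close to the
value of 12 reported for real central-cornea data, while the peripheral
k_min lands at 4–5, below the reported 7 — real peripheral counts are
evidently more variable than Poisson, and the generator exposes a
negative-binomial dispersion knob to explore that.

The other examples (`examples/01…04`) generate a dataset, compute the
inter-observer ICC of simulated recounts (≈ 0.92 on a 100-image panel),
and contrast unbiased with density-biased "representative image" choosers
(β = 2 observers overestimate density twofold; even unbiased 3-image
estimates have poor between-observer consistency, ICC(C,1) ≈ −0.30).

A thin CLI wraps the same pipeline for shell use:

```bash
icdensity simulate --seed 1 --out run/
icdensity analyze --counts run/counts.csv --out run/analysis/
icdensity compare --counts run/counts.csv --bias 2.0 --out run/compare/
```

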