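"""How many random images are needed for an acceptably precise estimate?

For each subset size k (2..15), every one of the C(16, k) image
combinations yields a density estimate; dividing by the 16-image true mean
gives a "mean ratio" centred at 1.  The band mu ± t·SD of the pooled ratio
distribution says how far a k-image estimate strays from the truth at a
given confidence; the smallest k whose 95% band stays inside 1 ± 0.30 is
the recommended minimum image sample size.
"""

from icdensity import (
    GeneratorConfig,
    PrecisionCriterion,
    analytic_minimal_sample_size,
    generate_counts,
    sample_size_analysis,
)

dataset = generate_counts(GeneratorConfig(seed=1))
criterion = PrecisionCriterion(delta=0.30, level=0.95)

for region in ("central", "peripheral"):
    result = sample_size_analysis(dataset, region, criterion)
    closed_form = analytic_minimal_sample_size(dataset, region, criterion)
    bands = result.bands.query("level == 0.95").set_index("k")
    print(f"\n=== {region} cornea ===")
    for k in sorted({3, 8, result.k_min}):
        row = bands.loc[k]
        print(
            f"  k = {k:2d}: 95% band [{row['lower']:.3f}, {row['upper']:.3f}] "
            f"from {int(row['n'])} enumerated combinations"
        )
    print(
        f"  k_min = {result.k_min} (exhaustive enumeration), "
        f"{closed_form.k_min} (closed-form finite-population oracle)"
    )

print(
    "\nA band [0.7, 1.3] means: a random k-image estimate lands within 30%\n"
    "of the participant's true density 95% of the time.  The denser\n"
    "peripheral cornea needs fewer images than the sparse central cornea."
)
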