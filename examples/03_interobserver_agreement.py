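"""Inter-observer agreement of manual cell counts, measured with the ICC.

Three simulated observers recount a 100-image panel (50 central, 50
peripheral).  Observer imperfection is binomial thinning (missed cells) plus
a Poisson false-positive term.  Agreement uses the single-rating,
absolute-agreement, two-way random-effects ICC — systematic over- or
under-counting by an observer counts against agreement.
"""

import numpy as np

from icdensity import (
    GeneratorConfig,
    ObserverModel,
    classify_reliability,
    generate_counts,
    icc_single_absolute,
    simulate_observer_counts,
)

dataset = generate_counts(GeneratorConfig(seed=1))
rng = np.random.default_rng(12)

frame = dataset.frame
panel = np.concatenate(
    [
        rng.permutation(frame.loc[frame["region"] == r, "count"].to_numpy())[:50]
        for r in ("central", "peripheral")
    ]
)

observers = [
    ObserverModel(detection_probability=1.00, false_positive_rate=0.0),
    ObserverModel(detection_probability=0.85, false_positive_rate=0.5),
    ObserverModel(detection_probability=0.75, false_positive_rate=1.0),
]
table = np.column_stack(
    [simulate_observer_counts(panel, m, rng) for m in observers]
)

result = icc_single_absolute(table, alpha=0.05)
print(f"ICC(A,1) = {result.estimate:.2f} "
      f"(95% CI {result.ci_lower:.2f} to {result.ci_upper:.2f})")
print(f"reliability: {classify_reliability(result.estimate)}")
print(
    "\nAn ICC near 0.9 means most of the recount variance reflects genuine\n"
    "image-to-image differences in cell number, not who did the counting —\n"
    "one observer's counts can stand in for the panel."
)
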