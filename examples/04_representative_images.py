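"""Are observer-chosen "three representative images" better than three random ones?

Each simulated observer picks 3 of a participant's 16 images; the selection
weight is exp(beta * z) on the standardized image density, so beta = 0 is an
unbiased chooser and beta = 2 strongly prefers dense images.  Observer
estimates are compared against the pooled distribution of ALL C(16,3) = 560
random three-image combinations per participant: a Student's t-test for
systematic bias, an F-test for precision, and the consistency ICC for
between-observer agreement.
"""

import numpy as np

from icdensity import (
    GeneratorConfig,
    SelectionModel,
    comparison_report,
    generate_counts,
    simulate_selection_table,
)

dataset = generate_counts(GeneratorConfig(seed=1))

for beta in (0.0, 2.0):
    rng = np.random.default_rng(34)
    selections = simulate_selection_table(
        dataset, SelectionModel(bias_strength=beta), rng
    )
    report = comparison_report(dataset, selections, region="central")
    print(f"\n=== beta = {beta:g} (central cornea) ===")
    print(f"random 3-image pool: mean ratio "
          f"{report['random']['mean_ratio']:.3f} over {report['random']['n']} "
          f"combinations")
    for name, obs in report["observers"].items():
        print(
            f"  {name}: mean ratio {obs['mean_ratio']:.3f}, "
            f"t-test p_adj = {obs['t']['p_adjusted']:.3f}, "
            f"F-test p_adj = {obs['f']['p_adjusted']:.3f}"
        )
    icc = report["consistency_icc"]
    print(f"  between-observer consistency ICC(C,1) = {icc['estimate']:.2f} "
          f"({icc['label']})")

print(
    "\nUnbiased choosers (beta = 0) track the random pool (mean ratios near 1,\n"
    "non-significant t-tests); density-biased choosers (beta = 2) overestimate\n"
    "substantially.  Low consistency ICCs show 3-image estimates disagree\n"
    "between observers even without bias — 3 images under-sample the cornea."
)
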