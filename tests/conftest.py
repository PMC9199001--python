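import numpy as np
import pandas as pd
import pytest

from icdensity import GeneratorConfig, RegionParams, generate_counts


@pytest.fixture(scope="session")
def default_dataset():
    """Full study geometry: 20 participants, 2 regions, 16 images each."""
    return generate_counts(GeneratorConfig(seed=123))


@pytest.fixture(scope="session")
def small_dataset():
    """Cheap dataset for smoke/CLI tests: 4 participants, 6 images, one region."""
    cfg = GeneratorConfig(
        n_participants=4,
        n_images=6,
        regions={"central": RegionParams(40.0, 10.0)},
        seed=7,
    )
    return generate_counts(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def constant_count_frame(n_participants=3, n_images=16, count=4, area=0.16,
                         regions=("central", "peripheral")):
    """Every image has the same count: all mean ratios are exactly 1."""
    rows = []
    for region in regions:
        for i in range(n_participants):
            for j in range(n_images):
                rows.append(
                    {
                        "participant_id": f"P{i + 1:02d}",
                        "region": region,
                        "image_id": f"I{j + 1:02d}",
                        "count": count,
                        "area_mm2": area,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def constant_dataset():
    from icdensity import ImageCountSet

    return ImageCountSet(frame=constant_count_frame())
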