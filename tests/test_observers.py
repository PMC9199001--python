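"""Representative-image evaluation: ratios, bias and precision tests, consistency."""

import numpy as np
import pandas as pd
import pytest

from icdensity import (
    GeneratorConfig,
    ImageCountSet,
    RegionParams,
    SelectionModel,
    compare_mean_to_random,
    compare_variance_to_random,
    comparison_report,
    generate_counts,
    observer_ratios,
    pooled_distribution,
    representative_consistency,
    simulate_image_selection,
    simulate_selection_table,
)
from icdensity.observers import SelectionError

from conftest import constant_count_frame


def selections_from_indices(dataset, picks, observer_id="obs1"):
    """Build a selections table from {(participant, region): [image ids]}."""
    rows = [
        {"observer_id": observer_id, "participant_id": pid, "region": region,
         "image_id": img}
        for (pid, region), imgs in picks.items()
        for img in imgs
    ]
    return pd.DataFrame(rows)


class TestObserverRatios:
    def test_constant_density_participant_ratio_one(self, constant_dataset):
        picks = {("P01", "central"): ["I01", "I05", "I09"]}
        sel = selections_from_indices(constant_dataset, picks)
        out = observer_ratios(sel, constant_dataset, region="central")
        assert out["ratio"].tolist() == [1.0]

    def test_selection_matching_true_mean(self):
        frame = constant_count_frame(n_participants=1, n_images=4,
                                     regions=("central",))
        frame["count"] = [2, 6, 4, 4]  # mean 4; images I03, I04 + I01,I02 average 4
        ds = ImageCountSet(frame=frame)
        picks = {("P01", "central"): ["I01", "I02", "I03"]}  # (2+6+4)/3 = 4 = mean
        out = observer_ratios(selections_from_indices(ds, picks), ds)
        assert out["ratio"].iloc[0] == pytest.approx(1.0)

    def test_unknown_image_rejected(self, constant_dataset):
        picks = {("P01", "central"): ["I01", "I02", "I99"]}
        with pytest.raises(SelectionError):
            observer_ratios(selections_from_indices(constant_dataset, picks),
                            constant_dataset)

    def test_repeated_image_rejected(self, constant_dataset):
        picks = {("P01", "central"): ["I01", "I01", "I02"]}
        with pytest.raises(SelectionError):
            observer_ratios(selections_from_indices(constant_dataset, picks),
                            constant_dataset)

    def test_biased_selection_inflates_mean_ratio(self):
        """beta = 1 selections overestimate density in most replicate datasets."""
        cfg = GeneratorConfig(regions={"central": RegionParams(21.7, 17.7)})
        model = SelectionModel(bias_strength=1.0, n_selected=3)
        above = 0
        n_rep = 40
        for seed in range(n_rep):
            ds = generate_counts(cfg, seed=seed)
            rng = np.random.default_rng(seed + 10_000)
            sel = simulate_selection_table(ds, model, rng, observer_ids=("o1",))
            out = observer_ratios(sel, ds, region="central")
            if out["ratio"].mean() > 1.0:
                above += 1
        assert above > n_rep / 2


class TestMeanComparison:
    def test_null_case_small_statistic(self, rng):
        pool = rng.normal(1.0, 0.2, size=5000)
        obs = rng.normal(1.0, 0.2, size=20)
        cmp = compare_mean_to_random(obs, pool, m_comparisons=3)
        assert abs(cmp.statistic) < 3.5
        assert cmp.p_adjusted == pytest.approx(min(1.0, cmp.p_raw * 3))

    def test_degenerate_zero_variance_flagged(self):
        cmp = compare_mean_to_random(np.ones(10), np.ones(100))
        assert cmp.degenerate

    def test_welch_option(self, rng):
        pool = rng.normal(1.0, 0.2, size=5000)
        obs = rng.normal(1.3, 0.4, size=20)
        student = compare_mean_to_random(obs, pool)
        welch = compare_mean_to_random(obs, pool, welch=True)
        assert student.statistic != pytest.approx(welch.statistic)


class TestVarianceComparison:
    def test_identical_samples_f_one(self, rng):
        x = rng.normal(1.0, 0.2, size=200)
        cmp = compare_variance_to_random(x, x)
        assert cmp.statistic == pytest.approx(1.0)
        assert cmp.p_raw == pytest.approx(1.0)

    def test_zero_variance_flagged(self, rng):
        cmp = compare_variance_to_random(np.ones(10),
                                         rng.normal(size=100))
        assert cmp.degenerate

    def test_null_resampled_from_pool(self, rng):
        """Observer samples drawn iid from the pool itself rarely reject."""
        pool = rng.normal(1.0, 0.25, size=11_200)
        rejections = sum(
            compare_variance_to_random(
                rng.choice(pool, size=20, replace=False), pool, m_comparisons=1
            ).p_raw
            < 0.05
            for _ in range(200)
        )
        assert rejections <= 20  # p > 0.05 in at least 90% of draws

    def test_bonferroni_caps_and_preserves_order(self, rng):
        pool = rng.normal(1.0, 0.2, size=2000)
        cmps = [
            compare_variance_to_random(rng.normal(1, s, size=20), pool,
                                       m_comparisons=3)
            for s in (0.2, 0.3, 0.5)
        ]
        raws = [c.p_raw for c in cmps]
        adjs = [c.p_adjusted for c in cmps]
        assert all(a <= 1.0 for a in adjs)
        assert np.argsort(raws).tolist() == np.argsort(adjs).tolist()


class TestRepresentativeConsistency:
    def test_identical_observers_icc_one(self, rng):
        col = rng.gamma(2.0, 1.0, size=20)
        wide = pd.DataFrame({"o1": col, "o2": col, "o3": col})
        assert representative_consistency(wide).estimate == pytest.approx(1.0)

    def test_deterministic_top3_selectors_icc_one(self, default_dataset):
        """Observers that always pick the 3 densest images agree exactly."""
        dens = default_dataset.with_density()
        rows = []
        for obs in ("o1", "o2", "o3"):
            for (pid, region), grp in dens.groupby(
                ["participant_id", "region"], sort=False
            ):
                top = grp.sort_values(["density", "image_id"]).tail(3)
                for img in top["image_id"]:
                    rows.append({"observer_id": obs, "participant_id": pid,
                                 "region": region, "image_id": img})
        sel = pd.DataFrame(rows)
        ratios = observer_ratios(sel, default_dataset, region="central")
        icc = representative_consistency(ratios)
        assert icc.estimate == pytest.approx(1.0)

    def test_incomplete_table_rejected(self):
        wide = pd.DataFrame({"o1": [1.0, 2.0], "o2": [1.0, np.nan]})
        with pytest.raises(ValueError):
            representative_consistency(wide)


class TestComparisonReport:
    def test_unbiased_smoke(self, default_dataset, rng):
        sel = simulate_selection_table(default_dataset, SelectionModel(), rng)
        rep = comparison_report(default_dataset, sel, "central")
        assert rep["random"]["n"] == 20 * 560
        assert set(rep["observers"]) == {"rater1", "rater2", "rater3"}
        for obs in rep["observers"].values():
            assert not obs["t"]["degenerate"]
            assert not obs["f"]["degenerate"]
        assert -1 <= rep["consistency_icc"]["estimate"] <= 1

    def test_biased_observers_flagged_high(self, default_dataset, rng):
        sel = simulate_selection_table(
            default_dataset, SelectionModel(bias_strength=2.0), rng
        )
        rep = comparison_report(default_dataset, sel, "central")
        assert any(o["mean_ratio"] > 1 for o in rep["observers"].values())
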