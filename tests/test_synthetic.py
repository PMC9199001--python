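"""Seeded synthetic data generator: densities, counts, recounts, selections."""

import math

import numpy as np
import pytest

from icdensity import (
    GeneratorConfig,
    ObserverModel,
    RegionParams,
    SelectionModel,
    draw_participant_densities,
    generate_counts,
    icc_single_absolute,
    simulate_image_selection,
    simulate_observer_counts,
    simulate_selection_table,
)
from icdensity.synthetic import _draw_counts


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_participants": 0},
            {"n_images": 1},
            {"image_area": 0.0},
            {"dispersion": 0.0},
            {"regions": {}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)

    def test_non_positive_density_mean_rejected(self):
        with pytest.raises(ValueError):
            RegionParams(0.0, 5.0)
        with pytest.raises(ValueError):
            RegionParams(10.0, -1.0)


class TestParticipantDensities:
    def test_degenerate_sd_all_equal(self, rng):
        cfg = GeneratorConfig(regions={"central": RegionParams(21.7, 0.0)})
        d = draw_participant_densities(cfg, "central", rng)
        np.testing.assert_array_equal(d, 21.7)

    def test_moment_matching_large_sample(self):
        cfg = GeneratorConfig(
            n_participants=100_000, regions={"central": RegionParams(21.7, 17.7)}
        )
        d = draw_participant_densities(cfg, "central", np.random.default_rng(5))
        assert d.mean() == pytest.approx(21.7, rel=0.01)
        assert d.std(ddof=1) == pytest.approx(17.7, rel=0.02)

    def test_strictly_positive(self, rng):
        cfg = GeneratorConfig(
            n_participants=10_000, regions={"peripheral": RegionParams(62.0, 26.1)}
        )
        d = draw_participant_densities(cfg, "peripheral", rng)
        assert (d > 0).all()

    def test_unknown_region(self, rng):
        with pytest.raises(ValueError):
            draw_participant_densities(GeneratorConfig(), "limbal", rng)


class TestGenerateCounts:
    def test_default_design_counts(self, default_dataset):
        assert default_dataset.n_records == 640
        assert default_dataset.regions == ["central", "peripheral"]

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(seed=42)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_counts(cfg).to_csv(p1)
        generate_counts(cfg).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_counts_are_nonnegative_integers(self, default_dataset):
        counts = default_dataset.frame["count"]
        assert (counts >= 0).all()
        assert (counts == counts.astype(int)).all()

    def test_provenance_carried(self, default_dataset):
        assert default_dataset.provenance["seed"] == 123
        assert default_dataset.provenance["config"]["n_images"] == 16

    def test_zero_rate_gives_zero_counts(self, rng):
        assert (_draw_counts(np.zeros(1000), math.inf, rng) == 0).all()
        assert (_draw_counts(np.zeros(1000), 5.0, rng) == 0).all()

    def test_poisson_dispersion_index(self, rng):
        # density 25 cells/mm^2 on 0.16 mm^2 => Poisson mean 4
        lam = np.full(100_000, 25.0 * 0.16)
        c = _draw_counts(lam, math.inf, rng)
        assert c.mean() == pytest.approx(4.0, rel=0.02)
        assert c.var() / c.mean() == pytest.approx(1.0, abs=0.03)

    def test_negative_binomial_variance_identity(self, rng):
        lam, size = 4.0, 2.5
        c = _draw_counts(np.full(100_000, lam), size, rng)
        assert c.mean() == pytest.approx(lam, rel=0.03)
        assert c.var() == pytest.approx(lam + lam**2 / size, rel=0.05)

    def test_dispersion_limit_recovers_poisson(self, rng):
        """As the NB size parameter grows, variance/mean tends to 1."""
        c = _draw_counts(np.full(1_000_000, 4.0), 1e9, rng)
        assert c.var() / c.mean() == pytest.approx(1.0, abs=0.01)


class TestObserverCounts:
    def test_perfect_observer_identity(self, rng):
        counts = rng.poisson(4.0, size=200)
        out = simulate_observer_counts(counts, ObserverModel(1.0, 0.0), rng)
        np.testing.assert_array_equal(out, counts)

    def test_binomial_thinning_mean(self, rng):
        out = simulate_observer_counts(
            np.full(100_000, 10), ObserverModel(0.9, 0.0), rng
        )
        assert out.mean() == pytest.approx(9.0, rel=0.01)

    def test_negative_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_observer_counts([-1, 2], ObserverModel(), rng)

    def test_recount_panel_icc_high(self, rng):
        """3 imperfect observers recounting a 100-image panel agree strongly."""
        ds = generate_counts(GeneratorConfig(seed=11))
        frame = ds.frame
        panel = np.concatenate(
            [
                frame.loc[frame["region"] == "central", "count"].to_numpy()[:50],
                frame.loc[frame["region"] == "peripheral", "count"].to_numpy()[:50],
            ]
        )
        model = ObserverModel(0.95, 0.2)
        table = np.column_stack(
            [simulate_observer_counts(panel, model, rng) for _ in range(3)]
        )
        assert icc_single_absolute(table).estimate > 0.8


class TestImageSelection:
    def test_uniform_when_unbiased(self):
        rng = np.random.default_rng(8)
        model = SelectionModel(bias_strength=0.0, n_selected=3)
        d = np.linspace(1.0, 16.0, 16)
        hits = np.zeros(16)
        n_rep = 100_000
        for _ in range(n_rep):
            hits[simulate_image_selection(d, model, rng)] += 1
        np.testing.assert_allclose(hits / n_rep, 3 / 16, atol=0.01)

    def test_extreme_bias_selects_top_densities(self, rng):
        d = np.arange(1.0, 17.0)
        model = SelectionModel(bias_strength=50.0, n_selected=3)
        for _ in range(200):
            assert set(simulate_image_selection(d, model, rng)) == {13, 14, 15}

    def test_constant_densities_uniform_despite_bias(self):
        rng = np.random.default_rng(9)
        model = SelectionModel(bias_strength=50.0, n_selected=3)
        d = np.full(16, 7.0)
        hits = np.zeros(16)
        n_rep = 20_000
        for _ in range(n_rep):
            hits[simulate_image_selection(d, model, rng)] += 1
        np.testing.assert_allclose(hits / n_rep, 3 / 16, atol=0.02)

    def test_selected_density_monotone_in_bias(self, rng):
        """Mean selected density is non-decreasing in the bias strength."""
        d = np.arange(1.0, 17.0)
        means = []
        for beta in (0.0, 0.5, 1.0, 2.0):
            model = SelectionModel(bias_strength=beta, n_selected=3)
            tot = 0.0
            for _ in range(10_000):
                tot += d[simulate_image_selection(d, model, rng)].mean()
            means.append(tot / 10_000)
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_too_many_selected_raises(self, rng):
        with pytest.raises(ValueError):
            simulate_image_selection(
                np.ones(4), SelectionModel(n_selected=5), rng
            )

    def test_selection_table_shape(self, small_dataset, rng):
        table = simulate_selection_table(
            small_dataset, SelectionModel(n_selected=3), rng
        )
        # 3 observers x 4 participants x 1 region x 3 images
        assert len(table) == 3 * 4 * 3
        grp = table.groupby(["observer_id", "participant_id", "region"])
        assert (grp["image_id"].nunique() == 3).all()
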