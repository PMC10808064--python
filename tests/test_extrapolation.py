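"""Aggregated-sampling simulation, bias regressions and corrected estimates."""

import math

import numpy as np
import pytest

from hyperdom.extrapolation import (
    AggregatedSamplingConfig,
    apply_correction,
    extrapolate_region,
    fit_bias_correction,
    fit_linear_map,
    sample_plots_with_aggregation,
    simulate_known_sad,
    uncorrected_estimates,
)
from hyperdom.plot_io import pool_to_sad
from hyperdom.sad import SAD


def small_config(**overrides):
    defaults = dict(
        j=60, N=1e6, region_area=2500.0, S_range=(400, 1200),
        aggregation_size=0.25, n_sims=12, seed=0,
    )
    defaults.update(overrides)
    return AggregatedSamplingConfig(**defaults)


class TestSimulateKnownSad:
    def test_contract(self):
        cfg = small_config()
        rng = np.random.default_rng(1)
        for _ in range(5):
            sad, known = simulate_known_sad(cfg, rng)
            assert cfg.S_range[0] <= known["S"] <= cfg.S_range[1]
            assert sad.richness == known["S"]
            assert known["H@0.5"] <= known["S"]
            assert known["P@0.5"] == pytest.approx(
                100.0 * known["H@0.5"] / known["S"]
            )

    def test_mean_total_near_N(self):
        cfg = small_config()
        rng = np.random.default_rng(2)
        totals = [
            simulate_known_sad(cfg, rng)[0].abundances.sum() for _ in range(20)
        ]
        assert np.mean(totals) == pytest.approx(cfg.N, rel=0.10)


class TestAggregatedSampling:
    def test_poisson_limit_variance(self):
        """Huge aggregation size: per-species variance/mean across plots -> 1."""
        sad = SAD(np.full(30, 40_000))
        cfg = small_config(j=400, region_area=10_000.0, aggregation_size=1e9)
        counts = []
        table = sample_plots_with_aggregation(sad, cfg, np.random.default_rng(3))
        mat, _, _ = table.counts_matrix()
        ratio = mat.var(axis=0, ddof=1) / mat.mean(axis=0)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.25)

    def test_independent_mode_grand_mean(self):
        """Law of large numbers: with independent per-plot draws, each
        species' mean count over many plots approaches mu within 3 s.e."""
        sad = SAD(np.array([200_000, 40_000, 8_000]))
        cfg = small_config(
            j=2000, region_area=10_000.0, aggregation_size=0.5,
            shared_aggregation=False,
        )
        mu = sad.abundances / cfg.region_area * cfg.plot_area
        table = sample_plots_with_aggregation(sad, cfg, np.random.default_rng(4))
        mat, _, species = table.counts_matrix()
        totals = {sp: mat[:, i].sum() for i, sp in enumerate(species)}
        for i, m in enumerate(mu):
            var = m + m * m / cfg.aggregation_size
            se = math.sqrt(var / cfg.j)
            got = totals.get(f"sp{i + 1}", 0) / cfg.j
            assert abs(got - m) <= 3 * se

    def test_shared_mode_marginal_mean(self):
        """Shared clumping: one network's plot-mean need not equal mu, but
        the mean over independently drawn networks does."""
        sad = SAD(np.array([200_000]))
        cfg = small_config(j=10, region_area=10_000.0, aggregation_size=0.5)
        mu = float(sad.abundances[0] / cfg.region_area)
        rng = np.random.default_rng(5)
        reps = 600
        means = np.empty(reps)
        for r in range(reps):
            t = sample_plots_with_aggregation(sad, cfg, rng)
            means[r] = t.total_stems / cfg.j
        # dominant variance term is the shared gamma: var ~ mu^2/k
        se = math.sqrt((mu * mu / cfg.aggregation_size + mu) / reps)
        assert abs(means.mean() - mu) <= 3 * se

    def test_plot_count_and_area(self):
        sad = SAD(np.array([50_000, 10_000]))
        cfg = small_config(j=17)
        t = sample_plots_with_aggregation(sad, cfg, np.random.default_rng(6))
        assert t.n_plots == 17
        assert all(p.area == cfg.plot_area for p in t.plots)


class TestUncorrectedEstimates:
    def test_percentage_consistency(self, small_network):
        _, _, _, table = small_network
        est = uncorrected_estimates(table, N=1e6)
        S_round = round(est.values["S"])
        assert est.values["P@0.5"] == pytest.approx(
            100.0 * est.values["H@0.5"] / S_round, rel=1e-9
        )

    def test_near_census_recovers_richness(self):
        """A complete Poisson census of the region estimates S within 5%."""
        from hyperdom.synthetic import generate_metacommunity, tiny_region_spec

        spec = tiny_region_spec(seed=1, N=50_000.0, region_area=60.0, S=120)
        meta, known = generate_metacommunity(spec)
        cfg = small_config(
            j=60, N=spec.N, region_area=spec.region_area,
            aggregation_size=1e9, shared_aggregation=False,
        )
        est = uncorrected_estimates(
            sample_plots_with_aggregation(meta, cfg, np.random.default_rng(7)),
            N=spec.N,
        )
        assert est.values["S"] == pytest.approx(known["S"], rel=0.05)

    def test_aggregation_biases_richness_down(self):
        """Clumped sampling underestimates true richness on average."""
        cfg = small_config(n_sims=3)
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(15):
            sad, known = simulate_known_sad(cfg, rng)
            sample = sample_plots_with_aggregation(sad, cfg, rng)
            est = uncorrected_estimates(sample, cfg.N)
            diffs.append(est.values["S"] - known["S"])
        assert np.mean(diffs) < 0

    def test_degenerate_sample_is_error(self):
        from hyperdom.plot_io import AbundanceTable, PlotRecord

        table = AbundanceTable(
            plots=(PlotRecord(plot_id="p", area=1.0, counts={"A": 5}),)
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            uncorrected_estimates(table, N=1e6)


class TestLinearMap:
    def test_exact_line_recovered(self):
        u = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        reg = fit_linear_map(u, 2.0 * u + 3.0)
        assert reg.slope == pytest.approx(2.0, abs=1e-10)
        assert reg.intercept == pytest.approx(3.0, abs=1e-9)
        assert reg.sigma_r == pytest.approx(0.0, abs=1e-7)

    def test_two_point_closed_form(self):
        # slope = (k2-k1)/(u2-u1), intercept = k1 - slope*u1
        reg = fit_linear_map(np.array([2.0, 6.0]), np.array([10.0, 22.0]))
        assert reg.slope == pytest.approx(3.0)
        assert reg.intercept == pytest.approx(4.0)

    def test_identity_when_estimates_exact(self):
        k = np.array([400.0, 700.0, 950.0, 1200.0])
        reg = fit_linear_map(k, k)
        assert reg.slope == pytest.approx(1.0, abs=1e-12)
        assert reg.intercept == pytest.approx(0.0, abs=1e-9)
        assert reg.sigma_r == pytest.approx(0.0, abs=1e-9)

    def test_refit_on_retained_pairs_is_identical(self):
        rng = np.random.default_rng(10)
        u = rng.uniform(100, 1000, size=40)
        k = 1.5 * u + rng.normal(0, 20, size=40)
        reg = fit_linear_map(u, k)
        again = fit_linear_map(reg.u_train, reg.k_train)
        assert again.slope == pytest.approx(reg.slope, abs=1e-10)
        assert again.intercept == pytest.approx(reg.intercept, abs=1e-10)


class TestFitBiasCorrection:
    def test_requires_enough_sims(self):
        with pytest.raises(ValueError, match="n_sims"):
            fit_bias_correction(small_config(n_sims=2))

    def test_singular_design_detected(self, monkeypatch):
        import hyperdom.extrapolation as ex

        real = ex.uncorrected_estimates
        frozen = []

        def constant_estimates(sample, N, grid):
            if not frozen:
                frozen.append(real(sample, N, grid))
            return frozen[0]

        monkeypatch.setattr(ex, "uncorrected_estimates", constant_estimates)
        with pytest.raises(ValueError, match="singular"):
            fit_bias_correction(small_config(n_sims=4))

    def test_pairs_frame_layout(self):
        # single-threshold grid: with very few sims the minor discrete
        # dominance counts can coincide and trip the singularity guard
        model = fit_bias_correction(small_config(n_sims=4, dominance_grid=(0.5,)))
        frame = model.pairs_frame()
        assert set(frame.columns) == {"metric", "uncorrected", "known"}
        assert (frame["metric"] == "S").sum() == 4


class TestApplyCorrection:
    def test_sigma_pi_combines_both_uncertainties(self):
        rng = np.random.default_rng(11)
        u = rng.uniform(100, 1000, size=50)
        k = 1.4 * u + rng.normal(0, 30, size=50)
        reg = fit_linear_map(u, k)
        point, se = reg.predict(500.0)
        assert math.hypot(se, reg.sigma_r) == pytest.approx(
            math.sqrt(se**2 + reg.sigma_r**2)
        )
        # statsmodels' own prediction of the mean agrees with m*u + c
        assert point == pytest.approx(reg.slope * 500.0 + reg.intercept)

    def test_exact_fit_collapses_interval_to_point(self):
        u = np.linspace(1, 10, 20)
        reg = fit_linear_map(u, 2 * u)
        point, se = reg.predict(5.0)
        assert se == pytest.approx(0.0, abs=1e-8)
        assert point == pytest.approx(10.0)

    def test_interval_orders_around_point(self, small_network):
        _, _, _, table = small_network
        cfg = small_config(j=40, n_sims=8)
        estimates, model, est = extrapolate_region(table, cfg)
        for e in estimates:
            assert e.pi_low <= e.point <= e.pi_high

    def test_prediction_interval_magnitude_vs_bootstrap(self):
        """Loose sanity: the analytic sigma_PI is the same order as a
        bootstrap of the training pairs."""
        rng = np.random.default_rng(12)
        u = rng.uniform(100, 1000, size=60)
        k = 1.5 * u + rng.normal(0, 40, size=60)
        reg = fit_linear_map(u, k)
        _, se = reg.predict(550.0)
        sigma_pi = math.hypot(se, reg.sigma_r)
        preds = []
        for _ in range(300):
            idx = rng.integers(0, 60, size=60)
            b = fit_linear_map(u[idx], k[idx])
            preds.append(b.slope * 550.0 + b.intercept + rng.normal(0, b.sigma_r))
        boot = np.std(preds)
        assert 0.3 * boot < sigma_pi < 3.0 * boot


class TestEndToEnd:
    def test_pipeline_determinism(self, small_network):
        _, _, _, table = small_network
        cfg = small_config(j=40, n_sims=6, seed=99)
        a, _, _ = extrapolate_region(table, cfg)
        b, _, _ = extrapolate_region(table, cfg)
        for x, y in zip(a, b):
            assert x.metric == y.metric
            assert x.point == y.point
            assert x.pi_low == y.pi_low
            assert x.pi_high == y.pi_high

    def test_correction_raises_richness_on_aggregated_data(self, small_network):
        _, _, _, table = small_network
        cfg = small_config(j=100, n_sims=15, seed=3)
        estimates, _, est = extrapolate_region(table, cfg)
        s = next(e for e in estimates if e.metric == "S")
        assert s.point >= s.uncorrected

    def test_correction_near_identity_without_aggregation(self):
        """No clumping and a near-census sample: the fitted correction is
        close to the identity map."""
        from hyperdom.synthetic import generate_metacommunity, tiny_region_spec

        spec = tiny_region_spec(
            seed=2, N=50_000.0, region_area=60.0, S=120, indet_fraction=0.0
        )
        meta, _ = generate_metacommunity(spec)
        cfg = small_config(
            j=60, N=spec.N, region_area=spec.region_area,
            S_range=(60, 240), aggregation_size=1e9,
            shared_aggregation=False, n_sims=20, seed=13,
        )
        sample = sample_plots_with_aggregation(meta, cfg, np.random.default_rng(14))
        estimates, model, est = apply_and_model(sample, cfg)
        s = next(e for e in estimates if e.metric == "S")
        # a Poisson census still misses singletons (P = 1/e each), so the
        # fitted correction retains a small upward pull; identity within 10%
        assert abs(s.point - s.uncorrected) / s.uncorrected < 0.10

    def test_h_percent_consistent_across_code_paths(self, small_network):
        """Corrected H% is the q=0.5 entry of the dominance-percentage
        regressions — one value, two framings."""
        _, _, _, table = small_network
        cfg = small_config(j=40, n_sims=8, seed=21)
        estimates, model, est = extrapolate_region(table, cfg)
        p05 = [e for e in estimates if e.metric == "P@0.5"]
        assert len(p05) == 1
        reg = model.regressions["P@0.5"]
        assert p05[0].point == pytest.approx(
            reg.slope * est.values["P@0.5"] + reg.intercept
        )


def apply_and_model(sample, cfg):
    est = uncorrected_estimates(sample, cfg.N, cfg.dominance_grid)
    model = fit_bias_correction(cfg)
    return apply_correction(model, est), model, est
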