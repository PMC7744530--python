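"""Monte Carlo ILCR: distributions, degeneracy, convergence, sensitivity."""

import numpy as np
import pytest

from hmrisk.datamodel import ExposureParameters, ValidationError
from hmrisk.montecarlo import (
    DistributionSpec,
    analytic_mean_ilcr,
    sample,
    sensitivity,
    simulate_ilcr,
)
from hmrisk.risk import ilcr as deterministic_ilcr


def point_params(p: ExposureParameters) -> dict:
    return {name: DistributionSpec.point(getattr(p, name)) for name in ("ingr_water", "ef", "ed", "bw", "at")}


class TestSample:
    def test_point_mass(self):
        assert sample(DistributionSpec.point(5.0), 4, seed=1).tolist() == [5.0, 5.0, 5.0, 5.0]

    def test_lognormal_moment_matching(self):
        draws = sample(DistributionSpec.lognormal(2.05, 0.54), 100_000, seed=7)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 2.05) < 3 * se
        assert draws.min() > 0

    def test_determinism(self):
        spec = DistributionSpec.lognormal(1.0, 0.3)
        assert np.array_equal(sample(spec, 1000, seed=3), sample(spec, 1000, seed=3))

    def test_supports_are_respected(self):
        assert sample(DistributionSpec.uniform(1, 2), 500, seed=0).min() >= 1
        tri = sample(DistributionSpec.triangular(0, 1, 2), 500, seed=0)
        assert 0 <= tri.min() and tri.max() <= 2
        tn = sample(DistributionSpec.normal_truncated_positive(1.0, 2.0), 2000, seed=0)
        assert tn.min() > 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            DistributionSpec.lognormal(-1.0, 0.5)
        with pytest.raises(ValidationError):
            DistributionSpec.uniform(2.0, 1.0)
        with pytest.raises(ValidationError):
            sample(DistributionSpec.point(1.0), 0, seed=1)


class TestSimulateIlcr:
    def test_point_mass_degenerates_to_deterministic_ilcr(self, toxicity, params):
        mc = simulate_ilcr(
            "Pb",
            DistributionSpec.point(1.67),
            point_params(params),
            toxicity,
            n_trials=200,
            seed=11,
            exposure=params,
        )
        expected = deterministic_ilcr(1.67 * params.ingr_water / params.bw, 8.5e-3)
        assert np.allclose(mc.draws, expected, rtol=1e-12)
        assert mc.mean == pytest.approx(expected, rel=1e-12)
        assert mc.p5 == pytest.approx(mc.p95, rel=1e-12)

    def test_mc_mean_within_three_se_of_analytic(self, toxicity, params):
        dists = {"cw": DistributionSpec.lognormal(1.67, 0.30), "sf": DistributionSpec.point(8.5e-3), **point_params(params)}
        mc = simulate_ilcr("Pb", dists["cw"], point_params(params), toxicity, n_trials=10_000, seed=5, exposure=params)
        analytic = analytic_mean_ilcr(dists)
        assert analytic == pytest.approx(4.06e-4, abs=5e-7)
        se = mc.draws.std(ddof=1) / np.sqrt(mc.n_trials)
        assert abs(mc.mean - analytic) < 3 * se

    def test_linearity_in_concentration_scale(self, toxicity, params):
        base = simulate_ilcr("Pb", DistributionSpec.lognormal(1.67, 0.30), point_params(params), toxicity, n_trials=1000, seed=9, exposure=params)
        k = 3.0
        scaled = simulate_ilcr("Pb", DistributionSpec.lognormal(k * 1.67, k * 0.30), point_params(params), toxicity, n_trials=1000, seed=9, exposure=params)
        assert np.allclose(scaled.draws, k * base.draws, rtol=1e-12)
        assert scaled.mean == pytest.approx(k * base.mean, rel=1e-12)
        assert scaled.p5 == pytest.approx(k * base.p5, rel=1e-12)
        assert scaled.p95 == pytest.approx(k * base.p95, rel=1e-12)

    def test_reproducible_and_percentiles_ordered(self, toxicity, params):
        kw = dict(n_trials=2000, seed=21, exposure=params)
        a = simulate_ilcr("Cd", DistributionSpec.lognormal(0.22, 0.03), point_params(params), toxicity, **kw)
        b = simulate_ilcr("Cd", DistributionSpec.lognormal(0.22, 0.03), point_params(params), toxicity, **kw)
        assert np.array_equal(a.draws, b.draws)
        assert (a.mean, a.p5, a.p50, a.p95) == (b.mean, b.p5, b.p50, b.p95)
        assert a.p5 <= a.p50 <= a.p95
        assert a.draws.min() >= 0 and a.draws.size == 2000

    def test_missing_sf_and_degenerate_n_rejected(self, toxicity, params):
        with pytest.raises(ValidationError, match="slope factor"):
            simulate_ilcr("Zn", DistributionSpec.point(2.15), point_params(params), toxicity, n_trials=200, seed=1)
        with pytest.raises(ValidationError):
            simulate_ilcr("Pb", DistributionSpec.point(1.67), point_params(params), toxicity, n_trials=10, seed=1)
        with pytest.raises(ValidationError, match="seed"):
            simulate_ilcr("Pb", DistributionSpec.point(1.67), point_params(params), toxicity, n_trials=200)


class TestSensitivity:
    def test_single_varying_driver_dominates(self, toxicity, params):
        dists = point_params(params)
        dists["ingr_water"] = DistributionSpec.uniform(1.0, 3.0)
        mc = simulate_ilcr("Pb", DistributionSpec.point(1.67), dists, toxicity, n_trials=2000, seed=2, exposure=params)
        ranked = {e.input_name: e for e in mc.sensitivity}
        assert mc.sensitivity[0].input_name == "ingr_water"
        assert abs(ranked["ingr_water"].rank_correlation) == pytest.approx(1.0, abs=1e-9)
        for name, entry in ranked.items():
            if name != "ingr_water":
                assert entry.constant and entry.rank_correlation == 0.0

    def test_body_weight_correlation_is_negative(self, toxicity, params):
        dists = point_params(params)
        dists["bw"] = DistributionSpec.normal_truncated_positive(70.0, 10.0)
        mc = simulate_ilcr("Pb", DistributionSpec.point(1.67), dists, toxicity, n_trials=2000, seed=3, exposure=params)
        bw = next(e for e in mc.sensitivity if e.input_name == "bw")
        assert bw.rank_correlation < -0.99

    def test_equal_cv_multiplicative_inputs_rank_comparably(self, toxicity, params):
        dists = point_params(params)
        dists["ingr_water"] = DistributionSpec.lognormal(2.0, 0.4)  # CV 20%
        mc = simulate_ilcr("Pb", DistributionSpec.lognormal(1.67, 0.334), dists, toxicity, n_trials=10_000, seed=4, exposure=params)
        by = {e.input_name: abs(e.rank_correlation) for e in mc.sensitivity}
        assert by["ingr_water"] == pytest.approx(by["cw"], abs=0.05)

    def test_no_stored_draws_rejected(self):
        from hmrisk.montecarlo import MCResult

        empty = MCResult("Pb", 100, 1, np.zeros(100), 0, 0, 0, 0, input_draws={})
        with pytest.raises(ValidationError):
            sensitivity(empty)
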