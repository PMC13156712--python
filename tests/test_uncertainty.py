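"""Monte Carlo, Pearson screening and Sobol estimation against closed forms."""

import math

import numpy as np
import pytest
import scipy.stats as st

from trophicast.core import ValidationError
from trophicast.uncertainty import (
    LognormalSpec,
    MCConfig,
    lognormal_from_mean_cv,
    monte_carlo_hq,
    pearson_screen,
    sobol_sensitivity,
)


class TestLognormalSpec:
    def test_moment_matching_closed_form(self):
        spec = lognormal_from_mean_cv(1.0, 0.30)
        assert spec.sigma == pytest.approx(math.sqrt(math.log(1.09)))
        assert spec.mu == pytest.approx(-0.5 * math.log(1.09))

    def test_inverted_moment_formulas(self):
        # sigma = 1 ⇔ cv = sqrt(e - 1); mean = e^{1/2} then forces mu = 0
        cv = math.sqrt(math.e - 1.0)
        spec = lognormal_from_mean_cv(math.exp(0.5), cv)
        assert spec.sigma == pytest.approx(1.0)
        assert spec.mu == pytest.approx(0.0, abs=1e-12)

    def test_small_cv_degenerates_at_mean(self):
        spec = lognormal_from_mean_cv(7.0, 1e-9)
        assert spec.sigma == pytest.approx(0.0, abs=1e-8)
        assert spec.median == pytest.approx(7.0)

    def test_sampled_mean_converges(self):
        spec = lognormal_from_mean_cv(3.0, 0.5)
        x = spec.sample(np.random.default_rng(0), 200_000)
        se = x.std() / math.sqrt(x.size)
        assert abs(x.mean() - 3.0) < 3 * se

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            lognormal_from_mean_cv(0.0, 0.3)
        with pytest.raises(ValidationError):
            lognormal_from_mean_cv(1.0, 0.0)


class TestMonteCarloHQ:
    def test_all_fixed_inputs_collapse_to_deterministic_hq(self):
        config = MCConfig(n_iterations=100, seed=1)
        out = monte_carlo_hq(
            lambda d: d["add"] / d["rfd"], {"add": 0.002, "rfd": 0.001}, config
        )
        assert out.median == out.mean == 2.0
        assert out.p_exceed_unity == 1.0
        assert out.log10_density is None

    def test_median_at_rfd_gives_half_exceedance(self):
        spec = lognormal_from_mean_cv(1.0, 0.4)
        rfd = spec.median  # log-normal median = e^mu
        config = MCConfig(n_iterations=10_000, seed=2)
        out = monte_carlo_hq(lambda d: d["x"] / rfd, {"x": spec}, config)
        assert out.p_exceed_unity == pytest.approx(0.5, abs=0.015)

    def test_product_of_lognormals_matches_closed_form_moments(self):
        """log10 HQ of a product/quotient model is Gaussian with summed moments."""
        specs = {
            "c": lognormal_from_mean_cv(2.0, 0.3),
            "btf": lognormal_from_mean_cv(1.5, 0.2),
            "bw": lognormal_from_mean_cv(5.0, 0.25),
        }
        rfd = 1e-2
        config = MCConfig(n_iterations=20_000, seed=3)
        out = monte_carlo_hq(
            lambda d: d["c"] / (d["btf"] * d["bw"]) / rfd, specs, config
        )
        log_hq = np.log10(out.samples)
        mu = (specs["c"].mu - specs["btf"].mu - specs["bw"].mu) / math.log(10) \
            - math.log10(rfd)
        var = sum(s.sigma**2 for s in specs.values()) / math.log(10) ** 2
        n = config.n_iterations
        assert abs(log_hq.mean() - mu) < 3 * math.sqrt(var / n)
        se_var = var * math.sqrt(2.0 / (n - 1))
        assert abs(log_hq.var(ddof=1) - var) < 3 * se_var

    def test_same_seed_is_bit_identical(self):
        spec = lognormal_from_mean_cv(1.0, 0.3)
        config = MCConfig(n_iterations=500, seed=9)
        a = monte_carlo_hq(lambda d: d["x"], {"x": spec}, config)
        b = monte_carlo_hq(lambda d: d["x"], {"x": spec}, config)
        assert np.array_equal(a.samples, b.samples)
        assert a.median == b.median


class TestPearsonScreen:
    def test_output_equal_to_parameter_is_flagged(self):
        x = np.linspace(0, 1, 100)
        res = pearson_screen({"x": x}, x)
        assert res[0].rho == pytest.approx(1.0)
        assert res[0].flagged

    def test_independent_noise_not_flagged(self):
        rng = np.random.default_rng(4)
        res = pearson_screen({"x": rng.normal(size=5000)}, rng.normal(size=5000))
        assert abs(res[0].rho) < 0.1
        assert not res[0].flagged

    def test_cholesky_constructed_correlation_half_is_flagged(self):
        rho = 0.5
        rng = np.random.default_rng(5)
        z = rng.normal(size=(2, 20_000))
        x = z[0]
        y = rho * z[0] + math.sqrt(1 - rho**2) * z[1]
        # independent check of the construction
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(rho, abs=0.02)
        res = pearson_screen({"x": x}, y)
        assert res[0].flagged

    def test_constant_column_reported_not_flagged(self):
        res = pearson_screen({"k": np.ones(10)}, np.arange(10.0))
        assert not res[0].flagged
        assert "constant" in res[0].note


def ishigami(x, a=7.0, b=0.1):
    return np.sin(x[0]) + a * np.sin(x[1]) ** 2 + b * x[2] ** 4 * np.sin(x[0])


def ishigami_truth(a=7.0, b=0.1):
    v = a**2 / 8 + b * math.pi**4 / 5 + b**2 * math.pi**8 / 18 + 0.5
    s1 = [
        0.5 * (1 + b * math.pi**4 / 5) ** 2 / v,
        a**2 / 8 / v,
        0.0,
    ]
    st_ = [
        (0.5 * (1 + b * math.pi**4 / 5) ** 2 + 8 * b**2 * math.pi**8 / 225) / v,
        a**2 / 8 / v,
        8 * b**2 * math.pi**8 / 225 / v,
    ]
    return s1, st_


class TestSobol:
    def test_additive_gaussian_splits_variance_evenly(self):
        res = sobol_sensitivity(
            lambda x: x[0] + x[1],
            {"a": st.norm(0, 1), "b": st.norm(0, 1)},
            MCConfig(n_iterations=2**14, seed=6),
        )
        for r in res:
            assert r.s1 == pytest.approx(0.5, abs=0.02)
            assert r.st == pytest.approx(0.5, abs=0.02)

    def test_single_active_parameter(self):
        res = sobol_sensitivity(
            lambda x: x[0],
            {"a": st.norm(0, 1), "b": st.norm(0, 1)},
            MCConfig(n_iterations=2**12, seed=7),
        )
        assert res[0].s1 == pytest.approx(1.0, abs=0.02)
        assert res[0].st == pytest.approx(1.0, abs=0.02)
        assert res[1].s1 == pytest.approx(0.0, abs=0.02)
        assert res[1].st == pytest.approx(0.0, abs=0.02)

    def test_ishigami_matches_closed_form(self):
        dists = {n: st.uniform(-math.pi, 2 * math.pi) for n in "xyz"}
        res = sobol_sensitivity(ishigami, dists, MCConfig(n_iterations=2**13, seed=8))
        s1_true, st_true = ishigami_truth()
        for r, s1t, stt in zip(res, s1_true, st_true):
            assert r.s1 == pytest.approx(s1t, abs=0.03)
            assert r.st == pytest.approx(stt, abs=0.03)
            assert r.st >= r.s1 - 0.02  # total ≥ first order up to noise

    def test_additive_indices_sum_to_one(self):
        res = sobol_sensitivity(
            lambda x: 2 * x[0] + 3 * x[1],
            {"a": st.norm(0, 1), "b": st.norm(0, 1)},
            MCConfig(n_iterations=2**13, seed=10),
        )
        assert sum(r.s1 for r in res) == pytest.approx(1.0, abs=0.03)

    def test_same_seed_reproducible(self):
        cfg = MCConfig(n_iterations=2**10, seed=11)
        args = (lambda x: x[0] + 0.5 * x[1],
                {"a": st.norm(0, 1), "b": st.norm(0, 1)})
        r1 = sobol_sensitivity(*args, cfg)
        r2 = sobol_sensitivity(*args, cfg)
        assert [(r.s1, r.st, r.s1_ci, r.st_ci) for r in r1] == \
            [(r.s1, r.st, r.s1_ci, r.st_ci) for r in r2]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            sobol_sensitivity(
                lambda x: np.ones(x.shape[1]),
                {"a": st.norm(0, 1)},
                MCConfig(n_iterations=2**8, seed=12),
            )

    def test_bootstrap_ci_coverage_on_additive_model(self):
        """Percentile CIs cover the true S1 = 0.5 at roughly nominal rate."""
        hits = 0
        runs = 30
        for seed in range(runs):
            res = sobol_sensitivity(
                lambda x: x[0] + x[1],
                {"a": st.norm(0, 1), "b": st.norm(0, 1)},
                MCConfig(n_iterations=2**9, seed=seed, bootstrap_reps=200),
            )
            lo, hi = res[0].s1_ci
            hits += lo <= 0.5 <= hi
        # 95% nominal; binomial 3-sigma band around 28.5/30 reaches ~24
        assert hits >= 24
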