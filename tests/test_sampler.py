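"""Gibbs sampler correctness: conjugate oracles, invariances, shrinkage."""

import numpy as np
import pandas as pd
import pytest

from rockpool.model import CloneVarianceModel, ObservationTable
from rockpool.registry import MCMCSettings, ModelSpec, PriorSpec

INTERCEPT_ONLY = ModelSpec(
    "M1-0", "fitness", "dev20_only", ("intercept",), {}, "shared")


def _clone_frame(seed=0, n_clones=12, reps=4, sigma_c=1.0, sigma_e=0.8):
    rng = np.random.default_rng(seed)
    effects = rng.normal(0, sigma_c, n_clones)
    rows = []
    for j in range(n_clones):
        for _ in range(reps):
            rows.append({
                "response": 5.0 + effects[j] + rng.normal(0, sigma_e),
                "clone": f"c{j:02d}", "pool": "p1",
                "year": 2018, "dev_temp": 20,
            })
    return pd.DataFrame(rows), effects


class TestObservationTable:
    def test_clone_in_two_pools_rejected(self):
        frame = pd.DataFrame({
            "response": [1.0, 2.0], "clone": ["c1", "c1"],
            "pool": ["p1", "p2"], "year": 2018, "dev_temp": 20,
        })
        with pytest.raises(ValueError, match="multiple pools"):
            ObservationTable(frame, response="fitness")

    def test_ctmax_requires_trial(self):
        frame = pd.DataFrame({
            "response": [1.0], "clone": ["c1"], "pool": ["p1"],
            "year": [2018], "dev_temp": [20],
        })
        with pytest.raises(ValueError, match="trial"):
            ObservationTable(frame, response="ctmax")

    def test_nonfinite_response_rejected(self):
        frame = pd.DataFrame({
            "response": [1.0, np.nan], "clone": "c1", "pool": "p1",
            "year": 2018, "dev_temp": 20,
        })
        with pytest.raises(ValueError, match="non-finite"):
            ObservationTable(frame, response="fitness")


class TestConjugateOracle:
    def test_intercept_posterior_matches_closed_form(self, intercept_frame):
        """Known error SD: sampler matches the normal-normal posterior."""
        y = intercept_frame["response"].to_numpy()
        n = len(y)
        model = CloneVarianceModel(INTERCEPT_ONLY, intercept_frame)
        res = model.fit(MCMCSettings(4000, 1000, thin=1, n_chains=3, seed=7),
                        fixed_error_sd=1.0)
        draws = res.param_draws()["intercept"].ravel()
        post_var = 1.0 / (n + 1.0 / 1000.0)
        post_mean = post_var * y.sum()
        mcse_mean = draws.std() / np.sqrt(len(draws) / 10)  # conservative ESS
        assert abs(draws.mean() - post_mean) < 3 * mcse_mean
        assert abs(draws.var() - post_var) < 3 * post_var * np.sqrt(20 / len(draws))

    def test_degenerate_constant_data(self):
        frame = pd.DataFrame({
            "response": np.full(40, 3.0), "clone": "c1", "pool": "p1",
            "year": 2018, "dev_temp": 20,
        })
        model = CloneVarianceModel(INTERCEPT_ONLY, frame)
        res = model.fit(MCMCSettings(1500, 500, thin=1, n_chains=2, seed=1))
        sigma = res._sigma_flat("error", "sigma_error")
        assert np.median(sigma) < 0.05 * 3.0


class TestSamplerInvariants:
    def test_reproducible_and_row_order_invariant(self, quick_settings):
        frame, _ = _clone_frame(seed=4)
        spec = ModelSpec("M1-1", "fitness", "dev20_only",
                         ("intercept", "year"), {"clone": "shared"}, "shared")
        res1 = CloneVarianceModel(spec, frame).fit(quick_settings)
        res2 = CloneVarianceModel(spec, frame).fit(quick_settings)
        assert np.array_equal(res1.beta, res2.beta)
        shuffled = frame.sample(frac=1.0, random_state=9).reset_index(drop=True)
        res3 = CloneVarianceModel(spec, shuffled).fit(quick_settings)
        assert np.array_equal(res1.beta, res3.beta)
        assert np.array_equal(
            res1.sigma_random["clone"], res3.sigma_random["clone"])

    def test_prior_support_respected(self, quick_settings):
        frame, _ = _clone_frame(seed=2)
        spec = ModelSpec("M1-1", "fitness", "dev20_only",
                         ("intercept",), {"clone": "shared"}, "shared")
        res = CloneVarianceModel(spec, frame).fit(quick_settings)
        for name, d in res.param_draws().items():
            assert np.isfinite(d).all()
            if name.startswith("sigma"):
                assert (d > 0).all() and (d < 100).all()

    def test_clone_means_shrink_toward_zero(self, quick_settings):
        """Posterior clone effects lie between 0 and the raw clone means."""
        frame, _ = _clone_frame(seed=6, n_clones=10, reps=5)
        spec = ModelSpec("M1-1", "fitness", "dev20_only",
                         ("intercept",), {"clone": "shared"}, "shared")
        model = CloneVarianceModel(spec, frame)
        res = model.fit(quick_settings)
        u = res.random_effects["clone"].reshape(-1, 10).mean(axis=0)
        grand = model.y.mean()
        raw = (pd.Series(model.y).groupby(model.data["clone"].values)
               .mean().sort_index().to_numpy() - grand)
        for uj, rawj in zip(u, raw):
            lo, hi = sorted((0.0, rawj))
            assert lo - 0.08 <= uj <= hi + 0.08

    def test_scale_invariance_of_heritability(self, quick_settings):
        """Scaling responses by k scales variances by k^2, H2 unchanged."""
        frame, _ = _clone_frame(seed=8)
        spec = ModelSpec("M3-0", "fitness", "both_temps",
                         ("intercept",), {"clone": "shared"}, "shared")
        res1 = CloneVarianceModel(spec, frame).fit(quick_settings)
        scaled = frame.assign(response=frame["response"] * 10.0)
        res2 = CloneVarianceModel(spec, scaled).fit(quick_settings)
        h1 = res1.heritability("all")
        h2 = res2.heritability("all")
        assert h2.v_g[0] == pytest.approx(100 * h1.v_g[0], rel=0.25)
        assert h2.h2[0] == pytest.approx(h1.h2[0], abs=0.05)


class TestPointwiseLoglik:
    def test_observation_at_fitted_mean_unit_sd(self):
        """Response equal to the draw's mean with sd 1 -> -log(sqrt(2 pi))."""
        frame = pd.DataFrame({
            "response": [2.0], "clone": "c1", "pool": "p1",
            "year": 2018, "dev_temp": 20,
        })
        model = CloneVarianceModel(INTERCEPT_ONLY, frame)
        res = model.fit(MCMCSettings(300, 100, thin=1, n_chains=2, seed=0),
                        fixed_error_sd=1.0)
        # force every draw's intercept to the observed value
        res.beta[:] = 2.0
        ll = res.pointwise_loglik()
        assert np.allclose(ll, -0.5 * np.log(2 * np.pi))

    def test_matches_direct_evaluation(self, quick_settings):
        frame, _ = _clone_frame(seed=12)
        spec = ModelSpec("M1-1", "fitness", "dev20_only",
                         ("intercept",), {"clone": "shared"}, "shared")
        model = CloneVarianceModel(spec, frame)
        res = model.fit(quick_settings)
        ll = res.pointwise_loglik()
        # direct joint conditional log-likelihood for a handful of draws
        from scipy.stats import norm
        term = model.random_terms[0]
        for s in (0, 50, len(ll) - 1):
            beta = res.beta.reshape(-1, res.k)[s]
            u = res.random_effects["clone"].reshape(-1, term.n_levels)[s]
            sd = res.sigma_error.reshape(-1, 1)[s, 0]
            mu = model.exog @ beta + u[term.idx]
            direct = norm.logpdf(model.y, mu, sd).sum()
            assert ll[s].sum() == pytest.approx(direct, rel=1e-10)

    def test_larger_sd_raises_tail_loglik(self):
        """For a far-out observation, doubling sigma increases its density."""
        frame = pd.DataFrame({
            "response": [10.0], "clone": "c1", "pool": "p1",
            "year": 2018, "dev_temp": 20,
        })
        model = CloneVarianceModel(INTERCEPT_ONLY, frame)
        res_narrow = model.fit(
            MCMCSettings(300, 100, thin=1, n_chains=2, seed=0),
            fixed_error_sd=1.0)
        res_wide = model.fit(
            MCMCSettings(300, 100, thin=1, n_chains=2, seed=0),
            fixed_error_sd=2.0)
        res_narrow.beta[:] = 0.0
        res_wide.beta[:] = 0.0
        assert (res_wide.pointwise_loglik() >
                res_narrow.pointwise_loglik()).all()


class TestVarianceScalePrior:
    def test_variance_scale_prior_bounds_sd_at_10(self, quick_settings):
        frame, _ = _clone_frame(seed=3)
        spec = ModelSpec("M1-1", "fitness", "dev20_only",
                         ("intercept",), {"clone": "shared"}, "shared")
        model = CloneVarianceModel(
            spec, frame, priors=PriorSpec(scale_on="variance"))
        res = model.fit(quick_settings)
        for name, d in res.param_draws().items():
            if name.startswith("sigma"):
                assert (d < 10.0).all()
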