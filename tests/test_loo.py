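"""PSIS-LOO, model comparison, and convergence/PPC diagnostics."""

import numpy as np
import pandas as pd
import pytest

from rockpool.diagnostics import gelman_rubin
from rockpool.loo import LOOResult, compare, comparison_frame, psis_loo
from rockpool.model import CloneVarianceModel
from rockpool.registry import MCMCSettings, ModelSpec


class TestPsisLoo:
    def test_constant_loglik_gives_zero_p_eff(self):
        ll = np.tile(np.array([-1.3, -0.7, -2.1]), (500, 1))
        res = psis_loo(ll)
        assert np.allclose(res.pointwise_elpd, [-1.3, -0.7, -2.1])
        assert abs(res.p_eff) < 1e-10
        assert res.elpd_loo == pytest.approx(-4.1)

    def test_pointwise_sums_to_elpd(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-1.0, 0.3, size=(400, 25))
        res = psis_loo(ll)
        assert res.elpd_loo == pytest.approx(res.pointwise_elpd.sum())
        assert res.p_eff >= 0

    def test_iid_normal_loglik_tails_are_mild(self):
        # log-normal importance ratios have all moments; with a draw count
        # large enough for the tail-index estimate to settle, k stays < 0.5
        rng = np.random.default_rng(1)
        ll = rng.standard_normal((5000, 30))
        res = psis_loo(ll)
        assert (res.pareto_k < 0.5).all()

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError, match="100"):
            psis_loo(np.zeros((50, 5)))

    def test_smoothed_weights_capped_at_raw_maximum(self):
        rng = np.random.default_rng(3)
        ll = rng.normal(-1.0, 1.0, size=(800, 10))
        from rockpool.loo import _smooth_tail
        S = ll.shape[0]
        tail = int(np.ceil(min(0.2 * S, 3 * np.sqrt(S))))
        for i in range(10):
            lw = -ll[:, i]
            lw = lw - lw.max()
            sm, _k = _smooth_tail(lw, tail)
            assert sm.max() <= 0.0 + 1e-12

    def test_matches_arviz_reference(self):
        """Cross-check elpd against the independent reference implementation."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(7)
        # conjugate normal-mean model: y ~ N(mu, 1), mu | y posterior draws
        n = 40
        y = rng.normal(0.3, 1.0, n)
        mu = rng.normal(y.mean(), 1 / np.sqrt(n), (2, 600))
        ll = (-0.5 * np.log(2 * np.pi)
              - 0.5 * (y[None, None, :] - mu[:, :, None]) ** 2)
        idata = az.from_dict(
            posterior={"mu": mu},
            log_likelihood={"y": ll},
        )
        ref = az.loo(idata, pointwise=True)
        mine = psis_loo(ll.reshape(1200, 40))
        assert mine.elpd_loo == pytest.approx(float(ref.elpd_loo), abs=0.1)
        assert mine.p_eff == pytest.approx(float(ref.p_loo), abs=0.1)
        assert np.allclose(
            mine.pointwise_elpd, ref.loo_i.values, atol=0.02)


class TestCompare:
    def _fake(self, pointwise, seed=0):
        pw = np.asarray(pointwise, dtype=float)
        return LOOResult(
            elpd_loo=float(pw.sum()), p_eff=1.0,
            se_elpd=float(np.sqrt(pw.size * pw.var(ddof=1))),
            pointwise_elpd=pw, pareto_k=np.zeros(pw.size), n_draws=1000,
        )

    def test_support_rule_table_calls(self):
        """The published qualitative calls follow from printed delta/SE."""
        # Fitness M1-0: delta -34.8, SE 10.69 -> |delta| > 2 SE: unsupported
        assert not (34.8 <= 2 * 10.69)
        # CTmax M1-0: delta -8.1, SE 4.41 -> supported
        assert 8.1 <= 2 * 4.41
        rng = np.random.default_rng(0)

        def rows_for(delta, se, n=300):
            base = rng.normal(-1.0, 0.5, n)
            noise = rng.standard_normal(n)
            noise = (noise - noise.mean()) / noise.std(ddof=1)
            diff = noise * (se / np.sqrt(n)) + delta / n
            return base, base + diff

        top, worse = rows_for(-34.8, 10.69)
        out = compare([("M1-3", self._fake(top)), ("M1-0", self._fake(worse))])
        assert out[0].model_id == "M1-3" and out[0].delta_elpd == 0.0
        assert out[1].delta_elpd == pytest.approx(-34.8)
        assert out[1].se_delta == pytest.approx(10.69, rel=1e-6)
        assert not out[1].supported

        top, worse = rows_for(-8.1, 4.41)
        out = compare([("M1-1", self._fake(top)), ("M1-0", self._fake(worse))])
        assert out[1].supported

    def test_order_invariance_and_ties(self):
        a = self._fake(np.array([-1.0, -2.0, -1.5]))
        b = self._fake(np.array([-1.2, -1.9, -1.6]))
        out1 = compare([("M1-0", a), ("M1-1", b)])
        out2 = compare([("M1-1", b), ("M1-0", a)])
        assert [r.model_id for r in out1] == [r.model_id for r in out2]
        # identical results tie, broken by registry order, both supported
        out = compare([("M1-1", a), ("M1-0", a)])
        assert [r.model_id for r in out] == ["M1-0", "M1-1"]
        assert all(r.supported for r in out)
        assert all(r.delta_elpd == 0.0 for r in out)

    def test_mismatched_observations_error(self):
        a = self._fake(np.zeros(5))
        b = self._fake(np.zeros(6))
        with pytest.raises(ValueError, match="mismatched"):
            compare([("M1-0", a), ("M1-1", b)])

    def test_frame_layout(self):
        a = self._fake(np.array([-1.0, -2.0]))
        frame = comparison_frame(compare([("M1-0", a)]))
        assert list(frame.columns) == [
            "model", "P_eff", "ELPD", "dELPD", "dELPD_SE", "supported"]


class TestGelmanRubin:
    def test_well_mixed_chains(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 1, size=(4, 2000))
        assert gelman_rubin(draws) < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0, 1, size=(2, 1000))
        draws[1] += 10.0
        assert gelman_rubin(draws) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(np.zeros((1, 100)))

    def test_constant_chains_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            val = gelman_rubin(np.full((3, 100), 2.5))
        assert val == 1.0

    def test_matches_arviz_reference(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        draws = rng.normal(0, 1, size=(3, 500)) + \
            np.array([[0.0], [0.2], [0.1]])
        mine = gelman_rubin(draws)
        ref = float(az.rhat(az.convert_to_dataset(draws))["x"].values)
        assert mine == pytest.approx(ref, abs=0.01)


class TestPpc:
    def test_gross_misfit_p_near_zero(self):
        frame = pd.DataFrame({
            "response": np.random.default_rng(0).normal(10.0, 1.0, 60),
            "clone": "c1", "pool": "p1", "year": 2018, "dev_temp": 20,
        })
        spec = ModelSpec("M1-0", "fitness", "dev20_only",
                         ("intercept",), {}, "shared")
        model = CloneVarianceModel(spec, frame)
        res = model.fit(MCMCSettings(1200, 400, thin=1, n_chains=2, seed=2),
                        fixed_error_sd=1.0)
        res.beta[:] = 0.0          # intercept forced 10 units below the data
        ppc = res.ppc_pvalues(seed=3)
        assert ppc.p_mean < 0.01

    def test_well_specified_p_values_central(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame({
            "response": rng.normal(5.0, 1.0, 80),
            "clone": "c1", "pool": "p1", "year": 2018, "dev_temp": 20,
        })
        spec = ModelSpec("M1-0", "fitness", "dev20_only",
                         ("intercept",), {}, "shared")
        res = CloneVarianceModel(spec, frame).fit(
            MCMCSettings(2000, 500, thin=1, n_chains=2, seed=5))
        ppc = res.ppc_pvalues(seed=6)
        assert 0.2 < ppc.p_mean < 0.8
        assert 0.2 < ppc.p_var < 0.8
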