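"""Bayesian Gaussian hierarchical variance models for clonal designs.

The observation model is

    y_i = x_i' beta + c_clone(i) + p_pool(i) + t_trial(i) + eps_i

with Normal(0, 1000) priors on coefficients and Uniform(0, 100) priors on
the random-effect and error standard deviations. Depending on the model
specification, the clone variance may be shared, pool-specific, or
developmental-temperature-specific, and the error variance shared or
temperature-specific.

Sampling is by Gibbs: conjugate normal updates for the coefficients and
random-effect levels, and univariate slice updates for the standard
deviations under their bounded uniform prior. Chains are initialised
overdispersed from the seed. Observations are sorted into a canonical
internal order before sampling so that posterior draws are invariant to the
row order of the input table; pointwise quantities are reported in the
original row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .registry import MCMCSettings, ModelSpec, PriorSpec, registry
from .results import MCMCResults

__all__ = ["ObservationTable", "CloneVarianceModel"]

_SIGMA_FLOOR = 1e-9


class ObservationTable:
    """Validated observation table for the hierarchical models.

    Required columns: ``response``, ``clone``, ``pool``, ``year`` (2017/2018),
    ``dev_temp`` (20/25); ``trial`` required iff the response is CTmax; any
    pool-level covariate columns must be constant within pool.
    """

    GROUP_COLS = ("clone", "pool", "trial", "year", "dev_temp")

    def __init__(self, frame: pd.DataFrame, response: str = "ctmax"):
        frame = frame.copy()
        needed = ["response", "clone", "pool", "year", "dev_temp"]
        missing = [c for c in needed if c not in frame.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        if response == "ctmax" and "trial" not in frame.columns:
            raise ValueError("CTmax observations require a 'trial' column")
        if not np.isfinite(frame["response"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite response values")
        bad_year = set(frame["year"].unique()) - {2017, 2018}
        if bad_year:
            raise ValueError(f"year values outside {{2017, 2018}}: {bad_year}")
        bad_temp = set(frame["dev_temp"].unique()) - {20, 25}
        if bad_temp:
            raise ValueError(f"dev_temp values outside {{20, 25}}: {bad_temp}")
        n_pools = frame.groupby("clone", observed=True)["pool"].nunique()
        multi = n_pools[n_pools > 1]
        if len(multi):
            raise ValueError(
                f"clones mapped to multiple pools: {list(multi.index)}"
            )
        self.frame = frame
        self.response = response

    def covariate_check(self, columns: tuple[str, ...]) -> None:
        for col in columns:
            if col not in self.frame.columns:
                raise ValueError(f"missing pool covariate column {col!r}")
            nun = self.frame.groupby("pool", observed=True)[col].nunique()
            if (nun > 1).any():
                raise ValueError(f"covariate {col!r} not constant within pool")

    def subset(self, which: str) -> pd.DataFrame:
        if which == "dev20_only":
            return self.frame[self.frame["dev_temp"] == 20].copy()
        return self.frame.copy()


@dataclass
class _RandomTerm:
    name: str
    idx: np.ndarray            # (n,) observation -> level
    n_levels: int
    level_labels: list[str]
    var_group: np.ndarray      # (J,) level -> variance group
    n_groups: int
    group_labels: list[str]    # sigma labels, e.g. "sigma_clone[25]"
    q_per_group: np.ndarray    # levels per variance group


def _slice_sigma(ln_coef: float, S: float, x0: float, hi: float,
                 rng: np.random.Generator) -> float:
    """Slice sample sigma with log density ln_coef*log(s) - S/(2 s^2) on (0, hi)."""
    lo = _SIGMA_FLOOR

    def logf(s: float) -> float:
        return ln_coef * math.log(s) - S / (2.0 * s * s)

    x0 = min(max(x0, lo * 2), hi * (1 - 1e-12))
    logy = logf(x0) + math.log(rng.uniform(1e-300, 1.0))
    # width: near the conditional mode when it exists
    if ln_coef < 0 and S > 0:
        w = max(math.sqrt(S / -ln_coef) * 0.7, 1e-6)
    else:
        w = max(x0, 1e-3)
    L = max(lo, x0 - rng.uniform() * w)
    R = min(hi, L + w)
    for _ in range(60):
        if L <= lo * 1.0000001 or logf(L) < logy:
            break
        L = max(lo, L - w)
    for _ in range(60):
        if R >= hi or logf(R) < logy:
            break
        R = min(hi, R + w)
    for _ in range(200):
        x1 = rng.uniform(L, R)
        if logf(x1) >= logy:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0  # pragma: no cover - shrinkage failed to move


class CloneVarianceModel:
    """One model of the twelve-model family, ready to sample.

    Parameters
    ----------
    spec : ModelSpec
        Which model to fit (see :func:`rockpool.registry.registry`).
    data : ObservationTable or pandas.DataFrame
        Observations; a bare DataFrame is wrapped and validated.
    priors : PriorSpec, optional

    Examples
    --------
    >>> model = CloneVarianceModel.from_registry("M1-1", "ctmax", frame)
    >>> res = model.fit(MCMCSettings(4000, 2000, thin=2, seed=7))
    >>> res.summary()                                      # doctest: +SKIP
    """

    def __init__(self, spec: ModelSpec, data, priors: PriorSpec | None = None):
        if not isinstance(data, ObservationTable):
            data = ObservationTable(data, response=spec.response)
        data.covariate_check(spec.covariate_columns)
        self.spec = spec
        self.priors = priors or PriorSpec()
        self.table = data

        sub = data.subset(spec.data_subset)
        if len(sub) == 0:
            raise ValueError("empty data subset")
        # canonical sort for row-order invariance; keep inverse permutation
        sort_cols = [c for c in ObservationTable.GROUP_COLS if c in sub.columns]
        order = sub.sort_values(sort_cols + ["response"], kind="stable").index
        self._perm = sub.index.get_indexer(order)
        self._inv_perm = np.argsort(self._perm)
        self.data = sub.loc[order].reset_index(drop=True)
        self.y = self.data["response"].to_numpy(dtype=float)
        self.n_obs = len(self.y)

        self._build_design()
        self._build_random_terms()
        self._build_error_groups()

    @classmethod
    def from_registry(cls, model_id: str, response: str, data,
                      priors: PriorSpec | None = None) -> "CloneVarianceModel":
        return cls(registry(model_id, response), data, priors)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, model_id: str,
                       response: str = "ctmax",
                       priors: PriorSpec | None = None) -> "CloneVarianceModel":
        return cls.from_registry(model_id, response, frame, priors)

    # ------------------------------------------------------------------ #
    def _build_design(self) -> None:
        d = self.data
        n = self.n_obs
        year = (d["year"].to_numpy() == 2018).astype(float)
        dev25 = (d["dev_temp"].to_numpy() == 25).astype(float)
        cols: list[np.ndarray] = []
        names: list[str] = []
        # (col, center/scale, absorb target index) for back-transform
        transforms: list[tuple[int, float, float, int]] = []
        col_index: dict[str, int] = {}

        def add(name: str, col: np.ndarray) -> int:
            cols.append(col)
            names.append(name)
            col_index[name] = len(names) - 1
            return len(names) - 1

        for term in self.spec.fixed_terms:
            if term == "intercept":
                add("intercept", np.ones(n))
            elif term == "year":
                add("year_2018", year)
            elif term == "dev_temp":
                add("dev_temp_25", dev25)
            elif term == "intercept_by_dev_temp":
                add("intercept[20]", 1.0 - dev25)
                add("intercept[25]", dev25)
            elif term == "year_by_dev_temp":
                add("year_2018[20]", year * (1.0 - dev25))
                add("year_2018[25]", year * dev25)
            elif term in ("pool_temperature_covariate", "variation_covariate",
                          "predictability_covariate"):
                colname = {
                    "pool_temperature_covariate":
                        self.spec.covariate_columns[0],
                    "variation_covariate": "daily_sd",
                    "predictability_covariate": "predictability_days",
                }[term]
                x = d[colname].to_numpy(dtype=float)
                m, s = x.mean(), x.std() or 1.0
                j = add(colname, (x - m) / s)
                transforms.append((j, m, s, col_index["intercept"]))
            elif term.startswith("dev_temp:"):
                colname = {"dev_temp:variation_covariate": "daily_sd",
                           "dev_temp:predictability_covariate":
                               "predictability_days"}[term]
                x = d[colname].to_numpy(dtype=float)
                m, s = x.mean(), x.std() or 1.0
                j = add(f"dev_temp_25:{colname}", dev25 * (x - m) / s)
                transforms.append((j, m, s, col_index["dev_temp_25"]))
            else:
                raise ValueError(f"unknown fixed term {term!r}")

        self.exog = np.column_stack(cols)
        self.exog_names = names
        k = len(names)
        T = np.eye(k)
        for j, m, s, target in transforms:
            T[j, j] = 1.0 / s
            T[target, j] = -m / s
        self._back_transform = T

    def _factor(self, col: str) -> tuple[np.ndarray, list[str]]:
        codes, uniques = pd.factorize(self.data[col], sort=True)
        return codes.astype(np.int64), [str(u) for u in uniques]

    def _build_random_terms(self) -> None:
        self.random_terms: list[_RandomTerm] = []
        d = self.data
        for name, grouping in self.spec.random_terms.items():
            if name == "clone" and grouping == "by_dev_temp":
                key = d["clone"].astype(str) + "@" + d["dev_temp"].astype(str)
                idx, labels = pd.factorize(key, sort=True)
                temps = np.array([lab.split("@")[1] for lab in labels])
                gidx, gl = pd.factorize(temps, sort=True)
                term = _RandomTerm(
                    name="clone", idx=idx.astype(np.int64),
                    n_levels=len(labels), level_labels=list(labels),
                    var_group=gidx.astype(np.int64), n_groups=len(gl),
                    group_labels=[f"sigma_clone[{g}]" for g in gl],
                    q_per_group=np.bincount(gidx, minlength=len(gl)).astype(float),
                )
            elif name == "clone" and grouping == "by_pool":
                idx, labels = self._factor("clone")
                pool_of_clone = (
                    d.groupby("clone", observed=True)["pool"].first()
                    .astype(str).reindex(labels).to_numpy()
                )
                gidx, gl = pd.factorize(pool_of_clone, sort=True)
                term = _RandomTerm(
                    name="clone", idx=idx, n_levels=len(labels),
                    level_labels=labels,
                    var_group=gidx.astype(np.int64), n_groups=len(gl),
                    group_labels=[f"sigma_clone[{g}]" for g in gl],
                    q_per_group=np.bincount(gidx, minlength=len(gl)).astype(float),
                )
            else:
                if grouping != "shared":
                    raise ValueError(
                        f"unsupported grouping {grouping!r} for term {name!r}"
                    )
                idx, labels = self._factor(name)
                term = _RandomTerm(
                    name=name, idx=idx, n_levels=len(labels),
                    level_labels=labels,
                    var_group=np.zeros(len(labels), dtype=np.int64), n_groups=1,
                    group_labels=[f"sigma_{name}"],
                    q_per_group=np.array([float(len(labels))]),
                )
            if (term.q_per_group < 2).any():
                import warnings
                warnings.warn(
                    f"random term {name!r}: a variance group has < 2 levels; "
                    "its variance is weakly identified",
                    stacklevel=3,
                )
            self.random_terms.append(term)

    def _build_error_groups(self) -> None:
        if self.spec.error_variance_grouping == "by_dev_temp":
            gidx, gl = pd.factorize(self.data["dev_temp"], sort=True)
            self.err_idx = gidx.astype(np.int64)
            self.err_labels = [f"sigma_error[{g}]" for g in gl]
        else:
            self.err_idx = np.zeros(self.n_obs, dtype=np.int64)
            self.err_labels = ["sigma_error"]
        self.n_err_groups = len(self.err_labels)
        self._err_counts = np.bincount(
            self.err_idx, minlength=self.n_err_groups
        ).astype(float)

    # ------------------------------------------------------------------ #
    def fit(self, settings: MCMCSettings,
            fixed_error_sd: float | np.ndarray | None = None) -> MCMCResults:
        """Run the Gibbs sampler and return an :class:`MCMCResults`.

        ``fixed_error_sd`` holds the error SD(s) at a known value (no
        update), used for conjugate validation against closed forms.
        """
        n, k = self.exog.shape
        X = self.exog
        y = self.y
        pri = self.priors
        sd_hi = pri.sd_upper
        ln_coef_re = {"sd": None, "variance": None}
        S_total = settings.n_retained_per_chain
        C = settings.n_chains

        beta_out = np.empty((C, S_total, k))
        u_out = {t.name: np.empty((C, S_total, t.n_levels))
                 for t in self.random_terms}
        sig_out = {t.name: np.empty((C, S_total, t.n_groups))
                   for t in self.random_terms}
        sige_out = np.empty((C, S_total, self.n_err_groups))

        fixed_e = None
        if fixed_error_sd is not None:
            fixed_e = np.broadcast_to(
                np.asarray(fixed_error_sd, dtype=float), (self.n_err_groups,)
            ).copy()

        prior_prec = np.eye(k) / pri.coef_variance
        prior_mean_term = pri.coef_mean / pri.coef_variance
        sd_y = y.std() or 1.0
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)

        ss = np.random.SeedSequence(settings.seed)
        child_seeds = ss.spawn(C)

        def ln_coef(q: float) -> float:
            # exponent on log(sigma) in the conditional density
            return -q if pri.scale_on == "sd" else 1.0 - q

        for c in range(C):
            rng = np.random.default_rng(child_seeds[c])
            beta = beta_ols + rng.standard_normal(k) * sd_y * 0.5
            u = [np.zeros(t.n_levels) for t in self.random_terms]
            sig = [
                np.clip(sd_y * 10 ** rng.uniform(-1.0, 0.5), 1e-4, sd_hi * 0.5)
                * np.ones(t.n_groups)
                for t in self.random_terms
            ]
            if fixed_e is not None:
                sige = fixed_e.copy()
            else:
                sige = np.clip(
                    sd_y * 10 ** rng.uniform(-0.7, 0.5, self.n_err_groups),
                    1e-4, sd_hi * 0.5,
                )
            fitted_random = np.zeros(n)
            for t, ut in zip(self.random_terms, u):
                fitted_random += ut[t.idx]

            s_out = 0
            for it in range(settings.n_iterations):
                w = 1.0 / (sige[self.err_idx] ** 2)
                # --- coefficients (conjugate) ---
                r = y - fitted_random
                Xw = X * w[:, None]
                A = Xw.T @ X + prior_prec
                b = Xw.T @ r + prior_mean_term
                L = linalg.cholesky(A, lower=True)
                mean = linalg.cho_solve((L, True), b)
                z = rng.standard_normal(k)
                beta = mean + linalg.solve_triangular(L.T, z, lower=False)
                mu_fixed = X @ beta
                base = y - mu_fixed
                # --- random-effect levels (conjugate) ---
                for ti, t in enumerate(self.random_terms):
                    fitted_random -= u[ti][t.idx]
                    rt = base - fitted_random
                    sw = np.bincount(t.idx, weights=w, minlength=t.n_levels)
                    swr = np.bincount(t.idx, weights=w * rt,
                                      minlength=t.n_levels)
                    prec = sw + 1.0 / (sig[ti][t.var_group] ** 2)
                    mean_u = swr / prec
                    u[ti] = mean_u + rng.standard_normal(t.n_levels) / np.sqrt(prec)
                    fitted_random += u[ti][t.idx]
                # --- random-effect scales (slice) ---
                for ti, t in enumerate(self.random_terms):
                    Sg = np.bincount(t.var_group, weights=u[ti] ** 2,
                                     minlength=t.n_groups)
                    for g in range(t.n_groups):
                        sig[ti][g] = _slice_sigma(
                            ln_coef(t.q_per_group[g]), float(Sg[g]),
                            sig[ti][g], sd_hi, rng,
                        )
                # --- error scales (slice) ---
                if fixed_e is None:
                    resid = base - fitted_random
                    Se = np.bincount(self.err_idx, weights=resid ** 2,
                                     minlength=self.n_err_groups)
                    for g in range(self.n_err_groups):
                        sige[g] = _slice_sigma(
                            ln_coef(self._err_counts[g]), float(Se[g]),
                            sige[g], sd_hi, rng,
                        )
                # --- retain ---
                if it >= settings.n_burn_in:
                    j = it - settings.n_burn_in
                    if j % settings.thin == 0 and s_out < S_total:
                        beta_out[c, s_out] = beta
                        for ti, t in enumerate(self.random_terms):
                            u_out[t.name][c, s_out] = u[ti]
                            sig_out[t.name][c, s_out] = sig[ti]
                        sige_out[c, s_out] = sige
                        s_out += 1

        return MCMCResults(
            model=self,
            beta=beta_out,
            random_effects=u_out,
            sigma_random=sig_out,
            sigma_error=sige_out,
            settings=settings,
            fixed_error_sd=fixed_e,
        )
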