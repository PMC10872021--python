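"""Posterior results container for the hierarchical variance models.

`MCMCResults` carries the retained draws organised by chain, knows how to
summarise them (posterior means, medians, 95% credible intervals, split
R-hat), exports the pointwise conditional log-likelihood for LOO, runs
posterior predictive checks, and derives broad-sense heritability and
temperature contrasts.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import heritability as h2mod
from .diagnostics import PpcResult, gelman_rubin
from .loo import LOOResult, psis_loo

__all__ = ["MCMCResults"]


class MCMCResults:
    """Draws and derived quantities from one fitted model.

    Attributes
    ----------
    beta : ndarray, shape (chains, draws, k)
        Fixed-effect draws on the internal (centred/scaled) design scale.
    random_effects : dict of ndarray (chains, draws, n_levels)
    sigma_random : dict of ndarray (chains, draws, n_variance_groups)
    sigma_error : ndarray (chains, draws, n_error_groups)
    """

    def __init__(self, model, beta, random_effects, sigma_random,
                 sigma_error, settings, fixed_error_sd=None):
        self.model = model
        self.spec = model.spec
        self.beta = beta
        self.random_effects = random_effects
        self.sigma_random = sigma_random
        self.sigma_error = sigma_error
        self.settings = settings
        self.fixed_error_sd = fixed_error_sd
        self.n_chains, self.n_draws_per_chain, self.k = beta.shape

    # ------------------------------------------------------------------ #
    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_draws_per_chain

    def beta_original(self) -> np.ndarray:
        """Coefficient draws back-transformed to the original covariate scale,
        flattened over chains: shape (n_draws, k)."""
        flat = self.beta.reshape(-1, self.k)
        return flat @ self.model._back_transform.T

    def param_draws(self) -> dict[str, np.ndarray]:
        """Scalar parameters as name -> (chains, draws) arrays.

        Coefficients are reported on the original scale; scale parameters
        are the random-effect and error SDs.
        """
        out: dict[str, np.ndarray] = {}
        T = self.model._back_transform
        beta_orig = np.einsum("csk,jk->csj", self.beta, T)
        for j, name in enumerate(self.model.exog_names):
            out[name] = beta_orig[:, :, j]
        for term in self.model.random_terms:
            arr = self.sigma_random[term.name]
            for g, label in enumerate(term.group_labels):
                out[label] = arr[:, :, g]
        for g, label in enumerate(self.model.err_labels):
            if self.fixed_error_sd is None:
                out[label] = self.sigma_error[:, :, g]
        return out

    def rhat(self) -> dict[str, float]:
        """Split-chain Gelman-Rubin statistic per parameter."""
        return {name: gelman_rubin(d) for name, d in self.param_draws().items()}

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd, median, 95% CI, R-hat."""
        rows = []
        rhats = self.rhat()
        for name, d in self.param_draws().items():
            flat = d.ravel()
            lo, med, hi = np.quantile(flat, [0.025, 0.5, 0.975])
            rows.append({
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "median": med,
                "ci_2.5": lo,
                "ci_97.5": hi,
                "rhat": rhats.get(name, np.nan),
            })
        return pd.DataFrame(rows).set_index("parameter")

    # ------------------------------------------------------------------ #
    def _conditional_means(self) -> np.ndarray:
        """Fitted mean per draw and observation (canonical order), (S, n)."""
        mu = self.beta.reshape(-1, self.k) @ self.model.exog.T
        for term in self.model.random_terms:
            u = self.random_effects[term.name].reshape(-1, term.n_levels)
            mu += u[:, term.idx]
        return mu

    def _error_sd_per_obs(self) -> np.ndarray:
        sige = self.sigma_error.reshape(-1, self.model.n_err_groups)
        return sige[:, self.model.err_idx]

    def pointwise_loglik(self) -> np.ndarray:
        """Conditional log-likelihood, (total draws x observations).

        Entry (s, i) is the log normal density of observation i given draw
        s's coefficients, its sampled random-effect levels, and the error SD
        of observation i's group. Columns follow the input row order of the
        fitted data subset.
        """
        mu = self._conditional_means()
        sd = self._error_sd_per_obs()
        y = self.model.y[None, :]
        ll = (
            -0.5 * math.log(2.0 * math.pi)
            - np.log(sd)
            - 0.5 * ((y - mu) / sd) ** 2
        )
        return ll[:, self.model._inv_perm]

    def loo(self) -> LOOResult:
        """PSIS-LOO of this fit."""
        return psis_loo(self.pointwise_loglik())

    # ------------------------------------------------------------------ #
    def _ppc(self, seed: int, redraw_random_effects: bool = False) -> PpcResult:
        rng = np.random.default_rng(seed)
        S = self.n_draws
        n = self.model.n_obs
        if redraw_random_effects:
            mu = self.beta.reshape(-1, self.k) @ self.model.exog.T
            for term in self.model.random_terms:
                sig = self.sigma_random[term.name].reshape(-1, term.n_groups)
                u_new = (
                    rng.standard_normal((S, term.n_levels))
                    * sig[:, term.var_group]
                )
                mu += u_new[:, term.idx]
        else:
            mu = self._conditional_means()
        sd = self._error_sd_per_obs()
        y_rep = mu + rng.standard_normal((S, n)) * sd
        y = self.model.y
        p_mean = float((y_rep.mean(axis=1) >= y.mean()).mean())
        p_var = float((y_rep.var(axis=1, ddof=1) >= y.var(ddof=1)).mean())
        return PpcResult(p_mean=p_mean, p_var=p_var)

    def ppc_pvalues(self, seed: int = 0,
                    redraw_random_effects: bool = False) -> PpcResult:
        """Bayesian p-values of the response mean and variance."""
        return self._ppc(seed=seed, redraw_random_effects=redraw_random_effects)

    # ------------------------------------------------------------------ #
    def _sigma_flat(self, component: str, label: str) -> np.ndarray:
        if component == "error":
            try:
                g = self.model.err_labels.index(label)
            except ValueError:
                raise KeyError(
                    f"no error group {label!r}; available: {self.model.err_labels}"
                ) from None
            return self.sigma_error[:, :, g].ravel()
        for term in self.model.random_terms:
            if term.name == component:
                try:
                    g = term.group_labels.index(label)
                except ValueError:
                    raise KeyError(
                        f"no {component} group {label!r}; "
                        f"available: {term.group_labels}"
                    ) from None
                return self.sigma_random[component][:, :, g].ravel()
        raise KeyError(f"model has no random term {component!r}")

    def _resolve_group(self, group: str) -> tuple[str, str]:
        """Map a user group label to (clone sigma label, error sigma label)."""
        clone_term = next(
            (t for t in self.model.random_terms if t.name == "clone"), None
        )
        if clone_term is None:
            raise KeyError("model has no clone random effect")
        group = str(group)
        if len(clone_term.group_labels) == 1:
            clone_label = clone_term.group_labels[0]
            if group not in ("all", "shared"):
                raise KeyError(
                    "clone variance is shared; use group='all' "
                    f"(got {group!r})"
                )
        else:
            clone_label = f"sigma_clone[{group}]"
            if clone_label not in clone_term.group_labels:
                avail = [
                    lab.split("[")[1].rstrip("]")
                    for lab in clone_term.group_labels
                ]
                raise KeyError(
                    f"no clone variance group {group!r}; available: {avail}"
                )
        if len(self.model.err_labels) == 1:
            err_label = self.model.err_labels[0]
        else:
            err_label = f"sigma_error[{group}]"
            if err_label not in self.model.err_labels:
                err_label = self.model.err_labels[0]
        return clone_label, err_label

    def heritability(self, group: str = "all") -> h2mod.HeritabilityEstimate:
        """Broad-sense H2 = Vclone/(Vclone + Verror) for one group.

        ``group`` is a developmental temperature ("20"/"25") for models with
        temperature-specific variances, a pool id for pool-specific genetic
        variances, or "all" for shared-variance models. Trial variance is
        excluded from the denominator.
        """
        clone_label, err_label = self._resolve_group(group)
        return h2mod.heritability_from_draws(
            group,
            self._sigma_flat("clone", clone_label),
            self._sigma_flat("error", err_label),
        )

    def temperature_contrast(
        self, per_draw_percent: bool = False
    ) -> h2mod.TemperatureContrast:
        """20 vs 25 degC contrast of V_G, V_E and H2.

        Requires a model whose clone or error variance is grouped by
        developmental temperature.
        """
        clone_term = next(
            (t for t in self.model.random_terms if t.name == "clone"), None
        )
        by_temp = (
            clone_term is not None and len(clone_term.group_labels) > 1
            and "[20]" in "".join(clone_term.group_labels)
        ) or len(self.model.err_labels) > 1
        if not by_temp:
            raise ValueError(
                "no contrast exists under this specification: neither the "
                "clone nor the error variance is grouped by developmental "
                "temperature"
            )
        return h2mod.contrast_from_draws(
            self.heritability("20"), self.heritability("25"),
            per_draw_percent=per_draw_percent,
        )

    # ------------------------------------------------------------------ #
    def save(self, directory: str | Path) -> Path:
        """Serialise draws to CSV columns plus a JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cols = {}
        for name, d in self.param_draws().items():
            cols[name] = d.ravel()
        frame = pd.DataFrame(cols)
        frame.insert(0, "chain", np.repeat(
            np.arange(self.n_chains), self.n_draws_per_chain))
        frame.insert(1, "draw", np.tile(
            np.arange(self.n_draws_per_chain), self.n_chains))
        frame.to_csv(directory / "draws.csv", index=False)
        meta = {
            "model_id": self.spec.model_id,
            "response": self.spec.response,
            "n_chains": self.n_chains,
            "n_draws_per_chain": self.n_draws_per_chain,
            "settings": {
                "n_iterations": self.settings.n_iterations,
                "n_burn_in": self.settings.n_burn_in,
                "thin": self.settings.thin,
                "n_chains": self.settings.n_chains,
                "seed": self.settings.seed,
            },
            "parameters": list(cols),
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
        return directory
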