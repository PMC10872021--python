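"""The frozen twelve-model registry of hierarchical variance models.

Three model sets address three questions for either response (CTmax in degC,
or fitness as per-day intrinsic rate of increase r):

* **M1-0 ... M1-4** (individuals developed at 20 degC only): is there genetic
  (among-clone) variation, among-pool variation, microgeographic adaptation
  to pool temperature, or among-pool differences in genetic variance?
* **M2-0 ... M2-3** (both developmental temperatures): is there developmental
  plasticity, and does plasticity track daily temperature variation or its
  predictability in the pool of origin?
* **M3-0 ... M3-3** (both temperatures, no pool-level terms): does
  developmental temperature change the genetic (clone) and/or nongenetic
  (residual) variance, and hence broad-sense heritability?

Every model is a Gaussian linear mixed model; the registry is pure data
mapping a model id to its fixed-effect terms, random terms with their
variance grouping, the error-variance grouping, and the data subset.
The CTmax assay-batch ("trial") random effect applies only to the CTmax
response; fitness models drop it. The pool-temperature covariate of M1-3 is
the hottest-month mean daily maximum for CTmax, and |mean pool temperature
- 20 degC| for fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "MCMCSettings",
    "MODEL_IDS",
    "registry",
    "default_settings",
]

MODEL_IDS = (
    "M1-0", "M1-1", "M1-2", "M1-3", "M1-4",
    "M2-0", "M2-1", "M2-2", "M2-3",
    "M3-0", "M3-1", "M3-2", "M3-3",
)

#: covariate column used by M1-3, per response
POOL_TEMP_COVARIATE = {
    "ctmax": "hottest_month_mean_daily_max",
    "fitness": "abs_mean_minus_20",
}
VARIATION_COVARIATE = "daily_sd"
PREDICTABILITY_COVARIATE = "predictability_days"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model in the family."""

    model_id: str
    response: str                       # "ctmax" | "fitness"
    data_subset: str                    # "dev20_only" | "both_temps"
    fixed_terms: tuple[str, ...]        # design-matrix terms, in order
    random_terms: dict[str, str]        # term -> "shared"|"by_pool"|"by_dev_temp"
    error_variance_grouping: str        # "shared" | "by_dev_temp"

    def __post_init__(self) -> None:
        if self.response not in ("ctmax", "fitness"):
            raise ValueError(f"unknown response {self.response!r}")
        if "trial" in self.random_terms and self.response != "ctmax":
            raise ValueError("trial random effect applies only to CTmax")

    @property
    def covariate_columns(self) -> tuple[str, ...]:
        cols = []
        for term in self.fixed_terms:
            if term == "pool_temperature_covariate":
                cols.append(POOL_TEMP_COVARIATE[self.response])
            elif term.endswith("variation_covariate"):
                cols.append(VARIATION_COVARIATE)
            elif term.endswith("predictability_covariate"):
                cols.append(PREDICTABILITY_COVARIATE)
        return tuple(dict.fromkeys(cols))


@dataclass(frozen=True)
class PriorSpec:
    """Vague priors: Normal(0, var 1000) coefficients; Uniform(0, 100) scales.

    ``scale_on`` selects whether the uniform prior sits on the standard
    deviations (default, the common JAGS idiom) or on the variances.
    """

    coef_mean: float = 0.0
    coef_variance: float = 1000.0
    scale_upper: float = 100.0
    scale_on: str = "sd"

    def __post_init__(self) -> None:
        if self.scale_on not in ("sd", "variance"):
            raise ValueError("scale_on must be 'sd' or 'variance'")
        if self.coef_variance <= 0 or self.scale_upper <= 0:
            raise ValueError("prior scales must be positive")

    @property
    def sd_upper(self) -> float:
        """Upper bound implied for standard deviations."""
        return self.scale_upper if self.scale_on == "sd" else self.scale_upper ** 0.5


@dataclass(frozen=True)
class MCMCSettings:
    n_iterations: int
    n_burn_in: int
    thin: int = 1
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations <= self.n_burn_in:
            raise ValueError("n_iterations must exceed n_burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.n_burn_in) // self.thin


def default_settings(model_id: str, seed: int = 0) -> MCMCSettings:
    """The published run lengths, by model complexity class."""
    if model_id in ("M1-0", "M1-1", "M1-2", "M1-3"):
        return MCMCSettings(10_000, 5_000, thin=5, n_chains=3, seed=seed)
    if model_id == "M1-4":
        return MCMCSettings(30_000, 25_000, thin=5, n_chains=3, seed=seed)
    if model_id in MODEL_IDS:
        return MCMCSettings(75_000, 25_000, thin=50, n_chains=3, seed=seed)
    raise KeyError(f"unknown model id {model_id!r}")


def _with_trial(random_terms: dict[str, str], response: str) -> dict[str, str]:
    if response == "ctmax":
        return {**random_terms, "trial": "shared"}
    return dict(random_terms)


def registry(model_id: str, response: str = "ctmax") -> ModelSpec:
    """Look up the frozen specification of one model.

    Raises ``KeyError`` listing the valid ids if ``model_id`` is unknown.
    """
    if model_id not in MODEL_IDS:
        raise KeyError(
            f"unknown model id {model_id!r}; valid ids: {', '.join(MODEL_IDS)}"
        )
    fam = model_id.split("-")[0]

    if fam == "M1":
        subset = "dev20_only"
        fixed = ("intercept", "year")
        rand: dict[str, str] = {}
        if model_id in ("M1-1", "M1-2", "M1-3"):
            rand["clone"] = "shared"
        if model_id in ("M1-2", "M1-3"):
            rand["pool"] = "shared"
        if model_id == "M1-3":
            fixed = fixed + ("pool_temperature_covariate",)
        if model_id == "M1-4":
            rand["clone"] = "by_pool"
        return ModelSpec(
            model_id, response, subset, fixed,
            _with_trial(rand, response), "shared",
        )

    if fam == "M2":
        fixed = ("intercept", "year")
        if model_id in ("M2-1", "M2-2", "M2-3"):
            fixed = fixed + ("dev_temp",)
        if model_id == "M2-2":
            fixed = fixed + ("variation_covariate", "dev_temp:variation_covariate")
        if model_id == "M2-3":
            fixed = fixed + (
                "predictability_covariate", "dev_temp:predictability_covariate",
            )
        rand = {"clone": "shared", "pool": "shared"}
        return ModelSpec(
            model_id, response, "both_temps", fixed,
            _with_trial(rand, response), "shared",
        )

    # M3 family: built from M1-1 (no pool term); intercept and year are
    # estimated separately within each developmental temperature.
    fixed = ("intercept_by_dev_temp", "year_by_dev_temp")
    clone_grouping = "by_dev_temp" if model_id in ("M3-2", "M3-3") else "shared"
    err_grouping = "by_dev_temp" if model_id in ("M3-1", "M3-3") else "shared"
    rand = {"clone": clone_grouping}
    return ModelSpec(
        model_id, response, "both_temps", fixed,
        _with_trial(rand, response), err_grouping,
    )
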