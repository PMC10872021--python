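"""CSV readers/writers, TOML configuration, and the pipeline driver.

All tabular I/O is comma-separated UTF-8 with a mandatory header row and
"." as the decimal separator; dates are ISO-8601 and day-of-year is
1-based. Columns beyond the documented schema are ignored with a logged
notice so deposited files with extra columns read cleanly. Readers raise
errors carrying file and line context; every pipeline run directory gets a
JSON manifest (input digests, config snapshot, seeds, timings, warnings)
sufficient to re-run it.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lifehistory import BroodEvent, IndividualRecord, fitness_table
from .loo import compare, comparison_frame
from .model import CloneVarianceModel
from .registry import MCMCSettings, default_settings
from .thermal import TemperatureSeries, fit_gls_quadratic, summarize_pool

__all__ = [
    "RunManifest",
    "read_temperature_csv",
    "read_phenotype_csv",
    "write_phenotype_csv",
    "write_climate_csv",
    "read_config",
    "pipeline_run",
]

logger = logging.getLogger(__name__)

_TEMP_COLS = {"pool_id", "date", "daily_max_c", "daily_mean_c"}
_PHENO_COLS = {
    "individual_id", "clone_id", "pool_id", "year", "dev_temp_c",
    "age_first_brood_d", "size_first_brood", "age_second_brood_d",
    "size_second_brood", "days_monitored", "trial_id", "ctmax_c",
}


class CsvFormatError(ValueError):
    """Malformed input file; message carries file and line context."""


def _check_columns(frame: pd.DataFrame, required: set, path: Path,
                   mapping: dict[str, str] | None = None) -> pd.DataFrame:
    if mapping:
        frame = frame.rename(columns={v: k for k, v in mapping.items()})
    missing = required - set(frame.columns)
    if missing:
        raise CsvFormatError(
            f"{path}: missing required columns: {sorted(missing)}"
        )
    extra = set(frame.columns) - required
    if extra:
        logger.info("%s: ignoring extra columns %s", path, sorted(extra))
    return frame


def read_temperature_csv(
    path: str | Path, column_mapping: dict[str, str] | None = None
) -> list[TemperatureSeries]:
    """Read per-pool logger series; one series per pool, sorted by pool id.

    ``column_mapping`` maps schema names to the file's column names, for
    deposited files with different headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    frame = _check_columns(frame, _TEMP_COLS, path, column_mapping)
    days = []
    for lineno, value in zip(frame.index + 2, frame["date"]):
        try:
            d = datetime.date.fromisoformat(str(value))
        except ValueError:
            raise CsvFormatError(
                f"{path}:{lineno}: unparseable ISO date {value!r}"
            ) from None
        days.append(d.timetuple().tm_yday)
    frame = frame.assign(_day=days, _line=frame.index + 2)
    dup = frame.duplicated(subset=["pool_id", "date"], keep=False)
    if dup.any():
        lines = frame.loc[dup, "_line"].tolist()
        raise CsvFormatError(
            f"{path}: duplicated (pool_id, date) rows at lines {lines}"
        )
    out = []
    for pool_id, grp in frame.groupby("pool_id", sort=True):
        grp = grp.sort_values("_day")
        out.append(TemperatureSeries(
            pool_id=str(pool_id),
            day=grp["_day"].to_numpy(dtype=float),
            daily_max=grp["daily_max_c"].to_numpy(dtype=float),
            daily_mean=grp["daily_mean_c"].to_numpy(dtype=float),
        ))
    return out


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) \
            or value == "":
        return None
    return float(value)


def read_phenotype_csv(
    path: str | Path, column_mapping: dict[str, str] | None = None
) -> list[IndividualRecord]:
    """Read individual phenotype/life-history records.

    Empty cells become absent fields; extra brood columns beyond the second
    are ignored. dev_temp must be 20 or 25; negative ages or sizes error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    frame = _check_columns(frame, _PHENO_COLS, path, column_mapping)
    records = []
    for i, row in frame.iterrows():
        lineno = i + 2
        ctx = f"{path}:{lineno}"
        dev = int(row["dev_temp_c"])
        if dev not in (20, 25):
            raise CsvFormatError(f"{ctx}: dev_temp_c must be 20 or 25, got {dev}")
        broods = []
        for acol, scol in (("age_first_brood_d", "size_first_brood"),
                           ("age_second_brood_d", "size_second_brood")):
            age = _opt_float(row[acol])
            size = _opt_float(row[scol])
            if age is None:
                continue
            if age <= 0 or (size is not None and size < 0):
                raise CsvFormatError(
                    f"{ctx}: negative or zero age/size in {acol}/{scol}"
                )
            broods.append(BroodEvent(age, int(size or 0)))
        trial = row.get("trial_id")
        trial = None if pd.isna(trial) or trial == "" else str(trial)
        try:
            rec = IndividualRecord(
                individual_id=str(row["individual_id"]),
                clone_id=str(row["clone_id"]),
                pool_id=str(row["pool_id"]),
                year=int(row["year"]),
                dev_temp=dev,
                broods=tuple(broods),
                days_monitored=float(row["days_monitored"]),
                ctmax=_opt_float(row["ctmax_c"]),
                trial_id=trial,
            )
        except ValueError as exc:
            raise CsvFormatError(f"{ctx}: {exc}") from None
        records.append(rec)
    return records


def write_phenotype_csv(records: list[IndividualRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        b = list(r.broods) + [None, None]
        rows.append({
            "individual_id": r.individual_id,
            "clone_id": r.clone_id,
            "pool_id": r.pool_id,
            "year": r.year,
            "dev_temp_c": r.dev_temp,
            "age_first_brood_d": b[0].age_days if b[0] else "",
            "size_first_brood": b[0].brood_size if b[0] else "",
            "age_second_brood_d": b[1].age_days if b[1] else "",
            "size_second_brood": b[1].brood_size if b[1] else "",
            "days_monitored": r.days_monitored,
            "trial_id": r.trial_id if r.trial_id is not None else "",
            "ctmax_c": r.ctmax if r.ctmax is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_climate_csv(climates, path: str | Path) -> None:
    pd.DataFrame([{
        "pool_id": c.pool_id,
        "mean_daily_mean": c.mean_daily_mean,
        "hottest_month_mean_daily_max": c.hottest_month_mean_daily_max,
        "daily_sd": c.daily_sd,
        "predictability_days": c.predictability_days,
        "seasonal_range": c.seasonal_range,
    } for c in climates]).to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    """Read a TOML pipeline configuration."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


@dataclass
class RunManifest:
    """Provenance record written alongside every pipeline run."""

    input_digests: dict[str, str]
    config: dict
    seed: int
    version: str
    stages: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, directory: str | Path) -> Path:
        path = Path(directory) / "manifest.json"
        path.write_text(json.dumps({
            "input_digests": self.input_digests,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "warnings": self.warnings,
        }, indent=2, default=str))
        return path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge_climate(fit_frame: pd.DataFrame, climate: pd.DataFrame) -> pd.DataFrame:
    clim = climate.rename(columns={"pool_id": "pool"}).set_index("pool")
    clim = clim.assign(abs_mean_minus_20=(clim["mean_daily_mean"] - 20.0).abs())
    merged = fit_frame.join(clim, on="pool")
    return merged


def pipeline_run(config: dict, out_dir: str | Path) -> RunManifest:
    """Run metrics -> fitness -> fit -> compare -> h2 end to end.

    ``config`` keys: ``inputs.temperature_csv``, ``inputs.phenotype_csv``,
    ``pipeline.response`` ("ctmax"/"fitness"), ``pipeline.models`` (list of
    model ids), ``pipeline.seed``, optional ``pipeline.hottest_month`` and
    ``mcmc`` setting overrides. Outputs and one manifest are written to
    ``out_dir``; a stage failure aborts with prior outputs intact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = config.get("inputs", {})
    temp_path = Path(inputs["temperature_csv"])
    pheno_path = Path(inputs["phenotype_csv"])
    for p in (temp_path, pheno_path):
        if not p.exists():
            raise FileNotFoundError(f"input file missing: {p}")
    pipe = config.get("pipeline", {})
    response = pipe.get("response", "ctmax")
    model_ids = pipe.get("models", ["M1-0", "M1-1"])
    seed = int(pipe.get("seed", 0))
    month = pipe.get("hottest_month", 8)
    mcmc_cfg = config.get("mcmc", {})

    manifest = RunManifest(
        input_digests={str(temp_path): _digest(temp_path),
                       str(pheno_path): _digest(pheno_path)},
        config=config, seed=seed, version=__version__,
    )

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest.stages[name] = round(time.perf_counter() - t0, 3)
            return out
        return deco

    # metrics
    def _metrics():
        series = read_temperature_csv(temp_path)
        climates = []
        for s in series:
            fit = fit_gls_quadratic(s)
            if not fit.converged:
                manifest.warnings.append(f"pool {s.pool_id}: GLS not converged")
                continue
            climates.append(summarize_pool(s, fit, month))
        write_climate_csv(climates, out_dir / "climate.csv")
        return pd.read_csv(out_dir / "climate.csv")
    climate = stage("metrics")(_metrics)

    # fitness
    def _fitness():
        records = read_phenotype_csv(pheno_path)
        table, excluded = fitness_table(records)
        table.to_csv(out_dir / "fitness.csv", index=False)
        (out_dir / "fitness_exclusions.json").write_text(
            json.dumps(dict(excluded)))
        if response == "ctmax":
            rows = [{
                "response": r.ctmax, "clone": r.clone_id, "pool": r.pool_id,
                "year": r.year, "dev_temp": r.dev_temp, "trial": r.trial_id,
            } for r in records
                if r.ctmax is not None and any(
                    b.brood_size >= 1 for b in r.broods)]
            obs = pd.DataFrame(rows)
        else:
            obs = table.rename(
                columns={"r": "response", "clone_id": "clone",
                         "pool_id": "pool"}
            )[["response", "clone", "pool", "year", "dev_temp"]]
        return _merge_climate(obs, climate)
    obs = stage("fitness")(_fitness)

    # fit
    def _fit():
        results = {}
        for mid in model_ids:
            settings = default_settings(mid, seed=seed)
            if mcmc_cfg:
                settings = MCMCSettings(
                    n_iterations=mcmc_cfg.get(
                        "n_iterations", settings.n_iterations),
                    n_burn_in=mcmc_cfg.get("n_burn_in", settings.n_burn_in),
                    thin=mcmc_cfg.get("thin", settings.thin),
                    n_chains=mcmc_cfg.get("n_chains", settings.n_chains),
                    seed=seed,
                )
            model = CloneVarianceModel.from_registry(mid, response, obs)
            res = model.fit(settings)
            res.save(out_dir / "draws" / mid)
            res.summary().to_csv(out_dir / "draws" / mid / "summary.csv")
            results[mid] = res
        return results
    results = stage("fit")(_fit)

    # compare
    def _compare():
        rows = compare([(mid, r.loo()) for mid, r in results.items()])
        comparison_frame(rows).to_csv(out_dir / "comparison.csv", index=False)
        return rows
    stage("compare")(_compare)

    # h2
    def _h2():
        rows = []
        for mid, res in results.items():
            clone_term = [t for t in res.model.random_terms
                          if t.name == "clone"]
            if not clone_term:
                continue
            groups = (
                [lab.split("[")[1].rstrip("]")
                 for lab in clone_term[0].group_labels]
                if clone_term[0].n_groups > 1 else ["all"]
            )
            for g in groups:
                est = res.heritability(g)
                rows.append({
                    "model": mid, "group": est.group,
                    "Vg_med": est.v_g[0], "Vg_lo": est.v_g[1],
                    "Vg_hi": est.v_g[2],
                    "Ve_med": est.v_e[0], "Ve_lo": est.v_e[1],
                    "Ve_hi": est.v_e[2],
                    "H2_med": est.h2[0], "H2_lo": est.h2[1],
                    "H2_hi": est.h2[2],
                })
        pd.DataFrame(rows).to_csv(out_dir / "h2.csv", index=False)
    stage("h2")(_h2)

    manifest.write(out_dir)
    return manifest
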