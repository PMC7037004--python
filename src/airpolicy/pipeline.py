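"""End-to-end orchestration: ingest -> prepost -> select -> fit -> report.

Each station is analysed independently (the study fits one model per
monitoring station). A run directory collects every stage's output plus a
manifest with the config hash, the seed, and a checksum per artifact, so a
rerun with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import prepost as prepost_mod
from .data_model import (
    DailySeries,
    assemble_regressors,
    build_calendar,
    build_date_index,
    daily_wind_quadrants,
    log_transform,
    read_long_csv,
    read_station_metadata,
)
from .intervention import estimate_policy, report_effects
from .selection import (
    CvPlan,
    assemble_final_spec,
    select_counterfactual,
    select_harmonics,
    smoothed_disturbances,
    stepwise_residual_screen,
    STEPWISE_TERMS,
)
from .ssm import BsmSpec, SeasonalSpec, fit_ml, fit_summary
from .synthetic_data import SimScenario, simulate_study, write_study

logger = logging.getLogger("airpolicy")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    data_csv: str | None = None
    stations_csv: str | None = None
    simulate: bool = False
    start: str = "2014-01-01"
    end: str = "2019-09-30"
    policy_date: str = "2019-02-25"
    pollutant: str = "NOx"
    train_end: str = "2018-02-24"
    test_start: str = "2018-02-25"
    test_end: str = "2019-02-24"
    h_max: int = 10
    prepost_window: str = "02-25:09-30"
    treat_year: int = 2019
    control_years: tuple[int, ...] = (2014, 2015, 2016, 2017, 2018)
    tolerance: float = 0.02
    harmonics: int | None = None        # None -> run step 1
    counterfactual: str | None = None   # None -> run step 2
    seed: int = 0
    outdir: str = "run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "control_years" in raw:
            raw["control_years"] = tuple(raw["control_years"])
        return cls(**raw)

    def cv_plan(self) -> CvPlan:
        return CvPlan(self.train_end, self.test_start, self.test_end, self.h_max)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(config: RunConfig):
    """Read (or simulate) the raw data and assemble the analysis inputs.

    Returns (target_log, candidates_log, regressors_without_counterfactual,
    target_raw, candidates_raw).
    """
    if config.simulate:
        scenario = SimScenario(
            start=config.start, end=config.end,
            policy_date=config.policy_date, seed=config.seed,
        )
        study = simulate_study(scenario)
        outdir = os.path.join(config.outdir, "simulated_input")
        write_study(study, outdir)
        config = dataclasses.replace(config, data_csv=os.path.join(outdir, "data.csv"),
                                     stations_csv=os.path.join(outdir, "stations.csv"))
    if config.data_csv is None or config.stations_csv is None:
        raise ValueError("either --simulate or data/stations CSV paths are required")

    series = read_long_csv(config.data_csv)
    meta = read_station_metadata(config.stations_csv)
    index = build_date_index(config.start, config.end)

    air = meta[meta["kind"] == "air_quality"]
    targets = air[air["role"] == "milan"].index
    cf_ids = air[air["role"] == "counterfactual"].index
    pollutant = config.pollutant
    missing = [sid for sid in list(targets) + list(cf_ids) if (sid, pollutant) not in series]
    if missing:
        raise ValueError(f"{config.data_csv}: no {pollutant!r} series for stations {missing}")

    target_raw = {sid: series[(sid, pollutant)].reindex(index) for sid in targets}
    cand_raw = {sid: series[(sid, pollutant)].reindex(index) for sid in cf_ids}
    target_log = {sid: log_transform(s) for sid, s in target_raw.items()}
    cand_log = {sid: log_transform(s) for sid, s in cand_raw.items()}

    weather_ids = meta[meta["kind"] == "weather"].index
    by_var = lambda var: {sid: series[(sid, var)].reindex(index)
                          for sid in weather_ids if (sid, var) in series}
    calendar = build_calendar(index)
    quads = None
    dirs, spds = by_var("wind_direction"), by_var("wind_speed")
    if dirs and spds:
        quads = daily_wind_quadrants(dirs, spds).reindex(index).fillna(0.0)
    weather_frame = {}
    for var in ("temperature", "rainfall", "radiation", "humidity"):
        stations = by_var(var)
        if stations:
            from .data_model import city_average_weather
            weather_frame[var] = city_average_weather(stations, var).values
    weather = pd.DataFrame(weather_frame, index=index) if weather_frame else None
    regressors = assemble_regressors(calendar, quads, None,
                                     policy_date=config.policy_date, weather=weather)
    return target_log, cand_log, regressors, target_raw, cand_raw


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and write a manifest.

    Any stage failure aborts with the stage name in the raised error.
    """
    os.makedirs(config.outdir, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "ingest"
    try:
        target_log, cand_log, regressors, target_raw, cand_raw = load_inputs(config)

        stage = "prepost"
        table = prepost_mod.prepost_table(
            list(target_raw.values()) + list(cand_raw.values()),
            config.treat_year, config.control_years,
            prepost_mod.Window.parse(config.prepost_window),
        )
        path = os.path.join(config.outdir, "prepost.csv")
        table.to_csv(path, index=False)
        artifacts["prepost"] = path

        plan = config.cv_plan()
        results = {}
        for sid, obs in target_log.items():
            stage = f"select[{sid}]"
            if config.harmonics is None:
                rep_k = select_harmonics(obs, plan, tolerance=config.tolerance,
                                         n_starts=1, seed=config.seed)
                rep_k.to_frame().to_csv(
                    os.path.join(config.outdir, f"select_harmonics_{sid}.csv"), index=False)
                k = int(rep_k.chosen)
            else:
                k = config.harmonics
            if config.counterfactual is None:
                rep_c = select_counterfactual(cand_log, obs, plan, harmonics=k,
                                              tolerance=config.tolerance,
                                              n_starts=1, seed=config.seed)
                rep_c.to_frame().to_csv(
                    os.path.join(config.outdir, f"select_counterfactual_{sid}.csv"), index=False)
                city = str(rep_c.chosen)
            else:
                city = config.counterfactual

            reg_full = assemble_regressors(
                regressors.frame[[c for c in regressors.frame.columns
                                  if c not in ("policy_step", "policy_impulse")]],
                None, cand_log[city], policy_date=config.policy_date,
            )
            pre_idx = reg_full.dates[reg_full.dates <= pd.Timestamp(plan.train_end)]
            pre_spec = BsmSpec(seasonal=SeasonalSpec(365, k), regressors=("counterfactual",))
            pre_obs = DailySeries(obs.station_id, obs.variable,
                                  obs.values.reindex(pre_idx), log_scale=True)
            pre_fit = fit_ml(pre_spec, reg_full.subset(pre_idx), pre_obs,
                             n_starts=1, seed=config.seed)
            eps = smoothed_disturbances(pre_spec, reg_full.subset(pre_idx), pre_obs, pre_fit)
            terms = [t for t in STEPWISE_TERMS if t in reg_full.frame.columns]
            sw_bic = stepwise_residual_screen(eps, reg_full.frame.loc[pre_idx, terms], "bic")
            sw_aic = stepwise_residual_screen(eps, reg_full.frame.loc[pre_idx, terms], "aic")

            stage = f"intervene[{sid}]"
            final_spec = assemble_final_spec(sw_bic, harmonics=k)
            final_spec = dataclasses.replace(
                final_spec,
                regressors=tuple(t for t in final_spec.regressors
                                 if t in reg_full.frame.columns),
            )
            effect = estimate_policy(final_spec, reg_full, obs, n_starts=3, seed=config.seed)
            fit_summary(effect.fit).to_csv(
                os.path.join(config.outdir, f"fit_{sid}.csv"), index=False)
            results[sid] = {
                "harmonics": k, "counterfactual": city,
                "stepwise_bic": list(sw_bic.retained),
                "stepwise_aic": list(sw_aic.retained),
                "effect": effect,
            }

        stage = "report"
        effects = report_effects([r["effect"] for r in results.values()])
        path = os.path.join(config.outdir, "effects.csv")
        effects.to_csv(path, index=False)
        artifacts["effects"] = path
        summary = {
            sid: {k: v for k, v in r.items() if k != "effect"}
            for sid, r in results.items()
        }
        path = os.path.join(config.outdir, "selection_summary.json")
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2)
        artifacts["selection_summary"] = path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": {
            name: {"path": p, "sha256": _sha256(p)} for name, p in artifacts.items()
        },
    }
    for fname in sorted(os.listdir(config.outdir)):
        fpath = os.path.join(config.outdir, fname)
        if os.path.isfile(fpath) and fname not in {"manifest.json"}:
            manifest["artifacts"].setdefault(
                fname, {"path": fpath, "sha256": _sha256(fpath)})
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
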