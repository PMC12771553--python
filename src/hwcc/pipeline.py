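"""End-to-end orchestration: climate -> exposure -> panel -> fits -> burden.

A single plain-text (YAML) config drives every stage; all defaults reproduce
the main analysis (95th-percentile thresholds, 2-day minimum duration,
May-October season, linear HWI exposures at lag 0, Bonferroni adjustment on
subgroup comparisons). Sensitivity toggles switch to 90th-percentile
thresholds, 3/4-day minimum duration, or a same-day relative-humidity
covariate. Given the same inputs and seed the pipeline is deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import attribution, design, estimator, heterogeneity, hwi, io, simulate

log = logging.getLogger("hwcc")


@dataclass
class PipelineConfig:
    output_dir: str = "hwcc_output"
    climate_path: str | None = None
    health_path: str | None = None
    scenario: str | None = None      # simulate instead of reading files
    seed: int = 0
    percentile_level: float = 0.95
    min_duration: int = 2
    season_months: tuple[int, ...] = hwi.DEFAULT_SEASON_MONTHS
    reference_period: tuple[int, int] = (1981, 2010)
    causes: list[str] | None = None  # None = every cause in the health table
    fit_binary: bool = False
    fit_spline: bool = False
    lags: tuple[int, ...] = (0,)
    humidity_covariate: bool = False
    subgroups: list[dict] | None = None
    n_draws: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("season_months", "lags", "reference_period"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _load_inputs(cfg: PipelineConfig):
    if cfg.scenario is not None:
        study = simulate.simulate_dataset(
            simulate.make_scenario(cfg.scenario, seed=cfg.seed)
        )
        ref = simulate.reference_period(study.config)
        return study.climate, study.health, ref, study.truth
    if not cfg.climate_path or not cfg.health_path:
        raise ValueError("config needs climate_path and health_path, or a scenario")
    climate = io.read_climate(cfg.climate_path)
    health = io.read_health(cfg.health_path)
    return climate, health, tuple(cfg.reference_period), None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write result tables under ``cfg.output_dir``.

    Returns a bundle with the in-memory frames (exposure, panels, fits,
    comparisons, attribution) keyed by stage.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, out_dir)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(cfg: PipelineConfig, out_dir: Path) -> dict:
    climate, health, ref_period, truth = _load_inputs(cfg)
    log.info("inputs: %d climate rows, %d health rows", len(climate), len(health))

    thresholds = hwi.compute_thresholds(
        climate,
        percentile_level=cfg.percentile_level,
        reference_period=ref_period,
        season_months=cfg.season_months,
    )
    analysis_years = pd.to_datetime(health["date"]).dt.year
    yrs = pd.to_datetime(climate["date"]).dt.year
    analysis = climate[yrs.between(analysis_years.min(), analysis_years.max())]
    events, exposure = hwi.compute_exposure(
        analysis, thresholds, min_duration=cfg.min_duration
    )
    log.info(
        "thresholds p=%.2f; %d events (%d daytime); %d exposure rows",
        cfg.percentile_level, len(events),
        int((events["event_type"] == hwi.DAYTIME).sum()) if len(events) else 0,
        len(exposure),
    )
    io.write_table(thresholds.values.reset_index(), out_dir / "thresholds.csv")
    io.write_table(events, out_dir / "events.csv")
    io.write_table(exposure, out_dir / "exposure.csv")

    covariates = None
    spec = estimator.ModelSpec()
    if cfg.humidity_covariate:
        if "rh" not in climate.columns:
            raise ValueError("humidity_covariate requires an 'rh' climate column")
        covariates = climate[["location_id", "date", "rh"]]
        spec = estimator.ModelSpec(covariates=("rh",))

    causes = cfg.causes or sorted(health["cause"].unique())
    bundle: dict = {
        "thresholds": thresholds, "events": events, "exposure": exposure,
        "panels": {}, "fits": {}, "effects": [], "comparisons": [],
        "attribution": {}, "truth": truth,
    }
    for cause in causes:
        panel = design.assemble_panel(
            health, exposure, cause=cause, covariates=covariates
        )
        log.info(
            "panel[%s]: %d rows, %d dropped missing-exposure days",
            cause, len(panel), panel.attrs["n_dropped_days"],
        )
        bundle["panels"][cause] = panel
        io.write_panel(panel, out_dir / f"panel_{cause}.csv")

        fits = {}
        for lag in cfg.lags:
            fit = estimator.fit_lag_model(panel, exposure, lag, spec)
            fits[("linear", lag)] = fit
            log.info(
                "fit[%s linear lag%d]: phi=%.3f, %d informative strata, %d rows",
                cause, lag, fit.dispersion, fit.n_informative_strata, fit.n_rows_used,
            )
            for expo, lab in (("dhwi", "daytime"), ("nhwi", "nighttime")):
                e = fit.effect(expo, label=f"{cause}|{lab}|lag{lag}")
                bundle["effects"].append(e)
        if cfg.fit_binary:
            fit_b = estimator.fit_binary_model(panel, spec)
            fits[("binary", 0)] = fit_b
            for expo, lab in (("dhw_flag", "daytime_event"), ("nhw_flag", "nighttime_event")):
                bundle["effects"].append(fit_b.effect(expo, label=f"{cause}|{lab}"))
        if cfg.fit_spline:
            fit_s, curves = estimator.fit_spline_model(panel)
            fits[("spline", 0)] = fit_s
            for expo, curve in curves.items():
                io.write_table(curve, out_dir / f"spline_{cause}_{expo}.csv")
        bundle["fits"][cause] = fits

        main = fits[("linear", cfg.lags[0])]
        e_night = main.effect("nhwi", label=f"{cause}|nighttime")
        e_day = main.effect("dhwi", label=f"{cause}|daytime")
        comp = heterogeneity.compare_estimates(e_night, e_day)
        bundle["comparisons"].append(comp)
        log.info(
            "compare[%s]: d=%.3f pp, p=%.3g", cause, comp.d, comp.p_value
        )

        daily_an, annual = attribution.attributable_number(panel, main)
        annual_ci = attribution.attribution_uncertainty(
            panel, main, n_draws=cfg.n_draws, seed=cfg.seed
        )
        bundle["attribution"][cause] = annual_ci
        io.write_table(annual_ci, out_dir / f"attribution_{cause}.csv")
        log.info(
            "attribution[%s]: mean annual AN total %.2f (n_draws=%d)",
            cause, annual["an_total"].mean(), cfg.n_draws,
        )

    io.write_table(io.effects_table(bundle["effects"]), out_dir / "effects.csv")
    m = len(bundle["comparisons"])
    io.write_table(
        io.comparisons_table(bundle["comparisons"], m=m), out_dir / "comparisons.csv"
    )
    log.info("Bonferroni family size m=%d for cause-level comparisons", m)
    if truth is not None:
        with open(out_dir / "truth.json", "w") as fhj:
            json.dump(truth, fhj, indent=2)
    return bundle
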