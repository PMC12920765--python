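"""Readers, writers, configuration and the simulate-fit-compare pipeline.

Observation tables travel as plain CSV with a header row; structured
results (fits, comparisons, endpoint tests) are serialised to JSON, and
a Table-style parameter CSV plus a dense fitted-curve prediction table
are written for downstream plotting.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .endpoints import fit_endpoint_model, group_means, residual_diagnostics, test_all_terms
from .fitting import (
    CONTAMINATION,
    DECONTAMINATION,
    FitResult,
    compare_nested,
    fit_phase,
    schedule_from_data,
)
from .model import ExposureSchedule, KineticParams, TwoPhaseModel, predict_trajectory
from .simulate import SimulationConfig, default_schedule, default_truth, generate_dataset

__all__ = [
    "CANONICAL_FIELDS",
    "ColumnMapping",
    "read_observations",
    "write_observations",
    "simulation_config_from_dict",
    "run_pipeline",
]

logger = logging.getLogger("cadkin")

CANONICAL_FIELDS = ("colony_id", "habitat", "region", "time_days", "concentration")


@dataclass(frozen=True)
class ColumnMapping:
    """Maps canonical field names to the columns of a source CSV."""

    colony_id: str = "colony_id"
    habitat: str = "habitat"
    region: str = "region"
    time_days: str = "time_days"
    concentration: str = "concentration"

    def as_dict(self) -> dict[str, str]:
        return {f: getattr(self, f) for f in CANONICAL_FIELDS}


def read_observations(path, mapping: ColumnMapping | None = None) -> pd.DataFrame:
    """Read and validate a long-format colony observation CSV.

    Habitat and region labels are normalised to lower case. Rows with a
    missing or non-numeric concentration, or a negative time, are
    rejected with row-numbered messages (row numbers count the header
    as line 1).
    """
    mapping = mapping or ColumnMapping()
    raw = pd.read_csv(path)
    missing = [c for c in mapping.as_dict().values() if c not in raw.columns]
    if missing:
        raise ValueError(
            f"{path}: mapped column(s) {missing} not present; file has "
            f"columns {list(raw.columns)}"
        )
    df = raw[[mapping.as_dict()[f] for f in CANONICAL_FIELDS]].copy()
    df.columns = list(CANONICAL_FIELDS)

    problems = []
    conc = pd.to_numeric(df["concentration"], errors="coerce")
    for idx in df.index[conc.isna()]:
        problems.append(
            f"row {idx + 2}: missing or non-numeric concentration "
            f"{df.at[idx, 'concentration']!r}"
        )
    time = pd.to_numeric(df["time_days"], errors="coerce")
    for idx in df.index[time.isna()]:
        problems.append(f"row {idx + 2}: non-numeric time {df.at[idx, 'time_days']!r}")
    for idx in df.index[time < 0]:
        problems.append(f"row {idx + 2}: negative time {time[idx]}")
    for idx in df.index[conc < 0]:
        problems.append(f"row {idx + 2}: negative concentration {conc[idx]}")
    if problems:
        raise ValueError(f"{path}: invalid observations:\n" + "\n".join(problems))

    df["concentration"] = conc.astype(float)
    df["time_days"] = time.astype(float)
    df["habitat"] = df["habitat"].astype(str).str.strip().str.lower()
    df["region"] = df["region"].astype(str).str.strip().str.lower()
    df["colony_id"] = df["colony_id"].astype(str)
    if df["colony_id"].duplicated().any():
        dups = sorted(df.loc[df["colony_id"].duplicated(), "colony_id"].unique())
        raise ValueError(
            f"{path}: duplicated colony_id(s) {dups} — destructive sampling "
            "means each colony is measured once"
        )
    return df


def write_observations(data: pd.DataFrame, path) -> None:
    cols = [c for c in data.columns if c in CANONICAL_FIELDS]
    data[cols].to_csv(path, index=False)


def _kp(d: dict) -> KineticParams:
    return KineticParams(kA=float(d["kA"]), kE=float(d["kE"]))


def simulation_config_from_dict(spec: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain (JSON-friendly) dictionary."""
    kwargs: dict = {}
    if "schedule" in spec:
        kwargs["schedule"] = ExposureSchedule(**spec["schedule"])
    if "truth" in spec:
        kwargs["truth"] = {
            hab: {phase: _kp(p) for phase, p in phases.items()}
            for hab, phases in spec["truth"].items()
        }
    for key in (
        "time_points",
        "colonies_per_cell",
        "regions",
        "noise_sd_contamination",
        "noise_sd_decontamination",
        "baseline_range",
        "exceedance_prob",
        "exceedance_scale",
        "noise_model",
        "seed",
    ):
        if key in spec:
            value = spec[key]
            kwargs[key] = tuple(value) if isinstance(value, list) else value
    return SimulationConfig(**kwargs)


def _round6(x: float) -> float:
    """Six significant digits for serialised concentrations/statistics."""
    return float(f"{x:.6g}")


def fits_to_table(fits: list[FitResult]) -> pd.DataFrame:
    """Flatten fit results into a parameter table (one row per parameter)."""
    rows = []
    for fit in fits:
        for name, est in fit.estimates.items():
            habitat = name.split("_", 1)[1] if "_" in name else "all"
            lo, hi = fit.ci95.get(name, (np.nan, np.nan))
            rows.append(
                {
                    "model": "pooled" if fit.grouping == "pooled" else "habitat",
                    "habitat": habitat,
                    "phase": fit.phase,
                    "parameter": name.split("_")[0],
                    "estimate": _round6(est),
                    "ci95_low": _round6(lo),
                    "ci95_high": _round6(hi),
                    "adjusted_r2": _round6(fit.adjusted_r2),
                    "aic": _round6(fit.aic),
                }
            )
    return pd.DataFrame(rows)


def prediction_table(
    fits: dict[str, FitResult], schedule: ExposureSchedule, step: float = 0.25
) -> pd.DataFrame:
    """Dense per-model trajectory over day 0-42 for plotting."""
    grid = np.arange(0.0, 42.0 + step / 2, step)
    frames = []
    pooled_cont = fits[(CONTAMINATION, "pooled")]
    pooled_dec = fits[(DECONTAMINATION, "pooled")]
    model = TwoPhaseModel(
        contamination=pooled_cont.params(),
        decontamination=pooled_dec.params(),
        schedule=schedule,
    )
    frames.append(
        pd.DataFrame(
            {
                "model": "pooled",
                "habitat": "all",
                "time_days": grid,
                "concentration": predict_trajectory(model, grid),
            }
        )
    )
    hab_cont = fits.get((CONTAMINATION, "by_habitat"))
    hab_dec = fits.get((DECONTAMINATION, "by_habitat"))
    if hab_cont is not None and hab_dec is not None:
        habitats = sorted(
            {n.split("_", 1)[1] for n in hab_cont.estimates if "_" in n}
        )
        for hab in habitats:
            model_h = TwoPhaseModel(
                contamination=hab_cont.params(hab),
                decontamination=hab_dec.params(hab),
                schedule=schedule,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "model": "habitat",
                        "habitat": hab,
                        "time_days": grid,
                        "concentration": predict_trajectory(model_h, grid),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out["concentration"] = out["concentration"].map(_round6)
    return out


def run_pipeline(
    config: dict,
    out_dir,
    seed: int | None = None,
) -> dict:
    """Run simulate (optional) -> fit -> compare -> endpoints -> report.

    ``config`` keys:
      ``data``        path to an observation CSV (mutually exclusive with
                      ``simulation``)
      ``mapping``     optional canonical-to-source column mapping
      ``simulation``  SimulationConfig dictionary (see
                      :func:`simulation_config_from_dict`)
      ``schedule``    optional exposure constants; C_I0 defaults to the
                      day-0 mean of the data
      ``anchor``      switch-concentration rule for the depuration fits

    Writes the report bundle into ``out_dir`` and returns it as a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "configuration"
    try:
        logger.info("cadkin %s (python %s)", __version__, sys.version.split()[0])
        if ("data" in config) == ("simulation" in config):
            raise ValueError("config must name exactly one of 'data' or 'simulation'")

        stage = "data loading"
        if "data" in config:
            mapping = ColumnMapping(**config.get("mapping", {}))
            data = read_observations(config["data"], mapping)
            logger.info("read %d colonies from %s", len(data), config["data"])
        else:
            sim_spec = dict(config["simulation"])
            if seed is not None:
                sim_spec["seed"] = seed
            sim_cfg = simulation_config_from_dict(sim_spec)
            dataset = generate_dataset(sim_cfg)
            data = dataset.observations
            write_observations(data, out_dir / "observations.csv")
            logger.info("simulated %d colonies with seed %s", len(data), sim_cfg.seed)

        stage = "schedule"
        sched_spec = dict(config.get("schedule", {}))
        if "C_I0" in sched_spec:
            schedule = ExposureSchedule(**sched_spec)
        else:
            schedule = schedule_from_data(data, **sched_spec)
        logger.info(
            "schedule: C_I0=%.6g C_Eu=%.6g C_Ed=%.6g t_C=%.6g",
            schedule.C_I0, schedule.C_Eu, schedule.C_Ed, schedule.t_C,
        )

        anchor = config.get("anchor", "pooled")
        fits: dict[tuple[str, str], FitResult] = {}
        comparisons = {}
        for phase in (CONTAMINATION, DECONTAMINATION):
            stage = f"{phase} fitting"
            for grouping in ("pooled", "by_habitat"):
                fit = fit_phase(data, phase, schedule, grouping, anchor=anchor)
                fits[(phase, grouping)] = fit
                logger.info(
                    "%s/%s: rss=%.6g aic=%.6g iterations=%d warnings=%s",
                    phase, grouping, fit.rss, fit.aic, fit.n_iterations, fit.warnings,
                )
                for entry in fit.start_log:
                    logger.info("  start %s -> %s", entry["start"], entry)
            stage = f"{phase} comparison"
            comparisons[phase] = compare_nested(
                fits[(phase, "pooled")], fits[(phase, "by_habitat")]
            )
            logger.info("%s comparison: %s", phase, comparisons[phase].to_dict())

        stage = "endpoint analysis"
        endpoint_fit = fit_endpoint_model(data)
        terms = test_all_terms(data)
        means = group_means(data)
        diagnostics = residual_diagnostics(endpoint_fit)

        stage = "report writing"
        fit_table = fits_to_table(list(fits.values()))
        fit_table.to_csv(out_dir / "parameters.csv", index=False)
        pred = prediction_table(fits, schedule)
        pred.to_csv(out_dir / "predictions.csv", index=False)
        means.to_csv(out_dir / "endpoint_means.csv", index=False)
        diagnostics["residual_table"].to_csv(
            out_dir / "endpoint_residuals.csv", index=False
        )

        report = {
            "package_version": __version__,
            "seed": seed,
            "schedule": {
                "C_I0": schedule.C_I0,
                "C_Eu": schedule.C_Eu,
                "C_Ed": schedule.C_Ed,
                "t_C": schedule.t_C,
            },
            "n_colonies": int(len(data)),
            "fits": {
                f"{phase}/{grouping}": fit.to_dict()
                for (phase, grouping), fit in fits.items()
            },
            "comparisons": {p: c.to_dict() for p, c in comparisons.items()},
            "endpoint": {
                "coefficients": endpoint_fit.coefficients,
                "reference_levels": endpoint_fit.reference_levels,
                "terms": [t.to_dict() for t in terms],
                "shapiro_stat": diagnostics["shapiro_stat"],
                "shapiro_p": diagnostics["shapiro_p"],
                "variance_ratio": diagnostics["variance_ratio"],
            },
        }
        with open(out_dir / "comparisons.json", "w") as fh:
            json.dump(report["comparisons"], fh, indent=2)
        with open(out_dir / "endpoint.json", "w") as fh:
            json.dump(report["endpoint"], fh, indent=2)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("report written to %s", out_dir)
        return report
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
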