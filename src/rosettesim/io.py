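"""Configuration files, tabular I/O and reproducible run entry points.

Configs are a YAML key-value tree mirroring the model's input groups
(schedule, constants, partitions, drivers).  Tabular outputs are plain CSV;
structured results are JSON.  Every run entry point writes a manifest
recording the seed, a content digest of the configuration, the package
version and wall-clock time, so two runs with equal manifests produce equal
outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    OBSERVABLES,
    MeasurementSeries,
    ParetoResult,
    cluster_and_rank,
    fit_nsga2,
)
from .config import (
    ModelConstants,
    PartitionSet,
    PhaseCoefficients,
    PhaseSchedule,
    PHASES,
)
from .core import ModelConfig, SimulationResult, simulate
from .drivers import OverlapRatioCurve, PhotosynthesisCurve
from .metrics import growth_summary
from .sensitivity import Perturbation, sensitivity_table
from .synthetic import SyntheticStudy, generate_measurements

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
    "config_digest",
    "read_measurements_csv",
    "write_measurements_csv",
    "RunManifest",
    "run_simulation",
    "run_calibration",
    "run_sensitivity",
    "run_synthetic",
]


# -- config serialization ----------------------------------------------------

def config_to_dict(config: ModelConfig) -> dict:
    sched = config.schedule
    return {
        "schedule": {
            "heterotrophic_days": list(sched.heterotrophic_days),
            "early_vegetative_days": list(sched.early_vegetative_days),
            "late_vegetative_days": list(sched.late_vegetative_days),
            "reproductive_days": list(sched.reproductive_days),
            "photoperiod_h": sched.photoperiod_h,
            "total_days": sched.total_days,
            "step_h": sched.step_h,
        },
        "constants": asdict(config.constants),
        "partitions": {
            phase: dict(zip(("iota", "rho", "lambda_s", "lambda_t"),
                            config.partitions.phase(phase).as_tuple()))
            for phase in PHASES
        },
        "drivers": {
            "photosynthesis": {
                "coeffs": list(config.photosynthesis.coeffs),
                "das_range": list(config.photosynthesis.das_range),
                "floor": config.photosynthesis.floor,
                "scale": config.photosynthesis.scale,
            },
            "overlap": {
                "a": config.overlap.a,
                "b": config.overlap.b,
                "clamp": list(config.overlap.clamp),
                "on_area": config.overlap.on_area,
            },
        },
    }


def config_from_dict(data: dict) -> ModelConfig:
    try:
        sched = data["schedule"]
        schedule = PhaseSchedule(
            heterotrophic_days=tuple(sched["heterotrophic_days"]),
            early_vegetative_days=tuple(sched["early_vegetative_days"]),
            late_vegetative_days=tuple(sched["late_vegetative_days"]),
            reproductive_days=tuple(sched["reproductive_days"]),
            photoperiod_h=sched["photoperiod_h"],
            total_days=sched["total_days"],
            step_h=sched.get("step_h", 1),
        )
        constants = ModelConstants(**data["constants"])
        phases = {}
        for phase in PHASES:
            row = data["partitions"][phase]
            try:
                phases[phase] = PhaseCoefficients(**row)
            except ValueError as exc:
                raise ValueError(f"partitions.{phase}: {exc}") from exc
        partitions = PartitionSet(**phases)
        dr = data["drivers"]
        photo = PhotosynthesisCurve(
            coeffs=tuple(dr["photosynthesis"]["coeffs"]),
            das_range=tuple(dr["photosynthesis"].get("das_range", (1.0, 90.0))),
            floor=dr["photosynthesis"].get("floor", 0.0),
            scale=dr["photosynthesis"].get("scale", 1.0),
        )
        overlap = OverlapRatioCurve(
            a=dr["overlap"]["a"],
            b=dr["overlap"]["b"],
            clamp=tuple(dr["overlap"].get("clamp", (1e-6, 1.0))),
            on_area=dr["overlap"].get("on_area", False),
        )
    except KeyError as exc:
        raise ValueError(f"config missing required key: {exc}") from exc
    return ModelConfig(
        schedule=schedule,
        constants=constants,
        partitions=partitions,
        photosynthesis=photo,
        overlap=overlap,
    )


def save_config(config: ModelConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path) -> ModelConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_digest(config: ModelConfig) -> str:
    """Stable content hash of a configuration."""
    canon = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# -- measurements CSV --------------------------------------------------------

_MEAS_COLUMNS = ["observable", "das", "mean", "sd", "n"]


def write_measurements_csv(series: dict[str, MeasurementSeries], path) -> None:
    rows = []
    for obs in OBSERVABLES:
        if obs in series:
            for das, mean, sd, n in series[obs].points:
                rows.append([obs, das, mean, sd, n])
    # %.17g keeps float64 exact through the text round trip
    pd.DataFrame(rows, columns=_MEAS_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_measurements_csv(path) -> dict[str, MeasurementSeries]:
    """Read the (observable, das, mean, sd, n) measurement table.

    Raises ValueError naming the offending column or row on schema problems.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _MEAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurements CSV missing column(s): {missing}")
    out: dict[str, MeasurementSeries] = {}
    for obs, grp in df.groupby("observable"):
        points = []
        for idx, row in grp.iterrows():
            if not np.isfinite([row["das"], row["mean"], row["sd"]]).all():
                raise ValueError(f"measurements CSV row {idx + 2}: non-finite value")
            if row["sd"] <= 0:
                raise ValueError(f"measurements CSV row {idx + 2}: sd must be positive")
            points.append((int(row["das"]), float(row["mean"]),
                           float(row["sd"]), int(row["n"])))
        out[str(obs)] = MeasurementSeries(str(obs), tuple(points))
    return out


# -- run entry points --------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record of one run."""

    command: str
    config_digest: str
    seed: int | None
    version: str
    outputs: list[str]
    wall_clock_s: float

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _manifest(command, config, seed, outputs, t0, out_dir) -> RunManifest:
    man = RunManifest(
        command=command,
        config_digest=config_digest(config),
        seed=seed,
        version=__version__,
        outputs=[str(p) for p in outputs],
        wall_clock_s=round(time.perf_counter() - t0, 3),
    )
    man.write(Path(out_dir) / f"{command}_manifest.json")
    return man


def run_simulation(config: ModelConfig, out_dir, hourly: bool = False) -> SimulationResult:
    """Simulate and write per-day (and optionally per-hour) CSVs plus the
    derived growth summary."""
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = simulate(config, record_hourly=hourly)
    outputs = [out / "daily.csv", out / "growth_summary.csv"]
    result.daily.to_csv(outputs[0], index=False)
    growth_summary(result).to_csv(outputs[1], index=False)
    if hourly:
        p = out / "hourly.csv"
        result.hourly.to_csv(p, index=False)
        outputs.append(p)
    _manifest("simulate", config, None, outputs, t0, out)
    return result


def run_calibration(
    config: ModelConfig,
    measurements: dict[str, MeasurementSeries],
    out_dir,
    seed: int = 0,
    population: int = 64,
    generations: int = 200,
    **fit_kwargs,
) -> ParetoResult:
    """Calibrate, cluster/rank the qualified settings, and write JSON + CSV
    results.  Extra keyword arguments are passed through to ``fit_nsga2``."""
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = fit_nsga2(config, measurements, population=population,
                       generations=generations, seed=seed, **fit_kwargs)
    payload = {
        "seed": seed,
        "population": population,
        "generations": generations,
        "threshold": result.threshold,
        "front": [
            {"coefficients": s.as_vector(),
             "objectives": dict(zip(OBSERVABLES, map(float, f)))}
            for s, f in zip(result.front_settings, result.front_objectives)
        ],
        "qualified": [
            {"coefficients": s.as_vector(),
             "objectives": dict(zip(OBSERVABLES, map(float, f)))}
            for s, f in zip(result.qualified_settings, result.qualified_objectives)
        ],
    }
    if len(result.qualified_settings) >= 2:
        report = cluster_and_rank(result.qualified_settings, result.qualified_objectives)
        payload["clusters"] = {
            "labels": report.labels.tolist(),
            "n_clusters": report.n_clusters,
            "medoid_indices": report.medoid_indices,
            "top_two": report.top_two,
        }
    outputs = [out / "calibration.json", out / "front_objectives.csv"]
    outputs[0].write_text(json.dumps(payload, indent=2))
    pd.DataFrame(result.front_objectives, columns=list(OBSERVABLES)).to_csv(
        outputs[1], index=False)
    _manifest("calibrate", config, seed, outputs, t0, out)
    return result


def run_sensitivity(
    config: ModelConfig,
    out_dir,
    perturbations: list[Perturbation] | None = None,
) -> pd.DataFrame:
    """Run the perturbation battery and write the sensitivity table CSV."""
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = sensitivity_table(config, perturbations)
    p = out / "sensitivity.csv"
    table.to_csv(p, index=False)
    _manifest("sensitivity", config, None, [p], t0, out)
    return table


def run_synthetic(study: SyntheticStudy, config: ModelConfig, out_dir):
    """Generate a synthetic study's measurements CSV."""
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = generate_measurements(study, config)
    p = out / "measurements.csv"
    write_measurements_csv(series, p)
    _manifest("synth", config, study.seed, [p], t0, out)
    return series
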