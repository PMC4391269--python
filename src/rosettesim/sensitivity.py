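"""One-at-a-time sensitivity analysis.

Each perturbation shifts one model input -- +/-1 percentage point for a
partition coefficient (with a named compensating coefficient absorbing the
opposite change so the phase stays on the simplex), or +/-1% relative for a
scalar input -- re-simulates, and reports the percent change in leaf area and
plant mass at the checkpoint days 26/44/66/86 DAS.  An input is deemed
sensitive when any output changes by more than 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import PHASES, PhaseCoefficients, PhaseSchedule
from .core import ModelConfig, simulate

__all__ = [
    "Perturbation",
    "apply_perturbation",
    "default_battery",
    "sensitivity_table",
    "CHECKPOINT_DAS",
]

CHECKPOINT_DAS = (26, 44, 66, 86)

_COEFF_NAMES = ("iota", "rho", "lambda_s", "lambda_t")
_SCALAR_TARGETS = ("photosynthesis", "sigma", "initial_leaf_area", "vegetative_length")


@dataclass(frozen=True)
class Perturbation:
    """One sensitivity experiment.

    ``target`` is a coefficient name (iota/rho/lambda_s/lambda_t, with
    ``phase`` set and ``compensation`` naming the coefficient that absorbs
    the opposite shift) or one of the scalar inputs: "photosynthesis"
    (driver curve scaled by 1 + delta), "sigma" (absolute shift),
    "initial_leaf_area" (relative), "vegetative_length" (delta whole days on
    the late-vegetative/reproductive boundary).
    """

    target: str
    delta: float
    phase: str | None = None
    compensation: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.target in _COEFF_NAMES:
            if self.phase not in PHASES:
                raise ValueError(f"coefficient perturbation needs a phase, got {self.phase!r}")
            if self.compensation not in _COEFF_NAMES or self.compensation == self.target:
                raise ValueError("coefficient perturbation needs a distinct compensation coefficient")
        elif self.target not in _SCALAR_TARGETS:
            raise ValueError(f"unknown perturbation target {self.target!r}")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        sign = "+" if self.delta >= 0 else "-"
        where = f" {self.phase}" if self.phase else ""
        return f"{self.target}{where} ({sign}{abs(self.delta):g})"


def apply_perturbation(config: ModelConfig, p: Perturbation) -> ModelConfig:
    """Return a config differing from baseline only in the perturbed input."""
    if p.target in _COEFF_NAMES:
        coeffs = config.partitions.phase(p.phase)
        vals = dict(zip(_COEFF_NAMES, coeffs.as_tuple()))
        vals[p.target] += p.delta
        vals[p.compensation] -= p.delta
        for name, v in vals.items():
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(
                    f"perturbation drives {name} to {v:.4f}, off the simplex"
                )
        new_phase = PhaseCoefficients(
            **{k: min(max(v, 0.0), 1.0) for k, v in vals.items()}
        )
        parts = replace(config.partitions, **{p.phase: new_phase})
        return config.with_(partitions=parts)
    if p.target == "photosynthesis":
        return config.with_(photosynthesis=config.photosynthesis.scaled(1.0 + p.delta))
    if p.target == "sigma":
        return config.with_(constants=config.constants.with_(
            sigma=config.constants.sigma + p.delta))
    if p.target == "initial_leaf_area":
        return config.with_(constants=config.constants.with_(
            initial_leaf_area=config.constants.initial_leaf_area * (1.0 + p.delta)))
    if p.target == "vegetative_length":
        sched = config.schedule
        shift = int(round(p.delta))
        new_end = sched.late_vegetative_days[1] + shift
        new_sched = PhaseSchedule(
            heterotrophic_days=sched.heterotrophic_days,
            early_vegetative_days=sched.early_vegetative_days,
            late_vegetative_days=(sched.late_vegetative_days[0], new_end),
            reproductive_days=(new_end + 1, sched.reproductive_days[1]),
            photoperiod_h=sched.photoperiod_h,
            total_days=sched.total_days,
            step_h=sched.step_h,
        )
        return config.with_(schedule=new_sched)
    raise AssertionError("unreachable")


def default_battery() -> list[Perturbation]:
    """The published perturbation battery.

    +/-1% photosynthesis, +/-1 point starch set-aside, +/-1% initial leaf
    area, +/-1 point early-vegetative leaf thickening (absorbed by area
    growth), +/-1 point early-vegetative roots (absorbed by thickening),
    +/-1 point late-vegetative inflorescence (absorbed by thickening), and
    +/-1 day of vegetative-phase length.
    """
    battery = []
    for d in (+0.01, -0.01):
        battery.append(Perturbation("photosynthesis", d,
                                    label=f"Photosynthesis ({d:+.0%})"))
    for d in (+0.01, -0.01):
        battery.append(Perturbation("sigma", d,
                                    label=f"Partitioning to starch ({d * 100:+g} pt)"))
    for d in (+0.01, -0.01):
        battery.append(Perturbation("initial_leaf_area", d,
                                    label=f"Initial leaf area ({d:+.0%})"))
    for d in (+0.01, -0.01):
        battery.append(Perturbation(
            "lambda_t", d, phase="early_vegetative", compensation="lambda_s",
            label=f"Leaf thickening, early veg ({d * 100:+g} pt)"))
    for d in (+0.01, -0.01):
        battery.append(Perturbation(
            "rho", d, phase="early_vegetative", compensation="lambda_t",
            label=f"Roots, early veg ({d * 100:+g} pt)"))
    for d in (+0.01, -0.01):
        battery.append(Perturbation(
            "iota", d, phase="late_vegetative", compensation="lambda_t",
            label=f"Inflorescence, late veg ({d * 100:+g} pt)"))
    for d in (+1, -1):
        battery.append(Perturbation("vegetative_length", d,
                                    label=f"Length of vegetative phase ({d:+d} day)"))
    return battery


def sensitivity_table(
    config: ModelConfig,
    perturbations: list[Perturbation] | None = None,
    checkpoints: tuple[int, ...] = CHECKPOINT_DAS,
) -> pd.DataFrame:
    """Percent change in leaf area and plant mass at the checkpoint days for
    each perturbation, relative to the unperturbed baseline.

    Columns: perturbation, target, delta, then ``leaf_area_<das>`` and
    ``plant_mass_<das>`` percent changes, plus a ``sensitive`` flag (any
    |change| > 1%).  Checkpoints at which the baseline is zero are NaN.
    """
    if perturbations is None:
        perturbations = default_battery()
    base = simulate(config)
    base_area = np.array([base.at(d)["leaf_area"] for d in checkpoints])
    base_mass = np.array([base.at(d)["plant_mass"] for d in checkpoints])
    rows = []
    for p in perturbations:
        pert = simulate(apply_perturbation(config, p))
        area = np.array([pert.at(d)["leaf_area"] for d in checkpoints])
        mass = np.array([pert.at(d)["plant_mass"] for d in checkpoints])
        with np.errstate(divide="ignore", invalid="ignore"):
            d_area = np.where(base_area > 0, 100.0 * (area - base_area) / base_area, np.nan)
            d_mass = np.where(base_mass > 0, 100.0 * (mass - base_mass) / base_mass, np.nan)
        row = {"perturbation": p.name, "target": p.target, "delta": p.delta}
        for das, v in zip(checkpoints, d_area):
            row[f"leaf_area_{das}"] = v
        for das, v in zip(checkpoints, d_mass):
            row[f"plant_mass_{das}"] = v
        changes = np.concatenate([d_area, d_mass])
        row["sensitive"] = bool(np.nanmax(np.abs(changes), initial=0.0) > 1.0)
        rows.append(row)
    return pd.DataFrame(rows)
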