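"""Derived growth quantities: SLA, relative growth rates, mass ratios,
carbon-partitioning summaries and leaf-area-vs-plant-mass relationship tables.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import SimulationResult

__all__ = [
    "sla",
    "rgr",
    "growth_summary",
    "partition_summary",
    "relationship_table",
]


def sla(s: float, M_L: float) -> float:
    """Specific leaf area s/M_L (m^2 g^-1); an inverse proxy for leaf
    thickness."""
    if M_L <= 0:
        raise ValueError("leaf mass must be positive")
    return s / M_L


def rgr(x1: float, x2: float, t1_das: float, t2_das: float, scale: str = "area") -> float:
    """Two-point relative growth rate (ln x2 - ln x1)/(t2 - t1).

    ``scale="area"`` returns m^2 m^-2 day^-1 (RGR_S); ``scale="mass"``
    multiplies by 1000 for g kg^-1 day^-1 (RGR_M).
    """
    if x1 <= 0 or x2 <= 0:
        raise ValueError("quantities must be positive for a log growth rate")
    if t2_das <= t1_das:
        raise ValueError("t2 must exceed t1")
    rate = (math.log(x2) - math.log(x1)) / (t2_das - t1_das)
    if scale == "mass":
        return 1000.0 * rate
    if scale == "area":
        return rate
    raise ValueError("scale must be 'area' or 'mass'")


def growth_summary(result: SimulationResult) -> pd.DataFrame:
    """Per-day derived quantities: SLA, daily RGR_S / RGR_M, organ mass
    ratios and leaf area ratio.

    Daily RGRs use successive end-of-day states; the first simulated day has
    no predecessor and gets NaN.
    """
    d = result.daily
    out = pd.DataFrame({"das": d["das"], "phase": d["phase"]})
    out["sla"] = d["leaf_area"] / d["leaf_mass"]
    out["leaf_mass_ratio"] = d["leaf_mass"] / d["plant_mass"]
    out["stem_mass_ratio"] = d["infl_mass"] / d["plant_mass"]
    out["root_mass_ratio"] = d["root_mass"] / d["plant_mass"]
    out["leaf_area_ratio"] = d["leaf_area"] / d["plant_mass"]
    log_s = np.log(d["leaf_area"].to_numpy())
    log_m = np.log(d["plant_mass"].to_numpy())
    dt = np.diff(d["das"].to_numpy(), prepend=np.nan)
    out["rgr_s"] = np.concatenate([[np.nan], np.diff(log_s)]) / dt
    out["rgr_m"] = 1000.0 * np.concatenate([[np.nan], np.diff(log_m)]) / dt
    return out


def partition_summary(result: SimulationResult) -> pd.DataFrame:
    """Per-day fractions of the available C going to each fate.

    Available C for a day is assimilation plus mobilized seed C plus the net
    starch carried in, plus any unmet deficit (so the fractions of
    maintenance, growth respiration, exudation and the four growth sinks sum
    to exactly 1).  Days with no available C are flagged undefined.
    """
    d = result.daily
    supply = d["d_fixed_C"] + d["d_mobilized_C"] + (d["d_starch_in"] - d["d_starch_out"])
    # unmet deficit is added to the denominator so the fates sum to exactly 1,
    # but a day with no real C supply is undefined regardless of its deficit
    avail = supply + d["d_deficit_C"]
    out = pd.DataFrame({"das": d["das"], "available_C": avail})
    undefined = supply <= 0
    safe = avail.where(~undefined, np.nan)
    out["maintenance"] = d["d_maint_C"] / safe
    out["growth_respiration"] = d["d_growth_resp_C"] / safe
    out["exudation"] = d["d_exuded_C"] / safe
    out["leaf_area_growth"] = d["d_leaf_area_C"] / safe
    out["leaf_thickening"] = d["d_leaf_thick_C"] / safe
    out["inflorescence_growth"] = d["d_infl_C"] / safe
    out["root_growth"] = d["d_root_C"] / safe
    # informational: unmet respiratory demand as a share of available C
    # (already counted inside available_C, so not part of the unit sum)
    out["deficit_share"] = d["d_deficit_C"] / safe
    out["undefined"] = undefined
    return out


def relationship_table(result: SimulationResult) -> pd.DataFrame:
    """Paired daily series relating leaf traits to whole-plant growth:
    projected and total leaf area vs plant mass, leaf mass vs plant mass,
    SLA vs plant mass, and RGR_S vs RGR_M."""
    d = result.daily
    overlap = result.config.overlap
    if overlap.on_area:
        r = np.array([overlap(a) for a in d["leaf_area"]])
    else:
        r = np.array([overlap(x) for x in d["das"]])
    gs = growth_summary(result)
    return pd.DataFrame(
        {
            "das": d["das"],
            "phase": d["phase"],
            "projected_area": r * d["leaf_area"],
            "total_area": d["leaf_area"],
            "leaf_mass": d["leaf_mass"],
            "plant_mass": d["plant_mass"],
            "sla": gs["sla"],
            "rgr_s": gs["rgr_s"],
            "rgr_m": gs["rgr_m"],
        }
    )
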