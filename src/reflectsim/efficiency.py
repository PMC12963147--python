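"""Consumption accounting and reflection-efficiency computation.

Liquid anaesthetic consumption is read off the device's reservoir level per
constant-target period, extrapolated to an hourly infusion rate IR, and the
reflection efficiency follows from the open-system comparison::

    RE [%] = 100 * (1 - (100 * IR * F / (60 * EC * VT * RR)))

with IR in mL liquid/h, F the liquid-to-vapour conversion factor (mL/mL),
EC the end-tidal concentration in vol%, VT the tidal volume in mL and RR
the respiratory rate per minute.  The numerator 100·IR·F/60 is the vapour
delivered per minute; the denominator EC·VT·RR/100 · 100 is the vapour
leaving the lung per minute in an open system at the same EC — so RE is the
fraction of exhaled vapour the reflector returns, and turns negative when
delivery exceeds the open-system equivalent (reflector overload).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import AgentSpec, TargetPeriod, VentilationSettings

__all__ = [
    "consumption_per_period",
    "period_table",
    "average_up_down",
    "reflection_efficiency",
    "vapour_per_breath_ml",
    "co2e_savings",
    "summarize_efficiency",
]


def consumption_per_period(
    device_log: pd.DataFrame,
    periods: list[TargetPeriod],
    initial_reservoir_ml: float | None = None,
    tolerance_ml: float = 1e-6,
) -> pd.DataFrame:
    """Liquid consumption and hourly rate per constant-target period.

    ``device_log`` must carry per-breath ``t_s`` (end-of-breath time) and
    ``reservoir_ml`` columns.  Consumption in a period is the reservoir
    level just before its first breath minus the level after its last
    breath; the hourly rate extrapolates by 3600/period duration.  A
    reservoir that *increases* by more than ``tolerance_ml`` anywhere is a
    data error.
    """
    res = device_log["reservoir_ml"].to_numpy(dtype=float)
    t = device_log["t_s"].to_numpy(dtype=float)
    if len(res) == 0:
        raise ValueError("empty device log")
    increases = np.diff(res)
    if increases.size and increases.max() > tolerance_ml:
        i = int(np.argmax(increases))
        raise ValueError(
            f"reservoir increases by {increases[i]:.3g} mL at breath {i + 1}; "
            "inconsistent device log"
        )
    r0_global = float(initial_reservoir_ml) if initial_reservoir_ml is not None else float(res[0])
    rows = []
    for p in periods:
        in_period = (t > p.t_start_s) & (t <= p.t_end_s + 1e-9)
        idx = np.flatnonzero(in_period)
        if idx.size == 0:
            raise ValueError(f"no breaths recorded in period [{p.t_start_s}, {p.t_end_s}) s")
        before = np.flatnonzero(t <= p.t_start_s + 1e-9)
        r_start = float(res[before[-1]]) if before.size else r0_global
        r_end = float(res[idx[-1]])
        consumed = r_start - r_end
        rows.append(
            {
                "mac_fraction": p.mac_fraction,
                "t_start_s": p.t_start_s,
                "t_end_s": p.t_end_s,
                "period_duration_s": p.duration_s,
                "liquid_consumed_ml": consumed,
                "hourly_rate_ml_h": consumed * 3600.0 / p.duration_s,
            }
        )
    return pd.DataFrame(rows)


def average_up_down(period_records: pd.DataFrame, by: str = "mac_fraction") -> pd.DataFrame:
    """Average each target level's ascending and descending occurrences.

    Expects one or two rows per target level (the staircase peak occurs
    once); numeric columns are averaged arithmetically across occurrences.
    """
    if len(period_records) == 0:
        raise ValueError("no period records to average")
    key = period_records[by].round(9)
    counts = key.value_counts()
    if (counts > 2).any():
        bad = counts[counts > 2].index.tolist()
        raise ValueError(f"more than two occurrences for target level(s) {bad}")
    numeric = period_records.select_dtypes(include=[np.number]).columns
    out = (
        period_records.assign(**{by: key})
        .groupby(by, as_index=False)[list(numeric)]
        .mean()
        .sort_values(by)
        .reset_index(drop=True)
    )
    out["n_occurrences"] = counts.sort_index().to_numpy()
    return out


def reflection_efficiency(
    ir_ml_h: float, f: float, ec_volpct: float, vt_ml: float, rr: float
) -> float:
    """Reflection efficiency in percent from an hourly liquid rate.

    May be negative when the delivered vapour exceeds the open-system
    equivalent (reflector overload at high concentration / short flow).
    """
    if np.any(np.asarray(ec_volpct) <= 0):
        raise ValueError(
            "EC must be > 0: reflection efficiency is defined from steady-state "
            "consumption relative to the open-system equivalent at that EC"
        )
    if vt_ml <= 0 or rr <= 0:
        raise ValueError("VT and RR must be > 0")
    return 100.0 * (1.0 - (100.0 * ir_ml_h * f) / (60.0 * ec_volpct * vt_ml * rr))


def vapour_per_breath_ml(ec_volpct: float, vt_ml: float) -> float:
    """Anaesthetic vapour volume contained in one exhaled breath (mL)."""
    return ec_volpct / 100.0 * vt_ml


def co2e_savings(
    delta_ir_ml_h: float, density_g_ml: float, gwp_kg_per_g: float, hours: float
) -> float:
    """Greenhouse-gas saving (kg CO2 equivalents) from a consumption reduction.

    Product of liquid-rate reduction (mL/h), liquid density (g/mL), warming
    potential (kg CO2e per g agent) and duration (h).  The density is a
    required explicit argument — published CO2e figures are sensitive to it.
    """
    for name, v in (
        ("delta_ir_ml_h", delta_ir_ml_h),
        ("density_g_ml", density_g_ml),
        ("gwp_kg_per_g", gwp_kg_per_g),
        ("hours", hours),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return delta_ir_ml_h * density_g_ml * gwp_kg_per_g * hours


def period_table(
    breaths: pd.DataFrame,
    device_log: pd.DataFrame,
    periods: list[TargetPeriod],
    initial_reservoir_ml: float | None = None,
) -> pd.DataFrame:
    """Per-period consumption and monitor EC, one row per staircase period.

    Combines the reservoir-derived consumption with each period's mean
    monitor EC (incomplete breaths excluded) and an EC drift diagnostic:
    the mean of the period's last quarter of breaths minus its first
    quarter, a proxy for how far the period is from steady state.
    """
    cons = consumption_per_period(device_log, periods, initial_reservoir_ml)
    t_breath = breaths["expiration_onset_ms"].to_numpy(dtype=float) / 1000.0
    ec = breaths["ec_volpct"].to_numpy(dtype=float)
    mean_ecs, drifts = [], []
    for p in periods:
        sel = ec[(t_breath >= p.t_start_s) & (t_breath < p.t_end_s)]
        sel = sel[~np.isnan(sel)]
        if sel.size == 0:
            mean_ecs.append(math.nan)
            drifts.append(math.nan)
            continue
        mean_ecs.append(float(sel.mean()))
        q = max(1, sel.size // 4)
        drifts.append(float(sel[-q:].mean() - sel[:q].mean()))
    cons["mean_ec_volpct"] = mean_ecs
    cons["ec_drift_volpct"] = drifts
    return cons


@dataclass(frozen=True)
class EfficiencyRecord:
    """Per-target-level efficiency summary."""

    target_volpct: float
    mean_ec_volpct: float
    period_duration_s: float
    liquid_consumed_ml: float
    hourly_rate_ml_h: float
    vapour_per_breath_ml: float
    re_percent: float
    low_target_flag: bool


def summarize_efficiency(
    breaths: pd.DataFrame,
    device_log: pd.DataFrame,
    periods: list[TargetPeriod],
    vent: VentilationSettings,
    agent: AgentSpec,
    initial_reservoir_ml: float | None = None,
    low_target_mac: float = 0.6,
) -> pd.DataFrame:
    """One efficiency row per target level for a full staircase experiment.

    Consumption comes from the reservoir series per period (see
    :func:`period_table`); ascending and descending occurrences of each
    level are averaged; RE and vapour-per-breath are computed on the
    averaged values.  Levels below ``low_target_mac`` MAC are flagged
    (scatter in 10-min consumption makes their REs unreliable); the flag
    is only a marker for summaries — no rows are dropped.
    """
    cons = period_table(breaths, device_log, periods, initial_reservoir_ml)
    per_target = average_up_down(cons)
    per_target["target_volpct"] = per_target["mac_fraction"] * agent.mac_volpct
    per_target["vapour_per_breath_ml"] = vapour_per_breath_ml(
        per_target["mean_ec_volpct"].to_numpy(), vent.tidal_volume_ml
    )
    per_target["re_percent"] = [
        reflection_efficiency(
            ir, agent.vapour_factor_f, e, vent.tidal_volume_ml, vent.respiratory_rate
        )
        if e > 0
        else math.nan
        for ir, e in zip(per_target["hourly_rate_ml_h"], per_target["mean_ec_volpct"])
    ]
    per_target["low_target_flag"] = per_target["mac_fraction"] < low_target_mac
    return per_target
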