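"""Validated CSV dialects, experiment configuration and the run pipeline.

All file writes are atomic (write to a temp file, then rename) so an
interrupted run never leaves a truncated CSV behind.  Numeric precision is
fixed and documented: agent concentrations 2 decimals (the monitor's native
resolution), CO2 1 decimal, derived quantities 4 decimals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .breaths import GasTrace, analyze_trace
from .efficiency import period_table, summarize_efficiency
from .protocol import (
    AgentSpec,
    TargetSchedule,
    VentilationSettings,
    build_staircase_schedule,
)
from .simulate import InjectorParams, ReflectorParams, SimulationResult, simulate_experiment
from .stats import bland_altman, render_report

log = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "PipelineError",
    "read_trace",
    "write_trace",
    "read_device_log",
    "write_device_log",
    "load_config",
    "config_from_dict",
    "default_config_dict",
    "run_pipeline",
]

TRACE_COLUMNS = ["t_ms", "agent_volpct", "co2_mmHg"]
DEVICE_LOG_COLUMNS = ["breath_index", "t_s", "device_ec_volpct", "reservoir_ml", "target_volpct"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def _atomic_to_csv(df: pd.DataFrame, path: Path, float_format: str = "%.4f") -> None:
    tmp = path.with_name(path.name + ".tmp")
    df.to_csv(tmp, index=False, float_format=float_format)
    tmp.replace(path)


def write_trace(trace: GasTrace, path: str | Path) -> None:
    """Write a trace as CSV: integer t_ms, agent at 2 dp, CO2 at 1 dp."""
    path = Path(path)
    t_ms = (np.arange(len(trace)) * trace.sample_period_s * 1000).round().astype(int)
    lines = ["t_ms,agent_volpct,co2_mmHg"]
    agent = trace.agent_volpct
    co2 = trace.co2_mmhg
    lines.extend(f"{t},{a:.2f},{c:.1f}" for t, a, c in zip(t_ms, agent, co2))
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_trace(path: str | Path) -> GasTrace:
    """Read and validate a trace CSV.

    The timestamp column must be uniformly spaced (the sample period is
    inferred from it); gaps, missing columns and non-numeric cells raise
    a parse error naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except ValueError as err:
        raise ValueError(f"{path}: cannot parse CSV: {err}") from err
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected {TRACE_COLUMNS}")
    for col in TRACE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        if df[col].isna().any():
            bad = np.concatenate([bad, np.flatnonzero(df[col].isna().to_numpy())])
        if bad.size:
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(f"{path}: non-numeric value in {col!r} at line {int(bad.min()) + 2}")
        df[col] = vals
    t = df["t_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: trace needs at least two samples")
    dt = np.diff(t)
    step = dt[0]
    irregular = np.flatnonzero(np.abs(dt - step) > 1e-6)
    if irregular.size:
        i = int(irregular[0])
        raise ValueError(
            f"{path}: non-uniform sampling at line {i + 3}: gap of {dt[i]:.6g} ms "
            f"(expected {step:.6g} ms after t={t[i]:.6g} ms)"
        )
    return GasTrace(
        agent_volpct=df["agent_volpct"].to_numpy(dtype=float),
        co2_mmhg=df["co2_mmHg"].to_numpy(dtype=float),
        sample_period_s=step / 1000.0,
    )


def write_device_log(device_log: pd.DataFrame, path: str | Path) -> None:
    _atomic_to_csv(device_log[DEVICE_LOG_COLUMNS], Path(path))


def read_device_log(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in DEVICE_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


# --- configuration -----------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully resolved configuration for one experiment."""

    vent: VentilationSettings
    agent: AgentSpec
    schedule: TargetSchedule
    reflector: ReflectorParams
    injector: InjectorParams
    noise_sd: float = 0.01
    co2_noise_sd: float = 0.1
    device_noise_sd: float = 0.01
    reservoir_ml: float = 250.0
    initial_lung_volpct: float = 0.0
    lung_volume_ml: float = 3000.0
    raw: dict = dataclasses.field(default_factory=dict, repr=False)


def default_config_dict() -> dict:
    """The bench defaults: VT 500 mL, RR 10/min, I:E 1:1, IF 12 L/min,
    isoflurane, 0.2→1.5→0.2 MAC staircase (10-min steps, 20-min peak)."""
    return {
        "ventilation": {
            "tidal_volume_ml": 500.0,
            "respiratory_rate": 10.0,
            "ie_ratio": [1.0, 1.0],
            "inspiratory_flow_lpm": 12.0,
            "peep_hpa": 3.0,
            "fio2": 0.21,
        },
        "agent": {"name": "isoflurane"},
        "schedule": {
            "max_fraction": 1.5,
            "step": 0.2,
            "step_duration_s": 600.0,
            "peak_duration_s": 1200.0,
        },
        "reflector": {},
        "injector": {},
        "simulation": {},
    }


def config_from_dict(d: dict) -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig` from a plain mapping.

    Every block is optional; omitted keys fall back to the bench defaults.
    The agent block accepts just a name, with optional ``mac_volpct`` /
    ``vapour_factor_f`` overrides.  The schedule block is either an explicit
    ``steps: [[mac_fraction, duration_s], ...]`` list or staircase-generator
    parameters.
    """
    base = default_config_dict()
    merged = {k: {**base.get(k, {}), **(d.get(k) or {})} for k in base}
    vent = VentilationSettings(
        tidal_volume_ml=float(merged["ventilation"]["tidal_volume_ml"]),
        respiratory_rate=float(merged["ventilation"]["respiratory_rate"]),
        ie_ratio=tuple(float(x) for x in merged["ventilation"]["ie_ratio"]),
        inspiratory_flow_lpm=float(merged["ventilation"]["inspiratory_flow_lpm"]),
        peep_hpa=float(merged["ventilation"]["peep_hpa"]),
        fio2=float(merged["ventilation"]["fio2"]),
    )
    a = merged["agent"]
    agent = AgentSpec.by_name(a.get("name", "isoflurane"))
    if "mac_volpct" in a or "vapour_factor_f" in a:
        agent = AgentSpec(
            name=agent.name,
            mac_volpct=float(a.get("mac_volpct", agent.mac_volpct)),
            vapour_factor_f=float(a.get("vapour_factor_f", agent.vapour_factor_f)),
        )
    s = merged["schedule"]
    if "steps" in s and s["steps"]:
        schedule = TargetSchedule(
            steps=tuple((float(f_), float(dur)) for f_, dur in s["steps"])
        )
    else:
        schedule = build_staircase_schedule(
            max_fraction=float(s["max_fraction"]),
            step=float(s["step"]),
            step_duration_s=float(s["step_duration_s"]),
            peak_duration_s=float(s["peak_duration_s"]),
        )
    reflector = ReflectorParams(**merged["reflector"])
    injector = InjectorParams(**merged["injector"])
    sim = merged["simulation"]
    return ExperimentConfig(
        vent=vent,
        agent=agent,
        schedule=schedule,
        reflector=reflector,
        injector=injector,
        noise_sd=float(sim.get("noise_sd", 0.01)),
        co2_noise_sd=float(sim.get("co2_noise_sd", 0.1)),
        device_noise_sd=float(sim.get("device_noise_sd", 0.01)),
        reservoir_ml=float(sim.get("reservoir_ml", 250.0)),
        initial_lung_volpct=float(sim.get("initial_lung_volpct", 0.0)),
        lung_volume_ml=float(sim.get("lung_volume_ml", 3000.0)),
        raw=d,
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML (or JSON — a YAML subset) config file."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return config_from_dict(d)


def simulate_from_config(config: ExperimentConfig, seed: int) -> SimulationResult:
    return simulate_experiment(
        vent=config.vent,
        agent=config.agent,
        schedule=config.schedule,
        reflector=config.reflector,
        injector=config.injector,
        noise_sd=config.noise_sd,
        co2_noise_sd=config.co2_noise_sd,
        device_noise_sd=config.device_noise_sd,
        seed=seed,
        lung_volume_ml=config.lung_volume_ml,
        reservoir_ml=config.reservoir_ml,
        initial_lung_volpct=config.initial_lung_volpct,
    )


def _config_digest(config: ExperimentConfig) -> str:
    payload = json.dumps(config.raw or dataclasses.asdict(config)["raw"], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_manifest(outdir: Path, config: ExperimentConfig, seed: int, outputs: list[str]) -> dict:
    manifest = {
        "tool": "reflectsim",
        "version": __version__,
        "seed": int(seed),
        "config_sha256": _config_digest(config),
        "outputs": sorted(outputs),
        "created_unix": time.time(),
    }
    _atomic_write_text(outdir / "manifest.json", json.dumps(manifest, indent=2) + "\n")
    return manifest


def run_pipeline(
    config: ExperimentConfig,
    seed: int,
    outdir: str | Path,
    write_plots: bool = True,
) -> dict[str, Any]:
    """End-to-end simulate → analyze → report run.

    Writes the trace, device log, ground truth, per-breath analysis,
    per-target efficiency table, agreement summary, report plots and a run
    manifest into ``outdir``.  Raises :class:`PipelineError` naming the
    failing stage.  Returns a dict of the in-memory results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        sim = simulate_from_config(config, seed)
    except Exception as err:
        raise PipelineError("simulate", str(err)) from err
    log.info("simulate: %d breaths, status %s", sim.n_breaths, sim.status)
    write_trace(sim.trace, outdir / "trace.csv")
    write_device_log(sim.device_log, outdir / "device_log.csv")
    _atomic_to_csv(sim.ground_truth, outdir / "ground_truth.csv", float_format="%.6f")

    try:
        breaths = analyze_trace(sim.trace)
    except Exception as err:
        raise PipelineError("analyze-breaths", str(err)) from err
    log.info("analyze-breaths: %d breaths segmented", len(breaths))

    try:
        period_df = period_table(
            breaths,
            sim.device_log,
            config.schedule.periods(),
            initial_reservoir_ml=config.reservoir_ml,
        )
        efficiency = summarize_efficiency(
            breaths,
            sim.device_log,
            config.schedule.periods(),
            config.vent,
            config.agent,
            initial_reservoir_ml=config.reservoir_ml,
        )
    except Exception as err:
        raise PipelineError("efficiency", str(err)) from err

    try:
        merged = pd.merge(
            sim.device_log[["breath_index", "device_ec_volpct"]],
            breaths[["breath_index", "ec_volpct"]],
            on="breath_index",
        )
        agreement = bland_altman(
            merged["device_ec_volpct"].to_numpy(), merged["ec_volpct"].to_numpy()
        )
    except Exception as err:
        raise PipelineError("stats", str(err)) from err

    try:
        formats = ("csv", "png") if write_plots else ("csv",)
        written = render_report(
            outdir,
            breaths=breaths,
            efficiency=efficiency,
            periods=period_df,
            agreement=agreement,
            device_log=sim.device_log,
            formats=formats,
        )
    except Exception as err:
        raise PipelineError("report", str(err)) from err

    outputs = ["trace.csv", "device_log.csv", "ground_truth.csv"] + [p.name for p in written]
    manifest = write_manifest(outdir, config, seed, outputs)
    return {
        "simulation": sim,
        "breaths": breaths,
        "efficiency": efficiency,
        "periods": period_df,
        "agreement": agreement,
        "manifest": manifest,
    }
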