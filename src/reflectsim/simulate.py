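"""Seeded bench simulator for reflection-based anaesthetic delivery.

The physical picture: a ventilator drives a test lung (a 3 L breathing bag;
perfect mixing, no wall uptake) through volume-controlled cycles.  Between
Y-piece and lung sits a reflector interface that adsorbs exhaled anaesthetic
vapour and releases it during the next inspiration, plus an injector that
adds saturated vapour at early inspiration under target control.  A
side-stream monitor at the airway samples anaesthetic (vol%) and CO2 (mmHg)
at 10 Hz.

Per-breath vapour bookkeeping (all volumes in mL of vapour):

* inspiration — the reflector releases its store and the controller may
  inject a bolus; whatever the injector cannot deliver within the
  inspiratory-flow phase spills into an interface cloud during the pause;
* expiration — the lung exhales at its mixed concentration; the exhaled
  vapour plus any interface cloud is pushed against the reflector, which
  captures ``min(base_efficiency × presented, capacity_per_breath)``; the
  remainder is vented from the circuit and irreversibly consumed;
* the liquid reservoir falls by (injected vapour)/F.

The CO2 channel reproduces the washout geometry the analysis relies on:
the expirogram crosses the 34 mmHg marking threshold with a delay after
true expiration onset and stays supra-threshold for a retention time into
the next inspiration, because expired gas held in the interface passes the
sampling port at early inspiration.  During that retention time the agent
channel shows the previous breath's gas (plus any injection peak), after
which the reflected-gas baseline and injection transients follow.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breaths import GasTrace
from .protocol import AgentSpec, TargetSchedule, VentilationSettings, phase_durations

log = logging.getLogger(__name__)

__all__ = [
    "ReflectorParams",
    "InjectorParams",
    "SimState",
    "SimulationResult",
    "simulate_experiment",
    "steady_state_true_re",
    "mass_balance_residual",
]

SAMPLE_PERIOD_S = 0.1
LUNG_VOLUME_ML = 3000.0  # 3 L breathing-bag test lung
CO2_RISE_DELAY_S = 0.8  # threshold crossing lags expiration onset
PEAK_DECAY_TAU_S = 0.8  # lingering vapour at the sampling port after injection
PORT_DELAY_S = 0.5  # transit of the injected bolus to the side-stream sampling port


@dataclass(frozen=True)
class ReflectorParams:
    """Anaesthetic reflector behaviour.

    base_efficiency : fraction of presented vapour captured per breath
        (and released during the following inspiration).
    capacity_per_breath_ml : hard ceiling on vapour captured per breath;
        overload (high concentrations, spill-over clouds) is vented.
    interface_retention_time_s : how long expired gas retained in the
        interface keeps the CO2 signal supra-threshold into inspiration.
    co2_reflection_floor_mmhg : inspiratory CO2 baseline (the reflector
        reflects a little CO2, so inspired CO2 is not zero).
    """

    base_efficiency: float = 0.85
    capacity_per_breath_ml: float = 7.2
    interface_retention_time_s: float = 1.0
    co2_reflection_floor_mmhg: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_efficiency <= 1.0:
            raise ValueError(f"base_efficiency must be in [0, 1], got {self.base_efficiency}")
        if not self.capacity_per_breath_ml > 0:
            raise ValueError("capacity_per_breath_ml must be > 0")
        if self.interface_retention_time_s < 0:
            raise ValueError("interface_retention_time_s must be >= 0")


@dataclass(frozen=True)
class InjectorParams:
    """Phenomenological target controller for vapour injection.

    The real device's control algorithm is not public; this controller
    reproduces the observed behaviour: end-tidal concentration drifts below
    target, a series of per-breath injections at early inspiration restores
    it with some overshoot, then the cycle repeats.

    vapour_rate_mls : saturated-vapour delivery rate (mL vapour/s).
        The value 0 disables the injector entirely.
    gain : fraction of the concentration deficit corrected per injection.
    min_bolus_ml : smallest vapour shot the injector fires (mL); deficits
        calling for less are rounded up to one quantum, which is what makes
        the end-tidal concentration overshoot the target after a series.
    trigger_hysteresis_volpct : how far (vol%) the controller's end-tidal
        estimate must fall below target before an injection series starts.
    ec_filter_alpha : first-order filter weight on the device's per-breath
        end-tidal measurement; stands in for side-stream delay and
        incomplete mixing, and is what makes injections come in series
        that overshoot the target before stopping.
    mode : "series" (normal target control) or "replacement" (inject
        exactly the vapour vented on the previous breath — a frozen
        controller that holds the lung concentration constant, used as a
        steady-state oracle).
    """

    vapour_rate_mls: float = 4.0
    gain: float = 0.9
    min_bolus_ml: float = 3.0
    trigger_hysteresis_volpct: float = 0.10
    ec_filter_alpha: float = 0.16
    mode: str = "series"

    def __post_init__(self) -> None:
        if self.vapour_rate_mls < 0:
            raise ValueError("vapour_rate_mls must be >= 0 (0 disables the injector)")
        if not 0.0 < self.gain <= 1.0:
            raise ValueError(f"gain must be in (0, 1], got {self.gain}")
        if self.min_bolus_ml < 0:
            raise ValueError("min_bolus_ml must be >= 0")
        if self.trigger_hysteresis_volpct < 0:
            raise ValueError("trigger_hysteresis_volpct must be >= 0")
        if not 0.0 < self.ec_filter_alpha <= 1.0:
            raise ValueError("ec_filter_alpha must be in (0, 1]")
        if self.mode not in ("series", "replacement"):
            raise ValueError(f"mode must be 'series' or 'replacement', got {self.mode!r}")

    @property
    def enabled(self) -> bool:
        return self.vapour_rate_mls > 0


@dataclass(frozen=True)
class SimState:
    """Snapshot of the simulator's physical state."""

    lung_concentration_volpct: float
    reflector_store_ml: float
    interface_cloud_ml: float
    reservoir_ml: float
    rng_seed: int


@dataclass(frozen=True)
class SimulationResult:
    """Everything a bench run produces.

    trace : the 10 Hz dual-channel monitor recording.
    device_log : per-breath device record (device-measured EC with its own
        noise, reservoir liquid level, target).
    ground_truth : per-breath vapour bookkeeping for validation — exhaled,
        injected, captured and vented volumes, the true lung plateau
        concentration, and the true injection time.
    """

    trace: GasTrace
    device_log: pd.DataFrame
    ground_truth: pd.DataFrame
    initial_state: SimState
    final_state: SimState
    status: str = "completed"
    lung_volume_ml: float = LUNG_VOLUME_ML

    @property
    def n_breaths(self) -> int:
        return len(self.ground_truth)


def simulate_experiment(
    vent: VentilationSettings,
    agent: AgentSpec,
    schedule: TargetSchedule,
    reflector: ReflectorParams | None = None,
    injector: InjectorParams | None = None,
    noise_sd: float = 0.01,
    co2_noise_sd: float = 0.1,
    device_noise_sd: float = 0.01,
    seed: int = 0,
    lung_volume_ml: float = LUNG_VOLUME_ML,
    reservoir_ml: float = 250.0,
    initial_lung_volpct: float = 0.0,
    interface_volume_ml: float = 100.0,
) -> SimulationResult:
    """Simulate one bench experiment over a target schedule.

    Returns the monitor trace, the per-breath device log and the per-breath
    ground truth.  The same seed always yields bit-identical output; the
    device log's measurement noise comes from a sub-stream independent of
    the trace noise.  If the liquid reservoir runs dry the simulation stops
    at that breath with status ``"reservoir_exhausted"`` and a truncated
    trace.
    """
    reflector = reflector or ReflectorParams()
    injector = injector or InjectorParams()
    phases = phase_durations(vent)
    insp_s = phases.flow_s + phases.pause_s
    if reflector.interface_retention_time_s >= insp_s:
        raise ValueError(
            f"interface_retention_time_s {reflector.interface_retention_time_s} must be "
            f"shorter than the inspiration duration {insp_s}"
        )
    if reservoir_ml < 0 or initial_lung_volpct < 0 or lung_volume_ml <= 0:
        raise ValueError("reservoir, lung volume and initial concentration must be valid")

    sp = SAMPLE_PERIOD_S
    cycle_s = vent.cycle_duration_s
    n_cycle = int(round(cycle_s / sp))
    if abs(n_cycle * sp - cycle_s) > 1e-9:
        raise ValueError("cycle duration must be a multiple of the 100 ms sample period")
    n_breaths = int(round(schedule.total_duration_s / cycle_s))
    n_samples = n_breaths * n_cycle

    rng = np.random.default_rng(seed)
    trace_rng, device_rng = rng.spawn(2)
    etco2_plateau = float(trace_rng.uniform(35.0, 45.0))

    n_insp = int(round(insp_s / sp))
    n_ret = int(round(reflector.interface_retention_time_s / sp))

    vt = vent.tidal_volume_ml
    v_lung = lung_volume_ml
    f = agent.vapour_factor_f
    flow_mls = vent.inspiratory_flow_lpm * 1000.0 / 60.0

    agent_ch = np.zeros(n_samples)
    co2_ch = np.full(n_samples, reflector.co2_reflection_floor_mmhg)

    lung_vapour = initial_lung_volpct / 100.0 * v_lung
    store = 0.0
    cloud = 0.0
    vapour_budget = reservoir_ml * f  # remaining injectable vapour
    prev_plateau = initial_lung_volpct

    initial_state = SimState(
        lung_concentration_volpct=initial_lung_volpct,
        reflector_store_ml=store,
        interface_cloud_ml=cloud,
        reservoir_ml=reservoir_ml,
        rng_seed=seed,
    )

    ec_ctrl = initial_lung_volpct  # controller's filtered end-tidal estimate
    series_active = False
    vented_prev = 0.0
    status = "completed"

    gt_rows: list[dict] = []
    dev_rows: list[dict] = []
    insp_times = np.arange(n_insp) * sp  # relative to inspiration onset

    for b in range(n_breaths):
        t0 = b * cycle_s
        target_volpct = schedule.target_at(t0) * agent.mac_volpct

        # --- controller decides the bolus for this inspiration ---
        bolus = 0.0
        if injector.enabled:
            if injector.mode == "replacement":
                bolus = vented_prev
            else:
                deficit = target_volpct - ec_ctrl
                if not series_active and deficit > injector.trigger_hysteresis_volpct:
                    series_active = True
                if series_active:
                    if deficit <= 0 or target_volpct <= 0:
                        series_active = False
                    else:
                        bolus = injector.gain * deficit / 100.0 * (v_lung + vt)
                        bolus = max(bolus, injector.min_bolus_ml)
                        bolus = min(bolus, injector.vapour_rate_mls * insp_s)
            if bolus > vapour_budget:
                bolus = max(vapour_budget, 0.0)
                status = "reservoir_exhausted"
        vapour_budget -= bolus
        in_flow = min(bolus, injector.vapour_rate_mls * phases.flow_s) if injector.enabled else 0.0
        spill = bolus - in_flow
        t_inj_true = bolus / injector.vapour_rate_mls if injector.enabled and bolus > 0 else 0.0

        # --- inspiration: reflector release + injection enter the lung ---
        release = store
        store = 0.0
        lung_vapour += release + in_flow
        cloud += spill
        c_ei = lung_vapour / (v_lung + vt) * 100.0

        # --- expiration: exhale, present to reflector, capture, vent ---
        exhaled_lung = lung_vapour * vt / (v_lung + vt)
        lung_vapour -= exhaled_lung
        exhaled_total = exhaled_lung + cloud
        captured = min(reflector.base_efficiency * exhaled_total, reflector.capacity_per_breath_ml)
        vented = exhaled_total - captured
        store = captured
        cloud = 0.0
        vented_prev = vented

        # --- agent waveform: retained-gas baseline, reflected-gas baseline,
        #     injection peak with a decaying tail, spill cloud in the pause ---
        i0 = b * n_cycle
        seg = np.full(n_insp, release / vt * 100.0)
        seg[:n_ret] = prev_plateau
        if in_flow > 0:
            t_flow_inj = in_flow / injector.vapour_rate_mls
            amp = injector.vapour_rate_mls / flow_mls * 100.0
            t_vis0 = PORT_DELAY_S
            t_vis1 = PORT_DELAY_S + t_flow_inj
            during = (insp_times >= t_vis0) & (insp_times < t_vis1)
            seg[during] += amp
            after = insp_times >= t_vis1
            seg[after] += amp * np.exp(-(insp_times[after] - t_vis1) / PEAK_DECAY_TAU_S)
        if spill > 0:
            cloud_conc = min(spill / interface_volume_ml * 100.0, 25.0)
            pause_mask = insp_times >= phases.flow_s
            seg[pause_mask] = np.maximum(seg[pause_mask], cloud_conc)
        agent_ch[i0 : i0 + n_insp] = seg
        agent_ch[i0 + n_insp : i0 + n_cycle] = c_ei

        # --- CO2 expirogram ---
        i_cross = i0 + n_insp + int(round(CO2_RISE_DELAY_S / sp))
        i_run_end = min(i0 + n_cycle + n_ret, n_samples)
        floor = reflector.co2_reflection_floor_mmhg
        rise_lo = max(i0 + n_insp, i_cross - int(round(0.5 / sp)))
        k = np.arange(i_cross - rise_lo)
        if len(k):
            frac = (k + 1) / (len(k) + 1)
            co2_ch[rise_lo:i_cross] = floor + (33.0 - floor) * frac**2
        kk = np.arange(i_run_end - i_cross) * sp
        co2_ch[i_cross:i_run_end] = 34.5 + (etco2_plateau - 34.5) * (1.0 - np.exp(-kk / 0.15))
        fall_hi = min(i_run_end + int(round(0.4 / sp)), n_samples)
        kk = np.arange(fall_hi - i_run_end) * sp
        if len(kk):
            co2_ch[i_run_end:fall_hi] = floor + (33.0 - floor) * np.exp(-kk / 0.25)

        # --- device log & controller update ---
        device_ec = c_ei + (device_rng.normal(0.0, device_noise_sd) if device_noise_sd > 0 else 0.0)
        ec_ctrl = (1 - injector.ec_filter_alpha) * ec_ctrl + injector.ec_filter_alpha * device_ec
        reservoir_now = vapour_budget / f
        prev_plateau = c_ei

        gt_rows.append(
            {
                "breath_index": b,
                "t_start_s": t0,
                "target_volpct": target_volpct,
                "lung_volpct": c_ei,
                "release_ml": release,
                "injected_ml": bolus,
                "in_flow_ml": in_flow,
                "spill_ml": spill,
                "exhaled_lung_ml": exhaled_lung,
                "exhaled_total_ml": exhaled_total,
                "captured_ml": captured,
                "vented_ml": vented,
                "t_inj_true_s": t_inj_true,
                "reservoir_ml": reservoir_now,
            }
        )
        dev_rows.append(
            {
                "breath_index": b,
                "t_s": t0 + cycle_s,
                "device_ec_volpct": device_ec,
                "reservoir_ml": reservoir_now,
                "target_volpct": target_volpct,
            }
        )
        if status == "reservoir_exhausted":
            log.warning("reservoir exhausted at breath %d; simulation stopped", b)
            agent_ch = agent_ch[: i0 + n_cycle]
            co2_ch = co2_ch[: i0 + n_cycle]
            break

    if noise_sd > 0:
        agent_ch = agent_ch + trace_rng.normal(0.0, noise_sd, size=len(agent_ch))
    if co2_noise_sd > 0:
        co2_ch = co2_ch + trace_rng.normal(0.0, co2_noise_sd, size=len(co2_ch))
    agent_ch = np.maximum(agent_ch, 0.0)
    co2_ch = np.maximum(co2_ch, 0.0)

    final_state = SimState(
        lung_concentration_volpct=lung_vapour / v_lung * 100.0,
        reflector_store_ml=store,
        interface_cloud_ml=cloud,
        reservoir_ml=vapour_budget / f,
        rng_seed=seed,
    )
    return SimulationResult(
        trace=GasTrace(agent_volpct=agent_ch, co2_mmhg=co2_ch, sample_period_s=sp),
        device_log=pd.DataFrame(dev_rows),
        ground_truth=pd.DataFrame(gt_rows),
        initial_state=initial_state,
        final_state=final_state,
        status=status,
        lung_volume_ml=lung_volume_ml,
    )


def steady_state_true_re(
    ground_truth: pd.DataFrame, t_start_s: float, t_end_s: float
) -> float:
    """Ground-truth reflection efficiency over a time window, in percent.

    RE = 100 × (1 − vented/exhaled) summed over the window's breaths: the
    fraction of exhaled vapour that was *not* irreversibly consumed.  This
    is the oracle against which the analysis-side RE (computed from liquid
    consumption) is validated at steady state.
    """
    sel = ground_truth[
        (ground_truth["t_start_s"] >= t_start_s) & (ground_truth["t_start_s"] < t_end_s)
    ]
    exhaled = sel["exhaled_total_ml"].sum()
    if exhaled <= 0:
        raise ValueError("no exhaled vapour in the window; true RE is undefined")
    return 100.0 * (1.0 - sel["vented_ml"].sum() / exhaled)


def mass_balance_residual(result: SimulationResult) -> float:
    """Relative closure error of the per-experiment vapour mass balance.

    injected = Δ(lung) + Δ(reflector store) + Δ(interface cloud) + vented,
    expressed relative to total injected vapour (or 1 mL if nothing was
    injected).
    """
    gt = result.ground_truth
    v = result.lung_volume_ml
    d_lung = (
        result.final_state.lung_concentration_volpct
        - result.initial_state.lung_concentration_volpct
    ) / 100.0 * v
    d_store = result.final_state.reflector_store_ml - result.initial_state.reflector_store_ml
    d_cloud = result.final_state.interface_cloud_ml - result.initial_state.interface_cloud_ml
    injected = gt["injected_ml"].sum()
    vented = gt["vented_ml"].sum()
    residual = injected - (d_lung + d_store + d_cloud + vented)
    return abs(residual) / max(injected, 1.0)
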