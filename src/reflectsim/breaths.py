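"""Breath-by-breath evaluation of dual-channel gas traces.

A 10 Hz side-stream monitor records anaesthetic concentration (vol%) and CO2
partial pressure (mmHg) at the airway.  Expiration is identified roughly as
the maximal runs of CO2 above a threshold (34 mmHg by default).  Because
expired gas retained in the reflector interface washes past the sampling
port at early inspiration, the supra-threshold run outlasts true expiration
by about a second; the end-tidal anaesthetic concentration (EC) is therefore
the mean of a fixed window of agent samples starting shortly after the run
begins, and the run's tail overlaps the next inspiration where injection
peaks appear.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GasTrace",
    "PeakMetrics",
    "segment_breaths",
    "ec_window",
    "compute_ec",
    "quantify_peak",
    "analyze_trace",
]

CO2_THRESHOLD_MMHG = 34.0
EC_OFFSET_S = 0.2
EC_WINDOW_SAMPLES = 20
DEBOUNCE_S = 0.5


@dataclass(frozen=True)
class GasTrace:
    """Uniformly sampled dual-channel gas trace.

    Sample ``i`` covers the time interval ``[i*sample_period_s,
    (i+1)*sample_period_s)``.  Channels must have equal length; gaps are an
    input error handled at read time, not here.
    """

    agent_volpct: np.ndarray
    co2_mmhg: np.ndarray
    sample_period_s: float = 0.1

    def __post_init__(self) -> None:
        agent = np.asarray(self.agent_volpct, dtype=float)
        co2 = np.asarray(self.co2_mmhg, dtype=float)
        object.__setattr__(self, "agent_volpct", agent)
        object.__setattr__(self, "co2_mmhg", co2)
        if agent.ndim != 1 or co2.ndim != 1:
            raise ValueError("channels must be one-dimensional")
        if len(agent) != len(co2):
            raise ValueError(
                f"channel lengths differ: agent {len(agent)} vs co2 {len(co2)}"
            )
        if not self.sample_period_s > 0:
            raise ValueError(f"sample_period_s must be > 0, got {self.sample_period_s}")

    def __len__(self) -> int:
        return len(self.agent_volpct)

    @property
    def duration_s(self) -> float:
        return len(self) * self.sample_period_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) * self.sample_period_s


def segment_breaths(
    trace: GasTrace,
    co2_threshold: float = CO2_THRESHOLD_MMHG,
    debounce_s: float = DEBOUNCE_S,
) -> list[tuple[int, int]]:
    """Maximal runs of strictly supra-threshold CO2, as half-open index pairs.

    Samples exactly at the threshold do not count (strict ``>``).  Runs
    shorter than ``debounce_s`` are discarded as noise; under regular
    volume-controlled ventilation each surviving run corresponds to one
    breath's expiration (plus its interface washout tail).
    """
    if co2_threshold <= 0:
        raise ValueError(f"co2_threshold must be > 0, got {co2_threshold}")
    above = trace.co2_mmhg > co2_threshold
    if not above.any():
        return []
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    min_len = max(1, int(round(debounce_s / trace.sample_period_s)))
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def ec_window(
    run: tuple[int, int],
    sample_period_s: float,
    offset_s: float = EC_OFFSET_S,
    window_samples: int = EC_WINDOW_SAMPLES,
) -> tuple[int, int] | None:
    """Index window (half-open) of agent samples entering the EC average.

    The window holds ``window_samples`` consecutive samples beginning
    ``offset_s`` after the run's first supra-threshold sample.  ``None`` if
    the run is too short to supply offset + window samples, in which case the
    breath is incomplete.
    """
    start, end = run
    n_offset = int(round(offset_s / sample_period_s))
    w_start = start + n_offset
    w_end = w_start + window_samples
    if w_end > end:
        return None
    return (w_start, w_end)


def compute_ec(
    trace: GasTrace,
    run: tuple[int, int],
    offset_s: float = EC_OFFSET_S,
    window_samples: int = EC_WINDOW_SAMPLES,
) -> float:
    """End-tidal anaesthetic concentration for one expiration run.

    Arithmetic mean of ``window_samples`` agent samples starting ``offset_s``
    after the run's first sample (with a 30-sample run at 10 Hz and the
    defaults, exactly 20 samples are averaged and the final 8 supra-threshold
    samples — contaminated by early-inspiration washout — are excluded).
    Returns NaN for runs too short for the window; such breaths are excluded
    from any downstream mean.
    """
    win = ec_window(run, trace.sample_period_s, offset_s, window_samples)
    if win is None:
        log.warning(
            "run [%d, %d) too short for EC window (offset %.2g s + %d samples); "
            "breath flagged incomplete",
            run[0],
            run[1],
            offset_s,
            window_samples,
        )
        return math.nan
    return float(np.mean(trace.agent_volpct[win[0] : win[1]]))


@dataclass(frozen=True)
class PeakMetrics:
    """Injection-peak quantification over one inspiratory window."""

    cpeak_volpct: float
    t_inj_s: float
    auc_volpct_s: float
    present: bool


def quantify_peak(
    trace: GasTrace,
    breath_window: tuple[int, int],
    next_ec: float,
    min_samples: int = 2,
    min_excess: float = 0.05,
) -> PeakMetrics:
    """Quantify anaesthetic injection over a between-run window.

    ``breath_window`` spans from the end of a breath's expiration run to the
    start of the next run.  The excess of the agent channel over the
    subsequent breath's EC is formed sample-wise; the count of positive
    excess values times the sample period is the injection duration T-inj,
    and their sum times the sample period is the AUC in vol%·s.  Cpeak is the
    maximum agent concentration in the window.  A peak is deemed present only
    when at least ``min_samples`` excess values are positive and Cpeak
    exceeds ``next_ec`` by ``min_excess`` vol%, which suppresses noise-only
    detections.
    """
    start, end = breath_window
    if end <= start:
        return PeakMetrics(math.nan, 0.0, 0.0, False)
    seg = trace.agent_volpct[start:end]
    excess = seg - next_ec
    positive = excess[excess > 0]
    sp = trace.sample_period_s
    t_inj = len(positive) * sp
    auc = float(positive.sum() * sp)
    cpeak = float(seg.max())
    present = bool(
        len(positive) >= min_samples
        and not math.isnan(next_ec)
        and cpeak - next_ec >= min_excess
    )
    return PeakMetrics(cpeak_volpct=cpeak, t_inj_s=t_inj, auc_volpct_s=auc, present=present)


def analyze_trace(
    trace: GasTrace,
    co2_threshold: float = CO2_THRESHOLD_MMHG,
    ec_offset_s: float = EC_OFFSET_S,
    ec_window_samples: int = EC_WINDOW_SAMPLES,
    min_peak_samples: int = 2,
    min_peak_excess: float = 0.05,
) -> pd.DataFrame:
    """Full breath-by-breath evaluation of a trace.

    Segments expirations, extracts per-breath EC, and quantifies the
    injection peak in each between-run inspiratory window.  The peak after
    breath *i*'s run is referenced to breath *i+1*'s EC (the subsequent
    breath); the final breath, having no successor, is referenced to its own
    EC.  Returns one row per breath::

        breath_index, expiration_onset_ms, ec_volpct, cpeak_volpct,
        t_inj_s, auc_volpcts, peak_present
    """
    runs = segment_breaths(trace, co2_threshold)
    n = len(runs)
    ecs = [
        compute_ec(trace, run, offset_s=ec_offset_s, window_samples=ec_window_samples)
        for run in runs
    ]
    n_incomplete = sum(math.isnan(e) for e in ecs)
    if n_incomplete:
        log.warning("%d of %d breaths incomplete (EC missing)", n_incomplete, n)
    rows = []
    for i, run in enumerate(runs):
        win_start = run[1]
        win_end = runs[i + 1][0] if i + 1 < n else len(trace)
        ref_ec = ecs[i + 1] if i + 1 < n else ecs[i]
        if math.isnan(ref_ec):  # fall back so peaks are not silently lost
            ref_ec = ecs[i]
        pk = quantify_peak(
            trace,
            (win_start, win_end),
            ref_ec,
            min_samples=min_peak_samples,
            min_excess=min_peak_excess,
        )
        rows.append(
            {
                "breath_index": i,
                "expiration_onset_ms": int(round(run[0] * trace.sample_period_s * 1000)),
                "ec_volpct": ecs[i],
                "cpeak_volpct": pk.cpeak_volpct,
                "t_inj_s": pk.t_inj_s,
                "auc_volpcts": pk.auc_volpct_s,
                "peak_present": pk.present,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "breath_index",
            "expiration_onset_ms",
            "ec_volpct",
            "cpeak_volpct",
            "t_inj_s",
            "auc_volpcts",
            "peak_present",
        ],
    )
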