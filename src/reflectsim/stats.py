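"""Agreement and regression statistics, and the tabular/plot report.

Two method-comparison tools are provided: classical Bland-Altman agreement
between the device's and the external monitor's end-tidal measurements
(bias = mean difference, limits of agreement = bias ± 1.96 × SD of the
differences), and polynomial regression of hourly consumption on mean EC
with a pooled linear-model contrast between experiment groups.  No
multiple-testing correction is applied; p < 0.05 is the significance
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = [
    "AgreementResult",
    "ConsumptionFit",
    "bland_altman",
    "fit_consumption",
    "render_report",
]


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement between two paired measurement series."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)


def bland_altman(device: np.ndarray, monitor: np.ndarray) -> AgreementResult:
    """Bland-Altman agreement of device vs monitor end-tidal concentrations.

    Differences are device − monitor; pairs with a missing member are
    dropped.  Limits of agreement use the sample SD (ddof=1) and the
    classical 1.96 multiplier.  Requires at least two complete pairs.
    """
    device = np.asarray(device, dtype=float)
    monitor = np.asarray(monitor, dtype=float)
    if device.shape != monitor.shape:
        raise ValueError(f"paired series differ in length: {device.shape} vs {monitor.shape}")
    ok = ~(np.isnan(device) | np.isnan(monitor))
    device, monitor = device[ok], monitor[ok]
    if len(device) < 2:
        raise ValueError("Bland-Altman needs at least two complete pairs")
    d = device - monitor
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n=len(d),
        means=(device + monitor) / 2.0,
        diffs=d,
    )


@dataclass(frozen=True)
class ConsumptionFit:
    """Per-group polynomial fits of hourly consumption on EC, plus contrasts.

    coefficients : dict group -> ndarray of polynomial coefficients in
        descending powers (numpy.polyfit convention).
    contrast_pvalues : dict (group_a, group_b) -> p-value of the group main
        effect in a pooled linear model on (EC, EC², …, group indicator).
    """

    degree: int
    coefficients: dict[str, np.ndarray]
    contrast_pvalues: dict[tuple[str, str], float]
    data: pd.DataFrame = field(repr=False)


def _design(ec: np.ndarray, degree: int) -> np.ndarray:
    return np.column_stack([ec**k for k in range(1, degree + 1)])


def fit_consumption(
    records: pd.DataFrame,
    degree: int = 2,
    exclusions: dict[str, list[float]] | None = None,
) -> ConsumptionFit:
    """Fit consumption–EC curves per experiment group and contrast groups.

    ``records`` needs columns ``group``, ``mean_ec_volpct``,
    ``hourly_rate_ml_h`` and (if exclusions are used) ``mac_fraction``.
    ``exclusions`` maps a group label to MAC-fraction target levels removed
    before fitting and contrasting — used to drop the top target levels of
    one agent when comparing across agents with different MAC references.

    Each group gets an ordinary least-squares polynomial of the requested
    degree (requiring ≥ degree + 2 points).  Every pair of groups is
    contrasted through a pooled linear model of consumption on EC powers
    plus a group indicator, whose main-effect p-value is reported.  A fitted
    curve dipping negative over a group's observed EC range is flagged with
    a warning (diagnostic only).
    """
    df = records.copy()
    if exclusions:
        for grp, levels in exclusions.items():
            mask = (df["group"] == grp) & df["mac_fraction"].round(9).isin(
                [round(x, 9) for x in levels]
            )
            df = df[~mask]
    df = df.dropna(subset=["mean_ec_volpct", "hourly_rate_ml_h"])
    groups = list(dict.fromkeys(df["group"]))
    coeffs: dict[str, np.ndarray] = {}
    for g in groups:
        sub = df[df["group"] == g]
        if len(sub) < degree + 2:
            raise ValueError(
                f"group {g!r} has {len(sub)} points; need at least {degree + 2} "
                f"for a degree-{degree} fit"
            )
        x = sub["mean_ec_volpct"].to_numpy(dtype=float)
        y = sub["hourly_rate_ml_h"].to_numpy(dtype=float)
        try:
            c = np.polyfit(x, y, degree)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"rank-deficient design for group {g!r}") from err
        coeffs[g] = c
        grid = np.linspace(x.min(), x.max(), 101)
        if np.polyval(c, grid).min() < 0:
            log.warning("fitted consumption curve for group %r dips negative", g)
    pvals: dict[tuple[str, str], float] = {}
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            sub = df[df["group"].isin([ga, gb])]
            x = sub["mean_ec_volpct"].to_numpy(dtype=float)
            y = sub["hourly_rate_ml_h"].to_numpy(dtype=float)
            ind = (sub["group"] == gb).to_numpy(dtype=float)
            design = sm.add_constant(np.column_stack([_design(x, degree), ind]))
            try:
                fit = sm.OLS(y, design).fit()
            except np.linalg.LinAlgError as err:
                raise ValueError(f"rank-deficient pooled design for {ga!r} vs {gb!r}") from err
            pvals[(ga, gb)] = float(fit.pvalues[-1])
    return ConsumptionFit(degree=degree, coefficients=coeffs, contrast_pvalues=pvals, data=df)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False, float_format="%.4f")
    tmp.replace(path)


def render_report(
    outdir: str | Path,
    breaths: pd.DataFrame | None = None,
    efficiency: pd.DataFrame | None = None,
    periods: pd.DataFrame | None = None,
    agreement: AgreementResult | None = None,
    fit: ConsumptionFit | None = None,
    device_log: pd.DataFrame | None = None,
    formats: tuple[str, ...] = ("csv", "png"),
) -> list[Path]:
    """Write the analysis report: CSV tables of record plus plot images.

    Sections with missing inputs are skipped with a log notice.  CSVs are
    the data of record; plots (EC-vs-time overlay, Bland-Altman panel,
    consumption and RE curves) are conveniences.  Returns the paths written.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    want_csv = "csv" in formats
    want_png = "png" in formats

    if breaths is not None:
        if want_csv:
            p = outdir / "breaths.csv"
            _write_csv(breaths, p)
            written.append(p)
        if want_png and device_log is not None:
            fig, ax = plt.subplots(figsize=(9, 4))
            t_b = breaths["expiration_onset_ms"] / 60000.0
            ax.plot(t_b, breaths["ec_volpct"], lw=0.5, color="grey", label="monitor EC")
            ax.plot(
                device_log["t_s"] / 60.0,
                device_log["device_ec_volpct"],
                lw=0.5,
                color="tab:purple",
                alpha=0.7,
                label="device EC",
            )
            ax.step(
                device_log["t_s"] / 60.0,
                device_log["target_volpct"],
                color="black",
                lw=1.0,
                where="post",
                label="target",
            )
            if periods is not None:
                for _, row in periods.iterrows():
                    ax.hlines(
                        row["mean_ec_volpct"],
                        row["t_start_s"] / 60.0,
                        row["t_end_s"] / 60.0,
                        color="tab:blue",
                        ls="--",
                        lw=1.0,
                    )
            ax.set_xlabel("time (min)")
            ax.set_ylabel("concentration (vol%)")
            ax.legend(loc="upper left", fontsize=8)
            p = outdir / "ec_vs_time.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    else:
        log.info("breaths section skipped (no input)")

    if agreement is not None:
        if want_csv:
            p = outdir / "agreement.csv"
            _write_csv(
                pd.DataFrame(
                    [
                        {
                            "bias_volpct": agreement.bias,
                            "loa_low_volpct": agreement.loa_low,
                            "loa_high_volpct": agreement.loa_high,
                            "sd_diff_volpct": agreement.sd_diff,
                            "n_pairs": agreement.n,
                        }
                    ]
                ),
                p,
            )
            written.append(p)
        if want_png:
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(agreement.means, agreement.diffs, s=4, alpha=0.4)
            for y, style in (
                (agreement.bias, "-"),
                (agreement.loa_low, "--"),
                (agreement.loa_high, "--"),
            ):
                ax.axhline(y, color="k", ls=style, lw=0.8)
            ax.set_xlabel("mean of device and monitor EC (vol%)")
            ax.set_ylabel("device − monitor EC (vol%)")
            p = outdir / "bland_altman.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    else:
        log.info("agreement section skipped (no input)")

    if periods is not None and want_csv:
        p = outdir / "periods.csv"
        _write_csv(periods, p)
        written.append(p)

    if efficiency is not None:
        if want_csv:
            p = outdir / "efficiency.csv"
            _write_csv(efficiency, p)
            written.append(p)
        if want_png:
            fig, axes = plt.subplots(1, 2, figsize=(9, 4))
            axes[0].plot(
                efficiency["mean_ec_volpct"], efficiency["hourly_rate_ml_h"], "o-"
            )
            axes[0].set_xlabel("mean EC (vol%)")
            axes[0].set_ylabel("consumption (mL liquid/h)")
            keep = ~efficiency["low_target_flag"]
            axes[1].plot(
                efficiency.loc[keep, "vapour_per_breath_ml"],
                efficiency.loc[keep, "re_percent"],
                "s-",
            )
            axes[1].set_xlabel("vapour volume per breath (mL)")
            axes[1].set_ylabel("reflection efficiency (%)")
            fig.tight_layout()
            p = outdir / "efficiency.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    else:
        log.info("efficiency section skipped (no input)")

    if fit is not None and want_csv:
        rows = [
            {"group": g, **{f"c{len(c) - 1 - k}": c[k] for k in range(len(c))}}
            for g, c in fit.coefficients.items()
        ]
        p = outdir / "consumption_fit.csv"
        _write_csv(pd.DataFrame(rows), p)
        written.append(p)
        prow = [
            {"group_a": a, "group_b": b, "p_value": v}
            for (a, b), v in fit.contrast_pvalues.items()
        ]
        if prow:
            p = outdir / "consumption_contrasts.csv"
            _write_csv(pd.DataFrame(prow), p)
            written.append(p)
    return written
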