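"""Full analysis orchestration: metrics -> trend table -> correlation table
-> change-point timeline -> plots.

The contract of a run is three tidy tables:

* **trend table** — one row per (instrument, parameter) with Mann–Kendall
  S/varS/z/p, Bonferroni-adjusted p, Sen slope and CI, percent change per
  scale unit and CI, and a significance flag;
* **correlation table** — Spearman rho and p per (instrument, parameter);
* **change-point table** — Pettitt K, tau (index and case number) and
  approximate p for the configured parameter subset.

LOESS smoothing appears only in plots: inference comes from the
rank statistics, never from the smoother.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .changepoint import DEFAULT_CHANGEPOINT_PARAMS, pettitt_test
from .exceptions import DegenerateInputError, InsufficientDataError
from .kinematics import METRIC_NAMES, CaseMetrics, case_metrics
from .track_io import CaseRecord
from .trend_stats import (
    TrendResult,
    bonferroni,
    mann_kendall,
    percent_change,
    spearman,
    theil_sen,
)

__all__ = [
    "AnalysisConfig",
    "metrics_frame",
    "compute_all_metrics",
    "run_analysis",
    "loess_curve",
    "render_report",
]

logger = logging.getLogger(__name__)

#: Minimum series length accepted for trend/change-point inference.
MIN_SERIES_LEN = 4


@dataclass
class AnalysisConfig:
    """Tunables of one analysis run.

    scale
        ``per_10_videos`` expresses percent changes per 10 recorded videos
        (10 x the mean inter-video case spacing, ~75 cases for the default
        acquisition design); ``per_case`` uses one surgical case as the
        unit. The abscissa for all statistics is always the case number.
    family_size
        Bonferroni family size m; None means (#instruments x #parameters)
        actually present in the input.
    """

    alpha: float = 0.05
    family_size: int | None = None
    scale: str = "per_10_videos"  # or "per_case"
    loess_span: float = 0.75
    changepoint_params: tuple[str, ...] = DEFAULT_CHANGEPOINT_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError("loess_span must lie in (0, 1]")
        if self.scale not in ("per_10_videos", "per_case"):
            raise ValueError("scale must be 'per_10_videos' or 'per_case'")


def metrics_frame(metrics: list[CaseMetrics] | pd.DataFrame) -> pd.DataFrame:
    """Normalize a metrics collection to a tidy DataFrame."""
    if isinstance(metrics, pd.DataFrame):
        return metrics.copy()
    return pd.DataFrame([dataclasses.asdict(m) for m in metrics])


def compute_all_metrics(records: list[CaseRecord]) -> pd.DataFrame:
    """Kinematic metrics for every (case, instrument) pair in the dataset."""
    rows: list[CaseMetrics] = []
    for rec in sorted(records, key=lambda r: r.case_number):
        rows.extend(case_metrics(rec))
    return metrics_frame(rows)


def _scale_factor(df: pd.DataFrame, scale: str) -> float:
    if scale == "per_case":
        return 1.0
    cases = np.sort(df["case_number"].unique())
    if cases.size < 2:
        return 1.0
    return 10.0 * float(np.mean(np.diff(cases)))


def run_analysis(
    metrics: list[CaseMetrics] | pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full trend / correlation / change-point battery.

    Per (instrument, parameter) series (ordered by case number, NaN
    metrics dropped listwise with a logged count, series shorter than 4
    excluded with a warning): Mann–Kendall test, Theil–Sen slope + CI,
    percent change per scale unit, Spearman correlation; Bonferroni
    adjustment over the whole table; Pettitt change-point for the
    configured parameter subset.

    Returns ``(trend_table, correlation_table, changepoint_table)``,
    sorted by (instrument, parameter). Input row order never affects the
    output.
    """
    cfg = cfg or AnalysisConfig()
    df = metrics_frame(metrics).sort_values(["instrument", "case_number"])
    instruments = sorted(df["instrument"].unique())
    params = [p for p in METRIC_NAMES if p in df.columns]
    scale_factor = _scale_factor(df, cfg.scale)

    trend_rows: list[TrendResult] = []
    corr_rows: list[dict] = []
    cp_rows: list[dict] = []
    for instrument in instruments:
        sub = df[df["instrument"] == instrument]
        for param in params:
            series = sub[["case_number", param]].dropna()
            n_dropped = len(sub) - len(series)
            if n_dropped:
                logger.info(
                    "%s/%s: dropped %d undefined value(s)", instrument, param, n_dropped
                )
            series = series.sort_values("case_number")
            t = series["case_number"].to_numpy(dtype=float)
            y = series[param].to_numpy(dtype=float)
            if y.size < MIN_SERIES_LEN:
                logger.warning(
                    "%s/%s: only %d defined values; series excluded",
                    instrument, param, y.size,
                )
                continue
            S, varS, z, p = mann_kendall(y)
            slope, lo, hi = theil_sen(t, y, alpha=cfg.alpha)
            try:
                pct, pct_ci = percent_change(slope, y, scale_factor, ci=(lo, hi))
            except DegenerateInputError:
                pct, pct_ci = np.nan, (np.nan, np.nan)
            try:
                rho, sp = spearman(t, y)
            except DegenerateInputError:
                rho, sp = np.nan, np.nan
            trend_rows.append(
                TrendResult(
                    parameter=param, instrument=instrument, n=y.size,
                    S=S, varS=varS, z=z, p=p, p_adj=np.nan,
                    sen_slope=slope, sen_ci=(lo, hi),
                    pct_change=pct, pct_ci=pct_ci,
                    spearman_rho=rho, spearman_p=sp,
                )
            )
            corr_rows.append(
                {
                    "instrument": instrument, "parameter": param, "n": y.size,
                    "spearman_rho": rho, "spearman_p": sp,
                }
            )
            if param in cfg.changepoint_params and y.size >= MIN_SERIES_LEN:
                res = pettitt_test(y, case_numbers=t.astype(int))
                cp_rows.append(
                    {
                        "instrument": instrument, "parameter": param, "n": res.n,
                        "tau_index": res.tau_index,
                        "tau_case_last_pre_change": res.tau_case,
                        "K": res.K, "p": res.p,
                    }
                )

    m = cfg.family_size if cfg.family_size is not None else len(instruments) * len(params)
    raw_p = np.array([r.p for r in trend_rows])
    adj = bonferroni(raw_p, m=max(m, raw_p.size)) if raw_p.size else np.array([])

    trend_table = pd.DataFrame(
        {
            "instrument": [r.instrument for r in trend_rows],
            "parameter": [r.parameter for r in trend_rows],
            "n": [r.n for r in trend_rows],
            "S": [r.S for r in trend_rows],
            "varS": [r.varS for r in trend_rows],
            "z": [r.z for r in trend_rows],
            "p": raw_p,
            "p_adj": adj,
            "sen_slope": [r.sen_slope for r in trend_rows],
            "sen_ci_lower": [r.sen_ci[0] for r in trend_rows],
            "sen_ci_upper": [r.sen_ci[1] for r in trend_rows],
            "pct_change": [r.pct_change for r in trend_rows],
            "pct_ci_lower": [r.pct_ci[0] if r.pct_ci else np.nan for r in trend_rows],
            "pct_ci_upper": [r.pct_ci[1] if r.pct_ci else np.nan for r in trend_rows],
            "spearman_rho": [r.spearman_rho for r in trend_rows],
            "spearman_p": [r.spearman_p for r in trend_rows],
        }
    )
    if len(trend_table):
        trend_table["significant"] = trend_table["p_adj"] < cfg.alpha
        trend_table = trend_table.sort_values(["instrument", "parameter"]).reset_index(
            drop=True
        )
    corr_table = pd.DataFrame(corr_rows)
    if len(corr_table):
        corr_table = corr_table.sort_values(["instrument", "parameter"]).reset_index(
            drop=True
        )
    cp_table = pd.DataFrame(cp_rows)
    if len(cp_table):
        cp_table["significant"] = cp_table["p"] < cfg.alpha
        cp_table = cp_table.sort_values(["instrument", "parameter"]).reset_index(
            drop=True
        )
    return trend_table, corr_table, cp_table


def loess_curve(t, y, span: float = 0.75):
    """LOESS trendline: local linear fit with tricube weights.

    For each point t_i, the ``ceil(span * n)`` nearest neighbors (by
    |t - t_i|) receive tricube weights w = (1 - (d/d_max)^3)^3 and a
    weighted straight line is solved; the fit at t_i is its value there.
    Exactly reproduces straight-line data at any span. A degenerate local
    design (all abscissae equal in the window, or d_max = 0) falls back to
    the weighted local mean.

    Returns the fitted values aligned with ``t``.
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = t.size
    if n < 5:
        raise InsufficientDataError(f"LOESS needs n >= 5, got {n}")
    k = int(np.ceil(span * n))
    if k < 3:
        raise InsufficientDataError("span * n must be at least 3")
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(t - t[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0.0:
            w = np.ones(idx.size)
        else:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 0.0, None)
        tw, yw = t[idx], y[idx]
        sw = w.sum()
        if sw == 0.0:
            fitted[i] = y[idx].mean()
            continue
        tbar = (w * tw).sum() / sw
        ybar = (w * yw).sum() / sw
        sxx = (w * (tw - tbar) ** 2).sum()
        if sxx == 0.0:
            fitted[i] = ybar
            continue
        beta = (w * (tw - tbar) * (yw - ybar)).sum() / sxx
        fitted[i] = ybar + beta * (t[i] - tbar)
    return fitted


def _write_table(df: pd.DataFrame, out_dir: Path, name: str) -> list[str]:
    csv_path = out_dir / f"{name}.csv"
    json_path = out_dir / f"{name}.json"
    df.to_csv(csv_path, index=False)
    df.to_json(json_path, orient="records", indent=2)
    return [csv_path.name, json_path.name]


def render_report(
    tables: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
    metrics: list[CaseMetrics] | pd.DataFrame,
    out_dir,
    cfg: AnalysisConfig | None = None,
    records: list[CaseRecord] | None = None,
) -> dict:
    """Write tables, plots and a run manifest to ``out_dir``.

    Produces per-instrument scatter + LOESS plots for every parameter,
    a change-point timeline plot, combined motion-path plots at the first,
    middle and last recorded case when raw ``records`` are supplied, all
    three tables as CSV + JSON, and ``manifest.json`` recording the config
    and library versions. Tables are the contract; plots are best-effort.

    Returns the manifest dict.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = cfg or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trend_table, corr_table, cp_table = tables
    mdf = metrics_frame(metrics)

    files: list[str] = []
    files += _write_table(trend_table, out_dir, "trend_table")
    files += _write_table(corr_table, out_dir, "correlation_table")
    files += _write_table(cp_table, out_dir, "changepoint_table")
    files += _write_table(mdf, out_dir, "case_metrics")

    # scatter + LOESS per (instrument, parameter)
    plots_dir = out_dir / "plots"
    plots_dir.mkdir(exist_ok=True)
    for instrument, sub in mdf.groupby("instrument"):
        fig, axes = plt.subplots(2, 3, figsize=(12, 7))
        for ax, param in zip(axes.ravel(), METRIC_NAMES):
            s = sub[["case_number", param]].dropna().sort_values("case_number")
            ax.scatter(s["case_number"], s[param], s=8, alpha=0.6)
            if len(s) >= 5:
                fit = loess_curve(
                    s["case_number"].to_numpy(float),
                    s[param].to_numpy(float),
                    span=cfg.loess_span,
                )
                ax.plot(s["case_number"], fit, color="crimson", lw=1.5)
            ax.set_title(param, fontsize=9)
            ax.set_xlabel("case number", fontsize=8)
        fig.suptitle(instrument)
        fig.tight_layout()
        for ext in ("png", "svg"):
            fp = plots_dir / f"trends_{instrument}.{ext}"
            fig.savefig(fp, dpi=110)
            files.append(f"plots/{fp.name}")
        plt.close(fig)

    # change-point timeline (machine analog of a per-instrument milestone chart)
    if len(cp_table):
        fig, ax = plt.subplots(figsize=(8, 0.45 * max(len(cp_table), 4) + 1.5))
        labels = cp_table["instrument"] + " / " + cp_table["parameter"]
        ax.scatter(
            cp_table["tau_case_last_pre_change"],
            np.arange(len(cp_table)),
            c=np.where(cp_table["significant"], "crimson", "gray"),
        )
        ax.set_yticks(np.arange(len(cp_table)))
        ax.set_yticklabels(labels, fontsize=7)
        ax.set_xlabel("change-point case number (last pre-change case)")
        ax.set_title("Pettitt change-point timeline")
        fig.tight_layout()
        for ext in ("png", "svg"):
            fp = plots_dir / f"changepoint_timeline.{ext}"
            fig.savefig(fp, dpi=110)
            files.append(f"plots/{fp.name}")
        plt.close(fig)

    # combined motion paths at first / middle / last recorded case
    if records:
        recs = sorted(records, key=lambda r: r.case_number)
        picks = [recs[0], recs[len(recs) // 2], recs[-1]]
        fig, axes = plt.subplots(1, 3, figsize=(14, 4))
        for ax, rec in zip(axes, picks):
            for track in rec.tracks:
                pts = track.all_xy()
                if pts.size:
                    ax.plot(pts[:, 0], pts[:, 1], lw=0.5, alpha=0.7,
                            label=track.instrument)
            ax.set_title(f"case {rec.case_number}", fontsize=9)
            ax.set_xlim(0, rec.tracks[0].frame_width if rec.tracks else 1920)
            ax.set_ylim(0, rec.tracks[0].frame_height if rec.tracks else 1080)
            ax.invert_yaxis()  # image convention: y grows downward
        axes[-1].legend(fontsize=5, loc="upper right")
        fig.tight_layout()
        for ext in ("png", "svg"):
            fp = plots_dir / f"motion_paths.{ext}"
            fig.savefig(fp, dpi=110)
            files.append(f"plots/{fp.name}")
        plt.close(fig)

    manifest = {
        "config": dataclasses.asdict(cfg),
        "files": files,
        "versions": {
            "surgmotion": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "tau_convention": "tau_case is the case number of the last pre-change observation",
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
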