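"""Store-operated calcium entry (SOCE) trace normalisation and quantification.

The three-addition protocol: cells in calcium-free buffer receive (1) CPA, a
SERCA inhibitor, so ER calcium leaks into the cytoplasm (first peak, "ER
release"); (2) extracellular Ca2+, so store depletion drives SOCE influx
(second peak); (3) ionomycin, an ionophore giving the maximal
cell-number-proportional signal used for normalisation. Traces are sampled
at 1 Hz; the canonical timeline images 260 s before the Ca2+ addition and a
further 270 s before ionomycin at 530 s.

Per-well normalisation maps the early-baseline minimum to ~0 and the
ionomycin-phase maximum to 1 — both taken on a short moving average so a
single noisy sample cannot set the anchors — which cancels well-to-well
gain/offset differences (including unequal cell numbers). Response metrics
are rises above each phase's own pre-addition level, plus per-phase AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FluxProtocol",
    "FluxTrace",
    "FluxMetrics",
    "normalize_trace",
    "flux_metrics",
    "group_summary",
    "compare_soce",
]


@dataclass(frozen=True)
class FluxProtocol:
    """Addition times and normalisation windows (seconds)."""

    cpa_add: float = 20.0
    ca_add: float = 260.0
    iono_add: float = 530.0
    baseline_end: float = 10.0
    iono_window_start: float = 530.0

    def __post_init__(self) -> None:
        ok = (0 < self.baseline_end < self.cpa_add < self.ca_add
              < self.iono_window_start <= self.iono_add)
        if not ok:
            raise ValueError(
                "protocol times must satisfy 0 < baseline_end < cpa_add "
                "< ca_add < iono_window_start <= iono_add"
            )


@dataclass
class FluxTrace:
    """One well's kinetic fluorescence trace."""

    well: str
    condition: str
    times: np.ndarray
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must match in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def value_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.intensities))


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    kernel = np.ones(width) / width
    # same-length smoothing; edges use the shorter available window
    csum = np.convolve(y, kernel, mode="same")
    norm = np.convolve(np.ones_like(y), kernel, mode="same")
    return csum / norm


def normalize_trace(trace: FluxTrace, protocol: FluxProtocol,
                    smooth_window: int = 3) -> FluxTrace:
    """(y - b) / (m - b): b = min of smoothed intensity before baseline_end,
    m = max of smoothed intensity after iono_window_start."""
    t, y = trace.times, trace.intensities
    base_mask = t < protocol.baseline_end
    iono_mask = t > protocol.iono_window_start
    if not base_mask.any() or not iono_mask.any():
        raise ValueError("trace does not span baseline and ionomycin windows")
    smooth = _moving_average(y, smooth_window)
    b = float(smooth[base_mask].min())
    m = float(smooth[iono_mask].max())
    if m <= b:
        raise ValueError(
            f"flat or inverted trace {trace.well!r}: ionomycin max {m:.4g} "
            f"<= baseline min {b:.4g}"
        )
    return FluxTrace(
        well=trace.well, condition=trace.condition, times=t.copy(),
        intensities=(y - b) / (m - b), normalized=True,
    )


@dataclass
class FluxMetrics:
    """Quantified responses of one normalised trace."""

    well: str
    condition: str
    er_release_peak: float
    soce_peak: float
    er_auc: float
    soce_auc: float


def _window(trace: FluxTrace, lo: float, hi: float):
    mask = (trace.times > lo) & (trace.times <= hi)
    if mask.sum() < 5:
        raise ValueError(
            f"window ({lo}, {hi}] holds {int(mask.sum())} samples; need >= 5"
        )
    return trace.times[mask], trace.intensities[mask]


def flux_metrics(trace: FluxTrace, protocol: FluxProtocol) -> FluxMetrics:
    """Peak rises above each phase's own pre-addition level, plus AUCs.

    er_release_peak = max over (cpa_add, ca_add] minus the value at cpa_add;
    soce_peak = max over (ca_add, iono_window_start] minus the value at
    ca_add. AUCs are trapezoids of the normalised trace over the same
    windows.
    """
    if not trace.normalized:
        raise ValueError("normalize the trace first")
    t_er, y_er = _window(trace, protocol.cpa_add, protocol.ca_add)
    t_so, y_so = _window(trace, protocol.ca_add, protocol.iono_window_start)
    er_base = trace.value_at(protocol.cpa_add)
    so_base = trace.value_at(protocol.ca_add)
    return FluxMetrics(
        well=trace.well,
        condition=trace.condition,
        er_release_peak=float(y_er.max() - er_base),
        soce_peak=float(y_so.max() - so_base),
        er_auc=float(np.trapezoid(y_er, t_er)),
        soce_auc=float(np.trapezoid(y_so, t_so)),
    )


@dataclass
class GroupSummary:
    """Pointwise mean +/- SEM per condition, plus per-condition metrics."""

    timecourse: pd.DataFrame    # condition, time_s, mean, sem, n
    metrics: pd.DataFrame       # per-well metrics
    metric_summary: pd.DataFrame  # condition x metric mean/sem


def group_summary(traces: list[FluxTrace], protocol: FluxProtocol,
                  trim_for_display: bool = False) -> GroupSummary:
    """Aggregate normalised traces by condition on their common time grid.

    ``trim_for_display`` drops t < baseline_end and t > iono_window_start
    from the timecourse, matching how such traces are conventionally
    plotted; metrics are always computed on the full trace.
    """
    if not traces:
        raise ValueError("no traces")
    by_cond: dict[str, list[FluxTrace]] = {}
    for tr in traces:
        by_cond.setdefault(tr.condition, []).append(tr)
    for cond, group in by_cond.items():
        if len(group) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 traces")
        grid = group[0].times
        for tr in group[1:]:
            if tr.times.shape != grid.shape or not np.allclose(tr.times, grid):
                raise ValueError(
                    f"inconsistent time grids within condition {cond!r}"
                )

    rows = []
    for cond, group in by_cond.items():
        grid = group[0].times
        mat = np.vstack([tr.intensities for tr in group])
        mean = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        keep = np.ones_like(grid, dtype=bool)
        if trim_for_display:
            keep = (grid >= protocol.baseline_end) & \
                   (grid <= protocol.iono_window_start)
        for t, mu, se in zip(grid[keep], mean[keep], sem[keep]):
            rows.append((cond, float(t), float(mu), float(se), len(group)))
    timecourse = pd.DataFrame(
        rows, columns=["condition", "time_s", "mean", "sem", "n"])

    metric_rows = [flux_metrics(tr, protocol) for tr in traces]
    metrics = pd.DataFrame([m.__dict__ for m in metric_rows])
    value_cols = ["er_release_peak", "soce_peak", "er_auc", "soce_auc"]
    summary = metrics.groupby("condition")[value_cols].agg(["mean", "sem"])
    return GroupSummary(timecourse=timecourse, metrics=metrics,
                        metric_summary=summary)


def compare_soce(summary: GroupSummary, cond_a: str, cond_b: str,
                 metric: str = "soce_peak") -> tuple[float, float]:
    """Welch two-sample t-test of a flux metric between conditions; returns
    (t statistic, two-sided p)."""
    m = summary.metrics
    a = m.loc[m["condition"] == cond_a, metric]
    b = m.loc[m["condition"] == cond_b, metric]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
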