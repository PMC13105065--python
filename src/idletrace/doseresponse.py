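"""DIP-rate estimation and four-parameter log-logistic dose-response fitting.

The drug-induced proliferation (DIP) rate is the slope of an ordinary
least-squares line fit to the log2-scaled cell-count curve from the time of
drug treatment onward, in log2 cells/hour. Unlike percent-viability
endpoints it is insensitive to the pre-treatment growth phase and captures
negative (regressing), zero (idling) and positive (expanding) net growth on
one axis.

Dose-response uses the 4-parameter log-logistic (4PL) model with DIP rate as
the drug effect:

    E(d) = Emax + (E0 - Emax) / (1 + (d / EC50)^h)

E0 is the zero-dose effect, Emax the high-dose plateau, EC50 the curve
midpoint (reported as the IC50) and h the Hill slope. Fitting is nonlinear
least squares with multi-start initialisation (E0/Emax from the extreme-dose
means, EC50 from the geometric mid-dose, h in {0.5, 1, 2}); EC50 is
parameterised on the log10 scale for stability. Zero doses are valid inputs:
the model evaluates to E0 there exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GrowthCurve",
    "DipEstimate",
    "DoseResponseCurve",
    "PotencyComparison",
    "dip_rate",
    "fit_4pl",
    "four_pl",
    "compare_potency",
    "DegenerateFitError",
    "FitConvergenceError",
]


class DegenerateFitError(ValueError):
    """Effects carry no dose signal (e.g. all equal)."""


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed from every start."""


@dataclass
class GrowthCurve:
    """One well's cell-count time course under a drug concentration."""

    well: str
    condition: str
    conc_molar: float
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape or self.times.size < 3:
            raise ValueError("need >= 3 matched (time, count) points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts <= 0):
            raise ValueError("counts must be positive (log2 must exist)")


@dataclass
class DipEstimate:
    rate: float           # log2 cells / hour
    stderr: float
    window: tuple[float, float]
    n_points: int
    intercept: float = 0.0

    def ci95(self) -> tuple[float, float]:
        if self.n_points <= 2:
            return (self.rate, self.rate)
        t = stats.t.ppf(0.975, self.n_points - 2)
        return (self.rate - t * self.stderr, self.rate + t * self.stderr)


def dip_rate(curve: GrowthCurve, t_start: float = 0.0) -> DipEstimate:
    """OLS slope of log2(count / count at treatment time) vs time.

    The window runs from the first point with t >= t_start to the end of
    the curve. The slope is invariant to multiplying all counts by a
    constant; normalising to the treatment-time count only moves the
    intercept.
    """
    mask = curve.times >= t_start
    t = curve.times[mask]
    c = curve.counts[mask]
    if t.size < 3:
        raise ValueError(f"fewer than 3 points with t >= {t_start}")
    y = np.log2(c / c[0])
    res = stats.linregress(t, y)
    return DipEstimate(
        rate=float(res.slope),
        stderr=float(res.stderr),
        window=(float(t[0]), float(t[-1])),
        n_points=int(t.size),
        intercept=float(res.intercept),
    )


def four_pl(d, e0: float, emax: float, ec50: float, h: float):
    """4PL response E(d) = Emax + (E0 - Emax) / (1 + (d / EC50)^h).

    Evaluates to E0 at d = 0 for h > 0.
    """
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / ec50) ** h, 0.0)
    return emax + (e0 - emax) / (1.0 + ratio)


@dataclass
class DoseResponseCurve:
    """Fitted 4PL parameters, asymptotic CIs and fit diagnostics."""

    e0: float
    emax: float
    ec50: float
    hill: float
    stderr: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    rss: float = np.nan
    n_points: int = 0
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)
    doses: np.ndarray | None = None
    effects: np.ndarray | None = None

    @property
    def ic50(self) -> float:
        """The curve midpoint EC50, reported as the IC50."""
        return self.ec50

    def predict(self, doses):
        return four_pl(doses, self.e0, self.emax, self.ec50, self.hill)

    def zero_crossing_dose(self) -> float:
        """Dose at which the fitted DIP rate crosses 0 (absolute IC50
        variant); nan when the fitted curve does not cross zero."""
        if not (min(self.e0, self.emax) < 0 < max(self.e0, self.emax)):
            return float("nan")
        # solve Emax + (E0-Emax)/(1+x) = 0 with x = (d/EC50)^h
        x = (self.e0 - self.emax) / (-self.emax) - 1.0
        if x <= 0:
            return float("nan")
        return float(self.ec50 * x ** (1.0 / self.hill))

    def is_monotone_decreasing(self) -> bool:
        return self.hill > 0 and self.e0 > self.emax

    def to_dict(self) -> dict:
        return {
            "e0": self.e0, "emax": self.emax, "ec50": self.ec50,
            "hill": self.hill, "stderr": self.stderr, "ci95": self.ci95,
            "rss": self.rss, "n_points": self.n_points,
            "converged": self.converged, "diagnostics": self.diagnostics,
        }


def _fit_once(d, e, p0, log_ec50_bounds):
    def model(dd, e0, emax, log_ec50, h):
        return four_pl(dd, e0, emax, 10.0 ** log_ec50, h)

    lo = [-np.inf, -np.inf, log_ec50_bounds[0], 1e-3]
    hi = [np.inf, np.inf, log_ec50_bounds[1], 50.0]
    popt, pcov = optimize.curve_fit(
        model, d, e,
        p0=[p0[0], p0[1], np.log10(p0[2]), p0[3]],
        bounds=(lo, hi), maxfev=20000,
    )
    resid = e - model(d, *popt)
    return popt, pcov, float(resid @ resid)


def fit_4pl(doses, effects) -> DoseResponseCurve:
    """Fit the 4PL model to (dose, effect) pairs; replicates are passed as
    repeated dose entries (pooled-points fit).

    Multi-start nonlinear least squares; the best (lowest-RSS) converged
    start wins. Parameter standard errors and 95% CIs come from the
    asymptotic covariance. Raises DegenerateFitError when the effects carry
    no signal and FitConvergenceError when no start converges.
    """
    d = np.asarray(doses, dtype=float)
    e = np.asarray(effects, dtype=float)
    if d.shape != e.shape:
        raise ValueError("doses and effects must have equal length")
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    pos = np.unique(d[d > 0])
    if pos.size < 3:
        raise ValueError("need >= 3 distinct positive doses")
    if pos.size < 4 or pos.max() / pos.min() < 100:
        warnings.warn("dose range is narrow (< 4 doses or < 2 orders of "
                      "magnitude); fit may be poorly constrained")
    if np.ptp(e) == 0:
        raise DegenerateFitError("all effects equal; no dose response")

    lo_d = d[d <= pos.min()]
    hi_d = d[d >= pos.max()]
    e0_init = float(e[np.isin(d, lo_d)].mean())
    emax_init = float(e[np.isin(d, hi_d)].mean())
    ec50_init = float(np.sqrt(pos.min() * pos.max()))
    log_bounds = (np.log10(pos.min()) - 3, np.log10(pos.max()) + 3)

    best = None
    tried = 0
    for h0 in (0.5, 1.0, 2.0):
        for ec0 in (ec50_init, pos.min() * 10, pos.max() / 10):
            tried += 1
            try:
                popt, pcov, rss = _fit_once(
                    d, e, (e0_init, emax_init, ec0, h0), log_bounds)
            except (RuntimeError, ValueError):
                continue
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
    if best is None:
        raise FitConvergenceError(
            f"4PL fit failed to converge from {tried} starts")
    popt, pcov, rss = best
    e0, emax, log_ec50, h = popt
    ec50 = 10.0 ** log_ec50

    names = ["e0", "emax", "log10_ec50", "hill"]
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    dof = max(d.size - 4, 1)
    tcrit = stats.t.ppf(0.975, dof)
    stderr = dict(zip(names, perr.tolist()))
    ci = {n: (float(p - tcrit * s), float(p + tcrit * s))
          for n, p, s in zip(names, popt, perr)}
    ci["ec50"] = tuple(10.0 ** np.array(ci["log10_ec50"]))
    return DoseResponseCurve(
        e0=float(e0), emax=float(emax), ec50=float(ec50), hill=float(h),
        stderr=stderr, ci95=ci, rss=rss, n_points=int(d.size),
        converged=True,
        diagnostics={"n_starts_tried": tried, "dof": dof},
        doses=d, effects=e,
    )


@dataclass
class PotencyComparison:
    fold: float                       # IC50_b / IC50_a; > 1: a more potent
    ci95: tuple[float, float] | None
    n_boot: int = 0

    def contains_unity(self) -> bool:
        return self.ci95 is not None and self.ci95[0] <= 1.0 <= self.ci95[1]


def compare_potency(
    fit_a: DoseResponseCurve,
    fit_b: DoseResponseCurve,
    n_boot: int = 200,
    seed: int = 0,
) -> PotencyComparison:
    """IC50 fold-shift of condition a relative to b, with a bootstrap CI.

    fold = IC50_b / IC50_a, so fold > 1 means condition a responds at lower
    doses (is more sensitive). The CI resamples each fit's (dose, effect)
    points within dose groups and refits; it requires both fits to carry
    their data (as fits from :func:`fit_4pl` do).
    """
    for f in (fit_a, fit_b):
        if not f.converged:
            raise ValueError("cannot compare a non-converged fit")
    fold = fit_b.ec50 / fit_a.ec50
    if n_boot <= 0 or fit_a.doses is None or fit_b.doses is None:
        return PotencyComparison(fold=float(fold), ci95=None)

    rng = np.random.default_rng(seed)

    def resample_refit(fit: DoseResponseCurve) -> float | None:
        d, e = fit.doses, fit.effects
        idx = []
        for dose in np.unique(d):
            pool = np.flatnonzero(d == dose)
            idx.extend(rng.choice(pool, size=pool.size, replace=True))
        try:
            return fit_4pl(d[idx], e[idx]).ec50
        except (ValueError, FitConvergenceError):
            return None

    folds = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_boot):
            ra = resample_refit(fit_a)
            rb = resample_refit(fit_b)
            if ra and rb:
                folds.append(rb / ra)
    if len(folds) < max(10, n_boot // 4):
        return PotencyComparison(fold=float(fold), ci95=None,
                                 n_boot=len(folds))
    lo, hi = np.percentile(folds, [2.5, 97.5])
    return PotencyComparison(fold=float(fold), ci95=(float(lo), float(hi)),
                             n_boot=len(folds))
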