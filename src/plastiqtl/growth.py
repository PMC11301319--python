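"""Logistic growth curves: evaluation and constrained least-squares fitting.

Leaf-number trajectories of *Arabidopsis* RILs follow an S-shaped curve
well described by the three-parameter logistic

    mu(t) = a / (1 + b * exp(-r * t))

where ``a`` is the asymptotic leaf number, ``b`` shapes the initial
growth (the curve starts at ``a / (1 + b)`` at t = 0) and ``r`` is the
specific growth rate per week.  Fitting is done by nonlinear least
squares on log-transformed parameters, which enforces positivity without
explicit constraints, with a multi-start strategy because short noisy
series make the problem multi-modal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TimeGrid",
    "LogisticParams",
    "LogisticFit",
    "logistic_mean",
    "fit_logistic",
    "fit_treatment_mean_curves",
]

# box for log-parameters during optimisation (generous but keeps exp finite)
_LOG_LO = np.log([1e-6, 1e-8, 1e-4])
_LOG_HI = np.log([1e6, 1e8, 1e3])


@dataclass(frozen=True)
class TimeGrid:
    """Ordered measurement times (weeks since planting)."""

    times: tuple

    def __init__(self, times) -> None:
        t = tuple(float(x) for x in times)
        if len(t) < 3:
            raise ValueError("TimeGrid needs at least 3 time points")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("TimeGrid times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def weekly(cls, n_weeks: int = 8) -> "TimeGrid":
        """Weekly grid 1..n_weeks, the default measurement design."""
        return cls(range(1, n_weeks + 1))


@dataclass(frozen=True)
class LogisticParams:
    """Parameters (a, b, r) of the logistic curve a/(1 + b e^{-rt})."""

    a: float
    b: float
    r: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.r > 0):
            raise ValueError("logistic parameters must all be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.r], dtype=float)


@dataclass(frozen=True)
class LogisticFit:
    """Result of a logistic fit: parameters, residual sum of squares, flag."""

    params: LogisticParams
    rss: float
    success: bool

    def __iter__(self):
        # allows ``params, rss = fit_logistic(...)``
        return iter((self.params, self.rss))


def logistic_mean(t, p: LogisticParams):
    """Evaluate a/(1 + b e^{-rt}) at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    out = p.a / (1.0 + p.b * np.exp(-p.r * t))
    return float(out) if out.ndim == 0 else out


def _curve_logp(logp: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, b, r = np.exp(logp)
    return a / (1.0 + b * np.exp(-r * t))


def _starts(y: np.ndarray, t: np.ndarray) -> list[np.ndarray]:
    """Coarse data-seeded starting points in log-parameter space."""
    ymax = max(float(np.max(y)), 1e-3)
    a0 = ymax * 1.05
    # log-linearised slope of logit(y/a0) against t gives -r and log b
    yy = np.clip(y, 1e-3, a0 * (1.0 - 1e-6))
    v = np.log(a0 / yy - 1.0)
    slope, intercept = np.polyfit(t, v, 1)
    r0 = float(np.clip(-slope, 5e-2, 20.0))
    b0 = float(np.clip(np.exp(intercept), 1e-6, 1e6))
    starts = [np.log([a0, b0, r0])]
    for a_s in (a0, 1.3 * a0):
        for r_s in (0.3, 0.8, 1.5):
            b_s = max(np.exp(r_s * t[0]) * (a_s / max(yy[0], 1e-3) - 1.0), 1e-6)
            starts.append(np.log([a_s, b_s, r_s]))
    return starts


def fit_logistic(y, grid: TimeGrid, n_starts: int | None = None) -> LogisticFit:
    """Fit a logistic curve to one trajectory by multi-start least squares.

    Parameters are optimised on the log scale (positivity for free).  The
    best local optimum by RSS wins, ties broken toward the smallest
    asymptote ``a``.  All-NaN input is rejected; if no start converges a
    flagged failure result is returned with the least-bad point.
    """
    t = grid.values
    y = np.asarray(y, dtype=float)
    if y.shape != t.shape:
        raise ValueError(f"trajectory length {y.size} != grid length {t.size}")
    if not np.any(np.isfinite(y)):
        raise ValueError("trajectory has no finite values")
    if np.any(y[np.isfinite(y)] < 0):
        raise ValueError("leaf numbers must be non-negative")
    finite = np.isfinite(y)
    tf, yf = t[finite], y[finite]

    best = None  # (rss, a, logp, ok)
    starts = _starts(yf, tf)
    if n_starts is not None:
        starts = starts[:n_starts]
    for x0 in starts:
        x0 = np.clip(x0, _LOG_LO, _LOG_HI)
        try:
            sol = least_squares(
                lambda lp: _curve_logp(lp, tf) - yf,
                x0,
                bounds=(_LOG_LO, _LOG_HI),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        a = float(np.exp(sol.x[0]))
        cand = (rss, a, sol.x, bool(sol.success))
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
        if best[0] <= 1e-12 * max(1.0, float(np.sum(yf**2))):
            break  # numerically exact fit; further starts cannot improve
    if best is None:
        raise RuntimeError("logistic fit failed from every start")
    rss, _, logp, ok = best
    a, b, r = np.exp(logp)
    return LogisticFit(LogisticParams(float(a), float(b), float(r)), rss, ok)


def fit_treatment_mean_curves(panels: dict, grid: TimeGrid) -> dict:
    """Fit one logistic curve per treatment to the across-RIL mean trajectory.

    ``panels`` maps treatment label -> TrajectoryPanel.  Returns a dict of
    treatment -> LogisticFit.
    """
    fits = {}
    for label, panel in panels.items():
        if panel.values.shape[0] == 0:
            raise ValueError(f"treatment {label!r} has no RILs")
        mean_traj = np.nanmean(panel.values, axis=0)
        fits[label] = fit_logistic(mean_traj, grid)
    return fits
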