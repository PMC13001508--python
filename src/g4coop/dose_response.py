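"""Constrained four-parameter logistic (LL.4) dose-response analysis.

Splicing changes (delta-PSI) measured across a titration of relative HNRNPH
protein levels are fitted with a four-parameter logistic curve

    f(x) = min + (max - min) / (1 + exp(b * (log x - log ec50)))

under box constraints tying the asymptotes to the control-condition inclusion
levels.  The magnitude of the slope ``b`` is reported as the Hill coefficient
``n_H``; events with a good fit (pseudo-R^2 >= 0.75) are classified as
cooperatively (n_H >= 2) or non-cooperatively regulated, crossed with the
direction of regulation (enhanced / repressed by HNRNPH).

The module also provides the model-free EC10/EC90 Hill-coefficient estimator

    n_H = log(81) / log(EC90 / EC10)

applied to a min-max-normalized monotone dose-response curve, which is shared
by the equilibrium-binding and splicing-cascade models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationSeries",
    "DoseResponseFit",
    "fit_ll4",
    "ll4",
    "pseudo_r2",
    "classify_event",
    "hill_coefficient_ec",
    "fit_hill",
]

#: pseudo-R^2 threshold below which an event is excluded from classification
PSEUDO_R2_CUTOFF = 0.75
#: Hill-coefficient threshold separating cooperative from non-cooperative events
COOPERATIVITY_CUTOFF = 2.0


@dataclass
class TitrationSeries:
    """Delta-PSI observations of one splicing event across protein levels.

    ``levels`` are relative HNRNPH protein levels (1.0 = control) and may
    contain repeated values (replicates are fitted pointwise).  The control
    inclusion levels ``psi_kd_control`` / ``psi_oe_control`` (fractions in
    [0, 1]) bound the fitted asymptotes: delta-PSI cannot drop below minus the
    larger control PSI nor rise above one minus the smaller control PSI.
    """

    event_id: str
    levels: np.ndarray
    delta_psi: np.ndarray
    psi_kd_control: float = 0.5
    psi_oe_control: float = 0.5
    event_type: str = "CE"

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.delta_psi = np.asarray(self.delta_psi, dtype=float)
        if self.levels.shape != self.delta_psi.shape:
            raise ValueError("levels and delta_psi must have equal length")
        if np.any(self.levels <= 0):
            raise ValueError("protein levels must be strictly positive")
        if np.any(np.abs(self.delta_psi) > 1 + 1e-9):
            raise ValueError("|delta_psi| must not exceed 1")
        for name in ("psi_kd_control", "psi_oe_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class DoseResponseFit:
    """Result of a constrained LL.4 fit.

    ``n_H`` is the magnitude of the fitted slope; the sign information is
    carried separately in ``direction`` (enhanced = delta-PSI increases with
    HNRNPH level).
    """

    event_id: str
    n_H: float
    min: float
    max: float
    ec50: float
    pseudo_r2: Optional[float]
    direction: str
    converged: bool
    category: str = "excluded"
    slope: float = field(default=np.nan, repr=False)


def ll4(x, b, lo, hi, ec50):
    """Four-parameter logistic curve evaluated at levels ``x``."""
    x = np.asarray(x, dtype=float)
    return lo + (hi - lo) / (1.0 + np.exp(b * (np.log(x) - np.log(ec50))))


def _box_bounds(series: TitrationSeries):
    lo_min = -max(series.psi_kd_control, series.psi_oe_control)
    hi_max = 1.0 - min(series.psi_kd_control, series.psi_oe_control)
    return lo_min, hi_max


def fit_ll4(series: TitrationSeries) -> DoseResponseFit:
    """Fit the constrained LL.4 model to a titration series.

    Bounded least squares from a grid of starting points
    (slope in {+-1, +-5, +-15}, ec50 in {0.7, 1.0, 1.3}); the best SSE wins,
    ties broken by the smallest |slope|.  Raises ``ValueError`` with fewer
    than five distinct protein levels; an all-identical response is flagged
    non-converged and excluded.
    """
    if len(np.unique(series.levels)) < 5:
        raise ValueError("at least 5 distinct protein levels required")

    x, y = series.levels, series.delta_psi
    if np.allclose(y, y[0]):
        fit = DoseResponseFit(series.event_id, np.nan, 0.0, 0.0, np.nan,
                              None, "none", converged=False)
        fit.category = "excluded"
        return fit

    lo_min, hi_max = _box_bounds(series)
    lower = np.array([-np.inf, lo_min, 0.0, 1e-12])
    upper = np.array([np.inf, 0.0, hi_max, np.inf])

    lo0 = float(np.clip(min(y.min(), 0.0), lo_min, 0.0))
    hi0 = float(np.clip(max(y.max(), 0.0), 0.0, hi_max))

    def resid(theta):
        return ll4(x, *theta) - y

    best = None
    for b0 in (1.0, -1.0, 5.0, -5.0, 15.0, -15.0):
        for e0 in (0.7, 1.0, 1.3):
            theta0 = np.clip([b0, lo0, hi0, e0], lower, upper)
            try:
                sol = least_squares(resid, theta0, bounds=(lower, upper),
                                    ftol=1e-14, xtol=1e-14, gtol=1e-14)
            except ValueError:
                continue
            if not sol.success:
                continue
            sse = float(np.sum(sol.fun ** 2))
            key = (round(sse, 12), abs(sol.x[0]))
            if best is None or key < best[0]:
                best = (key, sol)

    if best is None:
        fit = DoseResponseFit(series.event_id, np.nan, np.nan, np.nan, np.nan,
                              None, "none", converged=False)
        return fit

    b, lo, hi, ec50 = best[1].x
    yhat_lo = float(ll4(x.min(), b, lo, hi, ec50))
    yhat_hi = float(ll4(x.max(), b, lo, hi, ec50))
    direction = "enhanced" if yhat_hi > yhat_lo else "repressed"
    fit = DoseResponseFit(series.event_id, abs(b), float(lo), float(hi),
                          float(ec50), None, direction, converged=True,
                          slope=float(b))
    fit.pseudo_r2 = pseudo_r2(fit, series)
    fit.category = classify_event(fit)
    return fit


def pseudo_r2(fit: DoseResponseFit, series: TitrationSeries) -> Optional[float]:
    """1 - SS_residual / SS_total against the mean of the observations.

    May be negative for fits worse than the mean.  Returns ``None`` (and the
    event is excluded) when SS_total is zero.
    """
    if not fit.converged:
        return None
    y = series.delta_psi
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return None
    yhat = ll4(series.levels, fit.slope, fit.min, fit.max, fit.ec50)
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def classify_event(fit: DoseResponseFit) -> str:
    """Four-way cooperativity category of a fitted event.

    Excluded when the fit did not converge or pseudo-R^2 < 0.75; otherwise
    cooperative iff n_H >= 2, crossed with the direction of regulation.
    """
    if not fit.converged or fit.pseudo_r2 is None:
        return "excluded"
    if fit.pseudo_r2 < PSEUDO_R2_CUTOFF:
        return "excluded"
    coop = "coop" if fit.n_H >= COOPERATIVITY_CUTOFF else "noncoop"
    return f"{coop}_{fit.direction}"


def hill_coefficient_ec(xs: Sequence[float], ys: Sequence[float],
                        mono_tol: float = 1e-9) -> float:
    """EC10/EC90-based Hill coefficient of a monotone dose-response curve.

    The curve is min-max-normalized to [0, 1]; decreasing curves are flipped
    (steepness is sign-free).  EC10 and EC90 are located by piecewise-linear
    interpolation and ``n_H = log(81) / log(EC90 / EC10)``.

    Raises ``ValueError`` if the normalized curve is not monotone (beyond
    ``mono_tol``) or if either crossing lies outside the sampled range.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.ndim != 1 or xs.shape != ys.shape or len(xs) < 3:
        raise ValueError("xs and ys must be 1-d arrays of equal length >= 3")
    if np.any(np.diff(xs) <= 0):
        raise ValueError("xs must be strictly increasing")
    span = ys.max() - ys.min()
    if span == 0:
        raise ValueError("flat curve: Hill coefficient undefined")
    y = (ys - ys.min()) / span
    if y[-1] < y[0]:
        y = 1.0 - y
    d = np.diff(y)
    if np.any(d < -mono_tol):
        raise ValueError("normalized dose-response curve is not monotone")
    # enforce weak monotonicity so interpolation is well defined
    y = np.maximum.accumulate(y)

    def crossing(level: float) -> float:
        i = int(np.searchsorted(y, level))
        if i == 0 or i >= len(y):
            raise ValueError(f"EC{int(level * 100)} outside the sampled range")
        x0, x1, y0, y1 = xs[i - 1], xs[i], y[i - 1], y[i]
        if y1 == y0:
            return x0
        return x0 + (level - y0) / (y1 - y0) * (x1 - x0)

    ec10, ec90 = crossing(0.1), crossing(0.9)
    return math.log(81.0) / math.log(ec90 / ec10)


def fit_hill(conc, signal):
    """Least-squares fit of a Hill binding curve ``A * c^n / (c^n + K^n)``.

    Convenience for refitting simulated in vitro titrations; returns
    ``(n_H, K, amplitude)``.
    """
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    def model(theta):
        n, logK, amp = theta
        t = np.exp(n * (np.log(conc) - logK))
        return amp * t / (1.0 + t) - signal

    k0 = float(np.log(np.median(conc)))
    best = None
    for n0 in (0.5, 1.0, 2.0, 4.0):
        sol = least_squares(model, [n0, k0, max(signal.max(), 1e-6)],
                            bounds=([0.05, k0 - 40, 0], [60.0, k0 + 40, np.inf]))
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    n, logK, amp = best[1]
    return float(n), float(np.exp(logK)), float(amp)
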