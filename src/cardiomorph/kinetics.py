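"""Gravity-decantation kinetics: plateau followed by one-phase decay.

During settling-based purification, heavy intact cardiomyocytes sink while
lighter non-myocytes stay suspended; the supernatant's optical density
(absorbance at 595 nm) therefore stays flat and then decays exponentially to
an asymptote.  The model is

    Y(X) = Y0                                          for X <  X0
    Y(X) = Plateau + (Y0 - Plateau) exp(-k (X - X0))   for X >= X0

with X0 the time decay begins, Y0 the initial absorbance, Plateau the
asymptote and k (1/min) the rate constant.  The minimal decantation time is
the X at which Y has come within a small band of the plateau:

    Xt = X0 - (1/k) ln((Yt - Plateau) / (Y0 - Plateau))

Under the default *span* convention the band is a fraction of the decay span,
Yt = Plateau + f (Y0 - Plateau), which simplifies to the closed form
Xt = X0 + ln(1/f) / k and remains well defined as Plateau -> 0.  The literal
*plateau-relative* reading, Yt = Plateau (1 + f), is available behind a flag.

Fitting: for fixed (X0, k) the model is linear in (Plateau, Y0 - Plateau),
so the sum of squares is profiled in closed form over a deterministic
(X0, k) grid and the best cell is polished with Nelder-Mead in
(X0, log k).  No stochastic start-point selection is involved, so fits are
exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class DecaySeries:
    """Absorbance-vs-time settling series (>= 5 points, strictly increasing
    times in minutes)."""

    times_min: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times_min.shape != self.absorbance.shape:
            raise ValueError("times and absorbance must have equal length")
        if self.times_min.size < 5:
            raise ValueError("need at least 5 time points")
        if not (np.diff(self.times_min) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (self.times_min < 0).any():
            raise ValueError("times must be >= 0")


#: The sampling grid of the reference settling experiment (minutes).
DEFAULT_TIMES_MIN = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0])


def decay_curve(t, x0: float, y0: float, plateau: float, k: float) -> np.ndarray:
    """Evaluate the plateau-then-decay model."""
    t = np.asarray(t, dtype=float)
    return plateau + (y0 - plateau) * np.exp(-k * np.clip(t - x0, 0.0, None))


@dataclass
class DecayFit:
    """Fitted parameters plus the solved minimal decantation time."""

    X0: float
    Y0: float
    Plateau: float
    k: float
    residual_sse: float
    t_min: float


class PlateauDecay(RegressorMixin, BaseEstimator):
    """Least-squares estimator for the plateau-then-one-phase-decay model.

    Parameters
    ----------
    fix_x0 : float or None
        Pin the decay onset (e.g. 0.0 for sparse series) instead of
        fitting it.
    band_fraction : float
        Plateau band used by :meth:`plateau_time` (0.5% by default).
    grid_size : int
        Resolution of the deterministic (X0, k) profiling grid.

    Attributes (after :meth:`fit`)
    ------------------------------
    x0_, y0_, plateau_, k_, sse_ : fitted parameters and residual SSE.
    """

    def __init__(self, fix_x0: float | None = None,
                 band_fraction: float = 0.005, grid_size: int = 40):
        self.fix_x0 = fix_x0
        self.band_fraction = band_fraction
        self.grid_size = grid_size

    @staticmethod
    def _profile_sse(t, y, x0, k):
        """Closed-form linear profiling of (plateau, amplitude) for grids of
        x0 (shape Gx) and k (shape Gk); returns (sse, plateau, amp) arrays of
        shape (Gx, Gk)."""
        f = np.exp(-np.multiply.outer(
            np.clip(t[None, :] - np.asarray(x0)[:, None], 0.0, None),
            np.asarray(k)).transpose(0, 2, 1))  # (Gx, Gk, n)
        n = t.size
        sy = y.sum()
        syy = float(y @ y)
        sf = f.sum(axis=2)
        sff = (f * f).sum(axis=2)
        sfy = f @ y
        det = n * sff - sf * sf
        det = np.where(np.abs(det) < 1e-30, np.nan, det)
        plateau = (sff * sy - sf * sfy) / det
        amp = (n * sfy - sf * sy) / det
        sse = syy - plateau * sy - amp * sfy
        return sse, plateau, amp

    def fit(self, X, y=None):
        """Fit to a series.  ``X`` may be a :class:`DecaySeries` or an array
        of times (then ``y`` is the absorbance)."""
        if isinstance(X, DecaySeries):
            series = X
        else:
            series = DecaySeries(np.asarray(X, dtype=float).ravel(),
                                 np.asarray(y, dtype=float).ravel())
        t, yv = series.times_min, series.absorbance
        span = float(yv.max() - yv.min())
        if span == 0:
            raise ValueError("constant series: no decay to fit")
        if yv[-1] >= yv[0] + 0.5 * span:
            raise ValueError("series increases: not a decay")

        tspan = t[-1] - t[0]
        g = self.grid_size
        if self.fix_x0 is None:
            x0_grid = np.unique(np.concatenate(
                [np.linspace(t[0], t[-2], g), t[:-1]]))
        else:
            x0_grid = np.array([float(self.fix_x0)])
        k_grid = np.geomspace(0.05 / tspan, 50.0 / tspan, g)
        sse, _, amp = self._profile_sse(t, yv, x0_grid, k_grid)
        sse = np.where(amp > 0, sse, np.inf)  # decays only
        if not np.isfinite(sse).any():
            raise ValueError("series increases: not a decay")
        i, j = np.unravel_index(int(np.nanargmin(sse)), sse.shape)

        n = t.size
        sy = yv.sum()
        syy = float(yv @ yv)

        def scalar_sse(x0, k):
            f = np.exp(-k * np.clip(t - x0, 0.0, None))
            sf = f.sum()
            sff = float(f @ f)
            sfy = float(f @ yv)
            det = n * sff - sf * sf
            if abs(det) < 1e-30:
                return np.inf, np.nan, np.nan
            plateau = (sff * sy - sf * sfy) / det
            amp = (n * sfy - sf * sy) / det
            return syy - plateau * sy - amp * sfy, plateau, amp

        def objective(p):
            x0 = p[0] if self.fix_x0 is None else float(self.fix_x0)
            if x0 < 0 or x0 > t[-1]:
                return 1e12 + x0 * x0
            s, _, a = scalar_sse(x0, np.exp(p[-1]))
            if not np.isfinite(s) or a <= 0:
                return 1e12
            return float(s)

        starts = ([[x0_grid[i], np.log(k_grid[j])], [0.0, np.log(k_grid[j])]]
                  if self.fix_x0 is None else [[np.log(k_grid[j])]])
        best = None
        for p0 in starts:
            res = minimize(objective, np.asarray(p0, dtype=float),
                           method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-16,
                                    "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            trace = {"grid_best_sse": float(sse[i, j]),
                     "x0": float(x0_grid[i]), "k": float(k_grid[j])}
            raise RuntimeError(f"decay fit did not converge: {trace}")

        x0 = float(best.x[0]) if self.fix_x0 is None else float(self.fix_x0)
        k = float(np.exp(best.x[-1]))
        s, plateau, amp = scalar_sse(max(x0, 0.0), k)
        self.x0_ = max(x0, 0.0)
        self.k_ = k
        self.plateau_ = float(plateau)
        self.y0_ = float(plateau + amp)
        self.sse_ = max(float(s), 0.0)  # guard fp cancellation on exact fits
        return self

    def predict(self, t) -> np.ndarray:
        check_is_fitted(self, "k_")
        return decay_curve(t, self.x0_, self.y0_, self.plateau_, self.k_)

    def plateau_time(self, band_fraction: float | None = None,
                     convention: str = "span") -> float:
        """Solve for the minimal decantation time (see module docstring)."""
        check_is_fitted(self, "k_")
        fit = DecayFit(self.x0_, self.y0_, self.plateau_, self.k_,
                       self.sse_, np.nan)
        return solve_plateau_time(
            fit, self.band_fraction if band_fraction is None else band_fraction,
            convention)


def fit_decay(series: DecaySeries | tuple, fix_x0: float | None = None,
              band_fraction: float = 0.005) -> DecayFit:
    """Fit the plateau-then-decay model; returns parameters plus the solved
    minimal decantation time under the span convention."""
    if not isinstance(series, DecaySeries):
        series = DecaySeries(*series)
    est = PlateauDecay(fix_x0=fix_x0, band_fraction=band_fraction).fit(series)
    t_min = est.plateau_time()
    return DecayFit(est.x0_, est.y0_, est.plateau_, est.k_, est.sse_, t_min)


def solve_plateau_time(fit: DecayFit, band_fraction: float = 0.005,
                       convention: str = "span") -> float:
    """Time at which the curve enters the plateau band.

    span (default): Yt = Plateau + f (Y0 - Plateau)  =>  Xt = X0 + ln(1/f)/k
    plateau:        Yt = Plateau (1 + f)             (literal reading;
                    requires Plateau > 0 and Yt below Y0)
    """
    if not 0 < band_fraction <= 1:  # f = 1 is the boundary identity Xt = X0
        raise ValueError("band_fraction must be in (0, 1]")
    if fit.k <= 0:
        raise ValueError("decay rate k must be positive")
    span = fit.Y0 - fit.Plateau
    if span == 0:
        raise ValueError("degenerate fit: Y0 equals Plateau")
    if convention == "span":
        yt = fit.Plateau + band_fraction * span
    elif convention == "plateau":
        if fit.Plateau <= 0:
            raise ValueError("plateau-relative band undefined for "
                             "non-positive Plateau")
        yt = fit.Plateau * (1.0 + band_fraction)
        if not (min(fit.Plateau, fit.Y0) < yt < max(fit.Plateau, fit.Y0)):
            raise ValueError("plateau band lies outside the decay range")
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return fit.X0 - (1.0 / fit.k) * np.log((yt - fit.Plateau) / span)


def read_decay_csv(path) -> DecaySeries:
    """Read a two-column (time_min, od595) CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected a two-column CSV (time_min, od595)")
    return DecaySeries(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
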