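"""Power-law flow-curve fitting, AUFC, and avalanche statistics.

The flow curve is the bright-pixel area of a fixed vertical image slice as
a function of time while a particle pile grows under the funnel.  Its trend
follows the cone-growth power law

    y(t) = a + b * t**c

with ``c -> 1/3`` in the ideal-cone limit (see :mod:`pileflow.geometry`).
The intercept ``a`` is free (typically negative: an off-center slice only
starts filling once the pile footprint reaches it), ``b`` carries the
pixel-per-volume calibration, and ``c`` measures the growth-rate shape —
larger ``c`` means a more cylindrical (poorly flowing, stacking) pile.

Avalanches — discrete slip events of the pile flank — ride on the trend as
sawtooth-like oscillations.  They are quantified on the detrended residual
series by a peak-to-trough drop detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FlowCurve",
    "PowerLawFit",
    "AvalancheStats",
    "AvalancheEvent",
    "PowerLawRegressor",
    "fit_power_law",
    "area_under_flow_curve",
    "detrend",
    "detect_avalanches",
]


@dataclass(frozen=True)
class FlowCurve:
    """Time series of slice bright-area versus time.

    ``times`` are seconds on a uniform grid ``t_k = k / fps``; ``areas``
    are bright-pixel counts (non-negative).
    """

    times: np.ndarray
    areas: np.ndarray
    fps: float = 25.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "areas", areas)
        if times.ndim != 1 or areas.ndim != 1:
            raise ValueError("times and areas must be 1-D")
        if len(times) != len(areas):
            raise ValueError("times and areas must have equal length")
        if len(times) < 2:
            raise ValueError("a flow curve needs at least 2 samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_areas(cls, areas: Sequence[float], fps: float = 25.0) -> "FlowCurve":
        areas = np.asarray(areas, dtype=float)
        return cls(times=np.arange(len(areas)) / fps, areas=areas, fps=fps)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "time_s": self.times,
                "area_px": self.areas,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fps: float | None = None) -> "FlowCurve":
        import pandas as pd

        df = pd.read_csv(path)
        required = {"frame", "time_s", "area_px"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"flow-curve CSV must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        times = df["time_s"].to_numpy(float)
        if fps is None:
            dt = np.diff(times)
            fps = 1.0 / float(np.median(dt)) if len(dt) else 25.0
        return cls(times=times, areas=df["area_px"].to_numpy(float), fps=fps)


@dataclass(frozen=True)
class PowerLawFit:
    """Result of fitting ``y = a + b * t**c`` to a flow curve."""

    a: float
    b: float
    c: float
    rss: float
    r_squared: float
    converged: bool
    stderr: tuple[float, float, float] | None = None

    @property
    def a_plus_b(self) -> float:
        """Model value at t = 1 s; the ``a + b`` column of the field's tables."""
        return self.a + self.b

    def predict(self, times: np.ndarray) -> np.ndarray:
        return _model(np.asarray(times, dtype=float), self.a, self.b, self.c)


@dataclass(frozen=True)
class AvalancheEvent:
    """One slip event: residual peak position, drop size, gap to previous peak."""

    position: int
    amplitude: float
    gap: float  # frames since previous event's peak; nan for the first


@dataclass(frozen=True)
class AvalancheStats:
    """Summary of detected avalanches on a detrended flow curve."""

    count: int
    amplitude_mean: float
    wavelength_mean: float  # frames (1 frame = 1/fps s); nan if count < 2
    per_event: tuple[AvalancheEvent, ...] = field(default_factory=tuple)


def _model(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    # 0**c = 0 for c > 0, so the model value at t = 0 is a
    out = np.full_like(t, a, dtype=float)
    pos = t > 0
    out[pos] += b * t[pos] ** c
    return out


class PowerLawRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of ``y = a + b * t**c``.

    A scikit-learn style regressor over a single time feature.  The
    exponent is bounded to ``c_bounds`` (default (0.05, 1.5)) and the
    solver uses the analytic Jacobian.  If the default initialization does
    not converge, a small multi-start over ``c0 in {0.25, 1/3, 0.5}`` is
    tried and the best residual sum of squares kept.

    Parameters
    ----------
    init : tuple (a0, b0, c0), optional
        Explicit starting point.  Default: ``a0`` = first observed area,
        ``c0 = 1/3`` (the ideal-cone exponent), ``b0`` from the endpoints
        ``(y_last - y_first) / t_last**c0``.
    c_bounds : tuple of float
        Box bounds on the exponent.
    max_nfev : int
        Function-evaluation budget per start.

    Attributes
    ----------
    a_, b_, c_ : float
        Fitted parameters.
    rss_ : float
        Residual sum of squares.
    r_squared_ : float
        Coefficient of determination on the training curve.
    converged_ : bool
        Solver success flag (best start).
    stderr_ : ndarray of shape (3,)
        Asymptotic standard errors of (a, b, c) from the Jacobian.
    """

    _MULTISTART_C0 = (0.25, 1.0 / 3.0, 0.5)

    def __init__(
        self,
        init: tuple[float, float, float] | None = None,
        c_bounds: tuple[float, float] = (0.05, 1.5),
        max_nfev: int = 2000,
    ) -> None:
        self.init = init
        self.c_bounds = c_bounds
        self.max_nfev = max_nfev

    def _default_init(self, t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
        c0 = 1.0 / 3.0
        a0 = float(y[0])
        t_last = t[-1] if t[-1] > 0 else 1.0
        b0 = float((y[-1] - y[0]) / t_last**c0)
        if b0 == 0.0:
            b0 = 1.0
        return a0, b0, c0

    def fit(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("expected a single time feature")
            t = t[:, 0]
        y = np.asarray(y, dtype=float)
        if len(t) != len(y):
            raise ValueError("X and y length mismatch")
        if len(t) < 10:
            raise ValueError("need at least 10 points to fit the power law")
        if np.ptp(y) == 0:
            raise ValueError("degenerate flat curve: all areas equal")

        lo, hi = self.c_bounds
        bounds = ([-np.inf, -np.inf, lo], [np.inf, np.inf, hi])

        def residuals(p):
            return _model(t, *p) - y

        def jacobian(p):
            a, b, c = p
            J = np.zeros((len(t), 3))
            J[:, 0] = 1.0
            pos = t > 0
            tc = t[pos] ** c
            J[pos, 1] = tc
            J[pos, 2] = b * tc * np.log(t[pos])
            return J

        starts = [self.init if self.init is not None else self._default_init(t, y)]
        best = None
        for trial, (a0, b0, c0) in enumerate(starts):
            c0 = min(max(c0, lo + 1e-9), hi - 1e-9)
            res = least_squares(
                residuals,
                x0=[a0, b0, c0],
                jac=jacobian,
                bounds=bounds,
                max_nfev=self.max_nfev,
            )
            if best is None or res.cost < best.cost:
                best = res
            if not best.success and trial == 0 and self.init is None:
                a0d, b0d, _ = self._default_init(t, y)
                starts.extend(
                    (a0d, b0d, c0m)
                    for c0m in self._MULTISTART_C0
                )

        self.a_, self.b_, self.c_ = (float(v) for v in best.x)
        self.rss_ = float(2.0 * best.cost)
        sst = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - self.rss_ / sst if sst > 0 else float("nan")
        self.converged_ = bool(best.success)
        J = jacobian(best.x)
        dof = max(len(t) - 3, 1)
        JtJ = J.T @ J
        try:
            cov = np.linalg.inv(JtJ) * (self.rss_ / dof)
            self.stderr_ = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            self.stderr_ = np.full(3, np.nan)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        return _model(t, self.a_, self.b_, self.c_)


def fit_power_law(
    curve: FlowCurve, init: tuple[float, float, float] | None = None
) -> PowerLawFit:
    """Fit the cone-growth power law to a flow curve.

    See :class:`PowerLawRegressor` for the optimizer details.  Raises on
    fewer than 10 points or a perfectly flat curve; non-convergence is
    reported via ``converged=False`` with the best iterate retained.
    """
    reg = PowerLawRegressor(init=init).fit(curve.times, curve.areas)
    return PowerLawFit(
        a=reg.a_,
        b=reg.b_,
        c=reg.c_,
        rss=reg.rss_,
        r_squared=reg.r_squared_,
        converged=reg.converged_,
        stderr=tuple(float(s) for s in reg.stderr_),
    )


def area_under_flow_curve(curve: FlowCurve) -> float:
    """Trapezoidal area under the flow curve over the frame-index abscissa.

    Integrating against frame number (not seconds) keeps the magnitude on
    the conventional reporting scale for 25 fps recordings, matching the
    frame-unit convention used for avalanche wavelengths.
    """
    if len(curve) < 2:
        raise ValueError("AUFC needs at least 2 points")
    return float(np.trapezoid(curve.areas))


def detrend(curve: FlowCurve, fit: PowerLawFit) -> np.ndarray:
    """Residuals ``y_k - (a + b * t_k**c)`` of the fitted trend."""
    return curve.areas - _model(curve.times, fit.a, fit.b, fit.c)


def detect_avalanches(
    residuals: np.ndarray,
    min_prominence: float = 2.0,
    min_gap: int = 5,
) -> AvalancheStats:
    """Count avalanches as peak-to-trough drops of the residual series.

    An avalanche is a local maximum of the detrended curve followed by a
    relaxation drop: the pile flank steepens past its critical slope, then
    sheds material.  Peaks are located with prominence >= ``min_prominence``
    (pixels) and spacing >= ``min_gap`` frames; each event's amplitude is
    the drop from its peak to the lowest residual before the next peak, and
    the wavelength is the frame gap between successive peaks.

    Boundary plateaus count: the series is padded with its minimum so a
    leading high plateau that steps down is still one event.
    """
    res = np.asarray(residuals, dtype=float)
    if res.ndim != 1 or len(res) < 10:
        raise ValueError("residual series must be 1-D with length >= 10")

    padded = np.concatenate([[res.min()], res, [res.min()]])
    peaks, _ = find_peaks(padded, prominence=min_prominence, distance=max(min_gap, 1))
    peaks = peaks - 1  # undo padding offset
    peaks = peaks[(peaks >= 0) & (peaks < len(res))]

    events: list[AvalancheEvent] = []
    for i, p in enumerate(peaks):
        stop = peaks[i + 1] if i + 1 < len(peaks) else len(res)
        trough = float(res[p : stop + 1].min()) if p < stop else float(res[p])
        amplitude = float(res[p]) - trough
        gap = float(p - peaks[i - 1]) if i > 0 else float("nan")
        events.append(AvalancheEvent(position=int(p), amplitude=amplitude, gap=gap))

    count = len(events)
    amp_mean = float(np.mean([e.amplitude for e in events])) if count else float("nan")
    gaps = [e.gap for e in events if np.isfinite(e.gap)]
    wav_mean = float(np.mean(gaps)) if len(gaps) >= 1 and count >= 2 else float("nan")
    return AvalancheStats(
        count=count,
        amplitude_mean=amp_mean,
        wavelength_mean=wav_mean,
        per_event=tuple(events),
    )
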