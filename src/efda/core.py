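"""Geometric kernel for elastic registration of 1-D signals.

Signals live on normalized time ``t in [0, 1]`` sampled on the uniform grid
``t_k = k/(n-1)``.  The central object is the square-root rate function
(SRSF, also called SRRF or SRVF in the literature)

    q(t) = xdot(t) / sqrt(|xdot(t)|)

under which the Fisher-Rao metric between signals becomes the plain L2
distance between their SRSFs, and re-parametrization by a warping function
``gamma`` acts by the isometry ``q -> (q o gamma) * sqrt(gammadot)``.  These
two facts are what make elastic alignment symmetric and pinch-free, and
every higher-level module builds on the operators defined here.

Conventions (fixed throughout the package):

* derivatives by central differences, one-sided at the boundaries
  (``numpy.gradient``);
* ``q = 0`` wherever ``xdot = 0`` (the continuous limit of ``xdot/sqrt|xdot|``);
* piecewise-linear interpolation for signals and warps;
* all integrals by the trapezoidal rule on the closed grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "TimeSeries",
    "SRSF",
    "WarpFunction",
    "InvalidArgumentError",
    "InvalidDataError",
    "InvalidWarpError",
    "resample_uniform",
    "to_srrf",
    "from_srrf",
    "l2_srsf_distance",
    "apply_warp",
    "warp_srsf",
    "invert_warp",
    "compose_warps",
]


class InvalidArgumentError(ValueError):
    """An argument violates a precondition (sizes, ranges, indices)."""


class InvalidDataError(ValueError):
    """Input data are unusable (non-finite values, empty input)."""


class InvalidWarpError(ValueError):
    """A warping function is not a monotone map of [0, 1] onto itself."""


#: slack below which successive warp differences are clamped to non-decreasing
WARP_MONOTONE_TOL = 1e-12
#: slack on the fixed endpoints gamma(0)=0, gamma(1)=1
WARP_ENDPOINT_TOL = 1e-9


def _uniform_grid(n: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


@dataclass(frozen=True)
class TimeSeries:
    """One sampled signal on the uniform normalized-time grid.

    Parameters
    ----------
    values : array-like of float
        Samples of the signal; at least 3 points, all finite.
    duration_s : float, optional
        Original clock duration of the trial in seconds, if known.  Purely
        metadata: all geometry happens on normalized time.
    id : str, optional
        Trial label.
    """

    values: np.ndarray
    duration_s: float | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 3:
            raise InvalidArgumentError(
                f"a TimeSeries needs a 1-D array of >= 3 samples, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidDataError("TimeSeries values must be finite (no NaN/inf)")
        if self.duration_s is not None and not self.duration_s > 0:
            raise InvalidArgumentError("duration_s must be positive when given")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def t(self) -> np.ndarray:
        """The implicit uniform grid t_k = k/(n-1) on [0, 1]."""
        return _uniform_grid(self.n_samples)


@dataclass(frozen=True)
class SRSF:
    """Square-root rate function q(t) of a signal, on the same grid.

    ``x0`` stores the source signal's initial value so the transform can be
    inverted: x(t) = x0 + int_0^t q|q| ds.
    """

    q: np.ndarray
    x0: float = 0.0

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or q.size < 3:
            raise InvalidArgumentError("an SRSF needs a 1-D array of >= 3 samples")
        if not (np.all(np.isfinite(q)) and np.isfinite(self.x0)):
            raise InvalidDataError("SRSF values and x0 must be finite")
        object.__setattr__(self, "q", q)

    @property
    def n_samples(self) -> int:
        return self.q.size

    @property
    def t(self) -> np.ndarray:
        return _uniform_grid(self.n_samples)


@dataclass(frozen=True)
class WarpFunction:
    """A monotone re-parametrization gamma of [0, 1] with fixed endpoints.

    Sampled on the uniform grid; gamma[0] = 0 and gamma[-1] = 1 exactly
    (values within a small tolerance are snapped, anything further raises).
    Successive differences down to -1e-12 are accepted and clamped to
    non-decreasing; a genuinely decreasing input raises InvalidWarpError.
    """

    gamma: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim != 1 or g.size < 3:
            raise InvalidWarpError("a warp needs a 1-D array of >= 3 samples")
        if not np.all(np.isfinite(g)):
            raise InvalidWarpError("warp values must be finite")
        if abs(g[0]) > WARP_ENDPOINT_TOL or abs(g[-1] - 1.0) > WARP_ENDPOINT_TOL:
            raise InvalidWarpError(
                f"warp endpoints must be 0 and 1, got {g[0]!r} and {g[-1]!r}"
            )
        if np.any(np.diff(g) < -WARP_MONOTONE_TOL):
            raise InvalidWarpError("warp is decreasing beyond tolerance")
        g = np.maximum.accumulate(g)
        g = np.clip(g, 0.0, 1.0)
        g[0], g[-1] = 0.0, 1.0
        object.__setattr__(self, "gamma", g)

    @property
    def n_samples(self) -> int:
        return self.gamma.size

    @property
    def t(self) -> np.ndarray:
        return _uniform_grid(self.n_samples)

    @classmethod
    def identity(cls, n: int) -> "WarpFunction":
        return cls(_uniform_grid(n))


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def resample_uniform(ts: TimeSeries, n: int) -> TimeSeries:
    """Resample a signal to ``n`` points by linear interpolation.

    Endpoints are preserved exactly; duration and id metadata carry over.
    """
    if n < 3:
        raise InvalidArgumentError(f"need n >= 3 samples, got {n}")
    new = np.interp(_uniform_grid(n), ts.t, ts.values)
    new[0], new[-1] = ts.values[0], ts.values[-1]
    return TimeSeries(new, duration_s=ts.duration_s, id=ts.id)


def _srsf_values(x: np.ndarray) -> np.ndarray:
    dt = 1.0 / (x.size - 1)
    xdot = np.gradient(x, dt)
    return np.sign(xdot) * np.sqrt(np.abs(xdot))


def to_srrf(ts: TimeSeries) -> SRSF:
    """Transform a signal to its square-root rate function.

    q_k = xdot(t_k)/sqrt(|xdot(t_k)|), with q_k = 0 where the derivative
    vanishes; derivative by central differences (one-sided at the ends).
    """
    return SRSF(_srsf_values(ts.values), x0=float(ts.values[0]))


def from_srrf(q: SRSF, duration_s: float | None = None, id: str | None = None) -> TimeSeries:
    """Invert the SRSF transform: x(t) = x0 + cumulative integral of q|q|."""
    dt = 1.0 / (q.n_samples - 1)
    x = q.x0 + cumulative_trapezoid(q.q * np.abs(q.q), dx=dt, initial=0.0)
    return TimeSeries(x, duration_s=duration_s, id=id)


def l2_srsf_distance(q1: SRSF, q2: SRSF) -> float:
    """L2 distance between two SRSFs == the Fisher-Rao distance of the signals.

    sqrt of the trapezoidal integral of (q2 - q1)^2 over [0, 1].
    """
    if q1.n_samples != q2.n_samples:
        raise InvalidArgumentError(
            f"SRSF length mismatch: {q1.n_samples} vs {q2.n_samples}"
        )
    dt = 1.0 / (q1.n_samples - 1)
    return float(np.sqrt(np.trapezoid((q2.q - q1.q) ** 2, dx=dt)))


def apply_warp(ts: TimeSeries, g: WarpFunction) -> TimeSeries:
    """Re-parametrize a signal: (x o gamma)(t_k) by linear interpolation.

    Stretches/compresses the timeline without changing the amplitude range
    (up to interpolation).  The warp is resampled if its grid differs.
    """
    gamma = g.gamma
    if g.n_samples != ts.n_samples:
        gamma = np.interp(ts.t, g.t, gamma)
    warped = np.interp(gamma, ts.t, ts.values)
    return TimeSeries(warped, duration_s=ts.duration_s, id=ts.id)


def warp_srsf(q: SRSF, g: WarpFunction) -> SRSF:
    """Group action on SRSFs: (q o gamma) * sqrt(gammadot).

    This is the SRSF of the warped signal; the action is an L2 isometry,
    which is what prevents pinching during alignment.
    """
    gamma = g.gamma
    if g.n_samples != q.n_samples:
        gamma = np.interp(q.t, g.t, gamma)
    dt = 1.0 / (q.n_samples - 1)
    gdot = np.clip(np.gradient(gamma, dt), 0.0, None)
    qw = np.interp(gamma, q.t, q.q) * np.sqrt(gdot)
    return SRSF(qw, x0=q.x0)


def invert_warp(g: WarpFunction) -> WarpFunction:
    """Inverse warp by swapping axes and re-interpolating to the grid."""
    t = g.t
    gamma = g.gamma
    # np.interp needs strictly increasing abscissae; break exact flats
    gs = gamma + np.arange(gamma.size) * 1e-14
    inv = np.interp(t, gs / gs[-1], t)
    inv[0], inv[-1] = 0.0, 1.0
    return WarpFunction(inv)


def compose_warps(g1: WarpFunction, g2: WarpFunction) -> WarpFunction:
    """Composition gamma1(gamma2(t)), sampled on g2's grid."""
    comp = np.interp(g2.gamma, g1.t, g1.gamma)
    comp[0], comp[-1] = 0.0, 1.0
    return WarpFunction(comp)
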