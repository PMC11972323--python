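"""Ground-truth synthetic benchmark signals and peak-feature extraction.

The generator produces two-peaked signals with a small, narrow "flick"
riding on the shoulder of the second peak:

    x(t) = A1 exp(-4 ln2 / W1^2 (t - T1)^2)
         + A2 exp(-4 ln2 / W2^2 (t - T2)^2)
         + (A2/3) exp(-4 ln2 / (W2/5)^2 (t - T2 - W2/2)^2)

with T1 = t0 and T2 = t0 + dT, on t in [0, 1] seconds.  W1, W2 are full
widths at half maximum (for a lone Gaussian the FWHM equals W exactly), and
the flick reuses scaled parameters of the second peak — a salient landmark
that survives elastic alignment but washes out under naive averaging.

An ensemble draws independent zero-mean Gaussian perturbations of the
parameters (defaults below), evaluates each signal on a dense grid, and trims
it to where it exceeds 2% of its own maximum, so trials end up with
different lengths and durations — exactly the situation the alignment
methods are compared on.

Default parameters (signal units are arbitrary, times in seconds):
A1 = 3 (sd 0.3), A2 = 4 (sd 0.3), W1 = W2 = 0.16 s (sd 0.05), dT = 0.4 s
(sd 0.03), t0 = 0.3 s (no noise by default; ``sigma_t0`` is available for
users who want first-peak-time noise too), trim at 2% of max, dt = 0.002 s.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.signal import find_peaks

from .core import InvalidArgumentError, TimeSeries

__all__ = [
    "GaussianParams",
    "FeatureSet",
    "FeatureExtractionError",
    "triple_gaussian",
    "generate_ensemble",
    "extract_features",
]

_4LN2 = 4.0 * np.log(2.0)


class FeatureExtractionError(RuntimeError):
    """The requested number of peaks could not be identified."""


@dataclass(frozen=True)
class GaussianParams:
    """Generator configuration; defaults are the benchmark conditions."""

    A1: float = 3.0
    A2: float = 4.0
    W1: float = 0.16
    W2: float = 0.16
    t0: float = 0.3
    dT: float = 0.4
    sigma_A1: float = 0.3
    sigma_A2: float = 0.3
    sigma_W1: float = 0.05
    sigma_W2: float = 0.05
    sigma_dT: float = 0.03
    sigma_t0: float = 0.0
    trim_frac: float = 0.02
    dt: float = 0.002
    flick: bool = True

    def __post_init__(self) -> None:
        for name in ("A1", "A2", "W1", "W2", "dT", "dt"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if not 0 <= self.trim_frac < 1:
            raise InvalidArgumentError("trim_frac must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianParams":
        return cls(**d)


@dataclass(frozen=True)
class FeatureSet:
    """Peak features of a (one- or) two-peaked signal, time-ordered.

    Amplitudes in signal units; times and widths in the units of the time
    axis the features were extracted on.  Single-peak extraction leaves the
    second peak's fields NaN.
    """

    A1_hat: float
    T1_hat: float
    W1_hat: float
    A2_hat: float = np.nan
    T2_hat: float = np.nan
    W2_hat: float = np.nan


def _gauss(t: np.ndarray, A: float, W: float, T: float) -> np.ndarray:
    return A * np.exp(-_4LN2 / W**2 * (t - T) ** 2)


def triple_gaussian(p: GaussianParams, tgrid: np.ndarray) -> TimeSeries:
    """Evaluate the (noise-free) generator function on an explicit grid."""
    t = np.asarray(tgrid, dtype=float)
    T1, T2 = p.t0, p.t0 + p.dT
    x = _gauss(t, p.A1, p.W1, T1) + _gauss(t, p.A2, p.W2, T2)
    if p.flick:
        x = x + _gauss(t, p.A2 / 3.0, p.W2 / 5.0, T2 + p.W2 / 2.0)
    return TimeSeries(x, duration_s=float(t[-1] - t[0]) or None)


def _positive_draw(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """Gaussian draw, redrawn until positive (widths/amplitudes must stay valid)."""
    if sigma == 0:
        return mean
    while True:
        v = rng.normal(mean, sigma)
        if v > 0:
            return float(v)


def generate_ensemble(
    p: GaussianParams,
    n_signals: int,
    seed: int,
    return_params: bool = False,
):
    """Draw a seeded ensemble of noisy, onset/offset-trimmed signals.

    Each signal perturbs (A1, A2, W1, W2, dT) — and t0 if ``sigma_t0 > 0`` —
    by independent zero-mean Gaussian noise, is evaluated on the dense grid
    over [0, 1] s at interval ``dt``, and is trimmed to the span where it
    reaches ``trim_frac`` of its own maximum.  Signals therefore differ in
    length and duration.

    With ``return_params=True`` also returns a pandas DataFrame of the drawn
    parameters plus each trial's onset/offset/duration in seconds — the
    ground truth for benchmark scoring.
    """
    if n_signals < 2:
        raise InvalidArgumentError("need n_signals >= 2")
    rng = np.random.default_rng(seed)
    tgrid = np.arange(0.0, 1.0 + p.dt / 2, p.dt)
    signals: list[TimeSeries] = []
    rows = []
    for i in range(n_signals):
        a1 = _positive_draw(rng, p.A1, p.sigma_A1)
        a2 = _positive_draw(rng, p.A2, p.sigma_A2)
        w1 = _positive_draw(rng, p.W1, p.sigma_W1)
        w2 = _positive_draw(rng, p.W2, p.sigma_W2)
        dT = _positive_draw(rng, p.dT, p.sigma_dT)
        t0 = p.t0 if p.sigma_t0 == 0 else _positive_draw(rng, p.t0, p.sigma_t0)
        pi = replace(p, A1=a1, A2=a2, W1=w1, W2=w2, dT=dT, t0=t0)
        x = triple_gaussian(pi, tgrid).values
        thr = p.trim_frac * x.max()
        above = np.flatnonzero(x >= thr)
        lo, hi = int(above[0]), int(above[-1])
        vals = x[lo: hi + 1]
        duration = (hi - lo) * p.dt
        signals.append(TimeSeries(vals, duration_s=duration, id=f"sig{i:04d}"))
        rows.append(
            dict(A1=a1, A2=a2, W1=w1, W2=w2, dT=dT, t0=t0,
                 onset_s=lo * p.dt, offset_s=hi * p.dt, duration_s=duration)
        )
    if return_params:
        import pandas as pd

        return signals, pd.DataFrame(rows)
    return signals


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

#: fractional prominence (of the global max) below which a bump is not a peak
_PROMINENCE_FRAC = 0.01
#: fractional rise (of the peak amplitude) above the running minimum at which
#: an outward half-max walk stops: it has entered a neighbouring bump (e.g.
#: the flick on the second peak's half-max shoulder)
_RISE_FRAC = 0.02


def _parabolic_refine(v: np.ndarray, t: np.ndarray, k: int) -> tuple[float, float]:
    """Refine an argmax by the vertex of the parabola through 3 samples."""
    if k == 0 or k == v.size - 1:
        return float(v[k]), float(t[k])
    y0, y1, y2 = v[k - 1], v[k], v[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # flat or degenerate: keep the sample
        return float(v[k]), float(t[k])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    tpk = t[k] + delta * (t[k + 1] - t[k]) if delta >= 0 else t[k] + delta * (t[k] - t[k - 1])
    apk = y1 - 0.25 * (y0 - y2) * delta
    return float(apk), float(tpk)


def _half_crossing(
    v: np.ndarray, t: np.ndarray, peak: int, half: float, amp: float, direction: int
) -> float | None:
    """Walk outward from a peak to the half-max crossing (linear interp).

    Returns None when the walk starts rising appreciably before crossing —
    it has run into a neighbouring peak (the search is thereby bounded at
    the valley), or when it falls off the sampled span.
    """
    run_min = v[peak]
    k = peak
    while True:
        k += direction
        if k < 0 or k >= v.size:
            return None
        if v[k] <= half:
            kin = k - direction  # still above half
            f = (v[kin] - half) / (v[kin] - v[k])
            return float(t[kin] + f * (t[k] - t[kin]))
        run_min = min(run_min, v[k])
        if v[k] > run_min + _RISE_FRAC * amp:
            return None


def extract_features(
    signal, t: np.ndarray | None = None, n_peaks: int = 2
) -> FeatureSet:
    """Amplitudes, times, and FWHMs of the one or two main peaks.

    Parameters
    ----------
    signal : TimeSeries or 1-D array
        The curve to analyse.  NaNs (e.g. the tail of a padded mean curve)
        are allowed; analysis is restricted to the finite run containing the
        global maximum.
    t : 1-D array, optional
        Time axis; defaults to the TimeSeries' normalized grid (or sample
        index/(n-1) for a bare array).  Features are in these units.
    n_peaks : {1, 2}
        Restrict to single-peak mode, or extract both main peaks.

    Notes
    -----
    The two peaks are the two most prominent local maxima, reported in time
    order.  Peak times/amplitudes are refined by a parabola through the
    three samples around the argmax.  Each FWHM comes from the half-maximum
    crossings found walking outward from the peak; a walk that starts rising
    before it crosses (a neighbouring bump, such as the narrow flick that
    sits on the second peak's half-max shoulder) is abandoned and that side's
    half-width is mirrored from the opposite side.  Raises
    :class:`FeatureExtractionError` when fewer than ``n_peaks`` peaks exist
    or no half-width can be established.
    """
    if isinstance(signal, TimeSeries):
        v = signal.values
        t = signal.t if t is None else np.asarray(t, float)
    else:
        v = np.asarray(signal, dtype=float)
        if t is None:
            t = np.linspace(0.0, 1.0, v.size)
        else:
            t = np.asarray(t, float)
    if n_peaks not in (1, 2):
        raise InvalidArgumentError("n_peaks must be 1 or 2")

    finite = np.isfinite(v)
    if not finite.all():
        # restrict to the contiguous finite run containing the global max
        idx_max = int(np.nanargmax(v))
        lo = idx_max
        while lo > 0 and finite[lo - 1]:
            lo -= 1
        hi = idx_max
        while hi < v.size - 1 and finite[hi + 1]:
            hi += 1
        v, t = v[lo: hi + 1], t[lo: hi + 1]

    prom = _PROMINENCE_FRAC * (v.max() - v.min())
    peaks, props = find_peaks(v, prominence=prom)
    if peaks.size < n_peaks:
        raise FeatureExtractionError(
            f"found {peaks.size} peaks, need {n_peaks}"
        )
    order = np.argsort(props["prominences"])[::-1][:n_peaks]
    chosen = np.sort(peaks[order])  # time order

    feats = []
    for pk in chosen:
        amp, tpk = _parabolic_refine(v, t, int(pk))
        half = amp / 2.0
        left = _half_crossing(v, t, int(pk), half, amp, -1)
        right = _half_crossing(v, t, int(pk), half, amp, +1)
        if left is None and right is None:
            raise FeatureExtractionError("no half-maximum crossing on either side")
        if left is None:
            width = 2.0 * (right - tpk)
        elif right is None:
            width = 2.0 * (tpk - left)
        else:
            width = right - left
        feats.append((amp, tpk, width))

    if n_peaks == 1:
        return FeatureSet(*feats[0])
    (a1, t1, w1), (a2, t2, w2) = feats
    return FeatureSet(a1, t1, w1, a2, t2, w2)
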