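"""Spatial / temporal decomposition of ensemble variability.

After elastic alignment, what remains across an ensemble splits into three
scalars, each the time-average of a pointwise standard-deviation curve:

* ``Var_Spat``  — SD across the aligned signals at each time point, averaged
  over time; amplitude variability in the signal's own units.
* ``Var_Temp``  — SD across the warping functions at each time point,
  averaged over time; timing variability in (unitless) normalized time.
* ``Var_Temp2Spat`` — the aligned mean warped by each trial's warp gives an
  ensemble with identical shape but varying timing; its spatial variability
  expresses the timing noise back in signal units.

Sample SDs use denominator M-1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InvalidArgumentError, TimeSeries, WarpFunction, apply_warp

__all__ = [
    "VariabilityReport",
    "spatial_variability",
    "temporal_variability",
    "temporal_to_spatial",
    "variability_report",
]


@dataclass(frozen=True)
class VariabilityReport:
    var_spat: float
    var_temp: float
    var_temp2spat: float
    sd_curve_spat: np.ndarray
    sd_curve_temp: np.ndarray
    sd_curve_temp2spat: np.ndarray

    def to_dict(self) -> dict:
        return {
            "var_spat": self.var_spat,
            "var_temp": self.var_temp,
            "var_temp2spat": self.var_temp2spat,
        }


def _stack(aligned) -> np.ndarray:
    if isinstance(aligned, np.ndarray):
        X = np.asarray(aligned, dtype=float)
    else:
        X = np.vstack([
            s.values if isinstance(s, TimeSeries) else np.asarray(s, float)
            for s in aligned
        ])
    if X.ndim != 2:
        raise InvalidArgumentError("expected an M x N matrix of aligned signals")
    return X


def spatial_variability(aligned) -> tuple[float, np.ndarray]:
    """Time-averaged pointwise SD across signals (matrix rows or TimeSeries)."""
    X = _stack(aligned)
    if X.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 signals")
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("aligned ensembles must be NaN-free")
    sd = X.std(axis=0, ddof=1)
    return float(sd.mean()), sd


def temporal_variability(warps: list[WarpFunction]) -> tuple[float, np.ndarray]:
    """Time-averaged pointwise SD across the warping functions.

    Subtracting the identity (or the mean warp) from every gamma first does
    not change the result: a per-time-point translation cancels in the SD.
    """
    if len(warps) < 2:
        raise InvalidArgumentError("need >= 2 warps")
    G = np.vstack([w.gamma for w in warps])
    sd = G.std(axis=0, ddof=1)
    return float(sd.mean()), sd


def temporal_to_spatial(
    mean_aligned: TimeSeries, warps: list[WarpFunction]
) -> tuple[float, np.ndarray]:
    """Spatial footprint of the timing noise.

    The aligned mean is warped by each trial's gamma, yielding an ensemble of
    identical shape and amplitude but varying temporal evolution; its
    spatial variability is returned.
    """
    Xw = [apply_warp(mean_aligned, w) for w in warps]
    return spatial_variability(Xw)


def variability_report(alignment_result) -> VariabilityReport:
    """All three statistics from an :class:`~efda.align.AlignmentResult`."""
    v_s, c_s = spatial_variability(alignment_result.aligned)
    v_t, c_t = temporal_variability(alignment_result.warps)
    v_ts, c_ts = temporal_to_spatial(alignment_result.template,
                                     alignment_result.warps)
    return VariabilityReport(v_s, v_t, v_ts, c_s, c_t, c_ts)
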