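"""Conventional length-equalization baselines: NaN-padding and
time-normalization, with NaN-aware ensemble statistics.

Padding keeps every original sample bit-exactly and fills the ragged tail
(or head) with NaN; normalization resamples every trial to a common number
of samples, which equalizes lengths but does not align features.  Both serve
as the comparison points for elastic alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InvalidArgumentError, TimeSeries, resample_uniform

__all__ = ["EnsembleMatrix", "pad_ensemble", "normalize_ensemble", "ensemble_stats"]


@dataclass(frozen=True)
class EnsembleMatrix:
    """M x N matrix of trials, NaN marking absent samples.

    ``alignment_mode`` records how the matrix was built: ``pad_left`` (common
    start, NaNs only at row ends), ``pad_right`` (common end, NaNs only at
    row starts), ``normalized`` or ``warped`` (complete, no NaNs).
    """

    data: np.ndarray
    alignment_mode: str

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise InvalidArgumentError("EnsembleMatrix needs a 2-D array")
        if self.alignment_mode not in {"pad_left", "pad_right", "normalized", "warped"}:
            raise InvalidArgumentError(f"unknown alignment_mode {self.alignment_mode!r}")
        object.__setattr__(self, "data", d)

    @property
    def counts(self) -> np.ndarray:
        """Number of finite entries per column."""
        return np.sum(np.isfinite(self.data), axis=0)


def pad_ensemble(signals: list[TimeSeries], side: str = "left") -> EnsembleMatrix:
    """Stack trials at a common start (``left``) or common end (``right``).

    No resampling: original samples are preserved exactly, shorter trials
    padded with NaN to the longest length.
    """
    if not signals:
        raise InvalidArgumentError("empty ensemble")
    if side not in {"left", "right"}:
        raise InvalidArgumentError(f"side must be 'left' or 'right', got {side!r}")
    width = max(s.n_samples for s in signals)
    data = np.full((len(signals), width), np.nan)
    for k, s in enumerate(signals):
        if side == "left":
            data[k, : s.n_samples] = s.values
        else:
            data[k, width - s.n_samples:] = s.values
    return EnsembleMatrix(data, alignment_mode=f"pad_{side}")


def normalize_ensemble(signals: list[TimeSeries], n: int) -> EnsembleMatrix:
    """Resample every trial to ``n`` samples (uniform time normalization)."""
    if not signals:
        raise InvalidArgumentError("empty ensemble")
    data = np.vstack([resample_uniform(s, n).values for s in signals])
    return EnsembleMatrix(data, alignment_mode="normalized")


def ensemble_stats(
    m: EnsembleMatrix, min_count: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NaN-aware per-column mean and sample SD (ddof=1).

    Columns with fewer than ``min_count`` finite entries are reported as NaN
    in both mean and SD: padded tails with few trials would otherwise
    dominate the statistics.
    """
    if min_count < 2:
        raise InvalidArgumentError("min_count must be >= 2")
    data = m.data
    counts = m.counts
    mean = np.full(data.shape[1], np.nan)
    sd = np.full(data.shape[1], np.nan)
    ok = counts >= min_count
    if np.any(ok):
        cols = data[:, ok]
        mean[ok] = np.nanmean(cols, axis=0)
        sd[ok] = np.nanstd(cols, axis=0, ddof=1)
    return mean, sd, counts
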