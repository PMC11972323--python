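"""CSV input/output for signal ensembles and warping functions.

Two dialects, both comma-separated, '.' decimal, UTF-8, header row required,
empty cell = missing:

* **long** — columns ``trial_id, t, value``; ``t`` in seconds, strictly
  increasing within a trial.  Preserves per-trial durations.
* **wide** — first column ``t`` (seconds, shared sampling) or ``sample``
  (bare index); one column per trial; shorter trials end in empty cells.
  Durations survive only when the first column is ``t``.

Warps are serialized wide on the common normalized grid (first column
``t`` in [0, 1]) so they can be re-loaded for temporal variability without
re-running the alignment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import TimeSeries, WarpFunction

__all__ = [
    "FormatError",
    "load_ensemble",
    "save_ensemble",
    "load_warps",
    "save_warps",
]


class FormatError(ValueError):
    """An ensemble/warp file violates the expected CSV dialect."""


def _check_increasing(t: np.ndarray, trial: str) -> None:
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"trial {trial!r}: t must be strictly increasing")


def load_ensemble(path: str | Path, format: str = "long") -> list[TimeSeries]:
    """Read an ensemble file; one TimeSeries per trial, durations preserved."""
    path = Path(path)
    if format not in {"long", "wide"}:
        raise FormatError(f"format must be 'long' or 'wide', got {format!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    signals: list[TimeSeries] = []
    if format == "long":
        required = {"trial_id", "t", "value"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: long format needs columns {sorted(required)}")
        for trial, grp in df.groupby("trial_id", sort=False):
            t = grp["t"].to_numpy(dtype=float)
            v = grp["value"].to_numpy(dtype=float)
            _check_increasing(t, str(trial))
            signals.append(
                TimeSeries(v, duration_s=float(t[-1] - t[0]) or None, id=str(trial))
            )
    else:
        first = df.columns[0]
        if first not in {"t", "sample"}:
            raise FormatError(f"{path}: wide format needs first column 't' or 'sample'")
        tcol = df[first].to_numpy(dtype=float) if first == "t" else None
        if tcol is not None:
            _check_increasing(tcol, first)
        for col in df.columns[1:]:
            v = df[col].to_numpy(dtype=float)
            n = int(np.max(np.flatnonzero(np.isfinite(v))) + 1) if np.any(np.isfinite(v)) else 0
            if n == 0:
                raise FormatError(f"{path}: trial {col!r} has no values")
            v = v[:n]
            if not np.all(np.isfinite(v)):
                raise FormatError(f"{path}: trial {col!r} has interior missing values")
            dur = float(tcol[n - 1] - tcol[0]) if tcol is not None else None
            signals.append(TimeSeries(v, duration_s=dur or None, id=str(col)))
    return signals


def save_ensemble(
    signals: list[TimeSeries], path: str | Path, format: str = "long"
) -> None:
    """Write an ensemble; the written file round-trips through load_ensemble."""
    path = Path(path)
    if format == "long":
        frames = []
        for k, s in enumerate(signals):
            dur = s.duration_s if s.duration_s is not None else 1.0
            frames.append(pd.DataFrame({
                "trial_id": s.id or f"trial{k:04d}",
                "t": s.t * dur,
                "value": s.values,
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return
    if format != "wide":
        raise FormatError(f"format must be 'long' or 'wide', got {format!r}")
    width = max(s.n_samples for s in signals)
    # a shared seconds axis requires one common sampling interval
    dts = [
        s.duration_s / (s.n_samples - 1) for s in signals if s.duration_s is not None
    ]
    data: dict[str, np.ndarray] = {}
    if len(dts) == len(signals) and np.ptp(dts) <= 1e-9 * max(dts):
        data["t"] = np.arange(width) * dts[0]
    else:
        data["sample"] = np.arange(width, dtype=float)
    for k, s in enumerate(signals):
        col = np.full(width, np.nan)
        col[: s.n_samples] = s.values
        data[s.id or f"trial{k:04d}"] = col
    pd.DataFrame(data).to_csv(path, index=False)


def save_warps(warps: list[WarpFunction], path: str | Path,
               ids: list[str] | None = None) -> None:
    """Wide CSV of warping functions on their common normalized grid."""
    n = warps[0].n_samples
    data = {"t": np.linspace(0.0, 1.0, n)}
    for k, w in enumerate(warps):
        name = ids[k] if ids else f"trial{k:04d}"
        data[name] = w.gamma
    pd.DataFrame(data).to_csv(path, index=False)


def load_warps(path: str | Path) -> list[WarpFunction]:
    df = pd.read_csv(path)
    if df.empty or df.columns[0] != "t":
        raise FormatError(f"{path}: warp files need a leading 't' column")
    return [WarpFunction(df[c].to_numpy(dtype=float)) for c in df.columns[1:]]
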