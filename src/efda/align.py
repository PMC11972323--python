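"""Elastic alignment of signal ensembles under the Fisher-Rao metric.

The workhorse is :class:`ElasticAligner`, a scikit-learn style transformer:
``fit`` registers an ensemble (rows of a 2-D array, signals on a common
uniform grid over normalized time) to an emerging Karcher-type template —
the mean shape with the smallest summed amplitude distance, with warps
centered so their pointwise mean is the identity — and ``transform`` warps
new signals onto the fitted template.  The module-level functions
(:func:`align_pair`, :func:`align_ensemble`, :func:`align_to_reference`,
:func:`elastic_distance`) are thin wrappers for the
:class:`~efda.core.TimeSeries`-based workflow.

Pairwise registration minimizes, by dynamic programming over monotone
lattice paths (see :mod:`efda._dp`),

    int (q_ref - (q_mov o gamma) sqrt(gammadot))^2 dt
        + lambda_smooth * int (sqrt(gammadot) - 1)^2 dt

The defaults — ``lambda_smooth=0.01``, ``max_iterations=3``, dynamic
programming, no pre-smoothing — are the conventional settings for this kind
of elastic registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import _dp
from .core import (
    SRSF,
    InvalidArgumentError,
    TimeSeries,
    WarpFunction,
    _srsf_values,
    compose_warps,
    invert_warp,
    resample_uniform,
    to_srrf,
    warp_srsf,
)

__all__ = [
    "AlignmentOptions",
    "AlignmentResult",
    "ElasticAligner",
    "align_pair",
    "align_ensemble",
    "align_to_reference",
    "elastic_distance",
]

#: relative L2 template change below which the Karcher iteration stops
TEMPLATE_CONVERGENCE_TOL = 1e-4
#: SRSF sup-norm below which a signal counts as flat (zero rate everywhere)
_FLAT_TOL = 1e-12


@dataclass(frozen=True)
class AlignmentOptions:
    """Settings of the elastic registration.

    lambda_smooth
        Weight of the warp-roughness penalty int (sqrt(gammadot)-1)^2 dt.
    max_iterations
        Maximum template-update rounds of the ensemble alignment.
    grid_stride
        DP slope-set resolution: admissible local slopes are ratios b/a with
        a, b in 1..grid_stride and gcd(a, b) = 1.
    presmooth
        Apply a width-3 box filter to the signals before computing SRSFs.
    """

    lambda_smooth: float = 0.01
    max_iterations: int = 3
    grid_stride: int = 7
    presmooth: bool = False

    def __post_init__(self) -> None:
        if self.lambda_smooth < 0:
            raise InvalidArgumentError("lambda_smooth must be >= 0")
        if self.max_iterations < 1:
            raise InvalidArgumentError("max_iterations must be >= 1")
        if self.grid_stride < 1:
            raise InvalidArgumentError("grid_stride must be >= 1")


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of an ensemble alignment.

    ``aligned[i]`` equals ``apply_warp(normalized_input[i], warps[i])`` up to
    interpolation; ``amplitude_distances[i]`` is the minimized Fisher-Rao
    distance of signal i to the template; ``objective_history`` holds the
    summed DP objective of each iteration (non-increasing).
    """

    template: TimeSeries
    aligned: list[TimeSeries]
    warps: list[WarpFunction]
    amplitude_distances: np.ndarray
    n_iterations_run: int
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def mean_warp(self) -> WarpFunction:
        g = np.mean([w.gamma for w in self.warps], axis=0)
        g[0], g[-1] = 0.0, 1.0
        return WarpFunction(g)


def _box3(x: np.ndarray) -> np.ndarray:
    s = x.copy()
    s[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    return s


def _trapz_norm(v: np.ndarray) -> float:
    dt = 1.0 / (v.size - 1)
    return float(np.sqrt(np.trapezoid(v**2, dx=dt)))


class ElasticAligner(TransformerMixin, BaseEstimator):
    """Fisher-Rao elastic registration of an ensemble to a common template.

    Parameters
    ----------
    lambda_smooth : float, default 0.01
        Warp-roughness penalty weight.
    max_iterations : int, default 3
        Template-update rounds (ignored when ``reference`` is set: a fixed
        reference needs a single pass).
    grid_stride : int, default 7
        DP slope-set resolution; local warp slopes are confined to
        [1/grid_stride, grid_stride].
    presmooth : bool, default False
        Width-3 box filter on the signals before the SRSF transform.
    reference : int or None, default None
        If an integer, align every signal to row ``reference`` of X instead
        of to an emerging template, and skip warp centering.
    center : bool, default True
        After template alignment, re-express the warps so their pointwise
        mean is the identity (composing each with the inverse mean warp) and
        move the template accordingly.
    n_samples : int or None, default None
        Resample the input rows to this many columns before aligning.

    Attributes
    ----------
    template_ : ndarray of shape (n_grid_,)
        The registered mean signal (after centering).
    template_q_ : ndarray of shape (n_grid_,)
        Its SRSF; ``transform`` registers new signals against it.
    aligned_ : ndarray of shape (M, n_grid_)
        The fitted ensemble after warping.
    warps_ : ndarray of shape (M, n_grid_)
        Warping functions gamma_i on the uniform grid.
    amplitude_distances_ : ndarray of shape (M,)
        Minimized Fisher-Rao distance of each signal to the template
        (computed before centering; centering is an isometry).
    objective_history_ : ndarray
        Summed DP objective per iteration, non-increasing.
    n_iterations_ : int
        Iterations actually run.
    """

    def __init__(
        self,
        lambda_smooth: float = 0.01,
        max_iterations: int = 3,
        grid_stride: int = 7,
        presmooth: bool = False,
        reference: int | None = None,
        center: bool = True,
        n_samples: int | None = None,
    ):
        self.lambda_smooth = lambda_smooth
        self.max_iterations = max_iterations
        self.grid_stride = grid_stride
        self.presmooth = presmooth
        self.reference = reference
        self.center = center
        self.n_samples = n_samples

    # ------------------------------------------------------------------

    def _validate(self, X: np.ndarray, *, fitting: bool) -> np.ndarray:
        X = check_array(X, dtype=float, ensure_min_samples=2 if fitting else 1,
                        ensure_min_features=3)
        n = self.n_samples if fitting else self.n_grid_
        if n is not None and X.shape[1] != n:
            told = np.linspace(0.0, 1.0, X.shape[1])
            tnew = np.linspace(0.0, 1.0, n)
            X = np.vstack([np.interp(tnew, told, row) for row in X])
        return X

    def _srsf_matrix(self, X: np.ndarray) -> np.ndarray:
        rows = X if not self.presmooth else np.vstack([_box3(r) for r in X])
        return np.vstack([_srsf_values(r) for r in rows])

    def _dp(self, q_ref: np.ndarray, q_mov: np.ndarray):
        if (np.max(np.abs(q_ref)) < _FLAT_TOL and np.max(np.abs(q_mov)) < _FLAT_TOL):
            n = q_ref.size
            gamma = np.linspace(0.0, 1.0, n)
            zero = np.zeros(n)
            return gamma, 0.0, 0.0, 0.0, zero, zero
        return _dp.dp_pair(q_ref, q_mov, self.lambda_smooth, self.grid_stride)

    # ------------------------------------------------------------------

    def fit(self, X, y=None):
        opts = AlignmentOptions(self.lambda_smooth, self.max_iterations,
                                self.grid_stride, self.presmooth)  # validates
        del opts
        if self.n_samples is not None and self.n_samples < 3:
            raise InvalidArgumentError("n_samples must be >= 3")
        self.n_grid_ = self.n_samples
        X = self._validate(X, fitting=True)
        M, n = X.shape
        self.n_grid_ = n
        t = np.linspace(0.0, 1.0, n)
        Q = self._srsf_matrix(X)
        x0_mean = float(np.mean(X[:, 0]))

        if self.reference is not None:
            if not 0 <= self.reference < M:
                raise InvalidArgumentError(
                    f"reference index {self.reference} out of range for {M} signals"
                )
            q_templ = Q[self.reference]
            results = [self._dp(q_templ, q) for q in Q]
            gammas = np.vstack([r[0] for r in results])
            self.objective_history_ = np.array([sum(r[1] for r in results)])
            self.n_iterations_ = 1
            dists = np.array(
                [np.sqrt(max(_dp.quad_dist2(q_templ, r[4], r[5]), 0.0)) for r in results]
            )
            self.template_q_ = q_templ.copy()
            templ_x0 = float(X[self.reference, 0])
        else:
            # medoid-like start: the signal whose SRSF is closest to the mean SRSF
            qbar = Q.mean(axis=0)
            start = int(np.argmin([_trapz_norm(q - qbar) for q in Q]))
            q_templ = Q[start].copy()
            history: list[float] = []
            results = None
            for it in range(self.max_iterations):
                results = [self._dp(q_templ, q) for q in Q]
                history.append(sum(r[1] for r in results))
                # exact minimizer of the summed DP quadrature: per-node mean of
                # the left/right warped-SRSF limits along each optimal path
                q_new = np.mean([(r[4] + r[5]) * 0.5 for r in results], axis=0)
                rel = _trapz_norm(q_new - q_templ) / max(_trapz_norm(q_templ), 1e-12)
                q_templ = q_new
                if rel < TEMPLATE_CONVERGENCE_TOL:
                    break
            gammas = np.vstack([r[0] for r in results])
            dists = np.array(
                [np.sqrt(max(_dp.quad_dist2(q_templ, r[4], r[5]), 0.0)) for r in results]
            )
            self.objective_history_ = np.asarray(history)
            self.n_iterations_ = len(history)
            self.template_q_ = q_templ
            templ_x0 = x0_mean

            if self.center:
                gbar = gammas.mean(axis=0)
                gbar[0], gbar[-1] = 0.0, 1.0
                ginv = invert_warp(WarpFunction(gbar))
                gammas = np.vstack([
                    compose_warps(WarpFunction(g), ginv).gamma for g in gammas
                ])
                self.template_q_ = warp_srsf(SRSF(self.template_q_, x0=templ_x0), ginv).q

        self.warps_ = gammas
        self.aligned_ = np.vstack([np.interp(g, t, x) for g, x in zip(gammas, X)])
        self.amplitude_distances_ = dists
        # report the template in signal space: the cross-sectional mean of the
        # aligned signals (the reference row in reference mode), which avoids
        # the discretization error of integrating the q-space template back
        if self.reference is not None:
            self.template_ = X[self.reference].copy()
        else:
            self.template_ = self.aligned_.mean(axis=0)
        self.n_features_in_ = n
        return self

    def transform(self, X) -> np.ndarray:
        """Warp each row of X onto the fitted template; returns the aligned rows."""
        check_is_fitted(self, "template_q_")
        X = self._validate(X, fitting=False)
        t = np.linspace(0.0, 1.0, self.n_grid_)
        Q = self._srsf_matrix(X)
        out = np.empty_like(X)
        for k, (x, q) in enumerate(zip(X, Q)):
            gamma = self._dp(self.template_q_, q)[0]
            out[k] = np.interp(gamma, t, x)
        return out

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).aligned_


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def align_pair(
    q_ref: SRSF, q_mov: SRSF, opts: AlignmentOptions | None = None
) -> tuple[WarpFunction, float]:
    """Optimal warp of ``q_mov`` onto ``q_ref`` and the minimized amplitude cost.

    The returned cost is the amplitude (Fisher-Rao) part only, i.e. the L2
    distance between ``q_ref`` and the warped ``q_mov`` along the optimal
    path; the roughness penalty influences the optimum but is not reported.
    Two flat (all-zero-rate) inputs are already aligned: identity warp,
    cost 0.
    """
    opts = opts or AlignmentOptions()
    if q_ref.n_samples != q_mov.n_samples:
        raise InvalidArgumentError(
            f"SRSF length mismatch: {q_ref.n_samples} vs {q_mov.n_samples}"
        )
    if np.max(np.abs(q_ref.q)) < _FLAT_TOL and np.max(np.abs(q_mov.q)) < _FLAT_TOL:
        return WarpFunction.identity(q_ref.n_samples), 0.0
    gamma, _total, amp2, _pen, _cL, _cR = _dp.dp_pair(
        q_ref.q, q_mov.q, opts.lambda_smooth, opts.grid_stride
    )
    return WarpFunction(gamma), float(np.sqrt(max(amp2, 0.0)))


def _common_grid(signals: list[TimeSeries], n_samples: int | None) -> int:
    return n_samples if n_samples is not None else max(s.n_samples for s in signals)


def _mean_duration(signals: list[TimeSeries]) -> float | None:
    durs = [s.duration_s for s in signals]
    if any(d is None for d in durs):
        return None
    return float(np.mean(durs))


def _wrap_result(est: ElasticAligner, signals: list[TimeSeries]) -> AlignmentResult:
    aligned = [
        TimeSeries(row, duration_s=s.duration_s, id=s.id)
        for row, s in zip(est.aligned_, signals)
    ]
    template = TimeSeries(est.template_, duration_s=_mean_duration(signals),
                          id="template")
    warps = [WarpFunction(g) for g in est.warps_]
    return AlignmentResult(
        template=template,
        aligned=aligned,
        warps=warps,
        amplitude_distances=est.amplitude_distances_,
        n_iterations_run=est.n_iterations_,
        objective_history=est.objective_history_,
    )


def align_ensemble(
    signals: list[TimeSeries],
    opts: AlignmentOptions | None = None,
    n_samples: int | None = None,
) -> AlignmentResult:
    """Align an ensemble to an emerging common template.

    Signals are resampled to a common grid (``n_samples``, default the
    longest input), iteratively registered to the template — initialized as
    the signal closest in SRSF space to the cross-sectional mean SRSF,
    updated as the mean of the aligned SRSFs — and finally centered so the
    pointwise mean warp is the identity.
    """
    if len(signals) < 2:
        raise InvalidArgumentError("ensemble alignment needs >= 2 signals")
    opts = opts or AlignmentOptions()
    n = _common_grid(signals, n_samples)
    X = np.vstack([resample_uniform(s, n).values for s in signals])
    est = ElasticAligner(
        lambda_smooth=opts.lambda_smooth,
        max_iterations=opts.max_iterations,
        grid_stride=opts.grid_stride,
        presmooth=opts.presmooth,
    ).fit(X)
    return _wrap_result(est, signals)


def align_to_reference(
    signals: list[TimeSeries],
    reference_index: int,
    opts: AlignmentOptions | None = None,
    n_samples: int | None = None,
) -> AlignmentResult:
    """Align every signal onto a chosen reference signal (no centering)."""
    if len(signals) < 2:
        raise InvalidArgumentError("ensemble alignment needs >= 2 signals")
    if not 0 <= reference_index < len(signals):
        raise InvalidArgumentError(
            f"reference index {reference_index} out of range for {len(signals)} signals"
        )
    opts = opts or AlignmentOptions()
    n = _common_grid(signals, n_samples)
    X = np.vstack([resample_uniform(s, n).values for s in signals])
    est = ElasticAligner(
        lambda_smooth=opts.lambda_smooth,
        max_iterations=opts.max_iterations,
        grid_stride=opts.grid_stride,
        presmooth=opts.presmooth,
        reference=reference_index,
        center=False,
    ).fit(X)
    return _wrap_result(est, signals)


def elastic_distance(
    x1: TimeSeries,
    x2: TimeSeries,
    opts: AlignmentOptions | None = None,
    n_samples: int | None = None,
) -> tuple[float, float]:
    """Amplitude and phase distance between two signals.

    Amplitude: the Fisher-Rao distance minimized over warps (shape difference
    with timing removed).  Phase: the L2 distance between the SRSF of the
    recovered warp, sqrt(gammadot), and that of the identity, 1 — a pure
    timing difference.
    """
    opts = opts or AlignmentOptions()
    n = max(x1.n_samples, x2.n_samples) if n_samples is None else n_samples
    q1 = to_srrf(resample_uniform(x1, n))
    q2 = to_srrf(resample_uniform(x2, n))
    g, amp = align_pair(q1, q2, opts)
    dt = 1.0 / (n - 1)
    psi = np.sqrt(np.clip(np.gradient(g.gamma, dt), 0.0, None))
    phase = float(np.sqrt(np.trapezoid((psi - 1.0) ** 2, dx=dt)))
    return amp, phase
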