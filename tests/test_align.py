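"""Tests of pairwise DP alignment and iterative ensemble registration."""

import numpy as np
import pytest
from sklearn.base import clone

from efda.align import (
    AlignmentOptions,
    ElasticAligner,
    align_ensemble,
    align_pair,
    align_to_reference,
    elastic_distance,
)
from efda.core import (
    InvalidArgumentError,
    TimeSeries,
    WarpFunction,
    apply_warp,
    compose_warps,
    invert_warp,
    l2_srsf_distance,
    to_srrf,
)
from efda import _dp
from conftest import bruteforce_min_cost, smooth_warp, two_peak_values


def _gaussian(n, center, width=0.08, amp=1.0):
    t = np.linspace(0, 1, n)
    return amp * np.exp(-(((t - center) / width) ** 2))


class TestAlignPair:
    def test_identical_inputs_give_identity_warp(self, two_peak):
        q = to_srrf(two_peak)
        g, cost = align_pair(q, q)
        assert cost < 1e-8
        assert np.max(np.abs(g.gamma - g.t)) < 1e-12

    def test_flat_signals_align_trivially(self):
        q = to_srrf(TimeSeries(np.full(64, 2.5)))
        g, cost = align_pair(q, q)
        assert cost == 0.0
        assert np.allclose(g.gamma, g.t)

    def test_length_mismatch_raises(self, two_peak):
        with pytest.raises(InvalidArgumentError):
            align_pair(to_srrf(two_peak), to_srrf(TimeSeries(two_peak_values(64))))

    def test_self_warp_recovery(self, rng):
        n = 301
        ref = TimeSeries(two_peak_values(n))
        g0 = smooth_warp(rng, n)
        mov = apply_warp(ref, g0)
        qr, qm = to_srrf(ref), to_srrf(mov)
        g, cost = align_pair(qr, qm)
        target = invert_warp(g0).gamma
        assert np.max(np.abs(g.gamma - target)) < 0.02
        # residual cost is bounded by the cusp-quantization floor of the
        # lattice DP; it must be a small fraction of the unwarped distance
        assert cost < 0.05 * l2_srsf_distance(qr, qm)

    def test_peak_relocation(self):
        n = 201
        ref = TimeSeries(_gaussian(n, 0.4))
        mov = TimeSeries(_gaussian(n, 0.6))
        g, _ = align_pair(to_srrf(ref), to_srrf(mov))
        aligned = apply_warp(mov, g)
        assert abs(int(np.argmax(aligned.values)) - int(np.argmax(ref.values))) <= 1

    def test_never_worse_than_identity_warp(self, rng):
        for _ in range(10):
            q1 = to_srrf(TimeSeries(rng.normal(size=64).cumsum() / 8))
            q2 = to_srrf(TimeSeries(rng.normal(size=64).cumsum() / 8))
            _, cost = align_pair(q1, q2)
            assert cost <= l2_srsf_distance(q1, q2) + 1e-9

    def test_dp_cost_matches_exhaustive_search(self, rng):
        # restricted slope set, tiny grids: DP must equal the brute-force
        # minimum over every admissible monotone lattice path, exactly
        for k in range(10):
            n = int(rng.integers(6, 9))
            q1 = rng.normal(size=n)
            q2 = rng.normal(size=n)
            _, total, _, _, _, _ = _dp.dp_pair(q1, q2, 0.01, 2)
            assert total == pytest.approx(bruteforce_min_cost(q1, q2, 0.01, 2), abs=1e-12)

    def test_large_penalty_pushes_warp_to_identity(self, rng):
        n = 201
        ref = TimeSeries(two_peak_values(n))
        mov = apply_warp(ref, smooth_warp(rng, n))
        qr, qm = to_srrf(ref), to_srrf(mov)
        devs = []
        for lam in (0.01, 100.0, 1e4):
            g, _ = align_pair(qr, qm, AlignmentOptions(lambda_smooth=lam))
            devs.append(np.max(np.abs(g.gamma - g.t)))
        assert devs[0] >= devs[1] >= devs[2]
        assert devs[2] < 0.01


class TestAlignEnsemble:
    def test_identical_signals(self, two_peak):
        res = align_ensemble([two_peak] * 5)
        ident = np.linspace(0, 1, two_peak.n_samples)
        for w in res.warps:
            assert np.max(np.abs(w.gamma - ident)) < 1e-6
        assert np.max(np.abs(res.template.values - two_peak.values)) < 1e-6
        assert np.all(res.amplitude_distances < 1e-8)

    def test_timing_only_noise_collapses(self, rng):
        n = 201
        base = TimeSeries(two_peak_values(n))
        signals = [apply_warp(base, smooth_warp(rng, n, strength=0.4))
                   for _ in range(20)]
        before = np.vstack([s.values for s in signals]).std(axis=0, ddof=1).mean()
        res = align_ensemble(signals)
        after = np.vstack([s.values for s in res.aligned]).std(axis=0, ddof=1).mean()
        assert after < 0.05 * before

    def test_mean_warp_is_identity(self, rng):
        n = 151
        signals = [
            TimeSeries(two_peak_values(n, t1=0.3 + 0.05 * rng.standard_normal(),
                                       t2=0.65 + 0.05 * rng.standard_normal(),
                                       a1=1 + 0.2 * rng.standard_normal(),
                                       a2=1.5 + 0.2 * rng.standard_normal()))
            for _ in range(12)
        ]
        res = align_ensemble(signals)
        dev = np.max(np.abs(res.mean_warp.gamma - np.linspace(0, 1, n)))
        assert dev < 1e-2

    def test_aligned_equals_warped_original(self, rng):
        n = 151
        base = TimeSeries(two_peak_values(n))
        signals = [apply_warp(base, smooth_warp(rng, n)) for _ in range(6)]
        res = align_ensemble(signals)
        for s, a, w in zip(signals, res.aligned, res.warps):
            redo = apply_warp(s, w)
            assert np.max(np.abs(redo.values - a.values)) < 1e-10

    def test_objective_non_increasing(self, rng):
        n = 151
        base = TimeSeries(two_peak_values(n))
        signals = [apply_warp(base, smooth_warp(rng, n)) for _ in range(10)]
        res = align_ensemble(signals, AlignmentOptions(max_iterations=5))
        hist = res.objective_history
        assert len(hist) >= 2
        assert np.all(np.diff(hist) <= 1e-9 * np.maximum(hist[:-1], 1.0))

    def test_template_invariant_to_input_order(self, rng):
        n = 121
        signals = [
            TimeSeries(two_peak_values(n, t1=0.3 + 0.04 * rng.standard_normal(),
                                       t2=0.68 + 0.04 * rng.standard_normal()))
            for _ in range(8)
        ]
        t1 = align_ensemble(signals).template.values
        perm = [signals[i] for i in rng.permutation(8)]
        t2 = align_ensemble(perm).template.values
        assert np.max(np.abs(t1 - t2)) < 1e-6

    def test_too_few_signals(self, two_peak):
        with pytest.raises(InvalidArgumentError):
            align_ensemble([two_peak])


class TestAlignToReference:
    def test_reference_gets_identity_warp(self, rng):
        n = 151
        base = TimeSeries(two_peak_values(n))
        signals = [base, apply_warp(base, smooth_warp(rng, n))]
        res = align_to_reference(signals, 0)
        assert np.max(np.abs(res.warps[0].gamma - np.linspace(0, 1, n))) < 1e-12
        assert np.max(np.abs(res.template.values - base.values)) < 1e-12

    def test_direction_symmetry_of_minimized_distance(self, rng):
        n = 201
        a = TimeSeries(two_peak_values(n))
        b = apply_warp(TimeSeries(two_peak_values(n, a1=1.15, a2=1.4)),
                       smooth_warp(rng, n, strength=0.3))
        d_ab = align_to_reference([a, b], 0).amplitude_distances[1]
        d_ba = align_to_reference([a, b], 1).amplitude_distances[0]
        assert d_ab == pytest.approx(d_ba, rel=0.05)

    def test_two_directions_nearly_invert(self, rng):
        n = 201
        a = TimeSeries(two_peak_values(n))
        b = apply_warp(a, smooth_warp(rng, n, strength=0.3))
        g_ab = align_to_reference([a, b], 0).warps[1]   # warps b onto a
        g_ba = align_to_reference([a, b], 1).warps[0]   # warps a onto b
        comp = compose_warps(g_ab, g_ba)
        assert np.max(np.abs(comp.gamma - np.linspace(0, 1, n))) < 0.05

    def test_bad_index(self, two_peak):
        with pytest.raises(InvalidArgumentError):
            align_to_reference([two_peak, two_peak], 5)


class TestElasticDistance:
    def test_zero_for_identical(self, two_peak):
        amp, phase = elastic_distance(two_peak, two_peak)
        assert amp < 1e-6 and phase < 1e-6

    def test_pure_retiming_moves_into_phase(self, rng):
        n = 301
        x1 = TimeSeries(two_peak_values(n))
        x2 = apply_warp(x1, smooth_warp(rng, n, strength=0.5))
        unwarped = l2_srsf_distance(to_srrf(x1), to_srrf(x2))
        amp, phase = elastic_distance(x1, x2)
        assert amp < 0.05 * unwarped
        assert phase > 0.01

    def test_pure_amplitude_scaling_stays_spatial(self):
        n = 301
        x1 = TimeSeries(_gaussian(n, 0.5))
        x2 = TimeSeries(2 * x1.values)
        amp, phase = elastic_distance(x1, x2)
        assert phase < 0.05
        assert amp > 0.1


class TestElasticAlignerEstimator:
    def test_sklearn_params_roundtrip(self):
        est = ElasticAligner(lambda_smooth=0.5, max_iterations=2)
        params = est.get_params()
        assert params["lambda_smooth"] == 0.5
        est2 = clone(est).set_params(grid_stride=3)
        assert est2.get_params()["grid_stride"] == 3

    def test_fit_attributes_and_transform(self, rng):
        n = 151
        base = two_peak_values(n)
        X = np.vstack([
            np.interp(smooth_warp(rng, n).gamma, np.linspace(0, 1, n), base)
            for _ in range(8)
        ])
        est = ElasticAligner().fit(X)
        assert est.aligned_.shape == X.shape
        assert est.warps_.shape == X.shape
        assert est.amplitude_distances_.shape == (8,)
        # transforming the training signals re-registers them onto the template
        Xt = est.transform(X[:3])
        sd_aligned = Xt.std(axis=0, ddof=1).mean()
        sd_raw = X[:3].std(axis=0, ddof=1).mean()
        assert sd_aligned < 0.2 * sd_raw

    def test_fit_transform_returns_centered_alignment(self, rng):
        n = 101
        base = two_peak_values(n)
        X = np.vstack([
            np.interp(smooth_warp(rng, n).gamma, np.linspace(0, 1, n), base)
            for _ in range(5)
        ])
        est = ElasticAligner()
        out = est.fit_transform(X)
        assert np.array_equal(out, est.aligned_)

    def test_resampling_via_n_samples(self, rng):
        X = np.vstack([two_peak_values(80), two_peak_values(80, a1=1.2)])
        est = ElasticAligner(n_samples=120).fit(X)
        assert est.aligned_.shape == (2, 120)
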