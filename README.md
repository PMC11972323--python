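# efda — elastic alignment of 1-D time-series ensembles

`efda` is a Python toolkit for analysing ensembles of repeated 1-D
measurements — hand-speed profiles, force traces, gait cycles, any signal
recorded over many trials of the same process — whose trials differ both in
**amplitude** and in **timing** (when features happen, and how fast each
trial's internal clock runs).  Naive ways of making trials comparable, NaN
padding or uniform time-normalization, leave features misaligned, so
cross-sectional means flatten every peak and inflate every SD band.  `efda`
implements elastic functional data analysis: each trial is re-timed by a
warping function so that shapes line up, and the observed variability is
decomposed into a spatial (amplitude) part and a temporal (timing) part.

## The method

Signals live on normalized time t ∈ [0, 1].  A trial x(t) is represented by
its square-root rate function (SRSF)

    q(t) = ẋ(t) / √|ẋ(t)| ,

under which the Fisher–Rao distance between trials is the plain L2 distance
of SRSFs, d_FR(x₁, x₂) = ‖q₂ − q₁‖₂, and re-timing by a warp γ acts as the
isometry q ↦ (q∘γ)·√γ̇.  Pairwise alignment minimizes

    ∫ (q_ref − (q_mov∘γ)·√γ̇)² dt + λ ∫ (√γ̇ − 1)² dt

over monotone lattice paths by dynamic programming (λ = 0.01 by default).
Ensembles are aligned to an emerging Karcher-type template — the mean shape
with the smallest summed d_FR, with warps centered so their mean is the
identity — and three statistics summarize what remains:

* **Var_Spat** — time-averaged pointwise SD of the aligned signals
  (signal units);
* **Var_Temp** — time-averaged pointwise SD of the warps (normalized time);
* **Var_Temp2Spat** — spatial footprint of the timing noise: the aligned
  mean warped by each trial's γ, then treated as an ensemble.

The package also ships the two conventional baselines (NaN-padding,
time-normalization) with NaN-aware statistics, a ground-truth synthetic
benchmark (noisy triple-Gaussian signals with a small "flick" landmark),
FWHM peak-feature extraction, a scikit-learn style `ElasticAligner`
transformer, and an `efda` command line.  See `docs/methods.md` for the
numerical details and design choices.

## Worked example

```python
import numpy as np
from efda import (GaussianParams, generate_ensemble, align_ensemble,
                  variability_report, extract_features)

params = GaussianParams()                      # benchmark defaults
signals = generate_ensemble(params, n_signals=100, seed=42)
print(f"{len(signals)} trials, lengths {min(s.n_samples for s in signals)}"
      f"-{max(s.n_samples for s in signals)} samples")

result = align_ensemble(signals, n_samples=200)
feats = extract_features(result.template)
mean_dur = np.mean([s.duration_s for s in signals])
print(f"template peaks: A1={feats.A1_hat:.3f}, A2={feats.A2_hat:.3f}, "
      f"dT={(feats.T2_hat - feats.T1_hat) * mean_dur:.3f} s")

rep = variability_report(result)
print(f"Var_Spat={rep.var_spat:.3f}  Var_Temp={rep.var_temp:.4f}  "
      f"Var_Temp2Spat={rep.var_temp2spat:.3f}")
```

Output:

```
100 trials, lengths 263-497 samples
template peaks: A1=2.991, A2=3.991, dT=0.403 s
Var_Spat=0.196  Var_Temp=0.0604  Var_Temp2Spat=0.740
```

The generator drew trials around true peak amplitudes 3 and 4 with a 0.4 s
peak separation; despite per-trial noise on every parameter and trial
lengths varying by almost a factor of two, the aligned template recovers
A1, A2 and ΔT to within ~0.01.  The decomposition says most of the raw
spread was timing: re-expressed in signal units, timing noise contributes
0.740 while the residual amplitude variability is only 0.196.

The same pipeline from a shell:

```bash
efda simulate --n 100 --seed 42 --out-dir run/
efda align --input run/ensemble.csv --n-samples 200 --out-dir run/aligned/
efda variability --aligned run/aligned/aligned.csv \
     --warps run/aligned/warps.csv --template run/aligned/template.csv \
     --out run/variability.json
efda compare --n 500 --seed 1 --out-dir run/compare/   # three-way benchmark
```

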