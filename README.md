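# flimstorm

Quantitative analysis of amyloid-β (Aβ) aggregation in live cells from
fluorescence-lifetime imaging (FLIM/TCSPC), single-molecule localization
microscopy (dSTORM), and aggregation-kinetics traces — together with a
seeded photon-level simulator that generates every input the analysis
consumes, so the whole pipeline can be exercised and validated end to end
without microscope data.

## The problem

When a dye-labelled Aβ peptide incorporates into β-sheet amyloid, the
fluorescence lifetime τ of the label drops (here from ≈3.7 ns for the
labelled monomer toward ≈3.3 ns for fibrillar material). Imaging τ per
pixel therefore reports *where* and *when* aggregation happens inside a
cell, and superresolution imaging of the same aggregates reports how large
they grow. This package implements the three analysis legs:

1. **FLIM / TCSPC** (`flimstorm.flim`) — per-pixel photon-arrival
   histograms are fitted with a monoexponential decay convolved with the
   instrument response and folded over the laser period,

   F(t) = A · (IRF ⊛ e^(−t/τ)) + B,

   by Poisson maximum likelihood (default) or Neyman-weighted least
   squares. Pixels are adaptively binned with a sliding window until the
   median pixel reaches ≈3500–5000 photons. Region summaries use two-level
   averaging (per-image mean, then mean ± SEM across images).
2. **dSTORM** (`flimstorm.storm`) — per-frame local-maximum detection, a
   Gaussian PSF fit per candidate, localization precision via the Thompson
   closed form σ_loc² = s²/N + a²/(12N) + 8π s⁴ b²/(a² N²), density-
   histogram rendering, and a resolution estimate (precision FWHM vs
   Nyquist sampling, whichever is worse).
3. **Morphometry** (`flimstorm.morphometry`) — aggregates are segmented as
   connected components of the rendered density image and sized by pixel
   counting along their longest dimension (Feret diameter + one-bin
   end-cap); objects smaller than the resolution limit are discarded.
4. **Kinetics & statistics** (`flimstorm.kinetics`) — sigmoidal fits
   L(t) = L∞ + (L0−L∞)/(1+e^{k(t−t50)}) with the amyloid lag time from the
   tangent construction (lag = t50 − 2/k, clamped at 0), plus paired
   Student t tests and protected Fisher's-LSD multiple comparisons.

Model fits follow the statsmodels convention: `MonoExpDecayModel(...).fit()`
and `SigmoidModel(...).fit()` return results objects with estimates,
diagnostics and a `summary()`.

## Worked example

```python
import numpy as np
import flimstorm as fs

irf = fs.simulate_irf(fwhm=0.2)                 # 256 ch over 25 ns
truth = fs.DecayTruth(tau=3.7, amplitude_fraction=0.9, n_photons=5000)
curve = fs.simulate_decay(truth, irf, seed=1)
print(fs.fit_decay(curve, irf).summary())
```

```
Monoexponential TCSPC decay fit
---------------------------------------
method           mle
converged        True
photons used     5000
tau              3.5580 ns
amplitude        4450.0 photons
background       2.149 photons/channel
chi2_reduced     1.011
```

The fitted lifetime (3.558 ns) recovers the 3.7 ns ground truth to within
twice the ≈0.08 ns shot-noise standard error at this photon count (the
fitter is unbiased: averaged over many seeds the mean estimate is 3.70 ns,
which `scripts/acceptance.py` recomputes); the fitted background matches
the 10% uniform-background fraction spread over 256 channels. A kinetics
example:

```python
times = np.linspace(0, 8, 17)
trace = fs.simulate_lifetime_timecourse(
    dict(L0=3.7, Linf=3.3, k=1.6, t50=3.75), times, noise_sd=0.03, seed=0)
fit = fs.fit_sigmoid(trace)
print(f"t50 = {fit.t50:.2f} hr, lag = {fit.lag:.2f} hr")
# t50 = 3.84 hr, lag = 2.87 hr   (truth: t50 3.75 hr, lag 2.5 hr)
```

A full simulate → fit → localize → size → kinetics run is available from
the command line:

```bash
flimstorm run --config examples/demo.yaml --out-dir out/
```

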