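# Methods

This note documents the models implemented in `flimstorm`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## TCSPC decay model and fitting

A pulsed laser at 40 MHz repetition rate gives a 25 ns observation window;
arrival times of detected photons relative to the pulse are histogrammed
into 256 channels (both configurable — the hardware class this emulates
does not fix the channel count). The per-pixel histogram is modelled as

F(t) = A · (IRF ⊛ e^(−t/τ)) + B

with a flat background B. The documentation of commercial TCSPC fitters is typically
silent on whether B floats; we float it by default because uniform dark
and after-pulse counts exist in all TCSPC data and omitting B biases τ
upward. The convolution is circular: photons emitted after the end of the
window appear in the next period, so the single-period arrival density of
an exponential is exactly a truncated exponential, and the IRF convolution
folds over the window.

**Channel discretization.** The discretized IRF locates each excitation
photon only to within one channel. The exact per-channel kernel is
therefore the truncated exponential convolved with a one-channel uniform
offset (closed form in `flim._decay_kernel`). Using the naive
edge-difference kernel instead biases τ̂ by ≈ +0.05 ns at a 0.098 ns
channel width — comparable to the entire monomer/fibril contrast budget —
which is why the exact kernel matters.

**Estimators.** The default fit is a Poisson (multinomial) maximum-
likelihood fit; at 3500–5000 photons spread over 256 channels most
channels hold tens of counts and Gaussian weighting is noticeably biased.
A Neyman-weighted least-squares fit (`method="lsq"`) is retained for
parity with commercial TCSPC software. Both estimators reduce to a 1-D
profile over τ: at fixed τ the signal fraction is a concave 1-D problem
(MLE, solved by bounded golden-section/Brent search) or a 2×2 weighted
linear solve (LSQ). The outer search brackets τ on a 60-point log grid
over [0.1, 10] ns (ties break toward the smallest τ) and refines by
bounded Brent to 10⁻⁷ ns; the log-likelihood converges far below the 10⁻⁸
tolerance that matters. Optimizer failure is reported as
`converged=False`, never an exception, so whole-image maps always
complete. Reduced χ² uses n−3 degrees of freedom (A, B, τ), Pearson
weighting for MLE and Neyman for LSQ.

**Adaptive binning.** Per-pixel counts are raised by summing each pixel's
(2b+1)×(2b+1) neighbourhood (sliding window, edge-truncated) — the
resolution-preserving convention of the standard TCSPC software, which
leaves image dimensions unchanged. The factor b is global per image: the
smallest b for which the median masked pixel reaches the 3500-photon
target (b ≤ 3 by default). Typical confocal budgets of a few hundred
photons/pixel land at b = 1–2; a uniform 150-photon image needs b = 2.

**Summaries.** Region means use two-level averaging — mean over converged
pixels per image, then mean ± SEM across images with equal image weights —
so a large image cannot dominate a time-point summary. Per-pixel lifetime
histograms are normalized to unit maximum for display.

## Blinking-movie simulation and localization

The generator draws, per frame, an independent Bernoulli on/off state per
fluorophore (memoryless blinking — no explicit dark-state kinetics, no
photobleaching), a Poisson photon count for each on-fluorophore, Gaussian
photon positions around the true emitter (PSF σ, default 150 nm), binned
into camera pixels (default 100 nm; neither value is fixed by the
emulated instrument, both are configuration), plus Poisson background and
optional Gaussian read noise. The EMCCD gain register is approximated by
that Gaussian read-noise term rather than a full gamma cascade model;
at the hundreds-to-thousands of photons per localization simulated here
the approximation is immaterial.

Reconstruction is segmentation-and-sparse-Gaussian-fitting:

* **Detection** — 8-neighbourhood maxima above median + k·1.4826·MAD
  (k = 6 by default; the robust MAD scale keeps bright molecules from
  inflating the threshold). Integer counts tie at peaks, so ties both
  qualify and duplicate suppression (5 px radius, brighter wins) resolves
  them.
* **Fitting** — symmetric 2-D Gaussian with floating background over a
  9×9 window (±3σ of the default PSF; a 7×7 window lets the background
  degenerate with the amplitude and measurably inflates the position
  error). Residuals are formed on Anscombe-transformed counts
  (2√(x+3/8)), which variance-stabilizes Poisson noise so ordinary least
  squares approximates the maximum-likelihood estimator. Integrated
  photons N = 2π·I0·s². Quality control rejects (typed outcomes, not
  exceptions): border candidates, non-convergence, fitted σ outside
  [0.5, 2]·σ_expected, N < 100 photons, and fits whose center drifted
  more than 2 px from their candidate (a noise pixel near a bright
  molecule otherwise fits the molecule's flank and produces ~100 nm
  outliers). Fitted positions within 5 px in the same frame are merged,
  keeping the brighter.
* **Precision** — the Thompson closed form
  σ_loc² = s²/N + a²/(12N) + 8π s⁴ b²/(a²N²), with b estimated per
  localization as √(fitted background) (shot-noise limit). Note the exact
  Cramér–Rao bound for this imaging model is already 9–13% above the
  closed form at N = 200–2000, so Monte-Carlo agreement within ±20% is
  the realistic expectation, and the implementation achieves 1.03–1.19×.
* **Resolution** — estimated as the worse of the precision-limited FWHM
  (2.355 × mean precision) and the Nyquist sampling term
  2/√(localization density over the occupied support). Blind
  density-estimation approaches exist but involve estimator choices that
  cannot be pinned down reproducibly, so this simpler surrogate is the
  documented default; the estimator is pluggable and Fourier ring
  correlation is the natural future alternative.
* No drift correction and no frame linking: the emulated experiments are
  fixed-cell and the simulator has no drift; consecutive-frame
  localizations of one fluorophore count separately.

## Morphometry

Aggregates are 8-connected components of superresolution pixels holding at
least `min_count` localizations (default 2, suppressing single-blink
noise). Size is measured by pixel counting along the longest dimension:
the maximum pairwise distance between occupied pixel centers plus one bin
(end-cap), i.e. the Feret diameter realized on the grid — exact for
collinear runs (n pixels → n·bin). Shape is summarized by the aspect
ratio of the extents along the principal axes of the pixel scatter.
Records below the resolution limit are excluded (strictly greater-than
semantics at the 55 nm lower bound of the resolution band).

Bin size matters: at 20 nm bins the half-diagonal pixel spill plus the
end-cap inflates a dense 160 nm disc by ~20–30 nm; 10 nm bins (the scale
of the localization precision) keep the bias within a few nm, and the
end-to-end tests render at 10 nm. Summaries pool all passing aggregates
per condition; finer grouping (per image or per cell) can be applied by
the caller before summarizing.

**Rod geometry.** Rod-like aggregates are sampled uniformly in a
rectangle of width size/3 whose *diagonal* equals `size`, so that the
longest dimension of both shape classes equals the nominal size (a
rectangle with length `size` would have a Feret diameter 5.4% larger than
its nominal length). Orientation is uniform random.

## Kinetics and statistics

Aggregation traces are fitted with the four-parameter logistic
L(t) = L∞ + (L0−L∞)/(1+e^{k(t−t50)}) by multi-start Levenberg–Marquardt
(a data-driven start plus 7 deterministic perturbations; the perturbation
RNG is fixed so fits are reproducible). The lag phase is defined by the
tangent construction lag = t50 − 2/k — the intercept of the maximal-slope
tangent with the baseline, the standard amyloid-kinetics convention —
clamped at 0 for lag-free kinetics. The definition is exposed so
alternatives (e.g. time to 5% signal change) can be swapped in.
Half-time offsets between paired readouts are differences of
independently fitted t50 values; rising traces fit in the same form with
L0 < L∞.

Group comparisons: two-sided paired Student t (t = d̄/(s_d/√n), df = n−1)
and Fisher's LSD after one-way ANOVA for multiple comparisons. The LSD is
*protected*: pairwise results are flagged significant only when the
omnibus F is significant at α — the conservative convention, which keeps
the per-comparison type-I error at or below α under the global null.
Significance stars follow the conventional thresholds 0.05 / 0.01 /
0.001 / 0.0001. Under the null the paired t and the omnibus F reject at
4.8–5.3% (10⁴ replicates, n = 8, the representative sample size for the
6–9-image groups the tests are used on); the protected per-comparison
rate is ≈2.8%.

## What the synthetic data does and does not show

The generators reproduce the *statistics* the analysis assumes — Poisson
photon counting, IRF convolution and periodic fold-in, Bernoulli
blinking, Gaussian PSF, Poisson+Gaussian camera noise, Gaussian trace
noise — with photon budgets matched to the emulated experiments
(3500–5000 photons/pixel after binning; ~2000 photons/localization for
bright morphometry data; ~400 photons over ~40 background
photons/px/frame for the resolution-limited regime; 0.03 ns trace noise
over 13–17 time points). They do not emulate: re-excitation pile-up
(count rates are assumed < 1% of the repetition rate), dark-state
blinking kinetics or photobleaching, EMCCD excess noise, stage drift,
cellular autofluorescence structure, or optical aberrations. Passing
tests therefore validate the estimators and the pipeline plumbing under
the stated noise models, not robustness to instrument artifacts absent
from those models.

Problem sizes in the test suite and acceptance script (50–200 decays per
lifetime condition, 400-frame precision movies, 4–10 aggregates per shape
class, 20-seed kinetics ensembles, 10⁴ statistical replicates) were
chosen to make Monte-Carlo standard errors small relative to each
tolerance being checked.

## Known limitations

* Single-exponential decays only; no multi-exponential or phasor
  analysis, no FRET.
* 2-D localization only; no astigmatic 3-D, no multi-emitter fitting —
  overlapping on-events yield midpoint fits that quality control only
  partially rejects, so the simulator keeps per-aggregate on-densities
  below ~1 active fluorophore per PSF per frame.
* The Feret + end-cap sizing overestimates compact objects at coarse
  bins (see above); no skeletonization for high-aspect fibrils.
* Mechanistic rate-law fitting (primary/secondary nucleation) is out of
  scope; the sigmoid is purely phenomenological.
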