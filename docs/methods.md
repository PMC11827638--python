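# Methods

This note records the models, the default parameter choices and their
rationale, the numerical decisions, and the known limits of what the test
suite demonstrates.

## Generative model (synthetic data)

A particle cross-section is an ellipse (semi-axes a ≥ b, tilt θ) whose
analyte-accessible region is the annulus of normalized elliptical radius
ρ ∈ [1−f, 1]; f = 1 is a fully accessible cross-section, f ≈ 0.37
reproduces a superficially porous particle with a 0.5-µm shell on a
1.35-µm radius. Adsorption sites are a spatial Poisson process on the
annulus: the count is Poisson(site density × accessible area) and
positions are area-uniform (ρ² uniform on [(1−f)², 1]).

Surface heterogeneity is an *n*-site mixture: each site draws a class
(weight wᵢ, desorption rate k_dᵢ, arrival rate k_aᵢ) i.i.d. Arrivals at a
site form a homogeneous Poisson process; dwells are Exponential(1/k_d).
Arrivals are non-blocking — at ~1 nM analyte the per-site occupancy is
≪ 1, and non-blocking arrivals are exactly the Poisson-sojourn picture the
stochastic elution theory assumes. An optional photobleaching clock
(exponential, default off) can truncate dwells.

Rendering: every event active in a frame deposits a pixel-integrated
(erf-based) symmetric Gaussian with expected photons = photons/frame ×
fractional temporal overlap × axial sheet weight; pixels then draw
Poisson(signal + background) plus Gaussian read noise and are stored as
16-bit integers. The light sheet is Gaussian in z (FWHM 2.3 µm — only the
thickness is known, so the shape is a modeling choice); each acquisition
is a single 2D optical slice, and 3D maps are stacks of independently
simulated slices. Freely diffusing analyte is not rendered: at 32-ms
exposure it contributes a nearly uniform haze, absorbed by the background
parameter.

### Default study conditions (and why)

| parameter | default | rationale |
|---|---|---|
| frame interval | 32 ms | camera rate of the HILO single-molecule setup being emulated |
| pixel size / PSF σ | 100 nm / 130 nm | typical for a 1.4-NA HILO configuration; magnification is not otherwise constrained |
| photons/frame, background, read noise | 800, 10 photons/px, 1.6 e⁻ | bright single fluorophore at 32 ms; gives ~10–15 nm typical precision |
| sheet FWHM | 2.3 µm | measured sheet thickness |
| site density | 300 /µm² | sub-diffraction site spacing (~60 nm), as expected on high-surface-area silica; also what makes the binarize+close map reconstruction contiguous |
| kinetic mixture | (0.5, 25 s⁻¹), (0.35, 8 s⁻¹), (0.15, 2 s⁻¹), k_a ≈ 0.0055 s⁻¹/site | dwell CDF dominated by few-frame sojourns with a long-dwell minority that carries the tailing; arrival rates keep ~4–5 active molecules per frame — the sparsity localization microscopy requires |
| acquisitions per particle | 4 × 2000 frames, pooled | matches the pooled-movie protocol of real experiments (tens of thousands of localizations per particle) and gives the area-ratio estimator a dense enough map |

These are the conditions under which the recovery suites run; they were
fixed once from the considerations above (plus a truth-level, render-free
design calculation of map coverage) and are not tuned per test.

## Localization

Detection: difference-of-Gaussians bandpass (low σ 1 px, high σ 2× the
PSF), local maxima above median + 4×1.4826×MAD of the filtered frame,
minimum separation 4 px. A 4σ threshold over ~4000 pixels admits a few
noise maxima per movie; they are eliminated by the fit gates (photon count
≥ 100, fitted σ within [0.5, 2]× the PSF, center shift ≤ 2 px), so the
accepted-localization false-positive rate is what the suite bounds.

Fitting: least-squares pixel-integrated 2D Gaussian + constant offset on a
7×7 ROI, unbounded Levenberg–Marquardt from a robust initial guess (the
acceptance windows reject implausible optima; |σ| keeps the model defined).
Least squares rather than MLE: simpler, and adequate at these photon
counts. Precision follows the Thompson-style formula
var = (σ² + p²/12)/N + 8πσ⁴b²/(p²N²). No drift correction (single
particles, short acquisitions) and no fitted z — axial structure comes
from slice stacking.

Super-resolution maps are plain 2D count histograms at 30-nm map pixels.

## Accessibility

Outline: binarize the map (count ≥ 1), close with a 3-map-pixel disc,
keep the largest connected component, fill holes, and take the ellipse
from second-order image moments (principal variances a²/4, b²/4 for a
filled ellipse). Hole filling is applied only for the outline, so a
hollow (shell) particle still yields its outer boundary; the closing
radius (90 nm) bridges the ~60-nm inter-site gaps of the default
conditions without filling a genuine core: a 3-px disc cannot close the
≥ 25-px-radius hollow of an f ≤ 0.4 particle at these geometries.

Depths use the elliptical coordinate, so %r is exact for eccentric
outlines; r is reported as (a+b)/2. d99 is the 99th percentile of depth
with linear interpolation — the reading of "the depth 99% of analytes do
not exceed" that reproduces the ~37 %r geometric limit of the core-shell
particle, which supports this convention over percentile-of-the-
complement readings. Localizations with ρ > 1.05 (noise outside the
contour) are excluded and counted.

A_p counts covered map pixels (after the same closing, without hole
filling) whose centers fall inside the ellipse. Systematics: the one-pixel
bands at the outer edge and at the shell's inner boundary cannot be
credited exactly, which biases A_p/A_i low by ~0.03–0.05 for a 1.35-µm
particle at 30-nm pixels; d99 is far less sensitive because it is a
quantile of the localization positions, not of the rasterized area.

Aggregation across particles reports mean ± sample SD (ddof = 1) of d99,
A_p/A_i and of the per-bin depth CDF on a shared 0.5-%r grid.

## Kinetics

Linking: greedy nearest-neighbor association frame to frame within 100 nm,
tolerating one missed frame (blink); events touching the first/last frame
of an acquisition are flagged censored and excluded from dwell statistics
(counts are kept for k_a). Pooled acquisitions are linked independently.
The dwell of an event is its frame span × Δt (a single detection is one
frame, 32 ms) — the same convention the simulator's discretized oracle
uses, so CDF comparisons are exact.

Two desorption-rate estimators are provided, because frame quantization
and detection both bias the span:

* **k_d = 1/(mean dwell)** — the field's headline convention, used for
  per-site rates. For ideal detection the span overestimates the true
  dwell by exactly one frame (E[span] = τ/Δt + 1 for uniform start phase),
  but at realistic SNR the dim partial end frames are often missed
  (~20% each) and occasional overlap-induced fragmentation shortens
  events, which largely cancels that bias: on rendered movies this
  estimator lands within ~5% of truth for mean dwells ≳ 6 frames.
* **`desorption_rate`** — subtracts the one-frame bias
  (k_d = 1/(mean − Δt)), exact for ideal sampling; it is validated on
  noise-free per-frame detections down to 3-frame mean dwells. On real
  movies it overcorrects by roughly the end-frame miss fraction.

The frame-quantized dwell CDF of an exponential mixture has the closed
form P(span ≤ n) = Σᵢ wᵢ[1 − e^{−kᵢnΔt}(e^{kᵢΔt} − 1)/(kᵢΔt)]
(averaging the continuous CDF over the uniform start phase), which is the
oracle for the linked-event dwell distribution.

Sites are single-linkage clusters of event positions at 60 nm (connected
components of the radius graph — at sub-resolution site spacing a
"site" is necessarily a diffraction-scale group). ΔG uses the declared
pseudo-first-order convention K_eq = k_a/(k_d·C/C°), C° = 1 M; the
absolute ΔG offset depends on that reference-state choice (which is why
only the several-kJ/mol *span* across sites is asserted), while site-to-
site differences do not.

## Elution model

The empirical characteristic function is used directly — no
exponential-mixture fit — so the full measured heterogeneity enters the
peak. Numerical choices:

* FFT grid: power-of-two length; step = min(dwell)/4 bounded below by a
  quarter frame; span covers t_M + n̄·mean + 12 peak SDs. Frame-quantized
  dwell sets make the CF periodic (it never decays), so the step is then
  the lattice spacing itself, which samples the discrete retention
  distribution exactly; if the dwell parities defeat even that, the
  divisor falls back from 4 to 5 to 6.
* Aliasing guard: |Φ| at the frequency-grid edge must be < 10⁻⁶, except
  at n̄ = 0 where Φ is a pure phase (delta peak at t_M) and the guard is
  meaningless.
* The inverse transform's real part is clipped at zero only if the
  negative excursion is < 10⁻³ of the peak maximum (otherwise the grid is
  declared inadequate), then renormalized to unit area.
* On an FFT-ordered frequency grid the CF is evaluated by a running-power
  recursion with conjugate-symmetric mirroring (error ~N·ε ≈ 10⁻¹²),
  which is ~30× faster than direct complex exponentials.

Defaults n̄ = 100 and t_M = 0 present a "scaled elution" axis; n̄ and t_M
are user parameters since the mapping to a specific column is not part of
the model. Mobile-phase dispersion (Eddy, longitudinal diffusion, packing
effects) is deliberately excluded: the model isolates the
adsorption-kinetics contribution to retention and tailing, so predicted
positions/widths are comparisons of trends, not absolute chromatograms.

Peak moments are trapezoidal (area, centroid, central variance,
standardized skew), with optional linear baseline subtraction anchored on
the first/last 5% of points for measured chromatograms.

## What the tests show — and what they do not

The simulator realizes exactly the assumptions the analysis makes
(static sites, first-order kinetics, Gaussian PSF, Poisson camera,
uniform site placement). Passing recovery tests therefore demonstrates
the pipeline's internal consistency and its statistical calibration at
realistic SNR, sparsity and sample sizes — not robustness to effects the
generator omits: stage drift, dye blinking/bleaching kinetics (beyond the
optional single-rate bleach clock), diffusing-analyte streaks, refractive
aberrations inside particles, flow-dependent arrival anisotropy, or
correlated site kinetics. The accessible-area estimator carries a known
rasterization bias (above); d99 recovery is accurate to ~1–2 %r under the
study conditions.

## Problem sizes

The validation suites use per-particle data pooled from four (accessibility
recovery) or two (kinetics recovery) 2000-frame acquisitions of 64×64
pixels, ~5·10³–4·10⁴ localizations per particle; closed-form oracles are
checked at n = 10⁵ samples; the elution model is cross-checked against
10⁵ Monte-Carlo draws. These sizes put Monte-Carlo error well inside the
stated tolerances while keeping a full run in minutes on one CPU.
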