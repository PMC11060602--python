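# Methods

This note documents the models, numerical choices, and limitations behind
`sarcoscan`: the forward simulator, the measurement pipeline, the
statistics, and what the desk-scale validation does and does not show.

## Forward model

**Geometry.** A sarcomere lattice is a 1D sequence of Z-disc centers along
the stripe-normal axis, `c_i = origin + Σ_{j≤i} L_j`, with spacings `L_j ~
Normal(L, σ_L)` truncated below at `max(400 nm, 4·w_Z)` by rejection
sampling (`n_sarcomeres` counts centers). Each labeled structure is a
top-hat density band: the Z-disc of width `w_Z` at every center, and each
epitope at `c_i ± offset` (both sides by default). Defaults — L = 2400 nm
(midpoint of the resting 2.3–2.47 µm range in mouse), σ_L = 60 nm, w_Z =
60 nm (inside the 30–140 nm range reported across muscles and species),
N2A offset 285 nm and PEVK offset 115 nm with 30 nm intrinsic band width —
place the N2A pair 570 nm apart across the Z-disc and N2A–PEVK 170 nm
apart on the same side, the geometry the pipeline is expected to recover.

**Rendering.** Bands are constant along the stripe direction and rotated by
`orientation_deg`. Pixel values are exact area fractions: the projection of
a square pixel onto the band normal is the sum of two uniform variables, so
coverage is a closed-form trapezoid-CDF difference. This anti-aliases
sub-pixel band edges and conserves first moments. Positions are in nm;
pixel `i` spans `[i·p, (i+1)·p)` with center `(i+0.5)·p`. Zero-width bands
render as unit line mass spread over the pixels their center crosses.

**Optics.** PSF and antibody linkage error are combined into one isotropic
Gaussian blur of SD `σ_tot = sqrt((FWHM/2.3548)² + ε²)` (FWHM/SD factor
`2·sqrt(2 ln 2)`). Linkage error is modeled as blur rather than
per-molecule scatter: at immunolabeling densities the ensemble of displaced
fluorophores is equivalent to convolving the epitope density with the
displacement distribution, which keeps the model analytic. Convolution uses
reflective padding, conserving flux to well under 0.1%. Preset values —
confocal FWHM 280 nm, SIM FWHM 120 nm, IgG ε = 17.5 nm, nanobody ε = 2 nm —
are order-of-magnitude stand-ins (no specific instrument is modeled) and
are fully configurable; every conclusion drawn from simulation is about
orderings and recoveries, not absolute optical constants.

**Noise.** `out = Poisson(photons·img + background)/photons +
Normal(0, σ_read)`, clipped at zero; background enters before the Poisson
draw. Defaults (photons_per_unit 2000, background 20 photons, σ_read 0.002
image units, 40 nm pixels) emulate a well-exposed 300 ms sCMOS acquisition
with peak SNR ≈ 20 under confocal blur. Exposure matters: at substantially
dimmer settings single-pixel threshold dropouts fragment bands along scan
rows, an artifact of under-exposure rather than of the method. Every
stochastic step is a pure function of (parameters, seed).

## Measurement pipeline

**Background ROI.** User rectangle, or automatically the 64×64 tile with
minimal mean (summed-area table). In simulated fields the striations cross
every tile, so the automatic ROI mean includes a small stripe contribution
(~w_Z/L of the band amplitude); the threshold step adapts, so the effect on
measured geometry is negligible. An ROI whose mean reaches the image
maximum triggers a "likely contains signal" warning but still subtracts.

**Threshold.** Classical iterative intermeans on a 256-bin histogram,
iterated on the induced class partition until it is exactly stable (the
final step is then zero, well under the one-bin stopping width). A
histogram can admit more than one discrete fixed point; the iteration lands
on one of them, and the test oracle verifies membership in the exhaustively
enumerated fixed-point set rather than equality with a single scan winner.
The ImageJ "Default" thresholder is a lookup-table variant of the same
algorithm; the classical form is used because it is reproducible from the
literature without ImageJ internals. Bin count is exposed.

**Particles.** 8-connected foreground / 4-connected background (the ImageJ
convention, recorded on the mask). Components outside `[min_area, max_area]`
are discarded; `min_area = 4 px` suppresses shot-noise specks (the original
workflow states no size filter; this is configurable). Survivors are
relabeled 1..K in raster order of first pixel. Bare outline = particle
pixels with a 4-connected background neighbor, the image border counting as
background.

**Line scans.** Scan paths are placed automatically: the stripe normal is
the direction of the dominant non-DC peak of the Hann-windowed 2D power
spectrum (ties break toward lower spatial frequency; a peak must exceed
3× the expected maximum of a featureless spectrum — median ×
sqrt(ln n / ln 2) for Rayleigh magnitudes — or "no striation" is raised).
Paths are parallel, span the field, keep ≥ `min_separation_px` apart, and
are deterministic per seed. Binary masks are sampled nearest-neighbor — no
sub-threshold values are invented — and sub-pixel precision comes from the
0.25 px sample step; crossings sit at sample midpoints, so band edges are
located to ±half a sample step. Incomplete bands (truncated by scan ends)
are excluded from both width and length statistics.

**Pairings.** N2A–N2A uses flanking pairs: consecutive N2A bands that
straddle a Z-disc band center. N2A–PEVK uses nearest cross-channel pairing
within a half-sarcomere cutoff (1200 nm); an exactly ambiguous pairing
resolves toward the lower position and is flagged. The nearest-neighbor
rule is a documented stand-in — the original workflow does not specify its
pairing rule.

**FFT comparator.** Mean-detrended, Hann-windowed, 4× zero-padded magnitude
spectrum; the peak inside the 1–5 µm period band is refined by parabolic
interpolation; a peak below 3× the median spectral magnitude raises "no
dominant period". All settings are exposed; none are claimed optimal — the
comparator exists to benchmark the line-scan estimator against the common
automated alternative.

## Statistics

Aggregation is two-stage: all technical measurements in a biological
replicate pool to one replicate mean; group mean/SD/CV are computed on
replicate means (unweighted, so unequal image counts cannot bias a group).
Sample SD (n−1) throughout; CV in percent. Two-group comparisons: Welch
t-test on replicate means plus variance F-tests reported at both leaf and
replicate level (leaf level is the default reading for variability
comparisons). Multi-group: one-way ANOVA on replicate means — exactly
equivalent to a nested ANOVA for balanced designs and conservative
otherwise — with Holm-adjusted pairwise Welch tests. Holm replaces the
post-ANOVA Dunn's procedure sometimes used with this design: Dunn's test is
a rank-based post-hoc for Kruskal–Wallis, and pairing it with a parametric
ANOVA is non-standard.

## Validation experiments and problem sizes

All validation runs use 768×128 px fields at 40 nm/px (~12 sarcomeres per
scan), chosen so every experiment completes in seconds while leaving ≥ 10
length measurements per scan.

* **Noise-free recovery**: zero jitter, zero noise, zero blur — lengths are
  exact and band centers land within one sample step of ground truth.
* **Parameter recovery**: SIM+nanobody preset, 5 images × 5 scans — mean
  length within 1% of L; mean width within 10 nm of an independent 1D
  oracle (fine-grid blurred top-hat, exhaustive-scan threshold,
  interpolated crossings).
* **Modality ordering**: matched lattice and noise seeds across
  confocal+IgG → SIM+IgG → SIM+nanobody isolate the optics; measured width
  decreases strictly along that order and the ANOVA on replicate means is
  decisive. Note the SIM+IgG vs SIM+nanobody gap is only a few nm here
  because quadrature blur composition makes σ_tot insensitive to linkage
  error when FWHM dominates.
* **FFT vs line scan**: 25 independent images × 1 scan (scans within one
  simulated image are near-identical because bands are constant along the
  stripe, so independent images keep the variance-test degrees of freedom
  honest). Under cumulative spacing jitter the per-scan mean of line-scan
  lengths telescopes to `(c_last − c_first)/n` — the minimum-variance
  estimator for random-walk centers — while the windowed spectral peak is
  an inefficient weighted version of the same slope estimate. The FFT SD
  reliably exceeds the line-scan SD, but the variance ratio this model
  induces is ≈ 1.7, so a 25-scan F-test at α = 0.01 (critical ratio ≈ 3)
  rarely reaches significance; the variance inflation seen on real
  disrupted tissue is far larger than Gaussian spacing jitter produces.
* **Null calibration**: the two-group Welch test on replicate means rejects
  at its nominal 5% rate over 200 null simulations.

## What the simulation does not capture

Real sections add myofibril-to-myofibril disorder in 2D (simulated bands
are coherent across the full stripe), out-of-plane tilt, labeling-density
variation, autofluorescence structure, fixation artifacts, and SIM
reconstruction artifacts. Passing these tests therefore demonstrates that
the pipeline's geometry, thresholding, and statistics are correct and
unbiased under a controlled forward model — not that any particular
absolute width measured on tissue is accurate. Absolute width claims on
real data depend on the instrument's true PSF and the antibody stack, both
of which are configurable inputs here, not outputs.
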