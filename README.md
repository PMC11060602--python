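# sarcoscan

Objective quantification of sarcomere structure from immunofluorescence
microscopy of longitudinal skeletal-muscle sections — sarcomere length,
Z-disc width, and titin inter-epitope distances — together with a forward
simulator that makes every stage of the pipeline verifiable against ground
truth at desk scale.

## Who this is for

Muscle physiologists measuring striation geometry from confocal or
structured-illumination (SIM) images of labeled sections (α-actinin for the
Z-disc; titin N2A/PEVK epitopes as intra-sarcomere landmarks), and anyone
who wants a reproducible, scriptable replacement for manual line-scan
measurements in ImageJ.

## The method

Raw fluorescence profiles have broad, subjective peaks. The pipeline
replaces them with automatically assigned band borders:

1. **Background subtraction** — the mean gray value of a signal-free ROI is
   subtracted per channel (clipped at zero).
2. **IsoData binarization** — the Ridler–Calvard iterative-intermeans
   threshold `t* = (μ_below(t*) + μ_above(t*)) / 2` computed on a 256-bin
   histogram.
3. **Particle analysis** — 8-connected components, area-filtered, reduced to
   their *bare outlines* (foreground pixels with a 4-connected background
   neighbor).

Line scans placed along the stripe normal (estimated from the 2D power
spectrum) then sample the binary mask at sub-pixel steps (default 0.25 px).
Each 0→1 / 1→0 transition marks a band edge at the midpoint of the
straddling samples; an edge pair gives one band with center `c = (enter +
exit)/2` and width `w = exit − enter`. From the bands:

* sarcomere length `L_i = c_{i+1} − c_i` between neighboring Z-disc bands,
* Z-disc width = width of the α-actinin band,
* N2A–N2A distance across the Z-disc (flanking-pair pairing) and N2A–PEVK
  distance (nearest cross-channel pairing).

Measurements aggregate scan → image → biological replicate → group with
two-stage averaging (technical replicates pooled per biological replicate;
group statistics on replicate means; sample SD and CV%). Group comparisons:
Welch t-test and variance F-test for two groups, one-way ANOVA on replicate
means with Holm-adjusted pairwise tests for three or more. An FFT period
estimator (Hann window, 4× zero-padding, parabolic peak refinement) is
included as the comparator the line-scan method is benchmarked against.

The simulator renders quasi-periodic Z-disc lattices (default L = 2400 nm,
spacing jitter SD 60 nm, Z-disc width 60 nm, N2A at ±285 nm and PEVK at
±115 nm per Z-disc) as top-hat fluorophore-density bands, blurs them with a
Gaussian combining the PSF FWHM and the antibody linkage error in
quadrature, and adds Poisson shot noise plus Gaussian read noise. Presets:
`confocal_igg`, `sim_igg`, `sim_nanobody`.

## Worked example

```python
import numpy as np
import sarcoscan as sc

mci = sc.simulate(sc.DEFAULT_LATTICE, sc.PRESETS["sim_nanobody"], seed=1)
im = sc.measure_multichannel(mci, n_scans=5, seed=1)
lengths = [v for s in im.scans for v in s.sarcomere_lengths_nm]
widths = [v for s in im.scans for v in s.zdisc_widths_nm]
nn = [v for s in im.scans for v in s.epitope_distances["N2A-N2A"]]
print(f"sarcomere length: {np.mean(lengths):.1f} +/- {np.std(lengths, ddof=1):.1f} nm (n={len(lengths)})")
print(f"Z-disc width:     {np.mean(widths):.1f} +/- {np.std(widths, ddof=1):.1f} nm (n={len(widths)})")
print(f"N2A-N2A distance: {np.mean(nn):.1f} nm (n={len(nn)})")
```

prints

```
sarcomere length: 2418.3 +/- 54.5 nm (n=60)
Z-disc width:     151.4 +/- 16.6 nm (n=65)
N2A-N2A distance: 572.3 nm (n=60)
```

The measured mean length (2418 nm) recovers this realization's true mean
spacing under 60 nm jitter; the measured Z-disc width (151 nm) is the
optically broadened image of the 60 nm ground-truth disc under the
SIM+nanobody blur (σ ≈ 51 nm) — it matches an independent 1D
blurred-top-hat oracle to a few nm; and the N2A–N2A distance recovers the
570 nm built into the lattice geometry.

## Command line

```sh
sarcoscan simulate --preset sim_nanobody -n 3 --seed 7 --outdir fixtures
sarcoscan measure fixtures/*.tif --outdir measures
sarcoscan experiment fft_vs_linescan --seed 1 --outdir exp
sarcoscan experiment modality_ordering --seed 1 --outdir exp2
```

`measure` writes `bands.csv`, `scans.csv` (leaf measurements),
`summary.csv` (n/mean/SD/CV at image, replicate, and group level),
`tests.csv`, and a provenance log recording every data-dependent decision
(subtracted background, threshold, excluded incomplete bands). Pixel size
comes from a CLI flag or TIFF metadata — never guessed.

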