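# Methods

## Signal model

A phase-stepping scan samples, per pixel, one period of the
interferometer's stepping curve

```
I_k = a0 · (1 + v · cos(2π f_k + φ)),   f_k = k/N,  k = 0..N−1
```

with `N = 16` steps by default. The sample-free reference scan has
mean flux `I0` and visibility `V0`; a sample multiplies the mean by
its transmission `T` and the modulation by its relative visibility
(dark-field) `V`, and shifts the phase by the refraction-induced
differential phase. The forward model used by the simulator is, per
pixel,

* water bath: `T = 1`, `V = 1`;
* formalin inside the container: `T = exp(c)`, `V = 1`, where `c` is
  the container's log-transmission offset (default 0.02);
* lung tissue: `T = exp(u + c)`, `V = exp(−s·u)`, where `u > 0` is the
  log-transmission excess over the formalin background (a thickness ×
  density quantity) and `s > 0` is the true normalized scatter.

Both `ln T` and `ln V` are linear in `u`, so the statistic
`S = −ln(V)/(ln(T) − c)` returns `s` regardless of thickness; this
identity is what the whole analysis leans on, and it is exercised
directly by the thickness-rescaling tests (`u → λu` changes `T` and
`V` but not `S`).

The differential-phase channel is carried through retrieval (`Δφ`
wrapped to (−π, π], no unwrapping) but set to zero in the simulator
and not analyzed downstream.

## Cohort calibration

Each group's per-pixel `u` and `s` are drawn independently from
distributions pinned to configurable quartiles: transmission
(1.07, 1.11, 1.17) vs (1.04, 1.06, 1.10) relative to water, and
normalized scatter (4.1, 4.9, 5.8) vs (7.5, 10.8, 14.7), for the
emphysema and control groups respectively. The printed quartiles are
not log-symmetric, so no two-parameter log-normal matches all three
points; instead each marginal is a monotone piecewise-linear map of a
standard normal (`QuantileMap`): body slopes between the quartile
knots reproduce (q1, median, q3) *exactly*, and the slopes beyond the
knots are free tail scales.

The dark-field median is an emergent quantity,
`median(V) = exp(−median(s·u))`, and the quartiles alone do not pin
it. The lower-tail scale of the `s` marginal is therefore solved at
construction (1-D quadrature over the convolution CDF plus Brent's
method) so that the emergent dark-field median equals the configured
target — 0.66 in both groups, reproducing the observation that
emphysema leaves the raw dark-field median unchanged even though both
of its factors shift. Degenerate (zero-spread) quartile triples are
supported and yield constant fields.

Spatial texture: the latent standard-normal fields are low-pass
filtered (Gaussian, σ = 3 px, periodic boundaries) and rescaled by the
exact filter gain, which keeps the marginal law exactly N(0, 1); the
quantile transform is applied afterwards, so the correlation is
rank-preserving and the marginal calibration is untouched. The
correlation length is cosmetic (maps look tissue-like rather than like
salt-and-pepper noise) but it does reduce the effective number of
independent pixels per projection by roughly the correlated-patch
area.

Geometry: a two-lobe elliptical lung inside an elliptical formalin
container in a water bath, all scaled to the 128×128 default frame;
the lung rotates with the projection index (11 projections over 180°).
Formalin and water ROIs are margins-eroded bands inside and outside
the container, pairwise disjoint from the lung.

## Noise

Per-frame Poisson noise with a reference flux of 4000 counts per pixel
per frame and reference visibility `V0 = 0.3`. The flux was chosen so
that photon noise stays well below the group separation: the per-pixel
transmission error floor for the DFT estimator is
`sqrt(2·T/(N·I0))` ≈ 0.006 (measured RMS agrees), and the
noise-induced bias on every recovered group median — the denominator
`ln T − c` is only ≈ 0.04 in controls, so the statistic is sensitive
to transmission noise — stays below 1%. At substantially lower fluxes
the control-group S median acquires a percent-level downward bias from
the nonlinear dependence on the noisy denominator and from the
exclusion of pixels whose estimated denominator falls below the
ε-floor.

## Retrieval

Discrete Fourier components of the stepping curve: `a0` = frame mean,
`a1 = 2|Σ_k I_k e^{−2πi f_k}|/N`, `φ` = the argument of the same sum.
For uniform sampling over exactly one period this estimator is exact
on a single-harmonic curve to floating-point precision (the test suite
keeps an independent linear least-squares sinusoid fit as an oracle).
Channels: `T = a0ˢ/a0ʳ`, `V = (a1/a0)ˢ/(a1/a0)ʳ`, `Δφ` wrapped.
Pixels whose reference `a0` or `a1` falls below 1% of the frame-wide
median are flagged invalid (NaN channels); an all-dark reference
yields an all-invalid triplet with a warning rather than an exception.
`V` is not clipped at 1 — noisy background pixels may exceed it, and
segmentation handles them. After retrieval, `T` and `V` are divided by
their medians over the water ROI, anchoring both channels at 1 in
water.

## Segmentation

Lung pixels scatter strongly, so they sit at low `V`; the water and
formalin background clusters tightly near `V = 1`. The threshold is
found on the histogram of `V` over valid pixels (256 bins, 5-bin
moving-average smoothing): peaks are detected with a minimum
separation of 1/16 of the bin range (so maxima belong to distinct
modes, not adjacent noise bins), the tallest peak is taken as the
background mode, and the threshold is the minimum between it and the
nearest peak below it — the border of the background noise and the
lung signal peak. The valley must dip below 25% of the background
peak; otherwise the histogram is treated as unimodal and the threshold
falls back to Otsu's criterion with a warning (or raises, if the
fallback is disabled). A `manual` mode accepts a user-supplied
threshold. Connected components below 20 px are dropped (removing
isolated noise and trachea-like remnants). The same mask indexes all
three channels.

Thresholds are computed per projection by default; a
`global_threshold` flag pools all projections into one histogram.

On default phantoms the mask captures ~94% of true emphysematous lung
and ~89% of control lung with essentially no background (< 0.1% false
positives). The control deficit is intrinsic, not algorithmic: with
the control dark-field quartiles calibrated up to q3 = 0.85, roughly a
tenth of control lung pixels have true `V` inside the background noise
mode, and no dark-field threshold can keep them without flooding the
mask with background. A direct consequence is that the *recovered*
(post-segmentation) dark-field medians land a few percent below the
configured 0.66 — the segmentation truncates the high-`V` tail — while
`T` and `S`, whose lung distributions sit far from the background
mode, recover to ~1%. Passing tests therefore demonstrate faithful
recovery of transmission, normalized scatter and the correction
factor, and document the dark-field truncation; on real data the same
caveat applies to any statistic of a dark-field-segmented region.

## Correction factor and statistic

`c = ln(mean T over formalin ROI / mean T over water ROI)`, arithmetic
means (the mean-of-logs alternative differs at O(variance),
negligible here), averaged over a specimen's projections into one
value per specimen. `S` is computed per pixel over the segmentation
mask where `ln T − c > ε` (default ε = 1e−4); pixels below the floor
would produce unstable or negative values and are excluded and
counted (the run report carries the count).

## Group statistics

Per-pixel summaries pool all defined pixels of all projections of all
specimens in a group (specimens implicitly weighted by pixel count);
per-individual summaries first reduce each specimen to the median of
its pooled pixels. Quartiles use linear interpolation; group
comparisons use the two-sided Mann-Whitney U test. The per-pixel test
treats pixels as independent observations — anticonservative under
spatial correlation and repeated anatomy across projections — and the
run report flags this assumption explicitly.

## ROC, DeLong, cutoffs

Empirical ROC curves with one operating point per unique score and
midrank tie handling; the trapezoidal AUC equals the tie-corrected
Mann-Whitney statistic to 1e−12 (tested). Channel orientations follow
the physiology: transmission and dark-field greater-is-diseased,
normalized scatter less-is-diseased (the dark-field orientation is
configurable; at fixed thickness emphysema retains more visibility).

Paired AUCs are compared with DeLong's test via structural components
computed from midranks (O(n log n), usable at pixel scale); the
variance was validated against a stratified bootstrap. Three pairwise
comparisons (S vs T, S vs V, T vs V) are reported, two-sided, without
multiplicity correction.

"Optimal" cutoffs use the Youden index J = sens + spec − 1, ties
broken toward higher specificity, and the returned cutoff is the
midpoint between the chosen threshold and the next-lower observed
score (so separated classes yield the gap midpoint). Reference cutoff
presets (1.087 / 0.715 / 7.00 for T / V / S) are available for the
mapping stage. Sensitivity-at-specificity uses the interpolation-free
conservative convention (smallest threshold reaching the requested
specificity), with linear interpolation as an option.

Per-individual ROC with 3 vs 3 specimens lives on an AUC grid of
spacing 1/9; the report carries a granularity note, and the analysis
is skipped (with a warning) below 2 specimens per group.

## Parametric maps

Deviation toward disease = `(x − cutoff)` or `(cutoff − x)` per
orientation, divided by the control-group per-pixel IQR of the channel
(pooled over the current run by default; reference presets
0.06 / 0.37 / 7.2 available), clipped to [0, 1]; healthy-direction
deviations render as 0. Overlays blend a perceptually simple
yellow-to-red ramp over the 1st–99th-percentile-windowed grayscale
transmission image, with blend weight rising linearly from 0.35 (so
mild disease stays visible) to 1 at a full-IQR deviation. Output bytes
are deterministic for fixed inputs.

## Determinism and seeding

One seed in the configuration feeds per-(specimen, projection, stage)
`SeedSequence` substreams, so truth fields and noise draws are
independent across projections and stages, cohort generation streams
lazily without holding all stacks in memory, and identical config +
seed reproduce bit-identical cohorts, reports and file checksums (the
report manifest carries SHA-256 of every artifact). Raw scans are
written as float32 multi-frame TIFFs — lossless for Poisson counts —
with JSON sidecars; maps as float32 TIFFs; masks as uint8.

## What the simulator does not emulate

No grating pitches, Talbot distances, beam spectrum, detector PSF or
dose modelling; no ribs, fur, breathing motion or other anatomical
confounders; no registration between projections (each projection
draws fresh latent fields, so per-pixel pooling across projections
does not model repeated anatomy); `u` and `s` are independent per
pixel, whereas real parenchyma likely couples density and
microstructure. Conclusions from passing tests are therefore about
the *estimators and the analysis chain*, not about the biological
variability of real lungs; in particular the real-data AUCs and
operating points depend on joint pixel distributions the phantom does
not model, and are deliberately not reproduction targets — the tests
assert the qualitative ordering (S best, T intermediate, V at chance)
instead.

## Default problem sizes

The default cohort (6 specimens × 11 projections × 128² pixels × 16
steps) analyzes in a few seconds on one CPU and keeps the full
analysis ≈ tens of MB in memory; the acceptance script and the test
suite both run it at this size. Unit tests use 48–64 px frames and
reduced cohorts.
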