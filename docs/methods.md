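# Methods

This note documents the models behind `valveoptics`, the defaults that
matter, what the synthetic phantom does and does not emulate, and the design
choices made where the underlying analysis workflow left them open.

## TPEF autofluorescence ratios

Tissue autofluorescence intensity is recorded in four excitation/emission
channels, A_755/460, A_860/525, A_810/460 and A_810/525 (arbitrary units —
absolute intensity scales depend on laser power and PMT gain and are not
modeled). Two bounded per-pixel ratios are computed:

    755–860 ratio = A_860/525 / (A_755/460 + A_860/525)
    Col–Cal ratio = A_810/525 / (A_810/460 + A_810/525)

Both are invariant to a common gain on their channel pair. Region summaries
report the **mean of per-pixel ratios** over each region, not the ratio of
region-mean intensities; the two differ under spatial heterogeneity, and the
per-pixel convention matches ratio maps averaged over manually outlined
regions. The alternative is one line of user code
(`mean_a860_525 / (mean_a755_460 + mean_a860_525)` from the same summary
table) if a sensitivity check is wanted.

**Intensity floor.** Ratios of near-zero intensities are noise. Pixels whose
pair-sum falls below a floor are flagged invalid and excluded from region
means. Default floor: mean + 2 sd of the pair-sum intensity outside all
annotated regions (a data-driven background estimate); pass `floor=0` to
disable. No flat-field or spectral-bleed correction is applied; the
channel-set abstraction leaves room to add one upstream.

## QPLI: retardation, orientation, directional variance

Forward model per pixel over polarizer angle θ (rotating linear polarizer,
fixed circular analyzer):

    I(θ) = B · (1 + sin δ · sin 2(θ − φ)),   θ ∈ [0°, 180°)

with B the mean transmitted intensity, δ ∈ [0°, 90°] the retardation and φ
the axial orientation. The 180° range suffices because the signal is
2θ-periodic (axial symmetry). On an even K-angle grid (K ≥ 4; default K = 18)
the single-harmonic discrete Fourier component at frequency 2 recovers the
model exactly in O(K) per pixel:

    B̂ = mean_k I_k
    C  = (2/K) Σ_k I_k e^{−2iθ_k},  Â = |C|
    δ̂ = arcsin(clip(Â/B̂, 0, 1)),   φ̂ = mod(−(arg C + π/2)/2, 180°)

Uneven grids fall back to a per-pixel least-squares harmonic fit
(`allow_uneven=True`). The arcsin branch caps δ̂ at 90° (thin-section
assumption); values are clamped, not wrapped. Pixels with B̂ below an
intensity floor are invalid; pixels with negligible modulation (Â/B̂ <
1e−12) keep δ̂ = 0 but carry an undefined (NaN) orientation. The sign
convention of φ is fixed by the forward model above, which the phantom
shares; against real hardware the orientation axis may need a fixed offset
calibration.

With the default 2% Gaussian frame noise and K = 18, the retardation RMSE
over mixed δ ∈ [5°, 50°] is ≈ 0.85° (error grows as 1/cos δ toward the 90°
branch point).

**Directional variance.** Orientations are axial, so all circular statistics
double the angle: V = 1 − |⟨e^{2iφ}⟩| over the collagen-positive pixels in a
window. V = 0 for perfect alignment; orthogonal equal-weight populations
cancel to V = 1. For orientations whose doubled angle is von Mises with
concentration κ, E[V] → 1 − I₁(κ)/I₀(κ), which serves as the Monte-Carlo
oracle in tests. Defaults: window 11 px, at least 10 collagen pixels per
window (windows below that are invalid), collagen-positive threshold
δ > 5°. All three are analysis conventions rather than physical constants
and are exposed in `PipelineConfig`.

## Histology quantification

**PSR hue binning.** RGB → HSV; collagen-positive pixels need saturation
≥ 0.25 and value ≥ 0.10 (excludes unstained/background material). Hue bins
(degrees): thick/red [0, 10) ∪ [350, 360), thick-intermediate/orange
[10, 40), thin-intermediate/yellow [40, 60), thin/green [60, 140) — common
picrosirius hue-segmentation practice, fully overridable; overlapping bins
are rejected. Percentages are taken among collagen-positive pixels per
region and sum to 100 whenever any exist; empty regions report NaN rather
than 0.

**ARS percent area.** Mirrors the ImageJ constant-threshold +
Analyze-Particles workflow: 8-bit grayscale by ITU-R 601 luminance weights,
positive = gray < threshold (default 100; red deposits are dark against the
bright background — a `polarity` switch covers inverted material), 8-connected
components, particles < 4 px discarded, percent positive area and particle
areas (px and µm²) per region. The threshold and size floor are config
values validated against phantom truth, since no canonical constants exist;
percent area is monotone non-increasing in threshold strictness and particle
floor by construction.

## Echocardiography and IHC grading

LV volumes use the Teichholz cube correction V(D) = 7.0·D³/(2.4 + D) (µL, D
in mm); EF = (LVIDd³ − LVIDs³)·100/LVIDd³; CO = (EDV − ESV)·HR. Sources
occasionally typeset the volume formula as (7.0 + D³)/(2.4 + D); that
literal variant is kept behind `literal_volumes=True` for auditability, and
EF is identical under both since it uses diameters directly.

IHC panels (αSMA, vimentin, RUNX2, osteopontin, BMP4, Ki67, TGFβ1) are
scored 0/1/2 by three blinded raters. The mean is held as an exact rational
and graded "−" iff 0, "+" on (0, 2/3], "++" on (2/3, 4/3], "+++" above —
the conventional 0.66/1.33 cut points are rounded thirds, and exact
arithmetic keeps boundary triples such as (1, 1, 0) from floating-point
misgrading. Grades are monotone in every rater's score and the 27 ordered
triples cover the scale without gaps or overlaps.

## Statistics

Comparisons of diet groups over time use a two-way ANOVA on the diet × week
cells with Type-II sums of squares (cell counts are small and unbalanced, so
the decomposition must be fixed for reproducibility), gated by Shapiro–Wilk
on the within-cell residuals at α = 0.05. Parametric data get Tukey HSD
(Tukey–Kramer for unequal n) over all cell pairs; non-normal data get
Kruskal–Wallis with Dunn's pairwise rank contrasts (pooled midranks, tie
correction, Holm adjustment). Residuals with zero spread make the normality
gate untestable and the parametric error model degenerate, so such tables
route to the rank test; fully constant data raise an error rather than
yield p = 0. All p-values are reported uncensored. The empirical type-I
error of the diet factor under a shared normal null is 0.050 at 1,000
simulated tables (seeded).

Correlations: Pearson for normal pairs, Spearman (midrank ties) for ordinal
or non-normal data; `method='auto'` applies a Shapiro gate and an explicit
`ordinal` flag (score data always rank-based). A seeded permutation p-value
is available for small n. No multiplicity correction is applied across
metrics or regions beyond Tukey/Holm within a comparison. The report
computes correlation panels both pooled across regions and per region,
labelled by `scope`, since pooling changes both n and interpretation.

## The synthetic phantom

The phantom generates every pipeline input with known truth so each stage is
testable without animal data:

* **Channels.** Four source fields (NADH-, FAD-, collagen-, calcium-like),
  constant per region with calcium concentrated 6× on the calcified
  deposits, mixed through a nonnegative 4×4 matrix and scaled to ~100
  arbitrary units. Default mixing puts NADH → 755/460, FAD → 860/525,
  collagen → 810/525 and calcium → 460-nm emission at both 755 and 810 nm,
  so raising calcium depresses both ratios — the behavior the pipeline is
  meant to detect. Noise: Gaussian, sd = 2% of the maximum clean signal
  (optional Poisson shot noise), clipped at zero.
* **Polarization stack.** The exact forward model above, with per-region
  retardation proportional to the collagen weight (display range 0–50°),
  ±10% pixel jitter, and axial von Mises orientations (default κ = 4) about
  per-region mean directions.
* **Stains.** PSR: region pixels assigned to the four hue classes at
  configured fractions (largest-remainder rounding, so class counts are
  exact). ARS: compact deposits whose pixel count equals
  round(fraction × region area) exactly — deposits are the `target` region
  pixels nearest a set of seeded centers, giving blob-like geometry with no
  quantization error beyond rounding.
* **Study structure.** Diet (control / pro-calcific) × week (4/16/28), with
  a single pro-calcific modifier that is 1 at week 4, `effect_size` at week
  16 and ramps linearly on (default effect 3 at week 16, the regime used in
  the end-to-end checks). The modifier scales calcium weight and ARS
  fraction, disorganizes the orientation field (κ divided by the effect) and
  shifts the IHC latent scores. Between-animal biology: 3% lognormal jitter
  per fluorophore weight (ratio metrics cancel common gain, and a study that
  resolves these contrasts at N = 3–4 implies effect sizes well clear of
  animal-to-animal spread), a latent remodeling level coupling collagen
  thickness and alignment (producing the negative retardation–variance
  correlation across sections), and 25% lognormal spread on calcific burden.
  Echo traces and three-rater IHC scores are sampled per animal with
  effect-shifted means. Per-animal seeds derive from the master seed via
  `SeedSequence.spawn`, so studies are reproducible and order-independent.

**What the phantom does not emulate** — and therefore what passing tests do
not show about real data: optics (no PSF, no ray tracing, no wavelength-
dependent birefringence), 3-D tissue structure and sectioning artifacts,
spectral bleed-through and flat-field inhomogeneity, stain variability and
imaging white balance, and any biological coupling beyond the single
pro-calcific modifier. The phantom validates the estimators and the
statistical machinery against a known generative model, not the biology.

## Problem sizes and numerical choices

Phantom sections default to 96×96 px (single-section work) and 64×64 px with
K = 18 angles for multi-animal studies; the 200-replicate sign-reproduction
simulation uses the 64×64 study at n = 4/group, which completes in a couple
of minutes on one CPU while leaving every stage (including Tukey contrasts at
N = 4) statistically meaningful. Rasterization uses the pixel-center rule
(pixel (r, c) belongs to a polygon iff (c + 0.5, r + 0.5) is strictly
inside), which is resolution-stable and makes an axis-aligned w×h rectangle
cover exactly w·h pixels. Region means over empty selections return NaN with
a zero count, never a silent 0. Tukey HSD p-values come from the studentized
range distribution directly (no critical-value inversion), which keeps
simulation loops fast; they match the statsmodels reference implementation
to 1e−6 in tests.

## Known limitations

* The phantom's fluorophore weights and mixing matrix are plausible, not
  calibrated to measured spectra; absolute ratio values are therefore
  arbitrary even though their orderings and responses are meaningful.
* The QPLI estimator assumes a single-harmonic forward model; real optical
  trains can add higher harmonics (imperfect circular analyzer), which the
  DFT estimator would alias into δ̂.
* Spectral unmixing of NADH/FAD/collagen/mineral contributions is out of
  scope; the ratios remain composite measures.
* The Dunn post-hoc uses a normal approximation; at very small n its
  adjusted p-values are conservative.
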