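# Methods

## Forward model and inversion

Each pixel of a polarization-resolved acquisition integrates the absorption
of many fluorophore dipoles, I(α) ∝ ∫∫ |μ(θ, φ)·E(α)|² sinθ dθ dφ, where
E(α) is the in-plane linear excitation polarization. We model the dipole
distribution as a uniform-filled cone of total aperture Ψ centred on the
in-plane axis ρ. For the in-plane (2-D) cone the angular integral has the
closed form

I(α) = a₀/K · (1 + M(Ψ) cos 2(α − ρ)),  M(Ψ) = sin(Ψ_rad)/Ψ_rad,

with Ψ_rad the total aperture in radians. M is strictly decreasing on
(0°, 180°], M → 1 as Ψ → 0 and M(180°) = 0, so Ψ is recovered from the
measured modulation amplitude by monotone bisection (80 halvings of
(0, π], i.e. a bracket far below 10⁻⁶ rad; derivative-free, no Newton
pathologies). A numeric 3-D solid-cone kernel (`cone_modulation_3d`,
midpoint quadrature of ⟨|μ·E|²⟩ over the cone solid angle) is provided as
an alternative inversion kernel for model-sensitivity studies; the 2-D
closed form is the default because the exact instrument kernel (including
high-NA corrections) is not public, and the Ψ scale is in any case relative
to an irreducible probe-wobble offset.

Modulation coefficients use the discrete sums a₀ = Σ I(α_k),
a₂ = 2/a₀ Σ I cos 2α_k, b₂ = 2/a₀ Σ I sin 2α_k, which are unbiased only on
uniform angle grids tiling [0°, 180°); on any other grid the package
switches to general linear least squares on the design
[1, cos 2α, sin 2α] (identical on uniform grids, which the test suite
verifies to 10⁻¹⁰). Amplitudes √(a₂² + b₂²) above 1 — possible under shot
noise — are clamped to 1 and flagged (`clipped`) rather than rejected, so
maps stay complete and the flag can drive QC. Pixels with a₀ below an
intensity floor (default 1% of the per-image maximum) are flagged invalid.

ρ is axial (period 180°), reported in degrees in [0°, 180°) measured from
the image x-axis (columns). At exactly zero modulation the orientation is
undefined; the package reports ρ = 0 with Ψ = 180° serving as the isotropy
flag.

### Distortion compensation

The excitation path can impose per-angle diattenuation (gain g_k) and
ellipticity (modulation-contrast factor ε_k), characterized by an external
calibration. The distorted model I_k = g_k(A + ε_k(p₁ cos 2α_k +
p₂ sin 2α_k)) is linear in (A, p₁, p₂) and the three measured sums are
linear functionals of I, so compensation is an exact per-pixel 3×3 linear
solve given the calibration — equivalent to dividing out g_k and re-fitting
with an ε-weighted harmonic design, without needing the raw stack again.

### Precision

With K = 10 uniform angles and independent Poisson counts,
σ(a₂) ≈ σ(b₂) ≈ √(2/a₀). Error propagates to Ψ through 1/|dM/dΨ|; at
Ψ = 130° (M ≈ 0.338, |dM/dΨ| ≈ 0.432 rad⁻¹) a total budget of 10⁴
counts/pixel gives σ(Ψ) ≈ 0.0137/0.432 rad ≈ 1.8°, which the Monte-Carlo
acceptance check reproduces. Sub-degree precision at this Ψ requires
roughly 3–4×10⁴ counts per pixel. This estimator sits at the information
floor for the model, so the reported precision is a property of the photon
budget, not of the implementation.

## Synthetic scenes

The generator emulates phalloidin-stained developing flight muscle:
parallel myofibrils rendered as Gaussian stripes (FWHM `fibril_width`)
spaced `fibril_spacing` apart, carrying an axial intensity profile with a
Gaussian Z-disc brightening (`zdisc_boost`, width `zdisc_width`) every
`period` and a Gaussian M-line dip (`mline_dip`) half a period away. On the
fibril support, ρ* equals the myofibril axis and Ψ* follows a band profile
(optionally more ordered at the Z-disc); off the tissue the scene is dim
and near-isotropic (Ψ* = 175°). Probe wobble is folded into Ψ* as an
additive aperture, never fitted — it is an unremovable offset of the
labeling chemistry. Ground-truth Z-disc centres are recorded for
segmentation scoring (interior centres owe a detection; any in-frame centre
legitimizes one).

The forward simulation scales scene intensity so the brightest pixel
receives `photon_budget` expected counts summed over angles (default 10⁴,
a mid-range EMCCD spinning-disc figure; real photon counts for the original
acquisitions are not published), applies the per-angle cone model with
optional distortion, and adds per-pixel per-angle Poisson noise from a
seeded generator (same seed ⇒ bit-identical stacks).

Stage presets encode the developmental series: periods 2.1 / 2.7 / 3.1 µm
at 48 / 72 / 90 h APF; fibril Ψ* of 149 / 137 / 133 / 129° at
32 / 48 / 72 / 90 h, chosen so masked-mean Ψ reproduces the stage means
relative to the 90-h reference of 129° (early myotubes at 163° give the
ΔΨ = 34° gap); a 4° Z-disc order excess at 48 h shrinking with maturation;
no banding at 32 h (immature fibrils have no periodic actin pattern yet).
The `mhc10` preset mimics a myosin point mutant: mature-like lattice with a
smooth spatial ρ jitter of 8° SD. Preset scenes fill the field of view with
fibrils by default, as in acquisitions framed on the muscle fibre —
leaving large dark background in frame is both unrealistic and makes the
ratio mask admit noise pixels. Angle grid: 10 angles, 0°–162° in 18° steps
(α and α + 180° are the same polarization, so the half-open grid avoids a
duplicate); pixel pitch 154 nm so that 65 px ≈ 10 µm.

What the generator does **not** emulate: the optical PSF and high-NA
depolarization, spinning-disc sectioning, photobleaching, detector gain and
read noise, tissue autofluorescence, curved or branching myofibrils, and
depth-dependent aberrations. Passing tests therefore demonstrate the
correctness of the analysis chain and its statistical behaviour at realistic
photon budgets — not robustness to every optical artefact of real data.

## Masking and segmentation

The actin mask is intensity / Gaussian-smoothed intensity > threshold
(default 1.0, strict, so constant images yield empty masks). The smoothing
scale (default σ = 2 µm, several sarcomere half-periods) makes the ratio a
local-contrast measure: Z-disc-centred actin bands exceed 1, dim M-lines
and background fall below. The construction is invariant to global
intensity scaling, and raising the threshold can only remove pixels. An
optional polygon ROI (µm coordinates) replaces interactive area selection;
default is the full frame.

Segmentation labels 8-connected mask components (robust to 1-px diagonal
breaks), fits each with the second-central-moment equivalent ellipse
(a 1/12-px² variance term keeps single-pixel-wide components
non-degenerate) and accepts components whose area, convexity
(area / convex-hull area) and major/minor ratio fall inside stage bounds.
Published per-stage bounds are unavailable, so the defaults (area
0.3–2.5 / 0.5–4 / 0.8–6 µm² at 48 / 72 / 90 h; convexity ≥ 0.75; ratio
1.5–8) were tuned once on the noiseless synthetic presets and are plain
config values. Convexity 0.75 rather than a stricter cut reflects the
slight mid-band bulge that a brighter Z-disc imprints on a band's outline;
strongly concave objects (merged or U-shaped components) still fail.
Object order is the deterministic scan-line label order; "most central"
selection is by Euclidean centroid distance to the frame centre with ties
broken by that order.

## Sarcomere averaging and length

Each selected object's neighbourhood is rotated by minus its orientation
(major axis → horizontal, Z-disc at the centre since the mask discards
M-lines), resampled bilinearly onto a common odd-sized grid (extent 1.5× the
median major axis, pitch = source pixel), and averaged pixelwise with the
interpolated validity as weight. ρ is transported into the object frame
(ρ → ρ − orientation) and averaged axially via doubled angles. The profile
is the 1-pixel central row; a reference value (e.g. the minimum of the
mature-stage profile) can be subtracted for cross-stage display. Stick
rendering amplifies the signed ρ deviation from horizontal (conventionally
50×) and is export-only.

Sarcomere length is measured independently of segmentation: intensity is
sampled bilinearly along user- or axis-derived myofibril lines at half-pixel
steps, lightly smoothed (Gaussian, default 0.2 µm — without it shot noise
jitters sub-pixel peak positions), and local maxima with prominence ≥ 20%
of the profile's dynamic range are taken as band centres. Both raw-grid and
3-point-parabola-refined peak spacings are reported (refined is the
default); lines with < 2 peaks are flagged and excluded. Per-pupa
statistics pool all spacings; one value per pupa enters group statistics.

## Summaries and statistics

Per-image Ψ is the unweighted mean over masked valid pixels (an
intensity-weighted option exists in config); hemithorax and population
levels take plain means of the level below, so the population mean equals
the mean of hemithorax means by construction. Disorder is
ΔΨ = Ψ − Ψ_ref with Ψ_ref = 129° (mature 90-h APF) by default; ΔΨ is
exactly linear in the reference.

ρ variability is the axial circular SD over a centred square window
(default 65 px ≈ 10 µm): angles are doubled, the circular SD
√(−2 ln R̄₂) of the doubled angles is halved, making the statistic
wrap-safe by construction — a field mixing 1° and 179° is tight, and a
global rotation of the field leaves the result unchanged. Windowed sums are
separable mean filters (zero-padded borders); pixels with fewer than two
masked neighbours are excluded, and R̄₂ within 10⁻¹² of 1 is snapped to 1
so constant fields report exactly 0. Whether the original workflow's SD was
wrap-safe is not documented; a naive linear SD would report ≈ 89° on the
1°/179° mixture, which is the practical difference between conventions.

Longitudinal order profiles average masked Ψ in arc-length bins (default
2 µm) along fibre-spanning polylines, interpolate and flag empty bins, and
report values relative to the per-pupa mean so end-to-end flatness can be
assessed. Group comparisons delegate to `scipy.stats`: two-sided
Mann-Whitney U (unpaired) and Wilcoxon signed-rank (paired); groups with
n < 3 are reported underpowered without a p-value; all-zero paired
differences report the maximal p = 1 by convention. No multiple-testing
correction is applied by default.

## Problem sizes and determinism

Tests and examples use 128–256 px frames, 10-angle stacks, populations of
2–3 hemithoraxes × 2–3 images, and 2,000-pixel precision ensembles — sizes
at which every statistical check is comfortably resolved. All randomness
(noise realizations, jitter fields) flows from explicit integer seeds
through `numpy.random.default_rng`; reruns of the pipeline with identical
inputs produce byte-identical tables, and the pipeline writes a manifest of
input hashes and the resolved configuration next to its outputs.

## Known limitations

- The 2-D cone closed form is a model choice; absolute Ψ values shift under
  the 3-D kernel, though orderings and differences are stable.
- Touching sarcomeres are not split (no watershed); heavily fused masks
  undercount objects.
- Per-pixel Ψ uncertainty is characterized by simulation only, not
  propagated analytically per pixel.
- Myofibril lines for length measurement are straight; strongly curved
  fibrils would need polyline input.
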