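# Methods

This note documents the models, defaults, numerical choices and known
limitations of the `esip` package. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Axial profile models

**Layer.** The axial response of a thin homogeneous fluorescent layer is
modelled as a peaked profile in the warped centred coordinate
`u = (z − z0)·exp(s·(z − z0))`:

- Gaussian `G(u) = exp(−4 ln2 (u/w)²)`,
- Lorentzian `L(u) = w² / (4u² + w²)`,
- pseudo-Voigt `mL·L + (1 − mL)·G`, `mL ∈ [0, 1]`.

All three are unit-peak kernels, so the maximum is exactly `I0 + A` at
`z0` (for `s = 0`) and the half maximum sits at `z0 ± w/2`; `w` is the
FWHM in µm for every shape.

*Skew warp on the centred coordinate.* A warp of the absolute coordinate
(`zs = z·e^{s·z}`) makes the profile depend on where the acquisition's
z-origin happens to lie, which no physical profile does. The warp is
therefore applied to `z − z0`. For a profile centred at the origin the two
readings coincide; the toy protocol (below) uses `z0 ≈ 0`, so this choice
does not alter any simulated result, but it makes `fit_profile`
translation-equivariant (a tested invariant).

**Solution.** A fluorescent solution behind the coverslip produces the
integral of the layer kernel from the interface at `z0` to infinity,
attenuated per penetration depth by `(1 − ol)·exp(−LC·(z' − z0)) + ol`.
For the Gaussian kernel the integral is evaluated in closed form;
`solution_model_exact` is verified against adaptive quadrature of the
integrand to 1e−6 relative. The sign convention is decay for `LC > 0`
(negative `LC`, signal increase with depth, is accepted and flagged).
The computationally cheaper approximation (`solution_model_approx`) treats
the attenuation as constant across the excitation PSF and factors it out
of the integral; it is exact for `LC = 0` and is the default for chart
fitting, with the exact form selectable (`variant="exact"`). The
Lorentzian and pseudo-Voigt solution branches exist only in this
factored-out approximation; no exact Lorentz-kernel integral is
implemented.

Because a solution profile offers no practical handle on asymmetry, the
solution fit fixes `s = 0`.

*Numerical stability.* The closed form contains the pattern
`exp(big)·erfc(big)`, which overflows when composed naively. It is
evaluated through `erfcx` in two branches: for `x ≥ 0` directly as
`erfcx(x)·exp(−4 ln2 ((z−z0)/w)²)/2`, and for `x < 0` via
`erfcx(x) = 2·exp(x²) − erfcx(−x)`, where the `exp(x²)` term combines with
the Gaussian tail into the plain exponential attenuation. A dedicated test
shows the naive composition producing `inf·0 = nan` where this evaluation
stays finite.

**Penetration drop.** `1 − exp(−LC·depth)` summarises the solution
attenuation as the intensity fraction lost at a given depth; with
`LC` = 9.52 mm⁻¹ (an oil objective on an aqueous sample) the drop at
100 µm is ≈ 61%. `LC` is stored in µm⁻¹ throughout; summary tables
display mm⁻¹ (labelled), chart maps µm⁻¹.

**Pseudo-Voigt fidelity.** `voigt_mixture_error` fits the mixture form
(shared width, free fraction and amplitude) to a numerically convolved
true Voigt profile and reports the maximum residual as percent of peak;
across Lorentz/Gauss width ratios 0.1–10 it stays below 1% (measured
≈ 0.7% at ratio 1). The true Voigt is a test oracle only, never a fit
model.

## Lookup estimator

The lookup baseline reproduces the classic SIPchart recipe: amplitude =
brightest value minus offset; `z0` = position of that value (first index
on ties, flagged); offset = mean of the ten samples most distant from
`z0` (five per end of the z range, re-derived from points outside
`±2·w` when the ends intrude into the peak); half-max crossings by linear
interpolation between the outermost above-half sample and its below-half
neighbour on each side; `w = a + b` and skew `= (b − a)/(a + b)` from the
crossing distances. Missing crossings mark the estimate incomplete and the
fit engine falls back to plain heuristics.

*Skew conversion.* On noise-free skewed Gaussian profiles the lookup skew
responds to the generating factor with slope `−w/2` (≈ −0.5 for the 1 µm
reference profile); equivalently, converting skew readings into `s` units
takes a factor of ≈ −2 (`s ≈ −2·skew`). `skew_conversion_factor` measures
both directions by regression over `s ∈ [−0.05, 0.05]` on the reference
grid; the conversion is what the simulation study uses to place lookup
skew readings on the `s` axis.

The solution lookup (plateau/offset from intensity deciles, `z0` from the
half-rise crossing, steepness from the 25–75% rise converted through the
Gaussian-edge IQR, `LC` start from the deep-region log-slope) is this
package's own seeding heuristic — no published recipe exists — and all its
constants are keyword arguments.

## Fit engine

Bounded trust-region least squares (scipy `least_squares`, `trf`), unit
weights, tolerances `ftol = 1e−10`, `xtol = 1e−8`, at most `400·n_free`
function evaluations, one restart from a perturbed start (`w × 1.2`,
`z0 ± 0.5 µm`) on non-convergence. Bounds keep `A ≥ 0`, `w > 0`,
`mL, ol ∈ [0, 1]` (out-of-range pulls clip at the bounds rather than
failing). Start values come from the lookup. Saturated samples
(≥ 2¹⁶ − 1 by default) are excluded from the residual and flagged; the
threshold is a parameter because synthetic toy data are not
detector-limited. Parameter standard errors come from the Jacobian at the
solution (`cov = (JᵀJ)⁻¹·SSR/dof`), `R² = 1 − SSres/SStot`.

`fit_stack` averages each `bin × bin` pixel tile per plane (mean, not sum,
so amplitudes stay in per-pixel DL; trailing pixels that do not fill a
tile are dropped), fits every tile independently, and assembles parameter,
`R²` and convergence maps. Non-uniform z spacing enters the residual
unweighted — one sample, one residual — matching the per-sample noise
model of mixed-spacing acquisitions. A warning is raised when fewer than
half the bins converge.

## Photon calibration

Per 4×4 bin and z-plane the sample mean and unbiased (n−1) variance over
the 16 pixels are computed; bins containing saturated pixels and bins
above the 99.5th mean percentile (detector nonlinearity near full scale)
are excluded, and at least 200 pairs and a dynamic range of 10× the noise
floor are required. Pairs are aggregated into 50 equal-count mean-groups
(heteroscedasticity control; raw pairs selectable) and fitted linearly.
Without a dark reference the intercept is free and the implied dark offset
`−c/CF` absorbs the constant read-noise variance (flagged); with a dark
frame the fit is anchored at the measured dark level and the dark-frame
variance is subtracted from the pairs first. Calibration is per detection
channel; the channel key is recorded in the result. Monte-Carlo tests show
the slope estimator unbiased within 1% on pure scaled-Poisson data, and
that constant-variance read noise moves only the intercept.

## Synthetic data (what it emulates, what it does not)

`generate_toy_profile` follows the reference toy protocol: evaluate the
noise-free model in expected-photon units (layer: Gaussian with
`w = 1 µm`, `s = −0.025/µm` on z −10..10 µm step 0.2; solution: exact
Gaussian-kernel interface with `LC = 0` on the piecewise 0.1/1/5 µm grid
to 200 µm), then `I = CF·Poisson(λ) + I0 + N(0, σr)` with
`CF = 500 DL/photon` and `I0 = 500 DL`; the profile position is jittered
uniformly within ± half the local z step per replicate so grid features
never coincide permanently with the sampling. Two protocol constants are
not published: the read-noise magnitude (the detector is named, its noise
is not) — default 0.5 photon-equivalents (250 DL), config-exposed — and
the jitter law, taken uniform because it exactly decorrelates
feature/grid coincidence. 500 replicates per peak-photon level, levels
1–1000.

`generate_synthetic_stack` renders per-pixel truth maps (amplitude,
position, width, skewness or length constant) through the same noise
model into 16-bit stacks; `GridTruth`/`generate_grid_image` render a
square lattice of Gaussian-cross-section lines with uniform second-order
line bending, cubic (barrel) field distortion, per-channel chromatic
offsets, and point sampling (so pixel pitch near the period produces
genuine Moiré beats). Generators are pure functions of (config, seed).

What the synthetic data does **not** contain: optical diffraction of the
grid lines, reabsorption spectral shifts, dye precipitation or
evaporation drift, detector nonlinearity, and spatially correlated noise.
Passing tests therefore validate the estimators against the stated noise
model, not against every artefact of real acquisitions.

## Simulation study and derived thresholds

`run_simulation_study` applies the lookup and the fit to the same toy
replicates and tabulates mean, STD, accuracy (mean − truth; for `z0`
errors are taken against the per-replicate jittered truth) and relative
STD per estimator, parameter and level. Reproduced orderings (tested):
fit amplitude scatter ≤ lookup scatter at ≥ 10 photons; lookup `z0`
precision floored by the z spacing while fit `z0` precision keeps
improving; lookup amplitude biased high at low photon counts.

The skewness parameter is the least determined: its relative STD decays
as a power law in the peak photon number. `skew_precision_threshold`
locates the level at which it reaches 100% by log-log regression of
relative STD on level, excluding levels where the mean skew estimate is
not significantly non-zero (there the ratio is dominated by the vanishing
denominator). The regression-based crossing is used instead of "first
sampled level below 100%" because under the stated noise model the
crossing lies at the very top of the protocol's level range, where a
grid-minimum is undefined for about half of the random seeds; the
power-law fit gives a well-defined estimate (of order 10³ photons — the
skewness needs very bright profiles before its scatter drops below its
own magnitude).

## Charts and tuning series

`build_chart` runs the photon calibration, fits every bin, converts the
amplitude map to photons and to percent of the maximal photon number
(99.9th percentile of the photon map, robust to single-bin outliers), and
stores five representative profiles: the centre bin and four bins inset
10% from the corners (the exact inset positions are a convention;
configurable). A failed photon calibration downgrades the chart (the note
is recorded) rather than failing it. Charts serialise to a versioned JSON
schema; maps additionally export as PNG + CSV.

`analyze_tuning_series` reduces charts taken across an instrument setting
(correction collar, collimator) to centre-region means (default: central
third of the field) and locates optima by a 3-point parabola around the
best sample — settings series are usually coarser than the optimum, so
vertex interpolation is required — for amplitude (maximum) and axial
resolution (minimum). For two-excitation series the axial offset
`Δz0` between the channels is driven to zero: the sign-change root when
the series crosses zero, otherwise the parabola on `|Δz0|`. A boundary
optimum is reported with an "extend series" warning. Optima are invariant
under affine rescaling of the setting axis (tested).

## Grid analysis

Crossing detection: a structure gate first requires the grid frequency to
stand out of the mean row/column power spectra (50× the median power by
default) — thresholding alone cannot distinguish a faint grid from pure
noise. Then Gaussian smoothing (σ = half the line width), Otsu threshold,
binary closing, skeletonisation, branch-point extraction (skeleton pixels
with ≥ 3 skeleton neighbours), clustering, and sub-pixel refinement by a
Gaussian-weighted intensity centroid on a patch interpolated symmetrically
around the running estimate (an integer-aligned window biases the
centroid toward its own centre; the re-centred window is bias-free and
reaches ~0.01 px on noise-free lattices, tested at < 0.1 px). Crossings
whose refinement window would leave the image are dropped.

Distortion: crossings are grouped into vertical lines by x and horizontal
lines by y (rounding against the period raster, then iterative
re-assignment to the nearest fitted line; near-equidistant points are
flagged ambiguous), and each line is fitted with `c0 + c1·t + c2·t²` in
centred field coordinates. `c2` (1/µm) is the distortion metric — zero
under any affine transformation of a perfect lattice (tested to 1e−10);
×10⁵ is a display convention. Chromatic shift: nearest-neighbour matching
of two channels' crossings within half a period; vectors are
antisymmetric under channel exchange; a warning is raised when > 20% stay
unmatched. Moiré diagnosis: per-row mean-subtracted power spectra along
the scan axis are averaged; peaks above a noise-floor multiple are
classified as the grid frequency or as aliased beats
`|m·f_grid − k·f_s|` of grid harmonics with the sampling frequency.

## I/O and configuration

Stacks are read from OME-TIFF (per-plane z positions from the OME Plane
elements, channel selection by index or OME channel name) or plain TIFF
plus a one-column sidecar CSV of z positions; 16-bit data and non-uniform
spacing are preserved exactly. Outputs embed the run-configuration hash
and seed. The CLI (`esip chart|photons|simulate|tune|grid`) is a thin
layer over the library; a YAML config can stand in for any flag.

## Problem sizes used in validation

The bundled validation runs are sized for a single CPU: toy ensembles of
500 replicates at one level (FWHM recovery), 300–400 replicates per level
over a 10-level log grid (skewness precision), 96–128 px stacks for the
photon calibration, 32 px stacks for chart round-trips, and 128 px grid
images. These sizes keep every Monte-Carlo standard error well inside the
tolerances they are tested against.

## Known limitations

- No per-pixel (unbinned) fitting, spatial regularisation across bins, or
  GPU batching.
- The solution model family assumes a clean glass/solution interface;
  precipitation layers and evaporation drift are out of scope.
- The Lorentz/pseudo-Voigt solution branches inherit the factored-out
  attenuation approximation at all `LC`.
- Vendor file formats beyond what generic TIFF readers expose are not
  handled; spectral (32-channel) stacks are processed one channel at a
  time.
- The grid renderer is geometric (Gaussian line cross-sections); it does
  not model diffraction, so resolution metrics are out of scope for the
  grid analysis.
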