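# Methods

This note records the models, conventions and numerical choices behind
`helixcdi`, and what the synthetic experiments do and do not demonstrate.

## Geometry and conventions

Real space uses 0-based `(row, col)` pixels with `y` = rows along the
filament (helical) axis and `x` = columns perpendicular to it; lengths are
in nm. The default real-space raster is 1024×1024 pixels at 0.5 nm/pixel
(512 nm field), which oversamples a ~30 nm-wide filament more than
fifteen-fold in x and leaves room for the 159 nm FWHM axial support.

Detector space uses the exact scattering geometry `tan 2θ = r/D`,
`ν = 2 sin θ / λ`, with ν the spatial frequency 1/d in nm⁻¹ (the 4 nm layer
line sits at ν = 0.25 nm⁻¹). The radial-analysis module alone reports
pseudo-SAXS profiles in the SAXS convention `q = 2πν` rad/nm so that the
J01 relation keeps its standard form, `q₀₁ = 7.66/2R`. The default detector
is a 256×256 monolith at 520 μm pitch, 565 mm distance and 2.07 Å — a
4×-rebinned stand-in for a CSPAD-class tiled detector that covers the
2 nm layer line along its axes — with a cross-shaped 3-pixel gap mask
emulating tile seams.

## Models

**Featureless tube.** A uniform annulus of inner/outer radius (a, b)
projected through its axis: p(x) = 2(√(b²−x²) − √(max(a²−x², 0))). The
profile peaks at |x| = a, which is why the recovered "peak-to-peak
diameter" of a filament wall is smaller than its outer diameter. The
closed-form COM radius 2(b³−a³)/(3(b²−a²)) parameterises starting models.

**Sphere-helix wall lattice.** The oversimplified microtubule: spheres of
4 nm (one tubulin monomer) on a cylinder of radius 11.2 nm, 14 per turn
with a stagger of 3 monomers per turn, the turn replicated axially at the
4 nm monomer repeat so every protofilament is a vertical chain of touching
spheres. The replication at the monomer repeat matters: a single
continuous helix with the same per-sphere rise would put its dominant
layer line at the 12 nm pitch, whereas the wall lattice — like the real
polymer — confines layer lines to multiples of 1/(4 nm), with the first
order strongest and the second at 2 nm. Protofilament counts n other than
14 scale the centre radius linearly, R(n) = 11.2·n/14 nm (constant lateral
subunit spacing). Each sphere is stamped as its projected chord profile,
normalised to deposit exactly its volume so projected mass is conserved
under rotation to 1e−6.

## Synthetic shot generator

One shot draws a jet angle (Normal, default mean 0°, σ 10° — the
shot-to-shot wander that classification later corrects), a Poisson
filament count (mean 20, matching ~20 filaments in the ~0.16 μm³ probed
volume), and per filament: a protofilament count from the mixture
{11: 2%, 12: 8%, 13: 40%, 14: 35%, 15: 10%, 16: 5%} (an in-vitro,
taxol-stabilised population dominated by 13/14), an axial rotation from 8
precomputed template orientations, and an in-plane angle = jet angle +
Normal(0, 5°) alignment jitter. Filament intensities add incoherently —
filaments sit at random relative positions far larger than any fringe of
interest — and each contributes `photons_per_pulse × scattering_fraction`
detected photons (defaults 2×10¹² and 1e−8; the product, 2×10⁴ photons
per filament, is the physically meaningful knob and the fraction is a
stand-in, not a calibrated cross-section). A smooth isotropic Lorentzian
background (mean 0.5 photons/pixel) is added, Poisson noise applied, and
gap/bad pixels zeroed. An optional artefact class replaces the filaments
with a razor-thin, near-saturation streak through the beam centre
(peak 5×10⁴ photons), emulating jet-edge diffraction that dominates the
exposure. Seeding is `default_rng([root_seed, shot_index])`, so any shot
is bit-reproducible in isolation.

What the generator does *not* emulate: detector gain/geometry calibration
residuals, polarization and solid-angle corrections, water-ring background
structure, inter-filament interference, filament bending or length
polydispersity. Passing end-to-end tests therefore demonstrates the
internal consistency of the chain on data with the right statistical
skeleton, not performance on raw experimental frames.

## Sorting and classification

Per-shot statistics are computed on the central-quarter crop (mirroring
the use of only the central four of sixteen detector tiles). The angular
intensity distribution over the 0.05–0.30 nm⁻¹ annulus (0.5° bins,
count-normalised so lattice-induced bin-occupancy structure does not fake
anisotropy) yields: an anisotropy score (max−mean)/mean; and a jet-edge
score = (fraction of angular excess within ±2° of the maximum) ×
anisotropy / (0.2 + CV), where CV is the coefficient of variation of the
intensity along the brightest line — a streak is a smooth ridge, an
equator oscillates through form-factor lobes. On labelled synthetic shots
filament exposures stay below ~15 and true streaks above ~50; shots above
the (dimensionless) threshold 30 are pushed to the bottom of the ranking,
and the remainder rank by anisotropy. The best 40% survive.

The equatorial angle estimator is two-pass: the angular-histogram maximum
locates the basin, then the radon-style line-sum score is scanned at 0.1°
around it and refined by a three-point parabola; agreement with an
exhaustive 0.1° scan is better than 0.1°. Confidence is the histogram
maximum in robust (median/MAD) units; below 6 the estimate is flagged
low-confidence (isotropic images score ~3, single-filament shots ~10²).

Classification is circular k-means (k-means++ seeded, unit vectors on the
doubled-angle circle) within consecutive blocks of ~1000 shots, five
classes per block. Class averages are stored as pixel sums plus per-pixel
member counts; normalisation is deferred to the merge so that rotated gap
regions simply drop out of the denominator. Classes are ranked by
layer-line contrast — the two highest local maxima along the 4 nm layer
line over the line mean (a flat line scores 2) — the top 69/186 ≈ 37%
are rotated about the beam centre to a common horizontal equator
(bilinear interpolation) and averaged.

## Peak fitting

Candidate peaks are local maxima exceeding 5× a MAD noise scale over a
median-filtered background, at least 5 px apart, with Friedel pairing
enforced. The forward-scattering region (ν < 0.03 nm⁻¹) is excluded: the
central-lobe shoulder is not a diffraction peak, and the centre is
modelled by the scaled tube during retrieval. Peaks are fitted
brightest-first with separable Gaussians (amplitude, sub-pixel centre,
σx, σy, local offset; windows grow adaptively up to 65 px for elongated
equatorial streaks; centre-at-window-edge fits are rejected), and each
accepted Gaussian is subtracted before the next fit so overlapping lobes
are not double-counted; any peak whose own fit failed is restored as the
mirror image of its Friedel mate. Rendering sums the Gaussians (offsets
dropped — between-peak intensity is exactly what this representation
removes) on a gap-free grid.

## Phase retrieval

Amplitudes are √intensity resampled from the detector onto the centred
Fourier grid of the retrieval raster. Frequencies beyond the detector
q-range are constrained to zero (a hard resolution cutoff): leaving them
free lets the starting model's high-frequency content survive every cycle
unconstrained, which visibly locks the reconstruction to the start.
In-range holes (masked detector regions) remain free. The unmeasurable
centre is filled, out to half the distance to the tube model's first
equatorial peak by default, with tube amplitudes scaled so the model's
first equatorial peak matches the first measured one.

Each of the 100 cycles: combine measured amplitudes with the current
phases, inverse transform, take the real part (no positivity by default;
both toggleable), multiply by the support, every 10th cycle average the
object with its 180° rotation, forward transform, update phases, and
record the misfit ‖(|F(ρ)|−A)·M‖/‖A·M‖. The support is separable: flat to
|x| ≤ 15.6 nm falling as a half Gaussian whose FWHM beyond the flat top
is 11.8 nm (a "sigma" convention is selectable; results are insensitive),
times a y-Gaussian of FWHM 159 nm, divided out after the last cycle
(clipped where it falls below 1e−3). Because the smooth support is not a
projection, the misfit has a positive floor (~0.25 on realistic data)
even at a good solution; with an effectively binary support the loop is a
true alternating projection and the misfit falls below 1e−6 on
self-consistent input.

**Convergence basin.** Systematic scans (1D and 2D, clean and pipeline
data) show that this plain error-reduction scheme refines rather than
solves: starting tubes whose wall COM radius is within ~1.5–2 nm of the
truth converge to the data (wall separation recovered to ≤ 2 px, sub-pixel
at matched start), while more distant starts stall near a start-biased
solution. Restarts with randomly perturbed phases do not widen the basin.
The COM-radius scan therefore reports, per start, the recovered wall
separation and the Pearson correlation between the reconstruction's
equatorial intensities and the measured ones (0.03–0.30 nm⁻¹); the
correlation cleanly flags stalled and degenerate runs (~0.5 versus >0.95
inside the basin) and is the quantity to rank starts by.

## Radial analysis

Azimuthal integration bins unmasked pixels by the q of their centre into
half-open equal-width bins; the default bin width matches the q-spacing
of one detector pixel (finer binning on a coarse detector produces a comb
of alternately empty low-q bins). The J01 locator weights the profile by
q before searching — the azimuthal *mean* of a fiber pattern dilutes the
equatorial line by the 1/q annulus arc length, dragging the apparent lobe
maximum 13–25% low; the Lorentz weight restores the lobe to qR = 3.83,
and on simulated shells of radius 9–16 nm the radius is recovered to
better than 5%. The lobe must clear a 5% prominence over the running
minimum of the (5-bin box-smoothed) weighted profile; refinement is a
three-point parabola. The protofilament estimate N = round(13·R/R₁₃) uses
R₁₃ = 11.94 nm, a calibration constant chosen so 12.9 nm maps to 14 while
11.5–12.3 nm maps to 13 — an assumption, not a derived relation.

The wall peak-to-peak separation averages the density over the central
half of the rows and takes the distance between the two highest local
maxima (parabola-refined). On a cusped annulus projection the quadratic
refinement biases each peak outward by under a pixel; comparisons between
a reconstruction and a reference measured with the same estimator are
unaffected.

## Problem sizes

The end-to-end synthetic study uses 2000 shots on the 256² detector
(≈ 800 kept, 5 classes, 2 merged), a 1024² retrieval grid and 100 cycles;
it completes in a few minutes on one CPU. Single-shot unit tests use 64²
or 128² detectors and single-species populations. The COM-radius
robustness scan runs six starts (10–15 nm) against the fitted pattern of
the end-to-end run.

## Known limitations

* Error reduction's finite convergence basin (above) is the method's main
  scientific caveat: agreement of the recovered wall separation across
  starting models should be read together with the Pearson column.
* The incoherently averaged data (mixture, axial rotations, class
  averaging) are not the diffraction of any single real object; the
  retrieval finds a compromise object whose equator matches the averaged
  envelope and whose layer lines carry the (incoherently strong) 4 nm
  modulation. This mirrors the experimental situation.
* The protofilament calibration R₁₃ and the jet-edge threshold are
  synthetic-data calibrations, documented above, not derived constants.
* No polarization, solid-angle, or gain corrections; no 3D reconstruction;
  no hybrid input-output or shrink-wrap variants.
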