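# Methods

`cortiq` quantifies cortical (membrane-localized) fluorescence in midplane
time-lapse images of roughly ellipsoidal cells — the setting of PAR polarity
imaging in nematode oocytes and zygotes — and ships a synthetic-image
generator so every stage can be validated by parameter recovery without any
external data.

## The measurement problem

A perpendicular intensity profile across the cell edge mixes three sources:

1. extracellular background (level *B*),
2. cytoplasmic fluorescence: a step of amplitude *C* rising from outside to
   inside the cell, softened by the optics,
3. the cortical signal of interest: a near-Gaussian peak of mass *M*
   (a.u.·px) sitting on the step, produced by fluorophores in a thin layer
   at the membrane.

The pipeline estimates *M* at each time point (whole-cortex traces) or at
each circumference position (polarity profiles) by subtracting a scaled,
shifted *cytoplasmic reference profile* — the edge profile of a purely
cytoplasmic fluorophore, which contains every source except bona fide
cortical signal — and integrating the residual peak.

## Pipeline stages

**Straightening.** The cell outline (an input; outlines are drawn or
generated, never segmented here) is resampled at 1-px arc-length steps and a
band of `band_width` = 50 samples is interpolated bilinearly along the
inward normal at every position, ordered exterior → interior. The band is
centered on the contour; the reference fit absorbs residual centering error.

**Smoothing.** A rolling average of `rolling_window` = 50 positions runs
along the cortex axis (circular for closed contours, reflecting for arcs),
then a Savitzky-Golay filter (`sg_window` = 11, `sg_order` = 3) smooths each
perpendicular profile. The SG defaults preserve the edge's rising flank
within a 50-sample band while suppressing pixel noise; both are
configurable.

**Reference derivation.** Cytoplasmic profiles are registered to their
maximum slope (quadratically interpolated sub-pixel argmax of the first
difference), divided by their cytoplasmic plateau (mean of the innermost 10
samples) and averaged; the plateau of the mean is renormalized to exactly 1.
Profile shape is insensitive to absolute signal, which is what makes the
collapse meaningful.

**Reference fit and subtraction.** For each measured profile the reference
magnitude *a* and alignment *s* are fit: *s* is searched on a 0.1-px grid
over ±5 px (quadratic refinement, kept only if it lowers the error), and for
each *s* the scale is the closed-form non-negative least-squares solution on
a fit window that excludes `band_center ± exclusion_halfwidth` samples. The
residual `p − a·r(x−s)` over the full band is the cortical component.

**Integration.** The residual is summed over `band_center ±
integration_halfwidth` (= 10) samples. Negative residuals are kept: under a
zero-signal null the integral then averages to zero rather than being
positively biased.

**Normalization.** Whole-cortex traces are divided by a
maintenance-measurement — the same integral evaluated on user-designated
frames where the protein occupies its stable domain. The pipeline requires
this choice to be explicit (or defaults, loudly, to the final three frames).

**ASI.** The asymmetry index is computed from a circumferential profile as
`ASI = (A − P) / (2(A + P))`, where *A* and *P* are the summed corrected
values in windows covering 30% of the circumference centered on the
anterior and posterior poles. ASI spans −0.5 … +0.5, 0 meaning symmetric.
Window membership is by circular arc distance with boundary ties broken
toward the lower-index side, so 1000 positions give exactly 300 per window.
Pole positions default to the contour's principal-axis endpoints but the
anterior/posterior identity is biological knowledge the user must confirm.
For treatment experiments the series is normalized to a pre-treatment
reference frame (normalized ASI 1 = unchanged, 0 = fully symmetric).

**Clusters.** Punctate structures in near-membrane images are detected with
a Crocker-Grier scheme (Gaussian noise smoothing minus a boxcar background,
local maxima separated by the feature diameter, centroid refinement, a mass
threshold that must be chosen per dataset) and each candidate is fit with an
isotropic 2D Gaussian plus constant offset. A cluster's integrated intensity
is the analytic integral `2π·amplitude·σ²`, robust to the local offset; the
per-frame statistic is the sum over clusters divided by the analyzed area.

**Timing.** All times are minutes relative to ovulation. When ovulation is
not observable (dissected embryos), it is inferred as the annotated
symmetry-breaking time minus `ovulation_sb_interval_min` = 56 min, a
measured cohort mean kept configurable because strains and conditions
differ. Frame times are products of integer frame offsets and the frame
interval, computed with exact rational arithmetic.

## Identifiability: why registration must not use the membrane peak

A subtle degeneracy governs the whole design. If the optics blurred a sharp
cytoplasm edge and a thin membrane layer with the *same* kernel, then to
first order in *M/C*

    C·S(x) + M·S′(x)  ≈  C·S(x + M/C),

i.e. a membrane peak is indistinguishable from the cytoplasm step shifted
outward by *M/C* pixels. Two consequences:

* Registering a membrane-bearing profile to its own maximum slope places
  the *membrane peak's flank*, not the cytoplasm edge, at the band center —
  an error that grows with signal — and the subsequent subtraction then
  cancels most of the true cortical mass. The pipeline therefore registers
  measured profiles through the reference fit's shift search, whose window
  excludes the peak; max-slope alignment is used where it is unbiased
  (deriving the reference, registering cytoplasm-edge profiles across
  positions or embryos).
* The fit window must contain edge structure the membrane peak does not
  touch. In real midplane images it does: a thick cell contributes
  defocused light from the cytoplasm above and below the focal plane, so
  the cytoplasmic edge has long soft shoulders extending well beyond the
  in-focus edge spread, while the thin equatorial membrane band adds
  essentially no defocused light. These shoulders are what lets the fit
  register the cytoplasm edge independently of the peak.

The synthetic generator reproduces exactly this structure (see below).

`exclusion_halfwidth` = 11 is sized so the window clears the peak's full
smoothed support: ≈ 2.5 σ of the blurred peak plus the `(sg_window−1)/2`
samples over which the SG filter spreads side lobes. With a smaller
exclusion the fitted shift acquires a bias proportional to the cortical
signal; at 11 the noise-free integrated signal is linear in true membrane
density over a 10× range with R² > 1 − 10⁻¹⁴ and slope 1.00.

**Shared registration.** The band-to-reference offset is one physical
quantity per movie (it reflects the contour convention, not the frame), but
per-frame estimates of it are noisy because the fit window sees only the
soft shoulders, and a shift error δ couples into the integral as
≈ a·δ·[r(c+h) − r(c−h)]. With `shared_shift` (default on), per-frame (or
per-position) shifts are estimated first, their median becomes the movie's
registration, and scales are refit with it fixed. On the standard noisy
movie this reduces the per-frame scatter from ~5% to below 1%.

## The synthetic generator

Scenes are 2D midplane images of an ellipse: uniform cytoplasm inside,
uniform background outside, and a membrane shell of configurable thickness
(3 px default) whose fluorophore surface density (a.u. per pixel of contour
length) is an arbitrary function of arc-length position. The shell is
rendered at 4× supersampling by depositing mass bilinearly along fine arc
steps and across the shell thickness, then block-averaged to native
resolution — total shell intensity equals ∫density·ds to machine precision.

Blur: the volume composite (cytoplasm + background) is convolved with a
core + halo mixture — 75% Gaussian σ = 1.2 px (in-focus PSF at ~0.1 µm/px)
plus 25% Gaussian σ = 6 px emulating defocused light from the cell volume;
the shell is convolved with the core only (a thin equatorial band
contributes negligible defocus at the midplane). Noise: Poisson applied at
a gain of 0.5 a.u./photon plus Gaussian read noise of 2 a.u., both
configurable, giving edge SNR ≈ 14 at the default cytoplasm level of
100 a.u. — ordinary confocal conditions. None of these acquisition
constants is prescribed by any dataset; they are the package's standing
choices and remain user-configurable.

Kinetic templates produce movies that walk through the qualitative stages
of the cortical polarity program — a refractory period with no membrane
loading, uniform accumulation, a transient dip, and a polarized domain
covering part of the circumference — with the exact per-frame, per-position
density recorded as ground truth.

What the generator does **not** emulate: 3D image formation (the halo is a
phenomenological stand-in), cortical flows and contour deformation,
photobleaching, position-dependent cortex thickness, structured
(non-uniform) cytoplasm. Passing recovery tests therefore demonstrate the
correctness of the measurement chain under the stated optical model, not
robustness to every property of real embryos.

## Numerical choices and degenerate inputs

* Bilinear interpolation everywhere (straightening, profile shifting):
  minimal, linearity-preserving; it attenuates sharp peaks by ≈ |f″|/8,
  visible only in direct profile-shape comparisons.
* Flat profiles (no positive forward difference) are flagged and passed
  through unshifted rather than failing a whole frame.
* Per-frame fit failures leave NaN in the trace and are recorded; runs
  continue.
* Clockwise contours are re-oriented transparently; self-intersecting
  polygons are rejected.
* ASI with empty windows (A + P = 0) raises rather than returning 0/0.
* Boundary ties in window membership are resolved deterministically
  (included on the approaching side).

## Known limitations

* Per-position circumferential values carry a curvature-dependent
  systematic of a few a.u.·px on strongly eccentric cells, because one
  reference shape is fit to positions whose edge curvature varies; against
  typical cortical signals (~200 a.u.·px at the default density) this is a
  2–3% floor. ASI is scale-invariant and unaffected to first order.
* Registration noise sets the zero-signal floor: with short movies or small
  cells the shared shift still carries a residual error of a few hundredths
  of a pixel, which appears as a constant offset of order 1% of a typical
  cortical signal.
* Measured integrals are proportional to true membrane density with a
  geometry-dependent factor within a few percent of 1; maintenance-phase
  normalization cancels it, so only normalized quantities should be
  compared across cells.
* Overlapping clusters are fit independently and flagged, not deconvolved.
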