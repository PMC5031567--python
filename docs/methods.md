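# Methods

## Model overview

`marrowdose` estimates the mean absorbed dose to the red bone marrow from
planar post-therapy scintigrams of <sup>177</sup>Lu-DOTATATE patients.  The
body is modelled as two source compartments on the geometric-mean image:

* **high-uptake** — organs and tumours with high somatostatin-receptor
  expression, treated as a slab of general organ thickness `x_high = 8 cm`
  centred at mid-depth of the abdominal thickness `T_high`;
* **low-uptake** — the remainder of the body (muscle, fat, bone, marrow),
  treated as a uniform slab whose thickness follows from body mass at unit
  density: `t_low = (weight − m_high)/area_low`, with
  `m_high = area_high · x_high · 1 g/cm³`.

The marrow dose is the MIRD sum

    D_bm = Ã_bm·S(bm←bm) + Ã_high·S(bm←high) + Ã_low·S(bm←low),

with the marrow time-integrated activity derived from the low compartment
through a fixed activity-concentration ratio:
`Ã_bm = (Ã_low/m_low) · r · m_bm`.

## Stage-by-stage assumptions and defaults

### Geometric-mean images (`imageio`)

Anterior and mirrored posterior grids are normalised to count rates by
their acquisition durations before the pixelwise square root.  Frame
convention: row 0 cranial, column 0 patient-right in the anterior view;
posterior images are stored as acquired and mirrored at combination time.
Noise-free simulated images carry expected (float) counts so that
forward/inverse consistency can be tested exactly; acquired or
Poisson-noised images are integer counts.

### Whole-body ROI (`segmentation.lowpass_filter`, `whole_body_roi`)

A radially symmetric frequency-domain Butterworth filter with gain
`1/(1 + (ρ/ρ_c)^(2·order))` (order 2) smooths the geometric-mean image;
the whole-body mask is the largest connected component above a contour
level, holes filled, and is transposed onto the *unfiltered* image for all
downstream steps.  Two numerical choices matter:

* **Cutoff units.** `lowpass_filter` takes the cutoff in cycles/pixel
  (0.5 = Nyquist; default 0.03, appropriate for the ~2.4 mm pixels of
  clinical whole-body scans).  The pipeline's body-contour step converts a
  *physical* cutoff of 0.125 cycles/cm to cycles/pixel via the image pixel
  size, so the amount of physical smoothing does not depend on how coarsely
  an image is sampled.  At the phantom's 1 cm pixels a fixed 0.03
  cycles/pixel would blur four times too much and push the contour ~2 px
  outside the body, biasing the low-compartment thickness by ~−15%.
* **Contour level.** Default is half the body-plateau estimate (median of
  filtered values above 2% of the maximum): the blur turns the body edge
  into a smooth ramp that crosses half its interior plateau at the true
  boundary, so this level hugs the body rather than its blur halo.  A plain
  max-fraction level is available via `level_fraction`.
* The filter output keeps its (small) negative ringing by default so the
  image sum is exactly preserved (DC gain 1); `clip_negative=True` floors
  at zero when a non-negative image is required.

### Compartment separation (`nuf_curve`, `compartment_masks`)

For every distinct pixel value `C_thr` from `C_max` down to 0, pixels
≥ `C_thr` inside the body are binarised and connected uptake foci counted
(8-connectivity by default, configurable to 4).  Sweeping distinct values
is exact — the count is constant between consecutive distinct values — and
reduces to the per-integer sweep for integer images; values closer than
`1e-9·C_max` are merged to guard float round-off.  Plotted against
`ThI = (C_max − C_thr)/C_max`, the normalised count nNUF rises gently while
real organs appear and explodes once noise speckle is included.

The chosen threshold is the largest `C_thr` on the **rising flank of the
global NUF maximum** with nNUF ≥ cutoff (default 0.1): walking up in
threshold from the maximum until the curve drops below the cutoff.
Anchoring to the global maximum ignores small secondary humps produced by
counting-noise fragments *inside* the hot organs, which on desk-scale
grids can reach ~0.1 of the maximum and would otherwise truncate the high
mask.  When nNUF crosses the cutoff between two distinct values the higher
threshold is taken (conservative high compartment).  Degenerate cases: a
curve that never reaches the cutoff falls back to `C_thr = C_max`
(single-pixel high compartment, warning); a threshold that captures the
whole body (an image with no high-uptake contrast) degenerates to an empty
high compartment so everything quantifies through the low path.

### Calibration and quantification (`quantify`)

`μ_eff` and the sensitivity come from a bounded nonlinear least-squares fit
of `rate = C_sens·A·exp(−μ_eff·d)` to a counts-versus-depth series
(log-linear initialisation; exact on noise-free data).  Compartment
activities use the conjugate-view formula with the source self-attenuation
factor `f(x) = sinh(μ_eff·x/2)/(μ_eff·x/2)` (the canonical form; `f ≥ 1`,
thin-source limit 1).  No scatter correction; counts outside the body are
ignored, not subtracted.

The activity of low-uptake tissue lying under and over the organ slab is
estimated per time point as `conc_low · (T_high − x_high) · area_high`
(concentration from the pre-transfer low estimate, one pass) and moved from
the high to the low series; the transfer is zero-sum and capped at the raw
high estimate.  Performing the reassignment on activities per time point
and then integrating is equivalent to reassigning pre-integrated activities
because integration is linear.  Compartment geometry (areas, masses,
thicknesses) is fixed from the masks at the acquisition nearest 24 h (the
best-statistics late time point); per-time-point mask areas feed the count
sums and the transfer.

### Kinetics (`kinetics`)

Low compartment: bi-exponential at four points, mono-exponential at three,
extrapolated to injection time and integrated analytically to infinity
(`Ã = Σ Aᵢ/λᵢ`).  High compartment: a two-point line through the earliest
(≤ 4 h) point and the point nearest 24 h, clipped at zero if the
extrapolation to t = 0 goes negative, plus a mono-exponential through the
points from 24 h on; `Ã = ∫₀²⁴ line dt + A(24)/λ`.  A rising line flags an
initial uptake phase.

Fits are bounded nonlinear least squares initialised by curve peeling.
Because four points determine the bi-exponential exactly, counting noise in
the single early point can interpolate a non-physiological fast phase whose
extrapolated area diverges; decay constants are therefore bounded to
effective half-lives ≥ 0.5 h — well below any plasma clearance phase seen
with peptide radioligands, so the bound is inactive for physiological
curves.  A bi-exponential that fails or cannot match the nested
mono-exponential's residual is re-seeded from it and, failing that,
replaced by it with a warning (the fallback never has a larger squared
residual than the model it replaces).

### Dose model (`dosimetry`)

`S(bm←high)` is the mass-weighted mean of the liver/spleen/kidney S values;
`S(bm←low)` the mean of the muscle and bone values; `S(bm←bm)` scales
inversely with the red-marrow mass (charged particles absorbed locally).
Red-marrow mass defaults to `1.17 kg · weight/73.7 kg` (reference-adult
scaling).  The marrow/low concentration ratio is a cohort constant, default
1.8, with per-patient override.  `Ã_low` enters the cross-dose term as
quantified, i.e. it geometrically contains the marrow — a small, documented
double counting inherent to the two-compartment formulation.

The shipped S-value table (`src/marrowdose/data/svalues.json`) holds
plausible <sup>177</sup>Lu magnitudes constructed from energy-per-decay
reasoning (β ≈ 147 keV/decay absorbed locally; photons ≈ 35 keV/decay with
small absorbed fractions).  It is flagged `synthetic-plausible defaults` in
its provenance field and is a configurable input, **not** reference
dosimetry data.  Because the phantom truth and the estimator use the same
table, end-to-end recovery tests are insensitive to its absolute values.

The partial-volume recovery coefficient is the fraction of emissions from a
uniformly active box VOI imaged inside it after isotropic Gaussian blurring
(FWHM of the imaging system), estimated by Monte-Carlo sampling with common
random numbers per seed (hence exactly monotone in the FWHM for a fixed
seed).  This point-spread-function model replaces photon-transport
simulation of the reconstruction chain; it captures resolution loss but not
scatter or reconstruction artefacts.

### Toxicity statistics (`haemtox`)

The endpoint per analyte is the decrease from the pre-treatment baseline to
the global in-treatment nadir (negative when counts never drop, returned
unclipped).  Association with dose: Pearson `r`, two-sided `p` from the
t-transform with n−2 df, OLS slope/intercept, and the regression-ANOVA `F`
(= t² of the slope for simple regression; reported as `inf` and flagged
when the fit is numerically perfect, `1 − r² < 1e-12`).  No
multiple-testing correction.

## The synthetic phantom: what it emulates and what it does not

The phantom is 2.5-D — a 2-D activity layout plus per-pixel thickness —
because the planar method only ever sees conjugate projections.  Defaults
define the study conditions: a 72 kg elliptical body (≈4000 cm², 18 cm
uniform thickness), four equal-concentration organ foci (liver, spleen,
two kidneys; ≈6% of body area; 8 cm slabs) holding 3000 MBq at t = 0 with a
69 h terminal half-life, and a 4400 MBq low compartment clearing with
2.4 h/61 h effective half-lives — 7400 MBq injected, ≈63% of the
time-integrated activity in the high compartment.  `μ_eff = 0.11 cm⁻¹` and
`C_sens = 10 cps/MBq` are plausible 208-keV medium-energy-collimator
values; both are configuration knobs.  Acquisitions at 2/24/48/168 h, 600 s
each; Poisson noise on integer counts per pixel per acquisition (the only
noise source modelled — real cameras add scatter, septal penetration and
dead time).  Physical decay of <sup>177</sup>Lu (6.647 d) is folded into
the effective decay constants.

Each pixel column is a set of mid-depth slabs, so every component projects
as `A·C_sens·exp(−μ_eff·T/2)·f(x)` per view and the phantom is
depth-symmetric (geometric mean = anterior).  Consequences worth knowing:

* The forward model matches the quantification assumptions by
  construction.  Passing round-trip tests therefore demonstrates internal
  consistency of the chain, **not** accuracy on real bodies, where depth
  asymmetry, non-uniform thickness and scatter break the assumptions.
* One approximation of the method itself remains visible: spreading all
  low-uptake mass over the low area makes `t_low` slightly larger than the
  true body thickness, biasing the low activity by ≈ +3% at the default
  geometry.  This is inherent to the uniform-slab bookkeeping, not a bug.
* Foci have equal activity concentration by default, so the noise-free
  threshold sweep selects all organs at exactly one value; unequal
  concentrations are supported and behave like real images once noise is
  present.

The synthetic cohort draws per-fraction doses uniformly (default
0.1–0.4 Gy) and signed nadir changes as `slope·dose + N(0, σ)` per analyte,
with the blood series constructed so the nadir reproduces the drawn change
exactly.  At the default noise (set for r ≈ −0.4) the single-cohort
(n = 200) slope standard error is ≈16% of the true slope, so recovery is
measured as the median over several seeded cohorts.

## Problem sizes and determinism

Default grids are 180×44 px at 1 cm pixels (≈4000 body pixels), chosen so a
full study — simulation, four threshold sweeps, quantification, fits, dose
— runs in about a second and repeated-seed experiments (50–100 replicates)
in well under a minute.  All stochastic outputs are bit-reproducible under
a fixed seed; the segmentation/quantification chain itself is
deterministic.  Truth time-integrated activities are closed-form integrals
of the generating kinetics and match adaptive quadrature to < 0.1%.

## Known limitations

* Planar two-compartment bookkeeping: organ overlap, depth asymmetry and
  patient-specific attenuation maps are out of scope.
* The recovery model is a Gaussian PSF on a box VOI; no scatter,
  reconstruction or CT-registration effects.
* The marrow/low concentration ratio is a cohort constant; patients with
  extensive bone involvement would violate it.
* S values and red-marrow mass are configurable defaults, not validated
  reference data; absolute doses from the defaults are illustrative.
* The dose–toxicity module quantifies association (Pearson/OLS), not
  causal or multivariable models (age, renal function, prior chemotherapy
  are not modelled).
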