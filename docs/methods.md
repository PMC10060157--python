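# Methods

This note records the models implemented in `trxmap`, the conventions and
defaults chosen where the underlying methods admit more than one reading,
and what the synthetic study conditions do and do not establish.

## Synthetic two-state crystals

The generator (`trxmap.synthetic`) emulates the statistical structure of a
pump-probe crystallography dataset rather than any particular protein:

- **Contents.**  A toy cell (default orthogonal P1, 24 × 26 × 22 Å) with
  8–15 point atoms (default 12, cycling C/N/O, B = 10 Å²).  The light state
  equals the dark state except that a random subset of atoms (default 3)
  is displaced by vectors of exactly `displacement` Å (default 1.1 Å —
  large enough to be resolved at the 1.8 Å resolution limit, small enough
  that vacated and new sites interact in the maps, as real photoproduct
  shifts do).
- **Structure factors.**  Textbook direct summation
  `F(h) = Σ_j occ_j f_j exp(−B_j s²/4) exp(2πi h·x_j)` with point-atom
  scattering factors f = Z.  Angular form-factor falloff is deliberately
  omitted: the downstream algebra is linear in the coefficients, so the
  Cromer–Mann shape adds cost without changing what the tests probe.  P2₁
  is supported by expanding the cell contents over the screw operator and
  excluding the (0, k, 0), k odd absences; all shipped fixtures are P1
  because the source study does not state its space group.
- **Mixing.**  A crystal with light fraction α scatters coherently:
  `F_mix = (1−α) F_dark + α F_light`.  This is the regime the linear
  extrapolation formula presumes, so the recovery tests validate the
  approximation rather than assuming it.
- **Disorder and noise.**  The two-domain LTD modulation `I·G(h)` and
  Gaussian intensity noise `σ_I = f·I + floor` (seeded, reproducible;
  negative noisy intensities are retained for the amplitude-conversion
  stage).  Default noise in the acceptance conditions is 5% where a noisy
  condition is specified, 0 otherwise.

What the toy does *not* emulate: per-pattern partiality and merging
statistics (the package starts from merged data), solvent, bulk-solvent
scaling, anisotropy, radiation damage, and realistic completeness.
Parameter recovery on these fixtures therefore demonstrates correctness of
the algebra and the estimators under controlled conditions, not performance
on deposited experimental data, whose activation levels and κ cannot be
reproduced at this scale.

## Reflection and map conventions

- Reflections are stored Friedel-unique; synthesis expands over the space
  group and Friedel before an FFT on a grid chosen so the spacing is at
  most d_min/3 (finer than the common d_min/2 so that 1.5 Å integration
  spheres at d_min = 1.8 Å contain ≈ 30+ voxels; integrals are then stable
  to < 10% under halving the spacing).
- F(000) is always zero, so maps are zero-mean; the map σ is the rms
  density over the whole cell after mean removal, and all contour/threshold
  arithmetic is in these σ units.
- Sphere integration counts a voxel when its *center* lies within the
  radius (periodic minimum-image), with no partial-volume weighting —
  exactly reproducible and testable against a brute-force loop.  Results
  are reported in σ·Å³ (value/σ × voxel volume); whether the original
  analysis multiplied by voxel volume is not documented, so the convention
  is fixed here.  For cross-map comparisons (the fluence-response curve)
  integrals default to absolute map-units·Å³ instead, because the rms σ of
  a noise-free difference map itself grows with excitation and a per-map σ
  scale would cancel the very response being measured.
- French–Wilson conversion integrates the exact posterior numerically (in
  u = √J, which also absorbs the centric prior's singularity) under a
  Wilson prior with Σ estimated per resolution shell; shells with fewer
  than 10 reflections fall back to √max(I,0) with a warning.  Centric
  reflections (P2₁ h0l zone) use the centric prior.
- Relative scaling fits a single (k, B) by least squares on common
  reflections, initialized log-linearly.  Per-shell scaling is not
  implemented; the difference-map stage documents this as its reading of
  "multiscaling".

## LTD detection and correction

- The Patterson used for detection and for the κ scan is *origin-removed*
  (per-shell mean subtracted from the coefficients), which suppresses the
  origin peak and its series-termination ripple while leaving the
  translation peak — the same practice as standard intensity-statistics
  tools.  The reported peak height is in map σ; the local background is the
  median |density| in a 2–4 Å shell around the peak.
- "Flattened" is formalized as the signed residual at **t** (density at the
  nearest grid point minus shell background); the scan over κ = 0…0.5 in
  0.01 steps returns the argmin of its magnitude, ties toward smaller κ.
  On few-atom toys the global off-origin Patterson maximum of LTD-free data
  is a genuine interatomic vector (≈ 10σ), so the negative control is
  evaluated at the candidate vector, where LTD-free flatness is < 1σ; in a
  protein-sized structure interatomic peaks are at noise level and the
  global-maximum and at-vector readings coincide.
- Correction divides by `max(G(h), clamp)` with clamp = 0.05.  The floor
  only matters as κ → 0.5 where G → 0 for half-integral projections;
  clamped records are flagged and excluded from difference maps.  σ_I
  scales by the same deterministic factor.

## Difference maps and extrapolation

- The amplitude cut is read as |F|/σF < 3 *in either input set* (the common
  interpretation of excluding amplitudes smaller than 3σ); the resolution
  window is 9–1.8 Å.  Every rejected record carries exactly one primary
  reason (resolution, sigma-cut, ltd-clamp, missing-mate/phase), and
  used + rejected always equals the number of common indices.
- Extrapolated-map coefficients are `(2F_extra − F_calc, φ_dark)`.
  Negative `F_extra` from the linear formula (inevitable at small A) is
  clamped to zero and flagged; the count of clamped records is a
  diagnostic, not an error.
- Negative density is integrated over the *union* of reporter spheres
  (each voxel once), radius 1.5 Å, cut-off 1.5σ; no shell-background
  subtraction is applied because none is documented for the original
  script.  Reporter centers default to the positions showing negative
  difference density (for the toys, the dark positions of the displaced
  atoms); positive-density integration uses the light-state positions.
- The breakpoint is exactly two ordinary-least-squares lines over an
  exhaustive interior split search (≥ 3 points per side), A* their
  intersection.  The split must have the steeper (more negative) slope on
  the left — the orientation of an activation elbow; without this
  constraint a clamping-induced plateau at small A can masquerade as the
  elbow.  Degenerate scans are explicit: a flat curve returns the split
  abscissa flagged `near_parallel`; a curve still declining at the top of
  the grid returns the grid edge flagged `clamped` (the elbow lies at or
  beyond it, as when the true occupancy sits at the edge of the scanned
  range).  Scans for different datasets share no state.
- On the default noise-free fixtures the recovered A* tracks 100·α within
  ≈ 2–3 percent-points across α = 0.15–0.30, with a small systematic
  underestimate caused by the curvature of the rising branch (the 1/A
  amplification makes it convex) pulling the left line's chord down.  The
  1.5σ threshold also delays the apparent onset slightly.  Both effects are
  properties of the estimator itself, not of the implementation.

## Dosimetry

Constants are CODATA (via `scipy.constants`); 1 kcal = 4184 J.  A Gaussian
beam of 1/e² radius w has peak fluence `2E/(πw²)`; exactly half the pulse
energy falls inside the FWHM disc, giving the FWHM-averaged fluence
`(E/2)/(π(FWHM/2)²)`; FWHM = w·√(2 ln 2).  The cross-section is
`σ = 1000·ln10·ε/N_A` (cm²) and the excitation upper bound `σF/hν`.  The
heating estimate `ΔT·C_P/(c·N_A·hν)` converts the molar concentration to
mol cm⁻³ so a volumetric heat capacity (J cm⁻³ K⁻¹) applies directly;
`concentration_rescale` moves an estimate between sample concentrations
inverse-linearly.  Published two-significant-figure values are reproduced
to ±5%, the slack implied by the quoted 47–50 µm beam-width range.

SVD heating uses the first left-singular vector as the heating basis (sign
fixed so its mean is positive), projection amplitudes per measurement,
piecewise-linear calibration interpolation (with linear extension and a
flag outside the calibrated span), and a through-origin straight-line fit
of ΔT versus fluence.  Only the mechanism is reproduced; the calibration
curves themselves are instrument-specific inputs.

## Problem sizes

The standard fixture (12 atoms, d_min 1.8 Å, ≈ 4 900 unique reflections,
48³-ish grids) keeps a full κ scan at ≈ 2 s and a full 41-point activation
scan at ≈ 6 s on one core, so the entire test suite and the acceptance
script each run in a couple of minutes.  These sizes were chosen as the
smallest at which the Patterson and difference-density features are
comfortably above discretization effects.

## Known limitations

- Single (k, B) scaling only; no anisotropic or per-shell scaling.
- Space groups beyond P1/P2₁, twin laws beyond the two-domain translation
  model, and three-or-more-domain translocation are out of scope.
- No q-weighting of difference amplitudes and no refinement against
  extrapolated data.
- The activation estimator inherits the documented small-A bias of the
  two-line method; it is reported as-is rather than corrected.
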