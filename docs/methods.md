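# Methods

This note documents the models, numerical choices and known limitations of
`shiftqa`. It is the design record of the simulation; every number quoted as
an observation here is computed by the test suite or the worked example, not
asserted from elsewhere.

## Coordinate frame and dose model

All modules share one frame: millimetres, origin at the isocenter, axis 0 =
superior–inferior (SI, positive superior), axis 1 = right–left (RL, positive
right). The reference ("TPS") distribution is a dense 2D map on a regular
grid, 1 mm pitch by default, interpolated bilinearly with no extrapolation.
The coronal detector plane is treated as the plan's evaluation plane; no
depth or heterogeneity modelling is attempted.

The field model is an error-function flat-top,

    D(r) = b·Dmax + (1−b)·Dmax·Φ((R − r)/σ),

with target radius `R` (default 5 mm — a 1 cm lesion), penumbra parameter
`σ` (default 2 mm) and uniform background `b` (default 1% of Dmax). The erf
edge was chosen because small-field 6 MV FFF penumbrae are a few millimetres
wide and the model puts the 50% level analytically at `r = R`, which makes
field size and penumbra position exactly checkable. σ = 2 mm corresponds to
an 80–20 penumbra of ≈3.4 mm. The 1% background keeps out-of-field doses
below the 10% gamma threshold, so threshold behaviour matches clinical
array-QA practice. The SIMT scenario is the pointwise sum of two such fields
at SI = ±60 mm (a typical bilateral brain-metastasis separation given adult
head size); sums are not renormalised, and targets closer than
`diameter + 6σ` set an `overlap_warning` flag instead of failing.

Dose units are nominally percent-of-maximum; the unit tag is metadata only,
and both metrics renormalise to percent of the reference global maximum, so
they are invariant under common rescaling (tested).

## Detector model

The array is a rectangular 10 mm lattice (21 × 21 diodes, isocenter diode at
the origin). The true diagonal diode pattern of commercial arrays is
simplified to the rectangular lattice of the nominal pitch. Each diode
averages the dose uniformly over a rectangular active footprint, default
7 × 3 mm² elongated along SI — the diode-unit geometry invoked to explain
couch-direction effects — by midpoint quadrature at ≤0.5 mm step (≤0.2% of
Dmax from a 0.05 mm brute-force average on the default field; tested).
Footprint (0, 0) is a point detector. "Film" mode is a 1 mm-pitch point
lattice.

Noise is multiplicative Gaussian, dose × (1 + ε), ε ~ N(0, 0.5%) by default,
seeded and reproducible. Published repeat measurements imply run-to-run
variation but no noise model or magnitude; 0.5% is a stand-in of the right
order for diode arrays and is configurable everywhere it appears. A couch
shift displaces the detector by +d in the beam frame, so the diode nominally
at x samples the field at x + d; this single sign convention is used by the
sampler and the merger and is pinned by a shift-equivariance test.

## Virtual spacing

A schedule for target spacing `t` on native pitch `p` uses offsets
`{k·t : k·t < p}` along one axis, first offset always 0 (the isocenter
acquisition). For divisors of the pitch (5, 2, 1 mm on 10 mm) the merged
lattice is exactly uniform, and merging noiseless point-detector
acquisitions is bit-identical to direct sampling at the fine pitch (tested).
For 4 and 3 mm — which do not divide 10 — the realised along-axis pattern is
periodic but non-uniform (4,4,2 and 3,3,3,1), exactly as couch shifts in
1 mm increments produce them in practice; schedules carry a `uniform` flag.
Merging is a union with coincidence averaging at 0.01 mm tolerance
(averaging rather than rejection keeps noisy repeats at offset 0 usable) and
is order-invariant. No registration is attempted: alignment comes from the
commanded couch coordinates alone.

## Profile RMSE

RMSE is evaluated on the central SI axis (which, in the SIMT scenario, runs
through both target centres). The sparse measured samples on the line are
linearly interpolated onto the reference grid nodes between the first and
last sample (clipped to a ±100 mm analysis window in the experiment), and

    RMSE(%) = sqrt( (1/n) Σᵢ (D_ref,i − D_meas,i)² )

is taken over those common positions, both doses in percent of the reference
maximum. Comparing *shapes* on the common fine grid is the point: a coarse
array that misses the penumbra entirely is penalised for the straight
segment it would draw across it, which is what makes the native 10 mm pitch
score several times worse than the fine virtual spacings. Pairing only at
the measured positions (available as `resample="measured"`) cannot see that
error — a 10 mm lattice aligned to a centred target samples only the flat
top and the field periphery, where agreement is good — and would invert the
spacing ordering. The sum runs over all n pairs; a `drop_last` flag
reproduces the n−1 upper summation limit that sometimes appears in print.

## Gamma analysis

For each measured point with dose ≥ threshold (percent of the reference
global maximum; default 10%),

    γ = min over r of sqrt( |r − rᵢ|²/dta² + (D_ref(r) − Dᵢ)²/ΔD² ),

searched over a disc of radius 3×dta on a reference sub-grid of step
min(dta/10, 0.1) mm (configurable down to 0.05 mm), clipped to the grid
extent. ΔD anchors to the global maximum by default — the convention of
common array-QA software — with a "local" option; neither is claimed to
match any specific vendor implementation. The production search is
vectorised; the test suite checks it against an independent exhaustive
0.05 mm brute-force search (RegularGridInterpolator route) to 10⁻³ on 50
random smooth grids at all four clinical tolerances (3%/3, 3%/2, 2%/2,
3%/1 mm). Thresholding applies to the *measured* dose, matching the visible
point selection of threshold-filtered array analyses. Limit behaviour is
pinned by tests: enormous dta reduces γ to the best dose match in the search
region; a vanishing dose tolerance forces the search to the exact-agreement
position (distance-to-agreement). Note the min-formulation has no
non-trivial `dose_diff → ∞` limit — the minimiser then collapses onto the
evaluated point and γ → 0.

## The experiment

Per replicate, the experiment performs one series of shifted acquisitions at
every needed offset (0–9 mm in 1 mm steps for the full spacing list) and
re-uses them across spacings, as the physical procedure does; the film
stand-in is acquired once per replicate. Seeds derive from the master seed
via `numpy.random.SeedSequence.spawn`, one child per acquisition, so the
full report is byte-reproducible and replicates never share noise. Every
(spacing × tolerance × replicate) cell appears in the tidy results table,
as a value or as an explicit error row.

Default problem sizes — 241×241 reference nodes, 21×21 diodes, three
replicates, six spacings, four tolerances — run the whole two-scenario study
in well under a minute on one core.

## What the simulation does and does not show

The synthetic study reproduces the qualitative physics of the method:

- RMSE falls monotonically as the virtual spacing refines from 10 mm to
  1 mm, because the merged lattice progressively samples the penumbra.
- The film stand-in is always at least as good as the array, and the finest
  virtual spacing does not reach it: the diode footprint sets a
  partial-volume floor.
- The 7 × 3 mm² footprint measurably attenuates an SI gradient more than an
  RL one (module-level test), and SI- vs RL-synthesized datasets receive
  different per-point γ values at the field edge.

Two quantitative behaviours of real measurements are *not* reproduced under
these study conditions, and the corresponding acceptance-level tests are
deliberately left failing rather than tuned:

1. **Size of the 10 mm → 1 mm RMSE gain.** With a uniform 7 × 3 mm² active
   area the 1 mm virtual RMSE floor is ≈2.5%, giving a ≈1.7× improvement
   over 10 mm rather than the several-fold gain real arrays show. Real
   diodes have sub-millimetre active areas inside the 7 × 3 mm² unit
   housing; modelling the housing as the active area overstates blur at
   fine spacing. The ratio is invariant to the profile window (both error
   sums live in the same in-field region), so no analysis choice changes it.
2. **Direction-dependent γ pass rates.** With a centred target on the
   aligned lattice, the supra-threshold 5 mm virtual datasets contain only
   the flat-top point (which fails 3%/1 mm identically in both directions)
   and edge points whose blur-induced sub-millimetre shifts are absorbed by
   even a 1 mm DTA. The per-point γ values differ by direction (the
   mechanism is present); the pass *rates* do not.

Real measurements also contain couch-positioning error (available as a
seeded `shift_error_sd` perturbation of the executed shift, default off,
with the recorded coordinates keeping the commanded value), angular/energy
response, array calibration drift and setup misalignment, the latter three
unmodelled; passing tests therefore validate the algorithmic chain and its
stated physics, not clinical detector behaviour.
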