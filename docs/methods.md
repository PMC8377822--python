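# Methods

## Data model and geometry

Velocity fields are stored as `(phase, z, y, x, component)` arrays in m/s
with voxel spacing in mm and per-phase trigger times in ms.  All landmarks,
cutting planes and particle positions live in physical millimetre
coordinates derived from the NIfTI affine; only axis-aligned (near-diagonal
affine) grids are supported — oblique acquisitions must be resampled
upstream, since the finite-difference operators assume an orthogonal grid.
Internal computation is SI throughout; the reporting layer converts to the
conventional clinical units (normalized vorticity 1/s, absolute vorticity
L/s, region volume mL, power mW).

## Preprocessing

**Background-phase correction.**  Eddy currents leave a spatially smooth,
temporally static offset on each velocity component.  A polynomial of total
degree 1–3 (default 1) is least-squares fit to the *time-averaged* velocity
over voxels marked as static tissue and subtracted from every phase.
Fitting the temporal mean rather than each phase is the standard
stationary-tissue approach: the offset is static while genuine flow
averages toward zero over the cycle.  The fit uses centred, scaled
monomials for conditioning; rank deficiency (too few or degenerately
arranged static voxels) is an error.  The operation is idempotent to
1e-10 m/s.  Static tissue is an explicit input label; an automatic
fallback (lowest-decile temporal speed SD outside the RV) exists but is
off by default because an explicit mask is more reproducible.

**Noise screening.**  A voxel is removed from every region when the
temporal standard deviation of its speed exceeds `sd_fraction x venc`
(default 0.3): random phase noise makes speed fluctuate across the cycle
far more than physiological flow does.  Removal applies to all phases (the
mask is static); emptying a region is an error, not a silent result.
Screening is monotone (a smaller threshold removes a superset) and never
adds voxels.

**venc handling.**  Samples beyond the encoding limit are flagged and
clipped once, after background correction; aliased velocities are not
unwrapped (out of scope).

## Regional division

Two planes computed once from end-diastolic landmarks and held static over
the cycle: cut 1 through the tricuspid antero-septal commissure with the
4-chamber-plane normal (the side containing the pulmonary-valve centroid
becomes RVOT), cut 2 through the midpoint of the tricuspid-centroid-to-apex
axis with the axis as normal (tricuspid side becomes inflow, the rest
apex).  Voxel membership is decided by the voxel-centre position — the
simplest consistent rule, with error bounded by a one-voxel shell at each
plane.  Centres lying exactly on a plane are assigned deterministically
(RVOT for cut 1, inflow for cut 2).  The three regions always partition the
input RV voxel set; an empty region is an error.

## Flow operators

Spatial derivatives use central differences on voxels whose 6-neighbours
lie inside the mask and first-order one-sided differences where one
neighbour leaves it, so zero-filled out-of-domain voxels never contaminate
a gradient; a mask voxel with no in-mask neighbour along a needed axis is
an error.  Central differencing is exact for affine fields, which makes the
rigid-rotation check (curl = 2Ω) exact even at the mask boundary.  For the
dissipation integral the sum runs over all nine ordered index pairs, so a
Poiseuille tube yields the closed form 2πμU²L; at 1 mm voxels the grid
value is within 2.6% (boundary stencils are the first-order error source)
and halving the voxel size reduces the error about tenfold.  Per-region
integrals are voxel-centre sums times voxel volume; normalized vorticity
equals the volume-weighted mean of ‖ω‖ and is intensive by construction.
Blood viscosity defaults to μ = 0.004 Pa·s (config-exposed).

Gradients for the region time series are evaluated once per phase on the
union of all labelled voxels, so boundaries *between* regions keep their
central stencils; only the RV surface uses one-sided stencils.

## Phase windows and peaks

Explicit systole/diastole phase ranges in the acquisition metadata win.
Otherwise windows are auto-detected from the sign of the mean RVOT velocity
along the outflow axis (cut-1 normal oriented toward the pulmonary valve):
systole is the longest contiguous forward-flow run, diastole the longest
run of the complement.  Peaks are per-window maxima of the discrete series
with no temporal smoothing by default (an odd moving-average width is
available but off, since the upstream definition is simply the peak
value).  Quotients are formed from these peaks and their defining ratios
are asserted to 1e-12 on every construction; a zero denominator peak is an
error naming the quotient.

## Particle advection

Pathlines use classic fourth-order Runge–Kutta in time with trilinear
spatial and linear temporal interpolation, periodic over the cardiac cycle.
Positions are mm and time ms, so 1 m/s = 1 mm/ms and no unit factor enters
the update.  Particles whose nearest voxel leaves the mask are frozen and
flagged.  A particle in a rigid rotation conserves its radius to better
than 0.1% per revolution at 400 steps/cycle.

## Synthetic phantoms

**Analytic flows** (uniform, rigid rotation, Poiseuille, Lamb–Oseen, ring
vortex) provide closed-form vorticity and dissipation for operator
verification; they are time-constant fields replicated across phases.

**RV phantom.**  An ellipsoidal RV body (long axis along z, semi-axes
20×20×28 mm) with an oblique tubular outflow tract (radius 9 mm) rising to
a pulmonary-valve marker, on a 48×32×32 grid at 2 mm — volumes and voxel
counts comparable to a clinical short-axis stack.  Defaults: 20 phases,
RR 800 ms, venc 2.5 m/s.  Systole carries a forward Gaussian-profile
outflow jet (peak 1.0 m/s); diastole carries (i) a toroidal ring vortex
around the tricuspid inflow (Lamb–Oseen cross-section swept around an
11 mm circle, core 4.5 mm, peak swirl 0.8 m/s) and (ii) a regurgitant
swirling jet down the outflow tract whose amplitude scales with the
severity parameter `s` ∈ [0, 1].  The inflow vortex is attenuated by
(1 − 0.5·s), encoding disruption of the inflow vortex by the regurgitant
jet; the 0.5 coupling is a design constant, not a physiological estimate.
Optional iid Gaussian velocity noise (SD as a fraction of venc) and a
smooth static background offset emulate acquisition artifacts; a static
tissue slab supports background correction.  Temporal envelopes are
half-sines over each window.  One-voxel spurs on the discretized surface
are pruned so every mask voxel supports a stencil.  Geometry constants were
fixed at design time so the construction realizes its defining behaviour:
RV-DVQ < 1 without regurgitation, > 1 at full severity, strictly monotone
between.

What the phantom does *not* emulate: chamber-wall motion (regions and mask
are static), through-plane valve dynamics, realistic chamber pressure
coupling, turbulence, and CFD-grade velocity profiles.  Passing tests
demonstrate that the measurement chain recovers programmed flow structure,
not that clinical effect sizes are reproduced.

**Cohorts.**  Subjects are drawn per group (defaults 20/18/20 severe/
moderate/mild regurgitation, 28 RV dilation, 12 controls) with severity
bands mapped exactly onto the regurgitant fraction (PR% = 60·s, so the
40%/20% severity cut-points sit at s = 2/3 and 1/3).  Covariates (RVEDVI,
RVESVI, RVEF, QRS, VO₂-max, % predicted) and flow metrics follow linear
response curves in s with Gaussian noise; magnitudes were chosen to
resemble a mixed congenital cohort, and the RV-dilation group carries a
shunt-driven volume offset at near-zero regurgitant fraction so that its
RV-DVQ stays normal despite dilation.  Quotients are computed from the
generated peaks so the defining ratios hold by row.  A target-correlation
mode back-solves the noise SD from the empirical spread of s to program a
population Pearson r for a chosen column.  Exercise covariates are present
for roughly half of the repaired patients and missing elsewhere,
exercising complete-case handling.  "Full" mode instead runs every
subject's phantom through the measurement pipeline (slow; meant for small
n).

## Statistics

One-way ANOVA (classic F on k−1, N−k df) across the five groups and
two-sided Pearson correlations with complete-case n per pair; correlation
tables render p ≥ 0.05 as "ns".  No multiple-testing correction by default
(each cell judged at p < 0.05); Benjamini–Hochberg is available but off.
Only the omnibus F is computed — pairwise group claims are reported
descriptively by rank of means, since no post-hoc procedure is part of the
analysis.  Degenerate ANOVA inputs (zero within-group variance with
unequal means) report F = ∞, p = 0 with a flag.

## Numerical choices and problem sizes

The validation suite uses a ~10 mL sphere at 1 mm voxels for rotation
checks, a 10 mm × 50 mm Poiseuille tube at 1 and 0.5 mm for the dissipation
closed form, and severity sweeps over five noise-free phantoms at the
default grid; statistical recovery uses 500 simulated samples at n = 36 and
100 random two-group datasets for the F = t² identity.  These sizes were
chosen so each check isolates one property at comfortable desk scale.

## Known limitations

- **Noise bias of magnitude integrals.**  ∫‖ω‖ dV is a magnitude integral,
  so velocity noise enters in quadrature rather than averaging out: iid
  noise of SD σ_v adds a vorticity floor ~σ_v/h (h the voxel size) that
  inflates weak-signal terms most.  At the default 2 mm grid the quotients
  shift by <10% for noise SD up to ~1% of venc, but by 15–40% at 2–5%
  (measured on the mid-severity phantom; RVOT-VQ and RVOT-EQ are the most
  sensitive because their systolic denominators are signal-rich).
  Comparisons across subjects therefore assume comparable noise levels, as
  they do for the clinical metric.
- First-order accuracy at mask boundaries dominates grid error; thin
  structures (< 3 voxels) are at the scheme's limit.
- Static planes and masks ignore cardiac motion; region membership near
  the planes is uncertain by one voxel shell.
- The phantom severity coupling is a single linear dial; real regurgitant
  jets vary in direction, timing and core size.
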