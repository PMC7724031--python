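# Methods

`lvflow` implements pathline-based decomposition of the left-ventricular (LV)
end-diastolic blood volume into four functional flow components, with
per-component kinetic-energy (KE) quantification and a paired rest-vs-stress
study design, validated against a synthetic LV velocity phantom whose ground
truth is exact by construction.

## The flow-component model

A 4D-flow acquisition provides a velocity field **v**(**x**, t) over one
cardiac cycle (three-directional velocity per voxel per timeframe), plus
binary LV blood-pool segmentations at end-diastole (ED) and end-systole (ES).
One pathline is emitted from the centre of every voxel of the end-diastolic
volume (EDV) at the ED time and integrated forward to the following ES and
backward to the preceding ES, so both legs together cover the whole cycle.
Each pathline represents a blood parcel of one voxel volume; the traced
parcels therefore partition the EDV exactly.

Two booleans decide the component of each parcel:

* *ejected in systole* — the forward endpoint lies outside the ES blood pool;
* *entered in diastole* — the backward endpoint lies outside the (preceding)
  ES blood pool.

| entered | ejected | component |
|---|---|---|
| yes | yes | Direct flow (DF) |
| yes | no | Retained inflow (RI) |
| no | yes | Delayed ejection flow (DEF) |
| no | no | Residual volume (RV) |

Endpoint membership is a nearest-voxel lookup (half-up rounding per axis);
masks are binary, so fractional membership would manufacture precision the
data lack.  An endpoint that left the imaged volume counts as outside the ES
pool — the physical case of blood that exited through the aorta — and is
tallied in the QC counters.  Because both reference regions belong to the
same (periodic) cycle, the backward-trace reference is the same-cycle ES pool
reached by periodic wrap.

Kinetic energy per parcel is KE(t) = ½ ρ V |**v**(t)|² with blood density
ρ = 1060 kg/m³, V the parcel (voxel) volume, and **v** the interpolated
velocity stored along the trace (so trajectory and energy always agree).
Reported units are µJ and µJ/mL; the headline summary is KE/mL at the exact
ED time per component.

## Pathline integration

Classical fixed-step RK4 (Euler available for cross-scheme checks) with
trilinear spatial and linear temporal interpolation, periodic in time.
Positions are kept in mm and time in ms so that velocities in m/s need no
conversion factor (1 m/s = 1 mm/ms).  The step is dt/substeps_per_frame
(default 8 substeps), so integration steps align with frame boundaries and
never straddle a temporal interpolation kink.  Out-of-field parcels are
frozen at their last in-field position and flagged (volume-conserving);
`drop` blanks the remainder of the trajectory instead.  Backward tracing
integrates with a negative step — mathematically the time-reversed field —
rather than duplicating data.

On fields that are linear in space (uniform translation, rigid rotation,
radial expansion) trilinear interpolation is exact, so integrator error is
attributable to the time stepper alone; these benchmark fields carry their
closed-form solutions and anchor the integrator tests (endpoint error
< 0.1 voxel over a cycle at default settings; empirical convergence order
above one; forward-then-backward reversibility within 0.25 voxel).

## The synthetic LV phantom

The phantom emulates the study's acquisition geometry: 2.8 mm isotropic
voxels on a 64³ grid, 20 timeframes per cycle (≈ 45 ms temporal resolution
at 66 bpm), VENC 140 cm/s, a prolate-ellipsoidal blood pool (~145 mL at
default scale) with diastolic inflow at one basal end and systolic outflow
at the other, and optional VENC-scaled Gaussian velocity noise.

Construction is flow-map-first: the velocity waveform is spatially uniform
and purely axial, with a systolic ejection bump (sin², zero velocity at ES),
a diastolic filling bump of fixed 300 ms width (an E-wave analogue, so a
shorter diastole puts the early-filling peak relatively later — the stress
signature), and a late-diastolic plateau at 20 % of peak speed so blood is
still moving at ED.  The per-frame waveform samples are rescaled so that the
trapezoid integral of the linearly-interpolated samples — exactly what the
tracer transports — equals a whole number of voxels over systole and over
diastole.  For a spatially uniform field trilinear interpolation is exact
and RK4 reduces to Simpson quadrature of a piecewise-linear function, exact
when substeps align with frames; the prescribed flow map is therefore
realized to machine precision and every EDV voxel's label is exact.

Ground-truth labels are assigned by sorting EDV voxels base-to-apex and
apportioning them to the four components with largest-remainder quotas, so
realized fractions match the targets within one voxel-count quantum.  The
ES reference masks are then constructed as the integer-shifted images of the
non-ejected (forward) and non-entered (backward) voxel sets, which makes the
endpoint classification recover the prescribed labels exactly in the
noiseless case.  Default targets are the rest-like decomposition
(36/20/17/27 % for DF/RI/DEF/RV); the stress-like set is 52/20/13/15 %
(the published means sum to 101 % after rounding; RV absorbs the excess).

`peak_speed_m_s` sets the waveform amplitude; the realized displacement is
rounded to whole voxels (≥ 1) and the waveform rescaled, so the effective
peak speed can differ from the request by up to half a voxel of
displacement per phase.  Defaults are 0.10 m/s at rest and 0.18 m/s under
stress — deliberately slower than physiological jet velocities, because a
*uniform* field moving at jet speed for a whole cardiac phase would
translate the pool out of the imaged volume.  Phantom KE magnitudes are
therefore below the published values and only orderings and rest-to-stress
changes are meaningful on the phantom.

What the phantom does **not** emulate, and hence what passing tests do not
show about real data: spatial velocity heterogeneity (all components share
one speed at each instant, so per-component KE/mL at ED is equal across
components on the default phantom; the DF-vs-RV KE ordering is exercised at
the energetics-operation level with constructed trajectories), wall motion
and pool deformation (masks are shifted voxel sets, not a deforming
anatomy), an A-wave, valve geometry, phase wrap, eddy currents, and gating
artifacts.  The Gaussian noise model (SD = noise_sigma × VENC per component
per voxel per frame) is a generic stand-in with no claim of matching scanner
noise statistics.

## Quality control and volumetrics

Volumes are exact voxel counts times the voxel volume: SV = EDV − ESV,
EF = 100·SV/EDV, CO = SV·HR.  Inflow (DF + RI volumes) and outflow
(DF + DEF volumes) are compared per dataset; a discrepancy
100·|in − out| / max(in, out) above 15 % excludes the dataset from group
statistics.  Inflow/outflow come from the component decomposition itself
rather than valve-plane flux integration, which keeps the check internally
consistent and needs no user-drawn planes.  Segmentation masks drawn on
other grids are resampled to the flow grid by nearest-neighbour sampling at
flow-voxel centres (preserves binarity).  Velocities exceeding VENC are
counted as wrap flags, never unwrapped.

## The synthetic study and statistics

`run_study` emulates the 12-subject two-condition design.  Stress is
represented by its physiological signature — cycle shortened from 909 ms
(66 bpm) to 556 ms (108 bpm), faster flow, a larger DF and smaller RV
target share, a slightly smaller pool — not by modelling dobutamine
pharmacology.  Between-subject dispersion uses the published group SDs
(fractions ±6/3/3/4 pp at rest, ±8/3/3/4 pp under stress; HR ±9/±13 bpm),
split 70/30 between a stable per-subject trait (shared by the subject's two
acquisitions, as in a paired design on the same heart) and an independent
acquisition-level part.  RI and DEF deviations are drawn with correlation
0.8: mass conservation couples them in a periodic heart, and without the
coupling the inflow-outflow QC would exclude an unrealistically large share
of the cohort.  All randomness derives from one master seed.

Velocity noise (default noise_sigma = 0.01, i.e. 1.4 cm/s) perturbs traced
endpoints and flips the labels of voxels near component-block boundaries.
The flips are not perfectly symmetric between conditions (the two waveforms
and reference-mask geometries differ), which leaves a small systematic
component — a few tenths of a percentage point — in the paired differences.
In particular the retained-inflow comparison, a true null under the default
targets (20 % at rest and stress), can reach nominal significance for an
occasional master seed; this mirrors the way registration and segmentation
artifacts perturb component estimates in real data and is left in place
rather than idealized away.

Paired rest-vs-stress comparisons follow the study's plan: a
Kolmogorov–Smirnov normality check on the paired differences (Lilliefors
correction, since mean and SD are estimated from the data; α = 0.05) gates
a paired t-test versus a Wilcoxon signed-rank test (exact null for small
samples).  P-values are per-variable and two-sided with no multiple-testing
correction — faithful to the published analysis, and a known limitation.
Observer agreement uses ICC(2,1) (two-way random effects, absolute
agreement, single measures) from the mean-squares decomposition,
cross-checked against an independent implementation in the tests.

On a mass-balanced (periodic) phantom the RI and DEF fractions must agree —
they are the same blood counted at the two cycle boundaries — and the
pipeline recovers this identity within one voxel quantum.  The rest-like
default targets deliberately carry the published RI≠DEF gap (20 vs 17 %),
which reflects measurement error in the source data, so the identity is
asserted on a balanced-target phantom.

## Numerical choices and degenerate inputs

* Voxel convention: 0-based indices, a voxel's world position is its centre,
  world units mm via the image affine; frame k is at time k·dt.
* Voxel volume uses the product of axis scales for orthogonal affines
  (exact; no determinant drift), the determinant otherwise.
* Velocity interchange is cm/s in NIfTI with a JSON sidecar; internal
  computation is SI.  The NIfTI header stores the affine in float32, so
  affine round trips are exact at that precision; data round trips are exact
  to well below 1e-12 m/s.
* A fully-ejected decomposition (100 % DF) leaves an empty ES reference
  mask; constructed reference masks may be empty, segmented masks may not.
* Zero inflow and outflow define a QC discrepancy of 0 with a warning;
  ESV ≥ EDV is computed but logged as abnormal; an empty flow component is
  reported absent (not zero) in KE summaries.
* Problem sizes in the shipped tests: most unit tests run a 32³ phantom
  (~800 parcels); ground-truth recovery and the study run the full 64³
  default (~6 600 parcels, 12 subjects × 2 conditions).

## Known limitations

Beyond the phantom's idealizations listed above: no valve-plane tracking
(component routes are decided by ES-pool membership only), no sub-component
splits (E- vs A-wave inflow), no phase unwrapping, no divergence-free
correction, no adaptive step size, and no DICOM ingestion.  Statistical
results on the phantom cohort quantify the pipeline, not human physiology.
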