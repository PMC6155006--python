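# Methods

## Scope and shape of the model

`mpcsim` is a forward model plus measurement pipeline. The forward
model couples three layers — geometry, flow, mineral dynamics — under a
quasi-static assumption: mineral growth is orders of magnitude slower
than flow equilibration, so the flow field is re-solved once per time
step against the current lumen geometry. The measurement pipeline
(voxelization, segmentation, zonation) is deliberately independent of
the forward model's internals: it sees only the rendered grayscale
volumes, the way a tomography workstation sees a specimen, and its
outputs are compared against the rendered ground-truth labels.

## Geometry

The envelope uses the linear taper `R(h) = R_o − h·tanθ` (clamped at
zero); a paraboloid profile sharing the base radius and apex is
available behind the `paraboloid` flag for sensitivity work, since the
gross shape of the papilla is often described as paraboloid while the
linear law is the analytically convenient anchor.

The default study scene is a scaled-down complex: `R_o = 600 µm`,
`θ = 8°`, `depth = 1200 µm`. A human MPC is closer to a centimetre; the
scaled scene keeps a full-envelope phantom at the 10X preset (5 µm/voxel)
inside a 256³ grid so the entire loop — simulate, render, quantify — runs
on a workstation. All geometric parameters scale through the config, so
nothing in the code assumes the scaled size. The taper angle is chosen
so the tip retains room for the collecting duct and zone Z4 keeps a
plausible tubule-to-tissue ratio.

Nephrons come in the two classical populations: *short-looped* nephrons
placed in a peripheral annulus (0.60–1.0 of the usable radius, U-bends
at 0.30–0.50 of depth) and *long-looped* nephrons near the axis
(0.28–0.45, clear of the duct column, U-bends at 0.85–0.95). The
anti-correlation between radial position and loop depth is thus built
in and additionally enforced by the envelope, which clips peripheral
columns shallow. Loop clusters (nephron + paired vas rectum) are placed
by dart-throwing with a minimum separation of 55 µm; diameters sit in
the 15–20 µm band (increasing toward the axis), branches at 30–60 µm,
the duct at 175 µm by default. Wall thickness defaults to 10% of lumen
radius. Zone bands default to equal depth quartiles.

Axial tubule runs carry a gentle lateral tortuosity (waypoints every
150 µm displaced by N(0, 3 µm)). This is physiological — real tubules
wander — and also matters numerically: a perfectly straight digital
prism is translation-symmetric, and parallel 3-D thinning algorithms
can erase such an object entirely. The generator therefore never emits
exactly straight tubes.

## Flow

Hagen–Poiseuille conductances `g = πr⁴/(8µL)` per segment; Kirchhoff
balance solved as a sparse linear system in SI units; interface units
are mm Hg, nL/min, µm/s and Pa (1 mm Hg = 133.322 Pa). Defaults:
viscosity 1.0 mPa·s, density 1000 kg/m³ (water-like filtrate).

Boundary conditions: 120 mm Hg at the cortical face, 5 mm Hg at the
papillary-tip outlet, vasa recta at capillary pressures (20/8 mm Hg in
and out), interstitial reference pressure 6 mm Hg. Nephron and vasa
inlets are fed through a *cortical supply conductance* — a Robin-type
boundary term whose radial profile `(1 − (ρ/R_o)²)²` (floored at 0.02)
stands in for the upstream cortex and delivers less flow to peripheral
columns. This is what realizes the lower peripheral velocities that the
tapering architecture dictates; plain Dirichlet inlets remain available
(`use_supply=False`) and are what the series/parallel oracle tests use.
The supply conductance is derived once from the pristine geometry
(half the median nephron-path conductance, scaled by 0.02) and is *not*
updated as lumina occlude — the cortex upstream does not narrow because
the medulla mineralizes.

Venturi corrections `½ρ(v_out² − v_in²)` are computed at degree-2
calibre transitions and reported, not iterated to self-consistency: at
the creeping-flow Reynolds numbers of the default scene (max Re ≈ 0.1)
they are negligible against viscous drops, and the effect is used
qualitatively. The solver warns if any segment's Re exceeds 1.

Hoop strain uses the thin-wall Laplace closure `ε = P_trans·r/(tE)` with
wall moduli of 10 kPa (compliant) and 30 kPa (mineralizing). The
resulting numbers exceed the linear-elastic regime and are used as a
relative mechanical index, not a finite-deformation prediction.

Fully occluded segments get zero conductance. Interior nodes sealed off
by occlusion are pinned to the interstitial pressure (their luminal
pressure is physically indeterminate at steady state); if no path from
any inlet to the tip remains, the solver returns a zero-flow state with
the `disconnected` flag rather than raising.

## Mineral dynamics

Wall deposition rate (µm/h): `k·S(osm)·exp(−τ/τ₀)` with `k = 0.12 µm/h`,
`τ₀ = 0.12 Pa`, and `S = clip((osm − 350)/300, 0, 1)` on the linear
corticomedullary osmolality profile (320 mOsm cortex → 1200 mOsm tip).
The shear fed into the law by the stepper is the *perfusion shear*
`4µ|Q|/(πr₀³)` referenced to the pristine lumen: it measures how briskly
the segment is being perfused and falls monotonically as deposits starve
it of flow. (Shear evaluated on the narrowed lumen rises at fixed
supply, which would self-quench deposition and contradicts the
progressive-occlusion picture; the rate function itself remains strictly
decreasing in its shear argument.) The defaults are calibrated so the
default run occludes peripheral proximal tubules within simulated weeks
(first occlusion ≈ day 7–9) while long central nephrons accumulate only
sub-micron films over the same horizon. Deposition applies to nephron
segments by default; the scaled collecting duct is excluded because its
wall shear in the miniature scene is unrepresentatively low
(configurable via `deposit_kinds`).

"Fully occluded" means ≥ 95% cross-sectional area loss. The functional
radius of the complex is the outer edge of the outermost still-open
tubule column — it shrinks as occlusion marches inward from the
periphery (the narrowing-annulus picture).

The mechanobiological switch latches ON when either (a) the maximum
strain differential across nephron/vasa pairs reaches 2.0, or (b) a
quarter of the peripheral nephrons are fully occluded; both criteria
are evaluated every step and OR-ed, since the narrative supports both a
mechanics-threshold and an occlusion-burden reading. Latching reflects
the progressive clinical picture; a non-latching mode is a flag.

While the switch is on, interstitial mineral accrues at 12 mg/cc/h
(capped at 1200 mg/cc) on a 10 µm grid within 20 µm of the outer walls
of distal tubules, and the wall shells of those tubules mineralize at
20 mg/cc/h. "Distal" means zones Z3–Z4 *and* the whole segment deeper
than 0.70·depth — the depth gate (on the segment's shallowest point, so
the accrual reach cannot spill upward) is what preserves a mineral-free
mid-papillary transition band between the proximal intratubular and
distal interstitial compartments. Accrual is uniform where several
tubule neighbourhoods overlap, and lumina/walls are excluded from the
field. Interstitial accrual only begins on the step *after* activation,
so the event ordering first-occlusion < switch-on < first-interstitial
is strict by construction of the coupling (the first two are emergent).

## Phantoms

Voxelization samples each voxel centre against the analytic scene on a
(z, y, x) grid, z being depth and the transverse origin on the envelope
axis — placed on a voxel centre, again because exact grid symmetry is a
degenerate input for thinning. Class densities default to soft tissue
50, lumen 0, wall deposit 800 and interstitial cap 1200 mg/cc; grayscale
is 16-bit with a linear calibration (0.05 mg/cc per grey level) stored
in the metadata so quantification never hard-codes it. PSF blur
(Gaussian, 0.7 voxel) and additive Gaussian noise (60 grey levels) are
applied in that order, seeded. The iodine mode renders open lumina
bright on darker parenchyma and does not render mineral (it emulates a
stained patent-tubule acquisition). The 4X preset's voxel pitch is not a
standard value and defaults to 8 µm — a placeholder, flagged here.

Ground-truth labels ride along with every rendering. What center-point
sampling does *not* emulate: partial-volume averaging within a voxel,
beam hardening, ring artifacts, detector blooming and reconstruction
filters. Passing recovery tests on these phantoms therefore validates
the *algorithms*, not robustness to scanner physics.

## Quantification

Region growing follows the seeded mean-comparison description used by
tomography suites rather than a gradient watershed (a marker-based
watershed is available behind a flag for comparison): a voxel joins a
region iff 26-connected to it with intensity within `delta` of the
running region mean. Growth proceeds in synchronous sweeps — each sweep
floods to every voxel reachable at the current mean, then the mean is
recomputed — making the fixed point independent of voxel visit order;
contested voxels go to the earlier seed. `delta` has no
literature-derived default and must be chosen per study; the pipeline
default is 4000 grey levels (200 mg/cc).

Unattended operation seeds one region per connected component of each
density stratum (bins of width `delta`) above a calibrated
detectability threshold (default 300 mg/cc), iterating over unclaimed
voxels, so a faint plaque fused to a dense shell still gets its own
seed. Compartment labels (intratubular / tubule wall / interstitial)
come from painting the network's lumen and wall-shell geometry in
segment order — the same overwrite semantics as the renderer, so
classification and ground truth agree at capsule joints. Volume
fractions are voxel counts over a reference mask, as percentages;
mineral densities are calibrated means ± sd [range] in mg/cc; empty
compartments are reported as absent, never as zeros.

## Zonation

Tubule lumina are thresholded (automatic default: deterministic 1-D
3-medians on the histogram — background, parenchyma, lumen — with the
cut at the half-maximum between the tissue and lumen levels, which
preserves object size under PSF blur; tiny lumen fractions defeat both
plain and multi-class Otsu), skeletonized with 3-D thinning, and sized
by the Euclidean distance transform. The local diameter at a skeleton
voxel is `2·max(EDT in the 3³ neighbourhood)`: thinning can park the
skeleton a voxel off the true axis, where the raw EDT understates the
radius, and the neighbourhood maximum recovers the centred value
(validated on analytic cylinders: < 4% bias across 17.5–175 µm at
5 µm/voxel, within one voxel in the median). Junction and endpoint
voxels (neighbour count ≠ 2) are excluded. Diameters pool per zone;
Gaussian mixtures are fitted for k = 1..3 with BIC order selection and
the component variance floored at (½ voxel)² so BIC cannot split
sub-resolution quantization spikes into spurious peaks. Peak pairs are
compared with the half-width-at-half-maximum rule, boundary inclusive.
Histograms default to Freedman–Diaconis binning. Tubule fraction is
lumen volume over tissue volume per zone, undefined (absent) where a
zone holds no tissue.

Both the 3-D skeleton measurement implemented here and a 2-D
section-based measurement are legitimate readings of zonal diameters;
the package implements the 3-D route and makes no claim about which a
given histology-based figure used.

## Pipeline, seeds, determinism

One global seed fans out to per-stage seeds via
`numpy.random.SeedSequence.spawn` in a fixed order (generation, course,
voxelize, iodine, quantify, zonate). Identical config + seed reproduce
byte-identical artifacts and recovery reports; the config, its hash and
all stage seeds and durations are persisted into every run directory.
Mineral states checkpoint to a documented JSON schema (sparse encoding
of the interstitial field), and resuming a course from a checkpoint
reproduces the uninterrupted trajectory exactly.
The recovery report compares recovered quantities against the phantom's
rendered ground truth, with truth volume fractions restricted to
detectable mineral (≥ the quantification threshold) since a
detection-based VF is only comparable against detectable truth.
Default pass tolerances: VF 5%, MD 2%, diameter peaks 10%, tubule
fractions 25% (relative).

Problem sizes used by the default study: 56 nephron loops (+56 vasa
recta), ~1600 segments after zone- and tortuosity-splitting, courses of
up to 900 hourly steps with early stop 72 h after first interstitial
deposit, phantoms at the 10X preset on ≤256³ grids.

## Known limitations

* The deposition law is a phenomenological closure; no nucleation
  chemistry, speciation or ripening kinetics are modelled, and mineral
  density within a deposit is a configured constant, not an outcome.
* The scaled scene's absolute flows (~1 µL/min) and times are not
  calibrated to human physiology; orderings and contrasts are the
  claims, not absolute magnitudes.
* Counter-current exchange, pulsatility and non-Newtonian blood
  rheology in vasa recta are out of scope; vasa recta exist as
  mechanical comparators and geometric neighbours only.
* Hoop strain is a linear index used far outside the small-strain
  regime.
* The phantom renderer performs no projection/reconstruction physics;
  see the phantom section for what recovery tests do and do not show.
* 3-D thinning of near-symmetric straight tubes is degenerate; the
  generator's tortuosity avoids this regime, but user-supplied
  perfectly straight geometries may skeletonize poorly.
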