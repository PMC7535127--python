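# Methods

## Tissue model

Atrial tissue is a voxelized domain (isotropic spacing `dx`, mm) carrying
a scalar diffusion coefficient `D` (mm²/ms). The transmembrane potential
is normalized: 0 at rest, ~1 at the peak of the action potential. The
monodomain equation

    du/dt = ∇·(D ∇u) − (J_fi + J_so + J_si) + I_stim

is discretized with central finite differences (7-point Laplacian, face
diffusivity = arithmetic mean of the two adjacent voxels; harmonic mean
available as a config option) and integrated with explicit Euler. No-flux
boundaries are imposed by zeroing the flux across any face that leaves
the wall mask or touches a `D = 0` voxel; ablation lesions have `D = 0`
and are additionally clamped at rest. Stability requires
`max(D)·dt/dx² ≤ 1/6`; the solver refuses to run otherwise.

Stimuli are saturating forcings, `du/dt += A·(1 − u)` inside a region
while active (default `A = 0.5 /ms` for 2 ms). The `(1 − u)` factor makes
a stimulus delivered into depolarized tissue a no-op instead of an
unphysical overshoot, which matters for cross-field S2 pulses that
necessarily overlap refractory tissue.

## Cell model

The three-current atrial Fenton–Karma model: fast inward
`J_fi = −(v/τ_d)·H(u−u_c)·(1−u)(u−u_c)`, outward
`J_so = (u/τ_0)·H(u_c−u) + (1/τ_r)·H(u−u_c)`, and slow inward
`J_si = −(w/2τ_si)·(1+tanh(k(u−u_c_si)))·H(u−u_v)`, with two gates `v`
(fast, recovery time constants τ_v1⁻/τ_v2⁻ split at `u_v`) and `w`
(slow). Gating `J_si` off below `u_v` makes `u = 0` an exact fixed point;
without it the tanh tail leaks a small inward current at rest.

Shipped default (`AFK_AF_DEFAULT`), representing an AF-remodelled atrial
myocyte:

| parameter | value | role |
|---|---|---|
| τ_d | 0.25 ms (calibrated, see below) | upstroke speed / CV |
| τ_r | 30 ms | plateau outward current, APD |
| τ_si | 35 ms | slow inward strength, APD |
| τ_0 | 12.5 ms | sub-threshold decay |
| τ_v⁺, τ_v1⁻, τ_v2⁻ | 3.33, 1250, 19.6 ms | fast-gate kinetics |
| τ_w⁺, τ_w⁻ | 870, 41 ms | slow-gate kinetics |
| u_c, u_v, u_c_si, k | 0.18, 0.04, 0.6, 4 | thresholds / steepness |

Design constraints behind these numbers, all checked by tests: APD90 ≈
73 ms at rest, so a 130 ms pacing cycle captures on every beat; a
cross-field-initiated spiral is sustained for seconds on a 60 × 60 mm
sheet (wavelength ≈ CV·APD ≈ 44 mm); the spiral is stable under uniform
conduction (last-second mean tip position within 5 mm of the initiation
locus) yet drifts into and anchors at a 15 mm slow-conducting patch
placed 20 mm away. The anchoring behaviour required a raised excitation
threshold (`u_c = 0.18`; lower excitability enlarges the core and its
sensitivity to conduction heterogeneity). The softened slow-inward
activation (`u_c_si = 0.6, k = 4`) keeps the action-potential duration a
smooth function of the plateau parameters, avoiding the near-bistable
APD collapse of the classic steep-tanh sets.

`τ_d` is not a free choice: `calibrate_cv` pins it by root-finding so
that planar CV on a 30 × 3 × 0.9 mm reference strip (D = 0.1 mm²/ms,
dx = 0.3 mm, dt = 0.005 ms, activation measured as the mean u = 0.5
crossing time on planes 10 and 20 mm from the stimulus) equals
0.6 m/s ± 1 %. With the default set this lands at τ_d ≈ 0.094 ms. At the
dense-fibrosis coefficient (0.017 mm²/ms) the same cell conducts at
≈ 0.18 m/s — slowed, not blocked, consistent with the 0.1–0.6 m/s range
expected for fibrotic tissue.

### Numerical accuracy

The production resolutions are dx = 0.3 mm / dt = 0.005 ms for strip
measurements and coarsened lattices (dx = 0.6–0.8 mm, dt = 0.1 ms, still
far inside the stability bound) for sheet and shell studies. Two
documented discretization effects:

* APD90 at dt = 0.005 ms matches a dt = 0.001 ms reference within 2 ms.
* CV carries a lattice effect: halving dx from 0.3 to 0.15 mm raises CV
  by ~12 %. The effect is a property of the sharp wavefront foot that
  comes with the raised excitation threshold; it is bounded (< 15 %,
  asserted by a test) and absorbed by calibrating CV *on the production
  lattice*, so all velocity-dependent conclusions hold at the calibrated
  resolution.

## Synthetic data

The generator replaces patient imaging. Geometry: an ellipsoidal
endocardial blood pool dilated by the 3 mm wall thickness; four PV
openings and one mitral opening punched out with spheres at anatomically
placed rim points; PV regions recorded as 3 mm spheres around the rims.
The wall mask is a single connected component whose Euler characteristic
equals 2 − (number of openings) — the topology test for correct hole
punching. Default desk-scale geometry uses semi-axes well below the
anatomical ~35 mm and dx = 0.6–0.8 mm so that full studies run on one
CPU in minutes; strip-based velocity measurements always use the 0.3 mm
production lattice.

Intensities: the blood pool receives `Normal(μ_bp, σ)` values; the wall
receives `μ_bp · (baseline + offset + a·G + w_pv·bump)` where `G` is a
unit-variance Gaussian random field made by Gaussian-filtering white
noise (filter scale = correlation length / 2, giving 1/e autocorrelation
at the stated length, default 8 mm) and `bump` is a Gaussian enrichment
around each PV rim for PV-dominant fibrosis patterns. `tune_fb` bisects
the offset until the thresholded fibrosis burden (optionally measured
after transmural projection, as the mapping stage reports it) hits the
target within 0.5 %. Everything is bit-reproducible from (spec, seed).

What the generator does *not* emulate: real LA anatomy (appendage,
asymmetric veins), MRI physics (bias fields, partial-volume effects,
anisotropic voxels), and non-transmural or endomysial fibrosis. Passing
tests therefore demonstrate the pipeline's internal correctness and the
qualitative substrate–driver interactions, not patient-level accuracy.

## Fibrosis mapping

IIR = intensity / mean blood-pool intensity. Labels: healthy iff
IIR < 1.08; dense iff IIR ≥ 1.24; border zone between. The boundary
convention follows the diffusion assignment (dense at exactly 1.24). The
lower cut is the average of two previously reported thresholds (1.2 and
0.97); the upper is the dense-scar threshold 1.32 reduced by 6 % for
post-ablation imaging — both derivations are implemented as documented
functions but stored as constants. D is linear in IIR across the border
zone, from 0.1 to 0.017 mm²/ms (an ~83 % reduction), clamped outside.
Labels are made fully transmural by assigning every wall voxel the label
of its nearest endocardial-surface voxel. Patches are 26-connected
components of the fibrotic voxels (face-only connectivity would
fragment thin transmural patches); all patch volumes are reported as
percent of wall volume, and the PV/wall split partitions fibrotic voxels
by membership of the 3 mm PV spheres.

## RD initiation, tracking, target areas

Cross-field initiation: an S1 plane wave, then an S2 half-space stimulus
timed into the S1 wake. The vulnerable window depends on geometry, so
the S2 onset is auto-searched: candidates around (S1 transit to the
domain center + 0.9·APD90) in ±10–30 ms steps are probed with short
runs, and the first that leaves a phase singularity persisting ≥ 150 ms
is used for the full run. Ectopic-pacing initiation: n point stimuli
(default 7) at the basic cycle length (default 130 ms) near a PV,
followed by a plane wave 20 ms after the last beat. Initiation sites are
spread by seeded farthest-point sampling (8–12 per study). A site where
no candidate forms an RD is reported and skipped, not an error.

Tips: activation phase by time-delay embedding,
θ = atan2(u(t−τ) − u*, u(t) − u*) with τ = 10 ms, u* = 0.5; singularities
where the wrapped phase differences around a 2 × 2 plaquette wind by
±2π. Thin 3-D walls are scanned slice-wise along all three axes and the
points clustered (single linkage, 3 mm) into filaments whose centroid is
the reported tip; chirality is the winding sign. An independent
isoline-intersection detector (u = u* crossing du/dt = 0) ships as a
cross-check. Tracking associates tips frame-to-frame (2 ms) by
minimal-total-displacement assignment with a 5 mm gate; tracks shorter
than 50 ms are discarded as detection noise. Each run's final region is
the majority residence (pv > fibrosis > healthy on ties) over the last
second; runs whose RD died earlier are "extinguished".

Tip-visit counts accumulate per voxel; runs whose RD anchored at a PV
opening are excluded from the combined map (those anchors are artefacts
of vein clipping). The combined map is normalized by its maximum, and
target areas are the 26-connected components above the 0.2 cutoff (a
mean + 2·SD mode over the nonzero values is available; the mode used is
recorded in the output). Dice overlap is 2|A∩B|/(|A|+|B|), defined as 1
when both masks are empty (flagged).

## Virtual ablation

Lesions are "perfect": transmural, zero conductance, clamped, applied
simultaneously at a stated time on the running state. Strategy 1 builds
closed 3 mm-wide bands around the left and right PV pairs (band = wall
voxels whose distance to the nearest opening center of the pair lies in
[r₀, r₀+3] mm); strategy 2 adds a roof line joining the bands and a line
to the mitral rim; strategy 3 dilates the TAs to the 3 mm catheter
diameter; strategy 4 adds shortest-wall-path (Dijkstra on the
26-neighbour voxel graph) connectors from each TA to the nearest
anatomical boundary (PV opening or mitral rim — deliberately not the PVI
rings, so strategy 5 = 4 + rings is a strict superset); line lesions are
dilated to 3 mm.

Outcomes over a ≥ 2 s post-ablation window: *terminated* if no RD
trajectory survives the final second; *AT* if exactly one survives with
all last-second positions within 5 mm of lesion/PV/MV tissue (the
anchoring radius is half the lesion-band width — not a published value);
otherwise *unaffected*. The mean frequency is the wall average of
per-voxel dominant frequencies (spectral peak of mean-removed u(t),
rectangular window, last second); voxels whose half peak-to-peak
amplitude is below 0.05 (5 % of the AP amplitude) are excluded, and a
fully quiescent recording reports MF = 0 with nothing passing the floor.
Re-inducibility repeats the initiation protocol on the ablated tissue
from freshly sampled sites, classifying each attempt no-AF / AT / AF.

## Problem sizes

Tests and the acceptance battery run at desk scale by design: reference
strips (30 × 3 × 0.9 mm, dx = 0.3 mm) for every velocity number,
60 × 60 mm sheets at dx = 0.6 mm for spiral-dynamics properties, and
reduced ellipsoidal shells (semi-axes 16–20 mm, dx = 0.8 mm, 2–3 s of
activity, 3–6 initiation sites) for end-to-end studies. These sizes keep
a full study within minutes on a single core while preserving the
phenomena of interest (sustained re-entry, fibrosis anchoring,
TA formation).

## Known limitations

* Isotropic conduction only: no fibre orientation, no electrophysiologic
  heterogeneity beyond the fibrosis-derived diffusion map.
* Fully transmural fibrosis and lesions; no endo-epicardial dissociation.
* The cell parameter set is a calibrated phenomenological stand-in for
  AF-remodelled atrial kinetics; only CV (0.6 m/s) and capture at the
  130 ms cycle length are pinned to published constraints.
* Desk-scale shells are smaller than real atria; absolute RD counts,
  TA counts and ablation success fractions are not comparable to
  patient-scale studies — directional comparisons (burden vs anchoring
  region, TA volume vs fibrosis volume) are.
* The re-inducibility advantage of TA-plus-connector ablation over
  TA-only ablation is weakly expressed on the synthetic substrate:
  re-induced drivers often anchor in the broad border-zone ring around a
  random-field patch, away from the sharply localized tip-visit hotspots
  that define the TAs, so connector lines intersect re-entrant circuits
  far less often than on real patient substrates with recurrent,
  localized anchors. The shipped paired comparison reproduces the
  expected strict ordering, but direction is all that should be read
  from it — the effect size is not comparable to patient-scale
  studies.
* Layer-wise tip detection assumes near-transmural filaments (valid for
  a 3 mm wall); filament topology (rings, twist) is out of scope.
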