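# Methods

This note records the model's assumptions, the parameters that matter, the
numerical choices, and what the reduced-order surrogate can and cannot say
about the 3D system it emulates.

## Geometry fixture

The model's spatial backbone is a column of 1 mm axial slices (z in mm from
the foramen magnum, positive caudal; cranial slices carry negative z down to
the vertex at z = −28 mm, the spinal canal ends at z = 231 mm, the last
sacral root attachment). Each slice stores CSF cross-sectional area (CSA),
wetted perimeter, dura- and CNS-contact areas, enclosed tissue
cross-section, and an effective lumen radius — the radius of the circle
whose area equals CSF CSA + enclosed CNS CSA, which is the cylinder radius
the wall-motion equation acts on.

Only regional aggregates of the NHP geometry are known (regional CSF
volumes, contact areas, rootlet records, a handful of axial observations),
so axial profiles between them are under-determined. We draw smooth
monotone-cubic (PCHIP) profiles through per-region anchor values and then
scale each region by a single factor so slice sums reproduce the regional
volumes exactly (lumbar 3.60, thoracic 2.75, cervical 1.45, cranial
8.43 mL; grand total 16.23 mL). Contact areas are distributed within each
region proportionally to the local equivalent perimeter and scaled to the
regional targets. The wetted perimeter is set as P_w = 4·CSA/HD with a
target hydraulic diameter of 2 mm, the value observed throughout the real
geometry.

Two internal tensions in the source measurements are worth recording:

* A mean spinal CSA of ~60 mm² is *incompatible* with 7.8 mL of spinal CSF
  over a 231 mm canal (volume/length forces ~34 mm²). The fixture honors
  the volumes — they are the quantity conserved by the transport solver —
  and accepts the smaller mean spinal CSA. The cranial mean CSA (~300 mm²)
  and HD (~2 mm) are honored.
* The cranial CNS-contact areas of the five cranial compartments sum to
  111.3 cm², not the printed 111.4; totals here are always computed from
  constituents.

Rootlet records (level, side, attachment z, descending angle, radicular
line, diameter, count) are packaged as a versioned CSV with a provenance
column; two cervical rows whose printed diameter/count digits are ambiguous
are flagged `table-parsed`. Rootlets enter the model as bookkeeping (tissue
volume and contact area per region) — the 1D solver cannot resolve their
local mixing, which is exactly what the dispersion closure stands in for.
`scale_rootlet_lattice` applies the canal-length ratio (NHP 30.1 cm / human
61.5 cm ≈ 0.49, commonly rounded to 0.5) linearly to positions, radicular
lines and diameters.

## Flow synthesis

Parameters (defaults are the measured NHP study conditions):

| parameter | default | meaning |
|---|---|---|
| cardiac rate | 115 bpm | cardiac-induced CSF oscillation rate |
| respiratory rate | 28 bpm | respiration rate |
| amplitude ratio | 0.52 | respiratory : cardiac flow amplitude |
| rate ratio used | 4.0 | 115/28 = 4.10 rounded down to avoid aliasing |
| C2/3 peak | 0.65 mL/min | composite amplitude calibration at C2/3 |
| aqueduct ratio | 1/24 | aqueduct : C2/3 amplitude |
| net production | 25 mL/day | CSF formation = clearance rate |

The in vivo per-station waveform shapes are not published, so the cardiac
waveform is a documented two-harmonic sine template with a sharp systolic
lobe, normalized to unit peak; the respiratory component is a sinusoid.
One composite cycle spans one respiratory period (60/28 ≈ 2.143 s) and
contains exactly 4 cardiac cycles; "amplitude" always means max |q| over
the cycle. Station peaks are defined on the composite signal, so station
builders rescale the composite to the target peak (the 0.52 component ratio
is invariant under that rescale). Default station peaks (FM 0.62, C2/3
0.65, C5/6 0.58, T4/5 0.35, T10/11 0.15, L3/4 0.065 mL/min) realize the
measured ten-fold caudal attenuation between C2/3 and L3/4 with a monotone
profile; they are config-exposed.

The compliant field gives every slice the same unit-peak waveform (zero
inter-level phase lag — no phase data exist; a lag hook is config-exposed)
with amplitude interpolated through the stations by shape-preserving PCHIP
(a linear scheme is available), pinned to zero at the sacral termination
and the cranial vertex. The rigid field is z-invariant by construction.
The aqueduct waveform is the C2/3 composite scaled to 1/24 amplitude plus
the constant offset that makes its cycle mean 25 mL/day; whether the
aqueduct leads or lags C2/3 is unknown, so the default lag is zero.

A note on units: the reported flow amplitudes (mL/min) imply section
velocities of ~0.5 mm/s and Reynolds numbers of order one; published Re
values of 60–250 for the same system require flow amplitudes roughly two
orders of magnitude larger. The package follows the printed mL/min
amplitudes. Because the dispersion closure is calibrated to a transport
anchor rather than computed from first principles, this scale ambiguity is
absorbed by `k_disp` and does not affect the dose predictions; it does mean
the model's own Re values should not be compared against the published ones.

## Wall-motion (compliance) algorithm

Craniospinal compliance is emulated kinematically, not by a pressure-volume
law: each slice's dura radius moves so the swept volume absorbs the net
volumetric efflux the target flow field demands,

    r_new = sqrt(r² − ΔQ·Δt/(π·h)),   ΔQ = Q(caudal face) − Q(cranial face),

applied to the *instantaneous* radius each step (geometrically exact
bookkeeping; a linearized reference-radius variant exists for comparison).
Positive Q is caudally directed, so positive net efflux moves the wall
inward. Face flows come from linear interpolation of the slice-centered
field; both model ends are closed for the compliant field. Swept volumes
are integrated with the trapezoidal rule over each step.

The inverse map reconstructs face flows by cumulative summation of swept
volumes from the closed sacral end and averages them to slice centers;
reconstructed flows are step averages assigned to the step's left endpoint,
so the forward/inverse round trip carries an O(Δt) discretization gap that
vanishes under step refinement. At Δt = 10 ms the maximum peak-systolic
station error is ~0.3 % and the reconstructed L3/4 peak is 0.065 mL/min to
within 1 %.

With the printed mL/min flow amplitudes the resulting dura displacements
are sub-micron to a few microns (cervical > lumbar), far below the ~100 μm
scale published for the 3D model; the discrepancy follows directly from
volume bookkeeping at those amplitudes and is another face of the unit
ambiguity above. The algorithm's verification is therefore stated in
relative terms (round-trip error, reconstructed peaks), which are
amplitude-scale invariant.

## Transport surrogate

The central, openly-stated surrogate decision: the 3D multiphase problem is
reduced to cross-section-averaged 1D advection plus an explicit dispersion
closure. Two closure forms exist — mechanical, D_eff = k·|u(z,t)|·HD(z)
(default), and oscillatory-shear, D_eff = k·U_amp(z)²/ω — standing in for
the geometric mixing (nerve rootlets, secondary flows, steady streaming)
the 3D model resolves. `k_disp` is dimensionless and calibrated ONCE by
bisection so that the rigid-mode tracer front reaches the cranial base
(z = 0) 60 minutes post-injection; the calibrated value is 3.0 at the
reference conditions and ships as the default. The same value is reused for
the compliant run, so the compliant/rigid contrast emerges purely from flow
attenuation.

Front definition: the most cranial slice holding ≥ 0.5 % ID (config
exposed). The *calibration* anchor uses a lower 0.05 %/slice threshold: a
uniform spread of the whole dose over the 259 slices is only ~0.4 %/slice,
so a 0.5 %/slice front can never reach the cranial base for any k and would
make the anchor undefined.

Numerics: conservative finite-volume update of tracer volume per slice with
explicit flux-limited (minmod/MUSCL) upwind advection, operator-split with
Crank–Nicolson dispersion; slice fluid volumes are updated from the face
divergence so the moving-wall field conserves tracer volume to round-off.
The injection (1 mL at 1 mL/min through a 25 G needle at L3/4) enters as a
pure-tracer source plus a bulk flow of 1 mL/min directed cranially toward
the open superior-sagittal-sinus outlet (a config weight can divert part of
it into local wall expansion; default 100 % cranial). Net production
(25 mL/day) enters at a mid-cranial source and leaves through the SSS
outlet with zero-gradient concentration. The sacral end of the rigid model
is driven through a well-mixed re-entrant plenum — the bench pump tube —
which keeps the rigid field exactly z-invariant while conserving mass. Time
steps: 1 ms during the infusion, 10 ms after (Courant number ≪ 0.5 on the
1 mm grid); a coarsened 5/50 ms schedule is used for the calibration sweep
and the test suite, and changes 60-minute regional %ID by well under one
point (the refinement test halves dz and dt and requires < 2 points).
Snapshots are recorded every 1 s, as the AUC definition requires.

Mass-balance integrity (injected = in-domain + outlet efflux + plenum,
within 0.1 %) is enforced at every output instant; the solver raises rather
than report an unbalanced field. Concentrations stay in [0, 1] under the
limiter.

## Quantification

Regional %ID is the slice-wise volume-weighted sum Σ c·CSA·h / bolus × 100
(exact volume weighting; the coarser "mean concentration × region volume"
form is equivalent when c is uniform). Region cuts follow the rootlet
table: cervicothoracic at the T1 attachment (z = 50.7), thoracolumbar at L1
(z = 181.3), foramen magnum at z = 0. AUC(z) sums slice %ID at 1 s cadence
over the post-injection hour (%·hr). Hydrodynamics report signed peak
systolic/diastolic flow, U_peak = Q_peak/CSA and Re = ρ·U_peak·HD/μ
evaluated in SI. Agreement statistics are ordinary least squares of map B
on map A over all (z, t) samples plus Bland–Altman bias ± 1.96·SD.

## What the surrogate does and does not show

At the reference conditions the compliant model keeps 91.5 % of the dose in
the lumbar region at 60 min with the 0.5 %-ID front caudal of T11, versus
~74 % lumbar for the rigid model with measurable cervical/cranial dose —
the ten-fold flow attenuation translating directly into confinement of an
LP bolus. Known limits of the reduction:

* No needle-jet momentum: the 3D model spreads tracer tens of mm during the
  60 s infusion itself; the 1D source spreads only by bulk displacement and
  dispersion (~20 mm), so early-time front positions are conservative.
* No radial structure: near-site concentrations are higher than a 3D model
  would show (no radial dilution), so near-site AUC is overestimated
  (~4 %·hr vs ~3 %·hr scale) while the compliant > rigid exposure contrast
  is preserved.
* No drug-tissue uptake, paravascular transport or clearance kinetics; no
  buoyancy or viscosity contrast; no pressure-volume compliance law.
* The closure is calibrated, not predictive: transferring `k_disp` to other
  injection protocols assumes the mixing physics scales with |u|·HD.

The test suite exercises the model at the reference conditions with the
coarsened step schedule noted above; passing it shows the surrogate's
internal consistency (conservation, boundedness, round-trip identity,
monotone compliance effect) and its agreement with the anchor values, not
fidelity to any specific animal.
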