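# csftwin

A reduced-order, slice-wise digital model of the cerebrospinal-fluid (CSF)
system of a non-human primate (NHP), built for predicting where an
intrathecally injected drug goes. Lumbar-puncture (LP) dosing bypasses the
blood-brain barrier, but how far a bolus spreads along the neuraxis depends
on CSF pulsations — and on how strongly craniospinal *compliance* attenuates
those pulsations along the spine. `csftwin` packages that physics at desk
scale for modellers and pharmacologists who want to explore injection
protocols without a 3D CFD solver.

## What the model computes

The spatial backbone is a stack of 1 mm axial slices from the cranial vertex
through the foramen magnum (z = 0) to the sacral termination (z ≈ 231 mm),
calibrated so that regional CSF volumes, tissue-contact areas and hydraulic
diameters reproduce measured NHP values (total CSF 16.2 mL; spinal 7.8 mL).

Four coupled pieces sit on that backbone:

1. **Flow synthesis.** The CSF oscillation is a cardiac harmonic template
   (115 bpm class) superposed with a respiratory sinusoid at an amplitude
   ratio of 0.52; one composite cycle is one respiratory period containing
   exactly 4 cardiac cycles. In *rigid* mode the C2/3 composite waveform
   (peak 0.65 mL/min) applies uniformly along the spine; in *compliant* mode
   station peak amplitudes are interpolated along z and attenuate to zero at
   both model ends (L3/4 peak 0.065 mL/min). The aqueduct of Sylvius carries
   a 1/24-scaled oscillation plus a 25 mL/day net production flow.

2. **Wall motion (compliance emulation).** For each slice, the dura radius
   absorbs the section's net volumetric efflux ΔQ over a step Δt:

       Δr(z,t) = sqrt( r(z)² − ΔQ(z,t)·Δt / (π·h) ) − r(z)

   with h = 1 mm the slice height. The inverse map — reconstructing flow
   from swept wall volumes, integrated from the closed sacral end — is the
   verification oracle: at Δt = 10 ms the round trip reproduces the target
   flow with a peak-systolic error well below 2.8 % and recovers the
   0.065 mL/min lumbar peak.

3. **Solute transport.** A conservative 1D finite-volume solver
   (flux-limited upwind advection, Crank–Nicolson dispersion) moves the
   tracer volume fraction c(z,t) under the oscillatory flow, the
   injection-driven bulk flow (1 mL at 1 mL/min at L3/4 through a 25 G
   needle) and the net production efflux at the superior-sagittal-sinus
   outlet. Geometric mixing that a 3D model resolves explicitly enters as a
   dispersion closure `D_eff = k_disp·|u|·HD`, with the single coefficient
   `k_disp` calibrated once against the rigid-model anchor (tracer front at
   the cranial base 60 min post-injection) and then reused unchanged for the
   compliant run.

4. **Quantification.** Regional percent injected dose
   (%ID = Σ c·CSA·h / bolus × 100), the per-slice exposure AUC(z) in %·hr
   over the post-injection hour, hydrodynamic summaries (Q_peak, U_peak =
   Q/CSA, Re = ρ·U·HD/μ) and regression + Bland–Altman agreement statistics
   between two spatial-temporal dose maps.

## Worked example

```python
from csftwin import (
    WaveformParams, build_reference_geometry, build_flow_stations,
    interpolate_axial, simulate_transport, InjectionProtocol,
    percent_injected_dose,
)

geometry, table = build_reference_geometry()
params = WaveformParams()
stations = build_flow_stations(params)
field = interpolate_axial(stations, geometry, params)   # compliant mode
conc = simulate_transport(InjectionProtocol(), field, geometry)
for region in ("lumbar", "thoracic", "cervical", "cranial"):
    print(region, round(percent_injected_dose(conc, geometry, region, 3660.0), 1))
```

prints (60 minutes after the injection ends):

```
lumbar 91.5
thoracic 8.5
cervical 0.0
cranial 0.0
```

i.e. with compliance included, ~92 % of the dose is still in the lumbar
spine one hour after a standard LP bolus — the tracer front (0.5 % ID per
slice) never crosses the T11 level. Running the same protocol in rigid mode
(`rigid_field`) spreads the dose much further (lumbar ≈ 74 %, with measurable
cervical and cranial dose), which is the central compliance effect the model
exists to demonstrate.

The same pipeline is available from the shell:

```sh
csftwin run --mode compliant --out my_run      # geometry -> flow -> transport -> metrics
csftwin build-geometry --out geom_out
csftwin compare runA/concentration.csv runB/concentration.csv
```

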