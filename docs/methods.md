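# Methods

This note documents the models implemented in `optrodesim`, the default
parameter choices, the numerical decisions, and what the synthetic-data
tests do and do not demonstrate.

## Stimulation field and volume of tissue activated

The bipolar DBS microelectrode pair is modeled as an ideal current source
(+I) and sink (−I) in an infinite, homogeneous, isotropic volume conductor
of conductivity K (default 4.120 S/m, the value obtained from the
two-electrode in vivo impedance measurement via K = D/(R·S)). Under
quasi-static conditions the potential is the superposition of two monopole
solutions of Poisson's equation,

    Ve(p) = I/(4πK) · (1/|p − p_src| − 1/|p − p_sink|).

The relative permittivity (80) is carried as metadata only; it does not
enter the DC field. Electrode surfaces are idealized as points at the
microelectrode centres — no electrode mesh or interface impedance is
modeled — and the 1/r singularity is clamped at half a voxel edge when the
potential is sampled onto the grid.

A finite-difference Poisson solver (7-point stencil, voxel-centred,
Dirichlet boundary with either zero or analytic values, conjugate
gradients at 1e-8 relative residual) provides an independent numerical
route to the same field. On a 50³ grid the two agree to better than 5%
relative error at every voxel at least 3 voxels from either electrode; the
residual discrepancy is the known O(h²/r³) error of the lattice point
source.

Neural activation is predicted by the activating function — the second
spatial difference of Ve along a putative axon axis (default x,
configurable because fibers of passage have no stated orientation):

    f(n) = [Ve(n−1) − 2·Ve(n) + Ve(n+1)] / L²   [V/m²]

with L the voxel spacing (default 10 μm). Boundary voxels along the axis
carry 0. The VTA is the superlevel set f > t.

**Threshold degeneracy.** The literal activation rule is f(n) > 0, and
that is the library default. For a field linear in I, however, the sign
of f is invariant to the current, so the zero-threshold VTA is identical
at every intensity — a property the test suite asserts explicitly. To
obtain the current-dependent VTA volumes that the dose-response pipeline
studies, a strictly positive threshold is required; the pipeline default
is t = 1e5 V/m², chosen so that across 50–300 μA the VTA spans a few
hundred μm around the electrodes, well inside the 2-mm tissue cube.
Volumes are then strictly nested and monotone in current (linearity of f
in I implies nested superlevel sets).

## Photon transport and fluorescence

Photon propagation uses a voxel-based weighted Monte Carlo (hop-drop-spin)
on the same grid. Per interaction: step ΔS = −ln ξ/(μa+μs); deposit
ΔW = W·μa/(μa+μs) into the current voxel; Henyey–Greenstein deflection;
Russian roulette below weight 1e-4 with survival probability 0.1. Packets
crossing the cube faces are recorded as escaped (index-matched boundary,
no Fresnel reflection). Roulette kills and boosts are tracked in a ledger
so the energy balance launched = absorbed + escaped + roulette-net closes
to machine precision; the net roulette term itself is a statistically
negligible fraction (≲1e-4) of the launched weight.

Measured white-matter coefficients parameterize the two wavelengths:
μa = 4.642 cm⁻¹, μs = 257.631 cm⁻¹ at 465 nm (excitation) and
μa = 4.873 cm⁻¹, μs = 224.074 cm⁻¹ at 525 nm (emission). The anisotropy
and refractive index are not part of that measurement set; the defaults
g = 0.9 and n = 1.37 are typical white-matter values, and n = 1.37 is
consistent with the 20.5° fiber launch half-angle (asin(0.48/1.37)).
μs is treated as the full scattering coefficient with explicit g, not a
reduced coefficient. All four quantities are configuration fields.

The fiber source is a defocused uniform beam: start positions uniform over
the 200-μm core disc, directions uniform in solid angle within the
20.5° cone about the fiber axis.

Fluorescence is gated by a per-voxel quantum-yield map (QY = 1 inside the
VTA in the pipeline, 0 outside; a global multiplier is exposed for reduced
indicator expression). Every absorption event in a QY > 0 voxel spawns one
emission packet of weight Wf = ΔW·QY, launched isotropically from the
absorption point and transported at the emission-wavelength optics within
the same seeded run ("excitation first, spawned emission second").
Emission packets do not re-fluoresce. Per-voxel fluence is
φ = W_absorbed/(μa·V) with V the voxel volume in cm³ (1e-9 cm³ at 10 μm);
the summed emission φ is the simulated fluorescence-intensity readout.

Validation: Beer–Lambert attenuation in a non-scattering slab (within 3 MC
standard errors per depth bin at 1e5 packets); exact energy ledger;
bit-identical maps under a fixed seed; Henyey–Greenstein first moment;
and shell-averaged fluence of an isotropic point source in a scattering
medium against the diffusion-approximation Green's function
φ(r) = exp(−μeff·r)/(4πDr) within 15% at 10–14 transport mean free paths.

The library default is 1e7 packets per run; tests and the acceptance
script use 1e4–1e6 packets and a 20-μm-voxel 100³ grid, sizes at which the
asserted structural properties are already stable.

## Dosimetry

K = D/(R·S) with the printed measurement inputs (R = 0.543 MΩ, D = 450 μm,
S = 200.960 μm²) gives 4.124 S/m, matching the published 4.120 ± 0.041
within the precision the rounded inputs support. The printed area implies
π evaluated at three significant figures; `electrode_area` defaults to
full-precision π (201.0619 μm² for r = 8 μm) with a `paper_pi`
compatibility flag reproducing 200.960 μm².

TEED per second is E = (I·R)²·pw·f/R = I²·R·pw·f; the train total is
E × duration, checked against a safety limit of 1.12e-2 J — the published
energy equivalent of the 30 μC/cm² charge-capacity ceiling, taken as a
configurable constant because its derivation from the stated quantities is
not available.

## Evoked-signal statistics

LFP traces (1 kHz) are band-passed 0.3–300 Hz; photometry traces are
low-passed at 100 Hz. Both filters are zero-phase forward-backward
Butterworth designs (default order 4; no filter family is prescribed by
the recording description, and zero-phase filtering preserves evoked
latencies).

Epochs are clipped at a fixed period from the start of the 15–25 s
analysis window — fixed-period clipping, not artifact-triggered alignment.
The default period is 0.333 s verbatim; because the 3 Hz train implies
333.33 ms, an exact 1/3 s period is used wherever epochs must align with
pulses (the per-epoch start indices are rounded individually so fractional
periods accumulate no drift). The evoked average is the samplewise mean
across epochs, and ∑LFP sums |evoked average| over the first 30 ms. The
phrase "amplitudes at 30 ms post-stimulus" is ambiguous between the 30-ms
window sum and the single sample at 30 ms; the window sum is the default
(it is what the evoked-response figures plot) and a single-sample mode is
provided.

ΔF/F = (Fs − F0)/F0 with F0 the 0–10 s baseline mean; the session
statistic is the mean ΔF/F over 15–25 s, the window chosen because the
calcium response rises ≈5 s after stimulation onset. Dose-response
relations are summarized by ordinary least squares with R² and a two-sided
slope p-value.

## Synthetic sessions

The generator emulates the statistical structure of anesthetized-rat
thalamic-DBS sessions: 40 s (10 baseline / 20 stimulation / 10 rest),
3 Hz pulses. Per pulse the LFP receives a one-sample-per-phase biphasic
artifact and a negative evoked deflection −A·exp(−(t−5 ms)/8 ms); the
photometry channel is F0·(1 + a·s(t)) where s(t) rises as
1 − exp(−(t−15 s)/1.5 s) from 5 s after stimulation onset and decays with
τ = 3 s after the train. Default amplitudes follow a linear dose-response
(evoked 1 μV/μA, ΔF/F 0.001/μA, artifact 5 μV/μA) with noise sd 20 μV
(LFP) and 0.005 (photometry, F0 = 1) — values chosen once as realistic for
this preparation. All randomness derives from a master seed
(`SeedSequence` children per session).

Because the saturating rise begins 5 s into the stimulation epoch, the
15–25 s mean ΔF/F sits ≈15% below the plateau for the default rise time;
recovery of the *injected* plateau amplitude is therefore assessed on the
late-stimulation window (27–30 s), where the rise has converged to within
0.1%, while the 15–25 s mean remains the session statistic used in
dose-response fits (it is proportional to the plateau for fixed kinetics,
so linearity and R² are unaffected).

What passing these tests shows: the analysis chain recovers known injected
parameters (≤1% error without noise, within estimator standard error with
noise) and preserves linear dose-response structure. What it does not
show: anything about real indicator kinetics, artifact shapes, electrode
drift, hemodynamic or motion contamination, or non-linear neural
recruitment — the generator is phenomenological by design.

## Pipeline geometry

No coordinate frame is prescribed for the probe, so the pipeline default
places the electrode pair on the z-axis through the centre of the 2-mm
cube at z = 775 and 1225 μm (450 μm separation) with the fiber tip coaxial
at z = 500 μm aiming at the pair — a simple stand-in for the physical
channel layout in which the fiber sits beside the microelectrode sites.
With the default positive VTA threshold, VTA volume and total emission
fluence rise monotonically across 50/100/200/300 μA and are nearly
linearly related (R² ≈ 0.98 at the reduced scale); the fluence-per-volume
relation is slightly concave because voxels added at higher currents lie
farther from the fiber where excitation fluence has decayed.

## Known limitations

Homogeneous isotropic tissue only; no multicompartment axon models behind
the activating-function rule; no Fresnel refraction or fiber collection
efficiency (fluence is summed over all voxels, not detected through the
fiber); no cascaded fluorescence; stimulation artifacts are not subtracted
but excluded by design of the epoch statistic; printed in vivo R² values
depend on animal data and are outside what simulation can reproduce —
only their structural analogues are asserted.
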