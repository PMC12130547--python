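# Methods

## Physical model and assumptions

`holobeam` models monochromatic, linear, scalar pressure propagation in a
homogeneous lossless medium (degassed water: c = 1480 m/s,
ρ = 1000 kg/m³). Fields are complex amplitudes p(x, y) on transverse
planes; propagation between planes uses the angular spectrum method with
the transfer factor

    H(kx, ky, Δz) = exp( j Δz √(k₀² − kx² − ky²) ),  kx² + ky² ≤ k₀².

Evanescent components (kx² + ky² > k₀²) decay as exp(−|Δz|κ) on forward
steps and are zeroed on backward steps, so back-propagation can never
amplify them exponentially. Before every propagation the field is embedded
in a zero-padded computational grid (default 2× linear extent, rounded to
an FFT-friendly length) so that the periodic images of the FFT do not
alias into the focal region; the factor is exposed as
`DesignConfig.padding_factor`.

Out of scope by design: heterogeneous media (skull), nonlinear
propagation, shear waves, and time-domain solving. The solver is the
desk-scale stand-in for full-wave pseudo-spectral simulation: identical
physics for water-only propagation, at a tiny fraction of the cost.

## The design loop

The hologram phase is estimated by a weighted Gerchberg–Saxton iteration
(iterative angular spectrum approach) with amplitude constraints at both
ends:

1. propagate the current hologram-plane field to every target plane;
2. record the achieved amplitude at each focus — the maximum |p| inside
   its rasterized disk, which is robust to sub-pixel focus drift;
3. stop if the spread (max−min)/max of achieved-to-desired ratios is below
   `uniformity_tol` (the recorded amplitudes then describe exactly the
   returned design, so re-propagation reproduces them bit-for-bit);
4. otherwise update the weights wᵢ ← wᵢ (desiredᵢ/achievedᵢ)^γ,
   renormalized to mean 1;
5. impose the target constraint: per plane, replace the magnitude by the
   weighted target image (zero background included), keep the phase;
6. back-propagate every plane to z = 0 and sum the complex fields;
7. impose the source constraint: piston magnitude, keep phase;
8. optionally recalibrate the hologram-plane magnitude by the physical
   lens transmission of the current phase map (`lens_material` set).

Initialization is the piston magnitude with zero phase — fully
deterministic. A seeded random-phase initialization is available for
escaping symmetric stagnation but is never needed for the bundled cases.

Design choices made where the procedure was genuinely open:

* **Stopping rule.** Both a hard iteration cap (100) and the <5%
  focal-spread criterion are in force; whichever comes first stops the
  loop. Single-focus designs have no spread to measure and run to the cap.
* **Multi-plane merge.** The back-propagated planes are summed coherently
  (step 6); sequential plane cycling was rejected in favour of the
  summation form.
* **Focus rasterization.** Each focus is a filled disk of radius λ/2
  (≈0.49 mm at 1.5 MHz in water) rather than a single pixel: point targets
  waste source energy into sidelobes, while a resolvable disk gives the
  loop a realizable objective. Disks must not overlap.
* **Target background.** The amplitude constraint imposes the full target
  image including its zero background; leaving the background free was
  rejected because it lets energy pool into ghost foci.
* **Weight exponent.** γ = 1 (direct proportional correction) by default;
  γ = 0 disables amplitude modulation entirely and serves as the
  "unweighted" control.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| pixel size `dx` | 100 | µm | ≈ λ/10 in water at 1.5 MHz; resolves the finest phase zones |
| grid | 384 × 384 | px | 38.4 mm side: 30 mm aperture + ≥4 mm margin |
| aperture diameter | 30 | mm | the transducer's active diameter is not published; 30 mm matches the element family and is exposed per case |
| frequency | 1.5 | MHz | transducer centre frequency |
| `max_iterations` | 100 | — | convergence cap |
| `uniformity_tol` | 0.05 | — | focal-amplitude spread stopping criterion |
| disk radius | λ/2 | m | focus rasterization (above) |
| `padding_factor` | 2.0 | — | FFT wrap-around guard |
| lens material | 2290 m/s, 1030 kg/m³, 4.6 dB/cm | — | MultiJet acrylate (Visjet M2R-WT) at 1.5 MHz |
| `base_thickness` | 0.5 | mm | minimum printable substrate |

## Lens conversion conventions

Because the lens material is acoustically faster than water, a thicker
pixel advances the transmitted phase; the wrapped design phase maps to the
minimal positive thickness t = t₀ + φ/(k_water − k_lens), with 2π of phase
per ≈2.79 mm of material. The three-layer transmission factor interprets
its internal phase as k_lens·t. Two simulation modes exist:

* **apply-phase (default):** the designed phase is imprinted on the piston
  field at z = 0 and propagated in water. Fast, and the mode whose results
  the package reports.
* **physical slab (`simulate_through_lens`):** the lens body is traversed
  in 0.1 mm split-step slices, each applying the material's differential
  phase and absorption where the relief is still present. This captures
  diffraction inside the lens and pushes the axial peak slightly deeper
  than the design focus, qualitatively matching what full-wave treatments
  of the printed lens show; quantitatively the shift depends on mounting
  geometry that is not modeled, so the default reporting stays with
  apply-phase.

Thickness export supports an optional vertical quantization step
(e.g. 25 µm, a typical MultiJet layer height), applied at export only.

## Steering model

Axial translation of the hologram under plane-wave illumination leaves the
exit field unchanged, so the focus moves by exactly the translation; this
is exact in the model and the package verifies it to machine precision.
Rotation of the transducer+hologram assembly is modeled spectrally: the
exit field's plane-wave components are rigidly rotated and resampled onto
the untilted computational plane (with the Jacobian amplitude correction),
then propagated. The model is guarded to |angle| ≤ 45°; the resampling is
linear interpolation of a smooth spectrum (the real-space origin is
shifted to remove the FFT's linear phase ramp first, which is essential).
Mirror symmetry between ±angle holds to a few percent of peak — the
residual is interpolation asymmetry of the even-sized FFT grid, not
physics.

## Focus characterization

Foci are local maxima of |p| in a simulated plane stack, greedily accepted
in descending amplitude with a minimum pairwise separation, refined per
axis by quadratic interpolation (sub-0.1-pixel accuracy on synthetic
blobs). Lateral FWHM is measured along x through the peak in its axial
plane, axial FWHM along z at the peak's lateral position, both with
linearly interpolated half-maximum crossings; a profile that never drops
below half maximum on either side raises an error rather than returning a
truncated width. Axial evaluation windows must therefore generously
bracket the focal lobe — low-Fresnel-number configurations (small
apertures) have surprisingly long foci and also peak proximal to the
geometric focus, which is focal-shift physics, not a solver artifact.

Exposure metrics use I_sppa = p²/(2ρc) with the conventional reporting
impedance ρc = 1.5 MRayl (the tank simulation value, 1.48 MRayl, is
available by argument), I_spta = I_sppa × duty, and derated pressure
pnp × (1 − loss), with a 20% loss standing in for mouse-skull insertion
loss. Report rounding follows treatment-table convention (pressures to
two decimals in MPa).

## What the fixtures emulate — and what they do not

The bundled cases regenerate the reference study geometries: single
on-axis foci at 10/20/30 mm and the biplane three-focus layout
((−1.8, 2.6) and (1.7, 2.6) mm at 17.8 mm; (−0.3, −0.5) mm at 19.8 mm),
all at 1.5 MHz, 100 µm pixels, unit initial weights, in water. They do
**not** emulate: the physical lens as a refracting body in the reported
simulations (see the two modes above), transducer surface-velocity
non-uniformity, hydrophone spatial averaging, tank reverberation, or any
tissue/skull effects. Consequently the idealized model focuses exactly at
the design distance and equalizes multi-focus amplitudes somewhat better
than a printed lens measured in a tank; passing tests demonstrate the
correctness of the design/propagation/characterization chain, not
millimetre-exact agreement with any particular experimental rig.

## Numerical choices

* FFTs via `scipy.fft` with real-space zero-padding to `next_fast_len`.
* Evanescent policy: decay forward, hard zero backward (prevents blow-up).
* FWHM crossings: linear interpolation between samples; ties at the peak
  resolved by the first global maximum.
* Quadratic sub-pixel refinement clipped to ±0.5 sample.
* Degenerate inputs fail loudly: empty target lists, overlapping focus
  disks, apertures larger than the grid, profiles truncated at half
  maximum, non-finite fields mid-iteration.
* Problem sizes: the full-scale cases run on a 384² design grid (768²
  padded FFTs) with 0.2 mm axial sampling — about 40 s for the complete
  acceptance recomputation on one CPU.

## Known limitations

* The focal-amplitude uniformity of the idealized water-only model is
  better than measured reality; thickness-dependent attenuation and
  mounting geometry widen the spread for printed lenses.
* Lateral FWHM scales inversely with the assumed aperture; since the
  transducer's active diameter is unpublished, absolute spot sizes carry
  that systematic.
* The spectral rotation model treats the assembly as rigidly rotated in
  homogeneous water; it does not model the tilted lens as a refracting
  slab.
* No mechanical index, thermal dose, or cavitation-dose computation.
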