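# Methods

## The problem

A cryo-EM image is usually treated as a projection of the specimen: its 2D
Fourier transform is a central slice of the 3D transform.  A real particle
has thickness, so its top and bottom sit at different defoci, and the
scattered amplitudes actually lie on the Ewald sphere (radius 1/λ), not on
a plane.  The phase error this causes grows with spatial frequency; at
resolution d the defocus-phase difference across a particle of diameter t
is

    Δχ = π λ t / d²,

which reaches π at the Spence limit d = √(λt).  For a 250 Å capsid at
300 kV (λ = 0.0197 Å) that is 2.22 Å — exactly the regime of modern
sub-2 Å single-particle work.  This package implements the *simple
insertion* correction — every image coefficient is inserted into the 3D
transform twice, at the two curved (left/right beam) positions related by
Friedel symmetry, each demodulated by the transfer function of its beam —
and provides the simulation and resolution-accounting machinery to
demonstrate the correction end-to-end on synthetic phantoms.

## Image-formation model (simulator)

The simulator is deliberately independent of the reconstructor's
paraboloid-sampling machinery: it never references reciprocal-space
curvature at all.  The rotated specimen is partitioned into slabs along
the optical axis; each slab is projected, filtered by the CTF at defocus
`Δf + z_slab`, and the slab images are summed (weak-phase object,
first-order, no multiple scattering or per-slab attenuation).  Curvature
effects then *emerge* from the focus gradient, which is their physical
cause.

* CTF: `-[√(1-A²)·sin χ + A·cos χ]`, `χ = πλΔf s² − (π/2)Csλ³s⁴ + φ`,
  underfocus positive, low-resolution contrast negative (dark particles).
* Slab thickness: the single-coefficient phase-error bound allows
  `d²/(4λ)`; the default uses `d²/(8λ)` at Nyquist, which keeps the
  residual discretisation error below ~0.5% RMS (verified by the
  doubling test).
* Conventions: intrinsic ZYZ Euler angles (rot/tilt/psi); the
  object-to-lab matrix is `Rz(psi)·Ry(theta)·Rz(phi)`; the lab z axis
  points from the detector toward the source, so a slab at height z is
  imaged at defocus `Δf + z`.  Images and volumes keep DC at the array
  centre.
* Noise: additive white Gaussian with variance `var(signal)/snr`.
* Orientations: uniform over SO(3) by quaternion sampling, to avoid
  preferred-orientation artifacts that would confound the curvature
  comparison.  All randomness flows from explicit integer seeds.

## Reconstruction

Direct Fourier inversion with trilinear gridding: for each image
coefficient at in-plane frequency g, `numerator += w·CTF·I(g)` and
`denominator += w·CTF²` at the central-plane position (uncorrected mode),
and the map is `IFFT[num/(den + w₀)]` after Hermitian symmetrisation,
with the Wiener constant w₀ defaulting to 0.01×max(den).

With Ewald correction the insertion position moves to the curved point
`(g, hand·z(g))`, `z(g) = λ|g|²/2` (paraboloid approximation; the exact
sphere is available but differs negligibly at λs ≪ 1), and the inserted
value becomes `w·|CTF|·conj(Ĉ₊)·I(g)`, where `Ĉ₊ = -(A + i√(1-A²))e^{-iχ}`
is the unit-modulus transfer function of the left beam.  Looping the full
plane of the real image automatically performs the second (Friedel-mate)
insertion, so each datum constrains both sphere points and the
accumulator stays Hermitian.  Two design points deserve note:

* **The per-beam *phase* is what corrects curvature and resolves the
  hand.**  A real-valued per-beam weight cannot distinguish the two
  sheets (conjugation symmetry makes both hands accumulate identically in
  expectation); the `e^{±iχ}` demodulation is essential.
* **The |CTF| magnitude keeps the noise weighting of the central-slice
  reconstructor.**  The denominator accumulates `w·CTF²` in both modes,
  so in the zero-curvature limit the corrected and uncorrected routes
  agree in every Fourier phase and differ only by a positive
  per-coefficient demodulation factor — the specificity control relies
  on this.

`hand = −1` mirrors the curvature (the analogue of reconstructing the
wrong enantiomer); the Euler transformation
`(phi, theta, psi) → (−phi, 180−theta, psi)` produces the
opposite-handed particle set.  Symmetry is imposed by inserting each
image once per group rotation (C1, Cn, icosahedral I2 with its 60
rotations generated and closure-verified programmatically).  Half-sets
are split even/odd after a seeded shuffle so the two half-maps are
independent.

Per-particle defocus refinement is a grid search maximising the
Fourier-space correlation between the image and the CTF-filtered
reference projection at the particle's known orientation — a transparent
re-implementation of per-particle CTF refinement; its score is that
correlation, not any package-specific figure of merit.

## Resolution accounting

* FSC over half-open voxel-radius shells [k, k+1), no masking or
  smoothing (phantom experiments are solvent-free); resolution is the
  linearly interpolated first downward crossing of the threshold (0.143
  for half-maps, 0.5 against the known phantom).
* ResLog/B-factor: least-squares fit of ln N against 1/d², restricted to
  the first linear portion (the largest prefix of particle counts whose
  residual RMS stays below a configurable limit, default 0.2 in ln N
  units), B = 2×slope.
* Gain onset: the lowest frequency from which the corrected-minus-
  uncorrected FSC difference is ≥ min_gain for min_run consecutive
  shells.  "Noticeable" is operationalised as min_gain = 0.02 over 3
  shells; both knobs are exposed.  The primary onset uses the FSC against
  the known phantom (the oracle a simulation affords); the half-map-FSC
  onset — the only comparison available on real data — is reported
  alongside.
* Depth-of-field limits: d = √(πλt/ε).  Spence corresponds to ε = π; the
  DeRosier and Downing–Glaeser presets ship as ε = π/2 and π/4, flagged
  as approximations since the original sources plot but do not print
  their tolerated-phase-error constants.
* Magnification anisotropy: a scale distortion of α% makes the apparent
  astigmatism (defocusU − defocusV) grow linearly with defocus; the
  least-squares slope of that difference against mean defocus, ×100,
  estimates α.
* Sharpening: amplitudes ×exp(−Bs²/4), optionally after flattening the
  rotationally averaged amplitude spectrum inside a band.

## The desk-scale curvature experiment

The headline experiment reproduces, at desk scale, the design of the
real-data demonstration on an icosahedral capsid: the physics depends on
the product λt, so a 60 Å phantom imaged at an exaggerated λ = 0.15 Å
stands in for a 250 Å capsid at λ = 0.02 Å, with the Spence limit at
√(0.15·60) = 3.0 Å.  Study conditions (fixed once, as the package's
defaults): box 72, pixel 1.1 Å (Nyquist 2.2 Å, so the limit sits at shell
26 of 36 with headroom above it), 150 Gaussian blobs of width 0.7–1.4
pixels (atom-like contrast across the whole band), n = 800 particles,
defocus uniform in 0.4–1.2 μm, SNR 8, C1 reconstruction, five replicate
seeds.  The SNR is chosen so that the half-map FSC declines through 0.143
slightly beyond the Spence limit — the regime in which the real
experiment operated (resolution 1.86 Å against a 2.22 Å limit).

Under these conditions the correction improves the half-map resolution by
roughly one shell (~0.1 Å at this scale), the gain onset converts to a
top-to-bottom phase shift of ~0.8–0.9π (the real-data onset at
2.4–2.3 Å corresponds to ~0.9π), the same-hand reconstruction beats the
opposite-hand one in every replicate, and with λ = 10⁻⁴ Å in the
simulator (curvature-free data) the corrected and uncorrected FSC curves
coincide to < 0.01 and no onset is detected.

## What the synthetic data do and do not show

The generator emulates: uniform orientations, a defocus distribution,
shot-noise-like white noise, atom-scale density texture, an exact
weak-phase focus gradient, magnification anisotropy, and per-frame
dose/motion envelopes.  It does not emulate: amplitude/multiple
scattering, detector DQE and coincidence loss, beam tilt and coma,
structural heterogeneity, solvent, or alignment errors (orientations are
known exactly).  Passing tests therefore show that the *correction
recovers what the focus gradient destroys* under controlled conditions;
they do not by themselves predict the size of the gain on any real
dataset, which also depends on all the effects listed above.

## Numerical choices and limitations

* Trilinear gridding without iterative gridding correction: adequate at
  desk scale; it caps phantom-FSC at the top ~10% of shells, which is why
  the study conditions keep the Spence limit below 0.75 Nyquist.
* Wiener constant as a fraction of max(denominator): a documented knob,
  not an estimate of the true SSNR.
* The MRC header stores the cell as float32, so voxel sizes round-trip at
  float32 precision; array data round-trip exactly (mode 2).
* The exact-sphere height `(1 − √(1−λ²s²))/λ` requires λs < 1 and is
  exposed but off by default; at the λs ≤ 0.06 of the experiments the
  paraboloid error is < 10⁻⁴ relative.
* `min_box_size` returns the standard delocalisation lower bound
  `ceil[(D + 2λ·Δf_max/d)/pixel]` (even-rounded); practical box choices
  may legitimately exceed it.
* Real aligned stacks + STAR metadata can be reconstructed through the
  CLI, but no orientation refinement is provided: orientations are taken
  as given.
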