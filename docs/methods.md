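# Methods

## Kinetic model

A photocycle is a closed first-order network over compartments
(species), one of which is the ground/terminal state.  The rate matrix K
has K[i,j] = rate j→i and column sums of zero, so total population is
conserved.  Excitation deposits the post-branching initial populations c₀
smeared by a single Gaussian IRF (fwhm ↔ σ via σ = fwhm/(2√(2 ln 2)));
chirp (wavelength-dependent time zero) is not modelled.  Populations are
evaluated in closed form through the eigendecomposition of K and the
analytic exponential⊗Gaussian kernel; the kernel switches to an erfcx
formulation where the naive expression overflows, keeping it stable to
k·σ ~ 10³.  Time is in ps, rates in ps⁻¹, reported constants τ = 1/k.

Degenerate schemes: a *defective* rate matrix (Jordan block, e.g. equal
sequential rates) cannot be expanded in pure exponentials.  We detect this
via the eigenvector-matrix condition number (> 10⁸), perturb every rate by
a deterministic relative 10⁻⁹ and warn.  Degenerate but diagonalizable
cases — notably two non-decaying compartments (ground plus a static
offset) — pass through untouched, which is why the trigger is
conditioning, not eigenvalue gaps.  Cyclic schemes with complex
eigenvalues are out of scope and rejected.

## The fap560 scheme and its parameterization

Compartments: D1* (excited FAD•⁻), P1 = [FADox e⁻H], P2 = [FADox X⁻],
ground.  The printed observables are a sub-IRF branching of ~50%, one
~2.5-ps phase in which the oxidized-flavin band roughly doubles while the
730-nm band partially decays, and a 37-ps full recovery.  Microscopic
forward/backward rates are not observable individually, so the preset is
parameterized by observables:

* φ — branching: c₀ = (1−φ, φ, 0); default 0.5.
* τ₂ — the 2.5-ps phase.  It plays both printed roles at once:
  k_d = 1/τ₂ for the delayed D1*→P1 conversion and k_f + k_b = 1/τ₂ for
  the relaxation rate of the reversible P1 ⇌ P2 exchange.
* ρ — equilibrium fraction left in P1: k_b = ρ/τ₂, k_f = (1−ρ)/τ₂.
  Default 0.3 (not quantified experimentally; chosen so the red band
  decays incompletely in the first phase, and documented as arbitrary).
* τ_slow — the recovery rate k_g (P2→ground) is solved from the exchange
  block's characteristic quadratic so that the slowest eigenvalue is
  exactly −1/τ_slow: k_g = λ_s(s − λ_s)/(k_f − λ_s), λ_s = 1/τ_slow.

This yields observed lifetimes {2.42, 2.50, 37} ps — two phases at the
instrument's effective resolution — while keeping the rate matrix
diagonalizable.  The same parameterization is used by the fit model, so
φ and ρ are directly fittable.

## Component spectra

All transient compartments carry *difference* spectra (that is what ΔA
measures): the ground-state FAD•⁻ absorption is folded in as negative
Gaussian bands at 520 nm (110 nm fwhm, −3 mOD) and 368 nm (60 nm, −1.5),
and the ground compartment is identically zero.  Bands are Gaussian in
wavelength space (the data give no line-shape model).  The positive
oxidized-flavin component band is (468.3 nm, 86.0 nm fwhm, +6 mOD) —
solved once (scratch 0.01-nm grid) so that the *composite* difference
spectrum shows the observed induced-absorption band: 460.0 nm center,
70.0 nm FWHM.  With that bleach magnitude the noiseless blue-band growth
ratio between 0.3 and 10 ps is 1.94, the "almost a factor of 2" the
branching implies.  The hydrated-electron band is (730 nm, 160 nm, +3);
the D1* excited-state absorption is unknown and deliberately omitted
(bleach only) — a documented placeholder.  fap390 uses a broadened hot
band (120 nm fwhm, area-conserving amplitude) that narrows on cooling,
plus a static offset compartment (10% of the population) with a weak band
below 550 nm standing in for a two-electron-reduced fraction outside the
photocycle.

## Global fitting

Variable projection: for trial nonlinear parameters the spectra are
solved per wavelength by linear least squares and only the nonlinear
parameters are iterated (scipy trust-region reflective; analytic model,
numerical Jacobian).  Conventions and defaults:

* rates/lifetimes in log₁₀ space (positivity by construction); IRF width
  bounded [0.02, 0.3] ps; delays before −3σ of the initial IRF guess are
  excluded (coherent-artifact region).
* multi-start: 5 jittered starts (±0.2 decades on log parameters),
  seeded; best cost wins.  Starting values are round plausible guesses,
  not the generator truth.
* standard errors from the Jacobian at the optimum (linearized
  covariance), delta-method-mapped for log parameters.
* **Spectral zero-constraints.**  A target model whose compartment count
  equals its number of kinetic eigenmodes has full rotational freedom:
  any invertible mixing of the concentrations can be absorbed by the
  (free) spectra, leaving φ undetermined.  The standard remedy is prior
  spectral knowledge; the fap560 model constrains the D1* and [FADox X⁻]
  spectra to zero above 620 nm — only the hydrated-electron compartment
  absorbs in the red — implemented as per-wavelength active-column masks
  in the projection.  With the constraint the projection solution at the
  truth is unique and φ, ρ are well determined (over 20 noise seeds:
  φ = 0.50 ± 0.006).

DAS are the spectra attached to the kinetic eigenmodes (parallel model);
EAS are the spectra of the equivalent unbranched sequential chain with
the same lifetimes, fastest first.  We use population-conserving
(unnormalized) sequential concentrations, so EAS ≡ SAS for a sequential
target scheme and EAS₁ = DAS₁ + DAS₂ for two components.  Other codes
renormalize the sequential columns and therefore quote rate-ratio-scaled
relations; only the convention differs — every representation
reconstructs the identical model matrix (checked to 10⁻⁸ relative).

The SVD component-count diagnostic thresholds singular values at the
Marchenko–Pastur bulk edge σ(√m + √n) inflated by a 3-sigma Tracy–Widom
fluctuation allowance.  The bare edge is the *center* of the largest
noise singular value's distribution, so without the allowance pure noise
would be flagged as signal in a large fraction of runs.

## Band metrics

`band_stats` reports the grid argmax refined by a 3-point quadratic plus
the linearly interpolated half-maximum width.  On noisy spectra the raw
argmax of a broad, flat-topped band (the 160-nm-wide 730-nm feature)
scatters by several nm; the optional `smooth_fwhm` applies a Gaussian
kernel first.  A Gaussian kernel leaves a symmetric band's center
unshifted and widens it in quadrature, so the kernel width is deconvolved
from the reported FWHM.  Kernel widths of ~¼ of the expected band width
(30 nm for the red window, 20 nm for the blue) reduce the peak scatter to
<1 nm at 0.1 mOD noise with <0.5-nm bias on the composite band shapes.

## Synthetic data

Default grids: 360–780 nm in 2-nm steps (211 points); delays −1…200 ps,
linear at 0.1 ps to 2 ps then log-spaced to 200 ps (60 points total);
noise 0.1 mOD additive Gaussian, seeded.  These mimic the real
measurement's sampling and signal-to-noise (~3-mOD signals).  What the
generator does **not** emulate: chirp/coherent artifacts, anisotropy,
detector nonlinearity, correlated (pink) noise, and any real uncertainty
about the model class — the fit model matches the generative scheme, so
passing recovery tests demonstrates estimator correctness and
identifiability under the documented conditions, not robustness to model
misspecification on real data.

## Hydration analytics

* **Pocket volume**: cubic grid centered on a seed point (cell edge
  0.4 Å by default); a cell is free if its center is farther than
  vdW + probe (probe 1.4 Å; vdW C 1.7, N 1.55, O 1.52, S 1.8, generic
  1.7 Å, overridable) from every occluding atom and within the search
  radius of the seed; the pocket is the 6-connected flood fill from the
  seed cell; volume = cell count × spacing³.  Cell-center membership and
  6-connectivity are chosen for determinism over marching-cubes
  accuracy; halving the spacing changes smooth-geometry volumes by <5%.
  No periodic imaging (active sites are far from box edges).
* **Water counting**: water = oxygen position only (hydrogens ignored);
  a water resides in the pocket if its position falls in a region cell.
* **RDF**: g(r) = ⟨n(r)⟩/(4πr²Δr ρ) averaged over frames and reference
  atoms, Δr = 0.2 Å by default; minimum-image only when a box is
  present, otherwise the bulk density must be supplied.
* **Distances**: ring–probe distance is centroid–centroid by default
  (the underlying metric is not defined by the observations); min
  heavy-atom pair distance is available for sensitivity checks.
* **Dihedral**: signed atan2-of-cross-products construction, (−180°,
  180°], matching the MDAnalysis convention; the flavin butterfly angle
  is the C4–N5–N10–C9 dihedral.
* **Density maps**: per-cell fraction of frames with ≥1 target atom,
  0.4-Å default grid, written in a plain-text volumetric format.

The toy trajectory generator builds a sealed spherical cage (occluder
spacing ~3 Å, so no probe-sized corridor leaks), a planar 4-atom ring
stand-in, a 3-atom probe group placed on a distance schedule with
isotropic Gaussian jitter, Poisson-distributed pocket waters (placed with
a 3.6-Å clearance so every placed water lands in a solvent-accessible
cell) and bulk waters parked outside the cage to keep the atom roster
fixed.  Randomness uses one spawned stream per frame index, so a frame's
draws do not depend on other frames' schedule entries.
`occupancy_coupling` scales the per-frame Poisson mean linearly with the
scheduled probe distance, emulating a pocket that hydrates as the probe
retreats.

## Problem sizes and tolerances

The bundled analyses run on the default 211×60 grids; fits converge in
well under a second, the full test suite in ~20 s, and the acceptance
script in a few seconds.  Equality tolerances used in the test suite:
eigen vs. stiff-ODE populations 10⁻⁶ (10⁻⁸ on the fap560 preset), kernel
vs. quadrature convolution 10⁻⁶, variable projection vs. dense least
squares 10⁻¹⁰, flood-fill vs. Monte-Carlo volume 3%, dihedral
cross-implementation 10⁻⁹ degrees.

## Known limitations

Single-Gaussian IRF without dispersion; real-rate (non-oscillatory)
schemes only; no Bayesian uncertainty (linearized errors only); binary
trajectory formats (DCD/XTC) are an extension point, not implemented;
the toy trajectories carry no realistic water geometry or protein
topology and the pocket-volume defaults are not calibrated against any
particular cavity-analysis tool, so absolute volumes are validated by
construction (oracle equivalence), not against published cavity numbers.
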