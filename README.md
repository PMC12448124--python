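# photokin

Target analysis of flavin-radical photocycles: global fitting of
transient-absorption (TA) data to compartmental kinetic schemes, and
hydration analytics for the active-site molecular picture behind them.

## The problem

Photoexcitation of the anionic flavin radical (FAD•⁻) in flavoproteins such
as fatty acid photodecarboxylase (FAP) triggers an ultrafast electron
ejection–recombination cycle.  Pump–probe spectroscopy measures the
difference absorption ΔA(λ, t) over ~100 fs – 200 ps; the mechanistic
questions — how much oxidized flavin is formed within the instrument
response, where the ejected electron resides (a hydrated-electron-like
species absorbing near 730 nm vs. an amino-acid acceptor), and how fast the
ground state recovers — are answered by *target analysis*: fitting the full
ΔA matrix with a mechanistic compartmental scheme rather than free
exponentials.  The complementary structural question — whether the
FAD•⁻-state active site is hydrated enough to solvate an electron — is
addressed with pocket-volume, water-count, RDF and density-map metrics on
molecular-dynamics-style trajectories.

`photokin` is for spectroscopists and simulators who want both halves in
one tested toolbox, exercised end-to-end on synthetic data with known
ground truth.

## The model

Populations of the compartments c(t) obey first-order kinetics driven by a
Gaussian instrument response g(t; μ, σ):

    dc/dt = K c + g(t) c₀,     ΔA(λ, t) = Σⱼ cⱼ(t) Sⱼ(λ)

where K is the (closed, column-sum-zero) rate matrix, c₀ the post-branching
initial populations and Sⱼ the species-associated difference spectra (SAS).
Eigendecomposition K = V Λ V⁻¹ gives the closed form

    c(t) = Σₘ vₘ aₘ · ½ exp(λₘ(t−μ) + λₘ²σ²/2) · erfc((μ + λₘσ² − t)/(√2 σ))

(the exponential-convolved-with-Gaussian kernel, evaluated in a stable
erfcx formulation).  Fitting uses **variable projection**: the spectra are
conditionally linear and eliminated per wavelength by least squares, while
the nonlinear parameters (rates in log₁₀ space, branching fraction φ,
equilibrium fraction ρ, IRF center/width) are optimized by a trust-region
method with seeded multi-start.  The recovered spectra can be viewed as
SAS, decay-associated (DAS, eigenbasis/parallel model) or
evolution-associated (EAS, sequential model) spectra — all reconstruct the
identical model matrix.

Three bundled presets encode the studied photocycles:

| preset   | scheme                                             | constants |
|----------|----------------------------------------------------|-----------|
| `fap560` | D1* → [FADox e⁻H] ⇌ [FADox X⁻] → ground, φ = 0.5   | 2.5 ps, 37 ps |
| `fap390` | hot-FADox → FADox → ground, + static offset        | 2.2 ps, 37 ps |
| `gox520` | [FADox acceptor⁻] → ground                         | 20 ps |

## Worked example

```python
import numpy as np
import photokin as pk

data = pk.simulate_ta(pk.build_preset("fap560"))          # 211 x 60 matrix, 0.1 mOD noise
fit = pk.fit_global(data, pk.model_for_preset("fap560"))

print("converged:", fit.converged)
print("time constants (ps):", np.round(fit.time_constants, 2))
print("branching phi: %.3f +/- %.3f" % (fit.parameters["phi"], fit.stderr["phi"]))

red, _ = pk.band_stats(pk.Spectrum(fit.wavelengths, fit.sas["FADox_eH"]),
                       (600, 780), smooth_fwhm=30)
blue, width = pk.band_stats(pk.Spectrum(fit.wavelengths, fit.sas["FADox_X"]),
                            (400, 520), smooth_fwhm=20)
print("e-H band maximum: %.0f nm" % red)
print("FADox band: %.0f nm, FWHM %.0f nm" % (blue, width))
```

prints

```
converged: True
time constants (ps): [ 2.48  2.56 36.89]
branching phi: 0.501 +/- 0.006
e-H band maximum: 730 nm
FADox band: 459 nm, FWHM 68 nm
```

i.e. from a noisy synthetic measurement the fit recovers the ~2.5-ps
equilibration, the 37-ps ground-state recovery, the ~50% sub-IRF branching
into oxidized flavin, the broad hydrated-electron band peaking at 730 nm
and the ~70-nm-wide oxidized-flavin band near 460 nm.

The same stages are scriptable from the shell:

```bash
photokin simulate --preset fap560 --seed 1 --out run/
photokin fit --data run/ta_fap560.csv --preset fap560 --out run/
photokin report --result run/result.json --out run/
```

For the hydration side, `photokin.make_toy_trajectory` generates
role-tagged trajectories (flavin-ring stand-in, probe group stepping
4.2 → 6.5 Å, Poisson-occupied pocket waters inside an occluding cage), and
`pocket_region` / `count_pocket_waters` / `rdf` / `density_map` /
`dihedral` compute the corresponding metrics (flood-filled
solvent-accessible volume on a 0.4-Å grid, resident waters, g(r) at 0.2-Å
resolution, per-cell occupancy maps, the isoalloxazine butterfly dihedral).

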