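# mieinvert

Reconstruction of the frequency-dependent complex permittivity (equivalently
the complex refractive index) of a homogeneous absorbing microsphere from its
mid-infrared extinction-efficiency spectrum.

The observable `Qext(ν̃)` of a wavelength-scale sphere mixes absorption with
strong scattering, so band positions and intensities read off an apparent
absorbance spectrum are distorted. `mieinvert` inverts the scattering problem
directly: it represents the sphere's permittivity as a superposition of
Lorentz dielectric functions — each parameterized by a resonance wavenumber
`nu0`, a strength `nup` and a width `gamma` (all cm⁻¹) plus a constant offset
`eps_inf` — pushes that model through an exact Lorenz–Mie forward computation,
and minimizes the residual sum of squares against the given extinction
spectrum with bounded trust-region least squares. Because every basis
function satisfies the Kramers–Kronig relations with non-negative parameters,
the reconstructed optical constants are physically admissible by
construction.

## Layout

| module                  | contents                                                                 |
|-------------------------|--------------------------------------------------------------------------|
| `mieinvert.dispersion`  | spectral containers, Lorentz and anti-symmetrized-Lorentzian bases, permittivity ↔ refractive-index conversions, numerical Kramers–Kronig validator |
| `mieinvert.mie`         | Mie efficiencies (log-derivative downward recursion, Wiscombe truncation), extinction forward model, absorbance ↔ Qext conversion |
| `mieinvert.inversion`   | residuals/objective, Case I / Case II initializers, `reconstruct_from_qext`, direct permittivity fitting, band matching and error metrics |
| `mieinvert.synthetic`   | random polymer-like materials, six deterministic polymer fixtures, simulated extinction spectra with optional noise |
| `mieinvert.io` / `.cli` | delimited-text readers/writers, fit bundles, run manifests, `mieinvert` command line |

## Command line

```sh
# synthetic material + simulated extinction spectrum of a 5 µm sphere
mieinvert simulate --output sim/ --fixture PMMA --grid 500:4000:600 --seed 1

# forward model: dispersion table -> extinction table
mieinvert forward --input sim/dispersion_truth.csv --output qext.csv --radius-um 5

# inverse reconstruction with the informed (Case II) initializer
mieinvert invert --input sim/qext_given.csv --output fit/ \
    --n-bands 25 --init case2 --truth sim/material.json

# direct permittivity fit (no scattering model in the loop)
mieinvert fit-eps --input sim/permittivity_truth.csv --output epsfit/ --n-bands 17

# Kramers-Kronig consistency report for a permittivity table
mieinvert kk-check --input eps_wide.csv --eps-inf 2.25
```

Every run writes a JSON manifest (config, inputs, outputs, seed, version)
sufficient to reproduce it. Case I places the initial bands equi-spaced over
500–4000 cm⁻¹; Case II concentrates them in the absorbing intervals
500–2200 and 2800–3500 cm⁻¹, leaving the silent windows empty.

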