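# hydrodyn

Site-resolved protein hydration dynamics from femtosecond fluorescence.

`hydrodyn` implements the analysis chain used in tryptophan-probe studies of
water dynamics at protein surfaces — for example around the two cavity probes
(equatorial F44W, apical F281W) of the GroEL chaperonin in its apo
(GroEL₁₄) and football (GroEL₁₄:GroES₁₄) states:

1. **Transient decomposition** — wavelength-resolved fluorescence transients
   (310–370 nm, femtosecond upconversion) are fitted with IRF-convolved
   multiexponentials: up to three *solvation* components (decays on the blue
   side of the emission band, rises on the red side) plus one or two
   *lifetime* components shared globally across wavelengths.
2. **FRES reconstruction** — the fitted models, scaled so their time
   integrals match the steady-state spectrum, are resampled at each delay
   into femtosecond-resolved emission spectra; a lognormal band fit per slice
   (in wavenumber, with the λ²/10⁷ Jacobian) yields the relaxing emission
   peak ν_p(t).
3. **Solvation analysis** — the solvation correlation function
   c(t) = (ν_p(t) − ν_∞)/(ν_p(0) − ν_∞) is decomposed into exponentials
   (τ_Si, f_i); each component carries a Stokes-shift energy
   ΔE_i = f_i·Δν_total and a solvation speed **S_i = ΔE_i/τ_Si** (cm⁻¹/ps).
4. **Anisotropy analysis** — polarized transient pairs from two windows
   (femtosecond upconversion, 3 ns; TCSPC with ~600 ps IRF, 100 ns) give
   r(t) = (I∥ − gI⊥)/(I∥ + 2gI⊥), jointly fitted with four components
   (sub-100-fs internal conversion, two wobbling motions τ_W2/τ_W3, constant
   tumbling floor).  Sequential wobbling-in-cone analysis converts the
   amplitudes into cone semiangles θ_i via S_cone = ½cosθ(1+cosθ) and
   angular speeds **ω_i = θ_i/τ_Wi** (deg/ps).
5. **Hydration-shell census** — water oxygens within distance classes of the
   probe's indole ring (10 Å universe, 5 Å) and of the protein surface
   (5 Å, 7 Å, beyond 7 Å), per frame, averaged across symmetry-equivalent
   monomer sites of a multi-model PDB.

A synthetic-data module forward-simulates every input with known ground
truth — a relaxing lognormal emission band times a lifetime decay, analytic
polarized pairs, Gaussian/Poisson detection noise, and geometric water
scenes — so the full chain is testable as a parameter-recovery problem
without any experimental data.

## Worked example

```python
from hydrodyn import run_pipeline

summary = run_pipeline({
    "preset": {"site": "F44W", "state": "apo"},
    "seed": 1,
    "total_shift": "back_derived",
})
print(f"lambda_peak = {summary.lambda_peak:.1f} nm")
print("tau_S (ps)  =", [round(x, 2) for x in summary.tau_s])
print("fractions   =", [round(x, 2) for x in summary.fractions])
print("S (cm-1/ps) =", [round(x, 1) for x in summary.speeds_s])
print("tau_W (ps)  =", [round(x, 1) for x in summary.tau_w])
print("omega (deg/ps) =", [round(x, 4) for x in summary.omega])
```

prints

```
lambda_peak = 349.6 nm
tau_S (ps)  = [1.12, 6.2, 52.64]
fractions   = [0.48, 0.41, 0.1]
S (cm-1/ps) = [459.8, 71.6, 2.1]
tau_W (ps)  = [27.0, 699.0]
omega (deg/ps) = [0.71, 0.0269]
```

i.e. the full chain run on noiseless synthetic data generated from the
equatorial-probe apo reference parameters (solvation times 1.1/6.0/51 ps at
47/42/11 % of the total Stokes shift, wobbling times 27/699 ps at
0.71/0.0269 °/ps) recovers those parameters: three heterogeneous
few-picosecond water relaxations and two side-chain wobbling motions whose
speeds track the solvation speeds.

The same stages are exposed on the command line:

```bash
hydrodyn simulate --site F44W --state apo --seed 1 --out sim/
hydrodyn fit-transients --in-dir sim/ --n-solv 3 --n-life 2 --out fits.json
hydrodyn solvation --fits fits.json --steady-state sim/F44W_apo_steady_state.tsv --out solv.json
hydrodyn shells --pdb traj.pdb --out census.tsv
```

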