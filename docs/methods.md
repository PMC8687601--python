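# Methods

## The physical model

### Emission band and spectral relaxation

Tryptophan emission is modelled as a lognormal band in wavenumber
(Maroncelli–Fleming form) with height h, peak ν_p, full width Δ (cm⁻¹) and
dimensionless asymmetry γ:

    α(ν) = 2γ(ν − ν_p)/Δ
    g(ν) = h · exp[−ln2 · (ln(1+α)/γ)²]   for 1+α > 0, else 0.

γ → 0 recovers a Gaussian; γ < 0 puts the tail on the low-energy side, as
observed for indole emission.  Solvation relaxation is modelled as a pure
peak shift at constant width and asymmetry:

    ν_p(t) = ν_∞ + (ν_0 − ν_∞) Σ_i f_i e^(−t/τ_Si),   Σ f_i = 1,

multiplied by a population decay K(t) = Σ_j w_j e^(−t/τ_life,j).  The band
shape itself is a modelling choice — the analysis chain only consumes the
peak trajectory, and the slice fitter assumes the same lognormal family, so
generator and fitter are self-consistent by construction.  Defaults:
Δ = 5200 cm⁻¹, γ = −0.3, typical of tryptophan emission; both configurable.

A transient detected at wavelength λ is the per-nm intensity
I(λ,t) = g(ν(λ); ν_p(t)) · (10⁷/λ²) · K(t) convolved with a Gaussian IRF.
ν = 10⁷/λ is the vacuum wavenumber, and the 10⁷/λ² Jacobian converts
per-cm⁻¹ to per-nm intensity; since all reported energies and speeds are in
cm⁻¹, every band fit is done on the energy axis.

### Reference parameter sets

Four probe/state systems (equatorial F44W and apical F281W of the GroEL
cavity, each in the apo and football states) are bundled as presets: three
solvation components, two lifetimes, the steady-state emission peak, and two
wobbling components each.  Two derived quantities need construction:

* **Total Stokes shift.** Only fractions and speeds are tabulated, so the
  total is back-derived from the second component as S₂τ₂/f₂ (≈1071 cm⁻¹
  for apo F44W; 957, 914, 1161 cm⁻¹ for the others).  The three components
  of each row give the same total within ~6 % (rounding), which is also a
  consistency test.  This back-out is an internal construction, not an
  independently reported value.
* **Band placement.** The relaxed-peak parameter ν_∞ is calibrated by root
  finding so that the time-integrated (steady-state) spectrum of the full
  model peaks at the tabulated wavelength; ν_0 = ν_∞ + total shift.  The
  steady state is computed by Simpson quadrature in log-time (relative
  accuracy ~1e-9), and the spectrum peak is located on the fitted band, not
  the sampling grid.

### Instruments and noise

Two detection schemes are modelled.  Femtosecond upconversion: Gaussian IRF
of 0.15 ps FWHM (configurable; sub-pulse-width resolution), log-spaced
sampling 0.01–3000 ps (301 points), additive Gaussian noise scaled to the
trace peak.  TCSPC: 600 ps FWHM IRF, linear 0–100 ns grid (1001 points),
Poisson counting noise with the parallel-channel peak scaled to a target
count (default 10⁴).  Band-model transients are convolved numerically
(trapezoid over the ±8σ Gaussian span, truncated at t = 0); all polarized
and multiexponential signals use the closed-form exp⊗Gaussian kernel
0.5·erfcx(z)·exp(−t²/2σ²), evaluated in a two-branch form that is stable
from σ/τ ≪ 1 to σ/τ ≫ 1.

## Fitting

### Per-wavelength and global transient fits

Each transient is fitted as an IRF-convolved sum of solvation exponentials
(amplitudes free in sign: rises on the red side) and lifetime exponentials
(non-negative).  Decay times are bounded by class — solvation 0.05–200 ps,
lifetime 0.1–20 ns — encoding the empirically clean timescale separation;
both bounds are overridable.  Optimisation is variable projection:
trust-region least squares over log-times with the amplitudes solved by
weighted linear least squares at each step, multi-start over log-spaced
initial times.  The global mode links the lifetime times across all
wavelengths (one lifetime pair per dataset) and is the default; independent
per-wavelength fitting is also available since either protocol is defensible.
Components with fitted time below IRF_FWHM/3 are flagged unidentifiable
rather than trusted.

Note that the *per-wavelength* solvation times are not the c(t) times: a
fixed detection wavelength samples the moving band nonlinearly, so local
timescales vary across the band (they are reported as per-trace ranges in
this kind of experiment).  Recovery of the generating times is therefore
asserted at the c(t) level, and at the single-trace level only for traces
that are exactly multiexponential.

### FRES and ν_p(t)

Fitted models are rescaled so each analytic time integral Σ a_k τ_k equals
the steady-state intensity at that wavelength (the IRF conserves the
integral), then evaluated IRF-free at 60 log-spaced delays 0.05–3000 ps plus
t = 0.  Each slice is converted to the energy axis and fitted with the
lognormal; fits are warm-started from the neighbouring slice and flagged
slices are interpolated over.  The t = 0 slice defines the time-zero
spectrum and hence ν_p(0) after deconvolution.

### c(t) and speeds

c(t) = (ν_p(t) − ν_∞)/(ν_p(0) − ν_∞).  ν_∞ defaults to the mean of ν_p over
the last decade of the window (the plateau); a steady-state-derived value
may be supplied instead, and the difference between the two conventions is
visible in the stored nu_inf.  A shift below 0.5 cm⁻¹ is treated as
degenerate and rejected — no peak fit resolves less.  The multiexponential
fit of c(t) uses non-negative amplitudes (normalised to fractions
afterwards) and weights each delay by the inverse RMS misfit of its slice
fit (1/√gof): the slice residual is the natural noise scale for ν_p(t), and
the reconstruction error concentrates at early delays where the
multiexponential per-wavelength models approximate the band kinetics least
well.  On noiseless synthetic data this chain recovers the generating times
within ~4 % and fractions within ~1.5 points; the residual bias is the
multiexponential-approximation ripple (≈0.1 % of peak per trace, ≈3 cm⁻¹ in
ν_p), which also means ν_p(t) is monotone only up to that ripple.

Energies and speeds: ΔE_i = f_i · Δν_total and S_i = ΔE_i/τ_Si.  The energy
partition total defaults to the measured ν_p(0) − ν_∞; the back-derived
preset total can be requested when comparing with tabulated speeds.

### Anisotropy

r(t) is built per window from (I∥ − gI⊥)/(I∥ + 2gI⊥) with per-point error
propagation (g = 1 for synthetic data).  Because the detected intensities
are lifetime-weighted, an IRF-broadened anisotropy is conv(K·r)/conv(K),
not conv(r); both numerator and denominator are exponential sums, so each
branch's model is analytic in its IRF width.  The joint fit shares four
components across windows — β_IC (τ_IC ≤ 0.2 ps, bounding the sub-100-fs
internal conversion), β₂/τ_W2 (1–200 ps), β₃/τ_W3 (0.2–20 ns), and a
constant floor β_T (tumbling of the MDa-scale complex, effectively
non-decaying in both windows).  The TCSPC branch pins β_T; fitting without
it is allowed but flagged, and a TCSPC-only fit fixes the IC component,
which a 600 ps IRF cannot resolve.  The population decay entering the model
is fitted from the isotropic combination I∥ + 2I⊥ of the long-window pair.

Cone analysis uses the sequential (nested) wobbling-in-cone decomposition:
for cone i, S²_cone,i = (Σ of strictly slower amplitudes incl. β_T)/(Σ of
at-or-slower amplitudes), and θ solves S = ½cosθ(1+cosθ) on (0°, 90°]
(closed form via the quadratic in cosθ).  An independent-cones convention
(each cone referenced to the total wobbling amplitude) is provided as an
alternative since the decomposition convention is not uniquely fixed by the
data; the choice is recorded in the result metadata, and the two agree for
the fastest cone.  Angular speeds are ω_i = θ_i/τ_Wi in deg/ps.

## Hydration-shell census

Distances are minima over heavy atoms; waters are represented by their
oxygen; hydrogens are ignored.  The per-frame universe is waters within
10 Å of the probe's indole ring (9 heavy atoms, default TRP names CG, CD1,
CD2, NE1, CE2, CE3, CZ2, CZ3, CH2); sub-classes are within 5/7 Å of any
protein heavy atom ("surface" — the accessible-surface subset is not used),
within 5 Å of the ring, and beyond 7 Å of the surface (outer hydration
layers).  Counts use k-d trees and match a brute-force double loop exactly.
No periodic boundaries by default (cavity geometry); an orthorhombic box is
accepted for real trajectories.  Multi-model PDBs are read through
MDAnalysis; symmetry-equivalent probe residues are censused separately and
averaged (mean and n−1 standard deviation per class).

### Synthetic scenes

Scenes are geometric stand-ins (no chaperonin structure is simulated): a
slab surface, optionally with a cylindrical cave or pit, a standard indole
ring placed at a preset height, and water oxygens rejection-sampled into the
three surface-distance classes at requested occupancies (exact by
construction; infeasible requests fail loudly after bounded attempts).
Presets: *exposed* (180 waters, 40 beyond 7 Å), *caved* (170 waters, 125
within 5 Å, 8 beyond 7 Å), *buried* (90 waters, all within 5 Å) — the
proportions characteristic of a fully exposed probe, a probe in an open
cave, and a probe inserted into the surface.  Water–water spacing is a loose
1.6 Å floor; these scenes exercise the counting geometry, not water
structure.  Monomer copies are placed on a 120 Å ring so replicas cannot
interact.

## What the synthetic data do and do not establish

The generator shares the band family, kinetic structure, and noise models
with the fitter, so passing recovery tests demonstrates that the chain is
internally consistent, deconvolves the IRF correctly, and propagates
energies and angles without bias — not that real data obey a lognormal band
with time-independent shape, discrete exponential kinetics, or Gaussian
IRFs.  Width/asymmetry relaxation, lifetime heterogeneity across the band,
scattering backgrounds, and g-factor drift are all absent.  The quenching
interaction — a sub-ns lifetime that can merge with the slowest solvation
component — is present in the parameter sets (315/271/240/284 ps short
lifetimes), and its main symptom survives: the slowest solvation time is the
least precisely recovered quantity in the chain.

## Problem sizes and numerical choices

Synthetic studies run at the experiment's own scale: nine wavelengths
spanning 310–370 nm, 301 points per upconversion trace, 1001 per TCSPC
trace, 61 FRES slices, 20 replicates for the noisy-lifetime study.  All fits
use tight tolerances (xtol = ftol = 1e-14) so noiseless recoveries are
limited by model structure, not optimizer early exit.  Multi-start counts
(5 single-trace, 3 global/correlation/anisotropy starts) were chosen as the
smallest sets that made every preset fit land in the same basin from
disjoint initialisations.  Default seed 20210615; every stochastic operation
takes an explicit seed and is bit-reproducible.

## Known limitations

* Discrete exponentials only; no lifetime/solvation-time distributions.
* Spectral relaxation is peak-shift only; width/asymmetry dynamics are
  neither generated nor interpreted.
* The cone decomposition convention (nested vs independent) is a modelling
  choice for the slower cone; results record which was used.
* The census treats "protein surface" as any heavy atom, not an
  accessible-surface subset, and reports counts only (no residence times).
* Back-derived Stokes-shift totals inherit the rounding of the tabulated
  speeds (~6 % row-internal spread).
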