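# Methods

## Spectral model and transforms

The raw Stokes intensity of a low-frequency Raman band is treated as
proportional to (ω₀−ω)⁴·(n(ω,T)+1)·S: the ω⁴ factor is instrument/scattering
throughput, n(ω,T)+1 = [1−exp(−c₂ω/T)]⁻¹ the thermal occupation (Bose)
factor, and S the intrinsic scattering activity. Below ~150 cm⁻¹ the Bose
factor varies strongly across a band and distorts broad features, so all
fitting operates on

* reduced intensity I_r(ω) = I(ω,T)/[(n+1)·ω], or
* Raman susceptibility χ″(ω) = ω·I_r(ω) = I(ω,T)/(n+1).

Choices and constants:

* c₂ = hc/k_B is fixed at **1.4387769 cm·K** (CODATA second radiation
  constant).
* Only the Stokes side is handled; anti-Stokes is out of scope.
* The 1/ω divergence of the reduction is handled by a hard low-frequency
  **cutoff, default 5 cm⁻¹** — the practical elastic-rejection limit of
  triple-monochromator instruments — never by regularization. Points below
  the cutoff are dropped.
* The (ω₀−ω)⁴ correction is **off by default** (the proportionality is a
  statement about the raw signal, not a mandated correction; whether to
  apply it before fitting is a lab convention). When applied it is
  normalized to 1 at ω = 0, so corrected and uncorrected spectra share an
  intensity scale, and it is exactly invertible.
* The light–vibration coupling coefficient C(ω) is never separated from the
  density of states; only the product χ″ = ω·I_r is computed.
* Temperatures are accepted in °C in manifests (the unit experimentalists
  log) and carried in kelvin internally (the unit the Bose factor needs).

## Decomposition of the low-frequency spectrum

In reduced/susceptibility representation the spectrum of a (partially)
disordered molecular solid is modeled as the sum of

* **QES** — quasi-elastic scattering from fast local relaxational motions: a
  Lorentzian centered at ω = 0 evaluated on ω > 0,
  L(ω) = A·Γ²/(ω²+Γ²), with amplitude A (height at ω→0) and HWHM Γ;
* **VDOS** — a lognormal envelope
  V(ω) = A·exp(−[ln(ω/ω_c)]²/(2σ²)) parameterized by its mode position ω_c
  (cm⁻¹) and dimensionless log-width σ (the lognormal shape reflects the
  distribution of local molecular packings; the parameterization by mode and
  log-width is this package's choice — the shape family itself carries no
  canonical parameterization);
* optional **phonon peaks** as pseudo-Voigt profiles with free Lorentzian
  fraction η ∈ [0,1], shared FWHM between the two parts, amplitude = height.

I_QES is reported as the **integrated Lorentzian area over the fit window**
(closed form A·Γ·[arctan(ω_hi/Γ) − arctan(ω_lo/Γ)]), not the peak amplitude:
the area is robust against the amplitude/half-width trade-off of shallow
minima. Its uncertainty is first-order (delta-method) from the parameter
standard errors.

Numerical choices: bounded nonlinear least squares (lmfit/trust-region
reflective), uniform weights by default, iteration cap 500×(n_params+1)
function evaluations; component templates (initial values and bounds) are
always caller-supplied — no automatic peak detection; along a series each
fit is warm-started from the previous converged solution, and a
non-converged spectrum flags its row of the I_QES trace rather than aborting
the trace. Identifiability is handled by bounds (all amplitudes ≥ 0,
η ∈ [0,1], widths > 0), not penalties. Standard errors are asymptotic, from
the local curvature.

## Transformation fraction ρ(t)

Two estimators, reported side by side:

* **Unmixing (primary).** Each spectrum is fitted as a·S_h + b·S_a with
  a, b ≥ 0 by non-negative least squares against hydrate/anhydrate endmember
  references; ρ = b/(a+b), clipped to [0,1]. Closure a+b = 1 is *not*
  enforced — overall scattering efficiency can drift during a run — and the
  ratio makes ρ invariant under uniform intensity rescaling. Unmixing
  operates on the reduced-intensity representation by default, which removes
  the trivial temperature dependence first.
* **Water-band tracking (secondary).** The trapezoidal area A(t) of the
  water-marker band (default window 60–100 cm⁻¹, around the ~80 cm⁻¹ band
  present only in hydrates) anchored to the first and last spectra:
  ρ = (A₀−A)/(A₀−A_∞). The normalized remaining area
  (A−A_∞)/(A₀−A_∞) is reported as the **water-escape trace** (1 → 0), so
  lattice transformation (unmix ρ) and water escape can be compared
  directly.

t_1/2 is the first upward crossing of ρ = 0.5, linearly interpolated between
the bracketing samples (deterministic under noise); the master curve plots ρ
against t/t_1/2, which removes the rate constant and collapses curves
sharing one mechanism.

## Kinetic models and fitting

Catalog (integral forms g(ρ) = k·t): Avrami A(n) ρ = 1−exp(−k·tⁿ);
F1 −ln(1−ρ); R2 1−(1−ρ)^{1/2}; R3 1−(1−ρ)^{1/3}; D1 ρ²;
D2 (Valensi) (1−ρ)ln(1−ρ)+ρ; D3 (Jander) [1−(1−ρ)^{1/3}]²;
D4 (Ginstling–Brounshtein) 1−2ρ/3−(1−ρ)^{2/3}. The Avrami law is written
with **k in min⁻ⁿ** (f = 1−exp(−k·tⁿ)), with a helper to convert to the
(k′·t)ⁿ convention. D2 and D4 have no closed ρ(t); g is inverted by a dense
monotone interpolation table refined with Newton steps to ~1e−14 residual,
with the exact asymptotic value ρ = 1 past completion.

Fitting is nonlinear least squares on ρ(t) directly (Levenberg–Marquardt in
log-parameter space, which enforces positivity without active bounds),
restricted by default to **ρ ∈ [0.05, 0.95]** — the baseline and saturation
tails carry no mechanistic information and are the regions most biased by
the anchored estimators. The window is overridable. The Avrami fit is
initialized from the Sharp–Hancock linearization (slope of ln(−ln(1−ρ)) vs
ln t); one-parameter models from the observed half-transformation time via
k₀ = g(0.5)/t_half. Standard errors are asymptotic (curvature in log space,
delta method back to linear), matching the "value ± error" convention for
reported exponents.

Model selection ranks by **AICc** with K = n_params + 1 (the noise variance
counted as a parameter, the standard least-squares convention); R² is
reported alongside. Ties break deterministically by fewer parameters, then
model id. "Best agreement" in the source experiments is thereby made
operational as an information criterion; the ranking, not just the winner,
is always reported.

## Synthetic data: what it emulates, and what it does not

Endmember spectra are deterministic sums of pseudo-Voigt phonon peaks, an
optional lognormal VDOS and an optional QES Lorentzian, in susceptibility
units, loosely styled on the low-frequency spectra of the two xanthine
hydrates: sharp lattice modes below 150 cm⁻¹; the ~80 cm⁻¹ water band in
both hydrates; an extra 25 cm⁻¹ lattice mode in the theophylline
dehydration product; broad librational bands (no sharp phonons) in the
orientationally disordered caffeine anhydrate; and a slightly larger QES in
the dehydrated forms (disorder induced by water escape). The peak tables
claim no spectroscopic accuracy. In the unmixing (reduced-intensity)
representation the hydrate's 60–100 cm⁻¹ band area exceeds the anhydrate's
by a factor ≥ 5 for both pairs (verified by test), so band tracking is
well-posed.

A simulated run evolves ρ*(t) under a chosen kinetic law, mixes endmembers
linearly in susceptibility, adds **additive homoscedastic Gaussian noise in
susceptibility units** (σ as a fraction of the maximum endmember intensity;
Poisson/shot noise, baseline drift and cosmic rays are not modeled), and
converts to raw counts by the exact inverse of the transforms
(I = χ·(n+1)), so at σ = 0 the forward pipeline recovers ρ* at machine
precision. All randomness flows through one seeded generator.

Named fixtures (the package's study conditions):

| fixture     | law          | exponent | t_1/2    | T, RH        | seed |
|-------------|--------------|----------|----------|--------------|------|
| tp_noRH     | Avrami       | n = 2.95 | 100 min  | 35 °C, —     | 42   |
| tp_1RH_23C  | Jander (D3)  | —        | 600 min  | 23 °C, 1 %   | 44   |
| caf_20RH    | Avrami       | n = 1.410| 200 min  | 23 °C, 20 %  | 43   |

The exponents and mechanisms are the published isothermal fits for these
systems; the t_1/2 anchors are desk-scale conveniences (no rate constants or
half-times are tabulated for the original runs — the package therefore makes
no claim about absolute rates), and noise σ = 0.005 reflects the high
signal-to-noise of minutes-long lattice-region acquisitions. Each fixture
uses 60 time points log-spaced from t_1/2/50 to 4·t_1/2 — log spacing
resolves both the induction and saturation regimes the way a practitioner
schedules acquisitions, and the start/end span is chosen so the default
ρ ∈ [0.05, 0.95] fit window contains well over the minimum six points for
every law.

Passing tests on these fixtures demonstrate estimator correctness and
calibration under the stated noise model; they do not demonstrate robustness
to baseline drift, intermediate (third-phase) crystalline forms, or
heteroscedastic counting noise, all of which real runs can contain.
Intermediate metastable forms are explicitly not simulated: the two-endmember
model is exact in the simulation and only approximate in experiments that
traverse such states.

## Known limitations

* The ρ estimators are two-endmember; series traversing distinct
  intermediate phases violate the mixture model (the unmixing residual, not
  currently reported per spectrum, would flag this).
* The band-tracking estimator anchors to the first/last spectra and is
  biased when the run starts after nucleation or ends before completion.
* Kinetic uncertainties are asymptotic; for strongly correlated (k, n) pairs
  near the window edges a profile or bootstrap interval would be wider.
* Non-isothermal (Kissinger/Friedman) analysis and Arrhenius activation
  energies across temperatures are out of scope; fits are per-run,
  isothermal.
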