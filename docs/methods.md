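# Methods

This note records the models implemented in `aaokin`, their assumptions,
the defaults that matter, and the numerical choices made where the design
was genuinely open. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Bi-substrate steady-state kinetics

Initial rates per enzyme (v0/e, s^-1) over an (alcohol A, acceptor B)
grid follow either the ternary-complex (sequential) law

v0/e = kcat·A·B / (KmB·A + KmA·B + A·B + Kd·KmB)

or its nested ping-pong limit (Kd → 0). Both are fitted by unweighted
nonlinear least squares (lmfit/Levenberg–Marquardt): on a saturating grid
rates span less than an order of magnitude, so unweighted residuals are
the standard choice for initial-rate data. Initial guesses come from the
Hanes–Woolf linearization — kcat from the reciprocal slope at the highest
acceptor level, KmA from intercept·kcat, KmB from the B-dependence of the
slopes — with five additional log-normally perturbed restarts (σ = 0.7 in
log space) as a safety net. Standard errors are the asymptotic
(covariance-matrix) estimates.

Identifiability requires at least three distinct levels of each
substrate; anything less is rejected as a rank-deficient design.

### Mechanism discrimination

In Hanes–Woolf coordinates ([A]/v0 against [A]) the ping-pong law gives
lines with a common intercept KmA/kcat; the sequential law adds
Kd·KmB/(kcat·B), raising intercepts at low acceptor. The verdict
combines:

1. ΔAICc = AICc(sequential) − AICc(ping-pong) > −2 (the extra constant
   must pay for itself), and
2. a chi-square homogeneity test of the per-level Hanes intercepts
   against their inverse-variance weighted mean (α = 0.005).

Ping-pong is chosen when both hold, otherwise sequential. The stringent
α reflects that intercept standard errors from five-point lines are
themselves noisy: interval-overlap rules built on them veto the
ping-pong hypothesis far too often on data actually generated from it,
while the pooled chi-square statistic keeps the false-sequential rate at
the few-percent level and still rejects homogeneity decisively for
sequential data down to Kd ≈ KmA/2 (both behaviours are exercised in the
test suite).

### Oxygen concentrations

Gas-mixture percentages convert to dissolved concentration as
[O2] µM = (%O2/100)·(258/0.21), anchored at an air-saturation value of
258 µM (25 °C, aqueous buffer). The anchor and air fraction are
arguments of `o2_percent_to_uM`: the Henry's-law constant is temperature-
and medium-dependent, so any tabulated Km(O2) is meaningful only together
with the conversion used.

## Transient-state kobs analysis

Three functional forms, all fitted on kobs series averaged over
replicates:

* **Reduction** (hyperbolic): kobs = kred·A/(Kd+A) + krev. Starting
  values: kred ← 1.2·max(kobs), Kd ← concentration at half-maximum
  (interpolated), krev ← min(kobs)/2; krev is bounded at zero. A
  "krev negligible" flag is set when its 95% CI touches zero (or it is a
  vanishing fraction of kred), and a saturation warning when
  max(kobs) < 0.7·kred — in that linear regime only the ratio kred/Kd is
  determined.
* **Reoxidation** (linear): kobs = app_kox·[acceptor] + intercept,
  weighted by 1/SE² when per-point errors exist. The y-intercept is an
  empirical quantity distinct from the hyperbolic krev (reverse hydride
  transfer); the two live in separate result types to prevent
  conflation, and no mechanistic model is attached to the intercept.
* **Dead-end binding** (linear): kobs = kon·[L] + koff, with
  Kd = koff/kon (reported in µM from s^-1 and s^-1 mM^-1 inputs). The SE
  of Kd uses the first-order delta method (relative variances add); the
  test suite checks it against an empirical seed ensemble. When the
  fitted koff is statistically indistinguishable from zero the Kd is
  reported as a "not detected" sentinel (`None`), never as zero; a koff
  negative beyond 2 SE raises a data-inconsistency error.

## Global spectral analysis

A photodiode-array measurement is a matrix D (n_times × n_wavelengths)
modelled as D = C(k)·S: C holds the closed-form concentration profiles of
a sequential first-order scheme (A→B, or A→B→C with the confluent limit
k1·t·e^(−k1·t) when the two rates coincide), S the species spectra.
Fitting uses variable projection: for candidate rates S is the linear
least-squares solution, and only the (log) rates are optimized on the
projected residual, seeded by a log-spaced grid scan spanning
0.05/t_max to 5/t_min. This separable treatment is the standard, stable
approach for exponential models and operates on the native
(typically logarithmic) time grid without resampling.

Species spectra are deliberately **not** constrained non-negative —
difference spectra can dip below zero — though non-negative least squares
is available behind a flag. Reported rates are ordered fast phase first
(k1 ≥ k2); this also resolves the well-known k1↔k2 amplitude-exchange
ambiguity of two-step schemes in favour of the solution whose first phase
carries the larger amplitude in the generated cases.

Rank estimation retains singular values above
5·noise_sd·sqrt(max(n_times, n_wavelengths)), a Marchenko–Pastur-style
noise-floor bound (multiplier configurable; a machine-precision relative
threshold is used for noiseless input). Step-model selection fits both
schemes and picks two steps only when AICc improves by more than 10 *and*
the rank estimate supports three spectrally distinct species; rank-1
(no-evolution) input degrades to a one-step result with a zero-amplitude
warning. Single-wavelength traces are fitted with the equivalent
offset-plus-exponentials model by the same separable strategy; rates
separated by less than 3× trigger a collinearity warning.

## Catalytic-cycle simulation

Three nested variants of the redox cycle are integrated by mass action
(scipy `solve_ivp`, BDF, rtol 1e-8, atol 1e-12 µM — rates span
10^0–10^3 s^-1, so a stiff method is required):

* **minimal**: Eox →(kred·A/(Kd+A)) Ered →(app_kox·[B]) Eox. Alcohol
  binding is folded into the effective hyperbolic rate.
* **product_release**: adds an oxidized product-bound state EoxQ that
  releases the reduced acceptor at krel — the variant for probing
  whether hydroquinone/product release limits turnover.
* **explicit_binding**: mass-action alcohol binding (kon_S, koff_S)
  followed by hydride transfer at kred.

Pools (alcohol, aldehyde, acceptor, reduced acceptor) deplete unless
clamped; enzyme and both pool balances are conserved to 1e-9 relative
(bound substrate counted), which the tests assert. Band-I absorbance is
A462 = Σ ε_i·[species_i]·ℓ with defaults ε_ox = 11,300 and
ε_red = 900 M^-1 cm^-1 — typical flavoprotein band-I magnitudes that
**must** be replaced by measured values for quantitative comparison with
a real trace.

The King–Altman closed form for an irreversible cycle of
pseudo-first-order steps gives turnover 1/Σ(1/k_i) and state occupancies
∝ 1/k_i; for the minimal cycle this is algebraically the ping-pong law
with kcat = kred, Km(alcohol) = Kd and Km(acceptor) = kred/app_kox, an
identity `scan_apparent_kinetics` exposes and the tests verify to
machine precision. For the explicit-binding variant the closed form uses
the Briggs–Haldane effective constant (koff_S+kred)/kon_S. The
clamped-pool ODE relaxes to the closed-form steady state (tested to
1e-4); the plateau detector for absorbance traces uses the longest
interval with |dA462/dt| below 1% of the maximal reduction slope by
default — note that at half-reaction rates of order 10^2 s^-1 this window
still contains a small relaxation tail, so oracle comparisons use a
stricter slope threshold.

Rate constants are taken verbatim with their declared measurement
temperatures; reduction (25 °C) and reoxidation (12 °C) constants from a
single characterization are physically inconsistent inside one
simulation, so mixed declared temperatures raise a warning rather than an
error, and no temperature correction is attempted.

## ITC one-site analysis

The cell is modelled with the perfusion approximation: constant volume
V0 (default 200 µL, an ITC200-class cell), each injection of volume v
diluting both species by (1 − v/V0) and adding syringe·v/V0 of ligand.
Bound concentration follows the quadratic binding polynomial with n·M
total sites; the heat of injection i is
q_i = ΔH·V0·(B_i − (1 − v/V0)·B_{i−1}). The instrument's exact mixing
convention differs between vendors; this one is declared, internally
consistent between simulation and fitting, and reproduces the
stoichiometric tight-binding limit (first-injection heat ≈ ΔH × injected
moles).

Fitting optimizes log10(Ka), ΔH and n (multi-start over log10 Ka from 4
to 9). Derived quantities use Kd = 1/Ka, ΔG = RT·ln Kd (R = 1.987×10^-3
kcal mol^-1 K^-1, T default 298.15 K) and −TΔS = ΔG − ΔH, which hold to
machine precision by construction. Identifiability flags follow the
Wiseman parameter c = n·Ka·[cell]: c < 1 (shallow isotherm) and c > 1000
(step-like, Ka only bounded below). For low-c titrations the
stoichiometry is unidentifiable and should be clamped via `fix_n`
(standard practice when the 1:1 stoichiometry is known); with n free at
c ≈ 0.5 the strong Ka–ΔH–n correlation inflates the ΔH scatter several-
fold. Buffer-ionization corrections are deliberately not modelled: all
enthalpies are observed values in the assay buffer. A first-injection
discard flag exists (off by default).

## Synthetic data

Generators evaluate the exact forward models above and add declared
noise: multiplicative Gaussian 2% on initial rates, 3% on kobs,
additive 0.002 AU on spectra, and additive 2% of the largest |heat| on
ITC injections — typical scatter for these instrument classes; none is
dictated by the underlying data. All seeds are explicit arguments
(numpy `default_rng`), identical seeds giving bit-identical output.
Replicate averaging (3–5 draws per point, as practiced for stopped-flow
kobs) shrinks effective noise by √replicates.

The flavin spectral template is a sum of Gaussian bands: oxidized band I
at 462 nm and band II at 385 nm, a low broad reduced spectrum, and — for
three-species schemes — an intermediate given the oxidized/reduced
midpoint plus a distinct long-wavelength (560 nm) feature, since an
intermediate that is an exact linear mixture of the end states would be
spectrally rank-deficient and unidentifiable by any global method.

What the generators do **not** emulate: instrument dead time,
stray-light or baseline drift, wavelength-correlated noise (noise is
i.i.d. per pixel), photodegradation of benzoquinone, and buffer
ionization heats. Passing recovery tests therefore demonstrate the
estimators' correctness and statistical behaviour under the declared
noise models, not robustness to these real-data artefacts.

## Problem sizes and defaults

Recovery experiments use the designs of the underlying study: 5×5
concentration grids spanning 0.2–10×Km; 8-point reduction series up to
6×Kd; 6-point binding series 0.5–8 mM; 19×2 µL titrations; 30×61
spectral matrices over 0.003–0.15 s and 400–700 nm. Medians over five
seeds are reported wherever noise is involved. All computations run in
seconds on a single CPU.

## Known limitations

* Reproduction of absolute Km(O2) values depends on the %O2→µM
  convention, which published tables rarely state; only the configurable
  conversion above is provided.
* The cycle simulator's minimal variant predicts the oxidized
  steady-state fraction implied by its two effective rate constants;
  when reduction and reoxidation constants were measured at different
  temperatures the prediction cannot be compared quantitatively with a
  turnover trace recorded at a single temperature.
* Asymptotic standard errors are first-order; for strongly correlated
  parameters (low-c ITC, closely spaced exponentials) they understate
  the true uncertainty, which the warning flags are meant to signal.
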