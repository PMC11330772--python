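# aaokin

Kinetic and thermodynamic analysis for flavoenzymes with dual
oxidase/dehydrogenase activity, built around aryl-alcohol oxidase (AAO), a
GMC-superfamily FAD enzyme that oxidizes aryl alcohols to aldehydes and
re-oxidizes its flavin with either O2 (oxidase) or quinones such as
1,4-benzoquinone (dehydrogenase). The package is aimed at enzymologists who
characterize such systems by steady-state bi-substrate kinetics,
stopped-flow transient kinetics and isothermal titration calorimetry, and
want one tested, scriptable pipeline — plus seeded synthetic-data
generators standing in for the instruments.

## What it computes

**Steady state** (`aaokin.steady_state`). Initial rates v0/e over an
(alcohol A, acceptor B) grid are fitted to the ternary-complex law

    v0/e = kcat·A·B / (KmB·A + KmA·B + A·B + Kd·KmB)

or its ping-pong (substituted-enzyme) limit Kd → 0. Mechanism
discrimination combines AICc with the Hanes–Woolf criterion: in [A]/v0 vs
[A] coordinates a ping-pong mechanism gives lines sharing the y-intercept
KmA/kcat at every acceptor level. Efficiencies kcat/Km are reported in
s^-1 mM^-1.

**Transient state** (`aaokin.transient`). Observed stopped-flow rate
constants are fitted to the hyperbolic reductive half-reaction
kobs = kred·A/(Kd+A) + krev, the linear reoxidation
kobs = app_kox·[acceptor] + krev, and the linear dead-end binding form
kobs = kon·[L] + koff with Kd = koff/kon.

**Global spectral analysis** (`aaokin.spectral`). Photodiode-array
matrices D(t, λ) are fitted to A→B or A→B→C first-order schemes by
variable projection (spectra solved linearly for candidate rates, rates
optimized on the projected residual), with SVD rank estimation and
AICc-based step-model selection; single-wavelength traces get the
equivalent sum-of-exponentials fit.

**Catalytic cycle** (`aaokin.mechanism`). A stiff ODE simulator of the
oxidase/dehydrogenase cycle (with substrate depletion, band-I 462 nm
absorbance readout and conservation checks) plus King–Altman closed forms
for turnover and the oxidized steady-state fraction.

**Binding thermodynamics** (`aaokin.binding_thermo`). Wiseman one-site
ITC isotherms (simulation and fitting) and the relations
Kd = 1/Ka, ΔG = RT·ln Kd, −TΔS = ΔG − ΔH.

**Synthetic data** (`aaokin.synthetic_data`). Deterministic, seeded
generators for all of the above, with presets encoding published
steady-state, transient and ITC parameter sets for the *Pleurotus
eryngii* (PeAAO) and *Bjerkandera adusta* (BaAAO) enzymes.

The fitting classes follow scikit-learn conventions
(`fit`/`predict`, `get_params`, fitted attributes with trailing
underscores), so they compose with sklearn tooling; the module-level
functions (`fit_bisubstrate`, `fit_reduction`, `fit_itc`, ...) are thin
wrappers returning domain result records.

## Worked example

```python
import numpy as np
from aaokin.steady_state import fit_bisubstrate, discriminate_mechanism
from aaokin.synthetic_data import STEADY_STATE_PRESETS, NoiseSpec, gen_bisubstrate

truth = STEADY_STATE_PRESETS[("PeAAO", "4-methoxybenzyl", "O2")]
data = gen_bisubstrate(truth, noise=NoiseSpec(sd=0.02, seed=1))  # 5x5 grid
verdict = discriminate_mechanism(data)
print(f"mechanism: {verdict.chosen_model}  (dAICc = {verdict.delta_aicc:+.1f})")
params, fit = fit_bisubstrate(data, verdict.chosen_model)
print(f"kcat = {params.kcat:.1f} +/- {params.kcat_se:.1f} s^-1")
print(f"Km(alcohol) = {params.Km_alcohol_uM:.1f} +/- {params.Km_alcohol_se:.1f} uM")
print(f"Km(O2)      = {params.Km_acceptor_uM:.1f} +/- {params.Km_acceptor_se:.1f} uM")
print(f"kcat/Km(alcohol) = {params.eff_alcohol:.0f} s^-1 mM^-1")
print(f"kcat/Km(O2)      = {params.eff_acceptor:.0f} s^-1 mM^-1")
```

prints

```
mechanism: ping-pong  (dAICc = +2.2)
kcat = 195.1 +/- 2.1 s^-1
Km(alcohol) = 47.9 +/- 1.4 uM
Km(O2)      = 164.7 +/- 4.7 uM
kcat/Km(alcohol) = 4071 s^-1 mM^-1
kcat/Km(O2)      = 1185 s^-1 mM^-1
```

i.e. on a 5×5 grid with 2% rate noise the ping-pong mechanism is
identified (the sequential model does not improve AICc) and the
generating parameters (kcat 201 s^-1, KmA 50 µM, KmB 176 µM) are
recovered within a few percent.

The same analyses are available from the shell:

```sh
aaokin simulate-data bisubstrate --preset PeAAO/4-methoxybenzyl/O2 --seed 1 --out rates.csv
aaokin fit-steady --model auto --data rates.csv --out report.json
```

Exit codes: 0 success, 2 input error, 3 fit failure.

## Units

Concentrations are µM internally; rates s^-1; second-order constants
s^-1 mM^-1 as conventionally tabulated; ITC heats µcal and enthalpies
kcal/mol. Gas-mixture %O2 converts to dissolved µM through a configurable
air-saturation anchor (258 µM at 21% O2, 25 °C). See `docs/methods.md`
for the models, assumptions and numerical choices.
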