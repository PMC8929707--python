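# kaikinetics

Kinetic models of KaiB–KaiC(C1) complex formation for the cyanobacterial
circadian clock, with relaxation-rate analysis, Bayesian parameter
inference, and mixed-hexamer predictions.

## The problem

KaiC, the hexameric core of the reconstitutable KaiABC oscillator, binds six
KaiB monomers on its C1 ring only after the ring accumulates ADP through its
own ATPase cycle.  Experimentally, phosphorylation of the C2 domain
(mimicked by the S431E/T432E mutant, KaiC-EE) makes this complex formation
both *larger* and *faster* — puzzling, because phosphorylation is thought to
act by inhibiting the ADP/ATP exchange (a backward step), and inhibiting a
backward step normally slows a process down.

This package implements discrete threshold models of the pre-binding
process.  In "Model n" the C1 ring of a hexamer is a linear chain over its
ATP count k = 6…0,

    C6,6 ⇌ C6,5 ⇌ … ⇌ C6,0        (hydrolysis k·k_h forward, (6−k)·k_e back)

and six KaiB monomers bind cooperatively, rapidly and effectively
irreversibly once the ring holds ≥ n ADP; transitions leaving KaiB-bound
(binding-competent, starred) states use the starred constants k_h*, k_e*.
The apparent binding rate γ is the smallest non-zero eigenvalue magnitude of
the chain's rate matrix.  For a monomeric control γ_mono = k_h + k_e*
exactly, so exchange inhibition can never accelerate it.  For hexamers with
small k_e*,

    γ ≈ γ₀ + 6·α·k_e*,

where the generalized forward rate γ₀ *decreases* with k_e — so lowering the
exchange rate (what C2 phosphorylation does) raises γ while also promoting
binding.  The same equilibrium shift explains why KaiB binding reduces the
measured C1 ATPase activity.  The package also contains the MWC
(Monod–Wyman–Changeux) equilibrium description whose sharp-step limit
reduces to the discrete models, a Bayesian fitting pipeline (uniform priors
on [0, 100] h⁻¹, Gaussian likelihood with σ = 0.05, one-sided ATPase
penalties, emcee ensemble sampling), and the predicted loss of KaiB binding
when ATPase-dead monomers (KaiC-C1cat⁻-EE) contaminate re-hexamerized
KaiC-EE — binomially weighted over the number of dead sites, which
discriminates sharply between threshold models.

## Worked example

```python
import numpy as np
from kaikinetics import (RateConstants, ModelSpec, build_rate_matrix,
    build_state_space, steady_state, initial_condition_with_kaib,
    integrate, relaxation_analysis)

rc = RateConstants(k_h=1.15, k_h_star=1.15, k_e=1.15, k_e_star=0.013)
spec = ModelSpec(kind="hexamer", threshold_n=6, kaib_present=True)

x0 = steady_state(build_rate_matrix(rc, spec.replace(kaib_present=False)))
xinit = initial_condition_with_kaib(x0, spec)   # KaiB snaps onto eligible hexamers
M = build_rate_matrix(rc, spec)
tc = integrate(M, xinit, [0, 4, 8, 12, 24],
               space=build_state_space(spec), rc=rc)
for t, b, a in zip(tc.times, tc.bound_fraction, tc.atpase_activity):
    print(f"t={t:5.1f} h  bound={b:.3f}  atpase={a:.2f}/day")
res = relaxation_analysis(rc, spec)
print(f"gamma = {res.gamma:.4f} /h   gamma_0 = {res.gamma_zeroth:.4f} /h")
print(f"alpha = {res.alpha:.4f}   pct error = {res.percent_error:.3f} %")
```

prints

```
t=  0.0 h  bound=0.016  atpase=13.80/day
t=  4.0 h  bound=0.277  atpase=10.31/day
t=  8.0 h  bound=0.417  atpase=8.27/day
t= 12.0 h  bound=0.493  atpase=7.16/day
t= 24.0 h  bound=0.569  atpase=6.05/day
gamma = 0.1520 /h   gamma_0 = 0.0891 /h
alpha = 0.8097   pct error = 0.151 %
```

Reading: at these Model 6 rates, 1.6% of hexamers already hold six ADP and
bind KaiB instantly; the rest bind with apparent rate γ = 0.152 h⁻¹ as slow
bound-state exchange (k_e* ≪ k_e) pulls the nucleotide equilibrium toward
the bound complex, and the C1 ATPase activity falls from 13.8 to ~6
ADP·monomer⁻¹·day⁻¹ along the way.  The first-order approximation
γ₀ + 6αk_e* reproduces γ to 0.15%.

A command-line interface mirrors the library:

```sh
kaikinetics generate --model 6 --seed 1 --out curves.csv
kaikinetics fit --model 6 --data curves.csv --out chains.csv --summary fit.json
kaikinetics gamma --model 6 --rates model.json --out surface.csv
kaikinetics mixture --model 4 --rates model.json --out mixture.csv
```

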