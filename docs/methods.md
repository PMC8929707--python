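# Methods

## Models

A KaiC hexamer's C1 ring holds six nucleotide sites, assumed always occupied
by ATP or ADP.  The state of a hexamer is its ATP count k = 6…0; hydrolysis
(k → k−1) fires at `max(k − m, 0)·k_h`, ADP/ATP exchange (k → k+1) at
`(6 − k)·k_e`, with m the number of ATPase-dead monomers (0 except in the
mixed-hexamer prediction).  ATP synthesis is neglected (prohibitively high
activation energy).  In Model n (n = 1…6), six binding-competent KaiB
monomers bind cooperatively, rapidly and effectively irreversibly once the
ring holds at least n ADP; KaiB binding stabilises the binding-competent C1
conformation, and all transitions leaving a bound state use the starred
constants k_h*, k_e*.  The hydrolysis step that *enters* the first bound
state keeps the unstarred k_h (the source hexamer is still unbound), and
the exchange step leaving the first bound state uses k_e*.  Because
conformational transitions and KaiB association/dissociation are much
faster than the ATPase cycle, the whole process is a linear 7-state chain;
a 2-state monomeric control (C_ATP ⇌ C_ADP, bound when KaiB is present) is
carried for comparison.  Model 6's single bound state holds no ATP, so
k_h* drops out of it (and out of the monomer): those parameter vectors are
5-dimensional, Models 1–5 are 6-dimensional.

Bound-state membership follows the reaction schemes: binding at ADP count
≥ n, i.e. ATP count ≤ 6 − n.  The "amount of bound KaiB" observable is the
fraction of hexamers in bound states (total hexamer concentration
normalised to 1); with KaiB in excess and six KaiB per complex this is the
natural saturable observable.  ATPase activity is reported per KaiC monomer
per day: `(24/6)·Σ_states max(k − m, 0)·k_h^(state)·x_state`, matching the
/day units of the measured constraints.

## Relaxation analysis

The apparent binding rate γ is the smallest non-zero eigenvalue magnitude
of the with-KaiB rate matrix (eigenvalues of these chains are real and
non-positive).  An eigenvalue counts as zero below 1e−12 of the spectral
radius; a degenerate zero (disconnected chain) is an error, not a fallback.
The first-order expansion in k_e* writes M = A₀ + k_e*·A₁ and corrects the
slow eigenvalue of A₀ by `q₀·A₁·p₀` (right/left eigenvectors normalised
q₀·p₀ = 1); α is defined by γ ≈ γ₀ + 6αk_e*.  The slow eigenvalue must be
simple (relative gap > 1e−8); degenerate cases are rejected.  Signs are
fixed so the expansion reads as above, with α > 0 throughout the
slow-bound-exchange regime the fits occupy.

## Time propagation

Time courses use the exact matrix exponential of the 7-state generator
(no solver tolerances; repeated step sizes reuse the propagator).  An
adaptive LSODA integration serves as an independent oracle in the tests,
agreeing to 1e−8 sup-norm.  Steady states are computed from the SVD null
space of the generator; chains with more than one closed communicating
class are rejected as ambiguous.  The initial condition of every binding
simulation is the steady state of the KaiB-free chain with populations at
ADP count ≥ n relabelled as bound ("instantaneous" KaiB capture); since
both chains are indexed by ATP count the population vector itself is
unchanged.

## Inference

- Priors: independent uniform on [0, 100] h⁻¹ per rate constant.
- Likelihood: Gaussian, σ fixed at 0.05 bound-fraction units for every
  point (the observable's scale, not estimated; exposed as configuration).
- ATPase constraints: the measured whole-KaiC activities — (8.9 ± 0.9)/day
  with KaiB, (14.5 ± 2.0)/day without — include the C2 contribution, so
  they bound the model's C1 activity from above: one-sided penalties
  `−½·min{y_obs − y_model, 0}²/σ²`.  The with-KaiB model activity is
  evaluated at the steady state of the with-KaiB chain (the measurement is
  post-equilibration); the without-KaiB activity at the KaiB-free steady
  state.  The measurements are not attributed to a variant; they are
  applied to the WT rate set by default (configurable), the variant whose
  unphosphorylated C2 matches the reference activity assays.
- Models 2–5 additionally take a symmetric penalty on the KaiB-induced
  activity *reduction* (target 14.5 − 8.9 = 5.6/day, pooled variance
  0.9² + 2.0²).  Without it, the k_h* > k_h hydrolysis boost in the bound
  states can cancel the exchange-driven decrease these models are meant to
  reproduce.
- MAP: multi-start L-BFGS-B (default 20 seeded starts drawn log-uniformly
  over [0.01, 5] h⁻¹ — the physically sensible window for the C1 cycle),
  bounds [0, 100], ftol 1e−10.
- MCMC: emcee ensemble sampler, walkers initialised by perturbing the MAP
  (10% multiplicative Gaussian plus 1e−4 absolute jitter, so no coordinate
  is identical across walkers).  A differential-evolution move mixture
  (80% DEMove, 20% DESnookerMove) replaces the default stretch move: on
  this correlated 5–6 dimensional posterior it cuts integrated
  autocorrelation times roughly threefold.  Post-processing discards
  2·max(τ) steps and thins by ⌈0.5·min(τ)⌉, with τ the per-parameter
  integrated autocorrelation time (non-finite estimates fall back to 1;
  burn-in is capped at half the chain so short diagnostic runs remain
  usable).  Full production settings are 32 walkers × 50 000 steps; the
  test suite and acceptance run use scaled-down chains (16 × 2000) that
  keep the whole pipeline within a workstation budget.

## Synthetic data

No machine-readable binding curves are deposited for the WT/EE comparison,
so datasets are generated from packaged ground-truth rate constants with
the statistical structure the inference assumes: 13 samples per variant on
0–24 h every 2 h, i.i.d. Gaussian noise σ = 0.05 added to the exact model
curves (unclipped — the Gaussian noise model is unbounded), per-variant
noise streams derived deterministically from one seed.  The packaged rates
(one set per model) were chosen once to embody the study conditions:

- k_e* < k_e per variant and (k_eEE, k_eEE*) < (k_eWT, k_eWT*);
- EE binding visibly higher *and* faster than WT for n = 2…6, with the WT
  curve showing a small instantaneous jump followed by saturation over
  ~24 h (apparent rates ≈ 0.15–0.5 h⁻¹);
- no-KaiB ATPase activity under the measured 14.5/day limit, with-KaiB
  activity under 8.9/day, and (Models 2–5) a net KaiB-induced reduction;
- k_h* slightly above k_h for Models 1–5, the ordering the fits favour;
- for Model 6, bound-state exchange small enough (k_e*/k_h ≈ 0.01) that
  the perturbative γ is accurate to ~0.2% at the truth.

The lower the threshold n, the closer k_e* must sit to k_e for WT binding
to stay partial — low-n sets therefore carry larger starred rates.  Model 1
and the monomeric control reuse the Model 6 exchange rates: no rate set can
make them faster for EE, which is the structural point the comparison
makes.  What passing tests show is therefore internal consistency of the
method under its own noise model — not agreement with laboratory curves,
whose noise need not be Gaussian or homoscedastic and whose time grids and
normalisation differ.

## Mixed-hexamer prediction

Monomerised and re-hexamerised mixtures of KaiC-EE with an ATPase-dead
variant at dead-monomer fraction p yield hexamers with m dead sites at
binomial weight B(6, p).  A hexamer with m dead sites hydrolyses at
`max(k − m, 0)·k_h` (or k_h*), can accumulate at most 6 − m ADP, and never
binds when m > 6 − n (returned exactly as 0).  The "final amount" of bound
KaiB is the steady-state bound fraction of the modified with-KaiB chain —
the only reading consistent with a long-time endpoint — averaged over m.
For Model 6 this collapses to (1 − p)⁶ times the uncontaminated value.
Both absolute and p = 0-normalised curves are reported (the experimental
normalisation is not fixed); ensembles over posterior-sampled rate sets
report the median and a 2.5–97.5% envelope.

## MWC reduction

The equilibrium description uses K_conf(n_D) = K_conf0·e^(−μ·n_D) for the
binding-incompetent/competent conformational equilibrium and a single
dissociation constant K_d for the cooperative six-KaiB binding.  With
strong conformational bias (K_conf(n_D) ≫ 1) the bound proportion is the
logistic α*(n_D) = 1/(1 + e^(−μ(n_D − ξ))), ξ = (1/μ)·log(K_d·K_conf0/[B*]⁶)
— the ratio form of the bracket is adopted, the only one that makes the
occupancy decrease with K_d.  The reduction to discrete Model n
(n − 1 < ξ < n) is declared when μ ≥ 20 and min K_conf ≥ 10² — concrete
thresholds standing in for the qualitative conditions μ ≫ 1, K_conf ≫ 1;
at μ = 20 the occupancy is within 4.5e−5 of a step at every integer n_D.
Exact occupancies are evaluated in log space so that the astronomically
large equilibrium constants the sharp limit requires do not overflow.

## Numerical choices and limitations

- Eigen-decompositions and null spaces of 7×7 matrices are numerically
  benign; the only guarded degeneracies are disconnected chains and
  non-simple slow eigenvalues, both rejected with explicit errors.
- The posterior is set to −∞ wherever the steady state is undefined
  (e.g. the all-rates-zero corner of the prior box).
- Credible intervals for derived quantities (apparent rates, final bound
  fractions) are plug-in percentiles over posterior draws.
- At σ = 0.05 and a 0–24 h horizon, the final level and the apparent rate
  are partially degenerate for slowly saturating curves; occasional
  synthetic datasets legitimately place 95% intervals away from their
  generating values.  This is a property of the study conditions, not of
  the sampler.
- The package does not model the full phosphorylation oscillator (no KaiA,
  no C2 dynamics), sub-hexamer KaiB stoichiometries, nucleotide-free
  states, or the monomer-shuffling process itself.
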