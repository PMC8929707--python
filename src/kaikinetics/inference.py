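"""Bayesian estimation of the C1 rate constants from KaiB binding curves.

The data are bound-fraction time courses for two KaiC variants — wild type
(WT) and the phosphomimetic S431E/T432E mutant (EE) — plus measured ATPase
activities of whole KaiC with and without KaiB.  C2 phosphorylation is
assumed to modulate only the ADP/ATP exchange rates, so the parameter vector
is (k_h, k_h*, k_eWT, k_eWT*, k_eEE, k_eEE*) with the hydrolysis rates
shared between variants; k_h* is absent for Model 6 (its only bound state
holds no ATP) and for the monomeric control.

The log-posterior combines
  * a uniform prior on [0, 100] h^-1 per rate,
  * a Gaussian likelihood of the binding curves with fixed sigma = 0.05,
  * one-sided ATPase penalties — the measured whole-KaiC activities bound
    the model's C1 activity from above, penalising only excess,
  * and (Models 2-5) a symmetric penalty on the KaiB-induced ATPase
    *reduction*, which keeps the k_h* > k_h hydrolysis boost from cancelling
    the exchange-driven decrease.

Maximisation uses seeded multi-start L-BFGS-B; sampling uses the emcee
ensemble sampler initialised by perturbing the MAP point, with
autocorrelation-based burn-in (2 max tau) and thinning (0.5 min tau).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import emcee
import numpy as np
from scipy.optimize import minimize

from .schemes import (
    ModelSpec,
    RateConstants,
    atpase_activity,
    bound_fraction,
    build_rate_matrix,
    build_state_space,
    initial_condition_with_kaib,
    integrate,
    steady_state,
)

__all__ = [
    "VARIANTS",
    "PRIOR_UPPER",
    "AtpaseConstraint",
    "AtpaseDifference",
    "BindingDataset",
    "ParameterVector",
    "PosteriorSample",
    "MapResult",
    "param_names",
    "log_prior",
    "predict_curves",
    "log_likelihood",
    "model_atpase",
    "atpase_upper_penalty",
    "atpase_diff_penalty",
    "log_posterior",
    "map_estimate",
    "run_mcmc",
    "apparent_rate",
    "final_bound_fraction",
]

VARIANTS = ("WT", "EE")
#: upper edge of the uniform prior on every rate constant (h^-1).
PRIOR_UPPER = 100.0
#: fixed observation noise of the binding curves (bound-fraction units).
DEFAULT_SIGMA = 0.05


@dataclass(frozen=True)
class AtpaseConstraint:
    """An upper limit on the model's C1 ATPase activity (per monomer per day).

    The measured values are whole-KaiC activities (C1 plus C2), hence upper
    bounds on the C1 contribution.  ``kaib_present`` selects whether the
    model activity is evaluated at the no-KaiB steady state or at the
    long-time (steady) state of the with-KaiB scheme.
    """

    value: float
    sigma: float
    kaib_present: bool
    variant: str = "WT"


@dataclass(frozen=True)
class AtpaseDifference:
    """Target KaiB-induced ATPase reduction (absence minus presence)."""

    delta: float
    variance: float  # pooled: sum of the squared sigmas of the two limits
    variant: str = "WT"


@dataclass(frozen=True)
class BindingDataset:
    """Binding time courses per variant plus ATPase constraints.

    ``curves`` maps a variant label to ``(times_h, bound_fraction)`` arrays.
    """

    curves: Mapping[str, tuple[np.ndarray, np.ndarray]]
    sigma: float = DEFAULT_SIGMA
    atpase_constraints: tuple[AtpaseConstraint, ...] = ()
    atpase_difference: AtpaseDifference | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for variant, (t, y) in self.curves.items():
            t = np.asarray(t, dtype=float)
            y = np.asarray(y, dtype=float)
            if t.shape != y.shape:
                raise ValueError(f"times/values length mismatch for variant {variant!r}")
            if np.any(t < 0):
                raise ValueError(f"negative times in variant {variant!r}")


@dataclass(frozen=True)
class ParameterVector:
    """The rate constants under estimation (h^-1); k_h, k_h* shared by WT/EE."""

    k_h: float
    k_eWT: float
    k_eWT_star: float
    k_eEE: float
    k_eEE_star: float
    k_h_star: float | None = None

    def rates_for(self, variant: str, spec: ModelSpec) -> RateConstants:
        """Per-variant :class:`RateConstants`; k_h* falls back to k_h where absent."""
        if variant == "WT":
            ke, kes = self.k_eWT, self.k_eWT_star
        elif variant == "EE":
            ke, kes = self.k_eEE, self.k_eEE_star
        else:
            raise ValueError(f"unknown variant {variant!r}")
        kh_star = self.k_h if self.k_h_star is None else self.k_h_star
        return RateConstants(k_h=self.k_h, k_h_star=kh_star, k_e=ke, k_e_star=kes)

    def to_array(self, spec: ModelSpec) -> np.ndarray:
        return np.array([getattr(self, n) for n in param_names(spec)], dtype=float)

    @staticmethod
    def from_array(x: Sequence[float], spec: ModelSpec) -> "ParameterVector":
        names = param_names(spec)
        if len(x) != len(names):
            raise ValueError(f"expected {len(names)} parameters, got {len(x)}")
        return ParameterVector(**dict(zip(names, map(float, x))))


def _uses_kh_star(spec: ModelSpec) -> bool:
    # Model 6's only bound state holds no ATP, so bound-state hydrolysis never
    # fires; the monomeric bound state likewise. k_h* is then not a parameter.
    return spec.kind == "hexamer" and spec.threshold_n < 6


def param_names(spec: ModelSpec) -> tuple[str, ...]:
    """Ordered free-parameter names for a model (5 or 6 dimensional)."""
    if _uses_kh_star(spec):
        return ("k_h", "k_h_star", "k_eWT", "k_eWT_star", "k_eEE", "k_eEE_star")
    return ("k_h", "k_eWT", "k_eWT_star", "k_eEE", "k_eEE_star")


def log_prior(x: np.ndarray) -> float:
    """Uniform prior on [0, 100] h^-1 per rate: 0 inside, -inf outside."""
    x = np.asarray(x, dtype=float)
    if np.all((x >= 0.0) & (x <= PRIOR_UPPER)):
        return 0.0
    return -math.inf


def predict_curves(
    theta: ParameterVector, spec: ModelSpec, times: Mapping[str, np.ndarray] | np.ndarray
) -> dict[str, np.ndarray]:
    """Model bound-fraction curves per variant.

    The initial state is the steady state of the KaiB-absent scheme; adding
    KaiB instantaneously binds the already-eligible hexamers, after which the
    with-KaiB chain is propagated exactly.  ``times`` may be one shared grid
    or a per-variant mapping.
    """
    shared = not isinstance(times, Mapping)
    out: dict[str, np.ndarray] = {}
    for variant in VARIANTS:
        t = np.asarray(times if shared else times[variant], dtype=float)
        rc = theta.rates_for(variant, spec)
        no_kaib = spec.replace(kaib_present=False)
        x0 = steady_state(build_rate_matrix(rc, no_kaib))
        xinit = initial_condition_with_kaib(x0, spec)
        with_kaib = spec.replace(kaib_present=True)
        M = build_rate_matrix(rc, with_kaib)
        space = build_state_space(with_kaib)
        tc = integrate(M, xinit, t, space=space)
        out[variant] = tc.bound_fraction
    return out


def log_likelihood(theta: ParameterVector, data: BindingDataset, spec: ModelSpec) -> float:
    """Gaussian log-likelihood of the binding curves (additive constant dropped)."""
    times = {v: np.asarray(t, dtype=float) for v, (t, _) in data.curves.items()}
    pred = predict_curves(theta, spec, times)
    total = 0.0
    for variant, (t, y) in data.curves.items():
        r = np.asarray(y, dtype=float) - pred[variant]
        total += -0.5 * float(np.sum(r**2)) / data.sigma**2
    return total


def model_atpase(theta: ParameterVector, spec: ModelSpec, kaib_present: bool, variant: str) -> float:
    """Model C1 ATPase activity (per monomer per day) for one condition.

    Without KaiB: at the steady state of the KaiB-absent scheme.  With KaiB:
    at the steady state (long-time limit) of the with-KaiB scheme.
    """
    rc = theta.rates_for(variant, spec)
    cond = spec.replace(kaib_present=kaib_present)
    M = build_rate_matrix(rc, cond)
    x = steady_state(M)
    return atpase_activity(x, rc, build_state_space(cond), dead_sites_m=cond.dead_sites_m if cond.kind == "hexamer" else 0)


def atpase_upper_penalty(theta: ParameterVector, data: BindingDataset, spec: ModelSpec) -> float:
    """One-sided penalty: only model activity exceeding the measured limit counts."""
    total = 0.0
    for c in data.atpase_constraints:
        y_model = model_atpase(theta, spec, c.kaib_present, c.variant)
        excess = min(c.value - y_model, 0.0)
        total += -0.5 * excess**2 / c.sigma**2
    return total


def atpase_diff_penalty(theta: ParameterVector, data: BindingDataset, spec: ModelSpec) -> float:
    """Symmetric penalty on the KaiB-induced ATPase reduction (Models 2-5)."""
    d = data.atpase_difference
    if d is None:
        return 0.0
    if not (_uses_kh_star(spec) and spec.kind == "hexamer"):
        warnings.warn(
            "ATPase-difference penalty is intended for Models 2-5 only",
            stacklevel=2,
        )
    delta_model = model_atpase(theta, spec, False, d.variant) - model_atpase(
        theta, spec, True, d.variant
    )
    return -0.5 * (d.delta - delta_model) ** 2 / d.variance


def _include_diff_default(data: BindingDataset, spec: ModelSpec) -> bool:
    return (
        data.atpase_difference is not None
        and spec.kind == "hexamer"
        and 2 <= spec.threshold_n <= 5
    )


def log_posterior(
    x: np.ndarray,
    data: BindingDataset,
    spec: ModelSpec,
    include_diff: bool | None = None,
) -> float:
    """Unnormalised log-posterior of the parameter array ``x``."""
    lp = log_prior(x)
    if not np.isfinite(lp):
        return -math.inf
    theta = ParameterVector.from_array(x, spec)
    if include_diff is None:
        include_diff = _include_diff_default(data, spec)
    try:
        total = lp + log_likelihood(theta, data, spec)
        total += atpase_upper_penalty(theta, data, spec)
        if include_diff:
            total += atpase_diff_penalty(theta, data, spec)
    except (ValueError, np.linalg.LinAlgError):
        # degenerate chains (e.g. all rates zero) have no defined steady state
        return -math.inf
    if not np.isfinite(total):
        return -math.inf
    return float(total)


@dataclass(frozen=True)
class MapResult:
    theta: ParameterVector
    log_posterior: float
    x: np.ndarray


def map_estimate(
    data: BindingDataset,
    spec: ModelSpec,
    *,
    n_starts: int = 20,
    seed: int = 0,
    starts: Sequence[Sequence[float]] | None = None,
    include_diff: bool | None = None,
) -> MapResult:
    """Multi-start bound-constrained maximisation of the log-posterior.

    Starting points (unless given) are drawn log-uniformly over
    [0.01, 5] h^-1, a physically sensible window for the C1 ATPase cycle;
    deterministic for a given seed.
    """
    names = param_names(spec)
    dim = len(names)
    if starts is None:
        rng = np.random.default_rng(seed)
        starts = 10.0 ** rng.uniform(-2.0, math.log10(5.0), size=(n_starts, dim))
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    if len(starts) == 0:
        raise ValueError("at least one start is required")

    def neg(x: np.ndarray) -> float:
        lp = log_posterior(x, data, spec, include_diff=include_diff)
        # large finite penalty keeps L-BFGS-B's finite differences usable
        return -lp if np.isfinite(lp) else 1e12

    best_x, best_val = None, math.inf
    for x0 in starts:
        res = minimize(
            neg,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, PRIOR_UPPER)] * dim,
            options={"ftol": 1e-10, "maxiter": 500},
        )
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, best_x = float(res.fun), np.asarray(res.x, dtype=float)
    if best_x is None:
        raise RuntimeError("no optimization start converged to a finite posterior")
    return MapResult(
        theta=ParameterVector.from_array(best_x, spec),
        log_posterior=-best_val,
        x=best_x,
    )


@dataclass(frozen=True)
class PosteriorSample:
    """MCMC output: raw chains plus the burn-in/thinning actually applied."""

    chain: np.ndarray  # (steps, walkers, dim)
    log_prob: np.ndarray  # (steps, walkers)
    tau: np.ndarray  # integrated autocorrelation time per parameter
    burn_in: int
    thin: int
    names: tuple[str, ...]

    @property
    def flat_samples(self) -> np.ndarray:
        return self.chain[self.burn_in :: self.thin].reshape(-1, self.chain.shape[2])

    @property
    def flat_log_prob(self) -> np.ndarray:
        return self.log_prob[self.burn_in :: self.thin].reshape(-1)


def run_mcmc(
    data: BindingDataset,
    spec: ModelSpec,
    *,
    map_result: MapResult | None = None,
    walkers: int = 32,
    steps: int = 50000,
    seed: int = 0,
    perturb_scale: float = 0.1,
    include_diff: bool | None = None,
    log_prob_fn=None,
    progress: bool = False,
) -> PosteriorSample:
    """Ensemble MCMC over the posterior, seeded and reproducible.

    Walkers start from the MAP point with small multiplicative Gaussian
    perturbations.  After sampling, the per-parameter integrated
    autocorrelation times ``tau`` set the burn-in (``2 max tau``) and the
    thinning interval (``ceil(0.5 min tau)``).  ``log_prob_fn`` may override
    the posterior (used for validation against analytic densities).
    """
    custom = log_prob_fn is not None
    if not custom:
        def log_prob_fn(x):
            return log_posterior(x, data, spec, include_diff=include_diff)
        if map_result is None:
            map_result = map_estimate(data, spec, seed=seed, include_diff=include_diff)
    elif map_result is None:
        raise ValueError("map_result (initial point) is required with a custom log_prob_fn")
    center = np.asarray(map_result.x, dtype=float)
    dim = len(center)

    rng = np.random.default_rng(seed)
    p0 = center * (1.0 + perturb_scale * rng.standard_normal((walkers, dim)))
    p0 += 1e-4 * rng.standard_normal((walkers, dim))
    p0 = np.clip(np.abs(p0), 1e-8, PRIOR_UPPER - 1e-8)
    if not any(np.isfinite(log_prob_fn(p)) for p in p0):
        raise RuntimeError("log-posterior is non-finite at every initial walker")

    # differential-evolution move mixture: mixes much faster than the default
    # stretch move on this correlated 5-6 dimensional posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(walkers, dim, log_prob_fn, moves=moves)
    sampler.random_state = np.random.RandomState(seed % (2**32)).get_state()
    sampler.run_mcmc(p0, steps, progress=progress, skip_initial_state_check=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tau = sampler.get_autocorr_time(tol=0, quiet=True)
    tau = np.where(np.isfinite(tau) & (tau > 0), tau, 1.0)
    burn = min(int(2 * np.max(tau)), steps // 2)
    thin = max(1, int(math.ceil(0.5 * np.min(tau))))
    names = tuple(f"x{i}" for i in range(dim)) if custom else param_names(spec)
    return PosteriorSample(
        chain=sampler.get_chain(),
        log_prob=sampler.get_log_prob(),
        tau=tau,
        burn_in=burn,
        thin=thin,
        names=names,
    )


# --- derived observables used for model comparison and recovery checks -----

def apparent_rate(theta: ParameterVector, spec: ModelSpec, variant: str) -> float:
    """Apparent binding rate gamma of one variant under this model."""
    from .relaxation import gamma_mono, relaxation_rate

    rc = theta.rates_for(variant, spec)
    if spec.kind == "monomer":
        return gamma_mono(rc)
    return relaxation_rate(build_rate_matrix(rc, spec.replace(kaib_present=True)))


def final_bound_fraction(theta: ParameterVector, spec: ModelSpec, variant: str) -> float:
    """Long-time (steady-state) bound fraction of one variant."""
    rc = theta.rates_for(variant, spec)
    with_kaib = spec.replace(kaib_present=True)
    x = steady_state(build_rate_matrix(rc, with_kaib))
    return bound_fraction(x, build_state_space(with_kaib))
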