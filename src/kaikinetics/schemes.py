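"""Discrete kinetic schemes of KaiB binding to the KaiC C1 ring.

The C1 ring of a KaiC hexamer carries six nucleotide sites that interconvert
between ATP- and ADP-bound through ATP hydrolysis (forward) and ADP/ATP
exchange (backward); ATP synthesis is neglected.  In "Model n" six KaiB
monomers bind cooperatively, rapidly and effectively irreversibly to the ring
as soon as it holds at least ``n`` ADP, stabilising the binding-competent C1
conformation; the complex dissociates as soon as the ADP count drops below
``n``.  Because binding/unbinding and the conformational transitions are much
faster than the ATPase cycle, the whole process reduces to a linear 7-state
birth--death chain over the ATP count ``k = 6 .. 0``, with starred rate
constants (``k_h*``, ``k_e*``) acting in the bound (binding-competent)
states.  A 2-state monomeric control chain is included for comparison.

This module builds the state spaces and transition-rate matrices of these
chains, computes their steady states and time courses, and evaluates the two
observables of interest: the fraction of hexamers in KaiB-bound states and
the ATPase activity of C1 (ADP production per KaiC monomer per day).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "RateConstants",
    "ModelSpec",
    "ChainState",
    "StateSpace",
    "TimeCourse",
    "build_state_space",
    "build_rate_matrix",
    "steady_state",
    "initial_condition_with_kaib",
    "integrate",
    "bound_fraction",
    "atpase_activity",
    "HOURS_PER_DAY",
    "N_SITES",
]

#: hours in a day; ATPase activities are reported per day.
HOURS_PER_DAY = 24.0
#: nucleotide binding sites per hexamer (one per monomer).
N_SITES = 6


@dataclass(frozen=True)
class RateConstants:
    """Per-monomer first-order rate constants of the C1 ATPase cycle (h^-1).

    Parameters
    ----------
    k_h
        ATP hydrolysis rate of a binding-incompetent C1 monomer.
    k_h_star
        ATP hydrolysis rate of a binding-competent (KaiB-bound) C1 monomer.
    k_e
        ADP/ATP exchange rate of a binding-incompetent C1 monomer.
    k_e_star
        ADP/ATP exchange rate of a binding-competent C1 monomer.
    """

    k_h: float
    k_h_star: float
    k_e: float
    k_e_star: float

    def __post_init__(self) -> None:
        for name in ("k_h", "k_h_star", "k_e", "k_e_star"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def replace(self, **kwargs: float) -> "RateConstants":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one kinetic scheme.

    ``kind`` is ``"hexamer"`` or ``"monomer"``.  For hexamers,
    ``threshold_n`` is the minimum number of bound ADP at which the
    cooperative six-KaiB binding occurs (Model n), and ``dead_sites_m`` is
    the number of ATPase-disabled monomers in the hexamer (used for the
    mixed-hexamer experiment; 0 for the plain models).  The monomeric kind
    ignores both.
    """

    kind: str = "hexamer"
    threshold_n: int = 6
    kaib_present: bool = True
    dead_sites_m: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("hexamer", "monomer"):
            raise ValueError(f"kind must be 'hexamer' or 'monomer', got {self.kind!r}")
        if self.kind == "hexamer":
            if not 1 <= int(self.threshold_n) <= 6:
                raise ValueError(f"threshold_n must be in 1..6, got {self.threshold_n}")
            if not 0 <= int(self.dead_sites_m) <= 6:
                raise ValueError(f"dead_sites_m must be in 0..6, got {self.dead_sites_m}")

    def replace(self, **kwargs) -> "ModelSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ChainState:
    """One state of the linear chain: ATP count and KaiB-bound flag."""

    atp_count: int
    bound: bool
    n_sites: int = N_SITES

    @property
    def adp_count(self) -> int:
        return self.n_sites - self.atp_count

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.bound:
            return f"C*(ATP={self.atp_count})B6*"
        return f"C(ATP={self.atp_count})"


@dataclass(frozen=True)
class StateSpace:
    """Ordered chain states, decreasing ATP count (hexamer: 6 -> 0)."""

    states: tuple[ChainState, ...]
    n_monomers: int

    def __len__(self) -> int:
        return len(self.states)

    @property
    def atp_counts(self) -> np.ndarray:
        return np.array([s.atp_count for s in self.states], dtype=int)

    @property
    def bound_mask(self) -> np.ndarray:
        return np.array([s.bound for s in self.states], dtype=bool)


@dataclass(frozen=True)
class TimeCourse:
    """Sampled trajectory of a chain: times (h), observables, populations."""

    times: np.ndarray
    bound_fraction: np.ndarray
    atpase_activity: np.ndarray | None
    populations: np.ndarray  # shape (len(times), n_states)


def build_state_space(spec: ModelSpec) -> StateSpace:
    """Construct the ordered chain states for a model.

    Hexamer: seven states with ATP count 6 down to 0; a state is KaiB-bound
    when KaiB is present and its ADP count (6 - ATP count) is at least the
    model threshold ``n``.  Monomer: two states (ATP-bound, ADP-bound), the
    ADP state bound when KaiB is present.
    """
    if spec.kind == "monomer":
        states = (
            ChainState(atp_count=1, bound=False, n_sites=1),
            ChainState(atp_count=0, bound=spec.kaib_present, n_sites=1),
        )
        return StateSpace(states=states, n_monomers=1)
    n = int(spec.threshold_n)
    states = tuple(
        ChainState(atp_count=k, bound=spec.kaib_present and (N_SITES - k) >= n)
        for k in range(N_SITES, -1, -1)
    )
    return StateSpace(states=states, n_monomers=N_SITES)


def build_rate_matrix(rc: RateConstants, spec: ModelSpec) -> np.ndarray:
    """Transition-rate matrix over :func:`build_state_space` (column-to-row).

    Entry ``(i, j)`` is the rate from state ``j`` to state ``i``; diagonal
    entries are negative column sums so that probability is conserved.  From
    an ATP-count-``k`` state, hydrolysis proceeds to ``k - 1`` at rate
    ``max(k - m, 0) * k_h`` (``k_h*`` if the source state is bound, i.e. the
    step crossing into the first bound state still uses the unstarred
    constant), and exchange proceeds to ``k + 1`` at rate ``(6 - k) * k_e``
    (``k_e*`` if the source state is bound).  ``m`` is the number of
    ATPase-dead monomers.  The monomeric chain uses ``k_h`` forward and
    ``k_e`` (``k_e*`` with KaiB) backward.
    """
    space = build_state_space(spec)
    ns = len(space)
    M = np.zeros((ns, ns))
    m = 0 if spec.kind == "monomer" else int(spec.dead_sites_m)
    n_sites = space.n_monomers
    for i, s in enumerate(space.states):
        k = s.atp_count
        # hydrolysis: atp k -> k-1 (next state in the ordering)
        if k > 0:
            kh = rc.k_h_star if s.bound else rc.k_h
            M[i + 1, i] = max(k - m, 0) * kh
        # exchange: atp k -> k+1 (previous state in the ordering)
        if k < n_sites:
            ke = rc.k_e_star if s.bound else rc.k_e
            M[i - 1, i] = (n_sites - k) * ke
    np.fill_diagonal(M, -M.sum(axis=0))
    return M


def steady_state(M: np.ndarray, *, rcond: float = 1e-10) -> np.ndarray:
    """Normalized stationary distribution: the null vector of ``M``.

    Raises
    ------
    ValueError
        If the null space is not one-dimensional (the chain has multiple
        closed communicating classes, so the stationary state is ambiguous).
    """
    scale = np.abs(M).max()
    if scale == 0:
        raise ValueError("zero rate matrix: every state is closed, steady state ambiguous")
    ns = null_space(M / scale, rcond=rcond)
    if ns.shape[1] != 1:
        raise ValueError(
            f"rate matrix has a {ns.shape[1]}-dimensional null space; "
            "multiple closed communicating classes make the steady state ambiguous"
        )
    v = ns[:, 0]
    v = v / v.sum()
    if v.min() < -1e-9:
        raise ValueError("null vector has substantially negative entries")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def initial_condition_with_kaib(no_kaib_steady: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Initial populations after adding abundant KaiB to the equilibrated system.

    KaiB binds instantaneously to every hexamer already holding at least the
    threshold number of ADP, relabelling those populations as the
    corresponding bound states.  The chain is indexed by ATP count in both
    schemes, so the population vector is numerically unchanged; it is
    returned as a copy aligned with the with-KaiB state space.
    """
    x = np.asarray(no_kaib_steady, dtype=float)
    with_kaib = build_state_space(spec.replace(kaib_present=True))
    if x.shape != (len(with_kaib),):
        raise ValueError("state vector does not match the model's state space")
    return x.copy()


def integrate(
    M: np.ndarray,
    x0: np.ndarray,
    times: Sequence[float],
    space: StateSpace | None = None,
    rc: RateConstants | None = None,
    dead_sites_m: int = 0,
) -> TimeCourse:
    """Propagate ``x(t) = exp(M t) x0`` exactly at the requested times.

    ``times`` must be non-negative and strictly increasing.  When ``space``
    is given the bound fraction is reported; when ``rc`` is also given the
    ATPase activity trace is reported.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("times must be a non-empty 1-d sequence")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    x0 = np.asarray(x0, dtype=float)
    xs = np.empty((len(t), len(x0)))
    cache: dict[float, np.ndarray] = {}
    x = x0
    prev = 0.0
    for i, ti in enumerate(t):
        dt = ti - prev
        if dt > 0:
            P = cache.get(dt)
            if P is None:
                P = expm(M * dt)
                cache[dt] = P
            x = P @ x
        xs[i] = x
        prev = ti
    if space is not None:
        bf = xs @ space.bound_mask.astype(float)
        act = None
        if rc is not None:
            act = np.array(
                [atpase_activity(xi, rc, space, dead_sites_m=dead_sites_m) for xi in xs]
            )
    else:
        bf = np.full(len(t), np.nan)
        act = None
    return TimeCourse(times=t, bound_fraction=bf, atpase_activity=act, populations=xs)


def bound_fraction(x: np.ndarray, space: StateSpace) -> float:
    """Total population of KaiB-bound states."""
    return float(np.asarray(x, dtype=float) @ space.bound_mask.astype(float))


def atpase_activity(
    x: np.ndarray,
    rc: RateConstants,
    space: StateSpace,
    dead_sites_m: int = 0,
) -> float:
    """Instantaneous ADP production of C1, per KaiC monomer per day.

    The hydrolysis flux of a state with ATP count ``k`` is
    ``max(k - m, 0)`` times ``k_h`` (unbound) or ``k_h*`` (bound); the total
    is converted from h^-1 to day^-1 and divided by the number of monomers.
    """
    x = np.asarray(x, dtype=float)
    k = space.atp_counts
    eff = np.maximum(k - dead_sites_m, 0).astype(float)
    kh = np.where(space.bound_mask, rc.k_h_star, rc.k_h)
    rate_per_hexamer = float(np.sum(eff * kh * x))
    return HOURS_PER_DAY * rate_per_hexamer / space.n_monomers
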