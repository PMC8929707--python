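"""MWC (Monod-Wyman-Changeux) equilibrium picture of KaiB-C1 binding.

The discrete Models 1-6 are limiting cases of a concerted-allostery
description in which the conformational equilibrium constant of the C1 ring
(binding-incompetent over binding-competent) depends multiplicatively on the
number of bound ADP, ``n_D``:

    K_conf(n_D) = K_conf0 * exp(-mu * n_D)

With a large conformational bias ``K_conf(n_D) >> 1`` (the binding-competent
form is negligibly populated without KaiB), the equilibrium fraction of
hexamers in the six-KaiB complex is a logistic function of ``n_D``:

    alpha*(n_D) = 1 / (1 + exp(-mu * (n_D - xi)))
    xi = (1/mu) * log(K_d * K_conf0 / [B*]^6)

When the nucleotide dependence is sharp (``mu >> 1``) this occupancy becomes
an all-or-none step at ``n_D = xi``; choosing parameters with
``n - 1 < xi < n`` recovers the threshold rule of discrete Model n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "MWCParameters",
    "conf_equilibrium",
    "xi",
    "alpha_star",
    "alpha_star_exact",
    "discrete_model_index",
    "SHARPNESS_MU_MIN",
    "CONF_BIAS_MIN",
]

#: mu at or above which the occupancy step counts as discrete-equivalent.
SHARPNESS_MU_MIN = 20.0
#: minimum K_conf(n_D) over n_D = 0..6 for the conformational-bias condition.
CONF_BIAS_MIN = 1e2


@dataclass(frozen=True)
class MWCParameters:
    """Equilibrium parameters of the MWC description.

    ``mu``: strength of the bound-ADP dependence (dimensionless).
    ``K_confC0``: conformational equilibrium constant of C1 at ``n_D = 0``.
    ``K_d``: dissociation constant of the cooperative six-KaiB binding
    (units of concentration^6).  ``B_star_conc``: free binding-competent
    KaiB concentration ``[B*]``.  ``K_confB`` (KaiB conformational
    equilibrium) is carried for completeness; it only rescales the
    effective ``[B*]``.
    """

    mu: float
    K_confC0: float
    K_d: float
    B_star_conc: float
    K_confB: float = 1.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        for name in ("K_confC0", "K_d", "B_star_conc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def conf_equilibrium(n_D: int, p: MWCParameters) -> float:
    """``K_conf(n_D) = K_confC0 * exp(-mu * n_D)`` for ``0 <= n_D <= 6``."""
    if not 0 <= n_D <= 6:
        raise ValueError("n_D must be in 0..6")
    return p.K_confC0 * math.exp(-p.mu * n_D)


def xi(p: MWCParameters) -> float:
    """Midpoint of the equilibrium binding step in ADP-count units.

    ``xi = (1/mu) * log(K_d * K_confC0 / [B*]^6)``; at ``n_D = xi`` the
    occupancy ``alpha*`` equals 1/2.  Undefined (raises) for ``mu = 0``.
    """
    if p.mu == 0:
        raise ValueError("xi is undefined for mu = 0 (no occupancy step)")
    log_arg = math.log(p.K_d) + math.log(p.K_confC0) - 6.0 * math.log(p.B_star_conc)
    return log_arg / p.mu


def alpha_star(n_D, p: MWCParameters):
    """Equilibrium bound proportion ``1 / (1 + exp(-mu (n_D - xi)))``.

    Valid in the strong conformational-bias regime ``K_conf(n_D) >> 1``;
    see :func:`alpha_star_exact` for the unapproximated expression.
    Accepts scalar or array ``n_D``.
    """
    n_D = np.asarray(n_D, dtype=float)
    out = expit(p.mu * (n_D - xi(p)))
    return float(out) if out.ndim == 0 else out


def alpha_star_exact(n_D, p: MWCParameters):
    """Exact equilibrium bound proportion, evaluated in log space.

    ``alpha* = [B*]^6 / ([B*]^6 + K_d (1 + K_conf(n_D)))``, which reduces to
    :func:`alpha_star` when ``K_conf(n_D) >> 1``.
    """
    n_D = np.asarray(n_D, dtype=float)
    log_kconf = math.log(p.K_confC0) - p.mu * n_D
    log_ratio = (
        math.log(p.K_d)
        + np.logaddexp(0.0, log_kconf)
        - 6.0 * math.log(p.B_star_conc)
    )
    out = expit(-log_ratio)
    return float(out) if out.ndim == 0 else out


def discrete_model_index(
    p: MWCParameters,
    *,
    mu_min: float = SHARPNESS_MU_MIN,
    conf_bias_min: float = CONF_BIAS_MIN,
) -> int | None:
    """The discrete Model n equivalent to these parameters, or ``None``.

    Returns the integer ``n`` with ``n - 1 < xi < n`` provided the step is
    sharp (``mu >= mu_min``) and the binding-competent conformation is
    negligibly populated without KaiB (``K_conf(n_D) >= conf_bias_min`` for
    every ``n_D`` in 0..6, i.e. at ``n_D = 6``).  ``None`` when ``xi`` lies
    outside ``(0, 6)``, falls on an integer, or the conditions fail.
    """
    if p.mu < mu_min:
        return None
    log_kconf_min = math.log(p.K_confC0) - 6.0 * p.mu
    if log_kconf_min < math.log(conf_bias_min):
        return None
    x = xi(p)
    if not 0.0 < x < 6.0 or x == math.floor(x):
        return None
    return int(math.floor(x)) + 1
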