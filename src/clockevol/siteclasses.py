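"""Site-class specifications for codon substitution models.

A site class is a selection regime: a value of the nonsynonymous/synonymous
rate ratio omega and the probability that a site belongs to that class.  The
classic model ladder is

* M0   — one ratio: every site shares a single omega,
* M1a  — nearly neutral: a conserved class (0 < omega0 < 1) and a neutral
  class (omega = 1),
* M2a  — positive selection: M1a plus a class with omega2 > 1,
* M7   — beta: omega ~ Beta(p, q) on (0, 1), discretised,
* M8   — beta & omega: a Beta(p, q) component with probability p0 plus an
  extra class at omega_s >= 1 with probability 1 - p0.

The beta component is discretised into K equal-probability categories
represented by their category means (K = 10 by default, the convention the
estimator and the simulator share so that both sides of a recovery test speak
the same language).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc

SITE_MODELS = ("M0", "M1a", "M2a", "M7", "M8")
DEFAULT_NCAT = 10


@dataclass(frozen=True)
class SiteClassSpec:
    """Selection regime: omega classes with probabilities, plus kappa.

    ``omegas`` and ``probs`` are parallel arrays; probabilities sum to 1.
    ``beta_params``/``p0``/``omega_s`` record the generating parameters for
    the beta-derived models so fits can report them.
    """

    model_name: str
    kappa: float
    omegas: tuple[float, ...]
    probs: tuple[float, ...]
    beta_params: tuple[float, float] | None = None
    p0: float | None = None
    omega_s: float | None = None

    def __post_init__(self):
        if self.model_name not in SITE_MODELS:
            raise ValueError(f"unknown site model {self.model_name}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        om = np.asarray(self.omegas, dtype=float)
        pr = np.asarray(self.probs, dtype=float)
        if om.shape != pr.shape:
            raise ValueError("omegas and probs must be parallel")
        if np.any(om < 0):
            raise ValueError("omega values must be non-negative")
        if np.any(pr < 0) or abs(pr.sum() - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        object.__setattr__(self, "omegas", tuple(float(x) for x in om))
        object.__setattr__(self, "probs", tuple(float(x) for x in pr))

    @property
    def n_classes(self) -> int:
        return len(self.omegas)

    def omega_array(self) -> np.ndarray:
        return np.asarray(self.omegas)

    def prob_array(self) -> np.ndarray:
        return np.asarray(self.probs)

    def mean_omega(self) -> float:
        return float(np.dot(self.omegas, self.probs))


def discretize_beta(p: float, q: float, ncat: int = DEFAULT_NCAT) -> np.ndarray:
    """Means of the K equal-probability categories of Beta(p, q).

    Category k covers the quantile interval [k/K, (k+1)/K]; its mean is
    obtained from the regularised incomplete beta function of Beta(p+1, q):
    E[X | a < X < b] = (p/(p+q)) * (I_b(p+1,q) - I_a(p+1,q)) / (1/K).
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta parameters must be positive")
    from scipy.stats import beta as beta_dist

    edges = beta_dist.ppf(np.linspace(0, 1, ncat + 1), p, q)
    mass_inc = betainc(p + 1, q, edges)
    means = (p / (p + q)) * np.diff(mass_inc) * ncat
    # guard against quantile round-off at extreme shapes
    return np.clip(means, 0.0, 1.0)


def spec_m0(omega: float, kappa: float = 2.0) -> SiteClassSpec:
    return SiteClassSpec("M0", kappa, (omega,), (1.0,))


def spec_m1a(p0: float, omega0: float, kappa: float = 2.0) -> SiteClassSpec:
    return SiteClassSpec("M1a", kappa, (omega0, 1.0), (p0, 1.0 - p0), p0=p0)


def spec_m2a(
    p0: float, p1: float, omega0: float, omega2: float, kappa: float = 2.0
) -> SiteClassSpec:
    p2 = 1.0 - p0 - p1
    if p2 < -1e-12:
        raise ValueError("class probabilities exceed 1")
    return SiteClassSpec(
        "M2a", kappa, (omega0, 1.0, omega2), (p0, p1, max(p2, 0.0)), p0=p0
    )


def spec_m7(p: float, q: float, kappa: float = 2.0, ncat: int = DEFAULT_NCAT) -> SiteClassSpec:
    means = discretize_beta(p, q, ncat)
    return SiteClassSpec(
        "M7", kappa, tuple(means), tuple(np.full(ncat, 1.0 / ncat)), beta_params=(p, q)
    )


def spec_m8(
    p: float,
    q: float,
    p0: float,
    omega_s: float,
    kappa: float = 2.0,
    ncat: int = DEFAULT_NCAT,
) -> SiteClassSpec:
    if omega_s < 1.0:
        raise ValueError("the M8 extra class requires omega_s >= 1")
    means = discretize_beta(p, q, ncat)
    probs = np.append(np.full(ncat, p0 / ncat), 1.0 - p0)
    return SiteClassSpec(
        "M8",
        kappa,
        tuple(np.append(means, omega_s)),
        tuple(probs),
        beta_params=(p, q),
        p0=p0,
        omega_s=omega_s,
    )
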