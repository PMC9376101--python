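"""Parametric families for the true displacement distribution over one lag.

The families cover the phenomenological candidates (exponential, folded
Gaussian, Rayleigh, Weibull) and two physical models: diffusion with drift
(Rice distribution of step sizes) and the analytic 1-D position-jump law
(compound Poisson of exponential jumps, with a discrete atom at zero for
particles that never jump within the observation time).

Parameter conventions (``DisplacementDistribution.params``):

========================  ==========================================
family                    params
========================  ==========================================
``exponential``           ``(scale,)`` mean displacement, nm
``folded_gaussian``       ``(mu, sigma)`` nm (|N(mu, sigma^2)|)
``rayleigh``              ``(scale,)`` Rayleigh sigma, nm
``weibull``               ``(shape k, scale lam)`` nm
``rice``                  ``(nu, sigma)`` drift distance and
                          dispersion over the lag, nm
``jump_analytic``         ``(mu_tau, jump_scale)`` mean jump count
                          over the lag (dimensionless) and mean jump
                          length, nm
========================  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "FAMILIES",
    "DisplacementDistribution",
    "JumpModelParams",
    "family_pdf",
    "family_cdf",
    "family_mean",
    "jump_analytic_pdf",
    "jump_analytic_cdf",
    "sample_true_displacements",
]

FAMILIES = (
    "exponential",
    "folded_gaussian",
    "rayleigh",
    "weibull",
    "rice",
    "jump_analytic",
)

_N_PARAMS = {
    "exponential": 1,
    "folded_gaussian": 2,
    "rayleigh": 1,
    "weibull": 2,
    "rice": 2,
    "jump_analytic": 2,
}


@dataclass(frozen=True)
class DisplacementDistribution:
    """A true-displacement distribution over one observation timescale."""

    family: str
    params: tuple
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if len(self.params) != _N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} takes {_N_PARAMS[self.family]} parameters, "
                f"got {len(self.params)}"
            )
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        p = np.asarray(self.params, dtype=float)
        if self.family == "folded_gaussian":
            if p[1] <= 0:
                raise ValueError("folded_gaussian sigma must be positive")
            if p[0] < 0:
                raise ValueError("folded_gaussian mu must be nonnegative")
        elif self.family == "rice":
            if p[0] < 0 or p[1] <= 0:
                raise ValueError("rice requires nu >= 0 and sigma > 0")
        elif np.any(p <= 0):
            raise ValueError(f"{self.family} parameters must be positive")


@dataclass(frozen=True)
class JumpModelParams:
    """Parameters of the 1-D position-jump-with-reversals model.

    ``jump_scale``: mean jump distance (nm); ``wait_scale``: mean waiting
    time between jumps (s); ``p_switch``: probability that a jump reverses
    direction relative to the previous jump.
    """

    jump_scale: float
    wait_scale: float
    p_switch: float = 0.0

    def __post_init__(self) -> None:
        if self.jump_scale <= 0:
            raise ValueError("jump_scale must be positive")
        if self.wait_scale <= 0:
            raise ValueError("wait_scale must be positive")
        if not 0.0 <= self.p_switch <= 1.0:
            raise ValueError("p_switch must lie in [0, 1]")

    @property
    def jump_rate(self) -> float:
        """Mean jump rate mu = 1/wait_scale (1/s)."""
        return 1.0 / self.wait_scale


def _frozen(dist: DisplacementDistribution):
    """scipy frozen distribution for the continuous families."""
    p = dist.params
    if dist.family == "exponential":
        return stats.expon(scale=p[0])
    if dist.family == "folded_gaussian":
        mu, sigma = p
        return stats.foldnorm(c=mu / sigma, scale=sigma)
    if dist.family == "rayleigh":
        return stats.rayleigh(scale=p[0])
    if dist.family == "weibull":
        k, lam = p
        return stats.weibull_min(c=k, scale=lam)
    if dist.family == "rice":
        nu, sigma = p
        return stats.rice(b=nu / sigma, scale=sigma)
    raise ValueError(f"no frozen form for family {dist.family!r}")


def family_pdf(dist: DisplacementDistribution, s) -> np.ndarray:
    """Density of the family at displacement ``s`` (nm).

    The Weibull density is (k/lam)(s/lam)^(k-1) exp(-(s/lam)^k), with the
    exponential (k=1) and Rayleigh (k=2, lam = sqrt(2) sigma) special
    cases; the Rice family reduces to Rayleigh at zero drift.  For
    ``jump_analytic`` this returns only the continuous part (mass
    1 - exp(-mu_tau)); use :func:`jump_analytic_pdf` for the atom.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("displacement s must be nonnegative")
    if dist.family == "jump_analytic":
        mu_tau, jump_scale = dist.params
        return _jump_density(s, mu_tau, jump_scale)
    return _frozen(dist).pdf(s)


def family_cdf(dist: DisplacementDistribution, s) -> np.ndarray:
    """CDF of the family at ``s``; includes the atom for ``jump_analytic``."""
    s = np.asarray(s, dtype=float)
    if dist.family == "jump_analytic":
        mu_tau, jump_scale = dist.params
        return jump_analytic_cdf(mu_tau, jump_scale, s)
    return _frozen(dist).cdf(s)


def family_mean(dist: DisplacementDistribution) -> float:
    """Mean displacement (nm); divide by ``dist.tau`` for mean velocity.

    Closed forms: Weibull lam*Gamma(1+1/k); jump_analytic mu_tau*jump_scale
    (Wald identity, atom included).  Others via scipy.
    """
    p = dist.params
    if dist.family == "weibull":
        k, lam = p
        return float(lam * special.gamma(1.0 + 1.0 / k))
    if dist.family == "exponential":
        return float(p[0])
    if dist.family == "rayleigh":
        return float(p[0] * np.sqrt(np.pi / 2.0))
    if dist.family == "jump_analytic":
        mu_tau, jump_scale = p
        return float(mu_tau * jump_scale)
    return float(_frozen(dist).mean())


def _jump_density(s: np.ndarray, mu_tau: float, jump_scale: float) -> np.ndarray:
    """Continuous part of the compound-Poisson jump displacement law.

    Sum over n >= 1 of Poisson(n; mu_tau) * Gamma(n, jump_scale) densities,
    which collapses to the Bessel closed form
    exp(-m - s/L) * sqrt(m/(s L)) * I1(2 sqrt(m s / L)).
    Evaluated with the exponentially scaled I1 for stability; the s -> 0
    limit is m/L * exp(-m).
    """
    s = np.asarray(s, dtype=float)
    m, L = float(mu_tau), float(jump_scale)
    out = np.empty_like(s)
    zero = s == 0
    out[zero] = m / L * np.exp(-m)
    sp = s[~zero]
    z = 2.0 * np.sqrt(m * sp / L)
    out[~zero] = np.sqrt(m / (sp * L)) * special.i1e(z) * np.exp(z - m - sp / L)
    return out


def _jump_nmax(mu_tau: float, tail: float = 1e-10) -> int:
    return int(stats.poisson.isf(tail, mu_tau)) + 2


def jump_analytic_pdf(params: JumpModelParams, tau: float, s):
    """Displacement law of unidirectional 1-D jumps over timescale ``tau``.

    Returns ``(atom_at_zero, density)``: the probability exp(-tau/wait)
    of making no jump at all, and the continuous density of |displacement|
    for particles that jumped at least once.  ``p_switch`` is ignored
    (no reversals in the analytic model).  The continuous part integrates
    to ``1 - atom``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    mu_tau = tau / params.wait_scale
    atom = float(np.exp(-mu_tau))
    return atom, _jump_density(np.asarray(s, dtype=float), mu_tau, params.jump_scale)


def jump_analytic_cdf(mu_tau: float, jump_scale: float, s) -> np.ndarray:
    """CDF of the jump law (atom included) via a truncated Poisson-gamma series.

    The series is truncated where the Poisson tail falls below 1e-10.
    """
    s = np.asarray(s, dtype=float)
    nmax = _jump_nmax(mu_tau)
    ns = np.arange(1, nmax + 1)
    pois = stats.poisson.pmf(ns, mu_tau)
    out = np.full(s.shape, np.exp(-mu_tau))
    for n, w in zip(ns, pois):
        out += w * stats.gamma.cdf(s, a=n, scale=jump_scale)
    return out


def sample_true_displacements(
    dist: DisplacementDistribution,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` i.i.d. displacements from the family (deterministic per seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if dist.family == "jump_analytic":
        mu_tau, jump_scale = dist.params
        counts = rng.poisson(mu_tau, size=n)
        out = np.zeros(n)
        nz = counts > 0
        out[nz] = rng.gamma(shape=counts[nz], scale=jump_scale)
        return out
    return _frozen(dist).rvs(size=n, random_state=rng)
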