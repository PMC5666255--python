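"""Molecular-clock dating of population expansions.

The mismatch expansion age tau is measured in mutational units (2*u*t
generations).  With a per-site per-year substitution rate mu and a fragment of
L sites, the expansion time in years is T = tau / (2 * mu * L).  Short-term
(within-population) mitochondrial rates run roughly an order of magnitude
faster than long-term phylogenetic substitution rates, so a dimensionless
correction factor (default 10) divides the phylogenetically calibrated time.

The default rate ``DEFAULT_MU`` = 2.0e-8 substitutions/site/year is a
conventional long-term arthropod COI clock consistent with the expansion
chronologies this package is designed to reproduce; override it for other
markers or taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

DEFAULT_MU = 2.0e-8  # substitutions / site / year
DEFAULT_CORRECTION = 10.0


@dataclass(frozen=True)
class ExpansionTime:
    tau: float
    mu: float
    L: int
    correction_factor: float
    T_years: float
    T_corrected_years: float

    @property
    def T_kyr(self) -> float:
        return self.T_years / 1000.0

    @property
    def T_corrected_kyr(self) -> float:
        return self.T_corrected_years / 1000.0


@dataclass(frozen=True)
class EffectiveSizePair:
    theta0: float
    theta1: float
    u: float
    N0: float
    N1: float

    @property
    def ratio(self) -> float:
        """N1 / N0 expansion magnitude (inf for a bottleneck to zero)."""
        return self.N1 / self.N0 if self.N0 > 0 else float("inf")


def expansion_time(
    tau: float,
    mu: float = DEFAULT_MU,
    L: int = 554,
    correction_factor: float = DEFAULT_CORRECTION,
) -> ExpansionTime:
    """T = tau / (2 mu L), in years, with the short-term rate correction."""
    if tau < 0:
        raise DomainError("tau must be >= 0")
    if mu <= 0 or L <= 0:
        raise DomainError("mu and L must be > 0")
    if correction_factor < 1:
        raise DomainError("correction_factor must be >= 1")
    t_years = tau / (2.0 * mu * L)
    return ExpansionTime(
        tau=tau,
        mu=mu,
        L=L,
        correction_factor=correction_factor,
        T_years=t_years,
        T_corrected_years=t_years / correction_factor,
    )


def effective_sizes(theta0: float, theta1: float, u: float) -> EffectiveSizePair:
    """Invert theta = 2 N u: N0 = theta0/(2u), N1 = theta1/(2u)."""
    if u <= 0:
        raise DomainError("u must be > 0")
    if theta0 < 0 or theta1 < 0:
        raise DomainError("theta values must be >= 0")
    return EffectiveSizePair(theta0, theta1, u, theta0 / (2.0 * u), theta1 / (2.0 * u))
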