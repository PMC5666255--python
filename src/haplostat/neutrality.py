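"""Neutrality tests: Tajima's D and Fu's Fs with coalescent p-values.

Both statistics contrast observed polymorphism with the constant-size neutral
expectation.  D compares the mean pairwise difference with the Watterson
estimate S/a1; Fs asks how surprising the observed number of haplotypes K is
given the pairwise-difference estimate of theta, under the Ewens sampling
distribution.  Significantly negative values of either signal an excess of
rare variants, the footprint of population expansion (or a selective sweep).

P-values are obtained by parametric simulation: constant-size coalescent
replicates at theta = Pi_bar (Tajima's estimator, following Fu's original
recipe), left tail, with the (r+1)/(B+1) correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from . import coalsim
from .diversity import pairwise_diversity, segregating_sites
from .errors import SampleSizeError, StatisticUndefinedError
from .seq_io import Alignment, collapse_haplotypes


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The standard a1..e2 constants of Tajima's variance normalisation."""
    if n < 4:
        raise SampleSizeError("Tajima's D requires n >= 4")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d_from_summary(n: int, S: int, pi_bar: float) -> float:
    """D from the sufficient summary (n, S, Pi_bar)."""
    if S < 1:
        raise StatisticUndefinedError("Tajima's D undefined for S = 0")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi_bar - S / c["a1"]) / math.sqrt(var)


def tajimas_d(aln: Alignment) -> float:
    """Tajima's D of an alignment (complete-deletion site set)."""
    S = segregating_sites(aln)
    pi_bar, _ = pairwise_diversity(aln)
    return tajimas_d_from_summary(aln.n, S, pi_bar)


# ---------------------------------------------------------------------------
# Fu's Fs
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    Log-space row recurrence |s(n+1,k)| = n|s(n,k)| + |s(n,k-1)| to avoid
    overflow at study-scale n (|s(364, k)| overflows double precision).
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(n):
        new = np.full(n + 1, -np.inf)
        # |s(m+1,k)| = m*|s(m,k)| + |s(m,k-1)|
        with np.errstate(divide="ignore"):
            scaled = row + (math.log(m) if m > 0 else -np.inf)
        new[1:] = np.logaddexp(scaled[1:], row[:-1])
        new[0] = scaled[0]
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 0..n under the Ewens sampling distribution.

    P(K=k) = |s(n,k)| theta^k / (theta (theta+1) ... (theta+n-1)).
    """
    if n < 1:
        raise SampleSizeError("Ewens distribution requires n >= 1")
    if theta <= 0:
        raise StatisticUndefinedError("Ewens distribution requires theta > 0")
    ls = _log_stirling_row(n)
    k = np.arange(n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return ls + k * math.log(theta) - log_rising


def fus_fs_from_summary(n: int, k_obs: int, pi_bar: float) -> float:
    """Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta = Pi_bar)."""
    if n < 2:
        raise SampleSizeError("Fu's Fs requires n >= 2")
    if pi_bar <= 0:
        raise StatisticUndefinedError("Fu's Fs undefined for Pi_bar = 0")
    if not 1 <= k_obs <= n:
        raise StatisticUndefinedError(f"k_obs={k_obs} outside 1..{n}")
    logp = ewens_log_pmf(n, pi_bar)
    log_sp = logsumexp(logp[k_obs:])
    log_sp_c = logsumexp(logp[:k_obs]) if k_obs > 1 else -np.inf
    if not np.isfinite(log_sp_c):
        raise StatisticUndefinedError(
            "S' = 1 boundary (k_obs = 1): Fu's Fs diverges to +infinity"
        )
    if not np.isfinite(log_sp):
        raise StatisticUndefinedError("S' = 0 boundary: Fu's Fs diverges to -infinity")
    return float(log_sp - log_sp_c)


def fus_fs(aln: Alignment) -> float:
    """Fu's Fs of an alignment (strict haplotype identity, complete deletion)."""
    pi_bar, _ = pairwise_diversity(aln)
    table = collapse_haplotypes(aln, policy="strict")
    return fus_fs_from_summary(aln.n, table.K_hap, pi_bar)


# ---------------------------------------------------------------------------
# simulation-based significance
# ---------------------------------------------------------------------------

@dataclass
class NeutralityResult:
    D: float | None
    Fs: float | None
    p_D: float | None
    p_Fs: float | None
    n_sims: int
    seed: int | None
    dropped_D: int = 0
    dropped_Fs: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def fs_significant_005(self) -> bool | None:
        """Fu's convention: Fs is significant at the 0.05 level when p < 0.02."""
        if self.p_Fs is None:
            return None
        return self.p_Fs < 0.02


def neutrality_pvalues(
    n: int,
    theta_hat: float,
    observed_D: float | None = None,
    observed_Fs: float | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
    L: int = 554,
) -> NeutralityResult:
    """Left-tail coalescent p-values for observed D and/or Fs.

    Simulates ``n_sims`` constant-size replicates at ``theta_hat``, recomputes
    each statistic, and reports p = (r+1)/(B+1) where r counts simulated values
    <= observed (negative values signal expansion, hence the left tail).
    Replicates on which a statistic is undefined (monomorphic data for D,
    Pi_bar = 0 for Fs) are dropped and counted; a drop fraction above 10%
    surfaces a warning in the result.
    """
    if n_sims < 100:
        raise SampleSizeError("need n_sims >= 100 for a stable p-value")
    if theta_hat <= 0:
        raise StatisticUndefinedError("theta_hat must be > 0 to simulate the null")
    rng = np.random.default_rng(seed)
    spec = coalsim.SimulationSpec(n_per_deme=(n,), theta=theta_hat, L=L)

    r_D = r_Fs = used_D = used_Fs = drop_D = drop_Fs = 0
    for _ in range(n_sims):
        S, pi_bar, K = coalsim.simulate_summary(spec, rng)
        if observed_D is not None:
            if S >= 1:
                d = tajimas_d_from_summary(n, S, pi_bar)
                used_D += 1
                if d <= observed_D:
                    r_D += 1
            else:
                drop_D += 1
        if observed_Fs is not None:
            try:
                fs = fus_fs_from_summary(n, K, pi_bar)
            except StatisticUndefinedError:
                drop_Fs += 1
            else:
                used_Fs += 1
                if fs <= observed_Fs:
                    r_Fs += 1

    warnings = []
    if observed_D is not None and drop_D > 0.1 * n_sims:
        warnings.append(f"{drop_D}/{n_sims} D replicates undefined and dropped")
    if observed_Fs is not None and drop_Fs > 0.1 * n_sims:
        warnings.append(f"{drop_Fs}/{n_sims} Fs replicates undefined and dropped")

    return NeutralityResult(
        D=observed_D,
        Fs=observed_Fs,
        p_D=(r_D + 1) / (used_D + 1) if observed_D is not None and used_D else None,
        p_Fs=(r_Fs + 1) / (used_Fs + 1) if observed_Fs is not None and used_Fs else None,
        n_sims=n_sims,
        seed=seed,
        dropped_D=drop_D,
        dropped_Fs=drop_Fs,
        warnings=warnings,
    )


def analyze_alignment(
    aln: Alignment, n_sims: int = 1000, seed: int | None = None
) -> NeutralityResult:
    """Run both neutrality tests on an alignment with simulated p-values."""
    pi_bar, _ = pairwise_diversity(aln)
    try:
        D = tajimas_d(aln)
    except (StatisticUndefinedError, SampleSizeError):
        D = None
    try:
        Fs = fus_fs(aln)
    except (StatisticUndefinedError, SampleSizeError):
        Fs = None
    if pi_bar <= 0 or (D is None and Fs is None):
        return NeutralityResult(D, Fs, None, None, n_sims, seed)
    return neutrality_pvalues(
        aln.n, pi_bar, observed_D=D, observed_Fs=Fs, n_sims=n_sims, seed=seed, L=aln.L
    )
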