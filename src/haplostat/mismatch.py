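"""Mismatch distributions and expansion-model fitting.

The mismatch distribution is the histogram of pairwise nucleotide differences.
Under a stationary population it is ragged and geometric-ish; after a recent
demographic expansion it is a smooth unimodal wave whose position measures the
expansion age tau (in units of 1/(2u) generations, u = per-locus mutation
rate).

Two expected models are provided:

* sudden (demographic) expansion — a population at equilibrium scaled size
  theta0 jumps to theta1 at time tau before present.  The expected frequency
  of pairs with i differences is

      F_i(tau, theta0, theta1) = Fhat_i(theta1)
          + exp(-tau (theta1+1)/theta1)
            * sum_{j<=i} tau^(i-j)/(i-j)! (Fhat_j(theta0) - Fhat_j(theta1))

  with the equilibrium distribution Fhat_i(theta) = theta^i/(theta+1)^(i+1);

* spatial expansion — at time tau a single deme of size theta seeds an
  infinite array of islands (each of size theta) exchanging migrants at scaled
  rate M; pairs are sampled within one deme.  The within-deme coalescence
  density is pieced together from the pre- and post-expansion phases and the
  expected mismatch evaluated numerically (regularised incomplete-gamma
  terms plus a Poisson mixture over the ancestral equilibrium).

Fitting minimises the sum of squared deviations (SSD) between observed and
expected relative frequencies, Arlequin-style, with bounded multi-start
Nelder-Mead.  Goodness of fit (SSD and Harpending's raggedness) is judged by
parametric bootstrap: re-simulate under the fitted model, refit, and compare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaln

from . import _fast, coalsim
from .errors import (
    DomainError,
    FitError,
    IdentifiabilityError,
    NumericalError,
    SimulationError,
    UndefinedDistanceError,
)
from .seq_io import AMBIG_START, Alignment, DeletionPolicy, complete_deletion_mask

Model = Literal["demographic", "spatial"]

TAU_BOUNDS = (0.0, 50.0)
THETA_BOUNDS = (0.0, 1.0e5)
M_BOUNDS = (0.0, 1.0e5)

#: Stand-in for an effectively infinite post-expansion size in the
#: star-expansion (theta1 -> inf) variant of the demographic model.
LARGE_THETA1 = 1.0e5


@dataclass
class MismatchHistogram:
    """Histogram of pairwise differences over classes 0..d_max."""

    counts: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.sum() != self.n_pairs:
            raise DomainError("histogram counts do not sum to the pair count")

    @property
    def relative(self) -> np.ndarray:
        return self.counts / self.n_pairs

    @property
    def mean(self) -> float:
        """Mean pairwise difference; equals the diversity module's Pi_bar."""
        return float(np.arange(self.counts.size) @ self.counts / self.n_pairs)

    @property
    def d_max(self) -> int:
        return self.counts.size - 1


@dataclass
class MismatchFit:
    """Fitted expansion model with goodness-of-fit diagnostics."""

    model: Model
    tau: float
    theta0: float
    theta1: float | None  # demographic model
    M: float | None  # spatial model
    expected: np.ndarray
    SSD: float
    RAG: float
    d_max: int
    star: bool = False
    theta1_inf: bool = False
    p_SSD: float | None = None
    p_RAG: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    B: int = 0
    seed: int | None = None
    n_failed: int = 0
    warnings: list[str] = field(default_factory=list)

    def params(self) -> dict[str, float]:
        if self.model == "demographic":
            return {"tau": self.tau, "theta0": self.theta0, "theta1": self.theta1}
        return {"tau": self.tau, "theta": self.theta0, "M": self.M}


# ---------------------------------------------------------------------------
# observed histogram
# ---------------------------------------------------------------------------

def observed_mismatch(aln: Alignment, deletion: DeletionPolicy = "complete") -> MismatchHistogram:
    """Histogram of count distances over all unordered sequence pairs."""
    if aln.n < 2:
        raise UndefinedDistanceError("mismatch distribution requires n >= 2")
    arr = aln.to_array()
    if deletion == "complete":
        arr = arr[:, complete_deletion_mask(aln)]
    if arr.shape[1] == 0:
        raise UndefinedDistanceError("no unambiguous columns left after deletion")

    if np.all(arr < AMBIG_START):
        # fast path: collapse to unique rows, count pairs with multiplicity
        uniq, counts = np.unique(arr, axis=0, return_counts=True)
        k = uniq.shape[0]
        poly = np.any(uniq != uniq[0], axis=0)
        u = uniq[:, poly]
        dmat = np.zeros((k, k), dtype=np.int64)
        for i in range(k):
            dmat[i] = (u[i] != u).sum(axis=1)
        d_max = int(dmat.max()) if k > 1 else 0
        hist = np.zeros(d_max + 1, dtype=np.int64)
        hist[0] += int(np.sum(counts * (counts - 1) // 2))
        iu = np.triu_indices(k, 1)
        np.add.at(hist, dmat[iu], (counts[:, None] * counts[None, :])[iu])
        return MismatchHistogram(hist, aln.n * (aln.n - 1) // 2)

    clear = arr < AMBIG_START
    n = aln.n
    dists = []
    for i in range(n - 1):
        both = clear[i] & clear[i + 1:]
        if np.any(both.sum(axis=1) == 0):
            raise UndefinedDistanceError("a pair shares no unambiguous site")
        dists.append(((arr[i] != arr[i + 1:]) & both).sum(axis=1))
    d = np.concatenate(dists)
    hist = np.bincount(d)
    return MismatchHistogram(hist, n * (n - 1) // 2)


# ---------------------------------------------------------------------------
# expected distributions
# ---------------------------------------------------------------------------

def equilibrium_mismatch(theta: float, d_max: int) -> np.ndarray:
    """Fhat_i(theta) = theta^i / (theta+1)^(i+1), i = 0..d_max (untruncated mass)."""
    if theta < 0:
        raise DomainError("theta must be >= 0")
    i = np.arange(d_max + 1)
    if theta == 0.0:
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    return np.exp(i * math.log(theta) - (i + 1) * math.log(theta + 1.0))


def expected_sudden(
    tau: float, theta0: float, theta1: float, d_max: int, normalize: bool = True
) -> np.ndarray:
    """Sudden-expansion expected mismatch over classes 0..d_max.

    ``normalize=False`` returns the raw model probabilities (whose full sum
    over 0..infinity is 1); the default renormalises the truncated vector.
    """
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise DomainError("tau, theta0, theta1 must be >= 0")
    if theta1 == 0.0:
        # analytic limit: everything coalesces instantly in the present deme
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    f1 = equilibrium_mismatch(theta1, d_max)
    f0 = equilibrium_mismatch(theta0, d_max)
    log_damp = -tau * (theta1 + 1.0) / theta1
    k = np.arange(d_max + 1)
    if tau == 0.0:
        w = np.zeros(d_max + 1)
        w[0] = math.exp(log_damp)
    else:
        w = np.exp(log_damp + k * math.log(tau) - gammaln(k + 1.0))
    out = f1 + np.convolve(w, f0 - f1)[: d_max + 1]
    out = np.clip(out, 0.0, None)  # guard tiny negative round-off
    if normalize:
        total = out.sum()
        if total <= 0:
            raise NumericalError("sudden-expansion distribution vanished numerically")
        out = out / total
    return out


def expected_spatial(
    tau: float, theta: float, M: float, d_max: int, normalize: bool = True
) -> np.ndarray:
    """Infinite-island spatial-expansion expected mismatch over 0..d_max.

    Within-deme pairs either coalesce in the sampling deme before the
    expansion horizon tau (rate 1/theta, escaping it at migration rate
    M/theta), or survive to the ancestral deme where coalescence is
    exponential with mean theta.  The first phase yields regularised
    incomplete-gamma terms; the second a Poisson(tau) mixture of the
    ancestral equilibrium distribution.
    """
    if tau < 0 or theta < 0 or M < 0:
        raise DomainError("tau, theta, M must be >= 0")
    if theta == 0.0:
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    i = np.arange(d_max + 1)
    a = 1.0 + (1.0 + M) / theta
    # phase 1: coalescence in the sampling deme at time t < tau
    part1 = (1.0 / theta) * gammainc(i + 1.0, a * tau) * np.exp(-(i + 1.0) * math.log(a))
    # phase 2: survive to tau (coalesced nowhere), then ancestral equilibrium
    survive = 1.0 - (1.0 - math.exp(-(1.0 + M) * tau / theta)) / (1.0 + M)
    if tau == 0.0:
        pois = np.zeros(d_max + 1)
        pois[0] = 1.0
    else:
        pois = np.exp(-tau + i * math.log(tau) - gammaln(i + 1.0))
    part2 = survive * np.convolve(pois, equilibrium_mismatch(theta, d_max))[: d_max + 1]
    out = part1 + part2
    if not np.all(np.isfinite(out)):
        raise NumericalError(
            f"spatial-expansion evaluation not finite at tau={tau}, theta={theta}, M={M}"
        )
    if normalize:
        total = out.sum()
        if total <= 0:
            raise NumericalError("spatial-expansion distribution vanished numerically")
        out = out / total
    return out


def raggedness(x: np.ndarray) -> float:
    """Harpending's raggedness r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2, x_{d+1} = 0."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise DomainError("raggedness needs a 1-d distribution")
    if abs(x.sum() - 1.0) > 1e-6:
        raise DomainError("raggedness input must be a normalised distribution")
    return float(np.sum(np.diff(np.append(x, 0.0)) ** 2))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _expected(model: Model, params: np.ndarray, d_max: int) -> np.ndarray:
    if model == "demographic":
        return expected_sudden(params[0], params[1], params[2], d_max)
    return expected_spatial(params[0], params[1], params[2], d_max)


def _ssd(model: Model, params: np.ndarray, obs_rel: np.ndarray) -> float:
    try:
        exp = _expected(model, params, obs_rel.size - 1)
    except (DomainError, NumericalError):
        return np.inf
    return float(np.sum((obs_rel - exp) ** 2))


def _starting_points(model: Model, tau_moment: float) -> list[np.ndarray]:
    taus = [tau_moment, max(tau_moment / 2.0, 0.05)]
    pts = []
    if model == "demographic":
        for t in taus:
            for th0 in (0.01, 1.0):
                for th1 in (10.0, 100.0):
                    pts.append(np.array([t, th0, th1]))
    else:
        for t in taus:
            for th in (0.1, 1.0):
                for m in (1.0, 50.0):
                    pts.append(np.array([t, th, m]))
    return pts


def _star_starting_points(hist: MismatchHistogram) -> list[np.ndarray]:
    """Deterministic start grid for the theta1-fixed (star) fit.

    Dense in the tau/theta0 ridge direction plus the Rogers method-of-moments
    point (theta0 = sqrt(max(v - m, 0)), tau = m - theta0), so the global
    optimum is found consistently across datasets.
    """
    m = min(hist.mean, TAU_BOUNDS[1])
    i = np.arange(hist.counts.size)
    v = float(((i - hist.mean) ** 2 * hist.counts).sum() / hist.n_pairs)
    th0_mom = math.sqrt(max(v - hist.mean, 0.0))
    pts = [
        np.array([t, th0, LARGE_THETA1])
        for t in (m, 0.5 * m)
        for th0 in (1e-3, 0.3)
    ]
    pts.append(np.array([max(m - th0_mom, 0.05), th0_mom, LARGE_THETA1]))
    return pts


def fit_expansion(
    hist: MismatchHistogram,
    model: Model = "demographic",
    d_max: int | None = None,
    starts: list[np.ndarray] | None = None,
    star: bool = False,
) -> MismatchFit:
    """Least-squares fit of an expansion model to an observed histogram.

    ``d_max`` defaults to the largest observed difference + 5 (bounded support
    with negligible truncated model mass).  At least two histogram classes
    must carry mass for the parameters to be identifiable.

    ``star=True`` (demographic model only) fixes theta1 at its effectively
    infinite star-expansion limit, the classical large-expansion assumption.
    theta1 is weakly identified by the SSD objective, so the free fit often
    runs it to the boundary; the star variant is the stable estimator and the
    one whose parametric-bootstrap goodness of fit is well calibrated.
    """
    if model not in ("demographic", "spatial"):
        raise DomainError(f"unknown model {model!r}")
    if star and model != "demographic":
        raise DomainError("star variant applies to the demographic model only")
    if int(np.sum(hist.counts > 0)) < 2:
        raise IdentifiabilityError(
            "mismatch histogram is degenerate (all pairs in one difference class)"
        )
    if d_max is None:
        d_max = hist.d_max + 5
    obs = np.zeros(d_max + 1)
    obs[: hist.counts.size] = hist.relative

    if star:
        bounds = [TAU_BOUNDS, THETA_BOUNDS, (LARGE_THETA1, LARGE_THETA1)]
        if starts is None:
            starts = _star_starting_points(hist)
    else:
        bounds = (
            [TAU_BOUNDS, THETA_BOUNDS, THETA_BOUNDS]
            if model == "demographic"
            else [TAU_BOUNDS, THETA_BOUNDS, M_BOUNDS]
        )
        if starts is None:
            starts = _starting_points(model, min(hist.mean, TAU_BOUNDS[1]))

    best = None
    trace = []
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        f0 = _ssd(model, x0, obs)
        fast = (
            _fast.minimize_sudden(x0, obs, bounds) if model == "demographic" else None
        )
        if fast is not None:
            xb, fb = fast
        else:
            res = minimize(
                lambda p: _ssd(model, p, obs),
                x0,
                method="Nelder-Mead",
                bounds=bounds,
                options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 2000},
            )
            xb, fb = np.asarray(res.x), float(res.fun)
        trace.append((list(x0), fb))
        # never return uphill of the start
        cand = (f0, x0) if f0 < fb else (fb, xb)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None or not np.isfinite(best[0]):
        raise FitError(f"all optimisation starts failed; trace: {trace}")

    ssd_val, x = best
    exp = _expected(model, x, d_max)
    rag = raggedness(obs)
    if model == "demographic":
        theta1_inf = star or x[2] >= 0.99 * THETA_BOUNDS[1]
        return MismatchFit(
            model, float(x[0]), float(x[1]), float(x[2]), None,
            exp, ssd_val, rag, d_max, star=star, theta1_inf=theta1_inf,
        )
    return MismatchFit(
        model, float(x[0]), float(x[1]), None, float(x[2]), exp, ssd_val, rag, d_max
    )


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------

_SPATIAL_DEMES = 25  # finite stand-in for the infinite-island array


def _bootstrap_spec(fit: MismatchFit, n: int, L: int) -> coalsim.SimulationSpec:
    if fit.model == "demographic":
        return coalsim.SimulationSpec(
            n_per_deme=(n,),
            theta=None,
            theta0=max(fit.theta0, 0.0),
            theta1=max(fit.theta1, 1e-6),
            tau=fit.tau,
            L=L,
        )
    theta = max(fit.theta0, 1e-6)
    return coalsim.SimulationSpec(
        n_per_deme=(n,) + (0,) * (_SPATIAL_DEMES - 1),
        theta=None,
        theta0=theta,
        theta1=theta,
        tau=fit.tau,
        M=fit.M,
        L=L,
    )


def bootstrap_gof(
    fit: MismatchFit,
    aln_shape: tuple[int, int],
    B: int = 1000,
    seed: int | None = None,
    refit_starts: int = 2,
) -> MismatchFit:
    """Parametric-bootstrap p-values for SSD and raggedness, plus parameter CIs.

    Simulates ``B`` coalescent datasets under the fitted parameters with the
    observed sample size and length, refits each (warm-started at the parent
    estimates), and reports p = (number of replicates with statistic >= the
    observed value) / B — the raw-proportion convention of the software
    lineage this module mirrors — and 5th-95th percentile intervals of the
    refitted parameters.  Failed replicates are dropped and counted; more than
    10% failures surfaces a warning.
    """
    if B < 100:
        raise DomainError("need B >= 100 bootstrap replicates")
    n, L = aln_shape
    rng = np.random.default_rng(seed)
    spec = _bootstrap_spec(fit, n, L)
    parent = np.array([v for v in (
        [fit.tau, fit.theta0, fit.theta1] if fit.model == "demographic"
        else [fit.tau, fit.theta0, fit.M]
    )])

    ssd_ge = rag_ge = used = failed = 0
    params_boot = []
    for _ in range(B):
        try:
            S, hist = _simulate_histogram(spec, rng)
            if fit.star:
                starts = None  # deterministic star grid, same as the observed fit
            else:
                starts = [parent.copy()]
                if refit_starts > 1:
                    starts.append(np.array([max(hist.mean, 0.05), 0.01, 10.0]))
            bfit = fit_expansion(hist, model=fit.model, d_max=None, starts=starts,
                                 star=fit.star)
        except (SimulationError, IdentifiabilityError, FitError, UndefinedDistanceError):
            failed += 1
            continue
        used += 1
        if bfit.SSD >= fit.SSD:
            ssd_ge += 1
        obs_rel = np.zeros(hist.d_max + 1)
        obs_rel[: hist.counts.size] = hist.relative
        if raggedness(obs_rel) >= fit.RAG:
            rag_ge += 1
        params_boot.append(
            [bfit.tau, bfit.theta0, bfit.theta1 if fit.model == "demographic" else bfit.M]
        )

    warnings = list(fit.warnings)
    if failed > 0.1 * B:
        warnings.append(f"{failed}/{B} bootstrap replicates failed and were dropped")
    if used == 0:
        raise FitError("every bootstrap replicate failed")

    arr = np.array(params_boot)
    names = ("tau", "theta0", "theta1") if fit.model == "demographic" else ("tau", "theta", "M")
    ci = {
        name: (float(np.percentile(arr[:, j], 5)), float(np.percentile(arr[:, j], 95)))
        for j, name in enumerate(names)
    }
    return replace(
        fit,
        p_SSD=ssd_ge / used,
        p_RAG=rag_ge / used,
        ci=ci,
        B=B,
        seed=seed,
        n_failed=failed,
        warnings=warnings,
    )


def _simulate_histogram(
    spec: coalsim.SimulationSpec, rng: np.random.Generator
) -> tuple[int, MismatchHistogram]:
    counts = coalsim.simulate_mismatch(spec, rng)
    return 0, MismatchHistogram(counts, int(counts.sum()))
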