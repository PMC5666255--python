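"""Optional numba-accelerated kernels for the mismatch fitting hot loop.

The parametric bootstrap refits the sudden-expansion model tens of thousands
of times; a compiled objective plus a compact Nelder-Mead remove the
Python-level overhead.  Everything here mirrors the reference numpy/scipy
implementations in :mod:`haplostat.mismatch`; when numba is missing the
caller silently falls back to those.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _sudden_ssd_nb(tau: float, th0: float, th1: float, obs: np.ndarray) -> float:
    d = obs.shape[0] - 1
    if tau < 0.0 or th0 < 0.0 or th1 < 0.0:
        return 1e300
    expv = np.zeros(d + 1)
    if th1 == 0.0:
        expv[0] = 1.0
    else:
        f1 = np.empty(d + 1)
        f0 = np.empty(d + 1)
        r1 = th1 / (1.0 + th1)
        r0 = th0 / (1.0 + th0)
        v1 = 1.0 / (1.0 + th1)
        v0 = 1.0 / (1.0 + th0)
        for i in range(d + 1):
            f1[i] = v1
            f0[i] = v0
            v1 *= r1
            v0 *= r0
        w = np.zeros(d + 1)
        log_damp = -tau * (th1 + 1.0) / th1
        if tau == 0.0:
            w[0] = np.exp(log_damp)
        else:
            lw = log_damp
            w[0] = np.exp(lw)
            for k in range(1, d + 1):
                lw += np.log(tau) - np.log(k)
                w[k] = np.exp(lw)
        tot = 0.0
        for i in range(d + 1):
            acc = f1[i]
            for j in range(i + 1):
                acc += w[i - j] * (f0[j] - f1[j])
            if acc < 0.0:
                acc = 0.0
            expv[i] = acc
            tot += acc
        if tot <= 0.0:
            return 1e300
        for i in range(d + 1):
            expv[i] /= tot
    ssd = 0.0
    for i in range(d + 1):
        diff = obs[i] - expv[i]
        ssd += diff * diff
    return ssd


@njit(cache=False)
def _nm_sudden(x0, lo, hi, obs, xatol, fatol, maxiter):
    """Bounded Nelder-Mead (clip-to-box) on the sudden-model SSD."""
    ndim = 3
    npts = ndim + 1
    sim = np.empty((npts, ndim))
    fval = np.empty(npts)
    sim[0] = np.minimum(np.maximum(x0, lo), hi)
    for i in range(ndim):
        y = sim[0].copy()
        step = 0.05 * max(abs(y[i]), 1.0)
        y[i] = min(max(y[i] + step, lo[i]), hi[i])
        if y[i] == sim[0, i]:
            y[i] = min(max(y[i] - step, lo[i]), hi[i])
        sim[i + 1] = y
    for i in range(npts):
        fval[i] = _sudden_ssd_nb(sim[i, 0], sim[i, 1], sim[i, 2], obs)

    it = 0
    while it < maxiter:
        order = np.argsort(fval)
        sim = sim[order]
        fval = fval[order]
        # convergence
        if fval[npts - 1] - fval[0] <= fatol:
            spread = 0.0
            for i in range(1, npts):
                for j in range(ndim):
                    s = abs(sim[i, j] - sim[0, j])
                    if s > spread:
                        spread = s
            if spread <= xatol:
                break
        cent = np.zeros(ndim)
        for i in range(npts - 1):
            cent += sim[i]
        cent /= npts - 1
        xr = np.minimum(np.maximum(cent + (cent - sim[npts - 1]), lo), hi)
        fr = _sudden_ssd_nb(xr[0], xr[1], xr[2], obs)
        if fr < fval[0]:
            xe = np.minimum(np.maximum(cent + 2.0 * (cent - sim[npts - 1]), lo), hi)
            fe = _sudden_ssd_nb(xe[0], xe[1], xe[2], obs)
            if fe < fr:
                sim[npts - 1] = xe
                fval[npts - 1] = fe
            else:
                sim[npts - 1] = xr
                fval[npts - 1] = fr
        elif fr < fval[npts - 2]:
            sim[npts - 1] = xr
            fval[npts - 1] = fr
        else:
            if fr < fval[npts - 1]:
                xc = np.minimum(np.maximum(cent + 0.5 * (xr - cent), lo), hi)
            else:
                xc = cent + 0.5 * (sim[npts - 1] - cent)
            fc = _sudden_ssd_nb(xc[0], xc[1], xc[2], obs)
            if fc < min(fr, fval[npts - 1]):
                sim[npts - 1] = xc
                fval[npts - 1] = fc
            else:  # shrink
                for i in range(1, npts):
                    sim[i] = sim[0] + 0.5 * (sim[i] - sim[0])
                    fval[i] = _sudden_ssd_nb(sim[i, 0], sim[i, 1], sim[i, 2], obs)
        it += 1

    best = np.argmin(fval)
    return sim[best], fval[best]


def minimize_sudden(x0, obs, bounds, xatol=1e-4, fatol=1e-12, maxiter=2000):
    """Compiled minimiser for the demographic model; None when unavailable."""
    if not HAVE_NUMBA:
        return None
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x, f = _nm_sudden(
        np.asarray(x0, dtype=np.float64), lo, hi, np.asarray(obs, dtype=np.float64),
        xatol, fatol, maxiter,
    )
    return np.asarray(x), float(f)
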