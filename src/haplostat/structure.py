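"""Distance-based AMOVA, pairwise Phi_ST, and permutation significance.

The analysis of molecular variance partitions the total molecular variance —
computed from squared inter-individual distances, here squared mutational
differences — across a hierarchy of groups and populations, yielding variance
components and Phi fixation indices.  With the 0/1 "different haplotype"
metric (``use_distances=False``) the same machinery returns conventional
frequency-based F-statistics.

Negative variance components are reported as computed (they arise routinely
from the method-of-moments equations); a floor-at-zero view is left to the
caller.  Permutation p-values use the (r+1)/(B+1) corrected estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GroupingError
from .seq_io import Alignment, DistanceMatrix, pairwise_differences


@dataclass
class AmovaResult:
    levels: list[str]
    df: list[int]
    ssd: list[float]
    variance_components: list[float]
    percent_variation: list[float]
    phi: dict[str, float]
    p: dict[str, float]
    n_perm: int
    seed: int | None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": self.df,
                "SSD": self.ssd,
                "variance_component": self.variance_components,
                "percent_variation": self.percent_variation,
            },
            index=self.levels,
        )


@dataclass
class PairwiseFstMatrix:
    ids: list[str]
    phist: np.ndarray
    p: np.ndarray
    n_perm: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phist, index=self.ids, columns=self.ids)

    def p_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.ids, columns=self.ids)

    def sequential_bonferroni(self) -> pd.DataFrame:
        """Holm's sequentially rejective correction over the lower triangle."""
        k = len(self.ids)
        iu = np.triu_indices(k, 1)
        raw = self.p[iu]
        order = np.argsort(raw)
        m = raw.size
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * raw[idx]))
            adj[idx] = running
        out = np.zeros_like(self.p)
        out[iu] = adj
        out = out + out.T
        return pd.DataFrame(out, index=self.ids, columns=self.ids)


def _squared_distance_matrix(
    aln_or_dist: Alignment | DistanceMatrix, use_distances: bool
) -> tuple[list[str], np.ndarray]:
    if isinstance(aln_or_dist, DistanceMatrix):
        ids, d = aln_or_dist.ids, aln_or_dist.d
    else:
        dm = pairwise_differences(aln_or_dist, mode="count", deletion="pairwise")
        ids, d = dm.ids, dm.d
    if use_distances:
        return ids, d**2
    return ids, (d > 0).astype(float)  # 0/1 metric -> conventional F-statistics


def _ssd_within_sets(D2: np.ndarray, sets: Sequence[np.ndarray]) -> float:
    total = 0.0
    for idx in sets:
        if idx.size:
            sub = D2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * idx.size)
    return total


def _two_level_components(D2, pop_indices, n):
    P = len(pop_indices)
    sizes = np.array([idx.size for idx in pop_indices], dtype=float)
    ssd_total = D2.sum() / (2.0 * n)
    ssd_within = _ssd_within_sets(D2, pop_indices)
    ssd_among = ssd_total - ssd_within
    df_among, df_within = P - 1, n - P
    ms_among = ssd_among / df_among
    ms_within = ssd_within / df_within if df_within > 0 else np.nan
    n_c = (n - np.sum(sizes**2) / n) / (P - 1)
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_c
    return ssd_total, ssd_among, ssd_within, df_among, df_within, sigma_a, sigma_w


def amova(
    aln_or_dist: Alignment | DistanceMatrix,
    pops: Sequence[str],
    groups: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    use_distances: bool = True,
) -> AmovaResult:
    """Hierarchical AMOVA with permutation p-values.

    ``pops`` assigns each individual (alignment/matrix order) to a population;
    the optional ``groups`` assigns each individual to a higher-level group.
    Two-level: Phi_ST = sigma2_a / sigma2_total, p by permuting individuals
    among populations.  Three-level: Phi_CT (among groups, permuting whole
    populations among groups), Phi_SC (among populations within groups,
    permuting individuals among populations within their group) and Phi_ST
    (permuting individuals anywhere).
    """
    if n_perm < 1:
        raise GroupingError("n_perm must be >= 1")
    ids, D2 = _squared_distance_matrix(aln_or_dist, use_distances)
    n = len(ids)
    pops = list(pops)
    if len(pops) != n:
        raise GroupingError("pops must assign every individual")
    pop_labels = list(dict.fromkeys(pops))
    if len(pop_labels) < 2:
        raise GroupingError("AMOVA requires >= 2 populations")
    pop_arr = np.array([pop_labels.index(p) for p in pops])
    pop_indices = [np.flatnonzero(pop_arr == i) for i in range(len(pop_labels))]
    if any(idx.size == 0 for idx in pop_indices):
        raise GroupingError("a population has zero samples")
    rng = np.random.default_rng(seed)

    if groups is None:
        (ssd_total, ssd_among, ssd_within, df_a, df_w,
         sigma_a, sigma_w) = _two_level_components(D2, pop_indices, n)
        sigma_tot = sigma_a + sigma_w
        phi_st = sigma_a / sigma_tot if sigma_tot != 0 else 0.0

        r = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            perm_sets = [perm[idx] for idx in pop_indices]
            ssd_w_p = _ssd_within_sets(D2, perm_sets)
            *_, s_a, s_w = _two_level_from_within(D2, perm_sets, n, ssd_total, ssd_w_p)
            tot = s_a + s_w
            phi_p = s_a / tot if tot != 0 else 0.0
            if phi_p >= phi_st:
                r += 1
        p_st = (r + 1) / (n_perm + 1)

        comps = [sigma_a, sigma_w]
        pct = [100.0 * c / sigma_tot for c in comps] if sigma_tot != 0 else [0.0, 0.0]
        return AmovaResult(
            levels=["among_populations", "within_populations"],
            df=[df_a, df_w],
            ssd=[ssd_among, ssd_within],
            variance_components=comps,
            percent_variation=pct,
            phi={"phi_ST": phi_st},
            p={"phi_ST": p_st},
            n_perm=n_perm,
            seed=seed,
        )

    # --- three-level design ---------------------------------------------
    groups = list(groups)
    if len(groups) != n:
        raise GroupingError("groups must assign every individual")
    grp_labels = list(dict.fromkeys(groups))
    if len(grp_labels) < 2:
        raise GroupingError("hierarchical AMOVA requires >= 2 groups")
    grp_arr = np.array([grp_labels.index(g) for g in groups])
    pop_group = {}
    for p_idx, idx in enumerate(pop_indices):
        gset = set(grp_arr[idx])
        if len(gset) != 1:
            raise GroupingError(f"population {pop_labels[p_idx]!r} spans several groups")
        pop_group[p_idx] = gset.pop()

    obs = _three_level(D2, pop_indices, pop_group, grp_arr, n)
    phi_obs = obs["phi"]

    counts = {k: 0 for k in ("phi_ST", "phi_SC", "phi_CT")}
    for _ in range(n_perm):
        # phi_ST: individuals permuted anywhere
        perm = rng.permutation(n)
        sets_st = [perm[idx] for idx in pop_indices]
        st = _three_level(D2, sets_st, pop_group, grp_arr, n, only="phi_ST")
        if st >= phi_obs["phi_ST"]:
            counts["phi_ST"] += 1
        # phi_SC: individuals permuted within their group
        perm_sc = np.arange(n)
        for g in range(len(grp_labels)):
            members = np.flatnonzero(grp_arr == g)
            perm_sc[members] = rng.permutation(members)
        sets_sc = [perm_sc[idx] for idx in pop_indices]
        sc = _three_level(D2, sets_sc, pop_group, grp_arr, n, only="phi_SC")
        if sc >= phi_obs["phi_SC"]:
            counts["phi_SC"] += 1
        # phi_CT: whole populations permuted among groups
        perm_groups = rng.permutation([pop_group[p] for p in range(len(pop_indices))])
        pg = dict(enumerate(perm_groups))
        ct = _three_level(D2, pop_indices, pg, grp_arr, n, only="phi_CT")
        if ct >= phi_obs["phi_CT"]:
            counts["phi_CT"] += 1

    p = {k: (v + 1) / (n_perm + 1) for k, v in counts.items()}
    return AmovaResult(
        levels=["among_groups", "among_populations_within_groups", "within_populations"],
        df=obs["df"],
        ssd=obs["ssd"],
        variance_components=obs["components"],
        percent_variation=obs["pct"],
        phi=phi_obs,
        p=p,
        n_perm=n_perm,
        seed=seed,
    )


def _two_level_from_within(D2, perm_sets, n, ssd_total, ssd_within):
    P = len(perm_sets)
    sizes = np.array([s.size for s in perm_sets], dtype=float)
    ssd_among = ssd_total - ssd_within
    ms_among = ssd_among / (P - 1)
    ms_within = ssd_within / (n - P)
    n_c = (n - np.sum(sizes**2) / n) / (P - 1)
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_c
    return ssd_among, ssd_within, sigma_a, sigma_w


def _three_level(D2, pop_sets, pop_group, grp_arr, n, only=None):
    """Excoffier-style three-level variance components.

    ``pop_sets`` are index arrays per population; ``pop_group`` maps population
    index -> group index.  When ``only`` names a Phi statistic, returns just
    that scalar (permutation fast path).
    """
    G = len(set(pop_group.values()))
    P = len(pop_sets)
    sizes = np.array([s.size for s in pop_sets], dtype=float)
    group_of_pop = np.array([pop_group[p] for p in range(P)])
    group_sets = [
        np.concatenate([pop_sets[p] for p in range(P) if group_of_pop[p] == g])
        for g in sorted(set(pop_group.values()))
    ]
    n_g = np.array([s.size for s in group_sets], dtype=float)

    ssd_total = D2.sum() / (2.0 * n)
    ssd_wp = _ssd_within_sets(D2, pop_sets)
    ssd_wg = _ssd_within_sets(D2, group_sets)
    ssd_ap_wg = ssd_wg - ssd_wp  # among populations within groups
    ssd_ag = ssd_total - ssd_wg  # among groups

    df_ag = G - 1
    df_ap = P - G
    df_wp = n - P

    ms_wp = ssd_wp / df_wp
    ms_ap = ssd_ap_wg / df_ap if df_ap > 0 else 0.0
    ms_ag = ssd_ag / df_ag

    # unequal-sample-size coefficients
    sum_sq_by_group = np.zeros(len(group_sets))
    for p in range(P):
        g = group_of_pop[p]
        sum_sq_by_group[g] += sizes[p] ** 2
    A = float(np.sum(sum_sq_by_group / n_g))
    n1 = (n - A) / df_ap if df_ap > 0 else 0.0
    n2 = (A - np.sum(sizes**2) / n) / df_ag
    n3 = (n - np.sum(n_g**2) / n) / df_ag

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if n1 > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3

    total = sigma_a + sigma_b + sigma_c
    phi = {
        "phi_ST": (sigma_a + sigma_b) / total if total != 0 else 0.0,
        "phi_CT": sigma_a / total if total != 0 else 0.0,
        "phi_SC": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0,
    }
    if only is not None:
        return phi[only]
    return {
        "df": [df_ag, df_ap, df_wp],
        "ssd": [ssd_ag, ssd_ap_wg, ssd_wp],
        "components": [sigma_a, sigma_b, sigma_c],
        "pct": [100.0 * c / total for c in (sigma_a, sigma_b, sigma_c)]
        if total != 0
        else [0.0, 0.0, 0.0],
        "phi": phi,
    }


def pairwise_phist(
    aln_or_dist: Alignment | DistanceMatrix,
    pops: Sequence[str],
    n_perm: int = 1000,
    seed: int | None = None,
    use_distances: bool = True,
) -> PairwiseFstMatrix:
    """Two-level AMOVA applied to every population pair.

    One-sided p = proportion of permuted Phi_ST >= observed, with the
    (r+1)/(B+1) correction.  Populations with fewer than 2 samples leave their
    cells as NaN (statistic undefined).
    """
    ids, D2 = _squared_distance_matrix(aln_or_dist, use_distances)
    n = len(ids)
    pops = list(pops)
    if len(pops) != n:
        raise GroupingError("pops must assign every individual")
    labels = list(dict.fromkeys(pops))
    if len(labels) < 2:
        raise GroupingError("need >= 2 populations")
    pop_arr = np.array([labels.index(p) for p in pops])
    rng = np.random.default_rng(seed)

    k = len(labels)
    phist = np.zeros((k, k))
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            idx_i = np.flatnonzero(pop_arr == i)
            idx_j = np.flatnonzero(pop_arr == j)
            if idx_i.size < 2 or idx_j.size < 2:
                phist[i, j] = phist[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                continue
            sel = np.concatenate([idx_i, idx_j])
            sub = D2[np.ix_(sel, sel)]
            n_pair = sel.size
            sets = [np.arange(idx_i.size), np.arange(idx_i.size, n_pair)]
            ssd_total = sub.sum() / (2.0 * n_pair)
            ssd_w = _ssd_within_sets(sub, sets)
            *_, s_a, s_w = _two_level_from_within(sub, sets, n_pair, ssd_total, ssd_w)
            tot = s_a + s_w
            obs_phi = s_a / tot if tot != 0 else 0.0
            r = 0
            for _ in range(n_perm):
                perm = rng.permutation(n_pair)
                psets = [perm[: idx_i.size], perm[idx_i.size:]]
                ssd_w_p = _ssd_within_sets(sub, psets)
                *_, pa, pw = _two_level_from_within(sub, psets, n_pair, ssd_total, ssd_w_p)
                ptot = pa + pw
                if (pa / ptot if ptot != 0 else 0.0) >= obs_phi:
                    r += 1
            phist[i, j] = phist[j, i] = obs_phi
            pmat[i, j] = pmat[j, i] = (r + 1) / (n_perm + 1)
    np.fill_diagonal(phist, 0.0)
    np.fill_diagonal(pmat, np.nan)
    return PairwiseFstMatrix(labels, phist, pmat, n_perm, seed)
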