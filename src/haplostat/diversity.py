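"""Per-group diversity statistics for aligned haplotype data.

Reports, per geographic group and for the pooled dataset: sample size n,
number of haplotypes k, private haplotypes PH and PH/k, Nei's haplotype (gene)
diversity H, segregating sites S, mean pairwise difference Pi (per locus),
nucleotide diversity pi (per site), and Watterson's theta (per sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GroupingError, SampleSizeError
from .seq_io import (
    AMBIG_START,
    Alignment,
    DeletionPolicy,
    HaplotypeTable,
    check_metadata,
    collapse_haplotypes,
    complete_deletion_mask,
    mean_pairwise_sites,
    pairwise_differences,
)


@dataclass
class DiversitySummary:
    n: int
    K_hap: int
    PH: int | None
    PH_ratio: float | None
    H: float
    S: int
    Pi_bar: float
    pi: float
    theta_w: float


def segregating_sites(aln: Alignment, deletion: DeletionPolicy = "complete") -> int:
    """Number of columns with >= 2 distinct unambiguous states."""
    if aln.n < 2:
        raise SampleSizeError("segregating sites require n >= 2")
    arr = aln.to_array()
    if deletion == "complete":
        arr = arr[:, complete_deletion_mask(aln)]
    count = 0
    for col in arr.T:
        states = np.unique(col[col < AMBIG_START])
        if states.size >= 2:
            count += 1
    return count


def haplotype_diversity(counts, corrected: bool = True) -> float:
    """Nei's gene diversity H = n/(n-1) (1 - sum p_i^2).

    ``corrected=False`` drops the n/(n-1) small-sample factor.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise SampleSizeError("haplotype diversity requires n >= 2")
    h = 1.0 - np.sum((c / n) ** 2)
    return float(h * n / (n - 1.0)) if corrected else float(h)


def pairwise_diversity(
    aln: Alignment, deletion: DeletionPolicy = "complete"
) -> tuple[float, float]:
    """(Pi_bar, pi): mean pairwise difference per locus and per site."""
    if aln.n < 2:
        raise SampleSizeError("pairwise diversity requires n >= 2")
    dm = pairwise_differences(aln, mode="count", deletion=deletion)
    n = aln.n
    iu = np.triu_indices(n, k=1)
    pi_bar = float(dm.d[iu].mean())
    length = mean_pairwise_sites(aln, deletion=deletion)
    return pi_bar, pi_bar / length if length > 0 else float("nan")


def harmonic_number(m: int) -> float:
    """a1 = sum_{i=1}^{m} 1/i."""
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator theta_W = S / a1(n-1), per-sequence scale."""
    if n < 2:
        raise SampleSizeError("Watterson's theta requires n >= 2")
    if S < 0:
        raise SampleSizeError("S must be non-negative")
    return S / harmonic_number(n - 1)


def private_haplotypes(table: HaplotypeTable) -> tuple[pd.Series, pd.Series]:
    """Count of haplotypes seen only in each group, and PH/k per group.

    PH(g) counts haplotypes with non-zero frequency only in g; the ratio
    divides by k(g), the number of haplotypes observed in g.
    """
    if table.counts.shape[1] < 2:
        raise GroupingError("private haplotypes require >= 2 groups")
    present = table.counts.to_numpy() > 0
    n_groups_with = present.sum(axis=1)
    ph = pd.Series(0, index=table.counts.columns, dtype=int)
    for g_idx, g in enumerate(table.counts.columns):
        ph[g] = int(np.sum(present[:, g_idx] & (n_groups_with == 1)))
    k_per_group = pd.Series(present.sum(axis=0), index=table.counts.columns, dtype=int)
    with np.errstate(invalid="ignore"):
        ratio = ph / k_per_group.replace(0, np.nan)
    return ph, ratio


def summarize(
    aln: Alignment,
    meta: pd.DataFrame | None = None,
    grouping: str = "region",
    deletion: DeletionPolicy = "complete",
    policy: str = "wildcard",
) -> pd.DataFrame:
    """Diversity-table summary per group plus the pooled dataset.

    Returns a DataFrame indexed by group label (plus ``"all"``) with columns
    n, k, PH, PH_ratio, H, S, Pi, pi, theta_w.  PH is left missing for the
    pooled row (endemism is only defined relative to a grouping) and for
    single-group inputs.
    """
    table = collapse_haplotypes(aln, meta, grouping=grouping, policy=policy)
    groups = list(table.counts.columns)
    multi = len(groups) >= 2
    if multi:
        ph, ph_ratio = private_haplotypes(table)

    if meta is not None:
        check_metadata(aln, meta)
        group_of = dict(zip(meta["sample_id"], meta[grouping]))
    else:
        group_of = {i: "all" for i in aln.ids}

    rows = {}
    for g in groups + ["all"]:
        if g == "all":
            sub = aln
            counts = table.total_counts().to_numpy()
        else:
            ids = [i for i in aln.ids if group_of[i] == g]
            sub = aln.subset(ids)
            counts = table.counts[g].to_numpy()
        counts = counts[counts > 0]
        if sub.n >= 2:
            S = segregating_sites(sub, deletion=deletion)
            pi_bar, pi = pairwise_diversity(sub, deletion=deletion)
            H = haplotype_diversity(counts)
            theta = watterson_theta(S, sub.n)
        else:
            S, pi_bar, pi, H, theta = 0, np.nan, np.nan, np.nan, np.nan
        rows[g] = {
            "n": sub.n,
            "k": int((counts > 0).sum()),
            "PH": int(ph[g]) if (multi and g != "all") else np.nan,
            "PH_ratio": float(ph_ratio[g]) if (multi and g != "all") else np.nan,
            "H": H,
            "S": S,
            "Pi": pi_bar,
            "pi": pi,
            "theta_w": theta,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = grouping
    return df
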