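"""Coalescent simulation of COI-like alignments.

The simulator realises a standard n-coalescent genealogy and drops mutations on
it, producing rectangular alignments compatible with every statistic in the
package.  Supported histories:

* constant scaled size ``theta`` (per locus);
* sudden expansion: present size ``theta1`` switching to ``theta0`` at time
  ``tau`` before present (backwards in time), with ``tau`` measured in the same
  mutational units as the mismatch-distribution model;
* exponential growth at rate ``growth`` (size ``theta * exp(-growth t)``
  backwards in time, single deme only);
* finite-island migration among ``demes`` demes at scaled rate ``M``, with the
  demes merging into the ancestral deme at ``tau`` (spatial-expansion history)
  or never (plain island model, ``tau=None``).

Time units.  Internally one unit of time equals ``1/(2u)`` generations, where
``u`` is the per-locus per-generation mutation rate.  On that scale a pair of
lineages coalescing ``t`` units ago accumulates Poisson(``t``) differences, a
single lineage mutates at rate 1/2, a deme of scaled size ``theta = 2Nu``
coalesces each lineage pair at rate ``1/theta``, and each lineage migrates at
rate ``M/(2 theta)``.  This makes the simulator's ``(tau, theta0, theta1)``
directly commensurable with the sudden-expansion mismatch model: datasets
simulated at those parameters reproduce its expected mismatch distribution in
expectation.

Mutation models.  ``infinite_sites`` assigns every mutation its own column (so
segregating sites == mutation events by construction; more mutations than
columns raises :class:`SimulationError`).  ``finite_sites_hky`` picks a uniform
column per mutation and applies a transition-biased base change with
P(transition) = tstv/(tstv+1).  The root sequence is all-A; haplotype identity
only depends on differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError
from .seq_io import Alignment

_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T


@dataclass
class SimulationSpec:
    """Parameters of one simulated dataset."""

    n_per_deme: tuple[int, ...] = (20,)
    theta: float | None = 5.0
    theta0: float | None = None
    theta1: float | None = None
    tau: float | None = None
    growth: float | None = None
    M: float = 0.0
    L: int = 554
    tstv: float = 3.99
    model: str = "infinite_sites"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.n_per_deme = tuple(int(x) for x in self.n_per_deme)
        if any(x < 0 for x in self.n_per_deme) or sum(self.n_per_deme) < 1:
            raise SimulationError("need at least one sample")
        if self.model not in ("infinite_sites", "finite_sites_hky"):
            raise SimulationError(f"unknown mutation model {self.model!r}")
        if self.tstv <= 0:
            raise SimulationError("tstv must be > 0")
        if self.L < 1:
            raise SimulationError("L must be >= 1")
        if self.M < 0:
            raise SimulationError("M must be >= 0")
        expansion = self.theta0 is not None or self.theta1 is not None or self.tau is not None
        if expansion:
            if None in (self.theta0, self.theta1, self.tau):
                raise SimulationError("sudden expansion needs theta0, theta1 and tau together")
            if self.theta0 < 0 or self.theta1 <= 0 or self.tau < 0:
                raise SimulationError("expansion parameters must be non-negative (theta1 > 0)")
            if self.growth is not None:
                raise SimulationError("growth and sudden expansion are mutually exclusive")
        else:
            if self.theta is None or self.theta <= 0:
                raise SimulationError("constant-size model needs theta > 0")
        if self.growth is not None and len(self.n_per_deme) > 1:
            raise SimulationError("exponential growth is single-deme only")

    @property
    def demes(self) -> int:
        return len(self.n_per_deme)

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_deme))

    @property
    def is_expansion(self) -> bool:
        return self.tau is not None


@dataclass
class SimulatedDataset:
    alignment: Alignment
    metadata: pd.DataFrame
    true_params: SimulationSpec
    root_haplotype: str


# ---------------------------------------------------------------------------
# genealogy
# ---------------------------------------------------------------------------

def _genealogy_single(spec: SimulationSpec, rng: np.random.Generator):
    """Single-deme fast path: no migration bookkeeping, O(1) per event."""
    n = spec.n_total
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    if spec.is_expansion:
        theta_now, theta_anc, tau = spec.theta1, spec.theta0, spec.tau
    else:
        theta_now, theta_anc, tau = spec.theta, spec.theta, None
    growth = spec.growth or 0.0
    active = list(range(n))
    next_node = n
    t = 0.0
    while len(active) > 1:
        k = len(active)
        if tau is not None and t >= tau:
            if theta_anc == 0.0:
                while len(active) > 1:
                    a = active.pop()
                    b = active[-1]
                    new = next_node
                    next_node += 1
                    parent[a] = parent[b] = new
                    node_time[new] = t
                    active[-1] = new
                break
            theta_now, tau = theta_anc, None
            continue
        pairs = k * (k - 1) / 2.0
        if growth > 0.0:
            e_draw = rng.exponential()
            arg = math.exp(growth * t) + e_draw * growth * theta_now / pairs
            wait = math.log(arg) / growth - t
        else:
            wait = rng.exponential(theta_now / pairs)
        if tau is not None and t + wait > tau:
            t = tau
            continue
        t += wait
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        new = next_node
        next_node += 1
        parent[a] = parent[b] = new
        node_time[new] = t
        hi, lo = (i, j) if i > j else (j, i)
        active[hi] = active[-1]
        active.pop()
        active[lo] = active[-1]
        active.pop()
        active.append(new)
    root = active[0]
    leaf_deme = np.zeros(n, dtype=np.int64)
    return parent[:next_node], node_time[:next_node], leaf_deme, root


def _genealogy(spec: SimulationSpec, rng: np.random.Generator):
    """Simulate the coalescent tree.

    Returns (parent, node_time, leaf_deme): arrays over 2n-1 nodes with leaves
    0..n-1 at time 0 and the root as the last created internal node.  Parents
    are always created after their children, so parent ids exceed child ids —
    traversals below rely on that ordering.
    """
    if spec.demes == 1:
        return _genealogy_single(spec, rng)
    n = spec.n_total
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    leaf_deme = np.repeat(np.arange(spec.demes), spec.n_per_deme)

    active: list[int] = list(range(n))
    deme_of = {i: int(leaf_deme[i]) for i in active}
    next_node = n
    t = 0.0

    if spec.is_expansion:
        theta_now, theta_anc, tau = spec.theta1, spec.theta0, spec.tau
    else:
        theta_now, theta_anc, tau = spec.theta, spec.theta, None
    merged = tau is None and spec.demes == 1
    growth = spec.growth or 0.0

    while len(active) > 1:
        k = len(active)
        if tau is not None and t >= tau:
            # ancestral epoch: single deme of size theta0 (zero-size floor:
            # instantaneous coalescence of everything at tau)
            if theta_anc == 0.0:
                while len(active) > 1:
                    a = active.pop()
                    b = active[-1]
                    new = next_node
                    next_node += 1
                    parent[a] = parent[b] = new
                    node_time[new] = t
                    active[-1] = new
                break
            for i in active:
                deme_of[i] = 0
            theta_now, tau = theta_anc, None
            merged = True
            continue

        # per-deme lineage counts
        if merged:
            pairs_per_deme = {0: k * (k - 1) / 2.0}
        else:
            counts: dict[int, int] = {}
            for i in active:
                counts[deme_of[i]] = counts.get(deme_of[i], 0) + 1
            pairs_per_deme = {d: c * (c - 1) / 2.0 for d, c in counts.items()}
        total_pairs = sum(pairs_per_deme.values())
        coal_rate = total_pairs / theta_now
        mig_rate = 0.0 if (merged or spec.demes == 1) else k * spec.M / (2.0 * theta_now)
        total_rate = coal_rate + mig_rate

        if total_rate <= 0.0:
            # isolated lineages in separate demes: jump straight to tau
            if tau is None:
                raise SimulationError("lineages can never coalesce (M=0, separate demes)")
            t = tau
            continue

        if growth > 0.0:
            # size theta*exp(-g t) backwards: rate grows as exp(g t);
            # inversion of int_t^{t+w} (pairs/theta) e^{g s} ds = E
            e_draw = rng.exponential()
            arg = math.exp(growth * t) + e_draw * growth * theta_now / total_pairs
            wait = math.log(arg) / growth - t
        else:
            wait = rng.exponential(1.0 / total_rate)

        if tau is not None and t + wait > tau:
            t = tau
            continue
        t += wait

        if rng.random() < coal_rate / total_rate:
            # choose deme proportional to its pair count
            demes_list = list(pairs_per_deme)
            weights = np.array([pairs_per_deme[d] for d in demes_list])
            d = demes_list[rng.choice(len(demes_list), p=weights / weights.sum())]
            members = [i for i in active if merged or deme_of[i] == d]
            a_idx, b_idx = rng.choice(len(members), size=2, replace=False)
            a, b = members[a_idx], members[b_idx]
            new = next_node
            next_node += 1
            parent[a] = parent[b] = new
            node_time[new] = t
            deme_of[new] = d
            active.remove(a)
            active.remove(b)
            active.append(new)
        else:
            mover = active[rng.integers(len(active))]
            others = [d for d in range(spec.demes) if d != deme_of[mover]]
            deme_of[mover] = others[rng.integers(len(others))]

    root = active[0]
    return parent[:next_node], node_time[:next_node], leaf_deme, root


def _branch_lengths(parent: np.ndarray, node_time: np.ndarray, root: int) -> np.ndarray:
    br = np.zeros(parent.shape[0])
    for v in range(parent.shape[0]):
        if v != root and parent[v] >= 0:
            br[v] = node_time[parent[v]] - node_time[v]
    return br


# ---------------------------------------------------------------------------
# mutation placement and sequence realisation
# ---------------------------------------------------------------------------

def _drop_mutations(spec, rng, parent, node_time, root):
    """Poisson(branch/2) mutations per branch; returns per-node mutation lists."""
    br = _branch_lengths(parent, node_time, root)
    counts = rng.poisson(br / 2.0)
    return counts


def simulate(spec: SimulationSpec, rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Simulate one dataset under ``spec``; deterministic under a fixed seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_total
    if n == 1:
        seq = "A" * spec.L
        aln = Alignment.from_dict({"s1": seq})
        meta = _default_metadata(["s1"], [0], spec)
        return SimulatedDataset(aln, meta, spec, seq)

    parent, node_time, leaf_deme, root = _genealogy(spec, rng)
    counts = _drop_mutations(spec, rng, parent, node_time, root)
    n_nodes = parent.shape[0]
    total_mut = int(counts.sum())

    seqs = np.zeros((n_nodes, spec.L), dtype=np.uint8)
    order = range(n_nodes - 1, -1, -1)  # root (highest id) first

    if spec.model == "infinite_sites":
        if total_mut > spec.L:
            raise SimulationError(
                f"{total_mut} mutations exceed {spec.L} sites under infinite sites"
            )
        sites = rng.permutation(spec.L)[:total_mut]
        derived = rng.integers(1, 4, size=total_mut)  # anything but ancestral A
        offsets = np.concatenate([[0], np.cumsum(counts)])
        for v in order:
            if v == root:
                continue
            p = parent[v]
            seqs[v] = seqs[p]
            lo, hi = offsets[v], offsets[v + 1]
            if hi > lo:
                seqs[v, sites[lo:hi]] = derived[lo:hi]
    else:
        p_ts = spec.tstv / (spec.tstv + 1.0)
        for v in order:
            if v == root:
                continue
            p = parent[v]
            seqs[v] = seqs[p]
            for _ in range(int(counts[v])):
                s = rng.integers(spec.L)
                base = seqs[v, s]
                if rng.random() < p_ts:
                    seqs[v, s] = _TRANSITION[base]
                else:
                    choices = [b for b in range(4) if b != base and b != _TRANSITION[base]]
                    seqs[v, s] = choices[rng.integers(2)]

    ids = [f"s{i + 1}" for i in range(n)]
    aln = Alignment.from_array(seqs[:n], ids)
    meta = _default_metadata(ids, leaf_deme, spec)
    root_seq = "".join("ACGT"[c] for c in seqs[root])
    return SimulatedDataset(aln, meta, spec, root_seq)


def _default_metadata(ids, leaf_deme, spec) -> pd.DataFrame:
    labels = [f"deme{d + 1}" for d in np.asarray(leaf_deme, dtype=int)]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "population": labels,
            "region": labels,
            "subregion": "",
            "lat": 0.0,
            "lon": 0.0,
            "depth_m": 0.0,
        }
    )


# ---------------------------------------------------------------------------
# fast summary path (infinite sites): statistics without sequence realisation
# ---------------------------------------------------------------------------

def simulate_summary(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[int, float, int]:
    """(S, Pi_bar, K_hap) of one infinite-sites replicate.

    Equivalent in distribution to running :func:`simulate` and computing the
    statistics on the alignment, but skips building sequences.  Each mutation
    on a branch subtending c of the n leaves contributes c(n-c)/C(n,2) to the
    mean pairwise difference; haplotype identity is the leaf's set of carried
    mutations.
    """
    if spec.model != "infinite_sites":
        raise SimulationError("summary path is defined for the infinite-sites model")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_total
    if n == 1:
        return 0, 0.0, 1
    parent, node_time, _, root = _genealogy(spec, rng)
    counts = _drop_mutations(spec, rng, parent, node_time, root)
    n_nodes = parent.shape[0]

    # leaves below each node (children always carry smaller ids than parents)
    below = np.zeros(n_nodes, dtype=np.int64)
    below[:n] = 1
    for v in range(n_nodes):
        if v != root and parent[v] >= 0:
            below[parent[v]] += below[v]

    S = int(counts.sum())
    c = below.astype(float)
    pairs = n * (n - 1) / 2.0
    pi_bar = float(np.sum(counts * c * (n - c)) / pairs)

    # haplotype classes: leaves sharing an identical carried-mutation set.
    # Walk down from the root accumulating the branch ids with mutations.
    key = np.zeros(n_nodes, dtype=object)
    key[root] = ()
    for v in range(n_nodes - 1, -1, -1):
        if v == root:
            continue
        key[v] = key[parent[v]] + ((v,) if counts[v] > 0 else ())
    # nodes with mutations are distinct branches; identical key <=> same set
    K = len({key[i] for i in range(n)})
    return S, pi_bar, K


def simulate_mismatch(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Mismatch histogram counts of one infinite-sites replicate.

    Pair distance = number of mutations on the genealogical path between the
    two leaves, computed from the leaf-by-branch incidence matrix; identical
    in distribution to histogramming the simulated alignment but much
    cheaper.  Raises :class:`SimulationError` if the mutation count exceeds
    the number of sites (same contract as :func:`simulate`).
    """
    if spec.model != "infinite_sites":
        raise SimulationError("fast mismatch path is defined for the infinite-sites model")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_total
    if n < 2:
        raise SimulationError("mismatch histogram needs n >= 2")
    parent, node_time, _, root = _genealogy(spec, rng)
    counts = _drop_mutations(spec, rng, parent, node_time, root)
    if counts.sum() > spec.L:
        raise SimulationError(
            f"{int(counts.sum())} mutations exceed {spec.L} sites under infinite sites"
        )
    n_nodes = parent.shape[0]
    below = np.zeros((n_nodes, n), dtype=bool)
    below[np.arange(n), np.arange(n)] = True
    for v in range(n_nodes):
        if v != root and parent[v] >= 0:
            below[parent[v]] |= below[v]

    mutated = np.flatnonzero(counts > 0)
    if mutated.size == 0:
        hist = np.zeros(1, dtype=np.int64)
        hist[0] = n * (n - 1) // 2
        return hist
    G = below[mutated].T.astype(np.float64)  # n x branches
    m = counts[mutated].astype(np.float64)
    r = G @ m
    cross = (G * m) @ G.T
    D = np.rint(r[:, None] + r[None, :] - 2.0 * cross).astype(np.int64)
    iu = np.triu_indices(n, 1)
    return np.bincount(D[iu])


# ---------------------------------------------------------------------------
# study-like fixture generator
# ---------------------------------------------------------------------------

#: Regional histories for the study-like fixture.  EA and AP: old, diverse
#: expansions; WS: recent, low-diversity expansion.  tau and theta0 follow
#: the regional sudden-expansion estimates the demographic analysis produces
#: on the real data; theta1 values were calibrated once so the pooled
#: haplotype count lands in the study-scale band.
STUDY_REGIONS = {
    "EA": dict(tau=3.4, theta0=0.005, theta1=20.0),
    "AP": dict(tau=4.7, theta0=0.002, theta1=15.0),
    "WS": dict(tau=0.95, theta0=0.01, theta1=3.0),
}

#: Region-private stem mutations (lineage sorting): fixed substitutions
#: carried by every sequence of the region, producing the strong
#: among-region differentiation real regions show.  Island founders inherit
#: the stem of their source region.
STUDY_STEMS = {"EA": 1, "AP": 2, "WS": 2}

_EA_SUBREGIONS = [("TA", 167), ("RS", 28), ("BR", 19), ("DS", 13)]
_GEO = {  # (lat, lon, depth) anchors; synthetic but regionally plausible
    "EA": (-66.5, 140.0, 600.0),
    "AP": (-64.8, -63.5, 400.0),
    "WS": (-74.0, -30.0, 350.0),
    "AI": (-56.0, -12.0, 225.0),
    "BI": (-54.4, 3.4, 250.0),
    "SSI": (-57.8, -26.5, 200.0),
    "DS": (-68.6, 77.9, 25.0),
    "TA": (-66.5, 140.0, 600.0),
    "RS": (-74.5, 169.0, 500.0),
    "BR": (-65.5, 112.0, 450.0),
}


def make_study_like_dataset(seed: int = 42) -> SimulatedDataset:
    """Four-region synthetic dataset emulating the study's sampling design.

    364 sequences of 554 bp across EA (227), AP (95), WS (29) and AI (13);
    the AI samples are founder subsamples drawn from the EA and WS genealogies
    (SSI from EA, BI from WS), mirroring recent colonisation from the
    continent.  Deterministic under ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(3)
    sims = {}
    for (region, params), child in zip(STUDY_REGIONS.items(), seeds):
        extra = 8 if region == "EA" else (5 if region == "WS" else 0)
        n = {"EA": 227, "AP": 95, "WS": 29}[region] + extra
        spec = SimulationSpec(n_per_deme=(n,), theta=None, L=554, **params)
        sims[region] = simulate(spec, np.random.default_rng(child))

    rng = np.random.default_rng(ss.spawn(1)[0])

    # apply the region-private stems at disjoint sites
    stem_total = sum(STUDY_STEMS.values())
    stem_sites = rng.permutation(554)[:stem_total]
    offset = 0
    for region, count in STUDY_STEMS.items():
        sites = stem_sites[offset:offset + count]
        offset += count
        arr = sims[region].alignment.to_array().copy()
        arr[:, sites] = rng.integers(1, 4, size=count)[None, :]
        sims[region].alignment = Alignment.from_array(
            arr, sims[region].alignment.ids
        )
    records: list[tuple[str, str]] = []
    meta_rows: list[dict] = []

    def add(sample_id, seq, region, subregion):
        pop = subregion if subregion else region
        lat0, lon0, depth0 = _GEO.get(subregion or region, _GEO[region])
        records.append((sample_id, seq))
        meta_rows.append(
            dict(
                sample_id=sample_id,
                population=pop,
                region=region,
                subregion=subregion,
                lat=round(lat0 + rng.normal(0, 0.3), 4),
                lon=round(lon0 + rng.normal(0, 0.5), 4),
                depth_m=round(max(10.0, depth0 * math.exp(rng.normal(0, 0.3))), 1),
            )
        )

    ea = sims["EA"].alignment
    i = 0
    for sub, size in _EA_SUBREGIONS:
        for _ in range(size):
            add(f"EA{i + 1:03d}", ea.records[i].seq, "EA", sub)
            i += 1
    for j in range(8):  # SSI founders from the EA haplotype pool
        add(f"AI{j + 1:03d}", ea.records[227 + j].seq, "AI", "SSI")

    ap = sims["AP"].alignment
    for j in range(95):
        add(f"AP{j + 1:03d}", ap.records[j].seq, "AP", "")

    ws = sims["WS"].alignment
    for j in range(29):
        add(f"WS{j + 1:03d}", ws.records[j].seq, "WS", "")
    for j in range(5):  # BI founders from the WS haplotype pool
        add(f"AI{j + 9:03d}", ws.records[29 + j].seq, "AI", "BI")

    aln = Alignment.from_dict(dict(records))
    meta = pd.DataFrame(meta_rows)
    spec = SimulationSpec(n_per_deme=(227, 95, 29, 13), theta=1.0, L=554, seed=seed)
    return SimulatedDataset(aln, meta, spec, sims["EA"].root_haplotype)
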