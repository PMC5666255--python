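import numpy as np
import pytest

from haplostat import Alignment, amova, coalsim, pairwise_phist
from haplostat.errors import GroupingError


def _aln(seqs):
    return Alignment.from_dict(seqs)


class TestAmovaTwoLevel:
    def test_fixed_difference_full_differentiation(self):
        aln = _aln({"a1": "AAAA", "a2": "AAAA", "b1": "AAAT", "b2": "AAAT"})
        res = amova(aln, ["p1", "p1", "p2", "p2"], n_perm=99, seed=1)
        assert res.phi["phi_ST"] == pytest.approx(1.0)
        assert res.percent_variation[-1] == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_toy_zero_phi(self):
        # Pop1={A,A}, Pop2={A,B}, d(A,B)=1: SSD_total=0.75, SSD_within=0.5,
        # equal mean squares at both levels -> phi_ST = 0
        aln = _aln({"a1": "AAAA", "a2": "AAAA", "b1": "AAAA", "b2": "AAAT"})
        res = amova(aln, ["p1", "p1", "p2", "p2"], n_perm=99, seed=1)
        assert sum(res.ssd) == pytest.approx(0.75)
        assert res.ssd[-1] == pytest.approx(0.5)
        assert res.phi["phi_ST"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_composition_nonsignificant(self):
        aln = _aln({"a1": "AAAA", "a2": "AAAT", "b1": "AAAA", "b2": "AAAT"})
        res = amova(aln, ["p1", "p1", "p2", "p2"], n_perm=199, seed=1)
        assert res.phi["phi_ST"] <= 0.0  # negative component reported raw
        assert res.p["phi_ST"] > 0.3

    def test_percent_variation_sums_to_100(self):
        aln = _aln({"a1": "AATA", "a2": "AAAA", "b1": "ATAT", "b2": "AAAT", "b3": "TAAT"})
        res = amova(aln, ["p1", "p1", "p2", "p2", "p2"], n_perm=49, seed=0)
        assert sum(res.percent_variation) == pytest.approx(100.0, abs=1e-6)
        assert sum(res.df) == 4  # n - 1

    def test_empty_population_rejected(self):
        aln = _aln({"a1": "AAAA", "a2": "AAAT"})
        with pytest.raises(GroupingError):
            amova(aln, ["p1", "p1"], n_perm=10)


class TestAmovaInvariances:
    def test_within_population_relabeling_leaves_phi_unchanged(self):
        aln = _aln(
            {"a1": "AATA", "a2": "AAAA", "a3": "AATT",
             "b1": "TTAA", "b2": "TTAT", "b3": "TTAA"}
        )
        pops = ["p1"] * 3 + ["p2"] * 3
        r1 = amova(aln, pops, n_perm=9, seed=5)
        # swap members within each population
        aln2 = Alignment([aln.records[i] for i in (2, 0, 1, 5, 4, 3)])
        r2 = amova(aln2, pops, n_perm=9, seed=5)
        assert r1.phi["phi_ST"] == pytest.approx(r2.phi["phi_ST"], abs=1e-12)

    def test_distance_scaling_leaves_phi_unchanged(self):
        # Phi is a variance ratio: multiplying all distances by a constant
        # cancels exactly.  (Duplicating individuals does NOT leave the
        # estimator invariant: the sums of squares double but the degrees of
        # freedom do not, so the method-of-moments components shift.)
        from haplostat.seq_io import DistanceMatrix, pairwise_differences

        aln = _aln({"a1": "AATA", "a2": "AAAA", "b1": "TTAA", "b2": "TTAT"})
        pops = ["p1", "p1", "p2", "p2"]
        dm = pairwise_differences(aln, mode="count")
        r1 = amova(dm, pops, n_perm=9, seed=1)
        scaled = DistanceMatrix(dm.ids, dm.d * 3.7)
        r2 = amova(scaled, pops, n_perm=9, seed=1)
        assert r2.phi["phi_ST"] == pytest.approx(r1.phi["phi_ST"], abs=1e-12)

    def test_duplicating_individuals_shifts_phi_only_slightly_at_scale(self):
        """Duplicating every individual changes the df-corrected estimator by
        O(1/n): tiny for study-scale samples."""
        rng = np.random.default_rng(4)
        spec_seqs = {}
        for p, base in (("a", "AATAACGT"), ("b", "TTAAACGA")):
            for i in range(20):
                s = list(base)
                if rng.random() < 0.5:
                    s[rng.integers(len(s))] = "ACGT"[rng.integers(4)]
                spec_seqs[f"{p}{i}"] = "".join(s)
        aln = _aln(spec_seqs)
        pops = ["p1"] * 20 + ["p2"] * 20
        r1 = amova(aln, pops, n_perm=9, seed=1)
        doubled = {}
        for k, v in spec_seqs.items():
            doubled[k] = v
            doubled[k + "x"] = v
        ids = list(doubled)
        aln2 = _aln(doubled)
        pops2 = ["p1" if i.startswith("a") else "p2" for i in ids]
        r2 = amova(aln2, pops2, n_perm=9, seed=1)
        assert abs(r2.phi["phi_ST"] - r1.phi["phi_ST"]) < 0.02

    def test_pairwise_equals_two_level_amova(self):
        aln = _aln(
            {"a1": "AATA", "a2": "AAAA", "a3": "AATT",
             "b1": "TTAA", "b2": "TTAT", "b3": "TTAA"}
        )
        pops = ["p1"] * 3 + ["p2"] * 3
        pw = pairwise_phist(aln, pops, n_perm=99, seed=2)
        res = amova(aln, pops, n_perm=99, seed=2)
        i, j = pw.ids.index("p1"), pw.ids.index("p2")
        assert pw.phist[i, j] == pytest.approx(res.phi["phi_ST"], abs=1e-12)


class TestPairwisePhist:
    def test_fixed_difference_pair(self):
        seqs = {f"a{i}": "AAAA" for i in range(15)}
        seqs.update({f"b{i}": "AAAT" for i in range(15)})
        aln = _aln(seqs)
        pw = pairwise_phist(aln, ["p1"] * 15 + ["p2"] * 15, n_perm=99, seed=3)
        assert pw.phist[0, 1] == pytest.approx(1.0)
        assert pw.p[0, 1] == pytest.approx(1 / 100)

    def test_small_fixed_difference_pair_counts_tied_permutations(self):
        # with 2+2 a third of permutations reproduce the observed split, so
        # the tie-inclusive convention cannot reach the minimal p
        aln = _aln({"a1": "AAAA", "a2": "AAAA", "b1": "AAAT", "b2": "AAAT"})
        pw = pairwise_phist(aln, ["p1", "p1", "p2", "p2"], n_perm=999, seed=3)
        assert pw.phist[0, 1] == pytest.approx(1.0)
        assert 0.25 < pw.p[0, 1] < 0.45

    def test_identical_pair_raw_negative_or_zero(self):
        aln = _aln({"a1": "AAAA", "a2": "AAAT", "b1": "AAAA", "b2": "AAAT"})
        pw = pairwise_phist(aln, ["p1", "p1", "p2", "p2"], n_perm=99, seed=3)
        assert pw.phist[0, 1] <= 0.0
        assert pw.p[0, 1] > 0.3

    def test_undersized_population_flagged_missing(self):
        aln = _aln({"a1": "AAAA", "a2": "AAAT", "b1": "TTTT"})
        pw = pairwise_phist(aln, ["p1", "p1", "p2"], n_perm=19, seed=0)
        assert np.isnan(pw.phist[0, 1])

    def test_sequential_bonferroni_monotone(self):
        aln = _aln(
            {"a1": "AAAA", "a2": "AAAA", "b1": "AAAT", "b2": "AAAT",
             "c1": "TTTT", "c2": "TTTT"}
        )
        pw = pairwise_phist(aln, ["p1", "p1", "p2", "p2", "p3", "p3"],
                            n_perm=99, seed=1)
        adj = pw.sequential_bonferroni()
        iu = np.triu_indices(3, 1)
        assert np.all(adj.to_numpy()[iu] >= pw.p[iu] - 1e-12)


class TestHierarchicalAmova:
    def test_three_level_components_and_permutations(self):
        aln = _aln(
            {
                "a1": "AAAA", "a2": "AAAA", "b1": "AAAT", "b2": "AAAT",
                "c1": "TTTA", "c2": "TTTA", "d1": "TTTT", "d2": "TTTT",
            }
        )
        pops = ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"]
        groups = ["g1", "g1", "g1", "g1", "g2", "g2", "g2", "g2"]
        res = amova(aln, pops, groups=groups, n_perm=99, seed=7)
        assert len(res.levels) == 3
        assert sum(res.df) == 7
        assert sum(res.percent_variation) == pytest.approx(100.0, abs=1e-6)
        # among-group divergence dominates: 3 fixed differences across groups
        assert res.phi["phi_CT"] > 0.5
        assert set(res.p) == {"phi_ST", "phi_SC", "phi_CT"}

    def test_population_spanning_groups_rejected(self):
        aln = _aln({"a1": "AAAA", "a2": "AAAT", "b1": "TTTT", "b2": "TTTA"})
        with pytest.raises(GroupingError):
            amova(aln, ["p1", "p1", "p1", "p2"], groups=["g1", "g1", "g2", "g2"],
                  n_perm=9)


class TestIslandModelStructure:
    def test_high_migration_phist_near_zero(self, rng):
        """Strong migration homogenises demes: mean pairwise Phi_ST < 0.02."""
        spec = coalsim.SimulationSpec(n_per_deme=(12, 12), theta=3.0, M=100.0)
        vals = []
        for _ in range(200):
            ds = coalsim.simulate(spec, rng)
            pops = list(ds.metadata["population"])
            pw = pairwise_phist(ds.alignment, pops, n_perm=1, seed=0)
            vals.append(pw.phist[0, 1])
        assert np.nanmean(vals) < 0.02
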