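import numpy as np
import pytest

from haplostat import Alignment, collapse_haplotypes, pairwise_differences, seq_io
from haplostat.errors import (
    AlignmentError,
    InputError,
    MetadataError,
    UndefinedDistanceError,
)


class TestReadAlignment:
    def test_parses_records_in_order_uppercased(self, write_fasta):
        path = write_fasta({"a": "acgu", "b": "ACGA"})
        aln = seq_io.read_alignment(path)
        assert (aln.n, aln.L) == (2, 4)
        assert aln.records[0].seq == "ACGT"  # uppercase, U -> T
        assert aln.ids == ["a", "b"]

    def test_unequal_lengths_raise(self, write_fasta):
        path = write_fasta({"a": "ACGT", "b": "ACGTA"})
        with pytest.raises(AlignmentError):
            seq_io.read_alignment(path)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(InputError):
            seq_io.read_alignment(p)

    def test_invalid_characters_name_the_record(self, write_fasta):
        path = write_fasta({"ok": "ACGT", "bad": "ACXT"})
        with pytest.raises(InputError, match="bad"):
            seq_io.read_alignment(path)

    def test_wrapped_fasta(self, tmp_path):
        p = tmp_path / "wrapped.fasta"
        p.write_text(">a\nACGT\nACGT\n>b\nACGTACGT\n")
        aln = seq_io.read_alignment(p)
        assert (aln.n, aln.L) == (2, 8)


class TestMetadata:
    def test_round_trip_and_vocabulary(self, tmp_path, toy4, toy4_meta):
        p = tmp_path / "meta.csv"
        toy4_meta.to_csv(p, index=False)
        meta = seq_io.read_metadata(p)
        seq_io.check_metadata(toy4, meta)
        assert list(meta["region"]) == ["EA", "EA", "WS", "WS"]

    def test_unknown_region_rejected(self, tmp_path, toy4_meta):
        bad = toy4_meta.assign(region=["EA", "EA", "XX", "WS"])
        p = tmp_path / "meta.csv"
        bad.to_csv(p, index=False)
        with pytest.raises(MetadataError, match="XX"):
            seq_io.read_metadata(p)

    def test_missing_sample_raises(self, toy4, toy4_meta):
        with pytest.raises(MetadataError):
            seq_io.check_metadata(toy4, toy4_meta.iloc[:3])


class TestCollapseHaplotypes:
    def test_identity_collapse(self):
        aln = Alignment.from_dict({"s1": "ACGT", "s2": "ACGT", "s3": "ACGA"})
        t = collapse_haplotypes(aln)
        assert t.K_hap == 2
        assert list(t.total_counts()) == [2, 1]
        assert [h for h, _ in t.haplotypes] == ["H1", "H2"]

    def test_wildcard_policy_merges_compatible(self):
        aln = Alignment.from_dict({"s1": "ACGT", "s2": "ACGN"})
        assert collapse_haplotypes(aln, policy="wildcard").K_hap == 1
        assert collapse_haplotypes(aln, policy="strict").K_hap == 2

    def test_toy4_counts(self, toy4):
        t = collapse_haplotypes(toy4)
        assert t.K_hap == 3
        assert list(t.total_counts()) == [2, 1, 1]

    def test_counts_conserve_n_per_grouping(self, toy4, toy4_meta):
        for grouping in ("population", "region"):
            t = collapse_haplotypes(toy4, toy4_meta, grouping=grouping)
            assert t.n == toy4.n
            # column sums equal group sample sizes
            sizes = toy4_meta.groupby(grouping, sort=False).size()
            assert dict(t.counts.sum()) == dict(sizes)

    def test_record_without_metadata_raises(self, toy4, toy4_meta):
        with pytest.raises(MetadataError):
            collapse_haplotypes(toy4, toy4_meta.iloc[:2], grouping="population")


class TestPairwiseDifferences:
    def test_toy4_hand_enumeration(self, toy4):
        dm = pairwise_differences(toy4, mode="count")
        expect = {(0, 1): 1, (0, 2): 2, (0, 3): 0, (1, 2): 1, (1, 3): 1, (2, 3): 2}
        for (i, j), d in expect.items():
            assert dm.d[i, j] == d
            assert dm.d[j, i] == d
        assert np.all(np.diag(dm.d) == 0)

    def test_identical_rows_zero_matrix(self):
        aln = Alignment.from_dict({f"s{i}": "ACGTACGT" for i in range(1, 5)})
        assert np.all(pairwise_differences(aln).d == 0)

    def test_p_distance_times_L_equals_count_gap_free(self, toy4):
        c = pairwise_differences(toy4, mode="count").d
        p = pairwise_differences(toy4, mode="p_distance").d
        assert np.allclose(p * toy4.L, c)

    def test_permuting_records_permutes_matrix(self, toy4):
        dm = pairwise_differences(toy4).d
        perm = [2, 0, 3, 1]
        aln2 = Alignment([toy4.records[i] for i in perm])
        dm2 = pairwise_differences(aln2).d
        assert np.array_equal(dm2, dm[np.ix_(perm, perm)])

    def test_pairwise_deletion_excludes_ambiguous_sites(self):
        aln = Alignment.from_dict({"a": "ACGTN", "b": "ACGAA"})
        dm = pairwise_differences(aln, mode="p_distance", deletion="pairwise")
        assert dm.d[0, 1] == pytest.approx(0.25)  # 1 of 4 comparable sites

    def test_no_comparable_sites_raises(self):
        aln = Alignment.from_dict({"a": "NN", "b": "AC", "c": "AC"})
        with pytest.raises(UndefinedDistanceError):
            pairwise_differences(aln)

    def test_csv_writers_round_trip(self, tmp_path, toy4, toy4_meta):
        import pandas as pd

        table = collapse_haplotypes(toy4, toy4_meta, grouping="population")
        hp = tmp_path / "haps.csv"
        table.to_csv(hp)
        df = pd.read_csv(hp, index_col=0)
        assert list(df.columns) == ["sequence", "p1", "p2"]
        assert df[["p1", "p2"]].to_numpy().sum() == toy4.n

        dm = pairwise_differences(toy4)
        dp = tmp_path / "dist.csv"
        dm.to_csv(dp)
        back = pd.read_csv(dp, index_col=0)
        assert list(back.columns) == toy4.ids
        assert np.array_equal(back.to_numpy(), dm.d)

    def test_jukes_cantor_flag(self):
        aln = Alignment.from_dict({"a": "A" * 99 + "C", "b": "A" * 100})
        d = pairwise_differences(aln, mode="p_distance", jukes_cantor=True).d[0, 1]
        assert d == pytest.approx(-0.75 * np.log(1 - 4 * 0.01 / 3))
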