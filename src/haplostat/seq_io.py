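"""Alignment and metadata I/O, haplotype collapsing, pairwise distances.

The in-memory containers are deliberately small: an :class:`Alignment` wraps an
ordered list of equal-length nucleotide sequences plus a numeric encoding used
by every downstream statistic, a :class:`HaplotypeTable` holds the distinct
sequences with per-group frequency counts, and a :class:`DistanceMatrix` holds
pairwise mutational differences (or p-distances).

Two policies recur throughout the package and are configured here:

* ``policy`` for haplotype collapsing — ``"wildcard"`` (default) treats ``N``
  and ``-`` as compatible with anything, so two sequences share a haplotype
  when they agree at every site that is unambiguous in both; ``"strict"``
  requires literal identity.
* ``deletion`` for site handling in distances — ``"pairwise"`` excludes
  ambiguous sites per pair, ``"complete"`` drops any column containing an
  ambiguous character dataset-wide.  Complete deletion is the default for the
  summary statistics (S, Pi, pi, mismatch histograms) so they all share one
  site set, DnaSP-style; pairwise deletion is the default for raw distance
  matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentError,
    DomainError,
    GroupingError,
    InputError,
    MetadataError,
    UndefinedDistanceError,
)

# Numeric encoding of nucleotide states.  Codes >= AMBIG_START are ambiguous.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_DECODE = "ACGTN-"
AMBIG_START = 4

REGION_VOCABULARY = ("EA", "AP", "WS", "AI")
SUBREGION_VOCABULARY = ("TA", "RS", "DS", "BR", "BI", "SSI", "")

METADATA_COLUMNS = ("sample_id", "population", "region", "subregion", "lat", "lon", "depth_m")

DeletionPolicy = Literal["pairwise", "complete"]
CollapsePolicy = Literal["wildcard", "strict"]


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with its sample identifier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record with empty id")
        if not self.seq:
            raise InputError(f"sequence record {self.id!r} has empty sequence")


class Alignment:
    """Rectangular nucleotide alignment; the raw input all statistics consume."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise InputError("alignment with zero records")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sample ids: {dup}")
        self.records: list[SequenceRecord] = records
        self.L: int = lengths.pop()
        self._array: np.ndarray | None = None

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "Alignment":
        return cls([SequenceRecord(k, _clean_seq(k, v)) for k, v in seqs.items()])

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def to_array(self) -> np.ndarray:
        """(n, L) uint8 matrix using the package's nucleotide codes."""
        if self._array is None:
            table = np.full(128, 255, dtype=np.uint8)
            for ch, code in _CODE.items():
                table[ord(ch)] = code
            flat = np.frombuffer(
                "".join(r.seq for r in self.records).encode("ascii"), dtype=np.uint8
            )
            self._array = table[flat].reshape(self.n, self.L)
        return self._array

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        index = {r.id: r for r in self.records}
        missing = [i for i in wanted if i not in index]
        if missing:
            raise MetadataError(f"ids not in alignment: {missing}")
        return Alignment([index[i] for i in wanted])

    @classmethod
    def from_array(cls, arr: np.ndarray, ids: Sequence[str]) -> "Alignment":
        seqs = ["".join(_DECODE[c] for c in row) for row in arr]
        return cls([SequenceRecord(i, s) for i, s in zip(ids, seqs)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment(n={self.n}, L={self.L})"


@dataclass
class HaplotypeTable:
    """Distinct sequences with a haplotype x group frequency-count matrix."""

    haplotypes: list[tuple[str, str]]
    counts: pd.DataFrame  # index: haplotype_id, columns: group labels
    policy: CollapsePolicy = "wildcard"
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def K_hap(self) -> int:
        return len(self.haplotypes)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_csv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "sequence", [s for _, s in self.haplotypes])
        df.index.name = "haplotype_id"
        df.to_csv(path)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances (integer counts or proportions)."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise AlignmentError("distance matrix shape does not match ids")
        self.d = d

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path)


def _clean_seq(rec_id: str, raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - set(_CODE)
    if bad:
        raise InputError(f"record {rec_id!r} contains invalid characters: {sorted(bad)}")
    return seq


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment (wrapped or single-line).

    Sequences are uppercased and U is mapped to T.  Unequal lengths raise
    :class:`AlignmentError`; an empty file or invalid characters raise
    :class:`InputError` naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, _clean_seq(rec.id, str(rec.seq))))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return Alignment(records)


def read_metadata(
    path: str | Path,
    region_vocabulary: Sequence[str] = REGION_VOCABULARY,
    subregion_vocabulary: Sequence[str] | None = SUBREGION_VOCABULARY,
) -> pd.DataFrame:
    """Read the sample metadata CSV and validate the controlled vocabularies.

    Pass a custom ``region_vocabulary`` for non-Antarctic datasets;
    ``subregion_vocabulary=None`` disables subregion checking.
    """
    meta = pd.read_csv(path, dtype={"sample_id": str, "population": str,
                                    "region": str, "subregion": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise MetadataError(f"metadata missing columns: {missing_cols}")
    meta = meta.copy()
    meta["subregion"] = meta["subregion"].fillna("")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise MetadataError(f"duplicate sample ids in metadata: {dup}")
    bad_region = sorted(set(meta["region"]) - set(region_vocabulary))
    if bad_region:
        raise MetadataError(
            f"regions {bad_region} not in controlled vocabulary {tuple(region_vocabulary)}"
        )
    if subregion_vocabulary is not None:
        bad_sub = sorted(set(meta["subregion"]) - set(subregion_vocabulary))
        if bad_sub:
            raise MetadataError(
                f"subregions {bad_sub} not in controlled vocabulary "
                f"{tuple(subregion_vocabulary)}"
            )
    return meta


def check_metadata(aln: Alignment, meta: pd.DataFrame) -> None:
    """Every alignment record must match exactly one metadata row."""
    meta_ids = set(meta["sample_id"])
    missing = [i for i in aln.ids if i not in meta_ids]
    if missing:
        raise MetadataError(f"alignment records without metadata: {missing[:10]}")


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    """Wildcard compatibility: equal at every site unambiguous in both."""
    clear = (a < AMBIG_START) & (b < AMBIG_START)
    return bool(np.all(a[clear] == b[clear]))


def collapse_haplotypes(
    aln: Alignment,
    meta: pd.DataFrame | None = None,
    grouping: str = "population",
    policy: CollapsePolicy = "wildcard",
) -> HaplotypeTable:
    """Collapse identical (or wildcard-compatible) sequences into haplotypes.

    Haplotype ids are ``H`` + 1-based index of first appearance.  Counts are
    aggregated per ``grouping`` column of the metadata (``population``,
    ``region`` or ``subregion``); with ``meta=None`` a single pooled group
    ``"all"`` is used.  Under the wildcard policy a sequence joins the first
    existing haplotype class whose *representative* (first member) it is
    compatible with; compatibility is not transitive, so classes are anchored
    on representatives to keep the partition deterministic.
    """
    if meta is not None:
        check_metadata(aln, meta)
        if grouping not in ("population", "region", "subregion"):
            raise GroupingError(f"unknown grouping {grouping!r}")
        group_of = dict(zip(meta["sample_id"], meta[grouping]))
        groups = list(dict.fromkeys(meta[grouping]))  # stable order
    else:
        group_of = {i: "all" for i in aln.ids}
        groups = ["all"]

    arr = aln.to_array()
    reps: list[np.ndarray] = []
    hap_ids: list[str] = []
    hap_seqs: list[str] = []
    members: dict[str, list[str]] = {}
    assignment: list[int] = []

    if policy == "strict":
        seen: dict[bytes, int] = {}
        for i, rec in enumerate(aln.records):
            key = arr[i].tobytes()
            if key not in seen:
                seen[key] = len(hap_ids)
                hap_ids.append(f"H{len(hap_ids) + 1}")
                hap_seqs.append(rec.seq)
            assignment.append(seen[key])
    elif policy == "wildcard":
        for i, rec in enumerate(aln.records):
            for h, rep in enumerate(reps):
                if _compatible(arr[i], rep):
                    assignment.append(h)
                    break
            else:
                assignment.append(len(reps))
                reps.append(arr[i])
                hap_ids.append(f"H{len(reps)}")
                hap_seqs.append(rec.seq)
    else:
        raise InputError(f"unknown collapse policy {policy!r}")

    counts = pd.DataFrame(0, index=hap_ids, columns=groups, dtype=int)
    for rec, h in zip(aln.records, assignment):
        g = group_of[rec.id]
        counts.loc[hap_ids[h], g] += 1
        members.setdefault(hap_ids[h], []).append(rec.id)

    return HaplotypeTable(
        haplotypes=list(zip(hap_ids, hap_seqs)),
        counts=counts,
        policy=policy,
        members=members,
    )


def complete_deletion_mask(aln: Alignment) -> np.ndarray:
    """Boolean mask of columns free of N/gap in every sequence."""
    return np.all(aln.to_array() < AMBIG_START, axis=0)


def pairwise_differences(
    aln: Alignment,
    mode: Literal["count", "p_distance"] = "count",
    deletion: DeletionPolicy = "pairwise",
    jukes_cantor: bool = False,
) -> DistanceMatrix:
    """Pairwise mismatch counts or p-distances over pairwise-complete sites.

    ``jukes_cantor=True`` applies the multiple-hit correction
    ``d = -(3/4) ln(1 - 4p/3)`` to p-distances.  The study-style default is the
    plain (uncorrected) p-distance.
    """
    if aln.n < 2:
        raise AlignmentError("need at least 2 sequences for pairwise distances")
    if mode not in ("count", "p_distance"):
        raise InputError(f"unknown distance mode {mode!r}")
    arr = aln.to_array()
    if deletion == "complete":
        arr = arr[:, complete_deletion_mask(aln)]
    elif deletion != "pairwise":
        raise InputError(f"unknown deletion policy {deletion!r}")

    n = aln.n
    clear = arr < AMBIG_START
    diff = np.zeros((n, n))
    comp = np.zeros((n, n))
    for i in range(n):
        both = clear[i] & clear  # (n, L)
        comp[i] = both.sum(axis=1)
        diff[i] = ((arr[i] != arr) & both).sum(axis=1)
    np.fill_diagonal(diff, 0.0)

    if mode == "count":
        off = ~np.eye(n, dtype=bool)
        if np.any(comp[off] == 0):
            i, j = np.argwhere((comp == 0) & off)[0]
            raise UndefinedDistanceError(
                f"no pairwise-complete sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        return DistanceMatrix(aln.ids, diff)

    off = ~np.eye(n, dtype=bool)
    if np.any(comp[off] == 0):
        i, j = np.argwhere((comp == 0) & off)[0]
        raise UndefinedDistanceError(
            f"no pairwise-complete sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(comp > 0, diff / np.maximum(comp, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    if jukes_cantor:
        if np.any(p >= 0.75):
            raise DomainError("p-distance >= 0.75: Jukes-Cantor correction undefined")
        p = -0.75 * np.log1p(-4.0 * p / 3.0)
        np.fill_diagonal(p, 0.0)
    return DistanceMatrix(aln.ids, p)


def mean_pairwise_sites(aln: Alignment, deletion: DeletionPolicy = "complete") -> float:
    """Effective sequence length under the deletion policy.

    Complete deletion: number of retained columns.  Pairwise deletion: per-pair
    complete-site count averaged over pairs (keeps pi = Pi/L exact for gap-free
    data).
    """
    arr = aln.to_array()
    if deletion == "complete":
        return float(complete_deletion_mask(aln).sum())
    clear = arr < AMBIG_START
    n = aln.n
    total = 0.0
    for i in range(n - 1):
        total += (clear[i] & clear[i + 1:]).sum(axis=1).sum()
    return total / (n * (n - 1) / 2) if n > 1 else float(clear[0].sum())
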