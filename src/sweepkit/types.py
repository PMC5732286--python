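"""Core data containers shared by all pipeline stages.

Conventions
-----------
* Genotypes are alternate-allele dosages in ``{0, 1, 2}`` with ``-1`` for
  missing (`MISSING`).
* Haplotypes are phased alleles in ``{0, 1}``; chromosome copies of diploid
  sample *j* occupy rows ``2j`` and ``2j + 1``.
* Genomic coordinates are 1-based inclusive base pairs throughout; BED
  output converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "MarkerMap",
    "SampleTable",
    "GenotypeMatrix",
    "HaplotypeSet",
    "QCReport",
    "ScanTrack",
    "WindowTrack",
    "CandidateRegion",
    "RegionOverlap",
    "chrom_sort_key",
]


def chrom_sort_key(chrom: str):
    """Sort key placing numeric chromosome labels first, in numeric order.

    Non-numeric labels (``X``, ``MT`` ...) sort after all numeric ones,
    lexicographically.
    """
    s = str(chrom)
    if re.fullmatch(r"\d+", s):
        return (0, int(s), "")
    return (1, 0, s)


@dataclass
class MarkerMap:
    """Per-SNP identifiers and genomic coordinates, sorted by (chrom, pos).

    ``allele_a`` is the dosage-0 allele (major/REF), ``allele_b`` the
    dosage-2 allele (minor/ALT). Allele labels may be empty strings when
    unknown (e.g. purely synthetic maps).
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele_a: np.ndarray = field(default=None)  # type: ignore[assignment]
    allele_b: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n = len(self.snp_id)
        if self.allele_a is None:
            self.allele_a = np.full(n, "A", dtype=object)
        if self.allele_b is None:
            self.allele_b = np.full(n, "B", dtype=object)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.snp_id)
        if not (len(self.chrom) == len(self.pos) == n):
            raise ValueError("MarkerMap field lengths disagree")
        if n and self.pos.min() <= 0:
            raise ValueError("bp positions must be positive")
        if len(set(self.snp_id)) != n:
            dupes = pd.Series(self.snp_id).value_counts()
            raise ValueError(
                f"duplicate snp_id: {list(dupes[dupes > 1].index[:5])}"
            )
        pairs = list(zip(self.chrom, self.pos))
        if len(set(pairs)) != n:
            raise ValueError("two SNPs share the same (chrom, pos)")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def sort_order(self) -> np.ndarray:
        """Indices that sort markers by (chrom, pos)."""
        keys = [(chrom_sort_key(c), p) for c, p in zip(self.chrom, self.pos)]
        return np.array(sorted(range(len(keys)), key=keys.__getitem__),
                        dtype=np.intp)

    def is_sorted(self) -> bool:
        order = self.sort_order()
        return bool(np.all(order == np.arange(len(order))))

    def take(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.snp_id[idx], self.chrom[idx], self.pos[idx],
                         self.allele_a[idx], self.allele_b[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id, "chrom": self.chrom, "pos": self.pos,
            "allele_a": self.allele_a, "allele_b": self.allele_b,
        })

    def chrom_slices(self) -> list[tuple[str, np.ndarray]]:
        """Contiguous index blocks per chromosome, in map order."""
        out: list[tuple[str, np.ndarray]] = []
        if not len(self):
            return out
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or self.chrom[i] != self.chrom[start]:
                out.append((self.chrom[start], np.arange(start, i)))
                start = i
        return out


@dataclass
class SampleTable:
    """Sample → population → group assignment."""

    sample_id: np.ndarray
    population: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.population = np.asarray(self.population, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        if not (len(self.sample_id) == len(self.population) == len(self.group)):
            raise ValueError("SampleTable field lengths disagree")
        if len(set(self.sample_id)) != len(self.sample_id):
            raise ValueError("duplicate sample_id")
        # every population must map to exactly one group
        df = pd.DataFrame({"population": self.population, "group": self.group})
        bad = df.groupby("population")["group"].nunique()
        if (bad > 1).any():
            raise ValueError(
                f"population mapped to multiple groups: {list(bad[bad > 1].index)}"
            )

    def __len__(self) -> int:
        return len(self.sample_id)

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)

    def take(self, idx: np.ndarray) -> "SampleTable":
        return SampleTable(self.sample_id[idx], self.population[idx],
                           self.group[idx])

    def indices_of_population(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.population == pop)

    def indices_of_group(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.group == group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_id,
                             "population": self.population,
                             "group": self.group})


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs alternate-allele dosages, ``MISSING`` for no-calls."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        ok = np.isin(self.values, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.values[~ok])
            raise ValueError(f"genotype values outside {{0,1,2,{MISSING}}}: {bad}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[:, idx])

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[idx, :])


@dataclass
class HaplotypeSet:
    """(2 × individuals) × SNPs phased alleles in {0, 1}; no missing allowed."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("haplotype values must be 2-D")
        if self.values.shape[0] % 2:
            raise ValueError("haplotype row count must be even")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("haplotype values must be 0/1 with no missing")

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse phased copies into unphased dosages."""
        return GenotypeMatrix(self.values[0::2] + self.values[1::2])

    def take_snps(self, idx: np.ndarray) -> "HaplotypeSet":
        return HaplotypeSet(self.values[:, idx])

    def take_samples(self, idx: np.ndarray) -> "HaplotypeSet":
        rows = np.ravel(np.column_stack((2 * idx, 2 * idx + 1)))
        return HaplotypeSet(self.values[rows, :])


@dataclass
class QCReport:
    """Bookkeeping for one filtering pass over one axis (SNPs or samples)."""

    axis: str                      # "snp" | "sample"
    n_input: int
    n_retained: int
    thresholds: dict
    failures: dict                 # filter name -> count failing it (non-exclusive)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def validate(self) -> None:
        if self.n_removed + self.n_retained != self.n_input:
            raise ValueError("QCReport counts inconsistent")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": "input", "count": self.n_input},
                {"metric": "retained", "count": self.n_retained},
                {"metric": "removed", "count": self.n_removed}]
        rows += [{"metric": f"fail_{k}", "count": v}
                 for k, v in self.failures.items()]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ScanTrack:
    """Per-SNP statistic aligned to a MarkerMap; NaN marks undefined."""

    name: str
    values: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(len(self.values), dtype=bool)
        self.flags = np.asarray(self.flags, dtype=bool)
        if len(self.flags) != len(self.values):
            raise ValueError("flags and values length mismatch")
        if np.any(self.flags & np.isnan(self.values)):
            raise ValueError("flag set on undefined value")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self, mm: MarkerMap) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": mm.snp_id, "chrom": mm.chrom, "pos": mm.pos,
            "value": self.values, "flag": self.flags.astype(int),
        })

    def to_tsv(self, path, mm: MarkerMap) -> None:
        self.to_frame(mm).to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class WindowTrack:
    """Non-overlapping fixed-SNP-count window means of a ScanTrack."""

    name: str
    chrom: np.ndarray
    first_idx: np.ndarray
    last_idx: np.ndarray
    first_bp: np.ndarray
    last_bp: np.ndarray
    mean: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.first_idx = np.asarray(self.first_idx, dtype=np.intp)
        self.last_idx = np.asarray(self.last_idx, dtype=np.intp)
        self.first_bp = np.asarray(self.first_bp, dtype=np.int64)
        self.last_bp = np.asarray(self.last_bp, dtype=np.int64)
        self.mean = np.asarray(self.mean, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(len(self.mean), dtype=bool)
        self.flags = np.asarray(self.flags, dtype=bool)

    def __len__(self) -> int:
        return len(self.mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "first_idx": self.first_idx,
            "last_idx": self.last_idx, "first_bp": self.first_bp,
            "last_bp": self.last_bp, "mean": self.mean,
            "flag": self.flags.astype(int),
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass(frozen=True)
class CandidateRegion:
    """A called interval (1-based inclusive) with provenance."""

    chrom: str
    start: int
    end: int
    method: str
    n_snps: int = 0
    snp_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "CandidateRegion") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)


@dataclass(frozen=True)
class RegionOverlap:
    """Maximal interval shared by one region from each named method."""

    methods: tuple
    chrom: str
    start: int
    end: int
    members: tuple  # the CandidateRegion from each method, same order

    def __post_init__(self) -> None:
        for r in self.members:
            if not (r.chrom == self.chrom and r.start <= self.start
                    and self.end <= r.end):
                raise ValueError("overlap interval not contained in member region")


def regions_to_frame(regions) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "method": r.method, "n_snps": r.n_snps,
        "snp_ids": ",".join(map(str, r.snp_ids)),
    } for r in regions])


def regions_to_bed(regions, path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.method}\t{r.n_snps}\n")
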