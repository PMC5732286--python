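"""Synthetic phased SNP datasets with controlled differentiation and
injected selective sweeps, plus a machine-readable truth table.

The neutral background is linkage-free: group allele frequencies follow
the Balding-Nichols model around a shared ancestral frequency, and
chromosome copies are drawn independently per SNP. Sweeps are injected
afterwards by copying a template haplotype over geometrically distributed
spans around a core SNP, which creates the long shared haplotypes the
EHH-based scans must detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .types import GenotypeMatrix, HaplotypeSet, MarkerMap, SampleTable

__all__ = [
    "SweepSpec", "SweepTruth", "SimulationConfig", "SimulatedDataset",
    "bn_frequencies", "random_marker_map", "sample_haplotypes",
    "inject_sweep", "simulate_dataset", "write_dataset", "default_scenario",
]


@dataclass(frozen=True)
class SweepSpec:
    """One sweep to inject: which group, where, and how strong/long."""

    group: str
    core_idx: int
    f: float                      # carrier fraction of the group's copies
    mean_half_len: float          # mean one-sided span, in SNPs
    core_base_freq: float = 0.1   # pre-sweep frequency of the swept allele

    def __post_init__(self) -> None:
        if not (0.0 < self.f <= 1.0):
            raise ValueError(f"carrier fraction must be in (0,1], got {self.f}")
        if self.mean_half_len < 1:
            raise ValueError("mean_half_len must be >= 1")


@dataclass(frozen=True)
class SweepTruth:
    """Ground truth recorded for one injected sweep."""

    chrom: str
    core_idx: int
    core_bp: int
    group: str
    f: float
    mean_half_len: float
    n_carriers: int


@dataclass
class SimulationConfig:
    n_snps: int = 2000
    n_chroms: int = 2
    pop_sizes: dict = field(default_factory=dict)   # pop -> n diploids
    pop_groups: dict = field(default_factory=dict)  # pop -> group
    F: float = 0.05
    sweeps: list = field(default_factory=list)      # list[SweepSpec]
    seed: int = 0
    spacing: tuple = (500, 5000)                    # bp step bounds

    def __post_init__(self) -> None:
        if not (0.0 <= self.F <= 0.5):
            raise ValueError(f"F must be in [0, 0.5], got {self.F}")
        for pop, n in self.pop_sizes.items():
            if n < 2:
                raise ValueError(f"population {pop!r} must have >= 2 diploids")
            if pop not in self.pop_groups:
                raise ValueError(f"population {pop!r} has no group")
        for sw in self.sweeps:
            if not (0 <= sw.core_idx < self.n_snps):
                raise ValueError(f"sweep core {sw.core_idx} outside marker range")
            if sw.group not in self.pop_groups.values():
                raise ValueError(f"sweep group {sw.group!r} unknown")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.pop_groups.values()))

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Parse a flat key=value config.

        ``populations`` is a comma list of ``pop:group:n`` triples;
        ``sweeps`` a comma list of ``group:core_idx:f:mean_half_len``.
        """
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        pop_sizes, pop_groups = {}, {}
        for item in kv.get("populations", "").split(","):
            if not item:
                continue
            pop, group, n = item.split(":")
            pop_sizes[pop] = int(n)
            pop_groups[pop] = group
        sweeps = []
        for item in kv.get("sweeps", "").split(","):
            if not item:
                continue
            group, core, f, mhl = item.split(":")
            sweeps.append(SweepSpec(group, int(core), float(f), float(mhl)))
        return cls(n_snps=int(kv.get("n_snps", 2000)),
                   n_chroms=int(kv.get("n_chroms", 2)),
                   pop_sizes=pop_sizes, pop_groups=pop_groups,
                   F=float(kv.get("F", 0.05)), sweeps=sweeps,
                   seed=int(kv.get("seed", 0)))


def bn_frequencies(n_snps: int, groups, F: float, seed: int) -> pd.DataFrame:
    """Balding-Nichols per-group allele frequencies.

    Ancestral frequency ``p ~ Uniform(0.05, 0.95)`` per SNP; each group
    draws independently from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``; ``F = 0``
    gives every group the ancestral frequency exactly. The ancestral
    frequencies are attached as ``df.attrs['ancestral']``.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_snps)
    groups = list(groups)
    if F == 0:
        table = np.tile(p, (len(groups), 1))
    else:
        scale = (1.0 - F) / F
        table = np.vstack([rng.beta(p * scale, (1.0 - p) * scale)
                           for _ in groups])
    df = pd.DataFrame(table, index=groups)
    df.attrs["ancestral"] = p
    return df


def random_marker_map(n_snps: int, n_chroms: int, seed: int,
                      spacing: tuple = (500, 5000)) -> MarkerMap:
    """SNP50-like marker map: chromosomes of near-equal SNP counts with
    cumulative Uniform(spacing) bp steps."""
    rng = np.random.default_rng(seed)
    per = np.full(n_chroms, n_snps // n_chroms)
    per[:n_snps % n_chroms] += 1
    chrom, pos = [], []
    for c in range(n_chroms):
        steps = rng.integers(spacing[0], spacing[1] + 1, size=per[c])
        chrom += [str(c + 1)] * per[c]
        pos.append(np.cumsum(steps))
    snp_id = np.array([f"snp{i:06d}" for i in range(n_snps)], dtype=object)
    return MarkerMap(snp_id, np.array(chrom, dtype=object),
                     np.concatenate(pos) if pos else np.array([], dtype=np.int64),
                     np.full(n_snps, "A", dtype=object),
                     np.full(n_snps, "G", dtype=object))


def sample_haplotypes(freqs: pd.DataFrame, pop_sizes: dict, pop_groups: dict,
                      seed: int) -> tuple[HaplotypeSet, SampleTable]:
    """Draw linkage-free haplotypes: each chromosome copy's allele at each
    SNP is an independent Bernoulli draw at the group frequency. Diploids
    pair consecutive copies, so genotypes are Hardy-Weinberg by
    construction."""
    rng = np.random.default_rng(seed)
    blocks, sample_id, population, group = [], [], [], []
    for pop, n in pop_sizes.items():
        g = pop_groups[pop]
        f = freqs.loc[g].to_numpy()
        blocks.append((rng.random((2 * n, len(f))) < f).astype(np.int8))
        sample_id += [f"{pop}_{i:03d}" for i in range(n)]
        population += [pop] * n
        group += [g] * n
    H = HaplotypeSet(np.vstack(blocks))
    st = SampleTable(np.array(sample_id, dtype=object),
                     np.array(population, dtype=object),
                     np.array(group, dtype=object))
    return H, st


def inject_sweep(H: HaplotypeSet, st: SampleTable, mm: MarkerMap,
                 spec: SweepSpec, seed: int) -> tuple[HaplotypeSet, SweepTruth]:
    """Overwrite a fraction of one group's chromosome copies with a shared
    template around the core SNP.

    The template is a randomly chosen copy of the swept group forced to
    allele 1 at the core; each carrier copy is overwritten over
    ``[core - L, core + R]`` with ``L, R ~ Geometric(1 / mean_half_len)``
    drawn independently per copy, clipped to the core's chromosome.
    """
    rng = np.random.default_rng(seed)
    gsamples = st.indices_of_group(spec.group)
    rows = np.ravel(np.column_stack((2 * gsamples, 2 * gsamples + 1)))
    n_carriers = int(round(spec.f * len(rows)))
    if n_carriers < 2:
        raise ValueError("sweep would have <2 carrier copies (EHH undefined)")
    V = H.values.copy()
    template = V[rng.choice(rows)].copy()
    template[spec.core_idx] = 1

    lo = hi = spec.core_idx
    for chrom, idx in mm.chrom_slices():
        if idx[0] <= spec.core_idx <= idx[-1]:
            lo, hi, core_chrom = int(idx[0]), int(idx[-1]), chrom
            break
    else:
        raise ValueError("sweep core not on any chromosome")

    carriers = rng.choice(rows, size=n_carriers, replace=False)
    p_geom = 1.0 / spec.mean_half_len
    for row in carriers:
        L = rng.geometric(p_geom)
        R = rng.geometric(p_geom)
        a = max(lo, spec.core_idx - L)
        b = min(hi, spec.core_idx + R)
        V[row, a:b + 1] = template[a:b + 1]
    truth = SweepTruth(core_chrom, spec.core_idx, int(mm.pos[spec.core_idx]),
                       spec.group, spec.f, spec.mean_half_len, n_carriers)
    return HaplotypeSet(V), truth


@dataclass
class SimulatedDataset:
    H: HaplotypeSet
    G: GenotypeMatrix
    mm: MarkerMap
    st: SampleTable
    truths: list           # list[SweepTruth]
    config: SimulationConfig


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: frequencies -> map -> haplotypes -> sweeps.

    For each sweep, the ancestral and group frequencies at the core SNP
    are pinned to ``core_base_freq`` before sampling, so the swept allele
    rises from a low pre-sweep frequency (keeping the post-sweep derived
    frequency inside typical scan bounds).
    """
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(2 ** 31, size=3 + len(config.sweeps))
    freqs = bn_frequencies(config.n_snps, config.groups, config.F,
                           int(seeds[0]))
    for sw in config.sweeps:
        freqs.loc[:, sw.core_idx] = sw.core_base_freq
    mm = random_marker_map(config.n_snps, config.n_chroms, int(seeds[1]),
                           config.spacing)
    H, st = sample_haplotypes(freqs, config.pop_sizes, config.pop_groups,
                              int(seeds[2]))
    truths = []
    for k, sw in enumerate(config.sweeps):
        H, truth = inject_sweep(H, st, mm, sw, int(seeds[3 + k]))
        truths.append(truth)
    return SimulatedDataset(H, H.to_genotypes(), mm, st, truths, config)


def write_dataset(ds: SimulatedDataset, out_dir,
                  formats: tuple = ("vcf", "plink", "samples", "truth"),
                  ) -> dict:
    """Write the dataset as phased VCF, PED/MAP, sample TSV and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if "vcf" in formats:
        paths["vcf"] = out / "haplotypes.vcf"
        gio.write_phased_vcf(ds.H, ds.mm, ds.st, paths["vcf"])
    if "plink" in formats:
        paths["ped"] = out / "genotypes.ped"
        paths["map"] = out / "genotypes.map"
        gio.write_plink_textset(ds.G, ds.mm, ds.st, paths["ped"], paths["map"])
    if "samples" in formats:
        paths["samples"] = out / "samples.tsv"
        gio.write_sample_table(ds.st, paths["samples"])
    if "truth" in formats:
        paths["truth"] = out / "sweep_truth.tsv"
        pd.DataFrame([t.__dict__ for t in ds.truths]).to_csv(
            paths["truth"], sep="\t", index=False)
    return paths


def default_scenario(seed: int = 1, n_snps: int = 2000,
                     n_per_pop: int = 100, f: float = 0.8,
                     mean_half_len: float = 15.0, F: float = 0.05,
                     ) -> SimulationConfig:
    """Two groups of one population each, one sweep in group A on the
    first chromosome (core at the middle of chromosome 1).

    The default half-length keeps the sweep narrow enough that the core
    SNP itself, not only its neighbours, tops the genome-wide scans.
    """
    core = n_snps // 4  # middle of chromosome 1 when n_chroms=2
    return SimulationConfig(
        n_snps=n_snps, n_chroms=2,
        pop_sizes={"popA": n_per_pop, "popB": n_per_pop},
        pop_groups={"popA": "groupA", "popB": "groupB"},
        F=F, sweeps=[SweepSpec("groupA", core, f, mean_half_len)],
        seed=seed)
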