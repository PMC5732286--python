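"""Reading, writing, quality control and thinning of genotype data.

Supported external formats: PLINK PED/MAP text (whitespace-delimited, "0"
missing allele), VCF v4.x with phased GT fields, and a 3-column TSV sample
table (sample_id, population, group).
"""

from __future__ import annotations

import os
from collections import Counter

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (MISSING, GenotypeMatrix, HaplotypeSet, MarkerMap,
                    QCReport, SampleTable)

__all__ = [
    "read_plink_textset", "write_plink_textset",
    "read_phased_vcf", "write_phased_vcf",
    "read_sample_table", "write_sample_table",
    "snp_qc_filter", "sample_qc_filter", "thin_every_kth",
]


# ---------------------------------------------------------------------------
# PLINK PED/MAP text
# ---------------------------------------------------------------------------

def _read_map(map_path) -> pd.DataFrame:
    df = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str,
                     comment="#")
    if df.shape[1] != 4:
        raise ValueError(f"MAP file must have 4 columns, got {df.shape[1]}")
    df.columns = ["chrom", "snp_id", "cm", "pos"]
    try:
        df["pos"] = df["pos"].astype(np.int64)
    except ValueError as exc:
        raise ValueError(f"non-integer bp position in MAP file: {exc}") from exc
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_id in MAP file: {dup[:5]}")
    return df


def read_plink_textset(ped_path, map_path, sample_table: SampleTable | None = None,
                       ) -> tuple[GenotypeMatrix, MarkerMap, SampleTable]:
    """Read a PED/MAP pair into dosages of the file-wide minor allele.

    ``0`` alleles ("0 0" genotypes) become missing. Markers are re-sorted
    by (chrom, pos) and genotype columns permuted accordingly. If
    ``sample_table`` is given it supplies population/group labels (matched
    by sample id); otherwise the PED family id is used as population and
    group.
    """
    mp = _read_map(map_path)
    n_snps = len(mp)

    sample_ids: list[str] = []
    fids: list[str] = []
    rows: list[np.ndarray] = []
    # allele counts per SNP, to orient dosage toward the minor allele
    counters: list[Counter] = [Counter() for _ in range(n_snps)]
    allele_pairs: list[list[tuple[str, str]]] = []

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"PED line {lineno}: expected {6 + 2 * n_snps} fields "
                    f"(6 + 2x{n_snps} SNPs), got {len(fields)}")
            fids.append(fields[0])
            sample_ids.append(fields[1])
            pairs = [(fields[6 + 2 * j], fields[7 + 2 * j])
                     for j in range(n_snps)]
            allele_pairs.append(pairs)
            for j, (a, b) in enumerate(pairs):
                if a != "0" and b != "0":
                    counters[j][a] += 1
                    counters[j][b] += 1
                elif (a == "0") != (b == "0"):
                    raise ValueError(
                        f"PED line {lineno}: half-missing genotype at SNP "
                        f"{mp['snp_id'].iloc[j]}")

    # per-SNP allele orientation: dosage counts the file-wide minor allele;
    # ties and monomorphic sites break toward the lexically larger label
    a_major = np.full(n_snps, "A", dtype=object)
    b_minor = np.full(n_snps, "B", dtype=object)
    for j, cnt in enumerate(counters):
        alleles = sorted(cnt)
        if len(alleles) > 2:
            raise ValueError(
                f"SNP {mp['snp_id'].iloc[j]} has >2 alleles: {alleles}")
        if len(alleles) == 2:
            x, y = alleles
            if cnt[x] < cnt[y] or (cnt[x] == cnt[y] and x > y):
                a_major[j], b_minor[j] = y, x
            else:
                a_major[j], b_minor[j] = x, y
        elif len(alleles) == 1:
            a_major[j] = alleles[0]
            b_minor[j] = ""

    for pairs in allele_pairs:
        row = np.empty(n_snps, dtype=np.int8)
        for j, (a, b) in enumerate(pairs):
            if a == "0":
                row[j] = MISSING
            else:
                row[j] = (a == b_minor[j]) + (b == b_minor[j])
        rows.append(row)

    mm = MarkerMap(mp["snp_id"].to_numpy(object), mp["chrom"].to_numpy(object),
                   mp["pos"].to_numpy(), a_major, b_minor)
    order = mm.sort_order()
    mm = mm.take(order)
    G = GenotypeMatrix(np.vstack(rows)[:, order] if rows
                       else np.empty((0, n_snps), dtype=np.int8))

    if sample_table is not None:
        lookup = {s: i for i, s in enumerate(sample_table.sample_id)}
        idx = np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        st = sample_table.take(idx)
    else:
        st = SampleTable(np.array(sample_ids, dtype=object),
                         np.array(fids, dtype=object),
                         np.array(fids, dtype=object))
    return G, mm, st


def write_plink_textset(G: GenotypeMatrix, mm: MarkerMap, st: SampleTable,
                        ped_path, map_path) -> None:
    """Write genotypes as a PED/MAP pair (inverse of `read_plink_textset`)."""
    with open(map_path, "w") as fh:
        for c, s, p in zip(mm.chrom, mm.snp_id, mm.pos):
            fh.write(f"{c}\t{s}\t0\t{p}\n")
    a = np.where(mm.allele_a == "", "A", mm.allele_a)
    b = np.where(mm.allele_b == "", "B", mm.allele_b)
    with open(ped_path, "w") as fh:
        for i in range(G.n_samples):
            fields = [str(st.population[i]), str(st.sample_id[i]),
                      "0", "0", "0", "-9"]
            for j, g in enumerate(G.values[i]):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a[j], a[j]]
                elif g == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(vcf_path, sample_table: SampleTable | None = None,
                    ) -> tuple[HaplotypeSet, MarkerMap, SampleTable]:
    """Read a fully phased, biallelic VCF into a 0/1 haplotype matrix.

    Rows ``2j`` and ``2j+1`` hold the two phased alleles of sample *j*;
    REF maps to 0 and ALT to 1. Unphased, missing or multi-allelic records
    raise with the offending record named.
    """
    vcf = VCF(os.fspath(vcf_path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    snp_id, chrom, pos, ref, alt = [], [], [], [], []
    for var in vcf:
        label = f"{var.CHROM}:{var.POS}" + (f" ({var.ID})" if var.ID else "")
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {label}")
        gts = var.genotypes  # [allele_a, allele_b, phased] per sample
        col = np.empty(2 * len(samples), dtype=np.int8)
        for j, gt in enumerate(gts):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise ValueError(f"missing genotype at {label}, sample "
                                 f"{samples[j]}")
            if not phased:
                raise ValueError(f"unphased genotype at {label}, sample "
                                 f"{samples[j]}")
            col[2 * j], col[2 * j + 1] = a, b
        cols.append(col)
        snp_id.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    vcf.close()

    mm = MarkerMap(np.array(snp_id, dtype=object), np.array(chrom, dtype=object),
                   np.array(pos, dtype=np.int64), np.array(ref, dtype=object),
                   np.array(alt, dtype=object))
    order = mm.sort_order()
    mm = mm.take(order)
    values = (np.column_stack(cols)[:, order] if cols
              else np.empty((2 * len(samples), 0), dtype=np.int8))
    H = HaplotypeSet(values)

    if sample_table is not None:
        lookup = {s: i for i, s in enumerate(sample_table.sample_id)}
        idx = np.array([lookup[s] for s in samples], dtype=np.intp)
        st = sample_table.take(idx)
    else:
        unknown = np.full(len(samples), "unknown", dtype=object)
        st = SampleTable(np.array(samples, dtype=object), unknown.copy(),
                         unknown.copy())
    return H, mm, st


def write_phased_vcf(H: HaplotypeSet, mm: MarkerMap, st: SampleTable,
                     vcf_path) -> None:
    """Write haplotypes as an uncompressed phased VCF v4.2."""
    ref = np.where(mm.allele_a == "", "A", mm.allele_a)
    alt = np.where(mm.allele_b == "", "B", mm.allele_b)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(mm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, st.sample_id)) + "\n")
        V = H.values
        for j in range(mm.n_snps):
            gts = "\t".join(f"{V[2 * i, j]}|{V[2 * i + 1, j]}"
                            for i in range(H.n_samples))
            fh.write(f"{mm.chrom[j]}\t{mm.pos[j]}\t{mm.snp_id[j]}\t{ref[j]}\t"
                     f"{alt[j]}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Sample table TSV
# ---------------------------------------------------------------------------

def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample table must have columns {sorted(required)}")
    return SampleTable(df["sample_id"].to_numpy(object),
                       df["population"].to_numpy(object),
                       df["group"].to_numpy(object))


def write_sample_table(st: SampleTable, path) -> None:
    st.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def snp_call_rate(G: GenotypeMatrix) -> np.ndarray:
    return (G.values != MISSING).mean(axis=0)


def snp_maf(G: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency from non-missing genotypes; NaN if all missing."""
    called = G.values != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, G.values, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    return np.minimum(p, 1.0 - p)


def snp_qc_filter(G: GenotypeMatrix, mm: MarkerMap, *,
                  min_snp_call: float = 0.95, min_maf: float = 0.03,
                  autosomes: set | frozenset,
                  ) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """Retain SNPs with call rate >= threshold, MAF >= threshold, and an
    autosomal chromosome label; marker order is preserved."""
    call = snp_call_rate(G)
    maf = snp_maf(G)
    auto = np.isin(mm.chrom, list(map(str, autosomes)))
    pass_call = call >= min_snp_call
    with np.errstate(invalid="ignore"):
        pass_maf = maf >= min_maf  # NaN (all-missing) fails
    keep = pass_call & pass_maf & auto
    if not keep.any():
        raise ValueError("no SNPs survive QC")
    report = QCReport(
        axis="snp", n_input=mm.n_snps, n_retained=int(keep.sum()),
        thresholds={"min_snp_call": min_snp_call, "min_maf": min_maf,
                    "autosomes": sorted(map(str, autosomes))},
        failures={"call_rate": int((~pass_call).sum()),
                  "maf": int((~pass_maf).sum()),
                  "autosome": int((~auto).sum())},
    )
    report.validate()
    idx = np.flatnonzero(keep)
    return G.take_snps(idx), mm.take(idx), report


def sample_qc_filter(G: GenotypeMatrix, st: SampleTable, *,
                     min_sample_call: float = 0.95,
                     ) -> tuple[GenotypeMatrix, SampleTable, QCReport]:
    """Retain individuals genotyped at >= ``min_sample_call`` of SNPs."""
    call = (G.values != MISSING).mean(axis=1)
    keep = call >= min_sample_call
    if not keep.any():
        raise ValueError("no samples survive QC")
    report = QCReport(
        axis="sample", n_input=st.n_samples, n_retained=int(keep.sum()),
        thresholds={"min_sample_call": min_sample_call},
        failures={"call_rate": int((~keep).sum())},
    )
    report.validate()
    idx = np.flatnonzero(keep)
    return G.take_samples(idx), st.take(idx), report


def thin_every_kth(mm: MarkerMap, k: int = 10) -> np.ndarray:
    """Indices keeping one marker per consecutive block of ``k``.

    The (chrom, pos)-sorted list is cut into blocks of ``k``; the last
    marker of each complete block is kept and any incomplete trailing
    block is dropped, so exactly ``floor(n / k)`` markers survive.
    """
    if k <= 0:
        raise ValueError(f"k must be >= 1, got {k}")
    if not mm.is_sorted():
        raise ValueError("MarkerMap must be (chrom, pos)-sorted before thinning")
    return np.arange(k - 1, mm.n_snps, k, dtype=np.intp)
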