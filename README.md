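# sweepkit

Selection-signature scans on diploid SNP-array data: quality control and
LD thinning, PCA/DAPC population structure, per-SNP Weir–Cockerham FST
with the *di* statistic, EHH-based iHS and Rsb scans with a Gaussian-tail
significance transform, candidate-region calling/intersection/annotation,
and a synthetic-data generator with a sweep truth table so every stage is
verifiable without real genotypes.

## Layout

| module | contents |
|---|---|
| `sweepkit.io` | PLINK PED/MAP text and phased-VCF readers/writers, sample-table TSV, SNP/sample QC filters, 1-in-k thinning |
| `sweepkit.structure` | per-population allele frequencies, PCA (Patterson or centred scaling), DAPC |
| `sweepkit.differentiation` | Weir–Cockerham θ̂ per SNP, summed z-score *di* track, 20-SNP window means, top-fraction and threshold flagging |
| `sweepkit.ehh` | EHH/EHHS curves by partition refinement, iHH/iES trapezoidal integrals, iHS and Rsb scans, `p_transform`, random-ancestral consistency check |
| `sweepkit.regions` | adjacent-SNP run calling (±500 bp padding), window-run calling, cross-method interval intersection, BED/GFF3 gene-overlap annotation |
| `sweepkit.synthetic` | Balding–Nichols group frequencies, linkage-free haplotype sampling, template-copy sweep injection, dataset writer |
| `sweepkit.pipeline` / `sweepkit.cli` | end-to-end orchestration and the `sweepkit` command |

Conventions: genotypes are minor/alternate-allele dosages with `-1` for
missing; haplotypes are phased 0/1 rows (two per diploid); coordinates are
1-based inclusive bp internally (BED converts at the boundary).

## CLI

```sh
sweepkit simulate --out-dir sim --seed 1          # synthetic dataset + truth
sweepkit qc --ped sim/genotypes.ped --map sim/genotypes.map \
    --samples sim/samples.tsv --out-prefix qcd
sweepkit thin --map qcd.map --k 10 --out kept.txt
sweepkit pca --ped qcd.ped --map qcd.map --out-prefix pca
sweepkit dapc --ped qcd.ped --map qcd.map --samples sim/samples.tsv \
    --out-prefix dapc
sweepkit fst-di --ped qcd.ped --map qcd.map --samples sim/samples.tsv \
    --focal-group groupA --out-prefix di
sweepkit ihs --vcf sim/haplotypes.vcf --samples sim/samples.tsv \
    --group groupA --out ihs.tsv
sweepkit rsb --vcf sim/haplotypes.vcf --samples sim/samples.tsv \
    --group-a groupA --group-b groupB --out rsb.tsv
sweepkit regions --track rsb.tsv --method rsb --out-prefix rsb_regions
sweepkit run-all --ped sim/genotypes.ped --map sim/genotypes.map \
    --vcf sim/haplotypes.vcf --samples sim/samples.tsv --out-dir out
```

`run-all` writes QC reports, PCA/DAPC coordinates and plots, the three
scan tracks, per-method candidate regions (TSV + BED), cross-method
overlaps, optional gene annotation (`--genes`, BED or GFF3), and a JSON
run log with the config hash; reruns with the same config are
byte-identical.

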