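# sweepscan

A selection-sweep scan for comparing a domesticated/farmed population
against its wild counterpart from whole-genome resequencing data, plus a
synthetic data generator so the entire pipeline can be exercised at desk
scale without any external downloads.

The scan computes, over a fixed sliding-window grid (150 kb windows, 75 kb
step by default):

- **Hp** — pooled heterozygosity per window and population group,
  `Hp = 2*A*B/(A+B)^2` with `A = sum(n_MAJ)` and `B = sum(n_MIN)` summed
  over the window's SNPs, where `n_MAJ`/`n_MIN` are the read counts of the
  most/least abundant allele at each SNP within the group;
- **ZHp** — Hp standardized genome-wide within each group over its
  retained (≥ 20 SNP) windows;
- **dZHp** — the directional contrast `ZHp_wild − ZHp_farmed`; positive
  values mark windows where the farmed group lost heterozygosity;
- **FST** — the two-population Weir–Cockerham estimator on read counts,
  aggregated per window as a ratio of sums;
- outlier calls with one-sided normal tail p-values and Bonferroni
  correction over the tested windows, merged into maximal runs;
- cross-dataset concordance: window matching, a one-sided Wilcoxon
  rank-sum test of candidate windows' homozygosity shift in an independent
  dataset (exact null enumeration for small sets), same-direction
  intersection of significant windows, and dZHp correlation.

Input is a multi-sample VCF with per-sample allele depths (pool-seq) or
genotypes (individual sequencing), a sample→group assignment TSV, and
chromosome lengths (`.fai` or 2-column TSV). Site filters follow the
upstream calling conventions: biallelic SNPs only, mapping quality ≥ 50,
site depth ≥ 5, call rate strictly above 90 %.

## CLI

Three subcommands mirror the discovery / validation / comparison workflow:

```sh
# 1. generate a synthetic dataset (VCF + truth BED + groups TSV + lengths)
sweepscan simulate --config sim.yaml --seed 7 --out sim/

# 2. run the windowed scan
sweepscan scan --vcf sim/sim.vcf --groups sim/groups.tsv --fai sim/chroms.fai \
    --window 150000 --step 75000 --min-snps 20 \
    --mq 50 --dp 5 --call-rate 0.9 --zthr 3 --out scan1/

# 3. compare two scans built on the same grid
sweepscan concord --a scan1/ --b scan2/ --out concord/
```

`scan` accepts either `--zthr Z` (fixed threshold on the dZHp score) or
`--alpha A` (Bonferroni-corrected one-sided tails over the tested
windows). Outputs are plain text: `windows.tsv` (per-window statistics,
grid parameters embedded in the header line), `sweeps.bed` (merged outlier
calls, 0-based half-open), `summary.json`, and for `concord` a
`concordance.json` report plus `shared_regions.bed`.

A minimal simulation config:

```yaml
chromosomes: {chr1: 5000000, chr2: 5000000}
snp_density: 0.002        # expected SNPs per bp
error_rate: 0.001         # per-read flip probability
groups:
  - {name: farmed, mode: pooled, n_pools: 4, diploids: 22, depth: 22, divergence: 0.06}
  - {name: wild,   mode: pooled, n_pools: 6, diploids: 20, depth: 22, divergence: 0.06}
sweeps:
  - {chrom: chr1, start: 1000001, end: 1225000, group: farmed, f: 0.95}
```

`divergence` is the per-group Balding–Nichols F; 0.06 per group yields a
pairwise FST around 0.065. Groups can also use
`mode: individual` with `individuals: N` and a per-individual `depth`.
Sweeps push each in-interval SNP to fixation (toward the ancestral major
allele) in the target group with probability `f`; ground truth is written
as a BED alongside the VCF.

## Layout

- `src/sweepscan/simulate.py` — synthetic pool-seq / individual-seq VCF generator
- `src/sweepscan/variant_io.py` — VCF reading, site filters, per-group allele counts
- `src/sweepscan/windows.py` — sliding-window grid, SNP assignment, retention rule
- `src/sweepscan/stats.py` — Hp, ZHp, dZHp, Weir–Cockerham FST, outlier calling
- `src/sweepscan/concordance.py` — cross-dataset matching, rank-shift test, intersection, correlation
- `src/sweepscan/cli.py` — the three subcommands and file contracts
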