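# sweepscan

Selective-sweep scanning for a three-population contrast
(Target / Control / Background):

- **Site filtering** — the vcftools-style SNP filter set (site QUAL ≥ 30,
  biallelic SNPs only, mean depth 4–72, ≤ 10% missing, non-ref allele count
  ≥ 2, optional MAF floor).
- **Windowed statistics** — nucleotide diversity (π), pairwise
  Weir–Cockerham FST (ratio-of-sums), and the Target-branch length
  LSBL = (FST_TC + FST_TB − FST_CB)/2, all on a 50 kb / 25 kb sliding grid.
- **LD decay** — pairwise r² (haplotype D²-based when phased, dosage
  correlation otherwise), distance-binned decay curves, and the
  half-of-maximum decay distance, with per-population site filters
  (MAF / heterozygosity / missingness / exact HWE).
- **Outlier regions** — empirical top-1% windows on FST and LSBL, merged
  regions, gene overlap and the shared-gene intersection of the two scans.
- **Haplotype patterns** — the matrix of SNPs at high frequency in Target
  and low frequency in the pooled reference groups across a region.
- **Coding consequences** — synonymous/missense/stop classification with
  HGVS-like labels (e.g. `P107T`), honoring strand, exon order and phase.
- **Population structure** — IBS distance matrix and a Saitou–Nei
  neighbor-joining tree (newick).
- **Synthetic data** — a Balding–Nichols generator (unlinked sites, known
  drift F per population) and a forward Wright–Fisher simulator
  (recombination, mutation, three-way split, optional bottleneck and
  additive sweep, phased output), each returning a ground-truth record.

## CLI

Everything is exposed as `sweepscan <subcommand>`; each subcommand logs its
parameters and seed and reads/writes plain text formats (VCF 4.2, GFF3,
FASTA, TSV, BED, newick).

```sh
# synthetic three-population data (Balding-Nichols or Wright-Fisher)
sweepscan simulate --model bn --seed 1 --n-sites 20000 --spacing 2500 \
    --out-vcf sim.vcf --out-groups groups.tsv --out-truth truth.tsv

# the SNP filter stage
sweepscan filter --vcf sim.vcf --groups groups.tsv --out-vcf filtered.vcf

# windowed pi / FST / LSBL table
sweepscan scan --vcf filtered.vcf --groups groups.tsv --out windows.tsv

# LD decay for one population (7-per-group subsampling by default)
sweepscan ld-decay --vcf filtered.vcf --groups groups.tsv --pop Target \
    --seed 1 --out decay.tsv

# top-1% outlier windows -> merged regions -> gene overlap
sweepscan sweeps --table windows.tsv --gff genes.gff3 \
    --out-regions regions.tsv --out-bed regions.bed

# haplotype pattern of a region
sweepscan haplopattern --vcf filtered.vcf --groups groups.tsv \
    --region chr1:27750000-27860000 --out pattern.tsv

# coding consequence of one SNP
sweepscan effect --chrom chr1 --pos 27807636 --ref G --alt T \
    --gene-id GLIS1 --gff genes.gff3 --fasta ref.fa

# neighbor-joining tree of IBS distances
sweepscan njtree --vcf filtered.vcf --groups groups.tsv --out tree.nwk
```

The groups file is a two-column TSV `sample_id<TAB>population` with
populations drawn from `Target`, `Control`, `Background`.

Conventions: VCF/GFF coordinates are 1-based closed internally; window
spans in TSV output are 1-based half-open `[start, end)`; all BED exports
are 0-based half-open. Windows are anchored at position 1 per chromosome.
Negative window FSTs are legitimate Weir–Cockerham output and are not
clamped before the LSBL combination (a clamp flag exists on `scan`).

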