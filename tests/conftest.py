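"""Shared fixtures: hand-written VCF/GFF/FASTA toys and small simulations."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from sweepscan.variant_store import GenotypeMatrix


def write(path, text: str) -> str:
    path.write_text(textwrap.dedent(text).lstrip())
    return str(path)


@pytest.fixture()
def groups_file(tmp_path):
    return write(tmp_path / "groups.tsv", """
        s1\tTarget
        s2\tControl
        s3\tBackground
    """)


@pytest.fixture()
def toy_vcf(tmp_path):
    """3 samples, 5 sites; site 4 has one missing call; unphased."""
    return write(tmp_path / "toy.vcf", """
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=10000>
        ##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
        chr1\t100\t.\tA\tG\t50\t.\tDP=90\tGT\t0/0\t0/1\t1/1
        chr1\t200\t.\tC\tT\t60\t.\tDP=90\tGT\t0/1\t0/1\t0/1
        chr1\t300\t.\tG\tA\t70\t.\tDP=90\tGT\t1/1\t1/1\t1/1
        chr1\t400\t.\tT\tC\t80\t.\tDP=90\tGT\t./.\t0/0\t0/1
        chr1\t500\t.\tA\tC\t90\t.\tDP=90\tGT\t0/0\t0/0\t0/1
    """)


@pytest.fixture()
def phased_vcf(tmp_path):
    return write(tmp_path / "phased.vcf", """
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=10000>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
        chr1\t100\t.\tA\tG\t50\t.\t.\tGT\t0|1\t1|1\t0|0
        chr1\t200\t.\tC\tT\t60\t.\t.\tGT\t1|0\t0|1\t0|0
    """)


@pytest.fixture()
def filter_fixture_vcf(tmp_path):
    """10 sites: 2 indels, 1 triallelic, 1 low QUAL, 1 singleton non-ref,
    and 5 clean sites that pass the full filter set.

    Hand-applied rules (QUAL >= 30, biallelic, mean DP in [4, 72],
    <= 10% missing, non-ref AC >= 2, SNPs only):
      pos 100  clean               -> keep
      pos 200  indel (ref AT)      -> drop (snps_only)
      pos 300  QUAL 10             -> drop (min_qual)
      pos 400  clean               -> keep
      pos 500  triallelic G,T      -> drop (biallelic_only)
      pos 600  clean               -> keep
      pos 700  singleton non-ref   -> drop (min_nonref_allele_count)
      pos 800  clean               -> keep
      pos 900  indel (alt TTA)     -> drop (snps_only)
      pos 1000 clean               -> keep
    """
    return write(tmp_path / "filter10.vcf", """
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=10000>
        ##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
        chr1\t100\t.\tA\tG\t50\t.\tDP=90\tGT\t0/1\t0/1\t0/0
        chr1\t200\t.\tAT\tA\t50\t.\tDP=90\tGT\t0/1\t0/1\t0/0
        chr1\t300\t.\tC\tT\t10\t.\tDP=90\tGT\t0/1\t0/1\t0/0
        chr1\t400\t.\tG\tA\t50\t.\tDP=90\tGT\t1/1\t0/0\t0/1
        chr1\t500\t.\tC\tG,T\t50\t.\tDP=90\tGT\t0/1\t0/2\t0/0
        chr1\t600\t.\tT\tA\t50\t.\tDP=90\tGT\t0/1\t1/1\t0/0
        chr1\t700\t.\tA\tC\t50\t.\tDP=90\tGT\t0/1\t0/0\t0/0
        chr1\t800\t.\tG\tC\t50\t.\tDP=90\tGT\t0/1\t0/1\t0/1
        chr1\t900\t.\tC\tCTTA\t50\t.\tDP=90\tGT\t0/1\t0/1\t0/0
        chr1\t1000\t.\tT\tG\t50\t.\tDP=90\tGT\t1/1\t1/1\t1/1
    """)


@pytest.fixture()
def toy_gff(tmp_path):
    """Two genes; gene2 on the minus strand; single-CDS chains."""
    return write(tmp_path / "toy.gff3", """
        ##gff-version 3
        chr1\ttest\tgene\t101\t191\t.\t+\t.\tID=gene1
        chr1\ttest\tmRNA\t101\t191\t.\t+\t.\tID=mrna1;Parent=gene1
        chr1\ttest\tCDS\t101\t130\t.\t+\t0\tID=cds1a;Parent=mrna1
        chr1\ttest\tCDS\t141\t191\t.\t+\t0\tID=cds1b;Parent=mrna1
        chr1\ttest\tgene\t301\t360\t.\t-\t.\tID=gene2
        chr1\ttest\tmRNA\t301\t360\t.\t-\t.\tID=mrna2;Parent=gene2
        chr1\ttest\tCDS\t301\t360\t.\t-\t0\tID=cds2;Parent=mrna2
    """)


def make_gm(
    genotypes,
    pos=None,
    pops=("Target", "Control", "Background"),
    chrom="chr1",
    haplotypes=None,
    qual=100.0,
    mean_depth=30.0,
) -> GenotypeMatrix:
    """Build a small matrix from a per-site list of dosage rows.

    ``pops`` gives one label per sample column.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if pos is None:
        pos = 1 + 100 * np.arange(n_sites)
    return GenotypeMatrix(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        qual=np.full(n_sites, qual, dtype=float),
        genotypes=g,
        sample_ids=[f"s{i}" for i in range(n_samples)],
        pop_labels=np.asarray(pops, dtype=object),
        mean_depth=np.full(n_sites, mean_depth, dtype=float),
        haplotypes=None if haplotypes is None else np.asarray(haplotypes, dtype=np.int8),
    )
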