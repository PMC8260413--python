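"""Genotype, gene-model, and sequence I/O plus the site filter stage.

Coordinates are 1-based closed internally (VCF/GFF convention); any BED
export elsewhere in the package is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

POPULATIONS = ("Target", "Control", "Background")

MISSING = -1  # sentinel dosage / haplotype allele


class VariantStoreError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Sites x samples diploid alt-allele dosages with site metadata.

    ``genotypes`` holds values in {0, 1, 2, MISSING}.  ``haplotypes`` is
    present only for fully phased input and holds sites x (2 * samples)
    alleles in {0, 1, MISSING}; haplotype columns 2i and 2i+1 belong to
    sample i.
    """

    chrom: np.ndarray          # per-site chromosome label (str)
    pos: np.ndarray            # per-site 1-based position (int64)
    ref: np.ndarray            # per-site reference allele string
    alt: np.ndarray            # per-site alternative allele string (may hold "A,C")
    qual: np.ndarray           # per-site QUAL (nan = missing)
    genotypes: np.ndarray      # (n_sites, n_samples) int8
    sample_ids: list[str]
    pop_labels: np.ndarray     # per-sample population label (str)
    mean_depth: Optional[np.ndarray] = None   # per-site mean depth, None if unknown
    haplotypes: Optional[np.ndarray] = None   # (n_sites, 2 * n_samples) int8

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        if self.genotypes.shape != (self.n_sites, self.n_samples):
            raise VariantStoreError("genotype matrix shape mismatch")
        bad = set(np.unique(self.genotypes)) - {0, 1, 2, MISSING}
        if bad:
            raise VariantStoreError(f"illegal dosage values {sorted(bad)}")
        unknown = set(self.pop_labels) - set(POPULATIONS)
        if unknown:
            raise VariantStoreError(f"unknown population labels {sorted(unknown)}")
        for c in self.chroms():
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise VariantStoreError(f"positions not strictly increasing on {c}")

    # -- basic shape ---------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def is_phased(self) -> bool:
        return self.haplotypes is not None

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    # -- selection helpers ---------------------------------------------------

    def samples_for(self, pop: str | Sequence[str]) -> np.ndarray:
        """Column indices of the samples belonging to ``pop`` (one label or several)."""
        pops = (pop,) if isinstance(pop, str) else tuple(pop)
        for p in pops:
            if p not in POPULATIONS:
                raise VariantStoreError(f"unknown population {p!r}")
        return np.flatnonzero(np.isin(self.pop_labels, pops))

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            qual=self.qual[index],
            genotypes=self.genotypes[index],
            mean_depth=None if self.mean_depth is None else self.mean_depth[index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        hap = None
        if self.haplotypes is not None:
            hap_cols = np.stack([2 * index, 2 * index + 1], axis=1).ravel()
            hap = self.haplotypes[:, hap_cols]
        return replace(
            self,
            genotypes=self.genotypes[:, index],
            sample_ids=[self.sample_ids[i] for i in index],
            pop_labels=self.pop_labels[index],
            haplotypes=hap,
        )

    # -- per-site summaries --------------------------------------------------

    def called_mask(self, sample_index: Optional[np.ndarray] = None) -> np.ndarray:
        gt = self.genotypes if sample_index is None else self.genotypes[:, sample_index]
        return gt != MISSING

    def allele_counts(self, sample_index: Optional[np.ndarray] = None):
        """Per-site (called diploids, alt allele count, het count) over the chosen samples."""
        gt = self.genotypes if sample_index is None else self.genotypes[:, sample_index]
        called = gt != MISSING
        n = called.sum(axis=1)
        alt = np.where(called, gt, 0).sum(axis=1)
        het = (gt == 1).sum(axis=1)
        return n, alt, het

    def alt_freq(self, sample_index: Optional[np.ndarray] = None) -> np.ndarray:
        n, alt, _ = self.allele_counts(sample_index)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)


# ---------------------------------------------------------------------------
# Group file
# ---------------------------------------------------------------------------

def read_groups(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample_id<TAB>population`` -> mapping."""
    groups: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise VariantStoreError(f"malformed groups line: {line!r}")
        sample, pop = parts
        if pop not in POPULATIONS:
            raise VariantStoreError(
                f"population {pop!r} for sample {sample!r} not in {POPULATIONS}"
            )
        groups[sample] = pop
    return groups


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, groups_path: str | Path) -> GenotypeMatrix:
    """Load a VCF 4.x and a sample->population groups file.

    Site order is preserved.  Haplotypes are recorded only when every called
    genotype in the file is phased ("|" separator).  Mean depth comes from
    FORMAT/DP averaged over called samples, else INFO/DP divided by the
    sample count, else is left unset.
    """
    from cyvcf2 import VCF

    groups = read_groups(groups_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in groups]
    if missing_samples:
        raise VariantStoreError(f"samples absent from groups file: {missing_samples}")

    chrom, pos, ref, alt, qual = [], [], [], [], []
    dosages, hap_rows, depths = [], [], []
    all_phased = True
    any_fmt_dp = False
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(",".join(v.ALT) if v.ALT else ".")
        qual.append(np.nan if v.QUAL is None else float(v.QUAL))
        row = np.full(len(samples), MISSING, dtype=np.int8)
        hrow = np.full(2 * len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], bool(g[-1])
            if a < 0 or b < 0:
                continue
            row[i] = (a > 0) + (b > 0)
            hrow[2 * i] = a > 0
            hrow[2 * i + 1] = b > 0
            if not phased:
                all_phased = False
        dosages.append(row)
        hap_rows.append(hrow)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_fmt_dp = True
            dp = np.asarray(dp, dtype=float).ravel()
            dp = dp[dp >= 0]
            depths.append(float(dp.mean()) if dp.size else np.nan)
        else:
            info_dp = v.INFO.get("DP")
            depths.append(np.nan if info_dp is None else float(info_dp) / len(samples))

    n_sites = len(pos)
    mean_depth = np.asarray(depths, dtype=float) if n_sites else np.empty(0)
    if n_sites and np.all(np.isnan(mean_depth)) and not any_fmt_dp:
        mean_depth = None
    gt = (
        np.vstack(dosages)
        if n_sites
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    hap = None
    if all_phased and n_sites:
        hap = np.vstack(hap_rows)
    return GenotypeMatrix(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        qual=np.asarray(qual, dtype=float),
        genotypes=gt,
        sample_ids=samples,
        pop_labels=np.asarray([groups[s] for s in samples], dtype=object),
        mean_depth=mean_depth,
        haplotypes=hap,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 (QUAL, INFO/DP when known, GT)."""
    lines = ["##fileformat=VCFv4.2"]
    for c in gm.chroms():
        end = int(gm.pos[gm.chrom == c].max())
        lines.append(f"##contig=<ID={c},length={end + 1}>")
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids)
    )
    sep = "|" if gm.is_phased else "/"
    for i in range(gm.n_sites):
        qual = "." if np.isnan(gm.qual[i]) else f"{gm.qual[i]:g}"
        info = "."
        if gm.mean_depth is not None and not np.isnan(gm.mean_depth[i]):
            info = f"DP={int(round(gm.mean_depth[i] * gm.n_samples))}"
        gts = []
        for j in range(gm.n_samples):
            if gm.is_phased:
                a, b = gm.haplotypes[i, 2 * j], gm.haplotypes[i, 2 * j + 1]
                gts.append("." + sep + "." if a == MISSING else f"{a}{sep}{b}")
            else:
                d = gm.genotypes[i, j]
                if d == MISSING:
                    gts.append("./.")
                else:
                    gts.append(("0/0", "0/1", "1/1")[d])
        lines.append(
            f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t{qual}\t.\t"
            f"{info}\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_groups(gm: GenotypeMatrix, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{s}\t{p}\n" for s, p in zip(gm.sample_ids, gm.pop_labels))
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """The study's vcftools-style site filter set.

    ``max_missing_fraction`` is the largest tolerated fraction of missing
    genotypes; note this inverts the vcftools ``--max-missing 0.9`` number
    (which is the smallest tolerated fraction of *called* genotypes).
    """

    min_qual: Optional[float] = 30.0
    biallelic_only: bool = True
    min_mean_dp: Optional[float] = 4.0
    max_mean_dp: Optional[float] = 72.0
    max_missing_fraction: Optional[float] = 0.1
    min_nonref_allele_count: Optional[int] = 2
    snps_only: bool = True
    maf_min: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_missing_fraction is not None and not (
            0.0 <= self.max_missing_fraction <= 1.0
        ):
            raise VariantStoreError("max_missing_fraction must be in [0, 1]")


#: criterion evaluation order — a site failing several rules is reported
#: under the first one in this order.
FILTER_ORDER = (
    "min_qual",
    "biallelic_only",
    "min_mean_dp",
    "max_mean_dp",
    "max_missing_fraction",
    "min_nonref_allele_count",
    "snps_only",
    "maf_min",
)


@dataclass
class FilterReport:
    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)

    def total_removed(self) -> int:
        return sum(self.removed.values())


def _is_snp(ref: str, alt: str) -> bool:
    if len(ref) != 1 or ref not in "ACGTN":
        return False
    alts = alt.split(",")
    return all(len(a) == 1 and a in "ACGTN" for a in alts)


def _n_alleles(alt: str) -> int:
    return 1 if alt == "." else 2 + alt.count(",")


def apply_filters(
    gm: GenotypeMatrix, spec: FilterSpec = FilterSpec()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Retain the sites passing every enabled criterion.

    Returns the filtered matrix and a report counting, for each criterion,
    the sites it removed (each dropped site counted once, under the first
    failing criterion in ``FILTER_ORDER``).
    """
    n = gm.n_sites
    fails: dict[str, np.ndarray] = {}

    if spec.min_qual is not None:
        with np.errstate(invalid="ignore"):
            fails["min_qual"] = ~np.isnan(gm.qual) & (gm.qual < spec.min_qual)
    if spec.biallelic_only:
        fails["biallelic_only"] = np.array(
            [_n_alleles(a) != 2 for a in gm.alt], dtype=bool
        )
    if spec.min_mean_dp is not None or spec.max_mean_dp is not None:
        if gm.mean_depth is None:
            warnings.warn(
                "mean depth unavailable; depth criteria skipped", stacklevel=2
            )
        else:
            dp = gm.mean_depth
            with np.errstate(invalid="ignore"):
                if spec.min_mean_dp is not None:
                    fails["min_mean_dp"] = ~np.isnan(dp) & (dp < spec.min_mean_dp)
                if spec.max_mean_dp is not None:
                    fails["max_mean_dp"] = ~np.isnan(dp) & (dp > spec.max_mean_dp)
    called = gm.called_mask()
    if spec.max_missing_fraction is not None:
        miss_frac = 1.0 - called.sum(axis=1) / gm.n_samples
        fails["max_missing_fraction"] = miss_frac > spec.max_missing_fraction + 1e-12
    if spec.min_nonref_allele_count is not None:
        _, alt_count, _ = gm.allele_counts()
        fails["min_nonref_allele_count"] = alt_count < spec.min_nonref_allele_count
    if spec.snps_only:
        fails["snps_only"] = np.array(
            [not _is_snp(r, a) for r, a in zip(gm.ref, gm.alt)], dtype=bool
        )
    if spec.maf_min is not None:
        p = gm.alt_freq()
        with np.errstate(invalid="ignore"):
            maf = np.minimum(p, 1.0 - p)
        fails["maf_min"] = np.isnan(maf) | (maf < spec.maf_min - 1e-12)

    removed: dict[str, int] = {}
    claimed = np.zeros(n, dtype=bool)
    for name in FILTER_ORDER:
        if name not in fails:
            continue
        newly = fails[name] & ~claimed
        removed[name] = int(newly.sum())
        claimed |= fails[name]
    keep = ~claimed
    out = gm.take_sites(np.flatnonzero(keep))
    return out, FilterReport(n_input=n, n_output=out.n_sites, removed=removed)


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene with a single ordered CDS chain."""

    gene_id: str
    chrom: str
    strand: str                       # "+" or "-"
    start: int                        # 1-based closed gene span
    end: int
    cds: tuple[tuple[int, int, int], ...]  # (start, end, phase), genomic order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise VariantStoreError(f"bad strand {self.strand!r}")
        prev_end = 0
        for s, e, ph in self.cds:
            if s <= prev_end:
                raise VariantStoreError(f"CDS intervals of {self.gene_id} overlap or unsorted")
            if s < self.start or e > self.end:
                raise VariantStoreError(f"CDS outside gene span for {self.gene_id}")
            if ph not in (0, 1, 2):
                raise VariantStoreError(f"bad phase {ph} in {self.gene_id}")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def contains_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e, _ in self.cds)


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse gene + CDS features of a GFF3 into gene models.

    CDS features without a gene ancestor are skipped with a warning.
    Genes without CDS children yield models with an empty CDS chain.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except EmptyInputError:
        return []
    models: list[GeneModel] = []
    claimed_cds: set[str] = set()
    for gene in db.features_of_type("gene"):
        cds = sorted(
            db.children(gene, featuretype="CDS"), key=lambda f: (f.start, f.end)
        )
        for f in cds:
            claimed_cds.add(f.id)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                start=gene.start,
                end=gene.end,
                cds=tuple(
                    (f.start, f.end, int(f.frame) if f.frame in "012" else 0)
                    for f in cds
                ),
            )
        )
    orphans = [f.id for f in db.features_of_type("CDS") if f.id not in claimed_cds]
    if orphans:
        warnings.warn(f"CDS without parent gene skipped: {orphans}", stacklevel=2)
    return models


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta_region(path: str | Path, chrom: str, start: int, end: int) -> str:
    """Uppercase sequence of the 1-based closed interval [start, end]."""
    from pyfaidx import Fasta

    if start < 1 or end < start:
        raise VariantStoreError(f"bad interval [{start}, {end}]")
    fa = Fasta(str(path))
    if chrom not in fa:
        raise VariantStoreError(f"contig {chrom!r} not in FASTA")
    if end > len(fa[chrom]):
        raise VariantStoreError(
            f"interval end {end} beyond contig {chrom} length {len(fa[chrom])}"
        )
    return str(fa[chrom][start - 1 : end]).upper()


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
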