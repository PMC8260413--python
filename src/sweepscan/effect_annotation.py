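"""Coding-consequence annotation of single-nucleotide substitutions.

Maps a genomic SNP into the spliced CDS of a gene model (honoring exon
order, strand, and the phase of the first coding segment), translates the
affected codon before and after, and emits an HGVS-like protein label such
as "P107T".  Codon numbering is 1-based from the annotated start codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .variant_store import GeneModel, revcomp


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Consequence:
    chrom: str
    pos: int
    gene_id: str
    codon_number: Optional[int]
    ref_aa: Optional[str]
    alt_aa: Optional[str]
    consequence: str            # synonymous | missense | stop_gained | stop_lost | non_coding
    label: Optional[str]        # e.g. "P107T"; None for non_coding

    def to_tsv_row(self) -> str:
        f = lambda v: "." if v is None else str(v)
        return "\t".join([
            self.chrom, str(self.pos), self.gene_id, f(self.codon_number),
            f(self.ref_aa), f(self.alt_aa), self.consequence, f(self.label),
        ])


def _spliced_cds(gene: GeneModel, ref_seq: str, seq_start: int) -> str:
    """Concatenate CDS segments in translation order (5'->3' of the mRNA)."""
    parts = []
    for s, e, _ in gene.cds:
        parts.append(ref_seq[s - seq_start : e - seq_start + 1])
    cds = "".join(parts)
    return revcomp(cds) if gene.strand == "-" else cds


def _cds_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of genomic ``pos`` within the spliced, stranded CDS."""
    consumed = 0
    if gene.strand == "+":
        for s, e, _ in gene.cds:
            if s <= pos <= e:
                return consumed + (pos - s)
            consumed += e - s + 1
    else:
        for s, e, _ in reversed(gene.cds):
            if s <= pos <= e:
                return consumed + (e - pos)
            consumed += e - s + 1
    raise AnnotationError(f"position {pos} not inside a CDS of {gene.gene_id}")


def annotate_coding_snp(
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    gene: GeneModel,
    ref_seq: str,
    seq_start: int = 1,
) -> Consequence:
    """Classify a single-base substitution inside ``gene``.

    ``ref_seq`` is the plus-strand reference covering the gene span,
    starting at genomic position ``seq_start``.  The SNP's ref allele (given
    on the plus strand, as in a VCF) must match the reference base.
    """
    if len(ref_allele) != 1 or len(alt_allele) != 1:
        raise AnnotationError("only single-nucleotide substitutions are supported")
    if chrom != gene.chrom:
        raise AnnotationError(f"SNP chrom {chrom} != gene chrom {gene.chrom}")
    if not (seq_start <= pos < seq_start + len(ref_seq)):
        raise AnnotationError("reference sequence does not cover the SNP")

    ref_base = ref_seq[pos - seq_start].upper()
    if ref_base != ref_allele.upper():
        raise AnnotationError(
            f"ref allele {ref_allele} does not match reference base {ref_base} at {chrom}:{pos}"
        )

    if not gene.contains_cds(pos):
        return Consequence(chrom, pos, gene.gene_id, None, None, None, "non_coding", None)

    cds_seq = _spliced_cds(gene, ref_seq, seq_start)
    offset = _cds_offset(gene, pos)

    # honor the phase of the first coding segment in translation order
    first = gene.cds[0] if gene.strand == "+" else gene.cds[-1]
    phase = first[2]
    offset -= phase
    cds_seq = cds_seq[phase:]
    if offset < 0:
        return Consequence(chrom, pos, gene.gene_id, None, None, None, "non_coding", None)

    codon_number = offset // 3 + 1
    within = offset % 3
    codon_start = offset - within
    codon = cds_seq[codon_start : codon_start + 3]
    if len(codon) < 3:
        raise AnnotationError(f"truncated terminal codon in {gene.gene_id}")

    alt_base = alt_allele.upper() if gene.strand == "+" else revcomp(alt_allele.upper())
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]

    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        kind = "synonymous"
    elif alt_aa == "*":
        kind = "stop_gained"
    elif ref_aa == "*":
        kind = "stop_lost"
    else:
        kind = "missense"
    label = f"{ref_aa}{codon_number}{alt_aa}"
    return Consequence(chrom, pos, gene.gene_id, codon_number, ref_aa, alt_aa, kind, label)


# ---------------------------------------------------------------------------
# Alignment-column differences
# ---------------------------------------------------------------------------

def protein_alignment_view(sequences: dict[str, str]) -> list[dict]:
    """Columns of a pre-aligned amino-acid set where >= 2 residues differ.

    Returns one record per variable column: {"column": 1-based index,
    "residues": {species: residue}}.  All sequences must share one length.
    """
    if not sequences:
        return []
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise AnnotationError(f"sequences have unequal lengths {sorted(lengths)}")
    (length,) = lengths
    report = []
    for col in range(length):
        residues = {sp: seq[col] for sp, seq in sequences.items()}
        if len(set(residues.values())) >= 2:
            report.append({"column": col + 1, "residues": residues})
    return report
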