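"""Reference genome container: sequences, gene models, repeat intervals.

Coordinates are 1-based and inclusive throughout, matching GFF3 and
protein numbering (codon 1 = start codon).  CDS intervals of a gene are
stored in coding (5'→3' on the coding strand) order: ascending genomic
coordinates on '+' genes, descending on '-' genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import CoordinateError, DataIntegrityError

Interval = tuple[int, int]  # 1-based, inclusive


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: strand plus ordered CDS intervals."""

    id: str
    chromosome: str
    strand: str  # '+' or '-'
    cds_intervals: tuple[Interval, ...]  # coding order
    is_causal_gene: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise DataIntegrityError(f"gene {self.id}: strand must be + or -")
        ivs = self.cds_intervals
        if not ivs or any(s > e for s, e in ivs):
            raise DataIntegrityError(f"gene {self.id}: invalid CDS intervals")
        genomic = sorted(ivs)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise DataIntegrityError(f"gene {self.id}: overlapping CDS intervals")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(ivs) != expected:
            raise DataIntegrityError(
                f"gene {self.id}: CDS intervals not in coding order for strand "
                f"{self.strand}"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> Interval:
        starts = [s for s, _ in self.cds_intervals]
        ends = [e for _, e in self.cds_intervals]
        return (min(starts), max(ends))

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.cds_intervals)

    def cds_offset(self, position: int) -> int:
        """0-based offset of a genomic position within the coding sequence."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= position <= e:
                return offset + (position - s if self.strand == "+" else e - position)
            offset += e - s + 1
        raise CoordinateError(
            f"position {position} not in CDS of gene {self.id}"
        )

    def coding_sequence(self, chrom_seq: str) -> str:
        parts = []
        for s, e in self.cds_intervals:
            piece = chrom_seq[s - 1 : e]
            parts.append(piece if self.strand == "+" else revcomp(piece))
        return "".join(parts)


@dataclass
class GenomeModel:
    """Chromosome sequences with gene models and repeat annotations."""

    chromosomes: list[tuple[str, str]]  # (name, sequence over ACGT)
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise DataIntegrityError("chromosome names must be unique")
        self._seqs = {n: s.upper() for n, s in self.chromosomes}
        for gene in self.genes:
            if gene.chromosome not in self._seqs:
                raise DataIntegrityError(
                    f"gene {gene.id}: unknown chromosome {gene.chromosome}"
                )
            _, hi = gene.span
            if hi > len(self._seqs[gene.chromosome]):
                raise DataIntegrityError(
                    f"gene {gene.id}: CDS exceeds chromosome length"
                )
            if gene.cds_length % 3 != 0:
                raise DataIntegrityError(
                    f"gene {gene.id}: CDS length {gene.cds_length} not divisible by 3"
                )

    @property
    def chromosome_names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def sequence(self, chromosome: str) -> str:
        try:
            return self._seqs[chromosome]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chromosome!r}") from None

    def length(self, chromosome: str) -> int:
        return len(self.sequence(chromosome))

    def base(self, chromosome: str, position: int) -> str:
        seq = self.sequence(chromosome)
        if not (1 <= position <= len(seq)):
            raise CoordinateError(
                f"position {chromosome}:{position} outside chromosome "
                f"(length {len(seq)})"
            )
        return seq[position - 1]

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        seq = self.sequence(chromosome)
        if not (1 <= start <= end <= len(seq)):
            raise CoordinateError(
                f"interval {chromosome}:{start}-{end} outside chromosome"
            )
        return seq[start - 1 : end]

    @property
    def causal_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.is_causal_gene]

    @property
    def causal_gene(self) -> GeneModel:
        causal = self.causal_genes
        if not causal:
            raise DataIntegrityError("genome has no causal gene")
        return causal[0]

    def in_repeat(self, chromosome: str, position: int) -> bool:
        return any(
            c == chromosome and s <= position <= e for c, s, e in self.repeats
        )

    def gene_at(self, chromosome: str, position: int) -> GeneModel | None:
        for gene in self.genes:
            if gene.chromosome == chromosome and gene.contains(position):
                return gene
        return None
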