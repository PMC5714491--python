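"""Variant-effect classification and RNAi off-target scanning.

Candidate SNPs from the bulk-segregant pipeline are classified as
noncoding, synonymous, or nonsynonymous by reconstructing the affected
codon from the gene model (strand- and phase-aware) and translating
with the standard genetic code.  Nonsynonymous replacements are further
scored as conservative or nonconservative using a standard symmetric
amino-acid substitution matrix (BLOSUM62 by default; a pair scoring
below 0 is called nonconservative — e.g. M→K, the kind of drastic
replacement that flags a loss-of-function allele).

The off-target scanner supports RNAi construct design: it reports the
longest exact contiguous match (either strand) between a chosen
fragment and the rest of the genome, to be compared against a safety
threshold (default 16 bp — matches longer than this risk silencing
unintended transcripts).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .bsa import AnnotatedSnp, SnpRecord
from .errors import CoordinateError, DataIntegrityError, UsageError
from .genome import GeneModel, GenomeModel, revcomp

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_CATEGORY_ORDER = {"nonsynonymous": 0, "synonymous": 1, "noncoding": 2}
_CONSERVATION_ORDER = {"nonconservative": 0, "conservative": 1, "n/a": 2}


@dataclass(frozen=True)
class VariantEffect:
    """Predicted consequence of a single-nucleotide variant."""

    category: str  # noncoding | synonymous | nonsynonymous
    aa_change: tuple[str, int, str] | None = None  # (ref AA, codon number, alt AA)
    conservation_call: str = "n/a"  # conservative | nonconservative | n/a
    in_repeat: bool = False
    gene_id: str | None = None

    def __post_init__(self):
        if (self.category == "nonsynonymous") != (self.aa_change is not None):
            raise DataIntegrityError(
                "aa_change must be present exactly for nonsynonymous variants"
            )
        if self.aa_change is not None and self.aa_change[1] < 1:
            raise DataIntegrityError("codon number must be >= 1")

    def aa_change_str(self) -> str:
        if self.aa_change is None:
            return ""
        ref_aa, codon, alt_aa = self.aa_change
        return f"{ref_aa}{codon}{alt_aa}"

    def sort_key(self) -> tuple[int, int]:
        return (
            _CATEGORY_ORDER[self.category],
            _CONSERVATION_ORDER[self.conservation_call],
        )


class SubstitutionScorer:
    """Symmetric amino-acid pair scores with a nonconservative threshold."""

    def __init__(self, matrix, nonconservative_threshold: float = 0.0):
        self.matrix = matrix
        self.nonconservative_threshold = nonconservative_threshold

    @classmethod
    def default(cls) -> "SubstitutionScorer":
        return cls(substitution_matrices.load("BLOSUM62"))

    def score(self, ref_aa: str, alt_aa: str) -> float:
        for aa in (ref_aa, alt_aa):
            if aa not in STANDARD_AA:
                raise UsageError(f"nonstandard amino acid {aa!r}")
        return float(self.matrix[ref_aa, alt_aa])


def classify_replacement(
    ref_aa: str, alt_aa: str, scorer: SubstitutionScorer | None = None
) -> str:
    """'nonconservative' iff the substitution score is below the threshold."""
    scorer = scorer or SubstitutionScorer.default()
    score = scorer.score(ref_aa, alt_aa)
    return (
        "nonconservative"
        if score < scorer.nonconservative_threshold
        else "conservative"
    )


def annotate_variant(
    snp: SnpRecord,
    genome: GenomeModel,
    genes: list[GeneModel] | None = None,
    scorer: SubstitutionScorer | None = None,
) -> VariantEffect:
    """Classify one SNP against the reference genome and gene models.

    The reference allele is checked against the genome (a mismatch is a
    data-integrity error).  Positions inside a CDS are translated via
    the reconstructed codon; codon numbering is 1-based from the start
    codon, identical for '+' and '-' strand genes.  A replacement to or
    from a stop codon is treated as nonconservative (a truncation is at
    least as drastic as any scored pair).
    """
    genes = genes if genes is not None else genome.genes
    ref_base = genome.base(snp.chromosome, snp.position)  # raises CoordinateError
    if ref_base != snp.ref.upper():
        raise DataIntegrityError(
            f"{snp.chromosome}:{snp.position}: VCF ref {snp.ref!r} does not "
            f"match reference base {ref_base!r}"
        )
    in_repeat = genome.in_repeat(snp.chromosome, snp.position)

    gene = None
    for g in genes:
        if g.chromosome == snp.chromosome and g.contains(snp.position):
            gene = g
            break
    if gene is None:
        return VariantEffect("noncoding", in_repeat=in_repeat)

    offset = gene.cds_offset(snp.position)
    codon_index, pos_in_codon = divmod(offset, 3)
    cds = gene.coding_sequence(genome.sequence(gene.chromosome))
    codon = cds[codon_index * 3 : codon_index * 3 + 3]
    alt_coding = snp.alt.upper() if gene.strand == "+" else revcomp(snp.alt.upper())
    alt_codon = codon[:pos_in_codon] + alt_coding + codon[pos_in_codon + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return VariantEffect(
            "synonymous", in_repeat=in_repeat, gene_id=gene.id
        )
    if ref_aa in STANDARD_AA and alt_aa in STANDARD_AA:
        call = classify_replacement(ref_aa, alt_aa, scorer)
    else:
        call = "nonconservative"  # gain/loss of stop
    return VariantEffect(
        "nonsynonymous",
        aa_change=(ref_aa, codon_index + 1, alt_aa),
        conservation_call=call,
        in_repeat=in_repeat,
        gene_id=gene.id,
    )


def rank_candidates(candidates: list[AnnotatedSnp]) -> list[AnnotatedSnp]:
    """Most-damaging first: nonsynonymous nonconservative, nonsynonymous
    conservative, synonymous, noncoding; ties by (chromosome, position)."""
    def key(cand: AnnotatedSnp):
        effect_key = (
            cand.effect.sort_key() if cand.effect is not None else (99, 99)
        )
        return (*effect_key, cand.record.chromosome, cand.record.position)

    return sorted(candidates, key=key)


@dataclass(frozen=True)
class OffTargetResult:
    longest_match: int
    threshold: int

    @property
    def passes(self) -> bool:
        return self.longest_match <= self.threshold


def off_target_scan(
    fragment: str,
    genome: GenomeModel,
    source_locus: tuple[str, int, int],
    threshold: int = 16,
) -> OffTargetResult:
    """Longest exact contiguous match of a fragment outside its own locus.

    The fragment must occur at ``source_locus`` (chrom, start, end;
    1-based inclusive).  Both the fragment and its reverse complement
    are searched against every chromosome with the source locus masked
    out, so no reported match overlaps the locus the fragment came
    from.  ``passes`` is true when the longest match does not exceed
    the threshold.
    """
    fragment = fragment.upper()
    if not fragment:
        raise UsageError("fragment must be non-empty")
    chrom, start, end = source_locus
    if genome.fetch(chrom, start, end) != fragment:
        raise UsageError(
            f"fragment does not match the genome at {chrom}:{start}-{end}"
        )

    texts = []
    for name, seq in genome.chromosomes:
        seq = seq.upper()
        if name == chrom:
            seq = seq[: start - 1] + "N" * (end - start + 1) + seq[end:]
        texts.append(seq)

    queries = (fragment, revcomp(fragment))

    def has_match(length: int) -> bool:
        if length == 0:
            return True
        subs = set()
        for q in queries:
            for i in range(len(q) - length + 1):
                subs.add(q[i : i + length])
        for text in texts:
            for i in range(len(text) - length + 1):
                window = text[i : i + length]
                if "N" not in window and window in subs:
                    return True
        return False

    lo, hi = 0, len(fragment)
    while lo < hi:  # largest L with a match; has_match is monotone
        mid = (lo + hi + 1) // 2
        if has_match(mid):
            lo = mid
        else:
            hi = mid - 1
    return OffTargetResult(longest_match=lo, threshold=threshold)
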