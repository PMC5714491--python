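"""Codon-level effect classification and off-target scanning."""

import numpy as np
import pytest
from Bio.Seq import Seq

from bsakit import (
    AnnotatedSnp,
    GeneModel,
    GenomeModel,
    SnpRecord,
    SubstitutionScorer,
    VariantEffect,
    annotate_variant,
    classify_replacement,
    off_target_scan,
    rank_candidates,
)
from bsakit.errors import CoordinateError, DataIntegrityError, UsageError
from bsakit.genome import revcomp


def snp(chrom, pos, ref, alt):
    return SnpRecord(chrom, pos, ref, alt, 99, 100)


def build_gene_genome(n_codons=375, special=None, strand="+"):
    """Single-gene genome whose CDS is the whole chromosome (plus strand)
    or its reverse complement (minus strand).  ``special`` maps codon
    number (1-based) to a codon string."""
    codons = ["ATG"] + ["GGA"] * (n_codons - 2) + ["TAA"]
    for number, codon in (special or {}).items():
        codons[number - 1] = codon
    cds = "".join(codons)
    if strand == "+":
        chrom_seq = cds
        intervals = ((1, len(cds)),)
    else:
        chrom_seq = revcomp(cds)
        intervals = ((1, len(cds)),)
    gene = GeneModel("g1", "chr1", strand, intervals, is_causal_gene=True)
    return GenomeModel([("chr1", chrom_seq)], [gene])


class TestAnnotateVariant:
    def test_intergenic_is_noncoding(self):
        genome = GenomeModel([("chr1", "ACGTACGTACGT")], [])
        effect = annotate_variant(snp("chr1", 5, "A", "T"), genome)
        assert effect.category == "noncoding"
        assert effect.aa_change is None

    def test_m371k_drastic_replacement(self):
        # codon 371 = ATG (methionine); T->A at its second base gives AAG
        # (lysine): the canonical drastic replacement notation M371K
        genome = build_gene_genome(special={371: "ATG"})
        position = (371 - 1) * 3 + 2
        effect = annotate_variant(snp("chr1", position, "T", "A"), genome)
        assert effect.category == "nonsynonymous"
        assert effect.aa_change == ("M", 371, "K")
        assert effect.conservation_call == "nonconservative"
        assert effect.aa_change_str() == "M371K"

    def test_third_position_wobble_is_synonymous(self):
        genome = build_gene_genome(special={10: "GGA"})
        position = (10 - 1) * 3 + 3
        effect = annotate_variant(snp("chr1", position, "A", "G"), genome)
        assert effect.category == "synonymous"

    def test_reference_mismatch_detected(self):
        genome = build_gene_genome()
        with pytest.raises(DataIntegrityError):
            annotate_variant(snp("chr1", 1, "C", "T"), genome)

    def test_position_outside_chromosome(self):
        genome = build_gene_genome()
        with pytest.raises(CoordinateError):
            annotate_variant(snp("chr1", 10**6, "A", "T"), genome)

    def test_minus_strand_gene_gives_identical_aa_change(self):
        plus = build_gene_genome(special={371: "ATG"}, strand="+")
        minus = build_gene_genome(special={371: "ATG"}, strand="-")
        pos_plus = (371 - 1) * 3 + 2
        length = len(plus.sequence("chr1"))
        pos_minus = length - pos_plus + 1
        eff_plus = annotate_variant(snp("chr1", pos_plus, "T", "A"), plus)
        eff_minus = annotate_variant(snp("chr1", pos_minus, "A", "T"), minus)
        assert eff_plus.aa_change == eff_minus.aa_change == ("M", 371, "K")

    @pytest.mark.parametrize("gene_index", [0, 1])
    def test_agrees_with_full_cds_translation_oracle(
        self, small_genome, gene_index
    ):
        """Brute force: mutate the base in the full CDS, translate both
        proteins, and diff - must match the codon-level classification."""
        genome = small_genome
        gene = genome.genes[gene_index]
        chrom_seq = genome.sequence(gene.chromosome)
        cds = gene.coding_sequence(chrom_seq)
        protein = str(Seq(cds).translate())
        positions = [
            p for s, e in gene.cds_intervals for p in range(s, e + 1)
        ]
        rng = np.random.default_rng(3)
        for pos in rng.choice(positions, size=60, replace=False):
            pos = int(pos)
            ref = chrom_seq[pos - 1]
            for alt in (b for b in "ACGT" if b != ref):
                effect = annotate_variant(snp(gene.chromosome, pos, ref, alt), genome)
                offset = gene.cds_offset(pos)
                alt_coding = alt if gene.strand == "+" else revcomp(alt)
                mutant_cds = cds[:offset] + alt_coding + cds[offset + 1 :]
                mutant_protein = str(Seq(mutant_cds).translate())
                diffs = [
                    (a, i + 1, b)
                    for i, (a, b) in enumerate(zip(protein, mutant_protein))
                    if a != b
                ]
                if not diffs:
                    assert effect.category == "synonymous"
                else:
                    assert effect.category == "nonsynonymous"
                    assert effect.aa_change == diffs[0]


class TestReplacementScoring:
    def test_identity_is_conservative(self):
        assert classify_replacement("M", "M") == "conservative"

    @pytest.mark.parametrize(
        "pair,expected",
        [(("M", "K"), "nonconservative"), (("I", "L"), "conservative")],
    )
    def test_against_blosum62_oracle(self, pair, expected):
        scorer = SubstitutionScorer.default()
        score = scorer.matrix[pair[0], pair[1]]
        assert classify_replacement(*pair) == expected
        assert (score < 0) == (expected == "nonconservative")

    def test_symmetry_over_all_pairs(self):
        scorer = SubstitutionScorer.default()
        for a in "ACDEFGHIKLMNPQRSTVWY":
            for b in "ACDEFGHIKLMNPQRSTVWY":
                assert classify_replacement(a, b, scorer) == classify_replacement(
                    b, a, scorer
                )

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(UsageError):
            classify_replacement("M", "B")


class TestRanking:
    def test_category_order_and_tiebreak(self):
        def cand(pos, category, call="n/a", aa=None):
            effect = VariantEffect(category, aa, call)
            return AnnotatedSnp(snp("chr1", pos, "A", "T"), effect)

        mixed = [
            cand(40, "noncoding"),
            cand(30, "synonymous"),
            cand(100, "nonsynonymous", "nonconservative", ("M", 1, "K")),
            cand(20, "nonsynonymous", "conservative", ("I", 1, "L")),
            cand(50, "nonsynonymous", "nonconservative", ("W", 1, "G")),
        ]
        ranked = rank_candidates(mixed)
        assert [c.record.position for c in ranked] == [50, 100, 20, 30, 40]


class TestOffTargetScan:
    def _random_genome(self, rng, length=10_000):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        return seq

    def test_planted_copy_detected(self):
        rng = np.random.default_rng(21)
        seq = self._random_genome(rng)
        start, end = 2001, 2328  # a 328 bp fragment
        fragment = seq[start - 1 : end]
        planted = fragment[50:75]  # 25 bp copy elsewhere
        seq2 = seq[:6000] + planted + seq[6000 + len(planted):]
        genome = GenomeModel([("chr1", seq2)], [])
        fragment = seq2[start - 1 : end]
        result = off_target_scan(fragment, genome, ("chr1", start, end))
        assert result.longest_match >= 25
        assert not result.passes

    def test_unique_fragment_passes_threshold(self):
        rng = np.random.default_rng(22)
        seq = self._random_genome(rng)
        genome = GenomeModel([("chr1", seq)], [])
        fragment = seq[1000:1328]
        result = off_target_scan(fragment, genome, ("chr1", 1001, 1328))
        assert result.longest_match <= 16
        assert result.passes

    def test_whole_chromosome_fragment_matches_nothing(self):
        seq = "ACGTACGTACGTACGTACGT"
        genome = GenomeModel([("chr1", seq)], [])
        result = off_target_scan(seq, genome, ("chr1", 1, len(seq)))
        assert result.longest_match == 0

    def test_fragment_must_occur_at_source_locus(self):
        genome = GenomeModel([("chr1", "ACGTACGTACGT")], [])
        with pytest.raises(UsageError):
            off_target_scan("TTTTT", genome, ("chr1", 1, 5))

    def test_agrees_with_quadratic_lcs_oracle(self):
        rng = np.random.default_rng(23)
        seq = self._random_genome(rng, 4000)
        start, end = 501, 700
        genome = GenomeModel([("chr1", seq)], [])
        fragment = seq[start - 1 : end]
        result = off_target_scan(fragment, genome, ("chr1", start, end))

        masked = seq[: start - 1] + "N" * (end - start + 1) + seq[end:]
        best = 0
        for query in (fragment, revcomp(fragment)):
            prev = [0] * (len(query) + 1)
            for i in range(1, len(masked) + 1):
                cur = [0] * (len(query) + 1)
                ci = masked[i - 1]
                for j in range(1, len(query) + 1):
                    if ci != "N" and ci == query[j - 1]:
                        cur[j] = prev[j - 1] + 1
                        best = max(best, cur[j])
                prev = cur
        assert result.longest_match == best
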