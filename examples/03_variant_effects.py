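"""Classify a candidate SNP down to its amino-acid replacement.

A crafted gene carries methionine at codon 371; a T→A change at the
codon's second base produces M371K — a nonconservative replacement
(BLOSUM62 score M/K = -1 < 0), the kind of drastic change that singles
out a loss-of-function candidate among surviving SNPs.
"""

from bsakit import GeneModel, GenomeModel, SnpRecord, annotate_variant

n_codons = 375
codons = ["ATG"] + ["GGA"] * (n_codons - 2) + ["TAA"]
codons[370] = "ATG"  # codon 371
cds = "".join(codons)
genome = GenomeModel(
    [("chr1", cds)],
    [GeneModel("FNS-like", "chr1", "+", ((1, len(cds)),), is_causal_gene=True)],
)

position = 370 * 3 + 2  # second base of codon 371
snp = SnpRecord("chr1", position, "T", "A", alt_count=96, depth=98)
effect = annotate_variant(snp, genome)
print(f"SNP chr1:{position} T>A in {effect.gene_id}")
print(f"  category     : {effect.category}")
print(f"  aa change    : {effect.aa_change_str()}")
print(f"  conservation : {effect.conservation_call}")
# 'nonsynonymous / M371K / nonconservative' — a strong causal candidate.
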