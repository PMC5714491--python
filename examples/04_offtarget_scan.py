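"""Check an RNAi fragment for off-target matches before cloning.

An RNAi trigger should share no perfect contiguous block longer than
16 bp with any genomic region outside its source gene, or it risks
silencing unintended transcripts.  Here we cut a 328 bp fragment from
the causal gene's second exon of a simulated genome and scan both
strands of the rest of the genome for the longest exact match.
"""

from bsakit import SimParams, off_target_scan, simulate_genome

params = SimParams(seed=4)
genome = simulate_genome(params)
gene = genome.causal_gene
exon2 = sorted(gene.cds_intervals)[1]
start = exon2[0]
end = min(start + 327, exon2[1])  # a 328 bp trigger
fragment = genome.fetch(gene.chromosome, start, end)

result = off_target_scan(fragment, genome, (gene.chromosome, start, end))
print(f"fragment: {gene.chromosome}:{start}-{end} ({len(fragment)} bp) "
      f"from {gene.id} exon 2")
print(f"longest off-target exact match: {result.longest_match} bp "
      f"(threshold {result.threshold} bp)")
print("verdict:", "safe to use" if result.passes else "redesign the fragment")
# In a 100 kb random genome the longest chance match is ~12-16 bp, so a
# unique fragment passes; a fragment overlapping a repeat would not.
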