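# Methods

This note documents the models, parameter choices, and numerical
conventions behind `bsakit`, and what the synthetic-data generator does
and does not capture.

## The mapping model

A single biallelic causal locus with a recessive-visible phenotype
(here with an overdominant twist: +/+ light, +/− dark, −/− very pale;
phenotype is a deterministic function of causal genotype). An F2 from
mutant × progenitor segregates 1:2:1. Pooling n_pool phenotype-selected
homozygotes and sequencing gives, for a marker at recombination
fraction r from the causal locus, a pooled mutant-allele frequency with
expectation 1 − r: each selected individual's two gametes carry the
mutant causal allele, and each carries the mutant marker allele unless
a crossover separated them (probability r). The frequency filter at
0.95 therefore retains approximately the r < 0.05 linkage
neighbourhood plus the causal SNP itself.

### Filter semantics

* Frequency: strictly greater than `min_frequency` (default 0.95).
* Depth: keep records with depth ≤ `max_depth` (default 200). The two
  natural phrasings of a 200× cutoff ("keep < 200" vs "discard > 200")
  disagree only at exactly 200; we resolve in favour of keeping, since
  the discard rule is the operational statement. Both thresholds are
  configurable.
* Subtraction matches records by (chromosome, position, ref, alt) by
  default (`position_and_allele`): two EMS lines can mutate the same
  position differently, and only identical calls should cancel.
  `position_only` is available for compatibility with cruder callers.
* Other-line profiles are used **unfiltered** for subtraction: any call
  of the same key in another line removes the focal record. This is
  the conservative reading of "unique to the focal line" — artifacts
  need not reproduce their frequency across experiments.
* The final candidate set is order-independent in the other profiles
  (set algebra); only the per-stage audit counts depend on order.
  Candidate ranking breaks ties by genomic coordinate for
  reproducibility.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes,
at desk scale. Defaults (all in `SimParams`):

| parameter | default | meaning / rationale |
|---|---|---|
| `genome_length` | 100 kb (2 chromosomes) | desk-scale stand-in for a plant genome; large enough that unlinked SNPs dominate |
| `n_genes`, `cds_length` | 4 genes × 1200 bp CDS | one causal gene; CDSs split into 2 exons at non-codon-aligned boundaries to exercise phase handling |
| `repeat_fraction` | 0.10 | annotated repeat intervals, the preferred home of artifact SNPs |
| `n_induced_snps` | 50 per line | EMS load visible to the caller |
| `ems_transition_fraction` | 0.99 | canonical EMS chemistry: alkylation of guanine drives G:C→A:T transitions almost exclusively |
| `n_f2` | 455 | F2 family size |
| `pool_size` | 96 | selected very-pale homozygotes per pool |
| `mean_depth` | 100× | pooled sequencing coverage |
| `depth_dispersion` | 20 | negative-binomial shape k; var = μ + μ²/k = 6× Poisson at μ=100. Chosen so single-copy coverage is clearly overdispersed yet its >200× tail is negligible: in real short-read data the >200× pile-ups come from collapsed repeats and assembly errors, which are modeled separately by the artifact injector rather than by the single-copy noise model |
| `base_error_rate` | 0.001 | symmetric per-read allele flip |
| `n_lines` | 5 | one focal + four unrelated mutant lines |
| `n_artifact_snps` | 100 | shared across all profiles |
| `artifact_frequency_range` | (0.96, 1.0) | artifacts are *high-frequency* calls — that is what makes them dangerous |
| `artifact_highdepth_fraction` | 0.30 | fraction of artifacts given depth above the 200× cutoff (collapsed repeats) |
| `morgans_per_chromosome` | 1.0 | Haldane map r = ½(1 − e^(−2d)) for same-chromosome markers; r = 0.5 across chromosomes |

Depth model: the caller's depth distribution is not observable from a
finished study; negative binomial is the standard overdispersed choice
and is flagged as an assumption.

The causal SNP is required to be a nonsynonymous, *nonconservative*
replacement with standard amino acids on both sides (preferring a
G:C→A:T transition), since drastic replacements at conserved sites are
the alleles this class of screen recovers. Background mutations avoid
the causal gene's CDS: on a real-size genome the chance of a second hit
inside the causal gene is negligible, and a 100 kb toy genome would
otherwise grossly overstate it.

Artifact injection gives every profile identical (chrom, pos, ref, alt)
records, with per-profile frequencies and depths; the high-depth status
of an artifact is a per-artifact property (a collapsed repeat piles up
reads in every experiment). Positions fall in annotated repeat
intervals with probability 0.8.

`simulate_scenario` spawns all child seeds from a single root seed
(`numpy.random.SeedSequence`), so every object is bit-reproducible. A
cohort that happens to contain fewer than `pool_size` homozygotes (a
few-percent event at n=455) is redrawn — the analog of growing the F2
until enough segregants flower.

**What the generator does not capture:** read-level errors and mapping
(it emits site-level counts directly), EMS mutation clustering,
chromosome-scale recombination maps or interference, segregation
distortion, and caller-specific artifacts beyond the shared-SNP model.
Passing tests therefore demonstrate the correctness of the filtering
logic and its statistical assumptions, not robustness to every failure
mode of a real alignment pipeline.

## Variant annotation

Coordinates are 1-based inclusive (GFF3 convention); codon 1 is the
start codon for either strand. The affected codon is reconstructed
from the ordered CDS intervals respecting strand and phase and
translated with the standard genetic code (biopython). Replacement
severity uses BLOSUM62 with threshold 0: score < 0 ⇒ nonconservative
(M/K = −1 is nonconservative; I/L = +2 conservative). This is a stated
proxy for "drastic replacement" judged from alignments by eye;
cross-species conservation of the *site* is out of scope. Stop gain or
loss is treated as nonconservative. Splice sites, UTRs, indels and
multi-nucleotide variants are out of scope (EMS induces point
mutations).

## Off-target scan

Exact-match only: the reported quantity is the longest exact contiguous
match between the fragment (either strand) and the genome with the
source locus masked out, found by binary search over match length with
substring sets (verified against a quadratic longest-common-substring
oracle in the tests). The default pass threshold is 16 bp. An
alignment-tool search with an E-value cutoff would admit gapped or
imperfect matches; exact longest-common-substring is the verifiable
core of a "perfect contiguous match" criterion.

## MS identification arithmetic

All primary m/z values are nominal (integer atomic masses C=12, H=1,
O=16) because unit-resolution instruments report integers; a
monoisotopic mode exists for high-resolution inputs. [M−H]⁻ = nominal
mass − 1. Neutral-loss residues (dehydrated): glucuronyl 176, hexosyl
162, deoxyhexosyl 146, pentosyl 132, malonyl 86.

The 1,3 retro-Diels-Alder cleavage of the flavanone C ring (across
O1–C2 and C3–C4) is encoded as an explicit atom partition of the
naringenin skeleton C15H12O5: A side (ring A + O1 + C4 carbonyl) =
C7H4O4, B side (ring B + C2 + C3) = C8H8O. Extra hydroxylation of an
aglycone relative to the skeleton is assigned to the B side, where it
varies among common flavanones (eriodictyol = naringenin + one B-ring
hydroxyl ⇒ B-side neutral 136 instead of 120; the A side stays at
151). Element-wise complementarity A + B = parent holds by
construction and is asserted property-style. Formula arithmetic rather
than a bond graph keeps every value checkable by hand.

`annotate_spectrum` matches each peak, in precedence order, to (i) a
library species' molecular ion — either [M−H]⁻ or the neutral nominal
mass, since unit-resolution spectra are reported both ways (a flavanone
aglycone peak printed at 272 is the neutral mass; its deprotonated ion
is 271); (ii) the species minus combinations of up to two residues;
(iii) RDA fragments of the aglycone. Peaks that no rule explains are
reported unassigned rather than forced — several glycosylated-flavanone
precursor masses (e.g. a 247 Da adduct) do not decompose into single
standard residues and are intentionally left so.

A flavanone-family spectrum is reported to give the same 151/119 RDA
pair for the eriodictyol-derived precursor as for naringenin, although
eriodictyol's extra B-ring hydroxyl should shift the B fragment to
135; the scheme here reproduces the naringenin arithmetic and computes
the shifted eriodictyol fragment, leaving that discrepancy visible
rather than resolving it.

## qPCR and segregation

Relative expression is exactly E_ref^CP(ref) / E_target^CP(target).
Efficiency comes from the standard-curve method: least-squares slope m
of CP vs log10(relative concentration), E = 10^(−1/m); a flat series is
a fit error. Replicate CPs are averaged before the formula; the SD of
the ratio is propagated first-order (delta method) — a documented
choice, since averaging before vs after the formula is not uniquely
determined by the formula itself. Efficiencies are constrained to
(1, 2.2].

Knockdown = 1 − (transgenic relative expression)/(wild-type relative
expression); invariant to common rescaling, may be negative.

Segregation uses the Pearson goodness-of-fit χ² against an integer
ratio with df = classes − 1 and expected counts proportional to the
*observed total*. For the worked F2 example (112:235:98 against 1:2:1,
total 445 scored) this gives χ² = 2.285, p = 0.319: the single-locus
model stands. Note the family contained 455 individuals but only 445
scored counts are reported; the test must use the scored total. No
multiple-testing correction is applied (single-test setting).

## Problem sizes

The shipped defaults (100 kb genome, 5 lines, 455 F2, pools of 96,
100× depth, 500-replicate frequency summaries) run the whole suite in
well under a minute on one core; they were chosen as the smallest
sizes at which every stage of the pipeline — including the depth
filter's interaction with artifact coverage and the linkage structure
around the causal gene — is genuinely exercised.

## Known limitations

* The candidate pipeline reproduces the *method*, not any particular
  study's SNP counts, which depend on raw reads and a specific
  aligner/caller.
* Conservation scoring is substitution-matrix-based; it does not
  consult cross-species alignments.
* The color-intensity dose-response helper (`color_intensity`) is an
  explicitly invented toy for demos: production ∝ 1/(1+κd), retention ∝
  (ε+d)/(ε+d+K), defaults κ=4, ε=0.02, K=0.2 chosen to give the
  overdominant ordering intensity(0.5) > intensity(1) > intensity(0).
  No kinetic claim is attached to it.
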