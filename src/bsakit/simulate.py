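"""Synthetic genomes, EMS mutant lines, F2 cohorts, and pooled sequencing.

This module generates data with the statistical structure that the
bulk-segregant filtering pipeline assumes, so the whole analysis is
testable end to end without any sequencing download:

* a random reference genome with protein-coding gene models (one of
  which is designated the causal locus) and annotated repeat intervals;
* EMS mutant lines: a handful of induced point mutations per line,
  dominated by G:C→A:T transitions (the canonical EMS spectrum), with
  exactly one nonsynonymous causal SNP inside the causal gene;
* F2 cohorts segregating 1:2:1 at the causal locus, each induced SNP
  co-inherited with the causal allele per gamete with probability 1−r
  (r from a Haldane map on the same chromosome, 0.5 otherwise);
* pooled sequencing of phenotype-selected individuals: per-site depth
  is negative-binomial, alt read counts binomial around the pool allele
  frequency perturbed by a symmetric base-error rate;
* shared artifact SNPs — high-frequency calls injected at identical
  positions into every line's profile, preferentially inside repeats,
  a fraction with excessive depth — mimicking reference assembly errors
  and collapsed repeats that recur across independent mutant profiles.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .bsa import SnpProfile, SnpRecord
from .errors import ParameterError, SamplingError, SimulationError
from .genome import GeneModel, GenomeModel, revcomp

PHENOTYPES = {0: "light", 1: "dark", 2: "very_pale"}
GENOTYPE_LABELS = {0: "+/+", 1: "+/-", 2: "-/-"}

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the simulated mapping experiment.

    Defaults mirror the experimental design being emulated: an F2 of
    455 individuals, a pool of 96 phenotype-selected homozygotes, five
    mutant lines compared against each other, and an EMS spectrum of
    99% G:C→A:T transitions.  Genome size and depth are desk-scale
    stand-ins (100 kb, mean 100×) chosen so every pipeline stage is
    exercised, including the >200× depth filter.
    """

    genome_length: int = 100_000
    n_chromosomes: int = 2
    n_genes: int = 4
    cds_length: int = 1200  # per gene, includes the stop codon
    n_exons: int = 2
    intron_length: int = 150
    repeat_fraction: float = 0.10
    n_induced_snps: int = 50
    ems_transition_fraction: float = 0.99
    n_f2: int = 455
    morgans_per_chromosome: float = 1.0
    pool_size: int = 96
    mean_depth: float = 100.0
    depth_dispersion: float = 20.0
    base_error_rate: float = 0.001
    n_lines: int = 5
    n_artifact_snps: int = 100
    artifact_frequency_range: tuple[float, float] = (0.96, 1.0)
    artifact_highdepth_fraction: float = 0.30
    artifact_repeat_fraction: float = 0.80
    depth_filter_cutoff: int = 200
    seed: int = 0

    def __post_init__(self):
        positive = [
            "genome_length", "n_chromosomes", "n_genes", "cds_length",
            "n_exons", "n_f2", "pool_size", "mean_depth", "depth_dispersion",
            "n_lines", "depth_filter_cutoff",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        probabilities = [
            "ems_transition_fraction", "base_error_rate", "repeat_fraction",
            "artifact_highdepth_fraction", "artifact_repeat_fraction",
        ]
        for name in probabilities:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {value}")
        for name in ("n_induced_snps", "n_artifact_snps", "intron_length"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.cds_length % 3 != 0 or self.cds_length < 9:
            raise ParameterError("cds_length must be a multiple of 3 and >= 9")
        lo, hi = self.artifact_frequency_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ParameterError(
                "artifact_frequency_range must be an interval within [0, 1]"
            )
        if self.morgans_per_chromosome < 0:
            raise ParameterError("morgans_per_chromosome must be non-negative")
        if self.genome_length < 3 * self.n_genes * self.cds_length:
            raise ParameterError(
                "genome_length must be at least 3x the total requested CDS "
                f"length ({3 * self.n_genes * self.cds_length})"
            )


Snv = tuple[str, int, str, str]  # (chromosome, position, ref, alt)


@dataclass(frozen=True)
class MutantLine:
    """One EMS-mutagenized line: its induced SNPs and the causal one."""

    line_id: str
    induced_snps: tuple[Snv, ...]
    causal_snp: Snv

    def __post_init__(self):
        if self.causal_snp not in self.induced_snps:
            raise ParameterError("causal_snp must be one of induced_snps")
        positions = [(c, p) for c, p, _, _ in self.induced_snps]
        if len(set(positions)) != len(positions):
            raise ParameterError("induced SNP positions must be unique")


@dataclass
class F2Cohort:
    """Simulated F2 individuals with genotypes, markers, and phenotypes.

    ``causal_dosage`` is the number of mutant alleles (0/1/2) at the
    causal locus per individual; ``marker_dosage`` the same for every
    induced SNP (column order = ``snps``).  Phenotype is a deterministic
    function of causal genotype: +/+ → light, +/− → dark (the
    overdominant heterozygote), −/− → very_pale.
    """

    snps: tuple[Snv, ...]
    r_values: np.ndarray  # recombination fraction of each SNP vs the causal locus
    causal_index: int
    causal_dosage: np.ndarray  # shape (n,)
    marker_dosage: np.ndarray  # shape (n, len(snps))
    phenotypes: np.ndarray  # shape (n,), str labels

    @property
    def n(self) -> int:
        return len(self.causal_dosage)

    def genotype_labels(self) -> list[str]:
        return [GENOTYPE_LABELS[int(d)] for d in self.causal_dosage]

    def individuals(self) -> Iterable[tuple[str, np.ndarray, str]]:
        for i in range(self.n):
            yield (
                GENOTYPE_LABELS[int(self.causal_dosage[i])],
                self.marker_dosage[i],
                str(self.phenotypes[i]),
            )


def _rng(params: SimParams, seed=None) -> np.random.Generator:
    return np.random.default_rng(params.seed if seed is None else seed)


def simulate_genome(params: SimParams, seed=None) -> GenomeModel:
    """Random reference genome with gene models and repeat intervals.

    Genes are spread evenly across chromosomes with random strand; the
    first gene is the causal locus.  CDS sequences start with ATG, use
    only sense codons internally, and end with a stop, split across
    exons at arbitrary (not codon-aligned) boundaries so annotation
    must handle phase.  Repeat intervals are annotation only (the
    artifact injector targets them); their sequence is not duplicated.
    """
    rng = _rng(params, seed)
    chrom_len = params.genome_length // params.n_chromosomes
    footprint = params.cds_length + (params.n_exons - 1) * params.intron_length
    genes_per_chrom = [
        len(range(c, params.n_genes, params.n_chromosomes))
        for c in range(params.n_chromosomes)
    ]
    max_per_chrom = max(genes_per_chrom)
    if max_per_chrom and chrom_len // max_per_chrom < footprint + 200:
        raise ParameterError(
            "genome_length too small for the requested gene footprints "
            f"(need >= {(footprint + 200) * max_per_chrom} bp per chromosome)"
        )

    chromosomes: list[tuple[str, list[str]]] = []
    for c in range(params.n_chromosomes):
        seq = rng.choice(list("ACGT"), size=chrom_len)
        chromosomes.append((f"chr{c + 1}", list(seq)))

    genes: list[GeneModel] = []
    for gi in range(params.n_genes):
        ci = gi % params.n_chromosomes
        name, seq = chromosomes[ci]
        slot_index = gi // params.n_chromosomes
        slot = chrom_len // genes_per_chrom[ci]
        margin = slot - footprint - 100
        region_start = slot_index * slot + 50 + int(rng.integers(0, max(margin, 1)))

        n_codons = params.cds_length // 3
        codons = ["ATG"] + [
            _SENSE_CODONS[i]
            for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
        ] + ["TAA"]
        cds = "".join(codons)
        cuts = sorted(
            rng.choice(
                np.arange(1, params.cds_length), size=params.n_exons - 1,
                replace=False,
            )
        ) if params.n_exons > 1 else []
        bounds = [0] + [int(c) for c in cuts] + [params.cds_length]
        exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]

        region_parts = []
        exon_offsets = []  # (start, end) 0-based within region, coding order
        offset = 0
        for i, exon in enumerate(exon_seqs):
            if i > 0:
                intron = "".join(rng.choice(list("ACGT"), size=params.intron_length))
                region_parts.append(intron)
                offset += params.intron_length
            exon_offsets.append((offset, offset + len(exon) - 1))
            region_parts.append(exon)
            offset += len(exon)
        region = "".join(region_parts)

        strand = "+" if rng.random() < 0.5 else "-"
        placed = region if strand == "+" else revcomp(region)
        seq[region_start : region_start + len(region)] = list(placed)

        intervals = []
        for s, e in exon_offsets:
            if strand == "+":
                intervals.append((region_start + s + 1, region_start + e + 1))
            else:
                last = len(region) - 1
                intervals.append(
                    (region_start + (last - e) + 1, region_start + (last - s) + 1)
                )
        genes.append(
            GeneModel(
                id=f"gene{gi + 1}",
                chromosome=name,
                strand=strand,
                cds_intervals=tuple(intervals),
                is_causal_gene=(gi == 0),
            )
        )

    repeats: list[tuple[str, int, int]] = []
    target_repeat_bp = int(params.repeat_fraction * chrom_len)
    gene_spans = {
        name: [g.span for g in genes if g.chromosome == name]
        for name, _ in chromosomes
    }
    for name, seq in chromosomes:
        placed_bp = 0
        attempts = 0
        while placed_bp < target_repeat_bp and attempts < 200:
            attempts += 1
            size = int(rng.integers(300, 1200))
            start = int(rng.integers(1, len(seq) - size))
            end = start + size - 1
            if any(s <= end and start <= e for s, e in gene_spans[name]):
                continue
            if any(
                c == name and s <= end and start <= e for c, s, e in repeats
            ):
                continue
            repeats.append((name, start, end))
            placed_bp += size

    return GenomeModel(
        chromosomes=[(n, "".join(s)) for n, s in chromosomes],
        genes=genes,
        repeats=sorted(repeats),
    )


def _is_valid_causal(genome, gene, pos, ref, alt) -> bool:
    # The emulated mutants all carry drastic (nonconservative) amino acid
    # replacements, so the planted causal SNP is required to be one too.
    from .annotate import STANDARD_AA, annotate_variant

    snp = SnpRecord(gene.chromosome, pos, ref, alt, 1, 1)
    effect = annotate_variant(snp, genome, [gene])
    return (
        effect.category == "nonsynonymous"
        and effect.conservation_call == "nonconservative"
        and effect.aa_change[0] in STANDARD_AA
        and effect.aa_change[2] in STANDARD_AA
    )


def simulate_mutant_line(
    genome: GenomeModel,
    params: SimParams,
    seed=None,
    line_id: str = "line1",
) -> MutantLine:
    """One EMS line: a causal nonsynonymous SNP plus background mutations.

    The causal SNP is a G:C→A:T transition inside the causal gene's CDS
    whenever one yields a standard-amino-acid replacement (EMS almost
    always offers one); the remaining ``n_induced_snps - 1`` mutations
    are placed uniformly over the genome, each a transition at a G/C
    site with probability ``ems_transition_fraction`` and a random
    substitution otherwise.
    """
    rng = _rng(params, seed)
    gene = genome.causal_gene
    chrom_seq = genome.sequence(gene.chromosome)

    cds_positions = [
        p for s, e in gene.cds_intervals for p in range(s, e + 1)
    ]
    rng.shuffle(cds_positions)
    transition = {"G": "A", "C": "T"}
    causal = None
    # pass 1: EMS transitions; pass 2: any substitution
    for ems_only in (True, False):
        for pos in cds_positions:
            ref = chrom_seq[pos - 1]
            if ems_only:
                alts = [transition[ref]] if ref in transition else []
            else:
                alts = [b for b in "ACGT" if b != ref]
            for alt in alts:
                if _is_valid_causal(genome, gene, pos, ref, alt):
                    causal = (gene.chromosome, pos, ref, alt)
                    break
            if causal:
                break
        if causal:
            break
    if causal is None:
        raise SimulationError(
            f"no nonsynonymous site available in causal gene {gene.id}"
        )

    snvs: list[Snv] = [causal]
    used = {(causal[0], causal[1])}
    # Background mutations avoid the causal CDS: at real genome scale a
    # second EMS hit inside the causal gene is vanishingly unlikely, and
    # the desk-scale genome would otherwise overstate that probability.
    causal_cds = {
        (gene.chromosome, p)
        for s, e in gene.cds_intervals
        for p in range(s, e + 1)
    }
    chrom_names = genome.chromosome_names
    while len(snvs) < params.n_induced_snps:
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        seq = genome.sequence(chrom)
        pos = int(rng.integers(1, len(seq) + 1))
        ref = seq[pos - 1]
        if (chrom, pos) in used or (chrom, pos) in causal_cds:
            continue
        if rng.random() < params.ems_transition_fraction:
            if ref not in transition:
                continue  # EMS transitions hit G:C pairs only
            alt = transition[ref]
        else:
            choices = [b for b in "ACGT" if b != ref]
            alt = choices[int(rng.integers(0, 3))]
        used.add((chrom, pos))
        snvs.append((chrom, pos, ref, alt))

    return MutantLine(line_id=line_id, induced_snps=tuple(snvs), causal_snp=causal)


def recombination_fractions(
    genome: GenomeModel, line: MutantLine, params: SimParams
) -> np.ndarray:
    """Per-SNP recombination fraction with the causal locus.

    Same chromosome: Haldane map, r = 0.5(1 - exp(-2d)) with d the
    physical distance scaled by ``morgans_per_chromosome``; different
    chromosome: r = 0.5 (free recombination).  The causal SNP itself
    has r = 0.
    """
    c_chrom, c_pos, _, _ = line.causal_snp
    chrom_len = {n: genome.length(n) for n in genome.chromosome_names}
    rs = []
    for chrom, pos, _, _ in line.induced_snps:
        if chrom != c_chrom:
            rs.append(0.5)
        else:
            d = abs(pos - c_pos) / chrom_len[chrom] * params.morgans_per_chromosome
            rs.append(0.5 * (1.0 - np.exp(-2.0 * d)))
    return np.asarray(rs)


def simulate_f2(
    genome: GenomeModel,
    line: MutantLine,
    params: SimParams,
    seed=None,
    r_values: Optional[np.ndarray] = None,
) -> F2Cohort:
    """Draw an F2 cohort from a mutant × wild-type cross.

    Each individual receives two independent gametes; each gamete
    carries the mutant causal allele with probability 1/2 and each
    marker co-segregates with the causal allele unless a recombination
    event (probability r) separates them.  ``r_values`` overrides the
    map-derived fractions (useful for closed-form checks).
    """
    rng = _rng(params, seed)
    snps = line.induced_snps
    rs = (
        np.asarray(r_values, dtype=float)
        if r_values is not None
        else recombination_fractions(genome, line, params)
    )
    if len(rs) != len(snps):
        raise ParameterError("r_values must have one entry per induced SNP")
    if np.any((rs < 0) | (rs > 0.5)):
        raise ParameterError("recombination fractions must lie in [0, 0.5]")
    causal_index = snps.index(line.causal_snp)

    n = params.n_f2
    causal_gamete = rng.random((n, 2)) < 0.5  # True = mutant allele
    flips = rng.random((n, 2, len(snps))) < rs[None, None, :]
    marker_gamete = causal_gamete[:, :, None] ^ flips
    causal_dosage = causal_gamete.sum(axis=1).astype(np.int64)
    marker_dosage = marker_gamete.sum(axis=1).astype(np.int64)
    phenotypes = np.array([PHENOTYPES[int(d)] for d in causal_dosage])
    return F2Cohort(
        snps=snps,
        r_values=rs,
        causal_index=causal_index,
        causal_dosage=causal_dosage,
        marker_dosage=marker_dosage,
        phenotypes=phenotypes,
    )


def pool_and_sequence(
    cohort: F2Cohort,
    select_phenotype: str,
    line: MutantLine,
    params: SimParams,
    seed=None,
) -> SnpProfile:
    """Pool phenotype-selected individuals and sequence to finite depth.

    ``pool_size`` individuals of the selected class contribute equally;
    per SNP the sequencing depth is negative-binomial (mean
    ``mean_depth``, dispersion ``depth_dispersion``) and the alt read
    count binomial with success probability equal to the pool allele
    frequency perturbed by the symmetric base-error rate.  Sites that
    happen to draw depth 0 are omitted (they were not observed).
    """
    rng = _rng(params, seed)
    idx = np.flatnonzero(cohort.phenotypes == select_phenotype)
    if len(idx) < params.pool_size:
        raise SamplingError(
            f"need {params.pool_size} {select_phenotype!r} individuals, "
            f"only {len(idx)} available (short by {params.pool_size - len(idx)})"
        )
    chosen = rng.choice(idx, size=params.pool_size, replace=False)
    p_pool = cohort.marker_dosage[chosen].sum(axis=0) / (2 * params.pool_size)
    e = params.base_error_rate
    p_obs = p_pool * (1 - e) + (1 - p_pool) * e

    k = params.depth_dispersion
    depth = rng.negative_binomial(k, k / (k + params.mean_depth), size=len(p_obs))
    alt = rng.binomial(depth, p_obs)

    profile = SnpProfile(line.line_id)
    for (chrom, pos, ref, altbase), d, a in zip(cohort.snps, depth, alt):
        if d == 0:
            continue
        profile.add(SnpRecord(chrom, pos, ref, altbase, int(a), int(d)))
    return profile


def inject_artifacts(
    profiles: list[SnpProfile],
    genome: GenomeModel,
    params: SimParams,
    seed=None,
) -> tuple[list[SnpProfile], list[Snv]]:
    """Add shared artifact SNPs to every profile; returns (profiles, artifacts).

    Artifacts model reference assembly errors and collapsed repeats:
    identical (chrom, pos, ref, alt) in all profiles, frequencies drawn
    from ``artifact_frequency_range``, positions preferentially inside
    repeat intervals, and a fixed per-artifact fraction given depth
    above the depth-filter cutoff (consistently across profiles, as a
    collapsed repeat piles up reads in every experiment).
    """
    if len(profiles) < 2:
        raise ParameterError("inject_artifacts requires at least 2 profiles")
    rng = _rng(params, seed)
    existing = {
        (r.chromosome, r.position) for p in profiles for r in p
    }
    repeat_positions = [
        (c, p) for c, s, e in genome.repeats for p in range(s, e + 1)
    ]
    artifacts: list[Snv] = []
    highdepth_flags: list[bool] = []
    guard = 0
    while len(artifacts) < params.n_artifact_snps:
        guard += 1
        if guard > 100 * max(params.n_artifact_snps, 1):
            raise SimulationError("could not place requested artifact SNPs")
        if repeat_positions and rng.random() < params.artifact_repeat_fraction:
            chrom, pos = repeat_positions[
                int(rng.integers(0, len(repeat_positions)))
            ]
        else:
            chrom = genome.chromosome_names[
                int(rng.integers(0, len(genome.chromosome_names)))
            ]
            pos = int(rng.integers(1, genome.length(chrom) + 1))
        if (chrom, pos) in existing:
            continue
        existing.add((chrom, pos))
        ref = genome.base(chrom, pos)
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
        artifacts.append((chrom, pos, ref, alt))
        highdepth_flags.append(bool(rng.random() < params.artifact_highdepth_fraction))

    lo, hi = params.artifact_frequency_range
    cutoff = params.depth_filter_cutoff
    out: list[SnpProfile] = []
    for profile in profiles:
        new = SnpProfile(profile.line_id, profile.records)
        for (chrom, pos, ref, alt), high in zip(artifacts, highdepth_flags):
            freq = float(rng.uniform(lo, hi))
            if high:
                depth = int(rng.integers(cutoff + 1, 3 * cutoff + 1))
            else:
                depth = int(
                    np.clip(
                        rng.negative_binomial(
                            params.depth_dispersion,
                            params.depth_dispersion
                            / (params.depth_dispersion + params.mean_depth),
                        ),
                        20,
                        cutoff,
                    )
                )
            alt_count = int(np.clip(round(freq * depth), 0, depth))
            new.add(SnpRecord(chrom, pos, ref, alt, alt_count, depth))
        out.append(new)
    return out, artifacts


@dataclass
class Scenario:
    """A complete simulated mapping experiment (focal line = lines[0])."""

    params: SimParams
    genome: GenomeModel
    lines: list[MutantLine]
    cohorts: list[F2Cohort]
    profiles: list[SnpProfile]  # artifact-injected, same order as lines
    artifacts: list[Snv]

    @property
    def focal_line(self) -> MutantLine:
        return self.lines[0]

    @property
    def focal_profile(self) -> SnpProfile:
        return self.profiles[0]

    @property
    def other_profiles(self) -> list[SnpProfile]:
        return self.profiles[1:]


def simulate_scenario(params: SimParams) -> Scenario:
    """Simulate the full study: one genome, ``n_lines`` mutant lines,
    an F2 and a very-pale pool per line, shared artifacts injected.

    Child seeds for every stochastic stage are spawned from
    ``params.seed``, so the scenario is bit-reproducible.  If a cohort
    happens to contain fewer very-pale individuals than the pool needs
    (a few-percent event at n_f2=455), a fresh cohort is drawn for that
    line — the analog of growing the F2 until enough homozygotes are in
    hand.
    """
    root = np.random.SeedSequence(params.seed)
    genome = simulate_genome(params, seed=root.spawn(1)[0])
    lines, cohorts, profiles = [], [], []
    for i in range(params.n_lines):
        line = simulate_mutant_line(
            genome, params, seed=root.spawn(1)[0], line_id=f"ML{i + 1:03d}"
        )
        for _ in range(50):
            cohort_seed, pool_seed = root.spawn(2)
            cohort = simulate_f2(genome, line, params, seed=cohort_seed)
            try:
                profile = pool_and_sequence(
                    cohort, "very_pale", line, params, seed=pool_seed
                )
            except SamplingError:
                continue
            break
        else:  # pragma: no cover - astronomically unlikely
            raise SimulationError(
                f"could not obtain {params.pool_size} very_pale individuals "
                f"for line {line.line_id} in 50 cohorts"
            )
        lines.append(line)
        cohorts.append(cohort)
        profiles.append(profile)
    profiles, artifacts = inject_artifacts(
        profiles, genome, params, seed=root.spawn(1)[0]
    )
    return Scenario(params, genome, lines, cohorts, profiles, artifacts)


def color_intensity(
    dosage: float, kappa: float = 4.0, eps: float = 0.02, big_k: float = 0.2
) -> float:
    """Invented toy dose-response for demos: flower color intensity as a
    function of functional-enzyme dosage d (0, 0.5, or 1).

    Anthocyanin production falls with competition, ∝ 1/(1+κd);
    retention rises with copigment supply, ∝ (ε+d)/(ε+d+K).  Default
    constants give intensity(0.5) > intensity(1) > intensity(0) — the
    overdominant ordering.  This is a pedagogical cartoon, not a model
    claimed by any kinetic analysis.
    """
    if dosage < 0:
        raise ParameterError("dosage must be non-negative")
    production = 1.0 / (1.0 + kappa * dosage)
    retention = (eps + dosage) / (eps + dosage + big_k)
    return production * retention
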