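"""Generator behaviour: determinism, Mendelian structure, linkage, artifacts."""

import dataclasses

import numpy as np
import pytest

from bsakit import (
    FilterConfig,
    SimParams,
    color_intensity,
    filter_by_depth,
    inject_artifacts,
    pool_and_sequence,
    simulate_f2,
    simulate_genome,
    simulate_mutant_line,
    simulate_scenario,
    subtract_profiles,
)
from bsakit.annotate import annotate_variant
from bsakit.bsa import SnpRecord
from bsakit.errors import ParameterError, SamplingError


class TestGenome:
    def test_deterministic_under_fixed_seed(self, small_params):
        g1 = simulate_genome(small_params)
        g2 = simulate_genome(small_params)
        assert g1.chromosomes == g2.chromosomes
        assert g1.genes == g2.genes
        assert g1.repeats == g2.repeats

    def test_different_seeds_differ(self, small_params):
        g1 = simulate_genome(small_params, seed=1)
        g2 = simulate_genome(small_params, seed=2)
        assert g1.chromosomes != g2.chromosomes

    def test_oversized_cds_request_rejected(self):
        with pytest.raises(ParameterError):
            SimParams(genome_length=5_000, n_genes=4, cds_length=1200)

    def test_structure(self, small_genome, small_params):
        assert len(small_genome.causal_genes) == 1
        assert small_genome.repeats
        for gene in small_genome.genes:
            assert gene.cds_length == small_params.cds_length


class TestMutantLine:
    def test_single_snp_line_is_the_causal_one(self, small_genome, small_params):
        params = dataclasses.replace(small_params, n_induced_snps=1)
        line = simulate_mutant_line(small_genome, params)
        assert line.induced_snps == (line.causal_snp,)

    def test_causal_snp_is_nonsynonymous_in_causal_gene(
        self, small_genome, small_params
    ):
        line = simulate_mutant_line(small_genome, small_params)
        chrom, pos, ref, alt = line.causal_snp
        gene = small_genome.causal_gene
        assert gene.contains(pos) and gene.chromosome == chrom
        effect = annotate_variant(
            SnpRecord(chrom, pos, ref, alt, 1, 1), small_genome
        )
        assert effect.category == "nonsynonymous"

    def test_pure_ems_spectrum_forces_transitions(self, small_genome, small_params):
        params = dataclasses.replace(small_params, ems_transition_fraction=1.0)
        line = simulate_mutant_line(small_genome, params)
        for chrom, pos, ref, alt in line.induced_snps:
            if (chrom, pos, ref, alt) == line.causal_snp:
                continue
            assert (ref, alt) in (("G", "A"), ("C", "T"))

    def test_lines_rarely_collide_outside_causal_gene(
        self, small_genome, small_params
    ):
        """Background SNPs are uniform, so two lines sharing a non-causal
        position should be rare (collision expectation ~ n^2/genome)."""
        collisions = 0
        for seed in range(0, 40, 2):
            a = simulate_mutant_line(small_genome, small_params, seed=seed)
            b = simulate_mutant_line(small_genome, small_params, seed=seed + 1)
            pa = {s[:2] for s in a.induced_snps if s != a.causal_snp}
            pb = {s[:2] for s in b.induced_snps if s != b.causal_snp}
            collisions += len(pa & pb)
        assert collisions <= 3


class TestF2:
    def test_mendelian_class_frequencies(self, small_genome, small_params):
        params = dataclasses.replace(small_params, n_f2=455)
        line = simulate_mutant_line(small_genome, params)
        totals = np.zeros(3)
        n_rep = 200
        for seed in range(n_rep):
            cohort = simulate_f2(small_genome, line, params, seed=seed)
            for k in range(3):
                totals[k] += np.mean(cohort.causal_dosage == k)
        fractions = totals / n_rep
        expect = np.array([0.25, 0.5, 0.25])
        se = np.sqrt(expect * (1 - expect) / (n_rep * params.n_f2))
        assert np.all(np.abs(fractions - expect) < 3 * se)

    def test_phenotype_is_deterministic_in_genotype(self, small_genome, small_params):
        line = simulate_mutant_line(small_genome, small_params)
        cohort = simulate_f2(small_genome, line, small_params, seed=1)
        mapping = {0: "light", 1: "dark", 2: "very_pale"}
        for dosage, phenotype in zip(cohort.causal_dosage, cohort.phenotypes):
            assert phenotype == mapping[int(dosage)]

    def test_complete_linkage_marker_tracks_causal_genotype(
        self, small_genome, small_params
    ):
        line = simulate_mutant_line(small_genome, small_params)
        rs = np.zeros(len(line.induced_snps))
        cohort = simulate_f2(small_genome, line, small_params, seed=2, r_values=rs)
        assert np.array_equal(
            cohort.marker_dosage,
            np.tile(cohort.causal_dosage[:, None], (1, len(line.induced_snps))),
        )

    def test_free_recombination_marker_frequency_half_in_homozygotes(
        self, small_genome, small_params
    ):
        line = simulate_mutant_line(small_genome, small_params)
        rs = np.full(len(line.induced_snps), 0.5)
        freqs = []
        for seed in range(40):
            cohort = simulate_f2(
                small_genome, line, small_params, seed=seed, r_values=rs
            )
            mutants = cohort.causal_dosage == 2
            j = (cohort.causal_index + 1) % len(line.induced_snps)
            freqs.append(cohort.marker_dosage[mutants, j].mean() / 2)
        assert abs(np.mean(freqs) - 0.5) < 0.02


class TestPooling:
    def test_causal_frequency_exactly_one_without_error(
        self, small_genome, small_params
    ):
        params = dataclasses.replace(
            small_params, base_error_rate=0.0, pool_size=20, n_f2=200
        )
        line = simulate_mutant_line(small_genome, params)
        cohort = simulate_f2(small_genome, line, params, seed=3)
        profile = pool_and_sequence(cohort, "very_pale", line, params, seed=4)
        causal = [
            r for r in profile if (r.chromosome, r.position) == line.causal_snp[:2]
        ]
        assert causal and causal[0].frequency == 1.0

    def test_pool_frequency_matches_one_minus_r(self, small_genome, small_params):
        """Closed form: each pooled gamete carries the mutant marker
        allele with probability 1-r."""
        params = dataclasses.replace(small_params, base_error_rate=0.0)
        line = simulate_mutant_line(small_genome, params)
        m = len(line.induced_snps)
        for r in (0.0, 0.05, 0.1, 0.25, 0.5):
            rs = np.full(m, r)
            rs[line.induced_snps.index(line.causal_snp)] = 0.0
            j = (line.induced_snps.index(line.causal_snp) + 1) % m
            freqs = []
            for seed in range(60):
                cohort = simulate_f2(
                    small_genome, line, params, seed=seed, r_values=rs
                )
                try:
                    profile = pool_and_sequence(
                        cohort, "very_pale", line, params, seed=seed
                    )
                except SamplingError:
                    continue
                chrom, pos, _, _ = line.induced_snps[j]
                rec = [
                    x for x in profile if (x.chromosome, x.position) == (chrom, pos)
                ]
                if rec:
                    freqs.append(rec[0].frequency)
            freqs = np.asarray(freqs)
            expect = 1.0 - r
            if r == 0.0:
                assert np.all(freqs == 1.0)
            else:
                se = freqs.std(ddof=1) / np.sqrt(len(freqs))
                assert abs(freqs.mean() - expect) < 3 * se + 1e-9

    def test_depth_zero_sites_omitted(self, small_genome, small_params):
        params = dataclasses.replace(
            small_params, mean_depth=0.3, depth_dispersion=0.2
        )
        line = simulate_mutant_line(small_genome, params)
        cohort = simulate_f2(small_genome, line, params, seed=5)
        profile = pool_and_sequence(cohort, "very_pale", line, params, seed=6)
        assert len(profile) < len(line.induced_snps)
        assert all(r.depth > 0 for r in profile)

    def test_shortfall_raises_with_deficit(self, small_genome, small_params):
        params = dataclasses.replace(small_params, n_f2=20, pool_size=96)
        line = simulate_mutant_line(small_genome, params)
        cohort = simulate_f2(small_genome, line, params, seed=7)
        with pytest.raises(SamplingError, match="short"):
            pool_and_sequence(cohort, "very_pale", line, params, seed=8)


class TestArtifacts:
    def _profiles(self, small_genome, params, n=3):
        out = []
        for i in range(n):
            line = simulate_mutant_line(
                small_genome, params, seed=100 + i, line_id=f"m{i}"
            )
            cohort = simulate_f2(small_genome, line, params, seed=200 + i)
            out.append(
                pool_and_sequence(cohort, "very_pale", line, params, seed=300 + i)
            )
        return out

    def test_zero_artifacts_is_identity(self, small_genome, small_params):
        params = dataclasses.replace(small_params, n_artifact_snps=0)
        profiles = self._profiles(small_genome, params)
        injected, artifacts = inject_artifacts(profiles, small_genome, params)
        assert artifacts == []
        for before, after in zip(profiles, injected):
            assert [r.key for r in before] == [r.key for r in after]

    def test_every_artifact_shared_by_all_profiles(self, small_genome, small_params):
        profiles = self._profiles(small_genome, small_params, n=5)
        injected, artifacts = inject_artifacts(profiles, small_genome, small_params)
        assert len(artifacts) == small_params.n_artifact_snps
        for profile in injected:
            for key in artifacts:
                assert key in profile

    def test_all_highdepth_artifacts_die_at_depth_filter(
        self, small_genome, small_params
    ):
        params = dataclasses.replace(small_params, artifact_highdepth_fraction=1.0)
        profiles = self._profiles(small_genome, params)
        injected, artifacts = inject_artifacts(profiles, small_genome, params)
        filtered = filter_by_depth(injected[0], params.depth_filter_cutoff)
        assert not {r.key for r in filtered} & set(artifacts)


class TestScenario:
    def test_bit_reproducible(self):
        params = SimParams(
            genome_length=20_000, n_genes=2, cds_length=600, n_exons=2,
            intron_length=80, n_induced_snps=15, n_artifact_snps=10,
            n_lines=2, seed=17,
        )
        s1 = simulate_scenario(params)
        s2 = simulate_scenario(params)
        assert s1.genome.chromosomes == s2.genome.chromosomes
        assert s1.lines == s2.lines
        assert [[r.key for r in p] for p in s1.profiles] == [
            [r.key for r in p] for p in s2.profiles
        ]
        assert [
            (r.alt_count, r.depth) for p in s1.profiles for r in p
        ] == [(r.alt_count, r.depth) for p in s2.profiles for r in p]


class TestColorToy:
    def test_overdominant_ordering(self):
        het = color_intensity(0.5)
        assert het > color_intensity(1.0) > color_intensity(0.0)
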