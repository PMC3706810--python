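import numpy as np
import pytest
from scipy import stats

import popseqsim as pq
from popseqsim.errors import ValidationError
from popseqsim.meiosis import FOUNDER
from popseqsim.pedigree import (MutationSet, RecombinantGenome,
                                breed_population, breed_pool,
                                foreground_fraction, mutagenize, phenotype,
                                select_pool)


class TestMutagenize:
    def test_single_mutation_is_causal(self, tiny_genome, rng):
        m = mutagenize(tiny_genome, 1, rng)
        assert m.causal_index == 0 and len(m) == 1

    def test_positions_uniform_over_genome(self, rng):
        spec = pq.arabidopsis_like()
        m = mutagenize(spec, 1400, rng)
        # pool all positions scaled by chromosome length; KS against U(0,1)
        scaled = [p / spec.length_of(c)
                  for c, p in zip(m.chroms, m.positions)]
        assert stats.kstest(scaled, "uniform").pvalue > 0.01
        # chromosome shares proportional to lengths
        counts = {c: m.chroms.count(c) for c in spec.names}
        exp = np.array([spec.length_of(c) / spec.total_length * 1400
                        for c in spec.names])
        chi2 = ((np.array([counts[c] for c in spec.names]) - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, len(exp) - 1) > 0.01

    def test_deterministic_given_seed(self, tiny_genome):
        a = mutagenize(tiny_genome, 40, np.random.default_rng(5))
        b = mutagenize(tiny_genome, 40, np.random.default_rng(5))
        assert a == b

    def test_too_many_mutations_rejected(self, rng):
        spec = pq.GenomeSpec((("c1", 10),))
        with pytest.raises(ValidationError):
            mutagenize(spec, 11, rng)


class TestPhenotype:
    def test_genotype_two_is_mutant(self, tiny_genome, rng):
        m = mutagenize(tiny_genome, 5, rng)
        founder = RecombinantGenome.founder_mutant(tiny_genome)
        wt = RecombinantGenome.nonmutant_parent(tiny_genome)
        assert phenotype(founder, m) == "mutant"
        assert phenotype(wt, m) == "wildtype"

    def test_heterozygote_is_wildtype(self, tiny_genome, rng):
        from popseqsim.meiosis import Haplotype, PARTNER
        m = mutagenize(tiny_genome, 5, rng)
        het = RecombinantGenome(tiny_genome, (
            Haplotype.uniform(tiny_genome, FOUNDER),
            Haplotype.uniform(tiny_genome, PARTNER)))
        chrom, pos = m.causal
        assert int(het.genotype(chrom, pos)) == 1
        assert phenotype(het, m) == "wildtype"


class TestBreeding:
    def test_outcross_f2_segregates_1_2_1(self, tiny_model, rng):
        m = mutagenize(tiny_model.genome, 3, rng)
        pop = breed_population("outcross", 600, tiny_model, m, rng)
        chrom, pos = m.causal
        g = np.array([int(i.genotype(chrom, pos)) for i in pop])
        obs = np.bincount(g, minlength=3)
        exp = np.array([0.25, 0.5, 0.25]) * len(pop)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, 2) > 0.001

    def test_bc1f2_unselected_allele_frequency_half(self, tiny_model, rng):
        m = mutagenize(tiny_model.genome, 3, rng)
        pop = breed_population("backcross", 600, tiny_model, m, rng,
                               backcross_rounds=1)
        chrom, pos = m.causal
        freq = np.mean([int(i.genotype(chrom, pos)) for i in pop]) / 2
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / (2 * len(pop)))

    def test_zero_backcross_rounds_rejected(self, tiny_model, rng):
        m = mutagenize(tiny_model.genome, 3, rng)
        with pytest.raises(ValidationError):
            breed_population("backcross", 5, tiny_model, m, rng,
                             backcross_rounds=0)

    def test_sibling_lineages_share_population(self, tiny_model, rng):
        m = mutagenize(tiny_model.genome, 3, rng)
        pop = breed_population("backcross", 10, tiny_model, m, rng,
                               backcross_rounds=1, n_parent_siblings=3)
        assert len(pop) == 10

    def test_genotypes_consistent_with_segment_origins(self, tiny_model, rng):
        """Genotypes queried per mutation equal counts of founder-origin
        segments covering the position, for many random individuals."""
        m = mutagenize(tiny_model.genome, 30, rng)
        pop = breed_population("outcross", 50, tiny_model, m, rng)
        for ind in pop:
            for chrom, pos in zip(m.chroms, m.positions):
                by_query = int(ind.genotype(chrom, pos))
                by_segments = 0
                for hap in ind.haplotypes:
                    length = tiny_model.genome.length_of(chrom)
                    for start, end, origin in hap.segments(chrom, length):
                        if start <= pos <= end and origin == FOUNDER:
                            by_segments += 1
                assert by_query == by_segments


class TestSelectPool:
    def test_no_misscoring_pool_is_causal_homozygous(self, tiny_model, rng):
        m = mutagenize(tiny_model.genome, 3, rng)
        pool = breed_pool("outcross", 20, tiny_model, m, rng)
        chrom, pos = m.causal
        assert all(int(i.genotype(chrom, pos)) == 2 for i in pool.individuals)
        assert pool.misscored_count == 0

    def test_misscore_counts(self, tiny_model, rng):
        m = mutagenize(tiny_model.genome, 3, rng)
        pop = breed_population("outcross", 400, tiny_model, m, rng)
        pool = select_pool(pop, m, 50, 0.02, rng)
        assert pool.misscored_count == 1 and pool.size == 50
        pool = select_pool(pop, m, 4, 0.5, rng)
        assert pool.misscored_count == 2
        chrom, pos = m.causal
        mis = sum(int(i.genotype(chrom, pos)) != 2 for i in pool.individuals)
        assert mis == 2

    def test_insufficient_mutants_raises(self, tiny_model, rng):
        m = mutagenize(tiny_model.genome, 3, rng)
        pop = breed_population("outcross", 8, tiny_model, m, rng)
        with pytest.raises(ValidationError, match="pop_size"):
            select_pool(pop, m, 8, 0.0, rng)

    def test_unlinked_marker_frequency_near_half(self, tiny_model, rng):
        """In a selected pool, loci unlinked to the causal locus segregate
        around allele frequency 0.5."""
        m = mutagenize(tiny_model.genome, 2, rng)
        pool = breed_pool("outcross", 60, tiny_model, m, rng)
        chrom, pos = m.causal
        other = "c1" if chrom == "c2" else "c2"
        length = tiny_model.genome.length_of(other)
        freq = np.mean([int(i.genotype(other, length // 2))
                        for i in pool.individuals]) / 2
        assert abs(freq - 0.5) < 0.2


class TestForeground:
    def test_founder_fraction_is_one(self, tiny_genome):
        founder = RecombinantGenome.founder_mutant(tiny_genome)
        assert foreground_fraction(founder) == 1.0

    def test_unselected_backcross_matches_theory(self, ath_setup, rng):
        """Unconditioned BC_nF2 mean recurrent fraction follows
        (2^(n+1)-1)/2^(n+1) for n = 1..3."""
        land, markers, model = ath_setup
        for n in (1, 2, 3):
            vals = []
            for _ in range(250):
                m = mutagenize(model.genome, 2, rng)
                pop = breed_population("backcross", 1, model, m, rng,
                                       backcross_rounds=n,
                                       carrier_parent=False)
                vals.append(foreground_fraction(pop[0]))
            theory = 1 / 2 ** (n + 1)
            se = np.std(vals) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - theory) < 3 * se + 1e-4

    def test_causal_selection_inflates_foreground(self, ath_setup, rng):
        """Selecting causal homozygotes drags linked founder genome along:
        mean foreground of selected BC2F2 clearly exceeds the unselected
        12.5% expectation."""
        land, markers, model = ath_setup
        vals = []
        while len(vals) < 60:
            m = mutagenize(model.genome, 2, rng)
            pop = breed_population("backcross", 6, model, m, rng,
                                   backcross_rounds=2)
            vals += [foreground_fraction(i) for i in pop
                     if phenotype(i, m) == "mutant"]
        assert np.mean(vals) > 0.16
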