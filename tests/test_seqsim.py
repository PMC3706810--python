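import numpy as np
import pandas as pd
import pytest

import popseqsim as pq
from popseqsim.errors import ValidationError
from popseqsim.pedigree import mutagenize, breed_pool
from popseqsim.seqsim import (PoolCounts, SeqParams, assign_coverage,
                              read_pool_counts, sample_allele_counts,
                              sequence_pool, true_allele_frequencies,
                              write_pool_counts, write_vcf_like)


class TestAssignCoverage:
    def test_single_locus_gets_everything(self, rng):
        assert assign_coverage(np.array([3.0]), 1234, rng)[0] == 1234

    def test_zero_reads(self, rng):
        assert assign_coverage(np.ones(5), 0, rng).sum() == 0

    def test_conservation_and_moments(self, rng):
        k, m = 100, 10_000
        cov = assign_coverage(np.ones(k), m, rng)
        assert cov.sum() == m
        sigma = np.sqrt(m * (1 / k) * (1 - 1 / k))
        assert np.all(np.abs(cov - m / k) < 6 * sigma)
        assert abs(cov.mean() - m / k) < 3 * sigma / np.sqrt(k)

    def test_zero_weights_rejected(self, rng):
        with pytest.raises(ValidationError):
            assign_coverage(np.zeros(3), 10, rng)


class TestAlleleCounts:
    def test_pure_mutant_no_error(self, rng):
        mut, wt = sample_allele_counts(np.array([100]), np.array([1.0]),
                                       0.0, rng)
        assert mut[0] == 100 and wt[0] == 0

    def test_zero_coverage(self, rng):
        mut, wt = sample_allele_counts(np.array([0]), np.array([0.7]),
                                       0.003, rng)
        assert mut[0] == 0 and wt[0] == 0

    def test_error_floor_is_half_error_rate(self, rng):
        """At a1 = 1 under the split rule, other-allele reads appear at
        frequency s/2."""
        c = 200_000
        mut, wt = sample_allele_counts(np.array([c]), np.array([1.0]),
                                       0.003, rng)
        expected = c * 0.003 / 2
        sigma = np.sqrt(c * 0.0015 * (1 - 0.0015))
        assert abs(wt[0] - expected) < 3.5 * sigma

    def test_flip_mode_sends_all_errors_to_other_allele(self, rng):
        c = 200_000
        mut, wt = sample_allele_counts(np.array([c]), np.array([1.0]),
                                       0.003, rng, error_mode="flip")
        expected = c * 0.003
        sigma = np.sqrt(c * 0.003 * 0.997)
        assert abs(wt[0] - expected) < 3.5 * sigma

    def test_unbiased_at_half(self, rng):
        cov = np.full(10_000, 50)
        mut, wt = sample_allele_counts(cov, np.full(10_000, 0.5), 0.003, rng)
        freq = mut.sum() / cov.sum()
        sigma = np.sqrt(0.25 / cov.sum())
        assert abs(freq - 0.5) < 3 * sigma
        assert (mut + wt == cov).all()


class TestTrueAlleleFrequencies:
    def test_causal_locus_fixed_and_misscored_dilution(self, tiny_model, rng):
        m = mutagenize(tiny_model.genome, 3, rng)
        pool = breed_pool("outcross", 20, tiny_model, m, rng)
        chrom, pos = m.causal
        loci = pd.DataFrame({"chrom": [chrom], "pos": [pos]})
        assert true_allele_frequencies(pool, loci)[0] == 1.0

    def test_misscored_heterozygote_gives_99_percent(self, tiny_genome):
        """A pool of 50 with one mis-scored heterozygote has causal allele
        frequency 99/100."""
        from popseqsim.meiosis import Haplotype, PARTNER, FOUNDER
        from popseqsim.pedigree import Pool, RecombinantGenome, MutationSet
        hom = RecombinantGenome.founder_mutant(tiny_genome)
        het = RecombinantGenome(tiny_genome, (
            Haplotype.uniform(tiny_genome, FOUNDER),
            Haplotype.uniform(tiny_genome, PARTNER)))
        m = MutationSet(("c1",), (1000,), 0)
        pool = Pool(individuals=[hom] * 49 + [het], mutations=m,
                    scheme="backcross", generation="BC1F2", misscored_count=1)
        loci = pd.DataFrame({"chrom": ["c1"], "pos": [1000]})
        assert true_allele_frequencies(pool, loci)[0] == pytest.approx(0.99)


class TestSequencePool:
    def test_total_reads_from_coverage(self, tiny_model, tiny_landscape, rng):
        land, markers = tiny_landscape
        m = mutagenize(tiny_model.genome, 10, rng)
        pool = breed_pool("outcross", 10, tiny_model, m, rng)
        counts = sequence_pool(pool, markers, SeqParams(coverage=25), rng)
        n_loci = len(counts.df)
        assert counts.m == 25 * n_loci
        assert (counts.df["count_mut"] + counts.df["count_wt"]
                == counts.df["cov"]).all()

    def test_enrichment_mode_zeroes_off_target(self, tiny_genome, rng):
        land, markers = pq.synthesize_landscape(
            tiny_genome, markers_per_chrom=40, seed=3, enriched_fraction=0.25)
        model = pq.MeiosisModel(land, markers)
        m = mutagenize(tiny_genome, 10, rng)
        pool = breed_pool("outcross", 10, model, m, rng)
        counts = sequence_pool(pool, markers,
                               SeqParams(coverage=50, mode="enrichment"), rng)
        df = counts.df
        enr = markers.df.set_index(["chrom", "pos"])["enriched"]
        flags = [enr.get((c, p), False)
                 for c, p in zip(df["chrom"], df["pos"])]
        flags = np.asarray(flags)
        assert (df.loc[~flags, "cov"] == 0).all()
        assert df.loc[flags, "cov"].sum() == counts.m

    def test_enrichment_without_flags_rejected(self, tiny_model,
                                               tiny_landscape, rng):
        land, markers = tiny_landscape
        m = mutagenize(tiny_model.genome, 5, rng)
        pool = breed_pool("outcross", 5, tiny_model, m, rng)
        with pytest.raises(ValidationError):
            sequence_pool(pool, markers,
                          SeqParams(coverage=10, mode="enrichment"), rng)

    def test_two_seeds_differ_same_total(self, tiny_model, tiny_landscape):
        land, markers = tiny_landscape
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        m = mutagenize(tiny_model.genome, 10, np.random.default_rng(0))
        pool = breed_pool("outcross", 10, tiny_model, m,
                          np.random.default_rng(0))
        c1 = sequence_pool(pool, markers, SeqParams(coverage=20), rng1)
        c2 = sequence_pool(pool, markers, SeqParams(coverage=20), rng2)
        assert c1.m == c2.m
        assert not (c1.df["cov"] == c2.df["cov"]).all()

    def test_params_validation(self):
        with pytest.raises(ValidationError):
            SeqParams()                      # neither coverage nor reads
        with pytest.raises(ValidationError):
            SeqParams(coverage=10, total_reads=100)
        with pytest.raises(ValidationError):
            SeqParams(coverage=10, error_rate=1.5)


class TestInterchange:
    def test_tsv_round_trip(self, tiny_model, tiny_landscape, rng, tmp_path):
        land, markers = tiny_landscape
        m = mutagenize(tiny_model.genome, 10, rng)
        pool = breed_pool("outcross", 10, tiny_model, m, rng)
        counts = sequence_pool(pool, markers, SeqParams(coverage=10), rng)
        path = tmp_path / "counts.tsv"
        write_pool_counts(counts, path)
        back = read_pool_counts(path)
        pd.testing.assert_frame_equal(back.df, counts.df)
        assert back.m == counts.m

    def test_vcf_like_export(self, tiny_model, tiny_landscape, rng, tmp_path):
        land, markers = tiny_landscape
        m = mutagenize(tiny_model.genome, 5, rng)
        pool = breed_pool("outcross", 5, tiny_model, m, rng)
        counts = sequence_pool(pool, markers, SeqParams(coverage=5), rng)
        path = tmp_path / "counts.vcf"
        write_vcf_like(counts, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("##fileformat=VCF")
        assert len([l for l in lines if not l.startswith("#")]) == len(counts.df)
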