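"""Synthetic genome, read, mixture, and score-population generators."""

import numpy as np
import pytest

from decent import simgen
from decent.readio import LABEL_EMBRYONIC, LABEL_MATERNAL


def _config(**kw):
    base = dict(
        chrom_lengths={"chr1": 200_000, "chr2": 200_000},
        cpg_density=0.02,
        seed=7,
    )
    base.update(kw)
    return simgen.SimConfig(**base)


class TestGenerateGenome:
    def test_cpg_density_near_requested(self):
        g = simgen.generate_genome(_config(cpg_density=0.01))
        for chrom in g.chrom_names:
            density = len(g.cpg_positions[chrom]) / g.chrom_lengths[chrom]
            assert density == pytest.approx(0.01, rel=0.2)

    def test_deterministic_for_fixed_seed(self):
        g1 = simgen.generate_genome(_config())
        g2 = simgen.generate_genome(_config())
        for chrom in g1.chrom_names:
            np.testing.assert_array_equal(g1.seq[chrom], g2.seq[chrom])
            np.testing.assert_array_equal(g1.cpg_positions[chrom], g2.cpg_positions[chrom])

    def test_cpg_positions_strictly_increasing_and_in_bounds(self):
        g = simgen.generate_genome(_config())
        for chrom in g.chrom_names:
            pos = g.cpg_positions[chrom]
            assert (np.diff(pos) > 0).all()
            assert pos.size == 0 or pos[-1] < g.chrom_lengths[chrom]
            # every recorded position is an actual CpG in the sequence
            seq = g.seq[chrom]
            assert (seq[pos] == ord("C")).all()
            assert (seq[pos + 1] == ord("G")).all()

    def test_gc_track_in_unit_interval(self):
        g = simgen.generate_genome(_config())
        for chrom in g.chrom_names:
            assert g.gc_track[chrom].min() >= 0 and g.gc_track[chrom].max() <= 1

    def test_zero_density_yields_no_cpgs_and_no_methylation_channel(self):
        g = simgen.generate_genome(_config(cpg_density=0.0))
        assert all(g.cpg_positions[c].size == 0 for c in g.chrom_names)
        prof, _ = simgen.make_class_profiles(g, seed=1)
        rs = simgen.generate_reads(g, prof, 50, seed=2)
        assert all("Z" not in m and "z" not in m for m in rs.meth)

    @pytest.mark.parametrize("bad", [{"chr1": 0}, {"chr1": -5}])
    def test_non_positive_length_rejected(self, bad):
        with pytest.raises(ValueError):
            simgen.SimConfig(chrom_lengths=bad)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            _config(cpg_density=-0.01)


class TestGenerateReads:
    @pytest.fixture(scope="class")
    def genome(self):
        return simgen.generate_genome(_config(cpg_density=0.05))

    def test_methylation_fraction_matches_profile(self, genome):
        # flat regional probability 0.9 -> fraction of methylated CpGs 0.90 +- 0.01
        prof = simgen.ClassMethylProfile(
            LABEL_MATERNAL,
            {c: np.full(genome.n_regions(c), 0.9) for c in genome.chrom_names},
            genome.region_size,
        )
        rs = simgen.generate_reads(genome, prof, 10_000, seed=3)
        n_meth = sum(m.count("Z") for m in rs.meth)
        n_tot = n_meth + sum(m.count("z") for m in rs.meth)
        assert n_meth / n_tot == pytest.approx(0.90, abs=0.01)

    def test_meth_string_consistent_with_sequence(self, genome):
        prof, _ = simgen.make_class_profiles(genome, seed=4)
        rs = simgen.generate_reads(genome, prof, 200, seed=5)
        for read in rs:
            for base, call in zip(read.seq, read.meth):
                if base != "C":
                    assert call == "."
                else:
                    assert call in "ZzHh"

    def test_whole_chromosome_cn1_halves_read_density(self, genome):
        prof, _ = simgen.make_class_profiles(genome, seed=6)
        rs = simgen.generate_reads(
            genome, prof, 40_000, cnv_events=[("chr2", "whole", None, 1)], seed=7
        )
        n1 = sum(c == "chr1" for c in rs.chrom)
        n2 = sum(c == "chr2" for c in rs.chrom)
        assert n2 / n1 == pytest.approx(0.5, abs=0.05)

    def test_cnv_dosage_converges_to_expected_share(self, genome):
        # binomial oracle: share of reads on the CN-3 region ~ c/2 * |R|/G'
        prof, _ = simgen.make_class_profiles(genome, seed=8)
        region = ("chr1", 0, 100_000, 3)
        rs = simgen.generate_reads(genome, prof, 200_000, cnv_events=[region], seed=9)
        genome_w = sum(genome.chrom_lengths.values()) + 100_000 * (3 / 2 - 1)
        p = (3 / 2) * 100_000 / genome_w
        hits = sum(
            1 for c, s in zip(rs.chrom, rs.start) if c == "chr1" and s < 100_000
        )
        sigma = np.sqrt(p * (1 - p) * len(rs))
        assert abs(hits - p * len(rs)) < 3 * sigma

    def test_labels_attached(self, genome):
        prof, _ = simgen.make_class_profiles(genome, seed=10)
        rs = simgen.generate_reads(genome, prof, 10, seed=11)
        assert set(rs.label) == {LABEL_EMBRYONIC}

    def test_n_validation(self, genome):
        prof, _ = simgen.make_class_profiles(genome, seed=12)
        with pytest.raises(ValueError):
            simgen.generate_reads(genome, prof, 0, seed=13)
        assert len(simgen.generate_reads(genome, prof, 1, seed=13)) == 1

    def test_negative_copy_number_rejected(self, genome):
        prof, _ = simgen.make_class_profiles(genome, seed=14)
        with pytest.raises(ValueError):
            simgen.generate_reads(genome, prof, 10, cnv_events=[("chr1", 0, 1000, -1)], seed=15)


class TestMixReads:
    @pytest.fixture(scope="class")
    def pools(self):
        g = simgen.generate_genome(_config())
        emb_p, mat_p = simgen.make_class_profiles(g, seed=20)
        return (
            simgen.generate_reads(g, emb_p, 4000, seed=21),
            simgen.generate_reads(g, mat_p, 6000, seed=22),
        )

    def test_explicit_counts_record_exact_fraction(self, pools):
        embryo, maternal = pools
        mixed = simgen.mix_reads(embryo, maternal, simgen.MixSpec(2000, 3000, seed=1))
        assert len(mixed) == 5000
        assert mixed.provenance["true_fraction"] == 3000 / 5000

    def test_target_fraction_solves_for_maternal_count(self):
        # x / (2M + x) = 0.70  ->  x = 4,666,667
        assert simgen.maternal_reads_needed(2_000_000, 0.70) == 4_666_667
        # the published mixing table: 2M embryonic pool at 60% and 65%
        assert simgen.maternal_reads_needed(2_000_000, 0.60) == 3_000_000
        assert simgen.maternal_reads_needed(2_000_000, 0.65) == 3_714_286

    def test_zero_fraction_returns_embryo_pool_unchanged(self, pools):
        embryo, _ = pools
        mixed = simgen.mix_reads(embryo, pools[1], simgen.MixSpec(target_fraction=0.0, seed=2))
        assert len(mixed) == len(embryo)
        assert mixed.seq == embryo.seq
        assert mixed.provenance["true_fraction"] == 0.0

    def test_exhausted_pool_falls_back_with_replacement(self, pools):
        embryo, maternal = pools
        with pytest.warns(UserWarning, match="replacement"):
            mixed = simgen.mix_reads(embryo, maternal, simgen.MixSpec(2000, 10_000, seed=3))
        assert len(mixed) == 12_000

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            simgen.MixSpec(target_fraction=1.0)
        with pytest.raises(ValueError):
            simgen.MixSpec(target_fraction=-0.1)


class TestScorePopulations:
    def test_mode_locations_recovered(self):
        spec = simgen.ScorePopulationSpec(n_embryonic=20_000, n_maternal=20_000, seed=5)
        ss = simgen.generate_score_population(spec)
        emb = ss.scores[ss.labels == 0]
        mat = ss.scores[ss.labels == 1]
        # empirical modes via histogram peaks
        for scores, modes in ((emb, (0.2, 0.5)), (mat, (0.7, 0.5))):
            hist, edges = np.histogram(scores, bins=50, range=(0, 1))
            centers = (edges[:-1] + edges[1:]) / 2
            peak = centers[np.argmax(hist)]
            assert min(abs(peak - m) for m in modes) < 0.05

    def test_class_mean_matches_mixture_moments(self):
        spec = simgen.ScorePopulationSpec(n_embryonic=20_000, n_maternal=0, seed=6)
        ss = simgen.generate_score_population(spec)
        expected = 0.65 * 0.2 + 0.35 * 0.5  # component-weighted mean
        assert ss.scores.mean() == pytest.approx(expected, abs=0.01)

    def test_equal_classes_give_half_naive_fraction(self):
        spec = simgen.ScorePopulationSpec(n_embryonic=10_000, n_maternal=10_000, seed=7)
        ss = simgen.generate_score_population(spec)
        assert (ss.scores > 0.5).mean() == pytest.approx(0.5, abs=0.02)

    def test_empty_population(self):
        ss = simgen.generate_score_population(simgen.ScorePopulationSpec(0, 0, seed=8))
        assert len(ss) == 0

    def test_scores_in_unit_interval(self):
        spec = simgen.ScorePopulationSpec(n_embryonic=5000, n_maternal=5000, spread=0.3, seed=9)
        ss = simgen.generate_score_population(spec)
        assert ss.scores.min() >= 0 and ss.scores.max() <= 1


class TestPerturbScores:
    def test_zero_variance_is_identity(self):
        ss = simgen.generate_score_population(
            simgen.ScorePopulationSpec(n_embryonic=1000, n_maternal=0, seed=1)
        )
        out = simgen.perturb_scores(ss, variance_max=0.0, seed=2)
        np.testing.assert_array_equal(out.scores, ss.scores)

    def test_symmetric_noise_preserves_central_mean(self):
        from decent.scores import ScoreSet

        ss = ScoreSet(np.full(50_000, 0.5))
        out = simgen.perturb_scores(ss, seed=3)
        assert out.scores.mean() == pytest.approx(0.5, abs=0.01)

    def test_deterministic_per_seed(self):
        ss = simgen.generate_score_population(
            simgen.ScorePopulationSpec(n_embryonic=500, n_maternal=500, seed=4)
        )
        a = simgen.perturb_scores(ss, seed=5)
        b = simgen.perturb_scores(ss, seed=5)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_negative_variance_rejected(self):
        ss = simgen.generate_score_population(
            simgen.ScorePopulationSpec(n_embryonic=10, n_maternal=0, seed=6)
        )
        with pytest.raises(ValueError):
            simgen.perturb_scores(ss, variance_max=-0.1)
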