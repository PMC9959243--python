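import numpy as np
import pytest

from rilmap.genotypes import A, B, H, NA, MarkerDef
from rilmap.linkage import ril_observed
from rilmap.simulate import (
    ChromosomeSpec,
    GenomeSpec,
    QTL,
    QTLModel,
    SimConfig,
    simulate_goldengate,
    simulate_meiosis,
    simulate_phenotype,
    simulate_reads,
    simulate_ril_population,
    study_config,
    uniform_marker_loci,
)
from rilmap.simulate import Haplotype, _pure_haplotype


def het_pair(length):
    return (_pure_haplotype(0, length), _pure_haplotype(1, length))


class TestMeiosis:
    def test_tiny_chromosome_returns_a_parental_copy(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            g = simulate_meiosis(het_pair(1e-4), 1e-4, rng)
            assert len(g.origins) == 1

    def test_crossover_count_is_poisson_with_morgan_mean(self):
        rng = np.random.default_rng(1)
        counts = [
            len(simulate_meiosis(het_pair(100.0), 100.0, rng).origins) - 1
            for _ in range(10_000)
        ]
        # for fully heterozygous pairs every crossover is a mosaic switch
        mean = np.mean(counts)
        assert abs(mean - 1.0) < 3 * np.sqrt(1.0 / 10_000)

    def test_gamete_recombination_matches_haldane(self):
        rng = np.random.default_rng(2)
        d = 50.0
        expected = 0.5 * (1 - np.exp(-2 * d / 100))  # 0.3161
        rec = 0
        n = 20_000
        for _ in range(n):
            g = simulate_meiosis(het_pair(100.0), 100.0, rng)
            o = g.origin_at(np.array([10.0, 60.0]))
            rec += int(o[0] != o[1])
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec / n - expected) < 3 * se

    def test_mosaic_is_valid(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            g = simulate_meiosis(het_pair(200.0), 200.0, rng)
            assert np.all(np.diff(g.ends) > 0)
            assert g.ends[-1] == pytest.approx(200.0)
            assert np.all(g.origins[1:] != g.origins[:-1])  # segments alternate


class TestRilPopulation:
    def test_f2_single_locus_segregates_1_2_1(self):
        genome = GenomeSpec([ChromosomeSpec("1", 50.0, 1_000_000)])
        cfg = SimConfig(n_lines=10_000, final_generation=2, seed=4)
        truth = simulate_ril_population(genome, cfg)
        gm = truth.calls_at([MarkerDef("SNP/1/500000", "1", 500_000)])
        counts = [(gm.calls == c).sum() for c in (A, H, B)]
        freqs = np.array(counts) / 10_000
        for f, exp in zip(freqs, (0.25, 0.5, 0.25)):
            assert abs(f - exp) < 3 * np.sqrt(exp * (1 - exp) / 10_000)

    @pytest.mark.parametrize("t", [2, 3, 4, 5, 6, 7])
    def test_heterozygosity_halves_each_generation(self, t):
        genome = GenomeSpec([ChromosomeSpec("1", 100.0, 10_000_000)])
        cfg = SimConfig(n_lines=2_000, final_generation=t, seed=10 + t)
        truth = simulate_ril_population(genome, cfg)
        loci = uniform_marker_loci(genome, 25)
        expected = 0.5 ** (t - 1)
        # loci on one chromosome are correlated; SE over lines only
        obs = truth.het_fraction(loci)
        se = np.sqrt(expected * (1 - expected) / 2_000)
        assert abs(obs - expected) < 4 * se

    def test_completely_linked_loci_never_recombine(self):
        genome = GenomeSpec([ChromosomeSpec("1", 100.0, 10_000_000)])
        cfg = SimConfig(n_lines=300, final_generation=7, seed=5)
        truth = simulate_ril_population(genome, cfg)
        loci = [MarkerDef("a", "1", 5_000_000), MarkerDef("b", "1", 5_000_000 + 1)]
        gm = truth.calls_at(loci)
        hom = np.isin(gm.calls[0], (A, B)) & np.isin(gm.calls[1], (A, B))
        assert np.array_equal(gm.calls[0][hom], gm.calls[1][hom])

    @pytest.mark.parametrize("d_cM", [5.0, 20.0, 50.0])
    def test_ril_recombination_converges_to_haldane_waddington(self, d_cM):
        # checked near fixation (t = 15); at F7 a small downward
        # finite-generation bias remains
        genome = GenomeSpec([ChromosomeSpec("1", 55.0, 55_000_001)])
        cfg = SimConfig(n_lines=20_000, final_generation=15, seed=int(d_cM))
        truth = simulate_ril_population(genome, cfg)
        loci = [MarkerDef("a", "1", 1), MarkerDef("b", "1", int(d_cM * 1e6) + 1)]
        gm = truth.calls_at(loci)
        hom = np.isin(gm.calls[0], (A, B)) & np.isin(gm.calls[1], (A, B))
        R_hat = float((gm.calls[0][hom] != gm.calls[1][hom]).mean())
        r = 0.5 * (1 - np.exp(-2 * d_cM / 100))
        R_lim = ril_observed(r)
        se = np.sqrt(R_lim * (1 - R_lim) / hom.sum())
        assert abs(R_hat - R_lim) < 3 * se

    def test_reproducible_from_seed(self, small_genome):
        cfg = SimConfig(n_lines=20, final_generation=7, seed=99)
        loci = uniform_marker_loci(small_genome, 10)
        a = simulate_ril_population(small_genome, cfg).calls_at(loci)
        b = simulate_ril_population(small_genome, cfg).calls_at(loci)
        assert a.equals(b)

    def test_study_presets(self):
        assert study_config("ril71").n_lines == 190
        assert study_config("RIL98").n_lines == 96
        assert study_config("ril16").het_residual_expected == pytest.approx(0.015625)
        with pytest.raises(ValueError):
            study_config("ril00")


class TestReadSimulation:
    def test_absence_homozygotes_emit_zero(self, f7_population):
        truth, loci, cfg = f7_population
        amp = [MarkerDef(f"AMP/{m.chrom}/{m.pos_bp}", m.chrom, m.pos_bp, "AMP")
               for m in loci[:10]]
        table = simulate_reads(truth, amp, cfg, parent_presence=["P1"] * 10,
                               rng=np.random.default_rng(6))
        truth_calls = truth.calls_at(amp).calls
        assert (table.counts[truth_calls == B] == 0).all()

    def test_zero_count_fraction_matches_mixture_closed_form(self):
        genome = GenomeSpec([ChromosomeSpec("1", 10.0, 1_000_000)])
        cfg = SimConfig(n_lines=2_000, final_generation=7, seed=7,
                        amplicon_read_mean=3.0, amplicon_dropout=0.05)
        truth = simulate_ril_population(genome, cfg)
        amp = [MarkerDef("AMP/1/500000", "1", 500_000, "AMP")]
        table = simulate_reads(truth, amp, cfg, parent_presence=["P1"],
                               rng=np.random.default_rng(8))
        calls = truth.calls_at(amp).calls[0]
        carrier = (calls == A) | (calls == H)
        frac_zero = float((table.counts[0][carrier] == 0).mean())
        expected = 0.05 + 0.95 * np.exp(-3.0)  # 0.0973
        se = np.sqrt(expected * (1 - expected) / carrier.sum())
        assert abs(frac_zero - expected) < 3 * se


class TestGoldenGateSimulation:
    def test_noise_free_calls_equal_truth(self, f7_population):
        truth, loci, _ = f7_population
        cfg = SimConfig(n_lines=96, seed=1, missing_rate=0.0, genotype_error_rate=0.0)
        gm = simulate_goldengate(truth, loci, cfg, rng=np.random.default_rng(9))
        assert gm.equals(truth.calls_at(loci))

    def test_missing_and_flip_rates(self, f7_population):
        truth, loci, _ = f7_population
        cfg = SimConfig(n_lines=96, seed=1, missing_rate=0.10, genotype_error_rate=0.02)
        gm = simulate_goldengate(truth, loci, cfg, rng=np.random.default_rng(10))
        tgm = truth.calls_at(loci)
        n_cells = gm.calls.size
        na_frac = float((gm.calls == NA).mean())
        assert abs(na_frac - 0.10) < 3 * np.sqrt(0.1 * 0.9 / n_cells)
        hom = np.isin(tgm.calls, (A, B)) & (gm.calls != NA)
        flip = float((gm.calls[hom] != tgm.calls[hom]).mean())
        assert abs(flip - 0.02) < 3 * np.sqrt(0.02 * 0.98 / hom.sum())


class TestPhenotype:
    def test_null_model_variance(self, f7_population):
        truth, _, _ = f7_population
        model = QTLModel([], residual_sd=2.0, trait_mean=100.0)
        ph = simulate_phenotype(truth, model, np.random.default_rng(11))
        assert ph.values.mean() == pytest.approx(100.0, abs=1.0)
        assert ph.values.std() == pytest.approx(2.0, rel=0.35)

    def test_noiseless_single_qtl_gives_two_values(self, small_genome):
        cfg = SimConfig(n_lines=200, final_generation=7, seed=12)
        truth = simulate_ril_population(small_genome, cfg)
        model = QTLModel([QTL("1", 50.0, 1.0)], residual_sd=1e-12, trait_mean=0.0)
        ph = simulate_phenotype(truth, model, np.random.default_rng(13))
        x = truth.dosage_at("1", 50.0)
        hom = x != 0
        vals = np.unique(np.round(ph.values[hom], 6))
        assert set(vals) <= {-1.0, 1.0}

    def test_between_class_difference_is_2a(self, small_genome):
        cfg = SimConfig(n_lines=200, final_generation=7, seed=14)
        truth = simulate_ril_population(small_genome, cfg)
        model = QTLModel([QTL("1", 50.0, 1.0)], residual_sd=1.0)
        ph = simulate_phenotype(truth, model, np.random.default_rng(15))
        x = truth.dosage_at("1", 50.0)
        diff = ph.values[x == 1].mean() - ph.values[x == -1].mean()
        n1, n2 = (x == 1).sum(), (x == -1).sum()
        se = np.sqrt(1 / n1 + 1 / n2)
        assert abs(diff - 2.0) < 3 * se

    def test_qtl_outside_chromosome_rejected(self, small_genome):
        cfg = SimConfig(n_lines=10, seed=0)
        truth = simulate_ril_population(small_genome, cfg)
        model = QTLModel([QTL("1", 1000.0, 1.0)])
        with pytest.raises(ValueError, match="outside"):
            simulate_phenotype(truth, model, np.random.default_rng(0))
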