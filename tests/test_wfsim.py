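import numpy as np
import pandas as pd
import pytest

from rohload.wfsim import (DemographyConfig, DFEConfig, GenomeConfig,
                           SimResult, export_vcf, fitness, rescale_config,
                           run_simulation, sample_dfe, soay_demography)

NEUTRAL = DFEConfig(mean_s=-0.03, p_deleterious=0.0, p_neutral=1.0)


class TestDemography:
    def test_soay_schedule(self):
        trace = soay_demography().realize()
        assert trace.size == 11_000
        assert trace[0] == 1000 and trace[9_999] == 1000
        assert trace[10_000] == 200 and trace[10_969] == 200
        assert trace[10_970] == 10
        assert trace[10_990] == 200  # full recovery 20 generations later
        assert trace[10_971] > 10  # exponential growth under way
        assert trace[-1] == 200

    def test_exponential_recovery_values(self):
        trace = soay_demography().realize()
        expect = [round(10 * (200 / 10) ** (t / 20)) for t in range(1, 21)]
        assert trace[10_971:10_991].tolist() == expect

    def test_invalid_phase(self):
        with pytest.raises(ValueError):
            DemographyConfig(phases=[("const", 1, 10)]).realize()


class TestRescale:
    def test_identity_at_q1(self):
        demo, genome, dfe = rescale_config(soay_demography(), GenomeConfig(),
                                           DFEConfig(), 1)
        assert demo.phases == soay_demography().phases
        assert genome.mutation_rate == 1e-8 and dfe.mean_s == -0.03

    def test_q10_algebra(self):
        demo, genome, dfe = rescale_config(soay_demography(), GenomeConfig(),
                                           DFEConfig(), 10)
        assert demo.phases[0] == ("const", 100, 1000)
        assert dfe.mean_s == pytest.approx(-0.3)
        # theta = 4 N mu per site is preserved
        assert 100 * genome.mutation_rate == pytest.approx(1000 * 1e-8)
        # N s preserved
        assert 100 * dfe.mean_s == pytest.approx(1000 * -0.03)

    def test_small_sizes_clamped_to_two(self):
        demo, _, _ = rescale_config(soay_demography(), GenomeConfig(),
                                    DFEConfig(), 10)
        crash = demo.phases[2]
        assert crash == ("const", 2, 1)

    def test_error_when_size_falls_below_one(self):
        with pytest.raises(ValueError):
            rescale_config(soay_demography(), GenomeConfig(), DFEConfig(), 25)


class TestDFE:
    def test_moments_match_gamma(self):
        dfe = DFEConfig(mean_s=-0.03, shape=0.2)
        s = sample_dfe(1_000_000, dfe, rng=1)
        assert (s < 0).all()
        se_mean = np.sqrt(0.03**2 / 0.2 / s.size)
        assert s.mean() == pytest.approx(-0.03, abs=3 * se_mean)
        var = 0.03**2 / 0.2
        se_var = np.sqrt(2 / 0.2) * var / np.sqrt(s.size)  # gamma var of var
        assert s.var() == pytest.approx(var, abs=5 * se_var)

    def test_empty_draw(self):
        assert sample_dfe(0, DFEConfig(), rng=1).size == 0

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            DFEConfig(shape=0.0)


class TestFitness:
    def test_homozygous_effect(self):
        assert fitness([2], [-0.03], 0.05) == pytest.approx(0.97)

    def test_neutral_genome(self):
        assert fitness([], [], 0.05) == pytest.approx(1.0)

    def test_heterozygous_effect(self):
        assert fitness([1], [-0.03], 0.05) == pytest.approx(0.9985)

    def test_clamped_at_zero(self):
        assert fitness([2, 2], [-1.5, -0.01], 0.0) == 0.0


SMALL = DemographyConfig(phases=[("const", 20, 40)])
SMALL_GENOME = GenomeConfig(length_bp=1_000_000, recombination_rate=1e-6,
                            mutation_rate=1e-6)


class TestRunSimulation:
    def test_trace_bookkeeping(self):
        res = run_simulation(SMALL, NEUTRAL, SMALL_GENOME, seed=1)
        np.testing.assert_array_equal(res.demography_trace, SMALL.realize())
        assert res.n_individuals == 20

    def test_same_seed_is_identical(self):
        a = run_simulation(SMALL, NEUTRAL, SMALL_GENOME, seed=7)
        b = run_simulation(SMALL, NEUTRAL, SMALL_GENOME, seed=7)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        pd.testing.assert_frame_equal(a.mutation_table, b.mutation_table)

    def test_frequencies_match_genotypes(self):
        res = run_simulation(SMALL, NEUTRAL, SMALL_GENOME, seed=3)
        counts = res.haplotypes.sum(axis=0)
        np.testing.assert_allclose(res.mutation_table["frequency"],
                                   counts / res.haplotypes.shape[0])
        assert ((res.mutation_table["frequency"] > 0)
                & (res.mutation_table["frequency"] < 1)).all()

    def test_no_homozygous_lethals_among_the_living(self):
        dfe = DFEConfig(mean_s=-0.5, shape=0.3, h=0.0)
        res = run_simulation(DemographyConfig(phases=[("const", 15, 30)]),
                             dfe, SMALL_GENOME, seed=5)
        lethal = res.mutation_table["s"].to_numpy() <= -1.0
        if lethal.any():
            assert not (res.genotypes[:, lethal] == 2).any()

    def test_new_mutation_count_mean(self):
        # one generation from a monomorphic start: every segregating site is
        # a new mutation, so counts are Poisson(2 N mu L)
        demo = DemographyConfig(phases=[("const", 30, 2)])
        n_sites = [len(run_simulation(demo, NEUTRAL, SMALL_GENOME, seed=s)
                       .mutation_table) for s in range(25)]
        lam = 2 * 30 * 1e-6 * 1e6
        se = np.sqrt(lam / len(n_sites))
        assert np.mean(n_sites) == pytest.approx(lam, abs=3 * se)

    def test_seed_required(self):
        with pytest.raises(ValueError):
            run_simulation(SMALL, NEUTRAL, SMALL_GENOME, seed=None)


class TestVcfExport:
    def test_roundtrip(self, tmp_path):
        from rohload.io import read_vcf_genotypes

        res = run_simulation(SMALL, NEUTRAL, SMALL_GENOME, seed=11)
        path = tmp_path / "sample.vcf"
        export_vcf(res, path, tmp_path / "mut.tsv")
        gm = read_vcf_genotypes(path)
        np.testing.assert_array_equal(gm.calls, res.genotypes)
        np.testing.assert_array_equal(gm.markers["bp"], res.positions)
        mut = pd.read_csv(tmp_path / "mut.tsv", sep="\t")
        assert len(mut) == len(res.mutation_table)

    def test_header_only_when_no_sites(self, tmp_path):
        res = SimResult(haplotypes=np.zeros((4, 0), dtype=np.int8),
                        positions=np.empty(0, dtype=np.int64),
                        mutation_table=pd.DataFrame(
                            columns=["id", "position_bp", "s", "h", "kind",
                                     "origin_generation", "frequency"]),
                        demography_trace=np.array([2]), seed=0)
        path = tmp_path / "empty.vcf"
        export_vcf(res, path)
        lines = path.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)

    def test_allele_counts_consistent(self, tmp_path):
        res = run_simulation(SMALL, NEUTRAL, SMALL_GENOME, seed=13)
        path = tmp_path / "s.vcf"
        export_vcf(res, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        for line, (_, rec) in zip(body, res.mutation_table.iterrows()):
            gts = line.split("\t")[9:]
            ac = sum(int(a) for g in gts for a in g.split("|"))
            assert ac == round(2 * res.n_individuals * rec["frequency"])


class TestSelectionResponse:
    def test_purifying_selection_lowers_fitness_monotonically(self):
        # stronger DFEs leave lower mean fitness in the standing population
        def mean_log_fitness(mean_s, seed):
            dfe = DFEConfig(mean_s=mean_s, shape=0.2, h=0.05)
            res = run_simulation(DemographyConfig(phases=[("const", 25, 60)]),
                                 dfe, SMALL_GENOME, seed=seed)
            mt = res.mutation_table
            sel = mt["s"].to_numpy()
            g = res.genotypes.astype(float)
            hom = (g == 2) @ np.log(np.clip(1 + sel, 1e-12, None))
            het = (g == 1) @ np.log(np.clip(1 + 0.05 * sel, 1e-12, None))
            return float(np.mean(hom + het))
        weak = np.mean([mean_log_fitness(-0.005, s) for s in range(4)])
        strong = np.mean([mean_log_fitness(-0.1, s) for s in range(4)])
        assert strong < weak <= 0.0
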