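"""The forward simulator: map function, meiosis, bulking, read sampling."""

import math

import numpy as np
import pytest

from bsa_mutfind import (
    BulkDesign,
    ChromosomeSpec,
    ConfigurationError,
    SimulationConfig,
    SimulationError,
    Site,
    ValidationError,
    build_bulks,
    generate_variants,
    haldane_r,
    run_cascade,
    sample_depths,
    self_progeny,
    simulate_experiment,
    write_variants,
)

TRANSITIONS = {("C", "T"), ("G", "A")}


class TestHaldane:
    def test_limits_and_exact_value(self):
        assert haldane_r(0.0) == 0.0
        assert haldane_r(1e9) == pytest.approx(0.5, abs=1e-12)
        assert haldane_r(50.0) == pytest.approx(0.5 * (1 - math.exp(-1)), abs=1e-12)

    def test_monotone_and_bounded(self):
        d = np.linspace(0, 500, 200)
        r = haldane_r(d)
        assert np.all(np.diff(r) > 0)
        assert np.all((r >= 0) & (r < 0.5))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            haldane_r(-1.0)


class TestGenerateVariants:
    def test_no_background_yields_only_causal(self):
        cfg = SimulationConfig(n_background=0, n_fixed=0)
        sites = generate_variants(cfg, np.random.default_rng(0))
        (site,) = sites
        assert site.is_causal and (site.chrom, site.pos) == ("chr1", 2_771_134)
        assert (site.ref, site.alt) == ("C", "T")

    def test_forced_transition_spectrum(self):
        cfg = SimulationConfig(n_background=200, n_fixed=20, transition_fraction=1.0)
        sites = generate_variants(cfg, np.random.default_rng(1))
        assert all((s.ref, s.alt) in TRANSITIONS for s in sites)

    def test_transversions_present_when_unbiased(self):
        cfg = SimulationConfig(n_background=300, n_fixed=0, transition_fraction=0.0)
        sites = generate_variants(cfg, np.random.default_rng(1))
        assert all(
            (s.ref, s.alt) not in TRANSITIONS for s in sites if not s.is_causal
        )

    def test_determinism(self):
        cfg = SimulationConfig(n_background=100, n_fixed=10)
        a = generate_variants(cfg, np.random.default_rng(42))
        b = generate_variants(cfg, np.random.default_rng(42))
        assert a == b

    def test_zygosity_counts_and_no_collisions(self):
        cfg = SimulationConfig(n_background=500, n_fixed=50)
        sites = generate_variants(cfg, np.random.default_rng(2))
        assert sum(s.zygosity == "het" for s in sites) == 501  # causal is het
        assert sum(s.zygosity == "hom" for s in sites) == 50
        assert len({(s.chrom, s.pos) for s in sites}) == len(sites)

    def test_genome_too_small(self):
        cfg = SimulationConfig(
            chromosomes=(ChromosomeSpec("chr1", 10, 1.0),),
            causal_chrom="chr1",
            causal_pos=5,
            n_background=20,
            n_fixed=0,
        )
        with pytest.raises(ConfigurationError):
            generate_variants(cfg, np.random.default_rng(0))

    def test_genetic_position_linear_in_physical(self):
        cfg = SimulationConfig()
        assert cfg.genetic_position("chr1", 15_000_000) == pytest.approx(62.5)


def _causal_site(cm=10.0):
    return Site("chr1", 1000, "C", "T", cm=cm, zygosity="het", is_causal=True)


class TestSelfProgeny:
    def test_recessive_segregation_ratio(self):
        progeny = self_progeny([_causal_site()], 5000, np.random.default_rng(3))
        frac = progeny.is_mutant.mean()
        half_width = 2.576 * math.sqrt(0.25 * 0.75 / 5000)
        assert abs(frac - 0.25) < half_width

    def test_fully_linked_marker_tracks_causal_genotype(self):
        sites = [
            _causal_site(cm=10.0),
            Site("chr1", 2000, "G", "A", cm=10.0, zygosity="het"),
        ]
        progeny = self_progeny(sites, 500, np.random.default_rng(4))
        assert np.array_equal(progeny.genotypes[:, 0], progeny.genotypes[:, 1])

    def test_unlinked_marker_independent_of_phenotype(self):
        sites = [
            _causal_site(),
            Site("chr2", 2000, "G", "A", cm=10.0, zygosity="het"),
        ]
        progeny = self_progeny(sites, 8000, np.random.default_rng(5))
        for mask in (progeny.is_mutant, ~progeny.is_mutant):
            freq = progeny.genotypes[mask, 1].mean() / 2
            half_width = 2.576 * math.sqrt(0.5 * 0.5 * 0.5 / mask.sum())
            assert abs(freq - 0.5) < half_width

    def test_fixed_sites_always_homozygous(self):
        sites = [_causal_site(), Site("chr3", 5, "C", "T", cm=1.0, zygosity="hom")]
        progeny = self_progeny(sites, 200, np.random.default_rng(6))
        assert np.all(progeny.genotypes[:, 1] == 2)

    def test_misphenotyping_flips_labels(self):
        progeny = self_progeny(
            [_causal_site()], 4000, np.random.default_rng(7), misphenotyping_rate=1.0
        )
        assert np.array_equal(progeny.is_mutant, progeny.genotypes[:, 0] != 2)

    def test_linkage_decay_toward_free_recombination(self):
        """Mutant-bulk marker frequency falls from 1 toward 0.5 with distance."""
        distances = [0.0, 5.0, 20.0, 80.0, 300.0]
        sites = [_causal_site(cm=0.0)] + [
            Site("chr1", 1001 + i, "G", "A", cm=d, zygosity="het")
            for i, d in enumerate(distances[1:], start=1)
        ]
        design = BulkDesign()
        rng = np.random.default_rng(8)
        reps = []
        for _ in range(40):
            progeny = self_progeny(sites, 240, rng)
            _, mut_freqs = build_bulks(progeny, design, rng)
            reps.append(mut_freqs)
        means = np.mean(reps, axis=0)
        assert means[0] == 1.0
        assert np.all(np.diff(means) < 0)
        assert means[-1] == pytest.approx(0.5, abs=0.03)


class TestBuildBulks:
    def test_causal_frequencies(self):
        design = BulkDesign()
        rng = np.random.default_rng(9)
        wt_means = []
        for _ in range(200):
            progeny = self_progeny([_causal_site()], 240, rng)
            wt_freqs, mut_freqs = build_bulks(progeny, design, rng)
            assert mut_freqs[0] == 1.0  # recessive determinism
            wt_means.append(wt_freqs[0])
        # WT-phenotype class is 1/3 AA + 2/3 Aa -> mean allele frequency 1/3
        assert np.mean(wt_means) == pytest.approx(1 / 3, abs=0.01)

    def test_insufficient_progeny(self):
        progeny = self_progeny([_causal_site()], 40, np.random.default_rng(10))
        with pytest.raises(SimulationError, match="n_progeny"):
            build_bulks(progeny, BulkDesign(), np.random.default_rng(0))


class TestSampleDepths:
    def test_degenerate_frequencies(self):
        sites = [_causal_site()] + [
            Site("chr1", 2000 + i, "C", "T", cm=1.0, zygosity="het") for i in range(99)
        ]
        design = BulkDesign()
        variants = sample_depths(
            sites, np.zeros(100), np.ones(100), design, 0.0, np.random.default_rng(11)
        )
        for v in variants:
            wt, mut = v.depth(design.wt_bulk_id), v.depth(design.mut_bulk_id)
            assert wt.alt_depth == 0
            assert mut.alt_depth == mut.total_depth

    def test_heterozygous_pool_moments(self):
        n = 4000
        sites = [_causal_site()] + [
            Site("chr1", 2000 + i, "C", "T", cm=1.0, zygosity="het")
            for i in range(n - 1)
        ]
        design = BulkDesign(mean_depth_wt=20.0, mean_depth_mut=20.0)
        variants = sample_depths(
            sites, np.full(n, 0.5), np.full(n, 0.5), design, 0.0,
            np.random.default_rng(12),
        )
        idx = np.array(
            [
                v.depth(design.wt_bulk_id).alt_depth / v.depth(design.wt_bulk_id).total_depth
                for v in variants
                if v.depth(design.wt_bulk_id).total_depth > 0
            ]
        )
        assert idx.mean() == pytest.approx(0.5, abs=0.01)
        # compound Poisson-binomial variance: 0.25 * E[1/D | D >= 1] at lambda = 20
        from scipy import stats

        k = np.arange(1, 200)
        pmf = stats.poisson.pmf(k, 20.0)
        expected_var = 0.25 * float((pmf / k).sum() / pmf.sum())
        assert idx.var() == pytest.approx(expected_var, rel=0.15)

    def test_frequency_bounds_checked(self):
        with pytest.raises(ValidationError):
            sample_depths(
                [_causal_site()], np.array([1.5]), np.array([0.5]),
                BulkDesign(), 0.0, np.random.default_rng(0),
            )


class TestSimulateExperiment:
    def test_deterministic_output_bytes(self, tmp_path):
        cfg = SimulationConfig(n_background=80, n_fixed=8, seed=123)
        paths = []
        for name in ("a.tsv", "b.tsv"):
            variants, _ = simulate_experiment(cfg)
            paths.append(write_variants(variants, tmp_path / name, "tsv", cfg.design))
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_causal_site_fixed_in_mutant_bulk(self):
        cfg = SimulationConfig(n_background=0, n_fixed=0, seed=1)
        variants, truth = simulate_experiment(cfg)
        (v,) = variants
        assert (v.chrom, v.pos) == (truth.causal_chrom, truth.causal_pos)
        mut = v.depth(cfg.design.mut_bulk_id)
        assert mut.alt_depth == mut.total_depth

    def test_fixed_background_removed_at_wt_bound(self):
        cfg = SimulationConfig(n_background=0, n_fixed=100, seed=2)
        variants, truth = simulate_experiment(cfg)
        report = run_cascade(variants, cfg.design)
        survivors = {(iv.variant.chrom, iv.variant.pos) for iv in report.survivors}
        assert survivors == {(truth.causal_chrom, truth.causal_pos)}
        # the fixed sites pass the mutant-index stage but fail the wt bound
        assert report.stage_counts[2].n_total > 50

    def test_truth_site_classes(self):
        cfg = SimulationConfig(n_background=50, n_fixed=5, seed=3)
        _, truth = simulate_experiment(cfg)
        classes = {
            truth.site_class(s.chrom, s.pos, linked_window_cm=10.0) for s in truth.sites
        }
        assert "causal" in classes
        fixed = [s for s in truth.sites if s.zygosity == "hom"]
        assert all(truth.site_class(s.chrom, s.pos) == "fixed" for s in fixed)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(causal_chrom="chrX")
        with pytest.raises(ConfigurationError):
            SimulationConfig(error_rate=1.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_progeny=10)
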