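import numpy as np
import pytest

from sweepscan.core import DemographicModel, GenomicInterval, MaskProfile
from sweepscan.synthetic_data import (
    FixtureConfig,
    FixtureSweep,
    LabeledReplicate,
    SimParams,
    SimPriors,
    apply_mask_transfer,
    assemble_train_test,
    build_corpus,
    draw_sim_params,
    label_for,
    make_fixture_genome,
    rescale_for_region,
    simulate_replicate,
)

from conftest import make_gm

SMALL = SimPriors(L=110_000, n=6)


class TestPriors:
    def test_defaults_match_study_conditions(self):
        p = SimPriors()
        assert (p.mu_low + p.mu_high) / 2 == pytest.approx(4.851e-9, rel=1e-3)
        assert p.r_mean == 4.85e-9
        assert (p.s_low, p.s_high) == (0.005, 0.05)
        assert p.tau_high == 0.001
        assert p.f0_high == 0.05
        assert p.n_subwindows == 11

    def test_even_subwindow_count_rejected(self):
        with pytest.raises(ValueError):
            SimPriors(n_subwindows=10)

    def test_draws_respect_all_bounds(self, rng):
        p = SMALL
        for _ in range(2000):
            sp = draw_sim_params("soft", 5, p, rng)
            assert p.mu_low <= sp.mu <= p.mu_high
            assert 0 < sp.r <= p.r_cap_factor * p.r_mean
            assert p.s_low <= sp.s <= p.s_high
            assert 0 <= sp.tau <= p.tau_high
            assert 0 < sp.f0 <= p.f0_high
            assert 50_000 <= sp.sweep_pos < 60_000

    def test_mu_mean_matches_uniform_prior(self, rng):
        draws = np.array(
            [draw_sim_params("neutral", None, SMALL, rng).mu for _ in range(10_000)]
        )
        expected = (SMALL.mu_low + SMALL.mu_high) / 2
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se

    def test_r_truncated_at_three_times_mean(self, rng):
        draws = np.array(
            [draw_sim_params("neutral", None, SMALL, rng).r for _ in range(10_000)]
        )
        assert draws.max() <= 3 * SMALL.r_mean
        # truncation pulls the realized mean below the nominal parameter
        assert draws.mean() < SMALL.r_mean

    def test_s_log_uniform_median(self, rng):
        draws = np.array(
            [draw_sim_params("hard", 5, SMALL, rng).s for _ in range(5000)]
        )
        geo_median = np.sqrt(SMALL.s_low * SMALL.s_high)
        assert np.median(draws) == pytest.approx(geo_median, rel=0.1)

    def test_neutral_draw_has_no_selection(self, rng):
        sp = draw_sim_params("neutral", None, SMALL, rng)
        assert sp.s == 0 and sp.f0 == 0
        assert sp.sweep_pos is None and sp.sweep_subwindow is None

    def test_inconsistent_class_subwindow_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_sim_params("hard", 0, SMALL, rng)  # non-central but unlinked
        with pytest.raises(ValueError):
            draw_sim_params("hard-linked", 5, SMALL, rng)  # central but linked
        with pytest.raises(ValueError):
            draw_sim_params("neutral", 3, SMALL, rng)


class TestLabelRule:
    @pytest.mark.parametrize(
        "kind,sub,expected",
        [
            ("hard", 5, "hard"),
            ("hard", 0, "hard-linked"),
            ("soft", 5, "soft"),
            ("soft", 10, "soft-linked"),
            (None, None, "neutral"),
        ],
    )
    def test_label_for(self, kind, sub, expected):
        assert label_for(kind, sub, central=5) == expected


class TestRescaleForRegion:
    def test_full_to_half_megabase(self):
        p = SimPriors()  # L = 2.75 Mb, s in [0.005, 0.05]
        q = rescale_for_region(p, 550_000)
        assert q.s_low == pytest.approx(0.001)
        assert q.s_high == pytest.approx(0.01)
        assert q.L == 550_000
        assert q.mu_low == p.mu_low and q.r_mean == p.r_mean

    def test_identity(self):
        p = SimPriors()
        q = rescale_for_region(p, p.L)
        assert q == p

    def test_invertible(self):
        p = SimPriors()
        q = rescale_for_region(rescale_for_region(p, 550_000), p.L)
        assert q.s_low == pytest.approx(p.s_low)
        assert q.s_high == pytest.approx(p.s_high)


class TestSimulateReplicate:
    def test_wattersons_expectation_neutral(self):
        # E[S] = a_{2n-1} * 4 Ne mu L with n=10 diploids (20 haplotypes)
        ne, mu, L, n = 1e4, 1e-8, 100_000, 10
        dem = DemographicModel.constant(ne)
        a = np.sum(1 / np.arange(1, 20))
        expected = a * 4 * ne * mu * L
        counts = []
        for i in range(200):
            params = SimParams(
                class_label="neutral", mu=mu, r=1e-8, s=0, tau=0, f0=0,
                sweep_subwindow=None, sweep_pos=None, seed=5000 + i,
            )
            gm = simulate_replicate(params, dem, L=L, n=n)
            counts.append(gm.n_sites)
        assert np.mean(counts) == pytest.approx(expected, rel=0.1)

    def test_deterministic_given_seed(self):
        dem = DemographicModel.constant(1e4)
        params = SimParams(
            class_label="hard", mu=1e-8, r=1e-8, s=0.05, tau=1e-4, f0=0,
            sweep_subwindow=5, sweep_pos=55_000, seed=77,
        )
        a = simulate_replicate(params, dem, L=110_000, n=5)
        b = simulate_replicate(params, dem, L=110_000, n=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.dosages, b.dosages)

    def test_diploid_shape_and_interval(self):
        dem = DemographicModel.constant(1e4)
        params = SimParams(
            class_label="neutral", mu=1e-8, r=1e-8, s=0, tau=0, f0=0,
            sweep_subwindow=None, sweep_pos=None, seed=9,
        )
        gm = simulate_replicate(params, dem, L=50_000, n=7)
        assert gm.n_individuals == 7
        assert gm.interval == GenomicInterval("sim", 0, 50_000)

    def test_two_epoch_demography_reduces_diversity(self):
        # a strong recent bottleneck must reduce segregating sites
        dem_const = DemographicModel.constant(1e4)
        dem_bott = DemographicModel(epochs=[(0, 1e2), (5000, 1e4)])
        counts = {"const": [], "bott": []}
        for i in range(60):
            for name, dem in [("const", dem_const), ("bott", dem_bott)]:
                params = SimParams(
                    class_label="neutral", mu=1e-8, r=1e-8, s=0, tau=0, f0=0,
                    sweep_subwindow=None, sweep_pos=None, seed=100 + i,
                )
                counts[name].append(
                    simulate_replicate(params, dem, L=50_000, n=5).n_sites
                )
        assert np.mean(counts["bott"]) < 0.7 * np.mean(counts["const"])


class TestMaskTransfer:
    def _replicate(self):
        return make_gm(
            [[0, 1, 2, 1], [1, 0, 1, 2]], positions=[10, 30, 60, 90], length=100
        )

    def test_half_masked(self, rng):
        prof = MaskProfile(
            GenomicInterval("chr1", 0, 100), [GenomicInterval("chr1", 0, 50)]
        )
        rep = apply_mask_transfer(self._replicate(), [prof], rng)
        assert list(rep.genotypes.positions) == [60, 90]
        assert rep.mask.masked_fraction == pytest.approx(0.5)

    def test_empty_mask_identity(self, rng):
        prof = MaskProfile(GenomicInterval("chr1", 0, 100), [])
        rep = apply_mask_transfer(self._replicate(), [prof], rng)
        assert rep.genotypes.n_sites == 4

    def test_full_mask_degenerate(self, rng):
        prof = MaskProfile(
            GenomicInterval("chr1", 0, 100), [GenomicInterval("chr1", 0, 100)]
        )
        rep = apply_mask_transfer(self._replicate(), [prof], rng)
        assert rep.genotypes.n_sites == 0
        assert rep.mask.masked_fraction == pytest.approx(1.0)

    def test_empty_library_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_mask_transfer(self._replicate(), [], rng)

    def test_mask_rescaled_to_replicate_length(self, rng):
        # profile defined on a 200 bp window, replicate is 100 bp
        prof = MaskProfile(
            GenomicInterval("w", 0, 200), [GenomicInterval("w", 0, 100)]
        )
        rep = apply_mask_transfer(self._replicate(), [prof], rng)
        assert list(rep.genotypes.positions) == [60, 90]


class TestCorpusBookkeeping:
    def test_small_corpus_counts(self):
        priors = SimPriors(L=5500, n=3, mu_low=1e-9, mu_high=1e-8)
        dem = DemographicModel.constant(100)
        corpus = build_corpus(priors, dem, n_per_subwindow=2, seed=3)
        labels = [r.label for r in corpus]
        assert labels.count("hard") == 2
        assert labels.count("hard-linked") == 20
        assert labels.count("soft") == 2
        assert labels.count("soft-linked") == 20
        assert labels.count("neutral") == 2
        for rep in corpus:
            if rep.params.sweep_subwindow is not None:
                kind = "soft" if "soft" in rep.label else "hard"
                expected = (
                    kind if rep.params.sweep_subwindow == 5 else f"{kind}-linked"
                )
                assert rep.label == expected

    def test_corpus_reproducible(self):
        priors = SimPriors(L=5500, n=3)
        dem = DemographicModel.constant(100)
        a = build_corpus(priors, dem, n_per_subwindow=1, seed=11)
        b = build_corpus(priors, dem, n_per_subwindow=1, seed=11)
        for ra, rb in zip(a, b):
            assert ra.params == rb.params
            assert np.array_equal(ra.genotypes.dosages, rb.genotypes.dosages)


class TestAssembleTrainTest:
    def _corpus(self, n_per_class):
        from sweepscan.core import CLASS_LABELS

        gm = make_gm([[0, 1], [1, 0]], length=110)
        out = []
        seed = 0
        for label in CLASS_LABELS:
            for _ in range(n_per_class):
                sub = None if label == "neutral" else (5 if label in ("hard", "soft") else 0)
                params = SimParams(
                    class_label=label,
                    mu=1e-9,
                    r=1e-9,
                    s=0.01 if label != "neutral" else 0.0,
                    tau=1e-4 if label != "neutral" else 0.0,
                    f0=0.01 if "soft" in label else 0.0,
                    sweep_subwindow=sub,
                    sweep_pos=None if sub is None else 55,
                    seed=seed,
                )
                seed += 1
                out.append(LabeledReplicate(params=params, genotypes=gm))
        return out

    def test_paper_scale_counts(self, rng):
        corpus = self._corpus(3000)
        train, test = assemble_train_test(corpus, 2700, 300, rng)
        assert len(train) == 13_500
        assert len(test) == 1_500
        for split, n in [(train, 2700), (test, 300)]:
            labels = [r.label for r in split]
            assert all(labels.count(c) == n for c in set(labels))

    def test_small_counts(self, rng):
        corpus = self._corpus(10)
        train, test = assemble_train_test(corpus, 8, 2, rng)
        assert len(train) == 40 and len(test) == 10

    def test_disjoint_by_seed(self, rng):
        corpus = self._corpus(10)
        train, test = assemble_train_test(corpus, 8, 2, rng)
        train_seeds = {r.params.seed for r in train}
        test_seeds = {r.params.seed for r in test}
        assert not (train_seeds & test_seeds)

    def test_insufficient_pool_names_class(self, rng):
        corpus = self._corpus(5)
        with pytest.raises(ValueError, match="neutral|hard|soft"):
            assemble_train_test(corpus, 5, 1, rng)


@pytest.fixture(scope="module")
def fixture_cfg():
    return FixtureConfig(
        chrom_lengths={"chr1": 44_000, "chr2": 33_000},
        window_len=11_000,
        sweeps=[
            FixtureSweep("chr1", 11_000, "soft"),
            FixtureSweep("chr2", 11_000, "soft"),
        ],
        n_genes_per_chrom=5,
        zero_rate_interval=("chr1", 22_000, 33_000),
        overmasked_window=("chr2", 22_000),
        priors=SimPriors(L=11_000, n=4),
        demography=DemographicModel.constant(1e3),
    )


class TestFixtureGenome:
    def test_truth_table_lists_implanted_sweeps(self, fixture_cfg, tmp_path):
        fg = make_fixture_genome(fixture_cfg, seed=5, outdir=str(tmp_path / "a"))
        assert len(fg.truth) == 2
        assert set(fg.truth["kind"]) == {"soft"}

    def test_same_seed_byte_identical(self, fixture_cfg, tmp_path):
        fg1 = make_fixture_genome(fixture_cfg, seed=5, outdir=str(tmp_path / "x"))
        fg2 = make_fixture_genome(fixture_cfg, seed=5, outdir=str(tmp_path / "y"))
        for a, b in [
            (fg1.vcf_path, fg2.vcf_path),
            (fg1.mask_bed_path, fg2.mask_bed_path),
            (fg1.recomb_map_path, fg2.recomb_map_path),
            (fg1.gene_bed_path, fg2.gene_bed_path),
            (fg1.go_map_path, fg2.go_map_path),
        ]:
            assert open(a, "rb").read() == open(b, "rb").read()

    def test_zero_rate_interval_in_map(self, fixture_cfg, tmp_path):
        from sweepscan.core_io import read_recomb_map

        fg = make_fixture_genome(fixture_cfg, seed=5, outdir=str(tmp_path / "z"))
        rmap = read_recomb_map(fg.recomb_map_path)
        assert any(rate == 0 for _, rate in rmap.intervals)

    def test_misaligned_sweep_rejected(self):
        with pytest.raises(ValueError):
            FixtureConfig(
                chrom_lengths={"chr1": 44_000},
                window_len=11_000,
                sweeps=[FixtureSweep("chr1", 500, "hard")],
            )
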