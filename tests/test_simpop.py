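"""Generator checks: frequency model, tract process, meiosis, self-report."""

import numpy as np
import pandas as pd
import pytest

from admixscape import relate, simpop


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(123)


class TestAncestralFreqs:
    def test_fst_zero_limit_recovers_ancestral_frequency(self):
        cfg = simpop.SimConfig(ancestries=("A", "B"), fst_per_pop=(0.0, 0.2), dirichlet_alpha=(5.0, 5.0), n_variants=200)
        freqs = simpop.draw_ancestral_freqs(cfg, np.random.default_rng(0))
        cfg2 = simpop.SimConfig(ancestries=("A", "B"), fst_per_pop=(0.0, 0.2), dirichlet_alpha=(5.0, 5.0), n_variants=200)
        freqs2 = simpop.draw_ancestral_freqs(cfg2, np.random.default_rng(0))
        # F=0 population is deterministic given the rng stream: equals the common p
        np.testing.assert_allclose(freqs[0], freqs2[0])
        assert ((freqs > 0) & (freqs < 1)).all()

    def test_beta_variance_matches_closed_form(self, rng):
        # Var(p_a) = F p (1-p): F=0.1, p=0.5 -> 0.025, checked over 1e5 draws
        f, p, n = 0.1, 0.5, 100_000
        ratio = (1 - f) / f
        draws = rng.beta(p * ratio, (1 - p) * ratio, size=n)
        var = draws.var()
        expected = f * p * (1 - p)
        mc_se = np.sqrt(2.0) * expected / np.sqrt(n)  # se of a variance estimate, approx
        assert abs(var - expected) < 3 * mc_se

    def test_bounded_open_interval(self, rng):
        cfg = simpop.SimConfig(n_variants=500)
        freqs = simpop.draw_ancestral_freqs(cfg, rng)
        assert ((freqs > 0) & (freqs < 1)).all()


class TestTracts:
    def test_pure_ancestry_gives_single_tract_per_chromosome(self, rng):
        cfg = simpop.SimConfig(ancestries=("A", "B"), fst_per_pop=(0.1, 0.1), dirichlet_alpha=(5.0, 5.0), n_chromosomes=5)
        tr = simpop.simulate_tracts(np.array([1.0, 0.0]), cfg, rng)
        assert len(tr) == 5
        assert all(t[3] == 0 and t[1] == 0.0 and t[2] == cfg.chrom_length_cM for t in tr)

    def test_breakpoint_rate_is_g_per_morgan(self):
        # one 100 cM chromosome, g=10 -> Poisson mean 10 breakpoints
        cfg = simpop.SimConfig(
            ancestries=("A", "B"), fst_per_pop=(0.1, 0.1), dirichlet_alpha=(5.0, 5.0), n_chromosomes=1, generations_g=10
        )
        rng = np.random.default_rng(7)
        q = np.array([0.5, 0.5])
        tr_counts = []
        for _ in range(5000):
            tr = simpop.simulate_tracts(q, cfg, rng)
            tr_counts.append(len(tr))
        # visible segments = 1 + breakpoints with a label change; the visible
        # switch rate is g * (1 - sum q^2) = 5 per Morgan -> mean 6 segments
        mean_seg = np.mean(tr_counts)
        expected = 1 + 10 * (1 - 0.5)
        assert abs(mean_seg - expected) < 3 * np.std(tr_counts) / np.sqrt(len(tr_counts))

    def test_long_run_per_snp_frequency_matches_q(self):
        cfg = simpop.SimConfig(
            ancestries=("A", "B", "C"), fst_per_pop=(0.1, 0.1, 0.1), dirichlet_alpha=(4.0, 3.0, 3.0), n_chromosomes=1, generations_g=10
        )
        rng = np.random.default_rng(8)
        q = np.array([0.6, 0.3, 0.1])
        pos = np.array([10.0, 50.0, 90.0])
        n = 10_000
        hits = np.zeros((3, 3))
        for _ in range(n):
            tr = simpop.simulate_tracts(q, cfg, rng)
            lab = simpop.labels_at_positions(tr, "1", pos)
            for j, l in enumerate(lab):
                hits[j, l] += 1
        freq = hits / n
        se = np.sqrt(q * (1 - q) / n)
        assert (np.abs(freq - q) < 3 * se + 1e-9).all()


class TestGenotypes:
    def test_fixed_difference_site_follows_local_ancestry(self):
        cfg = simpop.SimConfig(
            ancestries=("AFR", "EUR"), fst_per_pop=(0.1, 0.1), dirichlet_alpha=(5.0, 5.0), n_variants=4, n_chromosomes=1
        )
        rng = np.random.default_rng(9)
        variants = simpop.make_variants(cfg, rng)
        freqs = np.array([[1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0]])  # AFR fixed alt
        tracts = [(("1", 0.0, 100.0, 0),)]  # all-AFR haplotype
        haps = simpop.genotypes_from_tracts(
            [(list(tracts[0]), list(tracts[0]))], freqs, variants, rng
        )
        assert (haps == 1).all()

    def test_cohort_frequency_is_mixture_of_panel_freqs(self):
        cfg = simpop.SimConfig(
            ancestries=("A", "B"),
            fst_per_pop=(0.3, 0.3),
            dirichlet_alpha=(3.0, 7.0),
            n_variants=40,
            n_chromosomes=2,
            n_ref_per_pop=5,
            household_plan={"singletons": 400, "couples": 0, "trios": 0},
            seed=3,
        )
        sim = simpop.simulate_cohort(cfg)
        qbar = sim.truth.q_true.mean().to_numpy()
        expected = qbar @ sim.truth.panel_freqs
        observed = sim.cohort.allele_freqs()
        se = np.sqrt(expected * (1 - expected) / (2 * 400))
        assert (np.abs(observed - expected) < 4 * se + 0.02).all()

    def test_phased_haplotype_sums_equal_calls(self, small_sim):
        gm = small_sim.cohort
        np.testing.assert_array_equal(gm.phased_haplotypes.sum(axis=1), gm.calls)


class TestHouseholds:
    @pytest.fixture(scope="class")
    def trio_sim(self):
        cfg = simpop.SimConfig(
            n_variants=3000,
            n_chromosomes=10,
            n_ref_per_pop=5,
            household_plan={"singletons": 0, "couples": 0, "trios": 50},
            seed=13,
        )
        return simpop.simulate_cohort(cfg)

    def test_parent_offspring_grm_near_half(self, trio_sim):
        grm = relate.compute_grm(trio_sim.cohort)
        idx = {s: i for i, s in enumerate(grm.sample_ids)}
        vals = []
        for child, (p1, p2) in trio_sim.truth.pedigree.items():
            vals += [grm.matrix[idx[child], idx[p1]], grm.matrix[idx[child], idx[p2]]]
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_spouses_unrelated(self, trio_sim):
        grm = relate.compute_grm(trio_sim.cohort)
        idx = {s: i for i, s in enumerate(grm.sample_ids)}
        vals = [grm.matrix[idx[p1], idx[p2]] for _, (p1, p2) in trio_sim.truth.pedigree.items()]
        assert abs(np.mean(vals)) < 0.05

    def test_child_q_true_is_mean_of_transmitted_fractions(self, trio_sim):
        total = trio_sim.config.n_chromosomes * trio_sim.config.chrom_length_cM
        a = trio_sim.config.n_ancestries
        for child in list(trio_sim.truth.pedigree)[:10]:
            f0 = simpop.tract_ancestry_fraction(trio_sim.truth.tracts[(child, 0)], a, total)
            f1 = simpop.tract_ancestry_fraction(trio_sim.truth.tracts[(child, 1)], a, total)
            np.testing.assert_allclose(
                trio_sim.truth.q_true.loc[child].to_numpy(), 0.5 * (f0 + f1), atol=1e-9
            )

    def test_tract_lengths_cover_chromosomes(self, small_sim):
        cfg = small_sim.config
        for (sid, hap), tr in list(small_sim.truth.tracts.items())[:20]:
            by_chrom = {}
            for chrom, a, b, _ in tr:
                by_chrom[chrom] = by_chrom.get(chrom, 0.0) + (b - a)
            for chrom in cfg.chrom_names:
                assert by_chrom[chrom] == pytest.approx(cfg.chrom_length_cM)


class TestSelfReport:
    def test_zero_noise_extreme_coefficients_deterministic(self):
        coef = {
            "Black": (0.0, 100.0, 0.0, 0.0),
            "White": (0.0, 0.0, 100.0, 0.0),
            "Indigenous": (0.0, 0.0, 0.0, 100.0),
        }
        cfg = simpop.SimConfig(selfreport_coef=coef, selfreport_noise=0.0, nonresponse_rate=0.0)
        q = np.array([[0.9, 0.05, 0.05, 0.0], [0.05, 0.9, 0.05, 0.0], [0.05, 0.05, 0.9, 0.0]])
        cats = simpop.assign_selfreport(q, cfg, np.random.default_rng(0))
        assert cats == ["Black", "White", "Indigenous"]

    def test_black_more_likely_in_top_afr_quartile(self):
        cfg = simpop.SimConfig()
        rng = np.random.default_rng(14)
        q = rng.dirichlet(np.asarray(cfg.dirichlet_alpha), size=10_000)
        cats = np.array(simpop.assign_selfreport(q, cfg, rng))
        afr = q[:, 0]
        top = afr >= np.quantile(afr, 0.75)
        bottom = afr <= np.quantile(afr, 0.25)
        assert (cats[top] == "Black").mean() > (cats[bottom] == "Black").mean()

    def test_categories_restricted_to_census_plus_not_answered(self, default_sim):
        allowed = {"Black", "Indigenous", "Mixed", "White", "Yellow", "NotAnswered"}
        assert set(default_sim.samples.frame["category"]) <= allowed


class TestDeterminismAndCalibration:
    def test_identical_truth_across_runs_with_same_seed(self):
        cfg = simpop.SimConfig(
            n_variants=200, n_chromosomes=2, n_ref_per_pop=5,
            household_plan={"singletons": 5, "couples": 2, "trios": 2}, seed=99,
        )
        s1 = simpop.simulate_cohort(cfg)
        s2 = simpop.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(s1.truth.q_true, s2.truth.q_true)
        np.testing.assert_array_equal(s1.cohort.calls, s2.cohort.calls)
        assert s1.samples.frame.equals(s2.samples.frame)
        assert s1.truth.tracts == s2.truth.tracts

    def test_cohort_mean_q_matches_dirichlet_mean(self, default_sim):
        mean_q = default_sim.truth.q_true.mean().to_numpy()
        target = default_sim.config.mean_q
        n = len(default_sim.truth.q_true)
        alpha0 = np.sum(default_sim.config.dirichlet_alpha)
        se = np.sqrt(target * (1 - target) / (alpha0 + 1) / n)
        # relatives shrink the effective n; allow 4 se
        assert (np.abs(mean_q - target) < 4 * se + 0.01).all()

    def test_reference_panel_is_unadmixed(self, default_sim):
        # panel individuals draw every allele from their own population
        labels = default_sim.panel_labels
        freqs = default_sim.truth.panel_freqs
        cfg = default_sim.config
        for a, pop in enumerate(cfg.ancestries):
            ids = [s for s in default_sim.panel.samples if labels[s] == pop]
            sub = default_sim.panel.subset_samples(ids[:50])
            emp = sub.allele_freqs()
            err = np.abs(emp - freqs[a])
            se = np.sqrt(freqs[a] * (1 - freqs[a]) / (2 * len(sub.samples)))
            assert (err < 5 * se + 1e-9).mean() > 0.99
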