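"""QC cascade: call rate, HWE exact test, variant exclusions, LD pruning, merge."""

import numpy as np
import pytest
from scipy.special import gammaln

from admixscape import genio, qc
from admixscape.genio import MISSING, GenotypeMatrix, Variant


def make_gm(calls, chroms=None, alleles=None, ids=None, positions=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chroms = chroms or ["1"] * m
    alleles = alleles or [("A", "G")] * m
    ids = ids or [f"rs{i+1}" for i in range(m)]
    positions = positions or [100 * (i + 1) for i in range(m)]
    variants = [
        Variant(id=ids[i], chrom=chroms[i], pos_bp=positions[i], ref_allele=alleles[i][0], alt_allele=alleles[i][1])
        for i in range(m)
    ]
    return GenotypeMatrix(samples=[f"S{j+1}" for j in range(n)], variants=variants, calls=calls)


class TestSampleCallRate:
    def test_threshold_semantics(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(3, 100)).astype(np.int8)
        calls[1, :4] = MISSING  # 96/100 -> kept
        calls[2, :6] = MISSING  # 94/100 -> removed
        gm = make_gm(calls)
        out, report = qc.sample_call_rate_filter(gm, qc.QCConfig())
        assert out.samples == ["S1", "S2"]
        assert report.steps[0]["reason"] == "call_rate"
        assert report.steps[0]["ids"] == ["S3"]

    def test_all_missing_sample_removed(self):
        calls = np.zeros((2, 10), dtype=np.int8)
        calls[1] = MISSING
        out, report = qc.sample_call_rate_filter(make_gm(calls), qc.QCConfig())
        assert out.samples == ["S1"]
        assert report.total_removed() == 1


def hwe_oracle(n_aa, n_ab, n_bb):
    """Independent direct enumeration of the Levene-Haldane distribution."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    if na == 0 or na == 2 * n:
        return 1.0

    def logp(h):
        a = (na - h) // 2
        b = n - h - a
        return (
            h * np.log(2)
            - gammaln(a + 1) - gammaln(h + 1) - gammaln(b + 1)
            + gammaln(n + 1) + gammaln(na + 1) + gammaln(2 * n - na + 1) - gammaln(2 * n + 1)
        )

    hets = range(na % 2, min(na, 2 * n - na) + 1, 2)
    probs = {h: float(np.exp(logp(h))) for h in hets}
    p_obs = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert qc.hwe_exact_test(100, 0, 0) == 1.0
        assert qc.hwe_exact_test(0, 0, 50) == 1.0

    def test_balanced_table_matches_enumeration(self):
        assert qc.hwe_exact_test(25, 50, 25) == pytest.approx(hwe_oracle(25, 50, 25), abs=1e-12)

    def test_all_het_far_below_threshold(self):
        p = qc.hwe_exact_test(0, 100, 0)
        assert p == pytest.approx(hwe_oracle(0, 100, 0), rel=1e-9)
        assert p < 1e-6  # excluded downstream at the 1e-6 threshold

    def test_randomized_sweep_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 201))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            assert qc.hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                hwe_oracle(n_aa, n_ab, n_bb), abs=1e-12
            )


class TestVariantFilter:
    def test_palindromic_removed_when_flagged(self):
        gm = make_gm(np.array([[0, 0], [1, 1], [2, 2], [1, 1]]), alleles=[("A", "T"), ("A", "G")])
        out, report = qc.variant_filter(gm, qc.QCConfig(variant_maf_min=0.0, exclude_palindromic=True))
        assert [v.id for v in out.variants] == ["rs2"]
        assert any(s["reason"] == "palindromic" and s["ids"] == ["rs1"] for s in report.steps)

    def test_maf_threshold_presets(self):
        # one alt allele in 12 -> MAF 1/24 ~ 0.042
        calls = np.array([[1], [0], [0], [0], [0], [0], [0], [0], [0], [0], [0], [0]])
        gm = make_gm(calls)
        kept_grm, _ = qc.variant_filter(gm, qc.preset("grm"))
        kept_pca, _ = qc.variant_filter(gm, qc.preset("pca"))
        assert kept_grm.n_variants == 0  # removed under MAF < 0.05
        assert kept_pca.n_variants == 1  # kept under MAF < 1e-4

    def test_sex_chromosome_removed(self):
        gm = make_gm(np.array([[1, 1], [0, 1], [1, 0], [2, 1]]), chroms=["X", "1"])
        out, report = qc.variant_filter(gm, qc.QCConfig(variant_maf_min=0.0))
        assert [v.chrom for v in out.variants] == ["1"]
        assert any(s["reason"] == "sex_chrom" and s["n_removed"] == 1 for s in report.steps)

    def test_region_mask_and_counts_conserve(self):
        gm = make_gm(
            np.array([[1, 1], [0, 1], [1, 0]]),
            chroms=["6", "6"],
            positions=[26_000_000, 40_000_000],
        )
        out, report = qc.variant_filter(gm, qc.QCConfig(variant_maf_min=0.0))
        assert out.n_variants + report.total_removed() == gm.n_variants
        assert any(s["reason"] == "region_mask" and s["ids"] == ["rs1"] for s in report.steps)

    def test_hwe_failure_removed(self):
        calls = np.ones((100, 1), dtype=np.int8)  # all het: extreme HWE deviation
        out, report = qc.variant_filter(make_gm(calls), qc.QCConfig(variant_maf_min=0.0))
        assert out.n_variants == 0
        assert any(s["reason"] == "hwe" for s in report.steps if s["n_removed"])


def ld_prune_oracle(gm, config):
    """Naive reimplementation of the window schedule + greedy removal rule."""
    freqs = gm.allele_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    alive = {v.id for v in gm.variants}
    idx_all = list(range(gm.n_variants))
    s = 0
    while True:
        window = idx_all[s : s + config.ld_window_snps]
        if len(window) >= 2:
            while True:
                live = [i for i in window if gm.variants[i].id in alive]
                pair = None
                for a in range(len(live)):
                    for b in range(a + 1, len(live)):
                        i, j = live[a], live[b]
                        x, y = gm.calls[:, i].astype(float), gm.calls[:, j].astype(float)
                        if x.std() == 0 or y.std() == 0:
                            continue
                        r = np.corrcoef(x, y)[0, 1] ** 2
                        if r > config.ld_r2_max:
                            pair = (i, j)
                            break
                    if pair:
                        break
                if not pair:
                    break
                i, j = pair
                drop = i if maf[i] < maf[j] else j if maf[j] < maf[i] else j
                alive.discard(gm.variants[drop].id)
        if s + config.ld_window_snps >= len(idx_all):
            break
        s += config.ld_step_snps
    return [v.id for v in gm.variants if v.id in alive]


class TestLDPrune:
    def test_duplicate_column_keeps_exactly_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=50)
        calls = np.column_stack([col, col, rng.integers(0, 3, size=50)]).astype(np.int8)
        gm = make_gm(calls)
        kept = qc.ld_prune(gm, qc.QCConfig(ld_window_snps=3, ld_step_snps=1))
        assert len([k for k in kept if k in ("rs1", "rs2")]) == 1
        assert "rs3" in kept

    def test_independent_variants_all_survive(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(200, 20)).astype(np.int8)
        gm = make_gm(calls)
        kept = qc.ld_prune(gm, qc.QCConfig(ld_window_snps=10, ld_step_snps=2, ld_r2_max=0.5))
        assert len(kept) == 20

    def test_matches_exhaustive_oracle_on_correlated_toy(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, size=(80, 4)).astype(np.int8)
        # build 10 variants with planted correlation structure
        cols = [base[:, 0], base[:, 0], base[:, 1], 2 - base[:, 1], base[:, 2],
                rng.integers(0, 3, 80), base[:, 3], base[:, 3], base[:, 3],
                rng.integers(0, 3, 80)]
        calls = np.column_stack(cols).astype(np.int8)
        gm = make_gm(calls)
        cfg = qc.QCConfig(ld_window_snps=5, ld_step_snps=2, ld_r2_max=0.5)
        assert qc.ld_prune(gm, cfg) == ld_prune_oracle(gm, cfg)

    def test_no_surviving_pair_above_threshold_in_any_window(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 3, size=(60, 6)).astype(np.int8)
        cols = [base[:, i % 6] for i in range(18)]
        calls = np.column_stack(cols).astype(np.int8)
        gm = make_gm(calls)
        cfg = qc.QCConfig(ld_window_snps=6, ld_step_snps=3, ld_r2_max=0.4)
        kept = set(qc.ld_prune(gm, cfg))
        idx = [i for i, v in enumerate(gm.variants) if v.id in kept]
        s = 0
        while True:
            window = [i for i in range(s, min(s + 6, 18)) if i in idx]
            for a in range(len(window)):
                for b in range(a + 1, len(window)):
                    x = gm.calls[:, window[a]].astype(float)
                    y = gm.calls[:, window[b]].astype(float)
                    if x.std() and y.std():
                        assert np.corrcoef(x, y)[0, 1] ** 2 <= 0.4
            if s + 6 >= 18:
                break
            s += 3


class TestHarmonizeMerge:
    def _pair(self, cohort_alleles, panel_alleles, cohort_call=1, panel_call=1):
        g1 = make_gm(np.array([[cohort_call]]), alleles=[cohort_alleles])
        g2 = make_gm(np.array([[panel_call]]), alleles=[panel_alleles])
        g2.samples = ["P1"]
        return g1, g2

    def test_ref_alt_swap_flips_dosage(self):
        g1, g2 = self._pair(("A", "G"), ("G", "A"), cohort_call=1, panel_call=0)
        merged, _ = qc.harmonize_merge(g1, g2)
        assert merged.calls[1, 0] == 2  # panel 0 -> flipped to 2

    def test_strand_complement_matches(self):
        g1, g2 = self._pair(("A", "G"), ("T", "C"), panel_call=2)
        merged, _ = qc.harmonize_merge(g1, g2)
        assert merged.calls[1, 0] == 2  # same orientation after complement

    def test_allele_mismatch_dropped(self):
        g1a = make_gm(np.array([[1, 1]]), alleles=[("A", "G"), ("A", "C")])
        g2a = make_gm(np.array([[1, 1]]), alleles=[("A", "G"), ("A", "G")])
        g2a.samples = ["P1"]
        merged, report = qc.harmonize_merge(g1a, g2a)
        assert [v.id for v in merged.variants] == ["rs1"]
        assert any(s["reason"] == "allele_mismatch" and s["ids"] == ["rs2"] for s in report.steps)

    def test_multiallelic_dropped(self):
        v_multi = Variant(id="rs1", chrom="1", pos_bp=100, ref_allele="A", alt_allele="G", extra_alts=["T"])
        v_bi = Variant(id="rs2", chrom="1", pos_bp=200, ref_allele="A", alt_allele="G")
        g1 = GenotypeMatrix(samples=["S1"], variants=[v_multi, v_bi], calls=np.array([[1, 1]], dtype=np.int8))
        g2 = make_gm(np.array([[1, 1]]))
        g2.samples = ["P1"]
        merged, report = qc.harmonize_merge(g1, g2)
        assert [v.id for v in merged.variants] == ["rs2"]

    def test_zero_shared_is_hard_error(self):
        g1 = make_gm(np.array([[1]]), ids=["rsX"])
        g2 = make_gm(np.array([[1]]), ids=["rsY"])
        g2.samples = ["P1"]
        with pytest.raises(genio.DataError, match="no shared variants"):
            qc.harmonize_merge(g1, g2)
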