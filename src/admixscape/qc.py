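"""Variant/sample quality control and cross-dataset harmonization.

The filter cascade mirrors common array-genotyping practice: sample call-rate
filtering, marker exclusions (non-rs ids, sex chromosomes, palindromic
alleles, masked regions such as the extended HLA), MAF and Hardy-Weinberg
thresholds, sliding-window LD pruning, and an allele-aware merge with a
reference panel.  Two presets are provided: "grm" (MAF 0.05, r2 0.5) for
relatedness estimation and "pca" (MAF 1e-4, r2 0.2) for structure analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, DataError

SEX_CHROMS = {"X", "Y", "XY", "MT", "23", "24", "25", "26", "chrX", "chrY"}

#: Long-range LD / extended MHC mask (GRCh37-style coordinates); overrideable.
DEFAULT_REGION_MASK = [("6", 25_000_000, 35_000_000)]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class QCConfig:
    sample_call_rate_min: float = 0.95
    variant_maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_max: float = 0.5
    exclude_sex_chroms: bool = True
    exclude_palindromic: bool = True
    require_rs_ids: bool = False
    region_mask: list = field(default_factory=lambda: list(DEFAULT_REGION_MASK))

    def __post_init__(self) -> None:
        if not 0 < self.sample_call_rate_min <= 1:
            raise ValueError("sample_call_rate_min must be in (0, 1]")
        if not 0 <= self.variant_maf_min < 0.5:
            raise ValueError("variant_maf_min must be in [0, 0.5)")
        if self.ld_window_snps <= self.ld_step_snps:
            raise ValueError("ld_window_snps must exceed ld_step_snps")


def preset(name: str) -> QCConfig:
    """The two QC presets: 'grm' (MAF 0.05, r2 0.5) and 'pca' (MAF 1e-4, r2 0.2)."""
    if name == "grm":
        return QCConfig(variant_maf_min=0.05, ld_r2_max=0.5)
    if name == "pca":
        return QCConfig(variant_maf_min=1e-4, ld_r2_max=0.2)
    raise ValueError(f"unknown QC preset {name!r} (expected 'grm' or 'pca')")


@dataclass
class QCReport:
    """Per-step removal counts with reason codes; kept + removed = input."""

    steps: list = field(default_factory=list)  # (step, reason, n_removed, ids)

    def add(self, step: str, reason: str, ids: list) -> None:
        self.steps.append({"step": step, "reason": reason, "n_removed": len(ids), "ids": list(ids)})

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: s[k] for k in ("step", "reason", "n_removed")} for s in self.steps]
        )

    def total_removed(self) -> int:
        return sum(s["n_removed"] for s in self.steps)


# ---------------------------------------------------------------------------
# Sample filter


def sample_call_rate_filter(gm: GenotypeMatrix, config: QCConfig) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples whose fraction of non-missing calls is below threshold."""
    report = QCReport()
    rate = (gm.calls != MISSING).mean(axis=1)
    keep = rate >= config.sample_call_rate_min
    removed = [s for s, k in zip(gm.samples, keep) if not k]
    report.add("sample_call_rate", "call_rate", removed)
    kept_ids = [s for s, k in zip(gm.samples, keep) if k]
    return gm.subset_samples(kept_ids), report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Levene-Haldane)


def _hwe_het_distribution(n_het: int, n_hom_minor: int, n_hom_major: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of heterozygote count given allele counts.

    Returns (possible het counts, probabilities).  Computed with the standard
    stable recurrence on the ratio of successive probabilities.
    """
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    het_min = n_minor % 2
    het_max = min(n_minor, 2 * n - n_minor)
    hets = np.arange(het_min, het_max + 1, 2)
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i]
        # P(h) / P(h-2) = [ (n_minor-h+2)(2n-n_minor-h+2) ] / [ h (h-1) ]  -- from the hypergeometric-type pmf
        num = (n_minor - h + 2) * (2 * n - n_minor - h + 2)
        logp[i] = logp[i - 1] + np.log(num) - np.log(h * (h - 1))
    p = np.exp(logp - logp.max())
    return hets, p / p.sum()


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value (Levene-Haldane).

    Sums the probabilities of all heterozygote counts whose conditional
    probability (given allele counts) does not exceed that of the observed
    count.  Monomorphic sites return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("empty genotype table")
    n_alt = 2 * n_hom_alt + n_het
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0
    if n_alt <= n:  # alt is minor
        hom_minor, hom_major = n_hom_alt, n_hom_ref
    else:
        hom_minor, hom_major = n_hom_ref, n_hom_alt
    hets, probs = _hwe_het_distribution(n_het, hom_minor, hom_major)
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Variant filter


def variant_filter(gm: GenotypeMatrix, config: QCConfig) -> tuple[GenotypeMatrix, QCReport]:
    """Marker exclusions: id/chromosome/allele/region rules, then MAF and HWE.

    Each removed variant carries one reason code (the first failing rule in
    the order: non_rs, sex_chrom, palindromic, region_mask, maf, hwe).
    """
    report = QCReport()
    reasons: dict[str, list[str]] = {k: [] for k in ("non_rs", "sex_chrom", "palindromic", "region_mask", "maf", "hwe")}
    keep = np.ones(gm.n_variants, dtype=bool)
    freqs = gm.allele_freqs()
    for i, v in enumerate(gm.variants):
        if config.require_rs_ids and not v.id.startswith("rs"):
            reasons["non_rs"].append(v.id); keep[i] = False; continue
        if config.exclude_sex_chroms and v.chrom in SEX_CHROMS:
            reasons["sex_chrom"].append(v.id); keep[i] = False; continue
        if config.exclude_palindromic and v.is_palindromic:
            reasons["palindromic"].append(v.id); keep[i] = False; continue
        if any(v.chrom == c and s <= v.pos_bp <= e for c, s, e in config.region_mask):
            reasons["region_mask"].append(v.id); keep[i] = False; continue
        f = freqs[i]
        maf = np.nan if np.isnan(f) else min(f, 1 - f)
        if np.isnan(maf) or maf < config.variant_maf_min:
            reasons["maf"].append(v.id); keep[i] = False; continue
        col = gm.calls[:, i]
        col = col[col != MISSING]
        counts = [int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())]
        if hwe_exact_test(*counts) < config.hwe_p_min:
            reasons["hwe"].append(v.id); keep[i] = False
    for reason, ids in reasons.items():
        report.add("variant_filter", reason, ids)
    return gm.subset_variants(keep), report


# ---------------------------------------------------------------------------
# LD pruning


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, config: QCConfig) -> list[str]:
    """PLINK-style sliding-window pruning; returns surviving variant ids.

    Windows of ``ld_window_snps`` markers advance by ``ld_step_snps`` within
    each chromosome (variants must be position-sorted).  Within a window, while
    any surviving pair exceeds ``ld_r2_max``, the first offending pair in scan
    order loses its lower-MAF member (ties: the later position is removed).
    """
    freqs = gm.allele_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    alive = np.ones(gm.n_variants, dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    last: dict[str, int] = {}
    for i, v in enumerate(gm.variants):
        by_chrom.setdefault(v.chrom, []).append(i)
        if v.chrom in last and v.pos_bp < gm.variants[last[v.chrom]].pos_bp:
            raise DataError("variants must be sorted by (chrom, pos) for LD pruning")
        last[v.chrom] = i
    for chrom, idx in by_chrom.items():
        idx = np.array(idx)
        starts = range(0, max(1, len(idx)), config.ld_step_snps)
        for s in starts:
            window = idx[s : s + config.ld_window_snps]
            if len(window) >= 2:
                r2 = _window_r2(gm.calls[:, window])
                changed = True
                while changed:
                    changed = False
                    live = [k for k, i in enumerate(window) if alive[i]]
                    for a in range(len(live)):
                        for b in range(a + 1, len(live)):
                            ka, kb = live[a], live[b]
                            if r2[ka, kb] > config.ld_r2_max:
                                i, j = window[ka], window[kb]
                                if maf[i] < maf[j]:
                                    drop = i
                                elif maf[j] < maf[i]:
                                    drop = j
                                else:  # tie: remove the later position
                                    drop = j if gm.variants[j].pos_bp >= gm.variants[i].pos_bp else i
                                alive[drop] = False
                                changed = True
                                break
                        if changed:
                            break
            if s + config.ld_window_snps >= len(idx):
                break
    return [gm.variants[i].id for i in np.flatnonzero(alive)]


def _window_r2(calls: np.ndarray) -> np.ndarray:
    """Pairwise dosage r2 within one window (pairwise-complete over samples)."""
    w = calls.shape[1]
    if (calls == MISSING).any():
        out = np.zeros((w, w))
        for a in range(w):
            for b in range(a + 1, w):
                out[a, b] = out[b, a] = _dosage_r2(calls[:, a], calls[:, b])
        return out
    x = calls.astype(float)
    sd = x.std(axis=0)
    ok = sd > 0
    out = np.zeros((w, w))
    if ok.sum() >= 2:
        c = np.corrcoef(x[:, ok], rowvar=False)
        sub = np.square(c)
        out[np.ix_(ok, ok)] = sub
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Cross-dataset merge


def harmonize_merge(g_cohort: GenotypeMatrix, g_panel: GenotypeMatrix) -> tuple[GenotypeMatrix, QCReport]:
    """Merge cohort and panel on shared variants with allele harmonization.

    Variants are intersected by id.  Alleles must match directly, by ref/alt
    swap (panel dosage flipped d -> 2-d), by strand complement, or by both;
    anything else is dropped, as are multiallelic records on either side.
    Samples are concatenated (cohort first) on the cohort's orientation.
    """
    report = QCReport()
    panel_by_id = {v.id: i for i, v in enumerate(g_panel.variants)}
    keep_cohort: list[int] = []
    panel_cols: list[np.ndarray] = []
    dropped_unmatched, dropped_multi, dropped_mismatch = [], [], []
    for i, v in enumerate(g_cohort.variants):
        j = panel_by_id.get(v.id)
        if j is None:
            dropped_unmatched.append(v.id)
            continue
        w = g_panel.variants[j]
        if v.is_multiallelic or w.is_multiallelic:
            dropped_multi.append(v.id)
            continue
        col = g_panel.calls[:, j]
        r, a = v.ref_allele.upper(), v.alt_allele.upper()
        wr, wa = w.ref_allele.upper(), w.alt_allele.upper()
        if (wr, wa) == (r, a):
            pass
        elif (wr, wa) == (a, r):
            col = np.where(col == MISSING, MISSING, 2 - col)
        elif (COMPLEMENT.get(wr), COMPLEMENT.get(wa)) == (r, a):
            pass
        elif (COMPLEMENT.get(wr), COMPLEMENT.get(wa)) == (a, r):
            col = np.where(col == MISSING, MISSING, 2 - col)
        else:
            dropped_mismatch.append(v.id)
            continue
        keep_cohort.append(i)
        panel_cols.append(col.astype(np.int8))
    report.add("harmonize", "not_in_panel", dropped_unmatched)
    report.add("harmonize", "multiallelic", dropped_multi)
    report.add("harmonize", "allele_mismatch", dropped_mismatch)
    if not keep_cohort:
        raise DataError("harmonize_merge: no shared variants after allele matching")
    sub = g_cohort.subset_variants(np.array(keep_cohort))
    merged_calls = np.concatenate([sub.calls, np.stack(panel_cols, axis=1)], axis=0)
    merged = GenotypeMatrix(
        samples=list(sub.samples) + list(g_panel.samples),
        variants=list(sub.variants),
        calls=merged_calls,
    )
    return merged, report
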