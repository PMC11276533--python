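"""Post-admixture selection scan on per-SNP mean local ancestry.

For each ancestry a, the scan statistic at SNP i is the cohort mean diploid
dosage/2, z-scored against the genome-wide mean and SD (across SNPs,
denominator M-1) of that ancestry.  Loci are flagged at |z| > 3 (suggestive)
and |z| > 4.42, the deviation equivalent to a two-sided normal p-value of
1e-5.  Each locus is considered independently; no correction for
autocorrelation between adjacent SNPs (LD / shared tracts) is applied, so
the z-scores are descriptive rather than calibrated test statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import Variant

THRESHOLD_SUGGESTIVE = 3.0
THRESHOLD_SELECTION = 4.42  # |z| for two-sided p = 1e-5, to 2 dp


@dataclass
class ScanTable:
    """Per-SNP, per-ancestry scan results plus per-ancestry summaries."""

    table: pd.DataFrame  # columns: chrom, pos, ancestry, mean, z, flag3sd, flag442sd
    summary: pd.DataFrame  # per ancestry: genome-wide mean, between-SNP SD, flag counts


def ancestry_scan(
    dosages: np.ndarray,
    variants: list[Variant],
    ancestries: tuple[str, ...],
    per_chromosome_sd: bool = False,
) -> ScanTable:
    """Scan mean local-ancestry dosages for deviations from the genome average.

    ``dosages`` is (N, M, A) diploid copies in [0, 2].  SD is computed across
    SNPs genome-wide per ancestry by default (``per_chromosome_sd`` recomputes
    mean/SD within each chromosome instead).  A degenerate ancestry with zero
    between-SNP SD yields undefined z, flagged via NaN.
    """
    n, m, a = dosages.shape
    if n < 30:
        warnings.warn(f"ancestry_scan: only {n} samples; means are noisy below ~30")
    mean_prop = dosages.mean(axis=0) / 2.0  # M x A
    chroms = np.array([v.chrom for v in variants])
    pos = np.array([v.pos_bp for v in variants])
    z = np.full((m, a), np.nan)
    mu = np.empty(a)
    sd = np.empty(a)
    if per_chromosome_sd:
        for chrom in dict.fromkeys(chroms):
            sel = chroms == chrom
            mu_c = mean_prop[sel].mean(axis=0)
            sd_c = mean_prop[sel].std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                z[sel] = (mean_prop[sel] - mu_c) / sd_c
        mu = mean_prop.mean(axis=0)
        sd = mean_prop.std(axis=0, ddof=1)
    else:
        mu = mean_prop.mean(axis=0)
        sd = mean_prop.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (mean_prop - mu) / sd
        z[:, sd == 0] = np.nan
    rows = []
    for k, anc in enumerate(ancestries):
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chroms,
                    "pos": pos,
                    "ancestry": anc,
                    "mean": mean_prop[:, k],
                    "z": z[:, k],
                    "flag3sd": np.abs(z[:, k]) > THRESHOLD_SUGGESTIVE,
                    "flag442sd": np.abs(z[:, k]) > THRESHOLD_SELECTION,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    summary = pd.DataFrame(
        {
            "ancestry": list(ancestries),
            "genome_mean": mu,
            "between_snp_sd": sd,
            "degenerate": sd == 0,
            "n_flag3sd": [int(table.loc[table.ancestry == anc, "flag3sd"].sum()) for anc in ancestries],
            "n_flag442sd": [int(table.loc[table.ancestry == anc, "flag442sd"].sum()) for anc in ancestries],
        }
    )
    return ScanTable(table=table, summary=summary)


def sd_to_pvalue(z: float) -> float:
    """Two-sided normal tail probability for a deviation of z SDs."""
    if z < 0:
        raise ValueError("z must be non-negative")
    return float(2.0 * stats.norm.sf(z))


def pvalue_to_sd(p: float) -> float:
    """Deviation in SDs equivalent to a two-sided normal p-value."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    return float(stats.norm.isf(p / 2.0))
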