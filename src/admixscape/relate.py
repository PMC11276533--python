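"""Genomic relatedness and selection of a pseudo-independent sample.

The GRM is the standard allele-frequency-standardized cross-product
(VanRaden/GCTA form).  Pairs whose estimated kinship K = A_jk / 2 exceeds the
configured threshold (default 0.125, the second-degree expectation) form a
graph; repeatedly deleting the most-connected individual — breaking ties with
the household prior (keep the head, then the elder) — leaves a set with no
remaining close pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, SampleTable


@dataclass
class GRM:
    sample_ids: list[str]
    matrix: np.ndarray  # symmetric N x N
    n_snps: int

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, float)
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if not np.isfinite(a).all():
            raise ValueError("GRM entries must be finite")
        self.matrix = a

    def long_frame(self) -> pd.DataFrame:
        """Long-format (id1, id2, value) for the upper triangle incl. diagonal."""
        ids = self.sample_ids
        rows = [
            (ids[i], ids[j], self.matrix[i, j])
            for i in range(len(ids))
            for j in range(i, len(ids))
        ]
        return pd.DataFrame(rows, columns=["id1", "id2", "value"])


@dataclass
class RelatednessConfig:
    #: Exclusion threshold on estimated kinship K (relatedness / 2).  The
    #: second-degree expectation is K = 0.125; set ``threshold_scale`` to
    #: "relatedness" to threshold A_jk itself at the same number instead.
    kinship_exclusion_threshold: float = 0.125
    threshold_scale: str = "kinship"  # or "relatedness"
    use_household_prior: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.kinship_exclusion_threshold < 0.5:
            raise ValueError("kinship_exclusion_threshold must be in (0, 0.5)")
        if self.threshold_scale not in ("kinship", "relatedness"):
            raise ValueError("threshold_scale must be 'kinship' or 'relatedness'")


def compute_grm(gm: GenotypeMatrix) -> GRM:
    """A_jk = (1/M) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1-p_i)).

    p_i is the sample alt-allele frequency; missing calls are imputed to 2p_i
    for their term (contributing zero).  Monomorphic variants are skipped with
    a warning.
    """
    p = gm.allele_freqs()
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    if (~poly).any():
        warnings.warn(f"compute_grm: skipping {(~poly).sum()} monomorphic/all-missing variants")
    x = gm.calls[:, poly].astype(float)
    p = p[poly]
    x[gm.calls[:, poly] == MISSING] = np.nan
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = np.nan_to_num(z, nan=0.0)  # missing contributes zero
    m = z.shape[1]
    a = (z @ z.T) / m
    a = (a + a.T) / 2
    return GRM(sample_ids=list(gm.samples), matrix=a, n_snps=m)


def expected_relatedness(degree: int) -> tuple[float, float]:
    """Expected (relatedness 2K, kinship K) for a relationship degree.

    Relatedness halves with each meiosis: 2K = (1/2)^degree, K = (1/2)^(degree+1);
    degree 2 gives the classic K = 0.125 exclusion threshold.
    """
    if degree < 1 or int(degree) != degree:
        raise ValueError("degree must be a positive integer")
    return 0.5 ** degree, 0.5 ** (degree + 1)


def select_pseudo_independent(
    grm: GRM, samples: SampleTable | None = None, config: RelatednessConfig | None = None
) -> list[str]:
    """Greedy max-degree pruning of the close-relative graph; returns kept ids.

    An edge joins two samples whose estimated kinship exceeds the threshold.
    The node with most edges is deleted until the graph is edgeless.  Ties are
    broken by the household prior (delete non-heads before heads, then the
    younger) and finally by sample id, making the result deterministic.
    """
    config = config or RelatednessConfig()
    ids = grm.sample_ids
    n = len(ids)
    est = grm.matrix / 2.0 if config.threshold_scale == "kinship" else grm.matrix
    adj = est > config.kinship_exclusion_threshold
    np.fill_diagonal(adj, False)

    is_head = np.zeros(n, dtype=bool)
    age = np.zeros(n)
    if samples is not None and config.use_household_prior:
        meta = samples.frame.set_index("sample_id")
        for i, sid in enumerate(ids):
            if sid in meta.index:
                is_head[i] = meta.at[sid, "relationship_to_head"] == "head"
                age[i] = meta.at[sid, "age_years"]

    alive = np.ones(n, dtype=bool)
    while True:
        deg = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max() == 0:
            break
        cand = np.flatnonzero(deg == deg.max())
        # delete preference: non-head before head, younger before elder, then larger id
        order = sorted(cand, key=lambda i: (is_head[i], age[i], [-ord(c) for c in ids[i]]))
        alive[order[0]] = False
    return [ids[i] for i in range(n) if alive[i]]
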