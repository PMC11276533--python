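"""Population structure and global ancestry proportions.

Two estimators of the per-individual ancestry simplex vector q are provided
and cross-checked against each other on synthetic cohorts:

* ``pc_simplex_proportions`` — PCA of the standardized genotype matrix with
  reference-population centroids as simplex vertices; q solves a constrained
  least-squares problem in PC space.  Related individuals excluded from the
  PCA fit are projected with the stored SNP loadings (no shrinkage
  correction is applied; projected scores are slightly attenuated).
* ``supervised_em`` — maximum-likelihood admixture proportions under
  x_i ~ Binomial(2, sum_a q_a f_ai) with fixed panel frequencies, fit by EM.

``homogenize_panel`` screens reference candidates by leave-self-out
supervised EM and keeps those whose estimated own-label ancestry exceeds a
threshold (default 0.95), mimicking the construction of a near-homogeneous
reference panel from a public catalog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .genio import MISSING, GenotypeMatrix, DataError


@dataclass
class PCAModel:
    """Fitted PCA of standardized genotypes (alleles scaled by sqrt(2p(1-p)))."""

    snp_ids: list[str]
    mean: np.ndarray  # per-SNP 2p
    scale: np.ndarray  # per-SNP sqrt(2p(1-p))
    loadings: np.ndarray  # M x K, orthonormal columns
    eigenvalues: np.ndarray  # length K, non-increasing
    scores: np.ndarray  # N x K for the fitting samples
    sample_ids: list[str]
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loadings must be orthonormal")


@dataclass
class AncestryProportions:
    """Per-sample simplex vectors over labeled ancestries."""

    q: pd.DataFrame  # index sample_id, columns ancestry labels
    method: str  # "pc_simplex" or "supervised_em"
    converged: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.q.to_numpy()
        if (arr < -1e-8).any():
            raise ValueError("ancestry proportions must be non-negative")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("ancestry proportions must sum to 1")


@dataclass
class ReferencePanel:
    genotypes: GenotypeMatrix
    labels: pd.Series  # sample_id -> population
    freqs: pd.DataFrame  # index variant id, columns populations

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)


def panel_allele_freqs(gm: GenotypeMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-population alt-allele frequencies over non-missing calls."""
    cols = {}
    for pop in pd.unique(labels):
        ids = [s for s in gm.samples if labels.get(s) == pop]
        sub = gm.subset_samples(ids)
        cols[pop] = sub.allele_freqs()
    return pd.DataFrame(cols, index=gm.variant_ids)


# ---------------------------------------------------------------------------
# PCA


def fit_pca(gm: GenotypeMatrix, n_components: int) -> PCAModel:
    """PCA of the N x M standardized genotype matrix via SVD.

    Standardization is (x - 2p) / sqrt(2p(1-p)) with p estimated from the
    fitting set; missing calls are centered to zero.  Eigenvalues are those of
    the sample covariance across individuals, sorted in decreasing order.
    Monomorphic variants are dropped with a warning.
    """
    if n_components > min(gm.n_samples, gm.n_variants):
        raise ValueError("n_components exceeds min(N, M)")
    p = gm.allele_freqs()
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    if (~poly).any():
        warnings.warn(f"fit_pca: dropping {(~poly).sum()} monomorphic variants")
    ids = [v.id for v, ok in zip(gm.variants, poly) if ok]
    p = p[poly]
    mean = 2 * p
    scale = np.sqrt(2 * p * (1 - p))
    x = gm.calls[:, poly].astype(float)
    x[gm.calls[:, poly] == MISSING] = np.nan
    z = (x - mean) / scale
    z = np.nan_to_num(z, nan=0.0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = n_components
    eigvals = (s ** 2) / max(1, gm.n_samples - 1)
    return PCAModel(
        snp_ids=ids,
        mean=mean,
        scale=scale,
        loadings=vt[:k].T,
        eigenvalues=eigvals[:k],
        scores=u[:, :k] * s[:k],
        sample_ids=list(gm.samples),
        variance_explained=eigvals[:k] / eigvals.sum(),
    )


def project_samples(model: PCAModel, gm: GenotypeMatrix) -> pd.DataFrame:
    """Project new samples onto fitted loadings using the model's means/scales.

    Missing sites (or model SNPs absent from the input) contribute zero after
    centering.  Fails if fewer than half the model SNPs are present.
    """
    pos = {vid: i for i, vid in enumerate(gm.variant_ids)}
    idx = np.array([pos.get(vid, -1) for vid in model.snp_ids])
    present = idx >= 0
    if present.sum() < 0.5 * len(model.snp_ids):
        raise DataError(
            f"project_samples: only {present.sum()}/{len(model.snp_ids)} model SNPs present (<50%)"
        )
    z = np.zeros((gm.n_samples, len(model.snp_ids)))
    x = gm.calls[:, idx[present]].astype(float)
    x[x == MISSING] = np.nan
    zp = (x - model.mean[present]) / model.scale[present]
    z[:, present] = np.nan_to_num(zp, nan=0.0)
    scores = z @ model.loadings
    cols = [f"PC{i + 1}" for i in range(model.loadings.shape[1])]
    return pd.DataFrame(scores, index=gm.samples, columns=cols)


def panel_centroids(scores: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-population mean PC scores of reference samples (simplex vertices)."""
    lab = labels.reindex(scores.index)
    return scores.groupby(lab).mean()


def pc_simplex_proportions(scores: pd.DataFrame | np.ndarray, centroids: pd.DataFrame) -> AncestryProportions:
    """Ancestry proportions from PC coordinates relative to panel centroids.

    Solves min_q || s - sum_a q_a c_a ||^2 subject to q >= 0 and sum q = 1 by
    non-negative least squares on the system augmented with a heavily weighted
    row of ones, then renormalizes.  Requires the A centroids to be affinely
    independent in K >= A-1 dimensions.
    """
    c = centroids.to_numpy(float)  # A x K
    pops = list(centroids.index)
    a_n, k = c.shape
    if k < a_n - 1:
        raise ValueError(f"need K >= A-1 PCs ({a_n - 1}), got {k}")
    diffs = c - c[0]
    if np.linalg.matrix_rank(diffs[1:], tol=1e-8) < a_n - 1:
        # name the closest pair for the error message
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(f"degenerate centroids: {pops[i]} and {pops[j]} are affinely dependent")
    if isinstance(scores, pd.DataFrame):
        index = list(scores.index)
        s = scores.to_numpy(float)
    else:
        s = np.atleast_2d(np.asarray(scores, float))
        index = list(range(len(s)))
    w = 1e4 * (1 + np.abs(c).max())
    design = np.vstack([c.T, w * np.ones((1, a_n))])  # (K+1) x A
    out = np.empty((len(s), a_n))
    for n in range(len(s)):
        target = np.concatenate([s[n], [w]])
        q, _ = nnls(design, target)
        total = q.sum()
        out[n] = q / total if total > 0 else np.full(a_n, 1.0 / a_n)
    return AncestryProportions(q=pd.DataFrame(out, index=index, columns=pops), method="pc_simplex")


# ---------------------------------------------------------------------------
# Supervised admixture EM


def _em_loglik(x: np.ndarray, miss: np.ndarray, theta: np.ndarray) -> np.ndarray:
    ll = x * np.log(theta) + (2 - x) * np.log1p(-theta)
    ll[miss] = 0.0
    return ll.sum(axis=1)


def supervised_em(
    gm: GenotypeMatrix,
    panel_freqs: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 2000,
    return_loglik: bool = False,
):
    """Maximum-likelihood admixture proportions with fixed panel frequencies.

    Model: alt dosage x_i ~ Binomial(2, theta_i), theta_i = sum_a q_a f_ai.
    The EM update is the standard supervised-admixture step; the observed-data
    log-likelihood is non-decreasing every iteration.  Iterates until
    max |delta q| < tol or ``max_iter``; non-convergence is flagged per sample,
    not fatal.
    """
    f = panel_freqs.reindex(gm.variant_ids).to_numpy(float)  # M x A
    if np.isnan(f).any():
        raise DataError("panel_freqs missing entries for some cohort variants")
    f = np.clip(f, 1e-6, 1 - 1e-6)
    pops = list(panel_freqs.columns)
    n, m = gm.n_samples, gm.n_variants
    a_n = f.shape[1]
    x = gm.calls.astype(float)
    miss = gm.calls == MISSING
    x[miss] = 0.0
    n_obs = np.maximum(2.0 * (~miss).sum(axis=1), 1.0)  # alleles observed per sample
    q = np.full((n, a_n), 1.0 / a_n)
    active = np.ones(n, dtype=bool)
    ll_hist = []
    for _ in range(max_iter):
        theta = q @ f.T  # N x M
        theta = np.clip(theta, 1e-12, 1 - 1e-12)
        if return_loglik:
            ll_hist.append(_em_loglik(x, miss, theta))
        # responsibilities: alt alleles to ancestry a w.p. q_a f / theta,
        # ref alleles w.p. q_a (1-f) / (1-theta)
        alt = x / theta
        ref = (2 - x) / (1 - theta)
        alt[miss] = 0.0
        ref[miss] = 0.0
        new_q = q * (alt @ f + ref @ (1 - f)) / n_obs[:, None]
        new_q /= new_q.sum(axis=1, keepdims=True)
        delta = np.abs(new_q - q).max(axis=1)
        q = np.where(active[:, None], new_q, q)
        active = active & (delta >= tol)
        if not active.any():
            break
    converged = pd.Series(~active, index=gm.samples)
    res = AncestryProportions(
        q=pd.DataFrame(q, index=gm.samples, columns=pops), method="supervised_em", converged=converged
    )
    if return_loglik:
        theta = np.clip(q @ f.T, 1e-12, 1 - 1e-12)
        ll_hist.append(_em_loglik(x, miss, theta))
        return res, np.array(ll_hist)
    return res


def homogenize_panel(
    gm: GenotypeMatrix, labels: pd.Series, threshold: float = 0.95, tol: float = 1e-5, max_iter: int = 500
) -> ReferencePanel:
    """Retain reference candidates whose own-label ancestry is >= threshold.

    Each candidate's q is estimated by supervised EM against allele
    frequencies computed from all *other* candidates of each population
    (leave-self-out for the candidate's own label, so a planted admixed sample
    cannot vouch for itself).  Frequencies are recomputed from the retained
    samples.  A population retaining fewer than 10 samples triggers a warning.
    """
    pops = list(pd.unique(labels.reindex(gm.samples).dropna()))
    lab = labels.reindex(gm.samples)
    calls = gm.calls.astype(float)
    miss = gm.calls == MISSING
    calls[miss] = 0.0
    # per-population alt counts and observed allele numbers per variant
    tot = {p: np.zeros(gm.n_variants) for p in pops}
    nobs = {p: np.zeros(gm.n_variants) for p in pops}
    for i, sid in enumerate(gm.samples):
        p = lab.iloc[i]
        tot[p] += calls[i]
        nobs[p] += 2.0 * (~miss[i])
    kept: list[str] = []
    for i, sid in enumerate(gm.samples):
        own = lab.iloc[i]
        cols = {}
        for p in pops:
            if p == own:
                denom = np.maximum(nobs[p] - 2.0 * (~miss[i]), 1.0)
                cols[p] = (tot[p] - calls[i]) / denom
            else:
                cols[p] = tot[p] / np.maximum(nobs[p], 1.0)
        freqs = pd.DataFrame(cols, index=gm.variant_ids)[pops]
        one = gm.subset_samples([sid])
        props = supervised_em(one, freqs, tol=tol, max_iter=max_iter)
        if threshold <= 0 or props.q.iloc[0][own] >= threshold:
            kept.append(sid)
    for p in pops:
        n_kept = sum(1 for s in kept if lab.loc[s] == p)
        if n_kept < 10:
            warnings.warn(f"homogenize_panel: population {p} retains only {n_kept} samples")
    sub = gm.subset_samples(kept)
    freqs = panel_allele_freqs(sub, labels)
    return ReferencePanel(genotypes=sub, labels=labels.loc[kept], freqs=freqs[pops])
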