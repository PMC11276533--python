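"""Haplotype-based local-ancestry inference with a hidden Markov model.

The hidden state at each SNP is the ancestral population of the haplotype
segment.  Between adjacent SNPs separated by d Morgans the chain stays with
probability e^(-g d) and otherwise re-draws the state from the individual's
global proportions q (g = generations since admixture), so tract lengths are
approximately exponential with mean 1/g Morgans.  Emissions are allele
frequencies of the reference panel with a symmetric error rate epsilon that
absorbs genotyping error and panel-frequency noise.  Chromosomes are
independent chains started from q.

Decoding yields per-SNP posteriors (forward-backward) and a Viterbi path;
tracts are maximal runs of constant Viterbi label, with physical bounds at
the outermost SNP positions of the run (not midpoints), exported 0-based
half-open in BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, Variant


@dataclass
class HMMParams:
    """Parameters of the local-ancestry chain for one or more samples."""

    ancestries: tuple[str, ...]
    panel_freqs: np.ndarray  # M x A, aligned with the variant list in use
    generations_g: float = 10.0
    q: np.ndarray | None = None  # stationary/global proportions; uniform if None
    emission_error: float = 0.01

    def __post_init__(self) -> None:
        if self.generations_g < 1:
            raise ValueError("generations_g must be >= 1")
        self.panel_freqs = np.clip(np.asarray(self.panel_freqs, float), 1e-6, 1 - 1e-6)
        a = len(self.ancestries)
        if self.panel_freqs.shape[1] != a:
            raise ValueError("panel_freqs second dimension must match ancestries")
        if self.q is None:
            self.q = np.full(a, 1.0 / a)
        self.q = np.asarray(self.q, float)
        if (self.q < 0).any() or not np.isclose(self.q.sum(), 1.0):
            raise ValueError("q must lie on the simplex")
        self.q = np.clip(self.q, 1e-12, None)
        self.q = self.q / self.q.sum()


def _chrom_blocks(variants: list[Variant]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous per-chromosome index blocks and cM positions (input order)."""
    blocks: list[tuple[list[int], list[float]]] = []
    current = None
    for i, v in enumerate(variants):
        if current is None or v.chrom != current:
            blocks.append(([], []))
            current = v.chrom
        blocks[-1][0].append(i)
        blocks[-1][1].append(v.pos_cM)
    return [(np.array(ix), np.array(cm)) for ix, cm in blocks]


def _emission_probs(alleles: np.ndarray, params: HMMParams) -> np.ndarray:
    """P(observed allele | ancestry) per site, shape (M, A); missing -> 1."""
    f = params.panel_freqs
    eps = params.emission_error
    e1 = f * (1 - eps) + (1 - f) * eps  # P(allele = 1 | a)
    m, a = f.shape
    out = np.ones((m, a))
    obs1 = alleles == 1
    obs0 = alleles == 0
    out[obs1] = e1[obs1]
    out[obs0] = 1 - e1[obs0]
    return out


def hmm_posteriors(
    alleles: np.ndarray, variants: list[Variant], params: HMMParams
) -> tuple[np.ndarray, float]:
    """Forward-backward posteriors for one phased haplotype.

    Returns (posteriors of shape (M, A) summing to 1 per site, log-likelihood).
    Missing sites emit uniformly.
    """
    e = _emission_probs(np.asarray(alleles), params)
    m, a = e.shape
    q = params.q
    post = np.empty((m, a))
    loglik = 0.0
    for idx, cm in _chrom_blocks(variants):
        eb = e[idx]
        t = len(idx)
        stay = np.exp(-params.generations_g * np.diff(cm) / 100.0)  # cM -> Morgans
        alpha = np.empty((t, a))
        c = np.empty(t)
        alpha[0] = q * eb[0]
        c[0] = alpha[0].sum()
        alpha[0] /= c[0]
        for s in range(1, t):
            pred = stay[s - 1] * alpha[s - 1] + (1 - stay[s - 1]) * q
            alpha[s] = pred * eb[s]
            c[s] = alpha[s].sum()
            alpha[s] /= c[s]
        beta = np.empty((t, a))
        beta[-1] = 1.0
        for s in range(t - 2, -1, -1):
            nxt = eb[s + 1] * beta[s + 1]
            beta[s] = (stay[s] * nxt + (1 - stay[s]) * (q @ nxt)) / c[s + 1]
        g = alpha * beta
        post[idx] = g / g.sum(axis=1, keepdims=True)
        loglik += float(np.log(c).sum())
    return post, loglik


def viterbi_path(alleles: np.ndarray, variants: list[Variant], params: HMMParams) -> np.ndarray:
    """Most probable ancestry path for one haplotype (per-SNP state indices).

    Ties are broken toward the previous state, then the lowest ancestry index.
    """
    e = np.log(_emission_probs(np.asarray(alleles), params))
    m, a = e.shape
    logq = np.log(params.q)
    path = np.empty(m, dtype=np.int8)
    for idx, cm in _chrom_blocks(variants):
        eb = e[idx]
        t = len(idx)
        stay = np.exp(-params.generations_g * np.diff(cm) / 100.0)
        v = logq + eb[0]
        back = np.empty((t, a), dtype=np.int8)
        for s in range(1, t):
            # T_ab = stay * delta_ab + (1 - stay) * q_b
            trans = stay[s - 1] * np.eye(a) + (1 - stay[s - 1]) * params.q[None, :]
            cand = v[:, None] + np.log(trans)
            best_val = cand.max(axis=0)
            prev = np.empty(a, dtype=np.int8)
            for b in range(a):
                ties = np.flatnonzero(cand[:, b] >= best_val[b] - 1e-12)
                prev[b] = b if b in ties else ties[0]
            back[s] = prev
            v = best_val + eb[s]
        states = np.empty(t, dtype=np.int8)
        best_end = v.max()
        states[-1] = int(np.flatnonzero(v >= best_end - 1e-12)[0])
        for s in range(t - 1, 0, -1):
            states[s - 1] = back[s, states[s]]
        path[idx] = states
    return path


@dataclass
class LocalAncestryResult:
    """Per-haplotype decodings and derived diploid ancestry dosages."""

    ancestries: tuple[str, ...]
    sample_ids: list[str]
    variants: list[Variant]
    hap_labels: np.ndarray  # N x 2 x M Viterbi states
    posterior_dosage: np.ndarray  # N x M x A, sums to 2 per site
    loglik: np.ndarray = field(default=None)  # N x 2

    def viterbi_dosage(self) -> np.ndarray:
        """Diploid 0/1/2 copies per ancestry from the two Viterbi paths."""
        n, _, m = self.hap_labels.shape
        a = len(self.ancestries)
        out = np.zeros((n, m, a), dtype=np.int8)
        for h in range(2):
            lab = self.hap_labels[:, h, :]
            for k in range(a):
                out[:, :, k] += (lab == k).astype(np.int8)
        return out

    def chrom_mean_proportions(self, use_posterior: bool = True) -> pd.DataFrame:
        """Mean dosage/2 over samples and SNPs for each chromosome."""
        dos = self.posterior_dosage if use_posterior else self.viterbi_dosage().astype(float)
        chroms = [v.chrom for v in self.variants]
        rows = {}
        for chrom in dict.fromkeys(chroms):
            idx = [i for i, c in enumerate(chroms) if c == chrom]
            rows[chrom] = dos[:, idx, :].mean(axis=(0, 1)) / 2.0
        return pd.DataFrame(rows, index=list(self.ancestries)).T

    def sample_mean_q(self, use_posterior: bool = True) -> pd.DataFrame:
        """Genome-wide mean dosage/2 per sample (comparable to global q)."""
        dos = self.posterior_dosage if use_posterior else self.viterbi_dosage().astype(float)
        return pd.DataFrame(dos.mean(axis=1) / 2.0, index=self.sample_ids, columns=list(self.ancestries))

    def tracts_frame(self) -> pd.DataFrame:
        """All haplotype tracts as a BED-like DataFrame."""
        rows = []
        for n, sid in enumerate(self.sample_ids):
            for h in range(2):
                for chrom, s0, e, anc in call_tracts(self.hap_labels[n, h], self.variants):
                    rows.append((chrom, s0, e, f"{sid}_h{h}", self.ancestries[anc]))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_hap", "ancestry"])


def call_tracts(labels: np.ndarray, variants: list[Variant]) -> list[tuple]:
    """Maximal constant-label runs -> (chrom, start_0based, end, ancestry_index).

    Bounds are the outermost SNP positions of the run, half-open BED-style
    (start = first bp - 1, end = last bp).
    """
    tracts = []
    for idx, _ in _chrom_blocks(variants):
        lab = labels[idx]
        run_start = 0
        for i in range(1, len(idx) + 1):
            if i == len(idx) or lab[i] != lab[run_start]:
                first = variants[idx[run_start]]
                last = variants[idx[i - 1]]
                tracts.append((first.chrom, first.pos_bp - 1, last.pos_bp, int(lab[run_start])))
                run_start = i
    return tracts


def tracts_to_labels(tracts: list[tuple], variants: list[Variant]) -> np.ndarray:
    """Re-expand tracts back to per-SNP labels (inverse of call_tracts)."""
    out = np.full(len(variants), -1, dtype=np.int8)
    for chrom, s0, e, anc in tracts:
        for i, v in enumerate(variants):
            if v.chrom == chrom and s0 < v.pos_bp <= e:
                out[i] = anc
    return out


def infer_local_ancestry(
    gm: GenotypeMatrix,
    panel_freqs: pd.DataFrame,
    q: pd.DataFrame | None = None,
    generations_g: float = 10.0,
    emission_error: float = 0.01,
) -> LocalAncestryResult:
    """Decode every phased haplotype in a cohort.

    ``panel_freqs`` is a variant-id-indexed frame (columns = ancestries); ``q``
    optionally supplies per-sample stationary proportions (global estimates),
    otherwise the chain is uniform over ancestries.
    """
    if gm.phased_haplotypes is None:
        raise ValueError("infer_local_ancestry requires phased haplotypes; see diploid_posteriors")
    ancestries = tuple(panel_freqs.columns)
    f = panel_freqs.reindex(gm.variant_ids).to_numpy(float)
    n, m = gm.n_samples, gm.n_variants
    a = len(ancestries)
    hap_labels = np.empty((n, 2, m), dtype=np.int8)
    dosage = np.zeros((n, m, a), dtype=np.float32)
    loglik = np.empty((n, 2))
    for i, sid in enumerate(gm.samples):
        qi = None if q is None else q.loc[sid].to_numpy(float)
        params = HMMParams(
            ancestries=ancestries, panel_freqs=f, generations_g=generations_g, q=qi, emission_error=emission_error
        )
        for h in range(2):
            alleles = gm.phased_haplotypes[i, h]
            post, ll = hmm_posteriors(alleles, gm.variants, params)
            hap_labels[i, h] = viterbi_path(alleles, gm.variants, params)
            dosage[i] += post.astype(np.float32)
            loglik[i, h] = ll
    return LocalAncestryResult(
        ancestries=ancestries,
        sample_ids=list(gm.samples),
        variants=list(gm.variants),
        hap_labels=hap_labels,
        posterior_dosage=dosage,
        loglik=loglik,
    )


def diploid_posteriors(
    genotypes: np.ndarray, variants: list[Variant], params: HMMParams
) -> np.ndarray:
    """Unphased fallback: paired-state HMM over ordered ancestry pairs (A^2 states).

    Emissions are Binomial over the two haplotype ancestries; transitions are
    the product of two independent haplotype chains.  Returns the expected
    diploid ancestry dosage per SNP, shape (M, A), summing to 2.
    """
    f = params.panel_freqs
    eps = params.emission_error
    a = f.shape[1]
    q = params.q
    e1 = f * (1 - eps) + (1 - f) * eps  # M x A
    x = np.asarray(genotypes)
    m = len(x)
    # emission for state (a1, a2): M x A x A
    p0 = (1 - e1)[:, :, None] * (1 - e1)[:, None, :]
    p1 = e1[:, :, None] * (1 - e1)[:, None, :] + (1 - e1)[:, :, None] * e1[:, None, :]
    p2 = e1[:, :, None] * e1[:, None, :]
    emis = np.ones((m, a, a))
    emis[x == 0] = p0[x == 0]
    emis[x == 1] = p1[x == 1]
    emis[x == 2] = p2[x == 2]
    dosage = np.empty((m, a))
    for idx, cm in _chrom_blocks(variants):
        t = len(idx)
        stay = np.exp(-params.generations_g * np.diff(cm) / 100.0)
        alpha = np.empty((t, a, a))
        c = np.empty(t)
        alpha[0] = np.outer(q, q) * emis[idx[0]]
        c[0] = alpha[0].sum()
        alpha[0] /= c[0]
        for s in range(1, t):
            st = stay[s - 1]
            mat = alpha[s - 1]
            # axis 0 (first haplotype), then axis 1 (second haplotype)
            mat = st * mat + (1 - st) * q[:, None] * mat.sum(axis=0)[None, :]
            mat = st * mat + (1 - st) * mat.sum(axis=1)[:, None] * q[None, :]
            alpha[s] = mat * emis[idx[s]]
            c[s] = alpha[s].sum()
            alpha[s] /= c[s]
        beta = np.empty((t, a, a))
        beta[-1] = 1.0
        for s in range(t - 2, -1, -1):
            st = stay[s]
            nxt = emis[idx[s + 1]] * beta[s + 1]
            # sum the next-step factor against the transition on each axis
            b1 = st * nxt + (1 - st) * (nxt * q[None, :]).sum(axis=1, keepdims=True)
            b0 = st * b1 + (1 - st) * (b1 * q[:, None]).sum(axis=0, keepdims=True)
            beta[s] = b0 / c[s + 1]
        g = alpha * beta
        g /= g.sum(axis=(1, 2), keepdims=True)
        dosage[idx] = g.sum(axis=2) + g.sum(axis=1)
    return dosage
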