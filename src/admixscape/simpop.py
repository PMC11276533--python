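"""Synthetic admixed-cohort generator with full ground truth.

Emulates the sampling situation of an urban household survey genotyped on a
SNP array: A ancestral populations differentiated at given F_ST
(Balding-Nichols allele frequencies), admixed individuals whose global
ancestry q is Dirichlet-distributed, local-ancestry mosaics with
exponentially distributed tract lengths from g generations since admixture,
household pedigrees creating first/second-degree relatives, and a noisy
self-report model mapping ancestry to census skin color/race categories.

The tract model places breakpoints as a Poisson process at rate g per Morgan
and draws each segment's ancestry i.i.d. from the individual's q; such
breakpoints may be invisible (same ancestry on both sides), so the effective
switch rate is g * (1 - sum(q^2)).

No post-admixture drift, no LD within ancestral populations, and no mutation
are simulated; genotyping error is limited to an optional uniform
missingness rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, SampleTable, Variant, age_group_of

ANCESTRIES = ("AFR", "EUR", "AMR", "EAS")

# Mean global ancestry of the default scenario (EUR-predominant urban Brazilian
# cohort), normalized onto the simplex.
_RAW_MEAN = np.array([0.19, 0.70, 0.07, 0.02])
DEFAULT_MEAN_Q = _RAW_MEAN / _RAW_MEAN.sum()

#: Self-report utility coefficients: rows = categories, columns = (1, qAFR, qEUR, qAMR).
#: Yellow's negative loadings on all three encode a positive loading on qEAS.
DEFAULT_SELFREPORT_COEF = {
    "Black": (-3.6, 15.0, 0.0, 0.0),
    "Mixed": (0.55, 3.5, 0.0, 3.0),
    "White": (-2.2, 0.0, 5.0, 0.0),
    "Indigenous": (-6.5, 0.0, 0.0, 14.0),
    "Yellow": (10.8, -14.0, -14.0, -14.0),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic scenario (defaults: "saopaulo-like").

    ``fst_per_pop`` orders with ``ancestries``; ``dirichlet_alpha`` is the
    Dirichlet concentration-weighted mean of global ancestry.  ``generations_g``
    is generations since admixture (tract-length scale).  Default sizes (M=5,000
    markers on 20 chromosomes of 100 cM, 400 reference samples per population —
    the scale of a public-catalog superpopulation panel — and a 300-person
    cohort of 60 singletons, 30 couples and 60 trios) are chosen for
    desk-scale runtime.
    """

    ancestries: tuple[str, ...] = ANCESTRIES
    fst_per_pop: tuple[float, ...] = (0.15, 0.16, 0.12, 0.11)  # AFR, EUR, AMR, EAS
    n_ref_per_pop: int = 400
    n_variants: int = 5000
    n_chromosomes: int = 20
    chrom_length_cM: float = 100.0
    generations_g: int = 10
    dirichlet_alpha: tuple[float, ...] = tuple(10.0 * DEFAULT_MEAN_Q)
    household_plan: dict = field(default_factory=lambda: {"singletons": 60, "couples": 30, "trios": 60})
    selfreport_coef: dict = field(default_factory=lambda: dict(DEFAULT_SELFREPORT_COEF))
    selfreport_noise: float = 0.5
    nonresponse_rate: float = 0.013
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.dirichlet_alpha, float)
        if not (a > 0).all():
            raise ValueError("dirichlet_alpha must be strictly positive")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.generations_g < 1:
            raise ValueError("generations_g must be >= 1")
        if len(self.fst_per_pop) != len(self.ancestries):
            raise ValueError("fst_per_pop length must match ancestries")
        if len(a) != len(self.ancestries):
            raise ValueError("dirichlet_alpha length must match ancestries")
        if not all(0 <= f < 1 for f in self.fst_per_pop):
            raise ValueError("F_ST values must be in [0, 1)")

    @property
    def n_ancestries(self) -> int:
        return len(self.ancestries)

    @property
    def mean_q(self) -> np.ndarray:
        a = np.asarray(self.dirichlet_alpha, float)
        return a / a.sum()

    @property
    def n_cohort(self) -> int:
        p = self.household_plan
        return p.get("singletons", 0) + 2 * p.get("couples", 0) + 3 * p.get("trios", 0)

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]


@dataclass
class TruthSet:
    """Ground truth of one simulated cohort.

    ``tracts`` maps (sample_id, hap in {0,1}) to a list of
    (chrom, start_cM, end_cM, ancestry_index) covering each chromosome.
    """

    q_true: pd.DataFrame  # index sample_id, columns ancestries
    tracts: dict
    pedigree: dict  # child_id -> (parent1_id, parent2_id)
    panel_freqs: np.ndarray  # A x M

    def dosages(self, variants: list[Variant], sample_ids: list[str] | None = None) -> np.ndarray:
        """True diploid ancestry copies per SNP, shape (N, M, A)."""
        if sample_ids is None:
            sample_ids = list(self.q_true.index)
        a_n = self.q_true.shape[1]
        m = len(variants)
        chrom_pos = {}
        for chrom in dict.fromkeys(v.chrom for v in variants):
            idx = np.array([i for i, v in enumerate(variants) if v.chrom == chrom])
            chrom_pos[chrom] = (idx, np.array([variants[i].pos_cM for i in idx]))
        out = np.zeros((len(sample_ids), m, a_n), dtype=np.int8)
        for n, sid in enumerate(sample_ids):
            for h in range(2):
                lab = np.empty(m, dtype=int)
                for chrom, (idx, pos) in chrom_pos.items():
                    lab[idx] = labels_at_positions(self.tracts[(sid, h)], chrom, pos)
                out[n, np.arange(m), lab] += 1
        return out

    def tracts_frame(self, variants: list[Variant]) -> pd.DataFrame:
        """Truth tracts as a BED-like frame (0-based half-open bp via 1 cM/Mb grid)."""
        rows = []
        ancestries = list(self.q_true.columns)
        for (sid, hap), tr in self.tracts.items():
            for chrom, a, b, anc in tr:
                rows.append((chrom, int(a * 1e6), int(b * 1e6), f"{sid}_h{hap}", ancestries[anc]))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_hap", "ancestry"])


# ---------------------------------------------------------------------------
# Building blocks


def draw_ancestral_freqs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols population allele frequencies, shape (A, M).

    A common ancestral frequency p ~ Uniform(0.05, 0.95) per variant; each
    population then draws p_a ~ Beta(p(1-F)/F, (1-p)(1-F)/F), so that
    Var(p_a) = F p (1-p).  F = 0 is the no-drift limit p_a = p.
    """
    m = config.n_variants
    p = rng.uniform(0.05, 0.95, size=m)
    out = np.empty((config.n_ancestries, m))
    for a, fst in enumerate(config.fst_per_pop):
        if fst == 0:
            out[a] = p
        else:
            ratio = (1.0 - fst) / fst
            out[a] = rng.beta(p * ratio, (1.0 - p) * ratio)
    return np.clip(out, 1e-9, 1.0 - 1e-9)


def make_variants(config: SimConfig, rng: np.random.Generator) -> list[Variant]:
    """Marker grid: variants spread uniformly over equal-length chromosomes.

    Physical positions follow the 1 cM/Mb convention.  Allele pairs are drawn
    among non-palindromic combinations (array-design style).
    """
    per = np.full(config.n_chromosomes, config.n_variants // config.n_chromosomes)
    per[: config.n_variants % config.n_chromosomes] += 1
    pairs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a and {r, a} not in ({"A", "T"}, {"C", "G"})]
    variants: list[Variant] = []
    k = 0
    for ci, chrom in enumerate(config.chrom_names):
        cms = np.sort(rng.uniform(0.0, config.chrom_length_cM, size=per[ci]))
        # enforce distinct bp positions
        bp = np.maximum.accumulate(np.round(cms * 1e6).astype(int) + 1 + np.arange(per[ci]))
        for j in range(per[ci]):
            ref, alt = pairs[rng.integers(len(pairs))]
            variants.append(
                Variant(id=f"rs{k + 1}", chrom=chrom, pos_bp=int(bp[j]), pos_cM=float(cms[j]), ref_allele=ref, alt_allele=alt)
            )
            k += 1
    return variants


def simulate_tracts(q_i: np.ndarray, config: SimConfig, rng: np.random.Generator) -> list[tuple]:
    """One haplotype's ancestry mosaic: list of (chrom, start_cM, end_cM, ancestry).

    Breakpoints are a Poisson process at rate g per Morgan; segment ancestries
    are i.i.d. draws from q_i, so some breakpoints join same-ancestry segments.
    """
    q_i = np.asarray(q_i, float)
    if not np.isclose(q_i.sum(), 1.0) or (q_i < 0).any():
        raise ValueError("q_i must lie on the simplex")
    rate_per_cM = config.generations_g / 100.0
    tracts = []
    for chrom in config.chrom_names:
        length = config.chrom_length_cM
        k = rng.poisson(rate_per_cM * length)
        cuts = np.sort(rng.uniform(0.0, length, size=k))
        bounds = np.concatenate(([0.0], cuts, [length]))
        labels = rng.choice(len(q_i), size=k + 1, p=q_i)
        prev_label, seg_start = int(labels[0]), 0.0
        for j in range(1, k + 1):
            if int(labels[j]) != prev_label:
                tracts.append((chrom, seg_start, float(bounds[j]), prev_label))
                seg_start = float(bounds[j])
                prev_label = int(labels[j])
        tracts.append((chrom, seg_start, length, prev_label))
    return tracts


def labels_at_positions(tracts: list[tuple], chrom: str, pos_cM: np.ndarray) -> np.ndarray:
    """Ancestry index of one haplotype at each query position on a chromosome."""
    segs = [(a, b, anc) for c, a, b, anc in tracts if c == chrom]
    starts = np.array([s[0] for s in segs])
    labels = np.array([s[2] for s in segs])
    idx = np.searchsorted(starts, pos_cM, side="right") - 1
    return labels[np.clip(idx, 0, len(segs) - 1)]


def genotypes_from_tracts(
    tract_pairs: list[tuple[list, list]],
    panel_freqs: np.ndarray,
    variants: list[Variant],
    rng: np.random.Generator,
) -> np.ndarray:
    """Phased haplotype alleles, shape (n_ind, 2, M): Bernoulli(p_a) per site.

    ``tract_pairs`` holds the two haplotype mosaics per individual; a is the
    local ancestry at the site.
    """
    m = len(variants)
    chrom_pos: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in dict.fromkeys(v.chrom for v in variants):
        idx = np.array([i for i, v in enumerate(variants) if v.chrom == chrom])
        chrom_pos[chrom] = (idx, np.array([variants[i].pos_cM for i in idx]))
    haps = np.empty((len(tract_pairs), 2, m), dtype=np.int8)
    for n, pair in enumerate(tract_pairs):
        for h, tracts in enumerate(pair):
            lab = np.empty(m, dtype=int)
            for chrom, (idx, pos) in chrom_pos.items():
                lab[idx] = labels_at_positions(tracts, chrom, pos)
            p = panel_freqs[lab, np.arange(m)]
            haps[n, h] = (rng.random(m) < p).astype(np.int8)
    return haps


def tract_ancestry_fraction(tracts: list[tuple], n_anc: int, total_cM: float) -> np.ndarray:
    """Length-weighted ancestry proportions of one haplotype mosaic."""
    out = np.zeros(n_anc)
    for _, a, b, anc in tracts:
        out[anc] += b - a
    return out / total_cM


def meiosis(
    hap_pair_tracts: tuple[list, list],
    hap_pair_alleles: np.ndarray,
    variants: list[Variant],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list, np.ndarray]:
    """One gamete: recombine a parent's two haplotypes at rate 1 per Morgan.

    Returns the gamete's ancestry tract list and its allele vector.  Crossovers
    are a Poisson process on the genetic map; the source haplotype alternates
    at each crossover starting from a random one per chromosome.
    """
    m = len(variants)
    gamete_tracts: list[tuple] = []
    source = np.empty(m, dtype=int)
    pos_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in config.chrom_names:
        idx = np.array([i for i, v in enumerate(variants) if v.chrom == chrom])
        pos_by_chrom[chrom] = (idx, np.array([variants[i].pos_cM for i in idx]))
    for chrom in config.chrom_names:
        length = config.chrom_length_cM
        k = rng.poisson(length / 100.0)
        cuts = np.sort(rng.uniform(0.0, length, size=k))
        bounds = np.concatenate(([0.0], cuts, [length]))
        start_hap = int(rng.integers(2))
        idx, pos = pos_by_chrom[chrom]
        for j in range(k + 1):
            src = (start_hap + j) % 2
            a, b = float(bounds[j]), float(bounds[j + 1])
            in_seg = (pos >= a) & (pos < b) if j < k else (pos >= a) & (pos <= b)
            source[idx[in_seg]] = src
            for c, s, e, anc in hap_pair_tracts[src]:
                if c != chrom or e <= a or s >= b:
                    continue
                gamete_tracts.append((chrom, max(s, a), min(e, b), anc))
    # merge adjacent same-ancestry pieces per chromosome
    merged: list[tuple] = []
    for chrom in config.chrom_names:
        segs = sorted((t for t in gamete_tracts if t[0] == chrom), key=lambda t: t[1])
        for seg in segs:
            if merged and merged[-1][0] == chrom and merged[-1][3] == seg[3] and np.isclose(merged[-1][2], seg[1]):
                merged[-1] = (chrom, merged[-1][1], seg[2], seg[3])
            else:
                merged.append(tuple(seg))
    alleles = hap_pair_alleles[source, np.arange(m)]
    return merged, alleles


def assign_selfreport(q_true: np.ndarray, config: SimConfig, rng: np.random.Generator) -> list[str]:
    """Draw self-reported census categories from noisy linear utilities.

    Utility of category c is b0 + b.(qAFR, qEUR, qAMR) plus Gaussian noise of
    scale ``selfreport_noise``; the argmax is reported.  A small nonresponse
    rate yields NotAnswered.  The noise scale is calibrated so that category
    explains roughly a third of the median-regression variation in African
    ancestry (pseudo-R-squared near 0.35).
    """
    q_true = np.atleast_2d(np.asarray(q_true, float))
    anc_idx = {a: i for i, a in enumerate(config.ancestries)}

    def comp(name: str) -> np.ndarray:  # absent ancestries contribute zero
        i = anc_idx.get(name)
        return q_true[:, i] if i is not None else np.zeros(len(q_true))

    design = np.column_stack([np.ones(len(q_true)), comp("AFR"), comp("EUR"), comp("AMR")])
    cats = list(config.selfreport_coef)
    coef = np.array([config.selfreport_coef[c] for c in cats])  # C x 4
    util = design @ coef.T
    if config.selfreport_noise > 0:
        util = util + config.selfreport_noise * rng.standard_normal(util.shape)
    picks = [cats[i] for i in np.argmax(util, axis=1)]
    if config.nonresponse_rate > 0:
        mask = rng.random(len(picks)) < config.nonresponse_rate
        picks = ["NotAnswered" if m else c for c, m in zip(picks, mask)]
    return picks


# ---------------------------------------------------------------------------
# Cohort assembly


@dataclass
class SimResult:
    cohort: GenotypeMatrix
    panel: GenotypeMatrix
    panel_labels: pd.Series  # sample_id -> population
    samples: SampleTable
    truth: TruthSet
    config: SimConfig


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> SimResult:
    """Run the full generator: panel, founders, households, self-report.

    One RNG seeded from ``config.seed`` (or ``seed`` override) drives every
    draw, so results are bit-identical across runs.
    """
    config = config or SimConfig()
    if seed is not None:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    rng = np.random.default_rng(config.seed)
    A = config.n_ancestries
    variants = make_variants(config, rng)
    panel_freqs = draw_ancestral_freqs(config, rng)
    total_cM = config.n_chromosomes * config.chrom_length_cM

    # Reference panel: unadmixed individuals, HWE within population.
    panel_ids, panel_pops, panel_haps = [], [], []
    for a, pop in enumerate(config.ancestries):
        p = panel_freqs[a]
        for j in range(config.n_ref_per_pop):
            panel_ids.append(f"{pop}{j + 1:03d}")
            panel_pops.append(pop)
            panel_haps.append((rng.random((2, len(variants))) < p).astype(np.int8))
    panel_h = np.stack(panel_haps)
    panel = GenotypeMatrix(
        samples=panel_ids, variants=list(variants), calls=panel_h.sum(axis=1), phased_haplotypes=panel_h
    )

    # Founders (unrelated admixed individuals).
    plan = config.household_plan
    n_singles, n_couples, n_trios = plan.get("singletons", 0), plan.get("couples", 0), plan.get("trios", 0)
    n_founders = n_singles + 2 * (n_couples + n_trios)
    alpha = np.asarray(config.dirichlet_alpha, float)
    q_founders = rng.dirichlet(alpha, size=n_founders)
    founder_tracts = [
        (simulate_tracts(q_founders[i], config, rng), simulate_tracts(q_founders[i], config, rng))
        for i in range(n_founders)
    ]
    founder_haps = genotypes_from_tracts(founder_tracts, panel_freqs, variants, rng)

    sample_ids: list[str] = []
    haps: list[np.ndarray] = []
    tracts: dict = {}
    q_rows: list[np.ndarray] = []
    pedigree: dict = {}
    meta_rows: list[dict] = []

    def realized_q(tr_pair) -> np.ndarray:
        return 0.5 * (
            tract_ancestry_fraction(tr_pair[0], A, total_cM) + tract_ancestry_fraction(tr_pair[1], A, total_cM)
        )

    def add(sid, tr_pair, hap, household, rel, age, sex):
        sample_ids.append(sid)
        haps.append(hap)
        tracts[(sid, 0)] = tr_pair[0]
        tracts[(sid, 1)] = tr_pair[1]
        q_rows.append(realized_q(tr_pair))
        meta_rows.append(
            {
                "sample_id": sid,
                "household_id": household,
                "relationship_to_head": rel,
                "age_years": int(age),
                "sex": sex,
                "category": "",
            }
        )

    fi = 0  # founder index
    sn = 0  # sample name counter
    hh = 0
    for _ in range(n_singles):
        hh += 1
        sn += 1
        age = rng.integers(18, 91)
        add(f"S{sn:04d}", founder_tracts[fi], founder_haps[fi], f"H{hh:04d}", "head", age, rng.choice(["F", "M"]))
        fi += 1
    for _ in range(n_couples):
        hh += 1
        head_age = rng.integers(25, 81)
        sexes = ["F", "M"] if rng.random() < 0.5 else ["M", "F"]
        for k, rel in enumerate(("head", "spouse")):
            sn += 1
            age = head_age if k == 0 else int(np.clip(head_age + rng.integers(-6, 7), 20, 94))
            add(f"S{sn:04d}", founder_tracts[fi], founder_haps[fi], f"H{hh:04d}", rel, age, sexes[k])
            fi += 1
    for _ in range(n_trios):
        hh += 1
        head_age = rng.integers(35, 76)
        sexes = ["F", "M"] if rng.random() < 0.5 else ["M", "F"]
        parents = []
        for k, rel in enumerate(("head", "spouse")):
            sn += 1
            age = head_age if k == 0 else int(np.clip(head_age + rng.integers(-6, 7), 20, 94))
            add(f"S{sn:04d}", founder_tracts[fi], founder_haps[fi], f"H{hh:04d}", rel, age, sexes[k])
            parents.append((f"S{sn:04d}", founder_tracts[fi], founder_haps[fi]))
            fi += 1
        sn += 1
        child_id = f"S{sn:04d}"
        g1_tr, g1_al = meiosis(parents[0][1], parents[0][2], variants, config, rng)
        g2_tr, g2_al = meiosis(parents[1][1], parents[1][2], variants, config, rng)
        child_hap = np.stack([g1_al, g2_al])
        child_age = int(np.clip(head_age - rng.integers(20, 46), 12, 60))
        add(child_id, (g1_tr, g2_tr), child_hap, f"H{hh:04d}", "child", child_age, rng.choice(["F", "M"]))
        pedigree[child_id] = (parents[0][0], parents[1][0])

    hap_arr = np.stack(haps)
    if config.missing_rate > 0:
        drop = rng.random((hap_arr.shape[0], hap_arr.shape[2])) < config.missing_rate
    else:
        drop = None
    calls = hap_arr.sum(axis=1).astype(np.int8)
    phased: np.ndarray | None = hap_arr
    if drop is not None:
        calls = np.where(drop, np.int8(-1), calls)
        phased = hap_arr.copy()
        phased[np.broadcast_to(drop[:, None, :], phased.shape)] = -1
    cohort = GenotypeMatrix(samples=sample_ids, variants=list(variants), calls=calls, phased_haplotypes=phased)

    q_true = pd.DataFrame(np.array(q_rows), index=sample_ids, columns=list(config.ancestries))
    cats = assign_selfreport(q_true.to_numpy(), config, rng)
    meta = pd.DataFrame(meta_rows)
    meta["category"] = cats
    meta["category_raw"] = cats
    meta["age_group"] = meta["age_years"].map(age_group_of)
    samples = SampleTable(meta)
    truth = TruthSet(q_true=q_true, tracts=tracts, pedigree=pedigree, panel_freqs=panel_freqs)
    return SimResult(
        cohort=cohort,
        panel=panel,
        panel_labels=pd.Series(panel_pops, index=panel_ids, name="population"),
        samples=samples,
        truth=truth,
        config=config,
    )
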