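# admixscape

Ancestry analysis of recently admixed cohorts, built around the workflow used
for urban Brazilian household surveys: genotype quality control, genomic
relatedness and pseudo-independent sample selection, global ancestry by PCA
projection and supervised admixture EM, local ancestry by a haplotype HMM,
a post-admixture selection scan, and association of self-reported skin
color/race with genetic ancestry. A synthetic-data generator with full ground
truth (global proportions, tract mosaics, pedigrees, self-report) makes every
stage testable end to end.

## Who it is for

Population geneticists and genetic epidemiologists who need a transparent,
reproducible re-implementation of the standard admixture toolchain
(PLINK-style QC, GRM pruning, ADMIXTURE/RFMix-style inference) as one
library, plus a simulator for validating that toolchain against known truth.

## The models

**Global ancestry.** Each individual carries a simplex vector
q = (q_AFR, q_EUR, q_AMR, q_EAS). Two estimators are provided:

- *Supervised EM*: alt-allele dosage x_i ~ Binomial(2, Σ_a q_a f_ai) with
  panel frequencies f fixed; q is fit by EM (monotone log-likelihood).
- *PC simplex*: PCA of the standardized genotype matrix
  (x − 2p)/√(2p(1−p)); q solves min‖s − Σ_a q_a c_a‖² with q ≥ 0, Σq = 1,
  where c_a are reference-population centroids in PC space. Individuals
  excluded from the PCA fit (close relatives) are projected with the stored
  SNP loadings.

**Local ancestry.** A hidden Markov chain along each phased haplotype:
between SNPs at genetic distance d Morgans the chain stays with probability
e^(−g·d) and otherwise re-draws the state from q (g = generations since
admixture); emissions are panel allele frequencies with error ε = 0.01.
Forward–backward gives per-SNP posteriors, Viterbi gives tract calls.

**Selection scan.** Per SNP and ancestry, the cohort mean diploid
dosage/2 is z-scored against the genome-wide mean and SD across SNPs;
|z| > 4.42 corresponds to a two-sided normal p < 1e-5, with |z| > 3 as an
inner suggestive tier.

**Relatedness.** GRM entries A_jk = (1/M) Σ_i (x_ij−2p_i)(x_ik−2p_i) /
(2p_i(1−p_i)); pairs with estimated kinship K = A_jk/2 > 0.125 (second
degree) form a graph pruned by repeated max-degree deletion with a
household-head/elder tie-break.

**Association.** Quartile tables and age-adjusted quantile regression
(τ = 0.5, 0.75) of ancestry proportion on self-reported category (reference
Black), with the Koenker–Machado pseudo-R².

## Worked example

```python
import numpy as np
from admixscape import simpop, globalanc

cfg = simpop.SimConfig(
    n_variants=1000, n_chromosomes=10, n_ref_per_pop=100,
    household_plan={"singletons": 30, "couples": 5, "trios": 10}, seed=42,
)
sim = simpop.simulate_cohort(cfg)
freqs = globalanc.panel_allele_freqs(sim.panel, sim.panel_labels)
props = globalanc.supervised_em(sim.cohort, freqs)
anc = list(cfg.ancestries)
rmse = np.sqrt(((props.q[anc].to_numpy() - sim.truth.q_true.to_numpy()) ** 2).mean())
print(props.q.head(3).round(3))
print(f"cohort median EUR: {props.q['EUR'].median():.3f}")
print(f"RMSE against truth: {rmse:.4f}")
```

Output:

```
         AFR    EUR    AMR    EAS
S0001  0.169  0.767  0.060  0.004
S0002  0.193  0.671  0.046  0.090
S0003  0.080  0.768  0.019  0.133
cohort median EUR: 0.756
RMSE against truth: 0.0444
```

Each row is one simulated individual's estimated ancestry proportions; the
cohort is EUR-predominant by construction (Dirichlet mean ≈ 0.71 EUR,
0.19 AFR, 0.07 AMR, 0.02 EAS), and the per-entry RMSE of about 0.04 at 1,000
markers shrinks to about 0.02 at the default 5,000.

The same pipeline runs from the shell:

```bash
admixscape run-all --seed 1 --out runs/demo
```

writing per-stage TSV/BED outputs and a `manifest.json` with stage timings
and filter counts. Individual verbs (`simulate`, `qc`, `relate`, `global`,
`local`, `scan`, `assoc`) expose the stages separately.

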