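"""Shared fixtures: small hand-checkable files and cached synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from admixscape import globalanc, simpop

TINY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1
1\t200\trs2\tC\tA\t.\tPASS\t.\tGT\t0|0\t0|1
1\t300\trs3\tG\tC,T\t.\tPASS\t.\tGT\t1|0\t0|0
"""


@pytest.fixture()
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return str(path)


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic scenario (A=4, M=5000, household cohort of 300)."""
    return simpop.simulate_cohort(simpop.SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_panel_freqs(default_sim):
    return globalanc.panel_allele_freqs(default_sim.panel, default_sim.panel_labels)


@pytest.fixture(scope="session")
def default_em(default_sim, default_panel_freqs):
    return globalanc.supervised_em(default_sim.cohort, default_panel_freqs)


@pytest.fixture(scope="session")
def a2_scenario():
    """High-divergence two-ancestry scenario for local-ancestry recovery."""
    cfg = simpop.SimConfig(
        ancestries=("AFR", "EUR"),
        fst_per_pop=(0.2, 0.2),
        dirichlet_alpha=(3.0, 7.0),
        n_variants=5000,
        n_chromosomes=20,
        n_ref_per_pop=50,
        household_plan={"singletons": 20, "couples": 0, "trios": 0},
        seed=21,
    )
    sim = simpop.simulate_cohort(cfg)
    freqs = globalanc.panel_allele_freqs(sim.panel, sim.panel_labels)
    return sim, freqs


@pytest.fixture(scope="session")
def a2_em(a2_scenario):
    sim, freqs = a2_scenario
    return globalanc.supervised_em(sim.cohort, freqs)


@pytest.fixture(scope="session")
def a2_local(a2_scenario, a2_em):
    from admixscape import localanc

    sim, freqs = a2_scenario
    return localanc.infer_local_ancestry(sim.cohort, freqs, q=a2_em.q, generations_g=10)


def truth_hap_labels(sim, sample_id, hap):
    """Per-SNP truth ancestry indices for one haplotype of a simulated sample."""
    variants = sim.cohort.variants
    lab = np.empty(len(variants), dtype=int)
    for chrom in dict.fromkeys(v.chrom for v in variants):
        idx = np.array([k for k, v in enumerate(variants) if v.chrom == chrom])
        pos = np.array([variants[k].pos_cM for k in idx])
        lab[idx] = simpop.labels_at_positions(sim.truth.tracts[(sample_id, hap)], chrom, pos)
    return lab


@pytest.fixture()
def small_sim():
    """Fast small scenario for plumbing tests."""
    cfg = simpop.SimConfig(
        n_variants=300,
        n_chromosomes=3,
        n_ref_per_pop=20,
        household_plan={"singletons": 10, "couples": 3, "trios": 4},
        seed=5,
    )
    return simpop.simulate_cohort(cfg)
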