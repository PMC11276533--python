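"""End-to-end orchestration of the ancestry analysis on a synthetic cohort.

``run_all`` replays the full study design on generated data: simulate ->
QC (grm preset) -> relatedness pruning -> QC (pca preset) -> panel merge ->
panel homogenization -> PCA fit on the pseudo-independent set + projection of
relatives -> global ancestry (PC-simplex and supervised EM) -> HMM local
ancestry -> selection scan -> association tables.  Every stage writes TSV/BED
outputs plus a JSON manifest recording inputs, seed, and row counts, and
reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc, genio, globalanc, localanc, qc, relate, scanstats, simpop


@dataclass
class PipelineConfig:
    sim: simpop.SimConfig = field(default_factory=simpop.SimConfig)
    relatedness: relate.RelatednessConfig = field(default_factory=relate.RelatednessConfig)
    pca_components: int | None = None  # default A - 1
    em_tol: float = 1e-6
    em_max_iter: int = 2000
    hmm_generations: float | None = None  # default: simulator's g
    hmm_emission_error: float = 0.01
    panel_homogeneity: float = 0.95
    assoc_n_boot: int = 200  # desk-scale bootstrap reps for CIs
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = simpop.SimConfig(**raw.pop("sim", {}))
        rel = relate.RelatednessConfig(**raw.pop("relatedness", {}))
        return cls(sim=sim, relatedness=rel, **raw)


def run_all(config: PipelineConfig, out_dir: str, force: bool = False) -> Path:
    """Execute every stage, writing results and a manifest under ``out_dir``."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{out_dir} already contains a run; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": []}
    t_all = time.time()

    def stage(name: str, **counts):
        manifest["stages"].append({"name": name, "elapsed_s": round(time.time() - t0, 2), **counts})

    # 1. simulate ---------------------------------------------------------
    t0 = time.time()
    sim_cfg = simpop.SimConfig(**{**config.sim.__dict__, "seed": config.seed})
    sim = simpop.simulate_cohort(sim_cfg)
    genio.write_vcf(sim.cohort, str(out / "cohort.vcf"))
    genio.write_vcf(sim.panel, str(out / "panel.vcf"))
    genio.write_sample_table(sim.samples, str(out / "samples.tsv"))
    sim.truth.q_true.rename_axis("sample_id").reset_index().to_csv(out / "truth_q.tsv", sep="\t", index=False)
    sim.truth.tracts_frame(sim.cohort.variants).to_csv(out / "truth_tracts.bed", sep="\t", index=False, header=False)
    panel_labels = sim.panel_labels.rename_axis("sample_id").reset_index()
    panel_labels.to_csv(out / "panel_labels.tsv", sep="\t", index=False)
    stage("simulate", n_cohort=sim.cohort.n_samples, n_panel=sim.panel.n_samples, n_variants=sim.cohort.n_variants)

    # 2. QC, grm preset ---------------------------------------------------
    t0 = time.time()
    grm_cfg = qc.preset("grm")
    cohort_cr, rep_cr = qc.sample_call_rate_filter(sim.cohort, grm_cfg)
    filt, rep_var = qc.variant_filter(cohort_cr, grm_cfg)
    kept_ids = qc.ld_prune(filt, grm_cfg)
    g_grm = filt.subset_variants([i for i, v in enumerate(filt.variants) if v.id in set(kept_ids)])
    pd.concat([rep_cr.frame(), rep_var.frame()]).to_csv(out / "qc_grm_report.tsv", sep="\t", index=False)
    stage("qc_grm", n_samples=g_grm.n_samples, n_variants=g_grm.n_variants)

    # 3. relatedness ------------------------------------------------------
    t0 = time.time()
    grm = relate.compute_grm(g_grm)
    grm.long_frame().to_csv(out / "grm.tsv", sep="\t", index=False)
    unrelated = relate.select_pseudo_independent(grm, sim.samples, config.relatedness)
    related = [s for s in sim.cohort.samples if s not in set(unrelated)]
    pd.Series(unrelated, name="sample_id").to_csv(out / "kept_ids.txt", index=False)
    stage("relate", n_kept=len(unrelated), n_excluded=len(related), n_total=sim.cohort.n_samples)

    # 4. QC, pca preset (marker QC on the pseudo-independent set) ---------
    t0 = time.time()
    pca_cfg = qc.preset("pca")
    indep = cohort_cr.subset_samples([s for s in cohort_cr.samples if s in set(unrelated)])
    filt_pca, rep_pca = qc.variant_filter(indep, pca_cfg)
    kept_pca = set(qc.ld_prune(filt_pca, pca_cfg))
    cohort_pca = cohort_cr.subset_variants(
        [i for i, v in enumerate(cohort_cr.variants) if v.id in kept_pca]
    )
    rep_pca.frame().to_csv(out / "qc_pca_report.tsv", sep="\t", index=False)
    stage("qc_pca", n_variants=cohort_pca.n_variants)

    # 5. harmonize with panel --------------------------------------------
    t0 = time.time()
    merged, rep_merge = qc.harmonize_merge(cohort_pca, sim.panel)
    rep_merge.frame().to_csv(out / "harmonize_report.tsv", sep="\t", index=False)
    stage("harmonize", n_variants=merged.n_variants, n_samples=merged.n_samples)

    # 6. homogenize reference panel --------------------------------------
    t0 = time.time()
    panel_shared = sim.panel.subset_variants(
        [i for i, v in enumerate(sim.panel.variants) if v.id in {w.id for w in merged.variants}]
    )
    panel_ref = globalanc.homogenize_panel(panel_shared, sim.panel_labels, threshold=config.panel_homogeneity)
    stage("homogenize_panel", n_retained=panel_ref.genotypes.n_samples, n_candidates=panel_shared.n_samples)

    # 7. PCA + projection -------------------------------------------------
    t0 = time.time()
    n_pc = config.pca_components or (sim_cfg.n_ancestries - 1)
    fit_ids = unrelated + list(panel_ref.genotypes.samples)
    fit_gm = merged.subset_samples([s for s in merged.samples if s in set(fit_ids)])
    model = globalanc.fit_pca(fit_gm, n_pc)
    scores_fit = pd.DataFrame(model.scores, index=fit_gm.samples, columns=[f"PC{i+1}" for i in range(n_pc)])
    cohort_shared = merged.subset_samples([s for s in merged.samples if s in set(sim.cohort.samples)])
    scores_rel = globalanc.project_samples(model, cohort_shared.subset_samples(related)) if related else None
    all_scores = pd.concat([scores_fit] + ([scores_rel] if scores_rel is not None else []))
    all_scores.rename_axis("sample_id").reset_index().to_csv(out / "scores.tsv", sep="\t", index=False)
    stage("pca", n_fit=fit_gm.n_samples, n_projected=0 if scores_rel is None else len(scores_rel))

    # 8. global ancestry --------------------------------------------------
    t0 = time.time()
    centroids = globalanc.panel_centroids(scores_fit, panel_ref.labels)
    cohort_scores = all_scores.loc[[s for s in sim.cohort.samples if s in all_scores.index]]
    q_pc = globalanc.pc_simplex_proportions(cohort_scores, centroids)
    q_em = globalanc.supervised_em(
        cohort_shared, panel_ref.freqs, tol=config.em_tol, max_iter=config.em_max_iter
    )
    for props, tag in ((q_pc, "pc_simplex"), (q_em, "supervised_em")):
        df = props.q.rename_axis("sample_id").reset_index()
        df["method"] = tag
        df.to_csv(out / f"q_{tag}.tsv", sep="\t", index=False)
    stage("global_ancestry", n_samples=len(q_em.q))

    # 9. local ancestry ---------------------------------------------------
    t0 = time.time()
    g = config.hmm_generations or sim_cfg.generations_g
    shared_ids = {v.id for v in merged.variants}
    cohort_phased = sim.cohort.subset_variants(
        [i for i, v in enumerate(sim.cohort.variants) if v.id in shared_ids]
    )
    local = localanc.infer_local_ancestry(
        cohort_phased, panel_ref.freqs, q=q_em.q, generations_g=g, emission_error=config.hmm_emission_error
    )
    local.tracts_frame().to_csv(out / "tracts.bed", sep="\t", index=False, header=False)
    local.chrom_mean_proportions().rename_axis("chrom").reset_index().to_csv(
        out / "chrom_means.tsv", sep="\t", index=False
    )
    stage("local_ancestry", n_samples=len(local.sample_ids), n_variants=len(local.variants))

    # 10. selection scan --------------------------------------------------
    t0 = time.time()
    scan = scanstats.ancestry_scan(local.viterbi_dosage(), local.variants, local.ancestries)
    scan.table.to_csv(out / "scan.tsv", sep="\t", index=False)
    scan.summary.to_csv(out / "scan_summary.tsv", sep="\t", index=False)
    stage("scan", n_flag442sd=int(scan.summary["n_flag442sd"].sum()))

    # 11. association -----------------------------------------------------
    t0 = time.time()
    meta_unrel = genio.SampleTable(sim.samples.frame[sim.samples.frame.sample_id.isin(unrelated)].copy())
    q_unrel = q_em.q.loc[[s for s in unrelated if s in q_em.q.index]]
    desc = assoc.descriptive_tests(meta_unrel, q_unrel)
    desc.to_csv(out / "table1_tests.tsv", sep="\t", index=False)
    cat = meta_unrel.frame.set_index("sample_id")["category"]
    age = meta_unrel.frame.set_index("sample_id")["age_years"]
    rows = []
    for anc in ("AFR", "AMR", "EUR"):
        if anc not in q_unrel.columns:
            continue
        qt = assoc.quartile_table(q_unrel[anc], cat)
        qt.percentages.rename_axis("category").reset_index().assign(ancestry=anc).to_csv(
            out / f"table2_quartiles_{anc}.tsv", sep="\t", index=False
        )
        for tau in (0.5, 0.75):
            fit = assoc.quantile_regression(
                q_unrel[anc], cat, age, tau=tau, n_boot=config.assoc_n_boot, seed=config.seed
            )
            for _, r in fit.coefficients.iterrows():
                rows.append({"ancestry": anc, "tau": tau, "pseudo_r2": fit.pseudo_r2, **r.to_dict()})
    pd.DataFrame(rows).to_csv(out / "table2_quantreg.tsv", sep="\t", index=False)
    stage("assoc", n_samples=len(q_unrel))

    manifest["elapsed_s"] = round(time.time() - t_all, 2)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
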