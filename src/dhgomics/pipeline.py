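"""End-to-end orchestration: simulate -> preprocess -> multivariate ->
differential -> enrich -> rank -> panel -> diagnostics.

A single seed in the pipeline config fans out to per-stage seeds through a
stable hash of the stage name, so any stage re-run in isolation reproduces
the full-run behaviour.  The run writes every intermediate table plus a JSON
manifest of seeds, thresholds and headline results.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, differential, io, multivariate, pathways, preprocess
from .matrix import IntensityMatrix
from .simulate import (SimulationConfig, generate_cohort,
                       generate_pathway_db, generate_symptom_links,
                       generate_validation_cohort)


class PipelineError(RuntimeError):
    pass


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from the run seed."""
    digest = hashlib.blake2s(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig | None = None
    input_paths: dict[str, str] | None = None  # met/met_sheet/prot/prot_sheet/gmt/links
    out_dir: str = "dhgomics_run"
    seed: int = 0
    n_ortho: int = 1
    n_folds: int = 7
    n_permutations: int = 100
    alpha_intersect: float = 0.05
    top_k: int | None = None  # None: smallest covering prefix
    rule: differential.SelectionRule = field(
        default_factory=differential.SelectionRule)
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig)
    rf_threshold: float = 14.0
    svm_threshold: float = 0.01
    mccv_iterations: int = 50
    train_fraction: float = 2 / 3
    with_validation: bool = True
    n_val_case: int = 25
    n_val_control: int = 15

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_paths is None):
            raise PipelineError(
                "supply exactly one of simulation config or input paths"
            )


@dataclass
class ScreenResult:
    """Everything the screen produced up to (and including) the panel."""

    met_imputed: IntensityMatrix
    met_scaled: IntensityMatrix
    prot_imputed: IntensityMatrix
    met_report: preprocess.PreprocessReport
    prot_report: preprocess.PreprocessReport
    opls: multivariate.OplsdaModel
    vip: dict[str, float]
    met_stats: list
    met_selected: list
    prot_stats: list
    prot_selected: list
    met_enrichment: list
    prot_enrichment: list
    common_pathways: list[str]
    ranking: list
    selected_pathways: list[str]
    covered_symptoms: frozenset[str]
    top_k: int
    full_coverage: bool
    crucial_met: set[str]
    crucial_prot: set[str]
    rf: diagnostics.ImportanceResult | None
    svm: diagnostics.ImportanceResult | None
    panel: diagnostics.BiomarkerPanel


def screen_cohort(
    met_raw: IntensityMatrix,
    prot_raw: IntensityMatrix,
    db: dict[str, tuple[str, set[str]]],
    links: list[tuple[str, str]],
    symptoms: io.SymptomTable,
    seed: int = 0,
    rule: differential.SelectionRule | None = None,
    pre_cfg: preprocess.PreprocessConfig | None = None,
    n_ortho: int = 1,
    n_folds: int = 7,
    alpha_intersect: float = 0.05,
    top_k: int | None = None,
    rf_threshold: float = 14.0,
    svm_threshold: float = 0.01,
) -> ScreenResult:
    """Run preprocess -> OPLS-DA/VIP -> differential screens -> dual-omics
    ORA -> symptom-weighted ranking -> coverage -> dual-importance panel."""
    rule = rule or differential.SelectionRule()
    pre_cfg = pre_cfg or preprocess.PreprocessConfig()
    met_imp, met_scaled, met_report = preprocess.preprocess(met_raw, pre_cfg)
    prot_imp, _, prot_report = preprocess.preprocess(prot_raw, pre_cfg)

    opls = multivariate.fit_oplsda(
        met_scaled, n_ortho=n_ortho, n_folds=n_folds,
        cv_seed=stage_seed(seed, "oplsda"))
    vip = multivariate.compute_vip(opls)

    met_stats = differential.univariate_stats(met_imp, vip)
    met_sel = differential.select_metabolites(met_stats, vip, rule)
    prot_stats = differential.univariate_stats(prot_imp)
    prot_sel = differential.select_proteins(prot_stats, rule)

    met_enr = pathways.ora({s.feature_id for s in met_sel}, db,
                           set(met_imp.feature_ids))
    prot_enr = pathways.ora({s.feature_id for s in prot_sel}, db,
                            set(prot_imp.feature_ids))
    common = pathways.intersect_pathways(met_enr, prot_enr, alpha_intersect)
    met_by_id = {r.pathway_id: r for r in met_enr}
    prot_by_id = {r.pathway_id: r for r in prot_enr}
    combined_enr = [
        pathways.EnrichmentResult(
            pathway_id=pid, description=db[pid][0],
            n_hits=met_by_id[pid].n_hits + prot_by_id[pid].n_hits,
            n_members=met_by_id[pid].n_members + prot_by_id[pid].n_members,
            # joint evidence: the -log10 p of both layers adds
            p_value=max(min(met_by_id[pid].p_value * prot_by_id[pid].p_value,
                            1.0), 1e-300),
            q_value=1.0,
        )
        for pid in common
    ]
    scores = {pid: pathways.symptom_score(pid, links, symptoms)
              for pid in common}
    ranking = pathways.combined_rank(combined_enr, scores, links)
    if ranking:
        selected_pw, covered, k_used, full_cov = pathways.topk_coverage(
            ranking, links, symptoms, k=top_k)
    else:
        selected_pw, covered, k_used, full_cov = [], frozenset(), 0, False
    crucial_met, crucial_prot = pathways.extract_pathway_members(
        selected_pw, db, {s.feature_id for s in met_sel},
        {s.feature_id for s in prot_sel})

    rf = svm = None
    candidates = sorted(crucial_met)
    if len(candidates) >= 2:
        cand_m = log_matrix(met_imp.subset_features(candidates))
        rf = diagnostics.rf_importance(cand_m, seed=stage_seed(seed, "rf"))
        svm = diagnostics.svm_importance(cand_m, seed=stage_seed(seed, "svm"))
        panel = diagnostics.assemble_panel(
            rf, svm, crucial_met, rf_threshold, svm_threshold)
    else:
        panel = diagnostics.BiomarkerPanel(marker_ids=[], provenance={},
                                           empty_warning=True)
    return ScreenResult(
        met_imputed=met_imp, met_scaled=met_scaled, prot_imputed=prot_imp,
        met_report=met_report, prot_report=prot_report,
        opls=opls, vip=vip,
        met_stats=met_stats, met_selected=met_sel,
        prot_stats=prot_stats, prot_selected=prot_sel,
        met_enrichment=met_enr, prot_enrichment=prot_enr,
        common_pathways=common, ranking=ranking,
        selected_pathways=selected_pw, covered_symptoms=frozenset(covered),
        top_k=k_used, full_coverage=full_cov,
        crucial_met=crucial_met, crucial_prot=crucial_prot,
        rf=rf, svm=svm, panel=panel,
    )


def log_matrix(m: IntensityMatrix) -> IntensityMatrix:
    """log2 view of an imputed linear-scale matrix."""
    return IntensityMatrix(np.log2(m.values), m.samples.copy())


def _simulate_inputs(cfg: PipelineConfig, symptoms: io.SymptomTable):
    sim = replace(cfg.simulation, seed=stage_seed(cfg.seed, "simulate"))
    met, prot, truth = generate_cohort(sim)
    db, truth = generate_pathway_db(sim, truth)
    links, truth = generate_symptom_links(sim, truth, symptoms)
    val = generate_validation_cohort(sim, cfg.n_val_case, cfg.n_val_control) \
        if cfg.with_validation else None
    return met, prot, db, links, truth, val


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.input_paths
    met = io.read_intensity_tsv(paths["met"], paths["met_sheet"])
    prot = io.read_intensity_tsv(paths["prot"], paths["prot_sheet"])
    db = io.read_gmt(paths["gmt"])
    links = io.read_links_tsv(paths["links"])
    return met, prot, db, links, None, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full chain and write a result bundle under ``out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    symptoms = io.load_table3_fixture()
    if cfg.simulation is not None:
        met_raw, prot_raw, db, links, truth, validation = _simulate_inputs(
            cfg, symptoms)
        io.write_intensity_tsv(met_raw, out / "met_discovery.tsv",
                               out / "met_discovery_samples.tsv")
        io.write_intensity_tsv(prot_raw, out / "prot_discovery.tsv",
                               out / "prot_discovery_samples.tsv")
        io.write_gmt(db, out / "pathways.gmt")
        io.write_links_tsv(links, out / "symptom_links.tsv")
    else:
        met_raw, prot_raw, db, links, truth, validation = _load_inputs(cfg)

    res = screen_cohort(
        met_raw, prot_raw, db, links, symptoms, seed=cfg.seed,
        rule=cfg.rule, pre_cfg=cfg.preprocess, n_ortho=cfg.n_ortho,
        n_folds=cfg.n_folds, alpha_intersect=cfg.alpha_intersect,
        top_k=cfg.top_k, rf_threshold=cfg.rf_threshold,
        svm_threshold=cfg.svm_threshold)
    perm = multivariate.permutation_test(
        res.met_scaled, n_ortho=cfg.n_ortho, n_folds=cfg.n_folds,
        n_perm=cfg.n_permutations, seed=stage_seed(cfg.seed, "permutation"))

    _write_stats(res.met_stats, {s.feature_id for s in res.met_selected},
                 out / "met_stats.tsv")
    _write_stats(res.prot_stats, {s.feature_id for s in res.prot_selected},
                 out / "prot_stats.tsv")
    _write_ranking(res.ranking, out / "pathway_ranking.tsv")
    _write_sankey(res.selected_pathways, db, links,
                  res.crucial_met | res.crucial_prot, out / "sankey_edges.tsv")

    manifest: dict = {
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in
                        ("simulate", "oplsda", "permutation", "rf", "svm",
                         "mccv")},
        "thresholds": {
            "vip_min": cfg.rule.vip_min, "p_max": cfg.rule.p_max,
            "log2fc_min": cfg.rule.log2fc_min,
            "protein_fc_up": cfg.rule.protein_fc_up,
            "protein_fc_down": cfg.rule.protein_fc_down,
            "rf_mda": cfg.rf_threshold, "svm_importance": cfg.svm_threshold,
            "alpha_intersect": cfg.alpha_intersect,
        },
        "preprocess": {"met": res.met_report.as_dict(),
                       "prot": res.prot_report.as_dict()},
        "oplsda": {"r2x": res.opls.r2x, "r2y": res.opls.r2y,
                   "q2": res.opls.q2, "p_q2": perm.p_q2, "p_r2y": perm.p_r2y,
                   "n_permutations": perm.n_permutations},
        "n_met_selected": len(res.met_selected),
        "n_prot_selected": len(res.prot_selected),
        "n_common_pathways": len(res.common_pathways),
        "selected_pathways": res.selected_pathways,
        "top_k": res.top_k,
        "full_symptom_coverage": res.full_coverage,
        "covered_symptoms": sorted(res.covered_symptoms),
        "panel": {"markers": res.panel.marker_ids,
                  "provenance": res.panel.provenance},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if truth is not None:
        manifest["truth"] = {
            "planted_met_ids": sorted(truth.planted_met_ids),
            "planted_prot_ids": sorted(truth.planted_prot_ids),
            "planted_pathway_ids": sorted(truth.planted_pathway_ids),
            "minimal_covering_k": truth.minimal_covering_k,
        }
    if res.rf is not None:
        _write_importance(res.rf, res.svm, res.panel, out / "importance.tsv")

    if res.panel.marker_ids:
        panel_m = log_matrix(res.met_imputed.subset_features(
            res.panel.marker_ids))
        manifest["per_marker_auc"] = {
            fid: {"auc": a, "ci": [lo, hi]}
            for fid, (a, lo, hi) in diagnostics.per_marker_auc(panel_m).items()
        }
        mccv_seed = stage_seed(cfg.seed, "mccv")
        manifest["combined_auc"] = {}
        for kind in ("LR", "RF", "SVM"):
            r = diagnostics.mccv_combined_roc(
                panel_m, model_kind=kind, n_iter=cfg.mccv_iterations,
                train_fraction=cfg.train_fraction, seed=mccv_seed)
            manifest["combined_auc"][kind] = {"auc": r.auc,
                                              "ci": [r.ci_low, r.ci_high]}
        if validation is not None:
            met_val_imp, _, _ = preprocess.preprocess(validation[0],
                                                      cfg.preprocess)
            if all(f in met_val_imp.feature_ids for f in res.panel.marker_ids):
                val_m = log_matrix(met_val_imp.subset_features(
                    res.panel.marker_ids))
                fitted = diagnostics.fit_panel_model(panel_m, "LR",
                                                     seed=mccv_seed)
                vres = diagnostics.evaluate_validation(fitted, val_m)
                manifest["validation_auc"] = {
                    "LR": {"auc": vres.auc, "ci": [vres.ci_low, vres.ci_high]}}

    io.write_json(manifest, out / "manifest.json")
    return manifest


def _write_stats(stats_list, selected_ids, path) -> None:
    rows = [{
        "id": s.feature_id, "p": s.p_value, "q": s.q_value,
        "log2_fc": s.log2_fc, "vip": "" if s.vip is None else s.vip,
        "trend": s.trend, "selected": s.feature_id in selected_ids,
    } for s in stats_list]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_ranking(ranking, path) -> None:
    rows = [{
        "pathway_id": r.pathway_id, "enrichment_score": r.enrichment_score,
        "symptom_score": r.symptom_score, "combined_rank": r.combined_rank,
        "covered_symptoms": ";".join(sorted(r.covered_symptoms)),
    } for r in ranking]
    pd.DataFrame(rows, columns=["pathway_id", "enrichment_score",
                                "symptom_score", "combined_rank",
                                "covered_symptoms"]).to_csv(
        path, sep="\t", index=False)


def _write_sankey(selected_pw, db, links, features, path) -> None:
    """Three-column edge list: feature->pathway and pathway->symptom."""
    rows = []
    for pid in selected_pw:
        for fid in sorted(db.get(pid, ("", set()))[1] & features):
            rows.append({"source": fid, "target": pid,
                         "kind": "feature-pathway"})
        for lp, sym in links:
            if lp == pid:
                rows.append({"source": pid, "target": sym,
                             "kind": "pathway-symptom"})
    pd.DataFrame(rows, columns=["source", "target", "kind"]).to_csv(
        path, sep="\t", index=False)


def _write_importance(rf, svm, panel, path) -> None:
    rows = [{
        "id": fid,
        "rf_mda": rf.rf_mda.get(fid, 0.0),
        "svm_importance": svm.svm_importance.get(fid, 0.0),
        "in_panel": fid in panel.marker_ids,
        "provenance": ";".join(panel.provenance.get(fid, [])),
    } for fid in rf.feature_ids]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
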