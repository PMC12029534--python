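"""End-to-end orchestration of the tissue-metabolomics analysis.

Stages run in dependency order — normalize → QC → univariate (+ optional
enrichment) → PLS-DA → differential correlation → ratio panel → biomarker
→ stage-wise network topology — each writing plain TSV/JSON artifacts into
the output bundle together with a provenance manifest (serialized config,
seeds, package version) that suffices to reproduce every number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import biomarker as bm
from . import core_data, diffcorr, nam, plsda, ratios, synthetic_data, univariate

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "normalize", "qc", "univariate", "enrichment", "plsda",
    "diffcorr", "ratios", "biomarker", "nam",
)


@dataclass
class PipelineConfig:
    peak_table: str | None = None          # None → simulate a cohort
    sample_metadata: str | None = None
    metabolite_metadata: str | None = None
    pathways_gmt: str | None = None        # optional GMT for enrichment
    out_dir: str = "gcmet_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # module thresholds
    alpha: float = 0.05
    fdr_threshold: float = 0.05
    fdr_method: str = "fdr_bh"
    missing_max_fraction: float = 0.5
    rsd_min_qc: int = 3
    plsda_max_components: int = 5
    plsda_folds: int = 5
    plsda_permutations: int = 2000
    diffcorr_fdr: float = 0.05
    split_ratio: float = 0.8
    top_k_markers: int = 10
    nam_alpha: float = 0.01
    nam_diff_min: float = 0.05
    nam_equal_tol: float = 0.02
    nam_hub_k: int = 15
    nam_stages: tuple[str, ...] = ("I", "II", "III")
    # synthetic cohort (used when peak_table is None)
    synthetic: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["nam_stages"] = list(self.nam_stages)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "nam_stages" in raw:
            raw["nam_stages"] = tuple(raw["nam_stages"])
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the enabled stages and return the output bundle directory.

    Any stage failure aborts the run with the stage name in the error and
    removes the partially written bundle.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(cfg, out)
    except Exception as err:
        shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline failed: {err}") from err


def _run(cfg: PipelineConfig, out: Path) -> Path:
    stage_reports: dict[str, dict] = {}

    # --- inputs -------------------------------------------------------------
    if cfg.peak_table is None:
        syn_kwargs = dict(cfg.synthetic)
        syn_kwargs.setdefault("seed", cfg.seed)
        syn = synthetic_data.SyntheticConfig(**syn_kwargs)
        pt_raw, samples, mets, truth = synthetic_data.generate_cohort(syn)
        core_data.write_peak_table(pt_raw, out / "raw_peak_table.csv")
        core_data.write_sample_metadata(samples, out / "sample_metadata.csv")
        core_data.write_metabolite_metadata(mets, out / "metabolite_metadata.csv")
        truth.to_json(out / "ground_truth.json")
        stage_reports["simulate"] = {
            "n_samples": len(samples), "n_metabolites": pt_raw.shape[1]}
    else:
        if cfg.sample_metadata is None:
            raise ValueError("sample_metadata is required with an input peak table")
        pt_raw, samples, mets = core_data.read_peak_table(
            cfg.peak_table, cfg.sample_metadata, cfg.metabolite_metadata)

    enabled = set(cfg.stages)

    # --- normalize ----------------------------------------------------------
    if "normalize" in enabled:
        pt = core_data.normalize_intensities(pt_raw, samples, mets)
        pt = core_data.handle_missing(pt, cfg.missing_max_fraction)
        core_data.write_peak_table(pt, out / "normalized_peak_table.csv")
        stage_reports["normalize"] = {
            "n_metabolites_in": pt_raw.shape[1], "n_metabolites_out": pt.shape[1]}
    else:
        pt = pt_raw

    tissue = [s for s in samples if not s.is_qc]
    tissue_pt = pt.subset_samples([s.sample_id for s in tissue])

    # --- QC -----------------------------------------------------------------
    if "qc" in enabled:
        rsd, summary = core_data.compute_qc_rsd(pt, samples)
        _write_tsv(
            pd.DataFrame({"metabolite_id": rsd.index, "rsd_percent": rsd.to_numpy()}),
            out / "qc_rsd.tsv")
        stage_reports["qc"] = summary

    # --- univariate ---------------------------------------------------------
    differential: list[univariate.DifferentialResult] = []
    if "univariate" in enabled:
        differential = univariate.differential_analysis(
            tissue_pt, tissue, fdr_method=cfg.fdr_method)
        _write_tsv(univariate.differential_table(differential), out / "differential.tsv")
        sig_p = [r for r in differential if r.p_value < cfg.alpha]
        sig_q = [r for r in sig_p if r.fdr < cfg.fdr_threshold]
        stage_reports["univariate"] = {
            "n_metabolites": len(differential),
            "n_p_significant": len(sig_p),
            "fraction_p_significant": len(sig_p) / len(differential),
            "n_fdr_significant": len(sig_q),
        }
        assoc = univariate.clinical_association_scan(
            tissue_pt, tissue, sig_p, alpha=cfg.alpha)
        _write_tsv(assoc, out / "clinical_associations.tsv")
        if len(assoc):
            flagged = assoc[assoc["significant"]]
            per_index = (flagged.groupby("clinical_index")["metabolite_id"]
                         .nunique().sort_values(ascending=False))
            stage_reports["univariate"]["clinical_index_counts"] = per_index.to_dict()

    # --- enrichment ---------------------------------------------------------
    if "enrichment" in enabled and cfg.pathways_gmt and differential:
        pathways = univariate.read_gmt(cfg.pathways_gmt)
        selected = [r.metabolite_id for r in differential if r.fdr < cfg.fdr_threshold]
        if selected:
            enr = univariate.hypergeometric_enrichment(
                selected, pathways, tissue_pt.metabolite_ids)
            _write_tsv(
                pd.DataFrame(
                    {
                        "pathway_id": [e.pathway_id for e in enr],
                        "pathway_size": [e.pathway_size for e in enr],
                        "overlap": [e.overlap_count for e in enr],
                        "p_value": [e.p_value for e in enr],
                        "fdr": [e.fdr for e in enr],
                    }
                ),
                out / "enrichment.tsv")
            stage_reports["enrichment"] = {"n_pathways": len(enr)}

    # --- PLS-DA -------------------------------------------------------------
    if "plsda" in enabled:
        X = tissue_pt.data.to_numpy()
        y = np.array([s.tissue_type for s in tissue])
        report = plsda.select_components_cv(
            X, y, max_components=cfg.plsda_max_components,
            k=cfg.plsda_folds, seed=cfg.seed)
        model = plsda.fit_plsda(X, y, report.chosen)
        perm = plsda.permutation_test(
            X, y, n_permutations=cfg.plsda_permutations,
            n_components=report.chosen, k=cfg.plsda_folds, seed=cfg.seed)
        scores = pd.DataFrame(
            model.scores, index=tissue_pt.sample_ids,
            columns=[f"t{a + 1}" for a in range(model.n_components)])
        scores.insert(0, "sample_id", scores.index)
        _write_tsv(scores, out / "plsda_scores.tsv")
        with open(out / "plsda_report.json", "w") as fh:
            json.dump(
                {
                    "chosen_components": report.chosen,
                    "accuracy": report.accuracy,
                    "r2y": report.r2y,
                    "q2": report.q2,
                    "permutation_p": perm.p_value,
                    "n_permutations": perm.n_permutations,
                    "observed_statistic": perm.observed,
                },
                fh, indent=1)
        stage_reports["plsda"] = {
            "chosen_components": report.chosen,
            "q2": report.q2[report.chosen - 1],
            "permutation_p": perm.p_value,
        }

    # --- differential correlation -------------------------------------------
    if "diffcorr" in enabled:
        pairs = core_data.paired_patient_samples(tissue)
        adj = tissue_pt.data.loc[[a for _, _, a in pairs]]
        tum = tissue_pt.data.loc[[t for _, t, _ in pairs]]
        edges, graph, modules, degree = diffcorr.build_differential_network(
            adj, tum, fdr_threshold=cfg.diffcorr_fdr)
        _write_tsv(edges, out / "diffcorr_edges.tsv")
        _write_tsv(degree, out / "diffcorr_degree.tsv")
        nx.write_graphml(graph, out / "diffcorr_network.graphml")
        with open(out / "diffcorr_modules.json", "w") as fh:
            json.dump(modules, fh, indent=1)
        stage_reports["diffcorr"] = {
            "n_pairs_tested": len(edges),
            "n_edges": int((edges["fdr"] < cfg.diffcorr_fdr).sum()) if len(edges) else 0,
            "n_modules": len(modules),
        }

    # --- ratio panel ---------------------------------------------------------
    if "ratios" in enabled:
        panel = ratios.compute_ratio_panel(tissue_pt, tissue)
        _write_tsv(ratios.ratio_table(panel), out / "ratio_panel.tsv")
        stage_reports["ratios"] = {
            "n_ratios": len(panel),
            "n_significant": sum(1 for r in panel if r.p_value < cfg.alpha),
        }

    # --- biomarker ------------------------------------------------------------
    if "biomarker" in enabled:
        split = bm.split_patients(tissue, ratio=cfg.split_ratio, seed=cfg.seed)
        _write_tsv(bm.split_table(split), out / "split_assignment.csv")
        disc_pids = set(split.patients("discovery"))
        disc_samples = [s for s in tissue if s.patient_id in disc_pids]
        disc_pt = tissue_pt.subset_samples([s.sample_id for s in disc_samples])
        disc_diff = univariate.differential_analysis(disc_pt, disc_samples)
        top = bm.rank_markers(disc_diff, top_k=cfg.top_k_markers)
        singles = {mid: bm.single_marker_roc(tissue_pt, tissue, split, mid)
                   for mid in top[:2]}
        combo = bm.combine_markers(tissue_pt, tissue, split, top[:2])
        payload = {
            "top_markers": top,
            "single": {
                mid: {"auc_discovery": r.auc_discovery,
                      "auc_validation": r.auc_validation}
                for mid, r in singles.items()
            },
            "combined": dataclasses.asdict(combo),
        }
        with open(out / "biomarker.json", "w") as fh:
            json.dump(payload, fh, indent=1, default=float)
        stage_reports["biomarker"] = {
            "markers": combo.markers,
            "auc_discovery": combo.auc_discovery,
            "auc_validation": combo.auc_validation,
        }

    # --- stage-wise network topology -----------------------------------------
    if "nam" in enabled:
        nets, subnets, hub_t, hubs, triplets = nam.run_nam(
            tissue_pt, tissue, alpha=cfg.nam_alpha, diff_min=cfg.nam_diff_min,
            equal_tol=cfg.nam_equal_tol, hub_k=cfg.nam_hub_k,
            stages=cfg.nam_stages)
        for t, sg in subnets.items():
            _write_tsv(sg.edges, out / f"nam_subnetwork_{t}.tsv")
        with open(out / "nam_hubs.json", "w") as fh:
            json.dump({"per_stage": hub_t, "union": hubs}, fh, indent=1)
        trip_rows = []
        for tr in triplets:
            for t, star in tr.stars.items():
                for _, e in star.iterrows():
                    trip_rows.append(
                        {"hub": tr.hub, "stage": t, "neighbor": e["neighbor"],
                         "weight": e["weight"], "sign": e["sign"]})
        _write_tsv(
            pd.DataFrame(trip_rows,
                         columns=["hub", "stage", "neighbor", "weight", "sign"]),
            out / "nam_triplets.tsv")
        g = nx.Graph()
        for tr in triplets:
            for t, star in tr.stars.items():
                for _, e in star.iterrows():
                    g.add_edge(f"{tr.hub}", f"{e['neighbor']}",
                               stage=t, weight=float(e["weight"]))
        nx.write_graphml(g, out / "nam_stars.graphml")
        stage_reports["nam"] = {
            "stages": list(nets.stages),
            "subnetwork_edges": {t: len(sg.edges) for t, sg in subnets.items()},
            "n_hubs": len(hubs),
        }

    # --- provenance ------------------------------------------------------------
    cfg_dict = cfg.to_dict()
    cfg_dict.pop("out_dir")  # output location is not part of provenance
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "stages_run": sorted(stage_reports),
        "reports": stage_reports,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return out
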