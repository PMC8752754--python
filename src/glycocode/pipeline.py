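"""End-to-end orchestration of the glyco-code analysis.

Stages run in dependency order inside one run directory — simulate (or
load), differential expression, cross-cohort panel, consensus
clustering, single-sample scoring, subtype concordance network, survival
and the single-cell circuit — each reading its inputs from the previous
stage's files, so every stage can also be re-run individually from the
command line.  A rerun with the same config and seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import catalog, consensus, diffexp, network, scoring, simulate, single_cell, survival
from .config import RunConfig
from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    load_clinical,
    load_expression,
    load_gmt,
    load_metadata,
    load_sc_counts,
    write_clinical,
    write_expression,
    write_gmt,
    write_metadata,
)

__all__ = ["run_pipeline", "STAGES"]

FLOAT_FMT = "%.10g"

STAGES = ("simulate", "de", "panel", "cluster", "score", "network", "survival", "sc")


class StageError(RuntimeError):
    pass


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"missing upstream output {path.name!r}: run stage {stage!r} first")
    return path


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def _cohort_ids(run_dir: Path) -> list[str]:
    data = _require(run_dir / "data", "simulate")
    return sorted(p.name[: -len("_expr.tsv")] for p in data.glob("*_expr.tsv"))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, run_dir: Path) -> dict:
    block = config["simulate"]
    data = run_dir / "data"
    data.mkdir(parents=True, exist_ok=True)

    bulk_cfg = simulate.BulkSimConfig(**{**block["bulk"], "seed": config.seed})
    cohorts = simulate.simulate_bulk(bulk_cfg)
    all_meta = []
    for matrix, metadata in cohorts:
        cohort = metadata[0].cohort_id
        write_expression(matrix, data / f"{cohort}_expr.tsv")
        write_metadata(metadata, data / f"{cohort}_meta.tsv")
        all_meta.extend(metadata)

    surv_cfg = simulate.SurvSimConfig(**{**block["survival"], "seed": config.seed + 1})
    records = simulate.simulate_survival(all_meta, surv_cfg)
    write_clinical(records, data / "clinical.tsv")

    sc_cfg = simulate.SCSimConfig(**{**block["single_cell"], "seed": config.seed + 2})
    adata = simulate.simulate_single_cell(sc_cfg)
    counts = sp.coo_matrix(adata.X.T).astype(int)  # genes x cells on disk
    scipy.io.mmwrite(str(data / "sc_matrix.mtx"), counts, field="integer")
    (data / "sc_features.tsv").write_text("\n".join(adata.var_names) + "\n")
    (data / "sc_barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    _write_tsv(adata.obs, data / "sc_obs.tsv")
    with open(data / "sc_patient_fucosylation.json", "w") as handle:
        json.dump(adata.uns["patient_fucosylation"], handle, sort_keys=True, indent=1)

    write_gmt(catalog.make_glyco_catalog(), data / "catalog.gmt")
    return {
        "cohorts": [meta[0].cohort_id for _, meta in cohorts],
        "n_bulk_samples": sum(m.n_samples for m, _ in cohorts),
        "n_cells": int(adata.n_obs),
    }


def _load_cohort(run_dir: Path, cohort: str):
    data = run_dir / "data"
    matrix = load_expression(_require(data / f"{cohort}_expr.tsv", "simulate"))
    metadata = load_metadata(_require(data / f"{cohort}_meta.tsv", "simulate"))
    return matrix, metadata


def stage_de(config: RunConfig, run_dir: Path) -> dict:
    out = run_dir / "de"
    out.mkdir(exist_ok=True)
    sizes = {}
    for cohort in _cohort_ids(run_dir):
        matrix, metadata = _load_cohort(run_dir, cohort)
        paired = any(m.pair_id is not None for m in metadata)
        design = diffexp.design_from_metadata(metadata, paired=paired)
        if paired:
            matrix = matrix.subset_samples([m.sample_id for m in metadata if m.pair_id])
        result = diffexp.moderated_t(matrix, design)
        _write_tsv(result.table, out / f"{cohort}_de.tsv")
        sizes[cohort] = int((result.table["q"] < 0.05).sum())
    return {"n_q05_per_cohort": sizes}


def stage_panel(config: RunConfig, run_dir: Path) -> dict:
    block = config["panel"]
    de_dir = _require(run_dir / "de", "de")
    results = {}
    for cohort in _cohort_ids(run_dir):
        table = pd.read_csv(_require(de_dir / f"{cohort}_de.tsv", "de"), sep="\t", index_col=0)
        results[cohort] = diffexp.DEResult(table=table, prior_df=np.nan, prior_var=np.nan)
    selection = diffexp.select_panel(
        results,
        p_max=block["p_max"],
        min_cohorts=block["min_cohorts"],
        use_adjusted=config["de"]["use_adjusted"],
    )
    out = run_dir / "panel"
    out.mkdir(exist_ok=True)
    _write_tsv(selection.table, out / "panel.tsv")
    (out / "panel_genes.txt").write_text("\n".join(selection.selected_genes) + "\n")
    return {"panel_size": len(selection.selected_genes)}


def _discovery_tumours(run_dir: Path, cohort: str):
    matrix, metadata = _load_cohort(run_dir, cohort)
    tumours = [m for m in metadata if m.condition == "tumour"]
    return matrix.subset_samples([m.sample_id for m in tumours]), tumours


def stage_cluster(config: RunConfig, run_dir: Path) -> dict:
    block = config["cluster"]
    panel_file = _require(run_dir / "panel" / "panel_genes.txt", "panel")
    genes = panel_file.read_text().split()
    matrix, _ = _discovery_tumours(run_dir, block["cohort"])
    genes = [g for g in genes if g in set(matrix.gene_ids)]
    run = consensus.consensus_cluster(
        matrix,
        genes=genes,
        k_range=tuple(block["k_range"]),
        n_iterations=block["n_iterations"],
        subsample_fraction=block["subsample_fraction"],
        seed=config.seed,
        center=block["center"],
    )
    k = consensus.select_k(run, delta_min=block["delta_min"])
    out = run_dir / "cluster"
    out.mkdir(exist_ok=True)
    for kk, c in run.consensus.items():
        _write_tsv(pd.DataFrame(c, index=run.ids, columns=run.ids), out / f"consensus_k{kk}.tsv")
    labels = pd.DataFrame(
        {f"k{kk}": run.labels[kk] for kk in run.k_range}, index=pd.Index(run.ids, name="sample_id")
    )
    _write_tsv(labels, out / "labels.tsv")
    summary = {
        "selected_k": k,
        "cdf_area": {str(kk): run.cdf_area[kk] for kk in run.k_range},
        "delta_area": {str(kk): run.delta_area[kk] for kk in run.k_range},
        "n_iterations": run.n_iterations,
        "subsample_fraction": run.subsample_fraction,
        "seed": run.seed,
        "cohort": block["cohort"],
        "panel_size": len(genes),
    }
    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, sort_keys=True, indent=1)
    return {"selected_k": k, "panel_size": len(genes)}


def _cluster_labels(run_dir: Path) -> tuple[pd.Series, int]:
    out = run_dir / "cluster"
    with open(_require(out / "summary.json", "cluster")) as handle:
        summary = json.load(handle)
    k = summary["selected_k"]
    labels = pd.read_csv(out / "labels.tsv", sep="\t", index_col=0)[f"k{k}"]
    return labels, k


def name_clusters(
    matrix: ExpressionMatrix, labels: pd.Series, sets: GeneSetCollection
) -> dict[int, str]:
    """Name consensus clusters from their glyco signature scores.

    The cluster with the highest mean fucosylation-programme score is
    Fucosylated; among the rest, the highest mesenchymal score is Basal;
    anything remaining is cluster C (no specific glycan signature).
    """
    signature = GeneSetCollection()
    signature.add(sets["FUC_ALL"])
    signature.add(sets["MESENCHYMAL"])
    scores = scoring.ss_enrichment(matrix, signature)
    clusters = sorted(set(labels))
    fuc = {c: scores.row("FUC_ALL")[labels.to_numpy() == c].mean() for c in clusters}
    mes = {c: scores.row("MESENCHYMAL")[labels.to_numpy() == c].mean() for c in clusters}
    names: dict[int, str] = {}
    fuc_cluster = max(clusters, key=lambda c: fuc[c])
    names[fuc_cluster] = "Fucosylated"
    rest = [c for c in clusters if c != fuc_cluster]
    if rest:
        basal_cluster = max(rest, key=lambda c: mes[c])
        names[basal_cluster] = "Basal"
        for c in rest:
            if c != basal_cluster:
                names[c] = "C" if len(rest) == 2 else f"C{c}"
    return names


def stage_score(config: RunConfig, run_dir: Path) -> dict:
    block = config["score"]
    cohort = config["cluster"]["cohort"]
    matrix, tumours = _discovery_tumours(run_dir, cohort)
    labels, k = _cluster_labels(run_dir)
    sets = load_gmt(_require(run_dir / "data" / "catalog.gmt", "simulate"))
    scores = scoring.ss_enrichment(matrix, sets, tau=block["tau"])
    out = run_dir / "score"
    out.mkdir(exist_ok=True)
    _write_tsv(scores.to_frame(), out / "scores.tsv")

    names = name_clusters(matrix, labels, sets)
    named = labels.map(names)
    emt = scoring.emt_score(scores)
    emt_frame = pd.DataFrame({"emt_score": emt, "cluster": named})
    _write_tsv(emt_frame, out / "emt.tsv")

    rows = []
    label_arr = labels.to_numpy()
    for name in scores.set_names:
        h, p = scoring.kruskal_wallis(scores.row(name), label_arr)
        rows.append({"set": name, "kw_h": h, "kw_p": p})
    h, p = scoring.kruskal_wallis(emt.to_numpy(), label_arr)
    rows.append({"set": "EMT_SCORE", "kw_h": h, "kw_p": p})
    purity = pd.Series({m.sample_id: m.purity for m in tumours}).reindex(labels.index)
    h, p = scoring.kruskal_wallis(purity.to_numpy(), label_arr)
    rows.append({"set": "PURITY", "kw_h": h, "kw_p": p})
    kw = pd.DataFrame(rows).set_index("set")
    _write_tsv(kw, out / "kruskal_wallis.tsv")

    bubble = []
    for name in scores.set_names:
        row = scores.row(name)
        for cluster_name in sorted(set(named)):
            mask = (named == cluster_name).to_numpy()
            bubble.append(
                {
                    "set": name,
                    "cluster": cluster_name,
                    "mean_score": row[mask].mean(),
                    "neg_log10_kw_p": -np.log10(max(kw.loc[name, "kw_p"], 1e-300)),
                }
            )
    _write_tsv(pd.DataFrame(bubble), out / "bubble.tsv", index=False)
    _write_tsv(named.rename("cluster_name").to_frame(), out / "cluster_names.tsv")
    return {"purity_kw_p": float(kw.loc["PURITY", "kw_p"]), "emt_kw_p": float(kw.loc["EMT_SCORE", "kw_p"])}


def default_schemes(sets: GeneSetCollection) -> list[network.SchemeDefinition]:
    """Two synthetic classification schemes used as concordance stand-ins.

    Real published classifiers are user-suppliable GMTs; these stand-ins
    mirror the epithelial/classical vs mesenchymal/basal axis.
    """
    classical = GeneSet(
        "classical_like", "epithelial + fucosylation classifier",
        tuple(dict.fromkeys(sets["EPITHELIAL"].members + sets["FUC_ALL"].members)),
    )
    basal_like = GeneSet(
        "basal_like", "mesenchymal + basal classifier",
        tuple(dict.fromkeys(sets["MESENCHYMAL"].members + sets["BASAL_MARKERS"].members)),
    )
    scheme_a = network.SchemeDefinition(
        "moffitt_like", ("classical_like", "basal_like"),
        {"classical_like": classical, "basal_like": basal_like},
    )
    epithelial = GeneSet("epithelial", "epithelial pole", sets["EPITHELIAL"].members)
    mesenchymal = GeneSet("mesenchymal", "mesenchymal pole", sets["MESENCHYMAL"].members)
    scheme_b = network.SchemeDefinition(
        "emt_class", ("epithelial", "mesenchymal"),
        {"epithelial": epithelial, "mesenchymal": mesenchymal},
    )
    return [scheme_a, scheme_b]


def stage_network(config: RunConfig, run_dir: Path) -> dict:
    block = config["network"]
    cohort = config["cluster"]["cohort"]
    matrix, _ = _discovery_tumours(run_dir, cohort)
    labels, _ = _cluster_labels(run_dir)
    sets = load_gmt(_require(run_dir / "data" / "catalog.gmt", "simulate"))
    names = name_clusters(matrix, labels, sets)
    assignments = {"glyco_cluster": {s: names[int(l)] for s, l in labels.items()}}
    for scheme in default_schemes(sets):
        assignments[scheme.name] = network.classify_scheme(
            matrix,
            scheme,
            n_iterations=block["n_iterations"],
            seed=config.seed,
        )
    table = network.AssignmentTable(assignments)
    net = network.build_network(table, alpha=block["alpha"], on_adjusted=block["on_adjusted"])
    out = run_dir / "network"
    out.mkdir(exist_ok=True)
    _write_tsv(net.edges, out / "edges.tsv", index=False)
    meta = pd.DataFrame(
        sorted(net.meta_clusters.items()), columns=["node", "meta_cluster"]
    )
    _write_tsv(meta, out / "meta_clusters.tsv", index=False)
    assign_frame = pd.DataFrame(assignments)
    assign_frame.index.name = "sample_id"
    _write_tsv(assign_frame, out / "assignments.tsv")
    import networkx as nx

    nx.write_graphml(net.graph, out / "network.graphml")
    return {"n_significant_edges": int(net.edges["significant"].sum())}


def stage_survival(config: RunConfig, run_dir: Path) -> dict:
    records = load_clinical(_require(run_dir / "data" / "clinical.tsv", "simulate"))
    labels, _ = _cluster_labels(run_dir)
    cohort = config["cluster"]["cohort"]
    matrix, _ = _discovery_tumours(run_dir, cohort)
    sets = load_gmt(run_dir / "data" / "catalog.gmt")
    names = name_clusters(matrix, labels, sets)
    groups = {s: names[int(l)] for s, l in labels.items()}
    records = [r for r in records if r.sample_id in groups]
    out = run_dir / "survival"
    out.mkdir(exist_ok=True)
    for name in sorted(set(groups.values())):
        sub = [r for r in records if groups[r.sample_id] == name]
        curve = survival.kaplan_meier(sub)
        _write_tsv(
            pd.DataFrame(
                {
                    "time": curve.event_times,
                    "survival": curve.survival,
                    "at_risk": curve.at_risk,
                }
            ),
            out / f"km_{name}.tsv",
            index=False,
        )
    result = survival.logrank(records, groups)
    with open(out / "logrank.json", "w") as handle:
        json.dump(
            {"chi2": result.chi2, "df": result.df, "p": result.p}, handle, sort_keys=True, indent=1
        )
    _write_tsv(survival.pairwise_logrank(records, groups), out / "pairwise.tsv", index=False)
    return {"logrank_p": result.p, "logrank_chi2": result.chi2}


def stage_sc(config: RunConfig, run_dir: Path) -> dict:
    block = config["sc"]
    data = run_dir / "data"
    adata = load_sc_counts(
        _require(data / "sc_matrix.mtx", "simulate"),
        data / "sc_features.tsv",
        data / "sc_barcodes.tsv",
    )
    obs = pd.read_csv(data / "sc_obs.tsv", sep="\t", index_col=0)
    adata.obs = obs.loc[adata.obs_names]
    adata = single_cell.run_sc_pipeline(
        adata,
        n_hvg=block["n_hvg"],
        n_comp=block["n_comp"],
        k_neighbors=block["k_neighbors"],
        resolution=block["resolution"],
        seed=config.seed,
    )
    sets = load_gmt(data / "catalog.gmt")
    programs = GeneSetCollection()
    for name in ("FUC_SYNTHESIS", "FUC_TRANSFERASES", "FUC_ALL"):
        programs.add(sets[name])
    corr = single_cell.cross_compartment_corr(
        adata,
        programs,
        cytokine_genes=list(block["cytokines"]),
        method=block["method"],
        seed=config.seed,
    )
    out = run_dir / "sc"
    out.mkdir(exist_ok=True)
    _write_tsv(
        adata.obs[["patient", "cell_type", "label", "cluster"]], out / "clusters.tsv"
    )
    scores = {
        s.name: single_cell.module_score(
            adata.layers["normalized"], list(adata.var_names), s, seed=config.seed
        )
        for s in programs
    }
    _write_tsv(pd.DataFrame(scores, index=adata.obs_names), out / "module_scores.tsv")
    _write_tsv(corr.table, out / "correlations.tsv", index=False)
    n_clusters = int(adata.obs["cluster"].nunique())
    rhos = {
        f"rho_FUC_ALL_{cyt}": corr.rho("FUC_ALL", cyt) for cyt in block["cytokines"]
    }
    return {"n_sc_clusters": n_clusters, **rhos}


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "de": stage_de,
    "panel": stage_panel,
    "cluster": stage_cluster,
    "score": stage_score,
    "network": stage_network,
    "survival": stage_survival,
    "sc": stage_sc,
}


def run_pipeline(config: RunConfig, run_dir, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in dependency order; write report.json.

    Returns the report dictionary: per-stage parameters and headline
    metrics.  Stages not requested must already have their outputs in
    ``run_dir`` or a dependency error is raised by the stage that needs
    them.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    config.to_yaml(run_dir / "config.yaml")
    report: dict = {"seed": config.seed, "stages": {}}
    for stage in STAGES:  # fixed dependency order
        if stage not in stages:
            continue
        metrics = STAGE_FUNCS[stage](config, run_dir)
        report["stages"][stage] = {"params": config[stage], "metrics": metrics}
    with open(run_dir / "report.json", "w") as handle:
        json.dump(report, handle, sort_keys=True, indent=1, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialise {type(obj)}")
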