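"""End-to-end orchestration: simulate/load -> select -> connectome ->
integrate -> enrich, with a reproducibility manifest.

All randomness flows from the single configured seed. Every stage's
tables are written as TSV (plus GraphML for the network) under the
output directory, and ``manifest.yaml`` records the configuration echo,
seed, per-stage row counts, package version and wall-clock seconds, so
a run can be audited and reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import omicnet
from omicnet import LAYERS
from omicnet.connectome import (
    build_graph,
    centralities,
    detect_clusters,
    edge_table,
    export_graphml,
    hub_ranking,
    interomic_connectivity,
    standardize_and_correlate,
)
from omicnet.differential import ThresholdSet, select_features, select_grade_features, volcano_table
from omicnet.enrichment import enrich
from omicnet.errors import ConfigError, InsufficientDataError, OmicnetError
from omicnet.integration import (
    cluster_clinical_association,
    cluster_samples,
    integrate,
    n_components_for,
    pca_scores,
)
from omicnet.io import (
    ClinicalTable,
    OmicsLayer,
    align_samples,
    display_symbol,
    read_clinical,
    read_gmt,
    read_layer,
)
from omicnet.simulate import (
    MultiOmicsDataset,
    SimulationConfig,
    make_synthetic_gene_sets,
    simulate_dataset,
)

log = logging.getLogger(__name__)

#: published correlation thresholds per analysis arm
DEFAULT_R_THRESHOLD = {"recurrence": 0.70, "grade": 0.75}


@dataclass
class RunConfig:
    """One pipeline run: either simulate a cohort or load matrices."""

    out_dir: str = "results/run"
    seed: int = 0
    contrast: str = "recurrence"  # 'recurrence' or 'grade'
    simulate: bool = True
    sim_config: SimulationConfig | None = None
    input_paths: dict[str, str] = field(default_factory=dict)  # layer/clinical paths
    gmt_path: str | None = None
    r_threshold: float | None = None  # default depends on contrast
    cluster_method: str = "components"
    k_clusters: int = 3
    fc_mode: str = "log2"
    grade_combine: str = "union"

    def resolved_r_threshold(self) -> float:
        if self.r_threshold is not None:
            if not (0.0 < self.r_threshold < 1.0):
                raise ConfigError("r_threshold: must lie in (0,1)")
            return self.r_threshold
        return DEFAULT_R_THRESHOLD["grade" if self.contrast == "grade" else "recurrence"]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim_config", None)
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim_config = SimulationConfig(
                **{
                    k: tuple(v) if k == "n_per_group" else v
                    for k, v in sim_raw.items()
                }
            )
        return cfg


def _load_inputs(cfg: RunConfig) -> tuple[list[OmicsLayer], ClinicalTable, MultiOmicsDataset | None]:
    if cfg.simulate:
        sim_cfg = cfg.sim_config or SimulationConfig(
            seed=cfg.seed,
            n_per_group=(35, 55) if cfg.contrast == "recurrence" else (37, 37, 16),
        )
        dataset = simulate_dataset(sim_cfg)
        return list(dataset.layers.values()), dataset.clinical, dataset
    missing = [p for p in cfg.input_paths.values() if not Path(p).exists()]
    if missing:
        raise ConfigError(f"input_paths: missing files {missing}")
    layers = [read_layer(cfg.input_paths[name], name) for name in LAYERS]
    clinical = read_clinical(cfg.input_paths["clinical"])
    return layers, clinical, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": omicnet.__version__,
        "seed": cfg.seed,
        "contrast": cfg.contrast,
        "r_threshold": cfg.resolved_r_threshold(),
        "cluster_method": cfg.cluster_method,
        "k_clusters": cfg.k_clusters,
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                info = fn()
            except OmicnetError as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(manifest, out)
                raise OmicnetError(f"stage {name!r} failed: {exc}") from exc
            info["status"] = "complete"
            info["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = info
            return info

        return wrap

    # -- stage 1: simulate / load ------------------------------------------
    holder: dict = {}

    def _stage_input():
        layers, clinical, dataset = _load_inputs(cfg)
        (layers, clinical) = align_samples(layers, clinical)
        holder.update(layers=layers, clinical=clinical, dataset=dataset)
        if dataset is not None:
            from omicnet.simulate import write_dataset

            write_dataset(dataset, out / "simulated")
            manifest["sim_config"] = dataclasses.asdict(dataset.config)
        return {
            "n_samples": len(clinical.sample_ids),
            "n_features": {ly.layer_name: ly.n_features for ly in layers},
        }

    stage("simulate" if cfg.simulate else "load")(_stage_input)

    # -- stage 2: differential selection -----------------------------------
    def _stage_select():
        layers, clinical = holder["layers"], holder["clinical"]
        selected: dict[str, list[str]] = {}
        counts = {}
        for ly in layers:
            if cfg.contrast == "grade":
                rec = select_grade_features(
                    ly, clinical, combine=cfg.grade_combine, fc_mode=cfg.fc_mode
                )
                passers = rec.loc[rec["passes_combined"], "feature_id"].unique()
            else:
                rec = select_features(
                    ly, clinical, "recurrence", fc_mode=cfg.fc_mode
                )
                passers = rec.loc[rec["passes"], "feature_id"].unique()
            rec.to_csv(out / f"differential_{ly.layer_name}.tsv", sep="\t", index=False)
            vt = volcano_table(rec.drop_duplicates("feature_id"))
            vt.to_csv(out / f"volcano_{ly.layer_name}.tsv", sep="\t", index=False)
            selected[ly.layer_name] = list(passers)
            counts[ly.layer_name] = len(passers)
        holder["selected"] = selected
        return {"selected": counts}

    stage("select")(_stage_select)

    # -- stage 3: connectome ------------------------------------------------
    def _stage_connectome():
        layers = holder["layers"]
        selected = holder["selected"]
        submats = []
        for ly in layers:
            keep = [display_symbol(f) for f in selected[ly.layer_name]]
            submats.append(
                OmicsLayer(layer_name=ly.layer_name, values=ly.values.loc[keep])
            )
        n_selected = sum(m.n_features for m in submats)
        info: dict = {"n_selected_features": n_selected}
        if n_selected < 2:
            holder["graph"] = None
            info.update(n_edges=0, n_clusters=0)
            return info
        R = standardize_and_correlate(submats)
        cg = build_graph(R, cfg.resolved_r_threshold(), n_samples=submats[0].n_samples)
        cent = centralities(cg)
        _, n_clusters = detect_clusters(cg, cfg.cluster_method)
        cent = cent.assign(cluster=[cg.cluster_of[n] for n in cent.index])
        cent.to_csv(out / "centrality.tsv", sep="\t", index_label="node")
        edge_table(cg).to_csv(out / "edges.tsv", sep="\t", index=False)
        export_graphml(cg, out / "connectome.graphml")
        hubs = hub_ranking(cg, k=min(10, cent.shape[0]))
        hubs.to_csv(out / "hubs.tsv", sep="\t", index_label="node")
        info.update(
            n_edges=cg.graph.number_of_edges(), n_clusters=n_clusters
        )
        if cg.graph.number_of_edges():
            frac, pair_counts = interomic_connectivity(cg)
            info["inter_edge_fraction"] = round(frac, 4)
            info["edge_classes"] = pair_counts
        holder["graph"] = cg
        return info

    stage("connectome")(_stage_connectome)

    # -- stage 4: integration + sample clustering ---------------------------
    def _stage_integrate():
        layers, clinical = holder["layers"], holder["clinical"]
        subset = [f for ly in layers for f in holder["selected"][ly.layer_name]]
        info: dict = {}
        if not subset:
            info["skipped"] = "no selected features"
            return info
        m = integrate(layers, feature_subset=subset)
        k_comp = max(2, n_components_for(m))
        scores, evr = pca_scores(m, k_comp)
        scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
        labels = cluster_samples(scores, k=cfg.k_clusters, seed=cfg.seed)
        labels.to_csv(out / "sample_clusters.tsv", sep="\t", index_label="sample_id")
        assoc_rows = []
        for variable in ("recurrence", "grade"):
            table, statistic, p, test = cluster_clinical_association(
                labels, clinical, variable, seed=cfg.seed
            )
            table.to_csv(out / f"association_{variable}.tsv", sep="\t")
            assoc_rows.append(
                {"variable": variable, "test": test, "statistic": statistic, "p": p}
            )
        info.update(
            n_components=k_comp,
            explained_variance=[round(float(v), 4) for v in evr],
            association={r["variable"]: r["p"] for r in assoc_rows},
        )
        holder["labels"] = labels
        return info

    stage("integrate")(_stage_integrate)

    # -- stage 5: enrichment -------------------------------------------------
    def _stage_enrich():
        layers = holder["layers"]
        universe = {
            display_symbol(f)
            for ly in layers
            if ly.layer_name in ("rna", "protein")
            for f in ly.namespaced().index
        }
        query = {
            display_symbol(f)
            for name in ("rna", "protein")
            for f in holder["selected"][name]
        }
        info: dict = {}
        if not query:
            info["skipped"] = "no selected gene symbols"
            return info
        if cfg.gmt_path:
            collection = read_gmt(cfg.gmt_path)
        elif holder.get("dataset") is not None:
            collection = make_synthetic_gene_sets(holder["dataset"], seed=cfg.seed)
        else:
            info["skipped"] = "no gene-set collection supplied"
            return info
        results = enrich(query, collection, universe)
        results.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        info.update(n_sets_tested=len(results))
        if len(results):
            info["top_set"] = str(results.iloc[0]["set_name"])
            info["top_p"] = float(results.iloc[0]["p_value"])
        return info

    stage("enrich")(_stage_enrich)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
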