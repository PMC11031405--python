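"""End-to-end orchestration: simulate -> preprocess -> de -> propagate ->
enrich -> classify -> integrate.

Every stage reads and writes flat TSV files, so any stage can be re-run alone
from a prior stage's outputs.  A run writes a machine-readable manifest
(parameters, package version, input checksums) and is bit-reproducible under
a fixed seed: all randomness flows from one seeded generator and all outputs
are written in deterministic order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import (
    default_contrasts,
    estimate_moderation,
    fit_models,
    moderated_test,
)
from .enrichment import fisher_enrichment, signed_scores
from .integrate import (
    classify_age_terms,
    classify_rapa_terms,
    classify_s6k_inhibition_terms,
    cross_dataset_concordance,
    restrict_to_common_genes,
)
from .io import (
    read_annotations,
    read_design,
    read_intensity_table,
    read_network_edges,
    read_protein_table,
    write_table,
)
from .netprop import PropagationConfig, build_operator, propagate, select_nodes
from .preprocess import (
    aggregate_peptides,
    filter_by_detection,
    impute_missing,
    log2_z_rescale,
    pca_scores,
    remove_batch_means,
)
from .simulate import SynthConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "analyze_dataset"]


@dataclass
class PipelineConfig:
    """All pipeline parameters with their study defaults."""

    seed: int = 0
    # preprocessing
    min_detected: int = 3
    knn_k: int = 10
    aggregate: str = "median"
    # network propagation
    score_threshold: int = 899
    alpha: float = 0.5
    iterations: int = 26
    normalization: str = "symmetric"
    weighting: str = "binary"
    min_degree: int = 5
    quantile: float = 0.05
    # enrichment + rules
    min_term_size: int = 5
    alpha_p: float = 0.05
    rule_margin: float = 2.0
    # contrast roles for the classification rules
    age_contrast: str = "old_vs_young_control"
    rapa_contrast: str = "rapa_vs_etoh_uninduced"
    rapa_under_activation_contrast: str = "rapa_vs_etoh_induced"
    rnai_induction_contrast: str = "ru_vs_etoh_uninduced"
    # synthetic-data overrides (fields of SynthConfig)
    synth: dict = field(default_factory=dict)

    def synth_config(self, seed: int | None = None, **overrides) -> SynthConfig:
        params = dict(self.synth)
        params.update(overrides)
        params["seed"] = int(self.seed if seed is None else seed)
        return SynthConfig(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def analyze_dataset(ds, config: PipelineConfig, contrast: str,
                    de_table: pd.DataFrame | None = None) -> dict:
    """Run preprocess -> differential -> propagate -> enrich on a simulated
    dataset in memory; returns every intermediate result.

    ``de_table`` lets callers substitute a (e.g. common-gene-restricted)
    differential table while reusing the dataset's graph and annotations.
    """
    if de_table is None:
        normalized, record = log2_z_rescale(ds.peptides)
        proteins = aggregate_peptides(normalized, method=config.aggregate)
        filtered = filter_by_detection(proteins, ds.design, min_detected=config.min_detected)
        imputed = impute_missing(filtered, k=config.knn_k)
        fit = fit_models(imputed, ds.design, covariates=("batch",))
        params = estimate_moderation(fit.s2, fit.df_residual)
        de_table = moderated_test(fit, params, default_contrasts()[contrast])
    prop_config = PropagationConfig(
        alpha=config.alpha, iterations=config.iterations,
        normalization=config.normalization, weighting=config.weighting,
    )
    op = build_operator(ds.graph, prop_config)
    scores = propagate(de_table["log2fc"], op, alpha=config.alpha,
                       iterations=config.iterations)
    measured = set(de_table.index)
    selection = select_nodes(
        scores, ds.graph, min_degree=config.min_degree, quantile=config.quantile,
        universe=measured,
    )
    background = [
        n for n, d in ds.graph.degree() if d >= config.min_degree and n in measured
    ]
    table = fisher_enrichment(selection, background, ds.annotations,
                              min_size=config.min_term_size)
    enrichment = signed_scores(table)
    return {
        "de": de_table,
        "scores": scores,
        "selection": selection,
        "background": background,
        "enrichment": enrichment,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, out: Path, seed: int | None = None,
                   dataset_id: str = "synthetic") -> dict[str, Path]:
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config.synth_config(seed=seed, dataset_id=dataset_id))
    paths = {
        "peptides": out / "peptides.tsv",
        "design": out / "design.tsv",
        "network": out / "network.tsv",
        "annotations": out / "annotations.tsv",
        "truth_log2fc": out / "truth_log2fc.tsv",
        "truth_modules": out / "truth_modules.tsv",
    }
    write_table(ds.peptides, paths["peptides"])
    write_table(ds.design.table.reset_index(drop=True), paths["design"])
    with open(paths["network"], "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b in sorted(tuple(sorted(e)) for e in ds.graph.edges()):
            fh.write(f"{a}\t{b}\t{ds.graph[a][b]['score']}\n")
    with open(paths["annotations"], "w") as fh:
        for term in sorted(ds.annotations.terms):
            for gene in sorted(ds.annotations.terms[term]):
                fh.write(f"{term}\t{gene}\n")
    write_table(ds.truth.true_log2fc, paths["truth_log2fc"])
    modules = pd.DataFrame(
        sorted(ds.truth.modules.items()), columns=["protein_id", "module"]
    )
    write_table(modules, paths["truth_modules"])
    _write_json(
        {"planted_terms": ds.truth.planted_terms, "seed": int(ds.config.seed)},
        out / "truth_planted_terms.json",
    )
    return paths


def stage_preprocess(peptides_path: Path, design_path: Path, config: PipelineConfig,
                     out: Path) -> Path:
    out.mkdir(parents=True, exist_ok=True)
    peptides = read_intensity_table(peptides_path, scale="raw")
    design = read_design(design_path)
    unknown = [c for c in peptides.values.columns if c not in set(design.sample_ids)]
    if unknown:
        raise ValueError(f"intensity columns not in design: {unknown}")
    normalized, record = log2_z_rescale(peptides)
    proteins = aggregate_peptides(normalized, method=config.aggregate)
    filtered = filter_by_detection(proteins, design, min_detected=config.min_detected)
    imputed = impute_missing(filtered, k=config.knn_k)
    write_table(imputed, out / "proteins.tsv")
    _write_json(
        {
            "global_mean": record.global_mean,
            "global_sd": record.global_sd,
            "dropped_constant_rows": record.dropped_constant_rows,
            "proteins_before_filter": int(proteins.values.shape[0]),
            "proteins_after_filter": int(filtered.values.shape[0]),
        },
        out / "normalization.json",
    )
    batch_removed = remove_batch_means(imputed, design)
    write_table(batch_removed, out / "proteins_batch_removed.tsv")
    scores, var_exp = pca_scores(batch_removed, n_components=min(5, len(design.table) - 1))
    pca_df = scores.rename_axis("sample_id").reset_index()
    write_table(pca_df, out / "pca_scores.tsv")
    _write_json({"variance_explained": [float(v) for v in var_exp]}, out / "pca_variance.json")
    return out / "proteins.tsv"


def stage_de(proteins_path: Path, design_path: Path, config: PipelineConfig,
             out: Path) -> dict[str, Path]:
    out.mkdir(parents=True, exist_ok=True)
    proteins = read_protein_table(proteins_path)
    design = read_design(design_path)
    fit = fit_models(proteins, design, covariates=("batch",))
    params = estimate_moderation(fit.s2, fit.df_residual)
    contrasts = default_contrasts()
    paths = {}
    for name in sorted(contrasts):
        result = moderated_test(fit, params, contrasts[name], adjust=True)
        path = out / f"de_{name}.tsv"
        write_table(result, path)
        paths[name] = path
    _write_json(
        {"d0": params.d0 if np.isfinite(params.d0) else "inf", "s0_sq": params.s0_sq,
         "residual_df": fit.df_residual},
        out / "moderation.json",
    )
    return paths


def stage_propagate(de_path: Path, edges_path: Path, config: PipelineConfig,
                    out: Path, contrast: str) -> tuple[Path, Path]:
    out.mkdir(parents=True, exist_ok=True)
    de = pd.read_csv(de_path, sep="\t", dtype={"protein_id": str}).set_index("protein_id")
    graph = read_network_edges(edges_path, score_threshold=config.score_threshold)
    prop_config = PropagationConfig(
        alpha=config.alpha, iterations=config.iterations,
        normalization=config.normalization, weighting=config.weighting,
    )
    op = build_operator(graph, prop_config)
    scores = propagate(de["log2fc"], op, alpha=config.alpha, iterations=config.iterations)
    measured = set(de.index)
    selection = select_nodes(
        scores, graph, min_degree=config.min_degree, quantile=config.quantile,
        universe=measured,
    )
    scores_path = out / f"prop_{contrast}.tsv"
    df = scores.scores.rename_axis("protein_id").reset_index()
    df["measured"] = df["protein_id"].isin(measured).astype(int)
    write_table(df, scores_path)
    sel_rows = [(n, "up") for n in sorted(selection.up)] + [
        (n, "down") for n in sorted(selection.down)
    ]
    sel_path = out / f"selection_{contrast}.tsv"
    write_table(pd.DataFrame(sel_rows, columns=["protein_id", "direction"]), sel_path)
    meta = {
        "contrast": contrast, "alpha": config.alpha, "iterations": config.iterations,
        "normalization": config.normalization, "weighting": config.weighting,
        "coverage": scores.coverage, "n_selected_per_direction": len(selection.up),
        "background_size": len(
            [n for n, d in graph.degree() if d >= config.min_degree and n in measured]
        ),
    }
    _write_json(meta, out / f"prop_{contrast}.json")
    return scores_path, sel_path


def stage_enrich(selection_path: Path, de_path: Path, edges_path: Path,
                 annotations_path: Path, config: PipelineConfig, out: Path,
                 contrast: str) -> Path:
    out.mkdir(parents=True, exist_ok=True)
    sel_df = pd.read_csv(selection_path, sep="\t", dtype=str)
    de = pd.read_csv(de_path, sep="\t", dtype={"protein_id": str}).set_index("protein_id")
    graph = read_network_edges(edges_path, score_threshold=config.score_threshold)
    annotations = read_annotations(annotations_path, format="two_column")
    measured = set(de.index)
    background = [
        n for n, d in graph.degree() if d >= config.min_degree and n in measured
    ]
    from .netprop import NodeSelection

    selection = NodeSelection(
        up=sorted(sel_df.loc[sel_df["direction"] == "up", "protein_id"]),
        down=sorted(sel_df.loc[sel_df["direction"] == "down", "protein_id"]),
        min_degree=config.min_degree, quantile=config.quantile,
    )
    table = fisher_enrichment(selection, background, annotations, min_size=config.min_term_size)
    collapsed = signed_scores(table)
    path = out / f"enrichment_{contrast}.tsv"
    write_table(collapsed, path)
    return path


def stage_classify(enrichment_paths: dict[str, Path], config: PipelineConfig,
                   out: Path) -> Path:
    out.mkdir(parents=True, exist_ok=True)

    def load(role: str) -> pd.DataFrame:
        return pd.read_csv(enrichment_paths[role], sep="\t", dtype={"term_id": str})

    age = classify_age_terms(load(config.age_contrast), alpha=config.alpha_p)
    rapa = classify_rapa_terms(
        load(config.rapa_contrast), load(config.rapa_under_activation_contrast),
        margin=config.rule_margin,
    )
    inh = classify_s6k_inhibition_terms(
        load(config.rnai_induction_contrast), threshold=config.rule_margin
    )
    labels = pd.concat([age, rapa, inh], ignore_index=True)
    path = out / "term_classes.tsv"
    write_table(labels, path)
    return path


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full chain on a simulated study and a three-dataset integration.

    Stages write into numbered subdirectories of ``out_dir``; re-running with
    the same config and seed reproduces every output bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    sim_paths = stage_simulate(config, out_dir / "01_simulate")
    proteins_path = stage_preprocess(
        sim_paths["peptides"], sim_paths["design"], config, out_dir / "02_preprocess"
    )
    de_paths = stage_de(proteins_path, sim_paths["design"], config, out_dir / "03_de")
    prop_dir = out_dir / "04_propagate"
    enr_dir = out_dir / "05_enrich"
    enrichment_paths: dict[str, Path] = {}
    for contrast, de_path in de_paths.items():
        _, sel_path = stage_propagate(de_path, sim_paths["network"], config, prop_dir, contrast)
        enrichment_paths[contrast] = stage_enrich(
            sel_path, de_path, sim_paths["network"], sim_paths["annotations"],
            config, enr_dir, contrast,
        )
    stage_classify(enrichment_paths, config, out_dir / "06_classify")
    _integrate_stage(config, out_dir, sim_paths, de_paths, enrichment_paths)

    manifest = {
        "package_version": __version__,
        "parameters": config.to_dict(),
        "inputs": {k: _sha256(p) for k, p in sorted(sim_paths.items())},
        "outputs": sorted(
            str(p.relative_to(out_dir)) for p in out_dir.rglob("*") if p.is_file()
        ),
    }
    _write_json(manifest, out_dir / "manifest.json")
    return out_dir


def _integrate_stage(config: PipelineConfig, out_dir: Path, sim_paths, de_paths,
                     enrichment_paths) -> Path:
    """Three-dataset concordance: the main run plus two sibling simulations.

    The siblings share the planted effect map (hence the planted term) but use
    their own seeds, so networks, annotations (decoys) and noise differ.
    """
    out = out_dir / "07_integrate"
    out.mkdir(parents=True, exist_ok=True)
    child_seeds = [
        int(s) for s in np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    ]
    datasets = [("dataset1", None)] + [
        (f"dataset{i + 2}", s) for i, s in enumerate(child_seeds)
    ]
    contrast = config.rapa_contrast
    de_tables = []
    contexts = []
    for name, seed in datasets:
        if seed is None:
            de = pd.read_csv(de_paths[contrast], sep="\t", dtype={"protein_id": str})
            de = de.set_index("protein_id")
            contexts.append((name, sim_paths["network"], sim_paths["annotations"]))
        else:
            sub = out / name
            paths = stage_simulate(config, sub / "01_simulate", seed=seed, dataset_id=name)
            prot = stage_preprocess(paths["peptides"], paths["design"], config, sub / "02_preprocess")
            des = stage_de(prot, paths["design"], config, sub / "03_de")
            de = pd.read_csv(des[contrast], sep="\t", dtype={"protein_id": str})
            de = de.set_index("protein_id")
            contexts.append((name, paths["network"], paths["annotations"]))
        de_tables.append(de)
    restricted, n_common = restrict_to_common_genes(de_tables)
    collapsed_tables = []
    for (name, network_path, annotations_path), de in zip(contexts, restricted):
        graph = read_network_edges(network_path, score_threshold=config.score_threshold)
        prop_config = PropagationConfig(
            alpha=config.alpha, iterations=config.iterations,
            normalization=config.normalization, weighting=config.weighting,
        )
        op = build_operator(graph, prop_config)
        scores = propagate(de["log2fc"], op, alpha=config.alpha, iterations=config.iterations)
        measured = set(de.index)
        selection = select_nodes(
            scores, graph, min_degree=config.min_degree, quantile=config.quantile,
            universe=measured,
        )
        background = [
            n for n, d in graph.degree() if d >= config.min_degree and n in measured
        ]
        annotations = read_annotations(annotations_path, format="two_column")
        table = fisher_enrichment(
            selection, background, annotations, min_size=config.min_term_size
        )
        collapsed = signed_scores(table)
        write_table(collapsed, out / f"enrichment_{name}.tsv")
        collapsed_tables.append(collapsed)
    names = [name for name, *_ in contexts]
    concordance = cross_dataset_concordance(collapsed_tables, alpha=config.alpha_p, names=names)
    write_table(concordance, out / "concordance.tsv")
    matrix = concordance.set_index("term_id")[[f"score_{n}" for n in names]]
    write_table(matrix.reset_index(), out / "concordance_matrix.tsv")
    _write_json({"n_common_genes": n_common, "datasets": names}, out / "integration.json")
    return out
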