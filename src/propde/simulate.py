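"""Synthetic factorial TMT-like data with known ground truth.

Emulates the structure of a fat-body aging proteomics study: a 2 age x 2 drug
x 2 induction factorial with four replicates per group, peptide-level offsets
around protein abundances, dissection-batch shifts, intensity-dependent
(MNAR) plus completely-random (MCAR) missingness, a modular interaction graph
(stochastic block model) whose edges all clear the high-confidence score
threshold, and annotation terms aligned with the planted modules.  Planted
differential effects enter at the protein level and are concentrated in
network modules, so every downstream stage (normalization, moderated testing,
propagation, enrichment, concordance) can be verified against the truth.

All randomness flows through one numpy Generator (PCG64) seeded once, drawn
in a fixed order, so a seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .differential import ContrastSpec, default_contrasts
from .io import AnnotationSet, PeptideTable, SampleDesign

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "SimulatedDataset",
    "generate_network",
    "generate_annotations",
    "generate_experiment",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic factorial experiment.

    Defaults mirror the fly design: 2 ages x {vehicle, drug} x {uninduced,
    induced} x 4 replicates, ~2000 proteins of which 10 modules x 20 nodes sit
    in the interaction network, a planted log2 effect of 1 on one module for
    the drug contrast, peptide noise of 0.25 log2 units and mild missingness.
    """

    n_proteins: int = 2000
    peptides_per_protein: float = 3.0  # mean of 1 + Poisson(mean - 1)
    ages: tuple[str, ...] = ("young", "old")
    drugs: tuple[str, ...] = ("EtOH", "Rapa")
    inductions: tuple[str, ...] = ("ctrl", "RU")
    n_replicates: int = 4
    # contrast name -> (targets, delta); targets is "module:<i>" or an id tuple
    effect_map: Mapping[str, tuple] = field(
        default_factory=lambda: {"rapa_vs_etoh_uninduced": ("module:0", 1.0)}
    )
    baseline_mean: float = 18.0  # log2 intensity location
    baseline_sd: float = 1.2
    batch_sd: float = 0.3
    peptide_offset_sd: float = 0.5
    noise_sd: float = 0.25
    mnar_midpoint: float = 15.0  # log2 intensity of 50% dropout
    mnar_slope: float = 1.0  # 0 disables intensity-dependent dropout
    mcar_rate: float = 0.02
    n_modules: int = 10
    module_size: int = 20
    within_module_edge_prob: float = 0.4
    between_module_edge_prob: float = 0.01
    score_floor: int = 900  # edge scores drawn in [score_floor, 999]
    n_terms: int = 30
    term_noise: float = 0.05
    dataset_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_sd", "batch_sd", "peptide_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "mcar_rate", "term_noise", "within_module_edge_prob", "between_module_edge_prob"
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_terms < self.n_modules:
            raise ValueError("n_terms must be >= n_modules")
        if self.n_modules * self.module_size > self.n_proteins:
            raise ValueError("modules cannot cover more proteins than exist")

    def protein_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.n_proteins)]

    def contrasts(self) -> dict[str, ContrastSpec]:
        return default_contrasts(self.ages, self.drugs, self.inductions)


@dataclass
class SynthTruth:
    true_log2fc: pd.DataFrame  # protein x contrast
    modules: dict[str, int]  # node -> module index
    planted_terms: dict[str, dict[str, list[str]]]  # contrast -> direction -> terms


@dataclass
class SimulatedDataset:
    graph: nx.Graph
    modules: dict[str, int]
    annotations: AnnotationSet
    peptides: PeptideTable
    design: SampleDesign
    truth: SynthTruth
    config: SynthConfig


def _resolve_targets(targets, modules: Mapping[str, int]) -> set[str]:
    if isinstance(targets, str) and targets.startswith("module:"):
        idx = int(targets.split(":", 1)[1])
        chosen = {n for n, m in modules.items() if m == idx}
        if not chosen:
            raise ValueError(f"no proteins in module {idx}")
        return chosen
    return set(targets)


def generate_network(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[nx.Graph, dict[str, int]]:
    """Stochastic-block-model interaction graph over the first module proteins.

    Within-module pairs connect with ``within_module_edge_prob``, between-
    module pairs with ``between_module_edge_prob``; every edge gets an integer
    combined score in [score_floor, 999] so all edges survive the read path.
    Nodes left isolated by the draw are removed (the graph contract requires
    degree >= 1).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids = config.protein_ids()
    nodes = ids[: config.n_modules * config.module_size]
    membership = np.repeat(np.arange(config.n_modules), config.module_size)
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    same = membership[iu] == membership[ju]
    probs = np.where(same, config.within_module_edge_prob, config.between_module_edge_prob)
    keep = rng.random(len(iu)) < probs
    scores = rng.integers(config.score_floor, 1000, size=len(iu))
    graph = nx.Graph()
    for a, b, s in zip(iu[keep], ju[keep], scores[keep]):
        graph.add_edge(nodes[a], nodes[b], score=int(s))
    if graph.number_of_edges() == 0:
        raise ValueError("edge probabilities produced an empty graph")
    modules = {nodes[i]: int(membership[i]) for i in range(n) if graph.has_node(nodes[i])}
    return graph, modules


def generate_annotations(
    modules: Mapping[str, int],
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> AnnotationSet:
    """One true term per module plus size-matched decoy terms.

    Each true term starts as its module's membership; every member is swapped
    for a uniformly chosen non-member node with probability ``term_noise``.
    Decoys are sampled uniformly from the graph nodes at the same size.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    universe = sorted(modules)
    terms: dict[str, set] = {}
    meta: dict[str, dict] = {}
    for m in range(config.n_modules):
        members = sorted(n for n, mm in modules.items() if mm == m)
        outside = [n for n in universe if modules[n] != m]
        kept: set[str] = set()
        for gene in members:
            if config.term_noise > 0 and rng.random() < config.term_noise and outside:
                kept.add(outside[int(rng.integers(len(outside)))])
            else:
                kept.add(gene)
        tid = f"T_mod{m:02d}"
        terms[tid] = kept
        meta[tid] = {"name": f"module {m} signature", "kind": "true", "module": m}
    for j in range(config.n_terms - config.n_modules):
        size = config.module_size
        picks = rng.choice(len(universe), size=min(size, len(universe)), replace=False)
        tid = f"T_dec{j:02d}"
        terms[tid] = {universe[i] for i in picks}
        meta[tid] = {"name": f"decoy {j}", "kind": "decoy"}
    return AnnotationSet(terms=terms, meta=meta)


def generate_experiment(
    config: SynthConfig,
    graph: nx.Graph,
    modules: Mapping[str, int],
    rng: np.random.Generator | None = None,
) -> tuple[PeptideTable, SampleDesign, SynthTruth]:
    """Raw-scale peptide intensities, design table and full ground truth.

    Protein log2 abundance = baseline + planted contrast effects + batch
    shift; each peptide adds a fixed offset and N(0, noise_sd) noise.  A
    planted (contrast, delta) shifts the samples in the contrast's
    positive-coefficient cells by delta, so the true contrast value equals
    delta times the positive coefficient mass (exactly delta for standard
    difference contrasts).  Missingness is MCAR at ``mcar_rate`` plus logistic
    intensity-dependent dropout (disabled when mnar_slope = 0).  Returned
    intensities are 2^value with missing cells as NaN.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    contrasts = config.contrasts()
    ids = config.protein_ids()
    id_pos = {p: i for i, p in enumerate(ids)}

    rows = []
    sample_idx = 0
    for age in config.ages:
        for drug in config.drugs:
            for ind in config.inductions:
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"S{sample_idx:02d}",
                            "age": age,
                            "drug": drug,
                            "induction": ind,
                            "replicate": rep,
                            # two dissection sittings, orthogonal to conditions
                            "batch": "b1" if rep <= config.n_replicates / 2 else "b2",
                            "dataset_id": config.dataset_id,
                        }
                    )
                    sample_idx += 1
    design = SampleDesign(pd.DataFrame(rows))
    cells = design.cells()
    n_samples = len(design.table)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_proteins)
    abundance = np.tile(baseline[:, None], (1, n_samples))

    truth_fc = pd.DataFrame(
        0.0, index=pd.Index(ids, name="protein_id"), columns=sorted(contrasts)
    )
    planted_terms: dict[str, dict[str, list[str]]] = {}
    for cname, (targets, delta) in config.effect_map.items():
        if cname not in contrasts:
            raise ValueError(f"effect_map contrast {cname!r} not expressible in the design")
        spec = contrasts[cname]
        target_set = _resolve_targets(targets, modules)
        pos_cells = {c for c, w in spec.weights.items() if w > 0}
        pos_mass = sum(w for w in spec.weights.values() if w > 0)
        shifted_cols = np.array([c in pos_cells for c in cells], dtype=bool)
        target_rows = np.array([p in target_set for p in ids], dtype=bool)
        abundance[np.ix_(target_rows, shifted_cols)] += delta
        # induced true value on every contrast sharing shifted cells
        for other_name, other in contrasts.items():
            overlap = sum(w for c, w in other.weights.items() if c in pos_cells)
            if overlap != 0:
                truth_fc.loc[list(target_set), other_name] += delta * overlap
        direction = "up" if delta * pos_mass > 0 else "down"
        if isinstance(targets, str) and targets.startswith("module:"):
            tid = f"T_mod{int(targets.split(':', 1)[1]):02d}"
            planted_terms.setdefault(cname, {"up": [], "down": []})[direction].append(tid)

    batch_levels = sorted(set(design.table["batch"]))
    batch_shift = rng.normal(0.0, config.batch_sd, size=(config.n_proteins, len(batch_levels)))
    batch_col = np.array([batch_levels.index(b) for b in design.table["batch"]])
    abundance = abundance + batch_shift[:, batch_col]

    mean_extra = max(config.peptides_per_protein - 1.0, 0.0)
    pep_counts = 1 + rng.poisson(mean_extra, size=config.n_proteins)
    pep_rows = []
    pep_ids = []
    pep_proteins = []
    for i, pid in enumerate(ids):
        offsets = rng.normal(0.0, config.peptide_offset_sd, size=pep_counts[i])
        noise = rng.normal(0.0, config.noise_sd, size=(pep_counts[i], n_samples))
        vals = abundance[i][None, :] + offsets[:, None] + noise
        pep_rows.append(vals)
        pep_ids.extend(f"{pid}_pep{j}" for j in range(pep_counts[i]))
        pep_proteins.extend([pid] * pep_counts[i])
    log2 = np.vstack(pep_rows)

    missing = rng.random(log2.shape) < config.mcar_rate
    if config.mnar_slope > 0:
        p_mnar = 1.0 / (1.0 + np.exp(config.mnar_slope * (log2 - config.mnar_midpoint)))
        missing |= rng.random(log2.shape) < p_mnar
    raw = np.exp2(log2)
    raw[missing] = np.nan

    values = pd.DataFrame(
        raw, index=pd.Index(pep_ids, name="peptide_id"), columns=design.table.index
    )
    peptides = PeptideTable(
        values=values,
        proteins=pd.Series(pep_proteins, index=values.index, name="protein_id"),
        scale="raw",
    )
    truth = SynthTruth(true_log2fc=truth_fc, modules=dict(modules), planted_terms=planted_terms)
    return peptides, design, truth


def simulate_dataset(config: SynthConfig) -> SimulatedDataset:
    """Generate network, annotations and experiment from one seeded RNG."""
    rng = np.random.default_rng(config.seed)
    graph, modules = generate_network(config, rng)
    annotations = generate_annotations(modules, config, rng)
    peptides, design, truth = generate_experiment(config, graph, modules, rng)
    return SimulatedDataset(
        graph=graph, modules=modules, annotations=annotations,
        peptides=peptides, design=design, truth=truth, config=config,
    )
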