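"""Diffusion of per-protein scores over a protein-protein interaction graph.

Log2 fold changes are imported onto the nodes of a high-confidence interaction
network (unmeasured nodes start at zero) and smoothed by the iteration

    x_{t+1} = alpha * W * x_t + (1 - alpha) * x_0

for a fixed number of iterations, where W is the degree-normalized adjacency
(symmetric D^-1/2 A D^-1/2 by default, or row-stochastic D^-1 A).  For
alpha in [0, 1) the iteration converges geometrically to the closed form
(1 - alpha)(I - alpha W)^-1 x_0, which is also provided as a direct solve.
Top and bottom quantiles of the smoothed scores, restricted to nodes with
degree above a threshold, form the up/down selections for enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "PropagationConfig",
    "PropagationOperator",
    "PropagationScores",
    "NodeSelection",
    "build_operator",
    "propagate",
    "propagate_closed_form",
    "select_nodes",
]


@dataclass(frozen=True)
class PropagationConfig:
    alpha: float = 0.5
    iterations: int = 26
    normalization: str = "symmetric"  # or "row"
    weighting: str = "binary"  # or "score"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.iterations < 1:
            raise ValueError("iterations must be a positive integer")
        if self.normalization not in ("symmetric", "row"):
            raise ValueError(f"normalization must be 'symmetric' or 'row', got {self.normalization!r}")
        if self.weighting not in ("binary", "score"):
            raise ValueError(f"weighting must be 'binary' or 'score', got {self.weighting!r}")


@dataclass
class PropagationOperator:
    """Normalized adjacency with its fixed node order."""

    w: sparse.csr_matrix
    nodes: pd.Index
    config: PropagationConfig


@dataclass
class PropagationScores:
    scores: pd.Series  # node -> smoothed score
    config: PropagationConfig
    coverage: float  # fraction of graph nodes with measured input
    iterations: int | None = None  # None for the closed form


@dataclass
class NodeSelection:
    up: list
    down: list
    min_degree: int
    quantile: float

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down selections overlap")


def build_operator(graph: nx.Graph, config: PropagationConfig | None = None) -> PropagationOperator:
    """Degree-normalized adjacency operator with a recorded node order.

    Binary weighting uses A_ij in {0, 1}; score weighting uses the STRING
    combined score / 1000.  Symmetric normalization W = D^-1/2 A D^-1/2 has
    spectrum in [-1, 1]; row normalization W = D^-1 A is stochastic.
    """
    if config is None:
        config = PropagationConfig()
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if any(d == 0 for _, d in graph.degree()):
        isolated = sorted(n for n, d in graph.degree() if d == 0)
        raise ValueError(f"graph contains isolated node(s): {isolated[:5]}")
    nodes = pd.Index(sorted(graph.nodes()))
    pos = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for a, b, attrs in graph.edges(data=True):
        wgt = 1.0 if config.weighting == "binary" else attrs.get("score", 1000) / 1000.0
        rows += [pos[a], pos[b]]
        cols += [pos[b], pos[a]]
        vals += [wgt, wgt]
    a = sparse.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    deg = np.asarray(a.sum(axis=1)).ravel()
    if config.normalization == "symmetric":
        d_inv_sqrt = sparse.diags(1.0 / np.sqrt(deg))
        w = d_inv_sqrt @ a @ d_inv_sqrt
    else:
        w = sparse.diags(1.0 / deg) @ a
    return PropagationOperator(w=w.tocsr(), nodes=nodes, config=config)


def _vectorize_x0(x0, op: PropagationOperator) -> tuple[np.ndarray, float]:
    if isinstance(x0, pd.Series):
        series = x0.dropna()
    else:
        series = pd.Series(dict(x0), dtype=float)
    measured = series.index.intersection(op.nodes)
    vec = np.zeros(len(op.nodes))
    if len(measured):
        vec[op.nodes.get_indexer(measured)] = series.loc[measured].to_numpy(dtype=float)
    coverage = len(measured) / len(op.nodes)
    return vec, coverage


def propagate(
    x0,
    op: PropagationOperator,
    alpha: float = 0.5,
    iterations: int = 26,
) -> PropagationScores:
    """Iterate x_{t+1} = alpha W x_t + (1-alpha) x_0 exactly ``iterations`` times.

    ``x0`` maps measured nodes to their input score (e.g. log2 fold change);
    unmeasured graph nodes start at zero.  With alpha = 0 the output equals
    the input for any iteration count.
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    vec, coverage = _vectorize_x0(x0, op)
    x = vec.copy()
    for _ in range(iterations):
        x = alpha * (op.w @ x) + (1.0 - alpha) * vec
    cfg = PropagationConfig(
        alpha=alpha, iterations=iterations,
        normalization=op.config.normalization, weighting=op.config.weighting,
    )
    return PropagationScores(
        scores=pd.Series(x, index=op.nodes, name="score"),
        config=cfg, coverage=coverage, iterations=iterations,
    )


def propagate_closed_form(x0, op: PropagationOperator, alpha: float = 0.5) -> PropagationScores:
    """Fixed point of the propagation: solve (I - alpha W) x = (1-alpha) x_0."""
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    vec, coverage = _vectorize_x0(x0, op)
    n = len(op.nodes)
    system = sparse.identity(n, format="csr") - alpha * op.w
    x = spsolve(system.tocsc(), (1.0 - alpha) * vec)
    if not np.all(np.isfinite(x)):
        raise ValueError("closed-form propagation produced non-finite scores")
    cfg = PropagationConfig(
        alpha=alpha, iterations=1,
        normalization=op.config.normalization, weighting=op.config.weighting,
    )
    return PropagationScores(
        scores=pd.Series(x, index=op.nodes, name="score"),
        config=cfg, coverage=coverage, iterations=None,
    )


def select_nodes(
    scores: PropagationScores | pd.Series,
    graph: nx.Graph,
    min_degree: int = 5,
    quantile: float = 0.05,
    universe=None,
) -> NodeSelection:
    """Top and bottom score quantiles among nodes of degree >= min_degree.

    The degree filter is applied first (min_degree = 5 keeps nodes with more
    than four interactions); then ceil(quantile * m) highest-scoring nodes
    form the up set and the same count of lowest-scoring nodes the down set.
    ``universe`` optionally restricts eligibility further (e.g. to nodes with
    measured input, the enrichment background).  Ties are broken toward the
    lexicographically smaller node id so repeated runs select identical sets.
    """
    series = scores.scores if isinstance(scores, PropagationScores) else scores
    missing = [n for n in graph.nodes() if n not in series.index]
    if missing:
        raise ValueError(f"scores do not cover graph node(s): {sorted(missing)[:5]}")
    eligible = sorted(n for n, d in graph.degree() if d >= min_degree)
    if universe is not None:
        allowed = set(universe)
        eligible = [n for n in eligible if n in allowed]
    m = len(eligible)
    if m == 0:
        raise ValueError(f"no nodes with degree >= {min_degree}")
    count = math.ceil(quantile * m)
    if 2 * count > m:
        raise ValueError(
            f"quantile {quantile} selects {count} up + {count} down nodes from only {m}"
        )
    vals = series.loc[eligible]
    up = sorted(eligible, key=lambda n: (-vals[n], n))[:count]
    # the up set is removed first so a fully tied score vector cannot place
    # the same node in both selections
    remaining = [n for n in eligible if n not in set(up)]
    down = sorted(remaining, key=lambda n: (vals[n], n))[:count]
    return NodeSelection(up=up, down=down, min_degree=min_degree, quantile=quantile)
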