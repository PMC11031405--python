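"""Fisher-exact term over-representation with signed significance scores.

Each annotation term with at least ``min_size`` genes in the background
universe is tested for over-representation in the up and down node selections
by the one-sided hypergeometric tail P(X >= k).  A term's signed significance
score is -log10(p) with a positive sign for up-regulated and a negative sign
for down-regulated annotations; when a term is tested in both directions the
direction with the smaller p is reported.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationSet
from .netprop import NodeSelection

logger = logging.getLogger(__name__)

__all__ = ["close_annotations", "fisher_enrichment", "signed_scores"]


def close_annotations(annotations: AnnotationSet) -> AnnotationSet:
    """Propagate gene memberships up the is_a parent map (ancestor closure).

    Every gene annotated to a term becomes annotated to all of the term's
    ancestors; with no parent map this is the identity.  A diamond-shaped DAG
    counts each ancestor once (set semantics).  Cycles are an error.
    """
    if not annotations.parents:
        return AnnotationSet(
            terms={t: set(g) for t, g in annotations.terms.items()},
            meta=dict(annotations.meta),
            parents=annotations.parents,
        )
    parents = annotations.parents
    ancestors: dict[str, set] = {}

    def walk(term: str, stack: tuple) -> set:
        if term in stack:
            cycle = stack[stack.index(term):] + (term,)
            raise ValueError(f"cycle in parent map involving {' -> '.join(cycle)}")
        if term in ancestors:
            return ancestors[term]
        acc: set = set()
        for parent in parents.get(term, ()):  # noqa: B905
            acc.add(parent)
            acc |= walk(parent, stack + (term,))
        ancestors[term] = acc
        return acc

    closed: dict[str, set] = {t: set(g) for t, g in annotations.terms.items()}
    for term, genes in annotations.terms.items():
        for anc in walk(term, ()):  # ancestors inherit the term's genes
            closed.setdefault(anc, set()).update(genes)
    return AnnotationSet(terms=closed, meta=dict(annotations.meta), parents=parents)


def fisher_enrichment(
    selection: NodeSelection,
    background: Iterable,
    annotations: AnnotationSet,
    min_size: int = 5,
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation per term and direction.

    For a term with K genes in the background of size N and a selection of
    size n overlapping it in k genes, p = P(X >= k) with
    X ~ Hypergeometric(N, K, n).  Terms with K < min_size are skipped with a
    logged count.  Both selections must be subsets of the background.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    restricted = annotations.restrict(bg)
    n_small = sum(1 for g in restricted.values() if len(g) < min_size)
    if n_small:
        logger.info("skipping %d term(s) below min_size=%d in background", n_small, min_size)
    rows = []
    big_n = len(bg)
    for direction, sel in (("up", selection.up), ("down", selection.down)):
        sel_set = set(sel)
        if not sel_set <= bg:
            raise ValueError(f"{direction} selection is not a subset of the background")
        n = len(sel_set)
        for term in sorted(restricted):
            genes = restricted[term]
            big_k = len(genes)
            if big_k < min_size:
                continue
            k = len(genes & sel_set)
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
            rows.append((term, direction, k, big_k, n, big_n, min(p, 1.0)))
    return pd.DataFrame(rows, columns=["term_id", "direction", "k", "K", "n", "N", "p"])


def signed_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse an enrichment table to one signed score per term.

    signed_score = -log10(p) for up terms and +log10(p) (i.e. the negated
    magnitude) for down terms.  A term tested in both directions keeps the
    direction with the smaller p; exact ties resolve to 'up' (both scores are
    then equal in magnitude).  p = 0 is capped at the smallest positive float
    with a warning.
    """
    if (table["p"] <= 0).any():
        warnings.warn("p = 0 encountered; capping at machine minimum", stacklevel=2)
    df = table.copy()
    df["p"] = df["p"].clip(lower=np.finfo(float).tiny, upper=1.0)
    # stable preference: smaller p first, 'up' before 'down' on exact ties
    df["_dir_rank"] = (df["direction"] == "down").astype(int)
    df = df.sort_values(["term_id", "p", "_dir_rank"], kind="mergesort")
    best = df.drop_duplicates("term_id", keep="first").drop(columns="_dir_rank")
    sign = np.where(best["direction"] == "up", 1.0, -1.0)
    best = best.assign(signed_score=sign * (-np.log10(best["p"])))
    # p = 1 carries no evidence in either direction
    best.loc[best["p"] >= 1.0, "signed_score"] = 0.0
    return best.reset_index(drop=True)
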