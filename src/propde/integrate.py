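"""Annotation-level classification rules and cross-dataset concordance.

The rules operate on collapsed enrichment tables (one row per term with a
direction and a p-value, as produced by :func:`propde.enrichment.signed_scores`)
and are pure functions of p-values and directions:

* age-related terms: significant (p < alpha) in the old-vs-young contrast of
  the untreated control group;
* drug-induced, activation-dependent terms: the drug-vs-vehicle annotation is
  at least 100x more significant than the same annotation under constitutive
  kinase activation (-log10 p difference > 2);
* drug-induced, activation-independent terms: drug-vs-vehicle -log10 p > 2
  without that difference;
* knockdown-induced terms: -log10 p above a threshold in the
  RNAi-induction contrast (same > 2 convention by default);
* three-dataset concordance: a term is shared iff p < alpha with the same
  direction in all three datasets.

Terms absent from a table are treated as p = 1 there (absence = no evidence).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "classify_age_terms",
    "classify_rapa_terms",
    "classify_s6k_inhibition_terms",
    "cross_dataset_concordance",
    "restrict_to_common_genes",
]

AGE_RELATED = "age_related"
S6KCA_DEPENDENT = "s6kca_dependent_rapa"
S6KCA_INDEPENDENT = "s6kca_independent_rapa"
S6K_INHIBITION = "s6k_inhibition_induced"


def _term_map(table: pd.DataFrame) -> pd.DataFrame:
    df = table.set_index("term_id")
    if df.index.duplicated().any():
        raise ValueError("enrichment table has duplicate term ids; collapse directions first")
    return df


def _neglog10(p: pd.Series) -> pd.Series:
    return -np.log10(p.astype(float).clip(lower=np.finfo(float).tiny, upper=1.0))


def classify_age_terms(enrichment: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label terms with p < alpha in the old-vs-young control contrast."""
    df = _term_map(enrichment)
    hits = df[df["p"] < alpha]
    out = pd.DataFrame(
        {
            "term_id": hits.index,
            "term_class": AGE_RELATED,
            "direction": hits["direction"].to_numpy(),
        }
    )
    return out.sort_values("term_id", kind="mergesort").reset_index(drop=True)


def classify_rapa_terms(
    enr_rapa_vs_control: pd.DataFrame,
    enr_rapa_under_activation: pd.DataFrame,
    margin: float = 2.0,
) -> pd.DataFrame:
    """Split drug-induced terms into activation-dependent and -independent.

    With la = -log10 p(drug vs vehicle) and lb = -log10 p(drug under
    constitutive activation): dependent iff la - lb > margin; independent iff
    la > margin and la - lb <= margin.  Directions come from the
    drug-vs-vehicle table; terms absent from a table contribute p = 1.
    """
    a = _term_map(enr_rapa_vs_control)
    b = _term_map(enr_rapa_under_activation)
    terms = a.index.union(b.index).sort_values()
    la = _neglog10(a["p"].reindex(terms, fill_value=1.0))
    lb = _neglog10(b["p"].reindex(terms, fill_value=1.0))
    diff = la - lb
    dependent = diff > margin
    independent = (la > margin) & ~dependent
    direction = a["direction"].reindex(terms)
    rows = []
    for term in terms:
        if dependent[term]:
            cls = S6KCA_DEPENDENT
        elif independent[term]:
            cls = S6KCA_INDEPENDENT
        else:
            continue
        rows.append((term, cls, direction[term] if pd.notna(direction[term]) else ""))
    return pd.DataFrame(rows, columns=["term_id", "term_class", "direction"])


def classify_s6k_inhibition_terms(
    enr_rnai_induction: pd.DataFrame, threshold: float = 2.0
) -> pd.DataFrame:
    """Label terms with -log10 p > threshold in the RNAi-induction contrast."""
    df = _term_map(enr_rnai_induction)
    score = _neglog10(df["p"])
    hits = df[score > threshold]
    out = pd.DataFrame(
        {
            "term_id": hits.index,
            "term_class": S6K_INHIBITION,
            "direction": hits["direction"].to_numpy(),
        }
    )
    return out.sort_values("term_id", kind="mergesort").reset_index(drop=True)


def cross_dataset_concordance(
    tables: Sequence[pd.DataFrame],
    alpha: float = 0.05,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Terms significant (p < alpha) with the same direction in all datasets.

    Requires exactly three enrichment tables; the output carries each
    dataset's signed score and the shared direction.
    """
    if len(tables) != 3:
        raise ValueError(f"concordance requires exactly 3 enrichment tables, got {len(tables)}")
    if names is None:
        names = [f"dataset{i + 1}" for i in range(3)]
    maps = [_term_map(t) for t in tables]
    common = maps[0].index
    for m in maps[1:]:
        common = common.intersection(m.index)
    rows = []
    for term in sorted(common):
        ps = [m.loc[term, "p"] for m in maps]
        dirs = [m.loc[term, "direction"] for m in maps]
        if any(p >= alpha for p in ps):
            continue
        if len(set(dirs)) != 1:
            continue
        scores = [m.loc[term, "signed_score"] for m in maps]
        rows.append((term, dirs[0], *scores))
    return pd.DataFrame(
        rows, columns=["term_id", "direction", *[f"score_{n}" for n in names]]
    )


def restrict_to_common_genes(
    de_tables: Sequence[pd.DataFrame],
) -> tuple[list[pd.DataFrame], int]:
    """Restrict differential-expression tables to their shared gene ids.

    All downstream propagation and enrichment for the integration must use
    only genes detected in every dataset.
    """
    if len(de_tables) < 2:
        raise ValueError("need at least two tables to intersect")
    common = set(de_tables[0].index)
    for t in de_tables[1:]:
        common &= set(t.index)
    if not common:
        raise ValueError("no genes shared across all tables")
    order = sorted(common)
    restricted = []
    for t in de_tables:
        r = t.loc[order]
        r.attrs = dict(t.attrs)
        restricted.append(r)
    return restricted, len(common)
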