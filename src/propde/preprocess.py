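"""Peptide normalization, detection filtering, imputation and QC.

The normalization follows the TMT convention of log2- and z-transforming each
peptide row, then rescaling every z-score by the global standard deviation of
the log2 data and re-adding the global mean, so all peptides share the global
location and spread while keeping interpretable log2 units.  Detection
filtering requires a protein to be seen in at least ``min_detected`` replicates
of *every* condition cell.  Missing values are then filled by k-nearest-
neighbour imputation in protein space.  Batch means are removed only for
visualization (PCA); differential models carry batch as a covariate instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import PeptideTable, ProteinTable, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationRecord",
    "log2_z_rescale",
    "aggregate_peptides",
    "filter_by_detection",
    "impute_missing",
    "remove_batch_means",
    "pca_scores",
]


@dataclass
class NormalizationRecord:
    global_mean: float
    global_sd: float
    dropped_constant_rows: int

    def __post_init__(self) -> None:
        if not self.global_sd > 0:
            raise ValueError("global SD must be positive")


def log2_z_rescale(table: PeptideTable) -> tuple[PeptideTable, NormalizationRecord]:
    """log2-transform, z-score each peptide row, rescale to global moments.

    For present values x_ij of row i (log2 scale), z_ij = (x_ij - mean_i)/sd_i
    and the output is y_ij = z_ij * SD_global + M_global where M_global and
    SD_global are the mean and (ddof=1) standard deviation of all present log2
    values.  Missing entries stay missing.  Rows with fewer than two present
    values or zero variance are dropped and counted.
    """
    x = table.values.to_numpy(dtype=float, copy=True)
    if table.scale == "raw":
        present = ~np.isnan(x)
        if (x[present] <= 0).any():
            raise ValueError("raw intensities must be positive for log2 transform")
        x[present] = np.log2(x[present])
    present = ~np.isnan(x)
    n_present = present.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(x, axis=1)
        row_sd = np.nanstd(x, axis=1, ddof=1)
    keep = (n_present >= 2) & (row_sd > 0)
    dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all peptide rows are constant or too sparse to normalize")
    # global moments over the rows that take part in the normalization:
    # dropped (constant/sparse) rows contribute nothing to the rescaling target
    vals = x[keep][present[keep]]
    m_global = float(np.mean(vals))
    sd_global = float(np.std(vals, ddof=1))
    if sd_global == 0:
        raise ValueError("all present values identical; global SD is zero")
    z = (x[keep] - row_mean[keep, None]) / row_sd[keep, None]
    y = z * sd_global + m_global
    out = pd.DataFrame(y, index=table.values.index[keep], columns=table.values.columns)
    record = NormalizationRecord(m_global, sd_global, dropped)
    logger.info(
        "normalized %d peptide rows (dropped %d); global mean %.4f, SD %.4f",
        int(keep.sum()), dropped, m_global, sd_global,
    )
    return PeptideTable(values=out, proteins=table.proteins[keep], scale="log2"), record


def aggregate_peptides(table: PeptideTable, method: str = "median") -> ProteinTable:
    """Roll normalized peptides up to proteins (median by default).

    A protein-sample cell is missing iff all of its peptides are missing there.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"method must be 'median' or 'mean', got {method!r}")
    grouped = table.values.groupby(table.proteins, sort=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        agg = grouped.median() if method == "median" else grouped.mean()
    agg.index.name = "protein_id"
    return ProteinTable(values=agg)


def filter_by_detection(
    table: ProteinTable,
    design: SampleDesign,
    min_detected: int = 3,
    group_by: tuple[str, ...] = ("age", "drug", "induction"),
) -> ProteinTable:
    """Keep proteins detected in >= min_detected samples of *every* group.

    Groups default to the condition cells (age x drug x induction), mirroring
    a 3-of-4-replicates rule per treatment.
    """
    cols = [c for c in table.values.columns]
    dtab = design.table.loc[cols]
    groups = list(zip(*(dtab[f] for f in group_by)))
    group_series = pd.Series(groups, index=cols)
    present = ~table.values.isna()
    keep = pd.Series(True, index=table.values.index)
    for group, samples in group_series.groupby(group_series).groups.items():
        if len(samples) < min_detected:
            raise ValueError(
                f"group {group} has only {len(samples)} sample(s), fewer than "
                f"min_detected={min_detected}"
            )
        keep &= present[list(samples)].sum(axis=1) >= min_detected
    out = table.values.loc[keep]
    logger.info(
        "detection filter (>=%d per group over %d groups): kept %d / %d proteins",
        min_detected, group_series.nunique(), int(keep.sum()), len(keep),
    )
    return ProteinTable(values=out)


def impute_missing(table: ProteinTable, k: int = 10, max_missing_frac: float = 0.5) -> ProteinTable:
    """k-nearest-neighbour imputation in protein space.

    For a protein with a missing sample value, the k proteins nearest in
    RMS Euclidean distance over mutually present samples (and observed in the
    target sample) are averaged.  Rows missing more than ``max_missing_frac``
    of their samples fall back to their row mean.  Observed entries are
    preserved bit-exactly; no missing values remain.
    """
    x = table.values.to_numpy(dtype=float, copy=True)
    mask = np.isnan(x)
    if not mask.any():
        return ProteinTable(values=table.values.copy())
    if (mask.all(axis=1)).any():
        bad = table.values.index[mask.all(axis=1)]
        raise ValueError(f"protein(s) with zero present values: {sorted(bad)[:5]}")
    n_prot, n_samp = x.shape
    ids = table.values.index.to_numpy()
    order_rank = np.argsort(np.argsort(ids, kind="mergesort"), kind="mergesort")
    row_means = np.nanmean(x, axis=1)
    out = x.copy()
    too_sparse = mask.sum(axis=1) > max_missing_frac * n_samp
    for i in np.flatnonzero(mask.any(axis=1)):
        missing_cols = np.flatnonzero(mask[i])
        if too_sparse[i]:
            out[i, missing_cols] = row_means[i]
            continue
        diff = x - x[i]
        sq = diff * diff
        shared = ~np.isnan(sq)
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            dist = np.sqrt(np.where(n_shared > 0, np.nansum(sq, axis=1) / np.maximum(n_shared, 1), np.inf))
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for j in missing_cols:
            cand = np.flatnonzero(~mask[:, j] & np.isfinite(dist))
            if cand.size == 0:
                out[i, j] = row_means[i]
                continue
            # deterministic: ties in distance broken by lexicographic protein id
            order = cand[np.lexsort((order_rank[cand], dist[cand]))]
            chosen = order[: min(k, order.size)]
            out[i, j] = float(np.mean(x[chosen, j]))
    return ProteinTable(values=pd.DataFrame(out, index=table.values.index, columns=table.values.columns))


def remove_batch_means(table: ProteinTable, design: SampleDesign) -> ProteinTable:
    """Center each protein's batch means on its grand mean (visualization only).

    Per protein, subtract the batch mean and add back the grand mean over all
    samples; the grand mean of every protein is left unchanged.  Differential
    models should instead include batch as a covariate.
    """
    cols = list(table.values.columns)
    batches = design.table.loc[cols, "batch"]
    if batches.nunique() == 1:
        warnings.warn("single batch: remove_batch_means is the identity", stacklevel=2)
        return ProteinTable(values=table.values.copy())
    x = table.values
    grand = x.mean(axis=1)
    out = x.copy()
    for batch, samples in batches.groupby(batches).groups.items():
        samples = list(samples)
        batch_mean = x[samples].mean(axis=1)
        out[samples] = x[samples].sub(batch_mean, axis=0).add(grand, axis=0)
    return ProteinTable(values=out)


def pca_scores(table: ProteinTable, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples in protein space (QC for factor separation).

    Returns the sample x component score matrix and the variance-explained
    fractions (non-increasing, summing to <= 1).
    """
    if table.values.isna().any().any():
        raise ValueError("pca_scores requires a complete (imputed) table")
    x = table.values.to_numpy(dtype=float).T  # samples x proteins
    max_comp = min(x.shape)
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds min(samples, proteins)={max_comp}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    frame = pd.DataFrame(
        scores,
        index=table.values.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, pca.explained_variance_ratio_
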