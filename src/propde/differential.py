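"""Per-protein factorial linear models with empirical-Bayes moderated t-tests.

Each protein is fit by ordinary least squares on a cell-means design (one
coefficient per age x drug x induction cell) plus batch covariates.  Residual
variances are shrunk toward a scaled inverse-chi-square prior whose
hyperparameters (prior df ``d0``, prior variance ``s0_sq``) are estimated by
moment matching on log s^2 via digamma/trigamma identities, the classical
variance-moderation scheme for small-replicate proteomics.  Named contrasts
are linear combinations of cell means with coefficients summing to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .io import GeneSet, ProteinTable, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSpec",
    "ModerationParams",
    "LinearFit",
    "default_contrasts",
    "fit_models",
    "estimate_moderation",
    "trigamma_inverse",
    "moderated_test",
    "classify_s6k_dependent",
    "gene_set_shift_test",
    "extract_geneset_fc_matrix",
]

S6K_DEPENDENT_LABEL = "TORC1-S6K-dependent"


@dataclass(frozen=True)
class ContrastSpec:
    """Named contrast: cell -> coefficient, coefficients summing to zero."""

    name: str
    weights: Mapping[tuple, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total) > 1e-9:
            raise ValueError(f"contrast {self.name!r} coefficients sum to {total}, not 0")


@dataclass(frozen=True)
class ModerationParams:
    d0: float  # prior degrees of freedom, may be math.inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        # d0 = 0 is allowed as the unmoderated limit (ordinary t-test)
        if self.d0 < 0:
            raise ValueError("prior df d0 must be nonnegative")
        if not self.s0_sq > 0:
            raise ValueError("prior variance s0_sq must be positive")


@dataclass
class LinearFit:
    """OLS results for all proteins on a shared design matrix."""

    coef: pd.DataFrame  # proteins x design columns
    s2: pd.Series  # residual variance per protein
    df_residual: int
    xtx_inv: np.ndarray
    columns: list  # design column labels; cells are tuples, covariates strings
    cells: list  # the cell labels in column order
    zero_residual: pd.Series = field(default=None)  # flag: s2 == 0


def default_contrasts(
    ages: Sequence[str] = ("young", "old"),
    drugs: Sequence[str] = ("EtOH", "Rapa"),
    inductions: Sequence[str] = ("ctrl", "RU"),
) -> dict[str, ContrastSpec]:
    """Within-stratum contrasts for the 2x2x2 factorial fly design.

    ``rapa_vs_etoh_uninduced``/``_induced`` are the drug effect within the
    uninduced and induced strata (averaged over age), ``old_vs_young_control``
    the age effect in untreated uninduced flies, and ``ru_vs_etoh_uninduced``
    the induction effect under vehicle.  "A_vs_B" means mean(A) - mean(B).
    """
    etoh, rapa = drugs
    ctrl, ru = inductions
    young, old = ages

    def drug_within(ind: str) -> dict[tuple, float]:
        w: dict[tuple, float] = {}
        for age in ages:
            w[(age, rapa, ind)] = 0.5
            w[(age, etoh, ind)] = -0.5
        return w

    def induction_within(drug: str) -> dict[tuple, float]:
        w: dict[tuple, float] = {}
        for age in ages:
            w[(age, drug, ru)] = 0.5
            w[(age, drug, ctrl)] = -0.5
        return w

    specs = {
        "rapa_vs_etoh_uninduced": ContrastSpec("rapa_vs_etoh_uninduced", drug_within(ctrl)),
        "rapa_vs_etoh_induced": ContrastSpec("rapa_vs_etoh_induced", drug_within(ru)),
        "old_vs_young_control": ContrastSpec(
            "old_vs_young_control", {(old, etoh, ctrl): 1.0, (young, etoh, ctrl): -1.0}
        ),
        "ru_vs_etoh_uninduced": ContrastSpec("ru_vs_etoh_uninduced", induction_within(etoh)),
    }
    return specs


def _design_matrix(
    design: SampleDesign, samples: Sequence[str], covariates: Sequence[str]
) -> tuple[np.ndarray, list, list]:
    cells = design.cells().loc[list(samples)]
    cell_levels = sorted(set(cells))
    columns: list = list(cell_levels)
    blocks = [np.column_stack([(cells == c).astype(float) for c in cell_levels])]
    for cov in covariates:
        levels = sorted(set(design.table.loc[list(samples), cov]))
        for lev in levels[1:]:  # first level absorbed by the cell means
            blocks.append(
                (design.table.loc[list(samples), cov] == lev).astype(float).to_numpy()[:, None]
            )
            columns.append(f"{cov}:{lev}")
    x = np.hstack(blocks)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]} columns); "
            f"aliased terms among {columns}"
        )
    return x, columns, cell_levels


def fit_models(
    table: ProteinTable,
    design: SampleDesign,
    covariates: Sequence[str] = ("batch",),
) -> LinearFit:
    """Ordinary least squares per protein on cell means + covariates.

    Returns coefficients, residual variances s^2 = RSS/d and the shared
    residual df d = n - rank(X).  Requires a complete (imputed) table.
    """
    if table.values.isna().any().any():
        raise ValueError("fit_models requires a complete table; impute first")
    samples = list(table.values.columns)
    x, columns, cells = _design_matrix(design, samples, covariates)
    y = table.values.to_numpy(dtype=float)  # proteins x samples
    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T  # proteins x p
    resid = y - beta @ x.T
    n, p = x.shape
    d = n - p
    if d <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / d
    zero = s2 <= 0
    if zero.any():
        logger.warning("%d protein(s) with zero residual variance", int(zero.sum()))
    xtx_inv = np.linalg.inv(x.T @ x)
    return LinearFit(
        coef=pd.DataFrame(beta, index=table.values.index, columns=pd.Index(columns, tupleize_cols=False)),
        s2=pd.Series(s2, index=table.values.index, name="s2"),
        df_residual=int(d),
        xtx_inv=xtx_inv,
        columns=columns,
        cells=cells,
        zero_residual=pd.Series(zero, index=table.values.index),
    )


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is positive, strictly decreasing and convex on (0, inf), so the
    iteration is monotone from the asymptotic starting value x ~ 0.5 + 1/y.
    """
    if y <= 0:
        return math.inf
    if y > 1e12:  # trigamma(x) ~ 1/x^2 as x -> 0
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(polygamma(1, x))
        step = (tri - y) / float(polygamma(2, x))
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * max(1.0, x):
            return x_new
        x = x_new
    return x


def estimate_moderation(s2: Iterable[float], d: int, min_proteins: int = 30) -> ModerationParams:
    """Fit the scaled inverse-chi-square prior by log-variance moment matching.

    With s^2 ~ s0^2 * (chi2_d / d) / (chi2_d0 / d0) marginally,
    E[log s^2] = log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2) and
    Var[log s^2] = psi'(d/2) + psi'(d0/2).  d0 solves the trigamma equation;
    if the empirical variance of log s^2 shows no excess dispersion over
    psi'(d/2), d0 = inf (all variances shrunk fully to s0^2).
    """
    s2 = np.asarray(list(s2), dtype=float)
    if d < 1:
        raise ValueError("residual df must be >= 1")
    positive = s2[s2 > 0]
    if positive.size < len(s2):
        logger.warning("excluding %d nonpositive s^2 from moment fit", len(s2) - positive.size)
    if positive.size < min_proteins:
        raise ValueError(
            f"need >= {min_proteins} proteins with positive s^2, got {positive.size}"
        )
    z = np.log(positive)
    emean = float(np.mean(z))
    evar = float(np.var(z, ddof=1))
    half_d = d / 2.0
    if evar <= 1e-15:
        # all residual variances identical: no dispersion at all
        return ModerationParams(d0=math.inf, s0_sq=float(np.exp(emean)))
    excess = evar - float(polygamma(1, half_d))
    if excess <= 0:
        d0 = math.inf
        s0_sq = float(np.exp(emean - digamma(half_d) + np.log(half_d)))
    else:
        half_d0 = trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        s0_sq = float(
            np.exp(emean - digamma(half_d) + np.log(half_d) + digamma(half_d0) - np.log(half_d0))
        )
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderated_test(
    fit: LinearFit,
    params: ModerationParams,
    contrast: ContrastSpec,
    adjust: bool = True,
) -> pd.DataFrame:
    """Moderated t-test of a contrast for every protein.

    Posterior variance s2_post = (d0*s0^2 + d*s^2)/(d0 + d) (s0^2 when
    d0 = inf); t_mod = fc / sqrt(s2_post * c' (X'X)^-1 c); two-sided p from a
    t distribution with d0 + d df (normal when infinite).  d0 = 0 recovers the
    ordinary t-test.
    """
    missing = [c for c in contrast.weights if c not in fit.cells]
    if missing:
        raise ValueError(f"contrast {contrast.name!r} references unknown cell(s) {missing}")
    w_full = np.zeros(len(fit.columns))
    for cell, w in contrast.weights.items():
        w_full[fit.columns.index(cell)] = w
    fc = fit.coef.to_numpy() @ w_full
    v = float(w_full @ fit.xtx_inv @ w_full)
    d0, s0 = params.d0, params.s0_sq
    d = fit.df_residual
    s2 = fit.s2.to_numpy()
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = math.inf
    else:
        if d0 + d <= 0:
            raise ValueError("total degrees of freedom d0 + d must be positive")
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fc / np.sqrt(s2_post * v)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "log2fc": fc,
            "t_mod": t_mod,
            "p": p,
            "residual_df": float(d),
        },
        index=fit.coef.index,
    )
    if adjust:
        out["p_adj"] = multipletests(p, method="fdr_bh")[1]
    out.index.name = "protein_id"
    out.attrs["contrast"] = contrast.name
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0
    return out


def classify_s6k_dependent(
    rnai_result: pd.DataFrame,
    rapa_result: pd.DataFrame,
    rapa_under_ca_result: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.Series:
    """Per-protein TORC1-S6K dependence call from three contrasts.

    A protein is labeled dependent iff it changes significantly both on S6K
    knockdown and on drug treatment (p < alpha in both) while the drug effect
    disappears under constitutive S6K activation (p >= alpha).
    """
    ids = rnai_result.index
    for other, name in ((rapa_result, "rapa"), (rapa_under_ca_result, "rapa_under_ca")):
        if set(other.index) != set(ids):
            raise ValueError(f"{name} result does not share protein ids with the RNAi result")
    p1 = rnai_result["p"]
    p2 = rapa_result["p"].reindex(ids)
    p3 = rapa_under_ca_result["p"].reindex(ids)
    dependent = (p1 < alpha) & (p2 < alpha) & (p3 >= alpha)
    labels = pd.Series(np.where(dependent, S6K_DEPENDENT_LABEL, ""), index=ids, name="label")
    return labels.sort_index()


@dataclass(frozen=True)
class GeneSetShift:
    statistic: float
    p: float
    median_shift: float
    n_set: int
    n_rest: int


def gene_set_shift_test(result: pd.DataFrame, gene_set: GeneSet) -> GeneSetShift:
    """Two-sided Wilcoxon rank-sum of set log2fc against the complement.

    Exact enumeration when both groups have <= 10 members, normal
    approximation with tie correction otherwise.
    """
    in_set = result.index.isin(gene_set.members)
    x = result.loc[in_set, "log2fc"].to_numpy()
    y = result.loc[~in_set, "log2fc"].to_numpy()
    if x.size < 3:
        raise ValueError(
            f"gene set {gene_set.name!r} has {x.size} member(s) in the result; need >= 3"
        )
    if y.size == 0:
        raise ValueError("complement of the gene set is empty")
    method = "exact" if (x.size <= 10 and y.size <= 10) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    shift = float(np.median(x) - np.median(y))
    return GeneSetShift(
        statistic=float(res.statistic), p=float(res.pvalue),
        median_shift=shift, n_set=int(x.size), n_rest=int(y.size),
    )


def extract_geneset_fc_matrix(
    results: Sequence[pd.DataFrame], gene_set: GeneSet, names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Gene x contrast log2 fold-change matrix for set members seen everywhere.

    Rows are restricted to set members detected in every supplied result
    (intersection rule); cells are the underlying log2fc values unchanged.
    """
    if names is None:
        names = [r.attrs.get("contrast", f"contrast_{i}") for i, r in enumerate(results)]
    common = set(gene_set.members)
    for r in results:
        common &= set(r.index)
    genes = sorted(common)
    data = {name: r["log2fc"].reindex(genes) for name, r in zip(names, results)}
    out = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    out.attrs["detection_rule"] = "intersection: set members detected in every contrast"
    return out
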