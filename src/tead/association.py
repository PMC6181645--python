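"""Per-TE association of expression with a quantitative pathology outcome.

Expression (batch-corrected, log2-transformed TPM) is regressed, one TE at
a time, on the outcome of interest — neurofibrillary tangle burden by
default, but any phenotype column (plaque burden, global cognition, a
diagnosis indicator) can be swapped in — adjusting for covariates such as
age at death, post-mortem interval (PMI) and RNA integrity number (RIN).
The outcome term's beta, standard error, t and two-sided p are reported
per TE, with Benjamini-Hochberg FDR q-values over the full scan.

Expression is the response and the outcome a predictor; the per-TE
t-statistics this produces feed the clade-level activation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AssociationResult:
    te_id: str
    beta: float
    se: float
    t_statistic: float
    p_value: float
    fdr_q: float | None
    n_subjects: int
    outcome_name: str


def log_transform(tpm_matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(TPM + pseudocount), elementwise; monotone in TPM."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = tpm_matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("TPM matrix contains negative values")
    return pd.DataFrame(
        np.log2(vals + pseudocount), index=tpm_matrix.index, columns=tpm_matrix.columns
    )


def batch_correct(matrix: pd.DataFrame, batch_labels: pd.Series) -> pd.DataFrame:
    """Remove per-TE batch means, restoring each TE's grand mean.

    ``matrix`` is TE x subject; ``batch_labels`` maps subject -> batch.
    Every batch needs >= 2 subjects, otherwise its mean is confounded with
    the subject.  Single-batch input returns unchanged values.
    """
    labels = batch_labels.reindex(matrix.columns)
    if labels.isna().any():
        missing = list(matrix.columns[labels.isna()])[:5]
        raise ValueError(f"subjects missing batch labels: {missing}")
    sizes = labels.value_counts()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(f"batch of size 1: {list(small.index)}")
    vals = matrix.to_numpy(dtype=float)
    grand = vals.mean(axis=1, keepdims=True)
    out = vals.copy()
    for batch in sizes.index:
        cols = (labels == batch).to_numpy()
        out[:, cols] -= vals[:, cols].mean(axis=1, keepdims=True)
    out += grand
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _ols_outcome_term(X: np.ndarray, Y: np.ndarray, term: int = 1):
    """OLS of each column of Y on X; returns (beta, se, t, p, dof) for ``term``.

    Y is n x m (m responses share the design); solved once through the
    pseudo-inverse for the whole scan.
    """
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"n={n} too small for p={p} predictors (need n >= p + 2)")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns for the caller
        bad = []
        for j in range(p):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(j)
        raise ValueError(f"design matrix rank-deficient; collinear columns {bad}")
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ Y  # p x m
    resid = Y - X @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    var_term = sigma2 * XtX_inv[term, term]
    beta = coef[term]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_term)
        t = beta / se
    # zero residual variance: evidence is undefined, not infinite
    degenerate = sigma2 <= np.finfo(float).eps * np.abs(Y).max(axis=0, initial=1.0) ** 2
    se = np.where(degenerate, np.nan, se)
    t = np.where(degenerate, np.nan, t)
    p_val = np.where(np.isnan(t), np.nan, 2 * stats.t.sf(np.abs(t), dof))
    return beta, se, t, p_val, dof


def fit_te_association(
    expression: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
    te_id: str = "",
    outcome_name: str = "outcome",
) -> AssociationResult:
    """OLS of one TE's expression on [intercept, outcome, covariates].

    Reports the outcome term.  Degenerate fits (zero residual variance)
    return the beta with se and p set to NaN.
    """
    y = np.asarray(expression, dtype=float)
    x = np.asarray(outcome, dtype=float)
    cols = [np.ones_like(x), x]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
    X = np.column_stack(cols)
    beta, se, t, p, _ = _ols_outcome_term(X, y[:, None])
    return AssociationResult(
        te_id=te_id,
        beta=float(beta[0]),
        se=float(se[0]),
        t_statistic=float(t[0]),
        p_value=float(p[0]),
        fdr_q=None,
        n_subjects=len(y),
        outcome_name=outcome_name,
    )


def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min over j with p_j >= p_i of m * p_j / rank_j, capped at 1;
    order-preserving in p and invariant to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_association_scan(
    matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    outcome_name: str,
    covariate_names: list[str],
    fdr_threshold: float = 0.1,
    batch_column: str | None = None,
    sqrt_outcome: bool = False,
) -> pd.DataFrame:
    """One covariate-adjusted regression per TE, with scan-wide BH FDR.

    Parameters
    ----------
    matrix
        Processed expression, TE x subject (already log-transformed and,
        if desired, batch-corrected).
    phenotypes
        Subject-indexed table holding the outcome and covariates.
    outcome_name, covariate_names
        Columns of ``phenotypes``; unknown names are an error.
    batch_column
        If given, batch enters the regression as dummy-coded factor
        covariates instead of (or on top of) mean-centering correction.
    sqrt_outcome
        Square-root transform the outcome before fitting (histologic count
        outcomes are right-skewed).

    Subjects are intersected between matrix and phenotypes, with listwise
    deletion of those missing any model variable.  Returns one row per TE
    sorted by p, with q over the full scan and a ``significant`` flag at
    ``fdr_threshold``.
    """
    pheno = phenotypes.copy()
    if pheno.index.name != "subject_id" and "subject_id" in pheno.columns:
        pheno = pheno.set_index("subject_id")
    for name in [outcome_name, *covariate_names]:
        if name not in pheno.columns:
            raise KeyError(f"unknown phenotype column {name!r}")
    if batch_column is not None and batch_column not in pheno.columns:
        raise KeyError(f"unknown batch column {batch_column!r}")

    subjects = matrix.columns.intersection(pheno.index)
    if subjects.empty:
        raise ValueError("no subjects shared between expression matrix and phenotypes")
    model_cols = [outcome_name, *covariate_names]
    pheno = pheno.loc[subjects]
    keep = pheno[model_cols].notna().all(axis=1)
    if batch_column is not None:
        keep &= pheno[batch_column].notna()
    pheno = pheno.loc[keep]
    subjects = pheno.index

    y_out = pheno[outcome_name].to_numpy(dtype=float)
    if sqrt_outcome:
        if (y_out < 0).any():
            raise ValueError("cannot sqrt-transform a negative outcome")
        y_out = np.sqrt(y_out)
    cols = [np.ones(len(subjects)), y_out]
    for c in covariate_names:
        cols.append(pheno[c].to_numpy(dtype=float))
    if batch_column is not None:
        dummies = pd.get_dummies(pheno[batch_column], drop_first=True)
        cols.extend(dummies.to_numpy(dtype=float).T)
    X = np.column_stack(cols)
    Y = matrix[subjects].to_numpy(dtype=float).T  # n x m

    beta, se, t, p, _ = _ols_outcome_term(X, Y)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    out = pd.DataFrame(
        {
            "te_id": matrix.index,
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "q": q,
            "n": len(subjects),
            "outcome": outcome_name,
        }
    )
    out["significant"] = out["q"] < fdr_threshold
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
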