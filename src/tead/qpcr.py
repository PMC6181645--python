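"""qPCR relative quantification and group statistics for the fly arm.

Implements the comparative-CT (delta-delta-CT) method against a reference
gene (RpL32 in the motivating design) and a reference group (1-day-old
control animals), one-way ANOVA per TE/time point across genotypes, Welch
post hoc t tests of each Tau genotype against control with the usual star
bands, two-way genotype x age ANOVA, and the identical math applied to
genomic-DNA CT values for relative copy number.

Input is a tidy measurement table with columns ``sample_id``, ``genotype``,
``age_days``, ``target``, ``replicate``, ``ct``.  Technical replicate CTs
are averaged within sample before any delta is taken; amplification
efficiency is fixed at 2.0 (no standard-curve data assumed), so
fold change = 2 ** (-delta_delta_ct).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

MEASUREMENT_COLUMNS = ["sample_id", "genotype", "age_days", "target", "replicate", "ct"]


def _mean_ct(measurements: pd.DataFrame) -> pd.DataFrame:
    """Average technical-replicate CTs within (sample, target)."""
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")
    return (
        measurements.groupby(
            ["sample_id", "genotype", "age_days", "target"], as_index=False
        )["ct"]
        .mean()
    )


def delta_delta_ct(
    measurements: pd.DataFrame,
    reference_gene: str,
    reference_group: tuple[str, int],
    label: str = "relative expression",
) -> pd.DataFrame:
    """Comparative-CT relative quantification.

    delta_ct = CT(target) - CT(reference gene), paired within sample;
    delta_delta_ct = delta_ct - mean delta_ct of the reference
    (genotype, age) group for that target; fold = 2^(-ddct).  Samples
    lacking the reference gene are dropped with a warning.  The reference
    group's fold changes have geometric mean 1 per target by construction.
    """
    mean_ct = _mean_ct(measurements)
    ref = mean_ct[mean_ct["target"] == reference_gene].set_index("sample_id")["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not measured")
    targets = mean_ct[mean_ct["target"] != reference_gene].copy()
    has_ref = targets["sample_id"].isin(ref.index)
    if (~has_ref).any():
        dropped = sorted(targets.loc[~has_ref, "sample_id"].unique())
        warnings.warn(
            f"dropping {len(dropped)} sample(s) lacking reference-gene CT: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
        targets = targets[has_ref]
    targets["delta_ct"] = targets["ct"] - ref.reindex(targets["sample_id"]).to_numpy()

    ref_geno, ref_age = reference_group
    in_ref = (targets["genotype"] == ref_geno) & (targets["age_days"] == ref_age)
    if not in_ref.any():
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_means = (
        targets[in_ref].groupby("target")["delta_ct"].mean().rename("ref_delta_ct")
    )
    targets = targets.join(ref_means, on="target")
    if targets["ref_delta_ct"].isna().any():
        bad = sorted(targets.loc[targets["ref_delta_ct"].isna(), "target"].unique())
        raise ValueError(f"targets absent from the reference group: {bad}")
    targets["delta_delta_ct"] = targets["delta_ct"] - targets["ref_delta_ct"]
    targets["fold_change"] = 2.0 ** (-targets["delta_delta_ct"])
    targets["quantity"] = label
    return targets.drop(columns=["ref_delta_ct"]).reset_index(drop=True)


def copy_number_relative(
    measurements: pd.DataFrame,
    reference_gene: str,
    reference_group: tuple[str, int],
) -> pd.DataFrame:
    """Relative copy number from genomic-DNA CTs; same math as expression."""
    return delta_delta_ct(
        measurements, reference_gene, reference_group, label="relative copy number"
    )


def one_way_anova(groups: dict[str, np.ndarray]) -> tuple[float, int, int, float]:
    """Classical fixed-effects one-way ANOVA: (F, df_between, df_within, p).

    Requires >= 2 groups with >= 2 values each.  Zero within-group variance
    everywhere makes F undefined: returns (nan, df1, df2, nan).
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every group needs at least 2 values")
    allvals = np.concatenate(list(arrays.values()))
    grand = allvals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df1 = len(arrays) - 1
    df2 = allvals.size - len(arrays)
    if ss_within <= np.finfo(float).eps * max(1.0, abs(grand)) ** 2 * allvals.size:
        return float("nan"), df1, df2, float("nan")
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def posthoc_t_tests(
    groups: dict[str, np.ndarray],
    control_group: str,
    welch: bool = True,
) -> pd.DataFrame:
    """Two-sided t tests of each genotype vs the control group.

    Welch (unequal-variance) by default; ``welch=False`` pools variances.
    Groups with fewer than 2 values yield NaN.  Star bands: * p<0.05,
    ** p<0.01, *** p<0.001.  Intended as post hoc follow-up to a
    significant omnibus ANOVA (gating by the caller, not enforced).
    """
    if control_group not in groups:
        raise KeyError(f"control group {control_group!r} not present")
    control = np.asarray(groups[control_group], dtype=float)
    rows = []
    for name, vals in groups.items():
        if name == control_group:
            continue
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2 or control.size < 2:
            t, p = float("nan"), float("nan")
        else:
            res = stats.ttest_ind(vals, control, equal_var=not welch)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"group": name, "t": t, "p": p, "stars": _stars(p), "vs": control_group}
        )
    return pd.DataFrame(rows)


def two_way_anova(
    data: pd.DataFrame,
    value_column: str = "delta_delta_ct",
    factor_a: str = "genotype",
    factor_b: str = "age_days",
    include_interaction: bool = False,
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with Type II sums of squares.

    Type II marginal SS handle unbalanced designs; for balanced data they
    coincide with the sequential decomposition.  Requesting the interaction
    with an empty factor cell is an error.  Returns a table of
    (effect, sum_sq, df, F, p).
    """
    df = data[[value_column, factor_a, factor_b]].dropna().copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
        df[f] = df[f].astype(str)
    if include_interaction:
        cells = df.groupby([factor_a, factor_b]).size()
        n_expected = df[factor_a].nunique() * df[factor_b].nunique()
        if len(cells) < n_expected:
            raise ValueError("empty factor cell; cannot estimate the interaction")
    rhs = f"C({factor_a}) + C({factor_b})"
    if include_interaction:
        rhs += f" + C({factor_a}):C({factor_b})"
    fit = smf.ols(f"Q('{value_column}') ~ {rhs}", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    table = table.rename(
        index=lambda s: s.replace(f"C({factor_a})", factor_a).replace(
            f"C({factor_b})", factor_b
        )
    )
    out = table.reset_index().rename(
        columns={"index": "effect", "PR(>F)": "p", "F": "F"}
    )
    return out


def group_sem(values: np.ndarray) -> float:
    """Standard error of the mean, for mean +/- SEM plotting exports."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(v.size))
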