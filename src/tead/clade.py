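"""Clade-level activation tests over per-TE association t-statistics.

Individual TE effects are small; aggregating the per-TE regression
t-statistics within a clade (L1, SINE, ERV1/2/3, ...) and testing the
within-clade mean against zero with a one-sample t test gains power to
detect a global activation shift.  The null of mean zero ignores the mild
correlation between per-TE statistics in real cohorts — a deliberate
caveat, documented rather than corrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from tead.association import bh_fdr


def clade_activation_test(
    results: pd.DataFrame,
    clade_map: dict[str, set[str]],
    min_clade_size: int = 5,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One-sample two-sided t test of per-clade member t-statistics vs 0.

    ``results`` is an association-scan table with columns ``te_id`` and
    ``t``.  Clades below ``min_clade_size`` members (default 5 — smaller
    sets make the t test fragile) are reported with p = NaN, as are clades
    with zero within-clade variance.  Raw p-values by default, matching
    the convention of reporting uncorrected clade p's; set ``bh_correct``
    for BH q-values across clades.
    """
    if min_clade_size < 2:
        raise ValueError("min_clade_size must be >= 2")
    t_by_id = results.set_index("te_id")["t"]
    claimed = set().union(*clade_map.values()) if clade_map else set()
    stray = set(t_by_id.index) - claimed
    if stray:
        raise ValueError(f"te_ids not covered by the clade map: {sorted(stray)[:5]}")

    rows = []
    for clade, members in clade_map.items():
        vals = t_by_id.reindex(sorted(members)).dropna().to_numpy(dtype=float)
        n = vals.size
        if n == 0:
            continue
        mean_t = float(vals.mean())
        if n < min_clade_size or np.allclose(vals.std(ddof=0), 0.0):
            stat, p = float("nan"), float("nan")
        else:
            res = stats.ttest_1samp(vals, 0.0)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "clade": clade,
                "n_te": n,
                "mean_t": mean_t,
                "test_statistic": stat,
                "p_value": p,
                "direction": int(np.sign(mean_t)),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if bh_correct:
        q = np.full(len(out), np.nan)
        ok = out["p_value"].notna().to_numpy()
        if ok.any():
            q[ok] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
        out["fdr_q"] = q
    return out.sort_values("p_value", kind="mergesort", na_position="last").reset_index(
        drop=True
    )


def clade_summary_plot_data(
    results: pd.DataFrame,
    clade_map: dict[str, set[str]],
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Boxplot-ready per-clade summaries of the t-statistic distribution.

    Returns, per clade: n, median, quartiles, Tukey whiskers (most extreme
    values within 1.5 IQR of the box) and the count of outliers beyond
    them.  ``t_threshold`` is the smallest |t| among TEs significant at
    ``fdr_threshold`` in the scan (NaN when none are) — the cut used to
    highlight the most extreme individual associations.
    """
    if results.empty:
        raise ValueError("empty association results")
    t_by_id = results.set_index("te_id")["t"]
    if "q" in results.columns:
        sig = results.loc[results["q"] < fdr_threshold]
    else:
        sig = results.iloc[0:0]
    t_threshold = float(sig["t"].abs().min()) if len(sig) else float("nan")

    rows = []
    for clade, members in sorted(clade_map.items()):
        vals = t_by_id.reindex(sorted(members)).dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        in_lo = vals[vals >= q1 - 1.5 * iqr]
        in_hi = vals[vals <= q3 + 1.5 * iqr]
        rows.append(
            {
                "clade": clade,
                "n_te": vals.size,
                "q1": q1,
                "median": med,
                "q3": q3,
                "whisker_low": in_lo.min(),
                "whisker_high": in_hi.max(),
                "n_outliers": int(
                    ((vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)).sum()
                ),
                "t_threshold": t_threshold,
            }
        )
    return pd.DataFrame(rows)
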