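"""Locus-level association between tangle burden and H3K9Ac ChIP-seq counts.

Built for low-copy TE families whose genomic loci can be enumerated (the
motivating case is an endogenous retrovirus present at a handful of sites):
given a locus x sample read-count table plus per-sample covariates, each
locus is tested for an association between tangle burden and H3K9Ac signal,
adjusting for library size, batch, PMI, ChIP cross-correlation QC, age and
sex.  Read extraction from alignments is out of scope — the module consumes
a pre-made count table.

The default model is OLS on the log2 scale:

    log2(count + 0.5 * libsize/1e6) ~ tangles + log2(libsize) + batch
                                      + pmi + cross_correlation + age + sex

The pseudocount is half a read per million, i.e. it scales with library
size: this makes the fit exactly invariant to a global rescaling of depth
(doubling all counts and library sizes shifts every response by one and the
log-libsize column by one, both absorbed without touching the tangle term).
A quasi-Poisson alternative with a log(libsize) offset is available via
``model="quasipoisson"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from tead.association import bh_fdr

SAMPLE_COVARIATES = ["pmi", "cross_correlation", "age", "sex"]
PSEUDOCOUNT_PER_MILLION = 0.5


@dataclass
class LocusCountTable:
    """Loci (BED-convention 0-based half-open), counts and sample covariates.

    ``loci``: DataFrame with locus_id, chrom, start, end.
    ``counts``: locus x sample grid of non-negative integers (NaN = no data).
    ``samples``: sample-indexed covariates incl. library_size, batch,
    tangle_burden and the adjustment covariates.
    """

    loci: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.loci["end"] <= self.loci["start"]).any():
            bad = self.loci.loc[self.loci["end"] <= self.loci["start"], "locus_id"]
            raise ValueError(f"loci with end <= start: {list(bad)}")
        vals = self.counts.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0) < 0:
            raise ValueError("negative counts")
        if (self.samples["library_size"] <= 0).any():
            raise ValueError("library sizes must be positive")
        over = vals > self.samples["library_size"].reindex(self.counts.columns).to_numpy()
        if np.any(np.nan_to_num(over)):
            raise ValueError("locus count exceeds its sample's library size")

    @classmethod
    def from_files(
        cls, bed_path: str | Path, counts_path: str | Path, samples_path: str | Path
    ) -> "LocusCountTable":
        loci = pd.read_csv(
            bed_path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "locus_id"],
            usecols=range(4),
            comment="#",
        )[["locus_id", "chrom", "start", "end"]]
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index.name = "locus_id"
        counts.columns.name = "sample_id"
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        samples.index.name = "sample_id"
        return cls(loci=loci, counts=counts, samples=samples)

    def to_files(
        self, bed_path: str | Path, counts_path: str | Path, samples_path: str | Path
    ) -> None:
        self.loci[["chrom", "start", "end", "locus_id"]].to_csv(
            bed_path, sep="\t", header=False, index=False
        )
        self.counts.to_csv(counts_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t")


def _design(samples: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """[intercept, tangles, log2 libsize, batch dummies, pmi, xcor, age, sex]."""
    batch_sizes = samples["batch"].value_counts()
    small = batch_sizes[batch_sizes < 2]
    if not small.empty:
        raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")
    n = len(samples)
    cols = [np.ones(n), samples["tangle_burden"].to_numpy(dtype=float)]
    names = ["intercept", "tangle_burden"]
    cols.append(np.log2(samples["library_size"].to_numpy(dtype=float)))
    names.append("log2_library_size")
    dummies = pd.get_dummies(samples["batch"], drop_first=True)
    for c in dummies.columns:
        cols.append(dummies[c].to_numpy(dtype=float))
        names.append(f"batch_{c}")
    for c in SAMPLE_COVARIATES:
        col = samples[c]
        if col.dtype == object:  # e.g. sex coded "M"/"F"
            col = pd.get_dummies(col, drop_first=True).iloc[:, 0]
        cols.append(col.to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError(
            f"insufficient degrees of freedom: n={X.shape[0]}, p={X.shape[1]}"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient ChIP design matrix")
    return X, names


def fit_locus_association(
    counts_row: pd.Series,
    covariate_table: pd.DataFrame,
    model: str = "ols",
) -> dict:
    """Tangle-burden term for one locus' ChIP counts.

    Samples with missing counts are dropped.  An all-zero locus is
    uninformative: the result is flagged ``low_information`` with p = NaN.
    """
    common = counts_row.dropna().index.intersection(covariate_table.index)
    y_counts = counts_row.loc[common].to_numpy(dtype=float)
    samples = covariate_table.loc[common]
    result = {
        "locus_id": counts_row.name,
        "n_samples": len(common),
        "low_information": False,
    }
    if len(common) == 0 or (y_counts == 0).all():
        result.update(beta=np.nan, se=np.nan, t=np.nan, p=np.nan, low_information=True)
        return result
    X, _ = _design(samples)
    lib = samples["library_size"].to_numpy(dtype=float)
    if model == "ols":
        y = np.log2(y_counts + PSEUDOCOUNT_PER_MILLION * lib / 1e6)
        fit = sm.OLS(y, X).fit()
        dof = fit.df_resid
        beta, se = fit.params[1], fit.bse[1]
        t = beta / se
        p = 2 * stats.t.sf(abs(t), dof)
    elif model == "quasipoisson":
        # Poisson mean model with log libsize offset; scale estimated (X2)
        glm = sm.GLM(
            y_counts,
            np.delete(X, 2, axis=1),  # offset replaces the libsize column
            family=sm.families.Poisson(),
            offset=np.log(lib),
        )
        fit = glm.fit(scale="X2")
        beta, se = fit.params[1], fit.bse[1]
        t = beta / se
        p = 2 * stats.norm.sf(abs(t))
    else:
        raise ValueError(f"unknown model {model!r}")
    result.update(beta=float(beta), se=float(se), t=float(t), p=float(p))
    return result


def scan_family_loci(
    table: LocusCountTable,
    alpha: float = 0.05,
    fdr_threshold: float = 0.1,
    model: str = "ols",
) -> tuple[pd.DataFrame, dict]:
    """Fit every locus of the family; summarize positive associations.

    Loci whose counts are entirely missing or zero lack data and are
    excluded from testing but counted.  Returns (per-locus results sorted
    by p, summary) where the summary reports n_loci, n_loci_with_data,
    n_positive_nominal (beta > 0 and p < alpha) and n_fdr_significant
    (BH q < fdr_threshold).
    """
    rows = [
        fit_locus_association(table.counts.loc[locus_id], table.samples, model=model)
        for locus_id in table.counts.index
    ]
    res = pd.DataFrame(rows)
    ok = res["p"].notna().to_numpy()
    q = np.full(len(res), np.nan)
    if ok.any():
        q[ok] = bh_fdr(res.loc[ok, "p"].to_numpy())
    res["fdr_q"] = q
    summary = {
        "n_loci": len(res),
        "n_loci_with_data": int(ok.sum()),
        "n_positive_nominal": int(((res["beta"] > 0) & (res["p"] < alpha)).sum()),
        "n_fdr_significant": int((res["fdr_q"] < fdr_threshold).sum()),
    }
    res = res.sort_values("p", kind="mergesort", na_position="last").reset_index(
        drop=True
    )
    return res, summary
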