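"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of a :class:`SimulationConfig` — same
seed, same bytes — and emits a truth table alongside its artifact so
recovery metrics never require re-simulation.  Each generator draws from
its own stream spawned from the master seed at a fixed offset, so adding
one generator never perturbs another's output.

What is emulated, at desk scale:

* a consensus retrotransposon library whose families share sequence
  (founder copied, the non-shared fraction mutated), producing genuine
  multi-mapping at k-mer scale; the default composition mirrors a
  547-element library of 366 LTR and 181 non-LTR elements across the
  usual clades (ERV1/2/3, Gypsy, Copia; L1, SINE);
* RNA-seq reads drawn with per-TE probability proportional to
  TPM x effective length (so a correct quantifier recovers TPM), uniform
  start positions, both strands, per-base substitution errors;
* a clinical-pathologic cohort with a right-skewed tangle-burden outcome,
  covariates (age at death, PMI, RIN, batch) and planted per-TE and
  per-clade expression effects on the log2-TPM scale;
* ChIP-seq locus count tables with Poisson counts, library-size variation
  and planted log-scale tangle effects;
* triplicate qPCR CT values by genotype x age with planted fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tead.chipseq import LocusCountTable
from tead.library import TELibrary, TERecord

# fixed stream offsets: one independent stream per generator
_STREAM_LIBRARY = 1
_STREAM_READS = 2
_STREAM_COHORT = 3
_STREAM_CHIP = 4
_STREAM_QPCR = 5

LTR_CLADES = ("ERV1", "ERV2", "ERV3", "Gypsy", "Copia")
NON_LTR_CLADES = ("L1", "SINE")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

FLY_TARGETS_LTR = ("copia", "gypsy", "blood", "412", "mdg1", "roo", "297", "17.6")
FLY_TARGETS_NON_LTR = ("het-a", "I-element", "jockey", "R2")


def _default_qpcr_effects() -> dict[tuple[str, int, str], float]:
    """Planted log2 fold changes per (genotype, age, target).

    Emulates activation of copia/het-a/gypsy in Tau genotypes in the
    3-10x band at day 20, with copia rising progressively with age.
    """
    eff: dict[tuple[str, int, str], float] = {}
    for geno in ("TauWT", "TauR406W"):
        eff[(geno, 20, "het-a")] = np.log2(6.0)
        eff[(geno, 1, "copia")] = np.log2(1.5)
        eff[(geno, 10, "copia")] = np.log2(3.0)
        eff[(geno, 20, "copia")] = np.log2(8.0)
    eff[("TauWT", 20, "gypsy")] = np.log2(4.0)
    eff[("TauR406W", 20, "het-a")] = np.log2(10.0)
    return eff


@dataclass
class SimulationConfig:
    """Knobs for every generator; defaults are the study conditions."""

    seed: int = 0

    # library
    n_te: int = 547
    ltr_fraction: float = 366 / 547
    te_length_range: tuple[int, int] = (300, 5000)
    family_similarity: float = 0.2  # fraction of founder sequence shared
    max_family_size: int = 5

    # reads
    n_reads: int = 100_000
    read_length: int = 100
    error_rate: float = 0.005

    # cohort
    n_subjects: int = 636
    tangle_shape: float = 1.5
    tangle_scale: float = 4.0
    n_batches: int = 4
    batch_sd: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    covariate_loading_sd: float = 0.02
    te_betas: dict = field(default_factory=dict)  # te_id -> beta per tangle unit
    clade_shifts: dict = field(default_factory=dict)  # clade -> added beta

    # chip
    chip_n_loci: int = 13
    chip_n_samples: int = 675
    chip_library_size_range: tuple[int, int] = (500_000, 2_000_000)
    chip_rate_range: tuple[float, float] = (2e-6, 2e-5)
    chip_effects: dict = field(default_factory=dict)  # locus_id -> ln-scale effect
    chip_n_batches: int = 3

    # qpcr
    qpcr_genotypes: tuple[str, ...] = ("control", "TauWT", "TauR406W")
    qpcr_ages: tuple[int, ...] = (1, 10, 20)
    qpcr_targets: tuple[str, ...] = FLY_TARGETS_LTR + FLY_TARGETS_NON_LTR
    qpcr_reference_gene: str = "RpL32"
    qpcr_n_samples: int = 3  # biological replicates per group
    qpcr_n_replicates: int = 3  # technical replicates per sample
    qpcr_sample_sd: float = 0.25  # biological CT noise
    qpcr_replicate_sd: float = 0.15  # technical CT noise
    qpcr_effects: dict = field(default_factory=_default_qpcr_effects)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_library(config: SimulationConfig) -> tuple[TELibrary, pd.DataFrame]:
    """Consensus library with within-family sequence sharing.

    Families are built by copying a founder: a contiguous block covering
    ``family_similarity`` of the founder is kept verbatim in every member
    and the remaining positions are redrawn uniformly per member.  Members
    therefore share the block — and its k-mers — exactly, the source of
    realistic multi-mapping, while the rest of each member diverges enough
    that no k-mer of useful length survives by chance.
    """
    if config.n_te < 1:
        raise ValueError("n_te must be >= 1")
    if not 0 <= config.family_similarity <= 1:
        raise ValueError("family_similarity must be in [0, 1]")
    rng = config.rng(_STREAM_LIBRARY)
    n_ltr = int(round(config.n_te * config.ltr_fraction))
    classes = ["LTR"] * n_ltr + ["non-LTR"] * (config.n_te - n_ltr)
    clades = [LTR_CLADES[i % len(LTR_CLADES)] for i in range(n_ltr)] + [
        NON_LTR_CLADES[i % len(NON_LTR_CLADES)] for i in range(config.n_te - n_ltr)
    ]
    lo, hi = config.te_length_range

    records: list[TERecord] = []
    truth_rows = []
    i = 0
    family_id = 0
    while i < config.n_te:
        size = min(int(rng.integers(1, config.max_family_size + 1)), config.n_te - i)
        if (
            config.family_similarity >= 1.0
            and size > 1
            and config.error_rate == 0.0
        ):
            warnings.warn(
                "family with similarity 1 and >1 member: multi-mapping is "
                "unresolvable by design",
                stacklevel=2,
            )
        length = int(rng.integers(lo, hi + 1))
        founder = rng.integers(0, 4, size=length)
        n_shared = int(round(config.family_similarity * length))
        block_start = int(rng.integers(0, length - n_shared + 1)) if n_shared else 0
        outside = np.ones(length, dtype=bool)
        outside[block_start : block_start + n_shared] = False
        n_out = int(outside.sum())
        for _ in range(size):
            member = founder.copy()
            if n_out:
                member[outside] = rng.integers(0, 4, size=n_out)
            te_id = f"TE{i + 1:04d}"
            records.append(
                TERecord(
                    te_id=te_id,
                    sequence=_decode(member),
                    te_class=classes[i],
                    clade=clades[i],
                )
            )
            truth_rows.append(
                {
                    "te_id": te_id,
                    "family_id": f"FAM{family_id:04d}",
                    "clade": clades[i],
                    "class": classes[i],
                    "length": length,
                }
            )
            i += 1
            if i == config.n_te:
                break
        family_id += 1
    return TELibrary(records), pd.DataFrame(truth_rows)


def simulate_reads(
    library: TELibrary,
    true_tpm: pd.Series | dict[str, float],
    config: SimulationConfig,
    out_fastq: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Error-prone reads drawn so a correct quantifier recovers ``true_tpm``.

    Per-TE read probability is proportional to tpm_t x efflen_t (TPM is a
    molar concentration; sampling reads weights molecules by the number of
    start positions).  TEs shorter than the read length are excluded with
    a warning.  Returns the read sequences plus a truth table; optionally
    writes FASTQ (constant quality — qualities are ignored downstream).
    """
    if rng is None:
        rng = config.rng(_STREAM_READS)
    tpm = pd.Series(true_tpm, dtype=float).reindex(library.te_ids).fillna(0.0)
    if (tpm < 0).any() or tpm.sum() <= 0:
        raise ValueError("true_tpm must be non-negative and not all zero")
    rl = config.read_length
    efflen = np.array([max(len(r) - rl + 1, 0) for r in library], dtype=float)
    short = (efflen == 0) & (tpm.to_numpy() > 0)
    if short.any():
        warnings.warn(
            f"{int(short.sum())} TE(s) shorter than the read length excluded",
            stacklevel=2,
        )
    weights = tpm.to_numpy() * efflen
    if weights.sum() <= 0:
        raise ValueError("no TE is long enough to yield reads")
    probs = weights / weights.sum()
    counts = rng.multinomial(config.n_reads, probs)

    reads: list[str] = []
    origins: list[str] = []
    for rec, n in zip(library, counts):
        if n == 0:
            continue
        codes = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        codes = np.searchsorted(_BASES, codes)  # ACGT -> 0..3 (founders are N-free)
        starts = rng.integers(0, len(rec) - rl + 1, size=n)
        mat = codes[starts[:, None] + np.arange(rl)]
        if config.error_rate > 0:
            err = rng.random(mat.shape) < config.error_rate
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum()))
                mat[err] = (mat[err] + shift) % 4
        rev = rng.random(n) < 0.5
        mat[rev] = 3 - mat[rev, ::-1]
        for row in mat:
            reads.append(_decode(row))
            origins.append(rec.te_id)

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    origins = [origins[i] for i in order]
    truth = pd.DataFrame(
        {
            "te_id": library.te_ids,
            "true_tpm": tpm.to_numpy(),
            "n_reads_simulated": counts,
        }
    )
    if out_fastq is not None:
        write_fastq(reads, out_fastq, origins=origins)
    return reads, truth


def write_fastq(
    reads: list[str], path: str | Path, origins: list[str] | None = None
) -> None:
    """Plain-text FASTQ with constant quality."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            tag = f"_{origins[i]}" if origins is not None else ""
            fh.write(f"@read{i}{tag}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_cohort(
    config: SimulationConfig,
    te_ids: list[str] | None = None,
    te_clades: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort expression (log2-TPM scale) + phenotypes + per-TE truth.

    Tangle burden is gamma-distributed (right-skewed, non-negative, like
    averaged histologic counts); expression is
    baseline + beta * tangles + covariate loadings + batch offset + noise.
    Clade-level activation is planted as a shared beta shift across member
    TEs (``config.clade_shifts``) on top of per-TE betas
    (``config.te_betas``).
    """
    if config.n_subjects < 20:
        raise ValueError("n_subjects must be >= 20")
    rng = config.rng(_STREAM_COHORT)
    if te_ids is None:
        te_ids = [f"TE{i + 1:04d}" for i in range(config.n_te)]
    m = len(te_ids)
    unknown = set(config.te_betas) - set(te_ids)
    if unknown:
        raise ValueError(f"te_betas reference unknown TEs: {sorted(unknown)[:5]}")
    if config.clade_shifts and te_clades is None:
        raise ValueError("clade_shifts given but no te_clades mapping")

    n = config.n_subjects
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    tangles = rng.gamma(config.tangle_shape, config.tangle_scale, size=n)
    pheno = pd.DataFrame(
        {
            "subject_id": subjects,
            "tangle_burden": tangles,
            "plaque_burden": rng.gamma(1.2, 3.0, size=n),
            "age_at_death": rng.normal(88.0, 6.0, size=n).clip(65, 108),
            "pmi": rng.gamma(2.0, 3.5, size=n),
            "rin": rng.normal(7.0, 1.0, size=n).clip(4, 10),
            "batch": [f"B{1 + i % config.n_batches}" for i in rng.permutation(n)],
        }
    ).set_index("subject_id")

    betas = np.array([config.te_betas.get(t, 0.0) for t in te_ids], dtype=float)
    if config.clade_shifts:
        shifts = np.array(
            [config.clade_shifts.get(te_clades[t], 0.0) for t in te_ids], dtype=float
        )
        betas = betas + shifts
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=m)
    loadings = rng.normal(0.0, config.covariate_loading_sd, size=(m, 3))
    covs = pheno[["age_at_death", "pmi", "rin"]].to_numpy()
    covs_c = covs - covs.mean(axis=0)
    batch_offsets = rng.normal(0.0, config.batch_sd, size=(m, config.n_batches))
    batch_idx = pheno["batch"].str.slice(1).astype(int).to_numpy() - 1

    expr = (
        baseline[:, None]
        + betas[:, None] * tangles[None, :]
        + loadings @ covs_c.T
        + batch_offsets[:, batch_idx]
        + rng.normal(0.0, config.noise_sd, size=(m, n))
    )
    matrix = pd.DataFrame(expr, index=pd.Index(te_ids, name="te_id"), columns=subjects)
    truth = pd.DataFrame(
        {"te_id": te_ids, "beta": betas, "baseline": baseline}
    )
    return matrix, pheno.reset_index(), truth


def expression_to_tpm(log2_expression: pd.DataFrame) -> pd.DataFrame:
    """Invert the log2(TPM + 1) scale per subject and renormalize to 1e6."""
    tpm = np.maximum(2.0 ** log2_expression.to_numpy() - 1.0, 0.0)
    tpm = 1e6 * tpm / tpm.sum(axis=0, keepdims=True)
    return pd.DataFrame(tpm, index=log2_expression.index, columns=log2_expression.columns)


def simulate_chip_counts(
    config: SimulationConfig,
) -> tuple[LocusCountTable, pd.DataFrame]:
    """Locus x sample Poisson ChIP counts with planted tangle effects.

    counts ~ Poisson(libsize x locus_rate x exp(effect x tangles + covariate
    terms)); effects are per natural-log unit per tangle unit
    (``config.chip_effects``, keyed by locus_id).
    """
    rng = config.rng(_STREAM_CHIP)
    L, n = config.chip_n_loci, config.chip_n_samples
    locus_ids = [f"locus{i + 1:02d}" for i in range(L)]
    unknown = set(config.chip_effects) - set(locus_ids)
    if unknown:
        raise ValueError(f"chip_effects reference unknown loci: {sorted(unknown)}")
    starts = rng.integers(1e5, 1e8, size=L)
    loci = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "chrom": [f"chr{int(c)}" for c in rng.integers(1, 23, size=L)],
            "start": starts,
            "end": starts + rng.integers(5_000, 10_000, size=L),
        }
    )
    lo, hi = config.chip_library_size_range
    samples = pd.DataFrame(
        {
            "sample_id": [f"C{i + 1:04d}" for i in range(n)],
            "library_size": rng.integers(lo, hi, size=n),
            "batch": [f"B{1 + i % config.chip_n_batches}" for i in rng.permutation(n)],
            "pmi": rng.gamma(2.0, 3.5, size=n),
            "cross_correlation": rng.normal(0.2, 0.05, size=n).clip(0.05, 0.5),
            "age": rng.normal(88.0, 6.0, size=n).clip(65, 108),
            "sex": rng.integers(0, 2, size=n),
            "tangle_burden": rng.gamma(config.tangle_shape, config.tangle_scale, size=n),
        }
    ).set_index("sample_id")

    r_lo, r_hi = config.chip_rate_range
    rates = np.exp(rng.uniform(np.log(r_lo), np.log(r_hi), size=L))
    effects = np.array([config.chip_effects.get(l, 0.0) for l in locus_ids])
    cov_term = (
        0.01 * (samples["pmi"] - samples["pmi"].mean())
        + 0.5 * (samples["cross_correlation"] - samples["cross_correlation"].mean())
    ).to_numpy()
    mu = (
        samples["library_size"].to_numpy()[None, :]
        * rates[:, None]
        * np.exp(
            effects[:, None] * samples["tangle_burden"].to_numpy()[None, :]
            + cov_term[None, :]
        )
    )
    counts = pd.DataFrame(
        rng.poisson(mu), index=pd.Index(locus_ids, name="locus_id"), columns=samples.index
    )
    truth = pd.DataFrame(
        {"locus_id": locus_ids, "rate": rates, "ln_effect_per_tangle": effects}
    )
    return LocusCountTable(loci=loci, counts=counts, samples=samples), truth


def simulate_qpcr(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triplicate CT table over genotype x age x target with planted folds.

    CT(target) = CT(reference) + base dCT - planted log2 fold + biological
    noise, plus technical replicate noise; planted effects are keyed by
    (genotype, age_days, target) in ``config.qpcr_effects`` as log2 fold
    changes relative to the reference group.
    """
    rng = config.rng(_STREAM_QPCR)
    base_dct = {t: rng.uniform(3.0, 8.0) for t in config.qpcr_targets}
    rows = []
    truth_rows = []
    for geno in config.qpcr_genotypes:
        for age in config.qpcr_ages:
            for s in range(config.qpcr_n_samples):
                sample_id = f"{geno}_d{age}_s{s + 1}"
                ref_ct = 15.0 + rng.normal(0.0, config.qpcr_sample_sd)
                for rep in range(1, config.qpcr_n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "genotype": geno,
                            "age_days": age,
                            "target": config.qpcr_reference_gene,
                            "replicate": rep,
                            "ct": ref_ct + rng.normal(0.0, config.qpcr_replicate_sd),
                        }
                    )
                for target in config.qpcr_targets:
                    lfc = config.qpcr_effects.get((geno, age, target), 0.0)
                    true_ct = (
                        ref_ct
                        + base_dct[target]
                        - lfc
                        + rng.normal(0.0, config.qpcr_sample_sd)
                    )
                    for rep in range(1, config.qpcr_n_replicates + 1):
                        rows.append(
                            {
                                "sample_id": sample_id,
                                "genotype": geno,
                                "age_days": age,
                                "target": target,
                                "replicate": rep,
                                "ct": true_ct
                                + rng.normal(0.0, config.qpcr_replicate_sd),
                            }
                        )
    for (geno, age, target), lfc in config.qpcr_effects.items():
        truth_rows.append(
            {
                "genotype": geno,
                "age_days": age,
                "target": target,
                "true_log2_fold": lfc,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
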