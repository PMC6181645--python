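"""End-to-end pipeline composition over synthetic cohorts.

Runs the full chain — simulate a library and a cohort with a planted
activated clade, draw per-subject reads from each subject's true TPM
profile, quantify every subject against the shared k-mer index, log2
transform, run the covariate-adjusted association scan against tangle
burden, and aggregate by clade — returning everything a recovery analysis
needs.  This is the loop the analysis drivers and the acceptance checks
exercise; its defaults are desk-scale (tens of TEs, tens of subjects,
thousands of reads per subject) so a full run takes seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from tead import simulate
from tead.association import run_association_scan
from tead.clade import clade_activation_test
from tead.library import clade_map
from tead.quant import QuantParams, build_index, quantify_reads
from tead.simulate import SimulationConfig


def desk_scale_config(seed: int, planted_clade: str = "L1", shift: float = 0.05) -> SimulationConfig:
    """Desk-scale study conditions for end-to-end recovery runs.

    60 TEs over 7 clades, 50 subjects, 1200 single-end 100-nt reads per
    subject, 20% within-family sequence sharing, 0.5% base error, and a
    planted activation of ``planted_clade``: +``shift`` log2-TPM per tangle
    unit shared by every member TE.  The shift is kept moderate because TPM
    is compositional: in a small TE-only universe a large activated clade
    mechanically depresses every other TE's TPM, which would plant a
    spurious coherent negative signal in the null clades.
    """
    return SimulationConfig(
        seed=seed,
        n_te=60,
        ltr_fraction=40 / 60,
        te_length_range=(500, 1500),
        family_similarity=0.2,
        n_reads=1200,
        read_length=100,
        error_rate=0.005,
        n_subjects=50,
        noise_sd=0.5,
        baseline_mean=6.0,
        baseline_sd=1.0,
        clade_shifts={planted_clade: shift},
    )


@dataclass
class EndToEndResult:
    clade_tests: pd.DataFrame
    association: pd.DataFrame
    estimated_log_tpm: pd.DataFrame
    true_expression: pd.DataFrame
    phenotypes: pd.DataFrame
    planted_clade: str | None

    @property
    def top_clade(self) -> str:
        tested = self.clade_tests.dropna(subset=["p_value"])
        return str(tested.iloc[0]["clade"])


def run_end_to_end(
    config: SimulationConfig,
    quant_params: QuantParams | None = None,
    covariates: list[str] | None = None,
) -> EndToEndResult:
    """simulate -> quantify -> associate -> clade test, with ground truth."""
    quant_params = quant_params or QuantParams(read_length=config.read_length)
    covariates = covariates if covariates is not None else ["age_at_death", "pmi", "rin"]

    library, _ = simulate.simulate_library(config)
    clades = {rec.te_id: rec.clade for rec in library}
    true_expr, pheno, truth = simulate.simulate_cohort(
        config, te_ids=library.te_ids, te_clades=clades
    )
    true_tpm = simulate.expression_to_tpm(true_expr)

    index = build_index(library, quant_params.k)
    read_rng = config.rng(simulate._STREAM_READS)
    est_log = {}
    for subject in true_tpm.columns:
        reads, _ = simulate.simulate_reads(
            library, true_tpm[subject], config, rng=read_rng
        )
        est = quantify_reads(reads, index, quant_params)
        est_log[subject] = np.log2(est.tpm.to_numpy() + 1.0)
    matrix = pd.DataFrame(est_log, index=pd.Index(library.te_ids, name="te_id"))

    assoc = run_association_scan(
        matrix, pheno, outcome_name="tangle_burden", covariate_names=covariates
    )
    clade_tests = clade_activation_test(assoc, clade_map(library), min_clade_size=2)
    planted = max(config.clade_shifts, key=config.clade_shifts.get) if config.clade_shifts else None
    return EndToEndResult(
        clade_tests=clade_tests,
        association=assoc,
        estimated_log_tpm=matrix,
        true_expression=true_expr,
        phenotypes=pheno,
        planted_clade=planted,
    )


def planted_clade_recovery_rate(
    n_runs: int = 20, base_seed: int = 0, **config_overrides
) -> float:
    """Fraction of seeded end-to-end runs ranking the planted clade first."""
    hits = 0
    for i in range(n_runs):
        config = desk_scale_config(seed=base_seed + i)
        if config_overrides:
            config = replace(config, **config_overrides)
        result = run_end_to_end(config)
        hits += result.top_clade == result.planted_clade
    return hits / n_runs
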