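"""Per-TE association scan against tangle burden on a synthetic cohort.

Simulates a 636-subject cohort (the study's sample size) with 200 TE
expression signatures, 10 of them planted with a positive tangle effect,
then runs the covariate-adjusted scan (age at death, PMI, RIN; batch
mean-centering) and reports the FDR < 0.1 hits — the synthetic analogue
of the top-ranked tangle-associated TE table.
"""

import argparse
from pathlib import Path

from tead.association import batch_correct, run_association_scan
from tead.simulate import SimulationConfig, simulate_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    planted = {f"TE{i + 1:04d}": 0.05 for i in range(10)}
    cfg = SimulationConfig(
        seed=args.seed, n_te=200, n_subjects=636, te_betas=planted
    )
    matrix, pheno, truth = simulate_cohort(cfg)
    matrix = batch_correct(matrix, pheno.set_index("subject_id")["batch"])
    res = run_association_scan(
        matrix, pheno, "tangle_burden", ["age_at_death", "pmi", "rin"],
        fdr_threshold=0.1,
    )
    res.to_csv(args.out / "tangle_association.tsv", sep="\t", index=False)

    hits = res[res["significant"]]
    true_pos = hits["te_id"].isin(planted).sum()
    print(f"{len(hits)} TEs at FDR < 0.1 ({true_pos}/{len(planted)} planted recovered)")
    print(hits.head(12).to_string(index=False))

    # specificity check: the same TEs against plaque burden (no planted effect)
    alt = run_association_scan(
        matrix, pheno, "plaque_burden", ["age_at_death", "pmi", "rin"]
    )
    print(f"plaque-burden scan: {int(alt['significant'].sum())} TEs at FDR < 0.1 "
          "(no effect planted)")
    alt.to_csv(args.out / "plaque_association.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
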