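# tead — transposable-element activation analysis

`tead` implements the statistical pipeline linking Tau neurofibrillary
tangle pathology to transposable-element (TE) activation, as a tested,
reusable Python package exercised end to end on synthetic data with
planted ground truth:

1. **Consensus-library quantification** (`tead.quant`) — per-TE expression
   from RNA-seq reads against a Repbase-style consensus library, using
   canonical k-mer pseudo-assignment and an expectation-maximization (EM)
   loop to resolve reads that map to several family members, reporting
   expected counts and TPM.
2. **Covariate-adjusted association** (`tead.association`) — per-TE OLS of
   batch-corrected log2 TPM on a quantitative tangle-burden outcome,
   adjusting for age at death, post-mortem interval and RNA integrity,
   with Benjamini–Hochberg FDR over the scan.
3. **Clade activation tests** (`tead.clade`) — one-sample t tests of the
   per-TE regression t-statistics aggregated within retrotransposon clades
   (L1, SINE, ERV1/2/3, Gypsy, Copia), the power-gaining step when
   individual TE effects are small.
4. **ChIP-seq locus association** (`tead.chipseq`) — log-scale regression
   of H3K9Ac read counts at the genomic loci of a low-copy TE family on
   tangle burden, adjusting for library size, batch, PMI, cross-correlation
   QC, age and sex.
5. **qPCR statistics** (`tead.qpcr`) — ΔΔCT relative quantification against
   a reference gene and reference group, one-way ANOVA per TE/time point,
   Welch post hoc tests vs control with star bands, two-way genotype × age
   ANOVA, and the same math for genomic-DNA relative copy number.
6. **Synthetic data** (`tead.simulate`) — generators for every input with
   known truth: TE families with shared sequence (hence genuine
   multi-mapping), cohorts with a skewed tangle outcome and planted per-TE
   or per-clade effects, Poisson ChIP count tables, and triplicate CT
   panels.

It is written for computational biologists who want to apply (or audit)
this analysis on their own cohorts, at desk scale, without restricted
data.

## The core models

**Quantification.** A read from TE *t* arrives with probability
∝ α_t / ℓ̃_t, where ℓ̃_t = max(L_t − r + 1, 1) is the effective length.
Read *i* with candidate set C_i gets fractional responsibility
γ_it = (α_t/ℓ̃_t) / Σ_{u∈C_i}(α_u/ℓ̃_u) (E-step); α_t ← Σ_i γ_it (M-step);
TPM_t = 10⁶ · (α_t/ℓ̃_t) / Σ_u(α_u/ℓ̃_u).

**Association.** For each TE, y = β₀ + β₁·tangles + β·covariates + ε; the
scan reports β₁, its t-statistic and two-sided p, and BH q-values.
Clade-level: for clade C, a one-sample t test of {t_j : j ∈ C} against
mean 0.

**ChIP.** log2(count + ½·libsize/10⁶) ~ tangles + log2(libsize) + batch +
PMI + cross-correlation + age + sex; the depth-scaled pseudocount makes
the tangle coefficient exactly invariant to a global rescaling of
sequencing depth.

**qPCR.** ΔCT = CT_target − CT_reference gene (within sample),
ΔΔCT = ΔCT − mean ΔCT of the reference group, fold = 2^(−ΔΔCT).

## Worked example

```python
import pandas as pd
from tead.simulate import SimulationConfig, simulate_library, simulate_reads
from tead.quant import QuantParams, build_index, quantify_reads

cfg = SimulationConfig(seed=1, n_te=50, ltr_fraction=0.6,
                       family_similarity=0.2, n_reads=100_000,
                       error_rate=0.0, te_length_range=(500, 3000))
library, truth = simulate_library(cfg)
rng = cfg.rng(97)
raw = rng.gamma(0.8, 1.0, size=50)
true_tpm = pd.Series(1e6 * raw / raw.sum(), index=library.te_ids)
reads, _ = simulate_reads(library, true_tpm, cfg)
est = quantify_reads(reads, build_index(library, 21), QuantParams(read_length=100))
print(est.diagnostics)
```

prints

```
QuantDiagnostics(n_reads_total=100000, n_assigned=100000, n_ambiguous=15434,
                 em_iterations=10, final_loglik=-327468.556...)
```

— all 100,000 error-free reads are assigned, 15% ambiguously (the shared
family blocks), and the EM resolves them: the log1p TPM correlation with
truth is r = 0.9988 here. The same objects feed the
association scan and clade test (see `analysis/04_clade_activation.py`
for the full chain).

The numbered scripts under `analysis/` drive each arm of the study on
synthetic inputs and write their tables under `results/`:

```bash
python analysis/01_simulate_library_and_reads.py --seed 1
python analysis/02_quantify_te_expression.py     --seed 1
python analysis/03_tangle_association_scan.py    --seed 1
python analysis/04_clade_activation.py           --seed 1
python analysis/05_hervfc1_chip_association.py   --seed 1
python analysis/06_fly_qpcr_panel.py             --seed 1
```

A thin CLI (`tead library validate`, `tead quant`, `tead associate`,
`tead clade-test`, `tead chip`, `tead qpcr`) wraps the same functions for
shell use.

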