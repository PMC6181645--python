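# Methods

This note documents the models implemented in `tead`, the defaults and
why, what the synthetic-data generators do and do not emulate, and the
numerical choices that matter.

## Quantification model

Consensus TE references (one representative sequence per family, with
class LTR / non-LTR and a clade label) are indexed by canonical k-mers:
each N-free window of length k is stored under the lexicographic minimum
of itself and its reverse complement, so the index is strand-agnostic.
Defaults: **k = 21** (odd, so a k-mer is never its own reverse
complement; long enough to be specific across unrelated consensi, short
enough that a 100-nt read with sub-percent error retains most of its
k-mers intact).

A read's candidate set contains every TE sharing at least
**min_hit_fraction = 0.5** of the read's distinct k-mers *and* lying
within **10%** of the best hit count (the tier rule). Near-ties are kept
deliberately: ambiguity is resolved by the EM, never by an arbitrary
choice. Reads shorter than k, or matching nothing, are unassigned and
counted in the diagnostics.

The abundance model is the standard transcript mixture. With effective
length ℓ̃_t = max(L_t − r + 1, 1) (the floor prevents division blow-ups
for consensi shorter than the read length):

- E-step: read i with candidates C_i gives TE t responsibility
  γ_it = (α_t/ℓ̃_t) / Σ_{u∈C_i} (α_u/ℓ̃_u);
- M-step: α_t ← Σ_i γ_it;
- initialization uniform; stop when max_t |Δα_t| / (assigned reads) <
  **tol = 1e-8** or **max_iter = 1000**.

Expected counts are the final α (they sum to the assigned-read count by
construction); TPM_t = 10⁶ (α_t/ℓ̃_t)/Σ_u(α_u/ℓ̃_u). Reads with identical
candidate sets are collapsed into equivalence classes, so runtime scales
with the number of distinct ambiguity patterns, not reads. The observed-
data log-likelihood Σ_i log Σ_{t∈C_i} θ_t is non-decreasing across
iterations (a tested invariant). Paired-end mates would be assigned
independently and counted as two observations; consensus references have
no fragment-level coordinates that would justify more.

The quantifier makes no claim about genomic locus of origin: assignment
is to the consensus family only.

## Association scan

Expression is processed as log2(TPM + 1) — pseudocount 1.0 bounds the
transform at 0 — and optionally batch-corrected by per-TE batch-mean
centering with the grand mean restored (batch may instead, or in
addition, enter the regression as a dummy-coded factor via
`batch_column`). Per TE, ordinary least squares of expression on
[intercept, outcome, covariates]; expression is the **response** and the
outcome (tangle burden by default; plaques, cognition or a diagnosis
indicator swap in by name) a predictor. The outcome term's β, SE,
t = β/SE and two-sided p (t distribution, n − p df) are reported, with
Benjamini–Hochberg q-values over the whole scan and a significance flag
at FDR < 0.1. Subjects with any missing model variable are dropped
listwise and the per-TE n reported. Degenerate fits (zero residual
variance) return the β with SE and p set to NaN — reporting p = 0 would
fabricate infinite evidence. A `sqrt_outcome` flag is available because
histologic count outcomes are right-skewed; untransformed is the default.
The whole scan is solved through one pseudo-inverse since all TEs share
the design matrix.

## Clade activation test

Per clade with at least **min_clade_size = 5** members (smaller sets make
a t test fragile; the floor is configurable and the end-to-end runs use
2), a two-sided one-sample t test of the member t-statistics against
mean 0. Raw p-values are reported by default, with an optional BH flag
across clades. The null of mean zero ignores the mild correlation between
per-TE statistics induced by shared subjects and by TPM compositionality;
this is a known caveat of the aggregation procedure and is documented
rather than corrected. `clade_summary_plot_data` emits boxplot-ready
quartiles, Tukey whiskers and the |t| cut of the FDR-significant TEs.

## ChIP-seq locus model

For a low-copy family whose loci can be enumerated (BED convention,
0-based half-open), each locus' counts are modeled on the log scale:

    log2(count + 0.5·libsize/10⁶) ~ tangles + log2(libsize) + batch
                                    + PMI + cross-correlation + age + sex

The pseudocount is **half a read per million**, i.e. proportional to
library size. With a fixed pseudocount, doubling every count and library
size would shift responses by slightly count-dependent amounts; with the
depth-scaled pseudocount the shift is exactly +1 for every sample and is
absorbed by the intercept and the log-libsize column, so the tangle
coefficient is exactly invariant to global depth rescaling (a tested
invariant). A quasi-Poisson alternative (`model="quasipoisson"`, log
libsize offset, X² scale) is provided; OLS on the log scale is the
default as the simpler of the two defensible readings of a "log-linear"
model. All-zero loci are reported as low-information with p = NaN rather
than tested. Multiple testing across loci uses BH at q < 0.1, matching
the transcriptome arm's convention.

## qPCR statistics

Technical replicate CTs are averaged within (sample, target) before any
delta. ΔCT pairs target and reference gene within sample; ΔΔCT subtracts
the reference group's mean ΔCT per target, so the reference group's fold
changes have geometric mean 1 by construction. Amplification efficiency
is fixed at 2.0 (no standard-curve data assumed), giving
fold = 2^(−ΔΔCT). Group tests run on the ΔΔCT (log) scale by default —
fold changes are log-normal-ish, so the linear-model assumptions fit the
log scale better; the fold scale remains available to the caller since
every row carries both. One-way ANOVA is the classical fixed-effects
decomposition; post hoc comparisons vs control use Welch's t test by
default (a pooled-variance flag exists) with star bands *p<0.05,
**p<0.01, ***p<0.001; the two-way genotype × age ANOVA uses Type II
(marginal) sums of squares so unbalanced data are handled, coinciding
with the sequential decomposition when balanced. Per-group SEM is exported
for mean ± SEM plotting. Genomic-DNA relative copy number reuses the
identical math with a different label.

## Synthetic-data generators

Every generator is a pure function of `SimulationConfig` (same seed, same
bytes); each draws from its own stream spawned from the master seed at a
fixed offset, so adding one generator never perturbs another. Truth
tables are emitted alongside every artifact.

- **Library**: families are founder sequences with a contiguous block
  (`family_similarity`, default 0.2 of the length) kept verbatim in every
  member and the rest redrawn per member — members share the block's
  k-mers exactly (real multi-mapping) and essentially nothing else.
  Default composition mirrors the human consensus set: 547 elements,
  366 LTR (ERV1/2/3, Gypsy, Copia) and 181 non-LTR (L1, SINE), lengths
  300–5000 nt.
- **Reads**: drawn per TE with probability ∝ TPM × effective length (so a
  correct quantifier recovers TPM), uniform starts, both strands,
  per-base substitution errors (default 0.5%), constant quality strings
  (qualities are ignored by contract).
- **Cohort**: tangle burden ~ Gamma(1.5, 4) — right-skewed and
  non-negative like averaged histologic counts; age at death ~ N(88, 6),
  PMI ~ Gamma(2, 3.5) hours, RIN ~ N(7, 1), 4 batches; expression on the
  log2-TPM scale = baseline + β·tangles + small covariate loadings +
  batch offsets + N(0, 0.5) noise; clade activation is a shared β shift
  across member TEs. Default n = 636 subjects, the cohort size of the
  motivating study.
- **ChIP**: counts ~ Poisson(libsize × locus rate × exp(effect·tangles +
  covariate terms)); defaults 13 loci × 675 samples, matching the
  low-copy-family design.
- **qPCR**: 3 genotypes × 3 ages × 12 fly TEs, 3 biological × 3 technical
  replicates; CT = reference CT + base ΔCT − planted log2 fold +
  biological (SD 0.25) and technical (SD 0.15) CT noise. The default
  planted pattern activates copia, het-a and gypsy 3–10× at day 20 with
  copia rising progressively with age.

**What the generators do not emulate**: real sequencing depth and quality
structure, splicing, genomic context or locus-level origin of TE reads,
cell-type composition, covariate–outcome confounding beyond linear
loadings, and PCR efficiency variation. Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability
of planted effects under the stated noise model — not that real cohorts
would yield any particular biological result.

## Problem sizes and numerical choices

- End-to-end recovery runs use a desk-scale configuration: 60 TEs over 7
  clades, a 10-member planted clade at +0.05 log2-TPM per tangle unit, 50
  subjects, 1200 reads per subject. The planted shift is deliberately
  moderate: TPM is compositional, and in a small TE-only universe a large
  activated clade mechanically depresses every other TE's TPM, planting a
  coherent spurious negative signal in the null clades. The per-TE
  regression t-statistics it produces (≈ 2–4) are of realistic magnitude.
- Oracle-equivalence checks run the EM at tol = 1e-12 / max_iter = 20,000
  against a plain-Python 10,000-iteration EM; agreement is required to
  1e-6 per TE. Slowly contracting instances (two TEs distinguished only
  by slightly different lengths) are the binding case for these settings.
- OLS is solved by pseudo-inverse with an explicit rank check that names
  collinear columns; BH is the exact step-up with validation that p ∈
  (0, 1].
- Ties in read assignment are never broken arbitrarily — near-ties stay
  in the candidate set for the EM.

## Known limitations

- Quantification is consensus-level pseudo-assignment, not selective
  alignment; no claim of equivalence with any specific aligner-based
  quantifier is made, and locus-of-origin resolution is out of scope.
- The clade test treats member t-statistics as exchangeable and
  independent under the null; correlated statistics inflate its type-I
  error in real data.
- The cohort generator plants linear effects on the log2-TPM scale;
  nonlinear dose-response or threshold effects are not modeled.
- Batch correction by mean-centering assumes batch is independent of the
  outcome; confounded designs need the factor-covariate route.
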