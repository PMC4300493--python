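# Methods

## The flow-conservation model

A translating ribosome occupies codon `(m, k)` for a dwell time `μ_mk`; at
steady state with no drop-off, the flow of ribosomes past every codon of
message `m` equals the protein synthesis rate `J_m`, so the footprint count
`d_mk` — the observable proxy for occupancy — is proportional to
`J_m · μ_mk`.  Inference proceeds in one pass:

1. **Fix the flow** to `D_m`, the mean raw count per codon of the gene.
2. **Transform counts**: add a pseudo-count of 1 (so empty positions carry
   information and logs exist), divide by the fixed flow, and rescale all
   genes by one global factor so the smallest included value is exactly 1.
   These are the `d'` the model trains on.
3. **Restrict training positions** to codons beyond the first 100 (beyond
   the first 25%, rounded up, for genes shorter than 100 codons): the early
   elongation region shows position effects that would otherwise bias the
   codon dwells.  Profiles cover sense codons only; the terminal stop codon
   is excluded at profile construction.  Genes of exactly 100 codons have
   an empty training region and receive flows via global dwells only.
4. **Fit dwells** by minimizing squared error in log space, with a soft
   penalty of weight `C` (default 100) tying each gene-level dwell to the
   global codon dwell through the occurrence-share weights `w_m^c`
   (Σ_m w_m^c = 1 per codon).  The log-Gaussian loss makes each per-codon
   subproblem a ridge-type linear system with an exact closed-form solution
   (the per-codon MLE is a weighted geometric mean, which is the loss's
   intent: geometric averaging resists count outliers).  Because the
   objective separates across codons once the flow is fixed, coordinate
   descent converges in a single sweep; the sweep loop, stopping rules
   (max |Δlog μ| < 5e-5 or |Δobjective| < 1e-5) and the objective trace are
   retained for the non-separable Poisson alternative.
5. **Recompute flows** as `J_m = Σ_k (c_mk/μ_mk)/L_m` over the whole gene,
   where `c_mk` are the pseudo-counted raw counts times the single global
   scale factor (flow normalization undone — dividing by `D_m` would cancel
   exactly the cross-gene flux information `J` exists to measure).  Codons
   without a gene-level dwell fall back to the global dwell.

Initialization recentres the baseline dwell estimates in log space on the
data mean of `d'` (recomputed per dataset rather than hardcoded) and adds a
seeded uniform ±0.01 log-space perturbation; with the closed-form solver the
optimum is exact and initialization-independent, which the tests assert via
bit-identical reruns and the global-only/C→∞ equivalence.

### Model variants

- `loss="poisson"`: data term `Σ (μ − d'·log μ)`, solved per codon by
  L-BFGS-B in log-parameter space.  Provided as the alternative reading of
  the objective; the log-Gaussian default carries the validation suite.
- `mode="per_position"`: a separate dwell per position, each tied to its
  codon's global dwell with weight `1/n_c`, initialized from `d_mk/D_m`
  with zeros replaced by the mean nonzero count; looser stopping
  tolerances (1e-2 / 1e-1) reflect the larger parameter count.
- `mode="global_only"`: only global codon dwells, no penalty term —
  equivalent to the `C→∞` limit of the default model (asserted to 1e-5).

### Baseline estimator

`baseline_dwells` averages `(d_mk + 1)/D_m` per codon over restricted
positions; rates are reciprocal dwells.  It initializes the model fit and
serves as the aggregate-style comparison method.

## Outlier model

Expected counts are `J_m · μ_m^c` on the same scaled axis as the observed
`c_mk`.  The noise scale `s_mk` is the ddof=1 standard deviation of
observed counts within an (abundance-bin, codon) cell; genes are binned
into abundance quantiles (abundance = `D_m`, 32 bins by default), and the
bin count automatically drops to the largest value for which every cell
holds ≥3 observations with nonzero spread.  Slow outliers have `Δ > T`;
non-outliers have `−1 < Δ < 1` (slow ones excluded); everything else —
including apparent fast outliers, which A-site ambiguity can fabricate —
is excluded from comparisons.

A candidate feature is "significant" only if Pearson and Spearman
correlations with `Δ` among slow outliers share one sign and reach
p < 0.05 at every threshold in {0, 0.5, 1, 1.5, 2, 2.5}, the per-codon
binned correlation is significant for ≥30 codons, and the sign matches the
slow-versus-non-outlier mean comparison.

On synthetic data, sensitivity/false-positive rates for injected pauses are
evaluated over the restricted region: outside it the model's expectations
rest on global-dwell fallback and are weaker by construction (in real data
that early region is where the biology of interest — 5' pausing — lives).
With 150 genes at depth 50, planted 10× pauses are recovered at ≥90%
sensitivity with ≤5% false positives at `T = 1`.

## TE comparison and the permutation test

`TE_m = J_m / M_m` over genes shared between samples.  Mutant comparisons
rank genes by `|log(TE_mut/TE_wt)|`, count reduced versus increased genes
among the top `n` (200 by default, ties at the boundary broken by gene id),
and compare the reduced-minus-increased difference against permutations of
the mutant TE values across genes.

A caveat established during validation: the across-gene permutation breaks
the wild-type/mutant pairing, which ties permuted ratio signs to wild-type
levels and concentrates the permutation distribution (its spread is ~40%
below the statistic's true sampling spread in the realistic regime where
between-gene TE variation exceeds mutant noise).  The resulting p-value is
anticonservative as a frequentist error rate (~0.10 at nominal 0.05) and
should be read as a plausibility reference — "is the observed imbalance
large even against random reassignment" — not as a calibrated test.  A
calibrated alternative would flip wild-type/mutant labels within genes;
it is deliberately not substituted, to keep the shipped procedure the
standard one.

## Kozak-motif TE regression

Standardized log TE is regressed on z-scored gene features plus the
sigmoid context feature `f = 1/(1+exp(x·g))`, where `g` one-hot encodes
the nine non-AUG positions of the 12-nt start context.  The objective
adds an L1 penalty `λ1‖w‖₁` and shrinkage `λ2(‖w‖₂² + ‖x‖₂²)`.  Fitting
alternates a scikit-learn elastic-net solve for `w` (unpenalized
intercept) with L-BFGS-B steps on `x`, to relative objective change
< 1e-5 or 100 alternations.  Decisions worth knowing:

- **Intercept and sign gauge.**  Flipping the sign of `x` maps `f` to
  `1−f`; with an intercept this is an exact reparametrization, so the
  motif's sign is a gauge.  After fitting, the motif is canonicalized
  (flip `x` and the Kozak weight if the latter is positive, folding the
  constant into the intercept) so preferred bases carry the largest
  weights and the PWM rule — shift each position's four weights so the
  minimum is 0, normalize by their sum — puts high probability on
  preferred bases.
- **Initialization.**  At `x = 0` the sigmoid column is constant, the
  elastic net zeroes its weight, and the alternation would never leave
  that saddle; `x` starts at small seeded Gaussian values instead.
- **The sigmoid column is not z-scored** (it is bounded in (0,1) and
  changes every `x`-step; re-standardizing it would make the alternation
  ill-defined).
- **Hyperparameters** come from a 5×5 grid ({1e-3..10}²) by 5-fold CV on
  the training split; the CV alternation budget equals the final-fit
  budget, because a shorter budget undertrains weakly regularized
  candidates and biases selection toward them.  The null model runs the
  complete pipeline — CV included — on training TE permuted among genes.
- **Test protocol**: a held-out set of 400 genes or 20% (whichever is
  smaller) per split, repeated over `n_splits` random splits; the reported
  motif averages the per-split canonicalized `x`.
- **Fixed-motif comparison**: the fixed weights are rescaled so each
  position's weight sum matches the learned motif's, computed in the PWM
  gauge (min-shifted weights) and re-centred — penalized learned motifs
  have near-zero raw per-position sums, under which a raw-sum match would
  scale any fixed motif into a constant feature.

The synthetic planted motif uses zero-mean per-position weights (preferred
base −0.75·strength, others +0.25·strength): an all-or-nothing motif
saturates the sigmoid for almost every random context and plants a nearly
constant, unidentifiable effect.  The planted-motif validation runs at
2400 genes so that the ~46 effective parameters are small against the
training size, mirroring the regime of a genome-scale dataset (~37
parameters against ~4600 training genes); at a few hundred genes the null
model's test error inflates by ~10% from overfitting alone, regardless of
implementation.

## DMS windows

Raw per-nucleotide DMS counts are normalized per 150-nt tile: the divisor
is the minimum count among the top 5% of A/C positions — boundary ties
included, since with tie-free counts a 150-nt window holds at most
`ceil(0.05·150) = 8` top positions and the ≥10-A/C mask rule could never
be met; with discrete counts the boundary value is routinely shared.
All values are divided by the divisor and capped at 1; windows with fewer
than 10 top A/C positions or a zero divisor are masked entirely, G/T
positions always (DMS does not report them).  Whole-gene windows (≥200
A/C) satisfy the ≥10 rule even with distinct counts and are what the
synthetic high-depth worlds use.

Sliding 40-nt window means (stride 1 nt, aligned to the start codon,
30 nt upstream to 250 downstream) are taken over non-missing positions,
normalized per gene by the gene's mean window value, and averaged across
genes.  TE correlations are Spearman per window position with Bonferroni
correction over the window count (280 reproduces the published span).
The structure dip is the first position at or downstream of the start
codon that is the minimum of its centred 90-nt span (half-open, clipped
at profile edges; ties break toward the smallest coordinate, so a flat
profile returns the first scanned position).

## Synthetic data: what it does and does not emulate

The generator draws global codon dwells log-normal (log-sd 0.5), per-gene
dwells log-normal around them (log-sd 0.2, mirroring the model's soft
constraint), fluxes and mRNA abundances log-normal (log-sd 0.5), and
Poisson footprint counts `d_mk ~ Poisson(depth · J_m · μ_m^c · fold)` with
optional planted pause folds.  It does **not** simulate ribosome
collisions or queueing, drop-off, library-preparation sequence bias, or
overdispersion beyond Poisson — so a green recovery test establishes that
the estimator inverts its own generative assumptions at realistic depth
and scale, not that it is robust to protocol artifacts.  Defaults (200
genes × ~300 codons, ~20 counts/codon for recovery; depth 50 for pause
detection) were chosen once to match the stated validation worlds.

## Numerical notes

- All randomness flows through `numpy.random.default_rng` seeds carried in
  the fit/simulation configurations; reruns are bit-identical.
- Fit tables are written at 17 significant digits and parsed with
  round-trip float precision, making write→read an identity.
- Codon iteration order is fixed lexicographic; abundance binning uses
  pandas quantile cuts; duplicate gene ids in any input are errors rather
  than silent overwrites.

## Known limitations

- The permutation test's reference distribution is not a calibrated null
  (see above).
- The dwell model treats positions independently given `(J, μ)`; strong
  ribosome interference (queueing) at high initiation rates violates this
  and is out of scope.
- Real A-site calibration varies between protocols; the 15/16/17-nt offset
  rule for 28–31-nt reads is fixed here.
- The feature-significance evaluator assumes features are available at
  every evaluated position; biological feature extraction (structure
  windows, wobble tables, nascent-peptide properties) is left to the user.
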