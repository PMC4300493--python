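# riboflow

Statistical inference of codon dwell times, protein synthesis rates and
translation efficiency from ribosome profiling data.

Ribosome profiling (ribo-seq) sequences the ~28–31 nt mRNA fragments
protected by translating ribosomes, giving codon-resolution counts `d_mk`
of ribosome occupancy at codon `k` of message `m`.  At steady state, with
no ribosome drop-off, conservation of matter forces the flow of ribosomes
through every codon of a message to equal its protein synthesis rate
`J_m`, so `d_mk ∝ J_m · μ_mk`, where `μ_mk` is the dwell time (inverse
elongation rate) at that codon.  `riboflow` fits this flow-conservation
model and everything the field builds on top of it:

- **Dwell-time inference** — one dwell `μ_m^c` per codon type `c` per gene,
  softly tied in log space to a global codon dwell `μ^c` by minimizing

  ```
  Σ_m Σ_{k∈K'_m} (log d'_mk − log μ_m^{c(m,k)})²
      + C · Σ_c Σ_m w_m^c (log μ_m^c − log μ^c)²
  ```

  over pseudo-counted, flow-normalized counts `d'`, with the first 100
  codons (25% for short genes) excluded from training and `w_m^c` the
  gene's share of codon `c`'s occurrences.  Each codon subproblem is solved
  in closed form; a Poisson quasi-likelihood, a per-position variant, and a
  global-only variant are available through the fit configuration.
- **Synthesis rates and TE** — `J_m = Σ_k (d_mk/μ_mk)/L_m` after fitting,
  and translation efficiency `TE_m = J_m / M_m` against mRNA abundance.
- **Pause detection** — outlier strength `Δ_mk = (observed − J_m μ_m^c)/s_mk`
  with noise scales `s_mk` estimated per abundance-quantile bin and codon;
  slow outliers (`Δ > T`), non-outliers (`−1 < Δ < 1`), and a stringent
  multi-threshold feature-significance evaluator.
- **Mutant comparisons** — per-codon correlations between TE changes and
  codon content, top-deviating-gene counts, and the across-gene TE
  permutation test.
- **Kozak-motif TE regression** — elastic-net regression of standardized
  log TE on gene features plus a learnable sigmoid context feature
  `f = 1/(1 + exp(x·g))` over the 12-nt start context (9 non-AUG positions,
  36 indicators), with cross-validated hyperparameters, a permuted-response
  null model, PWM export, and comparison against a fixed consensus motif
  (`WAMAMAATGTCY`).
- **DMS structure windows** — normalization of DMS probing counts to [0,1]
  reactivities in 150-nt windows, sliding-window profiles aligned to the
  start codon, Bonferroni-corrected TE correlations, and structure-dip
  localization.
- **Synthetic data** — generators for genomes, footprint datasets, TE
  datasets with planted motifs, and DMS tracks, all with known ground
  truth, used by the test suite for parameter-recovery checks.

## Worked example

```python
import riboflow as rf
from riboflow.flowmodel import FitConfig
from scipy import stats

genes = rf.synthdata.simulate_genome(100, mean_length=300, seed=1)
truth = rf.synthdata.simulate_dwells(genes, seed=2)
profiles = rf.synthdata.simulate_footprints(truth, depth=20.0)

fit = rf.fit_model(genes, profiles, FitConfig(C=100.0, seed=3))
codons = sorted(fit.mu_global)
print(stats.spearmanr([fit.mu_global[c] for c in codons],
                      [truth.mu_global[c] for c in codons]).statistic)
```

Running `examples/fit_dwell_times.py` (the same computation plus flux
recovery) prints:

```
fitted 61 global codon dwell times; objective 2291 -> 1045 over 2 sweeps
Spearman(fitted dwell, true dwell) = 0.997
Pearson(fitted flux, true flux)    = 0.996
fastest codon: AAT (rate 10.23x the slowest)
```

The Spearman value says the fitted global codon dwell times reproduce the
planted ranking almost exactly at ~20 counts per codon; the Pearson value
says the per-gene synthesis rates recover the planted fluxes; codon rates
are reciprocal dwells normalized so the slowest codon has rate 1.  The
other scripts in `examples/` demonstrate pause detection, mutant TE
comparison, Kozak-motif learning and the DMS window analyses, each printing
the numbers it computes and what they mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch: it simulates the 200-gene
recovery dataset at the stated depth, fits the model, reports dwell-time
and flux recovery, computes TE, and measures injected-pause sensitivity,
then writes the results JSON to `--out`.  All randomness derives from
`--seed`.

## Layout

```
src/riboflow/     ioformats, flowmodel, outliers, efficiency,
                  kozak_te, dmswindows, synthdata
examples/         one narrative script per capability
tests/            unit, property and acceptance suites
docs/methods.md   model assumptions, parameter choices, limitations
```
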