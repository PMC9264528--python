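# lfqimpute

Benchmarking missing-value imputation for label-free quantitative (LFQ)
proteomics, built around the data regime of a non-human-primate brain
study: ~45 samples, a few hundred proteins quantified in every sample, and
a much larger set with structured missingness.

LFQ intensity matrices routinely lose 10–50% of their cells to a mixture
of causes — random acquisition dropouts (MCAR), suppression of one
peptide's signal by another's abundance (MAR), and censoring below the
detection limit (MNAR). Whether a downstream age-association analysis can
be trusted after imputation depends on which algorithm filled the holes.
This package provides, as importable library code:

- **Synthetic cohorts** (`lfqimpute.synth`) — log2-intensity matrices with
  equicorrelated protein blocks, per-protein baselines, a linear age effect
  on a fraction of proteins, and optional built-in missingness with a
  hidden truth layer.
- **Missingness injection** (`lfqimpute.missingness`) — MCAR, MAR, MNAR
  and their sequential mixture at a target global rate, with full
  deleted-cell bookkeeping.
- **Ten single-imputation methods** (`lfqimpute.impute_si`) — zero, mean,
  KNN, sequential KNN, iterative SVD, Bayesian PCA (EM with automatic
  relevance determination), local least squares, generalized ridge
  regression, missForest-style iterative random forests, and sequential
  robust regression — all behind one registry that guarantees observed
  cells pass through bit-exact.
- **Multiple imputation** (`lfqimpute.impute_mi`) — chained equations with
  Bayesian-normal or random-forest conditional models, and Rubin's-rules
  pooling with Barnard–Rubin degrees of freedom.
- **Evaluation statistics** (`lfqimpute.evaluate`) — per-cell percent bias
  `100·|imputed − true|/|true|` and the fraction of cells under a 5%
  threshold; per-protein OLS age regressions (slope β, SE, p); Cronbach's
  α = k/(k−1)·(1 − Σσ²ᵢ/σ²ₜ) over proteins-as-items; one-sample t-tests
  with Bonferroni correction on imputed-vs-truth deltas; and a
  leave-one-out structural evaluation for matrices with built-in
  missingness.

The numbered scripts under `analysis/` run the four studies end to end
(accuracy screen, regression bias, α bias, random-forest deep dive) and
write their tables under `results/`.

## Worked example

```python
import numpy as np
from lfqimpute import (SyntheticConfig, MissingnessSpec, SIMethodParams,
                       generate_complete_dataset, inject, impute,
                       percent_bias_array, fraction_correct)

cfg = SyntheticConfig(seed=1)                  # 296 proteins x 45 samples
complete, meta = generate_complete_dataset(cfg)

spec = MissingnessSpec(mechanism="MIX", global_rate=0.2, seed=3)
injection = inject(complete, spec)
print(f"deleted {len(injection.deleted_cells)} cells "
      f"(realized rate {injection.realized_global_rate:.3f})")

imputed = impute(injection.masked_matrix,
                 SIMethodParams(method="grr"))
imp = np.array([imputed.values[i, j] for i, j in injection.cells()])
bias = percent_bias_array(imp, injection.truth_values())
print(f"fraction correct (<5% bias): {fraction_correct(bias):.3f}")
```

prints

```
deleted 2664 cells (realized rate 0.200)
fraction correct (<5% bias): 0.866
```

2664 cells is exactly 20% of the 296×45 grid; 86.6% of the deleted cells
were restored within 5% of their true log2 intensity by generalized ridge
regression over correlated neighbor proteins. Restricted to cells in
proteins missing ≤30% of their values (the regime in which imputation is
advisable at all), the same run scores 0.99.

A command-line interface mirrors the library
(`lfqimpute simulate | inject | impute | evaluate | run-experiment`).

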