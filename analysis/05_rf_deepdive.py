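#!/usr/bin/env python
"""In-depth evaluation of Random Forest imputation on structured data.

Part A — leave-one-out accuracy: on a 200-protein matrix with ~25%
built-in mixture missingness (proteins capped at 75% missing), masks one
observed cell at a time, imputes the whole matrix with RF, and summarizes
percent bias by the protein-missingness stratum of the masked cell.  The
question: at what per-protein missingness does RF accuracy deteriorate?

Part B — correlation distortion: over global missingness rates 10-60%,
compares Cronbach's alpha of the imputed matrix with the true complete
matrix to measure how strongly (and in which direction) RF's
conditional-mean fills shift the inter-protein correlation structure as
missingness grows. On this generator's block-structured data the shift is
a deflation that steepens with the rate; on data whose per-protein levels
are more stable across samples the same mechanism inflates alpha instead.

Writes results/rf_loo_records.tsv, results/rf_loo_summary.tsv and
results/rf_alpha_shift.tsv.
"""

from pathlib import Path

import pandas as pd

from lfqimpute import (MissingnessSpec, SIMethodParams, SyntheticConfig,
                       cronbach_alpha, generate_complete_dataset, impute,
                       inject)
from lfqimpute.experiments import rf_deepdive

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = SyntheticConfig(n_proteins=200, seed=2024)
    records, summary = rf_deepdive(cfg, rate=0.25, n_iter=100, master_seed=5,
                                   rf_trees=20)
    records.to_csv(OUT / "rf_loo_records.tsv", sep="\t", index=False)
    summary.to_csv(OUT / "rf_loo_summary.tsv", sep="\t", index=False)
    print("leave-one-out percent bias by protein-missingness stratum:")
    print(summary.round(3).to_string(index=False))

    complete, _ = generate_complete_dataset(SyntheticConfig(seed=2024))
    true_alpha = cronbach_alpha(complete)
    rows = []
    for rate in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6):
        masked = inject(complete, MissingnessSpec("MIX", rate, seed=9)) \
            .masked_matrix
        imputed = impute(masked, SIMethodParams(method="rf", n_trees=30,
                                                max_iter=3, seed=1))
        imp_alpha = cronbach_alpha(imputed)
        rows.append({"rate": rate, "true_alpha": true_alpha,
                     "imputed_alpha": imp_alpha,
                     "delta_alpha": imp_alpha - true_alpha})
    inflation = pd.DataFrame(rows)
    inflation.to_csv(OUT / "rf_alpha_shift.tsv", sep="\t", index=False)
    print("\nalpha shift vs global missingness rate:")
    print(inflation.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
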