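"""Bias and accuracy statistics for imputation evaluation.

The per-cell statistic is percent bias, 100 * |imputed - true| / |true|;
cells with bias below a threshold (5% by default) count as correctly
imputed.  Downstream bias is measured by comparing per-protein age
regressions and Cronbach's alpha between truth and imputed data, with
one-sample t-tests (Bonferroni-corrected) on the deltas, and by a
leave-one-out structural evaluation that masks one observed cell at a
time in a matrix with built-in missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .impute_si import SIMethodParams, impute
from .matrix import AbundanceMatrix, SampleMetadata, ValidationError
from .missingness import DEFAULT_BINS, InjectionResult, protein_stratum
from .synth import StructuredDataset

ZERO_TRUTH_EPS = 1e-12


def percent_bias(imputed_value: float, true_value: float) -> float:
    """100 * |imputed - true| / |true|; +inf when the truth is ~0."""
    if not math.isfinite(true_value):
        raise ValidationError("true value must be finite")
    if abs(true_value) < ZERO_TRUTH_EPS:
        return math.inf
    return 100.0 * abs(imputed_value - true_value) / abs(true_value)


def percent_bias_array(imputed: np.ndarray, true: np.ndarray) -> np.ndarray:
    imputed = np.asarray(imputed, dtype=float)
    true = np.asarray(true, dtype=float)
    if not np.isfinite(true).all():
        raise ValidationError("true values must be finite")
    out = np.full(true.shape, np.inf)
    ok = np.abs(true) >= ZERO_TRUTH_EPS
    out[ok] = 100.0 * np.abs(imputed[ok] - true[ok]) / np.abs(true[ok])
    return out


def fraction_correct(biases: Sequence[float], threshold: float = 5.0) -> float:
    """Proportion of biases strictly below the threshold (zero-truth cells,
    flagged as infinite bias, never count as correct)."""
    b = np.asarray(list(biases), dtype=float)
    if b.size == 0:
        raise ValidationError("fraction_correct undefined for an empty list")
    return float((b < threshold).mean())


# ---------------------------------------------------------------------------
# per-protein age regressions

def regress_covariate(m: AbundanceMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """OLS of each protein's abundance on age: slope, SE, two-sided p.

    Vectorized closed-form normal equations; requires a complete matrix and
    at least 3 samples.
    """
    if m.n_missing:
        raise ValidationError("regression requires a complete (imputed) matrix")
    if m.n_samples < 3:
        raise ValidationError("regression requires >= 3 samples")
    meta = meta.aligned_to(m)
    x = meta.age
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValidationError("zero age variance")
    y = m.values
    beta = (y @ xc) / sxx
    intercept = y.mean(axis=1) - beta * x.mean()
    resid = y - (intercept[:, None] + beta[:, None] * x[None, :])
    dof = m.n_samples - 2
    mse = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(mse / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2 * stats.t.sf(np.abs(tstat), dof), 1.0)
    return pd.DataFrame({"protein": m.protein_ids, "beta": beta, "se": se,
                         "p": p}).set_index("protein")


def compare_regressions(truth_fits: pd.DataFrame,
                        imputed_fits: pd.DataFrame) -> pd.DataFrame:
    """Per-protein deltas (imputed - truth) of slope and p-value.

    ``imputed_fits`` may come from :func:`regress_covariate` (SI) or from
    Rubin-pooled MI estimates; it only needs ``beta`` and ``p`` columns.
    """
    common = truth_fits.index.intersection(imputed_fits.index)
    if len(common) == 0:
        raise ValidationError("no shared proteins between the two fits")
    t = truth_fits.loc[common]
    i = imputed_fits.loc[common]
    return pd.DataFrame({
        "true_beta": t["beta"], "imputed_beta": i["beta"],
        "true_p": t["p"], "imputed_p": i["p"],
        "delta_beta": i["beta"] - t["beta"],
        "delta_p": i["p"] - t["p"],
    }, index=common)


# ---------------------------------------------------------------------------
# internal consistency

def cronbach_alpha(m: AbundanceMatrix | np.ndarray) -> float:
    """Cronbach's alpha with proteins as items and samples as observations:
    alpha = k/(k-1) * (1 - sum(item variances) / var(total score))."""
    values = m.values if isinstance(m, AbundanceMatrix) else np.asarray(m, float)
    if not np.isfinite(values).all():
        raise ValidationError("Cronbach's alpha requires complete data")
    k = values.shape[0]
    if k < 2:
        raise ValidationError("Cronbach's alpha requires >= 2 items")
    item_var = values.var(axis=1, ddof=1)
    total_var = values.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise ValidationError("zero total-score variance")
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))


# ---------------------------------------------------------------------------
# bias t-tests

@dataclass(frozen=True)
class BiasTest:
    t: float
    p: float
    p_bonferroni: float
    significant_05: bool
    significant_001: bool


def bias_ttest(deltas: Sequence[float], alpha_level: float = 0.05,
               n_tests: int = 1) -> BiasTest:
    """One-sample t-test of the deltas against 0 with Bonferroni correction
    over ``n_tests`` grid cells."""
    d = np.asarray(list(deltas), dtype=float)
    if d.size < 2:
        raise ValidationError("bias t-test requires >= 2 deltas")
    if d.std(ddof=1) == 0:
        p = 1.0 if d.mean() == 0 else 0.0
        t = 0.0 if d.mean() == 0 else math.inf * np.sign(d.mean())
    else:
        t, p = stats.ttest_1samp(d, 0.0)
        t, p = float(t), float(p)
    p_bonf = min(1.0, p * n_tests)
    return BiasTest(t, p, p_bonf, p_bonf < alpha_level, p_bonf < 0.001)


# ---------------------------------------------------------------------------
# injection-based accuracy

def evaluate_injection(imputed: AbundanceMatrix, injection: InjectionResult,
                       threshold: float = 5.0,
                       bins: Iterable[float] = DEFAULT_BINS) -> pd.DataFrame:
    """Per-deleted-cell record of truth, imputed value, percent bias and
    the protein-missingness stratum of the cell's protein."""
    rows = []
    n = imputed.n_samples
    for c in injection.deleted_cells:
        imp = imputed.values[c.protein, c.sample]
        rows.append({
            "protein": imputed.protein_ids[c.protein],
            "sample": imputed.sample_ids[c.sample],
            "true_value": c.true_value,
            "imputed_value": imp,
            "percent_bias": percent_bias(imp, c.true_value),
            "mechanism": c.mechanism,
            "protein_missing_fraction": injection.per_protein_rates[c.protein],
            "stratum": protein_stratum(injection.per_protein_rates[c.protein], bins),
        })
    df = pd.DataFrame(rows)
    df.attrs["fraction_correct"] = fraction_correct(df["percent_bias"], threshold) \
        if len(df) else float("nan")
    df.attrs["n_zero_truth"] = int(np.isinf(df["percent_bias"]).sum()) if len(df) else 0
    return df


# ---------------------------------------------------------------------------
# leave-one-out structural evaluation

def loo_structural_eval(dataset: StructuredDataset, params: SIMethodParams,
                        n_iter: int = 10000,
                        rng: np.random.Generator | None = None,
                        ) -> pd.DataFrame:
    """Mask one observed cell at a time in a matrix with built-in
    missingness, impute the whole matrix, and record truth vs imputed.

    Cells are drawn uniformly without replacement; the matrix is restored
    after every iteration.  The recorded protein missing fraction includes
    the newly masked point (the state the imputer saw).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    work = dataset.observed.copy()
    obs_cells = np.flatnonzero(work.mask.ravel())
    if n_iter > obs_cells.size:
        raise ValidationError(
            f"n_iter={n_iter} exceeds the {obs_cells.size} observed cells")
    picks = obs_cells[rng.permutation(obs_cells.size)[:n_iter]]
    n = work.n_samples
    rows = []
    for flat in picks:
        i, j = divmod(int(flat), n)
        true = work.values[i, j]
        work.values[i, j] = np.nan
        frac = (~np.isfinite(work.values[i])).sum() / n
        imp = impute(work, params).values[i, j]
        work.values[i, j] = true
        rows.append({
            "protein": work.protein_ids[i], "sample": work.sample_ids[j],
            "true_value": true, "imputed_value": imp,
            "percent_bias": percent_bias(imp, true),
            "protein_missing_fraction": frac,
            "stratum": protein_stratum(frac),
        })
    return pd.DataFrame(rows)


def summarize_loo(records: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum mean/median percent bias and fraction-correct."""
    finite = records[np.isfinite(records["percent_bias"])]
    grp = finite.groupby("stratum")["percent_bias"]
    out = grp.agg(["count", "mean", "median"])
    out["fraction_correct"] = grp.apply(lambda b: float((b < 5.0).mean()))
    return out.reset_index()
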