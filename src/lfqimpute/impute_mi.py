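"""Multiple imputation by chained equations and Rubin's-rules pooling.

Two conditional models are available for the chained-equations cycle:

* ``mice_norm`` — Bayesian normal linear regression: coefficients and the
  residual variance are drawn from their posterior before predicting, so
  imputations carry parameter uncertainty.
* ``mice_rf`` — random-forest prediction with a random draw from the
  terminal-node donors of a random tree, the non-parametric analogue.

By default every other protein is a predictor (no predictor selection),
which makes the conditional system singular once the number of proteins
reaches the number of samples — raised as :class:`SingularSystemError`
rather than silently regularized, because that failure regime is part of
what the pipeline measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .matrix import AbundanceMatrix, ValidationError

MI_METHODS = ("mice_norm", "mice_rf")


class SingularSystemError(RuntimeError):
    """The conditional regression system is computationally singular.

    Raised when a chained-equations design matrix has more columns than
    rows or is rank-deficient; reducing the number of predictor proteins
    (variable selection) is the standard remedy.
    """

    def __init__(self, n_predictors: int, n_rows: int):
        super().__init__(
            f"system is computationally singular: {n_predictors} predictors "
            f"(+ intercept) for {n_rows} observed samples; reduce the number "
            f"of proteins or enable predictor selection")
        self.n_predictors = n_predictors
        self.n_rows = n_rows


@dataclass
class MIResult:
    """m completed matrices sharing all observed cells."""

    imputations: list[AbundanceMatrix]
    method: str
    maxit: int
    converged: list[bool] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.imputations)


def _norm_draw(x_obs: np.ndarray, y_obs: np.ndarray, x_mis: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """mice's Bayesian normal draw: sample (sigma^2, beta) from the posterior
    under the noninformative prior, then predict missing rows with noise."""
    from scipy.linalg import solve_triangular

    n, k = x_obs.shape
    design = np.hstack([np.ones((n, 1)), x_obs])
    q = design.shape[1]
    if q > n:
        raise SingularSystemError(k, n)
    qmat, rmat = np.linalg.qr(design)
    diag = np.abs(np.diag(rmat))
    if diag.min() < 1e-10 * max(diag.max(), 1e-300):
        raise SingularSystemError(k, n)
    beta_hat = solve_triangular(rmat, qmat.T @ y_obs)
    resid = y_obs - design @ beta_hat
    dof = max(n - q, 1)
    sigma2_star = float(resid @ resid) / rng.chisquare(dof)
    # R^-1 z has covariance (X'X)^-1, the posterior covariance factor
    beta_star = beta_hat + np.sqrt(sigma2_star) * solve_triangular(
        rmat, rng.standard_normal(q))
    design_mis = np.hstack([np.ones((x_mis.shape[0], 1)), x_mis])
    return design_mis @ beta_star + rng.normal(0.0, np.sqrt(sigma2_star),
                                               size=x_mis.shape[0])


def _rf_draw(x_obs: np.ndarray, y_obs: np.ndarray, x_mis: np.ndarray,
             rng: np.random.Generator, n_trees: int = 10) -> np.ndarray:
    """mice.impute.rf-style draw: for each missing row pick a random tree
    and draw one donor from that tree's terminal node."""
    rf = RandomForestRegressor(n_estimators=n_trees, max_features=0.33,
                               random_state=int(rng.integers(2 ** 31)))
    rf.fit(x_obs, y_obs)
    leaves_obs = rf.apply(x_obs)           # n_obs x n_trees
    leaves_mis = rf.apply(x_mis)
    out = np.empty(x_mis.shape[0])
    for r in range(x_mis.shape[0]):
        t = int(rng.integers(n_trees))
        donors = np.flatnonzero(leaves_obs[:, t] == leaves_mis[r, t])
        if donors.size == 0:               # fall back to the tree prediction
            out[r] = rf.estimators_[t].predict(x_mis[r:r + 1])[0]
        else:
            out[r] = y_obs[int(rng.choice(donors))]
    return out


def mice_impute(m: AbundanceMatrix, method: str = "mice_norm",
                n_imputations: int = 5, maxit: int = 5,
                seed: int = 0,
                predictor_top_k: int | None = None) -> MIResult:
    """Chained-equations multiple imputation with ``n_imputations`` runs.

    ``predictor_top_k`` optionally restricts each protein's predictors to
    its top-k absolutely-correlated proteins (off by default, reproducing
    the all-predictor regime).
    """
    if method not in MI_METHODS:
        raise ValidationError(f"unknown MI method {method!r}")
    if n_imputations < 2:
        raise ValidationError("n_imputations must be >= 2")
    if m.n_proteins < 2:
        raise ValidationError("MICE requires at least 2 proteins")
    if (m.mask.sum(axis=1) < 2).any():
        raise ValidationError("every protein needs >= 2 observed values")

    obs = m.mask
    miss_rows = np.flatnonzero(~obs.all(axis=1))
    predictors: dict[int, np.ndarray] = {}
    for i in miss_rows:
        others = np.delete(np.arange(m.n_proteins), i)
        if predictor_top_k is not None and predictor_top_k < others.size:
            both = obs[i][None, :] & obs[others]
            corr = np.zeros(others.size)
            y = m.values[i]
            for t, l in enumerate(others):
                sel = both[t]
                if sel.sum() < 3:
                    continue
                a, b = y[sel], m.values[l, sel]
                if a.std() == 0 or b.std() == 0:
                    continue
                corr[t] = abs(np.corrcoef(a, b)[0, 1])
            others = others[np.argsort(corr)[::-1][:predictor_top_k]]
        predictors[int(i)] = others

    root = np.random.SeedSequence(seed)
    imputations, converged = [], []
    for child in root.spawn(n_imputations):
        rng = np.random.default_rng(child)
        filled = m.values.copy()
        for i in miss_rows:                 # init: draws from observed values
            k = int((~obs[i]).sum())
            filled[i, ~obs[i]] = rng.choice(m.values[i, obs[i]], size=k, replace=True)
        for _ in range(maxit):
            for i in miss_rows:
                sel = predictors[int(i)]
                x = filled[sel].T
                y_rows = obs[i]
                if method == "mice_norm":
                    filled[i, ~y_rows] = _norm_draw(x[y_rows], m.values[i, y_rows],
                                                    x[~y_rows], rng)
                else:
                    filled[i, ~y_rows] = _rf_draw(x[y_rows], m.values[i, y_rows],
                                                  x[~y_rows], rng)
        out = m.with_values(filled)
        imputations.append(out)
        converged.append(True)
    return MIResult(imputations, method, maxit, converged)


@dataclass
class PooledEstimate:
    """Rubin's-rules pooled inference for one coefficient."""

    estimate: float      # pooled estimate, mean of the m estimates
    within_var: float    # mean squared standard error
    between_var: float   # sample variance of the estimates
    total_var: float     # within + (1 + 1/m) * between
    df: float            # Barnard-Rubin degrees of freedom
    p_value: float
    std_error: float = field(init=False)

    def __post_init__(self) -> None:
        self.std_error = float(np.sqrt(self.total_var))


def pool_rubin(estimates: list[float], std_errors: list[float],
               df_com: float | None = None) -> PooledEstimate:
    """Pool m complete-data estimates and standard errors by Rubin's rules.

    ``df_com`` is the complete-data degrees of freedom (n - parameters);
    when given, the Barnard-Rubin small-sample adjustment is applied.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(std_errors, dtype=float)
    n_imp = est.size
    if n_imp < 2:
        raise ValidationError("pooling requires m >= 2 estimates")
    if (se < 0).any():
        raise ValidationError("standard errors must be non-negative")
    qbar = float(est.mean())
    ubar = float((se ** 2).mean())
    b = float(est.var(ddof=1))
    t_var = ubar + (1 + 1 / n_imp) * b

    if t_var == 0:
        return PooledEstimate(qbar, ubar, b, t_var, np.inf,
                              1.0 if qbar == 0 else 0.0)
    lam = (1 + 1 / n_imp) * b / t_var
    if lam <= 0:
        df = df_com if df_com is not None else np.inf
    else:
        df_old = (n_imp - 1) / lam ** 2
        if df_com is None:
            df = df_old
        else:
            df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            df = df_old * df_obs / (df_old + df_obs)
    stat = qbar / np.sqrt(t_var)
    if np.isinf(df):
        p = 2 * stats.norm.sf(abs(stat))
    else:
        p = 2 * stats.t.sf(abs(stat), df)
    return PooledEstimate(qbar, ubar, b, t_var, float(df), float(p))
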