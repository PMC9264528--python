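"""Single-imputation algorithms behind a uniform method registry.

Implemented methods (proteins are the imputation unit, samples the
observations):

* ``zero`` / ``mean`` — constant fills (0, per-protein observed mean).
* ``knn`` — per-cell average of the k nearest proteins by Euclidean
  distance over shared observed samples.
* ``seqknn`` — sequential KNN: proteins imputed in order of increasing
  missingness against a growing set of complete proteins.
* ``svd`` — iterative rank-r SVD reconstruction from a mean-filled start.
* ``bpca`` — variational Bayesian probabilistic PCA with automatic
  relevance determination; missing cells take their posterior-mean
  reconstruction.
* ``lls`` — local least squares on the k most-correlated neighbor proteins.
* ``grr`` — the same neighbor regression with per-component (generalized)
  ridge penalties chosen by the Hoerl-Kennard rule.
* ``impseq`` — sequential robust (Huber) regression imputation ordered by
  missingness.
* ``rf`` — missForest-style iterative random-forest imputation (median
  initial fill, visits proteins by increasing missingness, stops when the
  change in imputed values first increases).

All methods leave originally observed cells bit-exact and are deterministic
given their parameters (``rf`` given its seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .matrix import AbundanceMatrix, ValidationError

SI_METHODS = ("zero", "mean", "knn", "seqknn", "svd", "bpca", "lls", "grr",
              "rf", "impseq")


class ImputationFailure(RuntimeError):
    """A method could not complete; carries the method name."""

    def __init__(self, method: str, message: str):
        super().__init__(f"{method}: {message}")
        self.method = method


@dataclass(frozen=True)
class SIMethodParams:
    """Tuning parameters shared by the single-imputation registry."""

    method: str = "rf"
    k_neighbors: int = 10          # knn / seqknn / lls / grr / impseq
    rank: int | None = None        # svd / bpca; None -> min(dims) - 1
    max_iter: int = 10             # rf / svd / bpca
    tol: float = 1e-3              # relative-change stopping tolerance
    ridge_lambda: float | None = None  # grr; None -> generalized (per-component)
    n_trees: int = 100             # rf ensemble size
    seed: int = 0                  # rf

    def __post_init__(self) -> None:
        if self.method not in SI_METHODS:
            raise ValidationError(f"unknown method {self.method!r}; "
                                  f"choose from {SI_METHODS}")
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.ridge_lambda is not None and self.ridge_lambda < 0:
            raise ValidationError("ridge_lambda must be non-negative")


@dataclass
class ImputationResult:
    """One completed matrix plus method provenance."""

    matrix: AbundanceMatrix
    method: str
    params: SIMethodParams
    n_iter: int = 0
    converged: bool = True
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers

def _resolved_rank(params: SIMethodParams, shape: tuple[int, int],
                   saturation_cap: bool = False) -> int:
    """Default rank is min(dims) - 1; for the probabilistic model it is
    capped at 2/3 of that, because a factor count approaching the number
    of samples lets the model interpolate every protein profile and the
    noise variance collapses to zero (ARD prunes downward from the cap)."""
    cap = min(shape) - 1
    if params.rank is None:
        r = max(cap, 1)
        if saturation_cap:
            r = max(2 * r // 3, min(r, 2))
        return r
    if params.rank > min(shape):
        raise ValidationError("rank must not exceed min(n_proteins, n_samples)")
    return params.rank


def _pairwise_complete_corr(values: np.ndarray, target: int) -> np.ndarray:
    """|Pearson r| between the target protein and every other protein,
    computed on pairwise-complete observations."""
    p, _ = values.shape
    t = values[target]
    out = np.zeros(p)
    t_obs = np.isfinite(t)
    for l in range(p):
        if l == target:
            continue
        both = t_obs & np.isfinite(values[l])
        if both.sum() < 3:
            continue
        a, b = t[both], values[l][both]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        out[l] = abs(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return out


# ---------------------------------------------------------------------------
# constant fills

def _zero_fill(values: np.ndarray, params: SIMethodParams) -> tuple[np.ndarray, dict]:
    out = values.copy()
    out[~np.isfinite(out)] = 0.0
    return out, {}


def _mean_fill(values: np.ndarray, params: SIMethodParams) -> tuple[np.ndarray, dict]:
    out = values.copy()
    means = np.nanmean(out, axis=1)
    idx = np.where(~np.isfinite(out))
    out[idx] = means[idx[0]]
    return out, {}


def _median_fill(values: np.ndarray) -> np.ndarray:
    out = values.copy()
    med = np.nanmedian(out, axis=1)
    idx = np.where(~np.isfinite(out))
    out[idx] = med[idx[0]]
    return out


# ---------------------------------------------------------------------------
# k-nearest-neighbour family

def _knn_distances(values: np.ndarray, target: int) -> np.ndarray:
    """RMS difference over shared observed samples; inf when none shared."""
    diff2 = (values - values[target]) ** 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = np.sqrt(np.nanmean(diff2, axis=1))
    d[target] = np.inf
    d[~np.isfinite(d)] = np.inf
    return d


def _knn_fill(values: np.ndarray, params: SIMethodParams) -> tuple[np.ndarray, dict]:
    out = values.copy()
    k = params.k_neighbors
    for i in np.flatnonzero(~np.all(np.isfinite(values), axis=1)):
        d = _knn_distances(values, i)
        for j in np.flatnonzero(~np.isfinite(values[i])):
            cand = np.flatnonzero(np.isfinite(values[:, j]) & np.isfinite(d))
            if cand.size == 0:
                raise ImputationFailure("knn", f"no neighbor observed at sample {j} "
                                               f"for protein {i}")
            chosen = cand[np.argsort(d[cand])[:k]]
            out[i, j] = values[chosen, j].mean()
    return out, {}


def _seqknn_fill(values: np.ndarray, params: SIMethodParams) -> tuple[np.ndarray, dict]:
    out = values.copy()
    complete = np.flatnonzero(np.all(np.isfinite(values), axis=1))
    incomplete = np.flatnonzero(~np.all(np.isfinite(values), axis=1))
    if complete.size == 0:
        raise ImputationFailure("seqknn", "no complete proteins to seed the "
                                          "sequential neighbor pool")
    pool = list(complete)
    order = incomplete[np.argsort((~np.isfinite(values[incomplete])).sum(axis=1))]
    k = params.k_neighbors
    notes = []
    if complete.size < k:
        notes.append(f"only {complete.size} complete proteins for k={k}; using all")
    for i in order:
        obs = np.isfinite(out[i])
        pool_arr = np.asarray(pool)
        d = np.sqrt(((out[pool_arr][:, obs] - out[i, obs]) ** 2).mean(axis=1))
        chosen = pool_arr[np.argsort(d)[:k]]
        for j in np.flatnonzero(~obs):
            out[i, j] = out[chosen, j].mean()
        pool.append(int(i))
    return out, {"notes": notes} if notes else {}


# ---------------------------------------------------------------------------
# global-structure family

def _svd_fill(values: np.ndarray, params: SIMethodParams) -> tuple[np.ndarray, dict]:
    rank = _resolved_rank(params, values.shape)
    miss = ~np.isfinite(values)
    filled = _mean_fill(values, params)[0]
    n_iter, converged = 0, False
    for n_iter in range(1, params.max_iter + 1):
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
        prev = filled[miss].copy()
        filled[miss] = recon[miss]
        denom = np.linalg.norm(prev)
        change = np.linalg.norm(filled[miss] - prev) / (denom if denom else 1.0)
        if change < params.tol:
            converged = True
            break
    return filled, {"n_iter": n_iter, "converged": converged}


def _bpca_fill(values: np.ndarray, params: SIMethodParams) -> tuple[np.ndarray, dict]:
    """EM for probabilistic PCA with missing data and ARD priors on the
    factor loadings (variational Bayesian PCA in the Oba et al. style).

    Proteins are the observations, samples the dimensions; only observed
    cells enter the E- and M-steps.  Missing cells take their posterior-mean
    reconstruction mu_j + w_j . E[z_i].
    """
    p, n = values.shape
    q = _resolved_rank(params, values.shape, saturation_cap=True)
    obs = np.isfinite(values)
    miss = ~obs

    filled = _mean_fill(values, params)[0]
    mu = filled.mean(axis=0)
    x = filled - mu
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    w = (vt[:q].T * (s[:q] / np.sqrt(p)))          # n x q loadings
    resid = x - (u[:, :q] * s[:q]) @ vt[:q]
    sigma2 = max(float((resid ** 2).mean()), 1e-10)
    alpha = np.ones(q)

    ez = np.zeros((p, q))
    prev_imp = filled[miss].copy()
    n_iter, converged = 0, False
    for n_iter in range(1, params.max_iter + 1):
        ezz_all = np.empty((p, q, q))
        cov_cache: dict[bytes, np.ndarray] = {}
        for i in range(p):
            o = obs[i]
            key = o.tobytes()
            if key not in cov_cache:
                wo = w[o]
                cov_cache[key] = np.linalg.inv(wo.T @ wo + sigma2 * np.eye(q))
            minv = cov_cache[key]
            ez[i] = minv @ w[o].T @ (values[i, o] - mu[o])
            ezz_all[i] = sigma2 * minv + np.outer(ez[i], ez[i])

        # M-step: mean, loadings (per sample-dimension), noise
        recon = ez @ w.T                            # p x n
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(np.where(obs, values - recon, np.nan), axis=0)
        for j in range(n):
            rows = np.flatnonzero(obs[:, j])
            a = ezz_all[rows].sum(axis=0) + sigma2 * np.diag(alpha)
            b = (values[rows, j] - mu[j]) @ ez[rows]
            w[j] = np.linalg.solve(a, b)
        recon = ez @ w.T
        err = 0.0
        for i in range(p):
            o = obs[i]
            r = values[i, o] - mu[o] - recon[i, o]
            cov_i = ezz_all[i] - np.outer(ez[i], ez[i])
            err += float((r ** 2).sum() + np.einsum("jq,qr,jr->", w[o], cov_i, w[o]))
        sigma2 = max(err / obs.sum(), 1e-10)
        alpha = n / (np.sum(w ** 2, axis=0) + 1e-10)

        imp = (mu[None, :] + recon)[miss]
        denom = np.linalg.norm(prev_imp)
        change = np.linalg.norm(imp - prev_imp) / (denom if denom else 1.0)
        prev_imp = imp.copy()
        if change < params.tol:
            converged = True
            break

    out = values.copy()
    out[miss] = (mu[None, :] + ez @ w.T)[miss]
    diag = {"n_iter": n_iter, "converged": converged,
            "effective_rank": int((alpha < 1e6).sum()), "sigma2": sigma2}
    if not converged:
        diag["notes"] = [f"bpca did not reach tol={params.tol} in "
                         f"{params.max_iter} iterations"]
    return out, diag


# ---------------------------------------------------------------------------
# local-regression family

def _regression_fill(values: np.ndarray, params: SIMethodParams,
                     solver: Callable[[np.ndarray, np.ndarray, SIMethodParams],
                                      np.ndarray],
                     method: str) -> tuple[np.ndarray, dict]:
    """Local-regression fill: for each missing cell, regress the target
    protein on its k most-correlated neighbors among the proteins observed
    at that cell's sample (neighbors complete in the relevant samples).

    Missing cells sharing the same neighbor set are predicted from one fit.
    Neighbor rows are mean-prefilled on the fit side so scattered
    missingness in the neighbors never starves the design matrix; the
    prediction side always uses genuinely observed neighbor values.
    """
    prefilled = _mean_fill(values, params)[0]
    out = values.copy()
    notes: list[str] = []
    k = params.k_neighbors
    for i in np.flatnonzero(~np.all(np.isfinite(values), axis=1)):
        t_obs = np.flatnonzero(np.isfinite(values[i]))
        t_miss = np.flatnonzero(~np.isfinite(values[i]))
        corr = _pairwise_complete_corr(values, i)
        if t_obs.size < 3 or not (corr > 0).any():
            notes.append(f"protein {i}: no usable neighbors; protein-mean fallback")
            out[i, t_miss] = values[i, t_obs].mean()
            continue
        groups: dict[tuple[int, ...], list[int]] = {}
        for j in t_miss:
            cand = np.flatnonzero((corr > 0) & np.isfinite(values[:, j]))
            if cand.size == 0:
                notes.append(f"protein {i}: no neighbor observed at sample {j}; "
                             "protein-mean fallback")
                out[i, j] = values[i, t_obs].mean()
                continue
            k_eff = min(k, cand.size, max(t_obs.size - 2, 1))
            nb = tuple(sorted(cand[np.argsort(corr[cand])[::-1][:k_eff]]))
            groups.setdefault(nb, []).append(int(j))
        for nb, cols in groups.items():
            nb_arr = np.asarray(nb)
            x_fit = prefilled[np.ix_(nb_arr, t_obs)].T
            y_fit = values[i, t_obs]
            beta = solver(x_fit, y_fit, params)
            x_pred = values[np.ix_(nb_arr, np.asarray(cols))].T
            out[i, cols] = beta @ np.hstack([np.ones((len(cols), 1)), x_pred]).T
    return out, {"notes": notes} if notes else {}


def _ols_coefs(x: np.ndarray, y: np.ndarray, params: SIMethodParams) -> np.ndarray:
    design = np.hstack([np.ones((x.shape[0], 1)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta


def _grr_coefs(x: np.ndarray, y: np.ndarray, params: SIMethodParams) -> np.ndarray:
    """Generalized ridge in principal-component space: per-component
    penalties lambda_c = sigma^2 / gamma_c^2 (Hoerl-Kennard), or a uniform
    user-supplied penalty; the intercept is never penalized."""
    n = x.shape[0]
    xm, ym = x.mean(axis=0), y.mean()
    xc, yc = x - xm, y - ym
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    pos = s > max(s.max(), 1e-300) * 1e-10 if s.size else s.astype(bool)
    uty = u.T @ yc
    if params.ridge_lambda is not None:
        lam = np.full(s.shape, params.ridge_lambda)
    else:
        gamma_ols = np.where(pos, uty / np.where(pos, s, 1.0), 0.0)
        dof = n - int(pos.sum()) - 1
        rss = float(((yc - u @ (s * gamma_ols)) ** 2).sum())
        sigma2 = rss / dof if dof > 0 else float(yc.var()) or 1.0
        lam = sigma2 / np.maximum(gamma_ols ** 2, 1e-12)
    gamma = s * uty / (s ** 2 + lam)
    beta = vt.T @ gamma
    return np.concatenate([[ym - xm @ beta], beta])


def _lls_fill(values: np.ndarray, params: SIMethodParams) -> tuple[np.ndarray, dict]:
    return _regression_fill(values, params, _ols_coefs, "lls")


def _grr_fill(values: np.ndarray, params: SIMethodParams) -> tuple[np.ndarray, dict]:
    return _regression_fill(values, params, _grr_coefs, "grr")


def _impseq_fill(values: np.ndarray, params: SIMethodParams) -> tuple[np.ndarray, dict]:
    """Sequential imputation ordered by missingness with robust (Huber)
    least squares on the most-correlated already-complete proteins."""
    import statsmodels.api as sm

    out = values.copy()
    complete = list(np.flatnonzero(np.all(np.isfinite(values), axis=1)))
    incomplete = np.flatnonzero(~np.all(np.isfinite(values), axis=1))
    if not complete:
        raise ImputationFailure("impseq", "no complete proteins to seed the "
                                          "sequential regressions")
    order = incomplete[np.argsort((~np.isfinite(values[incomplete])).sum(axis=1))]
    notes: list[str] = []
    for i in order:
        t_obs = np.flatnonzero(np.isfinite(out[i]))
        t_miss = np.flatnonzero(~np.isfinite(out[i]))
        pool = np.asarray(complete)
        corr = np.zeros(pool.size)
        y = out[i, t_obs]
        if y.std() > 0:
            xs = out[np.ix_(pool, t_obs)]
            sd = xs.std(axis=1)
            ok = sd > 0
            corr[ok] = np.abs(((xs[ok] - xs[ok].mean(axis=1, keepdims=True))
                               * (y - y.mean())).mean(axis=1) / (sd[ok] * y.std()))
        k = min(params.k_neighbors, pool.size, max(t_obs.size - 2, 1))
        nb = pool[np.argsort(corr)[::-1][:k]]
        design = sm.add_constant(out[np.ix_(nb, t_obs)].T, has_constant="add")
        pred_design = sm.add_constant(out[np.ix_(nb, t_miss)].T, has_constant="add")
        pred = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # zero-scale Huber fits warn
                fit = sm.RLM(y, design, M=sm.robust.norms.HuberT()).fit()
                pred = np.asarray(fit.predict(pred_design))
        except (ValueError, ZeroDivisionError, np.linalg.LinAlgError):
            pred = None
        if pred is None or not np.isfinite(pred).all():
            # Huber scale can degenerate on near-perfect fits; fall back to OLS
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            pred = pred_design @ beta
            notes.append(f"protein {i}: robust fit degenerate, OLS fallback")
        if not np.isfinite(pred).all():
            raise ImputationFailure("impseq", f"non-finite prediction for protein {i}")
        out[i, t_miss] = pred
        complete.append(int(i))
    return out, {"notes": notes} if notes else {}


# ---------------------------------------------------------------------------
# missForest-style random forest

def _rf_fill(values: np.ndarray, params: SIMethodParams) -> tuple[np.ndarray, dict]:
    p, n = values.shape
    miss_rows = np.flatnonzero(~np.all(np.isfinite(values), axis=1))
    filled = _median_fill(values)
    order = miss_rows[np.argsort((~np.isfinite(values[miss_rows])).sum(axis=1))]
    seeds = np.random.SeedSequence(params.seed).generate_state(
        params.max_iter * max(len(order), 1)) % (2 ** 31)

    prev_filled = filled.copy()
    prev_delta = np.inf
    n_iter, converged = 0, False
    for n_iter in range(1, params.max_iter + 1):
        for t, i in enumerate(order):
            others = np.delete(np.arange(p), i)
            x = filled[others].T                       # samples x (p-1)
            t_obs = np.isfinite(values[i])
            # mtry = p/3, the regression-forest convention
            rf = RandomForestRegressor(
                n_estimators=params.n_trees, max_features=0.33,
                random_state=int(seeds[(n_iter - 1) * len(order) + t]))
            rf.fit(x[t_obs], values[i, t_obs])
            filled[i, ~t_obs] = rf.predict(x[~t_obs])
        miss = ~np.isfinite(values)
        num = float(((filled[miss] - prev_filled[miss]) ** 2).sum())
        den = float((filled[miss] ** 2).sum()) or 1.0
        delta = num / den
        if delta > prev_delta:     # missForest rule: stop when change rises,
            filled = prev_filled   # return the previous iteration's fill
            converged = True
            n_iter -= 1
            break
        if delta < params.tol ** 2:
            converged = True
            break
        prev_delta = delta
        prev_filled = filled.copy()
    return filled, {"n_iter": n_iter, "converged": converged}


# ---------------------------------------------------------------------------
# registry / dispatcher

_REGISTRY: dict[str, Callable[[np.ndarray, SIMethodParams],
                              tuple[np.ndarray, dict]]] = {
    "zero": _zero_fill,
    "mean": _mean_fill,
    "knn": _knn_fill,
    "seqknn": _seqknn_fill,
    "svd": _svd_fill,
    "bpca": _bpca_fill,
    "lls": _lls_fill,
    "grr": _grr_fill,
    "rf": _rf_fill,
    "impseq": _impseq_fill,
}

_NEEDS_OBSERVED_ROW = frozenset(SI_METHODS) - {"zero"}


def impute_with_provenance(m: AbundanceMatrix,
                           params: SIMethodParams) -> ImputationResult:
    """Run one single-imputation method; returns matrix plus diagnostics."""
    if params.method not in _REGISTRY:
        raise ValidationError(f"unknown method {params.method!r}")
    if params.k_neighbors >= m.n_proteins and params.method in (
            "knn", "seqknn", "lls", "grr", "impseq") and m.n_proteins > 1:
        params = replace(params, k_neighbors=m.n_proteins - 1)
    if params.method in _NEEDS_OBSERVED_ROW:
        empty = np.flatnonzero(~m.mask.any(axis=1))
        if empty.size:
            raise ImputationFailure(
                params.method,
                f"protein {m.protein_ids[empty[0]]!r} has zero observed values")
    if m.n_missing == 0:
        return ImputationResult(m.copy(), params.method, params, n_iter=0)

    values, diag = _REGISTRY[params.method](m.values, params)
    # observed cells are pass-through by construction; enforce bit-exactness
    obs = m.mask
    values[obs] = m.values[obs]
    if not np.isfinite(values).all():
        raise ImputationFailure(params.method, "produced non-finite imputations")
    out = m.with_values(values)
    return ImputationResult(out, params.method, params,
                            n_iter=int(diag.get("n_iter", 0)),
                            converged=bool(diag.get("converged", True)),
                            notes=list(diag.get("notes", [])))


def impute(m: AbundanceMatrix, params: SIMethodParams) -> AbundanceMatrix:
    """Complete a matrix with the named single-imputation method."""
    return impute_with_provenance(m, params).matrix
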