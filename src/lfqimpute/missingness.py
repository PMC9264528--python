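"""Mechanism-specific injection of missing values into a complete matrix.

Three mechanisms are simulated on the log-intensity matrix, plus their
mixture:

* MCAR — cells deleted uniformly at random.
* MAR  — a randomly chosen "driver" protein is paired with a distinct
  "victim"; the victim's cells are deleted in samples where the driver's
  standardized abundance exceeds a random cutpoint (high abundance of one
  protein suppressing detection of another).
* MNAR — per protein, a random cutpoint is drawn and all values below it
  (left-censoring at the detection limit) are deleted, so the removed
  values of an affected protein are exactly its smallest values.
* MIX  — MCAR, MAR and MNAR applied sequentially at equal thirds of the
  target rate.

Cutpoints are drawn by sampling c ~ chi-squared(df) and mapping it through
its own CDF to a standard-normal quantile on each protein's standardized
scale, which keeps the mechanism scale-free; df is exposed in the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from scipy import stats

from .matrix import AbundanceMatrix, ValidationError

MECHANISMS = ("MCAR", "MAR", "MNAR", "MIX")


class InjectionError(RuntimeError):
    """Requested missingness could not be realized."""


@dataclass(frozen=True)
class MissingnessSpec:
    """Fully determines one injection run."""

    mechanism: str = "MIX"
    global_rate: float = 0.2
    chi2_df: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValidationError(f"mechanism must be one of {MECHANISMS}")
        if not 0 <= self.global_rate <= 0.7:
            raise ValidationError("global_rate must lie in [0, 0.7]")
        if self.chi2_df < 1:
            raise ValidationError("chi2_df must be a positive integer")


class DeletedCell(NamedTuple):
    protein: int  # row index
    sample: int   # column index
    true_value: float
    mechanism: str


@dataclass
class InjectionResult:
    """Masked matrix plus truth bookkeeping for evaluation."""

    masked_matrix: AbundanceMatrix
    deleted_cells: list[DeletedCell]
    realized_global_rate: float = field(init=False)
    per_protein_rates: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = self.masked_matrix.values.size
        self.realized_global_rate = len(self.deleted_cells) / total
        counts = np.zeros(self.masked_matrix.n_proteins)
        for c in self.deleted_cells:
            counts[c.protein] += 1
        self.per_protein_rates = counts / self.masked_matrix.n_samples

    def truth_values(self) -> np.ndarray:
        return np.array([c.true_value for c in self.deleted_cells])

    def cells(self) -> list[tuple[int, int]]:
        return [(c.protein, c.sample) for c in self.deleted_cells]


def _sample_cutpoint(rng: np.random.Generator, chi2_df: int) -> float:
    # c ~ chi2(df) mapped through its own CDF to a standard-normal quantile:
    # scale-free on each protein's standardized values.
    c = rng.chisquare(chi2_df)
    return float(stats.norm.ppf(stats.chi2.cdf(c, chi2_df)))


def _standardize(v: np.ndarray) -> np.ndarray:
    obs = np.isfinite(v)
    mu = v[obs].mean()
    sd = v[obs].std()
    if sd == 0:
        sd = 1.0
    z = np.full_like(v, np.nan)
    z[obs] = (v[obs] - mu) / sd
    return z


def _check_rate(rate: float) -> None:
    if not 0 <= rate < 1:
        raise ValidationError("rate must lie in [0, 1)")


def introduce_mcar(m: AbundanceMatrix, rate: float, rng: np.random.Generator) -> InjectionResult:
    """Delete exactly round(rate * n_observed) cells uniformly at random."""
    _check_rate(rate)
    out = m.copy()
    obs = np.flatnonzero(m.mask.ravel())
    n_del = int(round(rate * obs.size))
    # permutation prefix keeps the deleted set monotone in the rate at fixed seed
    chosen = obs[rng.permutation(obs.size)[:n_del]]
    deleted = []
    for flat in chosen:
        i, j = divmod(int(flat), m.n_samples)
        deleted.append(DeletedCell(i, j, float(m.values[i, j]), "MCAR"))
        out.values[i, j] = np.nan
    return InjectionResult(out, deleted)


def _mar_rounds(values: np.ndarray, rng: np.random.Generator, chi2_df: int,
                quota: int, label: str = "MAR",
                max_attempts_factor: int = 200) -> list[DeletedCell]:
    """Driver/victim pairing rounds until ``quota`` cells are deleted (may
    slightly overshoot by one pair's worth)."""
    n_prot, n_samp = values.shape
    if n_prot < 2:
        raise ValidationError("MAR injection requires at least 2 proteins")
    deleted: list[DeletedCell] = []
    attempts = 0
    max_attempts = max_attempts_factor * max(n_prot, 10)
    while len(deleted) < quota:
        attempts += 1
        if attempts > max_attempts:
            raise InjectionError("MAR rate infeasible: pairing rounds exhausted")
        driver, victim = rng.choice(n_prot, size=2, replace=False)
        cut = _sample_cutpoint(rng, chi2_df)
        z = _standardize(values[driver])
        hit = np.isfinite(z) & (z > cut) & np.isfinite(values[victim])
        for j in np.flatnonzero(hit):
            if np.isfinite(values[victim]).sum() <= 1:
                break  # never fully empty a protein
            deleted.append(DeletedCell(int(victim), int(j),
                                       float(values[victim, j]), label))
            values[victim, j] = np.nan
    return deleted


def introduce_mar(m: AbundanceMatrix, rate: float, chi2_df: int,
                  rng: np.random.Generator) -> InjectionResult:
    """High abundance in a driver protein deletes cells of a victim protein."""
    _check_rate(rate)
    out = m.copy()
    quota = int(round(rate * m.n_observed))
    deleted = _mar_rounds(out.values, rng, chi2_df, quota)
    return InjectionResult(out, deleted)


def _mnar_rounds(values: np.ndarray, rng: np.random.Generator, chi2_df: int,
                 quota: int, label: str = "MNAR",
                 max_passes: int = 200) -> list[DeletedCell]:
    """Left-censor proteins below random cutpoints until ``quota`` deletions.

    Proteins are visited in random order; within a protein removals proceed
    from the smallest value upward, so the removed set of every affected
    protein is exactly its bottom-k order statistics.
    """
    n_prot, _ = values.shape
    deleted: list[DeletedCell] = []
    for _ in range(max_passes):
        if len(deleted) >= quota:
            break
        for i in rng.permutation(n_prot):
            if len(deleted) >= quota:
                break
            row = values[i]
            obs = np.flatnonzero(np.isfinite(row))
            if obs.size <= 1:
                continue  # keep at least one observed value per protein
            cut = _sample_cutpoint(rng, chi2_df)
            z = _standardize(row)
            cand = obs[z[obs] < cut]
            if cand.size == 0:
                continue
            cand = cand[np.argsort(row[cand])]        # smallest first
            cand = cand[:max(0, min(cand.size, quota - len(deleted),
                                    obs.size - 1))]   # leave one observed
            for j in cand:
                deleted.append(DeletedCell(int(i), int(j), float(row[j]), label))
                values[i, j] = np.nan
    if len(deleted) < quota:
        raise InjectionError("MNAR rate infeasible: ran out of removable values")
    return deleted


def introduce_mnar(m: AbundanceMatrix, rate: float, chi2_df: int,
                   rng: np.random.Generator) -> InjectionResult:
    """Delete each affected protein's smallest values below a random cutpoint."""
    _check_rate(rate)
    out = m.copy()
    quota = int(round(rate * m.n_observed))
    deleted = _mnar_rounds(out.values, rng, chi2_df, quota)
    return InjectionResult(out, deleted)


def introduce_mixture(m: AbundanceMatrix, rate: float, chi2_df: int,
                      rng: np.random.Generator) -> InjectionResult:
    """MCAR, then MAR, then MNAR, each contributing ~rate/3 of total cells."""
    _check_rate(rate)
    out = m.copy()
    n_obs0 = m.n_observed
    total = int(round(rate * n_obs0))
    first = int(round(total / 3))
    second = int(round(2 * total / 3))

    deleted: list[DeletedCell] = []
    # MCAR round: exact count
    obs = np.flatnonzero(out.mask.ravel())
    for flat in obs[rng.permutation(obs.size)[:first]]:
        i, j = divmod(int(flat), out.n_samples)
        deleted.append(DeletedCell(i, j, float(out.values[i, j]), "MCAR"))
        out.values[i, j] = np.nan
    # MAR round: until 2/3 of total (slight overshoot possible)
    if total > 0 and second > len(deleted):
        deleted += _mar_rounds(out.values, rng, chi2_df,
                               second - len(deleted), "MAR")
    # MNAR round: truncated to hit the target exactly
    if total > len(deleted):
        deleted += _mnar_rounds(out.values, rng, chi2_df,
                                total - len(deleted), "MNAR")
    return InjectionResult(out, deleted)


def inject(m: AbundanceMatrix, spec: MissingnessSpec,
           rng: np.random.Generator | None = None) -> InjectionResult:
    """Dispatch an injection fully determined by a :class:`MissingnessSpec`."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if spec.mechanism == "MCAR":
        return introduce_mcar(m, spec.global_rate, rng)
    if spec.mechanism == "MAR":
        return introduce_mar(m, spec.global_rate, spec.chi2_df, rng)
    if spec.mechanism == "MNAR":
        return introduce_mnar(m, spec.global_rate, spec.chi2_df, rng)
    return introduce_mixture(m, spec.global_rate, spec.chi2_df, rng)


DEFAULT_BINS = (0.0, 0.05, 0.10, 0.20, 0.30)


def stratum_labels(bins: Iterable[float] = DEFAULT_BINS) -> list[str]:
    edges = list(bins)
    labels = [f"[{int(lo * 100)}%,{int(hi * 100)}%)"
              for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f">={int(edges[-1] * 100)}%")
    return labels


def stratify_protein_missingness(result: InjectionResult,
                                 bins: Iterable[float] = DEFAULT_BINS,
                                 ) -> dict[str, list[int]]:
    """Assign each protein with >=1 deleted cell to a half-open [lo, hi) bin
    of its per-protein missing fraction (the last bin is unbounded above)."""
    edges = list(bins)
    if edges != sorted(edges):
        raise ValidationError("bins must be sorted ascending")
    labels = stratum_labels(edges)
    out: dict[str, list[int]] = {lab: [] for lab in labels}
    for i, frac in enumerate(result.per_protein_rates):
        if frac <= 0:
            continue
        k = int(np.searchsorted(edges, frac, side="right")) - 1
        out[labels[k]].append(i)
    return out


def protein_stratum(frac: float, bins: Iterable[float] = DEFAULT_BINS) -> str:
    """Label of the [lo, hi) bin containing a per-protein missing fraction."""
    edges = list(bins)
    labels = stratum_labels(edges)
    k = int(np.searchsorted(edges, frac, side="right")) - 1
    return labels[max(k, 0)]
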