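"""Synthetic protein-abundance data with the statistical structure of a
label-free brain-cortex LFQ study.

The generative model works on the log2 scale: proteins fall into blocks of
co-regulated proteins with equicorrelated within-block correlation, each
protein has its own baseline intensity, and a configurable fraction of
proteins carries a linear age effect.  Defaults emulate a 45-animal
prefrontal-cortex cohort (ages 7-23 years, 35 F / 10 M) with 296 complete
proteins.

For the structural (leave-one-out) evaluation, :func:`generate_structured_dataset`
produces a matrix with built-in mechanism-specific missingness while
retaining the complete truth layer internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrix import AbundanceMatrix, SampleMetadata, ValidationError
from .missingness import InjectionError, MissingnessSpec, inject

_FEMALE_FRACTION = 35 / 45  # cohort sex composition


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort; all intensities are log2 units."""

    n_samples: int = 45
    n_proteins: int = 296
    n_complete_target: int = 296
    block_sizes: tuple[int, ...] | None = None  # None: blocks of 10
    within_block_correlation: float = 0.8
    age_range: tuple[float, float] = (7.0, 23.0)
    age_effect_fraction: float = 0.3
    age_slope_sd: float = 0.05      # log2 units per year
    noise_sd: float = 0.5           # per-protein sd around its baseline
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValidationError("n_samples must be >= 3")
        for name in ("n_proteins", "n_complete_target"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.within_block_correlation < 1:
            raise ValidationError("within_block_correlation must lie in [0, 1)")
        if not self.age_range[0] < self.age_range[1]:
            raise ValidationError("age_range must be ordered (lo < hi)")
        if not 0 <= self.age_effect_fraction <= 1:
            raise ValidationError("age_effect_fraction must lie in [0, 1]")
        for name in ("age_slope_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.block_sizes is not None:
            object.__setattr__(self, "block_sizes", tuple(self.block_sizes))
            if any(b <= 0 for b in self.block_sizes):
                raise ValidationError("block_sizes must be positive")
            if sum(self.block_sizes) != self.n_proteins:
                raise ValidationError("block_sizes must sum to n_proteins")

    def resolved_blocks(self) -> list[int]:
        if self.block_sizes is not None:
            return list(self.block_sizes)
        full, rem = divmod(self.n_proteins, 10)
        return [10] * full + ([rem] if rem else [])


def _generate_metadata(config: SyntheticConfig, rng: np.random.Generator) -> SampleMetadata:
    ages = rng.uniform(*config.age_range, size=config.n_samples)
    n_f = int(round(_FEMALE_FRACTION * config.n_samples))
    sex = np.array(["F"] * n_f + ["M"] * (config.n_samples - n_f))
    rng.shuffle(sex)
    ids = [f"S{j + 1:02d}" for j in range(config.n_samples)]
    return SampleMetadata(ids, ages, list(sex))


def true_age_slopes(config: SyntheticConfig) -> np.ndarray:
    """The per-protein age slopes the generator uses (0 for unaffected
    proteins); reproducible from the config alone."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))
    slopes = np.zeros(config.n_proteins)
    n_eff = int(round(config.age_effect_fraction * config.n_proteins))
    idx = rng.choice(config.n_proteins, size=n_eff, replace=False)
    slopes[idx] = rng.normal(0.0, config.age_slope_sd, size=n_eff)
    return slopes


def generate_complete_dataset(config: SyntheticConfig,
                              ) -> tuple[AbundanceMatrix, SampleMetadata]:
    """Generate a fully observed log2-intensity matrix and aligned metadata.

    Within each protein block, samples are drawn from an equicorrelated
    multivariate normal (shared factor construction); a configured fraction
    of proteins carries a linear age slope centered at the mid-cohort age.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    meta = _generate_metadata(config, rng)

    p, n = config.n_proteins, config.n_samples
    rho = config.within_block_correlation
    values = np.empty((p, n))
    row = 0
    for size in config.resolved_blocks():
        shared = rng.normal(size=n)                      # per-sample block factor
        eps = rng.normal(size=(size, n))
        z = np.sqrt(rho) * shared[None, :] + np.sqrt(1 - rho) * eps
        values[row:row + size] = config.noise_sd * z
        row += size

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    slopes = true_age_slopes(config)
    age_centered = meta.age - np.mean(config.age_range)
    values += baselines[:, None] + slopes[:, None] * age_centered[None, :]

    ids = [f"P{i + 1:04d}" for i in range(p)]
    return AbundanceMatrix(ids, meta.sample_ids, values, scale_tag="log"), meta


@dataclass
class StructuredDataset:
    """Matrix with built-in missingness plus its hidden truth layer."""

    observed: AbundanceMatrix
    truth: AbundanceMatrix
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        if self.observed.values.shape != self.truth.values.shape:
            raise ValidationError("observed and truth layers must be congruent")


def generate_structured_dataset(config: SyntheticConfig,
                                missing_profile: MissingnessSpec,
                                max_protein_missing: float = 0.75,
                                ) -> StructuredDataset:
    """Generate a dataset whose missingness is built in per ``missing_profile``,
    with no protein exceeding ``max_protein_missing`` missing fraction.

    Per-protein caps are enforced by restoring a protein's largest deleted
    values (preserving left-censoring structure) and topping the global rate
    back up with MCAR deletions in proteins still under the cap.
    """
    if not 0 < max_protein_missing <= 1:
        raise ValidationError("max_protein_missing must lie in (0, 1]")
    if missing_profile.global_rate > max_protein_missing:
        raise InjectionError(
            f"global rate {missing_profile.global_rate} infeasible when every "
            f"protein is capped at {max_protein_missing} missing")
    truth, meta = generate_complete_dataset(config)
    if missing_profile.global_rate == 0:
        return StructuredDataset(truth.copy(), truth, meta)

    result = inject(truth, missing_profile)
    masked = result.masked_matrix
    n = masked.n_samples
    cap = int(np.floor(max_protein_missing * n))
    rng = np.random.default_rng(np.random.SeedSequence([missing_profile.seed, 1]))

    # restore over-cap proteins, largest deleted values first
    miss_count = (~masked.mask).sum(axis=1)
    for i in np.flatnonzero(miss_count > cap):
        gone = np.flatnonzero(~masked.mask[i])
        order = gone[np.argsort(truth.values[i, gone])[::-1]]
        for j in order[: miss_count[i] - cap]:
            masked.values[i, j] = truth.values[i, j]

    # top up to the target with MCAR in under-cap proteins
    target = int(round(missing_profile.global_rate * truth.values.size))
    while masked.n_missing < target:
        under = np.flatnonzero((~masked.mask).sum(axis=1) < cap)
        eligible = [(i, j) for i in under for j in np.flatnonzero(masked.mask[i])]
        if not eligible:
            raise InjectionError("rate infeasible under max_protein_missing cap")
        need = target - masked.n_missing
        take = rng.choice(len(eligible), size=min(need, len(eligible)), replace=False)
        for t in take:
            i, j = eligible[int(t)]
            if (~masked.mask[i]).sum() < cap:
                masked.values[i, j] = np.nan
    return StructuredDataset(masked, truth, meta)
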