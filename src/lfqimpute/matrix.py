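"""Core data containers: the protein-abundance matrix and sample metadata.

The whole pipeline trades in a single currency: a proteins x samples grid of
log-scale intensities with an explicit missing mask.  Missing cells are stored
as NaN; the boolean mask is derived (True = observed) so values and mask can
never disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

ScaleTag = Literal["raw", "normalized", "log"]


class ValidationError(ValueError):
    """A container or configuration invariant was violated."""


@dataclass
class AbundanceMatrix:
    """Protein x sample abundance grid with explicit missingness.

    Parameters
    ----------
    protein_ids :
        Unique row identifiers (proteins / protein groups).
    sample_ids :
        Unique column identifiers (MS runs / animals).
    values :
        Float array of shape ``(n_proteins, n_samples)``; NaN marks a
        missing cell.
    scale_tag :
        Provenance marker: ``raw`` intensities, ``normalized`` (rescaled,
        pre-log) or ``log`` (normalized and log2-transformed).
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: ScaleTag = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValidationError("duplicate protein ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if np.isinf(self.values).any():
            raise ValidationError("observed values must be finite (NaN marks missing)")

    # -- basic geometry -------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where a value is observed."""
        return np.isfinite(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    @property
    def n_missing(self) -> int:
        return int((~self.mask).sum())

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.values.size

    def per_protein_missing_fraction(self) -> np.ndarray:
        return (~self.mask).sum(axis=1) / self.n_samples

    # -- manipulation ---------------------------------------------------
    def copy(self) -> "AbundanceMatrix":
        return replace(self, values=self.values.copy(),
                       protein_ids=list(self.protein_ids),
                       sample_ids=list(self.sample_ids))

    def subset_proteins(self, index: Sequence[int]) -> "AbundanceMatrix":
        idx = np.asarray(index, dtype=int)
        return AbundanceMatrix(
            [self.protein_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx].copy(),
            self.scale_tag,
        )

    def with_values(self, values: np.ndarray) -> "AbundanceMatrix":
        return AbundanceMatrix(list(self.protein_ids), list(self.sample_ids),
                               np.asarray(values, dtype=float), self.scale_tag)

    # -- I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.protein_ids, name="protein"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale_tag: ScaleTag = "raw") -> "AbundanceMatrix":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)),
                   frame.to_numpy(dtype=float), scale_tag)

    def write_tsv(self, path: str | Path) -> None:
        """Write as TSV: rows = proteins, columns = samples, empty cell = missing."""
        self.to_frame().to_csv(path, sep="\t", na_rep="")

    def __eq__(self, other: object) -> bool:  # value equality incl. NaN pattern
        if not isinstance(other, AbundanceMatrix):
            return NotImplemented
        return (self.protein_ids == other.protein_ids
                and self.sample_ids == other.sample_ids
                and self.scale_tag == other.scale_tag
                and np.array_equal(self.values, other.values, equal_nan=True))


@dataclass
class SampleMetadata:
    """Per-sample covariates used in the regression-bias evaluation."""

    sample_ids: list[str]
    age: np.ndarray  # years
    sex: list[str] = field(default_factory=list)  # "F" / "M"

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.age.shape != (len(self.sample_ids),):
            raise ValidationError("one age per sample required")
        if (self.age <= 0).any():
            raise ValidationError("ages must be positive")
        if self.sex and len(self.sex) != len(self.sample_ids):
            raise ValidationError("one sex per sample required")
        if self.sex and not set(self.sex) <= {"F", "M"}:
            raise ValidationError("sex must be 'F' or 'M'")

    def aligned_to(self, m: AbundanceMatrix) -> "SampleMetadata":
        """Reorder metadata rows to match the matrix's sample order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in m.sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"metadata missing samples: {missing[:5]}")
        order = [pos[s] for s in m.sample_ids]
        return SampleMetadata(list(m.sample_ids), self.age[order],
                              [self.sex[i] for i in order] if self.sex else [])

    def to_frame(self) -> pd.DataFrame:
        d = {"sample_id": self.sample_ids, "age_years": self.age}
        if self.sex:
            d["sex"] = self.sex
        return pd.DataFrame(d)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        sex = list(df["sex"]) if "sex" in df.columns else []
        return cls(list(df["sample_id"]), df["age_years"].to_numpy(), sex)
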