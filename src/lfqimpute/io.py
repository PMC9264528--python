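"""Reading protein tables and the normalization / filtering preprocessing.

The preprocessing mirrors the standard label-free workflow: global intensity
normalization (every sample column rescaled to the same observed total),
log2 transform, and a presence filter keeping proteins quantified in at
least a given fraction of samples.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix, ValidationError

log = logging.getLogger(__name__)

Dialect = Literal["generic_tsv", "generic_csv", "flashlfq"]


def read_protein_table(path: str | Path, dialect: Dialect = "generic_tsv") -> AbundanceMatrix:
    """Read a proteins x samples intensity table.

    ``generic_tsv`` / ``generic_csv``: first column = protein id, remaining
    columns = samples; empty cells or ``NA`` are missing.  ``flashlfq``: the
    FlashLFQ ``QuantifiedProteins.tsv`` dialect — protein ids in the
    ``Protein Groups`` column, intensities in ``Intensity_<sample>`` columns,
    and 0 means unquantified (missing).
    """
    path = Path(path)
    sep = "," if dialect == "generic_csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: no sample columns found")

    if dialect == "flashlfq":
        if "Protein Groups" not in df.columns:
            raise ValidationError(f"{path}: flashlfq dialect requires a 'Protein Groups' column")
        ids = df["Protein Groups"].astype(str)
        int_cols = [c for c in df.columns if c.startswith("Intensity_")]
        if not int_cols:
            raise ValidationError(f"{path}: no 'Intensity_' columns found")
        body = df[int_cols]
        sample_ids = [c[len("Intensity_"):] for c in int_cols]
    else:
        ids = df.iloc[:, 0].astype(str)
        body = df.iloc[:, 1:]
        sample_ids = list(map(str, body.columns))

    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate protein id {dup!r}")

    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        coerced = pd.to_numeric(body[col].replace("NA", np.nan), errors="coerce")
        bad = coerced.isna() & body[col].notna() & (body[col].astype(str).str.strip() != "") \
            & (body[col].astype(str) != "NA")
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{path}: non-numeric cell at protein {ids.iloc[i]!r}, column {col!r}")
        values[:, j] = coerced.to_numpy()

    if dialect == "flashlfq":
        values[values == 0] = np.nan  # FlashLFQ emits 0 for unquantified

    return AbundanceMatrix(list(ids), sample_ids, values, scale_tag="raw")


def global_intensity_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Global intensity normalization followed by log2 transform.

    Each sample column is rescaled so that its observed-intensity total
    equals the mean column total, then all observed values are
    log2-transformed.  Requires raw (or normalized) non-negative input.
    """
    if m.scale_tag == "log":
        raise ValidationError("matrix is already log-scale")
    vals = m.values
    obs = m.mask
    if np.nanmin(vals[obs], initial=np.inf) < 0:
        raise ValidationError("raw intensities must be non-negative")
    totals = np.nansum(vals, axis=0)
    if (totals == 0).any():
        j = int(np.flatnonzero(totals == 0)[0])
        raise ValidationError(f"sample {m.sample_ids[j]!r} has zero total intensity")
    target = totals.mean()
    scaled = vals * (target / totals)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.log2(scaled)
    logged[~obs] = np.nan
    if not np.isfinite(logged[obs]).all():
        raise ValidationError("zero intensities cannot be log-transformed; "
                              "read them as missing instead")
    return AbundanceMatrix(list(m.protein_ids), list(m.sample_ids), logged, scale_tag="log")


def normalize_only(m: AbundanceMatrix) -> AbundanceMatrix:
    """The rescaling step alone (pre-log); useful for testing idempotence."""
    if m.scale_tag == "log":
        raise ValidationError("matrix is already log-scale")
    totals = np.nansum(m.values, axis=0)
    if (totals == 0).any():
        j = int(np.flatnonzero(totals == 0)[0])
        raise ValidationError(f"sample {m.sample_ids[j]!r} has zero total intensity")
    target = totals.mean()
    return AbundanceMatrix(list(m.protein_ids), list(m.sample_ids),
                           m.values * (target / totals)[None, :], scale_tag="normalized")


def filter_presence(m: AbundanceMatrix, min_fraction: float = 0.25) -> AbundanceMatrix:
    """Keep proteins observed in at least ``min_fraction`` of samples (inclusive)."""
    if not 0 <= min_fraction <= 1:
        raise ValidationError("min_fraction must lie in [0, 1]")
    frac = m.mask.sum(axis=1) / m.n_samples
    keep = np.flatnonzero(frac >= min_fraction)
    return m.subset_proteins(keep)


def complete_subset(m: AbundanceMatrix) -> AbundanceMatrix:
    """Proteins with zero missing cells."""
    keep = np.flatnonzero(m.mask.all(axis=1))
    if keep.size == 0:
        log.warning("no complete proteins in matrix")
    return m.subset_proteins(keep)
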