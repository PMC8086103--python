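"""Reading and writing methylation matrices, metadata and configs.

Matrices follow the GEO processed-file convention: CpG rows × sample
columns, a header row of sample identifiers and the CpG identifier in the
first column.  The value scale (``beta`` or ``m``) is never inferred from
the numbers — it is declared by the caller or stored alongside the data.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DataError, InvalidInputError
from .transforms import beta_to_m, m_to_beta

Scale = Literal["beta", "m"]

GROUP_LEVELS = ("Placebo", "Treatment")
METADATA_COLUMNS = ("sample_id", "group", "age", "sex")


@dataclass
class MethylationMatrix:
    """CpG × sample grid of methylation values with a declared scale."""

    values: pd.DataFrame  # index: cpg ids, columns: sample ids
    scale: Scale

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "m"):
            raise InvalidInputError(f"scale must be 'beta' or 'm', got {self.scale!r}")
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate CpG ids: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad_rows = self.values.index[~np.isfinite(arr).all(axis=1)].tolist()
            raise DataError(f"non-finite values in rows: {bad_rows[:5]}")
        if self.scale == "beta" and (arr.min() < 0.0 or arr.max() > 1.0):
            mask = (arr < 0.0) | (arr > 1.0)
            bad_rows = self.values.index[mask.any(axis=1)].tolist()
            raise DataError(
                f"beta-scale values outside [0, 1] in rows: {bad_rows[:5]}"
            )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_scale(self, scale: Scale, clamp_eps: float = 1e-6) -> "MethylationMatrix":
        """Return a copy on the requested scale (identity copy if equal)."""
        if scale == self.scale:
            return MethylationMatrix(self.values.copy(), self.scale)
        arr = self.values.to_numpy(dtype=float)
        if scale == "m":
            out = beta_to_m(arr, clamp_eps=clamp_eps)
        else:
            out = m_to_beta(arr)
        return MethylationMatrix(
            pd.DataFrame(out, index=self.values.index, columns=self.values.columns),
            scale,
        )


def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise DataError(f"{path}: header is neither tab- nor comma-separated")


def read_matrix(path: str, scale: Scale) -> MethylationMatrix:
    """Read a CpG × sample matrix from delimited text.

    The first column holds CpG ids; remaining columns are samples.  Rows
    containing non-numeric cells are rejected with a row-level diagnostic;
    Beta-scale values are range-checked.
    """
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.shape[1] < 2:
        raise DataError(f"{path}: matrix needs a CpG id column plus ≥1 sample column")
    raw = raw.set_index(raw.columns[0])
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        rows = numeric.index[bad.any(axis=1)].tolist()
        raise DataError(f"{path}: non-numeric cells in rows {rows[:5]}")
    if numeric.isna().to_numpy().any():
        rows = numeric.index[numeric.isna().any(axis=1)].tolist()
        raise DataError(f"{path}: missing values in rows {rows[:5]} (not supported)")
    try:
        return MethylationMatrix(numeric, scale)
    except DataError as err:
        raise DataError(f"{path}: {err}") from err


def _atomic_write(path: str, text: str) -> None:
    dirname = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=dirname, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_matrix(matrix: MethylationMatrix, path: str, sep: str = "\t") -> None:
    """Write a matrix as delimited text (12 significant digits, atomic)."""
    df = matrix.values.copy()
    df.index.name = "cpg_id"
    _atomic_write(path, df.to_csv(sep=sep, float_format="%.12g"))


def read_metadata(path: str, matrix: MethylationMatrix | None = None) -> pd.DataFrame:
    """Read a sample-metadata CSV (sample_id, group, age, sex).

    The group column must have exactly two levels; when a companion matrix
    is supplied the sample ids must match it exactly.
    """
    meta = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise DataError(f"{path}: missing metadata columns {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"{path}: duplicate sample ids {dupes[:5]}")
    levels = sorted(meta["group"].astype(str).unique())
    if len(levels) != 2:
        raise DataError(f"{path}: group column must have 2 levels, found {levels}")
    if meta[["age", "sex"]].isna().any().any():
        raise DataError(f"{path}: missing age/sex entries")
    if matrix is not None:
        meta_ids = set(meta["sample_id"].astype(str))
        mat_ids = set(map(str, matrix.sample_ids))
        if meta_ids != mat_ids:
            odd = sorted(meta_ids.symmetric_difference(mat_ids))
            raise DataError(f"{path}: sample ids do not match the matrix: {odd[:10]}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str) -> None:
    _atomic_write(path, meta.to_csv(index=False))


@dataclass
class RunConfig:
    """Flat key/value configuration for CLI runs; unknown keys rejected."""

    seed: int = 0
    log_level: str = "INFO"
    paths: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    _KNOWN = {"seed", "log_level", "paths", "options"}

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise DataError(f"{path}: config must be a mapping")
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise DataError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
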