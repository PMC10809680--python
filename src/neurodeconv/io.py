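"""Reading and writing beta matrices, sample sheets and result tables.

A beta matrix is a sites x samples table of DNA methylation beta values
(proportion methylated, in [0, 1], missing entries allowed).  Validation
happens once at the boundary: every :class:`MethylationMatrix` handed to the
rest of the package is guaranteed to satisfy the value-domain and uniqueness
invariants, so downstream code never re-checks them.

Default text dialect is tab-separated UTF-8 with "." decimals; CSV is
accepted via ``dialect="csv"``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import BetaDomainError, FormatError, NeurodeconvError

_DIALECTS = {"tab": "\t", "tsv": "\t", "csv": ","}

SHEET_COLUMNS = ["sample_id", "fraction_label", "individual_id", "batch"]


def _sep(dialect: str) -> str:
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")


class MethylationMatrix:
    """Validated sites x samples matrix of beta values.

    Parameters
    ----------
    data
        DataFrame with site ids as the index and sample ids as columns.
        Values must be floats in [0, 1] or NaN (missing).
    validate
        Skip validation only when the caller has just validated (internal use).
    """

    def __init__(self, data: pd.DataFrame, *, validate: bool = True):
        if validate:
            data = self._validated(data)
        self.data = data

    @staticmethod
    def _validated(data: pd.DataFrame) -> pd.DataFrame:
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise FormatError(f"duplicate site id {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        try:
            data = data.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric beta value: {exc}") from exc
        values = data.to_numpy()
        bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BetaDomainError(
                f"beta value {values[i, j]!r} outside [0, 1] at site "
                f"{data.index[i]!r}, sample {data.columns[j]!r}"
            )
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        return data

    # -- convenience accessors -------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "MethylationMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)[:5]}")
        return MethylationMatrix(self.data.loc[:, ids], validate=False)

    def subset_sites(self, site_ids: Iterable[str]) -> "MethylationMatrix":
        ids = list(site_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown site ids: {sorted(missing)[:5]}")
        return MethylationMatrix(self.data.loc[ids, :], validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MethylationMatrix({self.n_sites} sites x {self.n_samples} samples)"


def read_beta_matrix(path: str | Path, dialect: str = "tab") -> MethylationMatrix:
    """Read a delimited beta matrix (first column site ids, header sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    return MethylationMatrix(df)


def write_beta_matrix(matrix: MethylationMatrix, path: str | Path, dialect: str = "tab") -> None:
    matrix.data.to_csv(Path(path), sep=_sep(dialect), index_label="site_id", float_format="%.10g")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV with columns sample_id, fraction_label, individual_id, batch."""
    df = pd.read_csv(Path(path), dtype=str)
    missing = [c for c in SHEET_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns {missing}")
    if "batch" not in df.columns:
        df["batch"] = pd.NA
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r} in sample sheet")
    return df[SHEET_COLUMNS]


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(Path(path), index=False)


def validate_sheet_against(sheet: pd.DataFrame, matrix: MethylationMatrix) -> None:
    """Check that every sheet sample exists in the companion matrix."""
    unknown = set(sheet["sample_id"]) - set(matrix.sample_ids)
    if unknown:
        raise FormatError(f"sample sheet references unknown samples: {sorted(unknown)[:5]}")


def write_results(results: pd.DataFrame, path: str | Path, dialect: str = "tab") -> None:
    """Write a per-sample deconvolution result table.

    Expects one row per bulk sample with a ``sample_id`` column, one column per
    cell fraction, plus ``cetygo`` and ``n_sites_used``.
    """
    if results is None or len(results) == 0:
        raise NeurodeconvError("refusing to write an empty results table")
    for col in ("sample_id", "cetygo", "n_sites_used"):
        if col not in results.columns:
            raise FormatError(f"results table missing required column {col!r}")
    results.to_csv(Path(path), sep=_sep(dialect), index=False, float_format="%.10g")


def read_results(path: str | Path, dialect: str = "tab") -> pd.DataFrame:
    return pd.read_csv(Path(path), sep=_sep(dialect))
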