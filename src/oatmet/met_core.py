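"""Data model and I/O for multi-environment trial (MET) phenotypes.

A MET is a set of replicated variety trials repeated across site-year
"environments".  The central containers are:

``MetTable``
    long-format replicate-level records, one value per
    (environment, variety, replicate, trait) key;
``EnvironmentRecord``
    site/date metadata for one environment;
``CellMeanMatrix``
    the g x e variety-by-environment matrix of cell means for one
    trait, with an explicit observed mask and replicate counts.

Missing values are carried as an explicit mask throughout (never as
sentinel numbers) and every mean is an available-case mean: replicates
-> cell means -> environment / variety means.  Environment means are
unweighted over the varieties observed in that environment, not
replicate-weighted, which matches how balanced-trial summary tables are
conventionally reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, TraitNotFoundError

__all__ = [
    "KEY_COLUMNS",
    "MetTable",
    "EnvironmentRecord",
    "CellMeanMatrix",
    "read_met",
    "cell_means",
    "environment_means",
    "variety_means",
]

logger = logging.getLogger(__name__)

#: Canonical long-format columns, in order.
KEY_COLUMNS = ("environment", "variety", "replicate", "trait")

#: Tokens accepted as missing values in input CSV files.
DEFAULT_MISSING_TOKENS = ("", "na", "NA", "*", "* na")


@dataclass(frozen=True)
class EnvironmentRecord:
    """Metadata for one trial environment (a site x harvest-year)."""

    environment_id: str
    site: str
    latitude: float
    longitude: float
    sowing_date: date | None
    harvest_date: date
    spring_sown: bool = False
    excluded_traits: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise IntegrityError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise IntegrityError(f"longitude {self.longitude} outside [-180, 180]")
        if self.sowing_date is not None and self.harvest_date <= self.sowing_date:
            raise IntegrityError(
                f"environment {self.environment_id}: harvest date "
                f"{self.harvest_date} not after sowing date {self.sowing_date}"
            )


class MetTable:
    """Long-format replicate-level phenotype records.

    Wraps a :class:`pandas.DataFrame` with columns
    ``environment, variety, replicate, trait, value``.  The four key
    columns must be unique in combination; ``value`` may be NaN
    (missing) but non-missing values must be finite.  Trait labels are
    case-normalised (lower-cased, stripped); each trait may carry a
    registered unit.
    """

    def __init__(self, records: pd.DataFrame, units: Mapping[str, str] | None = None):
        missing_cols = [c for c in (*KEY_COLUMNS, "value") if c not in records.columns]
        if missing_cols:
            raise SchemaError(f"missing mandatory column(s): {missing_cols}")
        df = records.loc[:, [*KEY_COLUMNS, "value"]].copy()
        df["trait"] = df["trait"].astype(str).str.strip().str.lower()
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise")
        if (df["replicate"] < 1).any() or (df["replicate"] % 1 != 0).any():
            raise IntegrityError("replicate numbers must be positive integers")
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
        if dup.any():
            key = tuple(df.loc[dup.idxmax(), list(KEY_COLUMNS)])
            raise IntegrityError(f"duplicate record key {key}")
        if np.isinf(df["value"]).any():
            raise IntegrityError("non-missing values must be finite")
        self._df = df.reset_index(drop=True)
        self.units = {str(k).strip().lower(): v for k, v in (units or {}).items()}

    @property
    def records(self) -> pd.DataFrame:
        """The underlying long-format frame (copy-on-write view)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def traits(self) -> list[str]:
        return sorted(self._df["trait"].unique())

    @property
    def environments(self) -> list:
        return sorted(self._df["environment"].unique())

    @property
    def varieties(self) -> list:
        return sorted(self._df["variety"].unique())

    def n_missing(self) -> int:
        return int(self._df["value"].isna().sum())

    def for_trait(self, trait: str) -> pd.DataFrame:
        trait = str(trait).strip().lower()
        sub = self._df[self._df["trait"] == trait]
        if sub.empty:
            raise TraitNotFoundError(
                f"trait {trait!r} not present (have {self.traits})"
            )
        return sub

    def unit(self, trait: str) -> str:
        return self.units.get(str(trait).strip().lower(), "")


@dataclass
class CellMeanMatrix:
    """Variety-by-environment cell means for one trait.

    ``values`` is a g x e frame (varieties as rows, environments as
    columns); ``mask`` marks observed cells; ``counts`` holds per-cell
    replicate numbers.  Requires g >= 2 varieties, e >= 2 environments
    and at least two observed cells in every row and column (the
    analyses downstream are undefined below that).
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    counts: pd.DataFrame
    trait: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        g, e = self.values.shape
        if g < 2:
            raise IntegrityError(f"need >= 2 varieties, got {g}")
        if e < 2:
            raise IntegrityError(f"need >= 2 environments, got {e}")
        if not (self.mask.shape == self.values.shape == self.counts.shape):
            raise IntegrityError("values, mask and counts shapes differ")
        m = self.mask.to_numpy(dtype=bool)
        v = self.values.to_numpy(dtype=float)
        if not np.isfinite(v[m]).all():
            raise IntegrityError("masked-observed cells must hold finite values")
        row_obs = m.sum(axis=1)
        col_obs = m.sum(axis=0)
        if (row_obs < 2).any():
            bad = self.values.index[row_obs < 2].tolist()
            raise IntegrityError(f"varieties observed in < 2 environments: {bad}")
        if (col_obs < 2).any():
            bad = self.values.columns[col_obs < 2].tolist()
            raise IntegrityError(f"environments with < 2 observed varieties: {bad}")

    @property
    def varieties(self) -> list:
        return list(self.values.index)

    @property
    def environments(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.mask.to_numpy().sum())

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.to_numpy().all())

    def masked_values(self) -> np.ma.MaskedArray:
        """Cell means as a numpy masked array (mask = unobserved)."""
        return np.ma.masked_array(
            self.values.to_numpy(dtype=float),
            mask=~self.mask.to_numpy(dtype=bool),
        )

    @classmethod
    def from_dense(
        cls,
        values,
        varieties: Iterable | None = None,
        environments: Iterable | None = None,
        trait: str = "",
        unit: str = "",
    ) -> "CellMeanMatrix":
        """Build a complete matrix from a dense array (NaN = missing)."""
        arr = np.asarray(values, dtype=float)
        g, e = arr.shape
        idx = list(varieties) if varieties is not None else [f"V{i+1}" for i in range(g)]
        cols = (
            list(environments) if environments is not None else [f"E{j+1}" for j in range(e)]
        )
        vals = pd.DataFrame(arr, index=idx, columns=cols)
        mask = ~vals.isna()
        counts = mask.astype(int)
        return cls(vals, mask, counts, trait=trait, unit=unit)


def read_met(
    path,
    schema: Mapping[str, str] | None = None,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    units: Mapping[str, str] | None = None,
) -> MetTable:
    """Read a long-format phenotype CSV into a :class:`MetTable`.

    Parameters
    ----------
    path
        CSV file with a header row; UTF-8.
    schema
        Optional mapping from canonical column names
        (``environment, variety, replicate, trait, value``) to the
        names used in the file.
    missing_tokens
        Cell contents treated as missing (default: empty string and
        ``na`` variants).
    units
        Optional trait -> unit registry, attached to the table.

    Unparseable value cells are recorded as missing; their count is
    emitted as a single warning.
    """
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in (*KEY_COLUMNS, "value")}
    df = pd.read_csv(
        path,
        na_values=list(missing_tokens),
        keep_default_na=False,
        skipinitialspace=True,
    )
    absent = [src for src in rename if src not in df.columns]
    if absent:
        raise SchemaError(f"column(s) {absent} not found in {path}")
    df = df.rename(columns=rename)
    raw = df["value"]
    df["value"] = pd.to_numeric(raw, errors="coerce")
    n_unparseable = int((df["value"].isna() & raw.notna()).sum())
    if n_unparseable:
        warnings.warn(
            f"{n_unparseable} value cell(s) could not be parsed and were "
            "recorded as missing",
            stacklevel=2,
        )
    return MetTable(df, units=units)


def cell_means(met: MetTable, trait: str) -> CellMeanMatrix:
    """Average replicates into a variety x environment cell-mean matrix.

    Each cell is the arithmetic mean over its non-missing replicates;
    cells with no non-missing replicate are masked.  Requires the trait
    to be observed for at least 2 varieties in at least 3 environments.
    """
    sub = met.for_trait(trait)
    obs = sub.dropna(subset=["value"])
    if obs["variety"].nunique() < 2 or obs["environment"].nunique() < 3:
        raise IntegrityError(
            f"trait {trait!r} needs >= 2 varieties in >= 3 environments "
            f"(have {obs['variety'].nunique()} x {obs['environment'].nunique()})"
        )
    values = obs.pivot_table(
        index="variety", columns="environment", values="value", aggfunc="mean"
    )
    counts = obs.pivot_table(
        index="variety", columns="environment", values="value", aggfunc="count"
    )
    # reindex over the full label sets so fully-missing cells stay visible
    idx = sorted(sub["variety"].unique())
    cols = sorted(sub["environment"].unique())
    values = values.reindex(index=idx, columns=cols)
    counts = counts.reindex(index=idx, columns=cols).fillna(0).astype(int)
    mask = counts > 0
    return CellMeanMatrix(
        values, mask, counts, trait=str(trait).strip().lower(), unit=met.unit(trait)
    )


def environment_means(cells: CellMeanMatrix) -> pd.Series:
    """Unweighted mean over observed varieties, per environment."""
    return cells.values.mean(axis=0, skipna=True).rename(cells.trait or "mean")


def variety_means(cells: CellMeanMatrix) -> pd.Series:
    """Unweighted mean over observed environments, per variety."""
    return cells.values.mean(axis=1, skipna=True).rename(cells.trait or "mean")
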