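"""Wide-format longitudinal data: reading, writing, missingness summaries.

A study is stored as one row per subject with one outcome column per
measurement wave (plus optional auxiliary covariates and an optional
administrative dropout-group label).  Missing outcome cells are held as NaN
with the observed/missing mask always derivable from the storage itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("lgmsens")

__all__ = [
    "WideDataset",
    "PatternTable",
    "read_wide_csv",
    "write_wide_csv",
    "missingness_pattern_table",
    "response_summary",
]


class ConfigurationError(ValueError):
    """A request inconsistent with the data at hand (missing column, bad spec)."""


class ParseError(ValueError):
    """A cell that is neither numeric nor a recognised missing-value token."""


@dataclass
class WideDataset:
    """Subjects x waves outcome matrix with explicit missingness.

    Parameters
    ----------
    y : (n, T) float array
        Outcome per subject and wave; NaN marks a missing observation.
    wave_times : (T,) float array
        Slope loadings per wave, in years; strictly increasing, first is 0.
    subject_id : (n,) array
        Opaque identifiers.
    aux : DataFrame or None
        Auxiliary covariates aligned with rows of ``y``.
    dropout_group : (n,) int array or None
        Administrative dropout-pattern label per subject.
    """

    y: np.ndarray
    wave_times: np.ndarray
    subject_id: np.ndarray = None
    aux: pd.DataFrame | None = None
    dropout_group: np.ndarray | None = None
    wave_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be 2-d (subjects x waves)")
        self.wave_times = np.asarray(self.wave_times, dtype=float)
        n, T = self.y.shape
        if T < 2:
            raise ValueError("need at least 2 waves")
        if len(self.wave_times) != T:
            raise ValueError("wave_times length must match number of waves")
        if self.wave_times[0] != 0:
            raise ValueError("first wave time must be 0")
        if np.any(np.diff(self.wave_times) <= 0):
            raise ValueError("wave_times must be strictly increasing")
        if self.subject_id is None:
            self.subject_id = np.arange(n)
        self.subject_id = np.asarray(self.subject_id)
        if not self.wave_names:
            self.wave_names = [f"wave{t + 1}" for t in range(T)]
        if self.aux is not None and len(self.aux) != n:
            raise ValueError("aux must have one row per subject")
        if self.dropout_group is not None:
            self.dropout_group = np.asarray(self.dropout_group)
            if len(self.dropout_group) != n:
                raise ValueError("dropout_group must have one label per subject")

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_waves(self) -> int:
        return self.y.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean (n, T): True where the outcome is observed."""
        return ~np.isnan(self.y)

    def subset(self, rows: np.ndarray) -> "WideDataset":
        """A new dataset restricted to the given row selection."""
        return WideDataset(
            y=self.y[rows],
            wave_times=self.wave_times,
            subject_id=self.subject_id[rows],
            aux=None if self.aux is None else self.aux.iloc[np.atleast_1d(np.arange(self.n)[rows])].reset_index(drop=True),
            dropout_group=None if self.dropout_group is None else self.dropout_group[rows],
            wave_names=list(self.wave_names),
        )

    def complete_cases(self) -> "WideDataset":
        return self.subset(self.mask.all(axis=1))

    def with_y(self, y: np.ndarray) -> "WideDataset":
        return replace(self, y=np.asarray(y, dtype=float))

    def drop_empty_rows(self) -> tuple["WideDataset", int]:
        """Remove subjects observed at no wave; return (dataset, removed count)."""
        keep = self.mask.any(axis=1)
        removed = int((~keep).sum())
        if removed:
            logger.info("excluded %d subjects with no observed wave", removed)
            return self.subset(keep), removed
        return self, 0


@dataclass
class PatternTable:
    """Unique observed/missing patterns with their subject counts."""

    patterns: np.ndarray  # (J, T) bool, True = observed
    counts: np.ndarray  # (J,) int
    n_observed: np.ndarray  # (J,) int, observed-variable count p_j per pattern

    def to_frame(self, wave_names: list[str] | None = None) -> pd.DataFrame:
        T = self.patterns.shape[1]
        names = wave_names or [f"wave{t + 1}" for t in range(T)]
        df = pd.DataFrame(self.patterns.astype(int), columns=names)
        df["count"] = self.counts
        df["n_observed"] = self.n_observed
        return df

    def __len__(self) -> int:
        return len(self.counts)


def read_wide_csv(
    path: str | Path,
    wave_columns: list[str],
    aux_columns: list[str] | None = None,
    na_token: str = "NA",
    drop_all_missing: bool = True,
    wave_times: np.ndarray | None = None,
    id_column: str | None = None,
    group_column: str | None = None,
) -> WideDataset:
    """Read a wide longitudinal CSV into a :class:`WideDataset`.

    Both empty cells and ``na_token`` denote missing outcomes.  Rows with no
    observed wave are removed (and counted in the log) when
    ``drop_all_missing`` is set.

    Raises
    ------
    ConfigurationError
        If a requested column is absent from the header.
    ParseError
        If an outcome cell is neither numeric nor a missing marker; the error
        names the offending row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in wave_columns + list(aux_columns or []):
        if col not in raw.columns:
            raise ConfigurationError(f"column {col!r} not found in {path.name} header")
    if id_column is not None and id_column not in raw.columns:
        raise ConfigurationError(f"id column {id_column!r} not found in {path.name}")
    if group_column is not None and group_column not in raw.columns:
        raise ConfigurationError(f"group column {group_column!r} not found in {path.name}")

    n = len(raw)
    T = len(wave_columns)
    y = np.full((n, T), np.nan)
    for t, col in enumerate(wave_columns):
        cells = raw[col].str.strip()
        missing = (cells == "") | (cells == na_token)
        vals = pd.to_numeric(cells.where(~missing), errors="coerce")
        bad = vals.isna() & ~missing
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {cells.iloc[i]!r} at row {i + 1}, column {col!r}"
            )
        y[:, t] = vals.to_numpy()

    aux = None
    if aux_columns:
        def _coerce(s: pd.Series) -> pd.Series:
            s = s.str.strip().replace({"": None, na_token: None})
            num = pd.to_numeric(s, errors="coerce")
            # keep as text only if some non-missing cell is truly non-numeric
            return s if (num.isna() & s.notna()).any() else num

        aux = raw[list(aux_columns)].apply(_coerce).reset_index(drop=True)

    subject_id = raw[id_column].to_numpy() if id_column else np.arange(n)
    group = None
    if group_column:
        group = pd.to_numeric(raw[group_column].str.strip().replace({"": None, na_token: None})).to_numpy()

    if wave_times is None:
        wave_times = np.arange(T, dtype=float)
    ds = WideDataset(
        y=y,
        wave_times=wave_times,
        subject_id=subject_id,
        aux=aux,
        dropout_group=group,
        wave_names=list(wave_columns),
    )
    if drop_all_missing:
        ds, _ = ds.drop_empty_rows()
    return ds


def write_wide_csv(ds: WideDataset, path: str | Path, na_token: str = "NA") -> None:
    """Write the dataset in the same wide CSV dialect ``read_wide_csv`` accepts."""
    df = pd.DataFrame({"id": ds.subject_id})
    for t, name in enumerate(ds.wave_names):
        df[name] = ds.y[:, t]
    if ds.aux is not None:
        for col in ds.aux.columns:
            df[col] = ds.aux[col].to_numpy()
    if ds.dropout_group is not None:
        df["dropout_group"] = ds.dropout_group
    df.to_csv(path, index=False, na_rep=na_token, float_format="%.12g")


def missingness_pattern_table(ds: WideDataset) -> PatternTable:
    """Exhaustive, mutually exclusive observed/missing patterns with counts."""
    mask = ds.mask
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=len(patterns))
    # order patterns from most to least observed, ties by lexicographic pattern
    order = np.lexsort((*[~patterns[:, t] for t in range(patterns.shape[1])][::-1],
                        -patterns.sum(axis=1)))
    patterns = patterns[order]
    counts = counts[order]
    return PatternTable(
        patterns=patterns,
        counts=counts.astype(int),
        n_observed=patterns.sum(axis=1).astype(int),
    )


def response_summary(ds: WideDataset) -> pd.DataFrame:
    """Observed count per wave plus the complete-case count.

    Returns a one-row-per-wave frame with an extra ``complete`` attribute row
    appended as a summary line (column ``n_observed``).
    """
    mask = ds.mask
    per_wave = mask.sum(axis=0)
    rows = [
        {"wave": name, "n_observed": int(cnt), "fraction": float(cnt) / ds.n}
        for name, cnt in zip(ds.wave_names, per_wave)
    ]
    rows.append(
        {
            "wave": "complete",
            "n_observed": int(mask.all(axis=1).sum()),
            "fraction": float(mask.all(axis=1).mean()),
        }
    )
    return pd.DataFrame(rows)
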