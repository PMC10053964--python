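"""Reading, writing and validating methylation tables and cohort metadata.

Methylation tables are wide CSVs: first column ``sample_id``, remaining
columns canonical CpG site ids, cells percent methylation in [0, 100]
(empty or ``NA`` = missing).  Cohort metadata is a per-sample CSV with
tissue, chronological age, clinical group, optional binary risk factors
and continuous echocardiographic parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import Panel, parse_site_id

__all__ = [
    "MethylationMatrix",
    "CohortTable",
    "MethylationFormatError",
    "MethylationValidationError",
    "CohortValidationError",
    "read_methylation_csv",
    "write_methylation_csv",
    "read_cohort_csv",
    "write_cohort_csv",
]

TISSUES = ("blood", "heart")
GROUPS = ("AVR", "CABG", "HEALTHY")

RISK_FACTOR_COLUMNS = (
    "bmi_ge_30",
    "smoker",
    "hypertension",
    "dyslipidemia",
    "atrial_fibrillation",
)
ECHO_COLUMNS = ("SV", "LVEDV", "LVESV", "EF", "LVDd", "LVSd", "septal", "LVPW")

DEFAULT_NA_TOKENS = ("", "NA")


class MethylationFormatError(ValueError):
    """Malformed methylation table (header or column structure)."""


class MethylationValidationError(ValueError):
    """A methylation value violates the [0, 100] percent range."""


class CohortValidationError(ValueError):
    """Cohort metadata violates its contract (ids, vocabularies, ages)."""


@dataclass
class MethylationMatrix:
    """Samples x CpG-sites grid of percent methylation with missingness.

    ``values`` is a float DataFrame indexed by sample id with site-id
    columns; missing cells are NaN.  All non-missing values must lie in
    [0, 100] — validation happens at construction, never silent clipping.
    """

    values: pd.DataFrame
    tissue: Optional[str] = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = sorted(idx[idx.duplicated()].unique())
            raise MethylationValidationError(f"duplicate sample ids: {dupes}")
        if cols.has_duplicates:
            dupes = sorted(cols[cols.duplicated()].unique())
            raise MethylationValidationError(f"duplicate site ids: {dupes}")
        self.values = self.values.astype(float)
        self._validate_range()

    def _validate_range(self) -> None:
        vals = self.values.to_numpy()
        bad = (vals < 0.0) | (vals > 100.0)
        bad &= ~np.isnan(vals)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MethylationValidationError(
                f"methylation value {vals[r, c]!r} out of [0, 100] at "
                f"sample {self.values.index[r]!r}, site {self.values.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def completeness(self) -> pd.Series:
        """Per-sample fraction of observed (non-missing) sites."""
        return self.values.notna().mean(axis=1)

    def subset_samples(self, ids: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.values.loc[list(ids)].copy(), tissue=self.tissue)


def read_methylation_csv(
    path,
    panel: Optional[Panel] = None,
    *,
    strict: bool = True,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
    tissue: Optional[str] = None,
) -> MethylationMatrix:
    """Read a wide percent-methylation CSV.

    Unknown columns (not parseable as site ids, or outside ``panel`` when
    one is given) raise under ``strict`` and are dropped with a warning
    otherwise.  Any cell outside [0, 100] raises with its coordinates.
    """
    df = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=list(na_tokens)
    )
    if df.shape[1] < 2:
        raise MethylationFormatError(
            f"{path}: expected a sample-id column plus at least one CpG column"
        )
    id_col = df.columns[0]
    if id_col.lower() not in ("sample_id", "sample", "id"):
        raise MethylationFormatError(
            f"{path}: first column must be the sample id, got {id_col!r}"
        )

    keep, drop = [], []
    canonical = {}
    for col in df.columns[1:]:
        try:
            site = parse_site_id(col)
        except ValueError:
            site = None
        if site is None or (panel is not None and site.site_id not in panel):
            drop.append(col)
        else:
            keep.append(col)
            canonical[col] = site.site_id
    if drop:
        if strict:
            raise MethylationFormatError(
                f"{path}: unknown CpG columns {drop!r}"
            )
        warnings.warn(f"dropping unknown CpG columns: {drop}", stacklevel=2)

    out = df.set_index(id_col)[keep].rename(columns=canonical)
    numeric = out.apply(pd.to_numeric, errors="coerce")
    non_numeric = numeric.isna() & out.notna()
    if non_numeric.to_numpy().any():
        r, c = np.argwhere(non_numeric.to_numpy())[0]
        raise MethylationValidationError(
            f"{path}: non-numeric methylation value {out.iat[r, c]!r} at "
            f"sample {out.index[r]!r}, site {out.columns[c]!r}"
        )
    with np.errstate(invalid="ignore"):
        finite = numeric.to_numpy()
        fraction_like = (
            np.nanmax(finite) <= 1.0 and np.nanmax(finite) > 0.0
            if not np.all(np.isnan(finite))
            else False
        )
    if fraction_like:
        warnings.warn(
            "all methylation values are <= 1; values are interpreted as "
            "percent, not fractions — no rescaling is applied",
            stacklevel=2,
        )
    return MethylationMatrix(numeric, tissue=tissue)


def write_methylation_csv(matrix: MethylationMatrix, path) -> None:
    """Write a matrix back to canonical wide CSV (repr-round-trip floats)."""
    out = matrix.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, na_rep="", float_format=None)


class CohortTable:
    """Per-sample clinical metadata.

    ``data`` is indexed by unique sample id and carries ``tissue``
    (blood|heart), ``chronological_age`` (years, > 0), ``group``
    (AVR|CABG|HEALTHY) plus optional boolean risk factors and continuous
    echocardiographic columns.
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        if data.index.has_duplicates:
            dupes = sorted(data.index[data.index.duplicated()].unique())
            raise CohortValidationError(f"duplicate sample ids: {dupes}")
        for col, vocab in (("tissue", TISSUES), ("group", GROUPS)):
            if col in data.columns:
                norm = data[col].astype(str).str.strip()
                norm = norm.str.lower() if col == "tissue" else norm.str.upper()
                unknown = sorted(set(norm.dropna()) - set(vocab) - {"nan"})
                if unknown:
                    raise CohortValidationError(
                        f"unknown {col} tokens {unknown!r}; expected {vocab}"
                    )
                data[col] = norm
        if "chronological_age" in data.columns:
            age = pd.to_numeric(data["chronological_age"], errors="raise")
            bad = age[(~age.isna()) & ((age <= 0) | ~np.isfinite(age))]
            if len(bad):
                raise CohortValidationError(
                    f"non-positive chronological_age for samples {list(bad.index)}"
                )
            data["chronological_age"] = age.astype(float)
        for col in RISK_FACTOR_COLUMNS:
            if col in data.columns:
                data[col] = _coerce_bool(data[col], col)
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def ages(self) -> pd.Series:
        return self.data["chronological_age"]

    def subset(self, ids: Sequence[str]) -> "CohortTable":
        return CohortTable(self.data.loc[list(ids)])


def _coerce_bool(series: pd.Series, name: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }

    def conv(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, float, np.integer, np.floating)):
            return bool(v)
        key = str(v).strip().lower()
        if key in mapping:
            return mapping[key]
        raise CohortValidationError(f"cannot interpret {name}={v!r} as boolean")

    return series.map(conv)


def read_cohort_csv(path) -> CohortTable:
    """Read cohort metadata; vocabularies normalized case-insensitively."""
    df = pd.read_csv(path)
    required = {"sample_id", "tissue", "chronological_age"}
    missing = required - set(df.columns)
    if missing:
        raise CohortValidationError(f"{path}: missing required columns {sorted(missing)}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return CohortTable(df)


def write_cohort_csv(cohort: CohortTable, path) -> None:
    out = cohort.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path)
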