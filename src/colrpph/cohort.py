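"""Cohort table I/O, validation, stratification and Table-1-style summaries.

The analysis operates on a per-subject table with measured postpartum blood
loss (MBL, mL), the delivery mode, and prepartum laboratory values
(platelets in G/L, hemoglobin in g/L, fibrinogen in g/L, factor II and
factor XIII activity in %), plus optional postpartum platelets and FXIII.

Validation is complete-case on the outcome, the delivery mode, and the five
prepartum model covariates: rows with a missing or non-positive value in any
of those fields are excluded and counted in a :class:`ValidationReport`.
Postpartum fields may be missing (they only enter the platelet-FXIII
correlation, which deletes pairs with missing values); a non-positive
postpartum value is set to missing rather than dropping the row.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DELIVERY_MODES",
    "MODEL_COVARIATES",
    "OPTIONAL_COLUMNS",
    "CohortTable",
    "ValidationReport",
    "SchemaError",
    "read_cohort_csv",
    "validate_cohort_frame",
    "stratify",
    "summarize",
]

DELIVERY_MODES = ("vaginal", "elective_cs", "unplanned_cs")

#: the five prepartum covariates of the blood-loss model, in model order
MODEL_COVARIATES = (
    "platelets_pre",
    "hemoglobin_pre",
    "fibrinogen_pre",
    "fii_pre",
    "fxiii_pre",
)

OPTIONAL_COLUMNS = ("platelets_post", "fxiii_post")

REQUIRED_COLUMNS = ("mbl", "delivery_mode") + MODEL_COVARIATES

NUMERIC_COLUMNS = ("mbl",) + MODEL_COVARIATES + OPTIONAL_COLUMNS


class SchemaError(ValueError):
    """A mapped column is absent from the input file."""


@dataclass
class ValidationReport:
    n_input: int = 0
    n_retained: int = 0
    n_excluded: int = 0
    exclusions: dict[str, int] = field(default_factory=dict)
    n_optional_set_missing: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass
class CohortTable:
    """Validated per-subject cohort records.

    ``df`` holds one row per retained subject with the canonical column
    names above; ``delivery_mode`` is categorical over the three modes.
    """

    df: pd.DataFrame
    provenance: str = ""
    validation: ValidationReport = field(default_factory=ValidationReport)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mbl(self) -> np.ndarray:
        return self.df["mbl"].to_numpy(dtype=float)

    def covariate_matrix(self, covariates=MODEL_COVARIATES) -> pd.DataFrame:
        return self.df.loc[:, list(covariates)]

    def to_csv(self, path) -> None:
        cols = [c for c in ("mbl", "delivery_mode") + MODEL_COVARIATES + OPTIONAL_COLUMNS
                if c in self.df.columns]
        # %.17g guarantees binary round-trip of float64 values
        self.df.loc[:, cols].to_csv(path, index=False, float_format="%.17g")


def validate_cohort_frame(raw: pd.DataFrame, provenance: str = "") -> CohortTable:
    """Coerce and validate a raw frame already using canonical column names."""
    report = ValidationReport(n_input=len(raw))
    df = raw.copy()

    def _exact_float(v):
        # float() is a correctly rounded parser (pd.to_numeric's fast path
        # can be off by one ulp, breaking CSV round-trips)
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            if df[col].dtype == object or pd.api.types.is_string_dtype(df[col]):
                df[col] = df[col].map(_exact_float).astype(float)
            else:
                df[col] = df[col].astype(float)
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    keep = pd.Series(True, index=df.index)

    def _exclude(mask: pd.Series, reason: str) -> None:
        hit = mask & keep
        n = int(hit.sum())
        if n:
            report.exclusions[reason] = report.exclusions.get(reason, 0) + n
        keep[hit] = False

    mode = df["delivery_mode"].astype("string").str.strip()
    _exclude(~mode.isin(DELIVERY_MODES), "invalid_delivery_mode")
    for col in ("mbl",) + MODEL_COVARIATES:
        _exclude(df[col].isna(), f"missing_{col}")
        _exclude(df[col] <= 0, f"nonpositive_{col}")

    # non-positive optional lab values become missing, not exclusions
    for col in OPTIONAL_COLUMNS:
        bad = df[col].notna() & (df[col] <= 0)
        report.n_optional_set_missing += int(bad.sum())
        df.loc[bad, col] = np.nan

    out = df.loc[keep].copy()
    out["delivery_mode"] = pd.Categorical(
        mode.loc[keep], categories=list(DELIVERY_MODES)
    )
    out = out.reset_index(drop=True)
    report.n_retained = len(out)
    report.n_excluded = report.n_input - report.n_retained
    return CohortTable(df=out, provenance=provenance, validation=report)


def read_cohort_csv(
    path, column_map: dict[str, str] | None = None, provenance: str | None = None
) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    Parameters
    ----------
    path : str, Path or file-like
        Comma-separated UTF-8 file with a header row and "." decimals.
    column_map : dict, optional
        Mapping from canonical field name (e.g. ``"platelets_pre"``) to the
        column name used in the file.  Unmapped canonical names are looked
        up verbatim.  A mapped column absent from the file raises
        :class:`SchemaError` naming it.

    Unparseable numeric cells become missing values and fall under the
    complete-case exclusion rules rather than crashing the load.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    column_map = dict(column_map or {})
    rename: dict[str, str] = {}
    for canonical in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in REQUIRED_COLUMNS:
            raise SchemaError(
                f"required column '{source}' (field '{canonical}') "
                "not found in input"
            )
    frame = raw.rename(columns=rename)
    if provenance is None:
        provenance = getattr(path, "name", str(path))
    return validate_cohort_frame(frame, provenance=provenance)


def stratify(table: CohortTable, mode: str) -> CohortTable:
    """Subset a cohort to one delivery mode; ``"all"`` returns it unchanged.

    ``"cesarean"`` pools the elective and unplanned cesarean strata, the
    pooling used for the subgroup fits.  Row order is preserved.
    """
    if mode == "all":
        return table
    if mode == "cesarean":
        wanted = ["elective_cs", "unplanned_cs"]
    elif mode in DELIVERY_MODES:
        wanted = [mode]
    else:
        raise ValueError(
            f"unknown delivery mode {mode!r}; expected one of "
            f"{DELIVERY_MODES + ('cesarean', 'all')}"
        )
    sub = table.df[table.df["delivery_mode"].isin(wanted)].reset_index(drop=True)
    return CohortTable(
        df=sub,
        provenance=f"{table.provenance}[{mode}]",
        validation=table.validation,
    )


def summarize(table: CohortTable, by_stratum: bool = True) -> pd.DataFrame:
    """Median/IQR/range summary per variable and delivery-mode stratum.

    Quantiles use linear interpolation between order statistics (numpy's
    default, the "type 7" rule).  Returns a tidy frame with columns
    ``variable, stratum, n, median, q1, q3, min, max`` plus one row per
    stratum giving its size and percentage of the cohort.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty cohort")
    strata: list[tuple[str, pd.DataFrame]] = [("all", table.df)]
    if by_stratum:
        strata += [
            (m, table.df[table.df["delivery_mode"] == m]) for m in DELIVERY_MODES
        ]
    rows = []
    num_cols = [c for c in NUMERIC_COLUMNS if c in table.df.columns]
    for name, sub in strata:
        rows.append(
            {
                "variable": "n_subjects",
                "stratum": name,
                "n": len(sub),
                "median": np.nan, "q1": np.nan, "q3": np.nan,
                "min": np.nan, "max": np.nan,
                "pct": 100.0 * len(sub) / len(table),
            }
        )
        for col in num_cols:
            x = sub[col].dropna().to_numpy(dtype=float)
            if x.size == 0:
                continue
            q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "variable": col,
                    "stratum": name,
                    "n": x.size,
                    "median": med, "q1": q1, "q3": q3,
                    "min": x.min(), "max": x.max(),
                    "pct": np.nan,
                }
            )
    return pd.DataFrame(rows)
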