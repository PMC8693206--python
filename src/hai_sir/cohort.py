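"""Selection of the well-performing hospital modelling cohort.

The reference population for the infection prediction model is the set of
hospitals that both hold a top accreditation grade (excellent or grade 1)
and report a pooled HAI rate within a plausibility window (4%-15% of
hospitalizations by default): hospitals below the window likely under-report
and hospitals above it are outliers. Accreditation and rate filters act on
whole hospitals; records missing a required predictor are then dropped
individually.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import EXPOSURE_COLUMN, INFECTION_TYPES


class CohortError(ValueError):
    pass


@dataclass
class CohortCriteria:
    allowed_accreditations: tuple[str, ...] = ("excellent", "grade1")
    hai_rate_window: tuple[float, float] = (4.0, 15.0)
    required_complete_fields: tuple[str, ...] = ("surgery_to_surgery_bed_ratio",)

    def validate(self) -> None:
        lo, hi = self.hai_rate_window
        if not (0 <= lo < hi <= 100):
            raise CohortError("hai_rate_window must satisfy 0 <= low < high <= 100")


@dataclass
class CohortReport:
    """Record attrition through each filter stage, plus diagnostics."""

    n_input_records: int
    n_after_accreditation: int
    n_after_rate_window: int
    n_after_missing_drop: int
    n_hospitals_retained: int
    empty_cohort: bool = False
    similarity: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _observed_columns(records: pd.DataFrame) -> list[str]:
    cols = [f"observed_{t}" for t in INFECTION_TYPES if f"observed_{t}" in records.columns]
    if not cols:
        raise CohortError("records carry no observed infection-count columns")
    return cols


def hospital_hai_rate(records: pd.DataFrame) -> float:
    """Pooled HAI rate (%) of one hospital's records.

    All infection types and wards are pooled:
    100 * (total infections) / (total hospitalizations).
    """
    if len(records) == 0:
        raise CohortError("hospital_hai_rate requires at least one record")
    exposure = records[EXPOSURE_COLUMN].sum()
    if exposure <= 0:
        raise CohortError("total exposure is zero: HAI rate undefined")
    infections = records[_observed_columns(records)].to_numpy().sum()
    return 100.0 * float(infections) / float(exposure)


def select_well_performing(
    records: pd.DataFrame,
    criteria: CohortCriteria | None = None,
) -> tuple[pd.DataFrame, CohortReport]:
    """Apply the well-performing-hospital filters, reporting attrition.

    Stage 1 keeps hospitals with an allowed accreditation grade; stage 2
    keeps hospitals whose pooled HAI rate lies inside the (inclusive) window;
    stage 3 drops individual records missing any required field. An empty
    result sets a warning flag on the report rather than raising.
    """
    criteria = criteria or CohortCriteria()
    criteria.validate()
    n0 = len(records)

    by_accr = records[records["accreditation"].isin(criteria.allowed_accreditations)]
    n1 = len(by_accr)

    lo, hi = criteria.hai_rate_window
    keep_hospitals = [
        hid
        for hid, grp in by_accr.groupby("hospital_id", sort=False)
        if lo <= hospital_hai_rate(grp) <= hi
    ]
    by_rate = by_accr[by_accr["hospital_id"].isin(keep_hospitals)]
    n2 = len(by_rate)

    required = [f for f in criteria.required_complete_fields if f in records.columns]
    cohort = by_rate.dropna(subset=required) if required else by_rate
    n3 = len(cohort)

    report = CohortReport(
        n_input_records=n0,
        n_after_accreditation=n1,
        n_after_rate_window=n2,
        n_after_missing_drop=n3,
        n_hospitals_retained=cohort["hospital_id"].nunique(),
        empty_cohort=(n3 == 0),
    )
    return cohort.reset_index(drop=True), report


DEFAULT_SIMILARITY_VARIABLES = (
    "hospital_expertise",
    "ward_type",
    "hospital_type",
    "affiliation",
)


def distribution_similarity(
    cohort: pd.DataFrame,
    full: pd.DataFrame,
    variables: tuple[str, ...] = DEFAULT_SIMILARITY_VARIABLES,
) -> pd.DataFrame:
    """Compare categorical composition of the cohort against the full data.

    For each variable the table reports category proportions in cohort and
    full data plus a chi-square homogeneity statistic with p-value. Because
    the cohort is a subset of the full data, the test contrasts the cohort
    with its complement (the excluded records), which is the calibrated
    two-sample comparison; the proportions shown are cohort vs full. The
    statistic is diagnostic only and never drives selection.

    Degenerate cases (cohort identical to full, or a single observed
    category) report statistic 0 and p-value 1.
    """
    if len(cohort) == 0 or len(full) == 0:
        raise CohortError("distribution_similarity requires non-empty inputs")
    key = ["hospital_id", "ward_id"]
    if all(k in full.columns for k in key) and all(k in cohort.columns for k in key):
        in_cohort = pd.MultiIndex.from_frame(full[key]).isin(
            pd.MultiIndex.from_frame(cohort[key])
        )
        rest = full[~in_cohort]
    else:
        rest = full.drop(index=cohort.index, errors="ignore")

    rows = []
    for var in variables:
        categories = sorted(set(full[var].dropna().astype(str)) | set(cohort[var].dropna().astype(str)))
        c_counts = cohort[var].astype(str).value_counts()
        f_counts = full[var].astype(str).value_counts()
        r_counts = rest[var].astype(str).value_counts() if len(rest) else pd.Series(dtype=int)
        table = np.array(
            [
                [int(c_counts.get(cat, 0)) for cat in categories],
                [int(r_counts.get(cat, 0)) for cat in categories],
            ]
        )
        nonzero_cols = table.sum(axis=0) > 0
        table = table[:, nonzero_cols]
        kept = [c for c, nz in zip(categories, nonzero_cols) if nz]
        if len(rest) == 0 or table.shape[1] < 2 or np.any(table.sum(axis=1) == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        for cat in kept:
            rows.append(
                {
                    "variable": var,
                    "category": cat,
                    "prop_cohort": float(c_counts.get(cat, 0)) / len(cohort),
                    "prop_full": float(f_counts.get(cat, 0)) / len(full),
                    "chi2": float(stat),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "CohortCriteria",
    "CohortError",
    "CohortReport",
    "distribution_similarity",
    "hospital_hai_rate",
    "select_well_performing",
]
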