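"""Design matrices for exposure-offset count regression.

Ward-level surveillance records mix categorical hospital/ward attributes
with continuous utilization ratios. Models are rate models: the response is
an infection count and the natural log of the number of hospitalizations
enters as a fixed offset. Categorical predictors are reference-coded against
a declared level ordering so that coefficients fitted on one cohort can be
transferred unambiguously to another data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INFECTION_TYPES = ("RTI", "UTI", "SSI", "BSI")

#: Declared category orderings. The first level of each variable is the
#: reference level; indicator columns are emitted for the remaining levels
#: in this order, so column order is deterministic across data sets.
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "ward_type": (
        "internal",
        "icu",
        "ccu",
        "picu_nicu",
        "burn",
        "infectious",
        "surgery",
        "obgyn",
        "other",
    ),
    "hospital_expertise": (
        "general",
        "accident_burn",
        "heart",
        "pediatrics",
        "obgyn",
        "other",
    ),
    "affiliation": ("government", "semigov_other", "for_profit"),
    "hospital_type": ("nonteaching", "teaching"),
    "accreditation": ("grade1", "excellent", "grade23"),
}

#: The candidate predictors considered for the infection prediction model:
#: five categorical hospital/ward attributes plus nineteen continuous
#: utilization and case-mix measures (24 in total).
CANDIDATE_PREDICTORS: tuple[str, ...] = (
    "ward_type",
    "affiliation",
    "hospital_type",
    "hospital_expertise",
    "accreditation",
    "n_active_beds",
    "avg_los",
    "bto_rate",
    "nurse_bed_ratio",
    "device_days",
    "catheter_days",
    "ventilator_days",
    "mean_age",
    "los_until_infection",
    "duration_hospitalization",
    "male_female_ratio",
    "n_deaths_ward",
    "n_device_related_inf",
    "n_ventilator_related_inf",
    "n_catheter_related_inf",
    "bor",
    "surgery_to_surgery_bed_ratio",
    "death_to_bedridden_ratio",
    "vent_cath_day_ratio",
)

EXPOSURE_COLUMN = "n_hospitalizations"


class DesignError(ValueError):
    """Raised for invalid design-matrix construction requests."""


@dataclass
class DesignMatrix:
    """A fully numeric regression problem: counts, terms, log-exposure."""

    response: np.ndarray
    predictors: np.ndarray
    offset: np.ndarray
    term_names: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.response.shape[0]

    @property
    def k(self) -> int:
        return self.predictors.shape[1]

    def __post_init__(self) -> None:
        if not (len(self.response) == len(self.predictors) == len(self.offset)):
            raise DesignError("response, predictors and offset row counts differ")
        if not np.all(np.isfinite(self.offset)):
            raise DesignError("offset contains non-finite values (exposure must be >= 1)")
        if len(self.term_names) != self.predictors.shape[1]:
            raise DesignError("term_names length does not match predictor columns")

    def subset(self, mask: np.ndarray) -> "DesignMatrix":
        """Row-subset sharing term metadata (used by the hurdle positive part)."""
        return DesignMatrix(
            response=self.response[mask],
            predictors=self.predictors[mask],
            offset=self.offset[mask],
            term_names=list(self.term_names),
            reference_levels=dict(self.reference_levels),
        )

    def intercept_only(self) -> "DesignMatrix":
        """The null design: intercept plus offset on the same records."""
        return DesignMatrix(
            response=self.response,
            predictors=np.ones((self.n, 1)),
            offset=self.offset,
            term_names=["intercept"],
            reference_levels={},
        )


def observed_column(infection_type: str) -> str:
    if infection_type not in INFECTION_TYPES:
        raise DesignError(
            f"unknown infection type {infection_type!r}; expected one of {INFECTION_TYPES}"
        )
    return f"observed_{infection_type}"


def build_design(
    records: pd.DataFrame,
    predictor_names: list[str] | tuple[str, ...],
    infection_type: str,
    levels: dict[str, tuple[str, ...]] | None = None,
) -> DesignMatrix:
    """Assemble response, reference-coded predictors and log-exposure offset.

    Parameters
    ----------
    records
        Registry records, one row per hospital x ward.
    predictor_names
        Predictor columns to include, in order. Categorical variables expand
        to indicator blocks against their declared reference level.
    infection_type
        Which infection count is the response (RTI, UTI, SSI or BSI).
    levels
        Category orderings; defaults to :data:`CATEGORY_LEVELS`.

    Raises
    ------
    DesignError
        On duplicate or unknown predictors, missing values (naming the record
        and field), undeclared category values, or non-positive exposure.
    """
    levels = CATEGORY_LEVELS if levels is None else levels
    names = list(predictor_names)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DesignError(f"duplicate predictor name(s): {dupes}")

    ycol = observed_column(infection_type)
    for col in (ycol, EXPOSURE_COLUMN):
        if col not in records.columns:
            raise DesignError(f"records lack required column {col!r}")

    exposure = records[EXPOSURE_COLUMN].to_numpy(dtype=float)
    if np.any(~np.isfinite(exposure)) or np.any(exposure < 1):
        raise DesignError("n_hospitalizations must be a finite integer >= 1 in every record")

    columns: list[np.ndarray] = [np.ones(len(records))]
    term_names: list[str] = ["intercept"]
    reference_levels: dict[str, str] = {}

    for name in names:
        if name not in records.columns:
            raise DesignError(f"unknown predictor {name!r}")
        col = records[name]
        if col.isna().any():
            idx = col.index[col.isna()][0]
            raise DesignError(f"missing value in field {name!r} at record {idx!r}")
        if name in levels:
            declared = levels[name]
            observed = set(col.astype(str))
            undeclared = observed - set(declared)
            if undeclared:
                raise DesignError(
                    f"undeclared categories {sorted(undeclared)} in field {name!r}"
                )
            reference_levels[name] = declared[0]
            for level in declared[1:]:
                columns.append((col.astype(str) == level).to_numpy(dtype=float))
                term_names.append(f"{name}[{level}]")
        else:
            values = col.to_numpy(dtype=float)
            if np.any(~np.isfinite(values)):
                raise DesignError(f"non-finite value in field {name!r}")
            columns.append(values)
            term_names.append(name)

    return DesignMatrix(
        response=records[ycol].to_numpy(dtype=np.int64),
        predictors=np.column_stack(columns),
        offset=np.log(exposure),
        term_names=term_names,
        reference_levels=reference_levels,
    )


def base_predictors(term_names: list[str] | tuple[str, ...]) -> list[str]:
    """Recover the predictor (column) names behind a list of design terms."""
    seen: list[str] = []
    for term in term_names:
        if term == "intercept":
            continue
        base = term.split("[", 1)[0]
        if base not in seen:
            seen.append(base)
    return seen
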