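"""Standardized infection ratios (SIR) and calibration-corrected SIRs.

The SIR is observed infections divided by the infections a risk-adjustment
model predicts for the same records: SIR > 1 means more infections were
observed than expected for the hospital mix at hand. Confidence intervals
are exact Poisson (Garwood) intervals for the observed count, with the
expected count treated as fixed.

Because the prediction model is fitted on a well-performing reference
cohort, its predictions may be systematically off on the full registry. A
correction factor (CF) — the slope of a no-intercept regression of observed
on predicted counts in the calibration cohort — rescales the expected
counts; the corrected SIR is observed / (CF * expected).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class StandardizationError(ValueError):
    pass


STRATIFIERS = (
    "national",
    "ward_type",
    "hospital_expertise",
    "affiliation",
    "accreditation",
    "hospital_type",
)

DEFAULT_MIN_EXPECTED = 1.0


@dataclass
class CorrectionFactor:
    infection_type: str
    cf: float
    n_calibration_records: int
    residual_sum_squares: float


@dataclass
class SIRResult:
    stratum: str
    infection_type: str
    observed_total: int
    expected_total: float
    sir: float | None
    ci_low: float | None
    ci_high: float | None
    cf: float
    corrected_sir: float | None
    corrected_ci_low: float | None
    corrected_ci_high: float | None
    suppressed: bool = False
    suppression_reason: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def compute_sir(
    observed_total: float, expected_total: float, min_expected: float = DEFAULT_MIN_EXPECTED
) -> float | None:
    """Observed / expected, or None (suppressed) when expected < min_expected.

    Ratios on tiny expected counts are statistically unstable, so they are
    suppressed rather than reported.
    """
    if expected_total < min_expected:
        return None
    return float(observed_total) / float(expected_total)


def sir_confidence_interval(
    observed_total: int,
    expected_total: float,
    level: float = 0.95,
    min_expected: float = DEFAULT_MIN_EXPECTED,
) -> tuple[float, float] | None:
    """Exact Poisson (Garwood) interval for the SIR, E treated as fixed.

    low = q_Gamma(a/2; O) / E (0 when O = 0); high = q_Gamma(1 - a/2; O+1) / E.
    """
    if expected_total < min_expected:
        return None
    a = 1.0 - level
    o = int(observed_total)
    low = 0.0 if o == 0 else float(stats.gamma.ppf(a / 2.0, o) / expected_total)
    high = float(stats.gamma.ppf(1.0 - a / 2.0, o + 1) / expected_total)
    return low, high


def estimate_correction_factor(
    observed: np.ndarray, predicted: np.ndarray, infection_type: str = ""
) -> CorrectionFactor:
    """No-intercept least-squares slope of observed on predicted counts.

    cf = sum(O * P) / sum(P^2), the unique minimizer of sum((O - c * P)^2).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise StandardizationError("need equal-length vectors with at least 2 entries")
    den = float(np.sum(predicted**2))
    if den == 0:
        raise StandardizationError("predicted counts are all zero: CF undefined")
    cf = float(np.sum(observed * predicted)) / den
    rss = float(np.sum((observed - cf * predicted) ** 2))
    return CorrectionFactor(
        infection_type=infection_type,
        cf=cf,
        n_calibration_records=observed.size,
        residual_sum_squares=rss,
    )


def corrected_sir(
    observed_total: float,
    expected_total: float,
    cf: float,
    min_expected: float = DEFAULT_MIN_EXPECTED,
) -> float | None:
    """SIR with the expected count rescaled by the CF: O / (cf * E)."""
    if cf <= 0:
        raise StandardizationError("correction factor must be > 0")
    sir = compute_sir(observed_total, expected_total, min_expected)
    return None if sir is None else sir / cf


def stratified_sir(
    records: pd.DataFrame,
    expected: np.ndarray,
    cf: float,
    stratify_by: str,
    infection_type: str,
    level: float = 0.95,
    min_expected: float = DEFAULT_MIN_EXPECTED,
) -> list[SIRResult]:
    """SIR and corrected SIR per stratum of a hospital/ward attribute.

    Observed and expected counts are summed over member records; intervals
    are exact Poisson for the observed sum divided by E (and by cf * E for
    the corrected interval, the CF treated as a known constant). Strata whose
    expected sum falls below ``min_expected`` are reported suppressed.
    """
    if stratify_by not in STRATIFIERS:
        raise StandardizationError(
            f"unknown stratifier {stratify_by!r}; expected one of {STRATIFIERS}"
        )
    expected = np.asarray(expected, dtype=float)
    if len(expected) != len(records):
        raise StandardizationError("expected vector not aligned to records")
    ycol = f"observed_{infection_type}"
    observed = records[ycol].to_numpy(dtype=np.int64)

    if stratify_by == "national":
        groups = [("national", np.ones(len(records), dtype=bool))]
    else:
        values = records[stratify_by].astype(str).to_numpy()
        groups = [(v, values == v) for v in sorted(set(values))]

    results = []
    for label, mask in groups:
        o = int(observed[mask].sum())
        e = float(expected[mask].sum())
        sir = compute_sir(o, e, min_expected)
        if sir is None:
            results.append(
                SIRResult(
                    stratum=label, infection_type=infection_type,
                    observed_total=o, expected_total=e,
                    sir=None, ci_low=None, ci_high=None, cf=cf,
                    corrected_sir=None, corrected_ci_low=None, corrected_ci_high=None,
                    suppressed=True,
                    suppression_reason=f"expected {e:.3g} < minimum {min_expected}",
                )
            )
            continue
        ci = sir_confidence_interval(o, e, level, min_expected)
        cci = (ci[0] / cf, ci[1] / cf)
        results.append(
            SIRResult(
                stratum=label, infection_type=infection_type,
                observed_total=o, expected_total=e,
                sir=sir, ci_low=ci[0], ci_high=ci[1], cf=cf,
                corrected_sir=sir / cf, corrected_ci_low=cci[0], corrected_ci_high=cci[1],
            )
        )
    return results


def sir_table(results: list[SIRResult]) -> pd.DataFrame:
    """Flat table of stratified SIR results (one row per stratum)."""
    return pd.DataFrame([r.to_dict() for r in results])


def write_sir_results(results: list[SIRResult], csv_path: str | Path, json_path: str | Path | None = None) -> None:
    table = sir_table(results)
    table.to_csv(csv_path, index=False, float_format="%.6g")
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps([r.to_dict() for r in results], indent=2, sort_keys=True)
        )


__all__ = [
    "CorrectionFactor",
    "DEFAULT_MIN_EXPECTED",
    "SIRResult",
    "STRATIFIERS",
    "StandardizationError",
    "compute_sir",
    "corrected_sir",
    "estimate_correction_factor",
    "sir_confidence_interval",
    "sir_table",
    "stratified_sir",
    "write_sir_results",
]
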