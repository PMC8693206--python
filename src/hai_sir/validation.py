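"""Model validation and selection: splits, pseudo-R², RMSE, stepwise AIC.

The final infection prediction model is chosen per infection type by fitting
candidate families on a 70/30 training/testing split of the well-performing
cohort, validating on the held-out records with likelihood-based pseudo-R²
measures and the count-scale prediction error, and keeping the candidate
with the lowest test RMSE.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignMatrix, build_design
from .models import CountModelFit, ModelError, fit_family, loglik_at, predict_expected


class ValidationError(ValueError):
    pass


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    seed: int = 0
    unit: str = "record"  # "record" or "hospital"

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")
        if self.unit not in ("record", "hospital"):
            raise ValidationError("unit must be 'record' or 'hospital'")


@dataclass
class ValidationMetrics:
    mcfadden: float
    cox_snell: float
    nagelkerke: float | None
    mse: float
    rmse: float
    n_records: int
    data_label: str  # training | test | total

    def to_dict(self) -> dict:
        return asdict(self)


def split_train_test(
    records: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint, exhaustive partition, deterministic for a fixed seed.

    With ``unit='hospital'`` whole hospitals are assigned to one side, so no
    hospital contributes records to both sets.
    """
    spec.validate()
    n = len(records)
    if n < 2:
        raise ValidationError("need at least 2 records to split")
    rng = np.random.default_rng(spec.seed)
    if spec.unit == "hospital":
        hospitals = records["hospital_id"].unique()
        perm = rng.permutation(len(hospitals))
        n_train = min(max(int(np.rint(spec.train_fraction * len(hospitals))), 1), len(hospitals) - 1)
        train_h = set(hospitals[perm[:n_train]])
        mask = records["hospital_id"].isin(train_h).to_numpy()
        return records[mask].copy(), records[~mask].copy()
    perm = rng.permutation(n)
    n_train = min(max(int(np.rint(spec.train_fraction * n)), 1), n - 1)
    return (
        records.iloc[np.sort(perm[:n_train])].copy(),
        records.iloc[np.sort(perm[n_train:])].copy(),
    )


def pseudo_r2(
    fit: CountModelFit, null_fit: CountModelFit, n: int
) -> tuple[float, float, float | None]:
    """McFadden, Cox–Snell and Nagelkerke pseudo-R².

    ``null_fit`` must be the intercept-plus-offset model of the same family
    on the same records. Nagelkerke rescales Cox–Snell by its attainable
    maximum 1 - exp(2 * ll_null / n); it is undefined (None) when the null
    log-likelihood is exactly 0.
    """
    ll1, ll0 = fit.loglik, null_fit.loglik
    mcfadden = 1.0 - ll1 / ll0 if ll0 != 0 else math.inf
    cox_snell = 1.0 - math.exp(min(2.0 * (ll0 - ll1) / n, 700.0))
    denom = 1.0 - math.exp(min(2.0 * ll0 / n, 700.0))
    if ll0 == 0 or denom == 0:
        return mcfadden, cox_snell, None
    return mcfadden, cox_snell, cox_snell / denom


def prediction_error(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """(MSE, RMSE) between observed and predicted counts on the count scale."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size == 0:
        raise ValidationError("observed and predicted must have equal nonzero length")
    mse = float(np.mean((observed - predicted) ** 2))
    return mse, math.sqrt(mse)


def evaluate_fit(
    fit: CountModelFit,
    records: pd.DataFrame,
    infection_type: str,
    data_label: str,
    family: str | None = None,
) -> ValidationMetrics:
    """Validation metrics for a fitted model on a record set.

    The model's log-likelihood is evaluated at its fitted parameters on the
    given records (no refit, so held-out metrics reflect transfer), against
    an intercept-plus-offset null of the same family fitted to those records.
    MSE/RMSE compare observed counts with the model's expected counts.
    """
    from .design import base_predictors

    family = family or fit.family
    dm = build_design(records, base_predictors(fit.term_names), infection_type)
    null = fit_family(dm.intercept_only(), family)
    ll_model = loglik_at(fit, dm)
    shim = CountModelFit(
        family=family, beta=fit.beta, term_names=list(fit.term_names),
        loglik=ll_model, n_params=fit.n_params, converged=fit.converged,
        alpha=fit.alpha, gamma=fit.gamma,
    )
    mcf, cs, nag = pseudo_r2(shim, null, dm.n)
    expected = predict_expected(fit, dm)
    mse, rmse = prediction_error(dm.response, expected)
    return ValidationMetrics(
        mcfadden=mcf, cox_snell=cs, nagelkerke=nag,
        mse=mse, rmse=rmse, n_records=dm.n, data_label=data_label,
    )


# ---------------------------------------------------------------------------
# Stepwise AIC
# ---------------------------------------------------------------------------

def stepwise_aic(
    train_records: pd.DataFrame,
    candidate_terms: list[str] | tuple[str, ...],
    infection_type: str,
    family: str = "negbin",
) -> tuple[list[str], CountModelFit, list[dict]]:
    """Bidirectional greedy AIC search over candidate predictors.

    Starts from the intercept-plus-offset model. At each step every
    single-term addition and removal is evaluated; the move with the largest
    AIC decrease is applied; the search stops when no move lowers AIC.
    Categorical predictors enter and leave as whole indicator blocks. Moves
    whose fit fails or does not converge are skipped and logged in the trace.

    Returns (selected terms, final fit, trace of evaluated moves).
    """
    current: list[str] = []
    trace: list[dict] = []

    def try_fit(terms: list[str]) -> CountModelFit | None:
        try:
            dm = build_design(train_records, terms, infection_type)
            fit = fit_family(dm, family)
            return fit if fit.converged else None
        except (ModelError, np.linalg.LinAlgError):
            return None

    best_fit = try_fit(current)
    if best_fit is None:
        raise ValidationError("null model failed to fit")
    current_aic = best_fit.aic
    trace.append({"move": ("start", None), "aic": current_aic, "accepted": True})

    while True:
        moves: list[tuple[str, str]] = [("add", t) for t in candidate_terms if t not in current]
        moves += [("remove", t) for t in current]
        best_move, best_move_fit, best_aic = None, None, current_aic
        for action, term in moves:
            terms = current + [term] if action == "add" else [t for t in current if t != term]
            fit = try_fit(terms)
            if fit is None:
                trace.append({"move": (action, term), "aic": None, "accepted": False,
                              "note": "fit failed or did not converge"})
                continue
            trace.append({"move": (action, term), "aic": fit.aic, "accepted": False})
            if fit.aic < best_aic - 1e-10:
                best_move, best_move_fit, best_aic = (action, term), fit, fit.aic
        if best_move is None:
            break
        action, term = best_move
        current = current + [term] if action == "add" else [t for t in current if t != term]
        current_aic = best_aic
        best_fit = best_move_fit
        trace.append({"move": best_move, "aic": current_aic, "accepted": True})
    return current, best_fit, trace


_FAMILY_ORDER = {"poisson": 0, "negbin": 1, "hurdle_negbin": 2}


@dataclass
class ModelCandidate:
    fit: CountModelFit
    metrics: ValidationMetrics  # test-set metrics
    selected_terms: list[str] | None = None


def select_final_model(candidates: list[ModelCandidate]) -> ModelCandidate:
    """The candidate with minimum test RMSE.

    Ties break toward fewer parameters, then toward the simpler family
    (poisson < negbin < hurdle).
    """
    if not candidates:
        raise ValidationError("no candidate models to select from")
    return min(
        candidates,
        key=lambda c: (c.metrics.rmse, c.fit.n_params, _FAMILY_ORDER.get(c.fit.family, 99)),
    )


def validation_table(metrics: list[ValidationMetrics]) -> pd.DataFrame:
    """Metrics as a table: rows = measures, columns = data sets."""
    cols = {}
    for m in metrics:
        cols[m.data_label] = {
            "Pseudo R2: McFadden": m.mcfadden,
            "Pseudo R2: Cox and Snell (maximum likelihood)": m.cox_snell,
            "Pseudo R2: Nagelkerke (Cragg and Uhler)": m.nagelkerke,
            "Prediction error (MSE)": m.mse,
            "RMSE": m.rmse,
        }
    order = [c for c in ("training", "test", "total") if c in cols]
    return pd.DataFrame(cols)[order]


def write_validation_report(metrics: list[ValidationMetrics], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([m.to_dict() for m in metrics], indent=2, sort_keys=True)
    )


__all__ = [
    "ModelCandidate",
    "SplitSpec",
    "ValidationError",
    "ValidationMetrics",
    "evaluate_fit",
    "prediction_error",
    "pseudo_r2",
    "select_final_model",
    "split_train_test",
    "stepwise_aic",
    "validation_table",
    "write_validation_report",
]
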