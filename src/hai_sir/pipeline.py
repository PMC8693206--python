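"""End-to-end orchestration: registry -> cohort -> models -> SIR tables.

One run executes, per infection type: univariable predictor screening on the
well-performing cohort, a 70/30 training/testing split, bidirectional
stepwise AIC selection within each requested model family, validation on the
held-out records, choice of the lowest-test-RMSE model, coefficient transfer
to the full registry, correction-factor estimation on the cohort, and
stratified SIR / corrected-SIR tables. A JSON manifest records seeds, chosen
models and output file hashes so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortCriteria, distribution_similarity, select_well_performing
from .design import INFECTION_TYPES, build_design, base_predictors
from .models import predict_expected, univariable_screen
from .standardize import (
    DEFAULT_MIN_EXPECTED,
    estimate_correction_factor,
    stratified_sir,
    write_sir_results,
)
from .synthetic import SyntheticConfig, generate_registry, read_registry, write_registry
from .validation import (
    ModelCandidate,
    SplitSpec,
    evaluate_fit,
    select_final_model,
    split_train_test,
    stepwise_aic,
    validation_table,
    write_validation_report,
)


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one standardization run."""

    registry_csv: str | None = None          # path to an existing registry, or
    synthetic: dict = field(default_factory=dict)  # synthetic-generator overrides
    infection_types: tuple[str, ...] = INFECTION_TYPES
    candidate_predictors: dict[str, tuple[str, ...]] = field(default_factory=dict)
    families: tuple[str, ...] = ("poisson", "negbin", "hurdle_negbin")
    cohort: CohortCriteria = field(default_factory=CohortCriteria)
    train_fraction: float = 0.70
    split_unit: str = "record"
    screen_p_threshold: float = 0.20
    ci_level: float = 0.95
    min_expected: float = DEFAULT_MIN_EXPECTED
    stratifiers: tuple[str, ...] = ("national", "ward_type")
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.infection_types) - set(INFECTION_TYPES)
        if unknown:
            raise PipelineError(f"unknown infection types {sorted(unknown)}")
        for itype in self.infection_types:
            cands = self.candidate_predictors.get(itype)
            if cands is None or len(cands) == 0:
                raise PipelineError(
                    f"no candidate predictor list configured for infection type {itype}"
                )
        if self.registry_csv is not None and not Path(self.registry_csv).exists():
            raise PipelineError(f"registry file {self.registry_csv!r} does not exist")

    def candidates_for(self, itype: str) -> tuple[str, ...]:
        cands = self.candidate_predictors.get(itype)
        if cands is None:
            raise PipelineError(
                f"no candidate predictor list configured for infection type {itype}"
            )
        return tuple(cands)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "cohort":
                cfg.cohort = CohortCriteria(
                    allowed_accreditations=tuple(value.get("allowed_accreditations", cfg.cohort.allowed_accreditations)),
                    hai_rate_window=tuple(value.get("hai_rate_window", cfg.cohort.hai_rate_window)),
                    required_complete_fields=tuple(value.get("required_complete_fields", cfg.cohort.required_complete_fields)),
                )
            elif key in ("infection_types", "families", "stratifiers"):
                setattr(cfg, key, tuple(value))
            elif key == "candidate_predictors":
                cfg.candidate_predictors = {k: tuple(v) for k, v in value.items()}
            elif key in cls.__dataclass_fields__:
                setattr(cfg, key, value)
            else:
                raise PipelineError(f"unknown config key {key!r}")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full standardization flow; returns the run manifest.

    A stage failure for one infection type is recorded in the manifest and
    does not abort the other types; files already written are preserved.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
        "infection_types": {},
        "files": {},
    }

    # --- registry ---------------------------------------------------------
    if config.registry_csv is not None:
        records = read_registry(config.registry_csv)
        manifest["stages"]["registry"] = {"source": str(config.registry_csv), "n_records": len(records)}
    else:
        syn = SyntheticConfig.from_dict({**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        records, truth = generate_registry(syn)
        write_registry(records, out / "registry.csv")
        truth.to_json(out / "truth.json")
        manifest["stages"]["registry"] = {"source": "synthetic", "n_records": len(records)}

    # --- cohort -----------------------------------------------------------
    cohort, report = select_well_performing(records, config.cohort)
    if not report.empty_cohort:
        sim = distribution_similarity(cohort, records)
        report.similarity = {
            v: float(sim.loc[sim["variable"] == v, "p_value"].iloc[0])
            for v in sim["variable"].unique()
        }
    report.to_json(out / "cohort_report.json")
    write_registry(cohort, out / "cohort.csv")
    manifest["stages"]["cohort"] = {
        "n_input": report.n_input_records,
        "n_after_accreditation": report.n_after_accreditation,
        "n_after_rate_window": report.n_after_rate_window,
        "n_cohort": report.n_after_missing_drop,
    }
    if report.empty_cohort:
        manifest["stages"]["cohort"]["error"] = "empty cohort after filtering"
        _finalize(manifest, out)
        return manifest

    # --- per infection type ----------------------------------------------
    for i, itype in enumerate(config.infection_types):
        entry: dict = {}
        try:
            entry = _run_infection_type(config, records, cohort, itype, i, out)
        except Exception as exc:
            entry = {"error": f"{type(exc).__name__}: {exc}", **entry}
        manifest["infection_types"][itype] = entry

    _finalize(manifest, out)
    return manifest


def _run_infection_type(
    config: RunConfig,
    records: pd.DataFrame,
    cohort: pd.DataFrame,
    itype: str,
    type_index: int,
    out: Path,
) -> dict:
    entry: dict = {"stage": "screen"}
    candidates = config.candidates_for(itype)
    retained, notes = univariable_screen(
        cohort, candidates, itype, p_threshold=config.screen_p_threshold
    )
    entry["screen"] = {"candidates": list(candidates), "retained": retained, "notes": notes}

    entry["stage"] = "split"
    split_seed = config.seed * 1009 + 17 * (type_index + 1)
    spec = SplitSpec(train_fraction=config.train_fraction, seed=split_seed, unit=config.split_unit)
    train, test = split_train_test(cohort, spec)
    entry["split"] = {"seed": split_seed, "n_train": len(train), "n_test": len(test)}

    entry["stage"] = "stepwise"
    candidates_fit: list[ModelCandidate] = []
    for family in config.families:
        try:
            terms, fit, trace = stepwise_aic(train, retained, itype, family=family)
            metrics_test = evaluate_fit(fit, test, itype, "test")
            candidates_fit.append(ModelCandidate(fit=fit, metrics=metrics_test, selected_terms=terms))
            entry.setdefault("families", {})[family] = {
                "selected_terms": terms,
                "aic": fit.aic,
                "test_rmse": metrics_test.rmse,
                "n_steps": sum(1 for t in trace if t["accepted"]) - 1,
            }
        except Exception as exc:
            entry.setdefault("families", {})[family] = {"error": f"{type(exc).__name__}: {exc}"}
    if not candidates_fit:
        raise PipelineError(f"no family produced a usable model for {itype}")

    entry["stage"] = "validate"
    final = select_final_model(candidates_fit)
    fit = final.fit
    metrics = [
        evaluate_fit(fit, train, itype, "training"),
        final.metrics,
        evaluate_fit(fit, cohort, itype, "total"),
    ]
    write_validation_report(metrics, out / f"validation_{itype}.json")
    validation_table(metrics).to_csv(out / f"validation_{itype}.csv", float_format="%.6g")
    fit.to_json(out / f"model_{itype}.json")
    entry["final_model"] = {"family": fit.family, "terms": final.selected_terms,
                            "test_rmse": final.metrics.rmse}

    entry["stage"] = "standardize"
    predictors = base_predictors(fit.term_names)
    incomplete = [p for p in predictors if records[p].isna().any()]
    used_records = (
        records.dropna(subset=incomplete).reset_index(drop=True) if incomplete else records
    )
    entry["n_records_standardized"] = len(used_records)
    dm_total = build_design(used_records, predictors, itype)
    expected_total = predict_expected(fit, dm_total)

    dm_cal = build_design(cohort, predictors, itype)
    predicted_cal = predict_expected(fit, dm_cal)
    cf = estimate_correction_factor(dm_cal.response, predicted_cal, itype)
    entry["correction_factor"] = {"cf": cf.cf, "n": cf.n_calibration_records}

    for strat in config.stratifiers:
        results = stratified_sir(
            used_records, expected_total, cf.cf, strat, itype,
            level=config.ci_level, min_expected=config.min_expected,
        )
        write_sir_results(
            results,
            out / f"sir_{itype}_{strat}.csv",
            out / f"sir_{itype}_{strat}.json",
        )
        if strat == "national":
            nat = results[0]
            entry["national"] = {
                "observed": nat.observed_total,
                "expected": nat.expected_total,
                "sir": nat.sir,
                "corrected_sir": nat.corrected_sir,
            }
    entry["stage"] = "done"
    return entry


def _finalize(manifest: dict, out: Path) -> None:
    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


__all__ = ["PipelineError", "RunConfig", "run_pipeline"]
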