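"""End-to-end study orchestration.

Composes the full biomarker-qualification design: simulate (or load) a
cohort -> propensity matching -> poor-quality exclusion -> random split into
a small discovery cohort and a training/test cohort -> qPCR normalization
with data-driven internal controls -> discovery screening -> cross-validated
ROC evaluation (all-stage and stage-I strata) with bootstrap CIs and
stage-correlation analysis -> results document.

All randomness flows from one root seed: each stage draws its own seed as
``crc32(stage_name) XOR root`` reduced mod 2^31, so any stage can be rerun
independently and the whole run is byte-reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CtMatrix, SubjectRecord, subjects_to_frame
from .errors import ConfigurationError, SplitError, StageError
from .evaluation import kfold_cross_validate, mann_whitney, roc_auc, spearman
from .matching import MatchSpec, PropensityModel, covariate_balance
from .normalization import (
    ExpressionMatrix,
    aggregate_replicates,
    delta_ct,
    select_internal_controls,
)
from .screening import differential_screen, screen_table, stability_filter
from .synthetic import SimulationConfig, default_config, simulate_cohort

_STAGE_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4}


def derive_seed(root_seed: int, stage: str) -> int:
    """Per-stage seed derivation: crc32(stage) XOR root, mod 2^31."""
    return (zlib.crc32(stage.encode()) ^ (root_seed & 0xFFFFFFFF)) % (2**31)


@dataclass
class StudyConfig:
    """Everything needed to rerun one study end to end.

    Either ``simulation`` (a SimulationConfig) or both ``subjects_csv`` and
    ``ct_csv`` must be provided.  ``seed`` is the mandatory root seed.
    """

    seed: int
    simulation: SimulationConfig | None = None
    subjects_csv: str | None = None
    ct_csv: str | None = None
    match_spec: MatchSpec = field(default_factory=MatchSpec)
    n_discovery_control: int = 6
    n_discovery_case: int = 3
    n_internal_controls: int = 2
    discordance_limit: float = 1.0
    fc_threshold: float = 2.0
    screen_alpha: float = 0.05
    min_detect_rate: float = 0.8
    k: int = 5
    n_boot: int = 1000
    alpha: float = 0.05
    out_dir: str | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.simulation is None and not (self.subjects_csv and self.ct_csv):
            raise ConfigurationError(
                "provide either a simulation config or subjects_csv + ct_csv"
            )
        if self.n_discovery_control < 1 or self.n_discovery_case < 1:
            raise ConfigurationError("discovery counts must be >= 1")
        if self.simulation is not None:
            self.simulation.validate()
            if (
                self.n_discovery_control >= self.simulation.n_control
                or self.n_discovery_case >= self.simulation.n_case
            ):
                raise ConfigurationError(
                    "discovery counts must be strictly smaller than cohort counts"
                )
        self.match_spec.validate()


def default_study_config(seed: int, **sim_overrides) -> StudyConfig:
    """The emulated study design: 299/44 enrolled, 1:4 caliper matching,
    9.4% quality failures, 6/3 discovery split, 5-fold CV with B=1000."""
    return StudyConfig(seed=seed, simulation=default_config(seed, **sim_overrides))


def split_cohort(
    subjects: Sequence[SubjectRecord],
    n_discovery_control: int,
    n_discovery_case: int,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Seeded random split into discovery vs training/test subject ids.

    Disjoint and exhaustive: every subject lands in exactly one arm, with the
    requested discovery group counts honored exactly.
    """
    ctrl = [s.subject_id for s in subjects if s.group == "control"]
    case = [s.subject_id for s in subjects if s.group == "case"]
    if len(ctrl) < n_discovery_control or len(case) < n_discovery_case:
        raise SplitError(
            f"cannot draw {n_discovery_control} controls / {n_discovery_case} "
            f"cases from {len(ctrl)}/{len(case)} available"
        )
    rng = np.random.default_rng(seed)
    disc_ctrl = set(rng.choice(ctrl, size=n_discovery_control, replace=False))
    disc_case = set(rng.choice(case, size=n_discovery_case, replace=False))
    discovery = [s.subject_id for s in subjects
                 if s.subject_id in disc_ctrl or s.subject_id in disc_case]
    training = [s.subject_id for s in subjects if s.subject_id not in set(discovery)]
    return discovery, training


class DiagnosticStudy:
    """Model-style front end: a study design applied to (or simulating) a
    cohort; ``run()`` executes every stage and returns StudyResults."""

    def __init__(self, config: StudyConfig):
        config.validate()
        self.config = config

    @classmethod
    def from_simulation(cls, seed: int, **sim_overrides) -> "DiagnosticStudy":
        return cls(default_study_config(seed, **sim_overrides))

    def run(self, log=None) -> "StudyResults":
        return run_pipeline(self.config, log=log)


def _stage(log, name, fn, *args, **kwargs):
    if log is not None:
        log(f"[{name}] starting")
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - tagged and re-raised
        raise StageError(name, exc) from exc


def run_pipeline(config: StudyConfig, log=None) -> "StudyResults":
    """Execute the full qualification pipeline; see module docstring."""
    config.validate()
    root = config.seed
    seeds = {s: derive_seed(root, s) for s in
             ("simulate", "match", "quality", "split", "evaluate")}

    # --- cohort ------------------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        sim_for_run = SimulationConfig(**{**asdict_sim(sim), "seed": seeds["simulate"]})
        subjects, ct = _stage(log, "simulate", simulate_cohort, sim_for_run)
        poor_rate = sim.poor_quality_rate
    else:
        from .synthetic import read_ct_csv, read_subjects_csv

        subjects = _stage(log, "load", read_subjects_csv, config.subjects_csv)
        ct = _stage(log, "load", read_ct_csv, config.ct_csv)
        poor_rate = 0.0

    frame = subjects_to_frame(subjects)
    by_id = {s.subject_id: s for s in subjects}

    # --- propensity matching ----------------------------------------------
    def do_match():
        ps = PropensityModel(frame, ("age", "sex")).fit()
        res = ps.match(config.match_spec, seed=seeds["match"])
        res.balance = covariate_balance(frame, res.matched_subject_ids())
        return ps, res

    ps_results, match_result = _stage(log, "match", do_match)
    cohort_ids = match_result.matched_subject_ids()
    ct = ct.subset_samples(cohort_ids)

    # --- quality exclusion -------------------------------------------------
    from .synthetic import apply_quality_failures

    ct, excluded = _stage(
        log, "quality", apply_quality_failures, ct, poor_rate, seeds["quality"]
    )
    retained = [by_id[s] for s in ct.sample_ids]

    # --- discovery / training-test split ----------------------------------
    discovery_ids, training_ids = _stage(
        log, "split", split_cohort, retained,
        config.n_discovery_control, config.n_discovery_case, seeds["split"],
    )

    # --- normalization -----------------------------------------------------
    def do_normalize():
        agg, flagged = aggregate_replicates(ct, config.discordance_limit)
        refs = select_internal_controls(agg, config.n_internal_controls)
        return delta_ct(agg, refs), flagged

    expr, discordant = _stage(log, "normalize", do_normalize)

    # --- discovery screening -----------------------------------------------
    labels = frame.set_index("subject_id")["group"]

    def do_screen():
        disc_expr = ExpressionMatrix(
            expr.delta_ct.loc[[s for s in discovery_ids if s in expr.delta_ct.index]],
            expr.rel_expr.loc[[s for s in discovery_ids if s in expr.rel_expr.index]],
            expr.reference_assays,
        )
        records = differential_screen(
            disc_expr, labels, config.fc_threshold, config.screen_alpha
        )
        stable = stability_filter(records, config.min_detect_rate)
        return records, [r.marker_id for r in stable if r.selected]

    screen_records, qualified = _stage(log, "screen", do_screen)

    # --- training/test evaluation ------------------------------------------
    def do_evaluate():
        tt_ids = [s for s in training_ids if s in expr.rel_expr.index]
        tt_labels = labels.loc[tt_ids]
        stage = pd.Series(
            {s: _STAGE_ORDINAL.get(getattr(by_id[s], "tnm_stage", None))
             for s in tt_ids}
        )
        evaluations = {}
        for i, marker in enumerate(qualified):
            values = expr.rel_expr.loc[tt_ids, marker]
            case = values[tt_labels == "case"].dropna()
            ctrl = values[tt_labels == "control"].dropna()
            stage1_ids = [s for s in case.index if stage[s] == 1]
            mseed = seeds["evaluate"] + i
            cv_all = kfold_cross_validate(
                np.concatenate([case, ctrl]),
                np.r_[np.ones(case.size), np.zeros(ctrl.size)],
                k=config.k, seed=mseed, n_boot=config.n_boot,
            )
            roc_all = roc_auc(case.to_numpy(), ctrl.to_numpy(), seed=mseed)
            ev = {
                "n_case": int(case.size),
                "n_control": int(ctrl.size),
                "median_case_x100": float(case.median() * 100),
                "iqr_case_x100": [float(case.quantile(0.25) * 100),
                                  float(case.quantile(0.75) * 100)],
                "median_control_x100": float(ctrl.median() * 100),
                "iqr_control_x100": [float(ctrl.quantile(0.25) * 100),
                                     float(ctrl.quantile(0.75) * 100)],
                "p_value": mann_whitney(case, ctrl).p_value,
                "cv_all_stage": _cv_doc(cv_all),
                "roc_all_stage": _roc_doc(roc_all),
            }
            if len(stage1_ids) >= config.k:
                case1 = case.loc[stage1_ids]
                cv1 = kfold_cross_validate(
                    np.concatenate([case1, ctrl]),
                    np.r_[np.ones(case1.size), np.zeros(ctrl.size)],
                    k=config.k, seed=mseed + 1000, n_boot=config.n_boot,
                )
                roc1 = roc_auc(case1.to_numpy(), ctrl.to_numpy(), seed=mseed + 1000)
                ev["cv_stage1"] = _cv_doc(cv1)
                ev["roc_stage1"] = _roc_doc(roc1)
                # stage-I sensitivity can also be read at the all-stage cutoff
                ev["stage1_sensitivity_at_all_stage_cutoff"] = float(
                    np.mean(case1.to_numpy() >= roc_all.cutoff)
                )
            if stage.loc[case.index].nunique() > 1:
                corr = spearman(case.to_numpy(), stage.loc[case.index].to_numpy())
                ev["stage_correlation"] = {
                    "r": corr.r, "n": corr.n, "p_value": corr.p_value
                }
            evaluations[marker] = ev
        return evaluations

    evaluations = _stage(log, "evaluate", do_evaluate)

    # --- results document ---------------------------------------------------
    n_ctrl_kept = sum(1 for s in retained if s.group == "control")
    n_case_kept = sum(1 for s in retained if s.group == "case")
    document = {
        "seed": root,
        "stage_seeds": seeds,
        "consort": {
            "enrolled_control": int((frame["group"] == "control").sum()),
            "enrolled_case": int((frame["group"] == "case").sum()),
            "matched": len(cohort_ids),
            "quality_excluded": len(excluded),
            "analysis_control": n_ctrl_kept,
            "analysis_case": n_case_kept,
            "discovery": len(discovery_ids),
            "training_test": len(training_ids),
        },
        "propensity": {
            "coefficients": {k: float(v)
                             for k, v in ps_results.coefficients.items()},
            "c_statistic": ps_results.c_statistic,
            "caliper_width": match_result.caliper_width,
            "unmatched_cases": match_result.unmatched_cases,
        },
        "balance": match_result.balance.to_dict(orient="records"),
        "normalization": {
            "reference_assays": expr.reference_assays,
            "discordant_cells": [list(t) for t in discordant],
            "excluded_samples": expr.excluded_samples,
        },
        "screen": screen_table(screen_records).to_dict(orient="records"),
        "qualified_markers": qualified,
        "evaluation": evaluations,
    }
    results = StudyResults(
        config=config,
        subjects=frame,
        match_result=match_result,
        excluded_samples=excluded,
        discovery_ids=discovery_ids,
        training_ids=training_ids,
        expression=expr,
        screen_records=screen_records,
        qualified_markers=qualified,
        evaluations=evaluations,
        document=document,
    )
    if config.out_dir:
        results.write_outputs(config.out_dir)
    return results


def asdict_sim(sim: SimulationConfig) -> dict:
    from dataclasses import asdict
    d = asdict(sim)
    d["marker_specs"] = sim.marker_specs
    return d


def _cv_doc(cv) -> dict:
    return {
        "k": cv.k,
        "fold_train_aucs": [float(a) for a in cv.fold_train_aucs],
        "fold_test_aucs": [float(a) for a in cv.fold_test_aucs],
        "mean_train_auc": cv.mean_train_auc,
        "mean_test_auc": cv.mean_test_auc,
        "boot_ci_train": list(cv.boot_ci_train) if cv.boot_ci_train else None,
        "boot_ci_test": list(cv.boot_ci_test) if cv.boot_ci_test else None,
        "n_boot": cv.n_boot,
    }


def _roc_doc(r) -> dict:
    return {
        "auc": r.auc, "ci": [r.ci_low, r.ci_high], "cutoff": r.cutoff,
        "sensitivity": r.sensitivity, "specificity": r.specificity,
    }


@dataclass
class StudyResults:
    """Everything one pipeline run produced, with report writers."""

    config: StudyConfig
    subjects: pd.DataFrame
    match_result: object
    excluded_samples: list[str]
    discovery_ids: list[str]
    training_ids: list[str]
    expression: ExpressionMatrix
    screen_records: list
    qualified_markers: list[str]
    evaluations: dict
    document: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(self.document, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def marker_table(self) -> pd.DataFrame:
        """Per-marker qualification table (expression medians, p, CV AUCs)."""
        rows = []
        for marker, ev in self.evaluations.items():
            rows.append(
                {
                    "marker": marker,
                    "median_control_x100": ev["median_control_x100"],
                    "median_case_x100": ev["median_case_x100"],
                    "p_value": ev["p_value"],
                    "mean_train_auc": ev["cv_all_stage"]["mean_train_auc"],
                    "mean_test_auc": ev["cv_all_stage"]["mean_test_auc"],
                    "test_ci_low": (ev["cv_all_stage"]["boot_ci_test"] or [None, None])[0],
                    "test_ci_high": (ev["cv_all_stage"]["boot_ci_test"] or [None, None])[1],
                    "stage_r": ev.get("stage_correlation", {}).get("r"),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        c = self.document["consort"]
        p = self.document["propensity"]
        lines = [
            "Urinary-miRNA biomarker qualification study",
            "=" * 46,
            f"enrolled {c['enrolled_control']} controls / {c['enrolled_case']} cases; "
            f"matched cohort {c['matched']}; {c['quality_excluded']} poor-quality excluded",
            f"analysis cohort {c['analysis_control']}/{c['analysis_case']} "
            f"(discovery {c['discovery']}, training/test {c['training_test']})",
            f"PS model C-statistic {p['c_statistic']:.3f}, "
            f"caliper {p['caliper_width']:.4f} logit units",
            f"internal controls: "
            f"{', '.join(self.document['normalization']['reference_assays'])}",
            f"qualified markers: {', '.join(self.qualified_markers) or '(none)'}",
        ]
        for marker, ev in self.evaluations.items():
            cv = ev["cv_all_stage"]
            ci = cv["boot_ci_test"]
            ci_txt = f" [{ci[0]:.3f}-{ci[1]:.3f}]" if ci else ""
            lines.append(
                f"  {marker}: P={ev['p_value']:.3g}, mean test AUC "
                f"{cv['mean_test_auc']:.3f}{ci_txt}"
            )
        return "\n".join(lines)

    def write_outputs(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.expression.to_csv(out / "expression.csv")
        screen_table(self.screen_records).to_csv(out / "screen.csv", index=False)
        if self.match_result.balance is not None:
            self.match_result.balance.to_csv(out / "balance.csv", index=False)
        self.match_result.to_json(out / "match.json")
        self.marker_table().to_csv(out / "markers.csv", index=False)
        self.to_json(out / "results.json")
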