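"""Propensity-score estimation and nearest-neighbor caliper matching.

The propensity score (PS) is the modeled probability of being a case given
covariates (here age and sex), estimated by maximum-likelihood logistic
regression.  Cases are matched 1:ratio to controls by greedy nearest
neighbor on the logit of the PS within a caliper of 0.2 x SD(logit PS),
without replacement.  Balance is reported as absolute standardized
differences, the scale-free between-group difference conventional in
matched-cohort tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import SubjectRecord, subjects_to_frame
from .errors import ConfigurationError, MatchingError
from .evaluation import auc_from_scores


def standardized_difference(group_a_summary, group_b_summary, kind: str) -> float:
    """Absolute standardized difference d between two group summaries.

    continuous: summaries are (mean, sd); d = |m_a - m_b| / sqrt((v_a+v_b)/2)
    binary: summaries are proportions; d = |p_a - p_b| / sqrt((p_a(1-p_a)+p_b(1-p_b))/2)
    Zero pooled variance with unequal means yields inf (flagged non-finite).
    """
    if kind == "continuous":
        mean_a, sd_a = group_a_summary
        mean_b, sd_b = group_b_summary
        num = abs(mean_a - mean_b)
        denom = np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    elif kind == "binary":
        p_a, p_b = float(group_a_summary), float(group_b_summary)
        num = abs(p_a - p_b)
        denom = np.sqrt((p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0)
    else:
        raise ConfigurationError(f"unknown kind {kind!r}")
    if num == 0.0:
        return 0.0
    if denom == 0.0:
        return float("inf")
    return float(num / denom)


@dataclass
class MatchSpec:
    """Matching design: controls per case, caliper width multiplier, and
    whether controls may be reused."""

    ratio: int = 4
    caliper_multiplier: float = 0.2
    with_replacement: bool = False
    sd_method: str = "pooled"  # "pooled" | "within" (average of group SDs)

    def validate(self) -> None:
        if self.ratio < 1:
            raise ConfigurationError("ratio must be >= 1")
        if self.caliper_multiplier <= 0:
            raise ConfigurationError("caliper_multiplier must be > 0")
        if self.sd_method not in ("pooled", "within"):
            raise ConfigurationError("sd_method must be 'pooled' or 'within'")


@dataclass
class MatchResult:
    matched_sets: list[tuple[str, list[str]]]
    caliper_width: float  # logit units
    unmatched_cases: list[str]
    balance: pd.DataFrame | None = None

    @property
    def matched_case_ids(self) -> list[str]:
        return [c for c, ctrls in self.matched_sets if ctrls]

    @property
    def matched_control_ids(self) -> list[str]:
        return [g for _, ctrls in self.matched_sets for g in ctrls]

    def matched_subject_ids(self) -> list[str]:
        return self.matched_case_ids + self.matched_control_ids

    def to_json(self, path=None) -> str:
        doc = {
            "caliper_width": self.caliper_width,
            "matched_sets": [
                {"case": c, "controls": ctrls} for c, ctrls in self.matched_sets
            ],
            "unmatched_cases": self.unmatched_cases,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class PropensityModel:
    """Logistic model for P(case | covariates), statsmodels-style.

    Parameters
    ----------
    subjects : list of SubjectRecord or DataFrame
        Must carry a ``group`` column plus the covariates.
    covariates : sequence of str
        Covariate names; ``sex`` is encoded as a single male indicator.
    """

    def __init__(self, subjects, covariates: Sequence[str] = ("age", "sex")):
        if not isinstance(subjects, pd.DataFrame):
            subjects = subjects_to_frame(subjects)
        self.frame = subjects.reset_index(drop=True)
        if self.frame["group"].nunique() != 2:
            raise ConfigurationError("need both cases and controls")
        counts = self.frame["group"].value_counts()
        if counts.min() < 2:
            raise ConfigurationError("need >= 2 subjects per group")
        self.covariates = list(covariates)
        missing = [c for c in self.covariates if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"covariates not present: {missing}")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, covariates=("age", "sex")):
        return cls(frame, covariates)

    def _design(self) -> tuple[pd.DataFrame, list[str]]:
        cols = {}
        dropped = []
        for c in self.covariates:
            v = self.frame[c]
            if v.dtype == object or str(v.dtype) == "category":
                v = (v == "male").astype(float) if c == "sex" else pd.factorize(v)[0].astype(float)
                name = f"{c}[male]" if c == "sex" else c
            else:
                v = v.astype(float)
                name = c
            if v.nunique() <= 1:
                warnings.warn(f"covariate {c!r} is constant; dropped", stacklevel=3)
                dropped.append(c)
                continue
            cols[name] = v
        X = pd.DataFrame(cols, index=self.frame.index)
        return sm.add_constant(X, has_constant="add"), dropped

    def fit(self) -> "PropensityResults":
        """Maximum-likelihood fit; on (quasi-)complete separation, falls back
        to a ridge-penalized fit and flags the result."""
        y = (self.frame["group"] == "case").astype(int).to_numpy()
        X, dropped = self._design()
        separation = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                params = res.params
                if not res.mle_retvals.get("converged", True) or np.abs(params).max() > 30:
                    raise PerfectSeparationLike()
            except Exception:
                separation = True
                glm = sm.GLM(y, X, family=sm.families.Binomial())
                res = glm.fit_regularized(alpha=1e-3, L1_wt=0.0)
                params = res.params
        if separation:
            warnings.warn(
                "possible complete separation: penalized-likelihood fallback used",
                stacklevel=2,
            )
        lin = np.asarray(X) @ np.asarray(params)
        ps = 1.0 / (1.0 + np.exp(-lin))
        eps = 1e-12
        ps = np.clip(ps, eps, 1 - eps)
        c_stat = 0.5 if np.ptp(ps) < 1e-15 else auc_from_scores(ps[y == 1], ps[y == 0])
        return PropensityResults(
            model=self,
            coefficients=pd.Series(np.asarray(params), index=X.columns),
            ps=pd.Series(ps, index=self.frame["subject_id"].to_numpy()),
            c_statistic=float(c_stat),
            separation_flag=separation,
            dropped_covariates=dropped,
        )


class PerfectSeparationLike(Exception):
    pass


@dataclass
class PropensityResults:
    """Fitted propensity scores plus discrimination diagnostics."""

    model: PropensityModel
    coefficients: pd.Series
    ps: pd.Series  # indexed by subject_id, strictly in (0, 1)
    c_statistic: float
    separation_flag: bool = False
    dropped_covariates: list[str] = field(default_factory=list)

    @property
    def logit_ps(self) -> pd.Series:
        return np.log(self.ps / (1.0 - self.ps))

    def summary(self) -> str:
        lines = ["Propensity model (logistic regression)", "-" * 40]
        for name, val in self.coefficients.items():
            lines.append(f"{name:>16s}  {val:+.4f}")
        lines.append(f"{'C-statistic':>16s}  {self.c_statistic:.3f}")
        if self.separation_flag:
            lines.append("warning: separation detected; penalized fit")
        return "\n".join(lines)

    def match(self, spec: MatchSpec | None = None, seed: int = 0) -> MatchResult:
        return match_nearest_neighbor(self, spec or MatchSpec(), seed)


def fit_propensity(
    subjects, covariates: Sequence[str] = ("age", "sex")
) -> PropensityResults:
    """Functional entry point: fit the PS model on age and sex."""
    return PropensityModel(subjects, covariates).fit()


def match_nearest_neighbor(
    results: PropensityResults, spec: MatchSpec, seed: int = 0
) -> MatchResult:
    """Greedy 1:ratio nearest-neighbor caliper matching on logit(PS).

    Cases are visited in seeded random order; each takes its nearest
    remaining in-caliper controls (ties in distance broken by subject id).
    The caliper is ``caliper_multiplier x SD(logit PS)`` with the SD taken
    over the pooled sample by default.  Every matched pair satisfies
    ``|logit_ps(case) - logit_ps(control)| <= caliper_width``.
    """
    spec.validate()
    frame = results.model.frame
    logit = results.logit_ps
    case_ids = list(frame.loc[frame["group"] == "case", "subject_id"])
    ctrl_ids = list(frame.loc[frame["group"] == "control", "subject_id"])
    if not ctrl_ids:
        raise MatchingError("no controls available for matching")
    if spec.sd_method == "pooled":
        sd = float(np.std(logit.to_numpy(), ddof=1))
    else:
        sd_case = np.std(logit[case_ids].to_numpy(), ddof=1)
        sd_ctrl = np.std(logit[ctrl_ids].to_numpy(), ddof=1)
        sd = float(np.sqrt((sd_case**2 + sd_ctrl**2) / 2.0))
    caliper = spec.caliper_multiplier * sd

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(case_ids)))
    lg = {k: float(v) for k, v in logit.items()}
    available = dict.fromkeys(ctrl_ids)  # insertion-ordered set
    matched_sets: list[tuple[str, list[str]]] = []
    unmatched: list[str] = []
    for idx in order:
        case = case_ids[idx]
        lc = lg[case]
        pool = list(available) if not spec.with_replacement else ctrl_ids
        dists = sorted(
            ((abs(lg[g] - lc), g) for g in pool), key=lambda t: (t[0], t[1])
        )
        # in-caliper controls form a prefix of the distance-sorted list
        take = [g for d, g in dists[: spec.ratio] if d <= caliper]
        if not take:
            unmatched.append(case)
            matched_sets.append((case, []))
            continue
        if not spec.with_replacement:
            for g in take:
                del available[g]
        matched_sets.append((case, take))
    # report in original case order for stable output
    by_case = dict(matched_sets)
    matched_sets = [(c, by_case[c]) for c in case_ids]
    return MatchResult(
        matched_sets=matched_sets,
        caliper_width=float(caliper),
        unmatched_cases=[c for c in case_ids if c in set(unmatched)],
    )


def covariate_balance(
    frame: pd.DataFrame,
    matched_ids: Sequence[str] | None = None,
    covariates: Sequence[tuple[str, str]] = (
        ("age", "continuous"),
        ("sex", "binary"),
        ("serum_creatinine", "continuous"),
    ),
) -> pd.DataFrame:
    """Standardized-difference balance table, pre- and post-matching.

    ``covariates`` is (name, kind) with kind continuous or binary; ``sex``
    is summarized as the proportion female, mirroring a characteristics
    table.  Returns one row per covariate with d_pre and (if matched ids are
    given) d_post.
    """
    def _d(sub: pd.DataFrame, name: str, kind: str) -> float:
        a = sub[sub["group"] == "case"][name]
        b = sub[sub["group"] == "control"][name]
        if kind == "binary":
            pa = float((a == "female").mean()) if a.dtype == object else float(a.mean())
            pb = float((b == "female").mean()) if b.dtype == object else float(b.mean())
            return standardized_difference(pa, pb, "binary")
        return standardized_difference(
            (a.mean(), a.std(ddof=1)), (b.mean(), b.std(ddof=1)), "continuous"
        )

    rows = []
    for name, kind in covariates:
        if name not in frame.columns:
            continue
        row = {"covariate": name, "kind": kind, "d_pre": _d(frame, name, kind)}
        if matched_ids is not None:
            sub = frame[frame["subject_id"].isin(set(matched_ids))]
            row["d_post"] = _d(sub, name, kind)
        rows.append(row)
    return pd.DataFrame(rows)
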