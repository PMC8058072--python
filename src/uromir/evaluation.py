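"""Rank statistics and diagnostic-accuracy evaluation.

The statistical core of biomarker qualification: Mann-Whitney rank tests,
ROC/AUC (via the AUC = U / (n1*n2) identity), Youden-index optimal cutoffs,
label-stratified k-fold cross-validation of single-marker scores, stratified
percentile-bootstrap confidence intervals, Spearman rank correlation, and
2x2 categorical tests (Fisher exact / Pearson chi-square).

All tests are two-sided; ties are handled with midranks throughout.  The
classification rule at a cutoff is ``score >= cutoff => case`` (higher
expression indicates disease).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import EvaluationError


@dataclass
class TestResult:
    statistic_name: str
    statistic_value: float
    p_value: float
    alpha: float = 0.05
    method: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class RocResult:
    """Single-cohort ROC summary: AUC with 95% CI and the Youden-optimal
    operating point attained on the input data."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_case: int
    n_control: int
    ci_method: str = "bootstrap"


@dataclass
class CvResult:
    k: int
    fold_train_aucs: list[float]
    fold_test_aucs: list[float]
    mean_train_auc: float
    mean_test_auc: float
    boot_ci_train: tuple[float, float] | None
    boot_ci_test: tuple[float, float] | None
    n_boot: int


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    method: str = "spearman"


@dataclass
class BootstrapInterval:
    low: float
    high: float
    level: float = 0.95
    n_redrawn: int = 0

    def __iter__(self):
        return iter((self.low, self.high))


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise EvaluationError(f"{name} must be non-empty")
    return arr


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    The p-value is exact (full enumeration of the U null distribution) for
    small tie-free samples (n_x + n_y <= 12); otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    pooled = np.concatenate([xa, ya])
    n1, n2 = xa.size, ya.size
    if pooled.size <= 12:
        # permutation enumeration of all C(n, n1) group assignments; the U
        # null distribution is symmetric about n1*n2/2 even with midranks,
        # so the two-sided p sums both tails via |U - mu|
        import itertools

        ranks = stats.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        u_obs = ranks[:n1].sum() - offset
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        hits = total = 0
        for comb in itertools.combinations(range(pooled.size), n1):
            u = ranks[list(comb)].sum() - offset
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                hits += 1
        return TestResult("U", float(u_obs), hits / total, method="exact")
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return TestResult(
        statistic_name="U",
        statistic_value=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method="asymptotic",
    )


def auc_from_scores(case_scores, control_scores) -> float:
    """AUC = P(case > control) + 0.5 P(case = control), via midranks.

    Identical to U / (n_case * n_control) from the Mann-Whitney statistic.
    """
    case = _as_array(case_scores, "case_scores")
    ctrl = _as_array(control_scores, "control_scores")
    ranks = stats.rankdata(np.concatenate([case, ctrl]))
    n1, n2 = case.size, ctrl.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def optimal_cutoff(case_scores, control_scores) -> tuple[float, float, float]:
    """Youden-optimal threshold: maximize J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct pooled scores plus the
    two degenerate extremes (everything case / everything control).  Ties in
    J are broken toward higher sensitivity, then toward the lower cutoff.
    Returns (cutoff, sensitivity, specificity).
    """
    case = _as_array(case_scores, "case_scores")
    ctrl = _as_array(control_scores, "control_scores")
    distinct = np.unique(np.concatenate([case, ctrl]))
    candidates = [distinct[0]]  # cutoff at the minimum: all classified case
    candidates += [0.5 * (a + b) for a, b in zip(distinct[:-1], distinct[1:])]
    candidates.append(distinct[-1] + 1.0)  # above the maximum: none case
    best = None
    for c in candidates:
        sens = float(np.mean(case >= c))
        spec = float(np.mean(ctrl < c))
        j = sens + spec - 1.0
        if best is None:
            best = (c, sens, spec, j)
            continue
        _, bsens, _, bj = best
        if j > bj + 1e-12 or (abs(j - bj) <= 1e-12 and sens > bsens + 1e-12):
            best = (c, sens, spec, j)
        # equal J and sensitivity: keep the earlier (lower) cutoff
    cutoff, sens, spec, _ = best
    return float(cutoff), sens, spec


def bootstrap_ci(
    statistic: Callable[..., float],
    data: Sequence[Sequence[float]],
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapInterval:
    """Group-stratified percentile bootstrap interval for a statistic.

    ``data`` is a sequence of strata (e.g. [case_scores, control_scores]);
    each is resampled with replacement within its own stratum.  A resample on
    which the statistic is undefined (raises or returns NaN) is redrawn and
    counted in ``n_redrawn``.
    """
    if B < 100:
        raise EvaluationError("B must be >= 100")
    strata = [_as_array(d, f"stratum {i}") for i, d in enumerate(data)]
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    redrawn = 0
    i = 0
    while i < B:
        resamples = [s[rng.integers(0, s.size, size=s.size)] for s in strata]
        try:
            v = float(statistic(*resamples))
        except Exception:
            v = math.nan
        if math.isnan(v):
            redrawn += 1
            if redrawn > 50 * B:
                raise EvaluationError("statistic undefined on almost all resamples")
            continue
        values[i] = v
        i += 1
    tail = (1.0 - level) / 2.0
    # (B+1)p order-statistic positioning (Weibull): the classical percentile
    # interval convention, better calibrated than type-7 at modest B
    lo, hi = np.quantile(values, [tail, 1.0 - tail], method="weibull")
    return BootstrapInterval(float(lo), float(hi), level, redrawn)


def roc_auc(
    case_scores,
    control_scores,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> RocResult:
    """ROC analysis of a single score: AUC, CI, and Youden operating point.

    ``ci_method`` is "bootstrap" (stratified percentile, default) or
    "hanley-mcneil" (analytic binormal-free variance approximation).
    """
    case = _as_array(case_scores, "case_scores")
    ctrl = _as_array(control_scores, "control_scores")
    auc = auc_from_scores(case, ctrl)
    if ci_method == "bootstrap":
        ci = bootstrap_ci(auc_from_scores, [case, ctrl], B=n_boot, level=level,
                          seed=seed)
        lo, hi = ci.low, ci.high
    elif ci_method == "hanley-mcneil":
        lo, hi = hanley_mcneil_ci(auc, case.size, ctrl.size, level)
    else:
        raise EvaluationError(f"unknown ci_method {ci_method!r}")
    cutoff, sens, spec = optimal_cutoff(case, ctrl)
    return RocResult(
        auc=auc, ci_low=float(lo), ci_high=float(hi),
        cutoff=cutoff, sensitivity=sens, specificity=spec,
        n_case=case.size, n_control=ctrl.size, ci_method=ci_method,
    )


def hanley_mcneil_ci(
    auc: float, n_case: int, n_control: int, level: float = 0.95
) -> tuple[float, float]:
    """Analytic AUC confidence interval (Hanley & McNeil variance)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_case - 1) * (q1 - auc**2)
        + (n_control - 1) * (q2 - auc**2)
    ) / (n_case * n_control)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def _stratified_folds(n_case: int, n_control: int, k: int, rng) -> list[tuple]:
    """Label-stratified fold assignment; returns per-fold (case idx, ctrl idx)."""
    case_order = rng.permutation(n_case)
    ctrl_order = rng.permutation(n_control)
    case_chunks = np.array_split(case_order, k)
    ctrl_chunks = np.array_split(ctrl_order, k)
    return list(zip(case_chunks, ctrl_chunks))


def _kfold_mean_aucs(case, ctrl, k, rng) -> tuple[float, float, list, list]:
    folds = _stratified_folds(case.size, ctrl.size, k, rng)
    train_aucs, test_aucs = [], []
    all_case = np.arange(case.size)
    all_ctrl = np.arange(ctrl.size)
    for case_test, ctrl_test in folds:
        case_train = np.setdiff1d(all_case, case_test)
        ctrl_train = np.setdiff1d(all_ctrl, ctrl_test)
        train_aucs.append(auc_from_scores(case[case_train], ctrl[ctrl_train]))
        test_aucs.append(auc_from_scores(case[case_test], ctrl[ctrl_test]))
    return (
        float(np.mean(train_aucs)),
        float(np.mean(test_aucs)),
        train_aucs,
        test_aucs,
    )


def kfold_cross_validate(
    scores,
    labels,
    k: int = 5,
    seed: int = 0,
    n_boot: int = 1000,
    level: float = 0.95,
) -> CvResult:
    """k-fold cross-validated ROC of a single marker score.

    Subjects are partitioned into k label-stratified, seeded folds; within
    each fold the score itself is evaluated by ROC on the training portion
    (k-1 folds) and the held-out test fold -- single-marker scores need no
    trained classifier.  The reported AUC per set is the arithmetic mean over
    folds; 95% CIs come from a within-class subject bootstrap that reruns
    the full k-fold procedure on each of ``n_boot`` resamples (pass
    ``n_boot=0`` to skip the CIs).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels)
    if scores.size != labels.size:
        raise EvaluationError("scores and labels must have equal length")
    lab = np.asarray([1 if l in (1, True, "case") else 0 for l in labels])
    case = scores[lab == 1]
    ctrl = scores[lab == 0]
    if case.size < k or ctrl.size < k:
        raise EvaluationError(
            f"each class needs >= k={k} subjects (got {case.size} cases, "
            f"{ctrl.size} controls)"
        )
    rng = np.random.default_rng(seed)
    mean_train, mean_test, train_aucs, test_aucs = _kfold_mean_aucs(case, ctrl, k, rng)

    ci_train = ci_test = None
    if n_boot:
        boot_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))

        def stat_train(c, g, _rng_state=[0]):
            r = np.random.default_rng(boot_seed + _rng_state[0])
            _rng_state[0] += 1
            return _kfold_mean_aucs(c, g, k, r)[0]

        def stat_test(c, g, _rng_state=[0]):
            r = np.random.default_rng(boot_seed + _rng_state[0])
            _rng_state[0] += 1
            return _kfold_mean_aucs(c, g, k, r)[1]

        ci_train = tuple(bootstrap_ci(stat_train, [case, ctrl], B=n_boot,
                                      level=level, seed=boot_seed))
        ci_test = tuple(bootstrap_ci(stat_test, [case, ctrl], B=n_boot,
                                     level=level, seed=boot_seed + 1))
    return CvResult(
        k=k,
        fold_train_aucs=train_aucs,
        fold_test_aucs=test_aucs,
        mean_train_auc=mean_train,
        mean_test_auc=mean_test,
        boot_ci_train=ci_train,
        boot_ci_test=ci_test,
        n_boot=n_boot,
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of midranks, p-value
    by the t approximation."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise EvaluationError("x and y must have equal length")
    if xa.size < 3:
        raise EvaluationError("need at least 3 paired observations")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        raise EvaluationError("zero rank variance: correlation undefined")
    res = stats.spearmanr(xa, ya)
    return CorrelationResult(r=float(res.statistic), n=xa.size,
                             p_value=float(res.pvalue))


def categorical_test(table) -> TestResult:
    """2x2 association test: Fisher's exact two-sided p (sum of
    hypergeometric probabilities no larger than the observed table's) unless
    every expected count exceeds 5, in which case the Pearson chi-square
    test applies.  The rule applied is recorded in ``method``."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise EvaluationError("table must be 2x2 non-negative integer counts")
    if t.sum() == 0:
        raise EvaluationError("all-zero contingency table")
    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if (expected <= 5).any():
        odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        return TestResult("odds_ratio", float(odds), min(1.0, float(p)),
                          method="fisher_exact")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return TestResult("chi2", float(chi2), float(p), method="pearson_chi2")
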