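"""qPCR normalization: replicate aggregation, data-driven internal-control
selection, and relative expression by the 2^-dCt method.

dCt = Ct_marker - Ct_reference, so rel_expr = 2^-dCt is expression relative
to the internal controls on a linear scale.  The reference Ct per sample is
the arithmetic mean over the selected internal-control assays (equivalently
the geometric mean of their expression), the standard convention when two
reference assays are used.

Internal controls are chosen by a global-mean criterion: the assays whose Ct
deviates least (smallest across-sample SD of Ct minus the per-sample global
mean over all assays) are the ones that best track overall miRNA content and
therefore serve as normalizers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CtMatrix
from .errors import EvaluationError, SelectionError

#: duplicate reactions further apart than this (cycles) are flagged
DEFAULT_DISCORDANCE_LIMIT = 1.0


@dataclass
class ExpressionMatrix:
    """Normalized relative expression per sample x marker.

    ``rel_expr`` holds 2^-dCt values (dimensionless, > 0, NaN = marker
    undetermined); ``delta_ct`` the corresponding dCt in cycles.
    """

    delta_ct: pd.DataFrame  # samples x markers, cycles
    rel_expr: pd.DataFrame  # samples x markers, 2^-dCt
    reference_assays: list[str]
    excluded_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.delta_ct.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.delta_ct.columns)

    def table(self, scale: float = 100.0) -> pd.DataFrame:
        """Report-style table of rel_expr x10^-2 (stored values stay unscaled)."""
        return self.rel_expr * scale

    def to_csv(self, path) -> None:
        self.rel_expr.to_csv(path, index_label="sample_id", na_rep="NA")

    @classmethod
    def from_csv(cls, path, reference_assays=()) -> "ExpressionMatrix":
        rel = pd.read_csv(path, index_col="sample_id", na_values=["NA"])
        return cls(
            delta_ct=-np.log2(rel),
            rel_expr=rel,
            reference_assays=list(reference_assays),
        )


def aggregate_replicates(
    matrix: CtMatrix, discordance_limit: float = DEFAULT_DISCORDANCE_LIMIT
) -> tuple[CtMatrix, list[tuple[str, str]]]:
    """Collapse replicate reactions to one Ct per (sample, assay) cell.

    Per-cell Ct is the arithmetic mean of finite replicates; a cell whose
    replicate range exceeds ``discordance_limit`` cycles is flagged (second
    return value), not dropped.  Cells with every replicate undetermined
    remain undetermined (NaN).
    """
    grouped = matrix.data.groupby(["sample_id", "assay_id"], sort=False)["ct"]
    mean_ct = grouped.mean()
    rng_ct = (grouped.max() - grouped.min()).fillna(0.0)
    flagged = [tuple(ix) for ix in rng_ct[rng_ct > discordance_limit].index]
    out = mean_ct.reset_index()
    out["replicate"] = 1
    out = out[["sample_id", "assay_id", "replicate", "ct"]]
    return CtMatrix(out, dict(matrix.assay_role)), flagged


def global_mean_scores(matrix: CtMatrix) -> pd.Series:
    """Stability score per assay: SD across samples of (Ct - per-sample
    global mean Ct over all assays).  Lower is more stable; an assay that is
    a constant offset from the global mean scores exactly 0."""
    wide = matrix.to_wide()
    deviation = wide.sub(wide.mean(axis=1), axis=0)
    return deviation.std(axis=0, ddof=1 if len(wide) > 1 else 0)


def select_internal_controls(matrix: CtMatrix, n_controls: int) -> list[str]:
    """Pick the ``n_controls`` assays most stable under the global-mean
    criterion; ties broken deterministically by assay id."""
    if n_controls < 1:
        raise SelectionError("n_controls must be >= 1")
    wide = matrix.to_wide()
    complete = wide.columns[wide.notna().all(axis=0)]
    if len(complete) < n_controls:
        incomplete = sorted(set(wide.columns) - set(complete))
        raise SelectionError(
            f"only {len(complete)} assays have complete Ct across samples "
            f"(need {n_controls}); incomplete assays: {incomplete}"
        )
    scores = global_mean_scores(matrix).loc[complete]
    order = sorted(scores.index, key=lambda a: (scores[a], a))
    return order[:n_controls]


def delta_ct(matrix: CtMatrix, reference_assays: list[str]) -> ExpressionMatrix:
    """Relative expression 2^-dCt against the mean of the reference assays.

    A sample missing a finite Ct for any reference assay cannot be
    normalized: it is excluded with a warning and listed in
    ``excluded_samples``.  Markers with undetermined Ct yield missing
    entries, never zeros.
    """
    if not reference_assays:
        raise EvaluationError("reference_assays must be non-empty")
    wide = aggregate_replicates(matrix)[0].to_wide()
    missing = [a for a in reference_assays if a not in wide.columns]
    if missing:
        raise EvaluationError(f"reference assays not in matrix: {missing}")
    refs = wide[list(reference_assays)]
    ok = refs.notna().all(axis=1)
    excluded = list(wide.index[~ok])
    if excluded:
        warnings.warn(
            f"{len(excluded)} sample(s) lack a finite reference Ct and were "
            f"excluded: {excluded}",
            stacklevel=2,
        )
    markers = [a for a in wide.columns if a not in reference_assays]
    kept = wide.loc[ok]
    ref_ct = kept[list(reference_assays)].mean(axis=1)
    dct = kept[markers].sub(ref_ct, axis=0)
    return ExpressionMatrix(
        delta_ct=dct,
        rel_expr=np.exp2(-dct),
        reference_assays=list(reference_assays),
        excluded_samples=excluded,
    )
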