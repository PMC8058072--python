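"""Discovery-stage differential screening of candidate markers.

Reproduces a microarray-style selection rule on the expression domain:
a marker is a hit when its absolute fold change exceeds a threshold (> 2.0
up or < 0.5 down by default) AND its two-sided Mann-Whitney p-value is below
alpha.  A stability filter then removes markers detected in too few samples.
No multiple-testing correction is applied at this discovery stage; raw
p-values feed a deliberately permissive screen that the training/test stage
must confirm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import mann_whitney
from .normalization import ExpressionMatrix


@dataclass
class ScreenRecord:
    marker_id: str
    fold_change: float  # case / control central expression
    direction: str  # "up" | "down"
    p_value: float
    detect_rate_case: float
    detect_rate_control: float
    selected: bool


def differential_screen(
    expr: ExpressionMatrix,
    labels,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    center: str = "mean",
) -> list[ScreenRecord]:
    """Screen every marker for differential expression between groups.

    ``labels`` maps sample id -> "case"/"control" (mapping or pandas
    Series).  fold_change = center(case rel_expr) / center(control
    rel_expr), with ``center`` the group mean (conventional fold change) or
    median.  Markers with fewer than 2 usable values in either group are
    skipped with a warning.
    """
    lab = pd.Series(labels)
    lab = lab.reindex(expr.sample_ids)
    centerfn = {"mean": np.mean, "median": np.median}[center]
    records: list[ScreenRecord] = []
    for marker in expr.marker_ids:
        values = expr.rel_expr[marker]
        case = values[lab == "case"].dropna().to_numpy()
        ctrl = values[lab == "control"].dropna().to_numpy()
        n_case_total = int((lab == "case").sum())
        n_ctrl_total = int((lab == "control").sum())
        if case.size < 2 or ctrl.size < 2:
            warnings.warn(
                f"marker {marker!r} skipped: fewer than 2 usable values in a group",
                stacklevel=2,
            )
            continue
        fc = float(centerfn(case) / centerfn(ctrl))
        p = mann_whitney(case, ctrl).p_value
        selected = (fc > fc_threshold or fc < 1.0 / fc_threshold) and p < alpha
        records.append(
            ScreenRecord(
                marker_id=marker,
                fold_change=fc,
                direction="up" if fc > 1.0 else "down",
                p_value=p,
                detect_rate_case=case.size / n_case_total,
                detect_rate_control=ctrl.size / n_ctrl_total,
                selected=selected,
            )
        )
    return records


def stability_filter(
    records: list[ScreenRecord], min_detect_rate: float
) -> list[ScreenRecord]:
    """Keep markers detected in at least ``min_detect_rate`` of the samples
    of *both* groups; input ordering is preserved."""
    return [
        r
        for r in records
        if r.detect_rate_case >= min_detect_rate
        and r.detect_rate_control >= min_detect_rate
    ]


def screen_table(records: list[ScreenRecord]) -> pd.DataFrame:
    """Screening report sorted by p-value."""
    frame = pd.DataFrame(
        {
            "marker": [r.marker_id for r in records],
            "fold_change": [r.fold_change for r in records],
            "direction": [r.direction for r in records],
            "p_value": [r.p_value for r in records],
            "detect_rate_case": [r.detect_rate_case for r in records],
            "detect_rate_control": [r.detect_rate_control for r in records],
            "selected": [r.selected for r in records],
        }
    )
    return frame.sort_values("p_value", kind="stable").reset_index(drop=True)
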