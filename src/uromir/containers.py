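"""Core data containers: subject records and the raw Ct matrix.

A Ct (threshold-cycle) value is the qPCR cycle at which fluorescence crosses
the detection threshold; lower Ct means more template.  "Undetermined"
reactions (no amplification within the run's cycle limit) are represented as
NaN and are treated as missing data throughout, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

CT_MAX = 45.0  # upper physical bound on a finite threshold cycle


class Group(str, Enum):
    control = "control"
    case = "case"


class AssayRole(str, Enum):
    candidate_marker = "candidate_marker"
    internal_control_candidate = "internal_control_candidate"


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: demographics, group label, tumor descriptors.

    ``tnm_stage``/``t_stage``/``histology`` are present only for cases.
    """

    subject_id: str
    group: str  # "control" | "case"
    age: float  # years, enrollment window 20-90
    sex: str  # "female" | "male"
    serum_creatinine: float  # mg/dl
    tnm_stage: str | None = None  # "I".."IV"
    t_stage: str | None = None  # "T1".."T4"
    histology: str | None = None

    def __post_init__(self):
        if self.group not in ("control", "case"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.sex not in ("female", "male"):
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if not 20 <= self.age <= 90:
            raise ConfigurationError(
                f"age {self.age} outside the enrollment window [20, 90]"
            )
        if (self.group == "case") != (self.tnm_stage is not None):
            raise ConfigurationError(
                "tnm_stage must be present for cases and absent for controls "
                f"(subject {self.subject_id})"
            )


def subjects_to_frame(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records, one row per participant."""
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "serum_creatinine": s.serum_creatinine,
            "tnm_stage": s.tnm_stage,
            "t_stage": s.t_stage,
            "histology": s.histology,
        }
        for s in subjects
    ]
    return pd.DataFrame(rows)


def subjects_from_frame(frame: pd.DataFrame) -> list[SubjectRecord]:
    def _opt(v):
        return None if (v is None or (isinstance(v, float) and np.isnan(v))) else v

    return [
        SubjectRecord(
            subject_id=str(r.subject_id),
            group=str(r.group),
            age=float(r.age),
            sex=str(r.sex),
            serum_creatinine=float(r.serum_creatinine),
            tnm_stage=_opt(getattr(r, "tnm_stage", None)),
            t_stage=_opt(getattr(r, "t_stage", None)),
            histology=_opt(getattr(r, "histology", None)),
        )
        for r in frame.itertuples(index=False)
    ]


@dataclass
class CtMatrix:
    """Raw qPCR threshold cycles in long format.

    ``data`` has columns ``sample_id, assay_id, replicate, ct`` with NaN as the
    undetermined sentinel; ``assay_role`` maps each assay to its role
    (candidate marker vs. internal-control candidate).  Sample and assay order
    is the order of first appearance in ``data``.
    """

    data: pd.DataFrame
    assay_role: Mapping[str, str] = field(default_factory=dict)

    REQUIRED = ("sample_id", "assay_id", "replicate", "ct")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"Ct table missing columns: {missing}")
        ct = self.data["ct"].to_numpy(dtype=float)
        finite = ct[np.isfinite(ct)]
        if finite.size and (finite.min() <= 0 or finite.max() > CT_MAX):
            raise ConfigurationError(
                f"finite Ct values must lie in (0, {CT_MAX}]"
            )
        self.assay_role = dict(self.assay_role)
        for a in self.assay_ids:
            self.assay_role.setdefault(a, AssayRole.candidate_marker.value)

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.data["sample_id"]))

    @property
    def assay_ids(self) -> list[str]:
        return list(pd.unique(self.data["assay_id"]))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def internal_control_candidates(self) -> list[str]:
        return [
            a
            for a in self.assay_ids
            if self.assay_role[a] == AssayRole.internal_control_candidate.value
        ]

    def drop_samples(self, sample_ids: Sequence[str]) -> "CtMatrix":
        drop = set(sample_ids)
        kept = self.data[~self.data["sample_id"].isin(drop)].reset_index(drop=True)
        return CtMatrix(kept, dict(self.assay_role))

    def subset_samples(self, sample_ids: Sequence[str]) -> "CtMatrix":
        keep = set(sample_ids)
        kept = self.data[self.data["sample_id"].isin(keep)].reset_index(drop=True)
        return CtMatrix(kept, dict(self.assay_role))

    def to_wide(self) -> pd.DataFrame:
        """Samples x assays table of per-cell mean Ct over finite replicates."""
        wide = self.data.pivot_table(
            index="sample_id", columns="assay_id", values="ct", aggfunc="mean"
        )
        return wide.reindex(index=self.sample_ids, columns=self.assay_ids)

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.data.copy(), dict(self.assay_role))
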