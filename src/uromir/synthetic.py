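"""Synthetic case-control cohort and qPCR Ct-matrix generator.

Emulates the design of a urinary-miRNA biomarker study: an age/sex-matched
control group and a cancer case group, a panel of candidate marker assays
whose case-group Ct means are shifted down (higher expression), a few stably
expressed internal-control assays, TNM stage labels for cases with an
optional rank correlation between one marker's expression and stage, and a
small rate of poor-quality samples that are excluded, not imputed.

Noise model: Ct values are Gaussian in the cycle domain, i.e. expression
(2^-dCt) is log2-normal -- the cycle domain *is* the log2 scale, so a shift of
delta cycles is a 2^delta fold change and the single-marker AUC has the
binormal closed form Phi(delta / (sigma * sqrt(2))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .containers import AssayRole, CtMatrix, SubjectRecord
from .errors import ConfigurationError

#: technical jitter between duplicate qPCR reactions (cycles)
REPLICATE_JITTER_SD = 0.15

# Case-mix frequencies of the emulated cohort (43 ESCC cases):
# TNM stage I/II/III/IV and primary-tumor T1..T4.
DEFAULT_STAGE_PROBS = (16 / 43, 4 / 43, 12 / 43, 11 / 43)
DEFAULT_T_STAGE_PROBS = (21 / 43, 1 / 43, 10 / 43, 11 / 43)


def shift_for_auc(auc: float, noise_sd: float = 1.0) -> float:
    """Ct shift (cycles) giving a target single-marker AUC.

    Inverts the binormal identity AUC = Phi(delta / (sigma*sqrt(2))) for two
    Gaussian groups with common SD ``noise_sd`` on the Ct scale.
    """
    if not 0.0 < auc < 1.0:
        raise ConfigurationError("auc must be in (0, 1)")
    return float(noise_sd * math.sqrt(2.0) * norm.ppf(auc))


@dataclass(frozen=True)
class MarkerSpec:
    """One candidate marker assay: its case-vs-control Ct shift and noise."""

    name: str
    delta_ct_shift: float  # cycles; positive => lower Ct (higher expression) in cases
    noise_sd: float  # cycles, between-subject biological + assay noise


@dataclass
class SimulationConfig:
    """Full description of one simulated study; generation is a pure
    function of this object (including ``seed``)."""

    n_control: int = 299
    n_case: int = 44
    marker_specs: list[MarkerSpec] = field(default_factory=list)
    n_internal_controls: int = 2
    internal_control_sd: float = 0.3  # cycles
    stage_probs: tuple[float, float, float, float] = DEFAULT_STAGE_PROBS
    stage_corr_marker: str | None = None
    stage_corr_rho: float = 0.0  # target Spearman r between expression and stage
    poor_quality_rate: float = 0.094  # fraction of samples failing RNA QC
    replicate_count: int = 2
    seed: int = 0
    # marginals not pinned down by the emulated study beyond medians/IQRs;
    # exposed as parameters
    age_mean: float = 68.0
    age_sd: float = 7.5
    case_age_shift: float = 0.0  # pre-matching imbalance knob (years)
    female_prob: float = 0.10
    creatinine_log_mean: float = math.log(0.84)
    creatinine_log_sd: float = 0.16
    t_stage_probs: tuple[float, float, float, float] = DEFAULT_T_STAGE_PROBS
    sample_loading_sd: float = 0.0  # per-sample global Ct offset (cycles)
    replicate_jitter_sd: float = REPLICATE_JITTER_SD

    def validate(self) -> None:
        if self.n_control < 1:
            raise ConfigurationError("n_control must be >= 1")
        if self.n_case < 1:
            raise ConfigurationError("n_case must be >= 1")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ConfigurationError("stage_probs must sum to 1 within 1e-9")
        if any(p < 0 for p in self.stage_probs):
            raise ConfigurationError("stage_probs must be non-negative")
        for spec in self.marker_specs:
            if spec.noise_sd <= 0:
                raise ConfigurationError(
                    f"marker_specs: noise_sd must be > 0 (marker {spec.name!r})"
                )
        names = [m.name for m in self.marker_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("marker_specs: duplicate marker names")
        if self.n_internal_controls < 0:
            raise ConfigurationError("n_internal_controls must be >= 0")
        if self.internal_control_sd <= 0:
            raise ConfigurationError("internal_control_sd must be > 0")
        if not 0.0 <= self.poor_quality_rate < 1.0:
            raise ConfigurationError("poor_quality_rate must be in [0, 1)")
        if self.replicate_count < 1:
            raise ConfigurationError("replicate_count must be >= 1")
        if not -1.0 <= self.stage_corr_rho <= 1.0:
            raise ConfigurationError("stage_corr_rho must be in [-1, 1]")
        if self.stage_corr_marker is not None and self.stage_corr_marker not in names:
            raise ConfigurationError(
                f"stage_corr_marker {self.stage_corr_marker!r} not in marker_specs"
            )


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The emulated study's conditions: an 8-marker urinary panel whose Ct
    shifts are back-solved from the reported training-set AUCs (sigma = 1
    cycle), three of them null, two stable internal controls, and one marker
    whose expression decreases with stage (Spearman r = -0.435)."""
    target_aucs = {
        "miR-1273f": 0.792,
        "miR-619-5p": 0.786,
        "miR-150-3p": 0.692,
        "miR-4327": 0.639,
        "miR-3135b": 0.620,
        "miR-5585-3p": 0.5,
        "miR-6875-5p": 0.5,
        "miR-345-3p": 0.5,
    }
    markers = [
        MarkerSpec(name, 0.0 if auc == 0.5 else shift_for_auc(auc), 1.0)
        for name, auc in target_aucs.items()
    ]
    cfg = SimulationConfig(
        marker_specs=markers,
        stage_corr_marker="miR-4327",
        stage_corr_rho=-0.435,
        seed=seed,
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ConfigurationError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


_STAGES = ("I", "II", "III", "IV")
_T_STAGES = ("T1", "T2", "T3", "T4")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[list[SubjectRecord], CtMatrix]:
    """Generate the subject table and raw Ct matrix for one cohort.

    Case-group Ct means are shifted by -delta_ct_shift per marker (lower Ct =
    higher expression).  The stage correlation, when requested, is injected
    by a Gaussian copula between the designated marker's Ct noise and a
    latent stage variable, preserving both marginals while targeting the
    Spearman coefficient.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ctrl, n_case = config.n_control, config.n_case
    n = n_ctrl + n_case
    is_case = np.zeros(n, dtype=bool)
    is_case[n_ctrl:] = True

    ages = _truncated_normal(rng, config.age_mean, config.age_sd, 20.0, 90.0, n)
    ages[is_case] = np.clip(ages[is_case] + config.case_age_shift, 20.0, 90.0)
    sexes = np.where(rng.random(n) < config.female_prob, "female", "male")
    creat = np.exp(rng.normal(config.creatinine_log_mean, config.creatinine_log_sd, n))

    # latent stage variable for cases (Gaussian copula margin)
    z_stage = rng.standard_normal(n_case)
    cuts = norm.ppf(np.cumsum(config.stage_probs)[:-1])
    stage_idx = np.searchsorted(cuts, z_stage)
    t_idx = rng.choice(4, size=n_case, p=np.asarray(config.t_stage_probs))

    subjects: list[SubjectRecord] = []
    width = len(str(n))
    for i in range(n):
        case = bool(is_case[i])
        j = i - n_ctrl
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:0{width}d}",
                group="case" if case else "control",
                age=round(float(ages[i]), 1),
                sex=str(sexes[i]),
                serum_creatinine=round(float(creat[i]), 3),
                tnm_stage=_STAGES[stage_idx[j]] if case else None,
                t_stage=_T_STAGES[t_idx[j]] if case else None,
                histology="squamous cell carcinoma" if case else None,
            )
        )

    # assay panel: markers then internal controls, baselines fixed per assay
    marker_names = [m.name for m in config.marker_specs]
    ic_names = [f"IC-{k + 1}" for k in range(config.n_internal_controls)]
    if config.n_internal_controls >= 1:
        ic_names[0] = "miR-4669"
    if config.n_internal_controls >= 2:
        ic_names[1] = "miR-6756-5p"
    base_marker = rng.uniform(24.0, 32.0, size=len(marker_names))
    base_ic = rng.uniform(22.0, 26.0, size=len(ic_names))
    loading = rng.normal(0.0, config.sample_loading_sd, size=n) \
        if config.sample_loading_sd > 0 else np.zeros(n)

    # copula coupling for the stage-correlated marker: expression = 2^-dCt is
    # decreasing in Ct, so target Spearman(Ct, stage) = -rho; the Gaussian
    # latent correlation uses the bivariate-normal Spearman inversion.
    rho = config.stage_corr_rho
    r_gauss = 2.0 * math.sin(math.pi * (-rho) / 6.0)

    ct_cols: dict[str, np.ndarray] = {}
    for a, spec in enumerate(config.marker_specs):
        z = rng.standard_normal(n)
        if config.stage_corr_marker == spec.name and rho != 0.0:
            z[is_case] = r_gauss * z_stage + math.sqrt(1 - r_gauss**2) * z[is_case]
        ct = base_marker[a] + loading + spec.noise_sd * z
        ct[is_case] -= spec.delta_ct_shift
        ct_cols[spec.name] = ct
    for k, name in enumerate(ic_names):
        ct_cols[name] = base_ic[k] + loading + rng.normal(
            0.0, config.internal_control_sd, size=n
        )

    sample_ids = [s.subject_id for s in subjects]
    records = []
    for name in marker_names + ic_names:
        ct1 = np.clip(ct_cols[name], 1e-3, 45.0)
        for rep in range(1, config.replicate_count + 1):
            ct = ct1 if rep == 1 else np.clip(
                ct1 + rng.normal(0.0, config.replicate_jitter_sd, size=n), 1e-3, 45.0
            )
            records.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_ids,
                        "assay_id": name,
                        "replicate": rep,
                        "ct": np.round(ct, 4),
                    }
                )
            )
    data = pd.concat(records, ignore_index=True)
    roles = {m: AssayRole.candidate_marker.value for m in marker_names}
    roles.update({c: AssayRole.internal_control_candidate.value for c in ic_names})
    return subjects, CtMatrix(data, roles)


def apply_quality_failures(
    matrix: CtMatrix, rate: float, seed: int
) -> tuple[CtMatrix, list[str]]:
    """Exclude a random subset of samples as poor-RNA-quality failures.

    Each sample fails independently with probability ``rate`` (expected
    excluded count = rate * n).  Excluded samples are removed from the
    matrix, mirroring a study design that drops rather than imputes them.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError("poor-quality rate must be in [0, 1)")
    samples = matrix.sample_ids
    if rate == 0.0:
        return matrix.copy(), []
    rng = np.random.default_rng(seed)
    fail = rng.random(len(samples)) < rate
    excluded = [s for s, f in zip(samples, fail) if f]
    if len(excluded) == len(samples):
        raise ConfigurationError(
            "quality exclusion removed every sample; no cohort remains"
        )
    return matrix.drop_samples(excluded), excluded


# ---------------------------------------------------------------------------
# round-trippable on-disk formats

def write_subjects_csv(subjects: Sequence[SubjectRecord], path) -> None:
    from .containers import subjects_to_frame

    subjects_to_frame(subjects).to_csv(path, index=False)


def read_subjects_csv(path) -> list[SubjectRecord]:
    from .containers import subjects_from_frame

    return subjects_from_frame(pd.read_csv(path))


def write_ct_csv(matrix: CtMatrix, path) -> None:
    """Long-format CSV (sample_id, assay_id, replicate, ct), NA = undetermined."""
    matrix.data.to_csv(path, index=False, na_rep="NA")


def read_ct_csv(path, assay_role=None) -> CtMatrix:
    data = pd.read_csv(path, na_values=["NA"])
    return CtMatrix(data, assay_role or {})


def write_config(config: SimulationConfig, path) -> None:
    doc = asdict(config)
    doc["marker_specs"] = [list(asdict(m).values()) for m in config.marker_specs]
    doc["stage_probs"] = list(config.stage_probs)
    doc["t_stage_probs"] = list(config.t_stage_probs)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text())
    doc["marker_specs"] = [MarkerSpec(*row) for row in doc.get("marker_specs", [])]
    doc["stage_probs"] = tuple(doc["stage_probs"])
    doc["t_stage_probs"] = tuple(doc["t_stage_probs"])
    cfg = SimulationConfig(**doc)
    cfg.validate()
    return cfg
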