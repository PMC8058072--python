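import numpy as np
import pandas as pd
import pytest

import uromir as u


def make_ct(cells, roles=None):
    """Build a CtMatrix from {(sample, assay): ct-or-[replicates]}."""
    rows = []
    for (s, a), v in cells.items():
        vals = v if isinstance(v, (list, tuple)) else [v]
        for i, ct in enumerate(vals, start=1):
            rows.append({"sample_id": s, "assay_id": a, "replicate": i, "ct": ct})
    return u.CtMatrix(pd.DataFrame(rows), roles or {})


def make_ps_results(logits, groups):
    """Synthetic PropensityResults for matching tests: subject Si has the
    given logit propensity and group label."""
    from types import SimpleNamespace

    ids = [f"S{i}" for i in range(len(logits))]
    frame = pd.DataFrame({"subject_id": ids, "group": groups})
    ps = 1.0 / (1.0 + np.exp(-np.asarray(logits, dtype=float)))
    return u.PropensityResults(
        model=SimpleNamespace(frame=frame),
        coefficients=pd.Series(dtype=float),
        ps=pd.Series(ps, index=ids),
        c_statistic=0.5,
    )


@pytest.fixture
def small_cohort():
    """One deterministic 60/20 cohort with a strong and a null marker."""
    cfg = u.SimulationConfig(
        n_control=60,
        n_case=20,
        marker_specs=[u.MarkerSpec("hit", 1.5, 1.0), u.MarkerSpec("null", 0.0, 1.0)],
        n_internal_controls=2,
        poor_quality_rate=0.0,
        seed=42,
    )
    return u.simulate_cohort(cfg)
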