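import numpy as np
import pandas as pd
import pytest

from cyclekin import CyclePopulationParams, analytic_labeled_fraction


def exact_curve(
    params: CyclePopulationParams,
    times,
    n_replicates: int = 2,
    n_fields: int = 1,
) -> pd.DataFrame:
    """Noise-free labeling curve: fractions encoded with unit-weight rows.

    Float 'counts' keep the observed fractions exactly equal to the analytic
    law, so estimator exactness can be asserted to floating-point precision.
    """
    rows = []
    for rep in range(1, n_replicates + 1):
        for fld in range(1, n_fields + 1):
            for t in times:
                rows.append(
                    {
                        "time_h": float(t),
                        "replicate": rep,
                        "field": fld,
                        "label": params.label,
                        "n_total": 1.0,
                        "n_labeled": analytic_labeled_fraction(params, float(t)),
                    }
                )
    return pd.DataFrame(rows)


def curve_from_line(m: float, b: float, times, jitter=None, seed: int = 0):
    """Labeling-curve table whose pooled fractions lie on m*t + b."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in times:
        y = m * t + b
        if jitter:
            y += rng.normal(0, jitter)
        rows.append(
            {
                "time_h": float(t),
                "replicate": 1,
                "field": 1,
                "label": "marker_pos",
                "n_total": 1.0,
                "n_labeled": min(max(y, 0.0), 1.0),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def standard_params() -> CyclePopulationParams:
    return CyclePopulationParams(tc=40.0, ts=16.0, gf=0.8, label="marker_pos")
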