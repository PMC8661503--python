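"""Flow-cytometry gating and reporter-positive timecourses.

Gating follows the conventional two-step scheme for a knock-in fluorescent
reporter with a parental (non-reporter) control line:

1. viability gate — events whose viability-dye intensity exceeds a fixed
   multiple of the sample median are discarded as dead;
2. positivity gate — the threshold on the reporter channel is a high
   percentile (default 99.9) of the *matched negative control's* viable
   events; the positive fraction is the % of viable sample events above it.

Per-(day, condition) positive fractions are then assembled into a
timecourse with across-replicate mean +/- SEM, and condition contrasts are
summarized as percent reduction or fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MissingControlError, ParameterError
from .io import validate_flow_events

__all__ = [
    "GateResult",
    "gate_viable",
    "gate_positive",
    "gate_timecourse_events",
    "build_timecourse",
    "percent_reduction",
    "fold_change",
]

DEFAULT_VIABILITY_MULTIPLE = 4.0
DEFAULT_CONTROL_PERCENTILE = 99.9


@dataclass(frozen=True)
class GateResult:
    """Outcome of gating one sample against its matched negative control."""

    threshold: float  # reporter-intensity units
    positive_fraction: float  # % of viable events
    n_viable: int
    n_total: int
    n_positive: int = 0

    def to_dict(self) -> Dict:
        return {
            "threshold": self.threshold,
            "positive_fraction_pct": self.positive_fraction,
            "n_viable": self.n_viable,
            "n_total": self.n_total,
            "n_positive": self.n_positive,
        }


def gate_viable(
    events: pd.DataFrame, viability_multiple: float = DEFAULT_VIABILITY_MULTIPLE
) -> pd.DataFrame:
    """Discard dead events: viability-dye intensity above ``multiple`` x median.

    The dye (e.g. DAPI) enters only membrane-compromised cells, so dead
    events sit far above the live-cell median of the same sample.
    """
    validate_flow_events(events)
    if events.empty:
        raise ParameterError("cannot viability-gate an empty event table")
    if viability_multiple <= 1:
        raise ParameterError("viability multiple must exceed 1")
    threshold = viability_multiple * float(events["viability_intensity"].median())
    return events[events["viability_intensity"] <= threshold]


def gate_positive(
    sample: pd.DataFrame,
    control: pd.DataFrame,
    percentile: float = DEFAULT_CONTROL_PERCENTILE,
) -> GateResult:
    """Gate reporter positivity against a matched negative control.

    The threshold is the ``percentile``-th percentile of the control's
    reporter intensities (both tables are expected viability-gated); by
    construction roughly ``100 - percentile`` % of control events fall above
    it, which bounds the false-positive rate.
    """
    if sample.empty:
        raise ParameterError("cannot gate an empty sample")
    if control.empty:
        raise MissingControlError("empty/missing matched negative control")
    if not 0 < percentile < 100:
        raise ParameterError(f"percentile must be in (0,100), got {percentile}")

    threshold = float(np.percentile(control["reporter_intensity"], percentile))
    n_viable = len(sample)
    n_positive = int((sample["reporter_intensity"] > threshold).sum())
    return GateResult(
        threshold=threshold,
        positive_fraction=100.0 * n_positive / n_viable,
        n_viable=n_viable,
        n_total=n_viable,
        n_positive=n_positive,
    )


def gate_timecourse_events(
    events: pd.DataFrame,
    percentile: float = DEFAULT_CONTROL_PERCENTILE,
    viability_multiple: float = DEFAULT_VIABILITY_MULTIPLE,
) -> pd.DataFrame:
    """Gate every reporter sample in a multi-sample event table.

    Samples are keyed by (day, condition, replicate); the matched negative
    control is the ``role == "negative_control"`` sample with the same
    (day, replicate).  A missing control is an error — never silently
    gated against a pooled or neighbouring-day control.

    Returns one row per gated sample:
    ``day, condition, replicate, positive_fraction, threshold, n_viable, n_total``.
    """
    validate_flow_events(events)
    controls = {
        key: grp
        for key, grp in events[events["role"] == "negative_control"].groupby(
            ["day", "replicate"]
        )
    }
    rows = []
    reporters = events[events["role"] == "reporter"]
    for (day, cond, rep), grp in reporters.groupby(["day", "condition", "replicate"]):
        key = (day, rep)
        if key not in controls:
            raise MissingControlError(
                f"no matched negative control for day={day}, replicate={rep}"
            )
        n_total = len(grp)
        viable = gate_viable(grp, viability_multiple)
        control_viable = gate_viable(controls[key], viability_multiple)
        gr = gate_positive(viable, control_viable, percentile)
        rows.append(
            {
                "day": day,
                "condition": cond,
                "replicate": rep,
                "positive_fraction": gr.positive_fraction,
                "threshold": gr.threshold,
                "n_viable": gr.n_viable,
                "n_total": n_total,
            }
        )
    return pd.DataFrame(rows)


def build_timecourse(gated: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-replicate gate results into a (day, condition) timecourse.

    Returns mean positive fraction +/- SEM per (day, condition), days sorted
    ascending within condition.  SEM is NaN for a single replicate.  Missing
    days are simply absent — no interpolation.
    """
    required = {"day", "condition", "replicate", "positive_fraction"}
    missing = required - set(gated.columns)
    if missing:
        raise ParameterError(f"gated table missing columns {sorted(missing)}")
    dup = gated.duplicated(subset=["day", "condition", "replicate"])
    if dup.any():
        raise ParameterError(
            "duplicate (day, condition, replicate) keys in gated results"
        )

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    out = (
        gated.groupby(["condition", "day"])["positive_fraction"]
        .agg(mean_positive_fraction="mean", sem_positive_fraction=_sem,
             n_replicates="count")
        .reset_index()
        .sort_values(["condition", "day"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def percent_reduction(reference: float, treated: float) -> float:
    """Percent reduction of ``treated`` relative to ``reference`` (both %)."""
    if reference <= 0:
        raise ParameterError(f"reference must be > 0, got {reference}")
    return 100.0 * (reference - treated) / reference


def fold_change(reference: float, treated: float) -> float:
    """Fold decrease: reference / treated."""
    if treated <= 0:
        raise ParameterError(f"treated value must be > 0, got {treated}")
    return reference / treated
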