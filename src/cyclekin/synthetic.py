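"""Synthetic cycling/differentiating progenitor populations.

Every input table the estimation stages consume can be generated here from
known ground truth, so each estimator is validated by parameter recovery.

The population model is a non-expanding renewal process: cell-cycle positions
are uniform on ``[0, tc)`` and at each mitosis the mother is replaced by a
single tracked daughter (which inherits the EdU label).  Under this scheme
uniformity is exactly stationary, and the expected cumulatively-labeled
fraction follows the linear law

    f(t) = gf * min((ts + t) / tc, 1)

rising from the intercept ``gf*ts/tc`` to the plateau ``gf`` at
``t = tc - ts``.  ``analytic_labeled_fraction`` is that closed form and
serves as the oracle for the Monte-Carlo simulator.

EdU label is binary and permanent (no dilution across divisions), which is
adequate for exposure windows of a day or less.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ParameterError
from .params import CyclePopulationParams, FlowNoiseParams, MixtureSpec, TrajectoryParams

__all__ = [
    "analytic_labeled_fraction",
    "simulate_cumulative_labeling",
    "simulate_pulse_chase",
    "simulate_flow_sample",
    "simulate_flow_timecourse",
]


def analytic_labeled_fraction(
    params: CyclePopulationParams, t: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Expected labeled fraction after cumulative S-phase labeling for ``t`` hours.

    Closed form ``gf * min((ts + t)/tc, 1)``: at t=0 only cells currently in
    S are labeled (``gf*ts/tc``); the fraction grows linearly with slope
    ``gf/tc`` until every cycling cell has traversed S at ``t = tc - ts``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError(f"exposure time must be >= 0, got {t}")
    frac = params.gf * np.minimum((params.ts + t_arr) / params.tc, 1.0)
    return float(frac) if np.isscalar(t) else frac


def _labeled_mask(
    params: CyclePopulationParams, phases: np.ndarray, t: float
) -> np.ndarray:
    """Which cycling cells (at cycle position ``phases``) overlap S during [0, t].

    A cell is labeled iff it is in S at exposure start or enters S within the
    window; with positions advancing at unit rate mod tc the labeled arc has
    length min(ts + t, tc).
    """
    s0 = params.s_entry_phase
    in_s_now = (phases - s0) % params.tc < params.ts
    enters_s = (s0 - phases) % params.tc < t
    return in_s_now | enters_s


def _draw_phases(
    rng: np.random.Generator, n: int, params: CyclePopulationParams, mode: str
) -> np.ndarray:
    """Initial cycle positions: uniform (stationary) or growth-skewed.

    Exponential-growth mode inverts the CDF of the age density
    (2 ln2 / tc) * 2^(-a/tc), which overrepresents young (early-G1) cells.
    """
    u = rng.random(n)
    if mode == "exponential_growth":
        return -params.tc * np.log2(1.0 - u / 2.0)
    return u * params.tc


def simulate_cumulative_labeling(
    spec: MixtureSpec, times: Sequence[float]
) -> pd.DataFrame:
    """Simulate a cumulative-labeling experiment over exposure ``times``.

    Each (replicate, field, subpopulation) cell sample is drawn once and
    scored at every exposure time (common random numbers), so the labeled
    fraction is non-decreasing in ``t`` within a run, as it is for a real
    culture followed over time.

    Returns a tidy labeling-curve table with columns
    ``time_h, replicate, field, label, n_total, n_labeled``.
    """
    times = [float(t) for t in times]
    if not times:
        raise ParameterError("need at least one exposure time")
    if any(t <= 0 for t in times):
        raise ParameterError(f"exposure times must be > 0, got {times}")

    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(1, spec.n_replicates + 1):
        for fld in range(1, spec.n_fields + 1):
            for params, prop in spec.components:
                n = int(rng.poisson(spec.n_cells_per_field * prop))
                cycling = rng.random(n) < params.gf
                phases = _draw_phases(rng, n, params, spec.phase_distribution)
                for t in times:
                    labeled = cycling & _labeled_mask(params, phases, t)
                    rows.append(
                        {
                            "time_h": t,
                            "replicate": rep,
                            "field": fld,
                            "label": params.label,
                            "n_total": n,
                            "n_labeled": int(labeled.sum()),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_pulse_chase(
    spec: MixtureSpec, pulse: float, chase: float, ki67_lag: float = 0.0
) -> pd.DataFrame:
    """Simulate a pulse-chase experiment and cross-tabulate marker x EdU x Ki67.

    Cells in S during the pulse window become EdU+.  Whenever a cell reaches
    mitosis (during pulse or chase) the tracked daughter exits the cycle with
    probability ``quit_prob``; exited cells stop progressing and can no
    longer incorporate label.  Ki67 is lost ``ki67_lag`` hours after the exit
    mitosis (default 0: immediate loss), so late exits may still score Ki67+
    at the endpoint.  Non-cycling cells (the 1 - gf complement) are
    EdU-Ki67- throughout.

    Returns a tidy count table with columns
    ``replicate, field, marker, edu, ki67, count, pulse_h, chase_h``.
    """
    if pulse <= 0:
        raise ParameterError(f"pulse length must be > 0, got {pulse}")
    if chase < 0:
        raise ParameterError(f"chase length must be >= 0, got {chase}")
    if ki67_lag < 0:
        raise ParameterError(f"ki67_lag must be >= 0, got {ki67_lag}")

    rng = np.random.default_rng(spec.seed)
    total_t = pulse + chase
    rows = []
    for rep in range(1, spec.n_replicates + 1):
        for fld in range(1, spec.n_fields + 1):
            for params, prop in spec.components:
                n = int(rng.poisson(spec.n_cells_per_field * prop))
                cycling = rng.random(n) < params.gf
                phases = _draw_phases(rng, n, params, spec.phase_distribution)

                # first-exit mitosis index (1-based); inf when quit_prob == 0
                if params.quit_prob > 0:
                    j_exit = rng.geometric(params.quit_prob, size=n).astype(float)
                else:
                    j_exit = np.full(n, np.inf)

                edu, ki67 = _pulse_chase_fate(
                    params, phases, cycling, j_exit, pulse, total_t, ki67_lag
                )
                tab = (
                    pd.DataFrame({"edu": edu, "ki67": ki67})
                    .value_counts()
                    .reindex(
                        [(e, k) for e in ("pos", "neg") for k in ("pos", "neg")],
                        fill_value=0,
                    )
                )
                for (e, k), count in tab.items():
                    rows.append(
                        {
                            "replicate": rep,
                            "field": fld,
                            "marker": params.label,
                            "edu": e,
                            "ki67": k,
                            "count": int(count),
                            "pulse_h": pulse,
                            "chase_h": chase,
                        }
                    )
    return pd.DataFrame(rows)


def _pulse_chase_fate(
    params: CyclePopulationParams,
    phases: np.ndarray,
    cycling: np.ndarray,
    j_exit: np.ndarray,
    pulse: float,
    total_t: float,
    ki67_lag: float = 0.0,
):
    """Vectorized per-cell EdU/Ki67 outcome at the chase endpoint.

    For a cell at initial position ``a`` the k-th mitosis falls at
    ``k*tc - a``.  Let ``t_L`` be the first time in [0, pulse] the cell is in
    S (if any), ``k_L`` the number of mitoses strictly before ``t_L`` and
    ``K_m`` the number of mitoses early enough for Ki67 to have decayed by
    the endpoint (mitosis time <= total_t - ki67_lag).  With ``J`` the first
    mitosis at which exit fires, the cell is EdU+ iff it reaches S during
    the pulse before exiting (``J > k_L``), and Ki67- iff ``J <= K_m``.
    """
    tc, ts = params.tc, params.ts
    s0 = params.s_entry_phase

    in_s_now = (phases - s0) % tc < ts
    d_entry = (s0 - phases) % tc  # time to next S entry
    t_label = np.where(in_s_now, 0.0, d_entry)
    reaches_s = t_label < pulse

    k_before_label = np.floor((t_label + phases) / tc + 1e-12)
    k_ki67 = np.maximum(
        np.floor((total_t - ki67_lag + phases) / tc + 1e-12), 0.0
    )

    survives_to_label = j_exit > k_before_label
    edu_pos = cycling & reaches_s & survives_to_label
    ki67_lost = cycling & (j_exit <= k_ki67)
    ki67_pos = cycling & ~ki67_lost

    edu = np.where(edu_pos, "pos", "neg")
    ki67 = np.where(ki67_pos, "pos", "neg")
    return edu, ki67


def simulate_flow_sample(
    trajectory: TrajectoryParams,
    day: float,
    n_events: int,
    seed: int,
    condition: str = "control",
    replicate: int = 1,
    noise: Optional[FlowNoiseParams] = None,
    include_control: bool = True,
) -> pd.DataFrame:
    """Simulate one flow-cytometry sample (and its matched negative control).

    Events are a two-component reporter-intensity mixture: a log-normal
    background for reporter-negative cells and a right-shifted log-normal for
    reporter-positive cells, with positive prevalence given by the conversion
    trajectory at ``day``.  A ``dead_fraction`` of events carries elevated
    viability-dye intensity.  The matched negative-control sample (parental,
    non-reporter line) has zero positive prevalence by construction.

    Returns an event table with columns
    ``reporter_intensity, viability_intensity, day, condition, role, replicate``.
    """
    if n_events < 1:
        raise ParameterError(f"n_events must be >= 1, got {n_events}")
    noise = noise or FlowNoiseParams()
    rng = np.random.default_rng(seed)

    frames = [
        _flow_events(
            rng, n_events, trajectory.prevalence(day), noise, day, condition,
            "reporter", replicate,
        )
    ]
    if include_control:
        frames.append(
            _flow_events(
                rng, n_events, 0.0, noise, day, condition,
                "negative_control", replicate,
            )
        )
    return pd.concat(frames, ignore_index=True)


def _flow_events(
    rng: np.random.Generator,
    n: int,
    prevalence: float,
    noise: FlowNoiseParams,
    day: float,
    condition: str,
    role: str,
    replicate: int,
) -> pd.DataFrame:
    dead = rng.random(n) < noise.dead_fraction
    positive = (rng.random(n) < prevalence) & ~dead

    reporter = np.where(
        positive,
        noise.positive_median * np.exp(rng.normal(0, noise.positive_sigma, n)),
        noise.background_median * np.exp(rng.normal(0, noise.background_sigma, n)),
    )
    viability = noise.viability_median * np.exp(
        rng.normal(0, noise.viability_sigma, n)
    )
    viability = np.where(dead, viability * noise.dead_viability_multiple, viability)

    return pd.DataFrame(
        {
            "reporter_intensity": reporter,
            "viability_intensity": viability,
            "day": day,
            "condition": condition,
            "role": role,
            "replicate": replicate,
        }
    )


def simulate_flow_timecourse(
    trajectories: Mapping[str, TrajectoryParams],
    days: Sequence[float],
    n_events: int,
    n_replicates: int,
    seed: int,
    noise: Optional[FlowNoiseParams] = None,
) -> pd.DataFrame:
    """Simulate a differentiation timecourse across conditions.

    One reporter sample per (day, condition, replicate) plus one matched
    negative-control sample per (day, replicate), shared across conditions
    as in a single-batch experiment.
    """
    rng = np.random.default_rng(seed)
    noise = noise or FlowNoiseParams()
    frames = []
    for day in days:
        for rep in range(1, n_replicates + 1):
            for cond, traj in trajectories.items():
                frames.append(
                    _flow_events(
                        rng, n_events, traj.prevalence(day), noise,
                        day, cond, "reporter", rep,
                    )
                )
            frames.append(
                _flow_events(
                    rng, n_events, 0.0, noise, day, "control", "negative_control", rep
                )
            )
    return pd.concat(frames, ignore_index=True)
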