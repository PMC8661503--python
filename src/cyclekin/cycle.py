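"""Cumulative-labeling cell-cycle kinetics estimation.

In a cumulative S-phase labeling experiment the labeled fraction of a
population with growth fraction GF, cycle length tc and S-phase length ts
rises linearly with exposure time t,

    f(t) = (GF/tc) * t + GF * (ts/tc),

until it saturates at GF for t >= tc - ts.  Fitting a line f = m*t + b to
the pre-plateau points therefore identifies the kinetics through

    tc = GF / m,        ts = b * tc / GF.

This module fits that line (pooled across fields within each biological
replicate, plus per-replicate sub-fits for dispersion), inverts it, and
compares conditions on the replicate-level estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, NoEstimateError, ParameterError
from .io import validate_labeling_curve

__all__ = [
    "FitPolicy",
    "LinearFit",
    "CycleEstimate",
    "fit_labeling_curve",
    "estimate_growth_fraction",
    "estimate_cycle_params",
    "estimate_cycle_from_curve",
    "compare_conditions",
]


@dataclass(frozen=True)
class FitPolicy:
    """How the labeling-curve line is fitted.

    plateau_exclude
        If True (requires ``gf``), iteratively drop exposure times whose
        noise-free prediction from the current fit lies within
        ``plateau_tol`` of saturation, i.e. (ts + t)/tc >= 1 - plateau_tol,
        then refit.  Points at or past the plateau otherwise bias the slope
        downward and inflate tc.
    """

    plateau_exclude: bool = False
    plateau_tol: float = 0.01
    gf: Optional[float] = None
    max_iter: int = 5


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of labeled fraction on exposure time."""

    m: float  # slope, fraction per hour
    b: float  # intercept, fraction
    r2: float
    n_points: int
    times_used: Tuple[float, ...]
    replicate_fits: Tuple[Tuple[int, float, float], ...] = ()  # (rep, m, b)
    flags: Tuple[str, ...] = ()


@dataclass(frozen=True)
class CycleEstimate:
    """Inverted kinetics with replicate-level dispersion."""

    tc_hat: float  # hours
    ts_hat: float  # hours
    gf_used: float
    tc_replicates: Tuple[float, ...] = ()
    ts_replicates: Tuple[float, ...] = ()
    tc_sem: Optional[float] = None
    ts_sem: Optional[float] = None
    flags: Tuple[str, ...] = ()

    def to_dict(self) -> Dict:
        return {
            "tc_hat_h": self.tc_hat,
            "ts_hat_h": self.ts_hat,
            "gf_used": self.gf_used,
            "tc_replicates_h": list(self.tc_replicates),
            "ts_replicates_h": list(self.ts_replicates),
            "tc_sem_h": self.tc_sem,
            "ts_sem_h": self.ts_sem,
            "flags": list(self.flags),
        }


def _pool_fields(curve: pd.DataFrame) -> pd.DataFrame:
    """Pool field counts within (time, replicate): fraction weighted by totals."""
    g = curve.groupby(["time_h", "replicate"], as_index=False)[
        ["n_total", "n_labeled"]
    ].sum()
    g = g[g["n_total"] > 0].copy()
    g["fraction"] = g["n_labeled"] / g["n_total"]
    return g


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Plain least squares with intercept; returns (m, b, r2)."""
    m, b = np.polyfit(x, y, 1)
    resid = y - (m * x + b)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(m), float(b), r2


def fit_labeling_curve(
    curve: pd.DataFrame,
    policy: FitPolicy = FitPolicy(),
    label: Optional[str] = None,
) -> LinearFit:
    """Fit the cumulative-labeling line.

    Fields are pooled within each biological replicate; the pooled fit uses
    all (time, replicate) fractions and per-replicate sub-fits are retained
    for dispersion.  With ``policy.plateau_exclude`` the fit is re-run after
    dropping saturated exposure times (see :class:`FitPolicy`).
    """
    validate_labeling_curve(curve)
    if label is not None:
        curve = curve[curve["label"] == label]
        if curve.empty:
            raise InsufficientDataError(f"no rows for subpopulation {label!r}")

    pooled = _pool_fields(curve)
    times = tuple(sorted(pooled["time_h"].unique()))
    if len(times) < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct exposure times, got {len(times)}"
        )

    keep = set(times)
    fit = _fit_points(pooled, keep)
    if policy.plateau_exclude:
        if policy.gf is None or policy.gf <= 0:
            raise ParameterError("plateau_exclude policy requires a positive gf")
        for _ in range(policy.max_iter):
            if fit.m <= 0:
                break
            tc = policy.gf / fit.m
            ts = fit.b * tc / policy.gf
            new_keep = {
                t for t in times if (ts + t) / tc < 1.0 - policy.plateau_tol
            }
            if len(new_keep) < 2 or new_keep == keep:
                break
            keep = new_keep
            fit = _fit_points(pooled, keep)
    return fit


def _fit_points(pooled: pd.DataFrame, keep: set) -> LinearFit:
    sub = pooled[pooled["time_h"].isin(keep)]
    x = sub["time_h"].to_numpy(dtype=float)
    y = sub["fraction"].to_numpy(dtype=float)
    m, b, r2 = _ols(x, y)

    flags: List[str] = []
    if np.all(y == 0):
        flags.append("degenerate_all_zero")

    rep_fits = []
    for rep, grp in sub.groupby("replicate"):
        if grp["time_h"].nunique() >= 2:
            rm, rb, _ = _ols(
                grp["time_h"].to_numpy(dtype=float),
                grp["fraction"].to_numpy(dtype=float),
            )
            rep_fits.append((int(rep), rm, rb))

    return LinearFit(
        m=m,
        b=b,
        r2=r2,
        n_points=len(sub),
        times_used=tuple(sorted(keep)),
        replicate_fits=tuple(rep_fits),
        flags=tuple(flags),
    )


def estimate_growth_fraction(
    curve: Optional[pd.DataFrame] = None,
    method: str = "supplied",
    gf: Optional[float] = None,
    ki67_fraction: Optional[float] = None,
    label: Optional[str] = None,
    rel_tol: float = 0.02,
) -> float:
    """Growth fraction by one of three routes.

    ``supplied``  — pass-through of a known/assumed value.
    ``ki67``      — the Ki67+ fraction measured alongside the curve.
    ``plateau``   — pooled labeled fraction over the saturated exposure
                    times (those within ``rel_tol`` of the curve maximum);
                    requires at least two saturated times, otherwise the
                    design never reached the plateau and another method
                    must be used.
    """
    if method == "supplied":
        if gf is None:
            raise ParameterError("method 'supplied' requires gf")
        value = float(gf)
    elif method == "ki67":
        if ki67_fraction is None:
            raise ParameterError("method 'ki67' requires ki67_fraction")
        value = float(ki67_fraction)
    elif method == "plateau":
        if curve is None:
            raise ParameterError("method 'plateau' requires a labeling curve")
        validate_labeling_curve(curve)
        if label is not None:
            curve = curve[curve["label"] == label]
        pooled = (
            curve.groupby("time_h", as_index=False)[["n_total", "n_labeled"]].sum()
        )
        pooled = pooled[pooled["n_total"] > 0]
        frac = pooled["n_labeled"] / pooled["n_total"]
        fmax = frac.max()
        saturated = pooled[frac >= (1.0 - rel_tol) * fmax]
        if len(saturated) < 2 or fmax <= 0:
            raise InsufficientDataError(
                "no saturated exposure times detected; use method='ki67' or "
                "'supplied' instead"
            )
        value = float(saturated["n_labeled"].sum() / saturated["n_total"].sum())
    else:
        raise ParameterError(f"unknown growth-fraction method {method!r}")

    if not 0 < value <= 1:
        raise ParameterError(f"growth fraction must be in (0,1], got {value}")
    return value


def estimate_cycle_params(fit: LinearFit, gf: float) -> CycleEstimate:
    """Invert a labeling-curve fit into cycle kinetics: tc = GF/m, ts = b*tc/GF.

    Dispersion (SEM) of tc and ts is computed across the per-replicate
    inversions when sub-fits are present.  Replicates with non-positive
    slope cannot be inverted; they are flagged and excluded from dispersion.
    """
    if not 0 < gf <= 1:
        raise ParameterError(f"growth fraction must be in (0,1], got {gf}")
    if fit.m <= 0:
        raise NoEstimateError(
            f"non-positive slope ({fit.m:.4g}) violates the cumulative-labeling "
            "monotonicity; no cycle-length estimate is possible"
        )

    tc = gf / fit.m
    ts = fit.b * tc / gf

    flags: List[str] = list(fit.flags)
    if fit.b < 0:
        flags.append("negative_intercept")
    if ts > tc:
        flags.append("ts_exceeds_tc")

    tc_reps, ts_reps = [], []
    for rep, rm, rb in fit.replicate_fits:
        if rm <= 0:
            flags.append(f"replicate_{rep}_slope_nonpositive")
            continue
        rtc = gf / rm
        tc_reps.append(rtc)
        ts_reps.append(rb * rtc / gf)

    def _sem(vals: Sequence[float]) -> Optional[float]:
        if len(vals) < 2:
            return None
        return float(np.std(vals, ddof=1) / np.sqrt(len(vals)))

    return CycleEstimate(
        tc_hat=float(tc),
        ts_hat=float(ts),
        gf_used=float(gf),
        tc_replicates=tuple(tc_reps),
        ts_replicates=tuple(ts_reps),
        tc_sem=_sem(tc_reps),
        ts_sem=_sem(ts_reps),
        flags=tuple(flags),
    )


def estimate_cycle_from_curve(
    curve: pd.DataFrame,
    gf: float,
    policy: Optional[FitPolicy] = None,
    label: Optional[str] = None,
) -> CycleEstimate:
    """One-call convenience: fit the curve (policy inherits gf) and invert."""
    if policy is None:
        policy = FitPolicy(gf=gf)
    elif policy.plateau_exclude and policy.gf is None:
        policy = FitPolicy(
            plateau_exclude=True,
            plateau_tol=policy.plateau_tol,
            gf=gf,
            max_iter=policy.max_iter,
        )
    fit = fit_labeling_curve(curve, policy=policy, label=label)
    return estimate_cycle_params(fit, gf)


def compare_conditions(
    est_a: CycleEstimate,
    est_b: CycleEstimate,
    names: Tuple[str, str] = ("a", "b"),
    alpha: float = 0.05,
) -> Dict:
    """Compare two conditions on their replicate-level tc and ts estimates.

    Test choice (parametric vs rank-based) is delegated to the statistical
    gatekeeping stage; with fewer than three replicates per arm normality
    cannot be assessed and the parametric branch is taken, recorded in the
    decision trail.
    """
    from .stats import compare_groups

    out: Dict = {"names": list(names)}
    for attr, key in [("tc_replicates", "tc"), ("ts_replicates", "ts")]:
        va, vb = list(getattr(est_a, attr)), list(getattr(est_b, attr))
        if len(va) < 2 or len(vb) < 2:
            raise InsufficientDataError(
                f"condition comparison needs >= 2 replicate {key} estimates per arm"
            )
        res = compare_groups({names[0]: va, names[1]: vb}, alpha=alpha)
        out[key] = {
            "mean_" + names[0]: float(np.mean(va)),
            "mean_" + names[1]: float(np.mean(vb)),
            "difference": float(np.mean(vb) - np.mean(va)),
            "test_name": res.test_name,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "ci95": res.ci95,
            "decision_trail": res.decision_trail,
        }
    return out
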