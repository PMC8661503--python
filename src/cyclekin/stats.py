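"""Gatekept group comparisons.

Each comparison first checks normality per group (Shapiro–Wilk) and
homogeneity of variance across groups (Levene) at a gatekeeping alpha.
If both pass: unpaired two-tailed t test (two groups, equal variances) or
one-way ANOVA with Tukey's post-hoc (three or more).  If either fails, the
rank-based alternative is used instead: Mann–Whitney U, or Kruskal–Wallis
with Dunn's post-hoc under Holm adjustment.  The full decision trail is
recorded so the branch taken is auditable, never guessed.

Shapiro–Wilk requires at least three observations; with smaller groups the
normality check is recorded as not evaluable and treated as passing, which
keeps two-replicate designs on the parametric branch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, ParameterError

__all__ = ["StatResult", "compare_groups", "dunn_posthoc"]


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    normality_p: Dict[str, Optional[float]]
    variance_homogeneity_p: float
    posthoc: Optional[List[Dict]] = None
    ci95: Optional[Tuple[float, float]] = None
    decision_trail: Tuple[str, ...] = ()

    def to_dict(self) -> Dict:
        def _num(x):
            return None if x is None or np.isnan(x) else float(x)

        return {
            "test_name": self.test_name,
            "statistic": _num(self.statistic),
            "p_value": _num(self.p_value),
            "normality_p": {k: _num(v) for k, v in self.normality_p.items()},
            "variance_homogeneity_p": _num(self.variance_homogeneity_p),
            "posthoc": self.posthoc,
            "ci95": list(self.ci95) if self.ci95 else None,
            "decision_trail": list(self.decision_trail),
        }


def compare_groups(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> StatResult:
    """Compare named groups of measurements with assumption gatekeeping."""
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, arr in arrays.items():
        if arr.size < 2:
            raise InsufficientDataError(
                f"group {k!r} has {arr.size} observation(s); need >= 2"
            )

    trail: List[str] = []
    normality_p: Dict[str, Optional[float]] = {}
    normal_ok = True
    for k, arr in arrays.items():
        if arr.size < 3 or np.ptp(arr) == 0:
            normality_p[k] = None
            trail.append(f"shapiro[{k}]: not evaluable (n<3 or constant), passed")
            continue
        p = float(sps.shapiro(arr).pvalue)
        normality_p[k] = p
        ok = p > alpha
        normal_ok &= ok
        trail.append(f"shapiro[{k}]: p={p:.4g} -> {'pass' if ok else 'fail'}")

    if all(arr.size < 3 for arr in arrays.values()):
        # with two observations per group the absolute deviations from the
        # group center are identical within each group, so Levene's W is
        # degenerate (0/0 or infinite); treat as not evaluable
        lev_p = float("nan")
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            lev_p = float(sps.levene(*arrays.values()).pvalue)
    if np.isnan(lev_p):
        var_ok = True
        trail.append("levene: not evaluable (degenerate), passed")
    else:
        var_ok = lev_p > alpha
        trail.append(f"levene: p={lev_p:.4g} -> {'pass' if var_ok else 'fail'}")

    parametric = normal_ok and var_ok
    two_group = len(arrays) == 2
    posthoc = None
    ci95 = None

    if parametric and two_group:
        a, b = (arrays[n] for n in names)
        res = sps.ttest_ind(a, b, equal_var=True)
        ci = res.confidence_interval(0.95)
        ci95 = (float(ci.low), float(ci.high))
        test_name, stat, p = "t_test_equal_var", float(res.statistic), float(res.pvalue)
        trail.append("branch: parametric two-group (unpaired t, equal variances)")
    elif parametric:
        res = sps.f_oneway(*arrays.values())
        test_name, stat, p = "anova_oneway", float(res.statistic), float(res.pvalue)
        tuk = sps.tukey_hsd(*arrays.values())
        posthoc = [
            {
                "group_a": names[i],
                "group_b": names[j],
                "statistic": float(tuk.statistic[i, j]),
                "p_value": float(tuk.pvalue[i, j]),
            }
            for i, j in itertools.combinations(range(len(names)), 2)
        ]
        trail.append("branch: parametric multi-group (ANOVA + Tukey)")
    elif two_group:
        a, b = (arrays[n] for n in names)
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test_name, stat, p = "mann_whitney_u", float(res.statistic), float(res.pvalue)
        trail.append("branch: rank-based two-group (Mann-Whitney U)")
    else:
        res = sps.kruskal(*arrays.values())
        test_name, stat, p = "kruskal_wallis", float(res.statistic), float(res.pvalue)
        posthoc = dunn_posthoc(arrays)
        trail.append("branch: rank-based multi-group (Kruskal-Wallis + Dunn/Holm)")

    if np.isnan(p):
        # identical constant groups: no evidence of any difference
        stat, p = 0.0, 1.0
        trail.append("degenerate: zero variance everywhere, p set to 1")

    return StatResult(
        test_name=test_name,
        statistic=stat,
        p_value=p,
        normality_p=normality_p,
        variance_homogeneity_p=lev_p,
        posthoc=posthoc,
        ci95=ci95,
        decision_trail=tuple(trail),
    )


def dunn_posthoc(arrays: Mapping[str, np.ndarray]) -> List[Dict]:
    """Dunn's pairwise rank-sum z tests with tie correction and Holm adjustment.

    Standard follow-up to a Kruskal–Wallis omnibus: z_ij compares mean ranks
    of groups i and j in the pooled ranking, with variance
    N(N+1)/12 - tie-correction, scaled by (1/n_i + 1/n_j).
    """
    names = list(arrays)
    pooled = np.concatenate([arrays[k] for k in names])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)

    mean_ranks, sizes, start = {}, {}, 0
    for k in names:
        n_k = len(arrays[k])
        mean_ranks[k] = float(ranks[start : start + n_k].mean())
        sizes[k] = n_k
        start += n_k

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs, raw_p = [], []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        pairs.append((a, b, float(z), float(p)))
        raw_p.append(p)

    adjusted = _holm(np.array(raw_p))
    return [
        {
            "group_a": a,
            "group_b": b,
            "statistic": z,
            "p_value_raw": p,
            "p_value_holm": float(p_adj),
        }
        for (a, b, z, p), p_adj in zip(pairs, adjusted)
    ]


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, clipped at 1)."""
    order = np.argsort(pvals)
    m = len(pvals)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted
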