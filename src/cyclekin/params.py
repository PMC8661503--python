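"""Parameter containers for the synthetic cycling/differentiating populations.

The cell cycle is laid out as G1 -> S -> G2/M on a circle of circumference
``tc`` hours: G1 occupies ``[0, tc - ts - t_g2m)``, S occupies
``[tc - ts - t_g2m, tc - t_g2m)`` and G2/M the final ``t_g2m`` hours before
mitosis.  Only ``tc`` and ``ts`` enter the cumulative-labeling linear law;
``t_g2m`` matters solely for the timing of mitoses in pulse-chase experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

from .errors import ParameterError


@dataclass(frozen=True)
class CyclePopulationParams:
    """Ground-truth cell-cycle kinetics of one subpopulation.

    Parameters
    ----------
    tc : float
        Total cell-cycle length, hours.
    ts : float
        S-phase length, hours.  Must satisfy ``0 < ts <= tc``.
    gf : float
        Growth fraction: proportion of the population actively cycling,
        in [0, 1].  Non-cycling cells are Ki67- and never incorporate EdU.
    quit_prob : float
        Probability that the tracked daughter exits the cycle (loses Ki67)
        at each mitosis, in [0, 1].
    label : str
        Subpopulation tag, e.g. ``"marker_pos"`` / ``"marker_neg"``.
    t_g2m : float
        Combined G2+M length, hours.  Must satisfy ``ts + t_g2m <= tc``.
    """

    tc: float
    ts: float
    gf: float = 1.0
    quit_prob: float = 0.0
    label: str = "marker_pos"
    t_g2m: float = 2.0

    def __post_init__(self) -> None:
        if not (self.tc > 0 and 0 < self.ts <= self.tc):
            raise ParameterError(
                f"need 0 < ts <= tc, got ts={self.ts}, tc={self.tc}"
            )
        if not 0.0 <= self.gf <= 1.0:
            raise ParameterError(f"growth fraction must be in [0,1], got {self.gf}")
        if not 0.0 <= self.quit_prob <= 1.0:
            raise ParameterError(f"quit_prob must be in [0,1], got {self.quit_prob}")
        if self.t_g2m < 0 or self.ts + self.t_g2m > self.tc:
            raise ParameterError(
                f"phase layout needs ts + t_g2m <= tc, got "
                f"ts={self.ts}, t_g2m={self.t_g2m}, tc={self.tc}"
            )

    @property
    def s_entry_phase(self) -> float:
        """Cycle position (hours from birth) at which a cell enters S."""
        return self.tc - self.ts - self.t_g2m

    @property
    def plateau_time(self) -> float:
        """Exposure time at which cumulative labeling saturates: tc - ts."""
        return self.tc - self.ts


@dataclass(frozen=True)
class MixtureSpec:
    """Sampling design for a simulated counting experiment.

    ``components`` pairs each subpopulation's kinetics with its mixing
    proportion; proportions must sum to 1.  Field-level totals are drawn
    Poisson around ``n_cells_per_field`` x proportion, labeled counts are
    binomial given the per-cell geometry.
    """

    components: Tuple[Tuple[CyclePopulationParams, float], ...]
    n_cells_per_field: int = 200
    n_fields: int = 6
    n_replicates: int = 2
    seed: int = 0
    #: "uniform" is the exact stationary distribution of the non-expanding
    #: renewal scheme; "exponential_growth" is a robustness option with the
    #: young-skewed age density 2^(-a/tc) of a doubling population.
    phase_distribution: str = "uniform"

    def __post_init__(self) -> None:
        if self.phase_distribution not in ("uniform", "exponential_growth"):
            raise ParameterError(
                f"unknown phase distribution {self.phase_distribution!r}"
            )
        if not self.components:
            raise ParameterError("at least one mixture component required")
        total = sum(p for _, p in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"mixing proportions must sum to 1, got {total}")
        if any(p < 0 for _, p in self.components):
            raise ParameterError("mixing proportions must be non-negative")
        for n, name in [
            (self.n_cells_per_field, "n_cells_per_field"),
            (self.n_fields, "n_fields"),
            (self.n_replicates, "n_replicates"),
        ]:
            if n < 1:
                raise ParameterError(f"{name} must be >= 1, got {n}")

    @classmethod
    def single(cls, params: CyclePopulationParams, **kwargs) -> "MixtureSpec":
        """Convenience constructor for a one-population design."""
        return cls(components=((params, 1.0),), **kwargs)


@dataclass(frozen=True)
class TrajectoryParams:
    """Progenitor -> postmitotic conversion trajectory for flow samples.

    The reporter-positive prevalence at differentiation day ``d`` is

        p(d) = p_max * (1 - exp(-H(d))),
        H(d) = hazard_scale * hazard * max(0, d - onset_delay)
               + forced_exit_hazard * max(0, d - forced_exit_day)

    i.e. a constant conversion hazard switched on after the reporter-onset
    delay, optionally boosted from ``forced_exit_day`` onward (cell-cycle
    inhibitor mode, quit probability driven toward 1), saturating at a
    ceiling ``p_max`` set by the lineage composition of the culture.
    """

    hazard: float = 0.079  # per day
    onset_delay: float = 20.0  # days
    hazard_scale: float = 1.0  # condition multiplier (e.g. TGFbeta inhibition < 1)
    forced_exit_day: Optional[float] = None
    forced_exit_hazard: float = 0.25  # per day, applied after forced_exit_day
    p_max: float = 0.46

    def __post_init__(self) -> None:
        if self.hazard < 0 or self.forced_exit_hazard < 0 or self.hazard_scale < 0:
            raise ParameterError("hazards and scale factors must be >= 0")
        if self.onset_delay < 0:
            raise ParameterError("onset delay must be >= 0")
        if not 0.0 <= self.p_max <= 1.0:
            raise ParameterError(f"p_max must be in [0,1], got {self.p_max}")

    def prevalence(self, day: float) -> float:
        """Expected reporter-positive fraction of viable events at ``day``."""
        import math

        h = self.hazard_scale * self.hazard * max(0.0, day - self.onset_delay)
        if self.forced_exit_day is not None:
            h += self.forced_exit_hazard * max(0.0, day - self.forced_exit_day)
        return self.p_max * (1.0 - math.exp(-h))


@dataclass(frozen=True)
class FlowNoiseParams:
    """Intensity model for synthetic flow events (log-normal components)."""

    background_median: float = 100.0
    background_sigma: float = 0.5
    positive_median: float = 3000.0
    positive_sigma: float = 0.5
    viability_median: float = 100.0
    viability_sigma: float = 0.25
    dead_viability_multiple: float = 10.0
    dead_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.dead_fraction < 1.0:
            raise ParameterError("dead_fraction must be in [0,1)")
        for v in (
            self.background_median,
            self.positive_median,
            self.viability_median,
            self.dead_viability_multiple,
        ):
            if v <= 0:
                raise ParameterError("intensity medians/multiples must be > 0")
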