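"""Synthetic-population generator: closed-form oracles, invariants, determinism."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from cyclekin import (
    CyclePopulationParams,
    MixtureSpec,
    TrajectoryParams,
    analytic_labeled_fraction,
    compute_exit_index,
    simulate_cumulative_labeling,
    simulate_flow_sample,
    simulate_pulse_chase,
)
from cyclekin.errors import ParameterError


@pytest.mark.parametrize(
    "tc,ts,gf,t,expected",
    [
        (40, 16, 1.0, 0.0, 0.4),  # intercept gf*ts/tc
        (40, 16, 0.0, 8.0, 0.0),  # no cycling cells
        (40, 16, 0.8, 8.0, 0.48),  # 0.8*(16+8)/40
        (40, 16, 0.8, 24.0, 0.8),  # at the plateau t = tc - ts
        (40, 16, 0.8, 30.0, 0.8),  # past the plateau: stays at gf
    ],
)
def test_analytic_labeled_fraction_examples(tc, ts, gf, t, expected):
    params = CyclePopulationParams(tc=tc, ts=ts, gf=gf)
    assert analytic_labeled_fraction(params, t) == pytest.approx(expected, abs=1e-12)


def test_analytic_matches_phase_enumeration(standard_params):
    """Brute-force enumeration over uniformly placed cycle positions.

    A cell at position a is labeled during [0, t] iff it is in S now or the
    forward distance to S entry is below t; averaging that indicator over a
    dense phase grid must reproduce the closed form.
    """
    p = standard_params
    s0 = p.s_entry_phase
    a = (np.arange(400_000) + 0.5) * (p.tc / 400_000)
    for t in (0.0, 2.0, 8.0, 16.0, 23.0, 24.0, 40.0):
        in_s = (a - s0) % p.tc < p.ts
        enters = (s0 - a) % p.tc < t
        brute = p.gf * float((in_s | enters).mean())
        assert brute == pytest.approx(
            analytic_labeled_fraction(p, t), abs=2e-5
        )


@pytest.mark.parametrize(
    "tc,ts,gf",
    [(40.0, 16.0, 0.8), (30.0, 12.0, 0.85), (45.65, 21.76, 0.9)],
)
def test_simulated_fraction_matches_analytic_within_3se(tc, ts, gf):
    params = CyclePopulationParams(tc=tc, ts=ts, gf=gf)
    spec = MixtureSpec.single(
        params, n_cells_per_field=5000, n_fields=4, n_replicates=2, seed=11
    )
    times = [2.0, 8.0, 16.0]
    curve = simulate_cumulative_labeling(spec, times)
    pooled = curve.groupby("time_h")[["n_total", "n_labeled"]].sum()
    for t in times:
        n = pooled.loc[t, "n_total"]
        frac = pooled.loc[t, "n_labeled"] / n
        expected = analytic_labeled_fraction(params, t)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) <= 3 * se


def test_labeled_fraction_monotone_in_time(standard_params):
    """Common random numbers: same cells scored at each time -> non-decreasing."""
    spec = MixtureSpec.single(standard_params, n_cells_per_field=500, seed=5)
    times = [1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0, 30.0]
    curve = simulate_cumulative_labeling(spec, times)
    for _, grp in curve.groupby(["replicate", "field"]):
        ordered = grp.sort_values("time_h")["n_labeled"].to_numpy()
        assert np.all(np.diff(ordered) >= 0)


def test_fraction_plateaus_at_gf(standard_params):
    """For t >= tc - ts every cycling cell has traversed S: fraction == gf share."""
    spec = MixtureSpec.single(
        standard_params, n_cells_per_field=2000, n_fields=3, seed=9
    )
    curve = simulate_cumulative_labeling(spec, [24.0, 36.0, 48.0])
    merged = curve.groupby(["replicate", "field"])["n_labeled"].nunique()
    assert (merged == 1).all()  # identical labeled counts at every plateau time


def test_s_phase_spanning_cycle_labels_everyone():
    params = CyclePopulationParams(tc=40, ts=40, gf=1.0, t_g2m=0.0)
    spec = MixtureSpec.single(params, n_cells_per_field=300, seed=2)
    curve = simulate_cumulative_labeling(spec, [1.0])
    assert (curve["n_labeled"] == curve["n_total"]).all()


def test_generators_are_seed_deterministic(standard_params):
    spec = MixtureSpec.single(standard_params, seed=123)
    assert_frame_equal(
        simulate_cumulative_labeling(spec, [2, 8]),
        simulate_cumulative_labeling(spec, [2, 8]),
    )
    assert_frame_equal(
        simulate_pulse_chase(spec, 2.0, 48.0), simulate_pulse_chase(spec, 2.0, 48.0)
    )
    traj = TrajectoryParams()
    assert_frame_equal(
        simulate_flow_sample(traj, 40, 1000, seed=7),
        simulate_flow_sample(traj, 40, 1000, seed=7),
    )


class TestPulseChase:
    def test_no_exit_means_all_labeled_cells_keep_ki67(self):
        params = CyclePopulationParams(tc=40, ts=16, gf=1.0, quit_prob=0.0)
        spec = MixtureSpec.single(params, n_cells_per_field=1000, seed=3)
        table = simulate_pulse_chase(spec, 2.0, 20.0)
        edu_ki67_neg = table[(table["edu"] == "pos") & (table["ki67"] == "neg")]
        assert edu_ki67_neg["count"].sum() == 0
        assert compute_exit_index(table).index == 0.0

    def test_certain_exit_after_full_cycle_gives_index_one(self):
        params = CyclePopulationParams(tc=30, ts=12, gf=1.0, quit_prob=1.0)
        spec = MixtureSpec.single(params, n_cells_per_field=1000, seed=4)
        # chase >= tc guarantees every labeled cell passes a mitosis
        table = simulate_pulse_chase(spec, 2.0, 32.0)
        assert compute_exit_index(table).index == 1.0

    def test_noncycling_cells_are_edu_negative_ki67_negative(self):
        params = CyclePopulationParams(tc=40, ts=16, gf=0.5, quit_prob=0.0)
        spec = MixtureSpec.single(params, n_cells_per_field=2000, seed=6)
        table = simulate_pulse_chase(spec, 2.0, 10.0)
        neg_neg = table[(table["edu"] == "neg") & (table["ki67"] == "neg")][
            "count"
        ].sum()
        total = table["count"].sum()
        se = np.sqrt(0.5 * 0.5 / total)
        assert neg_neg / total == pytest.approx(0.5, abs=3 * se)


class TestFlowSample:
    def test_fixed_prevalence_recovered(self):
        from cyclekin import gate_positive, gate_viable

        # saturated trajectory pins prevalence at p_max
        traj = TrajectoryParams(hazard=100.0, onset_delay=0.0, p_max=0.40)
        events = simulate_flow_sample(traj, day=40, n_events=50_000, seed=21)
        sample = gate_viable(events[events["role"] == "reporter"])
        control = gate_viable(events[events["role"] == "negative_control"])
        result = gate_positive(sample, control)
        se = 100 * np.sqrt(0.4 * 0.6 / result.n_viable)
        assert result.positive_fraction == pytest.approx(40.0, abs=3 * se)

    def test_zero_hazard_gives_zero_prevalence(self):
        traj = TrajectoryParams(hazard=0.0)
        assert traj.prevalence(60) == 0.0
        events = simulate_flow_sample(traj, day=60, n_events=5000, seed=8)
        sample = events[events["role"] == "reporter"]
        assert (sample["reporter_intensity"] > 1000).mean() < 0.01

    def test_dead_fraction_near_generated_value(self):
        traj = TrajectoryParams()
        events = simulate_flow_sample(traj, day=40, n_events=50_000, seed=13)
        sample = events[events["role"] == "reporter"]
        dead = (
            sample["viability_intensity"] > 4 * sample["viability_intensity"].median()
        ).mean()
        se = np.sqrt(0.1 * 0.9 / len(sample))
        assert dead == pytest.approx(0.10, abs=3 * se)

    def test_reduced_hazard_curve_below_control_after_onset(self):
        control = TrajectoryParams()
        reduced = TrajectoryParams(hazard_scale=0.45)
        days = np.arange(30, 61, 5)
        for d in days:
            assert reduced.prevalence(d) < control.prevalence(d)

    def test_forced_exit_mode_converges_to_control(self):
        control = TrajectoryParams(forced_exit_day=35.0)
        reduced = TrajectoryParams(hazard_scale=0.45, forced_exit_day=35.0)
        gap = [
            control.prevalence(d) - reduced.prevalence(d) for d in (40, 50, 60, 70)
        ]
        assert all(g >= 0 for g in gap)
        assert np.all(np.diff(gap) < 0)  # gap shrinks as forced exit dominates


def test_growth_skewed_phase_mode_matches_density_oracle(standard_params):
    """The exponential-growth age mode overrepresents young cells; the
    labeled fraction must then match the density-weighted phase integral,
    not the uniform closed form."""
    p = standard_params
    spec = MixtureSpec.single(
        p, n_cells_per_field=5000, n_fields=4, n_replicates=2, seed=14,
        phase_distribution="exponential_growth",
    )
    t = 4.0
    curve = simulate_cumulative_labeling(spec, [t])
    n = curve["n_total"].sum()
    frac = curve["n_labeled"].sum() / n

    # numeric oracle: integrate the labeled-arc indicator against the
    # doubling-population age density (2 ln2 / tc) * 2^(-a/tc)
    a = (np.arange(200_000) + 0.5) * (p.tc / 200_000)
    w = 2.0 ** (-a / p.tc)
    w /= w.sum()
    s0 = p.s_entry_phase
    labeled = ((a - s0) % p.tc < p.ts) | ((s0 - a) % p.tc < t)
    expected = p.gf * float((w * labeled).sum())

    se = np.sqrt(expected * (1 - expected) / n)
    assert frac == pytest.approx(expected, abs=3 * se)
    # and it is genuinely different from the stationary-uniform law
    uniform = analytic_labeled_fraction(p, t)
    assert abs(expected - uniform) > 6 * se


@pytest.mark.parametrize(
    "bad",
    [
        dict(tc=40, ts=41, gf=0.8),  # ts > tc
        dict(tc=40, ts=16, gf=1.5),  # gf out of range
        dict(tc=40, ts=16, gf=0.8, quit_prob=-0.1),
        dict(tc=40, ts=39.5, gf=0.8, t_g2m=2.0),  # ts + t_g2m > tc
    ],
)
def test_invalid_population_params_rejected(bad):
    with pytest.raises(ParameterError):
        CyclePopulationParams(**bad)


def test_invalid_simulation_inputs_rejected(standard_params):
    spec = MixtureSpec.single(standard_params, seed=1)
    with pytest.raises(ParameterError):
        simulate_cumulative_labeling(spec, [])
    with pytest.raises(ParameterError):
        simulate_cumulative_labeling(spec, [0.0])
    with pytest.raises(ParameterError):
        simulate_pulse_chase(spec, 0.0, 10.0)
    with pytest.raises(ParameterError):
        MixtureSpec.single(standard_params, n_cells_per_field=0)
    with pytest.raises(ParameterError):
        simulate_flow_sample(TrajectoryParams(), 40, 0, seed=1)
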