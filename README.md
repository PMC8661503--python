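# cyclekin

Cell-cycle kinetics of cycling/differentiating neural progenitor populations
from three standard bench readouts, plus a matched synthetic-data simulator
so every estimator can be validated by parameter recovery:

1. **Cumulative EdU labeling → cycle length.** When cells are exposed to
   EdU continuously, the labeled fraction of an asynchronously cycling
   population with growth fraction *GF*, cycle length *t*<sub>c</sub> and
   S-phase length *t*<sub>s</sub> rises linearly,

   *GF*(t) = (*GF*/*t*<sub>c</sub>)·t + *GF*·(*t*<sub>s</sub>/*t*<sub>c</sub>),

   until it saturates at *GF* at t = *t*<sub>c</sub> − *t*<sub>s</sub>.
   Fitting a line f = m·t + b to the pre-plateau points identifies the
   kinetics through *t*<sub>c</sub> = *GF*/m and
   *t*<sub>s</sub> = b·*t*<sub>c</sub>/*GF*.

2. **Pulse-chase exit index.** After a short EdU pulse and a chase, the
   cell-cycle exit (quit) index is the fraction of labeled cells that have
   left the cycle: count(marker⁺ EdU⁺ Ki67⁻) / count(EdU⁺). A deterministic
   phase-integral oracle gives its expectation under a per-mitosis exit
   probability.

3. **Gated flow-cytometry timecourses.** Reporter-positive fractions over a
   differentiation timecourse, with viability exclusion (DAPI-like dye gate)
   and a positivity threshold set from a matched negative-control (parental,
   non-reporter) sample at each time point; condition contrasts summarized
   as percent reduction and fold change.

Group comparisons pass through assumption gatekeeping (Shapiro–Wilk
normality, Levene variance homogeneity) before an unpaired t test / one-way
ANOVA with Tukey's post-hoc, or their rank-based alternatives (Mann–Whitney,
Kruskal–Wallis with Dunn/Holm), with the full decision trail recorded.

Intended for quantitative biologists analyzing proliferation/neurogenesis
experiments in stem-cell-derived progenitor cultures — and for anyone who
wants a simulator with known ground truth to check such an analysis.

## Worked example

Simulate one bench-scale cumulative-labeling experiment (exposure times
2–24 h, six fields from two biological replicates, ~200 cells per field) at
known kinetics, then recover them:

```python
from cyclekin import (CyclePopulationParams, MixtureSpec,
                      simulate_cumulative_labeling, estimate_cycle_from_curve)
from cyclekin.cycle import FitPolicy

params = CyclePopulationParams(tc=40.0, ts=16.0, gf=0.9, label="nkx2.1_pos")
spec = MixtureSpec.single(params, n_cells_per_field=200,
                          n_fields=6, n_replicates=2, seed=42)
curve = simulate_cumulative_labeling(spec, [2, 4, 8, 16, 24])
est = estimate_cycle_from_curve(curve, gf=0.9,
                                policy=FitPolicy(plateau_exclude=True, gf=0.9),
                                label="nkx2.1_pos")
print(f"tc = {est.tc_hat:.2f} +/- {est.tc_sem:.2f} h   "
      f"ts = {est.ts_hat:.2f} +/- {est.ts_sem:.2f} h")
```

prints

```
tc = 39.60 +/- 1.22 h   ts = 15.69 +/- 0.35 h
```

i.e. the generating 40 h cycle and 16 h S phase are recovered to within the
counting noise of a single experiment of this size (± values are SEM across
the two replicate-level fits). The `plateau_exclude` policy drops exposure
times at or past saturation (here 24 h ≥ tc − ts) before fitting; leaving
them in flattens the slope and inflates tc.

The same study can be run from the shell:

```bash
cyclekin run --config examples/demo.yaml --out demo_out
```

which simulates two conditions (vehicle vs TGFβ-receptor inhibition) for
NKX2.1⁺/NKX2.1⁻ populations, a pulse-chase exit contrast, and an
8-time-point flow timecourse, and writes `report.json` plus tidy CSVs.
Stage-wise subcommands (`fixtures`, `estimate-cycle`, `exit-index`,
`flow-timecourse`, `stats`) operate on the documented CSV formats.

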