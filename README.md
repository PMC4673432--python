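# clonefate

Stochastic single-cell fate simulation and clonal-dominance analysis for
micro-well time-lapse experiments on stimulated CD4+ T cells.

## The problem

When naive CD4+ T cells are stimulated in vitro (anti-CD3/CD28 beads, IL-2,
TGF-β), single founder cells seeded in micro-wells proliferate, differentiate
towards the regulatory (Treg, Foxp3/GFP+) phenotype, or die — and they do so
with striking heterogeneity: the lag to the first division ranges from 15 h
to beyond 100 h, subsequent cycles vary in length, and death strikes
sporadically. The cumulative effect is a *Pareto-like* population structure:
after ~100 h a small minority of founder clones contributes most of the
living cells.

`clonefate` provides a tested pipeline to study whether simple stochastic
per-cell decisions suffice to produce this dominance:

1. **synthetic data** (`clonefate.synthetic`) — generate per-well hourly
   records (living cells, GFP+ cells, cumulative dead, bead count) with the
   experiment's statistical structure, including the bead-independent
   first-24 h stress mortality;
2. **estimation** (`clonefate.estimation`) — recover first-event and
   subsequent-event frequencies and empirical waiting-time distributions
   from the records, exactly as a manual tracker would tabulate them;
3. **simulation** (`clonefate.model`) — a discrete-time (1 h steps, 100 h
   horizon) stochastic decision-tree model: a founder's first decision is
   divide / differentiate / remain; every cell after a division or
   differentiation decides divide / differentiate / die / remain with
   probabilities conditioned on its GFP state, and event times are drawn
   from empirical cumulative distributions by inverse transform;
4. **inequality statistics** (`clonefate.gini`) — the Gini coefficient over
   clone sizes x_1..x_N,

       G = Σ_i Σ_j |x_i − x_j| / (2 N² μ),     μ = Σ_i x_i / N,

   computed hourly for all clones and for GFP+ clones, plus Lorenz curves;
5. **experiments** (`clonefate.experiments`, CLI `clonefate`) — Gini-vs-time
   bands over repeated runs, a six-variant parameter ablation
   (full / no death / fixed first cycle / fixed subsequent cycles /
   all synchronized / synchronized immortal) with Kruskal–Wallis and Dunn
   post-hoc tests, a bead vs no-bead mortality comparison, and a simulated
   CellTrace-Violet dye-dilution profile (intensity F0·2^−d after d
   divisions).

## Worked example

```python
from clonefate import default_ground_truth
from clonefate.experiments import run_ablation, run_gini_experiment

params = default_ground_truth()          # calibrated fate tables
band = run_gini_experiment(params, n_runs=100, seed=7)
for h in (0, 20, 40, 60, 80, 100):
    r = band.iloc[h]
    print(f"hour {h:3d}  gini_median {r.gini_median:.3f}  sd {r.gini_sd:.3f}"
          f"  cells {int(r.n_cells_median)}")
```

prints

```
hour   0  gini_median 0.000  sd 0.000  cells 133
hour  20  gini_median 0.122  sd 0.015  cells 156
hour  40  gini_median 0.255  sd 0.017  cells 197
hour  60  gini_median 0.359  sd 0.020  cells 277
hour  80  gini_median 0.417  sd 0.020  cells 409
hour 100  gini_median 0.442  sd 0.022  cells 629
```

Starting from 133 equal founders (G = 0), inequality rises steeply while the
first divisions spread out, then plateaus after ~70 h even though the
population keeps growing — the clonal hierarchy is locked in early.

```python
res = run_ablation(params, n_runs=100, seed=1)
print(res.summary.round(3).to_string(index=False))
```

```
              variant  median  mean    sd
                 full   0.443 0.445 0.022
             no_death   0.406 0.405 0.019
          fixed_first   0.369 0.369 0.024
     fixed_subsequent   0.417 0.419 0.020
     all_synchronized   0.336 0.334 0.023
synchronized_immortal   0.077 0.078 0.020
```

Each stochastic ingredient — death, the first-cycle lag, the subsequent
cycle lengths — contributes to the final dominance (Kruskal–Wallis
p ≈ 4e-109; Dunn full vs synchronized-immortal p ≈ 2e-81): fixing any one
of them lowers the final Gini, and synchronizing all divisions while
removing death collapses it to a low residual driven only by the remaining
fate-choice randomness.

The same experiments are available from the shell:

```bash
clonefate --seed 4 --out-dir out synth --n-wells 940
clonefate --out-dir out estimate --records out/records.csv --events out/events.csv
clonefate --seed 1 --out-dir out ablation --n-runs 100 --plot
clonefate --out-dir out mortality --records out/records.csv
```

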