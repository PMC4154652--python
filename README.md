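# isletcrit

Critical behavior in gap-junction-coupled pancreatic islet β-cell networks.

Pancreatic islets switch between globally active and globally quiescent
electrical states even though their constituent β-cells are individually
heterogeneous. `isletcrit` is for quantitative biologists studying how that
binary, multicellular behavior emerges from coupling. It implements two
engines and the analysis layer connecting them to percent-active
measurements:

* **Boolean bond-percolation engine** — cells on a cubic lattice (default
  `L = 11`, open boundaries) whose nearest-neighbor bonds open with coupling
  probability `p`. Within each coupled cluster of `n` cells, activity is
  all-or-none: with `X ~ Binomial(n, q)` inexcitable cells (`q = 1 − P_exc`),
  the cluster is active with probability `P(X < k)`,
  `k = floor(n·Sp) + 1`, i.e. it is suppressed as soon as the inexcitable
  fraction exceeds the threshold `Sp`. Network activity is the
  cluster-size-weighted mean. Above the cubic bond-percolation threshold
  (`p_c ≈ 0.2488`) a spanning cluster exists and the network shows a phase
  transition near `P_exc = 1 − Sp`.
* **Coupled dynamical islet engine** — a multicellular Chay-Keizer-class
  β-cell model (`V`, `n`, `Ca` per cell; K_ATP current
  `g_KATP_bar · p_open · (V − V_K)`) on sphere-packed or cubic
  architectures, with per-edge gap-junction conductances
  (`I_coup,i = Σ_j g_ij (V_i − V_j)`, mean 120 pS, SD/mean 70%), per-cell
  parameter heterogeneity, over-active mutant K_ATP cells
  (`p' = γ + (1−γ)p`) and a uniform channel opener (`p' = (1−α) + αp`).
  Forward Euler at 100 µs steps, sampled every 100 ms.
* **Metrics and fitting** — variance-rule activity classification, plateau
  fraction, synchronization, transition location, coupled-vs-uncoupled
  mappings, and χ² grid fitting of `(p, Sp)` or conductance-scaled `(p₀, Sp)`
  with Δχ²-contour confidence intervals and per-replicate fitted-parameter
  distributions.

See `docs/methods.md` for the model details, calibration and limitations.

## Worked example

```python
import numpy as np
from isletcrit import sweep_activity
from isletcrit.metrics import transition_drop

pexc = np.round(np.arange(0.0, 1.0001, 0.01), 4)
surf = sweep_activity(p_grid=[0.30], pexc_grid=pexc, sp=0.15, L=11,
                      reps=500, seed=101)
curve = surf.curve_vs_pexc(0.30)
print({k: round(v, 2) for k, v in
       transition_drop(curve.control, curve.mean_pct).items()})
```

prints

```
{'location': 0.85, 'sharpness': 1450.47, 'shoulder_pct': 90.79,
 'floor_pct': 21.92, 'pre_drop_pct_points': 9.21, 'relative_drop_pct': 75.85}
```

read as: with supra-critical coupling (`p = 0.30`) and a 15% suppression
threshold, islet activity declines only ~10 percentage points as
excitability falls from 100% to 90% (coupling recruits the few inexcitable
cells), then collapses at `P_exc ≈ 0.85` — the curve loses ~76% of its
shoulder value across the transition — leaving only small residual clusters
active below it. The same transition, driven dynamically, appears in the
coupled islet simulator when ~15% of cells carry over-active K_ATP
channels:

```python
from isletcrit.dynamics import SimConfig, phase_transition_scan
from isletcrit.metrics import half_activity_crossing

curve = phase_transition_scan(
    500, SimConfig(duration_ms=40000, glucose_mM=20.0, seed=11),
    "mutant_fraction", [0.0, 0.05, 0.10, 0.125, 0.15, 0.175, 0.20, 0.25, 0.30],
    mean_g_list=[120.0], seed=11)[120.0]
print(np.round(curve.mean_pct, 1))
print(round(half_activity_crossing(curve.control, curve.mean_pct), 3))
```

```
[100.   93.   77.2  63.8  64.   41.   15.8   5.2   5. ]
0.165
```

## Command line

Each engine is exposed as a subcommand writing delimited tables plus a
`run_meta.json` (command, seed, version) so any run can be replayed:

```
isletcrit boolean-sweep --p 0.30 --sp 0.15 --reps 500 --seed 1 --out out/sweep
isletcrit synth-obs --p-true 0.30 --sp-true 0.15 --noise-sd 5 --out out/obs
isletcrit boolean-fit --obs out/obs/observations.csv --out out/fit
isletcrit islet-scan --n-cells 500 --scan-kind mutant_fraction --glucose 20 --out out/scan
isletcrit islet-simulate --n-cells 200 --glucose 11 --out out/sim
isletcrit classify --traces out/sim/traces_ca.csv --out out/cls
```

`--config file.yaml` supplies any parameter; flags override; defaults are
`L = 11`, `reps = 500`, `Sp = 0.15`, mean conductance 120 pS, 100 µs step,
100 ms sampling.

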