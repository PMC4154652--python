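# Methods

## The scientific problem

Pancreatic islets maintain glucose homeostasis by switching between globally
quiescent and globally active electrical states. β-cells are individually
heterogeneous in glucose sensitivity, yet the islet responds as a unit:
gap-junction (Cx36) coupling both synchronizes active cells and lets a
minority of inexcitable cells suppress the rest. `isletcrit` implements two
complementary computational engines that explain this binary behavior as a
phase transition of a coupled network, together with the metrics and fitting
machinery used to compare them to percent-active measurements.

## Engine 1 — Boolean bond-percolation model

**Substrate.** Cells occupy the nodes of a finite cubic lattice of edge
length `L` (default 11, 1331 cells; open boundaries, mimicking a finite
islet). Each of the `3·L²·(L−1)` nearest-neighbor bonds is open
independently with coupling probability `p` (a bond variate `u ≤ p` opens
the bond). Connected components of the open-bond graph are "functionally
coupled" clusters (computed exactly with scipy's connected-components;
labeling-order independent).

**Suppression rule.** Each cell is intrinsically excitable with probability
`P_exc` (`q = 1 − P_exc` inexcitable). Within a cluster of `n` cells,
activity is all-or-none: if the inexcitable fraction exceeds the threshold
`Sp`, every cell in the cluster is inactive; otherwise every cell is active.
With `X ~ Binomial(n, q)` the cluster is active with probability
`P(X < k)` where `k = floor(n·Sp) + 1` is the smallest count whose fraction
strictly exceeds `Sp`. Network activity is the cluster-size-weighted mean of
this probability. The strict (`>`) reading of the threshold is the default;
a greater-or-equal variant (shifting `k` by one exactly when `n·Sp` is an
integer) is available via `rule="gte"`, since the verbal rule and the
cumulative-distribution notation conflict off-by-one in the source
literature.

Activity is evaluated analytically per cluster (no excitability labels are
sampled); a label-sampling Monte-Carlo mode exists purely as a
cross-validation path and is tested against the analytic expression.

**Sweeps.** `sweep_activity` samples `reps` fresh bond configurations per
`p` (default 500 per grid point at 0.01 increments) and evaluates the
binomial rule on each decomposition for every `P_exc`, yielding mean and
standard error per grid point. At `p = 0` every cluster is a singleton and
activity equals `P_exc` exactly; above the bond-percolation threshold of the
cubic lattice (`p_c ≈ 0.2488`) a spanning cluster exists and the suppression
rule acts network-wide, producing a sharp transition near
`P_exc = 1 − Sp`.

**Transition summary.** For the supra-critical curve
(`p = 0.30, Sp = 0.15`) the package quotes three numbers
(`metrics.transition_drop`): the steepest-descent location (≈ 0.85); the
pre-critical decrease from full excitability down to the shoulder at
location + 0.05 (≈ 10 percentage points); and the drop across the
transition between that shoulder and the post-critical boundary at
location − 0.10, expressed as a percentage of the shoulder activity
(≈ 75%). The band offsets mirror the named experimental regions
(pre-critical above ~10% mutant expression, post-critical beyond ~25%), and
the drop is quoted relative to the shoulder because, on this model's curve,
the shoulder sits near 90% and the post-critical boundary near 22%: the
relative drop (~76%) and the pre-critical decrease (~10 points) are then
jointly consistent, whereas no absolute-points reading reproduces both.

**Percolation threshold.** `estimate_percolation_threshold` estimates `p_c`
from the crossing of spanning-probability curves across system sizes
(spanning = one cluster touching two opposite faces of the box along any
axis, the standard finite-size criterion). Pairwise strict sign changes of
`S_{L2} − S_{L1}` are interpolated linearly and averaged; degenerate
families that never cross strictly (e.g. 1-D chains, which span only at
`p = 1`) fall back to the first grid point where every size spans, and an
estimate-failure flag is raised when neither applies.

## Engine 2 — coupled dynamical islet model

**Architecture.** Realistic islets are quasi-spherical random packings of
unit-diameter cells: random sequential insertion inside a spherical boundary
sized for packing fraction 0.30, with availability-based insertion next to
already-placed cells once blind insertion stalls, and a hard-core separation
of 0.95 diameters. Cells within the calibrated contact radius (1.44
diameters, fixed once so that 1000-cell packings average ≈ 5.3 contacts per
cell, SD ≈ 1.7) are coupled; rare disconnected fragments are attached
through their closest cell pair. A regular cubic architecture (6-neighbor,
open boundaries) is provided for geometry comparisons and produces a sharper
transition than the heterogeneous packing.

**Coupling.** Each edge carries a gap-junction conductance drawn from a
Gamma distribution with mean 120 pS and SD/mean = 0.70 (Gamma rather than a
zero-truncated Gaussian so the realized coefficient of variation equals the
specified one; junctional conductances are right-skewed and strictly
positive). `cv = 0` gives uniform conductances.

**Single-cell model.** The cell is a Chay-Keizer-class burster with three
state variables — membrane potential `V` (mV), delayed-rectifier activation
`n`, cytosolic calcium `c` (µM) — and currents (fA):

    Cm dV/dt = −(I_Ca + I_K + I_KCa + I_KATP + I_coup)
    I_Ca   = g_Ca·m∞(V)·(V − V_Ca)          m∞ = 1/(1+exp((vm−V)/sm))
    I_K    = g_K·n·(V − V_K)                 τn dn/dt = n∞(V) − n
    I_KCa  = g_KCa·c²/(c²+k_d²)·(V − V_K)
    I_KATP = g_KATP_bar·p_open·(V − V_K)
    dc/dt  = f_Ca·(−α_Ca·I_Ca − k_PMCA·c)
    I_coup,i = Σ_j g_ij (V_i − V_j)

Defaults: `Cm = 5300 fF`, `g_Ca = 1000 pS` (`V_Ca = 25 mV`, `vm = −20`,
`sm = 12`), `g_K = 2700 pS` (`V_K = −75 mV`, `vn = −16`, `sn = 5`,
`τn = 20 ms`), `g_KCa = 800 pS` (`k_d = 0.5 µM`), `f_Ca = 0.001`,
`α_Ca = 4.5·10⁻⁶ µM/(fA·ms)`, `k_PMCA = 0.2 ms⁻¹`. All constants are
package calibration for a reduced model of this class; the published
comprehensive β-cell current sets live behind the same interface
(`integrate_islet(..., custom_rhs=...)`) if a user wants to plug one in.

The fast `(V, n)` subsystem is bistable for an effective K⁺-leak
conductance between ≈ 200 and ≈ 215 pS, and slow calcium accumulation
through `I_KCa` carries the cell across that window: the single cell bursts
for effective K_ATP conductance `g_KATP_bar·p_open` in ≈ [140, 185] pS,
spikes continuously below, and is silent above ≈ 190 pS.

**Glucose, mutants, channel opener.** Glucose enters through a calibration
table for the baseline K_ATP open probability: 0.040 / 0.029 / 0.024 at
2 / 11 / 20 mM (linearly interpolated), i.e. effective 240 / 174 / 144 pS —
silent at 2 mM; bursting at 11 mM (plateau fraction ≈ 0.4); bursting at
20 mM with plateau fraction in the 50–70% band. Two K_ATP perturbations are
affine mixes of the open probability, the unique forms satisfying their
stated boundary conditions (untreated means identity; a uniform half-mix
equals 100% mutant expression at γ = 0.5):

    mutant (over-active subunit, per-cell flag):  p' = γ + (1−γ)·p
    uniform opener (diazoxide-like, all cells):   p' = (1−α) + α·p

with the mutant mix composed after the opener scaling, and γ = 0.5 by
default. The open-channel conductance `g_KATP_bar = 6000 pS` is deliberately
much larger than the active-state effective conductance (physiologically
K_ATP carries a large spare conductance): mutant cells then present
nanosiemens-scale hyperpolarizing sinks, which is what lets a ~15% minority
suppress a 120 pS-coupled islet. The choice is a calibration plateau, not a
knife edge — doubling it barely moves the transition. Its flip side is that
opener scans compress toward α = 1 (opening a few percent of the spare
conductance silences a cell), so α-scans use a fine grid near 1.

**Heterogeneity.** Per-cell multiplicative Gaussian scatter truncated at
zero: SD/mean = 10% on `g_Ca`, `g_K`, `g_KCa`, `k_PMCA` and the metabolic
drive (a multiplier on `p_open`), and 25% on `g_KATP_bar`. Modes `all`,
`katp_only`, `metabolic_only` and `none` reproduce the heterogeneity-source
ablations. Whether a mutant cell's γ-mix applies before or after its
heterogeneity is not constrained by the source; γ acts on the heterogeneous
open probability (after).

**Integration.** Forward Euler, fixed 100 µs step, states sampled every
100 ms; initial state `V = −65 mV` plus 0.5 mV per-cell Gaussian jitter to
break symmetry, `n = 0`, `c = 0.1 µM`; the first 10 s of every run are
discarded as transient before classification. Halving the step changes the
classified percent-active of a 500-cell scan by < 0.5 percentage points.
Non-finite states raise an integration error carrying the failing step. The
default model runs in a compiled (numba) kernel; the pluggable-model path is
a vectorized numpy loop verified against the kernel.

## Activity metrics

**Classification.** A trace is active when the variance of its linearly
detrended time-course exceeds the quiescent reference variance by more than
2 × the spread of the reference variance (the reference trace is split into
10 equal segments and the SD of per-segment variances estimates that
spread; the source describes the rule but not how the spread was obtained).
Linear detrending removes photobleaching-like drift. Two extra guards
matter only for noise-free simulated traces: a variance floor (default
10⁻⁴ µM² in scans, i.e. ~0.01 µM residual ripple) because a simulated
silent reference has vanishing variance, and a mean-elevation criterion
(default 0.06 µM above the reference mean) because cells driven into a
continuous depolarized plateau show strongly elevated calcium with little
variance. Imaging data needs neither.

**Plateau fraction** is the fraction of samples above the midpoint of the
10th/90th-percentile levels of the detrended trace — robust to spike
overshoot; the experimental definition is unstated, so simulated plateau
fractions are compared only as range checks. **Synchronization** is the
mean pairwise Pearson correlation over active cells. **Transition
location** is the midpoint of the adjacent pair with the largest absolute
difference quotient (3-point moving average first when the curve is
non-monotone); curves whose largest step is below 2 × the median absolute
adjacent difference are flagged as having no transition.

## χ² fitting

Model mean curves are precomputed once per grid cell — cluster
decompositions depend only on `(p, seed)`, so one set of replicates serves
every `Sp` and every `P_exc` — and compared to observed percent-active
points by `χ² = Σ (obs − pred)²/σ²` (unit weights unless the observation
table carries per-point SEMs; the absolute χ² scale therefore depends on
that choice and is not a comparison target). The `(p, Sp)` optimum is an
exhaustive grid search; 95% confidence intervals come from the
`Δχ² = 5.99` contour (two jointly fitted parameters), and optima on the
grid edge carry a boundary flag. Per-replicate fitted-parameter
distributions fit each single lattice's curve separately and histogram the
optima. Conductance-scaled fits map normalized conductance to effective
coupling `p = p₀·(G/G_wt)` at fixed `P_exc = 0.7` and search `(p₀, Sp)`.
The synthetic-observation generator evaluates the model mean at the
requested control points, adds i.i.d. Gaussian noise and clips to
[0, 100], tagging its output `synthetic`.

## What the synthetic data does and does not emulate

Synthetic observations share the model's mean structure plus homoscedastic
Gaussian noise; real percent-active measurements carry islet-to-islet
biological variability, heteroscedastic counting error and imaging
segmentation error, and the expression level of a mutant subunit is itself
measured with error. Parameter-recovery results therefore demonstrate the
identifiability of `(p, Sp, p₀)` under the model's own noise assumptions,
not the accuracy attainable from any particular imaging pipeline. Likewise
the dynamical engine's reduced cell model reproduces class-level behavior
(silent/bursting regimes, plateau-fraction ordering, coupling-dependent
phase transitions), not the quantitative electrophysiology of the full
published current sets, and no insulin-secretion or in-vivo physiology is
modeled.

## Problem sizes

The shipped analyses use: 500 bond-configuration replicates per grid point
for Boolean curves; 500 replicates per point and sizes L = 10, 16, 24 for
the threshold crossing; 500-cell islets simulated for 40 s (10 s transient
discarded) per scan point for the mutant-fraction transition; 300-cell
islets and 30 s for the opener-scan and conductance-ordering comparisons;
ten 1000-cell packings for architecture statistics. These sizes give
Monte-Carlo errors comfortably inside the tolerances asserted in the test
suite while keeping a full run in the minutes range on one CPU.

## Known limitations

* The reduced cell model's burst period (~2 s) is faster than typical islet
  oscillations; plateau fractions and activity classification, which are
  the quantities consumed downstream, are insensitive to this.
* The Boolean engine is static: it has no dynamics, oscillation waveforms
  or partial (graded) cluster activity, by design.
* Site percolation, non-cubic Bravais lattices and periodic boundaries are
  out of scope; gradient/continuous optimizers are deliberately absent (the
  fitting procedure is a grid search).
* The opener (α) scans compress near α = 1 as a consequence of the spare
  K_ATP conductance calibration; comparisons across coupling levels are
  made on a common fine grid and only slope ratios are interpreted.
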