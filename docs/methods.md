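# Methods

This note documents the model, the numerical choices and the design
decisions behind `spikevo`, and what the test suite does and does not
establish.

## Encoding

A feature with observed range `[I_min, I_max]` drives `L >= 3` Gaussian
receptive fields with centres
`mu_i = I_min + (2i-3)/2 * (I_max-I_min)/(L-2)` (evenly spaced, symmetric
about the range midpoint, outermost centres half a step outside the range)
and common spread `sigma = (1/beta) * (I_max-I_min)/(L-2)`. The Gaussian is
the standard receptive-field form `exp(-(x-mu)^2/(2 sigma^2))`, so responses
lie in [0, 1] for every real input, including values outside the observed
range (they simply approach 0).

Responses convert to spike times by `t = (1 - r) * (t_max - t_min) + t_min`
over the [0, 10] ms encoding window: the time-to-first-spike convention,
under which the best-matching field fires earliest and an indifferent field
fires at the window end. Times are rounded to the nearest multiple of the
simulation step `dt`, half-steps rounding up; the rounding adds a
1e-9-step epsilon before flooring so that exact half-steps (e.g. 6.75 ms at
`dt = 0.1`) stay on the "up" side despite binary floating point. Every
encoding neuron always emits exactly one spike — there is no late-spike
cutoff or "no-spike" code for weak responses.

Feature ranges are inferred from the **training split only** and frozen
into the encoder, so test-time encoding never leaks test statistics; a
constant training column is widened by ±0.5 to stay encodable. A bias
neuron firing at 0 ms is appended to every sample.

Class labels are coded as desired output spike times placed after the
encoding window: `start + k * spacing` in sorted label order, defaults
11 ms start and 1 ms spacing (so 3 classes sit at 11/12/13 ms and 2 classes
at 11/12 ms). The configuration is rejected if targets spill past the
simulation horizon `T`. The start/spacing are exposed because the choice is
empirical, not principled.

## Neuron model

Sub-threshold dynamics are leaky integration of a delayed, weighted drive:

    tau_m dv_j/dt = -(v_j - v_rest) + xi_j(t) R_m
    xi_j(t) = sum_i w_ij Psi(t - t_i - kappa_ij)
    Psi(x) = [exp(-x/tau_m) - exp(-x/tau_s)] H(x),  0 < tau_s < tau_m

with `H` the strict Heaviside step (`H(0) = 0`). The kernel peaks at
`x* = tau_m tau_s/(tau_m - tau_s) ln(tau_m/tau_s)` with value
`(tau_s/tau_m)^(tau_s/(tau_m-tau_s)) - (tau_s/tau_m)^(tau_m/(tau_m-tau_s))`;
for the default `tau_m = 10`, `tau_s = 5` this is `10 ln 2 ≈ 6.93` ms and
exactly 1/4, and both closed forms are exported and verified against a
dense-grid maximisation in the tests.

Integration is explicit Euler on the grid `t = dt, 2dt, ..., T` with
`v(0) = v_rest`: `v(t) = v(t-dt) + (dt/tau_m)(-(v(t-dt) - v_rest) + xi(t)
R_m)`. At the default `v_rest = 0` the leak reduces to `-v(t-dt)`; the
`-(v - v_rest)` form is a deliberate extension so that a nonzero rest
behaves sensibly. `R_m = 100` is treated as a dimensionless gain on the
drive — the physical units of `w * Psi * R_m` are not self-consistent under
any literal reading, and the gain interpretation together with weight
bounds [-0.25, 1] makes neurons fire within the 20 ms horizon without
firing trivially early.

Each neuron fires at most once: the first grid time with `v >= theta`
(default 1 mV) is its spike time and integration stops there; there is no
reset, refractoriness or noise. A neuron that never crosses by `T` is
*silent*, represented by NaN; silent pre-synaptic neurons contribute zero
drive downstream, and a silent output neuron is scored at the sentinel
time `T` (the latest legal spike time) so the training error stays finite.

The batch simulator (`layer_spike_times`) vectorises the same recursion
over instances and post-synaptic neurons; because the recursion has no
reset, extracting the first crossing of the full trajectory is identical
to stopping at the spike, and the test suite checks the batch path against
the per-neuron path and both against an independently written brute-force
reference, spike for spike.

## Training

The genome concatenates the input→hidden and hidden→output weight matrices
(real genes, bounds [-0.25, 1], initialised uniformly) and the equally
shaped delay matrices (integer genes, inclusive bounds {1..6}, initialised
uniformly) — `2 (M N + N P)` genes; the bias neuron's synapses are trained
like any other.

Fitness is `f = 1/(1 + e)`. The error `e` is accumulated as the half sum of
squared differences between output spike times and class targets and then
divided by the instance count, making `f` invariant to training-set size;
both the raw SSE and the MSE are logged. Training accuracy is tracked
separately in the trace — it is the selection criterion for nothing, only a
diagnostic and the basis of the convergence generation.

Per generation, with population 100 and `elite_frac = 0.2`:

* the 20 best genomes are copied unchanged (best fitness is therefore
  non-decreasing, which the tests assert);
* the remaining 80 slots are filled in pairs: parents are drawn by linear
  rank selection (worst rank 1, best rank n, probability rank/Σrank, ties
  ranked by index) **from the whole population**; with probability
  `crossover_rate = 0.8` the pair is crossed — arithmetic blending
  `c1 = p1 - r1 (p1 - p2)`, `c2 = p2 + r2 (p1 - p2)` with `r1, r2 ~ U[0,1]`
  drawn once per event (a per-gene variant is available behind
  `per_gene_crossover`) on the weight genes, single-point tail swap on the
  delay genes — otherwise the parents are cloned; every offspring gene is
  then mutated independently with probability 0.1 by a uniform redraw
  within its bounds (uniform *integer* redraw for delays). Elite slots are
  never crossed or mutated.

Letting elites serve as parents while protecting their slots was a
deliberate choice: restricting the parent pool to the non-elite remainder
cuts the best building blocks out of recombination, and in side-by-side
runs on the 3-class synthetic benchmark it stalled training around 60%
accuracy, versus ~97% with the whole-population pool. Arithmetic blending
is contractive and mutation redraws within bounds, so every weight gene
stays in [-0.25, 1] and every delay gene in {1..6} indefinitely (asserted
over 50-generation runs).

Training runs for exactly `max_generations` offspring generations; the
trace additionally records generation 0 (the random initial population).
The convergence generation `G` is defined as the last generation with a
strict improvement in the best genome's training accuracy, clamped to at
least 1 because the efficiency metric `CE = dt/(T G)` divides by it. `CE`
is reported exactly as `dt/(T G)`.

## Decoding and metrics

An output spike time decodes to the class with the nearest target time;
ties go to the earlier target, and a silent output is decoded at the
sentinel `T` (hence to the latest class, if nearest). Accuracy is percent
correct; the confusion matrix counts true class (rows) against predicted
class (columns) over an explicit label order. Repeated-run experiments
(`repeat_fit`, `spikevo train --repeats`) refit with consecutive seeds and
report mean ± sample standard deviation.

## Data handling

CSV tables are read with a header row; `?` is the recognised missing
marker, any other non-numeric cell is an error with its row/column. Rows
with missing features are dropped by default — for a 699-row table with 16
missing cells this leaves 683 usable instances, consistent with the
333/350 train/test protocol of the breast-cancer benchmark — or imputed
with the column median. Splits are stratified by default and seeded
(delegated to scikit-learn's `train_test_split`).

## Synthetic data

`make_synthetic` draws isotropic Gaussian clusters with class *c*'s mean at
`c * class_separation` on every axis. Defaults (3 classes × 50 instances,
4 features, separation 3, unit noise) emulate the size and difficulty of an
Iris-like table; separation 0 produces indistinguishable classes. What it
does **not** emulate: correlated or heteroscedastic features, class
imbalance, outliers, discrete-valued features, or the specific geometry of
real UCI data — so passing tests demonstrate that the pipeline can learn
well-separated Gaussian structure, not that it reproduces published
accuracies on the real benchmarks. With local copies of those datasets the
documented reproduction goal is mean test accuracy within a few percentage
points of the published 97.24% (Iris) and 97.92% (breast cancer) figures,
using the defaults and 10 repeats; this is not checked by the suite.

## Problem sizes and runtime choices

The acceptance script's end-to-end run uses the Iris-shaped synthetic
dataset at full published width (17-12-1 topology, population 100) trained
for 150 generations with 3 repeat seeds — by generation ~100 the best
fitness has typically plateaued on this problem, so longer runs change `G`
more than accuracy. The test suite's property runs use smaller nets
(2-class, 6–8 hidden neurons, 15–200 generations) for the same reason.

## Known limitations

* Single-spike coding only; the design cannot express multi-spike schemes,
  reset dynamics or rate codes.
* One hidden layer and exactly one output neuron; k-class problems share
  that neuron via k target times, which crowds together as k grows within
  the fixed [11, T] window.
* The GA is the only optimiser; no gradient or hybrid refinement.
* `dt` couples encoder rounding and simulation; very coarse `dt` quantises
  output times and caps achievable MSE.
* Fitness evaluation is O(pop · n · T/dt · M · N) per generation; the
  vectorised simulator keeps Iris-sized problems at a few hundred ms per
  generation on one core, but much larger tables would need batching of
  the population as well.
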