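# Methods

`apemu` couples three pieces: a desk-scale mechanistic simulator of the paced
human ventricular action potential (AP) with nine scalable current
magnitudes, a neural-network emulator that maps those nine scale factors to
the full transmembrane-potential time course, and the forward/inverse
pharmacological workflows built on both. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic world
does and does not establish.

## The ionic simulator

The simulator is a reduced Hodgkin–Huxley-style ventricular cardiomyocyte
model in the Luo–Rudy-1991 lineage, extended so that exactly nine current
magnitudes can be scaled relative to baseline:

| scale | current | formulation |
|---|---|---|
| gNa  | fast Na⁺            | 23·m³hj·(V−E_Na), LR1 rates |
| gNaL | late Na⁺            | 0.012·mL∞³·hL·(V−E_Na), τ_hL = 200 ms |
| pCa  | L-type Ca²⁺ (slow inward) | 0.1035·d·f·(V−E_si(Ca_i)), LR1 rates |
| gto  | transient outward   | 0.12·a·i·(V−E_K) |
| gKr  | rapid delayed rectifier | 0.3243·x·x_i(V)·(V−E_K) |
| gKs  | slow delayed rectifier | 0.06·x_s²·(V−E_K) |
| gK1  | inward rectifier    | 0.907·K1∞(V)·(V−E_K1) |
| gNCX | Na/Ca exchange      | phenomenological, Ca_i-dependent, saturating |
| pNaK | Na/K pump           | 1.0·f_NaK(V) |

Fixed (non-scalable) plateau-K and background currents anchor the resting
potential. Intracellular calcium follows the LR1 single-pool update; all
other concentrations are constant. The baseline magnitudes were calibrated
once so that the paced baseline AP places all seven biomarkers (below)
comfortably inside the experimental calibration ranges and so that APD90 is
monotone non-increasing in gKr and gK1 — after that calibration no model
constant was revisited.

EAD mechanism: with strong gKr block (≥ ~86%) and L-type enhancement the
model loses repolarization reserve; the L-type window current then sustains
depolarizing deflections during phase 2/3 (oscillations around a depolarized
quasi-equilibrium near −20 mV). This is the qualitative behaviour the
abnormal-AP drug grid (gKr scaling 0.05–0.14, pCa scaling 1.20–1.38) is
meant to probe. It is a stand-in: a full ionic model produces richer EAD
morphologies.

Numerics. Gating variables advance with the Rush–Larsen exponential update
(exact at frozen voltage); V and Ca_i use forward Euler. Gate steady states,
per-step decay factors and every purely voltage-dependent algebraic term are
pre-tabulated on a 0.02 mV grid and linearly interpolated inside a
numba-compiled loop, making the inner loop transcendental-free except for
one logarithm. Defaults: solver step 0.01 ms, sampling step 0.05 ms —
halving the solver step changes every biomarker by < 0.1% (the acceptance
bound is 2%). Pacing: 1000 ms cycle, 1 ms × 60 µA/cm² rectangular stimulus
(chosen so depolarization succeeds across scale factors in [0.5, 1.5]),
default 200 beats with early stop once the relative per-beat state change
falls below 10⁻⁴; starting from the shipped baseline limit-cycle state this
terminates after a handful of beats near baseline (the last beat then
differs from the 200-beat limit cycle by ~10⁻³ mV). Voltage escape from
(−120, 80) mV or a non-finite state raises an integration-failure error
naming the offending time.

## Biomarkers and abnormality rules

Seven scalar descriptors: RMP (pre-stimulus potential), dVmMax (max
finite-difference slope; its time is the activation reference), Peak,
APD40/50/90 (activation to the linearly interpolated crossing of
Peak − x%·amplitude), and Tri90−40 = APD90 − APD40. Calibration ranges
(population filter): RMP −95…−80 mV, dVmMax 100…1000 mV/ms, Peak 10…55 mV,
APD40 85…320 ms, APD50 110…350 ms, APD90 180…440 ms, Tri90−40 50…150 ms;
intervals are closed.

Unrepolarized rule: |vm(1000) − vm(0)| > 10% of the peak-to-trough
amplitude, strict inequality; such traces are excluded from training data
and counted.

EAD rule: on a 5-point moving-average-smoothed trace, starting a guard
interval after the AP peak, a local minimum followed by a later rise of at
least δ = 1 mV reaching above V_gate = −40 mV. The guard is 100 ms: the
built-in model has a physiological phase-1 notch-and-dome whose dome (a ~3 mV
depolarizing deflection ~50 ms post-peak) is not an EAD; a 30 ms guard would
misclassify every baseline AP. EADs in the drug regime occur later than
300 ms and are unaffected. All four parameters live in `EADConfig`.
Abnormality (population filter) = EAD or unrepolarized on either of the last
two consecutive beats.

## Training corpus

Conductance samples come from unscrambled Sobol' sequences (skip 0), half in
[0, 2]⁹ and half in [0.5, 1.5]⁹; a seed only controls optional scrambling,
so the default corpus is a deterministic function of its size. Each sample
is paced to the early-stop limit cycle; unrepolarized APs are excluded;
survivors are resampled onto the canonical non-uniform grid: 4 kHz on
[−10, −5), 10 kHz on [−5, 20) (depolarization), 4 kHz on [20, 1000] —
4191 points, with vm held at vm(0) on [−10, 0). 20% of the kept samples are
randomly labelled validation. The desk-scale default is 4000 samples
(~0.13 s each on one CPU); the tests use a few hundred.

## Emulator architecture

Inputs are normalized per-coordinate, x_i = G_i/(2·G_ref,i) − 0.5 ∈
[−0.5, 0.5], so x = 0 is baseline. An encoder (four dense layers of 256,
ELU; final layer linear) maps x to a 256-dimensional latent code θ plus
three depolarization parameters. A decoder (dense 264→64→64→64→64→1; ELU,
the last hidden layer bounded by tanh, final linear) evaluates f_θ at any
time t from the latent code and eight time features. The emulated potential
is

    Vm(t) = f_θ(t) + (d₃/2)·tanh((d₁/2)·(t − d₂)),

i.e. a learned smooth residual plus an explicit depolarization step with
slope d₁ (1/ms), offset d₂ (ms) and amplitude d₃ (mV). The multiplicative
placement of d₃ follows its role as an amplitude.

Time features. The decoder sees powers 1…8 of a normalized time. A linear
map of [−10, 1000] ms onto [−1, 1] proved unusable: the millisecond-scale
depolarization and notch occupy ~1% of the axis and a degree-8 basis cannot
resolve them (training plateaued at ~20 mV RMSE inside [0, 5] ms). The
implemented normalization warps time logarithmically, u = log1p((t+10)/τ)
with τ = 10 ms (linear continuation below t = −10), then maps affinely to
[−1, 1]. The warp spends resolution where the AP has structure and is
monotone and C¹, so dVm/dt stays analytic.

Heads and scales. The decoder works on Vm/100 internally (targets O(1), ×100
mV at the interface). d₁ = 16·σ(r₁) 1/ms and d₃ = 2·σ(r₃) (decoder units)
use bounded sigmoid maps — positive by construction, and immune to the two
failure modes observed with unbounded positive maps (amplitude collapse to
0 through saturation; slope runaway that makes the offset gradient spiky).
d₂ = 5·r₂ ms. Head biases are initialized near a physiological upstroke
(slope 8/ms, offset 0.8 ms, amplitude 130 mV). Other layers use fan-in
uniform initialization from a seeded generator.

Both networks, backprop (including ∂Vm/∂x and ∂Vm/∂t) and Adam are
implemented directly in numpy; all three gradient paths are checked against
central differences in the test suite (≤ 10⁻⁴ relative).

## Training

Loss per step: L = 1/(2|T|) Σ_samples Σ_{t∈T} (Vm(x,t) − V̂m(t))², with T a
uniform random subset of the canonical grid. Batch size and |T| grow
linearly between configured endpoints; the full-scale defaults are 5000
epochs with batches 1250→1800 and |T| from 1/16 of the grid to all of it.
The desk-scale recipe uses small constant batches (64–128) and caps |T| at
1/8 — with a fixed CPU budget, many cheap Adam steps fit the data better
than few expensive ones. Learning rate 3·10⁻³ decaying linearly to 5% (Adam,
β = (0.9, 0.999)); gradients are clipped at global norm 25 (the
depolarization-step parameters otherwise produce occasional spikes).
Validation trace RMSE is computed periodically on a strided grid; the
best-validation checkpoint is returned. Training is deterministic given the
config (seeded init and batching, fixed thread policy).

## Inverse fitting

Objective: mean squared trace mismatch (over the target grid, with the
emulator evaluated at t − t₀) plus (λ/2)‖x − x̂‖², minimized by Adam with
projection of x onto [−0.5, 0.5]⁹ after every step; λ = 10 by default.
t₀ is fitted jointly with its own step size (5·10⁻², vs 2·10⁻³ for x: they
live on different scales). Shifted times outside the trained domain are
clamped with a warning. Convergence is by fixed iteration count (defaults:
10⁴ synthetic; 5·10⁴/2.5·10⁴ for experimental-style control/drug fits); an
optional objective-change tolerance is off by default. Control APs are
fitted with x₀ = x̂ = 0, drugged APs with the control estimate as both; drug
scaling factors are element-wise ratios of the denormalized conductances.

Weakly identifiable coordinates (gKs above all — its current is small and
slow) are pinned to the prior by λ; recovery accuracy claims therefore apply
to the identifiable coordinates, defined operationally as those whose mean
AP sensitivity |∂Vm/∂x_i| is within a factor 4 of the largest.

## Preprocessing of raw recordings

Blanking replaces [0, 1.75] ms with the end-of-beat RMP (the operative
window; the artifact itself occupies [0, 1.5] ms). Filtering resamples to
100 kHz and applies a second-order Butterworth low-pass at 2.5 kHz
forward-backward (zero phase — a phase shift would be absorbed into t₀ by
the inverse fitter as a spurious offset); the effective magnitude response
is therefore |H|². Beats are aligned by stimulus time, averaged pointwise,
and resampled to 100 kHz on [0, 15) and 1 kHz on [15, 1000]. The QC report
flags across-beat standard deviation above 7 mV before / 2 mV after the
peak. Repeated application of the pipeline is idempotent to < 0.1 mV except
within a few ms of the upstroke, where each filter pass re-smooths the
near-discontinuous edge (bounded by a few mV).

The synthetic-recording generator emulates the structure of tissue
microelectrode data: the simulated AP delayed by a 2 ms stimulus-to-upstroke
latency, a 40 mV artifact spike in [0, 1.5] ms, independent Gaussian noise
per beat (default SD 1 mV) and Gaussian alignment jitter (default SD
0.1 ms). It does not model drift, correlated noise, cell-to-cell coupling
or fibroblast loading — a green preprocessing test establishes the
pipeline's signal-processing behaviour, not fidelity to real tissue.

## What the synthetic world establishes

All data here come from the built-in reduced model, not from a full human
ventricular simulator. Green tests establish: the pipeline's mechanics
(sampling, exclusion, resampling, splitting), the emulator's capacity to
learn a nine-parameter AP family to ~1–2 mV at desk scale, exactness of the
analytic machinery (gradients, metrics, pore-block model), self-consistent
inverse recovery on emulator-generated targets, and the qualitative
pharmacological phenomenology (APD prolongation under hERG block, EAD onset
under combined hERG block/Ca enhancement, error growth from control to drug
to scaling factors). They do not establish quantitative agreement with a
full ionic model's AP family, EAD classification statistics comparable to
detailed simulators, or performance on real microelectrode recordings.

## Known limitations

- The EAD phenotype is oscillation around a depolarized equilibrium; true
  take-off/plateau EAD morphologies of detailed models are richer.
- Validation RMSE at desk scale is dominated by a small number of
  near-discontinuous APs from the [0, 2] sampling range (the same region the
  full-scale study found hardest); the distribution is heavy-tailed (median
  well below the mean).
- The emulator has no pacing-cycle-length input; only 1000 ms pacing.
- Reference scaling-factor distributions are user-supplied or synthetic;
  no assay data ship with the package.
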