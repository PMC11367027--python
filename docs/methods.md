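# Methods note

This note records the modeling choices, parameter settings, and numerical
conventions used by `ecglearn`. Every empirical figure mentioned here is
computed by the test suite or by `scripts/acceptance.py`; nothing else is
claimed.

## Problem and model

The task is multi-label classification of 12-lead ECG recordings into five
diagnostic superclasses: NORM, MI (myocardial infarction), STTC (ST/T
change), CD (conduction disturbance), HYP (hypertrophy). A recording may
carry any subset of labels; records with an empty label set are dropped
before modeling.

The pipeline has three learned components:

**BiLSTM feature extractor** (`ecglearn.bilstm`). A standard LSTM cell with
input, forget and output gates and a tanh candidate:

    i = σ(W_i·[h, x] + b_i)      f = σ(W_f·[h, x] + b_f)
    o = σ(W_o·[h, x] + b_o)      g = tanh(W_C·[h, x] + b_C)
    C' = f ⊙ C + i ⊙ g           h' = o ⊙ tanh(C')

run over the subsampled sequence in both directions; the feature vector is
the concatenation of the two final hidden states, `[h_fwd; h_bwd]`. Training
uses a sigmoid multi-label head with binary cross-entropy (computed in the
softplus-stable form `mean(log(1+e^z) − y·z)`), inverted dropout on the
feature vector, mini-batches, and manual backpropagation through time.
Weights initialize uniform in (−0.1, 0.1) with forget-gate bias 1.0 (the
usual remedy against early forgetting).

**Stacked sparse autoencoder classifier** (`ecglearn.ssae`). Each layer maps
`z = σ(w₁x + b₁)`, `x' = σ(w₂z + b₂)` and is pretrained greedily on the
objective

    L = (1/2N) Σ‖x' − x‖² + β Σ_j KL(ρ ‖ ρ̂_j)

with Bernoulli KL divergence between the target sparsity `ρ` and the
per-unit mean activation `ρ̂_j` of the current batch. A supervised sigmoid
head (with optional encoder finetuning) is then fit on the stacked code;
prediction thresholds scores at ≥ 0.5.

**AdaMax** (`ecglearn.adamax`) performs every gradient update:

    m ← β₁m + (1−β₁)G        u ← max(β₂u, |G|)
    w ← w − (η/(1−β₁ᵗ)) · m/(u+ε)

with defaults η = 0.1, β₁ = 0.9, β₂ = 0.999, ε = 1e-8. The implementation
matches an independently coded reference to machine precision
(`adamax_max_abs_deviation ≈ 6e-17` over 100 steps on a quadratic).

**Dragonfly algorithm** (`ecglearn.dfa`) tunes the SSAE hyperparameters
(layer sizes, ρ, β, learning rate; sizes treated as integers, all searched
in log₁₀ space). Each swarm member updates its step from five behaviors —
separation `S = −Σ(X−X_j)`, alignment `A = mean V_j`, cohesion
`C = mean X_j − X`, food attraction `F = X⁺−X`, enemy distraction
`E = X⁻+X` — combined as `ΔX' = sS + aA + cC + fF + eE + wΔX`. Neighbors
are defined by a per-dimension box radius growing from 10% to 110% of each
bound's width over the run; inertia `w` anneals 0.9 → 0.4; per-iteration
coefficients are drawn as `s,a = 2·rand·0.1`, `c = 2·rand·0.7`,
`f = 2·rand`, `e = 0.1`. Members with no neighbors take a Lévy flight
(Mantegna's algorithm, exponent 1.5). Positions are clamped to bounds, with
the step zeroed on clamping. The fitness is 100 × the mean per-class
one-vs-rest misclassification rate on a held-out validation split.

## Parameters

| Parameter | Default | Rationale |
| --- | --- | --- |
| BiLSTM batch size | 7 | reference training condition |
| BiLSTM dropout | 0.5 | reference training condition |
| BiLSTM epochs | 50 | reference training condition |
| Sequence stride | 10 | 1000-sample records → length-100 sequences |
| AdaMax η | 0.1 | optimizer default; the pipeline example uses 0.01 for stable training on small problems |
| SSAE threshold | 0.5 | inclusive (score ≥ threshold → positive) |
| DFA population × iterations | 6 × 8 (pipeline default) | sufficient for the 5-dim search space |
| Stage seeds | global seed + fixed offsets | reproducible per-stage randomness, all < 2³¹ |

## Synthetic generator fidelity

`ecglearn.synthetic` builds beat trains from Gaussian bumps (P, Q, R, S, T)
plus an ST plateau, at a per-record heart rate uniform in 60–100 bpm with
per-beat timing jitter, scaled by a fixed 12-entry lead-gain vector, with
0.33 Hz sinusoidal baseline wander and additive Gaussian noise (0.05 mV).
Class effects follow textbook signatures: MI deepens Q (×3) and elevates ST
(+0.15 mV); STTC inverts T (−0.45) and depresses ST (−0.10 mV); CD widens
the QRS complex (×1.8); HYP raises QRS amplitude (×1.6). Labels are drawn
from configurable prevalences with a 0.25 multi-label co-occurrence rate (a
package choice; the generator exposes it as a parameter).

Limits: the generator produces stylized, nearly stationary morphology — no
arrhythmia, no inter-patient morphology variation beyond gain/rate/jitter,
no electrode artifacts, and identical underlying templates across leads up
to gain. Classes are therefore more separable than clinical data (a logistic
baseline on summary features reaches ~92% in the test suite), so absolute
performance figures on synthetic data characterize the pipeline's
correctness, not clinical performance. The `ptbxl_like` preset (3000
records, 35 null-labeled, 100 Hz, 10 s) mirrors the scale at which the
reference summaries were reported (2965 records after filtering).

## Numerical choices

- **Gradient checks** use central finite differences with the normalized
  error `|g−fd| / max(|g|+|fd|, 1e-6)`; the absolute-tolerance form is
  dominated by finite-difference noise for components near the rounding
  floor. Measured maxima: ≈7e-6 (BiLSTM), ≈2e-9 (SSAE), both well under the
  1e-4 acceptance bound.
- **Sparsity KL**: `ρ̂` is clamped to [1e-6, 1−1e-6] for log stability; the
  analytic gradient zeroes the KL term where the clamp is active so it stays
  consistent with the evaluated loss.
- **Metrics**: reported ×100; a vanishing denominator yields 0 with a
  `RuntimeWarning`. Reported values use round-half-up at 2 decimals
  (`round_half_up`), matching conventional clinical-table rounding rather
  than banker's rounding. One-vs-rest tables use the convention that the
  "absent" side of each class is the positive class, matching the reference
  summaries being reproduced. Agreement with scikit-learn over 1000 random
  confusion matrices is ≤3e-14 percentage points.
- **Confusion reconstruction** inverts printed (correct-count, sensitivity,
  specificity) triples via `fn = round(tp/(sens/100) − tp)` etc., and
  asserts the reconstructed total; it assumes inputs consistent within
  2-decimal rounding, which fails to be invertible only for extreme rates.
- **Resampling** uses integer-stride decimation without an anti-alias
  filter; acceptable for the smooth synthetic signals, an approximation for
  real high-frequency content.
- **Determinism**: all randomness flows through `numpy.random.default_rng`
  from explicit seeds; pipeline stages derive seeds as global seed + fixed
  offsets, and a repeated run reproduces `report.json` byte for byte.

## Problem sizes used in validation

The end-to-end validation run uses 600 synthetic records (reduced network:
hidden size 16, 10 extractor epochs, swarm 6 × 8, 20 autoencoder epochs) and
requires ≥ 75% macro one-vs-rest accuracy on a held-out 20%; measured runs
land near 89–90% across seeds. These sizes are package choices for a
single-core validation workload; the defaults in `pipeline.DEFAULT_CONFIG`
retain the full-scale training settings.
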