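# Methods

## Data model and state labeling

Scalp EEG arrives as multi-channel recordings on a per-patient continuous
timeline, with a table of seizure events (onset, offset in seconds). Four
physiological states are distinguished: ictal (the seizure), postictal (the
recovery right after), preictal (the window before onset — the positive
class), and interictal (everything else — the negative class). The labeling
rules, applied left-to-right over seizures sorted by onset:

* preictal = the `preictal_minutes` (default 30) before a retained
  seizure's onset, clipped to the recording and to the end of any preceding
  exclusion;
* the seizure span and the `postictal_hours` (default 2) after its offset
  are excluded from modeling;
* a seizure starting less than `postictal_hours` after the previous
  retained seizure's offset is dropped entirely (no preictal window of its
  own); note that such a seizure necessarily begins inside the previous
  postictal exclusion, so only any overhang of its span appears as a
  separately tagged exclusion;
* interictal is the remaining timeline.

Preictal windows shortened by a collision (recording start, prior
exclusion) are *truncated, not dropped*, and flagged in the epoch manifest;
the alternative (dropping them) discards usable positive-class data and
nothing in the state definitions requires it. Retained intervals are tiled
with nonoverlapping 60-s epochs (partial trailing windows discarded, never
padded — downstream stages assume a fixed q), and each 1-s block of fs
samples is averaged per channel, giving p×60 epoch matrices. Non-integer
sampling rates are rejected rather than resampled so that the averaging is
exact. Epochs are stored electrodes × seconds; one canonical orientation
avoids silent transposition bugs.

## Stage 1: dynamic connectivity

Each epoch X (p×q) is modeled as matrix-normal with separable covariance
Σ_T ⊗ Σ_S. For each time point t the kernel-weighted covariance
Σ̂(t) = Σ_i w_it x_i x_iᵀ / Σ_i w_it is formed with Gaussian weights
w_it = K(|i−t|/h), K(u) = exp(−u²/2), then averaged over the q time points
and passed to the graphical lasso; the result is a single sparse precision
matrix per epoch estimated through a *time-varying* covariance. Edge
strengths are partial correlations (a raw-precision mode exists for
ablation). Because every Σ̂(t) equals X·diag(w_t/Σw_t)·Xᵀ, the average is
computed as X·diag(d)·Xᵀ with d the mean normalized weight vector —
algebraically identical to the literal average and q times cheaper.

Parameter choices:

* **Bandwidth** h = q^(1/3) by default (q = 60 → h ≈ 3.91). The bandwidth
  rule's "sample size" is read as the number of within-epoch time points,
  since that is the axis the kernel smooths over; a fixed-bandwidth
  override exists for the alternative reading (total epoch count).
* **Centering**: electrodes are mean-centered within the epoch before
  covariance (the matrix-normal model has a mean term). `center=False`
  reproduces the uncentered second-moment formula exactly.
* **Penalty** λ = 0.1 by default, applied to the correlation-rescaled
  averaged covariance and shared by *all* epochs of a run, so edge scales
  are comparable across epochs; λ is a tuning input, not estimated.
* **Penalty scope**: off-diagonal entries only (the standard graphical-lasso
  convention — penalizing the diagonal shrinks overall scale without
  affecting the conditional-independence pattern); `penalize_diagonal=True`
  gives the literal unrestricted L1 reading.
* Zero-variance channels have their variance floored at `ridge_eps`
  (1e-8) with a logged warning rather than aborting the epoch.

### Graphical-lasso solver

The objective Tr(SΩ) − log det Ω + λ‖Ω‖₁,off is minimized by monotone
accelerated proximal gradient (MFISTA) alternated with an orthant-projected
Newton refinement:

* proximal sweeps use the natural step 0.95·λ_min(y)² (the inverse local
  Lipschitz constant of the log-det gradient), backtracking line search,
  and adaptive restart when the extrapolation point leaves the PD cone or
  overshoots; the accepted iterate never increases the objective;
* every 10 sweeps, the active set and its signs are frozen and Newton steps
  are taken in the free entries (diagonal + active off-diagonals), with
  entries that attempt to cross zero projected onto it; this polishes the
  solution to near machine precision once the proximal sweeps have
  identified the support;
* convergence is declared when the maximum KKT stationarity violation drops
  below `tol` (default 1e-5; the solver typically reaches ~1e-15);
* λ = 0 is solved in closed form as the inverse of S, ridged by `ridge_eps`
  if S is near-singular.

Positive definiteness is verified via Cholesky throughout: a determinant
check alone also accepts indefinite matrices with an even number of
negative eigenvalues, where the objective is unbounded below. Iteration cap
500; in practice ≤ 60 iterations suffice even for near-singular correlation
inputs. Support is reported at |entry| > 1e-8.

## Stage 2: bootstrap-ensembled sparse logistic regression

Columns of the predictor matrix are standardized with full-training
statistics (zero-variance columns dropped with a warning). The L1 penalty
is selected once by stratified 5-fold cross-validation on the training
split and reused across all B bootstrap fits (stability-selection practice;
per-bootstrap CV would be 10–50× slower for no benefit in the selection
frequencies). CV scoring is log-loss, a proper scoring rule: when the
signal is weak, accuracy cannot discriminate between penalty levels (every
λ scores ≈ 50%) and would admit needlessly dense models; log-loss prefers
the better-calibrated sparser fit, which keeps null-data ψ honest.

Each of the B (default 100) bootstrap resamples draws n₁ preictal and n₂
interictal epochs with replacement (both classes always present) and fits
an L1 logistic regression with effectively unpenalized intercept.
Coefficients are mapped back to the original column scale; ψ uses
|β| > 1e-8 on that scale. P̂_B is the exact mean of the B per-model
probabilities. All randomness (penalty CV split, bootstrap draws, fold
assignment) flows from one user seed through a named `SeedSequence`
hierarchy; identical seed ⇒ bit-identical fit.

The probability cutoff maximizes accuracy over the exhaustive candidate set
{0, 1} ∪ midpoints of adjacent sorted unique probabilities, ties broken
toward the smallest cutoff. Since cutoffs are probabilities confined to
[0, 1] and the decision rule is P̂ ≥ c, this candidate set realizes every
achievable prediction vector. SENS = TP/(TP+FN); FDR = FP/(TP+FP), defined
as 0 when nothing is predicted positive; AUC via the Mann–Whitney rank-sum
statistic with average ranks for ties.

## Evaluation protocol

`cross_validate` runs stratified k-fold (default k = 5) over epochs. Stage-1
features are per-epoch and unsupervised under the fixed global λ, so the
feature matrix is computed once and indexed per fold — identical results to
recomputing per fold at k× the cost; penalty CV and standardization use
training rows only. Out-of-fold probabilities are pooled, the cutoff is
chosen on the pooled probabilities, and SENS/FDR/AUC are computed from the
pooled predictions. ψ is reported from a final refit on all epochs. This
protocol is a documented package default: it is one reasonable choice among
several for per-patient evaluation, and outputs label it explicitly in
their protocol metadata.

## Synthetic benchmark

The simulator draws epochs from X ~ 𝓜𝓝(0, Σ_T ⊗ Σ_S) with:

* Σ_T an AR(1) matrix (entries ρ^|i−j|, default ρ = 0.5) — a one-parameter
  SPD family mimicking the temporal autocorrelation of per-second-averaged
  EEG;
* Σ_S the inverse of a planted sparse precision matrix: a shared
  Erdős–Rényi support (edge probability 0.1) with ±1 off-diagonal entries,
  plus `n_diff` (default 5) extra signed edges in the preictal class only;
  both classes share one diagonal value s = max(1/δ, |λ_min(pattern)|+0.1),
  which enforces positive definiteness by diagonal shift, keeps the
  differing-edge bookkeeping exact, and makes the planted partial
  correlations equal ±δ (default 0.4) whenever the first term binds — so
  the effect size is specified on the interpretable partial-correlation
  scale;
* iid N(0, 0.1²) observation noise on top of the signal.

Default problem sizes (p = 10 electrodes, q = 60 s, 60 + 60 epochs) are the
package's standing benchmark conditions; tests and the acceptance script
run at these sizes. What the simulator does *not* emulate: EEG waveform
morphology (spikes, rhythms, artifacts), within-epoch nonstationarity of
Σ_S, volume conduction, or montage effects. Passing tests therefore certify
the statistical machinery — covariance weighting, sparse precision
recovery, ensemble selection frequencies, metric arithmetic — under the
model's own assumptions, not clinical performance on recorded EEG.

## Degenerate inputs and tie-breaks

* Epoch intervals shorter than 60 s contribute zero epochs (logged).
* ψ ranking ties break toward the lower edge index (stable and
  deterministic).
* Accuracy ties in cutoff selection break toward the smaller cutoff.
* Single-class inputs: ensemble fitting and AUC raise validation errors;
  SENS/FDR remain defined where their denominators exist.
* AUC with tied probabilities uses average ranks (equivalently, half credit
  for tied pairs).

## Known limitations

* The preictal horizon is global (30 min for every patient); per-patient
  horizons are out of scope.
* λ for the graphical lasso is a fixed tuning input; the package does not
  search it per epoch (by design — comparability of edge scales). An
  optional coarse BIC selection on the pooled covariance is available as
  `select_lambda_bic`.
* The evaluation protocol pools out-of-fold probabilities before choosing
  one global cutoff; per-fold cutoffs would give slightly different SENS /
  FDR trade-offs.
* EDF writing is fixture-grade (16-bit, one record per second) and not
  intended for clinical archival.
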