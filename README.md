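# preictal

Explainable, patient-specific seizure prediction from scalp EEG via dynamic
brain functional connectivity.

Epileptic seizures are preceded by a *preictal* state whose network
signature differs from the *interictal* baseline. This package implements a
two-stage statistical pipeline that detects that signature and says *which
connections carry it*:

1. **Connectivity estimation.** Each 60-second EEG epoch, reduced to one
   averaged value per electrode per second, is a matrix
   X ∈ ℝ^{p×q} assumed matrix-normal, X ~ 𝓜𝓝(M, Σ_T ⊗ Σ_S). The spatial
   precision matrix Ω = Σ_S⁻¹ is estimated sparsely from a
   Gaussian-kernel-weighted, time-varying covariance

       Σ̂(t) = Σ_i w_it x_i x_iᵀ / Σ_i w_it,   w_it = exp(−(|i−t|/h)²/2),
       h = q^{1/3},

   averaged over t = 1…q and fed to the graphical lasso

       Ω̂ = argmin_Ω  Tr(S̄Ω) − log det Ω + λ‖Ω‖₁,off .

   Edge strengths are partial correlations −ω̂_ij/√(ω̂_ii ω̂_jj); the upper
   triangle (d = p(p−1)/2 edges) becomes one row of the network predictor
   matrix **V**.

2. **Ensemble classification.** B class-stratified bootstrap resamples of
   the epochs each fit an L1-penalized logistic regression of the state
   label Z on **V**. Averaging the B predicted probabilities yields P̂_B;
   the per-edge selection frequency

       ψ_i = (1/B) Σ_b 𝟙(β̂_i^{(b)} ≠ 0)

   ranks edges by how consistently they are needed to separate the states —
   the method's explainability output, usable for connectome-biomarker
   screening.

Performance is reported as sensitivity (SENS), false discovery rate among
predicted-preictal epochs (FDR), and ROC AUC, with the probability cutoff
chosen to maximize accuracy.

The package reads EDF/EDF+ recordings (CHB-MIT-style 21-signal bipolar
montages at 256 Hz, referential 19-electrode montages at 500 Hz, or any
custom channel list) plus a CSV seizure-annotation table, applies the state
rules (30-min preictal window, seizure + 2 h postictal excluded, short-gap
seizures dropped), and also ships a matrix-normal simulator with planted
class-differential networks so the entire pipeline is testable without any
data download.

## Worked example

```python
import numpy as np
from preictal import SimulationConfig, simulate_epoch_set, cross_validate

# 60 preictal + 60 interictal epochs, 10 electrodes, 5 planted
# differential edges of partial correlation 0.4
cfg = SimulationConfig(p=10, q=60, n1=60, n2=60, n_diff=5, delta=0.4, seed=1)
epochs, truth = simulate_epoch_set(cfg)

metrics, psi = cross_validate(epochs, mode="network", k=5, B=50, seed=1)
print(f"AUC  {metrics.auc:.3f}   SENS {100*metrics.sens:.1f}%   "
      f"FDR {metrics.fdr:.3f}   cutoff {metrics.cutoff:.3f}")
print(psi.to_frame().head(5).to_string(index=False))
print("true differential edges:", sorted(truth.diff_edges))
```

prints

```
AUC  1.000   SENS 100.0%   FDR 0.000   cutoff 0.531
edge_name  psi
 ch2--ch6 1.00
 ch2--ch7 1.00
 ch2--ch9 1.00
 ch3--ch7 1.00
 ch8--ch9 0.98
true differential edges: [(2, 6), (2, 7), (2, 9), (3, 7), (8, 9)]
```

The out-of-fold AUC of 1.000 says the two planted network regimes are
perfectly separable from 60-second epochs at this effect size, and the five
top-ranked ψ edges are exactly the five edges that truly differ between the
classes — the selection frequencies certify *which* connections drive the
prediction, not just that prediction works.

The same analysis runs from the shell on real recordings:

```bash
preictal extract  --config patient.yaml     # EDF + annotations -> epochs
preictal evaluate --config patient.yaml     # -> metrics.json, edges.csv
```

or on simulated data via `preictal simulate`, `features`, `fit`,
`importance`. Every output embeds the effective config hash and seed, so
reruns are byte-identical.

## Estimator interface

Both stages are scikit-learn estimators and compose with sklearn tooling:

```python
from sklearn.pipeline import Pipeline
from preictal import DynamicConnectivity, BootstrapLassoLogistic

pipe = Pipeline([
    ("connectivity", DynamicConnectivity(lam=0.1)),
    ("classifier",  BootstrapLassoLogistic(B=100, random_state=0)),
])
pipe.fit(epoch_array, labels)          # epoch_array: n x p x q
proba = pipe.predict_proba(epoch_array)[:, 1]
psi = pipe["classifier"].selection_frequency_
```

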