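# g4coop

Quantitative tools for studying how RNA G-quadruplexes (rG4s) turn
HNRNPH-dependent alternative splicing into a molecular switch.

HNRNPH is a splicing factor whose three quasi-RNA-recognition motifs (qRRMs)
bind single-stranded G-runs.  A folded rG4 sequesters four G-runs; once it
unfolds, all four become available, so several qRRMs — from one protein that
"backfolds", or from two proteins — can bind cooperatively and lock the RNA
in the unfolded state.  Downstream, cooperative binding feeds a multi-step
splicing cascade that converts modest per-step cooperativity into strongly
switch-like exon inclusion.  This package implements the models and the
bespoke data analyses of that study so they can be run, tested and extended
on synthetic data with known ground truth:

- **`dose_response`** — constrained four-parameter logistic (LL.4) fits of
  ΔPSI vs relative HNRNPH level, pseudo-R², and the four-way cooperativity
  classification (cooperative iff n_H ≥ 2, crossed with enhanced/repressed;
  events with pseudo-R² < 0.75 excluded).  Also the model-free estimator
  `n_H = log 81 / log(EC90/EC10)` used throughout.
- **`equilibrium_binding`** — the statistical-mechanics model of HNRNPH
  binding to an unfolded rG4 with four G-runs: state enumeration (modes like
  2^22 = two proteins with two qRRM contacts each), partition function, bound
  fraction, transition concentration K, Hill coefficient, a reduced
  double-backfolding model, a folded-rG4 "helper" state, and free-energy
  inversions (g_bind from K_d; g_backfold from a target K).
- **`splicing_cascade`** — the three-level kinetic model
  (binding → exon definition → splicing decision), per-level and overall Hill
  coefficients, log-normal population sampling, and the product-of-
  coefficients amplification bound for chained Hill stages.
- **`clip_binding_sites`** — the iterative 5-nt binding-site caller operating
  on per-nucleotide iCLIP crosslink tracks plus significant crosslink
  positions.
- **`rtstop_rg4`** — RT-stop profiling analysis of a barcoded 200-nt
  construct library: 3-nt stop-peak calling, KCl-vs-NaCl negative-binomial
  differential testing, 2-of-4-barcode region classification, and
  rG4-propensity scores.
- **`splice_maps`** — splice-site meta-profiles of normalized crosslink
  signal, PSI-matched control sampling, sliding 10-nt Wilcoxon window tests
  (BH, FDR ≤ 0.01), and junction-count PSI helpers.
- **`synthetic_data`** — seeded generators for every input modality
  (titration tables, crosslink tracks, the 18+146+15+21-nt oligo library
  with Hamming-separated barcodes, condition-dependent RT-stall count
  matrices, in vitro binding titrations).

## Worked example

Reproduce the central model result — cooperative binding with Hill
coefficient ≈ 2 emerging from backfolding — and refit a simulated in vitro
titration:

```python
import numpy as np
from g4coop import EnergyParams, model_hill, transition_concentration
from g4coop.dose_response import fit_hill
from g4coop.synthetic_data import gen_invitro_binding

params = EnergyParams(g_rG4=23.0, g_bind=9.2, g_backfold=0.8)
K = transition_concentration(params)
print(f"K = {K:.3g} mol/l, model n_H = {model_hill(params):.2f}")

conc = np.logspace(np.log10(K) - 2.5, np.log10(K) + 2.5, 30)
tab = gen_invitro_binding(params, conc, noise_sd=0.01, seed=8)
n_fit, k_fit, _ = fit_hill(tab.concentration, tab.signal)
print(f"refit from noisy titration: n_H = {n_fit:.2f}")
```

```
K = 1.93e-05 mol/l, model n_H = 1.99
refit from noisy titration: n_H = 1.97
```

The transition concentration is the protein level at half-maximal RNA
binding; the Hill coefficient near 2 says two HNRNPH molecules bind
conjointly — binding of the first makes binding of the second easier —
exactly the cooperativity measured for rG4-forming RNAs in vitro.  With
backfolding forbidden (`max_qrrm=1`) the same model instead approaches
n_H = 4, and with the penalty removed (`g_backfold=0`) it stays at n_H ≤ 2
for all transition concentrations well below molar.

Chaining three Hill stages with coefficient 2 each shows the cascade
amplification:

```python
from g4coop import max_chain_hill
print(max_chain_hill(2, 2, 2))
```

```
{'achieved': 7.999942781994229, 'bound': 8.0,
 'log10_K2': 0.0002600051164627075, 'log10_K3': -15.999639129638672}
```

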