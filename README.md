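# vmstress

Stress classification from multichannel EEG+ECG recordings via
variational mode decomposition (VMD) and second-order-difference Poincaré
descriptors.

## The problem

Performance under a short mental-arithmetic task separates subjects into
non-stressed ("G", good count quality) and stressed ("B", bad)
performers. Their physiological recordings — 20 EEG channels and one ECG
lead, one baseline trial and one task trial per subject, stored as EDF —
differ in how much the amplitude of the underlying oscillatory rhythms
fluctuates. `vmstress` turns that difference into a classifier:

1. **VMD** decomposes each channel into `K` band-limited modes `u_k`
   with center frequencies `w_k`, solving

   `min_{u_k,w_k} Σ_k ‖ ∂_t [ (δ(t) + j/πt) * u_k(t) ] e^{-j w_k t} ‖²
   s.t. Σ_k u_k = f`

   with the frequency-domain ADMM scheme (Wiener-filter mode updates,
   spectral-centroid frequency updates, optional dual ascent).
2. **Poincaré plots** of each retained mode scatter successive first
   differences: `X(t) = x(t+1) − x(t)` vs `Y(t) = x(t+2) − x(t+1)`.
3. **Three descriptors** per plot: ellipse area `πab` (from the
   eigenvalues of the raw second-moment matrix), mean radial distance
   `m`, and the central tendency measure `CTM(r)` — the fraction of
   points inside radius `r`.
4. **Wilcoxon signed-rank screening** (two-sided, exact for ≤ 25
   informative pairs) after balancing classes by minority replication.
5. **MLP / SVM classification** per brain-region channel group (frontal,
   temporal, central, parietal, occipital, behind-ear, ECG, all) and
   mode group (1–4, 5–8, 1–8), under a stratified subject-level 70/10/20
   split or 10-fold cross validation, reporting sensitivity, specificity,
   accuracy, F1 and Cohen's kappa.

A synthetic generator produces two-class cohorts in the exact EDF+CSV
layout the reader consumes, with the class difference planted in
mode-wise amplitude variability, so the whole pipeline is testable
without any data download. See `docs/methods.md` for the model details
and design choices.

## Worked example

```python
import numpy as np
from vmstress import (SynthConfig, generate, run_experiment,
                      VMDConfig, SubsetSpec, ClassifierConfig, SplitConfig)

recs, labels = generate(SynthConfig(
    n_good=10, n_bad=10, fs=128.0,
    duration_baseline_s=12.0, duration_task_s=4.0,
    effect_size=3.0, seed=1))

res = run_experiment(
    recs, labels,
    vmd_cfg=VMDConfig(K=10, max_iter=200),
    subset=SubsetSpec(region="all", mode_group="m1_8"),
    clf=ClassifierConfig(kind="mlp", seed=1),
    split_cfg=SplitConfig(mode="kfold", k=10, seed=1))

for name, r in res.screen.results.items():
    print(f"{name}: p={r.p_value:.3g} retained={r.retained}")
print(f"accuracy={res.report.accuracy:.1f}%  kappa={res.report.kappa:.2f}")
```

Output:

```
area: p=1.23e-156 retained=True
m: p=5.31e-45 retained=True
ctm: p=3.59e-17 retained=True
accuracy=100.0%  kappa=1.00
```

All three descriptors separate the classes decisively (the signed-rank
p-values are far below 0.05), and pooled 10-fold predictions classify
every subject-trial correctly — stressed subjects' modes fluctuate more,
widening their Poincaré clouds. Re-running with `effect_size=0.0` gives
`accuracy=45.0%`: with no planted class difference the classifier falls
back to chance.

The same pipeline is scriptable from the shell:

```bash
vmstress simulate --n-good 10 --n-bad 10 --effect-size 2 --fs 128 \
    --duration-task 4 --duration-baseline 12 --seed 1 --out cohort/
vmstress features --data-dir cohort/ --k 10 --modes 1-8 --out features.csv
vmstress classify --features features.csv --region frontal --modes 1-8 \
    --clf mlp --split kfold --k 10 --seed 7 --out report.json
```

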