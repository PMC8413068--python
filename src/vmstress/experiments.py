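"""Canonical desk-scale experiments on synthetic cohorts.

These are the package's reference experiments: fixed, documented problem
sizes at which the full pipeline (VMD with K=10, modes 1-8 retained,
Poincaré descriptors, minority-replication balancing, Wilcoxon screen,
MLP, subject-level cross validation) runs on a single CPU in minutes.
The trial durations keep the emulated protocol's 3:1 baseline:task ratio.

Two configurations are defined:

* the *cohort* experiment — 10+10 subjects, the full 21-channel montage,
  12 s baseline / 4 s task at 128 Hz, 10-fold CV — used to demonstrate
  near-perfect separation at a strong effect size and chance-level
  accuracy at a null effect;
* the *dose-response* experiment — 6+6 subjects, a 5-channel montage,
  6 s / 2 s trials, 6-fold CV — small enough to sweep effect sizes over
  many seeds and check that accuracy rises monotonically with the
  class-difference magnitude.
"""

from __future__ import annotations

import numpy as np

from .classify import ClassifierConfig, SplitConfig, SubsetSpec
from .io import EEGMAT_MONTAGE
from .pipeline import run_experiment
from .synthetic import SynthConfig, generate
from .vmd import VMDConfig

#: Reduced montage for the dose-response sweep: one channel per major
#: region plus the ECG lead.
SWEEP_MONTAGE = ("EEG Fp1", "EEG F3", "EEG T3", "EEG O1", "ECG ECG")

VMD_CFG = VMDConfig(K=10, alpha=2000.0, tau=0.0, tol=1e-7, max_iter=200)

DEFAULT_EFFECT_GRID = (0.0, 0.5, 1.0, 2.0, 3.0)


def cohort_config(effect_size: float, seed: int) -> SynthConfig:
    return SynthConfig(
        n_good=10, n_bad=10,
        fs=128.0,
        duration_baseline_s=12.0, duration_task_s=4.0,
        channels=EEGMAT_MONTAGE,
        effect_size=effect_size,
        seed=seed,
    )


def sweep_config(effect_size: float, seed: int) -> SynthConfig:
    return SynthConfig(
        n_good=6, n_bad=6,
        fs=128.0,
        duration_baseline_s=6.0, duration_task_s=2.0,
        channels=SWEEP_MONTAGE,
        effect_size=effect_size,
        seed=seed,
    )


def run_cohort(effect_size: float, seed: int, k: int = 10):
    """Full pipeline on the cohort configuration; returns the PipelineResult."""
    recs, labels = generate(cohort_config(effect_size, seed))
    return run_experiment(
        recs, labels,
        vmd_cfg=VMD_CFG,
        subset=SubsetSpec(region="all", mode_group="m1_8"),
        clf=ClassifierConfig(kind="mlp", seed=seed),
        split_cfg=SplitConfig(mode="kfold", k=k, seed=seed),
        balance_seed=seed,
    )


def run_sweep_point(effect_size: float, seed: int, k: int = 6) -> float:
    """Pooled k-fold accuracy (percent) at one dose-response grid point."""
    recs, labels = generate(sweep_config(effect_size, seed))
    res = run_experiment(
        recs, labels,
        vmd_cfg=VMD_CFG,
        subset=SubsetSpec(region="all", mode_group="m1_8"),
        clf=ClassifierConfig(kind="mlp", seed=seed),
        split_cfg=SplitConfig(mode="kfold", k=k, seed=seed),
        balance_seed=seed,
    )
    return res.report.accuracy


def dose_response(
    seeds, effect_grid=DEFAULT_EFFECT_GRID, k: int = 6
) -> dict[float, float]:
    """Median pooled accuracy per effect size over the given seeds."""
    return {
        eff: float(np.median([run_sweep_point(eff, s, k=k) for s in seeds]))
        for eff in effect_grid
    }
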