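"""Feature-table assembly, class balancing and nonparametric screening.

The feature table has one row per (subject, trial, channel, mode) with the
three Poincaré descriptors (area, m, ctm) and the subject's class label —
the shape of the paper-and-pencil "channel x mode x 3 descriptors" feature
map.  Classes are balanced by whole-subject replication of the minority
class, and each descriptor column is screened with the two-sided Wilcoxon
signed-rank test at a configurable significance level (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .poincare import ctm as _ctm
from .poincare import ellipse_descriptor, make_plot, mean_distance

FEATURE_COLUMNS = ("area", "m", "ctm")

#: Modes retained downstream of a K=10 decomposition (1-based).
DEFAULT_MODES_KEPT = tuple(range(1, 9))


@dataclass
class ScreenResult:
    feature: str
    statistic: float
    p_value: float
    retained: bool
    untestable: bool = False
    note: str = ""


@dataclass
class ScreenReport:
    alpha: float
    results: dict[str, ScreenResult] = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return [f for f, r in self.results.items() if r.retained]


def build_feature_table(
    decompositions: dict,
    labels,
    modes_kept=DEFAULT_MODES_KEPT,
    r: float = 0.5,
) -> pd.DataFrame:
    """Assemble the descriptor table from per-channel decompositions.

    Parameters
    ----------
    decompositions
        ``{(subject_id, trial): {channel: VMDResult}}``.
    labels
        Iterable of SubjectLabel; every subject appearing in
        ``decompositions`` must be labelled.
    modes_kept
        1-based mode indices to retain (default 1..8).
    r
        CTM radius, recorded in ``DataFrame.attrs``.
    """
    label_of = {lab.subject_id: lab.quality for lab in labels}
    modes_kept = list(modes_kept)
    rows = []
    for (subject, trial), per_channel in decompositions.items():
        if subject not in label_of:
            raise ValueError(f"subject {subject!r} has no label")
        for channel, res in per_channel.items():
            if max(modes_kept) > res.modes.shape[0]:
                raise ValueError(
                    f"subject {subject!r} channel {channel!r}: decomposition has "
                    f"{res.modes.shape[0]} modes, need mode {max(modes_kept)}"
                )
            for mode in modes_kept:
                pp = make_plot(res.modes[mode - 1])
                desc = ellipse_descriptor(pp)
                rows.append(
                    {
                        "subject_id": subject,
                        "trial": trial,
                        "channel": channel,
                        "mode": mode,
                        "area": desc.area,
                        "m": mean_distance(pp),
                        "ctm": _ctm(pp, r),
                        "label": label_of[subject],
                    }
                )
    table = pd.DataFrame(rows).sort_values(
        ["subject_id", "trial", "channel", "mode"], kind="mergesort"
    )
    table = table.reset_index(drop=True)
    table.attrs["r"] = r
    table.attrs["modes_kept"] = modes_kept
    return table


def balance_by_replication(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Replicate minority-class subjects (whole subjects, channel-wise) to parity.

    Replicas get fresh synthetic subject ids (``<orig>_rep<i>``); original
    rows are left untouched.  Deterministic under ``seed``.
    """
    per_class = table.groupby("label")["subject_id"].unique()
    if len(per_class) < 2:
        raise ValueError("need both classes present to balance")
    counts = {lab: len(subs) for lab, subs in per_class.items()}
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    deficit = counts[majority] - counts[minority]
    if deficit == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    pool = np.sort(per_class[minority])
    chosen = pool[rng.integers(0, len(pool), size=deficit)]
    extra = []
    for i, src in enumerate(chosen):
        rep = table[table["subject_id"] == src].copy()
        rep["subject_id"] = f"{src}_rep{i}"
        extra.append(rep)
    out = pd.concat([table] + extra, ignore_index=True)
    out.attrs.update(table.attrs)
    return out


def _paired_samples(table: pd.DataFrame, feature: str):
    """Class-wise value vectors in deterministic sorted order, paired positionally."""
    key = ["subject_id", "trial", "channel", "mode"]
    g = table[table["label"] == "G"].sort_values(key, kind="mergesort")[feature]
    b = table[table["label"] == "B"].sort_values(key, kind="mergesort")[feature]
    return g.to_numpy(), b.to_numpy()


def wilcoxon_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    features=FEATURE_COLUMNS,
) -> ScreenReport:
    """Two-sided Wilcoxon signed-rank screen of each descriptor column.

    The two class samples are paired positionally after sorting by
    (subject, trial, channel, mode) — meaningful once classes are balanced
    to equal size.  Zero differences are dropped (Wilcoxon's original
    rule); the null is enumerated exactly for n <= 25 informative pairs and
    approximated normally with continuity correction beyond.  A feature
    with fewer than two nonzero differences is untestable and not retained.
    """
    report = ScreenReport(alpha=alpha)
    for feat in features:
        g, b = _paired_samples(table, feat)
        if g.size != b.size:
            raise ValueError(
                f"class samples for {feat!r} differ in length ({g.size} vs {b.size}); "
                "balance the table first"
            )
        diff = g - b
        nonzero = diff[diff != 0]
        if nonzero.size < 2:
            report.results[feat] = ScreenResult(
                feature=feat,
                statistic=float("nan"),
                p_value=float("nan"),
                retained=False,
                untestable=True,
                note="fewer than 2 nonzero paired differences",
            )
            warnings.warn(
                f"feature {feat!r} untestable: fewer than 2 nonzero differences",
                stacklevel=2,
            )
            continue
        method = "exact" if nonzero.size <= 25 else "approx"
        res = stats.wilcoxon(
            nonzero, alternative="two-sided", method=method, correction=True
        )
        report.results[feat] = ScreenResult(
            feature=feat,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            retained=bool(res.pvalue < alpha),
        )
    return report


def to_table1_schema(table: pd.DataFrame) -> pd.DataFrame:
    """Serialize in the published feature-map layout:
    Subject, Trial, Channel, Mode, Area, m, ctm, Target (Target: G=1, B=0)."""
    out = table.rename(
        columns={
            "subject_id": "Subject",
            "trial": "Trial",
            "channel": "Channel",
            "mode": "Mode",
            "area": "Area",
        }
    )[["Subject", "Trial", "Channel", "Mode", "Area", "m", "ctm"]].copy()
    out["Target"] = (table["label"] == "G").astype(int)
    return out
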