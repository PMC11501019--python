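"""Shared statistical kernel and behavioral/physiological analyses.

Closed-form Student t tests (paired and two-sample), 95% confidence
intervals, Cohen's d, plus the two behavioral checks of the study
design: the valence-rating separation between tertile classes and the
breathing (inhalation area-under-curve) comparison between classes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float  # t
    df: float
    p: float  # two-tailed
    ci_low: float  # 95% CI of the mean difference
    ci_high: float
    effect_size: float  # Cohen's d (paired: mean diff / SD of diffs)
    mean_diff: float
    kind: str  # "paired" | "two-sample"
    formula: str  # provenance string for serialized reports

    def __post_init__(self):
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not (self.ci_low <= self.mean_diff <= self.ci_high):
            raise ValueError("CI must contain the point estimate")

    def to_dict(self) -> dict:
        return asdict(self)


def ttest(x, y, paired: bool = False, ci: float = 0.95) -> TestResult:
    """Two-tailed Student t test with exact df, CI, and Cohen's d.

    Classical (non-Welch) pooled-variance form for the two-sample case.
    Zero variance of the differences (paired) or of both samples
    (two-sample) is an error: the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal lengths")
        d = x - y
        n = len(d)
        if n < 2:
            raise ValueError("need n >= 2")
        md = d.mean()
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance of paired differences")
        se = sd / np.sqrt(n)
        df = n - 1
        t = md / se
        eff = md / sd
        kind = "paired"
        formula = "t = mean(d) / (sd(d)/sqrt(n)); d_cohen = mean(d)/sd(d)"
    else:
        nx, ny = len(x), len(y)
        if nx < 2 or ny < 2:
            raise ValueError("need n >= 2 per sample")
        md = x.mean() - y.mean()
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        if sp2 == 0:
            raise ValueError("zero pooled variance")
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
        t = md / se
        eff = md / np.sqrt(sp2)
        kind = "two-sample"
        formula = (
            "t = (mean(x)-mean(y)) / sqrt(sp2*(1/nx+1/ny)); "
            "d_cohen = (mean(x)-mean(y))/sp"
        )
    p = 2 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.5 + ci / 2, df)
    return TestResult(
        statistic=float(t), df=float(df), p=float(p),
        ci_low=float(md - tcrit * se), ci_high=float(md + tcrit * se),
        effect_size=float(eff), mean_diff=float(md),
        kind=kind, formula=formula,
    )


def paired_t_map(diffs: np.ndarray) -> tuple:
    """Vectorized paired t over the last-axis-free layout (n_subjects, ...).

    Returns (t, two-tailed p, Cohen's d) arrays over the trailing axes.
    Cells with zero difference variance get t = 0, p = 1, d = 0.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    md = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero = sd == 0
    sd_safe = np.where(zero, 1.0, sd)
    t = md / (sd_safe / np.sqrt(n))
    t = np.where(zero, 0.0, t)
    p = 2 * sps.t.sf(np.abs(t), n - 1)
    d = np.where(zero, 0.0, md / sd_safe)
    return t, p, d


def rating_separation(ratings: pd.DataFrame, class_labels: pd.DataFrame) -> TestResult:
    """Paired t of per-participant pleasant vs unpleasant mean ratings.

    ``class_labels`` must carry participant_id, trial_id and a ``class``
    column with at least the two extreme classes.
    """
    merged = ratings.merge(class_labels, on=["participant_id", "trial_id"])
    means = (
        merged[merged["class"].isin(["unpleasant", "pleasant"])]
        .groupby(["participant_id", "class"])["valence"]
        .mean()
        .unstack("class")
    )
    if means.shape[0] < 2:
        raise ValueError("need >= 2 participants")
    if means.isna().any().any():
        raise ValueError("every participant needs both extreme classes")
    return ttest(
        means["pleasant"].to_numpy(), means["unpleasant"].to_numpy(), paired=True
    )


def inhalation_auc(trace: np.ndarray, times: np.ndarray, rel_floor: float = 0.05):
    """Trapezoid area under the inhalation segment of one trial's trace.

    The segment runs from sniff onset to return-to-baseline, both defined
    as the trace crossing ``rel_floor`` of its peak (thermistor units are
    arbitrary, so the floor is relative).
    """
    peak = trace.max()
    if peak <= 0:
        return 0.0
    above = trace >= rel_floor * peak
    if not above.any():
        return 0.0
    i0, i1 = np.flatnonzero(above)[[0, -1]]
    return float(np.trapezoid(trace[i0:i1 + 1], times[i0:i1 + 1]))


def breathing_auc_compare(
    breaths: dict, class_labels: pd.DataFrame
) -> TestResult:
    """Paired t of per-participant class-mean inhalation AUC.

    ``breaths`` maps participant_id -> BreathTrace; labels assign each
    trial to a valence class (middle tertile ignored).
    """
    if not breaths:
        raise ValueError("no breathing traces supplied")
    rows = []
    for pid, bt in breaths.items():
        lbl = class_labels[class_labels["participant_id"] == pid]
        if lbl.empty:
            raise ValueError(f"no class labels for participant {pid}")
        lbl = lbl.sort_values("trial_id")
        if len(lbl) != bt.data.shape[0]:
            raise ValueError(f"label/trace count mismatch for {pid}")
        times = bt.times
        aucs = np.array([inhalation_auc(tr, times) for tr in bt.data])
        for cls in ("unpleasant", "pleasant"):
            sel = (lbl["class"] == cls).to_numpy()
            if not sel.any():
                raise ValueError(f"{pid}: no {cls} trials")
            rows.append((pid, cls, aucs[sel].mean()))
    tab = pd.DataFrame(rows, columns=["participant_id", "class", "auc"])
    wide = tab.pivot(index="participant_id", columns="class", values="auc")
    return ttest(
        wide["unpleasant"].to_numpy(), wide["pleasant"].to_numpy(), paired=True
    )


def monte_carlo_ci_range(p: float, n_perm: int) -> float:
    """Width of the 95% normal-approximation CI of a Monte Carlo p value."""
    half = 1.96 * np.sqrt(p * (1 - p) / n_perm)
    return float(2 * half)
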