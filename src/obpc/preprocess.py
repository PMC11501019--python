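"""Epoch-domain cleaning and trial labeling.

Line-noise removal by DFT component subtraction, artifact rejection on
z-scored Hilbert amplitudes (|z| > 7 drops the trial), exclusion of
participants who lose more than half of a valence category, correction
of the 200 ms olfactometer delivery delay, and per-participant tertile
class assignment from the subjective ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .containers import EpochSet

CLASSES_VALENCE = ("unpleasant", "middle", "pleasant")
CLASSES_INTENSITY = ("low", "middle", "high")


# ----------------------------------------------------------------------
# line-noise filter
# ----------------------------------------------------------------------

def dft_notch(epochs: EpochSet, line_freq: float = 50.0) -> EpochSet:
    """Subtract the fitted discrete Fourier component at ``line_freq``.

    Per trial and channel, a sine/cosine pair at the line frequency is
    fitted by least squares over the whole epoch and subtracted; all
    other components are untouched.  This is a linear projection, hence
    idempotent.
    """
    if line_freq >= epochs.fs / 2:
        raise ValueError("line frequency must be below Nyquist")
    n = epochs.n_samples
    t = np.arange(n) / epochs.fs
    basis = np.column_stack(
        [np.cos(2 * np.pi * line_freq * t), np.sin(2 * np.pi * line_freq * t)]
    )
    # projection matrix applied from the right: x_clean = x - x B (B'B)^-1 B'
    proj = basis @ np.linalg.solve(basis.T @ basis, basis.T)
    clean = epochs.data - epochs.data @ proj.T
    return replace(epochs, data=clean)


# ----------------------------------------------------------------------
# artifact rejection + participant exclusion
# ----------------------------------------------------------------------

@dataclass
class RejectionReport:
    """Per-trial artifact scores and the participant-level exclusion flag."""

    participant_id: str
    max_abs_z: np.ndarray  # per trial, max |z| over channels and samples
    kept: np.ndarray  # bool per trial
    z_thresh: float
    class_counts_before: dict = None  # class -> count (filled when labeled)
    class_counts_after: dict = None
    excluded: bool = False


def reject_artifacts(epochs: EpochSet, z_thresh: float = 7.0):
    """Drop trials whose Hilbert amplitude z-score exceeds the threshold.

    The analytic amplitude is computed per trial and channel; z-scoring
    pools all samples of all trials of that channel, so a large muscle
    burst in one trial stands out against the participant's own
    distribution.  A trial is dropped if max |z| > ``z_thresh`` on any
    channel.
    """
    if epochs.n_trials < 2:
        raise ValueError("need >= 2 trials for artifact rejection")
    amp = np.abs(hilbert(epochs.data, axis=-1))
    mu = amp.mean(axis=(0, 2), keepdims=True)
    sd = amp.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    z = (amp - mu) / sd
    max_abs_z = np.abs(z).max(axis=(1, 2))
    kept = max_abs_z <= z_thresh
    if not kept.any():
        raise ValueError("all trials rejected")
    report = RejectionReport(
        participant_id=epochs.participant_id,
        max_abs_z=max_abs_z,
        kept=kept,
        z_thresh=float(z_thresh),
    )
    return epochs.select_trials(np.flatnonzero(kept)), report


def count_classes(report: RejectionReport, class_labels: pd.DataFrame) -> None:
    """Fill per-class retained-trial counts into a rejection report.

    ``class_labels`` must be the participant's pre-rejection labels in
    trial order (one row per original trial).
    """
    cls = class_labels.sort_values("trial_id")["class"].to_numpy()
    if len(cls) != len(report.kept):
        raise ValueError("label/trial count mismatch")
    before, after = {}, {}
    for c in np.unique(cls):
        sel = cls == c
        before[c] = int(sel.sum())
        after[c] = int((sel & report.kept).sum())
    report.class_counts_before = before
    report.class_counts_after = after
    # excluded iff more than half eliminated in one or more categories
    report.excluded = any(
        before[c] - after[c] > before[c] / 2 for c in before
    )


def exclude_participants(reports: dict) -> list:
    """Participants kept by the more-than-half elimination rule.

    ``reports`` maps participant_id -> RejectionReport (with class counts
    filled).  A participant is kept iff no class lost more than half of
    its pre-rejection trials; exactly half lost is still kept.
    """
    kept = []
    for pid, rep in reports.items():
        if rep.class_counts_before is None:
            raise ValueError(f"{pid}: class counts not filled")
        if not rep.excluded:
            kept.append(pid)
    return kept


# ----------------------------------------------------------------------
# class assignment
# ----------------------------------------------------------------------

def assign_classes(ratings: pd.DataFrame, basis: str = "valence") -> pd.DataFrame:
    """Per-participant tertile split of trials by rating.

    Trials are ranked by the chosen rating (stable sort: ties broken by
    trial order); the bottom floor(n/3) form the low extreme class, the
    top floor(n/3) the high extreme, the remainder the middle.  Returns
    a frame with participant_id, trial_id, class, basis.
    """
    if basis == "valence":
        lo, mid, hi = CLASSES_VALENCE
    elif basis == "intensity":
        lo, mid, hi = CLASSES_INTENSITY
    else:
        raise ValueError("basis must be 'valence' or 'intensity'")
    out = []
    for pid, sub in ratings.groupby("participant_id", sort=True):
        sub = sub.sort_values("trial_id")
        vals = sub[basis].to_numpy(dtype=float)
        n = len(vals)
        if n < 3:
            raise ValueError(f"{pid}: need >= 3 trials")
        if np.ptp(vals) == 0:
            raise ValueError(f"{pid}: all {basis} ratings identical")
        k = n // 3
        order = np.argsort(vals, kind="stable")
        cls = np.array([mid] * n, dtype=object)
        cls[order[:k]] = lo
        cls[order[n - k:]] = hi
        out.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "trial_id": sub["trial_id"].to_numpy(),
                    "class": cls,
                    "basis": basis,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


# ----------------------------------------------------------------------
# onset correction
# ----------------------------------------------------------------------

def correct_onset(epochs: EpochSet, delay: float = 0.200) -> EpochSet:
    """Shift the time axis so t = 0 is odor arrival at the nose.

    The olfactometer reaches 50% odor concentration ~200 ms after
    trigger; samples are unchanged, only the stored t0 moves earlier by
    the delay.  Applying the correction twice is an error.
    """
    if delay < 0:
        raise ValueError("delay must be >= 0")
    if delay >= epochs.n_samples / epochs.fs:
        raise ValueError("delay exceeds the epoch length")
    if delay > 0 and epochs.onset_corrected:
        raise ValueError("onset delay already corrected for this EpochSet")
    if delay == 0:
        return epochs
    return replace(epochs, t0=epochs.t0 - delay, onset_corrected=True)
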