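"""Searchlight SVM decoding of odor valence from coherence spectrograms.

At every point of the time-frequency grid, the 11 x 11 neighborhood of
the participant- and class-averaged OB-PC coherence map (121 values,
fewer at edges) forms the feature vector; a linear SVM (C = 1, features
standardized by training-fold statistics) is evaluated with
leave-one-participant-out cross-validation (each participant
contributes one unpleasant-class and one pleasant-class sample).
Significance is a Monte Carlo permutation test that swaps the two class
samples within each participant with probability 1/2; clusters of
significant points (4-connectivity) and region-of-interest summaries
(accuracy distributions, confusion matrices) follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from ._svm import _solve_dual, fold_grams, loo_fold_accuracies
from .containers import PAIRS
from .spectral import CoherenceMap, TFGrid, coherence, hemisphere_average, multitaper_tfr

CLASS_ORDER = ("unpleasant", "pleasant")


# ----------------------------------------------------------------------
# per-participant class coherence maps
# ----------------------------------------------------------------------

def class_coherence_maps(
    epochs_by_pid: dict,
    class_labels,
    grid: TFGrid | None = None,
    classes: tuple = CLASS_ORDER,
    basis_column: str = "class",
    min_trials: int = 2,
    n_tapers: int = 2,
) -> dict:
    """Hemisphere-averaged coherence per participant and extreme class.

    ``class_labels`` is the labeling frame from
    :func:`obpc.preprocess.assign_classes` (middle tertile is simply
    never selected).  Participants with fewer than ``min_trials`` trials
    in either class are skipped with a warning.
    """
    grid = grid or TFGrid()
    out = {}
    for pid, ep in epochs_by_pid.items():
        lbl = class_labels[class_labels["participant_id"] == pid].sort_values(
            "trial_id"
        )
        if len(lbl) != ep.n_trials:
            raise ValueError(f"{pid}: label/trial count mismatch")
        cls = lbl[basis_column].to_numpy()
        idx = {c: np.flatnonzero(cls == c) for c in classes}
        if any(len(v) < min_trials for v in idx.values()):
            warnings.warn(f"participant {pid} below class trial floor; skipped")
            continue
        tfr = multitaper_tfr(ep, grid, n_tapers=n_tapers)
        maps = {}
        for c in classes:
            per_hemi = [
                coherence(tfr, PAIRS[h], idx[c], participant_id=pid, condition=c)
                for h in ("L", "R")
            ]
            maps[c] = hemisphere_average(per_hemi[0], per_hemi[1])
        out[pid] = maps
    return out


# ----------------------------------------------------------------------
# searchlight features
# ----------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Searchlight feature vectors at every valid grid center.

    ``features[k]`` is the (2 * n_participants, n_valid_neighbors) matrix
    for the k-th valid center; rows are ordered (participant, class)
    with classes in :data:`CLASS_ORDER`.
    """

    grid: TFGrid
    participants: list
    center_idx: np.ndarray  # (n_centers, 2) int (fi, ti)
    features: list
    valid_centers: np.ndarray  # bool (nf, nt)
    half_width: int


def build_features(
    maps: dict,
    grid: TFGrid | None = None,
    half_width: int = 5,
    min_neighbors: int = 10,
    neighbor_rule: str = "valid_bins",
    classes: tuple = CLASS_ORDER,
) -> FeatureTable:
    """Flatten 11 x 11 searchlight neighborhoods into feature vectors.

    ``maps``: participant -> {class -> CoherenceMap} (all on one grid).
    Centers are invalidated when the neighborhood holds fewer than
    ``min_neighbors`` valid bins (``neighbor_rule="valid_bins"``), or --
    alternative reading -- fewer than ``min_neighbors`` valid bins beside
    the center itself (``"valid_adjacent"``).
    """
    if not maps:
        raise ValueError("no participant maps")
    participants = sorted(maps)
    first = maps[participants[0]][classes[0]]
    grid = grid or first.grid
    nf, nt = grid.shape
    stack = np.empty((len(participants), 2, nf, nt))
    for pi, pid in enumerate(participants):
        for ci, c in enumerate(classes):
            cm = maps[pid][c]
            if not cm.grid.matches(grid):
                raise ValueError("coherence maps on different grids")
            stack[pi, ci] = cm.C
    cell_valid = np.isfinite(stack).all(axis=(0, 1))

    hw = half_width
    center_list = []
    feats = []
    valid_centers = np.zeros((nf, nt), dtype=bool)
    for fi in range(nf):
        f0, f1 = max(0, fi - hw), min(nf, fi + hw + 1)
        for ti in range(nt):
            if not cell_valid[fi, ti]:
                continue
            t0, t1 = max(0, ti - hw), min(nt, ti + hw + 1)
            nb = cell_valid[f0:f1, t0:t1]
            count = int(nb.sum())
            if neighbor_rule == "valid_adjacent":
                count -= 1  # exclude the center bin itself
            if count < min_neighbors:
                continue
            block = stack[:, :, f0:f1, t0:t1]
            X = block[:, :, nb].reshape(len(participants) * 2, -1)
            center_list.append((fi, ti))
            feats.append(np.ascontiguousarray(X))
            valid_centers[fi, ti] = True
    return FeatureTable(
        grid=grid,
        participants=participants,
        center_idx=np.array(center_list, dtype=int).reshape(-1, 2),
        features=feats,
        valid_centers=valid_centers,
        half_width=hw,
    )


# ----------------------------------------------------------------------
# leave-one-participant-out decoding
# ----------------------------------------------------------------------

@dataclass
class AccuracyMap:
    """Group-mean LOO accuracy A(f,t) with per-participant resolution."""

    A: np.ndarray  # (nf, nt), NaN at invalid centers
    per_participant: np.ndarray  # (P, nf, nt)
    predictions: np.ndarray  # (nf, nt, P, 2) int8 predicted class, -1 invalid
    grid: TFGrid
    participants: list
    valid: np.ndarray


@njit(cache=True)
def _loo_with_predictions(Gfolds, C, tol, max_passes):
    """Observed-label LOO: per-participant accuracy and predicted classes."""
    P = Gfolds.shape[0]
    n = 2 * P
    y = np.empty(n)
    for k in range(P):
        y[2 * k] = 1.0
        y[2 * k + 1] = -1.0
    acc = np.empty(P)
    pred = np.empty((P, 2), dtype=np.int8)
    train_idx = np.empty(n - 2, dtype=np.int64)
    f = np.empty(n)
    for i in range(P):
        t = 0
        for j in range(n):
            if j != 2 * i and j != 2 * i + 1:
                train_idx[t] = j
                t += 1
        _solve_dual(Gfolds[i], y, train_idx, C, tol, max_passes, f)
        correct = 0
        for ci in range(2):
            j = 2 * i + ci
            cls = 0 if f[j] > 0.0 else 1  # tie -> first class in CLASS_ORDER
            pred[i, ci] = cls
            if cls == ci:
                correct += 1
        acc[i] = correct / 2.0
    return acc, pred


def loo_decode(
    ft: FeatureTable,
    C: float = 1.0,
    tol: float = 1e-4,
    max_passes: int = 200,
) -> AccuracyMap:
    """Linear-SVM leave-one-participant-out accuracy at every center."""
    P = len(ft.participants)
    if P < 3:
        raise ValueError("need >= 3 participants")
    nf, nt = ft.grid.shape
    A = np.full((nf, nt), np.nan)
    per = np.full((P, nf, nt), np.nan)
    preds = np.full((nf, nt, P, 2), -1, dtype=np.int8)
    for k, (fi, ti) in enumerate(ft.center_idx):
        G = fold_grams(ft.features[k])
        acc, pred = _loo_with_predictions(G, C, tol, max_passes)
        A[fi, ti] = acc.mean()
        per[:, fi, ti] = acc
        preds[fi, ti] = pred
    return AccuracyMap(
        A=A, per_participant=per, predictions=preds,
        grid=ft.grid, participants=ft.participants, valid=ft.valid_centers,
    )


# ----------------------------------------------------------------------
# permutation test
# ----------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Monte Carlo permutation p-values per grid point.

    p = (1 + #{A_perm >= A_obs}) / (1 + n_perm) at fully-sampled points;
    sequentially stopped points (Besag-Clifford) report p = h / n_done,
    which is valid and conservative for thresholding at the requested
    alpha.  ``ci_range`` is the width of the 95% normal-approximation
    Monte Carlo CI of p.
    """

    p: np.ndarray
    n_perm: int
    n_used: np.ndarray
    observed: np.ndarray
    ci_range: np.ndarray
    alpha: float | None


@njit(cache=True)
def _perm_exceed(Gfolds, flips, obs, c_stop, C, tol, max_passes):
    """Count permuted mean accuracies >= observed; early-stop at c_stop."""
    n_perm = flips.shape[0]
    c = 0
    done = 0
    for r in range(n_perm):
        acc = loo_fold_accuracies(Gfolds, flips[r], C, tol, max_passes)
        if acc.mean() >= obs - 1e-12:
            c += 1
        done = r + 1
        if c_stop > 0 and c >= c_stop:
            break
    return c, done


def permutation_test(
    ft: FeatureTable,
    observed: AccuracyMap,
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
    sequential_alpha: float | None = None,
    C: float = 1.0,
    tol: float = 1e-4,
    max_passes: int = 200,
    region_mask: np.ndarray | None = None,
) -> PermutationResult:
    """Within-participant class-swap permutation test of the accuracy map.

    Each permutation independently swaps the two class samples of each
    participant with probability 1/2 and recomputes the LOO accuracy.
    With ``sequential_alpha`` set, sampling at a grid point stops as soon
    as enough exceedances have accrued to rule out p < alpha (the
    significance decision is then exactly that of the full run).
    ``region_mask`` restricts the test to an a-priori (f, t) region;
    points outside keep p = NaN.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is very low for a Monte Carlo test")
    rng = rng or np.random.default_rng()
    P = len(ft.participants)
    flips = (rng.random((n_perm, P)) < 0.5).astype(np.int8)
    if sequential_alpha is not None:
        c_stop = int(np.ceil(sequential_alpha * (1 + n_perm))) - 1
        c_stop = max(c_stop, 1)
    else:
        c_stop = 0
    nf, nt = ft.grid.shape
    p = np.full((nf, nt), np.nan)
    n_used = np.zeros((nf, nt), dtype=int)
    ci = np.full((nf, nt), np.nan)
    for k, (fi, ti) in enumerate(ft.center_idx):
        if region_mask is not None and not region_mask[fi, ti]:
            continue
        G = fold_grams(ft.features[k])
        obs = observed.A[fi, ti]
        c, done = _perm_exceed(G, flips, obs, c_stop, C, tol, max_passes)
        if done == n_perm and (c_stop == 0 or c < c_stop):
            pv = (1 + c) / (1 + n_perm)
        else:
            pv = c / done  # Besag-Clifford sequential estimate, >= alpha
        p[fi, ti] = pv
        n_used[fi, ti] = done
        ci[fi, ti] = 2 * 1.96 * np.sqrt(pv * (1 - pv) / done)
    return PermutationResult(
        p=p, n_perm=n_perm, n_used=n_used, observed=observed.A,
        ci_range=ci, alpha=sequential_alpha,
    )


# ----------------------------------------------------------------------
# clusters
# ----------------------------------------------------------------------

@dataclass
class Cluster:
    members: np.ndarray  # (k, 2) grid indices
    f_range: tuple
    t_range: tuple
    peak_accuracy: float
    peak_f: float
    peak_t: float


def find_clusters(
    p_map: np.ndarray,
    grid: TFGrid,
    alpha: float = 0.01,
    accuracy: np.ndarray | None = None,
) -> list:
    """4-connected components of significant (p < alpha) grid points."""
    sig = np.isfinite(p_map) & (p_map < alpha)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labeled, n = ndimage.label(sig, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        members = np.argwhere(labeled == lab)
        fi, ti = members[:, 0], members[:, 1]
        if accuracy is not None:
            accs = accuracy[fi, ti]
            k = int(np.nanargmax(accs))
            peak_acc = float(accs[k])
        else:
            k = 0
            peak_acc = float("nan")
        clusters.append(
            Cluster(
                members=members,
                f_range=(float(grid.freqs[fi.min()]), float(grid.freqs[fi.max()])),
                t_range=(float(grid.times[ti.min()]), float(grid.times[ti.max()])),
                peak_accuracy=peak_acc,
                peak_f=float(grid.freqs[fi[k]]),
                peak_t=float(grid.times[ti[k]]),
            )
        )
    return clusters


def cluster_mask(clusters: list, shape: tuple) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for cl in clusters:
        mask[cl.members[:, 0], cl.members[:, 1]] = True
    return mask


# ----------------------------------------------------------------------
# ROI summaries
# ----------------------------------------------------------------------

@dataclass
class RoiWindow:
    """Named rectangular region of interest on the (f, t) grid."""

    name: str
    f_range: tuple  # Hz, inclusive
    t_range: tuple  # s, inclusive


DEFAULT_ROIS = (
    RoiWindow("early_gamma", (50.0, 100.0), (0.05, 0.25)),
    RoiWindow("mid_beta", (10.0, 20.0), (0.50, 0.70)),
    RoiWindow("late_beta", (10.0, 20.0), (0.75, 0.95)),
)


def roi_summary(acc: AccuracyMap, roi: RoiWindow) -> dict:
    """Per-participant mean accuracy and the confusion matrix in one ROI.

    Confusion rows (true class) are aggregated over all valid ROI points
    and LOO folds, then normalized to sum to 1.
    """
    fsel = (acc.grid.freqs >= roi.f_range[0]) & (acc.grid.freqs <= roi.f_range[1])
    tsel = (acc.grid.times >= roi.t_range[0]) & (acc.grid.times <= roi.t_range[1])
    box = np.ix_(fsel, tsel)
    valid = acc.valid[box]
    if not valid.any():
        raise ValueError(f"ROI {roi.name} contains no valid grid points")
    per = acc.per_participant[:, box[0], box[1]][:, valid]
    participant_means = np.nanmean(per, axis=1)
    preds = acc.predictions[box][valid]  # (n_points, P, 2)
    confusion = np.zeros((2, 2))
    for true_cls in range(2):
        pr = preds[:, :, true_cls].ravel()
        pr = pr[pr >= 0]
        for pred_cls in range(2):
            confusion[true_cls, pred_cls] = np.mean(pr == pred_cls)
    return {
        "roi": roi,
        "participant_accuracy": participant_means,
        "mean_accuracy": float(participant_means.mean()),
        "confusion": confusion,
        "n_points": int(valid.sum()),
    }


# ----------------------------------------------------------------------
# overlap / controls / regression
# ----------------------------------------------------------------------

def overlap_report(mask_a: np.ndarray, mask_b: np.ndarray) -> dict:
    """Count and Jaccard index of jointly significant grid points."""
    inter = int(np.sum(mask_a & mask_b))
    union = int(np.sum(mask_a | mask_b))
    return {
        "n_overlap": inter,
        "n_a": int(mask_a.sum()),
        "n_b": int(mask_b.sum()),
        "jaccard": inter / union if union else 1.0,
    }


def decode_pipeline(
    maps: dict,
    grid: TFGrid | None = None,
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.01,
    sequential: bool = False,
    half_width: int = 5,
    min_neighbors: int = 10,
    classes: tuple = CLASS_ORDER,
    region_mask: np.ndarray | None = None,
) -> dict:
    """Features -> LOO accuracy -> permutation p -> clusters, in one call."""
    ft = build_features(maps, grid, half_width=half_width,
                        min_neighbors=min_neighbors, classes=classes)
    acc = loo_decode(ft)
    perm = permutation_test(
        ft, acc, n_perm=n_perm, rng=rng,
        sequential_alpha=alpha if sequential else None,
        region_mask=region_mask,
    )
    clusters = find_clusters(perm.p, ft.grid, alpha=alpha, accuracy=acc.A)
    return {
        "features": ft,
        "accuracy": acc,
        "permutation": perm,
        "clusters": clusters,
        "mask": cluster_mask(clusters, ft.grid.shape),
    }


def intensity_control(
    epochs_by_pid: dict,
    ratings,
    valence_mask: np.ndarray,
    grid: TFGrid | None = None,
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.01,
    sequential: bool = False,
) -> dict:
    """Re-run the decoding with intensity-tertile labels; report overlap.

    Returns the intensity pipeline results plus the count/Jaccard overlap
    of its significant mask with the supplied valence mask.
    """
    from .preprocess import assign_classes

    labels = assign_classes(ratings, basis="intensity")
    maps = class_coherence_maps(
        epochs_by_pid, labels, grid, classes=("low", "high")
    )
    res = decode_pipeline(
        maps, grid, n_perm=n_perm, rng=rng, alpha=alpha,
        sequential=sequential, classes=("low", "high")
    )
    res["overlap"] = overlap_report(valence_mask, res["mask"])
    return res


def accuracy_power_regression(
    roi_accuracy: np.ndarray, power_by_node: dict
) -> dict:
    """OLS of per-participant ROI accuracy on per-participant mean power.

    Returns per node: slope, two-tailed t, p, intercept.
    """
    import statsmodels.api as sm

    y = np.asarray(roi_accuracy, dtype=float)
    if len(y) < 3:
        raise ValueError("need >= 3 participants")
    out = {}
    for node, x in power_by_node.items():
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"zero-variance power regressor for {node}")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        out[node] = {
            "slope": float(model.params[1]),
            "intercept": float(model.params[0]),
            "t": float(model.tvalues[1]),
            "p": float(model.pvalues[1]),
        }
    return out
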