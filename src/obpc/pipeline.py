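"""End-to-end orchestration: simulate -> preprocess -> decode -> granger -> report.

A run directory receives every stage's artifacts plus a manifest
(parameters, seeds, package version, input hashes).  Randomness is
controlled by a single master seed fanned out to the stages with
``numpy.random.SeedSequence.spawn``, so reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .containers import save_ratings
from .decoding import (
    DEFAULT_ROIS,
    class_coherence_maps,
    decode_pipeline,
    roi_summary,
)
from .granger import group_contrast, per_condition_gc
from .preprocess import (
    assign_classes,
    correct_onset,
    count_classes,
    dft_notch,
    exclude_participants,
    reject_artifacts,
)
from .simulate import SimDesign, generate_breathing, generate_epochs, generate_ratings
from .spectral import TFGrid
from .stats import breathing_auc_compare, rating_separation

STAGES = ("simulate", "preprocess", "coherence", "decode", "granger", "report")


def stage_rngs(master_seed: int) -> dict:
    """One independent Generator per pipeline stage from the master seed."""
    seqs = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(STAGES, seqs)}


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def _grid(config: RunConfig) -> TFGrid:
    return TFGrid(
        freqs=np.arange(config.fmin, config.fmax + config.f_step / 2, config.f_step),
        times=np.arange(config.t_start, config.t_stop + config.t_step / 2,
                        config.t_step),
    )


def run(config: RunConfig, out_dir, design: SimDesign | None = None) -> dict:
    """Execute the full pipeline into ``out_dir``; returns the results dict.

    ``design`` overrides the synthetic design (defaults derive from the
    config's participant/trial counts).  Any stage failure aborts with
    the stage name in the exception message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = stage_rngs(config.seed)
    results = {}
    stage = "simulate"
    try:
        design = design or SimDesign(
            n_participants=config.n_participants,
            n_trials=config.n_trials,
            seed=config.seed,
        )
        ratings = generate_ratings(design, rngs["simulate"])
        epochs = generate_epochs(design, ratings, rngs["simulate"])
        breaths = generate_breathing(design, ratings, rngs["simulate"])
        save_ratings(ratings, out / "ratings.csv")

        stage = "preprocess"
        labels = assign_classes(ratings, basis="valence")
        labels.to_csv(out / "class_labels.csv", index=False)
        clean = {}
        reports = {}
        for pid, ep in epochs.items():
            ep = dft_notch(ep, config.line_freq)
            ep, rep = reject_artifacts(ep, config.z_thresh)
            count_classes(rep, labels[labels["participant_id"] == pid])
            ep = correct_onset(ep, 0.0)  # synthetic t=0 is odor-at-nose
            clean[pid] = ep
            reports[pid] = rep
        kept = exclude_participants(reports)
        clean = {p: clean[p] for p in kept}
        kept_labels = labels[labels["participant_id"].isin(kept)]
        # align labels with retained trials
        retained = {}
        for pid in kept:
            keep_mask = reports[pid].kept
            lbl = kept_labels[kept_labels["participant_id"] == pid].sort_values(
                "trial_id"
            )
            retained[pid] = lbl[keep_mask].reset_index(drop=True)
        retained_labels = pd.concat(retained.values(), ignore_index=True)
        rejection = pd.DataFrame(
            {
                "participant_id": list(reports),
                "n_trials": [len(r.kept) for r in reports.values()],
                "n_kept": [int(r.kept.sum()) for r in reports.values()],
                "excluded": [r.excluded for r in reports.values()],
            }
        )
        rejection.to_csv(out / "rejection_report.csv", index=False)
        results["n_participants_kept"] = len(kept)

        stage = "coherence"
        grid = _grid(config)
        maps = class_coherence_maps(
            clean, retained_labels, grid, n_tapers=config.coherence_tapers
        )

        stage = "decode"
        dec = decode_pipeline(
            maps,
            grid,
            n_perm=config.n_perm,
            rng=rngs["decode"],
            alpha=config.cluster_alpha,
            sequential=config.sequential_permutations,
            half_width=config.searchlight_half_width,
            min_neighbors=config.min_neighbors,
        )
        results["decoding"] = dec
        _save_map_tsv(out / "accuracy_map.tsv", grid, dec["accuracy"].A, "accuracy")
        _save_map_tsv(out / "p_map.tsv", grid, dec["permutation"].p, "p")
        rois = [r for r in DEFAULT_ROIS if _roi_in_grid(r, grid)]
        roi_res = {}
        for roi in rois:
            try:
                roi_res[roi.name] = roi_summary(dec["accuracy"], roi)
            except ValueError:
                continue
        results["rois"] = roi_res
        with open(out / "decoding_summary.json", "w") as f:
            json.dump(
                {
                    "clusters": [
                        {
                            "f_range": c.f_range,
                            "t_range": c.t_range,
                            "peak_accuracy": c.peak_accuracy,
                            "peak_f": c.peak_f,
                            "peak_t": c.peak_t,
                            "n_points": int(len(c.members)),
                        }
                        for c in dec["clusters"]
                    ],
                    "rois": {
                        name: {
                            "mean_accuracy": r["mean_accuracy"],
                            "confusion": r["confusion"].tolist(),
                            "participant_accuracy":
                                r["participant_accuracy"].tolist(),
                        }
                        for name, r in roi_res.items()
                    },
                },
                f,
                indent=2,
            )

        stage = "granger"
        gc = {}
        for pid, ep in clean.items():
            lbl = retained[pid]["class"].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spectra = per_condition_gc(
                    ep, lbl, window=config.gc_window,
                    bandwidth=config.gc_bandwidth, n_tapers=config.gc_tapers,
                    min_trials=config.gc_min_trials,
                    fmin=config.fmin, fmax=config.fmax,
                )
            if spectra:
                gc[pid] = spectra
        contrast = group_contrast(gc, alpha=config.gc_alpha)
        results["granger"] = contrast
        _save_gc_tsv(out / "granger_spectra.tsv", gc)
        with open(out / "granger_contrast.json", "w") as f:
            json.dump(
                {
                    d: {
                        "clusters": [
                            {
                                "f_range": c.f_range,
                                "peak_f": c.peak_f,
                                "peak_t_stat": c.peak_t,
                                "peak_p": c.peak_p,
                                "cohens_d": c.cohens_d,
                            }
                            for c in r["clusters"]
                        ]
                    }
                    for d, r in contrast["directions"].items()
                },
                f,
                indent=2,
            )

        stage = "report"
        sep = rating_separation(ratings, labels)
        breath = breathing_auc_compare(
            {p: breaths[p] for p in kept},
            labels[labels["participant_id"].isin(kept)],
        )
        results["rating_separation"] = sep
        results["breathing"] = breath
        with open(out / "behavior.json", "w") as f:
            json.dump(
                {"rating_separation": sep.to_dict(), "breathing_auc": breath.to_dict()},
                f,
                indent=2,
            )

        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "stages": list(STAGES),
            "n_participants_kept": len(kept),
            "input_hashes": {
                pid: _hash_array(ep.data) for pid, ep in clean.items()
            },
            "accuracy_map_hash": _hash_array(
                np.nan_to_num(dec["accuracy"].A)
            ),
            "p_map_hash": _hash_array(np.nan_to_num(dec["permutation"].p)),
        }
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True)
        results["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def _roi_in_grid(roi, grid: TFGrid) -> bool:
    return (
        roi.f_range[0] <= grid.freqs.max()
        and roi.f_range[1] >= grid.freqs.min()
        and roi.t_range[0] <= grid.times.max()
        and roi.t_range[1] >= grid.times.min()
    )


def _save_map_tsv(path, grid: TFGrid, arr: np.ndarray, name: str) -> None:
    fi, ti = np.meshgrid(
        np.arange(len(grid.freqs)), np.arange(len(grid.times)), indexing="ij"
    )
    pd.DataFrame(
        {
            "freq_hz": grid.freqs[fi.ravel()],
            "time_s": grid.times[ti.ravel()],
            name: arr.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def _save_gc_tsv(path, gc: dict) -> None:
    rows = []
    for pid, conds in gc.items():
        for cond, spec in conds.items():
            for d, vals in spec.values.items():
                rows.extend(
                    {
                        "participant_id": pid,
                        "condition": cond,
                        "direction": d,
                        "freq_hz": f,
                        "gc_nats": v,
                    }
                    for f, v in zip(spec.freqs, vals)
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# report rendering
# ----------------------------------------------------------------------

def report(run_dir) -> Path:
    """Render a markdown + PNG summary of a completed run directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    needed = [
        "manifest.json", "accuracy_map.tsv", "p_map.tsv",
        "decoding_summary.json", "granger_spectra.tsv",
        "granger_contrast.json", "behavior.json", "ratings.csv",
        "class_labels.csv",
    ]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"run directory incomplete, missing: {missing}")

    manifest = json.loads((run_dir / "manifest.json").read_text())
    acc = pd.read_csv(run_dir / "accuracy_map.tsv", sep="\t")
    pmap = pd.read_csv(run_dir / "p_map.tsv", sep="\t")
    summary = json.loads((run_dir / "decoding_summary.json").read_text())
    gc = pd.read_csv(run_dir / "granger_spectra.tsv", sep="\t")
    behavior = json.loads((run_dir / "behavior.json").read_text())
    ratings = pd.read_csv(run_dir / "ratings.csv")
    labels = pd.read_csv(run_dir / "class_labels.csv")

    freqs = np.sort(acc["freq_hz"].unique())
    times = np.sort(acc["time_s"].unique())
    A = acc.pivot(index="freq_hz", columns="time_s", values="accuracy").to_numpy()
    P = pmap.pivot(index="freq_hz", columns="time_s", values="p").to_numpy()

    fig, axes = plt.subplots(2, 2, figsize=(11, 8))
    ax = axes[0, 0]
    im = ax.pcolormesh(times, freqs, A, shading="nearest", cmap="viridis")
    alpha = manifest["config"]["cluster_alpha"]
    sig = np.isfinite(P) & (P < alpha)
    if sig.any():
        ax.contour(times, freqs, sig.astype(float), levels=[0.5], colors="k")
    ax.set(xlabel="time (s)", ylabel="frequency (Hz)",
           title="decoding accuracy (outlined: significant clusters)")
    fig.colorbar(im, ax=ax)

    ax = axes[0, 1]
    rois = summary.get("rois", {})
    for i, (name, r) in enumerate(rois.items()):
        accs = r["participant_accuracy"]
        ax.scatter(np.full(len(accs), i) + np.linspace(-0.15, 0.15, len(accs)),
                   accs, s=12)
    ax.axhline(0.5, color="gray", ls="--", lw=0.8)
    ax.set_xticks(range(len(rois)), list(rois), rotation=20)
    ax.set(ylabel="participant accuracy", title="ROI accuracy distributions")

    ax = axes[1, 0]
    mean_gc = (
        gc.groupby(["direction", "condition", "freq_hz"])["gc_nats"]
        .mean()
        .reset_index()
    )
    for (d, cond), sub in mean_gc.groupby(["direction", "condition"]):
        ax.plot(sub["freq_hz"], sub["gc_nats"], label=f"{d} {cond}", lw=1)
    ax.legend(fontsize=7)
    ax.set(xlabel="frequency (Hz)", ylabel="GC (nats)",
           title="Granger causality by direction and condition")

    ax = axes[1, 1]
    merged = ratings.merge(labels, on=["participant_id", "trial_id"])
    means = (
        merged[merged["class"].isin(["unpleasant", "pleasant"])]
        .groupby(["participant_id", "class"])["valence"].mean().unstack()
    )
    ax.bar([0, 1], [means["unpleasant"].mean(), means["pleasant"].mean()],
           color=["tab:red", "tab:green"], alpha=0.6)
    for _, row in means.iterrows():
        ax.plot([0, 1], [row["unpleasant"], row["pleasant"]],
                color="gray", lw=0.5, marker="o", ms=2)
    ax.set_xticks([0, 1], ["unpleasant", "pleasant"])
    ax.set(ylabel="rated valence", title="class mean ratings")

    fig.tight_layout()
    fig.savefig(run_dir / "report.png", dpi=110)
    plt.close(fig)

    sep = behavior["rating_separation"]
    breath = behavior["breathing_auc"]
    lines = [
        f"# Run report: {manifest['config']['label']}",
        "",
        f"Package version {manifest['package_version']}, "
        f"seed {manifest['config']['seed']}, "
        f"{manifest['n_participants_kept']} participants retained.",
        "",
        "## Behavior",
        f"- rating separation (pleasant - unpleasant): "
        f"t({sep['df']:.0f}) = {sep['statistic']:.2f}, p = {sep['p']:.2g}, "
        f"mean diff = {sep['mean_diff']:.1f} points",
        f"- breathing AUC (unpleasant - pleasant): "
        f"t({breath['df']:.0f}) = {breath['statistic']:.2f}, "
        f"p = {breath['p']:.2g}",
        "",
        "## Decoding clusters (p < %s)" % alpha,
    ]
    for c in summary["clusters"]:
        lines.append(
            f"- {c['f_range'][0]:.0f}-{c['f_range'][1]:.0f} Hz, "
            f"{c['t_range'][0]:.2f}-{c['t_range'][1]:.2f} s, "
            f"peak accuracy {c['peak_accuracy']:.2f} at "
            f"({c['peak_f']:.0f} Hz, {c['peak_t']:.2f} s)"
        )
    lines += ["", "## ROI summaries"]
    for name, r in rois.items():
        conf = np.array(r["confusion"])
        lines.append(
            f"- {name}: mean accuracy {r['mean_accuracy']:.2f}; "
            f"confusion rows (true unpleasant, true pleasant): "
            f"[{conf[0,0]:.2f}, {conf[0,1]:.2f}] / "
            f"[{conf[1,0]:.2f}, {conf[1,1]:.2f}]"
        )
    gc_contrast = json.loads((run_dir / "granger_contrast.json").read_text())
    lines += ["", "## Granger condition contrast clusters"]
    for d, r in gc_contrast.items():
        if r["clusters"]:
            for c in r["clusters"]:
                lines.append(
                    f"- {d}: {c['f_range'][0]:.0f}-{c['f_range'][1]:.0f} Hz, "
                    f"peak t = {c['peak_t_stat']:.2f} at {c['peak_f']:.0f} Hz "
                    f"(p = {c['peak_p']:.2g}, d = {c['cohens_d']:.2f})"
                )
        else:
            lines.append(f"- {d}: no significant clusters")
    lines += ["", "![summary figure](report.png)", ""]
    out_path = run_dir / "report.md"
    out_path.write_text("\n".join(lines))
    return out_path
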