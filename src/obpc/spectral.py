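"""Multitaper time-frequency decomposition and cross-spectra.

The coherence analysis uses a frequency-adaptive window: at target
frequency f the window length is

    T_f = max( n_cycles / f,  (K + 1) / (2 W_f) ),   W_f = 0.4 f,

i.e. at least 2 cycles and long enough to support K = 2 DPSS tapers at a
half-bandwidth of 40% of the target frequency (total smoothing 80% of
f).  Because (K+1)/(2*0.4 f) = 3.75/f always exceeds 2/f, the bandwidth
term is binding everywhere on the default grid.  Windows that would
extend beyond the epoch are marked missing (NaN) rather than
zero-padded, which avoids edge bias at low frequencies.

The Granger branch instead uses a single 1 s window with 7 DPSS tapers
and a fixed +/-5 Hz smoothing, giving the 1 Hz grid needed for spectral
matrix factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import dpss

from .containers import EpochSet
from .stats import paired_t_map


@dataclass
class TFGrid:
    """Uniform time-frequency analysis grid."""

    freqs: np.ndarray = field(
        default_factory=lambda: np.arange(4.0, 101.0, 1.0)
    )
    times: np.ndarray = field(
        default_factory=lambda: np.arange(-0.4, 1.4001, 0.025)
    )

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        for ax, name in ((self.freqs, "freqs"), (self.times, "times")):
            if len(ax) > 1:
                steps = np.diff(ax)
                if (steps <= 0).any():
                    raise ValueError(f"{name} must be strictly increasing")
                if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                    raise ValueError(f"{name} must be uniformly spaced")

    @property
    def shape(self) -> tuple:
        return (len(self.freqs), len(self.times))

    def matches(self, other: "TFGrid") -> bool:
        return np.array_equal(self.freqs, other.freqs) and np.array_equal(
            self.times, other.times
        )


def window_length(
    f: float, n_tapers: int = 2, bandwidth_frac: float = 0.8,
    min_cycles: float = 2.0,
) -> float:
    """Adaptive window length T_f in seconds at target frequency f."""
    half_bw = 0.5 * bandwidth_frac * f
    return max(min_cycles / f, (n_tapers + 1) / (2.0 * half_bw))


@dataclass
class TFR:
    """Complex multitaper Fourier coefficients X[trial, taper, roi, f, t].

    Invalid cells (window not fully inside the epoch) are NaN for every
    trial and taper alike; ``valid`` is the (f, t) mask.
    """

    coeff: np.ndarray
    grid: TFGrid
    roi_labels: tuple
    fs: float
    valid: np.ndarray  # bool (n_freqs, n_times)
    window_lengths: np.ndarray  # seconds per frequency

    def roi_index(self, label: str) -> int:
        return self.roi_labels.index(label)


def multitaper_tfr(
    epochs: EpochSet,
    grid: TFGrid | None = None,
    n_tapers: int = 2,
    bandwidth_frac: float = 0.8,
    min_cycles: float = 2.0,
) -> TFR:
    """Frequency-adaptive multitaper time-frequency transform.

    For each grid frequency the DPSS taper family (time-bandwidth product
    T_f * W_f) is applied to windows centered on each grid time, and the
    single Fourier coefficient at that frequency is returned.  Tapers are
    unit-energy, so |X|^2 / fs estimates the two-sided PSD.
    """
    grid = grid or TFGrid()
    nyq = epochs.fs / 2
    if grid.freqs.max() >= nyq:
        raise ValueError("grid frequency at or above Nyquist")
    n_trials, n_roi, n_samples = epochs.data.shape
    nf, nt = grid.shape
    coeff = np.full((n_trials, n_tapers, n_roi, nf, nt), np.nan, dtype=complex)
    valid = np.zeros((nf, nt), dtype=bool)
    win_lens = np.empty(nf)

    t_axis = epochs.times
    for fi, f in enumerate(grid.freqs):
        T = window_length(f, n_tapers, bandwidth_frac, min_cycles)
        win_lens[fi] = T
        n_win = int(round(T * epochs.fs))
        if n_win > n_samples:
            continue  # this frequency has no valid cells at all
        half_bw = 0.5 * bandwidth_frac * f
        nw = max(T * half_bw, (n_tapers + 1) / 2 * 0.5 + 0.01)
        tapers = dpss(n_win, nw, Kmax=n_tapers)  # (K, n_win), unit energy
        # complex demodulation kernel centered on the window
        offs = (np.arange(n_win) - (n_win - 1) / 2) / epochs.fs
        kernel = tapers * np.exp(-2j * np.pi * f * offs)  # (K, n_win)

        # center sample index per grid time (nearest sample)
        centers = np.round((grid.times - t_axis[0]) * epochs.fs).astype(int)
        starts = centers - (n_win - 1) // 2
        ok = (starts >= 0) & (starts + n_win <= n_samples)
        if not ok.any():
            continue
        valid[fi, ok] = True
        windows = sliding_window_view(epochs.data, n_win, axis=-1)
        w = windows[:, :, starts[ok], :]  # (trials, roi, n_ok, n_win)
        # (trials, roi, n_ok, K)
        c = np.tensordot(w, kernel, axes=([3], [1]))
        coeff[:, :, :, fi, ok] = c.transpose(0, 3, 1, 2)
    return TFR(
        coeff=coeff, grid=grid, roi_labels=epochs.roi_labels,
        fs=epochs.fs, valid=valid, window_lengths=win_lens,
    )


@dataclass
class CoherenceMap:
    """Magnitude coherence C(f, t) in [0, 1] for one node pair.

    ``m`` counts the (trial x taper) estimates per cell; cells with a
    missing window are NaN.
    """

    C: np.ndarray
    grid: TFGrid
    pair: tuple
    m: np.ndarray
    participant_id: str = ""
    condition: str = ""


def coherence(
    tfr: TFR, pair: tuple, trial_subset=None,
    participant_id: str = "", condition: str = "",
) -> CoherenceMap:
    """Magnitude coherence over trials (optionally a subset) and tapers.

    C(f,t) = |sum_n X_n conj(Y_n)| / sqrt(sum |X|^2 * sum |Y|^2) with the
    sum across the selected trials and all tapers.
    """
    ix, iy = tfr.roi_index(pair[0]), tfr.roi_index(pair[1])
    if trial_subset is None:
        trial_subset = np.arange(tfr.coeff.shape[0])
    trial_subset = np.asarray(trial_subset)
    if trial_subset.size == 0:
        raise ValueError("empty trial subset")
    X = tfr.coeff[trial_subset, :, ix]  # (n, K, f, t)
    Y = tfr.coeff[trial_subset, :, iy]
    m = int(trial_subset.size * tfr.coeff.shape[1])
    if m < 2:
        raise ValueError("need >= 2 trial x taper estimates per cell")
    with np.errstate(invalid="ignore"):
        sxy = np.nansum(X * Y.conj(), axis=(0, 1))
        sxx = np.nansum(np.abs(X) ** 2, axis=(0, 1))
        syy = np.nansum(np.abs(Y) ** 2, axis=(0, 1))
        denom = np.sqrt(sxx * syy)
        C = np.abs(sxy) / np.where(denom == 0, np.nan, denom)
    C[~tfr.valid] = np.nan
    m_map = np.where(tfr.valid, m, 0)
    return CoherenceMap(
        C=C, grid=tfr.grid, pair=tuple(pair), m=m_map,
        participant_id=participant_id, condition=condition,
    )


def save_coherence_map(cm: CoherenceMap, path) -> None:
    """Write a coherence map to HDF5: /C, /freqs, /times, /m + attrs."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("C", data=cm.C)
        f.create_dataset("freqs", data=cm.grid.freqs)
        f.create_dataset("times", data=cm.grid.times)
        f.create_dataset("m", data=cm.m)
        f.attrs["pair"] = repr(cm.pair)
        f.attrs["participant_id"] = cm.participant_id
        f.attrs["condition"] = cm.condition


def load_coherence_map(path) -> CoherenceMap:
    import ast

    import h5py

    with h5py.File(path, "r") as f:
        return CoherenceMap(
            C=f["C"][()],
            grid=TFGrid(freqs=f["freqs"][()], times=f["times"][()]),
            pair=ast.literal_eval(str(f.attrs["pair"])),
            m=f["m"][()],
            participant_id=str(f.attrs["participant_id"]),
            condition=str(f.attrs["condition"]),
        )


def hemisphere_average(map_L: CoherenceMap, map_R: CoherenceMap) -> CoherenceMap:
    """Cell-wise mean of the two hemispheres' coherence maps."""
    if not map_L.grid.matches(map_R.grid):
        raise ValueError("grid mismatch between hemispheres")
    return CoherenceMap(
        C=0.5 * (map_L.C + map_R.C),
        grid=map_L.grid,
        pair=(map_L.pair, map_R.pair),
        m=map_L.m + map_R.m,
        participant_id=map_L.participant_id,
        condition=map_L.condition,
    )


def coherence_null_threshold(m: int, alpha: float = 0.05) -> float:
    """Closed-form (1-alpha) null quantile of magnitude coherence.

    For m independent estimates of two incoherent Gaussian channels,
    P(C > c) = (1 - c^2)^(m-1), giving c_alpha = sqrt(1 - alpha^(1/(m-1))).
    """
    if m < 2:
        raise ValueError("need m >= 2")
    return float(np.sqrt(1.0 - alpha ** (1.0 / (m - 1))))


# ----------------------------------------------------------------------
# power
# ----------------------------------------------------------------------

def log_power_map(tfr: TFR, roi: str, trial_subset=None) -> np.ndarray:
    """Mean log power (f, t) map for one ROI over trials and tapers."""
    ir = tfr.roi_index(roi)
    if trial_subset is None:
        trial_subset = np.arange(tfr.coeff.shape[0])
    X = tfr.coeff[np.asarray(trial_subset), :, ir]
    with np.errstate(invalid="ignore", divide="ignore"):
        power = np.nanmean(np.abs(X) ** 2, axis=(0, 1)) / tfr.fs
        out = np.log(power)
    out[~tfr.valid] = np.nan
    return out


def power_contrast(maps_a: np.ndarray, maps_b: np.ndarray, alpha: float = 0.05):
    """Group paired t map of two per-participant (f, t) power conditions.

    ``maps_a``/``maps_b``: arrays (n_participants, n_freqs, n_times) of
    (log-)power per condition.  Returns (t, p, mask) where the mask marks
    cells with p < alpha; cluster extraction on the mask is shared with
    the decoding machinery (:func:`obpc.decoding.find_clusters`).
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape != maps_b.shape:
        raise ValueError("condition map shapes differ")
    if maps_a.shape[0] < 2:
        raise ValueError("need >= 2 participants")
    diffs = maps_a - maps_b
    finite = np.isfinite(diffs).all(axis=0)
    t, p, _ = paired_t_map(np.where(np.isfinite(diffs), diffs, 0.0))
    t = np.where(finite, t, np.nan)
    p = np.where(finite, p, np.nan)
    mask = finite & (p < alpha)
    return t, p, mask


# ----------------------------------------------------------------------
# cross-spectral density for Granger
# ----------------------------------------------------------------------

@dataclass
class CrossSpectralMatrix:
    """Trial/taper-averaged Hermitian cross-spectrum on 0..Nyquist."""

    freqs: np.ndarray
    S: np.ndarray  # (nf, 2, 2) complex, two-sided PSD (power per Hz)
    pair: tuple
    n_tapers: int
    bandwidth: float  # Hz half-bandwidth-free smoothing parameter W
    n_trials: int


def csd_multitaper(
    epochs: EpochSet,
    pair: tuple,
    window: tuple = (0.0, 1.0),
    bandwidth: float = 5.0,
    n_tapers: int = 7,
) -> CrossSpectralMatrix:
    """Multitaper cross-spectral matrix of a node pair on one window.

    The window (in seconds on the epoch's time axis, default the 1 s
    stimulation period) is tapered with DPSS at time-bandwidth T*W and
    Fourier transformed; S(f) is the average over trials and tapers of
    the outer products, in the two-sided PSD convention (for unit-variance
    white noise, S_xx ~ 1/fs).  The full grid from 0 to Nyquist is
    returned, as required by the spectral factorization.
    """
    times = epochs.times
    sel = (times >= window[0] - 1e-9) & (times < window[1] - 1e-9)
    n_win = int(sel.sum())
    if n_win < 8:
        raise ValueError("window outside the epoch (or too short)")
    T = n_win / epochs.fs
    nw = T * bandwidth
    if n_tapers > 2 * nw - 1:
        raise ValueError(
            f"{n_tapers} tapers exceed 2TW-1 = {2 * nw - 1:.1f}"
        )
    ix, iy = epochs.roi_index(pair[0]), epochs.roi_index(pair[1])
    x = epochs.data[:, [ix, iy], :][:, :, sel]  # (trials, 2, n_win)
    tapers = dpss(n_win, nw, Kmax=n_tapers)  # unit energy
    # (trials, K, 2, n_freq)
    tapered = x[:, None, :, :] * tapers[None, :, None, :]
    F = np.fft.rfft(tapered, axis=-1) / np.sqrt(epochs.fs)
    S = np.einsum("tkif,tkjf->fij", F, F.conj()) / (
        x.shape[0] * n_tapers
    )
    freqs = np.fft.rfftfreq(n_win, 1 / epochs.fs)
    return CrossSpectralMatrix(
        freqs=freqs, S=S, pair=tuple(pair), n_tapers=n_tapers,
        bandwidth=bandwidth, n_trials=x.shape[0],
    )
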