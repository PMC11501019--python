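"""Synthetic study generator.

Emulates the study conditions of the two-experiment design: 20-40
participants, 80-180 trials each, bimodal valence ratings separated by
~45 points on the 0-100 visual analogue scale, 512 Hz four-ROI source
time courses with 1/f background activity, and valence-dependent,
direction-specific band-limited coupling between the olfactory bulb (OB)
and piriform cortex (PC):

* gamma (65 Hz) OB->PC burst near 150 ms after odor onset,
* beta (15 Hz) PC->OB bursts near 600 and 850 ms,
* theta (6 Hz) PC->OB burst near 900 ms (peak of inhalation).

Coupling is realized as a delayed, class-gain-scaled copy of a
Gaussian-enveloped stochastic narrowband carrier, added on top of
independent 1/f noise in each ROI.  This single mechanism produces both
elevated OB-PC coherence (decodable by the searchlight) and genuinely
directional spectral Granger causality -- the carrier's innovations
enter the source and propagate to the target with the lag -- with the
valence class controlling the target-side gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ROI_LABELS, BreathTrace, EpochSet

CLASS_UNPLEASANT = "unpleasant"
CLASS_MIDDLE = "middle"
CLASS_PLEASANT = "pleasant"


@dataclass
class CouplingComponent:
    """One directed, band-limited, time-localized coupling burst.

    The carrier is a stationary stochastic narrowband oscillation: an
    AR(2) process with complex poles at ``center_freq`` and radius
    ``innovation_radius`` (unit variance).  The source node receives
    ``amplitude_source`` times the carrier under a Gaussian envelope
    centered at ``center_time`` (SD ``time_width``); the target node
    receives the same enveloped carrier delayed by ``lag`` and scaled by
    the gain of the trial's valence class.  Because the carrier's
    innovations arise fresh each sample and propagate only
    source->target, the injected Granger causality is directional, while
    the shared carrier still produces within-trial OB-PC coherence with
    a random phase per trial.  ``innovation_radius`` closer to 1 makes
    the carrier more narrowband but more predictable (less directional).
    """

    source: str  # node name, "OB" or "PC" (applied within each hemisphere)
    target: str
    center_freq: float  # Hz
    center_time: float  # s relative to odor onset
    time_width: float  # s, Gaussian envelope SD
    lag: float  # s, transmission delay, >= 0
    amplitude_source: float = 1.0
    gain_by_class: dict = field(
        default_factory=lambda: {CLASS_UNPLEASANT: 1.0, CLASS_PLEASANT: 1.0}
    )
    innovation_radius: float = 0.85
    carrier_order: int = 1  # cascaded AR(2) sections (skirt steepness)
    carrier_highpass: float | None = None  # Hz; confines the carrier band
    carrier_lowpass: float | None = None  # Hz; confines the carrier band

    def __post_init__(self):
        if not 0.0 < self.innovation_radius < 1.0:
            raise ValueError("innovation_radius must lie in (0, 1)")
        if self.carrier_order < 1:
            raise ValueError("carrier_order must be >= 1")
        if self.carrier_highpass is not None and not (
            0 < self.carrier_highpass < self.center_freq
        ):
            raise ValueError("carrier_highpass must lie below center_freq")
        if self.carrier_lowpass is not None and not (
            self.center_freq < self.carrier_lowpass
        ):
            raise ValueError("carrier_lowpass must lie above center_freq")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if not 4.0 <= self.center_freq <= 100.0:
            raise ValueError("center_freq must lie in [4, 100] Hz")
        if any(g < 0 for g in self.gain_by_class.values()):
            raise ValueError("class gains must be >= 0")
        if self.source == self.target:
            raise ValueError("source and target must differ")

    def gain(self, cls: str) -> float:
        """Gain for a valence class; middle tertile gets the extreme mean."""
        if cls in self.gain_by_class:
            return float(self.gain_by_class[cls])
        return float(np.mean(list(self.gain_by_class.values())))


def default_components() -> list:
    """Coupling layout of the default design.

    Gains were calibrated once so that searchlight decoding accuracy at
    the injected time-frequency points falls in the 0.65-0.85 range under
    the default design (see the methods note); the layout itself (which
    band, which direction, when) is fixed.
    """
    return [
        # broadband gamma feedforward: short predictability horizon for
        # clean directionality, high-passed so no beta-band tail couples
        CouplingComponent(
            "OB", "PC", center_freq=65.0, center_time=0.15, time_width=0.05,
            lag=0.020, amplitude_source=0.85,
            gain_by_class={CLASS_UNPLEASANT: 0.85, CLASS_PLEASANT: 0.28},
            innovation_radius=0.75, carrier_highpass=40.0,
        ),
        CouplingComponent(
            "PC", "OB", center_freq=15.0, center_time=0.60, time_width=0.08,
            lag=0.040, amplitude_source=0.40,
            gain_by_class={CLASS_UNPLEASANT: 0.40, CLASS_PLEASANT: 0.14},
            carrier_lowpass=30.0,
        ),
        CouplingComponent(
            "PC", "OB", center_freq=15.0, center_time=0.85, time_width=0.08,
            lag=0.040, amplitude_source=0.40,
            gain_by_class={CLASS_UNPLEASANT: 0.40, CLASS_PLEASANT: 0.14},
            carrier_lowpass=30.0,
        ),
        CouplingComponent(
            "PC", "OB", center_freq=6.0, center_time=0.90, time_width=0.12,
            lag=0.050, amplitude_source=0.22,
            gain_by_class={CLASS_UNPLEASANT: 0.17, CLASS_PLEASANT: 0.06},
            carrier_lowpass=20.0,
        ),
    ]


@dataclass
class SimDesign:
    """Generative specification of a synthetic experiment.

    Defaults follow the replication experiment's conditions: 20
    participants, 180 trials each, 512 Hz, 2 s epochs from -0.5 to +1.5 s
    around odor onset, 1/f background (alpha = 1), bimodal ratings with
    class means 25 and 70 (difference 45 points).
    """

    n_participants: int = 20
    n_trials: int = 180
    fs: float = 512.0
    epoch_window: tuple = (-0.5, 1.5)
    noise_exponent: float = 1.0
    components: list = field(default_factory=default_components)
    rating_params: dict = field(
        default_factory=lambda: {
            CLASS_UNPLEASANT: (25.0, 9.0),
            CLASS_PLEASANT: (70.0, 12.0),
        }
    )
    intensity_params: tuple = (50.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_trials % 3 != 0:
            raise ValueError("n_trials must be divisible by 3 (exact tertiles)")
        for mu, sd in self.rating_params.values():
            if not (np.isfinite(mu) and np.isfinite(sd)):
                raise ValueError("rating parameters must be finite")
            if sd < 0:
                raise ValueError("rating SDs must be >= 0")
        if len(self.rating_params) < 2:
            raise ValueError("need >= 2 rating classes")
        means = [m for m, _ in self.rating_params.values()]
        if len(set(means)) < 2:
            raise ValueError("rating class means must be distinct")
        fmax = max((c.center_freq for c in self.components), default=0.0)
        if self.fs <= 2 * fmax:
            raise ValueError("fs must exceed twice the maximum component frequency")
        epoch_len = self.epoch_window[1] - self.epoch_window[0]
        for c in self.components:
            if c.lag >= epoch_len:
                raise ValueError("component lag exceeds the epoch length")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * (self.epoch_window[1] - self.epoch_window[0])))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ----------------------------------------------------------------------
# ratings
# ----------------------------------------------------------------------

def _truncnorm(rng, mean, sd, size, lo=0.0, hi=100.0):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_ratings(design: SimDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-trial valence and intensity ratings for every participant.

    Per trial a generative valence class is drawn uniformly; the valence
    rating is truncated-normal around that class's mean.  Intensity is
    drawn from one shared distribution so it carries no class signal.
    The hidden generative class is returned in a ``true_class`` column
    (used by the epoch generator; the analysis itself only ever sees
    ratings).
    """
    classes = list(design.rating_params)
    rows = []
    for p in range(design.n_participants):
        cls_idx = rng.integers(len(classes), size=design.n_trials)
        valence = np.empty(design.n_trials)
        for i, c in enumerate(classes):
            mu, sd = design.rating_params[c]
            sel = cls_idx == i
            valence[sel] = _truncnorm(rng, mu, sd, int(sel.sum()))
        mu_i, sd_i = design.intensity_params
        intensity = _truncnorm(rng, mu_i, sd_i, design.n_trials)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": f"P{p:03d}",
                    "trial_id": np.arange(design.n_trials),
                    "valence": valence,
                    "intensity": intensity,
                    "true_class": [classes[i] for i in cls_idx],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ----------------------------------------------------------------------
# epochs
# ----------------------------------------------------------------------

def one_over_f_noise(rng, n_trials, n_channels, n_samples, fs, exponent):
    """Gaussian noise with a 1/f^alpha amplitude spectrum, unit variance."""
    nf = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, 1 / fs)
    shape = np.ones(nf)
    if exponent != 0:
        shape[1:] = freqs[1:] ** (-exponent / 2.0)
        shape[0] = 0.0  # no DC power
    spec = (
        rng.standard_normal((n_trials, n_channels, nf))
        + 1j * rng.standard_normal((n_trials, n_channels, nf))
    ) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _narrowband_carrier(rng, n_trials, n_samples, f0, radius, fs,
                        burn_in=300, order=1, highpass=None, lowpass=None):
    """Unit-variance stochastic narrowband oscillation per trial.

    ``order`` cascaded AR(2) sections with complex poles at angle
    2*pi*f0/fs and radius ``radius``.  A radius closer to 1 narrows the
    band but lengthens the predictability horizon.  ``highpass`` (Hz)
    additionally applies a causal 4th-order Butterworth high-pass: AR
    poles have heavy low-frequency tails, and a high-frequency carrier
    would otherwise leak real coupling into the low bands; the high-pass
    confines the carrier to its own band while barely lengthening its
    correlation time.
    """
    from scipy.signal import butter, lfilter

    w = 2 * np.pi * f0 / fs
    a1, a2 = 2 * radius * np.cos(w), -(radius**2)
    u = rng.standard_normal((n_trials, n_samples + burn_in))
    for _ in range(order):
        u = lfilter([1.0], [1.0, -a1, -a2], u, axis=-1)
    if highpass is not None:
        b, a = butter(4, highpass / (fs / 2), "highpass")
        u = lfilter(b, a, u, axis=-1)
    if lowpass is not None:
        b, a = butter(4, lowpass / (fs / 2), "lowpass")
        u = lfilter(b, a, u, axis=-1)
    u = u[:, burn_in:]
    sd = u.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return u / sd


def _tertile_classes(valence: np.ndarray) -> np.ndarray:
    """Tertile class per trial (bottom third unpleasant, top third pleasant).

    Stable ranking: ties broken by trial order.  Mirrors
    :func:`obpc.preprocess.assign_classes`, duplicated here only to keep
    the generator free of analysis-module imports.
    """
    n = len(valence)
    k = n // 3
    order = np.argsort(valence, kind="stable")
    cls = np.array([CLASS_MIDDLE] * n, dtype=object)
    cls[order[:k]] = CLASS_UNPLEASANT
    cls[order[n - k:]] = CLASS_PLEASANT
    return cls


def generate_epochs(
    design: SimDesign, ratings: pd.DataFrame, rng: np.random.Generator
) -> dict:
    """Generate the 4-ROI epoched time courses for every participant.

    Returns a dict participant_id -> :class:`EpochSet`.  Each ROI trace is
    1/f background noise plus, per coupling component, a Gaussian-windowed
    sinusoid in the source node and its lagged, class-gain-scaled copy in
    the target node.  The trial's class is the tertile of its valence
    rating; middle-tertile trials receive the mean of the extreme gains.
    """
    nyq = design.fs / 2
    for c in design.components:
        if c.center_freq >= nyq:
            raise ValueError(
                f"component frequency {c.center_freq} Hz >= Nyquist {nyq} Hz"
            )
    n_samples = design.n_samples
    t = design.epoch_window[0] + np.arange(n_samples) / design.fs
    out = {}
    for pid, sub in ratings.groupby("participant_id", sort=True):
        sub = sub.sort_values("trial_id")
        n_trials = len(sub)
        cls = _tertile_classes(sub["valence"].to_numpy())
        data = one_over_f_noise(
            rng, n_trials, len(ROI_LABELS), n_samples, design.fs,
            design.noise_exponent,
        )
        for comp in design.components:
            gains = np.array([comp.gain(c) for c in cls])
            lag_n = int(round(comp.lag * design.fs))
            env_s = np.exp(-0.5 * ((t - comp.center_time) / comp.time_width) ** 2)
            td = t - comp.lag
            env_t = np.exp(-0.5 * ((td - comp.center_time) / comp.time_width) ** 2)
            for hemi in ("L", "R"):
                src = ROI_LABELS.index(f"{comp.source}_{hemi}")
                tgt = ROI_LABELS.index(f"{comp.target}_{hemi}")
                u = _narrowband_carrier(
                    rng, n_trials, n_samples + lag_n,
                    comp.center_freq, comp.innovation_radius, design.fs,
                    order=comp.carrier_order,
                    highpass=comp.carrier_highpass,
                    lowpass=comp.carrier_lowpass,
                )
                # target sees the carrier lag_n samples in the past
                u_src = u[:, lag_n:]
                u_tgt = u[:, : n_samples]
                data[:, src, :] += comp.amplitude_source * env_s * u_src
                data[:, tgt, :] += gains[:, None] * (env_t * u_tgt)
        out[pid] = EpochSet(
            data=data,
            roi_labels=ROI_LABELS,
            fs=design.fs,
            t0=design.epoch_window[0],
            participant_id=str(pid),
        )
    return out


# ----------------------------------------------------------------------
# breathing
# ----------------------------------------------------------------------

def generate_breathing(
    design: SimDesign,
    ratings: pd.DataFrame,
    rng: np.random.Generator,
    fs: float = 400.0,
    peak_mean: float = 0.91,
    peak_sd: float = 0.05,
    duration: float = 0.8,
    amp_mean: float = 362.0,
    amp_sd: float = 225.0,
    class_amp_shift: float = 0.0,
) -> dict:
    """Raised-cosine inhalation traces, one per trial.

    Per-trial inhalation peak time ~ Normal(peak_mean, peak_sd) seconds
    (matching the reported group mean of 910 +/- 50 ms), amplitude
    independent of valence class by default.  ``class_amp_shift`` adds a
    (shift * amp_sd) amplitude offset to unpleasant-tertile trials, used
    for power analyses of the breathing comparison.  Amplitudes are in
    arbitrary thermistor-like units; the defaults put the inhalation
    area-under-curve near the reported ~145.
    """
    n_samples = int(round(fs * (design.epoch_window[1] - design.epoch_window[0])))
    t = design.epoch_window[0] + np.arange(n_samples) / fs
    out = {}
    for pid, sub in ratings.groupby("participant_id", sort=True):
        sub = sub.sort_values("trial_id")
        n_trials = len(sub)
        cls = _tertile_classes(sub["valence"].to_numpy())
        peaks = peak_mean + peak_sd * rng.standard_normal(n_trials)
        peaks = np.clip(peaks, design.epoch_window[0] + duration / 2,
                        design.epoch_window[1] - 1 / fs)
        amps = np.clip(amp_mean + amp_sd * rng.standard_normal(n_trials), 0, None)
        if class_amp_shift:
            amps = amps + class_amp_shift * amp_sd * (cls == CLASS_UNPLEASANT)
        onset = peaks - duration / 2
        phase = np.clip((t[None, :] - onset[:, None]) / duration, 0.0, 1.0)
        traces = amps[:, None] * 0.5 * (1 - np.cos(2 * np.pi * phase))
        out[pid] = BreathTrace(
            data=traces, fs=fs, t0=design.epoch_window[0],
            peak_times=peaks, participant_id=str(pid),
        )
    return out
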