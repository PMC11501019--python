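"""Nonparametric frequency-resolved Granger causality.

The directional analysis asks whether the OB's past improves prediction
of the PC beyond the PC's own past (and vice versa), resolved by
frequency.  Rather than fitting a VAR model, the multitaper
cross-spectral density matrix S(f) is factorized with the iterative
Wilson-Burg algorithm into a minimum-phase transfer function H(f) and an
innovation covariance Sigma,

    S(f) = H(f) Sigma H*(f),

from which Geweke's frequency-domain causality is

    F_{y->x}(f) = ln [ S_xx(f) / ( S_xx(f)
                    - (Sigma_yy - Sigma_xy^2 / Sigma_xx) |H_xy(f)|^2 ) ].

The group-level condition contrast (unpleasant vs pleasant) is a paired
two-tailed t test per frequency, with contiguous runs of significant
bins reported as clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import stats as _stats


@dataclass
class SpectralFactorization:
    """Result of Wilson-Burg factorization on the full 0..Nyquist grid."""

    freqs: np.ndarray  # Hz, 0..Nyquist, uniform
    H: np.ndarray  # (nf, m, m) complex minimum-phase transfer function
    Sigma: np.ndarray  # (m, m) real innovation covariance
    n_iter: int
    residual: float  # relative Frobenius reconstruction error
    converged: bool

    def reconstruct(self) -> np.ndarray:
        """H Sigma H* on the factorization grid (sample-spectrum units)."""
        return np.einsum("fij,jk,flk->fil", self.H, self.Sigma, self.H.conj())


@dataclass
class GCSpectrum:
    """Directional Geweke causality on a frequency grid (nats, >= 0)."""

    freqs: np.ndarray
    values: dict  # direction label -> ndarray over freqs
    participant_id: str = ""
    condition: str = ""

    def __post_init__(self):
        for k, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite GC values for direction {k}")
            self.values[k] = v


def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal part [g]_+ of a matrix function on the full frequency circle.

    Transforms to the lag domain, keeps non-negative lags (lag 0 halved
    and upper-triangularized so the factor stays normalized), and
    transforms back.
    """
    nfft = g.shape[0]
    gam = np.fft.ifft(g, axis=0)
    beta0 = 0.5 * gam[0]
    beta0 = np.triu(beta0)  # keep upper triangle incl. diagonal
    gam[0] = beta0
    gam[nfft // 2 + 1:] = 0.0  # zero the negative lags
    return np.fft.fft(gam, axis=0)


def wilson_factorize(
    S: np.ndarray,
    fs: float,
    tol: float = 1e-9,
    max_iter: int = 100,
    psd_tol: float = 1e-8,
) -> SpectralFactorization:
    """Wilson-Burg factorization of a Hermitian PSD cross-spectral matrix.

    Parameters
    ----------
    S : ndarray, shape (nf, m, m)
        Two-sided cross-spectral density (power per Hz) on a uniform grid
        from 0 to Nyquist inclusive.
    fs : float
        Sampling rate; S*fs is factorized so Sigma comes out in signal
        (variance) units.
    tol : float
        Relative update norm at which the iteration stops.
    max_iter : int
        Iteration cap; non-convergence raises a warning, not an error.

    Notes
    -----
    Initialized from the Cholesky factor of the zero-lag autocovariance
    (frequency-averaged spectrum).  The minimum-phase factor psi is
    iterated via ``psi <- psi [psi^-1 S psi^-H + I]_+``.
    """
    S = np.asarray(S, dtype=complex)
    nf, m, _ = S.shape
    if nf < 2:
        raise ValueError("need at least 2 frequency bins (0 and Nyquist)")
    herm_err = np.abs(S - S.conj().transpose(0, 2, 1)).max()
    if herm_err > psd_tol * (np.abs(S).max() + 1e-300):
        raise ValueError("S is not Hermitian")
    eigmin = np.linalg.eigvalsh(S).min()
    if eigmin < -psd_tol * np.abs(S).max():
        raise ValueError(f"S is not positive semidefinite (min eig {eigmin:g})")

    nfft = 2 * (nf - 1)
    Sfull = np.empty((nfft, m, m), dtype=complex)
    Sfull[:nf] = S * fs  # sample-spectrum convention
    # negative frequencies: S(-f) = conj(S(f)) = S(f)^T for Hermitian S
    Sfull[nf:] = Sfull[1:nf - 1][::-1].transpose(0, 2, 1)

    # equalize channel power before iterating: the max-norm convergence
    # test is otherwise dominated by the strongest channel and badly
    # scaled inputs converge to a poor factor.  A diagonal rescaling
    # commutes with the factorization (H -> D^-1 H D, Sigma -> D^-1
    # Sigma D^-1) and is undone below.
    d = np.sqrt(np.real(np.einsum("fii->i", Sfull)) / nfft)
    d[d == 0] = 1.0
    Sfull = Sfull / d[:, None] / d[None, :]

    # zero-lag autocovariance = mean of the spectrum over the circle
    gam0 = np.real(Sfull.mean(axis=0))
    # ridge for semidefinite inputs (e.g. coherent channels)
    scale = np.trace(gam0) / m
    L = None
    ridge = 0.0
    for _ in range(40):
        try:
            L = np.linalg.cholesky(gam0 + ridge * scale * np.eye(m))
            break
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10, 1e-12)
    if L is None:
        raise ValueError("zero-lag covariance is not positive definite")
    psi = np.broadcast_to(L.conj().T, (nfft, m, m)).copy()

    I = np.eye(m)
    n_iter = 0
    converged = False
    delta_prev = np.inf
    stalled = 0
    for n_iter in range(1, max_iter + 1):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ Sfull @ psi_inv.conj().transpose(0, 2, 1) + I
        gp = _plus_operator(g)
        psi_new = psi @ gp
        delta = np.abs(psi_new - psi).max() / max(np.abs(psi).max(), 1e-300)
        psi = psi_new
        if delta < tol:
            converged = True
            break
        # noisy (estimated) spectra admit no exact causal factorization of
        # restricted lag order; the iteration then settles into a small
        # limit cycle -- detect the stall and accept the stationary point
        if abs(delta - delta_prev) < 1e-3 * max(delta, 1e-300):
            stalled += 1
            if stalled >= 3:
                converged = True
                break
        else:
            stalled = 0
        delta_prev = delta

    # innovation covariance from the zero-lag coefficient of psi
    A0 = np.real(np.fft.ifft(psi, axis=0)[0])
    Sigma = A0 @ A0.T
    H = psi @ np.linalg.inv(A0)

    recon = np.einsum("fij,jk,flk->fil", H, Sigma, H.conj())
    residual = float(
        np.linalg.norm(recon - Sfull) / max(np.linalg.norm(Sfull), 1e-300)
    )
    # undo the channel equalization
    Sigma = Sigma * d[:, None] * d[None, :]
    H = H * (d[:, None] / d[None, :])
    if not converged:
        warnings.warn(
            f"Wilson factorization did not converge in {max_iter} iterations "
            f"(residual {residual:g})",
            RuntimeWarning,
        )
    freqs = np.arange(nf) * fs / nfft
    return SpectralFactorization(
        freqs=freqs, H=H[:nf], Sigma=Sigma,
        n_iter=n_iter, residual=residual, converged=converged,
    )


def geweke_from_transfer(
    H: np.ndarray, Sigma: np.ndarray, clip_tol: float = 1e-12
) -> tuple:
    """Geweke directional causality from a transfer function and Sigma.

    Returns ``(F_x_to_y, F_y_to_x)`` for channels ordered (x, y), i.e.
    index 0 and 1 of the 2x2 system.  Works in the sample-spectrum
    convention ``S = H Sigma H*`` (any constant spectral scaling cancels
    in the ratio).
    """
    H = np.asarray(H, dtype=complex)
    Sigma = np.asarray(Sigma, dtype=float)
    if H.shape[1:] != (2, 2) or Sigma.shape != (2, 2):
        raise ValueError("bivariate (2x2) system required")
    S = np.einsum("fij,jk,flk->fil", H, Sigma, H.conj())
    Sxx = np.real(S[:, 0, 0])
    Syy = np.real(S[:, 1, 1])

    def _one(S_aa, H_ab, sig_bb, sig_ab, sig_aa):
        cond = sig_bb - sig_ab**2 / sig_aa  # partial innovation variance
        denom = S_aa - cond * np.abs(H_ab) ** 2
        bad = denom <= 0
        if bad.any():
            worst = denom.min()
            if worst < -clip_tol * np.abs(S_aa).max():
                raise ValueError(
                    f"non-positive Geweke denominator ({worst:g}); "
                    "factorization invalid"
                )
            denom = np.maximum(denom, np.finfo(float).tiny)
        F = np.log(S_aa / denom)
        return np.clip(F, 0.0, None)

    # F_{y->x}: does y's past help predict x?
    F_y_to_x = _one(Sxx, H[:, 0, 1], Sigma[1, 1], Sigma[0, 1], Sigma[0, 0])
    F_x_to_y = _one(Syy, H[:, 1, 0], Sigma[0, 0], Sigma[0, 1], Sigma[1, 1])
    return F_x_to_y, F_y_to_x


def geweke_causality(
    fact: SpectralFactorization,
    fmin: float = 4.0,
    fmax: float = 100.0,
    directions: tuple = ("OB->PC", "PC->OB"),
    participant_id: str = "",
    condition: str = "",
) -> GCSpectrum:
    """Directional causality spectrum on the reporting band [fmin, fmax].

    Channel 0 of the factorized system is the first node of the pair
    (OB), channel 1 the second (PC).
    """
    F01, F10 = geweke_from_transfer(fact.H, fact.Sigma)
    sel = (fact.freqs >= fmin) & (fact.freqs <= fmax)
    return GCSpectrum(
        freqs=fact.freqs[sel],
        values={directions[0]: F01[sel], directions[1]: F10[sel]},
        participant_id=participant_id,
        condition=condition,
    )


def average_hemispheres(gc_L: GCSpectrum, gc_R: GCSpectrum) -> GCSpectrum:
    """Pointwise mean of the two hemispheres' causality spectra."""
    if not np.array_equal(gc_L.freqs, gc_R.freqs):
        raise ValueError("frequency grids differ between hemispheres")
    if set(gc_L.values) != set(gc_R.values):
        raise ValueError("direction labels differ between hemispheres")
    return GCSpectrum(
        freqs=gc_L.freqs.copy(),
        values={k: 0.5 * (gc_L.values[k] + gc_R.values[k]) for k in gc_L.values},
        participant_id=gc_L.participant_id,
        condition=gc_L.condition,
    )


@dataclass
class GCCluster:
    direction: str
    f_range: tuple  # (Hz, Hz) inclusive
    peak_f: float
    peak_t: float  # t statistic at the peak
    peak_p: float
    cohens_d: float  # paired: mean diff / SD of diffs, at the peak bin


def group_contrast(
    gc_by_participant: dict,
    condition_a: str = "unpleasant",
    condition_b: str = "pleasant",
    alpha: float = 0.05,
) -> dict:
    """Group-level paired contrast of causality between conditions.

    Parameters
    ----------
    gc_by_participant : dict
        participant_id -> {condition -> GCSpectrum}.  Participants missing
        either condition are dropped with a warning.

    Returns
    -------
    dict with per-direction arrays ``t``, ``p``, ``d`` over ``freqs`` and
    the list of significant ``clusters`` (maximal runs of p < alpha).
    """
    usable = {}
    for pid, conds in gc_by_participant.items():
        if condition_a in conds and condition_b in conds:
            usable[pid] = conds
        else:
            warnings.warn(f"participant {pid} missing a condition; dropped")
    if len(usable) < 2:
        raise ValueError("need >= 2 participants with both conditions")

    pids = sorted(usable)
    first = usable[pids[0]][condition_a]
    freqs = first.freqs
    directions = list(first.values)
    out = {"freqs": freqs, "n_participants": len(pids), "directions": {}}
    for d in directions:
        diffs = np.array(
            [
                usable[p][condition_a].values[d] - usable[p][condition_b].values[d]
                for p in pids
            ]
        )
        t, p, cd = _stats.paired_t_map(diffs)
        clusters = []
        sig = p < alpha
        i = 0
        nf = len(freqs)
        while i < nf:
            if sig[i]:
                j = i
                while j + 1 < nf and sig[j + 1]:
                    j += 1
                k = i + int(np.argmax(np.abs(t[i:j + 1])))
                clusters.append(
                    GCCluster(
                        direction=d,
                        f_range=(float(freqs[i]), float(freqs[j])),
                        peak_f=float(freqs[k]),
                        peak_t=float(t[k]),
                        peak_p=float(p[k]),
                        cohens_d=float(cd[k]),
                    )
                )
                i = j + 1
            else:
                i += 1
        out["directions"][d] = {"t": t, "p": p, "d": cd, "clusters": clusters}
    return out


def per_condition_gc(
    epochs,
    class_labels,
    window: tuple = (0.0, 1.0),
    bandwidth: float = 5.0,
    n_tapers: int = 7,
    min_trials: int = 10,
    fmin: float = 4.0,
    fmax: float = 100.0,
) -> dict:
    """Condition-wise OB->PC / PC->OB causality for one participant.

    Pipeline composition: multitaper CSD on each condition's trials for
    each hemisphere pair -> Wilson factorization -> Geweke causality ->
    hemisphere average.  Returns {condition -> GCSpectrum} (conditions
    below the trial floor are skipped with a warning).
    """
    from .containers import PAIRS
    from .spectral import csd_multitaper

    out = {}
    for cond in ("unpleasant", "pleasant"):
        idx = np.flatnonzero(np.asarray(class_labels, dtype=object) == cond)
        if len(idx) < min_trials:
            warnings.warn(
                f"{epochs.participant_id}: condition {cond!r} has "
                f"{len(idx)} trials (< {min_trials}); skipped"
            )
            continue
        sub = epochs.select_trials(idx)
        per_hemi = []
        for hemi, (roi_x, roi_y) in PAIRS.items():
            csd = csd_multitaper(
                sub, pair=(roi_x, roi_y), window=window,
                bandwidth=bandwidth, n_tapers=n_tapers,
            )
            fact = wilson_factorize(csd.S, fs=epochs.fs)
            per_hemi.append(
                geweke_causality(
                    fact, fmin=fmin, fmax=fmax,
                    participant_id=epochs.participant_id, condition=cond,
                )
            )
        out[cond] = average_hemispheres(per_hemi[0], per_hemi[1])
    return out
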