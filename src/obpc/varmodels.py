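"""Bivariate VAR ground truth for validating spectral estimators.

A stationary VAR(p) process

    x_t = A_1 x_{t-1} + ... + A_p x_{t-p} + e_t,   e_t ~ N(0, Sigma)

has the closed-form transfer function H(f) = (I - sum_k A_k e^{-i 2 pi f
k / fs})^{-1}, spectral matrix S(f) = H Sigma H* / fs (two-sided PSD),
and Geweke causality computable directly from (H, Sigma).  These
analytic quantities are the oracles against which the nonparametric
estimation path (multitaper CSD -> Wilson factorization -> Geweke) is
validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .containers import EpochSet
from .granger import geweke_from_transfer


@dataclass
class VarSpec:
    """Specification of a bivariate VAR(p) process.

    ``coeffs`` has shape (p, 2, 2); ``noise_cov`` must be symmetric
    positive definite; stationarity (companion spectral radius < 1) is
    enforced at construction.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    fs: float = 512.0

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1:] != (2, 2):
            raise ValueError("coeffs must be (p, 2, 2)")
        if self.noise_cov.shape != (2, 2):
            raise ValueError("noise_cov must be 2x2")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() <= 0:
            raise ValueError("noise_cov must be positive definite")
        rho = self.spectral_radius
        if rho >= 1:
            raise ValueError(
                f"unstable VAR: companion spectral radius {rho:.4f} >= 1"
            )

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def companion(self) -> np.ndarray:
        p = self.order
        m = 2
        C = np.zeros((m * p, m * p))
        C[:m] = np.concatenate(self.coeffs, axis=1)
        if p > 1:
            C[m:, :-m] = np.eye(m * (p - 1))
        return C

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion)).max())

    def autocovariance(self, max_lag: int) -> np.ndarray:
        """Gamma(0..max_lag) via the companion-form discrete Lyapunov equation."""
        p, m = self.order, 2
        Q = np.zeros((m * p, m * p))
        Q[:m, :m] = self.noise_cov
        C = self.companion
        G = linalg.solve_discrete_lyapunov(C, Q)
        # blocks of G give Gamma(0..p-1); higher lags by the YW recursion
        gam = [G[:m, j * m:(j + 1) * m].copy() for j in range(p)]
        for k in range(1, max_lag + 1):
            if k < p:
                continue
            g = np.zeros((m, m))
            for j in range(1, p + 1):
                g += self.coeffs[j - 1] @ gam[k - j]
            gam.append(g)
        return np.array(gam[: max_lag + 1])


def generate_var_epochs(
    spec: VarSpec,
    n_trials: int,
    n_samples: int,
    rng: np.random.Generator,
    burn_in: int = 1000,
) -> EpochSet:
    """Independent VAR realizations, one per trial, after burn-in."""
    p, m = spec.order, 2
    total = n_samples + burn_in
    L = np.linalg.cholesky(spec.noise_cov)
    e = rng.standard_normal((n_trials, total, m)) @ L.T
    x = np.zeros((n_trials, total, m))
    for t in range(total):
        acc = e[:, t, :].copy()
        for j in range(1, min(p, t) + 1):
            acc += x[:, t - j, :] @ spec.coeffs[j - 1].T
        x[:, t, :] = acc
    data = x[:, burn_in:, :].transpose(0, 2, 1)  # (trials, channels, samples)
    return EpochSet(
        data=data, roi_labels=("X", "Y"), fs=spec.fs, t0=0.0,
        participant_id="var",
    )


def analytic_var_spectra(spec: VarSpec, freqs) -> tuple:
    """Closed-form (S, H, GC_x->y, GC_y->x) of a bivariate VAR at ``freqs``.

    S is the two-sided PSD H Sigma H* / fs.  Raises if the lag operator
    is singular at any requested frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    if (freqs > spec.fs / 2).any() or (freqs < 0).any():
        raise ValueError("freqs must lie in [0, Nyquist]")
    p = spec.order
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / spec.fs)
    A = np.eye(2) - np.einsum("fk,kij->fij", z, spec.coeffs.astype(complex))
    cond = np.abs(np.linalg.det(A))
    if (cond < 1e-12).any():
        fbad = freqs[np.argmin(cond)]
        raise ValueError(f"singular transfer matrix at {fbad:g} Hz")
    H = np.linalg.inv(A)
    S = np.einsum("fij,jk,flk->fil", H, spec.noise_cov.astype(complex),
                  H.conj()) / spec.fs
    gc_xy, gc_yx = geweke_from_transfer(H, spec.noise_cov)
    return S, H, gc_xy, gc_yx
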