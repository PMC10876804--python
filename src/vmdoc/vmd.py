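"""Variational mode decomposition (VMD) of a 1-D signal.

VMD decomposes a signal x(t) into K narrow-band modes u_k(t) with center
frequencies omega_k by minimizing the summed bandwidth of the analytic,
baseband-shifted modes subject to (soft) reconstruction of the input.  The
saddle point of the augmented Lagrangian

    L(u, omega, lam) = alpha * sum_k || d/dt [ (delta + j/(pi t)) * u_k ] e^{-j omega_k t} ||^2
                       + || x - sum_k u_k ||^2 + < lam, x - sum_k u_k >

is found by alternating frequency-domain updates (ADMM): a Wiener-filter-like
mode update, a power-weighted center-frequency update, and dual ascent on the
reconstruction constraint with step tau.  tau = 0 turns the exact
reconstruction constraint off (quadratic penalty only), which is the usual
choice for noisy data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VMDConfig",
    "ModeSet",
    "decompose",
    "check_convergence",
    "reconstruct",
    "extend_signal",
    "crop_to_original",
]


@dataclass
class VMDConfig:
    """Solver configuration.

    Parameters
    ----------
    n_modes : int
        Number of modes K to extract (default 5).
    alpha : float
        Bandwidth penalty; larger values give narrower modes (default 2000).
    tau : float
        Dual-ascent step (noise tolerance).  0 disables the hard
        reconstruction constraint.
    rel_tol : float
        Relative stopping tolerance on the summed squared mode change.
    abs_tol : float or None
        Absolute stopping tolerance; ``None`` disables the absolute
        criterion.
    max_iter : int
        Iteration cap; non-convergence is reported, not raised.
    omega_init : str
        ``"uniform"`` (K frequencies evenly spaced strictly inside
        (0, 0.5) cycles/sample), ``"zero"`` or ``"random"``.
    random_seed : int
        Seed for ``omega_init="random"``.
    dc_mode : bool
        Pin the first mode's center frequency at 0.
    """

    n_modes: int = 5
    alpha: float = 2000.0
    tau: float = 0.0
    rel_tol: float = 1e-7
    abs_tol: Optional[float] = None
    max_iter: int = 500
    omega_init: str = "uniform"
    random_seed: int = 0
    dc_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not (self.rel_tol > 0 or (self.abs_tol is not None and self.abs_tol > 0)):
            raise ValueError("need rel_tol > 0 or abs_tol > 0")
        if self.omega_init not in ("zero", "uniform", "random"):
            raise ValueError(f"unknown omega_init {self.omega_init!r}")


@dataclass
class ModeSet:
    """Result of a decomposition: K modes of length N plus diagnostics.

    ``omegas`` are center frequencies in cycles/sample, sorted ascending
    (modes are reordered accordingly).  ``residual_energy`` is the energy of
    the difference between the input and the mode sum, relative to the input
    energy.
    """

    modes: np.ndarray
    omegas: np.ndarray
    n_iter: int
    converged: bool
    residual_energy: float


def extend_signal(signal: Sequence[float]) -> np.ndarray:
    """Mirror-extend a signal by half its length on each side.

    The extension suppresses boundary artifacts of the periodic FFT model.
    For even N the extended length is exactly 2N.
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("signal must have at least 2 samples")
    h = n // 2
    return np.concatenate([x[:h][::-1], x, x[n - h:][::-1]])


def crop_to_original(extended: np.ndarray, n: int) -> np.ndarray:
    """Invert :func:`extend_signal`: recover the central N samples."""
    extended = np.asarray(extended)
    h = n // 2
    return extended[..., h:h + n]


def check_convergence(prev_modes: np.ndarray, new_modes: np.ndarray,
                      eps_r: Optional[float], eps_a: Optional[float]) -> bool:
    """Stopping test on two successive mode estimates.

    True iff the relative criterion sum_k ||du_k||^2 / ||u_k||^2 < eps_r
    or the absolute criterion sum_k ||du_k||^2 < eps_a holds.  A mode whose
    previous estimate has zero norm contributes only to the absolute sum.
    Either tolerance may be ``None`` (criterion disabled).
    """
    prev = np.asarray(prev_modes)
    new = np.asarray(new_modes)
    if prev.shape != new.shape:
        raise ValueError(f"shape mismatch: {prev.shape} vs {new.shape}")
    diff = new - prev
    d2 = np.sum(np.abs(diff) ** 2, axis=-1)
    p2 = np.sum(np.abs(prev) ** 2, axis=-1)
    abs_sum = float(np.sum(d2))
    nz = p2 > 0
    rel_sum = float(np.sum(d2[nz] / p2[nz]))
    if eps_r is not None and rel_sum < eps_r:
        return True
    if eps_a is not None and abs_sum < eps_a:
        return True
    return False


def reconstruct(mode_set: ModeSet) -> np.ndarray:
    """Sum the modes back into a signal estimate."""
    modes = np.asarray(mode_set.modes, dtype=float)
    if modes.size == 0:
        raise ValueError("empty mode set")
    return modes.sum(axis=0)


def _init_omegas(config: VMDConfig) -> np.ndarray:
    k = config.n_modes
    if config.omega_init == "zero":
        om = np.zeros(k)
    elif config.omega_init == "uniform":
        # evenly spaced with the lowest frequency anchored just above DC,
        # matching the reference "init=1" convention; the positive floor
        # keeps every start strictly inside (0, 0.5)
        om = 0.5 * np.arange(k) / k
        om[0] = 1e-6
    else:  # random
        rng = np.random.default_rng(config.random_seed)
        om = np.sort(rng.uniform(0.0, 0.5, size=k))
    if config.dc_mode:
        om[0] = 0.0
    return om


def decompose(signal: Sequence[float], config: Optional[VMDConfig] = None) -> ModeSet:
    """Decompose a real signal into K narrow-band modes.

    The signal is mirror-extended, transformed to the frequency domain, and
    the one-sided (analytic-signal) half spectrum is split into K modes by
    alternating ADMM updates:

    - mode:   u_k(w) <- (x(w) - sum_{i != k} u_i(w) + lam(w)/2)
                        / (1 + 2 alpha (w - omega_k)^2)
    - center: omega_k <- int w |u_k|^2 dw / int |u_k|^2 dw  (w >= 0)
    - dual:   lam <- lam + tau (x - sum_k u_k)

    Iteration stops when either stopping criterion of
    :func:`check_convergence` is met or ``max_iter`` is reached (the latter
    sets ``converged=False`` rather than raising).  Returned modes are
    cropped to the input length and sorted by ascending center frequency.
    """
    if config is None:
        config = VMDConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    n = x.shape[0]
    k = config.n_modes
    if n < 8:
        raise ValueError("signal must have at least 8 samples")
    if k > n // 2:
        raise ValueError(f"n_modes={k} too large for signal length {n}")

    omegas = _init_omegas(config)

    if not np.any(x):
        # all-zero input: modes are zero, nothing to iterate
        return ModeSet(modes=np.zeros((k, n)), omegas=np.sort(omegas),
                       n_iter=0, converged=True, residual_energy=0.0)

    ext = extend_signal(x)
    t = ext.shape[0]
    half = t // 2
    # fftshift ordering: index half corresponds to frequency 0
    f_hat = np.fft.fftshift(np.fft.fft(ext))
    xh = f_hat[half:].copy()            # one-sided spectrum (w >= 0)
    freqs = np.arange(half) / t         # cycles/sample, 0 .. ~0.5

    u = np.zeros((k, half), dtype=complex)
    lam = np.zeros(half, dtype=complex)
    # Parseval scale so the stopping test sees time-domain-sized norms
    scale = np.sqrt(2.0 / t)

    converged = False
    n_iter = 0
    sum_u = u.sum(axis=0)
    for it in range(config.max_iter):
        u_prev = u.copy()
        for kk in range(k):
            sum_u = sum_u - u[kk]
            u[kk] = (xh - sum_u + lam / 2.0) / (1.0 + 2.0 * config.alpha * (freqs - omegas[kk]) ** 2)
            if not (config.dc_mode and kk == 0):
                p = np.abs(u[kk]) ** 2
                denom = p.sum()
                if denom > 0:
                    omegas[kk] = float(np.dot(freqs, p) / denom)
            sum_u = sum_u + u[kk]
        if config.tau > 0:
            lam = lam + config.tau * (xh - sum_u)
        n_iter = it + 1
        if it > 0 and check_convergence(u_prev * scale, u * scale,
                                        config.rel_tol, config.abs_tol):
            converged = True
            break

    if not converged:
        warnings.warn(f"VMD did not converge within {config.max_iter} iterations",
                      RuntimeWarning, stacklevel=2)

    # rebuild two-sided spectra with Hermitian symmetry, invert, crop
    full = np.zeros((k, t), dtype=complex)
    full[:, half:] = u
    full[:, 1:half] = np.conj(u[:, 1:][:, ::-1])
    full[:, 0] = np.conj(full[:, -1])
    modes_ext = np.real(np.fft.ifft(np.fft.ifftshift(full, axes=-1), axis=-1))
    modes = crop_to_original(modes_ext, n)

    order = np.argsort(omegas, kind="stable")
    modes = modes[order]
    omegas = omegas[order]

    resid = x - modes.sum(axis=0)
    residual_energy = float(np.sum(resid ** 2) / np.sum(x ** 2))
    return ModeSet(modes=modes, omegas=omegas, n_iter=n_iter,
                   converged=converged, residual_energy=residual_energy)
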