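"""Synthetic resting-state EEG cohorts with a graded consciousness structure.

The generator stands in for clinical recordings of three groups (coma, UWS,
MCS).  Each subject's channel signal is a mixture of

- 1/f ("pink") background noise with per-subject lognormal amplitude jitter,
- five narrowband oscillatory peaks (Gaussian-spectrum noise carriers), one
  per canonical band, mixed at class-specific band-power fractions
  (delta-dominant in coma, alpha present in MCS; posterior channels get
  extra alpha weight); the peak's position *within* each band slows with
  decreasing consciousness, a within-band cue that adaptive decomposition
  resolves and fixed band edges straddle,
- a broadband white component whose class-specific power ratio realizes the
  complexity gradient coma < UWS < MCS (reflected in sample/spectral
  entropy),

plus class-consistent CRS-R and GCS behavioral scores and subject-level
jitter of the profile, complexity ratio and peak position (inter-subject
variability).  ``effect_size`` scales every between-class difference: 0
gives class-exchangeable signals (the pipeline's negative control), 1 the
default separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import (CHANNELS_17, CLASS_LABELS, DEFAULT_BANDS,
                         BandDefinition, Recording)

__all__ = ["CohortSpec", "generate_cohort", "generate_tone_mixture"]

#: Channels given extra alpha weight (posterior scalp).
POSTERIOR = ("P3", "Pz", "P4", "O1", "O2")
#: Channels receiving blink artifacts (frontal scalp).
FRONTAL = ("F3", "Fz", "F4", "F7", "F8")

_DEF_PROFILES = {
    # relative band powers over (delta, theta, alpha, beta, gamma); sum 1
    "coma": (0.60, 0.18, 0.10, 0.08, 0.04),
    "UWS": (0.50, 0.22, 0.15, 0.09, 0.04),
    "MCS": (0.42, 0.22, 0.21, 0.10, 0.05),
}
_DEF_COMPLEXITY = {"coma": 0.25, "UWS": 0.35, "MCS": 0.49}
#: fractional position of the oscillatory peak within each band; the
#: rhythms of less conscious patients sit lower in their bands (slowing)
_DEF_PEAK_POSITION = {"coma": 0.25, "UWS": 0.50, "MCS": 0.75}
_DEF_CRSR = {"coma": (0, 2), "UWS": (3, 8), "MCS": (9, 20)}
_DEF_GCS = {"coma": (3, 7), "UWS": (6, 9), "MCS": (9, 12)}


@dataclass
class CohortSpec:
    """Cohort-generation parameters.

    ``effect_size`` linearly interpolates each class's spectral profile and
    complexity ratio between the class-average (0) and the class-specific
    default (1).  ``artifact_rate`` adds frontal low-frequency blink
    transients (per minute); default off so preprocessing can be tested on
    clean data.
    """

    n_per_class: int = 15
    fs: float = 256.0
    duration_s: float = 60.0
    effect_size: float = 1.0
    seed: int = 0
    artifact_rate: float = 0.0
    band_profiles: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEF_PROFILES))
    complexity_ratio: Dict[str, float] = field(
        default_factory=lambda: dict(_DEF_COMPLEXITY))
    crsr_range: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(_DEF_CRSR))
    gcs_range: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(_DEF_GCS))
    pink_power: float = 0.3
    amplitude_jitter_sigma: float = 0.2
    #: lognormal sigma of the per-subject complexity-ratio jitter; the
    #: default makes within-class spread comparable to the between-class
    #: gaps, as in heterogeneous clinical cohorts
    ratio_jitter_sigma: float = 0.35
    #: Dirichlet concentration of the per-subject band-profile jitter
    profile_concentration: float = 60.0
    #: per-class fractional peak position within each band (oscillatory
    #: slowing), its per-subject jitter, and the peak FWHM as a fraction of
    #: the band width
    peak_position: Dict[str, float] = field(
        default_factory=lambda: dict(_DEF_PEAK_POSITION))
    peak_position_jitter: float = 0.10
    peak_rel_bandwidth: float = 0.25
    posterior_alpha_weight: float = 1.5
    scale_uv: float = 20.0
    channels: Sequence[str] = field(default_factory=lambda: tuple(CHANNELS_17))
    bands: Sequence[BandDefinition] = field(default_factory=lambda: list(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        for cls, prof in self.band_profiles.items():
            if abs(sum(prof) - 1.0) > 1e-8:
                raise ValueError(f"band-power fractions for {cls} must sum to 1")
        r = self.complexity_ratio
        if not (r["coma"] < r["UWS"] < r["MCS"]):
            raise ValueError("complexity ratio must increase coma < UWS < MCS")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance noise with ~1/f power spectrum (f^-1 slope)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                      center_hz: float, fwhm_hz: float) -> np.ndarray:
    """Unit-variance noise with a Gaussian spectral peak at ``center_hz``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    sigma = fwhm_hz / 2.355
    spec *= np.exp(-0.5 * ((f - center_hz) / sigma) ** 2)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _blend(class_value, mean_value, effect_size):
    return mean_value + effect_size * (np.asarray(class_value) - np.asarray(mean_value))


def _make_subject(rng: np.random.Generator, spec: CohortSpec, label: str,
                  subject_id: str, mean_profile: np.ndarray,
                  mean_ratio: float, mean_peak: float) -> Recording:
    n = int(round(spec.fs * spec.duration_s))
    n_ch = len(spec.channels)
    e = spec.effect_size

    profile = np.clip(_blend(spec.band_profiles[label], mean_profile, e), 0.0, None)
    profile = profile / profile.sum()
    ratio = max(0.05, float(_blend(spec.complexity_ratio[label], mean_ratio, e)))
    peak_q = float(_blend(spec.peak_position[label], mean_peak, e))
    # inter-subject variability: resample the band profile around the class
    # profile, jitter the complexity ratio on the log scale, and jitter the
    # subject's overall peak position (coherent across bands)
    if spec.profile_concentration > 0:
        profile = rng.dirichlet(np.maximum(profile, 1e-3) * spec.profile_concentration)
    if spec.ratio_jitter_sigma > 0:
        ratio *= rng.lognormal(0.0, spec.ratio_jitter_sigma)
    peak_q = float(np.clip(peak_q + rng.normal(0.0, spec.peak_position_jitter),
                           0.05, 0.95))

    amp = rng.lognormal(mean=0.0, sigma=spec.amplitude_jitter_sigma)
    data = np.empty((n_ch, n))
    alpha_idx = [i for i, b in enumerate(spec.bands) if b.name == "alpha"]
    for ch_i, ch in enumerate(spec.channels):
        sig = np.sqrt(spec.pink_power) * _pink_noise(rng, n)
        for b_i, b in enumerate(spec.bands):
            width = b.high_hz - b.low_hz
            q = float(np.clip(peak_q + rng.normal(0.0, 0.05), 0.05, 0.95))
            fc = b.low_hz + q * width
            carrier = _narrowband_noise(rng, n, spec.fs, fc,
                                        spec.peak_rel_bandwidth * width)
            w = np.sqrt(profile[b_i])
            if b_i in alpha_idx and ch in POSTERIOR:
                w *= spec.posterior_alpha_weight
            sig += w * carrier
        sig += np.sqrt(ratio) * rng.standard_normal(n)
        data[ch_i] = amp * sig

    if spec.artifact_rate > 0:
        _add_blinks(rng, data, spec)

    data *= spec.scale_uv
    lo, hi = spec.crsr_range[label]
    crs_r = int(rng.integers(lo, hi + 1))
    lo, hi = spec.gcs_range[label]
    gcs = int(rng.integers(lo, hi + 1))
    return Recording(data=data, fs=spec.fs, channel_names=list(spec.channels),
                     subject_id=subject_id, label=label, crs_r=crs_r, gcs=gcs)


def _add_blinks(rng: np.random.Generator, data: np.ndarray, spec: CohortSpec) -> None:
    """Frontal-weighted low-frequency (<= 4 Hz) transients, in place."""
    n = data.shape[1]
    n_blinks = rng.poisson(spec.artifact_rate * spec.duration_s / 60.0)
    width = int(0.2 * spec.fs)
    t = np.arange(-3 * width, 3 * width + 1)
    shape = np.exp(-0.5 * (t / width) ** 2)  # ~0.8 Hz-wide Gaussian bump
    weights = np.array([1.0 if ch in FRONTAL else
                        0.3 if ch.startswith("C") else 0.1
                        for ch in spec.channels])
    for _ in range(n_blinks):
        center = int(rng.integers(3 * width, max(3 * width + 1, n - 3 * width)))
        amp = rng.uniform(5.0, 10.0)
        lo = center - 3 * width
        hi = lo + shape.size
        if hi > n:
            continue
        data[:, lo:hi] += amp * np.outer(weights, shape)


def generate_cohort(spec: Optional[CohortSpec] = None) -> List[Recording]:
    """Generate ``3 * n_per_class`` labeled recordings, fully seeded.

    Subjects are ordered coma, UWS, MCS; per-subject randomness is drawn
    from independent streams spawned from ``spec.seed`` so the cohort is
    bit-reproducible.
    """
    if spec is None:
        spec = CohortSpec()
    mean_profile = np.mean([spec.band_profiles[c] for c in CLASS_LABELS], axis=0)
    mean_ratio = float(np.mean([spec.complexity_ratio[c] for c in CLASS_LABELS]))
    mean_peak = float(np.mean([spec.peak_position[c] for c in CLASS_LABELS]))
    children = np.random.SeedSequence(spec.seed).spawn(3 * spec.n_per_class)
    cohort: List[Recording] = []
    i = 0
    for label in CLASS_LABELS:
        for k in range(spec.n_per_class):
            rng = np.random.default_rng(children[i])
            cohort.append(_make_subject(rng, spec, label, f"{label}{k + 1:02d}",
                                        mean_profile, mean_ratio, mean_peak))
            i += 1
    return cohort


def generate_tone_mixture(freqs_hz: Sequence[float], amps: Sequence[float],
                          fs: float = 256.0, duration_s: float = 4.0,
                          noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Sum of cosines with seeded random phases plus Gaussian noise.

    Solver test fixture: x(t) = sum_i a_i cos(2 pi f_i t + phi_i) + noise.
    """
    freqs = np.asarray(freqs_hz, dtype=float)
    amps = np.asarray(amps, dtype=float)
    if freqs.shape != amps.shape:
        raise ValueError("freqs and amps must have the same length")
    if np.any(freqs >= fs / 2):
        bad = freqs[freqs >= fs / 2]
        raise ValueError(f"frequencies at or above Nyquist ({fs / 2} Hz): {bad}")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(fs * duration_s))) / fs
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    x = np.zeros_like(t)
    for f, a, ph in zip(freqs, amps, phases):
        x += a * np.cos(2 * np.pi * f * t + ph)
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(t.size)
    return x
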