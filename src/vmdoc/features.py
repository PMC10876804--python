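"""Statistical features of EEG components and feature-table assembly.

Four features are computed per signal component: normalized spectral
entropy, sample entropy, skewness and (non-excess) kurtosis.  A component is
either a raw channel, one of the five frequency bands of a channel, or one
of the K VMD modes of a channel, giving per-subject feature vectors of
length 17*4 = 68 (raw), 17*5*4 = 340 (bands) and 17*5*4 = 340 (VMD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import welch
from scipy.stats import kurtosis as _scipy_kurtosis
from scipy.stats import skew as _scipy_skew

from .preprocess import (DEFAULT_BANDS, BandDefinition, Recording,
                         extract_bands)
from .vmd import VMDConfig, decompose

__all__ = [
    "FeatureSpec",
    "FeatureTable",
    "spectral_entropy",
    "sample_entropy",
    "skewness",
    "kurtosis",
    "extract_features",
    "FEATURE_NAMES",
    "APPROACHES",
]

FEATURE_NAMES = ("specent", "sampen", "skewness", "kurtosis")
APPROACHES = ("raw", "bands", "vmd")


@dataclass
class FeatureSpec:
    """Feature-computation parameters.

    ``sampen_m``/``sampen_r_factor`` are the sample-entropy embedding length
    and tolerance (as a fraction of the component's standard deviation);
    m = 2, r = 0.2 sigma is the field convention.  Spectral entropy uses a
    Welch periodogram with ``specent_nperseg``-sample segments and is
    normalized by the log of the number of frequency bins so it lies in
    [0, 1].  ``analysis_window_s`` selects the leading analysis segment of
    each (preprocessed) recording on which features are computed.
    """

    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    specent_nperseg: int = 512
    specent_normalized: bool = True
    specent_window: str = "hann"
    log_base: str = "e"
    analysis_window_s: float = 10.0

    def __post_init__(self) -> None:
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        if self.sampen_r_factor <= 0:
            raise ValueError("sampen_r_factor must be > 0")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")


@dataclass
class FeatureTable:
    """Subjects x features matrix with class labels and behavioral scores."""

    values: np.ndarray
    feature_names: List[str]
    labels: List[str]
    subject_ids: List[str]
    crs_r: Optional[np.ndarray] = None
    gcs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("values shape does not match names/subjects")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_classes(self, classes: Sequence[str]) -> "FeatureTable":
        keep = [i for i, lab in enumerate(self.labels) if lab in classes]
        return FeatureTable(
            values=self.values[keep],
            feature_names=list(self.feature_names),
            labels=[self.labels[i] for i in keep],
            subject_ids=[self.subject_ids[i] for i in keep],
            crs_r=None if self.crs_r is None else self.crs_r[keep],
            gcs=None if self.gcs is None else self.gcs[keep],
        )

    def select_columns(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            values=self.values[:, mask],
            feature_names=[n for n, m in zip(self.feature_names, mask) if m],
            labels=list(self.labels),
            subject_ids=list(self.subject_ids),
            crs_r=self.crs_r,
            gcs=self.gcs,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        df.insert(2, "crs_r", self.crs_r if self.crs_r is not None else np.nan)
        df.insert(3, "gcs", self.gcs if self.gcs is not None else np.nan)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        meta = ["subject_id", "label", "crs_r", "gcs"]
        feats = [c for c in df.columns if c not in meta]
        return cls(
            values=df[feats].to_numpy(float),
            feature_names=feats,
            labels=df["label"].astype(str).tolist(),
            subject_ids=df["subject_id"].astype(str).tolist(),
            crs_r=df["crs_r"].to_numpy(float) if "crs_r" in df else None,
            gcs=df["gcs"].to_numpy(float) if "gcs" in df else None,
        )


def spectral_entropy(signal: Sequence[float], spec: Optional[FeatureSpec] = None) -> float:
    """Shannon entropy of the normalized Welch power spectrum.

    The power spectral estimate is normalized to a probability distribution
    over frequency bins; zero-power bins contribute nothing.  With
    ``specent_normalized`` the entropy is divided by log(#bins) so the value
    lies in [0, 1] (1 = flat/white spectrum).  A signal with no spectral
    power (constant input) returns 0 by convention.
    """
    if spec is None:
        spec = FeatureSpec()
    x = np.asarray(signal, dtype=float)
    nperseg = min(spec.specent_nperseg, x.shape[0])
    _, psd = welch(x, nperseg=nperseg, window=spec.specent_window)
    total = psd.sum()
    if total <= 0:
        return 0.0
    p = psd / total
    p = p[p > 0]
    log = np.log2 if spec.log_base == "2" else np.log
    h = float(-(p * log(p)).sum())
    if spec.specent_normalized:
        h /= float(log(psd.shape[0]))
    return h


@njit(cache=True)
def _sampen_match_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover - jitted
    """Counts of template pairs (i < j) within Chebyshev tolerance r at
    lengths m (b) and m+1 (a), over the N-m templates starting at 0..N-m-1."""
    n = x.shape[0]
    nt = n - m
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            ok = True
            for d in range(m):
                if abs(x[i + d] - x[j + d]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(signal: Sequence[float], spec: Optional[FeatureSpec] = None,
                   r: Optional[float] = None) -> float:
    """Sample entropy SampEn(m, r, N) with self-matches included.

    -ln(A/B), where B counts template pairs of length m within Chebyshev
    distance r and A the pairs still matching at length m+1; both counts run
    over the N-m templates and include self-pairs.  By default
    r = ``sampen_r_factor`` x std(signal); an absolute tolerance can be
    passed directly via ``r``.  Returns ``nan`` if B = 0 and ``inf`` if
    A = 0 (unreachable when self-matches are included).
    """
    if spec is None:
        spec = FeatureSpec()
    x = np.ascontiguousarray(signal, dtype=float)
    m = spec.sampen_m
    n = x.shape[0]
    if n <= m + 1:
        raise ValueError(f"signal length {n} too short for m={m}")
    if r is None:
        sd = float(x.std())
        if sd == 0:
            return 0.0  # constant signal: every template matches
        r = spec.sampen_r_factor * sd
    a, b = _sampen_match_counts(x, m, float(r))
    nt = n - m
    a_tot = 2 * a + nt  # unordered pairs counted both ways + self-matches
    b_tot = 2 * b + nt
    if b_tot == 0:
        return float("nan")
    if a_tot == 0:
        return float("inf")
    return float(-math.log(a_tot / b_tot))


def skewness(signal: Sequence[float]) -> float:
    """Population-moment skewness E[(x-mu)^3]/sigma^3 (0 for constant input)."""
    x = np.asarray(signal, dtype=float)
    if x.std() == 0:
        return 0.0
    return float(_scipy_skew(x, bias=True))


def kurtosis(signal: Sequence[float]) -> float:
    """Non-excess (Pearson) kurtosis E[(x-mu)^4]/E[(x-mu)^2]^2.

    3 for a Gaussian; ``nan`` sentinel for a constant signal (excluded
    downstream).
    """
    x = np.asarray(signal, dtype=float)
    if x.std() == 0:
        return float("nan")
    return float(_scipy_kurtosis(x, fisher=False, bias=True))


def _component_features(x: np.ndarray, spec: FeatureSpec) -> List[float]:
    return [spectral_entropy(x, spec), sample_entropy(x, spec),
            skewness(x), kurtosis(x)]


def _analysis_segment(rec: Recording, spec: FeatureSpec) -> np.ndarray:
    n = min(rec.n_samples, int(round(spec.analysis_window_s * rec.fs)))
    return rec.data[:, :n]


def extract_features(cohort: Sequence[Recording],
                     approach: str = "vmd",
                     spec: Optional[FeatureSpec] = None,
                     vmd_config: Optional[VMDConfig] = None,
                     bands: Optional[Sequence[BandDefinition]] = None) -> FeatureTable:
    """Assemble the subjects x features table for one signal representation.

    ``approach``:

    - ``"raw"``   - 4 features per channel (68 columns for 17 channels);
    - ``"bands"`` - 4 features per channel per frequency band (340 columns);
    - ``"vmd"``   - 4 features per channel per VMD mode, modes indexed by
      ascending center frequency (340 columns for K = 5).

    Features are computed on the leading ``analysis_window_s`` seconds of
    each recording.  Column names follow ``approach/channel/component/feature``.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    if spec is None:
        spec = FeatureSpec()
    if vmd_config is None:
        vmd_config = VMDConfig()
    if bands is None:
        bands = DEFAULT_BANDS
    if not cohort:
        raise ValueError("empty cohort")
    ch0 = cohort[0].channel_names
    fs0 = cohort[0].fs
    for rec in cohort:
        if rec.channel_names != ch0 or rec.fs != fs0:
            raise ValueError("all recordings must share channel set and sampling rate")

    names: List[str] = []
    rows: List[List[float]] = []
    for rec in cohort:
        row: List[float] = []
        if approach == "bands":
            # filter the full recording, then crop, to avoid short-segment
            # transients of the long low-edge filters
            band_recs = extract_bands(rec, bands)
            for ch_i, ch in enumerate(ch0):
                for b in bands:
                    seg = _analysis_segment(band_recs[b.name], spec)[ch_i]
                    row.extend(_component_features(seg, spec))
        else:
            seg = _analysis_segment(rec, spec)
            for ch_i, ch in enumerate(ch0):
                if approach == "raw":
                    row.extend(_component_features(seg[ch_i], spec))
                else:  # vmd
                    ms = decompose(seg[ch_i], vmd_config)
                    for mode in ms.modes:
                        row.extend(_component_features(mode, spec))
        rows.append(row)

    if approach == "raw":
        names = [f"raw/{ch}/raw/{f}" for ch in ch0 for f in FEATURE_NAMES]
    elif approach == "bands":
        names = [f"bands/{ch}/{b.name}/{f}" for ch in ch0 for b in bands
                 for f in FEATURE_NAMES]
    else:
        names = [f"vmd/{ch}/mode{k + 1}/{f}" for ch in ch0
                 for k in range(vmd_config.n_modes) for f in FEATURE_NAMES]

    return FeatureTable(
        values=np.asarray(rows, dtype=float),
        feature_names=names,
        labels=[rec.label or "" for rec in cohort],
        subject_ids=[rec.subject_id for rec in cohort],
        crs_r=np.array([np.nan if rec.crs_r is None else rec.crs_r for rec in cohort]),
        gcs=np.array([np.nan if rec.gcs is None else rec.gcs for rec in cohort]),
    )
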