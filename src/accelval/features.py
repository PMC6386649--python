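"""Windowed time- and frequency-domain features of triaxial acceleration.

Each fixed-length, non-overlapping window is summarised by 15 features
computed from the vector-magnitude (VM) series and the raw axes:

==========  ==============================================================
mvm         mean VM in the window (g)
sdvm        sample SD of VM (g)
p625        fraction of VM spectral modulus mass in 0.6-2.5 Hz, the
            typical human locomotion band
df          dominant frequency: frequency of the largest VM modulus (Hz)
fpdf        modulus at df divided by the total modulus
mean_angle  mean of arcsin(x / VM) per sample (rad) — inclination of the
            acceleration vector relative to the device's vertical (x) axis
sd_angle    sample SD of those angles (rad)
covariance  sample variance of VM (g²) — covariance of VM with itself
skewness    standardized third moment of VM
kurtosis    standardized fourth moment of VM (non-excess: normal → 3)
entropy     Shannon entropy (bits) of the normalized VM modulus spectrum
cv          100 × sdvm / mvm (percent)
corr_xy,
corr_yz,
corr_xz     pairwise Pearson correlations between raw axes
==========  ==============================================================

Spectral features use the one-sided discrete Fourier moduli of the
mean-removed, Hann-tapered VM series with the DC bin excluded (the taper
keeps off-bin tones from leaking modulus mass across the whole band);
dominant-frequency ties break to the lowest frequency. Zero-variance axes contribute correlation
0 rather than an error so sedentary windows remain featurizable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .signal_io import AccelRecording

FEATURE_NAMES = (
    "mvm",
    "sdvm",
    "p625",
    "df",
    "fpdf",
    "mean_angle",
    "sd_angle",
    "covariance",
    "skewness",
    "kurtosis",
    "entropy",
    "cv",
    "corr_xy",
    "corr_yz",
    "corr_xz",
)

DEFAULT_WINDOW_LENGTHS = (1.0, 2.0, 4.0, 8.0, 15.0, 16.0)

LOCOMOTION_BAND = (0.6, 2.5)


@dataclass(frozen=True)
class WindowSpec:
    """Non-overlapping window specification (length in seconds)."""

    length: float = 16.0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("window length must be > 0")

    def n_samples(self, sampling_rate: float) -> int:
        n = int(round(self.length * sampling_rate))
        if n < 4:
            raise ValueError(
                f"window of {self.length} s at {sampling_rate} Hz has {n} < 4 samples"
            )
        return n


@dataclass
class Window:
    """One window of raw samples plus its source metadata."""

    samples: np.ndarray  # (m, 3)
    sampling_rate: float
    window_index: int
    device_id: str
    start_time: float


@dataclass
class FeatureWindow:
    """The 15 features of one window plus identifying metadata."""

    participant_id: str
    activity_name: str
    device_id: str
    window_index: int
    mvm: float
    sdvm: float
    p625: float
    df: float
    fpdf: float
    mean_angle: float
    sd_angle: float
    covariance: float
    skewness: float
    kurtosis: float
    entropy: float
    cv: float
    corr_xy: float
    corr_yz: float
    corr_xz: float

    def values(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)


def vector_magnitude(x, y, z):
    """Euclidean norm sqrt(x² + y² + z²) of a triaxial sample."""
    return np.sqrt(np.asarray(x) ** 2 + np.asarray(y) ** 2 + np.asarray(z) ** 2)


def segment_windows(rec: AccelRecording, spec: WindowSpec) -> list[Window]:
    """Cut a recording into consecutive non-overlapping windows.

    The trailing remainder is dropped. A recording shorter than one window
    yields an empty list with a warning (not an error).
    """
    m = spec.n_samples(rec.sampling_rate)
    n_win = rec.n_samples // m
    if n_win == 0:
        warnings.warn(
            f"recording of {rec.duration:.3g} s is shorter than the "
            f"{spec.length} s window; no windows produced",
            stacklevel=2,
        )
        return []
    return [
        Window(
            samples=rec.samples[i * m : (i + 1) * m],
            sampling_rate=rec.sampling_rate,
            window_index=i,
            device_id=rec.device_id,
            start_time=rec.start_time + i * m / rec.sampling_rate,
        )
        for i in range(n_win)
    ]


def _hann(m: int) -> np.ndarray:
    # periodic Hann taper; controls leakage of off-bin tones, whose
    # rectangular-window modulus tails would otherwise dominate L1 band
    # fractions
    return 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(m) / m)


def vm_spectrum(vm: Sequence[float], sampling_rate: float):
    """One-sided DFT moduli of the mean-removed, Hann-tapered VM series.

    The DC bin is excluded. Returns (frequencies in Hz up to Nyquist,
    moduli). An all-constant series yields all-zero moduli, which is
    valid output.
    """
    vm = np.asarray(vm, dtype=float)
    if len(vm) < 4:
        raise ValueError("spectrum needs >= 4 samples")
    mod = np.abs(np.fft.rfft((vm - vm.mean()) * _hann(len(vm))))[1:]
    freqs = np.fft.rfftfreq(len(vm), d=1.0 / sampling_rate)[1:]
    return freqs, mod


def power_fraction_band(freqs, moduli, low: float = LOCOMOTION_BAND[0], high: float = LOCOMOTION_BAND[1]) -> float:
    """Fraction of total spectral modulus mass with frequency in [low, high]."""
    moduli = np.asarray(moduli, dtype=float)
    total = moduli.sum()
    if total == 0:
        return 0.0
    in_band = (freqs >= low) & (freqs <= high)
    return float(moduli[in_band].sum() / total)


def dominant_frequency(freqs, moduli) -> tuple[float, float]:
    """(dominant frequency, fraction of modulus mass at it).

    Ties break to the lowest frequency; an all-zero spectrum returns (0, 0).
    """
    moduli = np.asarray(moduli, dtype=float)
    total = moduli.sum()
    if total == 0:
        return 0.0, 0.0
    k = int(np.argmax(moduli))  # argmax returns the first (lowest-frequency) maximum
    return float(freqs[k]), float(moduli[k] / total)


def angle_stats(samples: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD of the per-sample inclination angle.

    angle = arcsin(clamp(x / VM, -1, 1)); samples with VM = 0 are excluded.
    """
    samples = np.asarray(samples, dtype=float)
    vm = np.linalg.norm(samples, axis=1)
    ok = vm > 0
    if ok.sum() < 2:
        raise UndefinedStatisticError("angle undefined: fewer than 2 samples with VM > 0")
    ang = np.arcsin(np.clip(samples[ok, 0] / vm[ok], -1.0, 1.0))
    return float(ang.mean()), float(ang.std(ddof=1))


def _moments(vm: np.ndarray) -> tuple[float, float]:
    """(skewness, non-excess kurtosis) with the zero-variance convention 0."""
    m = vm.mean()
    d = vm - m
    m2 = np.mean(d**2)
    if m2 == 0:
        return 0.0, 0.0
    return float(np.mean(d**3) / m2**1.5), float(np.mean(d**4) / m2**2)


def _spectral_entropy(moduli: np.ndarray) -> float:
    total = moduli.sum()
    if total == 0:
        return 0.0
    p = moduli[moduli > 0] / total
    return float(-(p * np.log2(p)).sum())


def distribution_stats(vm: Sequence[float]):
    """Distributional VM features: (mvm, sdvm, covariance, skewness, kurtosis, entropy, cv).

    covariance is the sample variance of VM (covariance of VM with itself);
    entropy is the spectral entropy of the normalized VM modulus spectrum.
    """
    vm = np.asarray(vm, dtype=float)
    if len(vm) < 4:
        raise ValueError("need >= 4 samples")
    mvm = float(vm.mean())
    sdvm = float(vm.std(ddof=1))
    covariance = sdvm**2
    skewness, kurtosis = _moments(vm)
    # entropy is spectral, so the sampling rate is irrelevant (only moduli matter)
    _, mod = vm_spectrum(vm, sampling_rate=1.0)
    entropy = _spectral_entropy(mod)
    cv = 100.0 * sdvm / mvm if mvm != 0 else 0.0
    return mvm, sdvm, covariance, skewness, kurtosis, entropy, cv


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def axis_correlations(samples: np.ndarray) -> tuple[float, float, float]:
    """(corr_xy, corr_yz, corr_xz); a zero-variance axis contributes 0."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    x, y, z = samples[:, 0], samples[:, 1], samples[:, 2]
    return _safe_corr(x, y), _safe_corr(y, z), _safe_corr(x, z)


def extract_features(
    window: Window,
    participant_id: str = "",
    activity_name: str = "",
) -> FeatureWindow:
    """Compute all 15 features of one window (reference scalar path)."""
    s = window.samples
    vm = np.linalg.norm(s, axis=1)
    mvm, sdvm, covariance, skewness, kurtosis, entropy, cv = distribution_stats(vm)
    freqs, mod = vm_spectrum(vm, window.sampling_rate)
    p625 = power_fraction_band(freqs, mod)
    df, fpdf = dominant_frequency(freqs, mod)
    mean_angle, sd_angle = angle_stats(s)
    corr_xy, corr_yz, corr_xz = axis_correlations(s)
    return FeatureWindow(
        participant_id=participant_id,
        activity_name=activity_name,
        device_id=window.device_id,
        window_index=window.window_index,
        mvm=mvm,
        sdvm=sdvm,
        p625=p625,
        df=df,
        fpdf=fpdf,
        mean_angle=mean_angle,
        sd_angle=sd_angle,
        covariance=covariance,
        skewness=skewness,
        kurtosis=kurtosis,
        entropy=entropy,
        cv=cv,
        corr_xy=corr_xy,
        corr_yz=corr_yz,
        corr_xz=corr_xz,
    )


def _batch_features(windows: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Vectorized feature computation for a (n_windows, m, 3) sample stack."""
    x, y, z = windows[..., 0], windows[..., 1], windows[..., 2]
    vm = np.sqrt(x**2 + y**2 + z**2)  # (n, m)
    n, m = vm.shape

    mvm = vm.mean(axis=1)
    sdvm = vm.std(axis=1, ddof=1)
    covariance = sdvm**2
    d = vm - mvm[:, None]
    m2 = np.mean(d**2, axis=1)
    safe_m2 = np.where(m2 > 0, m2, 1.0)
    skewness = np.where(m2 > 0, np.mean(d**3, axis=1) / safe_m2**1.5, 0.0)
    kurtosis = np.where(m2 > 0, np.mean(d**4, axis=1) / safe_m2**2, 0.0)
    cv = np.where(mvm != 0, 100.0 * sdvm / np.where(mvm != 0, mvm, 1.0), 0.0)

    mod = np.abs(np.fft.rfft(d * _hann(m), axis=1))[:, 1:]
    freqs = np.fft.rfftfreq(m, d=1.0 / sampling_rate)[1:]
    total = mod.sum(axis=1)
    safe_total = np.where(total > 0, total, 1.0)
    in_band = (freqs >= LOCOMOTION_BAND[0]) & (freqs <= LOCOMOTION_BAND[1])
    p625 = np.where(total > 0, mod[:, in_band].sum(axis=1) / safe_total, 0.0)
    k = np.argmax(mod, axis=1)
    df = np.where(total > 0, freqs[k], 0.0)
    fpdf = np.where(total > 0, mod[np.arange(n), k] / safe_total, 0.0)
    p = mod / safe_total[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = np.where(total > 0, -plogp.sum(axis=1), 0.0)

    ok = vm > 0
    if np.any(ok.sum(axis=1) < 2):
        raise UndefinedStatisticError("a window has fewer than 2 samples with VM > 0")
    ang = np.arcsin(np.clip(np.where(ok, x / np.where(ok, vm, 1.0), np.nan), -1.0, 1.0))
    mean_angle = np.nanmean(ang, axis=1)
    # sample SD over the included angles only
    cnt = ok.sum(axis=1)
    dev = np.where(ok, ang - mean_angle[:, None], 0.0)
    sd_angle = np.sqrt(np.nansum(dev**2, axis=1) / (cnt - 1))

    def corr(a, b):
        da = a - a.mean(axis=1, keepdims=True)
        db = b - b.mean(axis=1, keepdims=True)
        sa = a.std(axis=1)
        sb = b.std(axis=1)
        good = (sa > 0) & (sb > 0)
        denom = np.where(good, sa * sb, 1.0)
        return np.where(good, np.mean(da * db, axis=1) / denom, 0.0)

    out = np.column_stack(
        [
            mvm,
            sdvm,
            p625,
            df,
            fpdf,
            mean_angle,
            sd_angle,
            covariance,
            skewness,
            kurtosis,
            entropy,
            cv,
            corr(x, y),
            corr(y, z),
            corr(x, z),
        ]
    )
    return out


def featurize(
    rec: AccelRecording,
    spec: WindowSpec,
    participant_id: str = "",
    activity_name: str = "",
) -> pd.DataFrame:
    """Segment a recording and compute the 15 features of every window.

    Returns a DataFrame with metadata columns (participant, activity,
    device, window_index) followed by the 15 feature columns. Agrees
    exactly with per-window :func:`extract_features`.
    """
    m = spec.n_samples(rec.sampling_rate)
    n_win = rec.n_samples // m
    if n_win == 0:
        warnings.warn(
            f"recording of {rec.duration:.3g} s is shorter than the "
            f"{spec.length} s window; empty feature table",
            stacklevel=2,
        )
        return pd.DataFrame(
            columns=["participant", "activity", "device", "window_index", *FEATURE_NAMES]
        )
    stack = rec.samples[: n_win * m].reshape(n_win, m, 3)
    feats = _batch_features(stack, rec.sampling_rate)
    df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
    df.insert(0, "window_index", np.arange(n_win))
    df.insert(0, "device", rec.device_id)
    df.insert(0, "activity", activity_name)
    df.insert(0, "participant", participant_id)
    return df
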