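"""Independent brute-force oracles for the windowed features.

These deliberately avoid the package's implementation paths: the DFT is a
direct O(n²) summation, moments are written out termwise, and Pearson
correlation uses the raw definition. They exist only to cross-check
``accelval.features``.
"""

import math

import numpy as np


def naive_dft_moduli(series):
    """Direct-summation DFT moduli of the mean-removed, Hann-tapered series.

    Returns (freq_indices k = 1..n//2 as cycles-per-window, moduli),
    mirroring the one-sided, DC-excluded layout of ``vm_spectrum``.
    """
    x = [float(v) for v in series]
    n = len(x)
    mean = sum(x) / n
    taper = [0.5 - 0.5 * math.cos(2 * math.pi * i / n) for i in range(n)]
    d = [(v - mean) * w for v, w in zip(x, taper)]
    ks = list(range(1, n // 2 + 1))
    moduli = []
    for k in ks:
        re = sum(d[i] * math.cos(-2 * math.pi * k * i / n) for i in range(n))
        im = sum(d[i] * math.sin(-2 * math.pi * k * i / n) for i in range(n))
        moduli.append(math.hypot(re, im))
    return ks, moduli


def naive_features(samples, sampling_rate):
    """All 15 features from first principles; samples is (m, 3)."""
    samples = np.asarray(samples, dtype=float)
    m = len(samples)
    vm = [math.sqrt(x * x + y * y + z * z) for x, y, z in samples]

    mvm = sum(vm) / m
    var1 = sum((v - mvm) ** 2 for v in vm) / (m - 1)
    sdvm = math.sqrt(var1)
    covariance = var1
    m2 = sum((v - mvm) ** 2 for v in vm) / m
    if m2 == 0:
        skewness = kurtosis = 0.0
    else:
        skewness = (sum((v - mvm) ** 3 for v in vm) / m) / m2**1.5
        kurtosis = (sum((v - mvm) ** 4 for v in vm) / m) / m2**2
    cv = 100.0 * sdvm / mvm if mvm != 0 else 0.0

    ks, mod = naive_dft_moduli(vm)
    freqs = [k * sampling_rate / m for k in ks]
    total = sum(mod)
    if total == 0:
        p625, df, fpdf, entropy = 0.0, 0.0, 0.0, 0.0
    else:
        p625 = sum(v for f, v in zip(freqs, mod) if 0.6 <= f <= 2.5) / total
        best = max(range(len(mod)), key=lambda i: (mod[i], -freqs[i]))
        df, fpdf = freqs[best], mod[best] / total
        entropy = -sum(
            (v / total) * math.log2(v / total) for v in mod if v > 0
        )

    angles = [
        math.asin(max(-1.0, min(1.0, s[0] / v)))
        for s, v in zip(samples, vm)
        if v > 0
    ]
    mean_angle = sum(angles) / len(angles)
    sd_angle = math.sqrt(
        sum((a - mean_angle) ** 2 for a in angles) / (len(angles) - 1)
    )

    def pearson(a, b):
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        sa = math.sqrt(sum((v - ma) ** 2 for v in a))
        sb = math.sqrt(sum((v - mb) ** 2 for v in b))
        if sa == 0 or sb == 0:
            return 0.0
        return sum((u - ma) * (v - mb) for u, v in zip(a, b)) / (sa * sb)

    x, y, z = samples[:, 0], samples[:, 1], samples[:, 2]
    return {
        "mvm": mvm,
        "sdvm": sdvm,
        "p625": p625,
        "df": df,
        "fpdf": fpdf,
        "mean_angle": mean_angle,
        "sd_angle": sd_angle,
        "covariance": covariance,
        "skewness": skewness,
        "kurtosis": kurtosis,
        "entropy": entropy,
        "cv": cv,
        "corr_xy": pearson(x, y),
        "corr_yz": pearson(y, z),
        "corr_xz": pearson(x, z),
    }
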