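"""The 45-feature registry computed on each accepted 2 s epoch.

Four groups:

* time-domain statistics (7): mean, SD, RMS, skewness, kurtosis, IQR,
  Shannon entropy of the 100-bin amplitude histogram;
* envelope statistics (2): Nakagami shape and scale fitted by moment
  estimators to the Hilbert-envelope magnitudes;
* envelope-DCT features (24): the 20 largest-magnitude orthonormal
  DCT-II coefficients of the Hilbert envelope (signed, sorted by
  descending magnitude), the number of coefficients holding 98% of the
  energy, and the area, peak and total power of the DCT spectrum;
* wavelet subband powers (12): relative power of detail levels 1-6 of a
  6-level orthogonal decomposition, for Haar and Daubechies-10 mothers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy import fft as spfft
from scipy import signal as sps
from scipy import stats as spstats

from .preprocess import Epoch

N_DCT_COEFFS = 20
ENTROPY_BINS = 100
ENERGY_THRESHOLD_PCT = 98.0
WAVELET_LEVELS = 6
WAVELET_MOTHERS = {"haar": "haar", "db10": "db10"}

FEATURE_NAMES: tuple[str, ...] = (
    "M", "SD", "RMS", "Skew", "Kurt", "IQR", "E",
    "mu_nakagami", "omega_nakagami",
    *[f"E_DCT_l{i}" for i in range(1, N_DCT_COEFFS + 1)],
    "N_DCT", "AUC_DCT", "Peak_DCT", "P_DCT",
    *[f"E_Haar{j}" for j in range(1, WAVELET_LEVELS + 1)],
    *[f"E_Db10_{j}" for j in range(1, WAVELET_LEVELS + 1)],
)

METADATA_COLUMNS = ("particle_id", "class_label", "epoch_index")

#: Features invariant under positive rescaling of the epoch.
SCALE_INVARIANT = frozenset(
    {"Skew", "Kurt", "E", "mu_nakagami", "N_DCT"}
    | {f"E_Haar{j}" for j in range(1, 7)}
    | {f"E_Db10_{j}" for j in range(1, 7)}
)


def time_domain_stats(samples: np.ndarray) -> dict[str, float]:
    """Mean, SD, RMS, skewness, kurtosis (non-excess), IQR and entropy.

    SD uses the n-1 denominator; kurtosis is Pearson's (Gaussian -> 3);
    the IQR quantiles use linear interpolation; entropy is the Shannon
    entropy in bits of the 100 equal-width bins spanning [min, max],
    empty bins contributing zero.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 4:
        raise ValueError("epoch too short for time-domain statistics")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate epoch (SD == 0)")
    counts, _ = np.histogram(x, bins=ENTROPY_BINS)
    p = counts[counts > 0] / len(x)
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "M": float(x.mean()),
        "SD": float(sd),
        "RMS": float(np.sqrt(np.mean(x ** 2))),
        "Skew": float(spstats.skew(x, bias=False)),
        "Kurt": float(spstats.kurtosis(x, fisher=False, bias=False)),
        "IQR": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "E": entropy,
    }


def nakagami_fit(magnitudes: np.ndarray) -> tuple[float, float]:
    """Moment estimators of the Nakagami shape and scale.

    omega_hat = mean(x^2); mu_hat = omega_hat^2 / Var(x^2) (the
    inverse-normalized-variance estimator).  Population-moment (ddof=0)
    variance is used for moment consistency.
    """
    x = np.asarray(magnitudes, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 magnitudes for a Nakagami fit")
    if np.any(x <= 0):
        raise ValueError("Nakagami support is x > 0")
    x2 = x ** 2
    omega = float(x2.mean())
    var_x2 = float(x2.var())
    if var_x2 == 0:
        raise ValueError("degenerate fit: Var(x^2) == 0")
    return omega ** 2 / var_x2, omega


def hilbert_envelope(samples: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (same length, non-negative)."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    return np.abs(sps.hilbert(x))


def dct_sorted(envelope: np.ndarray) -> np.ndarray:
    """Orthonormal DCT-II coefficients sorted by descending magnitude.

    Signed values are retained; ties break by ascending original index
    (stable sort).
    """
    env = np.asarray(envelope, dtype=float)
    if len(env) < N_DCT_COEFFS:
        raise ValueError("envelope too short")
    coeffs = spfft.dct(env, type=2, norm="ortho")
    order = np.argsort(-np.abs(coeffs), kind="stable")
    return coeffs[order]


def energy_percentage(sorted_coeffs: np.ndarray, k: int) -> float:
    """Percentage of total energy held by the first k sorted coefficients.

    P(k) = 100 * ||(c_1..c_k)|| / ||(c_1..c_n)||; non-decreasing in k,
    P(n) = 100.
    """
    c = np.asarray(sorted_coeffs, dtype=float)
    if not 1 <= k <= len(c):
        raise ValueError("k out of range")
    total = np.linalg.norm(c)
    if total == 0:
        raise ValueError("all-zero coefficient vector")
    return float(100.0 * np.linalg.norm(c[:k]) / total)


def n_dct(sorted_coeffs: np.ndarray,
          threshold_pct: float = ENERGY_THRESHOLD_PCT) -> int:
    """Smallest k whose leading-coefficient energy reaches threshold_pct."""
    c = np.asarray(sorted_coeffs, dtype=float)
    total2 = float(np.sum(c ** 2))
    if total2 == 0:
        raise ValueError("all-zero coefficient vector")
    cum = np.sqrt(np.cumsum(c ** 2) / total2) * 100.0
    return int(np.searchsorted(cum, threshold_pct - 1e-12) + 1)


def dct_spectrum_summary(envelope: np.ndarray, fs: float,
                         ) -> tuple[float, float, float]:
    """Area under |DCT| vs frequency, peak magnitude and total power.

    Coefficient l maps to frequency l*fs/(2N), spanning the full band
    0..fs/2.  AUC is the trapezoidal integral of |coefficient| over
    frequency, Peak the maximum magnitude, P the sum of squared
    coefficients (Parseval energy of the envelope).
    """
    env = np.asarray(envelope, dtype=float)
    coeffs = spfft.dct(env, type=2, norm="ortho")
    n = len(coeffs)
    freqs = np.arange(n) * fs / (2 * n)
    auc = float(np.trapezoid(np.abs(coeffs), freqs))
    peak = float(np.max(np.abs(coeffs))) if n else 0.0
    power = float(np.sum(coeffs ** 2))
    return auc, peak, power


def wavelet_relative_power(samples: np.ndarray, mother: str,
                           via: str = "coeffs") -> np.ndarray:
    """Relative power of detail levels 1..6 of a 6-level orthogonal DWT.

    The epoch is truncated to the largest multiple of 2^6 samples so the
    periodization-mode transform is exactly orthogonal; then the
    detail-coefficient energy at each level equals the energy of the
    corresponding reconstructed subband signal (isometry), and details
    plus the final approximation partition the epoch energy exactly.

    ``via='reconstruction'`` computes each subband energy from the
    explicitly reconstructed signal instead (same values; used as an
    internal cross-check).
    """
    if mother not in WAVELET_MOTHERS:
        raise ValueError(f"unknown mother wavelet {mother!r}")
    wav = pywt.Wavelet(WAVELET_MOTHERS[mother])
    x = np.asarray(samples, dtype=float)
    block = 2 ** WAVELET_LEVELS
    if len(x) < block * wav.dec_len:
        raise ValueError("epoch too short for a 6-level decomposition")
    x = x[: (len(x) // block) * block]
    total = float(np.sum(x ** 2))
    if total == 0:
        return np.zeros(WAVELET_LEVELS)
    coeffs = pywt.wavedec(x, wav, mode="periodization", level=WAVELET_LEVELS)
    # coeffs = [a6, d6, d5, d4, d3, d2, d1]
    powers = np.empty(WAVELET_LEVELS)
    for level in range(1, WAVELET_LEVELS + 1):
        pos = WAVELET_LEVELS + 1 - level  # d_level position
        if via == "coeffs":
            energy = float(np.sum(coeffs[pos] ** 2))
        elif via == "reconstruction":
            parts = [np.zeros_like(c) for c in coeffs]
            parts[pos] = coeffs[pos]
            rec = pywt.waverec(parts, wav, mode="periodization")
            energy = float(np.sum(rec[: len(x)] ** 2))
        else:
            raise ValueError("via must be 'coeffs' or 'reconstruction'")
        powers[level - 1] = energy / total
    return powers


def featurize(epoch: Epoch) -> dict[str, float]:
    """Assemble the full 45-value feature vector for one accepted epoch.

    Time statistics and wavelet powers are computed on the (filtered)
    epoch samples; the Nakagami fit and all DCT features on the Hilbert
    envelope of the epoch.
    """
    x = epoch.samples
    values = time_domain_stats(x)

    env = hilbert_envelope(x)
    env_pos = env[env > 0]
    mu, omega = nakagami_fit(env_pos)
    values["mu_nakagami"] = mu
    values["omega_nakagami"] = omega

    coeffs = dct_sorted(env)
    for i in range(N_DCT_COEFFS):
        values[f"E_DCT_l{i + 1}"] = float(coeffs[i])
    values["N_DCT"] = float(n_dct(coeffs))
    auc, peak, power = dct_spectrum_summary(env, epoch.fs)
    values["AUC_DCT"] = auc
    values["Peak_DCT"] = peak
    values["P_DCT"] = power

    for mother, prefix in (("haar", "E_Haar"), ("db10", "E_Db10_")):
        powers = wavelet_relative_power(x, mother)
        for j in range(WAVELET_LEVELS):
            values[f"{prefix}{j + 1}"] = float(powers[j])

    assert set(values) == set(FEATURE_NAMES)
    return {name: values[name] for name in FEATURE_NAMES}


def featurize_epochs(epochs) -> pd.DataFrame:
    """Feature table over accepted epochs: metadata columns then the 45
    features in registry order."""
    rows = []
    for e in epochs:
        if not e.accepted:
            continue
        row = {"particle_id": e.particle_id, "class_label": e.class_label,
               "epoch_index": e.index}
        row.update(featurize(e))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(FEATURE_NAMES))


def particle_average(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the epoch-level table to one mean feature row per particle."""
    feature_cols = [c for c in table.columns if c in FEATURE_NAMES]
    grouped = (table.groupby(["particle_id", "class_label"], sort=True)[feature_cols]
               .mean().reset_index())
    return grouped[["particle_id", "class_label"] + feature_cols]
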