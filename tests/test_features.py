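"""The 45-feature registry: definitions, oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from scatterid import (FEATURE_NAMES, dct_sorted, dct_spectrum_summary,
                       energy_percentage, featurize, featurize_epochs,
                       hilbert_envelope, n_dct, nakagami_fit,
                       particle_average, time_domain_stats,
                       wavelet_relative_power)
from scatterid.features import SCALE_INVARIANT, WAVELET_LEVELS
from scatterid.preprocess import Epoch

FS = 5000.0


def make_epoch(samples, index=0, particle="p0", label="ps"):
    return Epoch(samples=np.asarray(samples, float), fs=FS,
                 particle_id=particle, class_label=label, index=index)


# ---------------------------------------------------------------- registry

def test_registry_has_45_features_partitioned_7_2_24_12():
    assert len(FEATURE_NAMES) == 45
    assert len(set(FEATURE_NAMES)) == 45
    time_stats = {"M", "SD", "RMS", "Skew", "Kurt", "IQR", "E"}
    histogram = {"mu_nakagami", "omega_nakagami"}
    dct = {n for n in FEATURE_NAMES if n.startswith("E_DCT_l")} \
        | {"N_DCT", "AUC_DCT", "Peak_DCT", "P_DCT"}
    wavelet = {n for n in FEATURE_NAMES
               if n.startswith(("E_Haar", "E_Db10_"))}
    assert len(time_stats) == 7 and len(histogram) == 2
    assert len(dct) == 24 and len(wavelet) == 12
    assert time_stats | histogram | dct | wavelet == set(FEATURE_NAMES)


# ---------------------------------------------------- time-domain statistics

def test_time_stats_hand_arithmetic():
    s = time_domain_stats(np.array([1.0, 2.0, 3.0, 4.0]))
    assert s["M"] == pytest.approx(2.5)
    assert s["SD"] == pytest.approx(1.2909944, abs=1e-6)
    assert s["RMS"] == pytest.approx(2.7386128, abs=1e-6)
    # linear-interpolation quantiles: q75 - q25 = 3.25 - 1.75
    assert s["IQR"] == pytest.approx(1.5)


def test_gaussian_sample_moments(rng):
    x = rng.normal(size=100_000)
    s = time_domain_stats(x)
    assert abs(s["Skew"]) < 0.05
    assert s["Kurt"] == pytest.approx(3.0, abs=0.1)


def test_entropy_of_nearly_constant_two_level_epoch():
    x = np.full(1000, 1.0)
    x[:10] = 2.0  # 99% of mass in one bin
    s = time_domain_stats(x)
    expected = -(0.99 * np.log2(0.99) + 0.01 * np.log2(0.01))
    assert s["E"] == pytest.approx(expected, abs=1e-9)
    assert s["E"] < 0.1


def test_degenerate_epoch_rejected():
    with pytest.raises(ValueError):
        time_domain_stats(np.ones(100))


# ----------------------------------------------------------- Nakagami fit

def test_nakagami_scale_is_mean_square():
    mu, omega = nakagami_fit(np.array([1.0] * 5 + [2.0] * 5))
    assert omega == pytest.approx(2.5)


@pytest.mark.parametrize("mu_true", [0.5, 1.0, 2.0, 5.0])
def test_nakagami_moment_estimator_recovery(mu_true):
    rng = np.random.default_rng(100 + int(10 * mu_true))
    x = spstats.nakagami.rvs(mu_true, scale=np.sqrt(2.0), size=100_000,
                             random_state=rng)
    mu_hat, omega_hat = nakagami_fit(x)
    assert abs(mu_hat - mu_true) / mu_true < 0.05
    assert omega_hat == pytest.approx(2.0, rel=0.03)


def test_nakagami_domain_errors():
    with pytest.raises(ValueError):
        nakagami_fit(np.linspace(-1, 1, 50))
    with pytest.raises(ValueError):
        nakagami_fit(np.ones(50))


# -------------------------------------------------------- Hilbert envelope

def test_envelope_of_pure_tone_is_amplitude():
    t = np.arange(10_000) / FS
    for a in (1.0, 3.5):
        env = hilbert_envelope(a * np.sin(2 * np.pi * 1000 * t))
        interior = env[500:-500]
        assert np.all(np.abs(interior - a) < 0.02 * a)


def test_envelope_tracks_am_modulation():
    t = np.arange(10_000) / FS
    mod = 1 + 0.5 * np.cos(2 * np.pi * 10 * t)
    env = hilbert_envelope(mod * np.sin(2 * np.pi * 1000 * t))
    err = env[500:-500] - mod[500:-500]
    assert np.sqrt(np.mean(err ** 2)) / np.mean(mod) < 0.03


# ------------------------------------------------------------ DCT features

def test_dct_of_constant_envelope():
    c = dct_sorted(np.full(100, 2.0))
    assert c[0] == pytest.approx(np.sqrt(100) * 2.0)
    assert np.max(np.abs(c[1:])) < 1e-12


def test_dct_parseval_and_sorted_magnitudes(rng):
    env = rng.random(512)
    c = dct_sorted(env)
    assert np.sum(c ** 2) == pytest.approx(np.sum(env ** 2), rel=1e-12)
    assert np.all(np.diff(np.abs(c)) <= 1e-15)


def test_basis_aligned_cosine_has_single_dominant_coefficient():
    n, l = 256, 7
    k = np.arange(n)
    env = np.cos(np.pi * l * (2 * k + 1) / (2 * n))
    c = dct_sorted(env)
    assert abs(c[0]) / np.linalg.norm(c) > 0.999


def test_energy_percentage_examples():
    assert energy_percentage(np.array([4.0, 3.0]), 1) == pytest.approx(80.0)
    assert energy_percentage(np.array([4.0, 3.0]), 2) == pytest.approx(100.0)
    assert energy_percentage(np.ones(4), 2) == pytest.approx(100 * np.sqrt(2) / 2)
    with pytest.raises(ValueError):
        energy_percentage(np.zeros(5), 1)


def test_n_dct_examples(rng):
    assert n_dct(np.array([5.0, 0.0, 0.0])) == 1
    assert n_dct(np.array([4.0, 3.0])) == 2
    flat = dct_sorted(rng.normal(size=1000))
    assert n_dct(flat) > 500  # flat spectra need most coefficients for 98%


def test_dct_spectrum_summary_homogeneity(rng):
    env = rng.random(1000)
    auc, peak, power = dct_spectrum_summary(env, FS)
    auc2, peak2, power2 = dct_spectrum_summary(2 * env, FS)
    assert auc2 == pytest.approx(2 * auc)
    assert peak2 == pytest.approx(2 * peak)
    assert power2 == pytest.approx(4 * power)
    assert dct_spectrum_summary(np.zeros(100), FS) == (0.0, 0.0, 0.0)


def test_dct_constant_envelope_summary():
    n, c = 400, 1.5
    _, peak, power = dct_spectrum_summary(np.full(n, c), FS)
    assert peak == pytest.approx(np.sqrt(n) * c)
    assert power == pytest.approx(n * c ** 2)


# -------------------------------------------------------- wavelet features

@pytest.mark.parametrize("mother", ["haar", "db10"])
def test_wavelet_energy_conservation(mother, rng):
    x = rng.normal(size=10_000)
    via_coeffs = wavelet_relative_power(x, mother)
    via_rec = wavelet_relative_power(x, mother, via="reconstruction")
    np.testing.assert_allclose(via_coeffs, via_rec, atol=1e-9)
    assert np.all(via_coeffs >= 0) and np.all(via_coeffs <= 1)
    assert via_coeffs.sum() <= 1 + 1e-9


def test_wavelet_details_plus_approximation_sum_to_one(rng):
    import pywt
    x = rng.normal(size=9984)  # multiple of 2^6: transform is orthogonal
    for mother in ("haar", "db10"):
        details = wavelet_relative_power(x, mother)
        coeffs = pywt.wavedec(x, mother, mode="periodization",
                              level=WAVELET_LEVELS)
        approx = np.sum(coeffs[0] ** 2) / np.sum(x ** 2)
        assert details.sum() + approx == pytest.approx(1.0, abs=1e-6)


def test_haar_level1_captures_nyquist_alternation():
    x = np.tile([1.0, -1.0], 5000)
    p = wavelet_relative_power(x, "haar")
    assert p[0] > 0.999
    assert np.all(p[1:] < 1e-9)


def test_slow_ramp_has_no_fine_scale_energy():
    x = np.linspace(0.0, 1.0, 10_000)
    p = wavelet_relative_power(x, "haar")
    assert p[0] < 1e-3
    assert p.sum() < 0.2  # energy sits in the deep approximation


def test_wavelet_too_short_epoch_rejected():
    with pytest.raises(ValueError):
        wavelet_relative_power(np.ones(100), "db10")
    with pytest.raises(ValueError):
        wavelet_relative_power(np.ones(10_000), "sym4")


# --------------------------------------------------------------- featurize

def test_featurize_is_complete_finite_and_deterministic(gaussian_epoch):
    v1 = featurize(gaussian_epoch)
    v2 = featurize(gaussian_epoch)
    assert list(v1) == list(FEATURE_NAMES)
    assert all(np.isfinite(x) for x in v1.values())
    assert v1 == v2
    mags = [abs(v1[f"E_DCT_l{i}"]) for i in range(1, 21)]
    assert all(a >= b for a, b in zip(mags, mags[1:]))


def test_featurize_scaling_audit(gaussian_epoch):
    v1 = featurize(gaussian_epoch)
    doubled = Epoch(samples=2 * gaussian_epoch.samples, fs=FS,
                    particle_id="p0", class_label="ps", index=0)
    v2 = featurize(doubled)
    for name in SCALE_INVARIANT | {"E"}:
        assert v2[name] == pytest.approx(v1[name], rel=1e-6, abs=1e-9), name
    for name in ("SD", "RMS", "IQR", "Peak_DCT", "AUC_DCT"):
        assert v2[name] == pytest.approx(2 * v1[name], rel=1e-9), name
    assert v2["P_DCT"] == pytest.approx(4 * v1["P_DCT"], rel=1e-9)
    assert v2["omega_nakagami"] == pytest.approx(
        4 * v1["omega_nakagami"], rel=1e-9)


def test_particle_average():
    table = pd.DataFrame({
        "particle_id": ["a", "a", "b"],
        "class_label": ["ps", "ps", "pmma"],
        "epoch_index": [0, 1, 0],
        "M": [1.0, 3.0, 5.0],
        "SD": [2.0, 2.0, 7.0],
    })
    out = particle_average(table)
    assert len(out) == 2
    assert out.set_index("particle_id").loc["a", "M"] == pytest.approx(2.0)
    assert out.set_index("particle_id").loc["b", "SD"] == pytest.approx(7.0)


def test_featurize_epochs_skips_rejected(gaussian_epoch, rng):
    bad = Epoch(samples=rng.normal(size=10_000), fs=FS, particle_id="p1",
                class_label="ps", index=1, accepted=False)
    table = featurize_epochs([gaussian_epoch, bad])
    assert len(table) == 1
    assert list(table.columns[:3]) == ["particle_id", "class_label",
                                       "epoch_index"]
    assert list(table.columns[3:]) == list(FEATURE_NAMES)
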