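"""The 127-dimensional feature set: counts, oracles and invariances."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pgeskit import CANONICAL_CHANNELS, SnippetFeaturizer, extract_all, feature_names
from pgeskit.errors import ArgumentError
from pgeskit.features import (
    EPS,
    FAMILIES,
    PreparedSnippet,
    SLIDE_STEP,
    SLIDE_WINDOW,
    features_from_prepared,
    least_variance_channel,
    prepare_snippet,
)

from conftest import FS, N, make_snippet, sinusoid


def prepared(denoised, lowfreq=None, names=None):
    denoised = np.asarray(denoised, dtype=float)
    names = tuple(names or CANONICAL_CHANNELS[: denoised.shape[0]])
    low = denoised if lowfreq is None else np.asarray(lowfreq, dtype=float)
    return PreparedSnippet(denoised=denoised, lowfreq=low, channel_names=names)


# ---------------------------------------------------------------------------
# Structural counts


EXPECTED_FAMILY_COUNTS = {
    "correlation": lambda k: k * (k - 1) // 2,
    "temporal_ratio": lambda k: 2 * k + 4,
    "lowfreq_temporal_ratio": lambda k: 2 * k + 4,
    "lowfreq_signal": lambda k: 2 * k + 2,
    "sliding_difference": lambda k: k + 2,
}


@pytest.mark.parametrize("k", range(2, 11))
def test_feature_count_formula_by_name_enumeration(k):
    channels = CANONICAL_CHANNELS[:k]
    names = feature_names(channels=channels)
    assert len(names) == len(set(names))  # unique
    assert len(names) == k * (k - 1) // 2 + 7 * k + 12
    for fam, count in EXPECTED_FAMILY_COUNTS.items():
        assert len(feature_names(families=[fam], channels=channels)) == count(k)


def test_full_vector_matches_names(random_snippet):
    fv = extract_all(random_snippet)
    assert len(fv) == 127
    assert list(fv.index) == feature_names()
    assert np.isfinite(fv.to_numpy()).all()


def test_too_few_channels_rejected(random_snippet):
    with pytest.raises(ArgumentError):
        extract_all(random_snippet, channels=["Fz"])
    with pytest.raises(ArgumentError):
        extract_all(random_snippet, families=[])
    with pytest.raises(ArgumentError):
        extract_all(random_snippet, families=["bogus"])


# ---------------------------------------------------------------------------
# Correlation features


def brute_force_pearson(x, y):
    """Independent Pearson oracle: covariance over product of deviations."""
    dx, dy = x - x.mean(), y - y.mean()
    denom = np.sqrt((dx ** 2).sum() * (dy ** 2).sum())
    return (dx * dy).sum() / denom


def test_correlation_matches_brute_force(rng):
    for _ in range(20):
        s = make_snippet(rng.normal(0, 15, (10, N)))
        den = prepare_snippet(s).denoised
        fv = extract_all(s, families=["correlation"])
        for idx, (i, j) in enumerate(combinations(range(10), 2)):
            assert fv.iloc[idx] == pytest.approx(
                brute_force_pearson(den[i], den[j]), abs=1e-10)


def test_correlation_affine_and_sign(rng):
    base = rng.normal(size=N)
    p = prepared(np.vstack([base, 3.0 * base + 5.0, -base]),
                 names=("FP1", "F7", "T7"))
    fv = features_from_prepared(p, families=["correlation"])
    assert fv["corr.FP1_F7"] == pytest.approx(1.0, abs=1e-12)
    assert fv["corr.FP1_T7"] == pytest.approx(-1.0, abs=1e-12)


def test_correlation_zero_variance_channel_guard(rng):
    p = prepared(np.vstack([np.zeros(N), rng.normal(size=N)]),
                 names=("FP1", "F7"))
    fv = features_from_prepared(p, families=["correlation"])
    assert fv["corr.FP1_F7"] == 0.0


# ---------------------------------------------------------------------------
# Least-variance channel


def test_least_variance_channel_selection(rng):
    x = rng.normal(size=(4, N)) * np.array([2.0, 1.0, 3.0, 5.0])[:, None]
    s = make_snippet(x, channel_names=("FP1", "F7", "T7", "P7"))
    assert least_variance_channel(s) == 1
    tie = make_snippet(np.tile(rng.normal(size=N), (3, 1)),
                       channel_names=("FP1", "F7", "T7"))
    assert least_variance_channel(tie) == 0
    x[2] = 0.0
    assert least_variance_channel(make_snippet(
        x, channel_names=("FP1", "F7", "T7", "P7"))) == 2


# ---------------------------------------------------------------------------
# Temporal ratios


def test_temporal_ratio_identical_halves_all_ones(rng):
    half = rng.normal(1.0, 2.0, (10, N // 2))
    p = prepared(np.concatenate([half, half], axis=1))
    fv = features_from_prepared(p, families=["temporal_ratio"])
    for c in CANONICAL_CHANNELS:
        assert fv[f"tmr.{c}"] == pytest.approx(1.0)
        assert fv[f"tvr.{c}"] == pytest.approx(1.0)


def test_temporal_variance_ratio_of_doubled_half(rng):
    half = rng.normal(0.0, 3.0, N // 2)
    x = np.vstack([np.concatenate([half, 2.0 * half]),
                   rng.normal(0, 1, N)])
    p = prepared(x, names=("FP1", "F7"))
    fv = features_from_prepared(p, families=["temporal_ratio"])
    assert fv["tvr.FP1"] == pytest.approx(4.0, rel=1e-10)


def test_temporal_ratio_summaries_definition(rng):
    x = rng.normal(0.5, 2.0, (3, N))
    p = prepared(x, names=("FP1", "F7", "T7"))
    fv = features_from_prepared(p, families=["temporal_ratio"])
    half = N // 2
    full_var = x.var(axis=1)
    mean_ratio = x[:, half:].mean(axis=1) / x[:, :half].mean(axis=1)
    norm = mean_ratio / full_var
    assert fv["tmr.sum_norm"] == pytest.approx(norm.sum())
    assert fv["tmr.leastvar"] == pytest.approx(norm[np.argmin(full_var)])


def test_denominator_guard_yields_zero():
    # zero first-half mean and zero variance -> guarded ratios are 0, finite
    p = prepared(np.zeros((2, N)), names=("FP1", "F7"))
    fv = features_from_prepared(p)
    assert np.isfinite(fv.to_numpy()).all()
    assert fv["tmr.FP1"] == 0.0 and fv["tvr.FP1"] == 0.0
    assert fv["lf_mean.sum_norm"] == 0.0


def test_lowfreq_variance_ratio_of_amplitude_modulated_tone():
    # a 5 Hz tone stepping from amplitude a to 2a at the midpoint passes the
    # 3-8 Hz band, so the variance ratio survives the filtering within 10%
    x = sinusoid(5.0, amp=4.0)
    x[N // 2:] *= 2.0
    s = make_snippet(np.tile(x, (10, 1)))
    fv = extract_all(s, families=["lowfreq_temporal_ratio"])
    assert fv["lf_tvr.Fz"] == pytest.approx(4.0, rel=0.1)


def test_lowfreq_ratio_out_of_band_input_resolves_via_guards():
    s = make_snippet(np.tile(sinusoid(20.0, amp=1e-3), (10, 1)))
    fv = extract_all(s, families=["lowfreq_temporal_ratio"])
    assert np.isfinite(fv.to_numpy()).all()


# ---------------------------------------------------------------------------
# Sliding signal difference


def brute_force_sliding(x):
    """Independent oracle: scan every fully-contained window placement."""
    best = -np.inf
    for start in range(0, len(x) - SLIDE_WINDOW + 1, SLIDE_STEP):
        w = x[start:start + SLIDE_WINDOW]
        best = max(best, w[SLIDE_WINDOW // 2:].sum() - w[:SLIDE_WINDOW // 2].sum())
    return best


def test_sliding_difference_matches_brute_force(rng):
    x = rng.normal(0, 5, (10, N))
    p = prepared(x)
    fv = features_from_prepared(p, families=["sliding_difference"])
    for i, c in enumerate(CANONICAL_CHANNELS):
        assert fv[f"sld.{c}"] == pytest.approx(
            brute_force_sliding(x[i]), rel=1e-9, abs=1e-8)


def test_sliding_difference_constant_and_ramp(rng):
    m = 0.37
    ramp = m * np.arange(N)
    p = prepared(np.vstack([np.full(N, 2.0), ramp]), names=("FP1", "F7"))
    fv = features_from_prepared(p, families=["sliding_difference"])
    assert fv["sld.FP1"] == pytest.approx(0.0, abs=1e-9)
    # sum over samples 25..49 minus sum over 0..24 of a unit-slope ramp is 625
    assert fv["sld.F7"] == pytest.approx(625.0 * m, rel=1e-12)


def test_sliding_difference_rejects_short_snippet():
    p = prepared(np.zeros((2, 30)), names=("FP1", "F7"))
    with pytest.raises(ArgumentError):
        features_from_prepared(p, families=["sliding_difference"])


# ---------------------------------------------------------------------------
# Low-frequency signal features


def test_lowfreq_signal_variance_of_sinusoid():
    A = 6.0
    s = make_snippet(np.tile(sinusoid(5.0, amp=A), (10, 1)))
    fv = extract_all(s, families=["lowfreq_signal"])
    assert fv["lf_var.Cz"] == pytest.approx(A ** 2 / 2.0, rel=0.05)


def test_lowfreq_signal_definition(rng):
    x = rng.normal(0.2, 1.5, (3, N))
    p = prepared(x, names=("FP1", "F7", "T7"))
    fv = features_from_prepared(p, families=["lowfreq_signal"])
    means, variances = x.mean(axis=1), x.var(axis=1)
    np.testing.assert_allclose(
        [fv[f"lf_mean.{c}"] for c in ("FP1", "F7", "T7")], means)
    np.testing.assert_allclose(
        [fv[f"lf_var.{c}"] for c in ("FP1", "F7", "T7")], variances)
    assert fv["lf_mean.sum_norm"] == pytest.approx((means / variances).sum())
    lv = int(np.argmin(variances))
    assert fv["lf_mean.leastvar"] == pytest.approx(means[lv] / variances[lv])


# ---------------------------------------------------------------------------
# Invariances of the full vector


def test_scale_invariance_and_scaling_laws(random_snippet):
    c = 3.7
    fv = extract_all(random_snippet)
    scaled = make_snippet(random_snippet.samples * c)
    fv2 = extract_all(scaled)
    for name in fv.index:
        if name.startswith(("corr.", "tmr.", "tvr.", "lf_tmr.", "lf_tvr.")) \
                and not name.endswith(("sum_norm", "leastvar")):
            assert fv2[name] == pytest.approx(fv[name], rel=1e-9), name
    for ch in CANONICAL_CHANNELS:
        assert fv2[f"lf_mean.{ch}"] == pytest.approx(c * fv[f"lf_mean.{ch}"], rel=1e-9)
        assert fv2[f"lf_var.{ch}"] == pytest.approx(c ** 2 * fv[f"lf_var.{ch}"], rel=1e-9)


def test_channel_permutation_permutes_features(rng):
    x = rng.normal(0, 10, (10, N))
    i, j = 2, 6  # T7 <-> T8
    swapped = x.copy()
    swapped[[i, j]] = swapped[[j, i]]
    fv = extract_all(make_snippet(x))
    fv2 = extract_all(make_snippet(swapped))
    ci, cj = CANONICAL_CHANNELS[i], CANONICAL_CHANNELS[j]
    for fam in ("tmr", "tvr", "lf_mean", "lf_var", "sld"):
        assert fv2[f"{fam}.{ci}"] == pytest.approx(fv[f"{fam}.{cj}"], rel=1e-9)
        assert fv2[f"{fam}.{cj}"] == pytest.approx(fv[f"{fam}.{ci}"], rel=1e-9)
    # the pair feature maps to its renamed pair: (T7, F8)_swapped == (F8, T8)
    assert fv2["corr.T7_F8"] == pytest.approx(fv["corr.F8_T8"], rel=1e-9)
    assert fv2["corr.FP1_F7"] == pytest.approx(fv["corr.FP1_F7"], rel=1e-9)


def test_extract_all_is_deterministic(random_snippet):
    a = extract_all(random_snippet)
    b = extract_all(random_snippet)
    assert (a.to_numpy() == b.to_numpy()).all()


# ---------------------------------------------------------------------------
# Featurizer (transformer interface)


def test_featurizer_transform_shapes(rng):
    snips = [make_snippet(rng.normal(0, 10, (10, N))) for _ in range(3)]
    ft = SnippetFeaturizer()
    X = ft.fit_transform(snips)
    assert X.shape == (3, 127)
    assert list(X.columns) == feature_names()
    sub = SnippetFeaturizer(families=["correlation"], channels=["Fz", "Cz", "FP1"])
    assert sub.fit_transform(snips).shape == (3, 3)
    assert sub.get_params()["channels"] == ["Fz", "Cz", "FP1"]
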