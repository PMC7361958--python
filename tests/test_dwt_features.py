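"""Sub-band decomposition and the five coefficient statistics.

Each statistic is checked against an independent brute-force
implementation of its defining formula (plain Python loops), plus
hand-computed worked examples.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdx import (
    DomainError,
    FeatureConfig,
    ParameterError,
    Segment,
    build_feature_vector,
    dwt_decompose,
    dwt_reconstruct,
    feat_entropy,
    feat_kurtosis,
    feat_lbp,
    feat_sd,
    feat_variance,
    nominal_bands_for_fs,
)

# ---------------------------------------------------------------------------
# Brute-force oracles: direct transcriptions of the statistic definitions,
# written with explicit loops, independent of the implementation under test.
# ---------------------------------------------------------------------------


def brute_variance(s):
    n = len(s)
    mu = sum(s) / n
    return sum((x - mu) ** 2 for x in s) / n


def brute_sd(s):
    return math.sqrt(brute_variance(s))


def brute_kurtosis(s):
    n = len(s)
    mu = sum(s) / n
    sigma = math.sqrt(sum((x - mu) ** 2 for x in s) / n)
    return sum(((x - mu) / sigma) ** 4 for x in s) / n


def brute_entropy(s):
    total = 0.0
    for x in s:
        sq = x * x
        if sq > 0:
            total += sq * math.log(sq)
    return total


def brute_lbp(s):
    return math.log(sum(x * x for x in s) / len(s))


ORACLES = {
    feat_variance: brute_variance,
    feat_sd: brute_sd,
    feat_kurtosis: brute_kurtosis,
    feat_entropy: brute_entropy,
    feat_lbp: brute_lbp,
}


@pytest.mark.parametrize("impl", list(ORACLES), ids=lambda f: f.__name__)
def test_statistics_match_brute_force_oracles(impl, rng):
    """1000 random vectors: implementation == loop-based formula to 1e-12."""
    oracle = ORACLES[impl]
    for _ in range(1000):
        n = int(rng.integers(3, 80))
        s = rng.standard_normal(n) * rng.uniform(0.1, 10)
        expected = oracle(list(s))
        got = impl(s)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)


@pytest.mark.parametrize(
    "impl,data,expected",
    [
        (feat_variance, [1.0, 2.0, 3.0], 2.0 / 3.0),
        (feat_variance, [4.0, 4.0, 4.0], 0.0),
        (feat_sd, [1.0, 2.0, 3.0], math.sqrt(2.0 / 3.0)),
        (feat_sd, [7.0, 7.0], 0.0),
        (feat_kurtosis, [-1.0, 1.0, -1.0, 1.0], 1.0),
        (feat_entropy, [1.0, 1.0, 1.0], 0.0),
        (feat_entropy, [0.0], 0.0),
        (feat_entropy, [2.0], 4.0 * math.log(4.0)),
        (feat_lbp, [1.0] * 10, 0.0),
        (feat_lbp, [3.0, 4.0], math.log(12.5)),
    ],
)
def test_statistic_worked_examples(impl, data, expected):
    assert impl(data) == pytest.approx(expected, abs=1e-12)


def test_kurtosis_gaussian_limit(rng):
    """Kurtosis of a large standard-normal sample approaches 3."""
    s = rng.standard_normal(10**6)
    assert feat_kurtosis(s) == pytest.approx(3.0, abs=0.05)


def test_variance_is_squared_sd(rng):
    s = rng.standard_normal(50)
    assert feat_variance(s) == pytest.approx(feat_sd(s) ** 2, rel=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(-100, 100), min_size=2, max_size=40),
    st.floats(0.01, 50),
)
def test_sd_homogeneity(values, a):
    """SD scales as |a| under s -> a*s."""
    s = np.asarray(values)
    assert feat_sd(a * s) == pytest.approx(a * feat_sd(s), rel=1e-9, abs=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(0.01, 100), min_size=2, max_size=40),
    st.floats(0.01, 50),
)
def test_lbp_scaling_law(values, c):
    """LBP(c*s) = LBP(s) + 2 ln|c|."""
    s = np.asarray(values)
    assert feat_lbp(c * s) == pytest.approx(
        feat_lbp(s) + 2 * math.log(c), rel=1e-9, abs=1e-9
    )


@pytest.mark.parametrize(
    "impl", [feat_variance, feat_sd, feat_kurtosis, feat_entropy, feat_lbp],
    ids=lambda f: f.__name__,
)
def test_statistics_reject_empty_input(impl):
    with pytest.raises(DomainError):
        impl([])


def test_kurtosis_degenerate_raises_or_zero():
    with pytest.raises(DomainError):
        feat_kurtosis([5.0, 5.0, 5.0])
    assert feat_kurtosis([5.0, 5.0, 5.0], degenerate="zero") == 0.0


def test_lbp_all_zero_raises():
    with pytest.raises(DomainError):
        feat_lbp([0.0, 0.0])


def test_log_base_ten_option():
    assert feat_lbp([3.0, 4.0], log_base="10") == pytest.approx(
        math.log10(12.5), rel=1e-12
    )
    assert feat_entropy([2.0], log_base="10") == pytest.approx(
        4.0 * math.log10(4.0), rel=1e-12
    )


# ---------------------------------------------------------------------------
# DWT decomposition
# ---------------------------------------------------------------------------


def test_dwt_energy_conservation_and_reconstruction(rng, feature_config):
    """Orthonormal periodic db4: coefficient energy equals signal energy,
    and inversion reproduces the input, both to 1e-8 relative."""
    for _ in range(100):
        n = int(2 ** rng.integers(8, 13))
        seg = Segment(samples=rng.standard_normal((1, n)), fs=256.0,
                      duration_s=n / 256.0)
        sb = dwt_decompose(seg, feature_config)
        coeff_energy = sum(
            float(np.sum(c**2)) for c in sb.coeffs[seg.channel_labels[0]].values()
        )
        sig_energy = float(np.sum(seg.samples**2))
        assert abs(coeff_energy - sig_energy) / sig_energy < 1e-8
        recon = dwt_reconstruct(sb, feature_config)[:, : seg.n_samples]
        err = np.linalg.norm(recon - seg.samples) / np.linalg.norm(seg.samples)
        assert err < 1e-8


def test_dwt_zero_segment_gives_zero_coefficients(feature_config):
    seg = Segment(samples=np.zeros((1, 1024)), fs=256.0, duration_s=4.0)
    sb = dwt_decompose(seg, feature_config)
    for per in sb.coeffs.values():
        for c in per.values():
            assert np.all(c == 0)


def test_nominal_bands_halve_nyquist():
    bands = nominal_bands_for_fs(256.0)
    assert bands["D1"] == (64.0, 128.0)
    assert bands["D2"] == (32.0, 64.0)
    assert bands["D3"] == (16.0, 32.0)
    assert bands["D4"] == (8.0, 16.0)
    assert bands["A4"] == (0.0, 8.0)


def test_dwt_rejects_too_short_segment(feature_config):
    seg = Segment(samples=np.zeros((1, 64)), fs=256.0, duration_s=0.25)
    with pytest.raises(DomainError, match="minimum"):
        dwt_decompose(seg, feature_config)


def test_subband_frequency_localization(feature_config):
    """A sinusoid mid-band in nominal D3 concentrates its coefficient
    energy there."""
    fs = 256.0
    n = 4096
    t = np.arange(n) / fs
    f0 = 24.0  # middle of D3 = (16, 32] Hz
    seg = Segment(samples=np.sin(2 * np.pi * f0 * t)[None, :], fs=fs,
                  duration_s=n / fs)
    sb = dwt_decompose(seg, feature_config)
    per = sb.coeffs[seg.channel_labels[0]]
    energies = {b: float(np.sum(c**2)) for b, c in per.items()}
    assert energies["D3"] / sum(energies.values()) >= 0.6


def test_feature_vector_ordering_and_length(rng):
    seg = Segment(samples=rng.standard_normal((3, 1024)), fs=256.0,
                  duration_s=4.0, channel_labels=("c1", "c2", "c3"))
    cfg = FeatureConfig(statistics=("lbp", "entropy"))
    fv = build_feature_vector(dwt_decompose(seg, cfg), cfg)
    assert len(fv.values) == len(fv.ordering) == 3 * 5 * 2
    # channel-major, then D1..D4,A4, then statistic
    assert fv.ordering[0] == ("c1", "D1", "lbp")
    assert fv.ordering[1] == ("c1", "D1", "entropy")
    assert fv.ordering[10] == ("c2", "D1", "lbp")
    assert np.all(np.isfinite(fv.values))


def test_feature_vector_single_statistic_lengths(rng):
    seg = Segment(samples=rng.standard_normal((1, 1024)), fs=256.0, duration_s=4.0)
    cfg = FeatureConfig(statistics=("lbp",))
    fv = build_feature_vector(dwt_decompose(seg, cfg), cfg)
    assert len(fv.values) == 5


def test_feature_extraction_is_deterministic(rng):
    seg = Segment(samples=rng.standard_normal((2, 2048)), fs=256.0, duration_s=8.0)
    cfg = FeatureConfig(statistics=("lbp", "sd", "variance", "kurtosis", "entropy"))
    a = build_feature_vector(dwt_decompose(seg, cfg), cfg)
    b = build_feature_vector(dwt_decompose(seg, cfg), cfg)
    assert np.array_equal(a.values, b.values)


def test_zero_segment_variance_features_are_zero():
    seg = Segment(samples=np.zeros((1, 1024)), fs=256.0, duration_s=4.0)
    cfg = FeatureConfig(statistics=("variance",))
    fv = build_feature_vector(dwt_decompose(seg, cfg), cfg)
    assert np.all(fv.values == 0)


def test_invalid_config_rejected():
    with pytest.raises(ParameterError):
        FeatureConfig(statistics=("power",))
    with pytest.raises(ParameterError):
        FeatureConfig(subbands=())
    with pytest.raises(ParameterError):
        FeatureConfig(level=3)
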