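import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from flavoglyc.hptlc import (
    N_VARIABLES,
    ProfileMatrix,
    cow_align,
    extract_profile,
    kaiser_retain,
    pca,
    preprocess,
    top_loading_zones,
)


def _gauss(rf, pos, width=0.02, amp=1.0):
    return amp * np.exp(-0.5 * ((rf - pos) / width) ** 2)


def _lane_image(band_rfs, height=600, width=40):
    """Synthetic lane: bright Gaussian bands; row 0 = solvent front (top)."""
    img = np.zeros((height, width, 3))
    rows = np.arange(height)
    rf_of_row = 1.0 - rows / (height - 1)  # bottom row is the application line
    for rf in band_rfs:
        img[:, :, 1] += 200 * np.exp(-0.5 * ((rf_of_row - rf) / 0.01) ** 2)[:, None]
    return img


def test_extract_profile_band_position():
    prof = extract_profile(_lane_image([0.5]), (0, 40), "G")
    assert prof.intensity.size == N_VARIABLES
    assert abs(int(np.argmax(prof.intensity)) - 263) <= 2


def test_extract_profile_black_image_is_zero():
    prof = extract_profile(np.zeros((100, 20, 3)), (0, 20), "G")
    assert np.all(prof.intensity == 0)


def test_extract_profile_three_bands():
    prof = extract_profile(_lane_image([0.2, 0.5, 0.8]), (0, 40), "G")
    for rf in (0.2, 0.5, 0.8):
        idx = int(round(rf * (N_VARIABLES - 1)))
        window = prof.intensity[idx - 5 : idx + 6]
        assert window.max() > 0.5 * prof.intensity.max()


def test_extract_profile_bad_lane_bounds():
    with pytest.raises(ValueError, match="lane bounds"):
        extract_profile(np.zeros((10, 20, 3)), (10, 30))


def _matrix(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    rf = np.linspace(0, 1, rows.shape[1])
    ids = ids or [f"S{i}" for i in range(rows.shape[0])]
    return ProfileMatrix(pd.DataFrame(rows, index=ids, columns=rf))


def test_preprocess_normalizes_before_centering():
    rng = np.random.default_rng(0)
    rows = rng.uniform(0.5, 1.5, size=(4, 120))
    m = preprocess(_matrix(rows), slack=0, median_radius=0)
    # centering is exact ...
    assert np.allclose(m.data.to_numpy().mean(axis=0), 0, atol=1e-12)
    # ... and, with no warping, undoing it recovers unit-sum rows
    X = m.data.to_numpy()
    raw = _matrix(rows).data.to_numpy()
    norm = raw / raw.sum(axis=1, keepdims=True)
    assert np.allclose(X + norm.mean(axis=0, keepdims=True), norm, atol=1e-12)
    assert m.state == dict(filtered=False, normalized=True, warped=True, centered=True)


def test_preprocess_identical_rows_stay_identical():
    rf = np.linspace(0, 1, 200)
    row = _gauss(rf, 0.3) + 0.1
    m = preprocess(_matrix([row, row]))
    X = m.data.to_numpy()
    assert np.allclose(X[0], X[1])


def test_preprocess_all_zero_row_names_sample():
    rows = np.ones((3, 100))
    rows[1] = 0
    with pytest.raises(ValueError, match="S1"):
        preprocess(_matrix(rows))


def test_cow_identity_and_zero_slack():
    rf = np.linspace(0, 1, 526)
    target = _gauss(rf, 0.3) + 0.7 * _gauss(rf, 0.6, 0.03)
    assert np.allclose(cow_align(target, target, 50, 5), target, atol=1e-9)
    shifted = np.roll(target, 4)
    assert np.array_equal(cow_align(shifted, target, 50, 0), shifted)


def test_cow_recovers_small_shift():
    rf = np.linspace(0, 1, 526)
    target = _gauss(rf, 0.3) + 0.7 * _gauss(rf, 0.6, 0.03) + 0.4 * _gauss(rf, 0.82, 0.015)
    shifted = np.roll(target, 4)
    warped = cow_align(shifted, target, 50, 5)
    before = np.corrcoef(shifted, target)[0, 1]
    after = np.corrcoef(warped, target)[0, 1]
    assert after >= before
    assert after >= 0.99


def test_cow_validates_parameters():
    x = np.zeros(100)
    with pytest.raises(ValueError):
        cow_align(x, np.zeros(99))
    with pytest.raises(ValueError):
        cow_align(x, x, segment_len=8, slack=5)


@settings(deadline=None, max_examples=25)
@given(
    profile=arrays(
        float,
        st.just(160),
        elements=st.floats(0, 1, allow_nan=False, width=32),
    ),
    shift=st.integers(-4, 4),
)
def test_cow_preserves_length_and_endpoints(profile, shift):
    target = np.roll(profile, shift)
    warped = cow_align(profile, target, segment_len=40, slack=4)
    assert warped.shape == profile.shape
    assert warped[0] == profile[0] and warped[-1] == profile[-1]
    assert np.isfinite(warped).all()


def test_kaiser_retain_direct_rule():
    assert kaiser_retain(np.array([3.0, 1.5, 0.4])) == 2


def test_pca_variance_conservation_and_orthonormal_loadings():
    rng = np.random.default_rng(1)
    m = _matrix(rng.normal(size=(10, 50)))
    res = pca(m)
    assert res.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-6)
    assert np.all(np.diff(res.explained_variance_pct) <= 1e-12)
    L = res.loadings.to_numpy()
    assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)


def test_pca_requires_two_samples():
    with pytest.raises(ValueError):
        pca(_matrix(np.ones((1, 20))))


def test_pca_separates_two_clusters():
    rng = np.random.default_rng(3)
    rf = np.linspace(0, 1, 300)
    a = [_gauss(rf, 0.2) + rng.normal(0, 0.01, rf.size) for _ in range(6)]
    b = [_gauss(rf, 0.7) + rng.normal(0, 0.01, rf.size) for _ in range(6)]
    m = preprocess(_matrix(a + b), slack=0)
    res = pca(m)
    km = KMeans(2, n_init=10, random_state=0).fit(res.scores[["PC1", "PC2"]])
    assert adjusted_rand_score([0] * 6 + [1] * 6, km.labels_) == 1.0


def test_top_loading_zones_finds_band_positions():
    rng = np.random.default_rng(4)
    rf = np.linspace(0, 1, 526)
    a = [_gauss(rf, 0.2) + rng.normal(0, 0.005, rf.size) for _ in range(5)]
    b = [_gauss(rf, 0.7) + rng.normal(0, 0.005, rf.size) for _ in range(5)]
    res = pca(preprocess(_matrix(a + b), slack=0))
    zones = top_loading_zones(res, "PC1", n=2)
    assert np.any(np.abs(zones - 0.2) < 0.03)
    assert np.any(np.abs(zones - 0.7) < 0.03)
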