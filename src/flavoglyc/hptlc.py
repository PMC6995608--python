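"""HPTLC densitogram fingerprinting pipeline.

Lane intensity profiles are extracted from RGB plate images (one of the R/G/B
channels, read along the development direction), resampled onto a common
526-point retention-factor axis (R_F 0 at the application line, 1 at the
80 mm solvent front), and assembled into a samples × variables matrix.

Preprocessing is applied in a fixed order: median filtering (radius 2 px),
row normalization to unit sum, correlation optimized warping (COW) against a
chosen target lane, and mean centering. PCA is computed by SVD; the Kaiser
criterion (eigenvalues greater than 1) is applied to eigenvalues scaled to
mean 1 — the correlation-matrix convention that makes the ">1" cut-off
meaningful for pixel-intensity variables of arbitrary scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "N_VARIABLES",
    "DensitogramProfile",
    "ProfileMatrix",
    "PCAResult",
    "extract_profile",
    "preprocess",
    "cow_align",
    "pca",
    "kaiser_retain",
    "top_loading_zones",
]

#: default number of R_F variables per lane
N_VARIABLES = 526

_CHANNELS = {"R": 0, "G": 1, "B": 2}


@dataclass
class DensitogramProfile:
    """1-D intensity vs R_F for one lane and colour channel."""

    sample_id: str
    channel: str
    rf_axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.rf_axis = np.asarray(self.rf_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rf_axis.shape != self.intensity.shape:
            raise ValueError("rf_axis and intensity must have the same length")
        if np.any(np.diff(self.rf_axis) <= 0):
            raise ValueError("rf_axis must be strictly increasing")


@dataclass
class ProfileMatrix:
    """Samples × R_F-variables matrix for one channel, with processing state."""

    data: pd.DataFrame  # index: sample ids, columns: R_F grid
    channel: str = "G"
    state: dict = field(default_factory=lambda: dict(
        filtered=False, normalized=False, warped=False, centered=False
    ))

    @property
    def rf_axis(self) -> np.ndarray:
        return self.data.columns.to_numpy(dtype=float)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @classmethod
    def from_profiles(cls, profiles: list[DensitogramProfile]) -> "ProfileMatrix":
        if not profiles:
            raise ValueError("no profiles")
        rf = profiles[0].rf_axis
        channel = profiles[0].channel
        for p in profiles:
            if not np.allclose(p.rf_axis, rf) or p.channel != channel:
                raise ValueError("profiles must share R_F axis and channel")
        df = pd.DataFrame(
            [p.intensity for p in profiles], index=[p.sample_id for p in profiles], columns=rf
        )
        return cls(df, channel)


def extract_profile(
    image: np.ndarray,
    lane_bounds: tuple[int, int],
    channel: str = "G",
    sample_id: str = "",
    n_points: int = N_VARIABLES,
) -> DensitogramProfile:
    """Mean lane intensity per row, oriented application edge → solvent front.

    ``image`` is an (H, W, 3) RGB array with row 0 at the top of the plate
    (the solvent-front side) and the application line at the bottom, the
    usual orientation of plate documentation images. ``lane_bounds`` are
    (first, last+1) column indices of the lane.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB image array")
    c0, c1 = lane_bounds
    if not (0 <= c0 < c1 <= img.shape[1]):
        raise ValueError(f"lane bounds {lane_bounds} outside image width {img.shape[1]}")
    if channel not in _CHANNELS:
        raise ValueError(f"channel must be one of {sorted(_CHANNELS)}")
    lane = img[:, c0:c1, _CHANNELS[channel]].astype(float)
    profile = lane.mean(axis=1)[::-1]  # bottom (application) first
    rf_native = np.linspace(0.0, 1.0, profile.size)
    rf = np.linspace(0.0, 1.0, n_points)
    return DensitogramProfile(sample_id, channel, rf, np.interp(rf, rf_native, profile))


def _segment_correlation(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cow_align(
    profile: np.ndarray,
    target: np.ndarray,
    segment_len: int = 50,
    slack: int = 5,
) -> np.ndarray:
    """Correlation optimized warping of ``profile`` onto ``target``.

    The axis is split into segments of roughly ``segment_len`` points whose
    interior boundaries may shift by up to ±``slack`` points in the profile;
    dynamic programming picks the boundary offsets maximizing the summed
    per-segment Pearson correlation after linear stretching/compression.
    Endpoints are fixed, the warp is monotone and the length is preserved.
    """
    profile = np.asarray(profile, dtype=float)
    target = np.asarray(target, dtype=float)
    if profile.shape != target.shape:
        raise ValueError("profile and target must have equal length")
    if slack < 0:
        raise ValueError("slack must be non-negative")
    if slack == 0:
        return profile.copy()
    if segment_len <= 2 * slack:
        raise ValueError("segment_len must exceed 2*slack")
    n = profile.size
    n_seg = max(1, round((n - 1) / segment_len))
    bounds = np.round(np.linspace(0, n - 1, n_seg + 1)).astype(int)
    offsets = np.arange(-slack, slack + 1)

    # best[i][j]: best summed correlation with boundary i at bounds[i]+offsets[j]
    neg = -np.inf
    best = np.full((n_seg + 1, offsets.size), neg)
    back = np.zeros((n_seg + 1, offsets.size), dtype=int)
    zero = int(np.where(offsets == 0)[0][0])
    best[0, zero] = 0.0
    for i in range(1, n_seg + 1):
        js = [zero] if i == n_seg else range(offsets.size)
        tgt_seg = target[bounds[i - 1] : bounds[i] + 1]
        for j in js:
            end = bounds[i] + offsets[j]
            for jp in range(offsets.size):
                if best[i - 1, jp] == neg:
                    continue
                start = bounds[i - 1] + offsets[jp]
                if not (0 <= start < end <= n - 1):
                    continue
                seg = profile[start : end + 1]
                x = np.linspace(0, seg.size - 1, tgt_seg.size)
                warped = np.interp(x, np.arange(seg.size), seg)
                cand = best[i - 1, jp] + _segment_correlation(warped, tgt_seg)
                if cand > best[i, j]:
                    best[i, j] = cand
                    back[i, j] = jp
    # trace back the optimal boundary offsets
    j = zero
    path = [0] * (n_seg + 1)
    for i in range(n_seg, 0, -1):
        path[i] = j
        j = back[i, j]
    path[0] = zero

    out = np.empty(n)
    for i in range(1, n_seg + 1):
        start = bounds[i - 1] + offsets[path[i - 1]]
        end = bounds[i] + offsets[path[i]]
        seg = profile[start : end + 1]
        m = bounds[i] - bounds[i - 1] + 1
        x = np.linspace(0, seg.size - 1, m)
        out[bounds[i - 1] : bounds[i] + 1] = np.interp(x, np.arange(seg.size), seg)
    return out


def preprocess(
    m: ProfileMatrix,
    target: str | None = None,
    median_radius: int = 2,
    segment_len: int = 50,
    slack: int = 5,
) -> ProfileMatrix:
    """Median filter → unit-sum normalization → COW to target → mean centering.

    ``target`` is the sample id of the warping target lane (first sample by
    default). The order of steps is fixed.
    """
    X = m.data.to_numpy(dtype=float).copy()
    if median_radius > 0:
        X = median_filter(X, size=(1, 2 * median_radius + 1), mode="nearest")
    sums = X.sum(axis=1)
    for sid, s in zip(m.samples, sums):
        if s <= 0:
            raise ValueError(f"sample {sid!r}: all-zero profile cannot be sum-normalized")
    X = X / sums[:, None]
    tid = target if target is not None else m.samples[0]
    if tid not in m.samples:
        raise KeyError(f"target sample {tid!r} not in matrix")
    t_row = X[m.samples.index(tid)].copy()
    X = np.vstack([cow_align(row, t_row, segment_len, slack) for row in X])
    X = X - X.mean(axis=0, keepdims=True)
    df = pd.DataFrame(X, index=m.data.index, columns=m.data.columns)
    return ProfileMatrix(
        df, m.channel, dict(filtered=median_radius > 0, normalized=True, warped=True, centered=True)
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # variables × components
    explained_variance_pct: np.ndarray
    eigenvalues: np.ndarray  # covariance eigenvalues, descending
    n_retained: int


def kaiser_retain(eigenvalues: np.ndarray) -> int:
    """Number of components with eigenvalue greater than 1."""
    return int(np.sum(np.asarray(eigenvalues, dtype=float) > 1.0))


def pca(m: ProfileMatrix) -> PCAResult:
    """SVD-based PCA of a mean-centered profile matrix.

    The Kaiser criterion is evaluated on eigenvalues scaled to mean 1
    (correlation-matrix convention), so the returned ``n_retained`` does not
    depend on the raw intensity scale.
    """
    X = m.data.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    if not m.state.get("centered", False):
        X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n - 1, X.shape[1])
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    eig = S**2 / (n - 1)
    explained = S**2 / (S**2).sum() * 100.0 if S.size else S
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U * S, index=m.data.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=m.data.columns, columns=comp)
    scaled = eig / eig.mean() if eig.size else eig
    return PCAResult(scores, loadings, explained, eig, kaiser_retain(scaled))


def top_loading_zones(res: PCAResult, component: str = "PC1", n: int = 4) -> np.ndarray:
    """R_F positions of the ``n`` local maxima of |loading| on a component."""
    v = res.loadings[component].to_numpy()
    a = np.abs(v)
    local = np.flatnonzero((a[1:-1] >= a[:-2]) & (a[1:-1] >= a[2:])) + 1
    top = local[np.argsort(a[local])[::-1][:n]]
    rf = res.loadings.index.to_numpy(dtype=float)
    return np.sort(rf[top])
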