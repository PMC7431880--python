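"""Time-lapse feature construction from multivariate cell series.

Each univariate series (one per-frame feature over the observation
window) is summarised by a partial feature vector: seven global
statistics, magnitudes of the lowest nonzero-frequency Fourier
coefficients, discrete-wavelet approximation and detail coefficients,
the linear trend, approximate entropy, and a SAX symbol word.  Partial
vectors concatenate across the d per-frame features; PCA scores of the
flattened series and four motion features are appended.  The value-based
alternative concatenates the raw series columns.  Both vector kinds are
min-max normalised to [0, 1] with statistics learned on training cells
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pywt
from scipy import stats as sstats
from sklearn.decomposition import PCA

from .frame_features import MultivariateSeries

__all__ = [
    "TransformConfig",
    "TimelapseFeatureVector",
    "NormalizationStats",
    "stat_features",
    "fft_features",
    "dwt_features",
    "trend_features",
    "approximate_entropy",
    "sax_features",
    "motion_features",
    "PCAFeatures",
    "assemble_feature_based",
    "assemble_value_based",
    "fit_apply_normalization",
]

STAT_NAMES = ("mean", "median", "std", "min", "max", "skewness", "kurtosis")


@dataclass
class TransformConfig:
    """Tunable parameters of the per-series transforms."""

    n_fft_coeff: int = 5
    wavelet: str = "haar"
    dwt_level: int = 2
    apen_m: int = 2
    apen_r_factor: float = 0.2
    sax_word_len: int = 5
    sax_alphabet: int = 4
    n_pca: int = 3


@dataclass
class TimelapseFeatureVector:
    """Final per-cell vector, feature-based or value-based."""

    cell_id: int
    values: np.ndarray
    names: Tuple[str, ...]
    approach: str  # "feature_based" | "value_based"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values/names length mismatch")
        if self.approach not in ("feature_based", "value_based"):
            raise ValueError(f"unknown approach {self.approach!r}")


@dataclass
class NormalizationStats:
    """Per-feature min/max learned from a training matrix."""

    minimum: np.ndarray
    maximum: np.ndarray

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        span = self.maximum - self.minimum
        scaled = np.zeros_like(matrix, dtype=float)
        ok = span > 0
        scaled[:, ok] = (matrix[:, ok] - self.minimum[ok]) / span[ok]
        return np.clip(scaled, 0.0, 1.0)


def stat_features(x: np.ndarray) -> np.ndarray:
    """Seven global statistics: mean, median, std (population), min, max,
    skewness, kurtosis (non-excess; 0 by convention for constant series)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    std = float(np.std(x))
    if std > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            skew = float(sstats.skew(x, bias=True))
            kurt = float(sstats.kurtosis(x, fisher=False, bias=True))
        # scipy reports nan on catastrophic cancellation (near-constant
        # series); fall back to the constant-series convention
        if not np.isfinite(skew):
            skew = 0.0
        if not np.isfinite(kurt):
            kurt = 0.0
    else:
        skew = kurt = 0.0
    return np.array(
        [x.mean(), np.median(x), std, x.min(), x.max(), skew, kurt], dtype=float
    )


def fft_features(x: np.ndarray, n_coeff: int = 5) -> np.ndarray:
    """Magnitudes of the ``n_coeff`` lowest nonzero-frequency DFT
    coefficients of the mean-removed series.

    Fixed frequency positions keep feature meaning aligned across cells
    (selecting the largest magnitudes instead would not).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * n_coeff:
        raise ValueError(f"series of length {x.size} too short for {n_coeff} coefficients")
    spectrum = np.fft.rfft(x - x.mean())
    return np.abs(spectrum[1 : n_coeff + 1])


def dwt_features(x: np.ndarray, wavelet: str = "haar", level: int = 2) -> np.ndarray:
    """Orthonormal DWT coefficients: level-``level`` approximation followed
    by detail coefficients from coarsest to finest.

    Series whose length is not a power of two are zero-padded up to the
    next power (30 -> 32), which preserves Parseval energy for
    orthonormal wavelets.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 ** level:
        raise ValueError("series too short for requested decomposition level")
    n = int(2 ** np.ceil(np.log2(x.size)))
    if n != x.size:
        x = np.concatenate([x, np.zeros(n - x.size)])
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="periodization")
    return np.concatenate(coeffs)


def trend_features(x: np.ndarray, dt_min: float = 5.0) -> Tuple[float, float]:
    """Ordinary least-squares linear fit of value against time (minutes).

    Returns (slope per minute, intercept); captures the long-term change
    in the mean level of the feature.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    t = np.arange(x.size) * dt_min
    slope, intercept = np.polyfit(t, x, 1)
    return float(slope), float(intercept)


def approximate_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Approximate entropy ApEn(m, r) with r = r_factor * std(x).

    Phi_m is the mean log fraction of templates of length m within
    Chebyshev distance r (self-matches included); ApEn = Phi_m -
    Phi_{m+1}.  Repetitive series score low; a constant series returns 0
    by convention.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError("series too short for template length m")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = r_factor * sd

    def phi(mm: int) -> float:
        templates = np.lib.stride_tricks.sliding_window_view(x, mm)
        dist = np.max(
            np.abs(templates[:, None, :] - templates[None, :, :]), axis=2
        )
        counts = (dist <= r).mean(axis=1)
        return float(np.mean(np.log(counts)))

    return phi(m) - phi(m + 1)


def _sax_breakpoints(alphabet: int) -> np.ndarray:
    return sstats.norm.ppf(np.arange(1, alphabet) / alphabet)


def paa(x: np.ndarray, word_len: int) -> np.ndarray:
    """Piecewise aggregate approximation with fractional-overlap weighting.

    Segment s covers the real interval [s*n/w, (s+1)*n/w); sample i
    contributes to each segment in proportion to its overlap with [i, i+1).
    Exact for both divisible and non-divisible n/w.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < word_len:
        raise ValueError("series shorter than the PAA word length")
    edges = np.linspace(0.0, n, word_len + 1)
    out = np.empty(word_len)
    for s in range(word_len):
        lo, hi = edges[s], edges[s + 1]
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        idx = np.arange(i0, min(i1, n))
        weights = np.minimum(idx + 1, hi) - np.maximum(idx, lo)
        out[s] = np.sum(weights * x[idx]) / (hi - lo)
    return out


def sax_features(x: np.ndarray, word_len: int = 5, alphabet: int = 4) -> np.ndarray:
    """SAX symbol word as integer features in 0..alphabet-1.

    The series is z-normalised (a zero-variance series maps to the middle
    symbol, index alphabet // 2; values on a breakpoint round up), PAA-
    reduced to ``word_len`` segments and discretised by the standard
    Gaussian equiprobable breakpoints.
    """
    if not (2 <= alphabet <= 10):
        raise ValueError("alphabet size must be in [2, 10]")
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0:
        return np.full(word_len, alphabet // 2, dtype=float)
    z = (x - x.mean()) / sd
    segments = paa(z, word_len)
    symbols = np.searchsorted(_sax_breakpoints(alphabet), segments, side="right")
    return symbols.astype(float)


def motion_features(
    centroids_um: np.ndarray, dt_min: float = 5.0
) -> Tuple[float, float, float, float]:
    """Accumulated distance, Euclidean (net) distance, velocity, and
    directionality of a centroid trajectory.

    velocity = accumulated / elapsed time; directionality = euclidean /
    accumulated (1 for a perfectly straight path, and by convention for a
    stationary cell).
    """
    pts = np.asarray(centroids_um, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 centroids")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    accumulated = float(steps.sum())
    euclidean = float(np.linalg.norm(pts[-1] - pts[0]))
    velocity = accumulated / ((pts.shape[0] - 1) * dt_min)
    directionality = euclidean / accumulated if accumulated > 0 else 1.0
    return accumulated, euclidean, velocity, directionality


class PCAFeatures:
    """PCA scores of flattened multivariate series, fitted on training
    cells only so held-out projections stay leakage-free."""

    def __init__(self, n_components: int = 3):
        self.n_components = n_components
        self._pca: Optional[PCA] = None

    def fit(self, flattened_train: np.ndarray) -> "PCAFeatures":
        n_comp = min(self.n_components, *flattened_train.shape)
        self._pca = PCA(n_components=n_comp, svd_solver="full")
        self._pca.fit(flattened_train)
        return self

    def transform(self, flattened: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise RuntimeError("PCAFeatures not fitted")
        scores = self._pca.transform(np.atleast_2d(flattened))
        if scores.shape[1] < self.n_components:  # degenerate training sets
            pad = np.zeros((scores.shape[0], self.n_components - scores.shape[1]))
            scores = np.hstack([scores, pad])
        return scores


def flatten_series(series: MultivariateSeries) -> np.ndarray:
    """Column-major flattening (feature by feature) of the n x d table."""
    return series.values.T.ravel()


def _partial_names(feature: str, cfg: TransformConfig, n_dwt: int) -> List[str]:
    names = [f"{feature}__stat_{s}" for s in STAT_NAMES]
    names += [f"{feature}__fft_{k + 1}" for k in range(cfg.n_fft_coeff)]
    names += [f"{feature}__dwt_{k}" for k in range(n_dwt)]
    names += [f"{feature}__trend_slope", f"{feature}__trend_intercept"]
    names += [f"{feature}__apen"]
    names += [f"{feature}__sax_{k}" for k in range(cfg.sax_word_len)]
    return names


def partial_vector(x: np.ndarray, dt_min: float, cfg: TransformConfig) -> np.ndarray:
    """Partial time-lapse feature vector of one univariate series."""
    return np.concatenate(
        [
            stat_features(x),
            fft_features(x, cfg.n_fft_coeff),
            dwt_features(x, cfg.wavelet, cfg.dwt_level),
            np.array(trend_features(x, dt_min)),
            np.array([approximate_entropy(x, cfg.apen_m, cfg.apen_r_factor)]),
            sax_features(x, cfg.sax_word_len, cfg.sax_alphabet),
        ]
    )


def assemble_feature_based(
    series: MultivariateSeries,
    cfg: Optional[TransformConfig] = None,
    pca_scores: Optional[np.ndarray] = None,
    pixel_size_um: float = 1.0,
) -> TimelapseFeatureVector:
    """Concatenate the d partial vectors, then PCA scores, then the four
    motion features, in a deterministic mechanically-named order."""
    cfg = cfg or TransformConfig()
    parts: List[np.ndarray] = []
    names: List[str] = []
    n_dwt = dwt_features(series.values[:, 0], cfg.wavelet, cfg.dwt_level).size
    for j, feature in enumerate(series.feature_names):
        parts.append(partial_vector(series.values[:, j], series.frame_interval_min, cfg))
        names += _partial_names(feature, cfg, n_dwt)
    if pca_scores is not None:
        pca_scores = np.ravel(pca_scores)
        parts.append(pca_scores)
        names += [f"pca_{k + 1}" for k in range(pca_scores.size)]
    motion = motion_features(
        series.centroids_px * pixel_size_um, series.frame_interval_min
    )
    parts.append(np.array(motion))
    names += [
        "motion_accumulated_um",
        "motion_euclidean_um",
        "motion_velocity_um_per_min",
        "motion_directionality",
    ]
    return TimelapseFeatureVector(
        cell_id=series.cell_id,
        values=np.concatenate(parts),
        names=tuple(names),
        approach="feature_based",
    )


def assemble_value_based(series: MultivariateSeries) -> TimelapseFeatureVector:
    """Raw concatenation of the univariate series, one after another."""
    n = series.values.shape[0]
    names = [
        f"{feature}__t{t}" for feature in series.feature_names for t in range(n)
    ]
    return TimelapseFeatureVector(
        cell_id=series.cell_id,
        values=flatten_series(series),
        names=tuple(names),
        approach="value_based",
    )


def fit_apply_normalization(
    train: np.ndarray, test: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, Optional[np.ndarray], NormalizationStats]:
    """Min-max scale to [0, 1] with statistics from the training matrix.

    Test values outside the training range are clipped; zero-range
    features map to 0.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("training matrix must be non-empty")
    stats = NormalizationStats(train.min(axis=0), train.max(axis=0))
    train_scaled = stats.apply(train)
    test_scaled = stats.apply(np.asarray(test, dtype=float)) if test is not None else None
    return train_scaled, test_scaled, stats
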