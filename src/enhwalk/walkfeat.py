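"""Statistical and nonlinear features of the DNA walk.

The canonical feature set has exactly 8 entries, in fixed order:

``sd``      sample standard deviation of the walk
``dfa``     detrended-fluctuation scaling exponent (DFA-1) of the walk
``ac``      sample autocorrelation of the walk at lag 100
``ac_200``  ... at lag 200
``ac_300``  ... at lag 300
``sampen``  sample entropy of the walk (m = 2, r = 0.2 x SD)
``hurst``   rescaled-range Hurst exponent of the *step* series
``rvntsl``  (# distinct walk values) / walk length

The split of inputs is deliberate: DFA, entropy, autocorrelation and
rvntsl see the cumulative walk (a non-stationary, integrated series —
DFA of an uncorrelated-base walk scales with alpha ~ 1.5), while R/S
analysis sees the +/-1 increments, for which uncorrelated steps give the
Brownian value K = 0.5.

A largest-Lyapunov-exponent estimator (Rosenstein-style) and a set of
extended descriptive statistics are provided as standalone operations;
they are not part of the canonical 8-vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import cdist
from scipy.special import gammaln

from .errors import DegenerateSeriesError
from .walk import DNAWalk

logger = logging.getLogger(__name__)

WALK_FEATURE_NAMES = ("sd", "dfa", "ac", "ac_200", "ac_300", "sampen", "hurst", "rvntsl")
N_WALK_FEATURES = len(WALK_FEATURE_NAMES)
AC_LAGS = (100, 200, 300)


@dataclass(frozen=True)
class WalkFeatures:
    sd: float
    dfa: float
    ac: float
    ac_200: float
    ac_300: float
    sampen: float
    hurst: float
    rvntsl: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


@dataclass(frozen=True)
class SampEnParams:
    """Template length m and tolerance r (absolute; resolved from SD upstream)."""

    m: int = 2
    r: Optional[float] = None  # None -> 0.2 x series SD
    r_sd_factor: float = 0.2


@dataclass(frozen=True)
class HurstFit:
    K: float
    chunk_sizes: np.ndarray
    rescaled_ranges: np.ndarray  # mean R/sigma per chunk size
    fit_intercept: float


@dataclass(frozen=True)
class DFAFit:
    alpha: float
    window_sizes: np.ndarray
    fluctuations: np.ndarray
    poly_order: int


@dataclass(frozen=True)
class LyapunovFit:
    lambda_max: float
    lag: int
    emb_dim: int
    divergence_curve: np.ndarray  # <ln d(k)> for k = 1..traj_len (NaN where empty)
    fit_range: tuple[int, int]


def _as_series(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-D series")
    return a


def autocorrelation(x: Sequence[float], lag: int) -> float:
    """Sample autocorrelation rho(lag).

    rho(lag) = sum_{t=1..N-lag} (x_t - xbar)(x_{t+lag} - xbar)
             / sum_{t=1..N}     (x_t - xbar)^2
    """
    a = _as_series(x)
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if len(a) <= lag:
        raise DegenerateSeriesError(f"series length {len(a)} <= lag {lag}")
    d = a - a.mean()
    denom = float(d @ d)
    if denom == 0.0:
        raise DegenerateSeriesError("zero-variance series: autocorrelation undefined")
    if lag == 0:
        return 1.0
    return float(d[:-lag] @ d[lag:]) / denom


def rvntsl(walk: Sequence[float]) -> float:
    """Ratio of the number of distinct values attained to the series length."""
    a = np.asarray(walk)
    if a.size == 0:
        raise DegenerateSeriesError("empty series")
    return len(np.unique(a)) / a.size


def sample_entropy(x: Sequence[float], params: SampEnParams = SampEnParams()) -> float:
    """Sample entropy -ln(A/B) with Chebyshev template matching.

    B counts ordered template pairs (i != j, self-matches excluded) of
    length m within tolerance r; A the same at length m + 1. Both counts
    range over the first N - m templates (Richman-Moorman convention).
    Returns NaN when A or B is zero (undefined, reported as missing).
    """
    a = _as_series(x)
    m = params.m
    if m < 1:
        raise ValueError("template length m must be >= 1")
    N = len(a)
    if N < m + 2:
        raise DegenerateSeriesError(f"series length {N} < m + 2 = {m + 2}")
    r = params.r
    if r is None:
        sd = a.std(ddof=1)
        if sd == 0:
            raise DegenerateSeriesError("zero-variance series with SD-relative tolerance")
        r = params.r_sd_factor * sd
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    M = N - m  # number of (m+1)-length templates; m-templates restricted to same range
    D = np.abs(a[:, None] - a[None, :])
    cheb_m = D[:M, :M].copy()
    for off in range(1, m):
        np.maximum(cheb_m, D[off : off + M, off : off + M], out=cheb_m)
    cheb_m1 = np.maximum(cheb_m, D[m : m + M, m : m + M])
    iu = np.triu_indices(M, k=1)
    B = int(np.count_nonzero(cheb_m[iu] <= r))
    A = int(np.count_nonzero(cheb_m1[iu] <= r))
    if A == 0 or B == 0:
        return float("nan")
    return float(-np.log(A / B))


def _expected_rs(n: int) -> float:
    """Anis-Lloyd expected R/S of an i.i.d. series, with the Peters
    small-sample factor (n - 1/2)/n."""
    i = np.arange(1, n)
    s = float(np.sum(np.sqrt((n - i) / i)))
    if n <= 340:
        front = np.exp(gammaln((n - 1) / 2) - gammaln(n / 2)) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2)
    return front * s * (n - 0.5) / n


def hurst_rs(steps: Sequence[float], min_chunk: int = 8, corrected: bool = True) -> HurstFit:
    """Rescaled-range (R/S) Hurst exponent of a step/increment series.

    Chunk sizes are powers of 2 in [min_chunk, L/2]. Per chunk: R is the
    range of the mean-adjusted cumulative sum, sigma the sample SD; the
    mean R/sigma per size is regressed (log-log, OLS) against size.
    ``corrected`` applies the Anis-Lloyd-Peters finite-sample expectation,
    without which R/S overestimates K on short series; K is then 0.5 plus
    the slope of the log-deviation from that expectation.
    """
    a = _as_series(steps)
    L = len(a)
    if L < 8 * min_chunk:
        raise DegenerateSeriesError(f"series length {L} too short for R/S analysis")
    sizes = []
    n = min_chunk
    while n <= L // 2:
        sizes.append(n)
        n *= 2
    mean_rs, used = [], []
    for n in sizes:
        k = L // n
        chunks = a[: k * n].reshape(k, n)
        sd = chunks.std(axis=1, ddof=1)
        ok = sd > 0
        if not ok.any():
            continue
        Z = np.cumsum(chunks[ok] - chunks[ok].mean(axis=1, keepdims=True), axis=1)
        R = Z.max(axis=1) - Z.min(axis=1)
        mean_rs.append(float(np.mean(R / sd[ok])))
        used.append(n)
    if len(used) < 3:
        raise DegenerateSeriesError("degenerate series: fewer than 3 usable R/S chunk sizes")
    used_a = np.array(used, dtype=float)
    rs_a = np.array(mean_rs)
    logn = np.log(used_a)
    y = np.log(rs_a)
    if corrected:
        y = y - np.log([_expected_rs(int(n)) for n in used])
    slope, intercept = np.polyfit(logn, y, 1)
    K = (0.5 + slope) if corrected else slope
    return HurstFit(K=float(K), chunk_sizes=used_a.astype(int), rescaled_ranges=rs_a,
                    fit_intercept=float(intercept))


def dfa_exponent(
    x: Sequence[float],
    poly_order: int = 1,
    window_sizes: Optional[Sequence[int]] = None,
    n_sizes: int = 12,
) -> DFAFit:
    """Detrended fluctuation analysis scaling exponent alpha.

    The profile is the cumulative sum of the mean-centered input; each
    window size n partitions the profile into floor(L/n) windows, each
    detrended by a least-squares polynomial of ``poly_order``; alpha is
    the OLS slope of log RMS fluctuation against log n over a geometric
    grid of ~``n_sizes`` sizes in [4, L/4].
    """
    a = _as_series(x)
    L = len(a)
    if L < 100:
        raise DegenerateSeriesError(f"series length {L} < 100: DFA unreliable, refused")
    profile = np.cumsum(a - a.mean())
    if window_sizes is None:
        window_sizes = np.unique(np.round(np.geomspace(4, L // 4, n_sizes)).astype(int))
    window_sizes = np.asarray(window_sizes, dtype=int)
    flucts, used = [], []
    for n in window_sizes:
        if n < poly_order + 2 or n > L:
            continue
        k = L // n
        W = profile[: k * n].reshape(k, n).T  # (n, k): one column per window
        V = np.vander(np.arange(n, dtype=float), poly_order + 1)
        coef, *_ = np.linalg.lstsq(V, W, rcond=None)
        resid = W - V @ coef
        F = float(np.sqrt(np.mean(resid**2)))
        if F <= 0:
            logger.warning("DFA: zero fluctuation at window size %d; scale dropped", n)
            continue
        flucts.append(F)
        used.append(int(n))
    if len(used) < 4:
        raise DegenerateSeriesError("fewer than 4 usable DFA window sizes")
    used_a = np.array(used, dtype=float)
    F_a = np.array(flucts)
    alpha = float(np.polyfit(np.log(used_a), np.log(F_a), 1)[0])
    return DFAFit(alpha=alpha, window_sizes=used_a.astype(int), fluctuations=F_a,
                  poly_order=poly_order)


def _first_acf_minimum(a: np.ndarray, max_lag: int) -> int:
    prev = 1.0
    for lag in range(1, max_lag + 1):
        cur = autocorrelation(a, lag)
        if cur > prev:
            return max(lag - 1, 1)
        prev = cur
    return max_lag


def lyapunov_max(
    x: Sequence[float],
    lag: Optional[int] = None,
    emb_dim: int = 10,
    min_tsep: Optional[int] = None,
    traj_len: int = 20,
    fit_range: Optional[tuple[int, int]] = None,
) -> LyapunovFit:
    """Largest Lyapunov exponent via nearest-neighbor divergence
    (Rosenstein method).

    The series is delay-embedded (dimension ``emb_dim``, delay ``lag``;
    default lag is the first minimum of the autocorrelation function).
    Each embedded point is paired with its Euclidean nearest neighbor at
    temporal separation > ``min_tsep``; lambda is the OLS slope of the
    mean log-divergence <ln d(k)> over the initial linear region. With
    ``fit_range=None`` that region is detected as the prefix of the curve
    whose per-step increment stays above half the initial increment
    (divergence saturates at the attractor diameter, flattening the tail).
    """
    a = _as_series(x)
    L = len(a)
    if lag is None:
        lag = _first_acf_minimum(a, max_lag=min(50, L // 4))
    if min_tsep is None:
        min_tsep = lag
    M = L - (emb_dim - 1) * lag
    if M < traj_len + min_tsep + 2:
        raise DegenerateSeriesError(
            f"series length {L} too short to embed (dim {emb_dim}, lag {lag})"
        )
    idx = np.arange(M)
    emb = a[idx[:, None] + np.arange(emb_dim) * lag]
    D = cdist(emb, emb)
    D[np.abs(idx[:, None] - idx[None, :]) <= min_tsep] = np.inf
    nn = D.argmin(axis=1)
    if not np.isfinite(D[idx, nn]).any():
        raise DegenerateSeriesError("no valid neighbor pairs under temporal exclusion")

    ks = np.arange(1, traj_len + 1)
    curve = np.full(traj_len, np.nan)
    for j, k in enumerate(ks):
        valid = (idx + k < M) & (nn + k < M) & np.isfinite(D[idx, nn])
        if not valid.any():
            continue
        d = np.linalg.norm(emb[idx[valid] + k] - emb[nn[valid] + k], axis=1)
        d = d[d > 0]
        if d.size:
            curve[j] = np.mean(np.log(d))

    if fit_range is None:
        inc = np.diff(curve)
        hi = traj_len
        if len(inc) and np.isfinite(inc[0]) and inc[0] > 0:
            below = np.flatnonzero(~(inc > inc[0] / 2))
            if below.size:
                hi = max(int(below[0]) + 1, 3)
        fit_range = (1, hi)
    lo, hi = fit_range
    sel = (ks >= lo) & (ks <= hi) & np.isfinite(curve)
    if sel.sum() < 2:
        raise DegenerateSeriesError("divergence curve too short to fit")
    lam = float(np.polyfit(ks[sel], curve[sel], 1)[0])
    return LyapunovFit(lambda_max=lam, lag=int(lag), emb_dim=emb_dim,
                       divergence_curve=curve, fit_range=(int(lo), int(hi)))


def extended_stats(x: Sequence[float]) -> dict[str, float]:
    """Descriptive statistics of a walk series.

    Returns max, min, skewness (biased, Fisher-Pearson), excess kurtosis,
    interquartile range, zero/mean crossing rates ((# strict sign changes
    of the level-shifted series) / (L - 1)) and spectral entropy (Shannon
    entropy of the normalized positive-frequency periodogram of the
    mean-centered series, scaled by log #bins into [0, 1]). Moment-based
    entries are NaN on a zero-variance series.
    """
    a = _as_series(x)
    if len(a) < 4:
        raise DegenerateSeriesError(f"series length {len(a)} < 4")
    out: dict[str, float] = {"max": float(a.max()), "min": float(a.min())}
    degenerate = a.var() == 0

    out["skewness"] = float("nan") if degenerate else float(sps.skew(a))
    out["kurtosis"] = float("nan") if degenerate else float(sps.kurtosis(a))
    out["interquartile_range"] = float(sps.iqr(a))

    def crossing_rate(level: float) -> float:
        d = a - level
        return int(np.count_nonzero(d[:-1] * d[1:] < 0)) / (len(a) - 1)

    out["zero_crossing_rate"] = crossing_rate(0.0)
    out["mean_crossing_rate"] = crossing_rate(float(a.mean()))

    if degenerate:
        out["spectral_entropy"] = float("nan")
    else:
        power = np.abs(np.fft.rfft(a - a.mean()))[1:] ** 2
        p = power / power.sum()
        nz = p[p > 0]
        out["spectral_entropy"] = float(-(nz * np.log(nz)).sum() / np.log(len(p)))
    return out


def pairwise_feature_correlation(rows: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix across feature columns (reporting aid)."""
    return np.corrcoef(np.asarray(rows, dtype=float), rowvar=False)


def walk_features(walk: DNAWalk, sampen_params: SampEnParams = SampEnParams()) -> WalkFeatures:
    """Assemble the canonical 8 features from one DNA walk.

    Deterministic; raises on degenerate inputs (e.g. a homopyrimidine
    sequence, whose step series has zero variance everywhere).
    """
    if walk.length < max(AC_LAGS) + 2:
        raise DegenerateSeriesError(
            f"walk length {walk.length} < {max(AC_LAGS) + 2}: lag-300 statistics undefined"
        )
    w = walk.walk.astype(float)
    return WalkFeatures(
        sd=float(np.std(w, ddof=1)),
        dfa=dfa_exponent(w).alpha,
        ac=autocorrelation(w, AC_LAGS[0]),
        ac_200=autocorrelation(w, AC_LAGS[1]),
        ac_300=autocorrelation(w, AC_LAGS[2]),
        sampen=sample_entropy(w, sampen_params),
        hurst=hurst_rs(walk.steps.astype(float)).K,
        rvntsl=rvntsl(walk.walk),
    )
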