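"""Independent brute-force oracles and reference signal generators.

Everything here is deliberately naive (loops, O(N^2) scans, textbook
formulas) and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_kmer_count(seq: str, kmer: str) -> int:
    """Position-by-position overlapping substring scan."""
    k = len(kmer)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == kmer)


def naive_autocorrelation(x, lag: int) -> float:
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    num = sum((x[t] - mean) * (x[t + lag] - mean) for t in range(n - lag))
    den = sum((v - mean) ** 2 for v in x)
    return num / den


def naive_sample_entropy(x, m: int, r: float) -> float:
    """Exhaustive ordered-pair template count, Richman-Moorman ranges."""
    x = list(map(float, x))
    N = len(x)
    M = N - m

    def cheb(i, j, length):
        return max(abs(x[i + a] - x[j + a]) for a in range(length))

    B = sum(1 for i in range(M) for j in range(i + 1, M) if cheb(i, j, m) <= r)
    A = sum(1 for i in range(M) for j in range(i + 1, M) if cheb(i, j, m + 1) <= r)
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def naive_extended_stats(x) -> dict:
    """Direct-formula evaluation of every descriptive statistic."""
    a = np.asarray(x, dtype=float)
    n = len(a)
    mean = a.sum() / n
    dev = a - mean
    m2 = (dev**2).sum() / n
    m3 = (dev**3).sum() / n
    m4 = (dev**4).sum() / n
    out = {
        "max": a.max(),
        "min": a.min(),
        "skewness": m3 / m2**1.5,
        "kurtosis": m4 / m2**2 - 3.0,
        "interquartile_range": np.percentile(a, 75) - np.percentile(a, 25),
    }
    for name, level in (("zero_crossing_rate", 0.0), ("mean_crossing_rate", mean)):
        count = sum(1 for t in range(n - 1) if (a[t] - level) * (a[t + 1] - level) < 0)
        out[name] = count / (n - 1)
    spec = np.abs(np.fft.rfft(a - mean))[1:] ** 2
    p = spec / spec.sum()
    out["spectral_entropy"] = -sum(v * math.log(v) for v in p if v > 0) / math.log(len(p))
    return out


def naive_auc(scores, labels) -> float:
    """Mann-Whitney: fraction of (positive, negative) pairs ranked
    concordantly, ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def naive_lyapunov_curve(x, lag: int, emb_dim: int, min_tsep: int, traj_len: int):
    """All-pairs nearest-neighbor divergence curve <ln d(k)>, loop form."""
    x = list(map(float, x))
    M = len(x) - (emb_dim - 1) * lag
    emb = [[x[i + a * lag] for a in range(emb_dim)] for i in range(M)]

    def dist(i, j):
        return math.sqrt(sum((emb[i][a] - emb[j][a]) ** 2 for a in range(emb_dim)))

    nn = []
    for i in range(M):
        best, best_j = float("inf"), -1
        for j in range(M):
            if abs(i - j) <= min_tsep:
                continue
            d = dist(i, j)
            if d < best:
                best, best_j = d, j
        nn.append(best_j)
    curve = []
    for k in range(1, traj_len + 1):
        logs = []
        for i in range(M):
            j = nn[i]
            if j < 0 or i + k >= M or j + k >= M:
                continue
            d = dist(i + k, j + k)
            if d > 0:
                logs.append(math.log(d))
        curve.append(sum(logs) / len(logs) if logs else float("nan"))
    return curve


def fractional_gaussian_noise(n: int, H: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fGn sample via Davies-Harte circulant embedding."""
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    eig = np.fft.fft(row).real
    eig = np.clip(eig, 0, None)  # tiny negatives from round-off
    m = 2 * n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    f = np.fft.fft(z * np.sqrt(eig / (2 * m)))
    return f.real[:n]


def logistic_map(n: int, x0: float = 0.34, r: float = 4.0) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    for i in range(n - 1):
        x[i + 1] = r * x[i] * (1 - x[i])
    return x
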