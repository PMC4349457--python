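"""Log-domain partition-function recursions for 1-D hard rods.

Exact equilibrium statistics of non-overlapping rods of length F on a
lattice of L sites with per-start log-weights log w(i) = mu - E(i)
(Percus-style transfer recursions).  Kernels are JIT-compiled with numba
when it is importable and run as plain Python otherwise; both paths execute
the same function bodies.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        def deco(f):
            return f
        return deco

NEG_INF = -np.inf


@njit(cache=True)
def _ladd(a: float, b: float) -> float:
    """log(exp(a) + exp(b)) without overflow; tolerates -inf."""
    if a < b:
        a, b = b, a
    if b == NEG_INF:
        return a
    return a + math.log1p(math.exp(b - a))


@njit(cache=True)
def forward_logz(logw: np.ndarray, F: int) -> np.ndarray:
    """logZf[j] = log partition function of lattice sites [0, j).

    logw has one entry per admissible start (n = L - F + 1 entries);
    Zf[j] = Zf[j-1] + w[j-F] * Zf[j-F].
    """
    n = logw.shape[0]
    L = n + F - 1
    logZ = np.empty(L + 1)
    logZ[0] = 0.0
    for j in range(1, L + 1):
        v = logZ[j - 1]
        if j >= F:
            v = _ladd(v, logw[j - F] + logZ[j - F])
        logZ[j] = v
    return logZ


@njit(cache=True)
def backward_logz(logw: np.ndarray, F: int) -> np.ndarray:
    """logZb[j] = log partition function of lattice sites [j, L)."""
    n = logw.shape[0]
    L = n + F - 1
    logZ = np.empty(L + 1)
    logZ[L] = 0.0
    for j in range(L - 1, -1, -1):
        v = logZ[j + 1]
        if j < n:
            v = _ladd(v, logw[j] + logZ[j + F])
        logZ[j] = v
    return logZ


@njit(cache=True)
def _segment_logz(logw2: np.ndarray, start: int, L_seg: int, F: int) -> float:
    """log partition of a linear segment of L_seg sites whose admissible
    starts are logw2[start : start + L_seg - F + 1] (doubled-array view)."""
    if L_seg < F:
        return 0.0
    n = L_seg - F + 1
    buf = np.empty(L_seg + 1)
    buf[0] = 0.0
    for j in range(1, L_seg + 1):
        v = buf[j - 1]
        if j >= F:
            v = _ladd(v, logw2[start + j - F] + buf[j - F])
        buf[j] = v
    return buf[L_seg]


def linear_stats(logw: np.ndarray, F: int):
    """Start probabilities and log partition function, linear lattice.

    Returns (s, logZ) where s[i] = P(a rod starts at site i).
    """
    logw = np.ascontiguousarray(logw, dtype=np.float64)
    n = logw.shape[0]
    logZf = forward_logz(logw, F)
    logZb = backward_logz(logw, F)
    logZ = logZf[n + F - 1]
    with np.errstate(invalid="ignore"):
        s = np.exp(logZf[:n] + logw + logZb[F:n + F] - logZ)
    s[~np.isfinite(s)] = 0.0
    return s, logZ


@njit(cache=True)
def _circular_core(logw: np.ndarray, F: int):
    L = logw.shape[0]
    logw2 = np.concatenate((logw, logw))
    # conditioned on a rod at start i, the complement is a linear arc of
    # L - F sites beginning at i + F
    lse = NEG_INF
    cond = np.empty(L)
    for i in range(L):
        cond[i] = logw[i] + _segment_logz(logw2, i + F, L - F, F)
        lse = _ladd(lse, cond[i])
    # partition function: cut the bond (L-1, 0); either no rod crosses it
    # (plain linear lattice) or exactly one rod crosses, starting at
    # i in [L-F+1, L-1]
    buf = np.empty(L + 1)
    buf[0] = 0.0
    for j in range(1, L + 1):
        v = buf[j - 1]
        if j >= F and j - F <= L - F:
            v = _ladd(v, logw[j - F] + buf[j - F])
        buf[j] = v
    logZ = buf[L]
    for i in range(L - F + 1, L):
        logZ = _ladd(logZ, logw[i] + _segment_logz(logw2, i + F, L - F, F))
    return cond, logZ


def circular_stats(logw: np.ndarray, F: int):
    """Start probabilities and log partition function, circular lattice.

    Every one of the L sites is an admissible start; complexity O(L^2).
    """
    logw = np.ascontiguousarray(logw, dtype=np.float64)
    L = logw.shape[0]
    if L < F:
        raise ValueError("circular lattice shorter than the rod")
    cond, logZ = _circular_core(logw, F)
    with np.errstate(invalid="ignore"):
        s = np.exp(cond - logZ)
    s[~np.isfinite(s)] = 0.0
    return s, logZ


def coverage_from_starts(s: np.ndarray, F: int, circular: bool) -> np.ndarray:
    """Per-base occupancy o(j) = sum of s over the starts covering j."""
    if circular:
        L = s.shape[0]
        ext = np.concatenate([s, s[:F - 1]])
        o = np.convolve(ext, np.ones(F), mode="full")[F - 1:F - 1 + L]
        return o
    return np.convolve(s, np.ones(F), mode="full")


def enumerate_stats(logw: np.ndarray, F: int, circular: bool):
    """Brute-force oracle: enumerate every non-overlapping rod configuration.

    Exponential; intended for lattices of L <= ~16 in tests.  Returns
    (s, logZ) on the same convention as the recursions.
    """
    logw = np.asarray(logw, dtype=float)
    if circular:
        L = logw.shape[0]
        starts = list(range(L))
        def overlaps(i, j):
            d = (j - i) % L
            return d < F or (i - j) % L < F
    else:
        n = logw.shape[0]
        L = n + F - 1
        starts = list(range(n))
        def overlaps(i, j):
            return abs(i - j) < F

    configs = [[]]
    for i in starts:
        new = []
        for cfg in configs:
            if all(not overlaps(i, j) for j in cfg):
                new.append(cfg + [i])
        configs.extend(new)
    weights = np.array([sum(logw[i] for i in cfg) for cfg in configs])
    m = weights.max()
    Z = np.exp(weights - m).sum()
    logZ = m + math.log(Z)
    s = np.zeros(len(starts))
    for cfg, wt in zip(configs, weights):
        p = math.exp(wt - logZ)
        for i in cfg:
            s[i] += p
    return s, logZ
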