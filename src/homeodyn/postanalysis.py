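"""Characterisation of stable treatments.

Given treated trajectories and eigensystems, this module provides:

* DTW k-means clustering of the 14 per-factor time series (k=3) and
  co-occurrence counting across treatments,
* K-means clustering of treatments in a 16-dimensional eigenvalue
  feature space (min/max/mean/std of Re, Im, modulus, argument; k=9),
* dominant-term tables of the analytic solution, either by term
  magnitude exp(Re(lambda) t)|v_ij| at t = 100 days or by
  characteristic decay rate |Re(lambda)||v_ij| of the slow modes,
  flagging terms within 5% of the factor's extremal term,
* spectrogram/PSD (Hann STFT, 16-day segments, 8-day overlap),
  PSD-discrepancy, zero-lag cross-correlation and Pearson correlation
  of the 105 factor pairs (self-pairs included), and aggregation of the
  three per-metric rankings into a final pair ranking by rank sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal
from sklearn.cluster import KMeans

from .dynamics import EigenSystem, Trajectory
from .ontology import FACTORS

__all__ = [
    "DominantTermTable",
    "PairMetricRanking",
    "DTWKMeansResult",
    "dtw_distance",
    "dtw_kmeans",
    "cluster_cooccurrence",
    "eigen_feature_clustering",
    "eigen_features",
    "dominant_terms_by_magnitude",
    "dominant_terms_by_decay",
    "spectrogram_psd",
    "psd_discrepancy",
    "xcorr_zero",
    "pearson_pairs",
    "factor_pairs",
    "rank_pair_metrics",
    "aggregate_pair_ranking",
]


# --------------------------------------------------------------------------
# DTW k-means
# --------------------------------------------------------------------------

@njit(cache=True)
def _dtw_sq(x: np.ndarray, y: np.ndarray) -> float:  # pragma: no cover - numba
    n, m = len(x), len(y)
    big = 1e300
    prev = np.full(m + 1, big)
    prev[0] = 0.0
    for i in range(n):
        cur = np.full(m + 1, big)
        for j in range(m):
            d = x[i] - y[j]
            best = prev[j]
            if prev[j + 1] < best:
                best = prev[j + 1]
            if cur[j] < best:
                best = cur[j]
            cur[j + 1] = d * d + best
        prev = cur
    return prev[m]


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Dynamic-time-warping distance (sqrt of accumulated squared cost)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("dtw_distance expects 1-D series")
    return float(np.sqrt(_dtw_sq(x, y)))


@dataclass
class DTWKMeansResult:
    labels: np.ndarray
    centers: np.ndarray
    inertia: float


def dtw_kmeans(
    series: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 30,
) -> DTWKMeansResult:
    """K-means over equal-length time series with DTW assignment.

    Centers are the pointwise means of their members (series share one
    day grid); assignment uses DTW distance; inertia is the sum of
    squared DTW distances to the assigned center.  The best of
    ``n_restarts`` seeded restarts is kept, so results are reproducible
    for a fixed seed.
    """
    S = np.asarray(series, dtype=float)
    if S.ndim != 2:
        raise ValueError("series must be a (n_series, n_timepoints) array")
    n = S.shape[0]
    if len(np.unique(S, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct series for {k} clusters")
    rng = np.random.default_rng(seed)

    best: DTWKMeansResult | None = None
    for _ in range(n_restarts):
        centers = S[rng.choice(n, size=k, replace=False)].copy()
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            D = np.empty((n, k))
            for i in range(n):
                for c in range(k):
                    D[i, c] = _dtw_sq(S[i], centers[c])
            new_labels = np.argmin(D, axis=1)
            for c in range(k):
                members = S[new_labels == c]
                if len(members) == 0:  # re-seed empty cluster on farthest series
                    far = int(np.argmax(D[np.arange(n), new_labels]))
                    centers[c] = S[far]
                    new_labels[far] = c
                else:
                    centers[c] = members.mean(axis=0)
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
        inertia = float(
            sum(_dtw_sq(S[i], centers[labels[i]]) for i in range(n))
        )
        if best is None or inertia < best.inertia:
            best = DTWKMeansResult(labels.copy(), centers.copy(), inertia)
    assert best is not None
    return best


def cluster_cooccurrence(labelings: Sequence[np.ndarray]) -> np.ndarray:
    """Frequency table: how often each factor pair shares a cluster.

    Entry (a, b) counts the labelings that put a and b in the same
    cluster; symmetric, with the diagonal equal to the number of
    labelings.
    """
    labelings = [np.asarray(l) for l in labelings]
    if len(labelings) == 0:
        raise ValueError("at least one labeling is required")
    n = len(labelings[0])
    table = np.zeros((n, n), dtype=int)
    for lab in labelings:
        if len(lab) != n:
            raise ValueError("labelings must have equal lengths")
        table += (lab[:, None] == lab[None, :]).astype(int)
    return table


# --------------------------------------------------------------------------
# eigenvalue feature clustering
# --------------------------------------------------------------------------

_EIG_CHARACTERISTICS = ("real", "imag", "modulus", "argument")
_EIG_STATS = ("min", "max", "mean", "std")


def eigen_features(E: EigenSystem) -> pd.Series:
    """16 summary features of an eigensystem's spectrum.

    Min/max/mean/population-std of the real parts, imaginary parts,
    moduli and arguments of the eigenvalues.
    """
    lam = E.lambdas
    chars = {
        "real": lam.real,
        "imag": lam.imag,
        "modulus": np.abs(lam),
        "argument": np.angle(lam),
    }
    feats = {}
    for cname in _EIG_CHARACTERISTICS:
        v = chars[cname]
        feats[f"{cname}_min"] = float(np.min(v))
        feats[f"{cname}_max"] = float(np.max(v))
        feats[f"{cname}_mean"] = float(np.mean(v))
        feats[f"{cname}_std"] = float(np.std(v))  # population convention
    return pd.Series(feats)


def eigen_feature_clustering(
    eigensystems: Sequence[EigenSystem],
    k: int = 9,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """K-means over z-scored eigenvalue features; returns labels and centers.

    Features with zero variance across treatments are dropped with a
    warning (they carry no clustering information and break z-scoring).
    Cluster centers are reported in the original feature units.
    """
    if len(eigensystems) < k:
        raise ValueError(f"need at least {k} treatments for {k} clusters")
    X = pd.DataFrame([eigen_features(E) for E in eigensystems])
    sd = X.std(ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance eigen features: {dead}")
        X = X.drop(columns=dead)
        sd = sd.drop(dead)
    if X.shape[1] == 0:  # all spectra identical: one effective cluster
        centers = pd.DataFrame(columns=pd.Index([], dtype=object))
        centers.index.name = "cluster"
        return np.zeros(len(eigensystems), dtype=int), centers
    Z = (X - X.mean()) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z.to_numpy())
    centers = pd.DataFrame(
        km.cluster_centers_ * sd.to_numpy() + X.mean().to_numpy(), columns=X.columns
    )
    centers.index.name = "cluster"
    return labels, centers


# --------------------------------------------------------------------------
# dominant terms of the analytic solution
# --------------------------------------------------------------------------

@dataclass
class DominantTermTable:
    """Boolean table: is eigen-term i dominant for factor j?

    ``scores[i, j]`` is the criterion value (term magnitude at the
    reference day, or characteristic decay rate); ``flags`` marks terms
    within ``tolerance`` (fractionally) of the factor's extremal score.
    """

    flags: np.ndarray
    scores: np.ndarray
    criterion: str  # "magnitude_t100" | "decay_rate"
    tolerance: float


def dominant_terms_by_magnitude(
    E: EigenSystem, t: float = 100.0, tol: float = 0.05
) -> DominantTermTable:
    """Dominant eigen-terms by magnitude at ``t`` days (default 100).

    The general magnitude of term i for factor j, ignoring the
    initial-condition coefficient, is exp(Re(lambda_i) t) |v_ij|.  Terms
    within ``tol`` of the factor's largest magnitude are flagged; around
    day 100 (ALS onset, half the ~200-day ALS lifespan) these are the
    modes shaping disease dynamics.
    """
    scores = np.exp(E.lambdas.real[:, None] * t) * np.abs(E.vectors.T)
    top = scores.max(axis=0, keepdims=True)
    flags = scores >= (1.0 - tol) * top
    return DominantTermTable(flags, scores, "magnitude_t100", tol)


def dominant_terms_by_decay(
    E: EigenSystem,
    tol: float = 0.05,
    t_ref: float = 200.0,
    slow_cutoff: float = 0.1,
) -> DominantTermTable:
    """Dominant slow eigen-terms by characteristic decay rate.

    Valid only for stable systems: exp(Re(lambda) t) is linearised as
    1 - |Re(lambda)| t for slow modes, those with |Re(lambda)| t_ref
    below ``slow_cutoff`` over the reference lifespan ``t_ref``.  The
    characteristic rate of term i for factor j is
    |Re(lambda_i)| |v_ij|; per factor, the smallest rate and all rates
    within ``tol`` of it are flagged.  If no mode meets the slow-mode
    cutoff the single slowest mode is used.
    """
    re = E.lambdas.real
    if np.any(re >= 0):
        raise ValueError(
            "decay-rate dominance requires a stable system "
            "(slow-mode linearisation of the analytic solution)"
        )
    slow = np.abs(re) * t_ref < slow_cutoff
    if not slow.any():
        slow = np.abs(re) == np.abs(re).min()
    rates = np.abs(re[:, None]) * np.abs(E.vectors.T)  # (terms, factors)
    masked = np.where(slow[:, None], rates, np.inf)
    low = masked.min(axis=0, keepdims=True)
    flags = masked <= (1.0 + tol) * low
    return DominantTermTable(flags, rates, "decay_rate", tol)


# --------------------------------------------------------------------------
# spectrogram / PSD / correlations
# --------------------------------------------------------------------------

def spectrogram_psd(
    series: np.ndarray,
    segment: int = 16,
    overlap: int = 8,
    fs: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hann-window STFT power spectral density of a factor signal.

    Returns (frequencies in cycles/day, segment times in days, PSD
    matrix freq x time).  Defaults follow the analysis protocol:
    16-day segments, 8-day overlap (a 2-day overlap is used when
    feeding the pair-ranking pipeline).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("spectrogram_psd expects a 1-D series")
    if len(x) < segment:
        raise ValueError(f"series of length {len(x)} is shorter than one segment ({segment})")
    freqs, times, Sxx = signal.spectrogram(
        x,
        fs=fs,
        window="hann",
        nperseg=segment,
        noverlap=overlap,
        scaling="density",
        mode="psd",
        detrend=False,
    )
    return freqs, times, Sxx


def psd_discrepancy(psd_a: np.ndarray, psd_b: np.ndarray) -> float:
    """Total absolute PSD difference summed over all time-frequency bins."""
    a, b = np.asarray(psd_a, float), np.asarray(psd_b, float)
    if a.shape != b.shape:
        raise ValueError(f"PSD shapes differ: {a.shape} vs {b.shape}")
    return float(np.sum(np.abs(a - b)))


def xcorr_zero(x: np.ndarray, y: np.ndarray, center: bool = True) -> float:
    """Zero-lag cross-correlation: the dot product of the (centered) series."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xcorr_zero expects two equal-length 1-D series")
    if center:
        x = x - x.mean()
        y = y - y.mean()
    return float(np.dot(x, y))


def factor_pairs(n: int = len(FACTORS)) -> list[tuple[int, int]]:
    """The 105 unordered factor pairs, self-pairs included, lexicographic."""
    return list(combinations_with_replacement(range(n), 2))


def pearson_pairs(
    trajectory: Trajectory,
    horizons: Sequence[float] = (200.0, 365.0, 730.0, 1825.0, 3650.0),
    use_reported: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of every factor pair over each horizon.

    One row per unordered pair (105 for 14 factors, self-pairs
    included); one column per horizon, computed over the reported days
    up to that horizon.  Self-pairs are exactly 1; pairs involving a
    zero-variance series are NaN (undefined, not 0).
    """
    horizons = sorted(horizons)
    traj = trajectory.reported() if use_reported else trajectory
    if traj.days[-1] + 1e-9 < horizons[-1]:
        raise ValueError(
            f"trajectory ends at day {traj.days[-1]:g}, before the "
            f"largest horizon {horizons[-1]:g}"
        )
    n = traj.states.shape[1]
    pairs = factor_pairs(n)
    names = [f.name for f in FACTORS] if n == len(FACTORS) else [f"x{i}" for i in range(n)]
    out = pd.DataFrame(
        {
            "factor_a": [names[i] for i, _ in pairs],
            "factor_b": [names[j] for _, j in pairs],
        }
    )
    for h in horizons:
        X = traj.states[traj.days <= h + 1e-9]
        sd = X.std(axis=0)
        col = np.empty(len(pairs))
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X.T)
        for p, (i, j) in enumerate(pairs):
            if sd[i] == 0 or sd[j] == 0:
                col[p] = np.nan
            elif i == j:
                col[p] = 1.0
            else:
                col[p] = C[i, j]
        out[f"r_{int(h)}d"] = col
    return out


@dataclass
class PairMetricRanking:
    """Per-metric and aggregate similarity ranking of the factor pairs."""

    table: pd.DataFrame  # psd_rank, xcorr_rank, pearson_rank, rank_sum, aggregate_rank


def rank_pair_metrics(
    psd_discrepancies: pd.Series,
    xcorrs: pd.Series,
    pearsons: pd.Series,
    pearson_absolute: bool = False,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Orient raw pair metrics into similarity ranks (1 = most similar).

    Low PSD discrepancy, high |cross-correlation| and high (signed, or
    absolute if requested) Pearson correlation rank best; ties receive
    the mean rank.
    """
    psd_rank = psd_discrepancies.rank(method="average", ascending=True)
    xcorr_rank = xcorrs.abs().rank(method="average", ascending=False)
    p = pearsons.abs() if pearson_absolute else pearsons
    pearson_rank = p.rank(method="average", ascending=False)
    return psd_rank, xcorr_rank, pearson_rank


def aggregate_pair_ranking(
    psd_ranks: pd.Series,
    xcorr_ranks: pd.Series,
    pearson_ranks: pd.Series,
) -> PairMetricRanking:
    """Combine the three per-metric rankings by rank sum.

    Rankings (not raw metric values) are aggregated; the final order is
    by rank sum ascending with ties broken lexicographically by pair
    key.  All three rankings must cover the same complete set of pairs.
    """
    idx = psd_ranks.index
    for s, name in ((xcorr_ranks, "xcorr"), (pearson_ranks, "pearson")):
        if not idx.sort_values().equals(s.index.sort_values()):
            raise ValueError(f"{name} ranking does not cover the same pairs")
    if psd_ranks.isna().any() or xcorr_ranks.isna().any() or pearson_ranks.isna().any():
        raise ValueError("rankings are incomplete (NaN ranks present)")
    df = pd.DataFrame(
        {
            "psd_rank": psd_ranks,
            "xcorr_rank": xcorr_ranks.reindex(idx),
            "pearson_rank": pearson_ranks.reindex(idx),
        }
    )
    df["rank_sum"] = df.sum(axis=1)
    order = np.lexsort((df.index.to_numpy().astype(str), df["rank_sum"].to_numpy()))
    df = df.iloc[order]
    df["aggregate_rank"] = np.arange(1, len(df) + 1)
    return PairMetricRanking(df)
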