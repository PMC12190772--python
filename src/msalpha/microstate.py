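"""Microstate segmentation: GFP peaks, polarity-invariant modified K-means,
back-fitting, temporal parameters, and first-order Markov transitions.

Topographies are compared with the polarity-invariant spatial correlation
(absolute Pearson correlation across channels after removing each map's
channel mean). Clustering maximizes squared correlation between each
GFP-peak map and its template, with templates updated as the principal
eigenvector of the cluster's outer-product sum — the classic modified
K-means for microstates, which ignores map polarity by construction.

Model quality is summarized by GEV (global explained variance,
GFP²-weighted squared correlation between samples and their assigned
template) and the CV criterion (residual variance penalized by the number
of clusters); the number of states is chosen on min-max-normalized
GEV and CV across a candidate range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import linear_sum_assignment

from .core import EEGRecording, EpochSet, UNASSIGNED

__all__ = [
    "MicrostateModel",
    "compute_gfp",
    "select_gfp_peaks",
    "spatial_correlation",
    "modified_kmeans",
    "compute_gev",
    "compute_cv",
    "select_k",
    "backfit",
    "microstate_metrics",
    "transition_matrix",
    "match_templates",
    "collect_peak_maps",
]


@dataclass
class MicrostateModel:
    """k fitted template topographies with their fit diagnostics."""

    templates: np.ndarray  # k x n_channels, zero-mean, unit-norm
    gev: float
    cv: float
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if not self.label_names:
            self.label_names = [chr(ord("A") + i) for i in range(self.k)]

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


def compute_gfp(epoch: EEGRecording | np.ndarray) -> np.ndarray:
    """Global field power: per-sample population SD of voltages across channels."""
    data = epoch.data if isinstance(epoch, EEGRecording) else np.asarray(epoch, dtype=float)
    if data.shape[1] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return data.std(axis=1, ddof=0)


def select_gfp_peaks(
    gfp: np.ndarray,
    fs: float,
    min_interval_ms: float = 10.0,
    min_peak_uv: float = 20.0,
    sd_band: float = 1.0,
    max_peaks: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Indices of retained GFP peaks.

    Local maxima are spaced at least ``min_interval_ms`` apart (the larger of
    two conflicting peaks wins), peaks below ``min_peak_uv`` are dropped, and
    peaks whose GFP falls outside mean ± ``sd_band`` SD of the surviving peak
    amplitudes are excluded. If more than ``max_peaks`` remain, a uniform
    seeded subsample of exactly ``max_peaks`` is returned.
    """
    gfp = np.asarray(gfp, dtype=float)
    if gfp.size == 0:
        raise ValueError("empty GFP series")
    distance = max(1, int(round(min_interval_ms * fs / 1000.0)))
    idx, _ = signal.find_peaks(gfp, distance=distance)
    idx = idx[gfp[idx] >= min_peak_uv]
    if idx.size and sd_band is not None:
        vals = gfp[idx]
        m, s = vals.mean(), vals.std(ddof=0)
        idx = idx[(vals >= m - sd_band * s) & (vals <= m + sd_band * s)]
    if idx.size == 0:
        warnings.warn("no GFP peaks survived selection")
        return idx
    if idx.size > max_peaks:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_peaks, replace=False))
    return idx


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray, ignore_polarity: bool = True) -> float:
    """Pearson correlation between two topographies across channels.

    Channel means are removed from each map first; with ``ignore_polarity``
    the absolute value is returned.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have equal channel counts")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined for a zero-variance map")
    c = float(a @ b / (na * nb))
    return abs(c) if ignore_polarity else c


def _center(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=1, keepdims=True)


def _normalize_rows(t: np.ndarray) -> np.ndarray:
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _principal_map(cluster: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of the cluster's channel covariance (sign-free)."""
    s = cluster.T @ cluster
    w, v = np.linalg.eigh(s)
    return v[:, -1]


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int,
    n_init: int = 50,
    max_iter: int = 2000,
    tol: float = 1e-8,
    seed: int = 0,
) -> MicrostateModel:
    """Polarity-invariant modified K-means over GFP-peak topographies.

    Alternates (1) assigning each map to the template with the largest
    squared spatial correlation and (2) re-estimating each template as the
    dominant eigenvector of its cluster's outer-product sum. Restarts
    ``n_init`` times from seeded random map selections and keeps the restart
    with the highest GEV. An emptied cluster is reseeded from the currently
    worst-fit map.
    """
    X = _center(np.asarray(peak_maps, dtype=float))
    n, n_ch = X.shape
    if n < k:
        raise ValueError(f"need at least k={k} maps, got {n}")
    norms2 = np.einsum("ij,ij->i", X, X)
    if np.any(norms2 == 0):
        raise ValueError("peak maps must have nonzero spatial variance")
    gfp = X.std(axis=1, ddof=0)
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, float] | None = None
    for _ in range(n_init):
        T = _normalize_rows(X[rng.choice(n, size=k, replace=False)].copy())
        prev_sigma2 = np.inf
        for _ in range(max_iter):
            A = X @ T.T  # projections, n x k
            L = np.argmax(A**2, axis=1)
            a = A[np.arange(n), L]
            # reseed any emptied cluster from the worst-fit map
            for c in range(k):
                if not np.any(L == c):
                    worst = int(np.argmax(norms2 - a**2))
                    L[worst] = c
                    a[worst] = X[worst] @ T[c]
            sigma2 = float(np.sum(norms2 - a**2) / (n * (n_ch - 1)))
            for c in range(k):
                T[c] = _principal_map(X[L == c])
            if abs(prev_sigma2 - sigma2) <= tol * max(sigma2, 1e-300):
                break
            prev_sigma2 = sigma2
        A = X @ T.T
        L = np.argmax(A**2, axis=1)
        gev = _gev_from_projections(X, T, L, gfp)
        sigma2 = float(np.sum(norms2 - A[np.arange(n), L] ** 2) / (n * (n_ch - 1)))
        if best is None or gev > best[0]:
            best = (gev, T.copy(), sigma2)

    gev, T, sigma2 = best
    # deterministic polarity: largest-|value| channel positive
    for t in T:
        if t[np.argmax(np.abs(t))] < 0:
            t *= -1.0
    cv = sigma2 * ((n_ch - 1) / (n_ch - 1 - k)) ** 2 if n_ch > k + 1 else float("nan")
    return MicrostateModel(templates=T, gev=gev, cv=cv)


def _gev_from_projections(
    X: np.ndarray, T: np.ndarray, L: np.ndarray, gfp: np.ndarray
) -> float:
    corr = (X @ T.T)[np.arange(len(X)), L] / np.linalg.norm(X, axis=1)
    return float(np.sum((gfp * corr) ** 2) / np.sum(gfp**2))


def compute_gev(
    templates: np.ndarray,
    maps: np.ndarray,
    labels: np.ndarray,
    gfp: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Total and per-state GEV of labeled samples.

    GEV = sum_t (GFP_t * C_t)^2 / sum_t GFP_t^2 with C_t the
    polarity-invariant spatial correlation between sample t and its assigned
    template; unassigned samples contribute to the denominator only.
    """
    X = _center(np.asarray(maps, dtype=float))
    T = _normalize_rows(_center(np.asarray(templates, dtype=float)))
    labels = np.asarray(labels)
    if gfp is None:
        gfp = X.std(axis=1, ddof=0)
    gfp = np.asarray(gfp, dtype=float)
    denom = float(np.sum(gfp**2))
    if denom == 0:
        raise ValueError("GEV undefined for all-zero GFP")
    per_state = np.zeros(T.shape[0])
    norms = np.linalg.norm(X, axis=1)
    assigned = labels != UNASSIGNED
    for s in range(T.shape[0]):
        sel = assigned & (labels == s) & (norms > 0)
        if not np.any(sel):
            continue
        corr = (X[sel] @ T[s]) / norms[sel]
        per_state[s] = float(np.sum((gfp[sel] * corr) ** 2) / denom)
    return float(per_state.sum()), per_state


def compute_cv(templates: np.ndarray, maps: np.ndarray, labels: np.ndarray | None = None) -> float:
    """CV criterion: residual variance penalized by cluster count.

    CV = sigma2 * ((N-1)/(N-1-k))^2 with N the channel count and sigma2 the
    mean per-sample variance orthogonal to the assigned template.
    """
    X = _center(np.asarray(maps, dtype=float))
    T = _normalize_rows(_center(np.asarray(templates, dtype=float)))
    n, n_ch = X.shape
    k = T.shape[0]
    if n_ch <= k + 1:
        raise ValueError(f"CV needs n_channels > k+1, got {n_ch} channels, k={k}")
    A = X @ T.T
    if labels is None:
        labels = np.argmax(A**2, axis=1)
    a = A[np.arange(n), np.asarray(labels)]
    norms2 = np.einsum("ij,ij->i", X, X)
    sigma2 = float(np.sum(norms2 - a**2) / (n * (n_ch - 1)))
    return sigma2 * ((n_ch - 1) / (n_ch - 1 - k)) ** 2


def select_k(models: dict[int, MicrostateModel]) -> tuple[int, pd.DataFrame]:
    """Choose the number of states on min-max-normalized GEV and CV.

    Both criteria are normalized to [0, 1] across the candidate range; the
    chosen k maximizes normalized GEV minus normalized CV, ties broken toward
    the smaller k (with a warning).
    """
    if len(models) < 2:
        raise ValueError("need at least 2 candidate models")
    ks = sorted(models)
    gevs = np.array([models[k].gev for k in ks])
    cvs = np.array([models[k].cv for k in ks])

    def norm(x: np.ndarray) -> np.ndarray:
        span = x.max() - x.min()
        return np.zeros_like(x) if span == 0 else (x - x.min()) / span

    ngev, ncv = norm(gevs), norm(cvs)
    score = ngev - ncv
    near_max = np.isclose(score, score.max(), atol=1e-9)
    best = int(np.flatnonzero(near_max)[0])  # smallest k among ties
    if near_max.sum() > 1:
        warnings.warn("criterion tie across k; choosing the smallest")
    table = pd.DataFrame(
        {"k": ks, "gev": gevs, "cv": cvs, "norm_gev": ngev, "norm_cv": ncv, "score": score}
    )
    return ks[best], table


def backfit(
    model: MicrostateModel,
    epochs: EpochSet | EEGRecording | np.ndarray,
    min_segment_ms: float = 0.0,
    fs: float | None = None,
) -> list[np.ndarray]:
    """Label every sample with the template of maximal |spatial correlation|.

    Returns one label array per epoch. Zero-variance samples get the
    UNASSIGNED sentinel. With ``min_segment_ms`` > 0, segments shorter than
    that are merged into the neighboring state with the higher mean
    correlation (off by default: temporal smoothing systematically inflates
    durations).
    """
    if isinstance(epochs, EpochSet):
        data_list = [e.data for e in epochs]
        fs = epochs.fs
    elif isinstance(epochs, EEGRecording):
        data_list, fs = [epochs.data], epochs.fs
    else:
        data_list = [np.asarray(epochs, dtype=float)]
        if fs is None:
            raise ValueError("fs required for a bare array")
    T = _normalize_rows(_center(model.templates))
    out = []
    for data in data_list:
        X = _center(data)
        norms = np.linalg.norm(X, axis=1)
        A = np.abs(X @ T.T)
        labels = np.argmax(A, axis=1).astype(np.int64)
        labels[norms == 0] = UNASSIGNED
        if min_segment_ms > 0:
            labels = _merge_short_segments(labels, A, int(round(min_segment_ms * fs / 1000.0)))
        out.append(labels)
    return out


def _merge_short_segments(labels: np.ndarray, corr: np.ndarray, min_len: int) -> np.ndarray:
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = _run_bounds(labels)
        for i, (start, stop, state) in enumerate(runs):
            if state == UNASSIGNED or stop - start >= min_len:
                continue
            candidates = []
            if i > 0 and runs[i - 1][2] != UNASSIGNED:
                candidates.append(runs[i - 1][2])
            if i < len(runs) - 1 and runs[i + 1][2] != UNASSIGNED:
                candidates.append(runs[i + 1][2])
            if not candidates:
                continue
            means = [corr[start:stop, c].mean() for c in candidates]
            labels[start:stop] = candidates[int(np.argmax(means))]
            changed = True
            break
    return labels


def _run_bounds(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop, state) for each maximal run."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, int(labels[start])))
            start = i
    return runs


def microstate_metrics(
    labels: list[np.ndarray] | np.ndarray,
    gfp: list[np.ndarray] | np.ndarray,
    fs: float,
    k: int,
    per_state_gev: np.ndarray | None = None,
    state_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-state temporal parameters from back-fitted labels.

    coverage: fraction of assigned samples; occurrence: maximal runs per
    second of assigned time; duration: mean run length in ms; mean_gfp: mean
    GFP over the state's samples. Epoch boundaries break runs and unassigned
    samples do not bridge them. Under these conventions
    coverage = occurrence * duration / 1000 exactly.
    """
    label_list = labels if isinstance(labels, list) else [np.asarray(labels)]
    gfp_list = gfp if isinstance(gfp, list) else [np.asarray(gfp)]
    if len(label_list) != len(gfp_list):
        raise ValueError("labels and gfp must align per epoch")
    names = state_names or [chr(ord("A") + i) for i in range(k)]

    n_samples = np.zeros(k)
    n_runs = np.zeros(k)
    gfp_sum = np.zeros(k)
    total_assigned = 0
    for lab, g in zip(label_list, gfp_list):
        lab = np.asarray(lab)
        g = np.asarray(g, dtype=float)
        if lab.shape != g.shape:
            raise ValueError("labels and gfp lengths differ within an epoch")
        assigned = lab != UNASSIGNED
        total_assigned += int(assigned.sum())
        for start, stop, state in _run_bounds(lab):
            if state == UNASSIGNED:
                continue
            n_runs[state] += 1
            n_samples[state] += stop - start
            gfp_sum[state] += g[start:stop].sum()
    if total_assigned == 0:
        raise ValueError("no assigned samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        coverage = n_samples / total_assigned
        occurrence = n_runs / (total_assigned / fs)
        duration = np.where(n_runs > 0, n_samples / np.maximum(n_runs, 1) * 1000.0 / fs, np.nan)
        mean_gfp = np.where(n_samples > 0, gfp_sum / np.maximum(n_samples, 1), np.nan)
    df = pd.DataFrame(
        {
            "state": names,
            "coverage": coverage,
            "occurrence": occurrence,
            "duration": duration,
            "mean_gfp": mean_gfp,
        }
    ).set_index("state")
    if per_state_gev is not None:
        df["gev"] = np.asarray(per_state_gev, dtype=float)
    return df


def transition_matrix(labels: list[np.ndarray] | np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """First-order Markov transition probabilities on the run sequence.

    Consecutive duplicate labels are collapsed within each epoch (epoch
    boundaries are never bridged); TP(i->j) = transitions i->j divided by all
    transitions out of i. Rows with no observed transitions are NaN. Returns
    (tp, counts).
    """
    label_list = labels if isinstance(labels, list) else [np.asarray(labels)]
    counts = np.zeros((k, k))
    for lab in label_list:
        runs = [s for _, _, s in _run_bounds(np.asarray(lab)) if s != UNASSIGNED]
        for a, b in zip(runs[:-1], runs[1:]):
            if a != b:  # unassigned gaps can leave equal neighbors; not a transition
                counts[a, b] += 1
    if counts.sum() == 0:
        raise ValueError("no state transitions observed")
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = np.where(row_sums > 0, counts / row_sums, np.nan)
    return tp, counts


def match_templates(model: MicrostateModel, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimally pair fitted templates with reference maps (Hungarian, |corr|).

    Returns (permutation such that templates[perm[i]] matches reference[i],
    mean matched |spatial correlation|).
    """
    ref = np.asarray(reference, dtype=float)
    k = min(model.k, ref.shape[0])
    cost = np.zeros((ref.shape[0], model.k))
    for i in range(ref.shape[0]):
        for j in range(model.k):
            cost[i, j] = -spatial_correlation(ref[i], model.templates[j])
    rows, cols = linear_sum_assignment(cost)
    mean_corr = float(-cost[rows, cols].mean())
    perm = np.array(cols)
    return perm, mean_corr


def collect_peak_maps(
    epochs: EpochSet,
    min_interval_ms: float = 10.0,
    min_peak_uv: float = 20.0,
    sd_band: float = 1.0,
    max_peaks: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """GFP-peak topographies of one subject, pooled across epochs.

    The spacing/amplitude/SD-band rules apply within each epoch; the
    ``max_peaks`` cap applies to the subject's pooled peak set.
    """
    maps = []
    for e in epochs:
        g = compute_gfp(e)
        idx = select_gfp_peaks(
            g, e.fs, min_interval_ms, min_peak_uv, sd_band,
            max_peaks=len(g), seed=seed,
        )
        if idx.size:
            maps.append(e.data[idx])
    if not maps:
        raise ValueError("no GFP-peak maps collected")
    pooled = np.concatenate(maps, axis=0)
    if pooled.shape[0] > max_peaks:
        rng = np.random.default_rng(seed)
        pooled = pooled[np.sort(rng.choice(pooled.shape[0], size=max_peaks, replace=False))]
    return pooled
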