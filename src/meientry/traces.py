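"""Single-cell fluorescence time-series quantification.

Implements the trace-level pipeline used on microfluidics imaging data of
meiotic entry: calling the first meiotic nuclear division (MI) from a
nuclear marker, windowed peak detection before MI, alignment and
mean-with-CI summaries, k-means clustering of trajectories under
correlation distance, peak/MI correlation statistics, half-decay times for
return-to-growth experiments, nuclear/whole intensity ratios and
orange/red bleed-through correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.signal import medfilt

__all__ = [
    "PeakCall",
    "ClusterResult",
    "HalfDecayEstimate",
    "AlignedSummary",
    "call_mi",
    "detect_peak",
    "align_and_summarize",
    "kmeans_correlation",
    "peak_mi_correlation",
    "half_decay_time",
    "nc_ratio",
    "bleed_correct",
    "ks_compare",
]


class TraceError(ValueError):
    """Raised for malformed traces or undefined statistics."""


@dataclass(frozen=True)
class PeakCall:
    """Location and height of a pre-MI intensity peak."""

    cell_id: str
    channel: str
    peak_index: int
    peak_time: float
    peak_value: float
    window_used: int


@dataclass(frozen=True)
class ClusterResult:
    """Correlation-distance k-means output."""

    assignments: np.ndarray      # cluster id per cell, 1..k
    centroids: np.ndarray        # (k, n_frames)
    inertia: float               # sum of (1 - r) to own centroid
    replicate_chosen: int


@dataclass(frozen=True)
class HalfDecayEstimate:
    """Time to first sustained 50% drop after a medium switch."""

    cell_id: str
    compartment: str
    t50: float | None            # minutes from switch; None when censored
    censored: bool


@dataclass(frozen=True)
class AlignedSummary:
    """Frame-wise mean trace with a 95% normal-approximation CI."""

    rel_frames: np.ndarray
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_per_frame: np.ndarray


def _median3(x: np.ndarray) -> np.ndarray:
    """Window-3 median smoothing with edge passthrough."""
    return medfilt(np.asarray(x, dtype=float), kernel_size=3)


def call_mi(marker_trace, min_rise: float, times=None) -> int | None:
    """Call the first meiotic division from a nuclear-marker trace.

    The marker steps up sharply at MI; the call is the point of highest
    inflection: the frame just after the largest first difference of the
    window-3 median-smoothed trace.  Returns ``None`` (non-meiotic cell)
    when the largest rise is below ``min_rise``.
    """
    x = np.asarray(marker_trace, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise TraceError("marker trace must be 1-D with at least 3 frames")
    if times is not None:
        dt = np.diff(np.asarray(times, dtype=float))
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise TraceError("marker trace must be sampled on a uniform grid")
    diff = np.diff(_median3(x))
    i = int(np.argmax(diff))
    if diff[i] < min_rise:
        return None
    return i + 1


def detect_peak(
    trace,
    mi_index: int,
    window: int,
    cell_id: str = "",
    channel: str = "",
    dt: float = 0.2,
) -> PeakCall:
    """Find the highest-intensity frame in a window before MI.

    Frames ``[max(0, mi_index - window), mi_index)`` are searched; ties are
    broken toward the earlier frame (``argmax`` convention).
    """
    x = np.asarray(trace, dtype=float)
    if mi_index <= 0:
        raise TraceError(f"mi_index must be positive, got {mi_index}")
    if window < 1:
        raise TraceError(f"window must be >= 1, got {window}")
    start = max(0, mi_index - window)
    segment = x[start:mi_index]
    if segment.size == 0:
        raise TraceError("empty search window before MI")
    i = start + int(np.argmax(segment))
    return PeakCall(
        cell_id=cell_id,
        channel=channel,
        peak_index=i,
        peak_time=i * dt,
        peak_value=float(x[i]),
        window_used=mi_index - start,
    )


def align_and_summarize(traces, anchors, half_width: int) -> AlignedSummary:
    """Align traces on per-cell anchor frames and summarize frame-wise.

    Each trace is shifted so its anchor sits at relative frame 0; the mean
    and a 95% CI (mean ± 1.96·SE) are computed per relative frame over the
    cells that cover it.  Frames covered by no cell are omitted.
    """
    traces = [np.asarray(t, dtype=float) for t in traces]
    anchors = np.asarray(anchors, dtype=int)
    if len(traces) < 2:
        raise TraceError("alignment needs at least 2 cells")
    if len(traces) != anchors.size:
        raise TraceError("one anchor per trace required")
    rel = np.arange(-half_width, half_width + 1)
    rows = np.full((len(traces), rel.size), np.nan)
    for r, (tr, a) in enumerate(zip(traces, anchors)):
        idx = a + rel
        ok = (idx >= 0) & (idx < tr.size)
        rows[r, ok] = tr[idx[ok]]
    n = np.sum(~np.isnan(rows), axis=0)
    covered = n > 0
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # frames covered by a single cell have no sample SD (ddof=1)
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(rows[:, covered], axis=0)
        sd = np.nanstd(rows[:, covered], axis=0, ddof=1)
    se = np.where(n[covered] > 1, sd / np.sqrt(n[covered]), 0.0)
    se = np.nan_to_num(se)
    return AlignedSummary(
        rel_frames=rel[covered],
        mean=mean,
        ci_lower=mean - 1.96 * se,
        ci_upper=mean + 1.96 * se,
        n_per_frame=n[covered],
    )


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    return (mat - mu) / sd


def _correlation_distance(z_rows: np.ndarray, z_centroids: np.ndarray) -> np.ndarray:
    """1 - Pearson r between each row and each centroid (both z-scored)."""
    n = z_rows.shape[1]
    return 1.0 - (z_rows @ z_centroids.T) / n


def kmeans_correlation(
    traces_window,
    k: int,
    replicates: int = 10,
    max_iter: int = 10000,
    seed: int | np.random.Generator | None = 0,
) -> ClusterResult:
    """Lloyd's k-means under correlation distance ``d = 1 - Pearson r``.

    The assignment step minimizes ``d`` to each centroid; the update step
    takes the frame-wise mean of the z-scored member traces (so centroids
    live on the correlation sphere).  Each of ``replicates`` runs is seeded
    k-means++-style on the z-scored traces and the minimum-inertia run is
    returned.  Empty clusters are re-seeded from the worst-fit trace.
    """
    X = np.asarray(traces_window, dtype=float)
    if X.ndim != 2:
        raise TraceError("traces_window must be a (cells x frames) matrix")
    n_cells = X.shape[0]
    if k < 2:
        raise TraceError("k must be >= 2")
    if k > n_cells:
        raise TraceError(f"k={k} exceeds number of cells ({n_cells})")
    sd = X.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        raise TraceError(f"constant trace (correlation undefined) at row {flat[0]}")
    Z = _zscore_rows(X)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for rep in range(replicates):
        centroids = Z[_kpp_init(Z, k, rng)].copy()
        assign = np.zeros(n_cells, dtype=int)
        prev_inertia = np.inf
        for _ in range(max_iter):
            dist = _correlation_distance(Z, _zscore_rows(centroids))
            assign = np.argmin(dist, axis=1)
            # re-seed empties from the farthest point
            for c in range(k):
                if not np.any(assign == c):
                    worst = int(np.argmax(dist[np.arange(n_cells), assign]))
                    assign[worst] = c
            new_centroids = np.vstack([Z[assign == c].mean(axis=0) for c in range(k)])
            inertia = float(
                _correlation_distance(Z, _zscore_rows(new_centroids))[
                    np.arange(n_cells), assign
                ].sum()
            )
            if np.allclose(new_centroids, centroids) or inertia >= prev_inertia - 1e-12:
                centroids = new_centroids
                prev_inertia = inertia
                break
            centroids = new_centroids
            prev_inertia = inertia
        if best is None or prev_inertia < best[0]:
            best = (prev_inertia, assign.copy(), centroids.copy(), rep)

    inertia, assign, centroids, rep = best
    return ClusterResult(
        assignments=assign + 1,
        centroids=centroids,
        inertia=inertia,
        replicate_chosen=rep,
    )


def _kpp_init(Z: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under correlation distance."""
    n = Z.shape[0]
    chosen = [int(rng.integers(n))]
    d = _correlation_distance(Z, Z[chosen])[:, 0]
    for _ in range(1, k):
        w = np.clip(d, 0, None) ** 2
        total = w.sum()
        if total <= 0:
            probs = np.full(n, 1.0 / n)
        else:
            probs = w / total
        nxt = int(rng.choice(n, p=probs))
        chosen.append(nxt)
        d = np.minimum(d, _correlation_distance(Z, Z[[nxt]])[:, 0])
    return np.array(chosen)


def peak_mi_correlation(peak_times, mi_times) -> float:
    """Squared Pearson correlation between peak times and MI times."""
    x = np.asarray(peak_times, dtype=float)
    y = np.asarray(mi_times, dtype=float)
    if x.size != y.size or x.size < 3:
        raise TraceError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise TraceError("zero variance: correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def half_decay_time(
    trace,
    switch_index: int,
    smooth: int = 3,
    dt_minutes: float = 12.0,
    cell_id: str = "",
    compartment: str = "",
) -> HalfDecayEstimate:
    """Minutes from a medium switch to a sustained 50% intensity drop.

    The pre-switch level is the mean of the ``smooth`` frames before the
    switch; the crossing is located at the first frame at which the
    median-smoothed trace is at or below half that level and stays there
    for 2 consecutive frames (persistence guards against single-frame
    noise), then refined to sub-frame resolution by linear interpolation
    between the bracketing frames — at a 12-min cadence the grid alone
    would quantize fast nuclear decays far too coarsely.  ``censored``
    when the trace never crosses.
    """
    x = np.asarray(trace, dtype=float)
    if not (0 < switch_index < x.size):
        raise TraceError("switch_index must lie inside the record")
    pre = x[max(0, switch_index - smooth):switch_index].mean()
    if pre <= 0:
        raise TraceError(f"non-positive pre-switch level ({pre:.3g})")
    sm = (_median3(x) if x.size >= 3 else x)[switch_index:]
    half = 0.5 * pre
    below = sm <= half
    sustained = below[:-1] & below[1:]
    hits = np.where(sustained)[0]
    if hits.size == 0:
        return HalfDecayEstimate(cell_id, compartment, None, True)
    i = int(hits[0])
    t50 = float(i * dt_minutes)
    if i > 0 and sm[i - 1] > half and sm[i - 1] > sm[i]:
        frac = (sm[i - 1] - half) / (sm[i - 1] - sm[i])
        t50 = float((i - 1 + frac) * dt_minutes)
    return HalfDecayEstimate(cell_id, compartment, t50, False)


def nc_ratio(nuclear_mean: float, whole_mean: float) -> float:
    """Nuclear mean intensity over whole-cell mean intensity."""
    if whole_mean <= 0:
        raise TraceError(f"whole-cell mean must be > 0, got {whole_mean}")
    return float(nuclear_mean) / float(whole_mean)


def bleed_correct(orange, red, coeff: float = 0.51):
    """Subtract red-channel bleed-through from the orange channel.

    Returns ``orange - coeff * red`` floored at 0 elementwise.
    """
    o = np.asarray(orange, dtype=float)
    r = np.asarray(red, dtype=float)
    if o.shape != r.shape:
        raise TraceError(f"length mismatch: {o.shape} vs {r.shape}")
    if coeff < 0:
        raise TraceError("bleed coefficient must be >= 0")
    return np.clip(o - coeff * r, 0.0, None)


def ks_compare(a, b) -> tuple[float, bool]:
    """Two-sample Kolmogorov–Smirnov test.

    Returns ``(p_value, significant)`` with significance at P < 0.05.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise TraceError("each sample needs at least 5 observations")
    p = float(sps.ks_2samp(a, b, method="asymp").pvalue)
    return p, p < 0.05
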