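"""Per-axis head-motion events and 1D / conjunctive displacement statistics.

A motion event in one Eulerian component is a run of temporal bins in which
the angular head velocity keeps a constant direction, containing a core of at
least five consecutive bins faster than 0.5 deg/bin (25 deg/s at 50 Hz), and
extended backward and forward to the last same-direction bin.  Events whose
total extent is 2.5 deg or under are discarded as sensor jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

SPEED_THRESHOLD_DEG_S = 25.0  # 0.5 deg/bin at 50 Hz
CORE_MIN_S = 0.1  # five 20-ms bins at 50 Hz
MIN_EXTENT_DEG = 2.5


@dataclass(frozen=True)
class MotionEvent:
    """One detected motion event in a single Eulerian component.

    ``onset_bin``/``offset_bin`` index the velocity (first-difference) series:
    bin ``i`` is the displacement between angle samples ``i`` and ``i+1``.
    ``extent`` is the signed summed angular head velocity over the event and
    ``duration`` its length in seconds.
    """

    component: str
    onset_bin: int
    offset_bin: int  # inclusive
    extent: float
    duration: float

    @property
    def n_bins(self) -> int:
        return self.offset_bin - self.onset_bin + 1

    def onset_time(self, dt: float) -> float:
        return self.onset_bin * dt


def detect_motion_events(
    angles: np.ndarray,
    dt: float = 0.02,
    component: str = "",
    speed_threshold_deg_s: float = SPEED_THRESHOLD_DEG_S,
    min_core_s: float = CORE_MIN_S,
    min_extent: float = MIN_EXTENT_DEG,
) -> list[MotionEvent]:
    """Detect motion events in a single-component angle series (degrees).

    The per-bin velocity is the first difference of the series.  A candidate
    core is at least ``min_core_s`` seconds of consecutive bins of identical
    sign with speed strictly above ``speed_threshold_deg_s`` (25 deg/s = 0.5
    deg per 20-ms bin); the event is then extended in both directions over all
    contiguous same-sign bins (any speed; zero velocity terminates the
    extension).  Events with |extent| <= ``min_extent`` are dropped.  An empty
    or constant series yields an empty list.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 2:
        return []
    speed_threshold = speed_threshold_deg_s * dt  # deg per bin
    core_min_bins = int(round(min_core_s / dt))
    v = np.diff(angles)
    sign = np.sign(v)
    events: list[MotionEvent] = []
    n = len(v)
    i = 0
    while i < n:
        s = sign[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j < n and sign[j] == s:
            j += 1
        run = np.abs(v[i:j]) > speed_threshold
        # core: >= core_min_bins consecutive fast bins inside the run
        if _has_run(run, core_min_bins):
            extent = float(np.sum(v[i:j]))
            if abs(extent) > min_extent:
                events.append(
                    MotionEvent(
                        component=component,
                        onset_bin=i,
                        offset_bin=j - 1,
                        extent=extent,
                        duration=(j - i) * dt,
                    )
                )
        i = j
    return events


def _has_run(mask: np.ndarray, min_len: int) -> bool:
    count = 0
    for m in mask:
        count = count + 1 if m else 0
        if count >= min_len:
            return True
    return False


@dataclass
class DisplacementDistribution:
    """Histogram of per-event displacements with a fitted Gaussian."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    normalized_freq: np.ndarray
    peak: float
    center: float
    sigma: float
    converged: bool


def _gauss(x, peak, center, sigma):
    return peak * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def fit_displacement_distribution(extents) -> DisplacementDistribution:
    """Histogram event extents into 36 ten-degree bins and fit a Gaussian.

    The histogram spans [-180, 180) deg and is normalized to its maximum; the
    fit returns (peak, center, sigma) of a least-squares Gaussian.  A fit that
    fails to converge is reported through ``converged=False`` rather than
    raised.
    """
    extents = np.asarray(extents, dtype=float)
    if extents.size < 30:
        raise ValueError("need at least 30 events to fit a displacement distribution")
    edges = np.linspace(-180.0, 180.0, 37)
    counts, _ = np.histogram(extents, bins=edges)
    freq = counts / max(counts.max(), 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = [1.0, float(np.mean(extents)), max(float(np.std(extents)), 1.0)]
    try:
        popt, _ = optimize.curve_fit(_gauss, centers, freq, p0=p0, maxfev=10000)
        peak, center, sigma = popt
        converged = True
    except (RuntimeError, optimize.OptimizeWarning):
        peak, center, sigma = p0
        converged = False
    return DisplacementDistribution(
        bin_edges=edges,
        bin_centers=centers,
        normalized_freq=freq,
        peak=float(peak),
        center=float(center),
        sigma=float(abs(sigma)),
        converged=converged,
    )


def conjunctive_pairs(
    angles_a: np.ndarray,
    angles_b: np.ndarray,
    dt: float = 0.02,
    **detector_kwargs,
) -> np.ndarray:
    """Paired (component A, component B) displacements for conjunctive motion.

    For every motion event detected in A, the concurrent displacement of B is
    summed over the same event window, and vice versa.  Events that begin
    simultaneously in both components are counted once (the A-referenced pair
    is kept).  Returns an array of shape ``(n_pairs, 2)``.
    """
    angles_a = np.asarray(angles_a, dtype=float)
    angles_b = np.asarray(angles_b, dtype=float)
    va, vb = np.diff(angles_a), np.diff(angles_b)
    ev_a = detect_motion_events(angles_a, dt=dt, **detector_kwargs)
    ev_b = detect_motion_events(angles_b, dt=dt, **detector_kwargs)
    onsets_a = {e.onset_bin for e in ev_a}
    pairs = []
    for e in ev_a:
        pairs.append((e.extent, float(np.sum(vb[e.onset_bin : e.offset_bin + 1]))))
    for e in ev_b:
        if e.onset_bin in onsets_a:
            continue  # simultaneous onset: already counted from A
        pairs.append((float(np.sum(va[e.onset_bin : e.offset_bin + 1])), e.extent))
    return np.array(pairs) if pairs else np.empty((0, 2))


@dataclass
class ConjunctiveRegression:
    """OLS of component-B on component-A displacements with a log10 heatmap."""

    slope: float
    intercept: float
    r_squared: float
    stderr: float
    n_pairs: int
    valid: bool
    heatmap_log10: np.ndarray
    bin_edges: np.ndarray


def conjunctive_regression(pairs: np.ndarray) -> ConjunctiveRegression:
    """Ordinary least-squares regression on untransformed displacement pairs.

    Also builds the 36 x 36 ten-degree-bin heatmap of log10 pair frequencies
    (display only; the regression uses the raw pairs).  Fewer than 10 pairs
    yields ``valid=False`` with NaN statistics.
    """
    pairs = np.asarray(pairs, dtype=float)
    edges = np.linspace(-180.0, 180.0, 37)
    if len(pairs) < 10:
        return ConjunctiveRegression(
            slope=np.nan,
            intercept=np.nan,
            r_squared=np.nan,
            stderr=np.nan,
            n_pairs=len(pairs),
            valid=False,
            heatmap_log10=np.full((36, 36), np.nan),
            bin_edges=edges,
        )
    res = stats.linregress(pairs[:, 0], pairs[:, 1])
    counts, _, _ = np.histogram2d(pairs[:, 0], pairs[:, 1], bins=[edges, edges])
    heat = np.full_like(counts, np.nan)
    np.log10(counts, out=heat, where=counts > 0)
    return ConjunctiveRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr),
        n_pairs=len(pairs),
        valid=True,
        heatmap_log10=heat,
        bin_edges=edges,
    )
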