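"""Burst detection, burst-triggered displacement averages and tuning nulls.

A burst is a maximal run of three or more spikes with inter-spike intervals of
at most 50 ms spanning at least 20 ms.  Motion tuning is measured by aligning
per-component head displacement to burst onsets (burst-triggered average,
BTA): the heading at each onset is zeroed, the signed displacement of each
burst is the max-minus-min of the trace in the 500 ms after onset (positive
when the minimum precedes the maximum), and the cell statistic is the mean of
these signed displacements.  Significance is assessed against a wrap-around
shuffled null in which burst onsets are rigidly shifted by 20-150 s modulo the
trial length, which preserves the inter-burst structure while destroying the
alignment to behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MAX_ISI_S = 0.05
MIN_SPIKES = 3
MIN_DURATION_S = 0.02
ELIGIBILITY_MIN_BURSTS = 5
PRE_WINDOW_S = 0.5  # trace window before burst onset
POST_WINDOW_S = 1.0  # trace window after burst onset
DISP_WINDOW_S = 0.5  # displacement window: onset .. onset + 500 ms
SHIFT_RANGE_S = (20.0, 150.0)
DEFAULT_N_REPS = 1000


def _window_bins(dt: float) -> tuple[int, int, int]:
    """(pre, post, displacement) bin counts for the trace windows at ``dt``."""
    return (
        int(round(PRE_WINDOW_S / dt)),
        int(round(POST_WINDOW_S / dt)),
        int(round(DISP_WINDOW_S / dt)),
    )


@dataclass(frozen=True)
class Burst:
    """A detected bursting epoch of a spike train."""

    onset: float
    offset: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def rate(self) -> float:
        """Within-burst firing rate, (n_spikes - 1) / duration (ISI-based)."""
        return (self.n_spikes - 1) / self.duration if self.duration > 0 else np.inf

    @property
    def mean_isi(self) -> float:
        return self.duration / (self.n_spikes - 1)


def detect_bursts(
    spikes: np.ndarray,
    max_isi: float = MAX_ISI_S,
    min_spikes: int = MIN_SPIKES,
    min_duration: float = MIN_DURATION_S,
) -> tuple[list[Burst], bool]:
    """Find bursting epochs in a sorted spike-time array (seconds).

    Returns ``(bursts, eligible)`` where ``eligible`` is True when the train
    contains at least five bursts (the criterion for testing a cell's motion
    tuning).
    """
    spikes = np.asarray(spikes, dtype=float)
    bursts: list[Burst] = []
    if spikes.size >= min_spikes:
        breaks = np.flatnonzero(np.diff(spikes) > max_isi)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [spikes.size - 1]])  # inclusive
        for s, e in zip(starts, ends):
            n = e - s + 1
            span = spikes[e] - spikes[s]
            if n >= min_spikes and span >= min_duration - 1e-9:
                bursts.append(Burst(onset=float(spikes[s]), offset=float(spikes[e]), n_spikes=int(n)))
    return bursts, len(bursts) >= ELIGIBILITY_MIN_BURSTS


@dataclass
class BtaResult:
    """Burst-triggered average of one Eulerian component."""

    component: str
    trace_mean: np.ndarray  # pre + post + 1 bins (-500 ms .. +1 s); zero at onset bin
    trace_sem: np.ndarray
    per_burst_displacements: np.ndarray
    mean_displacement: float
    n_bursts: int
    used_onset_bins: np.ndarray


def _valid_onset_bins(onset_bins: np.ndarray, n_samples: int, dt: float) -> np.ndarray:
    """Keep onsets whose full -500 ms .. +1 s window lies inside the trace."""
    pre, post, _ = _window_bins(dt)
    return onset_bins[(onset_bins >= pre) & (onset_bins + post < n_samples)]


def _signed_displacements(
    onset_bins: np.ndarray, angles: np.ndarray, dt: float
) -> np.ndarray:
    """Signed (max - min) displacement in the 500 ms after each onset bin.

    Positive when the minimum precedes the maximum; ties in flat segments take
    the earliest extremum, so a constant trace contributes exactly zero.
    Vectorized over onsets.
    """
    if onset_bins.size == 0:
        return np.empty(0)
    _, _, disp_bins = _window_bins(dt)
    idx = onset_bins[:, np.newaxis] + np.arange(disp_bins + 1)
    seg = angles[idx] - angles[onset_bins][:, np.newaxis]
    imax = np.argmax(seg, axis=1)
    imin = np.argmin(seg, axis=1)
    amp = seg[np.arange(len(seg)), imax] - seg[np.arange(len(seg)), imin]
    sign = np.where(imin < imax, 1.0, np.where(imin > imax, -1.0, 0.0))
    return amp * sign


def burst_triggered_average(
    onsets_s: np.ndarray,
    angles: np.ndarray,
    dt: float = 0.02,
    component: str = "",
) -> BtaResult:
    """Burst-triggered average displacement of one angle series (degrees).

    ``onsets_s`` are burst-onset times in seconds relative to the start of the
    angle series.  Heading is normalized to zero at each onset; the trace
    spans 25 bins (500 ms) before to 50 bins (1 s) after onset.  Onsets whose
    window extends beyond the series are dropped.
    """
    angles = np.asarray(angles, dtype=float)
    pre, post, _ = _window_bins(dt)
    onset_bins = np.rint(np.asarray(onsets_s, dtype=float) / dt).astype(int)
    onset_bins = _valid_onset_bins(onset_bins, len(angles), dt)
    n = onset_bins.size
    width = pre + post + 1
    if n == 0:
        return BtaResult(component, np.full(width, np.nan), np.full(width, np.nan),
                         np.empty(0), np.nan, 0, onset_bins)
    idx = onset_bins[:, np.newaxis] + np.arange(-pre, post + 1)
    traces = angles[idx] - angles[onset_bins][:, np.newaxis]
    disps = _signed_displacements(onset_bins, angles, dt)
    sem = traces.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(width)
    return BtaResult(
        component=component,
        trace_mean=traces.mean(axis=0),
        trace_sem=sem,
        per_burst_displacements=disps,
        mean_displacement=float(disps.mean()),
        n_bursts=n,
        used_onset_bins=onset_bins,
    )


@dataclass
class ShuffleNull:
    """Wrap-around shuffled null distribution of the mean displacement."""

    displacements: np.ndarray
    lower: float  # 2.5th percentile
    upper: float  # 97.5th percentile
    n_reps: int


def wrap_around_shifts(
    n_reps: int,
    trial_length: float,
    rng: np.random.Generator,
    shift_range: tuple[float, float] = SHIFT_RANGE_S,
) -> np.ndarray:
    """Draw uniform temporal shifts in [20, 150] s, capped at the trial length."""
    low, high = shift_range
    if trial_length < high:
        logger.warning(
            "trial length %.1f s below maximum shift %.1f s; capping shift range",
            trial_length,
            high,
        )
        high = trial_length
        low = min(low, high / 2.0)
    return rng.uniform(low, high, size=n_reps)


def shuffled_null(
    onsets_s: np.ndarray,
    angles: np.ndarray,
    trial_length: float,
    dt: float = 0.02,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | np.random.Generator | None = None,
) -> ShuffleNull:
    """Null distribution of mean displacement under rigid wrap-around shifts.

    Each repetition adds one uniform random shift (20-150 s) to every burst
    onset modulo the trial length and recomputes the mean signed displacement.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    angles = np.asarray(angles, dtype=float)
    onsets_s = np.asarray(onsets_s, dtype=float)
    shifts = wrap_around_shifts(n_reps, trial_length, rng)
    shifted = (onsets_s[np.newaxis, :] + shifts[:, np.newaxis]) % trial_length
    bins = np.rint(shifted / dt).astype(int)
    null = np.empty(n_reps)
    for r in range(n_reps):
        ob = _valid_onset_bins(bins[r], len(angles), dt)
        null[r] = _signed_displacements(ob, angles, dt).mean() if ob.size else np.nan
    null = null[~np.isnan(null)]
    lo, hi = np.percentile(null, [2.5, 97.5])
    return ShuffleNull(displacements=null, lower=float(lo), upper=float(hi), n_reps=n_reps)


@dataclass
class ComponentTuning:
    """Two-trial tuning decision for one Eulerian component."""

    component: str
    tuned: bool
    direction: int  # +1 / -1 when tuned, 0 otherwise
    testable: bool
    mean_displacements: tuple[float, float]


def classify_motion_tuning(
    trial1: tuple[BtaResult, ShuffleNull],
    trial2: tuple[BtaResult, ShuffleNull],
    eligible1: bool = True,
    eligible2: bool = True,
) -> ComponentTuning:
    """Classify one component as motion tuned from two (light) trials.

    Tuned iff in *both* trials the mean displacement falls beyond the same
    null bound (both above the 97.5th or both below the 2.5th percentile) with
    a consistent sign.  A trial without at least five bursts makes the
    component untestable.
    """
    bta1, null1 = trial1
    bta2, null2 = trial2
    comp = bta1.component or bta2.component
    if not (eligible1 and eligible2) or bta1.n_bursts == 0 or bta2.n_bursts == 0:
        return ComponentTuning(comp, False, 0, False, (bta1.mean_displacement, bta2.mean_displacement))
    m1, m2 = bta1.mean_displacement, bta2.mean_displacement
    above = m1 > null1.upper and m2 > null2.upper
    below = m1 < null1.lower and m2 < null2.lower
    same_sign = np.sign(m1) == np.sign(m2) and np.sign(m1) != 0
    tuned = (above or below) and same_sign
    direction = int(np.sign(m1)) if tuned else 0
    return ComponentTuning(comp, bool(tuned), direction, True, (m1, m2))


@dataclass
class StaComparison:
    """Spike-triggered displacement, within-burst vs outside-burst spikes."""

    within_mean: float | None
    outside_mean: float | None
    n_within: int
    n_outside: int


def sta_within_outside_bursts(
    spikes: np.ndarray,
    bursts: list[Burst],
    angles: np.ndarray,
    dt: float = 0.02,
) -> StaComparison:
    """Mean spike-triggered displacement for within- vs outside-burst spikes.

    The BTA displacement procedure is applied with spike times (not burst
    onsets) as alignment points, separately per class.  An empty class is
    flagged with ``None`` rather than raised.
    """
    spikes = np.asarray(spikes, dtype=float)
    within_mask = np.zeros(spikes.size, dtype=bool)
    for b in bursts:
        within_mask |= (spikes >= b.onset) & (spikes <= b.offset)
    out = {}
    angles = np.asarray(angles, dtype=float)
    for name, sel in (("within", within_mask), ("outside", ~within_mask)):
        sub = spikes[sel]
        bins = _valid_onset_bins(np.rint(sub / dt).astype(int), len(angles), dt)
        if bins.size == 0:
            logger.warning("sta_within_outside_bursts: %s-burst class empty", name)
            out[name] = (None, 0)
        else:
            out[name] = (float(_signed_displacements(bins, angles, dt).mean()), bins.size)
    return StaComparison(
        within_mean=out["within"][0],
        outside_mean=out["outside"][0],
        n_within=out["within"][1],
        n_outside=out["outside"][1],
    )


LATENCY_WINDOWS_S = ((-0.16, -0.10), (-0.08, -0.02), (0.0, 0.06), (0.08, 0.14))


@dataclass
class BurstMotionLatency:
    """Z-scored burst counts around motion onset and 80-ms window means."""

    bin_starts: np.ndarray  # 50 bins of 20 ms spanning -500..+500 ms
    z_scores: np.ndarray
    window_means: dict[tuple[float, float], float]


def burst_motion_latency(
    burst_onsets: np.ndarray,
    event_onsets: np.ndarray,
    bin_width: float = 0.02,
    half_window: float = 0.5,
) -> BurstMotionLatency:
    """Timing of burst onsets relative to motion onsets.

    Burst onsets are counted in 20-ms bins over +/-500 ms around every motion
    onset, the counts are z-scored across the 50 bins, and the mean z is
    reported for each 80-ms window (four bins whose start times lie in the
    window, e.g. -160 to -100 ms).  Requires at least 10 motion events.
    """
    burst_onsets = np.asarray(burst_onsets, dtype=float)
    event_onsets = np.asarray(event_onsets, dtype=float)
    if event_onsets.size < 10:
        raise ValueError("burst_motion_latency requires at least 10 motion events")
    rel = burst_onsets[np.newaxis, :] - event_onsets[:, np.newaxis]
    rel = rel[(rel >= -half_window) & (rel < half_window)]
    n_bins = int(round(2.0 * half_window / bin_width))
    edges = np.linspace(-half_window, half_window, n_bins + 1)
    counts, _ = np.histogram(rel, bins=edges)
    sd = counts.std()
    z = (counts - counts.mean()) / sd if sd > 0 else np.zeros_like(counts, dtype=float)
    starts = edges[:-1]
    means = {}
    for w0, w1 in LATENCY_WINDOWS_S:
        sel = (starts >= w0 - 1e-9) & (starts <= w1 + 1e-9)
        means[(w0, w1)] = float(z[sel].mean())
    return BurstMotionLatency(bin_starts=starts, z_scores=z, window_means=means)


@dataclass
class RateDurationRegression:
    """OLS of per-burst displacement on burst rate and on burst duration."""

    slope_rate: float  # deg per Hz
    r2_rate: float
    slope_duration_per_10ms: float  # deg per 10 ms
    r2_duration: float
    n_bursts: int


def rate_duration_regression(
    bursts: list[Burst], per_burst_displacements: np.ndarray
) -> RateDurationRegression:
    """Regress per-burst displacement on within-burst rate and burst duration.

    Rate slope is reported in deg/Hz and duration slope in deg per 10 ms.
    Degenerate (constant) predictors or displacements yield zero slope and R^2.
    """
    disp = np.asarray(per_burst_displacements, dtype=float)
    if len(bursts) < 10 or disp.size != len(bursts):
        raise ValueError("need >= 10 bursts with matching displacement vector")
    rates = np.array([b.rate for b in bursts])
    durations = np.array([b.duration for b in bursts])

    def _ols(x):
        if np.ptp(x) == 0 or np.ptp(disp) == 0:
            return 0.0, 0.0
        res = stats.linregress(x, disp)
        return float(res.slope), float(res.rvalue**2)

    slope_r, r2_r = _ols(rates)
    slope_d, r2_d = _ols(durations)
    return RateDurationRegression(
        slope_rate=slope_r,
        r2_rate=r2_r,
        slope_duration_per_10ms=slope_d / 100.0,
        r2_duration=r2_d,
        n_bursts=len(bursts),
    )
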