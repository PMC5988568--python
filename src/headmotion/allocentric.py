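"""Allocentric (Earth-referenced) heading tuning of spike trains.

Heading about the yaw, pitch and roll axes is referred to as azimuth,
elevation and bank.  Tuning curves are dwell-normalized firing rates per
heading bin: 36 ten-degree bins over the full circle for azimuth, twenty
five-degree bins over [-45, 45] deg for elevation and bank.  Azimuth
modulation is tested with the Rayleigh mean resultant length against a
wrap-around shuffled null; elevation/bank use a tuning-width criterion suited
to the restricted sampling range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from headmotion.bursts import wrap_around_shifts

AZIMUTH_EDGES = np.linspace(-180.0, 180.0, 37)
ELEVATION_EDGES = np.linspace(-45.0, 45.0, 21)
WIDTH_THRESHOLD_FRACTION = 0.25
DIRECTION_TOL_DEG = 30.0


@dataclass
class AllocentricTuning:
    """Dwell-normalized heading tuning curve for one allocentric axis."""

    axis: str  # azimuth | elevation | bank
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    rate: np.ndarray  # spikes/s; NaN for unvisited bins
    dwell_s: np.ndarray
    spike_counts: np.ndarray

    @property
    def preferred_direction(self) -> float:
        """Bin center of the maximum firing rate (NaN if never visited)."""
        if np.all(np.isnan(self.rate)):
            return np.nan
        return float(self.bin_centers[np.nanargmax(self.rate)])


def _wrap_azimuth(deg: np.ndarray) -> np.ndarray:
    return (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0


def tuning_curve(
    spikes: np.ndarray,
    heading_deg: np.ndarray,
    dt: float = 0.02,
    axis: str = "azimuth",
) -> AllocentricTuning:
    """Heading tuning curve: spikes per second of dwell in each heading bin.

    Spikes are assigned the heading of the temporal bin containing them.
    For elevation and bank, samples (and their spikes) outside [-45, 45] deg
    are excluded; azimuth headings are wrapped onto [-180, 180).
    """
    heading = np.asarray(heading_deg, dtype=float)
    spikes = np.asarray(spikes, dtype=float)
    if axis == "azimuth":
        edges = AZIMUTH_EDGES
        heading = _wrap_azimuth(heading)
    elif axis in ("elevation", "bank"):
        edges = ELEVATION_EDGES
    else:
        raise ValueError(f"unknown axis: {axis!r}")
    n_bins = len(edges) - 1
    which = np.digitize(heading, edges) - 1
    valid = (which >= 0) & (which < n_bins) & (heading >= edges[0]) & (heading <= edges[-1])
    dwell = np.bincount(which[valid], minlength=n_bins) * dt

    spike_bins = np.floor(spikes / dt).astype(int)
    spike_bins = spike_bins[(spike_bins >= 0) & (spike_bins < heading.size)]
    ok = valid[spike_bins]
    counts = np.bincount(which[spike_bins[ok]], minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(dwell > 0, counts / np.where(dwell > 0, dwell, 1.0), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AllocentricTuning(axis, edges, centers, rate, dwell, counts)


def rayleigh_r(curve: AllocentricTuning) -> float:
    """Mean resultant length of the rate-weighted circular distribution.

    ``x`` and ``y`` are the rate-weighted mean rectangular coordinates over
    visited bin centers; ``r = sqrt(x^2 + y^2)`` lies in [0, 1] (0 uniform,
    1 all firing in one bin).
    """
    visited = ~np.isnan(curve.rate)
    rates = curve.rate[visited]
    total = rates.sum()
    if total <= 0:
        return 0.0
    theta = np.radians(curve.bin_centers[visited])
    x = float(np.sum(rates * np.cos(theta)) / total)
    y = float(np.sum(rates * np.sin(theta)) / total)
    return float(np.hypot(x, y))


def shuffled_curves(
    spikes: np.ndarray,
    heading_deg: np.ndarray,
    trial_length: float,
    dt: float = 0.02,
    axis: str = "azimuth",
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> list[AllocentricTuning]:
    """Tuning curves from wrap-around time-shifted spike trains (20-150 s)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spikes = np.asarray(spikes, dtype=float)
    shifts = wrap_around_shifts(n_reps, trial_length, rng)
    return [
        tuning_curve((spikes + s) % trial_length, heading_deg, dt=dt, axis=axis)
        for s in shifts
    ]


def rayleigh_test(
    curve: AllocentricTuning, shuffled: list[AllocentricTuning]
) -> tuple[float, bool]:
    """Rayleigh score and whether it exceeds 95% of the shuffled scores."""
    r = rayleigh_r(curve)
    null = np.array([rayleigh_r(c) for c in shuffled])
    return r, bool(r > np.percentile(null, 95.0))


def tuning_width_pct(curve: AllocentricTuning) -> float:
    """Percentage of bins whose rate exceeds min + 25% of (max - min).

    The threshold sits above the minimum rate so that background firing is
    discounted; a flat curve (max == min) has every bin at threshold and is
    reported as 100% (never modulated).
    """
    visited = ~np.isnan(curve.rate)
    if not visited.any():
        return 100.0
    rates = curve.rate[visited]
    lo, hi = float(rates.min()), float(rates.max())
    if hi == lo:
        return 100.0
    threshold = lo + WIDTH_THRESHOLD_FRACTION * (hi - lo)
    n_total = len(curve.bin_centers)
    return 100.0 * float(np.sum(rates > threshold)) / n_total


def tuning_width_test(
    curve: AllocentricTuning, shuffled: list[AllocentricTuning]
) -> tuple[float, bool]:
    """Tuning width and whether it is below the 5th percentile of the null."""
    width = tuning_width_pct(curve)
    null = np.array([tuning_width_pct(c) for c in shuffled])
    return width, bool(width < np.percentile(null, 5.0))


def _direction_difference_deg(d1: float, d2: float, circular: bool) -> float:
    diff = abs(d1 - d2)
    if circular:
        diff = min(diff, 360.0 - diff)
    return diff


@dataclass
class AllocentricClassification:
    """Two-trial allocentric modulation decision for one axis."""

    axis: str
    modulated: bool
    statistics: tuple[float, float]  # Rayleigh r (azimuth) or width pct
    preferred_directions: tuple[float, float]
    direction_difference_deg: float


def classify_allocentric_modulation(
    axis: str,
    trial1: tuple[AllocentricTuning, list[AllocentricTuning]],
    trial2: tuple[AllocentricTuning, list[AllocentricTuning]],
) -> AllocentricClassification:
    """Joint two-trial modulation test with preferred-direction consistency.

    Azimuth: Rayleigh score above the null's 95th percentile in both trials.
    Elevation/bank: tuning width below the null's 5th percentile in both.
    Either way the preferred direction (bin of maximum rate) must agree across
    trials to within 30 deg.
    """
    curve1, null1 = trial1
    curve2, null2 = trial2
    if axis == "azimuth":
        s1, pass1 = rayleigh_test(curve1, null1)
        s2, pass2 = rayleigh_test(curve2, null2)
    else:
        s1, pass1 = tuning_width_test(curve1, null1)
        s2, pass2 = tuning_width_test(curve2, null2)
    d1, d2 = curve1.preferred_direction, curve2.preferred_direction
    diff = _direction_difference_deg(d1, d2, circular=axis == "azimuth")
    modulated = bool(pass1 and pass2 and diff < DIRECTION_TOL_DEG)
    return AllocentricClassification(axis, modulated, (s1, s2), (d1, d2), diff)


def anticipatory_shift(
    spikes: np.ndarray,
    azimuth_deg: np.ndarray,
    dt: float = 0.02,
    shifts_s: np.ndarray | None = None,
) -> dict[float, float]:
    """Rayleigh score at spike-time shifts of -100..+100 ms in 20-ms steps.

    Positive shifts test anticipatory firing (spikes lead heading), negative
    shifts delayed firing.  Shifted spikes falling outside the trial are
    dropped.  Returns ``{shift_seconds: rayleigh_r}``.
    """
    if shifts_s is None:
        shifts_s = np.arange(-5, 6) * 0.02
    azimuth = np.asarray(azimuth_deg, dtype=float)
    spikes = np.asarray(spikes, dtype=float)
    t_max = azimuth.size * dt
    out = {}
    for s in shifts_s:
        shifted = spikes + s
        shifted = shifted[(shifted >= 0) & (shifted < t_max)]
        out[float(round(s, 3))] = rayleigh_r(tuning_curve(shifted, azimuth, dt=dt, axis="azimuth"))
    return out
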