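"""Activity classification and curve metrics for cell time-courses.

A cell (or pixel) counts as active when the variance of its linearly
detrended time-course exceeds the variance of a quiescent reference trace by
more than a threshold multiple (default 2) of the reference-variance spread;
linear detrending removes slow drift such as photobleaching.  Curve-level
metrics locate phase transitions (steepest descent), quantify burst plateau
fractions and synchronization, and pair coupled against uncoupled scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import detrend

__all__ = [
    "ActivityClassification",
    "classify_active",
    "percent_active",
    "plateau_fraction",
    "synchronization_index",
    "TransitionLocation",
    "transition_location",
    "transition_drop",
    "half_activity_crossing",
    "coupled_vs_uncoupled_curve",
]

N_REFERENCE_SEGMENTS = 10


class InvalidReferenceError(ValueError):
    """Reference trace is empty, too short or exactly constant."""


@dataclass(frozen=True)
class ActivityClassification:
    """Per-cell active flags with the variances that produced them."""

    active: np.ndarray = field(repr=False)
    variance: np.ndarray = field(repr=False)
    reference_variance: float = 0.0
    reference_spread: float = 0.0
    threshold_mult: float = 2.0
    threshold: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(len(self.active)),
                "variance": self.variance,
                "active_flag": self.active.astype(int),
            }
        )


def _reference_stats(reference: np.ndarray) -> tuple[float, float]:
    """Variance of the detrended reference and the SD of per-segment
    variances (the reference is split into equal segments to estimate the
    spread of its variance)."""
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 1 or len(ref) < 2:
        raise InvalidReferenceError("reference trace must be 1D with >= 2 samples")
    if np.ptp(ref) == 0:
        raise InvalidReferenceError("reference trace is constant")
    ref = detrend(ref, type="linear")
    var = float(np.var(ref))
    nseg = min(N_REFERENCE_SEGMENTS, len(ref) // 2)
    seg_vars = [np.var(s) for s in np.array_split(ref, nseg)]
    return var, float(np.std(seg_vars))


def classify_active(
    traces,
    reference=None,
    reference_stats: tuple[float, float] | None = None,
    threshold_mult: float = 2.0,
    variance_floor: float = 0.0,
    elevation_floor: float | None = None,
) -> ActivityClassification:
    """Classify each trace as active/inactive by the variance rule.

    ``traces`` is (cells, time); each trace is linearly detrended and its
    variance compared against ``reference_variance + threshold_mult *
    reference_spread``.  Supply either a quiescent ``reference`` trace or
    precomputed ``reference_stats = (variance, spread)``.  ``variance_floor``
    sets a lower bound on the threshold, useful for noise-free simulated
    traces whose reference variance is vanishingly small.

    ``elevation_floor`` (same units as the traces) additionally marks a
    trace active when its raw mean exceeds the reference mean by more than
    the floor.  Simulated cells driven into a continuous depolarized
    plateau carry strongly elevated calcium with little variance; imaging
    data rarely needs this criterion.  It requires a reference trace.
    """
    x = np.atleast_2d(np.asarray(traces, dtype=float))
    if x.shape[1] < 2:
        raise ValueError("traces need at least 2 time points")
    if reference_stats is not None:
        ref_var, ref_sd = map(float, reference_stats)
    elif reference is not None:
        ref_var, ref_sd = _reference_stats(reference)
    else:
        raise ValueError("supply a reference trace or reference_stats")
    det = detrend(x, axis=1, type="linear")
    var = det.var(axis=1)
    threshold = max(ref_var + threshold_mult * ref_sd, variance_floor)
    active = var > threshold
    if elevation_floor is not None:
        if reference is None:
            raise ValueError("elevation_floor requires a reference trace")
        ref_mean = float(np.mean(reference))
        active = active | (x.mean(axis=1) > ref_mean + elevation_floor)
    return ActivityClassification(
        active=active,
        variance=var,
        reference_variance=ref_var,
        reference_spread=ref_sd,
        threshold_mult=threshold_mult,
        threshold=threshold,
    )


def percent_active(classification: ActivityClassification, weights=None) -> float:
    """Weighted percent of active cells (unit weights for simulated cells;
    pixel-area weights for imaging data)."""
    flags = classification.active.astype(float)
    if weights is None:
        return float(flags.mean() * 100.0)
    w = np.asarray(weights, dtype=float)
    if w.shape != flags.shape:
        raise ValueError("weights must match the number of cells")
    return float(np.sum(w * flags) / np.sum(w) * 100.0)


def plateau_fraction(trace, detrend_first: bool = True) -> float:
    """Fraction of time an oscillating trace spends in its elevated phase:
    samples above the midpoint of the 10th/90th-percentile levels (robust to
    spike overshoot)."""
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("plateau_fraction expects a single trace")
    if detrend_first:
        x = detrend(x, type="linear")
    lo, hi = np.percentile(x, [10, 90])
    if hi <= lo:
        raise ValueError("trace has no elevated phase (undefined plateau)")
    mid = 0.5 * (lo + hi)
    return float(np.mean(x > mid))


def synchronization_index(traces, active_mask=None) -> float:
    """Mean pairwise Pearson correlation over (active) traces, in [−1, 1]."""
    x = np.atleast_2d(np.asarray(traces, dtype=float))
    if active_mask is not None:
        x = x[np.asarray(active_mask, dtype=bool)]
    if x.shape[0] < 2:
        raise ValueError("synchronization needs at least 2 (active) traces")
    r = np.corrcoef(x)
    iu = np.triu_indices_from(r, k=1)
    return float(np.mean(r[iu]))


@dataclass(frozen=True)
class TransitionLocation:
    """Steepest-descent location of an activity curve with its sharpness
    (max slope magnitude per unit control) and the transition flag."""

    location: float
    sharpness: float
    has_transition: bool
    smoothed: bool = False


def transition_location(
    control,
    activity,
    slope_floor_mult: float = 2.0,
) -> TransitionLocation:
    """Locate the steepest change of an activity curve.

    Returns the midpoint of the adjacent pair with the largest absolute
    difference quotient.  Noisy non-monotone curves are first smoothed with
    a 3-point moving average.  Curves whose maximum step is below
    ``slope_floor_mult`` times the median absolute adjacent difference are
    flagged as having no transition (e.g. a perfectly linear curve).
    """
    c = np.asarray(control, dtype=float)
    y = np.asarray(activity, dtype=float)
    if len(c) < 3 or len(c) != len(y):
        raise ValueError("need >= 3 aligned points")
    d = np.diff(y)
    smoothed = False
    if np.any(d > 0) and np.any(d < 0):  # non-monotone: smooth first
        y = np.convolve(y, np.ones(3) / 3.0, mode="same")
        y[0] = (2 * np.asarray(activity, float)[0] + activity[1]) / 3.0
        y[-1] = (2 * np.asarray(activity, float)[-1] + activity[-2]) / 3.0
        d = np.diff(y)
        smoothed = True
    steps = np.abs(d)
    i = int(np.argmax(steps))
    floor = slope_floor_mult * float(np.median(steps))
    has_transition = steps[i] > floor
    location = float(0.5 * (c[i] + c[i + 1]))
    sharpness = float(steps[i] / abs(c[i + 1] - c[i]))
    return TransitionLocation(
        location=location,
        sharpness=sharpness,
        has_transition=bool(has_transition),
        smoothed=smoothed,
    )


def transition_drop(
    control,
    activity,
    pre_offset: float = 0.05,
    post_offset: float = 0.10,
) -> dict:
    """Summary of a percent-active phase-transition curve.

    The transition band is anchored to the steepest-descent location: the
    pre-transition shoulder sits ``pre_offset`` above it and the
    post-transition boundary ``post_offset`` below it (matching the named
    pre-critical / post-critical regions of the mutant-expression
    experiments).  Returns the steepest-descent ``location``, the activity
    lost between full excitability and the shoulder (``pre_drop``,
    percentage points), and the drop across the transition expressed as a
    percentage of the shoulder activity (``relative_drop_pct``).
    """
    c = np.asarray(control, dtype=float)
    y = np.asarray(activity, dtype=float)
    loc = transition_location(c, y)
    a_top = float(y[np.argmax(c)])
    a_pre = float(np.interp(loc.location + pre_offset, c, y))
    a_post = float(np.interp(loc.location - post_offset, c, y))
    return {
        "location": loc.location,
        "sharpness": loc.sharpness,
        "shoulder_pct": a_pre,
        "floor_pct": a_post,
        "pre_drop_pct_points": a_top - a_pre,
        "relative_drop_pct": 100.0 * (a_pre - a_post) / a_pre if a_pre > 0 else float("nan"),
    }


def half_activity_crossing(control, activity) -> float:
    """Control value at which a descending activity curve first crosses half
    of its unimpaired (first-point) activity, linearly interpolated."""
    c = np.asarray(control, dtype=float)
    y = np.asarray(activity, dtype=float)
    half = y[0] / 2.0
    below = np.nonzero(y < half)[0]
    if len(below) == 0 or below[0] == 0:
        raise ValueError("curve never crosses half of its unimpaired activity")
    i = below[0]
    t = (y[i - 1] - half) / (y[i - 1] - y[i])
    return float(c[i - 1] + t * (c[i] - c[i - 1]))


def coupled_vs_uncoupled_curve(coupled, uncoupled) -> pd.DataFrame:
    """Pair a coupled scan against its uncoupled counterpart: resultant
    network activity as a function of the intrinsic excitability of the
    constituent cells (the uncoupled activity).

    Both curves must share the underlying control grid; rows are ordered by
    increasing uncoupled activity.
    """
    cc = np.asarray(coupled.control, dtype=float)
    cu = np.asarray(uncoupled.control, dtype=float)
    if cc.shape != cu.shape or not np.allclose(cc, cu):
        raise ValueError("coupled and uncoupled curves must share the scan grid")
    df = pd.DataFrame(
        {
            "control_value": cc,
            "uncoupled_pct_active": uncoupled.mean_pct,
            "coupled_pct_active": coupled.mean_pct,
        }
    ).sort_values("uncoupled_pct_active", kind="stable")
    return df.reset_index(drop=True)
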