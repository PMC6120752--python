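"""Lick metrics and behavioral epoch labeling.

A time point is in a *licking* epoch when a lick occurred within 0.25 s of it
(roughly two lick cycles, looking both backward and forward), and in a
*non-licking* epoch when no lick occurred within 0.75 s. Times falling in the
gap between the two thresholds are *unclassified* and are excluded from
epoch-conditioned averages.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LICKING",
    "NON_LICKING",
    "UNCLASSIFIED",
    "lick_rate",
    "epoch_at",
    "epoch_labels",
    "tone_response_time",
    "lick_probability",
]

LICKING = "licking"
NON_LICKING = "non-licking"
UNCLASSIFIED = "unclassified"

#: Boundary comparisons at float precision use this tolerance (seconds).
TIME_TOL = 1e-9

LICK_WINDOW = 0.25
QUIET_WINDOW = 0.75


def lick_rate(lick_times) -> float:
    """Lick rate as the inverse of the average inter-lick interval.

    Requires at least two licks; a rate is undefined otherwise.
    """
    lick_times = np.asarray(lick_times, dtype=float).ravel()
    if lick_times.size < 2:
        raise ValueError("lick rate is undefined for fewer than 2 licks")
    mean_ili = float(np.mean(np.diff(lick_times)))
    if mean_ili <= 0:
        raise ValueError("non-positive mean inter-lick interval")
    return 1.0 / mean_ili


def _nearest_lick_distance(times: np.ndarray, lick_times: np.ndarray) -> np.ndarray:
    """Distance from each query time to the nearest lick (inf if no licks)."""
    if lick_times.size == 0:
        return np.full(times.shape, np.inf)
    idx = np.searchsorted(lick_times, times)
    left = np.where(idx > 0, times - lick_times[np.maximum(idx - 1, 0)], np.inf)
    right = np.where(
        idx < lick_times.size,
        lick_times[np.minimum(idx, lick_times.size - 1)] - times,
        np.inf,
    )
    return np.minimum(left, right)


def epoch_labels(
    times,
    lick_times,
    lick_window: float = LICK_WINDOW,
    quiet_window: float = QUIET_WINDOW,
) -> np.ndarray:
    """Epoch label for each query time.

    ``licking`` if a lick lies within ``lick_window`` (inclusive, symmetric
    look-back/look-ahead), ``non-licking`` if no lick lies within
    ``quiet_window`` (strict: a lick at exactly the quiet threshold leaves the
    time unclassified), ``unclassified`` otherwise. The two thresholds make
    the three labels a partition of the time axis.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    lick_times = np.asarray(lick_times, dtype=float).ravel()
    if lick_times.size > 1 and np.any(np.diff(lick_times) < 0):
        raise ValueError("lick_times must be sorted")
    d = _nearest_lick_distance(times, lick_times)
    out = np.full(times.shape, UNCLASSIFIED, dtype=object)
    out[d <= lick_window + TIME_TOL] = LICKING
    out[d > quiet_window + TIME_TOL] = NON_LICKING
    return out


def epoch_at(t: float, lick_times, **kwargs) -> str:
    """Epoch label at a single time point (see :func:`epoch_labels`)."""
    return str(epoch_labels([t], lick_times, **kwargs)[0])


def tone_response_time(cue_offsets, lick_times, cue_onsets=None) -> np.ndarray:
    """Per-trial interval between the end of the tone cue and the first
    subsequent lick.

    A trial with no lick before the next cue begins is flagged absent (NaN).
    When ``cue_onsets`` is omitted the next cue offset bounds the trial.
    """
    cue_offsets = np.asarray(cue_offsets, dtype=float).ravel()
    lick_times = np.asarray(lick_times, dtype=float).ravel()
    if np.any(np.diff(cue_offsets) < 0) or np.any(np.diff(lick_times) < 0):
        raise ValueError("inputs must be sorted")
    if cue_onsets is not None:
        bounds = np.append(np.asarray(cue_onsets, dtype=float).ravel()[1:], np.inf)
    else:
        bounds = np.append(cue_offsets[1:], np.inf)
    out = np.full(cue_offsets.shape, np.nan)
    for i, (t_off, t_bound) in enumerate(zip(cue_offsets, bounds)):
        j = np.searchsorted(lick_times, t_off, side="right")
        if j < lick_times.size and lick_times[j] < t_bound:
            out[i] = lick_times[j] - t_off
    return out


def lick_probability(
    trial_lick_times,
    align_times=None,
    bin_width: float = 0.1,
    window: tuple[float, float] = (-1.0, 4.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial lick probability per time bin around an alignment point.

    Parameters
    ----------
    trial_lick_times:
        One array of lick times per trial.
    align_times:
        Per-trial alignment times (e.g. water delivery). If omitted, lick
        times are assumed already trial-relative.
    bin_width:
        Bin width in seconds (must be positive).
    window:
        (start, end) of the peri-event window in seconds relative to the
        alignment point.

    Returns
    -------
    bin_centers, probability
        ``probability[j]`` is the fraction of trials with at least one lick
        in bin j; values lie in [0, 1].
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    trials = [np.asarray(t, dtype=float).ravel() for t in trial_lick_times]
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    if align_times is not None:
        align_times = np.asarray(align_times, dtype=float).ravel()
        if align_times.size != len(trials):
            raise ValueError("align_times must match number of trials")
        trials = [t - a for t, a in zip(trials, align_times)]
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    for t in trials:
        hist, _ = np.histogram(t, bins=edges)
        counts += hist > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / len(trials)
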