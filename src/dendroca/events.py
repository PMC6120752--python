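"""Event inference, per-event dF/F, and isolation classification.

Ca2+ events are inferred by sparse nonnegative deconvolution of the trace
against the exponential indicator kernel: an L1-penalized nonnegative fit of
a per-frame spike vector (with a jointly fitted baseline offset) finds the
candidate onsets, and an unpenalized joint refit assigns each candidate a
debiased amplitude, which is thresholded against a MAD-derived noise scale.
Because the fit is joint over overlapping kernels, events riding on the
decay of earlier events remain detectable.

Per-event dF/F uses a baseline window immediately preceding the event
(~200 ms); for overlapping events that window simply sits on the
predecessor's decay, with no correction. The peak is either the raw maximum
within one decay constant of the event ("max") or the amplitude of a
least-squares fit of the indicator kernel with subframe onset refinement
("fit", the default, which is unbiased in noise and free of frame
discretization loss).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FluorescenceTrace, baseline_low_percentile
from .synthetic import evaluate_kernel, gcamp_kernel

__all__ = [
    "CaEvent",
    "infer_events",
    "compute_event_dff",
    "classify_isolation",
    "select_overlapping_pairs",
    "trial_average",
    "difference_average",
    "event_rate",
    "peri_event_rate",
    "isolation_counts",
]

TIME_TOL = 1e-9

ISOLATED = "isolated"
PAIR = "pair"
TRIPLET = "triplet"
OTHER = "other"


@dataclass
class CaEvent:
    """One inferred Ca2+ event."""

    time: float
    peak_dff: float
    baseline_window: tuple[float, float]
    isolation: str = OTHER
    epoch: str = "unclassified"

    def __post_init__(self) -> None:
        if not np.isfinite(self.peak_dff):
            raise ValueError("peak_dff must be finite")
        if self.baseline_window[1] > self.time + TIME_TOL:
            raise ValueError("baseline window must precede the event")


def _fista_deconv(
    x: np.ndarray, kernel: np.ndarray, lam: float, n_iter: int = 300
) -> np.ndarray:
    """L1-penalized nonnegative deconvolution (FISTA).

    Minimizes ``0.5 * ||x - kernel * s||^2 + lam * sum(s)`` subject to
    ``s >= 0`` over a per-frame spike vector ``s``.
    """
    n, ell = x.size, kernel.size
    lip = float(np.abs(kernel).sum()) ** 2
    step = 1.0 / lip
    s = np.zeros(n)
    z = s.copy()
    tk = 1.0
    b = float(np.median(x))
    pad = np.zeros(ell - 1)
    for _ in range(n_iter):
        fit = np.convolve(z, kernel)[:n]
        b = float(np.mean(x - fit))  # unpenalized baseline offset
        r = fit + b - x
        grad = np.correlate(np.concatenate([r, pad]), kernel, mode="valid")
        s_new = np.maximum(z - step * (grad + lam), 0.0)
        tk1 = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        z = s_new + ((tk - 1.0) / tk1) * (s_new - s)
        s, tk = s_new, tk1
    return s


def _support_peaks(s: np.ndarray, floor: float) -> np.ndarray:
    """Candidate onset frames: local maxima of the spike vector above floor."""
    idx = np.nonzero(s > floor)[0]
    if idx.size == 0:
        return idx
    peaks = []
    for i in idx:
        left = s[i - 1] if i > 0 else -np.inf
        right = s[i + 1] if i < s.size - 1 else -np.inf
        if s[i] >= left and s[i] > right:
            peaks.append(i)
    return np.asarray(peaks, dtype=int)


def _restricted_nnls(
    x: np.ndarray, kernel: np.ndarray, cand: np.ndarray, n_sweeps: int = 200
) -> np.ndarray:
    """Debiasing fit: NNLS of unit-peak kernels at the candidate frames plus
    an unconstrained baseline offset, by cyclic coordinate descent."""
    n, m = x.size, cand.size
    design = np.zeros((n, m + 1))
    for j, c in enumerate(cand):
        k = kernel[: n - c]
        design[c : c + k.size, j] = k
    design[:, m] = 1.0  # baseline offset, unconstrained
    gram = design.T @ design
    atb = design.T @ x
    a = np.zeros(m + 1)
    diag = np.clip(np.diag(gram), 1e-12, None)
    for _ in range(n_sweeps):
        delta = 0.0
        for j in range(m + 1):
            new = a[j] + (atb[j] - gram[j] @ a) / diag[j]
            if j < m:
                new = max(0.0, new)
            delta = max(delta, abs(new - a[j]))
            a[j] = new
        if delta < 1e-12:
            break
    return a[:m]


def infer_events(
    trace,
    frame_rate: float | None = None,
    tau_decay: float = 0.150,
    tau_rise: float = 0.010,
    threshold_mads: float = 3.5,
    support_mads: float = 1.5,
    refractory_frames: int = 2,
    return_amplitudes: bool = False,
) -> np.ndarray:
    """Event onset times by sparse nonnegative deconvolution of the trace
    against the exponential indicator kernel.

    The trace (as dF/F, so all thresholds are scale-invariant) is
    deconvolved by L1-penalized nonnegative least squares over a per-frame
    spike vector; the penalty is set from a MAD-derived noise scale of the
    AR(1) innovation ``f_t - g * f_{t-1}``. Local maxima of the recovered
    spike vector are then re-fit jointly without the penalty (debiasing),
    and candidates whose unbiased amplitude exceeds ``threshold_mads``
    times the amplitude noise scale become events. Because the fit is
    joint, events riding on the decay of earlier events remain detectable
    down to the refractory spacing. A flat trace yields no events.

    With ``return_amplitudes`` the debiased per-event dF/F amplitudes of
    the joint fit are returned alongside the onset times; unlike the
    windowed per-event measure they are free of contamination from
    overlapping transients.
    """
    if isinstance(trace, FluorescenceTrace):
        f, frame_rate = trace.samples, trace.frame_rate
    else:
        f = np.asarray(trace, dtype=float).ravel()
        if frame_rate is None:
            raise ValueError("frame_rate is required with an array trace")
    def empty():
        return (np.empty(0), np.empty(0)) if return_amplitudes else np.empty(0)

    if f.size < 2 or f.std() == 0:
        return empty()
    # detection operates on dF/F so thresholds are scale-invariant
    f0 = baseline_low_percentile(f)
    if f0 <= 0:
        f0 = float(np.mean(np.abs(f))) or 1.0
    x = f / f0 - 1.0
    kernel = gcamp_kernel(tau_rise, tau_decay, frame_rate, n_decay_constants=8.0)
    if x.size < kernel.size:
        raise ValueError("trace shorter than the indicator kernel")
    g = np.exp(-1.0 / (frame_rate * tau_decay))
    s = x[1:] - g * x[:-1]
    s = s - np.median(s)
    # robust noise scale; events are sparse so the MAD sees mostly noise.
    # The floor absorbs discretization/model error in the noiseless case.
    sigma_innov = 1.4826 * float(np.median(np.abs(s)))
    sigma_innov = max(sigma_innov, 1e-3 * float(np.ptp(x)))
    sigma_x = sigma_innov / np.sqrt(1.0 + g * g)
    hh = float(kernel @ kernel)
    sigma_amp = sigma_x / np.sqrt(hh)

    x = x - np.median(x)
    lam = support_mads * sigma_x * np.sqrt(hh)
    spikes = _fista_deconv(x, kernel, lam)
    if spikes.max() <= 0:
        return empty()
    cand = _support_peaks(spikes, floor=1e-3 * float(spikes.max()))
    if cand.size == 0:
        return empty()
    amps = _restricted_nnls(x, kernel, cand)
    # re-estimate the noise scale from the fit residual: unlike the raw
    # innovation MAD it is not inflated by the events themselves
    fit = np.zeros_like(x)
    for c, a in zip(cand, amps):
        k = kernel[: x.size - c]
        fit[c : c + k.size] += a * k
    resid = x - fit
    resid -= np.mean(resid)
    sigma_resid = 1.4826 * float(np.median(np.abs(resid)))
    sigma_amp = max(
        min(sigma_amp, sigma_resid / np.sqrt(hh)), 1e-3 * float(np.ptp(x)) / np.sqrt(hh)
    )
    keep = amps > threshold_mads * sigma_amp
    cand, amps = cand[keep], amps[keep]
    # merge sub-refractory splits of a single event onto the larger amplitude
    order = np.argsort(cand)
    cand, amps = cand[order], amps[order]
    kept_idx: list[int] = []
    for i in range(cand.size):
        if kept_idx and cand[i] - cand[kept_idx[-1]] < refractory_frames:
            if amps[i] > amps[kept_idx[-1]]:
                kept_idx[-1] = i
        else:
            kept_idx.append(i)
    times = cand[kept_idx] / frame_rate
    if return_amplitudes:
        return times, amps[kept_idx]
    return times


def quantify_at_times(
    trace,
    event_times,
    frame_rate: float | None = None,
    tau_decay: float = 0.150,
    tau_rise: float = 0.010,
) -> np.ndarray:
    """dF/F amplitudes of a fixed set of event onsets by joint NNLS.

    Fits unit-peak indicator kernels at the given onset times (plus a free
    baseline offset) to the whole trace at once. Because the onset set is
    supplied rather than detected, the estimator is linear in the data and
    free of detection-selection bias — the tool for paired designs, where
    both sessions are quantified on the pooled set of detected onsets so
    any estimator bias cancels in condition ratios.
    """
    if isinstance(trace, FluorescenceTrace):
        f, frame_rate = trace.samples, trace.frame_rate
    else:
        f = np.asarray(trace, dtype=float).ravel()
        if frame_rate is None:
            raise ValueError("frame_rate is required with an array trace")
    event_times = np.asarray(event_times, dtype=float).ravel()
    if event_times.size == 0:
        return np.empty(0)
    f0 = baseline_low_percentile(f)
    if f0 <= 0:
        raise ValueError("degenerate baseline: F0 must be positive")
    x = f / f0 - 1.0
    x = x - np.median(x)
    kernel = gcamp_kernel(tau_rise, tau_decay, frame_rate, n_decay_constants=8.0)
    cand = np.clip(np.round(event_times * frame_rate).astype(int), 0, x.size - 2)
    return _restricted_nnls(x, kernel, cand)


def pool_event_times(times_a, times_b, frame_rate: float, tol_frames: float = 1.5):
    """Union of two event-time sets, merging onsets within ``tol_frames``."""
    merged = np.sort(np.concatenate([np.asarray(times_a), np.asarray(times_b)]))
    if merged.size == 0:
        return merged
    out = [merged[0]]
    for t in merged[1:]:
        if t - out[-1] <= tol_frames / frame_rate:
            continue
        out.append(t)
    return np.asarray(out)


def _fit_amplitude(
    dff: np.ndarray,
    frame_rate: float,
    event_time: float,
    tau_decay: float,
    tau_rise: float,
    window: float,
    n_phases: int = 21,
) -> float:
    """LS amplitude of a unit-peak kernel with subframe onset refinement.

    Besides the event kernel the fit carries a constant and a decaying
    exponential (same tau) as nuisance regressors, which absorb the tail of
    a preceding transient running through the window — the baseline F0
    itself is left uncorrected, so only the peak estimate benefits.
    """
    n = dff.size
    # the window reaches back through the pre-event baseline: there the
    # event kernel is zero, so those samples anchor the nuisance terms
    i0 = int(np.floor((event_time - 0.2) * frame_rate))
    i1 = min(n, int(np.ceil((event_time + window) * frame_rate)) + 1)
    idx = np.arange(max(i0, 0), i1)
    if idx.size < 4:
        return float(np.max(dff[max(i0, 0) : i1], initial=0.0))
    t = idx / frame_rate
    y = dff[idx]
    tail = np.exp(-(t - t[0]) / tau_decay)
    ones = np.ones_like(t)
    best_amp, best_err = 0.0, np.inf
    for ph in np.linspace(-0.5, 0.5, n_phases) / frame_rate:
        k = evaluate_kernel(t - (event_time + ph), tau_rise, tau_decay)
        if not np.any(k):
            continue
        design = np.column_stack([k, tail, ones])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        a = max(float(coef[0]), 0.0)
        err = float(np.sum((y - design @ np.r_[a, coef[1:]]) ** 2))
        if err < best_err:
            best_err, best_amp = err, a
    return best_amp


def compute_event_dff(
    trace,
    event_time: float,
    frame_rate: float | None = None,
    baseline_dur: float = 0.2,
    tau_decay: float = 0.150,
    tau_rise: float = 0.010,
    method: str = "fit",
) -> float:
    """Peak dF/F of one event relative to its immediately preceding baseline.

    F0 is the mean fluorescence over the ``baseline_dur`` window (~200 ms)
    ending at the event; for overlapping events this window lies on the
    predecessor's decay and no correction is applied. ``method="max"`` takes
    the raw maximum within one decay constant after the event;
    ``method="fit"`` (default) returns the fitted kernel amplitude, which is
    also the fitted peak since the kernel has unit peak. The result is
    invariant to multiplicative rescaling of the raw trace.
    """
    if isinstance(trace, FluorescenceTrace):
        f, frame_rate = trace.samples, trace.frame_rate
    else:
        f = np.asarray(trace, dtype=float).ravel()
        if frame_rate is None:
            raise ValueError("frame_rate is required with an array trace")
    n = f.size
    b0 = int(np.floor((event_time - baseline_dur) * frame_rate))
    b1 = int(np.floor(event_time * frame_rate))
    if b0 < 0 or b1 <= b0 or b1 > n:
        raise ValueError("baseline window must lie within the trace")
    f0 = float(np.mean(f[b0:b1]))
    if f0 <= 0:
        raise ValueError("degenerate baseline: F0 must be positive")
    if method == "max":
        p0 = b1
        p1 = min(n, int(np.ceil((event_time + tau_decay) * frame_rate)) + 1)
        if p1 <= p0:
            raise ValueError("peak window must lie within the trace")
        peak = float(np.max(f[p0:p1]))
        return (peak - f0) / f0
    if method == "fit":
        dff = f / f0 - 1.0
        return _fit_amplitude(
            dff, frame_rate, event_time, tau_decay, tau_rise, window=2 * tau_decay
        )
    raise ValueError(f"unknown method {method!r}")


def classify_isolation(
    event_times, window: float = 0.5, tol: float = TIME_TOL
) -> np.ndarray:
    """Isolation class of each event in a sorted train.

    * ``isolated``: no neighbor within ``window`` (an exact gap of
      ``window`` still counts as isolated — "at least" the window apart).
    * ``pair``: exactly two events within ``window`` of each other, both at
      least ``window`` from all other events.
    * ``triplet``: three events spanning at most ``2 * window``, all at
      least ``window`` from any event outside the triple.
    * ``other``: everything else.

    Rules are applied in that order, so an event whose nearest neighbor is
    beyond the window is isolated even if a wider triple could span it.
    """
    t = np.asarray(event_times, dtype=float).ravel()
    if np.any(np.diff(t) < 0):
        raise ValueError("event_times must be sorted")
    n = t.size
    labels = np.full(n, OTHER, dtype=object)
    if n == 0:
        return labels
    prev_gap = np.empty(n)
    next_gap = np.empty(n)
    prev_gap[0] = np.inf
    next_gap[-1] = np.inf
    if n > 1:
        gaps = np.diff(t)
        prev_gap[1:] = gaps
        next_gap[:-1] = gaps

    def far(gap: float) -> bool:
        return gap >= window - tol

    def near(gap: float) -> bool:
        return gap < window - tol

    for i in range(n):
        if far(prev_gap[i]) and far(next_gap[i]):
            labels[i] = ISOLATED
    for i in range(n - 1):
        if labels[i] != OTHER or labels[i + 1] != OTHER:
            continue
        if near(next_gap[i]) and far(prev_gap[i]) and far(next_gap[i + 1]):
            labels[i] = labels[i + 1] = PAIR
    for i in range(n - 2):
        if any(labels[i + k] != OTHER for k in range(3)):
            continue
        span = t[i + 2] - t[i]
        if span <= 2 * window + tol and far(prev_gap[i]) and far(next_gap[i + 2]):
            labels[i] = labels[i + 1] = labels[i + 2] = TRIPLET
    return labels


def isolation_counts(event_times, window: float = 0.5) -> dict[str, int]:
    """Prevalence of isolation classes (count of events per class)."""
    labels = classify_isolation(event_times, window)
    return {
        k: int(np.sum(labels == k)) for k in (ISOLATED, PAIR, TRIPLET, OTHER)
    }


def select_overlapping_pairs(
    event_times,
    min_gap: float = 0.15,
    max_gap: float = 0.20,
    tol: float = TIME_TOL,
) -> list[tuple[int, int]]:
    """Indices of consecutive events whose gap lies in [min_gap, max_gap]
    (inclusive at both ends); all other events are excluded."""
    t = np.asarray(event_times, dtype=float).ravel()
    if np.any(np.diff(t) < 0):
        raise ValueError("event_times must be sorted")
    out = []
    for i in range(t.size - 1):
        gap = t[i + 1] - t[i]
        if min_gap - tol <= gap <= max_gap + tol:
            out.append((i, i + 1))
    return out


def trial_average(
    traces,
    frame_rate: float,
    align_times,
    window: tuple[float, float] = (-1.0, 3.0),
    f0_percentile: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged dF/F around alignment times.

    Each ROI's trace is converted to dF/F with F0 equal to the mean of the
    lowest ``f0_percentile`` percent of that ROI's session samples; snippets
    at ``align_times`` are then averaged. Returns ``(rel_times, avg)`` with
    ``avg`` shaped (n_rois, n_samples).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    align_times = np.asarray(align_times, dtype=float).ravel()
    if align_times.size < 1:
        raise ValueError("need at least one alignment time")
    i0 = int(round(window[0] * frame_rate))
    i1 = int(round(window[1] * frame_rate))
    if i1 <= i0:
        raise ValueError("empty averaging window")
    rel = np.arange(i0, i1) / frame_rate
    n_t = traces.shape[1]
    out = np.zeros((traces.shape[0], i1 - i0))
    dff = np.empty_like(traces)
    for r in range(traces.shape[0]):
        f0 = baseline_low_percentile(traces[r], f0_percentile)
        if f0 <= 0:
            raise ValueError("degenerate baseline: F0 must be positive")
        dff[r] = traces[r] / f0 - 1.0
    count = 0
    for a in align_times:
        c = int(round(a * frame_rate))
        if c + i0 < 0 or c + i1 > n_t:
            continue
        out += dff[:, c + i0 : c + i1]
        count += 1
    if count == 0:
        raise ValueError("no alignment window fits inside the trace")
    return rel, out / count


def difference_average(avg_cno: np.ndarray, avg_ctrl: np.ndarray) -> np.ndarray:
    """Condition difference of trial-averaged responses (CNO minus control)."""
    avg_cno = np.asarray(avg_cno, dtype=float)
    avg_ctrl = np.asarray(avg_ctrl, dtype=float)
    if avg_cno.shape != avg_ctrl.shape:
        raise ValueError("averages must share shape")
    return avg_cno - avg_ctrl


def event_rate(event_times, duration: float) -> float:
    """Mean event rate (count / duration) in Hz."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return np.asarray(event_times).size / duration


def peri_event_rate(
    event_times,
    align_times,
    bin_width: float = 0.25,
    window: tuple[float, float] = (-2.0, 4.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Event rate binned around alignment times (e.g. cue onsets), in Hz."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    event_times = np.asarray(event_times, dtype=float).ravel()
    align_times = np.asarray(align_times, dtype=float).ravel()
    if align_times.size == 0:
        raise ValueError("need at least one alignment time")
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    for a in align_times:
        hist, _ = np.histogram(event_times - a, bins=edges)
        counts += hist
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / (align_times.size * bin_width)
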