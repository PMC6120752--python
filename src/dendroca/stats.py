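"""Effect-size statistics for disinhibition and supralinearity analyses.

Implements the study-specific quantities around which the pipeline is built:

* the MLI-dependent movement (MDM) ratio — the CNO/control ratio of mean
  Ca2+ activity during movement divided by the same ratio at rest; values
  above 1 indicate movement-specific enhancement under disinhibition;
* the ROC effect fraction — the percent of dendritic pixels whose
  condition-shifted value distribution exceeds chance separability,
  derived from the area under the empirical ROC curve;
* inter-branch variability of simultaneous event amplitudes,
  ``2 |A1 - A2| / (A1 + A2)``;
* ex vivo supralinearity — the conjunctive PF+CF response as a percent of
  the pointwise-summed single-input responses, with peaks taken from
  exponential fits of the post-stimulus fluorescence decay (blanked
  stimulus-artifact regions excluded);
* neuropil correction for bouton traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import rankdata

__all__ = [
    "MdmInputs",
    "ConjunctiveSet",
    "DecayFit",
    "mdm_ratio",
    "mdm_map",
    "roc_effect_fraction",
    "branch_variability",
    "fit_decay_peak",
    "supralinearity",
    "neuropil_correct",
]


@dataclass
class MdmInputs:
    """Epoch-conditioned mean dF/F of one ROI in the four session cells."""

    dff_cno_move: float
    dff_ctrl_move: float
    dff_cno_rest: float
    dff_ctrl_rest: float

    def __post_init__(self) -> None:
        vals = (
            self.dff_cno_move,
            self.dff_ctrl_move,
            self.dff_cno_rest,
            self.dff_ctrl_rest,
        )
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise ValueError("all four MDM inputs must be finite and positive")


@dataclass
class ConjunctiveSet:
    """Trial-averaged dF/F traces of a conjunctive stimulation experiment."""

    conj_trace: np.ndarray
    pf_trace: np.ndarray
    cf_trace: np.ndarray
    stim_time: float
    frame_rate: float
    blank_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.conj_trace = np.asarray(self.conj_trace, dtype=float).ravel()
        self.pf_trace = np.asarray(self.pf_trace, dtype=float).ravel()
        self.cf_trace = np.asarray(self.cf_trace, dtype=float).ravel()
        if not (
            self.conj_trace.size == self.pf_trace.size == self.cf_trace.size
        ):
            raise ValueError("conjunctive-set traces must share length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


def mdm_ratio(inputs: MdmInputs | None = None, **kwargs) -> float:
    """MLI-dependent movement ratio.

    ``(dF/F_CNO / dF/F_Ctrl) during movement`` divided by
    ``(dF/F_CNO / dF/F_Ctrl) at rest``. Invariant under any common
    multiplicative rescaling of all four inputs; > 1 indicates a
    movement-specific effect of disinhibition.
    """
    if inputs is None:
        inputs = MdmInputs(**kwargs)
    move = inputs.dff_cno_move / inputs.dff_ctrl_move
    rest = inputs.dff_cno_rest / inputs.dff_ctrl_rest
    return move / rest


def mdm_map(
    ctrl_move, cno_move, ctrl_rest, cno_rest
) -> tuple[np.ndarray, float]:
    """Per-ROI (or per-pixel) MDM ratios and the fraction exceeding 1.

    Inputs are matched arrays of epoch-conditioned mean activity, one entry
    per ROI/pixel, for the four condition-epoch cells. Returns the
    elementwise ratio map and the fraction of entries with ratio > 1 (the
    enhancement-threshold summary).
    """
    arrs = [np.asarray(a, dtype=float).ravel() for a in (ctrl_move, cno_move, ctrl_rest, cno_rest)]
    n = arrs[0].size
    if any(a.size != n for a in arrs) or n == 0:
        raise ValueError("the four activity arrays must be matched and nonempty")
    if any(np.any(a <= 0) for a in arrs):
        raise ValueError("activity values must be positive")
    ratios = (arrs[1] / arrs[0]) / (arrs[3] / arrs[2])
    return ratios, float(np.mean(ratios > 1.0))


def roc_effect_fraction(values_ctrl, values_cno) -> tuple[float, float]:
    """Effect size of a condition shift as (AUC, percent of pixels).

    The empirical ROC sweeps every threshold of the pooled values; the area
    under the curve is computed rank-based (Mann-Whitney, ties shared). The
    percent of pixels showing an effect is ``100 * max(0, 2 * AUC - 1)``,
    the fraction separable beyond chance.
    """
    ctrl = np.asarray(values_ctrl, dtype=float).ravel()
    cno = np.asarray(values_cno, dtype=float).ravel()
    if ctrl.size == 0 or cno.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([ctrl, cno])
    ranks = rankdata(pooled)
    r_cno = ranks[ctrl.size :].sum()
    auc = (r_cno - cno.size * (cno.size + 1) / 2.0) / (ctrl.size * cno.size)
    percent = 100.0 * max(0.0, 2.0 * auc - 1.0)
    return float(auc), float(percent)


def branch_variability(a1, a2):
    """Inter-branch variability of one event: ``2 |A1 - A2| / (A1 + A2)``.

    Symmetric in its arguments, invariant to a common positive rescaling,
    and bounded in [0, 2]. Accepts scalars or matched arrays.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if np.any(a1 < 0) or np.any(a2 < 0):
        raise ValueError("amplitudes must be non-negative")
    s = a1 + a2
    if np.any(s <= 0):
        raise ValueError("A1 + A2 must be positive")
    out = 2.0 * np.abs(a1 - a2) / s
    return float(out) if out.ndim == 0 else out


@dataclass
class DecayFit:
    """Result of an exponential decay fit to a post-stimulus transient."""

    peak: float
    tau: float
    baseline: float
    converged: bool

    def __float__(self) -> float:
        return self.peak


def fit_decay_peak(
    trace,
    frame_rate: float,
    stim_time: float,
    blank_window: tuple[float, float] | None = None,
    baseline_dur: float = 0.1,
    max_decay_dur: float = 1.0,
    tau0: float = 0.15,
) -> DecayFit:
    """Peak of a stimulus-evoked transient from an exponential decay fit.

    A single exponential ``a * exp(-(t - t0) / tau) + c`` is fitted by
    least squares to the fluorescence decay immediately following the
    stimulus (from the post-stimulus maximum onward), excluding any samples
    inside ``blank_window`` (absolute times; used when a stimulus artifact
    was blanked). The returned peak is ``a + c - baseline`` where the
    baseline is the pre-stimulus mean. Initialization: tau = ``tau0``,
    a = max - last decay sample; at most 200 iterations. Non-convergence is
    flagged and falls back to the raw maximum minus baseline.
    """
    y = np.asarray(trace, dtype=float).ravel()
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    t = np.arange(y.size) / frame_rate
    pre = y[t < stim_time]
    baseline = float(pre[-int(max(1, baseline_dur * frame_rate)) :].mean()) if pre.size else 0.0
    post = (t >= stim_time) & (t <= stim_time + max_decay_dur)
    if blank_window is not None:
        post &= ~((t >= blank_window[0]) & (t <= blank_window[1]))
    ti, yi = t[post], y[post]
    if yi.size < 10:
        raise ValueError("need at least 10 samples in the decay")
    ipk = int(np.argmax(yi))
    td, yd = ti[ipk:], yi[ipk:]
    raw_peak = float(yi.max() - baseline)
    if yd.size < 3 or np.allclose(yd, yd[0]):
        return DecayFit(peak=raw_peak, tau=np.nan, baseline=baseline, converged=False)

    # amplitude anchored at the stimulus so the peak extrapolates cleanly
    # across any blanked (artifact) region at the start of the decay
    def model(tt, a, tau, c):
        return a * np.exp(-(tt - stim_time) / tau) + c

    a0 = max(float(yd[0] - yd[-1]), 1e-12)
    try:
        popt, _ = curve_fit(
            model,
            td,
            yd,
            p0=(a0, tau0, float(yd[-1])),
            bounds=([0.0, 1e-4, -np.inf], [np.inf, 10.0, np.inf]),
            maxfev=200 * (yd.size + 3),
            xtol=1e-8,
            ftol=1e-8,
        )
    except RuntimeError:
        return DecayFit(peak=raw_peak, tau=np.nan, baseline=baseline, converged=False)
    a, tau, c = popt
    return DecayFit(peak=float(a + c - baseline), tau=float(tau), baseline=baseline, converged=True)


def supralinearity(cset: ConjunctiveSet) -> float:
    """Conjunctive response as percent of the summed single-input responses.

    The denominator trace is the pointwise sum of the parallel-fiber-alone
    and climbing-fiber-alone trial averages; numerator and denominator peaks
    both come from :func:`fit_decay_peak` with the same stimulus clock and
    blank window. 100 means exact linear summation.
    """
    num = fit_decay_peak(
        cset.conj_trace, cset.frame_rate, cset.stim_time, cset.blank_window
    )
    den = fit_decay_peak(
        cset.pf_trace + cset.cf_trace,
        cset.frame_rate,
        cset.stim_time,
        cset.blank_window,
    )
    if den.peak <= 0:
        raise ValueError("summed-response peak must be positive")
    return 100.0 * num.peak / den.peak


def neuropil_correct(bouton_dff, neuropil_dff) -> np.ndarray:
    """Neuropil-corrected bouton dF/F: per-sample subtraction of the
    adjacent-neuropil dF/F signal."""
    b = np.asarray(bouton_dff, dtype=float).ravel()
    p = np.asarray(neuropil_dff, dtype=float).ravel()
    if b.size != p.size:
        raise ValueError("bouton and neuropil traces must share length")
    return b - p
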