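"""Synthetic two-photon sessions with full ground truth.

Generates the statistical structure the analysis assumes: a cued-licking
behavioral session, climbing-fiber-like Ca2+ event trains whose rate is
boosted during licking epochs, fluorescence traces built from a
double-exponential indicator kernel (GCaMP6f-like, decay tau ~150 ms),
pixel movies with optional rigid drift, branch pairs with shared event times
and independent per-branch amplitude jitter, and ex vivo conjunctive
stimulation trials for supralinearity analysis.

The defaults mirror the in vivo regime this pipeline targets: 30 frames/s
movies, a ~1.5 Hz baseline climbing-fiber event rate that rises roughly
five-fold during licking, mean event amplitude dF/F ~0.223, and a
``disinhibited`` condition that scales event amplitudes only during
movement (licking) epochs by ``cno_gain_move``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from . import behavior as _behavior
from .core import BehaviorLog, FluorescenceTrace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gcamp_kernel",
    "kernel_peak_time",
    "evaluate_kernel",
    "simulate_lick_bouts",
    "simulate_event_train",
    "draw_amplitudes",
    "render_trace",
    "render_movie",
    "simulate_branch_pair",
    "simulate_session",
    "simulate_movie_session",
    "simulate_conjunctive_set",
    "dendrite_band_masks",
]

#: Events closer than this many frames cannot be resolved by the detector;
#: the generator enforces it as a dead time.
REFRACTORY_FRAMES = 2

CONTROL = "control"
DISINHIBITED = "disinhibited"


@dataclass
class SimConfig:
    """Parameters of a synthetic session.

    Units: rates in Hz, times in seconds, amplitudes in dF/F (dimensionless).

    ``cno_gain_move`` is the amplitude multiplier applied only to events in
    movement (licking) epochs when the session condition is ``disinhibited``;
    1.0 reproduces the control condition. ``branch_jitter_sd`` is the SD of
    the per-branch lognormal amplitude jitter (log scale) used by
    :func:`simulate_branch_pair`, and ``jitter_shrink_move`` multiplies that
    SD for movement-epoch events in the disinhibited condition (values < 1
    model the drop in inter-branch variability under disinhibition).
    """

    frame_rate: float = 30.0
    duration: float = 200.0
    tau_decay: float = 0.150
    tau_rise: float = 0.010
    base_rate: float = 1.5
    lick_boost: float = 5.0
    mean_amp: float = 0.223
    amp_cv: float = 0.2
    noise_sigma: float = 0.0446
    cno_gain_move: float = 1.0
    branch_jitter_sd: float = 0.2
    jitter_shrink_move: float = 1.0
    lick_period: float = 0.13
    bout_duration: float = 3.0
    trial_interval: float = 10.0
    cue_duration: float = 0.5
    baseline_f: float = 1.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.tau_decay <= 0 or not (self.tau_decay > self.tau_rise >= 0):
            raise ValueError("require tau_decay > tau_rise >= 0")
        if self.base_rate < 0:
            raise ValueError("base_rate must be non-negative")
        if self.mean_amp <= 0:
            raise ValueError("mean_amp must be positive")
        if self.cno_gain_move < 1.0:
            raise ValueError("cno_gain_move >= 1 models enhancement")
        if self.amp_cv < 0 or self.branch_jitter_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.lick_period <= 0 or self.bout_duration <= 0:
            raise ValueError("lick_period and bout_duration must be positive")
        if self.baseline_f <= 0:
            raise ValueError("baseline_f must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """True event times, amplitudes, masks, and condition of a session.

    ``event_amps`` are the amplitudes actually rendered, i.e. after the
    movement-epoch gain of the disinhibited condition has been applied.
    Consumed only by tests and parameter-recovery analyses.
    """

    event_times: np.ndarray
    event_amps: np.ndarray
    condition: str = CONTROL
    epoch_of_event: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    true_masks: np.ndarray | None = None
    shifts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float).ravel()
        self.event_amps = np.asarray(self.event_amps, dtype=float).ravel()
        if self.event_times.size > 1 and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if np.any(self.event_amps <= 0):
            raise ValueError("event amplitudes must be positive")


# ---------------------------------------------------------------------------
# Indicator kernel
# ---------------------------------------------------------------------------

def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the continuous kernel's peak after event onset."""
    if tau_rise == 0:
        return 0.0
    return float(
        np.log(tau_decay / tau_rise) / (1.0 / tau_rise - 1.0 / tau_decay)
    )


def evaluate_kernel(t, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Continuous double-exponential indicator kernel, unit continuous peak.

    ``k(t) = exp(-t/tau_decay) - exp(-t/tau_rise)`` for t >= 0 (pure decay
    when ``tau_rise`` is 0), scaled so its continuous maximum is exactly 1.
    """
    if tau_decay <= 0 or not (tau_decay > tau_rise >= 0):
        raise ValueError("require tau_decay > tau_rise >= 0")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    if tau_rise == 0:
        out[pos] = np.exp(-t[pos] / tau_decay)
        return out
    tp = kernel_peak_time(tau_rise, tau_decay)
    peak = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    out[pos] = (np.exp(-t[pos] / tau_decay) - np.exp(-t[pos] / tau_rise)) / peak
    return out


def gcamp_kernel(
    tau_rise: float, tau_decay: float, frame_rate: float, n_decay_constants: float = 5.0
) -> np.ndarray:
    """Sampled indicator kernel normalized to a unit peak sample.

    The kernel is non-negative, spans at least ``n_decay_constants`` decay
    constants, and its largest sample is exactly 1 so deconvolution and
    amplitude bookkeeping share one scale.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    n = int(np.ceil(n_decay_constants * tau_decay * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    k = evaluate_kernel(t, tau_rise, tau_decay)
    return k / k.max()


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def simulate_lick_bouts(
    config: SimConfig, n_trials: int, rng=None, first_cue: float = 2.0
) -> BehaviorLog:
    """Cued lick bouts: one tone cue, water delivery, and a lick bout per trial.

    Each trial's bout starts a short reaction time after the tone ends and
    lasts ``config.bout_duration`` with inter-lick intervals jittered around
    ``config.lick_period``; no licking occurs between trials.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if n_trials == 0:
        return BehaviorLog()
    cue_onsets, licks = [], []
    for i in range(n_trials):
        onset = first_cue + i * config.trial_interval
        if onset + config.cue_duration >= config.duration:
            break
        cue_onsets.append(onset)
        t = onset + config.cue_duration + 0.1 + rng.exponential(0.1)
        bout_end = t + config.bout_duration
        while t < bout_end and t < config.duration:
            licks.append(t)
            ili = config.lick_period * (1.0 + 0.05 * rng.standard_normal())
            t += max(ili, 0.5 * config.lick_period)
    cue_onsets = np.asarray(cue_onsets)
    return BehaviorLog(
        cue_onsets=cue_onsets,
        cue_offsets=cue_onsets + config.cue_duration,
        water_times=cue_onsets + config.cue_duration,
        lick_times=np.asarray(licks),
    )


# ---------------------------------------------------------------------------
# Event trains and amplitudes
# ---------------------------------------------------------------------------

def simulate_event_train(
    config: SimConfig, behavior: BehaviorLog | None = None, rng=None
) -> np.ndarray:
    """Inhomogeneous-Poisson event train with a licking-epoch rate boost.

    The instantaneous rate is ``base_rate`` outside licking epochs and
    ``base_rate * lick_boost`` inside them (epochs per the 0.25 s lick
    proximity rule). A dead time of ``REFRACTORY_FRAMES`` frames is enforced
    between events; the driving intensity is compensated for the dead time so
    the realized rate matches the configured rate.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.base_rate == 0:
        return np.empty(0)
    dead = REFRACTORY_FRAMES / config.frame_rate
    lick_times = behavior.lick_times if behavior is not None else np.empty(0)

    def compensate(rate: float) -> float:
        if rate * dead >= 0.95:
            raise ValueError("event rate too high for the refractory dead time")
        return rate / (1.0 - rate * dead)

    lam_out = compensate(config.base_rate)
    lam_in = compensate(config.base_rate * config.lick_boost)
    lam_max = max(lam_out, lam_in)
    n_cand = rng.poisson(lam_max * config.duration)
    cand = np.sort(rng.uniform(0.0, config.duration, n_cand))
    labels = _behavior.epoch_labels(cand, lick_times) if cand.size else np.empty(0)
    lam = np.where(labels == _behavior.LICKING, lam_in, lam_out)
    keep = rng.uniform(0.0, 1.0, cand.size) < lam / lam_max
    cand = cand[keep]
    # sequential dead-time enforcement
    out = []
    last = -np.inf
    for t in cand:
        if t - last >= dead:
            out.append(t)
            last = t
    return np.asarray(out)


def draw_amplitudes(config: SimConfig, n: int, rng=None) -> np.ndarray:
    """Lognormal event amplitudes with mean ``mean_amp`` and CV ``amp_cv``.

    The lognormal keeps amplitudes positive and right-skewed, matching the
    skew of observed climbing-fiber event amplitudes.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.amp_cv == 0:
        return np.full(n, config.mean_amp)
    sigma2 = np.log1p(config.amp_cv**2)
    mu = np.log(config.mean_amp) - sigma2 / 2.0
    return np.exp(mu + np.sqrt(sigma2) * rng.standard_normal(n))


# ---------------------------------------------------------------------------
# Trace and movie rendering
# ---------------------------------------------------------------------------

def _movement_gained_amps(
    config: SimConfig,
    event_times: np.ndarray,
    amps: np.ndarray,
    lick_times: np.ndarray,
    condition: str,
) -> tuple[np.ndarray, np.ndarray]:
    epochs = _behavior.epoch_labels(event_times, lick_times)
    eff = np.array(amps, dtype=float, copy=True)
    if condition == DISINHIBITED:
        eff[epochs == _behavior.LICKING] *= config.cno_gain_move
    elif condition != CONTROL:
        raise ValueError(f"unknown condition {condition!r}")
    return eff, epochs


def render_trace(
    event_times,
    amps,
    config: SimConfig,
    lick_times=None,
    condition: str = CONTROL,
    rng=None,
) -> tuple[FluorescenceTrace, GroundTruth]:
    """Render a fluorescence trace from event times and amplitudes.

    The trace follows the multiplicative model
    ``F(t) = F0 * (1 + sum_i a_i * k(t - t_i))`` plus i.i.d. Gaussian noise of
    SD ``noise_sigma * F0`` per frame (or Poisson noise when configured), so
    dF/F recovery is exact and scale-invariant. In the disinhibited
    condition the amplitudes of movement-epoch events are multiplied by
    ``cno_gain_move`` before rendering.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    event_times = np.asarray(event_times, dtype=float).ravel()
    amps = np.asarray(amps, dtype=float).ravel()
    if event_times.size != amps.size:
        raise ValueError("event_times and amps must have equal length")
    if np.any(amps <= 0):
        raise ValueError("event amplitudes must be positive")
    lick_times = (
        np.empty(0) if lick_times is None else np.asarray(lick_times, dtype=float)
    )
    eff_amps, epochs = _movement_gained_amps(
        config, event_times, amps, lick_times, condition
    )

    n = int(round(config.duration * config.frame_rate))
    t = np.arange(n) / config.frame_rate
    dff = np.zeros(n)
    span = int(np.ceil(8 * config.tau_decay * config.frame_rate))
    for ti, a in zip(event_times, eff_amps):
        i0 = int(np.ceil(ti * config.frame_rate))
        i1 = min(n, i0 + span)
        if i0 >= n:
            continue
        dff[i0:i1] += a * evaluate_kernel(
            t[i0:i1] - ti, config.tau_rise, config.tau_decay
        )
    f = config.baseline_f * (1.0 + dff)
    if config.poisson_noise:
        # scale chosen so the SD at baseline equals noise_sigma * F0
        if config.noise_sigma > 0:
            gain = config.baseline_f * config.noise_sigma**2
            f = rng.poisson(np.maximum(f, 0.0) / gain) * gain
    elif config.noise_sigma > 0:
        f = f + config.baseline_f * config.noise_sigma * rng.standard_normal(n)
    trace = FluorescenceTrace(f, config.frame_rate)
    gt = GroundTruth(
        event_times=event_times,
        event_amps=eff_amps,
        condition=condition,
        epoch_of_event=epochs,
    )
    return trace, gt


def dendrite_band_masks(
    n_dendrites: int, shape: tuple[int, int] = (32, 32), margin: int = 4
) -> np.ndarray:
    """Disjoint vertical-band pixel masks emulating parasagittal dendrites.

    Returns a boolean array of shape (n_dendrites, H, W). Bands are separated
    by one-band gaps and inset by ``margin`` pixels so registration margins
    never clip them.
    """
    h, w = shape
    usable = w - 2 * margin
    band = usable // (2 * n_dendrites)
    if band < 2:
        raise ValueError("image too small for requested number of dendrites")
    masks = np.zeros((n_dendrites, h, w), dtype=bool)
    for k in range(n_dendrites):
        x0 = margin + k * 2 * band
        masks[k, margin : h - margin, x0 : x0 + band] = True
    return masks


def render_movie(
    masks,
    traces,
    background: float,
    config: SimConfig,
    rng=None,
    drift_sd: float = 0.0,
    noise_sigma_px: float | None = None,
    psf_sigma_px: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a pixel movie from source masks and traces.

    Each pixel's time series is ``background + sum_k mask_k(pixel) *
    trace_k(t)`` plus Gaussian pixel noise; the source weight maps are
    blurred by a Gaussian of ``psf_sigma_px`` pixels emulating the
    microscope point-spread function (0 disables). When ``drift_sd`` > 0 a
    slow rigid translation (smoothed Gaussian random walk with SD
    ``drift_sd`` pixels) is applied per frame; the applied (dx, dy) shifts
    are returned so ground truth can record them.

    Returns ``(movie, shifts)`` with movie shaped (T, H, W) and shifts
    (T, 2) as (dx, dy) in pixels.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    masks = np.asarray(masks, dtype=float)
    if masks.ndim == 2:
        masks = masks[None]
    if psf_sigma_px > 0:
        masks = np.stack(
            [ndimage.gaussian_filter(m, psf_sigma_px) for m in masks]
        )
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if masks.shape[0] != traces.shape[0]:
        raise ValueError("need one trace per mask")
    n_t = traces.shape[1]
    movie = np.einsum("khw,kt->thw", masks, traces) + background
    if noise_sigma_px is None:
        noise_sigma_px = config.noise_sigma * config.baseline_f
    shifts = np.zeros((n_t, 2))
    if drift_sd > 0:
        steps = rng.standard_normal((n_t, 2))
        walk = np.cumsum(steps, axis=0)
        walk = ndimage.gaussian_filter1d(walk, sigma=20.0, axis=0)
        walk -= walk.mean(axis=0)
        sd = walk.std(axis=0)
        sd[sd == 0] = 1.0
        shifts = walk / sd * drift_sd
        for i in range(n_t):
            dx, dy = shifts[i]
            movie[i] = ndimage.shift(movie[i], (dy, dx), order=1, mode="nearest")
    if noise_sigma_px > 0:
        movie = movie + noise_sigma_px * rng.standard_normal(movie.shape)
    return movie, shifts


# ---------------------------------------------------------------------------
# Whole sessions
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """A rendered synthetic session with its behavior log and ground truth."""

    config: SimConfig
    behavior: BehaviorLog
    traces: list[FluorescenceTrace]
    ground_truth: list[GroundTruth]
    movie: np.ndarray | None = None
    masks: np.ndarray | None = None
    shifts: np.ndarray | None = None


def _session_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_session(
    config: SimConfig,
    condition: str = CONTROL,
    n_rois: int = 1,
    seed: int | None = None,
) -> Session:
    """Simulate behavior plus ``n_rois`` independent trace ROIs.

    All randomness flows from a single generator seeded by ``seed`` (default
    ``config.seed``), so identical configs and seeds give identical sessions.
    The disinhibited condition differs from control only through the
    movement-epoch amplitude gain: with equal seeds the two conditions share
    event times, base amplitudes, and noise, emulating a paired design.
    """
    rng = _session_rng(config.seed if seed is None else seed)
    n_trials = max(1, int(config.duration // config.trial_interval))
    beh = simulate_lick_bouts(config, n_trials, rng)
    traces, gts = [], []
    for _ in range(n_rois):
        events = simulate_event_train(config, beh, rng)
        amps = draw_amplitudes(config, events.size, rng)
        tr, gt = render_trace(
            events, amps, config, beh.lick_times, condition, rng
        )
        traces.append(tr)
        gts.append(gt)
    return Session(config=config, behavior=beh, traces=traces, ground_truth=gts)


def simulate_movie_session(
    config: SimConfig,
    condition: str = CONTROL,
    n_dendrites: int = 2,
    shape: tuple[int, int] = (32, 32),
    background: float = 0.1,
    drift_sd: float = 0.0,
    seed: int | None = None,
) -> Session:
    """Simulate a movie session with band-shaped dendrites sharing behavior."""
    sess = simulate_session(
        config, condition, n_rois=n_dendrites, seed=seed
    )
    rng = _session_rng(
        (config.seed if seed is None else seed) + 7_654_321
    )
    masks = dendrite_band_masks(n_dendrites, shape)
    tr = np.stack([t.samples for t in sess.traces])
    movie, shifts = render_movie(
        masks, tr, background, config, rng, drift_sd=drift_sd
    )
    for gt in sess.ground_truth:
        gt.shifts = shifts
    sess.movie, sess.masks, sess.shifts = movie, masks, shifts
    for gt, m in zip(sess.ground_truth, masks):
        gt.true_masks = m
    return sess


def simulate_branch_pair(
    config: SimConfig,
    condition: str = CONTROL,
    seed: int | None = None,
) -> tuple[FluorescenceTrace, FluorescenceTrace, dict]:
    """Two dendritic-branch traces sharing event times.

    Each event has a common amplitude; each branch observes it through an
    independent unit-mean lognormal jitter with log-scale SD
    ``branch_jitter_sd``. For movement-epoch events in the disinhibited
    condition the jitter SD is multiplied by ``jitter_shrink_move``.

    Returns the two traces and a ground-truth dict with the shared event
    times, per-branch amplitudes, and epoch labels.
    """
    rng = _session_rng(config.seed if seed is None else seed)
    n_trials = max(1, int(config.duration // config.trial_interval))
    beh = simulate_lick_bouts(config, n_trials, rng)
    events = simulate_event_train(config, beh, rng)
    common = draw_amplitudes(config, events.size, rng)
    epochs = _behavior.epoch_labels(events, beh.lick_times)
    sd = np.full(events.size, config.branch_jitter_sd)
    if condition == DISINHIBITED:
        sd[epochs == _behavior.LICKING] *= config.jitter_shrink_move
    amps = []
    for _ in range(2):
        z = rng.standard_normal(events.size)
        amps.append(common * np.exp(sd * z - sd**2 / 2.0))
    traces = []
    for a in amps:
        tr, _ = render_trace(
            events,
            np.maximum(a, 1e-12),
            config,
            beh.lick_times,
            condition,
            rng,
        )
        traces.append(tr)
    gt = {
        "event_times": events,
        "amps_branch1": amps[0],
        "amps_branch2": amps[1],
        "epoch_of_event": epochs,
        "condition": condition,
        "behavior": beh,
    }
    return traces[0], traces[1], gt


# ---------------------------------------------------------------------------
# Ex vivo conjunctive stimulation
# ---------------------------------------------------------------------------

def simulate_conjunctive_set(
    gain: float = 1.0,
    n_trials: int = 10,
    noise_sigma: float = 0.05,
    seed: int = 0,
    frame_rate: float = 500.0,
    duration: float = 1.6,
    pf_time: float = 0.2,
    pf_amp: float = 0.3,
    cf_delay: float = 0.15,
    cf_amp: float = 0.5,
    tau_decay: float = 0.150,
    tau_rise: float = 0.010,
    blank_window: tuple[float, float] | None = None,
):
    """Trial-averaged line-scan traces for conjunctive PF+CF stimulation.

    Produces the three trial-averaged dF/F traces of a supralinearity
    experiment: parallel-fiber tetanus alone (a slower, smaller transient),
    climbing-fiber stimulus alone (an indicator-kernel transient), and the
    conjunctive response equal to ``gain`` times the pointwise sum of the
    two single-input responses, each averaged over ``n_trials`` noisy trials.

    Returns a :class:`dendroca.stats.ConjunctiveSet`.
    """
    from .stats import ConjunctiveSet

    if gain <= 0:
        raise ValueError("gain must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    stim_time = pf_time + cf_delay
    pf_true = pf_amp * evaluate_kernel(t - pf_time, 0.030, 0.250)
    cf_true = cf_amp * evaluate_kernel(t - stim_time, tau_rise, tau_decay)
    conj_true = gain * (pf_true + cf_true)

    def avg(true: np.ndarray) -> np.ndarray:
        trials = true + noise_sigma * rng.standard_normal((n_trials, n))
        return trials.mean(axis=0)

    return ConjunctiveSet(
        conj_trace=avg(conj_true),
        pf_trace=avg(pf_true),
        cf_trace=avg(cf_true),
        stim_time=stim_time,
        frame_rate=frame_rate,
        blank_window=blank_window,
    )
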