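"""Rigid-translation alignment of time-series images.

Each frame is aligned to a fixed template (the mean of the temporally middle
frames) by minimizing the mean squared intensity difference over the overlap
region across integer translations, followed by quadratic subpixel refinement
of the error surface. The estimated shift series from one channel can be
applied unchanged to a simultaneously acquired second channel of equal
geometry (dual-color co-registration).
"""

from __future__ import annotations

import numpy as np
from numpy.fft import irfft2, rfft2
from scipy import ndimage

__all__ = [
    "estimate_translation",
    "estimate_shifts",
    "apply_shifts",
    "register_stack",
    "valid_mask",
    "reference_image",
]

MAX_SHIFT = 10


def _windowed_sums(frame: np.ndarray, reference: np.ndarray, max_shift: int):
    """Sum of squared differences over the overlap for every integer shift.

    Computed via FFT cross-correlation on zero-padded images:
    ``SSD(v) = sum_overlap(frame^2) + sum_overlap(ref^2) - 2 * xcorr(v)``.
    Returns (ssd, counts) arrays of shape (2*max_shift+1, 2*max_shift+1)
    indexed by (dy, dx) offsets in [-max_shift, max_shift].
    """
    h, w = frame.shape
    ph, pw = h + 2 * max_shift, w + 2 * max_shift
    shape = (ph, pw)

    def corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # correlation of a with b over all relative offsets
        fa = rfft2(a, shape)
        fb = rfft2(b, shape)
        return irfft2(fa * np.conj(fb), shape)

    ones = np.ones_like(frame)
    xc = corr(frame, reference)
    s_f2 = corr(frame**2, ones)
    s_r2 = corr(ones, reference**2)
    counts = corr(ones, ones)
    ssd_full = s_f2 + s_r2 - 2.0 * xc
    # offset v means frame displaced by v relative to the reference
    idx = np.arange(-max_shift, max_shift + 1)
    ssd = ssd_full[np.ix_(idx, idx)]
    cnt = counts[np.ix_(idx, idx)]
    return ssd, np.maximum(cnt, 1.0)


def _quadratic_refine(surface: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Subpixel offset of a minimum via separable 3-point parabola fits."""

    def refine(fm1: float, f0: float, fp1: float) -> float:
        if f0 <= 1e-9 * (fm1 + fp1):
            # numerically perfect match at the node: refinement would only
            # chase FFT round-off, so the integer shift is exact
            return 0.0
        denom = fm1 - 2.0 * f0 + fp1
        if denom <= 0:
            return 0.0
        delta = 0.5 * (fm1 - fp1) / denom
        return float(np.clip(delta, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < iy < surface.shape[0] - 1:
        dy = refine(surface[iy - 1, ix], surface[iy, ix], surface[iy + 1, ix])
    if 0 < ix < surface.shape[1] - 1:
        dx = refine(surface[iy, ix - 1], surface[iy, ix], surface[iy, ix + 1])
    return dy, dx


def estimate_translation(
    frame: np.ndarray,
    reference: np.ndarray,
    max_shift: int = MAX_SHIFT,
    subpixel: bool = True,
) -> tuple[float, float]:
    """Translation (dx, dy) of ``frame`` relative to ``reference``.

    The returned shift minimizes the per-pixel mean squared difference over
    the overlap region across integer displacements within ``max_shift``
    pixels, refined to subpixel precision by a local quadratic fit of the
    error surface. Positive dx means the frame content sits to the right of
    the reference; applying the inverse translation aligns it.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must share dimensions")
    if frame.std() == 0 or reference.std() == 0:
        raise ValueError("flat (zero-variance) image: translation is degenerate")
    f = frame - frame.mean()
    r = reference - reference.mean()
    ssd, cnt = _windowed_sums(f, r, max_shift)
    mse = ssd / cnt
    iy, ix = np.unravel_index(np.argmin(mse), mse.shape)
    # window rows/cols run over offsets -max_shift .. +max_shift in order
    dy = float(iy - max_shift)
    dx = float(ix - max_shift)
    if subpixel:
        sy, sx = _quadratic_refine(mse, iy, ix)
        dy, dx = dy + sy, dx + sx
    return float(dx), float(dy)


def reference_image(frames: np.ndarray, n_frames: int = 100) -> np.ndarray:
    """Fixed alignment template: mean of the temporally middle frames."""
    frames = np.asarray(frames, dtype=float)
    t = frames.shape[0]
    n = min(n_frames, t)
    start = (t - n) // 2
    return frames[start : start + n].mean(axis=0)


def estimate_shifts(
    frames: np.ndarray,
    reference: np.ndarray | None = None,
    max_shift: int = MAX_SHIFT,
) -> np.ndarray:
    """Per-frame (dx, dy) translation of a stack relative to a template."""
    frames = np.asarray(frames, dtype=float)
    if reference is None:
        reference = reference_image(frames)
    shifts = np.empty((frames.shape[0], 2))
    for i, fr in enumerate(frames):
        shifts[i] = estimate_translation(fr, reference, max_shift)
    return shifts


def apply_shifts(frames: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Apply the inverse of per-frame (dx, dy) shifts with bilinear resampling.

    Pixels translated in from outside the frame are flagged invalid (NaN);
    use :func:`valid_mask` to exclude them from downstream statistics. The
    same shift series is applicable to a second channel of equal geometry.
    """
    frames = np.asarray(frames, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (frames.shape[0], 2):
        raise ValueError("need one (dx, dy) pair per frame")
    if not np.all(np.isfinite(shifts)):
        raise ValueError("shifts must be finite")
    out = np.empty_like(frames)
    for i, (fr, (dx, dy)) in enumerate(zip(frames, shifts)):
        out[i] = ndimage.shift(
            fr, (-dy, -dx), order=1, mode="constant", cval=np.nan
        )
    return out


def valid_mask(aligned: np.ndarray) -> np.ndarray:
    """Pixels finite in every frame of an aligned stack (H, W boolean)."""
    return np.all(np.isfinite(aligned), axis=0)


def register_stack(
    frames: np.ndarray,
    reference: np.ndarray | None = None,
    max_shift: int = MAX_SHIFT,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and apply rigid shifts; returns (aligned, shifts)."""
    shifts = estimate_shifts(frames, reference, max_shift)
    return apply_shifts(frames, shifts), shifts
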