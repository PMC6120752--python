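"""ROI segmentation of fluorescence movies by PCA reduction and
spatiotemporal ICA, plus hand-drawn-mask ingestion.

The movie is reduced to its leading principal components, which are then
rotated to maximize a skewness-based (third-moment) independence measure of
the concatenation [mu * spatial; (1 - mu) * temporal]; ``mu`` balances
spatial against temporal independence. Each independent component's spatial
filter is thresholded in SD units and split into connected components to
yield one ROI per surviving component. Cell-shaped sources (somata,
boutons) drawn by hand are ingested from labeled mask images instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from skimage import measure
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "PcaBasis",
    "IcaComponents",
    "RoiSegment",
    "pca_reduce",
    "spatiotemporal_ica",
    "threshold_masks",
    "deduplicate_segments",
    "segment_movie",
    "rois_from_label_image",
    "extract_trace",
    "match_rois",
]


@dataclass
class PcaBasis:
    """Leading principal components of a movie, split into spatial and
    temporal factors.

    ``spatial`` has shape (n_components, H, W) and unit norm per component;
    ``temporal`` has shape (n_components, T). ``explained_var`` holds the
    fraction of total variance captured per component (non-increasing).
    """

    spatial: np.ndarray
    temporal: np.ndarray
    singular_values: np.ndarray
    explained_var: np.ndarray
    mean_image: np.ndarray


@dataclass
class IcaComponents:
    """Independent components: per-pixel spatial filters and time courses."""

    spatial_filters: np.ndarray  # (n_ics, H, W)
    temporal: np.ndarray  # (n_ics, T)
    converged: bool = True


@dataclass
class RoiSegment:
    """A segmented ROI: pixel mask, spatial filter, extracted trace, kind."""

    mask: np.ndarray
    spatial_filter: np.ndarray | None = None
    trace: np.ndarray | None = None
    kind: str = "pc_dendrite"
    roi_id: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask must be nonempty")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(ys.mean()), float(xs.mean())


def _as_pixel_matrix(movie: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be a (T, H, W) array")
    t, h, w = movie.shape
    return movie.reshape(t, h * w), (h, w)


def pca_reduce(movie: np.ndarray, n_components: int) -> PcaBasis:
    """Leading spatiotemporal principal components of a (T, H, W) movie.

    The temporal mean image is removed per pixel before decomposition. A
    constant (zero-variance) movie is degenerate and rejected.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x, shape = _as_pixel_matrix(movie)
    t, p = x.shape
    if n_components > min(t, p):
        raise ValueError("n_components exceeds min(T, pixels)")
    mean_image = x.mean(axis=0)
    xc = x - mean_image
    total_var = float(np.sum(xc**2))
    if total_var == 0:
        raise ValueError("constant movie has zero variance")
    svd_solver = "randomized" if n_components < min(t, p) // 2 else "auto"
    pca = PCA(n_components=n_components, svd_solver=svd_solver, random_state=0)
    temporal = pca.fit_transform(xc)  # (T, n) scores
    spatial = pca.components_  # (n, P), unit norm
    sv = pca.singular_values_
    # normalize temporal factors to unit norm; scale lives in singular values
    temporal = (temporal / np.where(sv > 0, sv, 1.0)).T  # (n, T)
    return PcaBasis(
        spatial=spatial.reshape(-1, *shape),
        temporal=temporal,
        singular_values=sv,
        explained_var=pca.explained_variance_ratio_,
        mean_image=mean_image.reshape(shape),
    )


def n_significant_components(basis: PcaBasis, factor: float = 2.0) -> int:
    """Components whose variance exceeds ``factor`` times the median variance
    of the computed set — a simple noise-floor elbow rule."""
    ev = basis.explained_var
    floor = np.median(ev) * factor
    return int(max(1, np.sum(ev > floor)))


def spatiotemporal_ica(
    basis: PcaBasis,
    mu: float = 0.5,
    n_ics: int | None = None,
    max_iter: int = 400,
    random_state: int = 0,
) -> IcaComponents:
    """Rotate principal components to maximize skewness-based independence.

    Each candidate source is a linear combination of the PCA components; the
    rotation maximizes the third-moment (skewness) independence of the
    concatenated vector [mu * spatial; (1 - mu) * temporal] via fixed-point
    ICA with a cubic contrast. ``mu`` = 1 gives purely spatial ICA, 0 purely
    temporal. Components are sign-corrected so spatial skewness is positive
    ("bright" sources). Non-convergence produces a warning and the best
    iterate, never an exception.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    n_pcs = basis.spatial.shape[0]
    if n_ics is None:
        n_ics = n_pcs
    if not 1 <= n_ics <= n_pcs:
        raise ValueError("n_ics must lie in [1, n_components]")
    spatial_flat = basis.spatial.reshape(n_pcs, -1)
    blocks = []
    if mu > 0:
        blocks.append(mu * spatial_flat)
    if mu < 1:
        blocks.append((1.0 - mu) * basis.temporal)
    # weight rows by the PCA scale so the ICA's whitening keeps the
    # high-variance (signal) subspace rather than an arbitrary one
    joint = basis.singular_values[:, None] * np.concatenate(blocks, axis=1)
    def skew_contrast(u):
        # G(u) = u^3 / 3: a genuinely odd (third-moment) contrast, so the
        # rotation prefers one-sided sources; even contrasts like kurtosis
        # are blind to the sign structure and can return +/- mixtures
        return u**2, np.mean(2 * u, axis=-1)

    ica = FastICA(
        n_components=n_ics,
        fun=skew_contrast,
        whiten="unit-variance",
        max_iter=max_iter,
        random_state=random_state,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(joint.T)
        if any(issubclass(c.category, ConvergenceWarning) for c in caught):
            converged = False
            warnings.warn(
                "spatiotemporal ICA did not converge; returning best iterate",
                RuntimeWarning,
                stacklevel=2,
            )
    w = ica.components_  # (n_ics, n_pcs): maps PC space -> IC space
    spatial_filters = w @ spatial_flat
    temporal = w @ basis.temporal
    # sign correction: bright sources have positively skewed spatial filters
    sk = sp_stats.skew(spatial_filters, axis=1)
    flip = np.where(sk < 0, -1.0, 1.0)[:, None]
    spatial_filters *= flip
    temporal *= flip
    h, w_ = basis.spatial.shape[1:]
    return IcaComponents(
        spatial_filters=spatial_filters.reshape(-1, h, w_),
        temporal=temporal,
        converged=converged,
    )


def extract_trace(movie: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mask-mean time series of a movie (NaN-safe for aligned margins)."""
    movie = np.asarray(movie, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    px = movie[:, mask]
    return np.nanmean(px, axis=1)


def threshold_masks(
    components: IcaComponents | np.ndarray,
    z_thresh: float = 3.0,
    min_area: int = 20,
    movie: np.ndarray | None = None,
    kind: str = "pc_dendrite",
    rel_floor: float = 0.5,
) -> list[RoiSegment]:
    """ROIs from IC spatial filters by z-thresholding and size filtering.

    Pixels whose filter weight exceeds ``z_thresh`` SDs (robust, MAD-based)
    of that filter's weight distribution are kept; connected components
    smaller than ``min_area`` pixels are dropped; each surviving component
    becomes one segment, trimmed to its half-maximum footprint
    (``rel_floor`` of the component's peak weight) so point-spread blur
    skirts do not inflate the mask. If a movie is supplied, each segment's
    trace is extracted as the mask-mean. An empty list (no surviving
    pixels) is a valid outcome.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    filters = (
        components.spatial_filters
        if isinstance(components, IcaComponents)
        else np.asarray(components, dtype=float)
    )
    if filters.ndim == 2:
        filters = filters[None]
    segments: list[RoiSegment] = []
    for filt in filters:
        # robust z: sources may cover a sizable fraction of the field, which
        # would inflate a plain SD and hide them; the MAD sees the background
        med = np.median(filt)
        scale = 1.4826 * np.median(np.abs(filt - med))
        if scale == 0:
            scale = filt.std()
        if scale == 0:
            continue
        z = (filt - med) / scale
        above = z > z_thresh
        labels = measure.label(above, connectivity=2)
        for region in measure.regionprops(labels):
            mask = labels == region.label
            if rel_floor > 0:
                mask &= filt >= rel_floor * filt[mask].max()
            if mask.sum() < min_area:
                continue
            seg = RoiSegment(mask=mask, spatial_filter=filt, kind=kind)
            if movie is not None:
                seg.trace = extract_trace(movie, mask)
            segments.append(seg)
    for i, seg in enumerate(segments):
        seg.roi_id = i
    return segments


def deduplicate_segments(
    segments: list[RoiSegment], iou_thresh: float = 0.5
) -> list[RoiSegment]:
    """Drop near-duplicate ROIs (IoU above threshold), keeping the larger."""
    keep: list[RoiSegment] = []
    for seg in sorted(segments, key=lambda s: -s.area):
        dup = False
        for other in keep:
            inter = np.logical_and(seg.mask, other.mask).sum()
            union = np.logical_or(seg.mask, other.mask).sum()
            if union and inter / union > iou_thresh:
                dup = True
                break
        if not dup:
            keep.append(seg)
    for i, seg in enumerate(keep):
        seg.roi_id = i
    return keep


def default_n_components(n_frames: int, n_pixels: int) -> int:
    """Default PCA order: min(150, T/10), capped by the data dimensions."""
    return int(max(1, min(150, n_frames // 10, n_frames, n_pixels)))


def segment_movie(
    movie: np.ndarray,
    n_components: int | None = None,
    mu: float = 0.5,
    n_ics: int | None = None,
    z_thresh: float = 3.0,
    min_area: int = 20,
    temporal_skew_min: float = 0.15,
    kind: str = "pc_dendrite",
    random_state: int = 0,
) -> list[RoiSegment]:
    """Full ICA segmentation: PCA, noise-floor component selection,
    spatiotemporal ICA, component screening, thresholding, and duplicate
    removal.

    ICs whose time course has skewness below ``temporal_skew_min`` are
    discarded before thresholding: genuine Ca2+ sources are spiky and
    right-skewed in time, while residual-motion and noise components are
    roughly symmetric. The output is invariant to a global multiplicative
    rescaling of the movie (all steps are scale-equivariant and thresholds
    are in SD units).
    """
    movie = np.asarray(movie, dtype=float)
    t = movie.shape[0]
    p = movie.shape[1] * movie.shape[2]
    if n_components is None:
        n_components = default_n_components(t, p)
    basis = pca_reduce(movie, n_components)
    if n_ics is None:
        n_ics = n_significant_components(basis)
    ica = spatiotemporal_ica(basis, mu=mu, n_ics=n_ics, random_state=random_state)
    t_skew = sp_stats.skew(ica.temporal, axis=1)
    keep = t_skew >= temporal_skew_min
    ica = IcaComponents(
        spatial_filters=ica.spatial_filters[keep],
        temporal=ica.temporal[keep],
        converged=ica.converged,
    )
    segments = threshold_masks(
        ica, z_thresh=z_thresh, min_area=min_area, movie=movie, kind=kind
    )
    return deduplicate_segments(segments)


def rois_from_label_image(
    label_image: np.ndarray,
    movie: np.ndarray | None = None,
    kind: str = "manual",
) -> list[RoiSegment]:
    """Hand-drawn ROI ingestion from a labeled-integer mask image.

    Each positive integer label becomes one segment (bypassing ICA), the
    route used for MLI somata and parallel-fiber boutons.
    """
    label_image = np.asarray(label_image)
    segments = []
    for lab in np.unique(label_image):
        if lab <= 0:
            continue
        mask = label_image == lab
        seg = RoiSegment(mask=mask, kind=kind, roi_id=int(lab))
        if movie is not None:
            seg.trace = extract_trace(movie, mask)
        segments.append(seg)
    return segments


def match_rois(
    segments_a: list[RoiSegment],
    segments_b: list[RoiSegment],
    max_dist: float = 5.0,
) -> list[tuple[int, int]]:
    """Cross-session ROI matching by centroid nearest neighbor.

    Heuristic: greedy closest-pair assignment with a distance cap (pixels);
    not all ROIs need be re-identified across sessions.
    """
    pairs = []
    cand = []
    for i, a in enumerate(segments_a):
        for j, b in enumerate(segments_b):
            d = float(np.hypot(*(np.subtract(a.centroid, b.centroid))))
            if d <= max_dist:
                cand.append((d, i, j))
    used_a: set[int] = set()
    used_b: set[int] = set()
    for d, i, j in sorted(cand):
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return pairs
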