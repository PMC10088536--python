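"""Drug-depot segmentation in post-onset ultrasound frames.

Four stages, applied per frame after injection onset:

1. background removal — subtract the pixel-wise mean of the frames in the
   1-s window immediately preceding injection; negative residuals are
   clamped to zero (the depot is hyperechoic, i.e. brighter than tissue);
2. edge-preserving despeckling — Perona-Malik anisotropic diffusion, which
   smooths within regions while inhibiting diffusion across high-gradient
   boundaries;
3. intensity-cluster thresholding — a two-class Otsu split over the
   within-cone pixels, with a between-class variance floor so that pure
   noise is not thresholded into foreground;
4. morphological refinement — closing with a small disk to bridge nearby
   fragments, then filling of interior holes; finally only connected
   components that intersect a 1 cm x 1 cm window centered on the needle
   tip are retained (the depot forms at the tip; distant bright artifacts
   are discarded).

All stage parameters are recorded in the output for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .io import InjectionAnnotation, VideoSequence, roi_bounds

__all__ = [
    "BackgroundModel",
    "DepotMaskSeries",
    "compute_background",
    "despeckle",
    "threshold_clusters",
    "morph_refine",
    "segment_depot",
    "dice_coefficient",
]

#: If the Otsu between-class variance (normalized intensity^2) falls below
#: this floor the frame is declared depot-free and the mask left empty.
#: Calibrated on the phantom's depot-free condition at default speckle
#: (CV 0.3): noise-only frames reach ~9e-4 while frames holding a depot of
#: at least 0.05 cm^2 stay above ~1.5e-3.
VARIANCE_FLOOR = 1.2e-3


@dataclass
class BackgroundModel:
    """Pixel-wise mean of the frames immediately preceding injection."""

    image: np.ndarray
    window: float
    t0: float


@dataclass
class DepotMaskSeries:
    """Per-frame binary depot masks for the post-onset portion of a video."""

    masks: np.ndarray  # (T_post, H, W) bool
    times: np.ndarray  # seconds, re-zeroed at t0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.masks.shape[0] != self.times.shape[0]:
            raise ValueError("masks and times must align")

    @property
    def areas_px(self) -> np.ndarray:
        return self.masks.sum(axis=(1, 2))


def compute_background(video: VideoSequence, t0: float, window: float = 1.0) -> BackgroundModel:
    """Mean image over the ``window`` seconds immediately preceding t0."""
    if window <= 0:
        raise ValueError("window must be positive")
    if t0 < window:
        raise ValueError(
            f"t0 = {t0} s leaves less than the {window} s background window before injection"
        )
    i1 = int(round(t0 * video.frame_rate))
    i0 = int(round((t0 - window) * video.frame_rate))
    i1 = min(i1, video.n_frames)
    if i1 - i0 < 1:
        raise ValueError("background window contains no frames")
    return BackgroundModel(image=video.frames[i0:i1].mean(axis=0), window=window, t0=t0)


def despeckle(
    image: np.ndarray,
    iterations: int = 10,
    conductance: float | None = None,
    step: float = 0.2,
) -> np.ndarray:
    """Perona-Malik anisotropic diffusion with exponential conductance.

    Diffusion coefficient g(|grad I|) = exp(-(|grad I| / K)^2) suppresses
    smoothing across strong edges while averaging out speckle within
    regions.  ``conductance`` is K; when None it is set per image to the
    90th percentile of the 4-neighbor gradient magnitudes.  ``step`` is the
    explicit time step (stable for <= 0.25 on a 4-neighbor stencil).
    Zero iterations return the input unchanged.
    """
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    u = img.copy()
    for _ in range(int(iterations)):
        dn = np.zeros_like(u)
        ds = np.zeros_like(u)
        de = np.zeros_like(u)
        dw = np.zeros_like(u)
        dn[1:, :] = u[:-1, :] - u[1:, :]
        ds[:-1, :] = u[1:, :] - u[:-1, :]
        de[:, :-1] = u[:, 1:] - u[:, :-1]
        dw[:, 1:] = u[:, :-1] - u[:, 1:]
        if conductance is None:
            grads = np.abs(np.concatenate([dn.ravel(), de.ravel()]))
            k = np.percentile(grads[grads > 0], 90) if np.any(grads > 0) else 1.0
        else:
            k = conductance
        if k <= 0:
            k = 1.0
        gn = np.exp(-((dn / k) ** 2))
        gs = np.exp(-((ds / k) ** 2))
        ge = np.exp(-((de / k) ** 2))
        gw = np.exp(-((dw / k) ** 2))
        u = u + step * (gn * dn + gs * ds + ge * de + gw * dw)
    return u


def threshold_clusters(
    image: np.ndarray, cone: np.ndarray, variance_floor: float = VARIANCE_FLOOR
) -> np.ndarray:
    """Two-cluster (Otsu) intensity split over within-cone pixels.

    Pixels above the split are foreground.  If the between-class variance at
    the chosen threshold is below ``variance_floor`` the frame is treated as
    depot-free and an empty mask is returned.
    """
    cone = np.asarray(cone, dtype=bool)
    if not cone.any():
        raise ValueError("cone mask is empty")
    vals = np.asarray(image, dtype=np.float64)[cone]
    if np.ptp(vals) == 0:
        return np.zeros_like(cone)
    thr = threshold_otsu(vals)
    hi = vals > thr
    if not hi.any() or hi.all():
        return np.zeros_like(cone)
    w1 = hi.mean()
    w0 = 1.0 - w1
    between_var = w0 * w1 * (vals[hi].mean() - vals[~hi].mean()) ** 2
    if between_var < variance_floor:
        return np.zeros_like(cone)
    return (np.asarray(image) > thr) & cone


def morph_refine(mask: np.ndarray, radius_cm: float, px_per_cm: float) -> np.ndarray:
    """Close small gaps and fill interior holes.

    Morphological closing with a disk of radius round(radius_cm * px_per_cm)
    pixels bridges gaps up to twice that radius, then interior holes are
    flood-filled.  The result is a superset of the input; the outer boundary
    is preserved except where gaps are bridged.
    """
    if radius_cm < 0:
        raise ValueError("radius_cm must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    r = int(round(radius_cm * px_per_cm))
    out = closing(mask, disk(r)) if r > 0 else mask
    out = ndimage.binary_fill_holes(out)
    return out | mask


def segment_depot(
    video: VideoSequence,
    background: BackgroundModel,
    annotation: InjectionAnnotation,
    t0: float | None = None,
    iterations: int = 10,
    conductance: float | None = None,
    closing_radius_cm: float = 0.05,
    roi_side_cm: float = 1.0,
    variance_floor: float = VARIANCE_FLOOR,
) -> DepotMaskSeries:
    """Segment the drug depot in every post-onset frame.

    Per frame: subtract background (clamping negatives to zero), despeckle,
    Otsu-threshold within the cone, morphologically refine, then keep only
    connected components overlapping the needle-tip window.
    """
    t0 = background.t0 if t0 is None else t0
    i0 = video.frame_index(t0)
    cone = video.cone_mask
    roi = roi_bounds(video.shape, annotation.needle_tip, annotation.px_per_cm, roi_side_cm)
    roi_mask = np.zeros(video.shape, dtype=bool)
    roi_mask[roi.slices] = True

    masks = np.zeros((video.n_frames - i0,) + video.shape, dtype=bool)
    for j, frame in enumerate(video.frames[i0:]):
        sub = np.clip(frame - background.image, 0.0, None)
        sub[~cone] = 0.0
        filt = despeckle(sub, iterations=iterations, conductance=conductance)
        raw = threshold_clusters(filt, cone, variance_floor=variance_floor)
        refined = morph_refine(raw, closing_radius_cm, annotation.px_per_cm) & cone
        masks[j] = _keep_components_near(refined, roi_mask)
    times = video.times[i0:] - t0
    params = {
        "t0": t0,
        "background_window_s": background.window,
        "despeckle_iterations": iterations,
        "despeckle_conductance": conductance,
        "closing_radius_cm": closing_radius_cm,
        "roi_side_cm": roi_side_cm,
        "variance_floor": variance_floor,
    }
    return DepotMaskSeries(masks=masks, times=times, params=params)


def _keep_components_near(mask: np.ndarray, window: np.ndarray) -> np.ndarray:
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    keep_ids = np.unique(labels[window & mask])
    keep_ids = keep_ids[keep_ids > 0]
    if keep_ids.size == 0:
        return np.zeros_like(mask)
    return np.isin(labels, keep_ids)


def write_overlay(image: np.ndarray, mask: np.ndarray, path) -> None:
    """QC overlay PNG: mask outline (red) on a grayscale frame."""
    import imageio.v3 as iio
    from skimage.segmentation import find_boundaries

    gray = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    rgb = np.stack([gray, gray, gray], axis=-1)
    edge = find_boundaries(np.asarray(mask, dtype=bool), mode="outer")
    rgb[edge] = [1.0, 0.0, 0.0]
    iio.imwrite(path, (rgb * 255).astype(np.uint8))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
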