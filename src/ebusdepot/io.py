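"""Video, mask and annotation I/O for EBUS injection analysis.

Videos are held as :class:`VideoSequence` — ordered grayscale frames
normalized to [0, 1] plus the frame rate and a binary mask of the ultrasound
fan ("image cone").  Multi-page TIFF is the primary container (lossless
8-bit on export); AVI/MP4 are read through imageio when a suitable plugin is
available.  A JSON sidecar with the same stem as the video carries the frame
rate and, for synthetic videos, the stored cone mask path.

Annotations (needle-tip pixel, needle-axis angle, injection onset, injected
volume, pixel calibration) are manual inputs stored as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VideoSequence",
    "InjectionAnnotation",
    "RegionOfInterest",
    "read_video",
    "write_video",
    "read_masks",
    "write_masks",
    "read_annotation",
    "write_annotation",
    "extract_roi",
    "roi_bounds",
    "inherit_needle_tip",
    "estimate_cone_mask",
]


@dataclass
class VideoSequence:
    """Ordered grayscale frames with frame rate and cone mask.

    frames: (T, H, W) float array in [0, 1].
    frame_rate: frames per second.
    cone_mask: (H, W) boolean mask of the insonified fan; pixels outside
        are not imaged and are excluded from every intensity statistic.
    """

    frames: np.ndarray
    frame_rate: float
    cone_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.cone_mask is None:
            self.cone_mask = np.ones(self.frames.shape[1:], dtype=bool)
        else:
            self.cone_mask = np.asarray(self.cone_mask, dtype=bool)
            if self.cone_mask.shape != self.frames.shape[1:]:
                raise ValueError("cone_mask shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame k at k / frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    def frame_index(self, t: float) -> int:
        """Index of the frame whose timestamp is nearest to ``t`` seconds."""
        idx = int(round(t * self.frame_rate))
        if not 0 <= idx < self.n_frames:
            raise ValueError(f"time {t} s outside video span 0-{(self.n_frames - 1) / self.frame_rate:.3f} s")
        return idx


@dataclass
class InjectionAnnotation:
    """Manual per-injection annotation.

    needle_tip: (row, col) pixel of the needle tip, 0-based, origin top-left.
    needle_angle_deg: insertion direction, degrees from the image column
        (+X) axis toward the row (+down) axis; points away from the
        transducer.
    t0: injection onset time, seconds from the first frame.
    injected_volume_ml: total injected volume, mL.
    px_per_cm: pixel calibration.
    injection_id: label such as "A21".
    tip_provenance: "manual" or "inherited" (copied from the previous
        injection of the same intervention when the tip is not visible).
    """

    needle_tip: tuple[float, float] | None
    needle_angle_deg: float | None
    t0: float
    injected_volume_ml: float
    px_per_cm: float
    injection_id: str = ""
    tip_provenance: str = "manual"

    def __post_init__(self) -> None:
        if self.injected_volume_ml <= 0:
            raise ValueError("injected_volume_ml must be positive")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")


@dataclass(frozen=True)
class RegionOfInterest:
    """Square pixel region centered on the needle tip.

    bounds: (row_start, row_stop, col_start, col_stop), half-open, possibly
    clipped at the image border; side_cm records the nominal physical side.
    """

    bounds: tuple[int, int, int, int]
    side_cm: float = 1.0

    @property
    def slices(self) -> tuple[slice, slice]:
        r0, r1, c0, c1 = self.bounds
        return (slice(r0, r1), slice(c0, c1))


def roi_bounds(
    shape: tuple[int, int], needle_tip: tuple[float, float], px_per_cm: float, side_cm: float = 1.0
) -> RegionOfInterest:
    """Square ROI of side round(side_cm * px_per_cm) centered on the tip.

    For even side lengths the tip sits at index floor(side/2) of the square
    (tie broken toward the top-left).  The square is clipped to the image
    and the realized bounds are recorded.
    """
    side = int(round(side_cm * px_per_cm))
    if side < 1:
        raise ValueError("ROI side must be at least one pixel")
    tr, tc = int(round(needle_tip[0])), int(round(needle_tip[1]))
    h, w = shape
    if not (0 <= tr < h and 0 <= tc < w):
        raise ValueError(f"needle tip {needle_tip} outside image of shape {shape}")
    half = side // 2
    r0, c0 = tr - half, tc - half
    r1, c1 = r0 + side, c0 + side
    bounds = (max(r0, 0), min(r1, h), max(c0, 0), min(c1, w))
    return RegionOfInterest(bounds=bounds, side_cm=side_cm)


def extract_roi(
    frame: np.ndarray, annotation: InjectionAnnotation, side_cm: float = 1.0
) -> tuple[np.ndarray, RegionOfInterest]:
    """Square sub-image centered on the annotated needle tip.

    Returns the (possibly clipped) sub-image together with the realized
    bounds.
    """
    if annotation.needle_tip is None:
        raise ValueError("annotation has no needle tip; annotate or inherit one first")
    roi = roi_bounds(frame.shape, annotation.needle_tip, annotation.px_per_cm, side_cm)
    return frame[roi.slices], roi


def inherit_needle_tip(
    current: InjectionAnnotation, previous: InjectionAnnotation
) -> InjectionAnnotation:
    """Fill a missing needle tip from the previous injection's annotation.

    When the needle is not visible in a video, the tip is assumed to be at
    the same position as for the previous injection within the same
    intervention.  A current annotation that already has a tip is returned
    unchanged.
    """
    if current.needle_tip is not None:
        return current
    if previous.needle_tip is None:
        raise ValueError(
            "previous annotation has no needle tip either; manual annotation required"
        )
    return dataclasses.replace(
        current,
        needle_tip=previous.needle_tip,
        needle_angle_deg=previous.needle_angle_deg,
        tip_provenance="inherited",
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _to_grayscale(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 4:  # (T, H, W, C)
        if frames.shape[-1] == 1:
            return frames[..., 0]
        # ITU-R 601 luminance
        rgb = frames[..., :3].astype(np.float64)
        return rgb @ np.array([0.299, 0.587, 0.114])
    return frames


def _normalize(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if np.issubdtype(frames.dtype, np.integer):
        return frames.astype(np.float64) / np.iinfo(frames.dtype).max
    frames = frames.astype(np.float64)
    if frames.size and frames.max() > 1.0 + 1e-9:
        frames = frames / 255.0
    return np.clip(frames, 0.0, 1.0)


def read_video(
    path: str | Path,
    frame_rate_override: float | None = None,
    cone_mask_path: str | Path | None = None,
) -> VideoSequence:
    """Read a grayscale video from multi-page TIFF (or AVI/MP4 via imageio).

    Frames are luminance-converted and normalized to [0, 1].  The frame rate
    is taken from ``frame_rate_override``, else from a JSON sidecar
    ``<stem>.json`` with a ``frame_rate`` key.  The cone mask is loaded from
    ``cone_mask_path`` (or a ``cone_mask`` path in the sidecar); otherwise it
    is estimated from the temporal maximum image (:func:`estimate_cone_mask`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        frames = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        try:
            frames = iio.imread(path)
        except Exception as exc:  # pragma: no cover - plugin dependent
            raise IOError(f"could not decode video {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError(f"{path} holds a single frame; a video needs at least 2")
    frames = _normalize(_to_grayscale(frames))
    if frames.shape[0] < 2:
        raise ValueError(f"{path} holds a single frame; a video needs at least 2")

    sidecar = path.with_suffix(".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    frame_rate = frame_rate_override or meta.get("frame_rate")
    if frame_rate is None:
        raise ValueError(
            f"no frame rate for {path}: pass frame_rate_override or provide a "
            f"'frame_rate' key in {sidecar.name}"
        )
    cone_src = cone_mask_path or meta.get("cone_mask")
    if cone_src is not None:
        cone_src = Path(cone_src)
        if not cone_src.is_absolute():
            cone_src = path.parent / cone_src
        cone = tifffile.imread(cone_src) > 0
    else:
        cone = estimate_cone_mask(frames)
    return VideoSequence(frames=frames, frame_rate=float(frame_rate), cone_mask=cone)


def write_video(video: VideoSequence, path: str | Path, write_sidecar: bool = True) -> Path:
    """Write a video as 8-bit grayscale multi-page TIFF with a JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() not in _TIFF_SUFFIXES:
        raise ValueError("write_video exports multi-page TIFF; use a .tif/.tiff path")
    data = np.clip(np.round(video.frames * 255.0), 0, 255).astype(np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data)
    if write_sidecar:
        mask_path = path.with_name(path.stem + "_cone.tif")
        tifffile.imwrite(mask_path, (video.cone_mask.astype(np.uint8)) * 255)
        sidecar = {"frame_rate": video.frame_rate, "cone_mask": mask_path.name}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def write_masks(masks: np.ndarray, path: str | Path) -> Path:
    """Write a (T, H, W) boolean mask stack as multi-page TIFF ({0, 255})."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(masks, dtype=bool).astype(np.uint8)) * 255)
    return path


def read_masks(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF mask stack as a (T, H, W) boolean array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr > 0


def write_annotation(annotation: InjectionAnnotation, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = dataclasses.asdict(annotation)
    path.write_text(json.dumps(d, indent=2))
    return path


def read_annotation(path: str | Path) -> InjectionAnnotation:
    d = json.loads(Path(path).read_text())
    tip = d.get("needle_tip")
    if tip is not None:
        d["needle_tip"] = tuple(tip)
    return InjectionAnnotation(**d)


def estimate_cone_mask(frames: np.ndarray, floor: float = 2.0 / 255.0) -> np.ndarray:
    """Estimate the insonified fan from the temporal maximum image.

    Pixels whose maximum intensity over time exceeds a small floor are
    candidate cone pixels; the largest connected component is kept.  Intended
    for clinical-style inputs where the cone geometry is unknown; synthetic
    videos carry their exact cone mask in the sidecar.
    """
    from scipy import ndimage

    peak = np.max(np.asarray(frames, dtype=np.float64), axis=0)
    cand = peak > floor
    if not cand.any():
        raise ValueError("no pixels above the cone floor; cannot estimate cone mask")
    labels, n = ndimage.label(cand)
    if n == 1:
        return cand
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)
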