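"""Image-stack analysis: slice bright-area flow curves, static angle of
repose, flow time, and particle shape metrics.

The measurement rig records the silhouette of a particle pile growing on a
plane below a funnel, against a black background with forward illumination
(25 fps, 128 x 160 px by default).  Each frame is split into equal vertical
bands; the bright-pixel area of one fixed off-center band, tracked over
frames, is the flow curve.  The last frame gives the static angle of
repose; particle silhouettes give Crofton-perimeter sphericity.

Coordinate conventions: row 0 is the top of the image, columns are 0-based,
bands are half-open column intervals, and pile height is measured upward
from the bottom row.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _label
from skimage.measure import perimeter_crofton

from .flowfit import FlowCurve
from .geometry import sphericity_index

__all__ = [
    "ImageStack",
    "SliceSpec",
    "binarize_frame",
    "slice_area_series",
    "default_slice_index",
    "measure_static_angle",
    "measure_flow_time",
    "crofton_perimeter",
    "particle_sphericity",
    "classify_particle",
]


@dataclass(frozen=True)
class ImageStack:
    """An ordered stack of same-shaped grayscale frames at fixed fps."""

    frames: np.ndarray  # (n_frames, rows, cols)
    fps: float = 25.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if frames.shape[0] < 2:
            raise ValueError("an image stack needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @classmethod
    def from_directory(cls, path, fps: float = 25.0) -> "ImageStack":
        """Load a numerically sorted directory of PNG/TIFF grayscale frames."""
        import imageio.v3 as iio

        def numeric_key(p: Path):
            nums = re.findall(r"\d+", p.stem)
            return (int(nums[-1]) if nums else 0, p.name)

        path = Path(path)
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}),
            key=numeric_key,
        )
        if len(files) < 2:
            raise ValueError(f"no image sequence found in {path}")
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
        if frames.ndim == 4:  # RGB(A) -> luminance
            frames = frames[..., :3].mean(axis=-1)
        return cls(frames=frames, fps=fps)

    def to_directory(self, path) -> list[Path]:
        import imageio.v3 as iio

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        written = []
        for k, frame in enumerate(self.frames):
            f = path / f"frame_{k:05d}.png"
            iio.imwrite(f, np.asarray(frame, dtype=np.uint8))
            written.append(f)
        return written


@dataclass(frozen=True)
class SliceSpec:
    """Vertical slicing of frames into ``n_slices`` equal column bands."""

    n_slices: int = 32
    slice_index: int = 11

    def __post_init__(self) -> None:
        if not 0 <= self.slice_index < self.n_slices:
            raise ValueError(
                f"slice_index {self.slice_index} outside [0, {self.n_slices})"
            )

    def band(self, width: int) -> tuple[int, int]:
        """Half-open column interval of this slice for a frame of ``width``."""
        band_w = width // self.n_slices
        if band_w < 1:
            raise ValueError(
                f"{self.n_slices} slices on a {width}-px frame gives sub-pixel bands"
            )
        return self.slice_index * band_w, (self.slice_index + 1) * band_w


def binarize_frame(
    frame: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Boolean mask of bright (particle) pixels on a dark background.

    ``method="fixed"`` thresholds at the given intensity; ``method="otsu"``
    uses Otsu's global threshold, appropriate for the bimodal histograms of
    a back-lit black-background rig.  A constant frame under Otsu yields an
    all-false mask with a warning rather than an arbitrary split.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization requires a threshold")
        return frame > threshold
    if method == "otsu":
        if np.ptp(frame) == 0:
            warnings.warn("constant frame: Otsu undefined, returning all-false mask")
            return np.zeros(frame.shape, dtype=bool)
        return frame > threshold_otsu(frame)
    raise ValueError(f"unknown binarization method {method!r}")


def default_slice_index(n_slices: int) -> int:
    """Default analysis band: 4 bands off-center toward lower columns.

    The central bands are crossed by the falling particle jet, so the
    default starts from the band just left of center (index n/2 - 1) and
    moves a further 1/8 of the frame width toward lower columns — outside
    the jet but close enough to the middle that material arrives early
    (32 slices -> index 11).  Clamped to a valid index.
    """
    if n_slices < 4:
        raise ValueError("need at least 4 slices")
    return max(int(n_slices // 2 - 1 - n_slices / 8.0), 0)


def slice_area_series(
    stack: ImageStack,
    spec: SliceSpec | None = None,
    method: str = "otsu",
    threshold: float | None = None,
) -> FlowCurve:
    """Bright-area of one vertical band per frame -> flow curve.

    Crops the band, binarizes, and counts bright pixels; times are
    ``k / fps``.  With ``method="otsu"`` a single global threshold is
    derived from the final (fullest) frame and applied to every band —
    the illumination is fixed over a recording, and early bands are often
    entirely dark, where a per-frame histogram split would be undefined.
    """
    spec = spec or SliceSpec()
    lo, hi = spec.band(stack.frame_shape[1])
    if method == "otsu":
        ref = stack.frames[-1]
        if np.ptp(ref) == 0:
            warnings.warn("constant stack: Otsu undefined, flow curve is zero")
            return FlowCurve.from_areas(np.zeros(len(stack)), fps=stack.fps)
        method, threshold = "fixed", float(threshold_otsu(ref))
    areas = np.empty(len(stack), dtype=float)
    for k, frame in enumerate(stack.frames):
        band = frame[:, lo:hi]
        mask = binarize_frame(band, method=method, threshold=threshold)
        areas[k] = mask.sum()
    return FlowCurve.from_areas(areas, fps=stack.fps)


def _surface_heights(mask: np.ndarray) -> np.ndarray:
    """Pile surface height per column, in px up from the bottom row (0 = empty)."""
    rows = mask.shape[0]
    any_col = mask.any(axis=0)
    top = np.where(any_col, mask.argmax(axis=0), rows)
    return rows - top


def measure_static_angle(
    final_mask: np.ndarray,
    apex_trim: float = 0.10,
    base_trim_rows: int = 2,
) -> float:
    """Static angle of repose from the final pile silhouette, in degrees.

    The upper envelope (surface height per column) is split at the apex;
    each flank is fitted with a least-squares line, excluding the top
    ``apex_trim`` fraction of the pile height (apex rounding) and columns
    within ``base_trim_rows`` of the base (spreading).  Returns the mean of
    the absolute slope angles of the two flanks.
    """
    mask = np.asarray(final_mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("empty or non-2D pile mask")
    heights = _surface_heights(mask)
    cols = np.nonzero(heights > 0)[0]
    if len(cols) < 5:
        raise ValueError("pile narrower than 5 px; cannot fit flanks")
    h_max = heights.max()
    apex_col = int(np.mean(np.nonzero(heights == h_max)[0]))
    upper_cut = (1.0 - apex_trim) * h_max

    angles = []
    for side in ("left", "right"):
        sel = cols[cols <= apex_col] if side == "left" else cols[cols >= apex_col]
        h = heights[sel].astype(float)
        keep = (h <= upper_cut) & (h > base_trim_rows)
        if keep.sum() < 2:  # tiny pile: fall back to the full flank
            keep = np.ones_like(h, dtype=bool)
        if keep.sum() < 2:
            continue
        slope = np.polyfit(sel[keep], h[keep], 1)[0]
        angles.append(np.degrees(np.arctan(abs(slope))))
    if not angles:
        raise ValueError("could not fit either pile flank")
    return float(np.mean(angles))


def measure_flow_time(
    curve: FlowCurve,
    plateau_tol: float = 0.005,
    plateau_len: int = 25,
) -> float:
    """Time at which the flow curve settles onto its final plateau (seconds).

    The flow has stopped once the area stays within ``plateau_tol``
    (fraction of the final area) of the final value; the returned time is
    the first frame from which that holds for at least ``plateau_len``
    consecutive frames through the end of the recording.
    """
    if len(curve) <= plateau_len:
        raise ValueError("curve shorter than the required plateau length")
    final = curve.areas[-1]
    tol = plateau_tol * abs(final) if final != 0 else plateau_tol
    within = np.abs(curve.areas - final) <= tol
    # first index from which all remaining samples are on the plateau
    idx = len(curve)
    for k in range(len(curve) - 1, -1, -1):
        if within[k]:
            idx = k
        else:
            break
    if len(curve) - idx < plateau_len:
        raise ValueError(
            "no plateau found: recording appears truncated before flow stopped"
        )
    return float(curve.times[idx])


def crofton_perimeter(mask: np.ndarray) -> float:
    """Crofton perimeter estimate (px) from 4-direction intercept counts."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(perimeter_crofton(mask, directions=4))


def particle_sphericity(mask: np.ndarray) -> float:
    """Sphericity ``4*pi*A / P_crofton**2`` of a single particle silhouette."""
    mask = np.asarray(mask, dtype=bool)
    n_components = int(_label(mask, connectivity=2).max())
    if n_components != 1:
        raise ValueError(
            f"expected a single connected particle, found {n_components}; "
            "label and measure particles individually upstream"
        )
    return sphericity_index(float(mask.sum()), crofton_perimeter(mask))


def classify_particle(psi: float) -> str:
    """Classify a particle as ``"pellet"`` (psi > 0.91) or ``"granule"``.

    The conventional cut defines pellets above 0.91 and granules at or
    below 0.90; the undefined gap (0.90, 0.91] is resolved as granule with
    a warning.
    """
    if not 0 < psi <= 1:
        raise ValueError(f"sphericity must be in (0, 1], got {psi!r}")
    if psi > 0.91:
        return "pellet"
    if psi > 0.90:
        warnings.warn(
            f"sphericity {psi:.4f} falls in the (0.90, 0.91] classification "
            "gap; resolved as granule"
        )
    return "granule"
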