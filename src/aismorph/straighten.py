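"""Image straightening along traced axon paths and intensity-profile extraction.

All AIS and node-of-Ranvier morphometry in this package is measured along a
user-traced (or generator-emitted) polyline that runs from the somatic domain
through the structure of interest into the distal axon.  The image is
resampled along that path so the axon lies on the horizontal axis of a small
"straightened" sub-image.  Collapsing the transverse dimension yields a
per-channel intensity profile, normalized to [0, 1], which is the substrate
for the 40%-threshold extent rule (:mod:`aismorph.morphometry`) and for
nanoscale periodicity analysis (:mod:`aismorph.nanostructure`).

Conventions
-----------
* pixel coordinates are 0-based with the pixel-center convention; ROI
  vertices are ``(x, y)`` pairs in pixels, ordered from the somatic end;
* the straightened image has one column per pixel of path arclength, so the
  arclength position of column ``i`` is ``i * pixel_size`` micrometres from
  the trace start;
* interpolation is bilinear, honouring sub-pixel path points;
* 3D stacks are maximum-intensity projected over z before straightening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import NoSignalError

#: transverse half-width of the sampling band, micrometres (3 px at 0.21 µm/px)
DEFAULT_HALF_WIDTH_UM = 0.63


@dataclass
class ImageStack:
    """Multi-channel image with physical pixel size.

    Parameters
    ----------
    pixels
        Array of shape ``(C, Y, X)`` or ``(C, Z, Y, X)`` of nonnegative
        intensities.
    pixel_size
        Lateral pixel size in µm/pixel.
    channel_labels
        One label per channel (e.g. ``["ankG-GFP", "vGAT"]``).
    """

    pixels: np.ndarray
    pixel_size: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim not in (3, 4):
            raise ValueError("pixels must be (C, Y, X) or (C, Z, Y, X)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.pixels.shape[0])]
        if len(self.channel_labels) != self.pixels.shape[0]:
            raise ValueError("one channel label per channel required")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channel_labels.index(channel)
        return int(channel)

    def project_z(self) -> "ImageStack":
        """Maximum-intensity projection over z (identity for 2D stacks)."""
        if self.pixels.ndim == 3:
            return self
        return ImageStack(self.pixels.max(axis=1), self.pixel_size,
                          list(self.channel_labels))


@dataclass
class PolylineROI:
    """Ordered pixel-coordinate trace; the first vertex is the somatic end."""

    vertices: np.ndarray  # (N, 2) as (x, y)

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y)")
        if self.vertices.shape[0] < 2:
            raise ValueError("a polyline needs at least 2 vertices")
        seg = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive vertices must be distinct")

    def arclength(self) -> float:
        """Total polyline length in pixels."""
        return float(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum())


@dataclass
class StraightenedImage:
    """Sub-image resampled along a path: rows are transverse offsets."""

    pixels: np.ndarray  # (C, 2k+1, W)
    pixel_size: float
    channel_labels: list[str]
    half_width_um: float

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channel_labels.index(channel)
        return int(channel)


@dataclass
class StraightenedProfile:
    """Arclength-parameterized intensity profile per channel.

    ``normalized`` maps, per channel, [robust baseline, max] to [0, 1]
    (clipped below); channels with no contrast are NaN and flagged so that
    downstream extent detection refuses them.
    """

    positions_um: np.ndarray        # (W,), uniform spacing = pixel_size
    intensity: np.ndarray           # (C, W), arbitrary units
    normalized: np.ndarray          # (C, W) in [0, 1], NaN if no contrast
    pixel_size: float
    half_width_um: float
    channel_labels: list[str]
    flags: tuple = ()

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channel_labels.index(channel)
        return int(channel)


def resample_path(roi: PolylineROI, spacing_px: float = 1.0) -> np.ndarray:
    """Resample a polyline at uniform arclength spacing.

    Returns an ``(M, 2)`` array of (x, y) points with consecutive points
    ``spacing_px`` apart along the polyline; the covered arclength differs
    from the total by less than ``spacing_px / 2``.
    """
    if spacing_px <= 0:
        raise ValueError("spacing must be positive")
    verts = roi.vertices
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.arange(0.0, total + spacing_px / 2, spacing_px)
    x = np.interp(targets, cum, verts[:, 0])
    y = np.interp(targets, cum, verts[:, 1])
    return np.column_stack([x, y])


def path_normals(points: np.ndarray) -> np.ndarray:
    """Unit normals of a sampled path (left-hand normal of local tangent)."""
    tang = np.gradient(points, axis=0)
    norm = np.linalg.norm(tang, axis=1)
    norm[norm == 0] = 1.0
    tang = tang / norm[:, None]
    return np.column_stack([-tang[:, 1], tang[:, 0]])


def straighten(image: ImageStack, roi: PolylineROI,
               half_width_um: float = DEFAULT_HALF_WIDTH_UM) -> StraightenedImage:
    """Resample the image along the ROI into a straightened sub-image.

    Output row ``r``, column ``c`` is the bilinear sample at path point ``c``
    (1-pixel arclength spacing) offset ``r - k`` pixels along the local
    normal, where ``k = round(half_width_um / pixel_size)``.  Samples outside
    the image bounds are clipped to the border with a warning.
    """
    if half_width_um <= 0:
        raise ValueError("half_width must be positive")
    stack = image.project_z()
    pts = resample_path(roi, 1.0)
    normals = path_normals(pts)
    k = max(1, int(round(half_width_um / stack.pixel_size)))
    offsets = np.arange(-k, k + 1)

    xs = pts[None, :, 0] + offsets[:, None] * normals[None, :, 0]
    ys = pts[None, :, 1] + offsets[:, None] * normals[None, :, 1]
    ny, nx = stack.pixels.shape[-2:]
    if xs.min() < 0 or ys.min() < 0 or xs.max() > nx - 1 or ys.max() > ny - 1:
        warnings.warn("straightening band exits image bounds; samples clipped",
                      stacklevel=2)
    out = np.stack([
        ndimage.map_coordinates(ch, [ys, xs], order=1, mode="nearest")
        for ch in stack.pixels
    ])
    return StraightenedImage(out, stack.pixel_size, list(stack.channel_labels),
                             half_width_um)


def _normalize_channel(values: np.ndarray) -> np.ndarray | None:
    """Min-max normalization with a robust (1st percentile) baseline.

    Returns None when the channel has no contrast.
    """
    baseline = np.percentile(values, 1)
    peak = values.max()
    contrast = peak - baseline
    if contrast <= 1e-12 * max(1.0, abs(peak)):
        return None
    return np.clip((values - baseline) / contrast, 0.0, 1.0)


def extract_profile(simg: StraightenedImage,
                    aggregation: str = "max") -> StraightenedProfile:
    """Collapse the transverse band into a per-channel normalized profile.

    ``aggregation`` is the transverse aggregate per column: ``"max"``
    (default; robust to slight trace offsets) or ``"mean"``.
    """
    if simg.pixels.size == 0:
        raise ValueError("straightened image is empty")
    if aggregation == "max":
        inten = simg.pixels.max(axis=1)
    elif aggregation == "mean":
        inten = simg.pixels.mean(axis=1)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    flags: list[str] = []
    normalized = np.full_like(inten, np.nan)
    for c in range(inten.shape[0]):
        norm = _normalize_channel(inten[c])
        if norm is None:
            flags.append(f"no-signal:{simg.channel_labels[c]}")
        else:
            normalized[c] = norm
    positions = np.arange(inten.shape[1]) * simg.pixel_size
    return StraightenedProfile(positions, inten, normalized, simg.pixel_size,
                               simg.half_width_um, list(simg.channel_labels),
                               tuple(flags))


def profile_from_image(image: ImageStack, roi: PolylineROI,
                       half_width_um: float = DEFAULT_HALF_WIDTH_UM,
                       aggregation: str = "max") -> StraightenedProfile:
    """Convenience: straighten then extract the normalized profile."""
    return extract_profile(straighten(image, roi, half_width_um), aggregation)


def require_signal(profile: StraightenedProfile, channel: int | str) -> np.ndarray:
    """Return the normalized values of a channel, refusing flat channels."""
    idx = profile.channel_index(channel)
    values = profile.normalized[idx]
    if np.isnan(values).all():
        raise NoSignalError(
            f"channel {profile.channel_labels[idx]!r} has no contrast")
    return values
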