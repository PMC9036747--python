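"""Pose and size normalization into the "size-free" leaf frame.

Leaves arrive at arbitrary rotation and scale.  Each one is rotated
upright — petiole at the bottom, apex at the top — using the line through
the centroids of the petiole and apex halves of the mid-rib, found by
splitting the mid-rib's minimum-area oriented bounding box (OBB) across
its long axis: the petiole end of the mid-rib is markedly thicker, so the
half with more mid-rib pixels is the petiole half.  The upright leaf is
then scaled uniformly so the blade's horizontal extent equals a fixed
width (500 px by default).  The reported *scaling factor* is the
original (post-rotation) blade width divided by the normalized width, a
size proxy that must not depend on the input pose.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError
from skimage import transform

from .components import ComponentSet, LeafSample

logger = logging.getLogger(__name__)

DEFAULT_WIDTH = 500
CROP_MARGIN = 10  # px kept around the blade after normalization


@dataclass
class OrientedBox:
    """Minimum-area oriented bounding box of a mask's foreground.

    ``center`` is in (row, col) pixel coordinates, ``direction`` the unit
    vector (drow, dcol) of the long axis, ``half_extents`` the (long,
    short) half side lengths.  Foreground pixels are treated as unit
    squares, so a single pixel yields half extents (0.5, 0.5).
    """

    center: tuple[float, float]
    direction: tuple[float, float]
    half_extents: tuple[float, float]


@dataclass
class NormalizationResult:
    sample: LeafSample
    scaling_factor: float
    rotation_applied: float  # degrees
    flipped: bool = False
    normalized_width: int = DEFAULT_WIDTH


def min_area_obb(mask: np.ndarray) -> OrientedBox:
    """Minimum-area oriented bounding box over all foreground pixels."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("cannot bound an empty mask")
    pts = np.column_stack([xs, ys]).astype(float)
    if ys.size == 1:
        return OrientedBox((float(ys[0]), float(xs[0])), (0.0, 1.0),
                           (0.5, 0.5))
    try:
        hull = ConvexHull(pts)
        hull_pts = pts[hull.vertices]
    except QhullError:  # degenerate (collinear) foreground
        hull_pts = np.unique(pts, axis=0)
    env = shapely.oriented_envelope(shapely.multipoints(hull_pts))
    if env.geom_type == "Point":
        x, y = env.x, env.y
        return OrientedBox((y, x), (0.0, 1.0), (0.5, 0.5))
    if env.geom_type == "LineString":
        (x0, y0), (x1, y1) = env.coords
        d = np.array([x1 - x0, y1 - y0])
        length = np.linalg.norm(d)
        d /= length
        return OrientedBox(((y0 + y1) / 2, (x0 + x1) / 2),
                           (float(d[1]), float(d[0])),
                           (length / 2 + 0.5, 0.5))
    corners = np.asarray(env.exterior.coords)[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
    long_edge, long_len, short_len = (
        (e1, l1, l2) if l1 >= l2 else (e2, l2, l1))
    d = long_edge / long_len
    cx, cy = corners[:4].mean(axis=0)
    # +0.5 per side: pixels are unit squares, the envelope bounds centers
    return OrientedBox((float(cy), float(cx)), (float(d[1]), float(d[0])),
                       (long_len / 2 + 0.5, short_len / 2 + 0.5))


def locate_petiole_apex(
    mr: np.ndarray, box: OrientedBox | None = None
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Centroids of the petiole and apex halves of the mid-rib.

    The OBB is split at its midline perpendicular to the long axis; the
    half holding more mid-rib pixels is the petiole (it contains the
    thick petiole segment).  On an exact tie the half whose centroid lies
    lower in the image is taken as the petiole, with a warning.
    """
    if box is None:
        box = min_area_obb(mr)
    ys, xs = np.nonzero(mr)
    if ys.size == 0:
        raise ValueError("mid-rib mask is empty")
    d = np.array(box.direction)  # (drow, dcol)
    rel = np.column_stack([ys - box.center[0], xs - box.center[1]])
    s = rel @ d
    half_a = s <= 0
    half_b = ~half_a
    n_a, n_b = int(half_a.sum()), int(half_b.sum())

    def centroid(sel: np.ndarray) -> tuple[float, float]:
        return float(ys[sel].mean()), float(xs[sel].mean())

    if n_a == n_b:
        ca, cb = centroid(half_a), centroid(half_b)
        logger.warning("mid-rib halves tie (%d px each); taking the lower "
                       "half as petiole", n_a)
        warnings.warn("mid-rib OBB halves have equal pixel counts; "
                      "tie-broken by image position", stacklevel=2)
        pet, apx = (ca, cb) if ca[0] >= cb[0] else (cb, ca)
        return pet, apx
    pet_sel, apx_sel = (half_a, half_b) if n_a > n_b else (half_b, half_a)
    pet = centroid(pet_sel)
    if not apx_sel.any():
        # all mid-rib pixels in one half: apex = farthest pixel from petiole
        dist = (ys - pet[0]) ** 2 + (xs - pet[1]) ** 2
        i = int(np.argmax(dist))
        return pet, (float(ys[i]), float(xs[i]))
    return pet, centroid(apx_sel)


def _rotate_sample(sample: LeafSample, angle: float) -> LeafSample:
    if angle % 360 == 0:
        return sample.copy()
    image = transform.rotate(sample.image, angle, resize=True, order=1,
                             preserve_range=True)
    masks = {k: transform.rotate(v.astype(float), angle, resize=True,
                                 order=0, preserve_range=True) > 0.5
             for k, v in sample.components.masks.items()}
    return LeafSample(
        image=np.clip(image, 0, 255).astype(np.uint8),
        components=ComponentSet(masks, dict(sample.components.provenance)),
        leaf_id=sample.leaf_id, orientation=sample.orientation,
        pixel_scale=sample.pixel_scale)


def _rescale_sample(sample: LeafSample, factor: float) -> LeafSample:
    if factor == 1.0:
        return sample
    image = transform.rescale(sample.image, factor, order=1, channel_axis=2,
                              preserve_range=True)
    masks = {k: transform.rescale(v.astype(float), factor, order=0,
                                  preserve_range=True) > 0.5
             for k, v in sample.components.masks.items()}
    return LeafSample(
        image=np.clip(image, 0, 255).astype(np.uint8),
        components=ComponentSet(masks, dict(sample.components.provenance)),
        leaf_id=sample.leaf_id, orientation=sample.orientation,
        pixel_scale=sample.pixel_scale / factor)


def _crop_to_blade(sample: LeafSample, margin: int = CROP_MARGIN) -> LeafSample:
    ys, xs = np.nonzero(sample.components["BD"])
    h, w = sample.components.shape
    r0, r1 = max(ys.min() - margin, 0), min(ys.max() + margin + 1, h)
    c0, c1 = max(xs.min() - margin, 0), min(xs.max() + margin + 1, w)
    masks = {k: np.ascontiguousarray(v[r0:r1, c0:c1])
             for k, v in sample.components.masks.items()}
    return LeafSample(
        image=np.ascontiguousarray(sample.image[r0:r1, c0:c1]),
        components=ComponentSet(masks, dict(sample.components.provenance)),
        leaf_id=sample.leaf_id, orientation=sample.orientation,
        pixel_scale=sample.pixel_scale)


def _blade_width(bd: np.ndarray) -> int:
    cols = np.nonzero(bd.any(axis=0))[0]
    return int(cols[-1] - cols[0] + 1)


def normalize(sample: LeafSample, width: int = DEFAULT_WIDTH
              ) -> NormalizationResult:
    """Rotate a leaf upright and scale its blade to a fixed width.

    The upright rotation aligns the petiole→apex centroid line with the
    vertical axis (petiole down).  ``scaling_factor`` is the blade's
    horizontal extent after rotation divided by ``width``; the output is
    cropped to the blade bounding box plus a small margin.
    """
    bd = sample.components["BD"]
    mr = sample.components["MR"]
    if not bd.any() or not mr.any():
        raise ValueError("BD and MR masks must be non-empty")
    sample = _crop_to_blade(sample)  # shed empty canvas before rotating
    mr = sample.components["MR"]
    pet, apx = locate_petiole_apex(mr)
    dr, dc = apx[0] - pet[0], apx[1] - pet[1]
    # clockwise angle of petiole->apex from the "up" direction; rotating
    # the image by this angle (counter-clockwise on screen) brings the
    # vector upright
    angle = float(np.degrees(np.arctan2(dc, -dr)))
    upright = _rotate_sample(sample, angle)
    pre_width = _blade_width(upright.components["BD"])
    scaling_factor = pre_width / width
    scaled = _rescale_sample(upright, 1.0 / scaling_factor)
    out = _crop_to_blade(scaled)
    return NormalizationResult(sample=out, scaling_factor=scaling_factor,
                               rotation_applied=angle,
                               normalized_width=width)


def flip_to_canonical(result: NormalizationResult,
                      orientation: str | None = None) -> NormalizationResult:
    """Mirror back-side leaves so both faces share handedness.

    The adaxial ("positive") photograph is the reference; the abaxial
    ("back") photograph of the same leaf is its mirror image, so it is
    reflected about the vertical axis.  Applying the operation twice
    restores the original.
    """
    orientation = orientation or result.sample.orientation
    if orientation not in ("positive", "back"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "positive":
        return NormalizationResult(result.sample, result.scaling_factor,
                                   result.rotation_applied,
                                   flipped=result.flipped,
                                   normalized_width=result.normalized_width)
    s = result.sample
    masks = {k: np.ascontiguousarray(v[:, ::-1])
             for k, v in s.components.masks.items()}
    mirrored = LeafSample(
        image=np.ascontiguousarray(s.image[:, ::-1]),
        components=ComponentSet(masks, dict(s.components.provenance)),
        leaf_id=s.leaf_id, orientation=s.orientation,
        pixel_scale=s.pixel_scale)
    return NormalizationResult(mirrored, result.scaling_factor,
                               result.rotation_applied,
                               flipped=not result.flipped,
                               normalized_width=result.normalized_width)
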