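"""Parametric generator of annotated lettuce-style leaves with ground truth.

The generator emulates the annotation conventions of the real imagery the
pipeline targets: an ovate blade, a curved mid-rib whose petiole end is
markedly thicker than the first-order vein, ordered second-order veins
attached along the mid-rib at known angles, laminas as the fields between
consecutive veins (kept clear of a marginal band along the blade edge),
and a flat-colour RGB rendering with seeded Gaussian noise.

Every quantity the downstream pipeline estimates — component areas,
lamina counts and sides, attachment points, vein angles, petiole length —
is emitted as exact ground truth, which makes the whole pipeline testable
without photographs.

Geometry is built in an upright frame (petiole down, apex up); arbitrary
pose is produced afterwards with :func:`apply_rigid_transform`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.spatial import cKDTree
from skimage import draw as skdraw
from skimage import morphology, transform
from skimage.measure import label as cc_label

from .components import ComponentSet, LeafSample, complete_component_set

__all__ = [
    "LeafParams",
    "LaminaTruth",
    "GroundTruth",
    "GenerationError",
    "generate_leaf",
    "apply_rigid_transform",
    "random_params",
    "DEFAULT_PALETTE",
]


class GenerationError(ValueError):
    """Raised when parameters cannot produce a consistent annotated leaf."""


#: Flat fill colours per component plus the background, RGB 0-255.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (24, 22, 20),
    "BD": (86, 128, 62),     # blade fallback (gaps between components)
    "LM": (96, 154, 72),
    "MZ": (72, 118, 58),
    "VS": (168, 190, 128),
    "MR": (206, 214, 160),
}


@dataclass
class LeafParams:
    """Geometry, topology and rendering parameters of one synthetic leaf.

    Lengths are in pixels of the upright drawing frame.  ``vein_angles_*``
    are the true second-order vein angles in degrees, measured between the
    apex-ward mid-rib direction and the vein, listed base to apex; each
    must lie in (0, 180).  Within a side the list must be non-increasing
    base→apex so that straight veins never cross inside the blade.
    """

    blade_length: float = 600.0
    blade_width: float = 400.0
    midrib_curvature: float = 0.05   # bow amplitude as fraction of blade length
    petiole_length: float = 120.0    # arc length of the thick petiole segment
    petiole_width: float = 16.0
    vein_width: float = 5.0
    n_veins_left: int = 4
    n_veins_right: int = 4
    vein_angles_left: tuple[float, ...] | None = None
    vein_angles_right: tuple[float, ...] | None = None
    marginal_band_width: float = 12.0
    palette: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE))
    noise_sd: float = 3.0
    seed: int = 0

    # fractions of the blade span holding the first / last attachment
    attach_lo: float = 0.10
    attach_hi: float = 0.78
    #: clearance between laminas and venation, px
    gap: float = 2.0

    def __post_init__(self) -> None:
        if self.vein_angles_left is None:
            self.vein_angles_left = tuple(
                np.linspace(95.0, 60.0, self.n_veins_left))
        if self.vein_angles_right is None:
            self.vein_angles_right = tuple(
                np.linspace(95.0, 60.0, self.n_veins_right))
        self.vein_angles_left = tuple(float(a) for a in self.vein_angles_left)
        self.vein_angles_right = tuple(float(a) for a in self.vein_angles_right)
        if len(self.vein_angles_left) != self.n_veins_left:
            raise GenerationError("vein_angles_left length != n_veins_left")
        if len(self.vein_angles_right) != self.n_veins_right:
            raise GenerationError("vein_angles_right length != n_veins_right")
        for a in self.vein_angles_left + self.vein_angles_right:
            if not 0.0 < a < 180.0:
                raise GenerationError(f"vein angle {a} outside (0, 180)")
        for side in (self.vein_angles_left, self.vein_angles_right):
            if any(b > a + 1e-9 for a, b in zip(side, side[1:])):
                raise GenerationError(
                    "vein angles must be non-increasing base to apex "
                    "(veins would cross)")
        if min(self.petiole_width, self.vein_width) < 1:
            raise GenerationError("widths must be >= 1 px")
        if self.petiole_length >= self.petiole_length + self.blade_length:
            raise GenerationError("petiole longer than mid-rib")
        if self.petiole_width < 2 * self.vein_width:
            raise GenerationError(
                "petiole_width must be at least twice vein_width so the "
                "petiole half of the mid-rib dominates")


@dataclass
class LaminaTruth:
    """Ground truth for one first-order lamina."""

    side: str                 # "left" | "right"
    order_index: int          # 1-based, base to apex within the side
    area: int                 # px, exact count in the emitted LM mask
    attachment: tuple[float, float]   # (row, col) of the lamina corner
    vein_angle: float         # degrees, the generating angle
    arc_position: float       # px along the mid-rib from the base


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from a synthetic leaf."""

    areas: dict[str, int]
    PE_L: float
    MR_L: float
    AP_L: float
    LM_N: int
    LM_N_LT: int
    LM_N_RT: int
    laminas: list[LaminaTruth]
    vein_angles_left: tuple[float, ...]
    vein_angles_right: tuple[float, ...]
    rotation_deg: float = 0.0
    scale: float = 1.0
    flipped: bool = False
    seed: int = 0

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=1))


# ---------------------------------------------------------------------------
# geometry helpers (x = column, y = row; y grows downward)

_N_SAMPLES = 1200


def _midrib_polyline(p: LeafParams) -> tuple[np.ndarray, np.ndarray]:
    """Dense (x, y) polyline of the mid-rib, base (bottom) to apex (top).

    Returns the polyline and the cumulative arc length at each point.
    The curve bows sideways as a half sine wave.
    """
    total_h = p.petiole_length + p.blade_length
    u = np.linspace(0.0, 1.0, _N_SAMPLES)
    bow = p.midrib_curvature * p.blade_length
    x = bow * np.sin(np.pi * u)
    y = -u * total_h
    pts = np.column_stack([x, y])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, arc


def _ovate_half_width(v: np.ndarray, width: float) -> np.ndarray:
    """Half-width profile of an ovate blade, widest below the middle."""
    P, Q = 1.0, 1.8
    f = np.clip(v, 0, 1) ** P * np.clip(1 - v, 0, 1) ** Q
    peak = (P / (P + Q)) ** P * (Q / (P + Q)) ** Q
    return width / 2.0 * f / peak


def _tangents(pts: np.ndarray) -> np.ndarray:
    """Unit apex-ward tangents of a polyline."""
    t = np.gradient(pts, axis=0)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _draw_band(canvas: np.ndarray, pts: np.ndarray, radius: float,
               origin: np.ndarray) -> None:
    """Stamp disks of ``radius`` along a polyline (pixel-space rounding)."""
    h, w = canvas.shape
    for x, y in pts:
        rr, cc = skdraw.disk((y - origin[1], x - origin[0]), max(radius, 1.0),
                             shape=(h, w))
        canvas[rr, cc] = True


def _resample(pts: np.ndarray, step: float = 1.0) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.arange(0.0, arc[-1] + step, step)
    x = np.interp(s, arc, pts[:, 0])
    y = np.interp(s, arc, pts[:, 1])
    return np.column_stack([x, y])


def _line_intersection(p0, d0, p1, d1) -> np.ndarray:
    """Intersection of two parametric lines p + t*d (2-D)."""
    A = np.array([[d0[0], -d1[0]], [d0[1], -d1[1]]])
    b = np.asarray(p1) - np.asarray(p0)
    t = np.linalg.solve(A, b)
    return np.asarray(p0) + t[0] * np.asarray(d0)


def generate_leaf(params: LeafParams) -> tuple[LeafSample, GroundTruth]:
    """Render one synthetic leaf and its exact ground truth.

    The construction guarantees exactly one first-order lamina per
    second-order vein; parameter combinations that break this (veins too
    crowded for the requested blade) raise :class:`GenerationError`.
    Identical parameters (including ``seed``) give bit-identical output.
    """
    p = params
    pts, arc = _midrib_polyline(p)
    tans = _tangents(pts)
    mr_len = float(arc[-1])
    if p.petiole_length >= mr_len:
        raise GenerationError("petiole_length exceeds mid-rib arc length")

    # blade spans the mid-rib beyond the petiole segment
    blade_start = np.searchsorted(arc, p.petiole_length)
    v = (arc - arc[blade_start]) / (mr_len - arc[blade_start])
    half_w = np.zeros_like(arc)
    half_w[blade_start:] = _ovate_half_width(v[blade_start:], p.blade_width)

    normals_left = np.column_stack([tans[:, 1], -tans[:, 0]])
    left_edge = pts + half_w[:, None] * normals_left
    right_edge = pts - half_w[:, None] * normals_left
    outline = np.vstack([left_edge[blade_start:],
                         right_edge[blade_start:][::-1]])

    # attachments along the blade span, shared fractions for both sides
    blade_arc = mr_len - arc[blade_start]

    def attach_indices(n: int) -> np.ndarray:
        fr = (np.linspace(p.attach_lo, p.attach_hi, n) if n > 1
              else np.array([p.attach_lo]))
        target = arc[blade_start] + fr * blade_arc
        return np.searchsorted(arc, target)

    idx_l = attach_indices(p.n_veins_left)
    idx_r = attach_indices(p.n_veins_right)
    min_spacing = 2 * (p.vein_width + 2 * p.gap) + 4
    for idx in (idx_l, idx_r):
        if len(idx) > 1 and np.min(np.diff(arc[idx])) < min_spacing:
            raise GenerationError(
                "attachments too crowded along the mid-rib for the "
                "requested vein count")

    # canvas: 10% of blade length of padding on all sides
    pad = 0.10 * p.blade_length
    all_x = np.concatenate([outline[:, 0], pts[:, 0]])
    all_y = np.concatenate([outline[:, 1], pts[:, 1]])
    vein_reach = p.blade_width  # veins are clipped by the blade anyway
    x0 = all_x.min() - pad - vein_reach * 0.0
    y0 = all_y.min() - pad
    W = int(np.ceil(all_x.max() + pad - x0))
    H = int(np.ceil(all_y.max() + pad - y0))
    origin = np.array([x0, y0])

    def to_rc(xy: np.ndarray) -> np.ndarray:
        return np.column_stack([xy[:, 1] - y0, xy[:, 0] - x0])

    # --- rasterize blade ---------------------------------------------------
    rc = to_rc(outline)
    rr, cc = skdraw.polygon(rc[:, 0], rc[:, 1], shape=(H, W))
    blade_fill = np.zeros((H, W), dtype=bool)
    blade_fill[rr, cc] = True

    # --- mid-rib: thick petiole + thin first-order vein --------------------
    mr = np.zeros((H, W), dtype=bool)
    _draw_band(mr, _resample(pts[: blade_start + 1]), p.petiole_width / 2,
               origin)
    _draw_band(mr, _resample(pts[blade_start:]), p.vein_width / 2, origin)

    bd = blade_fill | mr

    # --- second-order veins -------------------------------------------------
    def vein_dirs(side: str, idx: np.ndarray,
                  angles: tuple[float, ...]) -> list[tuple[np.ndarray, np.ndarray]]:
        sgn = 1.0 if side == "left" else -1.0
        out = []
        for i, ang in zip(idx, angles):
            t = tans[i]
            n = sgn * np.array([t[1], -t[0]])
            rad = np.deg2rad(ang)
            d = np.cos(rad) * t + np.sin(rad) * n
            out.append((pts[i], d))
        return out

    veins_l = vein_dirs("left", idx_l, p.vein_angles_left)
    veins_r = vein_dirs("right", idx_r, p.vein_angles_right)

    vs = np.zeros((H, W), dtype=bool)
    reach = p.blade_width + p.blade_length  # long enough to always exit
    for p0, d in veins_l + veins_r:
        seg = np.array([p0, p0 + d * reach])
        _draw_band(vs, _resample(seg), p.vein_width / 2, origin)
    vs &= blade_fill
    vv = mr | vs

    # --- marginal band and lamina fields ------------------------------------
    m = int(round(p.marginal_band_width))
    inner = morphology.erosion(blade_fill, morphology.disk(m))
    mz = blade_fill & ~inner & ~vv

    gap_px = int(round(p.gap))
    obstacles = morphology.dilation(vv, morphology.disk(gap_px))
    lamina_space = inner & ~obstacles

    # classify candidate lamina pixels by side of the mid-rib and by the
    # number of vein lines they sit apex-ward of
    ys, xs = np.nonzero(lamina_space)
    pix = np.column_stack([xs + x0, ys + y0])
    tree = cKDTree(pts)
    _, nearest = tree.query(pix, workers=-1)
    tn = tans[nearest]
    rel = pix - pts[nearest]
    cross = tn[:, 0] * rel[:, 1] - tn[:, 1] * rel[:, 0]
    side_left = cross < 0

    def lamina_index(side_mask: np.ndarray,
                     veins: list[tuple[np.ndarray, np.ndarray]],
                     idx: np.ndarray) -> np.ndarray:
        """For each candidate pixel of one side: count of veins it lies
        apex-ward of (0 => below the first vein, not a lamina)."""
        k = np.zeros(side_mask.sum(), dtype=int)
        q = pix[side_mask]
        for (p0, d), i in zip(veins, idx):
            t = tans[i]
            apex_sign = np.sign(d[0] * t[1] - d[1] * t[0])
            c = d[0] * (q[:, 1] - p0[1]) - d[1] * (q[:, 0] - p0[0])
            k += (np.sign(c) == apex_sign)
        return k

    lm = np.zeros((H, W), dtype=bool)
    lamina_truths: list[LaminaTruth] = []
    mr_half = p.vein_width / 2.0  # mid-rib width inside the blade

    for side, veins, idx, angles in (
        ("left", veins_l, idx_l, p.vein_angles_left),
        ("right", veins_r, idx_r, p.vein_angles_right),
    ):
        smask = side_left if side == "left" else ~side_left
        if smask.sum() == 0:
            if len(veins) > 0:
                raise GenerationError(f"no lamina space on {side} side")
            continue
        k = lamina_index(smask, veins, idx)
        sy, sx = ys[smask], xs[smask]
        n_v = len(veins)
        for order in range(1, n_v + 1):
            sel = k == order
            if not sel.any():
                raise GenerationError(
                    f"lamina {order} on {side} side is empty")
            comp = np.zeros((H, W), dtype=bool)
            comp[sy[sel], sx[sel]] = True
            lab = cc_label(comp, connectivity=2)
            n_cc = lab.max()
            if n_cc > 1:
                # keep the dominant field, drop rasterization slivers
                sizes = np.bincount(lab.ravel())[1:]
                if np.sort(sizes)[-2] > 25:
                    raise GenerationError(
                        f"lamina {order} on {side} side fragmented")
                comp = lab == (np.argmax(sizes) + 1)
            area = int(comp.sum())
            if area < 50:
                raise GenerationError(
                    f"lamina {order} on {side} side too small ({area} px)")
            lm |= comp

            # true attachment corner of the rendered lamina: its pixel
            # closest to the exact centerline, ties (1 px) broken toward
            # the base; its arc position is measured from the rendered
            # base tip (the petiole band's round cap extends half its
            # width below the centerline start)
            crr, ccc = np.nonzero(comp)
            cxy = np.column_stack([ccc + x0, crr + y0]).astype(float)
            dc, ic = tree.query(cxy)
            tie = dc <= dc.min() + 1.0
            arcs = arc[ic]
            d_base = np.linalg.norm(cxy - pts[0], axis=1)
            j = np.flatnonzero(tie)[np.argmin(d_base[tie])]
            lamina_truths.append(LaminaTruth(
                side=side, order_index=order, area=area,
                attachment=(float(crr[j]), float(ccc[j])),
                vein_angle=float(angles[order - 1]),
                arc_position=float(arcs[tie].min()) + p.petiole_width / 2.0,
            ))

    # --- RGB rendering -------------------------------------------------------
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = p.palette["background"]
    for key, mask in (("BD", bd), ("LM", lm), ("MZ", mz),
                      ("VS", vs), ("MR", mr)):
        img[mask] = p.palette[key]
    rng = np.random.default_rng(p.seed)
    if p.noise_sd > 0:
        img += rng.normal(0.0, p.noise_sd, img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)

    cs = complete_component_set(
        {"BD": bd, "MR": mr, "VS": vs, "LM": lm, "VV": vv, "MZ": mz})
    sample = LeafSample(image=image, components=cs,
                        leaf_id=f"synth{p.seed}")

    laminas = sorted(lamina_truths,
                     key=lambda L: (L.side, L.order_index))
    pe_l = min(L.arc_position for L in laminas) if laminas else float("nan")
    # centerline length of the emitted mask, including both round caps
    mr_len_mask = mr_len + p.petiole_width / 2.0 + p.vein_width / 2.0
    truth = GroundTruth(
        areas={k: cs.area(k) for k in cs.masks},
        PE_L=pe_l,
        MR_L=mr_len_mask,
        AP_L=mr_len_mask - pe_l,
        LM_N=len(laminas),
        LM_N_LT=sum(L.side == "left" for L in laminas),
        LM_N_RT=sum(L.side == "right" for L in laminas),
        laminas=laminas,
        vein_angles_left=p.vein_angles_left,
        vein_angles_right=p.vein_angles_right,
        seed=p.seed,
    )
    if truth.LM_N != p.n_veins_left + p.n_veins_right:
        raise GenerationError("lamina count does not match vein count")
    return sample, truth


def apply_rigid_transform(sample: LeafSample, angle: float = 0.0,
                          scale: float = 1.0,
                          flip: bool = False) -> LeafSample:
    """Rotate, scale and optionally mirror a leaf sample.

    The canvas grows as needed so no foreground is clipped.  Masks use
    nearest-neighbour interpolation (areas preserved to within
    rasterization tolerance), the RGB image bilinear.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    image = sample.image
    masks = {k: v for k, v in sample.components.masks.items()}
    if angle % 360 != 0:
        image = transform.rotate(image, angle, resize=True, order=1,
                                 preserve_range=True)
        masks = {k: transform.rotate(v.astype(float), angle, resize=True,
                                     order=0, preserve_range=True) > 0.5
                 for k, v in masks.items()}
    if scale != 1.0:
        image = transform.rescale(image, scale, order=1, channel_axis=2,
                                  preserve_range=True)
        masks = {k: transform.rescale(v.astype(float), scale, order=0,
                                      preserve_range=True) > 0.5
                 for k, v in masks.items()}
    if flip:
        image = image[:, ::-1]
        masks = {k: v[:, ::-1] for k, v in masks.items()}
    cs = ComponentSet({k: np.ascontiguousarray(v) for k, v in masks.items()},
                      dict(sample.components.provenance))
    return LeafSample(
        image=np.ascontiguousarray(np.clip(image, 0, 255)).astype(np.uint8),
        components=cs, leaf_id=sample.leaf_id,
        orientation=sample.orientation, pixel_scale=sample.pixel_scale)


def random_params(seed: int, angle_low: float = 30.0,
                  angle_high: float = 150.0) -> LeafParams:
    """Draw realistic leaf parameters for one seed.

    Vein angles are drawn uniformly from ``(angle_low, angle_high)`` and
    sorted non-increasing base→apex (the generator's no-crossing
    requirement); sorting leaves the marginal distribution uniform.
    """
    rng = np.random.default_rng(seed)
    n_l = int(rng.integers(3, 6))
    n_r = int(rng.integers(3, 6))
    ang_l = np.sort(rng.uniform(angle_low, angle_high, n_l))[::-1]
    ang_r = np.sort(rng.uniform(angle_low, angle_high, n_r))[::-1]
    return LeafParams(
        blade_length=float(rng.uniform(480, 700)),
        blade_width=float(rng.uniform(300, 460)),
        midrib_curvature=float(rng.uniform(0.01, 0.07)),
        petiole_length=float(rng.uniform(80, 160)),
        petiole_width=float(rng.uniform(14, 20)),
        vein_width=float(rng.uniform(4, 6)),
        n_veins_left=n_l, n_veins_right=n_r,
        vein_angles_left=tuple(ang_l), vein_angles_right=tuple(ang_r),
        marginal_band_width=float(rng.uniform(10, 15)),
        noise_sd=3.0,
        seed=seed,
    )


def save_leaf(sample: LeafSample, truth: GroundTruth,
              out_dir: Path | str) -> None:
    """Write `<id>_{BD,...}.png`, `<id>_rgb.png` and `<id>_truth.json`."""
    from .components import save_component_set

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_component_set(sample.components, out_dir, sample.leaf_id)
    Image.fromarray(sample.image).save(out_dir / f"{sample.leaf_id}_rgb.png")
    truth.save(out_dir / f"{sample.leaf_id}_truth.json")
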