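"""The 266-trait vector of one leaf: 30 geometry, 20 venation, 216 colour.

Geometry and venation traits are measured in the normalized ("size-free")
frame, so leaves of different sizes are directly comparable; the scaling
factor preserves the absolute size information.  Colour traits are the
per-channel mean and population standard deviation of each semantic
component in six colour spaces (RGB, HSV, LAB, LUV, YCrCb and CIELab),
216 = 6 components x 6 spaces x 3 channels x 2 statistics.

The exact trait registry lives in :data:`GEO_TRAITS`, :data:`VEN_TRAITS`
and :func:`color_trait_names`; every name that is standard in the field's
notation (area ratios, ``PE_L``, ``LM_Ave_ANG``, ...) is used verbatim,
and the registry is the single place to swap a trait in or out.
"""

from __future__ import annotations

import numpy as np
from skimage import color as skcolor
from skimage import measure, morphology

from .components import COMPONENT_KEYS, ComponentSet, area_indicators

#: mm per pixel of the acquisition setup.
DEFAULT_PIXEL_SCALE = 4.785e-2

GEO_TRAITS = (
    "BD_L", "BD_W", "BD_A", "BD_P", "BD_CHA", "BD_Solidity",
    "BD_AspectRatio", "ScalingFactor",
    "MR_A", "VS_A", "VV_A", "LM_A", "MZ_A",
    "MR_A_Ratio", "VS_A_Ratio", "VV_A_Ratio", "LM_A_Ratio", "MZ_A_Ratio",
    "MR_VS_A_Ratio", "MR_VV_A_Ratio", "VS_VV_A_Ratio",
    "EVA_MR_VS_2_VV", "EVA_LM_VV_2_BD", "EVA_MZ_LM_2_BD",
    "LM_A_LT", "LM_A_RT", "BD_A_LT", "BD_A_RT",
    "LM_CHA", "VV_CHA",
)

VEN_TRAITS = (
    "PE_L", "MR_L", "AP_L", "BD_PE_PX",
    "LM_N", "LM_N_LT", "LM_N_RT",
    "LM1_A_LT", "LM1_A_RT",
    "LM_Ave_ANG", "LM_Ave_ANG_LT", "LM_Ave_ANG_RT",
    "LM_ANG_Std_LT", "LM_ANG_Std_RT",
    "VV_SKL_L", "VS_SKL_L", "SKL_EP_N", "SKL_BP_N",
    "VeinDensity", "PE_L_Ratio",
)

COLOR_SPACES = ("RGB", "HSV", "LAB", "LUV", "YCrCb", "CIELab")
COLOR_STATS = ("mean", "std")


def color_trait_names() -> list[str]:
    """The 216 colour trait names, `<COMP>_<SPACE>_<stat>_<ch>`."""
    return [f"{comp}_{space}_{stat}_{ch}"
            for comp in COMPONENT_KEYS
            for space in COLOR_SPACES
            for stat in COLOR_STATS
            for ch in (1, 2, 3)]


def trait_names() -> list[str]:
    """All 266 trait names in stable CSV column order."""
    return list(GEO_TRAITS) + list(VEN_TRAITS) + color_trait_names()


def trait_schema() -> list[dict]:
    """Name, group and unit of every trait (sidecar metadata)."""
    px, px2, deg = "px", "px^2", "deg"
    units = {
        "BD_L": px, "BD_W": px, "BD_P": px, "PE_L": px, "MR_L": px,
        "AP_L": px, "VV_SKL_L": px, "VS_SKL_L": px,
        "LM_Ave_ANG": deg, "LM_Ave_ANG_LT": deg, "LM_Ave_ANG_RT": deg,
        "LM_ANG_Std_LT": deg, "LM_ANG_Std_RT": deg,
        "VeinDensity": "1/px",
    }
    schema = []
    for name in trait_names():
        if name in GEO_TRAITS:
            group = "GEO"
            unit = units.get(
                name, "%" if "Ratio" in name or name.startswith("EVA") else px2)
            if name in ("BD_Solidity", "BD_AspectRatio", "ScalingFactor"):
                unit = ""
        elif name in VEN_TRAITS:
            group = "VEN"
            unit = units.get(name, px2 if "_A_" in name or name == "BD_PE_PX"
                             else "")
            if name.startswith("LM_N") or name.startswith("SKL"):
                unit = "count"
        else:
            group = "CLR"
            unit = ""
        schema.append({"name": name, "group": group, "unit": unit})
    return schema


def pixels_to_mm(length_px: float,
                 scale: float = DEFAULT_PIXEL_SCALE) -> float:
    """Convert a pixel length to millimetres (``scale`` is mm/pixel)."""
    if scale <= 0:
        raise ValueError("pixel scale must be positive")
    return length_px * scale


def _extent(mask: np.ndarray) -> tuple[int, int]:
    """(vertical, horizontal) extent of a mask's bounding box, px."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return 0, 0
    return int(ys.max() - ys.min() + 1), int(xs.max() - xs.min() + 1)


def _convex_hull_area(mask: np.ndarray) -> float | None:
    if not mask.any():
        return None
    return float(morphology.convex_hull_image(mask).sum())


def geometry_traits(cs: ComponentSet, scaling_factor: float,
                    lm_split: tuple[np.ndarray, np.ndarray],
                    bd_split: tuple[np.ndarray, np.ndarray]
                    ) -> dict[str, float | None]:
    """The 30 geometry traits of a normalized leaf.

    ``lm_split`` / ``bd_split`` are the (left, right) halves of the LM
    and BD masks from the mid-rib split.
    """
    bd = cs["BD"]
    if not bd.any():
        raise ValueError("empty blade mask")
    bd_l, bd_w = _extent(bd)
    bd_a = float(bd.sum())
    bd_cha = _convex_hull_area(bd)
    vals: dict[str, float | None] = {
        "BD_L": float(bd_l),
        "BD_W": float(bd_w),
        "BD_A": bd_a,
        "BD_P": float(measure.perimeter(bd)),
        "BD_CHA": bd_cha,
        "BD_Solidity": bd_a / bd_cha if bd_cha else None,
        "BD_AspectRatio": bd_l / bd_w if bd_w else None,
        "ScalingFactor": float(scaling_factor),
        "MR_A": float(cs.area("MR")),
        "VS_A": float(cs.area("VS")),
        "VV_A": float(cs.area("VV")),
        "LM_A": float(cs.area("LM")),
        "MZ_A": float(cs.area("MZ")),
    }
    vals.update(area_indicators(cs).as_dict())
    vals["LM_A_LT"] = float(lm_split[0].sum())
    vals["LM_A_RT"] = float(lm_split[1].sum())
    vals["BD_A_LT"] = float(bd_split[0].sum())
    vals["BD_A_RT"] = float(bd_split[1].sum())
    vals["LM_CHA"] = _convex_hull_area(cs["LM"])
    vals["VV_CHA"] = _convex_hull_area(cs["VV"])
    assert set(vals) == set(GEO_TRAITS)
    return {k: vals[k] for k in GEO_TRAITS}


def venation_traits(arch, vv_skel, vs_skel,
                    bd_area: float) -> dict[str, float | None]:
    """The 20 venation traits from the assembled vein architecture.

    ``vv_skel`` / ``vs_skel`` are the skeleton graphs of the venation and
    the second-order veins; ``VeinDensity`` is venation skeleton length
    per blade area.  Entries of an empty side are left undefined.
    """

    def pop_std(vals: list[float]) -> float | None:
        return float(np.std(vals)) if vals else None

    first = {side: next((L.area for L in arch.laminas
                         if L.side == side and L.order_index == 1), None)
             for side in ("left", "right")}
    vals: dict[str, float | None] = {
        "PE_L": arch.PE_L,
        "MR_L": arch.MR_L,
        "AP_L": arch.AP_L,
        "BD_PE_PX": float(arch.BD_PE_PX),
        "LM_N": float(arch.LM_N),
        "LM_N_LT": float(arch.LM_N_LT),
        "LM_N_RT": float(arch.LM_N_RT),
        "LM1_A_LT": first["left"],
        "LM1_A_RT": first["right"],
        "LM_Ave_ANG": arch.LM_Ave_ANG,
        "LM_Ave_ANG_LT": arch.LM_Ave_ANG_LT,
        "LM_Ave_ANG_RT": arch.LM_Ave_ANG_RT,
        "LM_ANG_Std_LT": pop_std(arch.LM_ANG_List_LT),
        "LM_ANG_Std_RT": pop_std(arch.LM_ANG_List_RT),
        "VV_SKL_L": float(vv_skel.total_length),
        "VS_SKL_L": float(vs_skel.total_length),
        "SKL_EP_N": float(len(vv_skel.endpoints)),
        "SKL_BP_N": float(len(vv_skel.branch_points)),
        "VeinDensity": (float(vv_skel.total_length) / bd_area
                        if bd_area else None),
        "PE_L_Ratio": (arch.PE_L / arch.MR_L
                       if arch.PE_L is not None and arch.MR_L else None),
    }
    assert set(vals) == set(VEN_TRAITS)
    return {k: vals[k] for k in VEN_TRAITS}


def _color_channels(image: np.ndarray) -> dict[str, np.ndarray]:
    """Convert an RGB uint8 image into all six colour spaces.

    Channel conventions: RGB raw 0-255; HSV hue in [0, 360), S and V in
    [0, 1]; LAB is the 8-bit-quantized L*a*b* (all channels in [0, 255]);
    CIELab the floating-point CIE L*a*b* (L in [0, 100]); LUV CIE L*u*v*
    (D65); YCrCb per ITU-R BT.601 with channels ordered (Y, Cr, Cb).
    """
    rgb01 = image.astype(np.float64) / 255.0
    hsv = skcolor.rgb2hsv(rgb01)
    hsv = np.stack([hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]], axis=-1)
    lab_f = skcolor.rgb2lab(rgb01)
    lab8 = np.stack([lab_f[..., 0] * 255.0 / 100.0,
                     lab_f[..., 1] + 128.0,
                     lab_f[..., 2] + 128.0], axis=-1)
    lab8 = np.clip(lab8, 0, 255)
    luv = skcolor.rgb2luv(rgb01)
    ycbcr = skcolor.rgb2ycbcr(rgb01)
    ycrcb = ycbcr[..., [0, 2, 1]]
    return {
        "RGB": image.astype(np.float64),
        "HSV": hsv,
        "LAB": lab8,
        "LUV": luv,
        "YCrCb": ycrcb,
        "CIELab": lab_f,
    }


def color_traits(image: np.ndarray,
                 cs: ComponentSet) -> dict[str, float | None]:
    """The 216 colour traits: per-component channel mean and std.

    Standard deviation is the population statistic (divisor N).  All 36
    values of an empty component are left undefined.
    """
    if image.shape[:2] != cs.shape:
        raise ValueError("image and masks are not aligned")
    channels = _color_channels(image)
    out: dict[str, float | None] = {}
    for comp in COMPONENT_KEYS:
        mask = cs[comp]
        empty = not mask.any()
        for space in COLOR_SPACES:
            if empty:
                for stat in COLOR_STATS:
                    for ch in (1, 2, 3):
                        out[f"{comp}_{space}_{stat}_{ch}"] = None
                continue
            vals = channels[space][mask]
            mean = vals.mean(axis=0)
            std = vals.std(axis=0)
            for ch in (1, 2, 3):
                out[f"{comp}_{space}_mean_{ch}"] = float(mean[ch - 1])
                out[f"{comp}_{space}_std_{ch}"] = float(std[ch - 1])
    return out


def extract_traits(image: np.ndarray, cs: ComponentSet,
                   scaling_factor: float, arch, vv_skel, vs_skel,
                   lm_split, bd_split) -> dict[str, float | None]:
    """Assemble the full ordered 266-trait record of one leaf."""
    vals = geometry_traits(cs, scaling_factor, lm_split, bd_split)
    vals.update(venation_traits(arch, vv_skel, vs_skel,
                                bd_area=float(cs.area("BD"))))
    vals.update(color_traits(image, cs))
    names = trait_names()
    assert set(vals) == set(names)
    return {k: vals[k] for k in names}
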