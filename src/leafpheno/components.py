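"""Semantic-component masks of a detached leaf and their set algebra.

A leaf is described by six aligned binary masks:

``BD``
    blade — the entire leaf region, petiole included.
``MR``
    mid-rib — petiole plus first-order vein, base to apex.
``VS``
    second-order veins branching off the mid-rib.
``LM``
    laminas — the flat photosynthetic fields bounded by veins.
``VV``
    venation, defined as the union ``MR | VS``.
``MZ``
    marginal zone, defined as the difference ``BD - VV - LM``.

``VV`` and ``MZ`` are derived components: when absent from an annotated
set they are filled in here and flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image

COMPONENT_KEYS = ("BD", "MR", "VS", "LM", "VV", "MZ")
ANNOTATED_KEYS = ("BD", "MR", "VS", "LM")

#: 8-bit PNG pixels strictly above this value are foreground.
FOREGROUND_THRESHOLD = 127


@dataclass
class ComponentSet:
    """The six aligned binary masks of one leaf.

    ``masks`` maps component key to a boolean ``(H, W)`` array;
    ``provenance`` records per key whether the mask was ``"annotated"``
    or ``"derived"`` from the others.
    """

    masks: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"mask dimensions differ: {sorted(shapes)}")
        for key in self.masks:
            self.provenance.setdefault(key, "annotated")

    def __getitem__(self, key: str) -> np.ndarray:
        return self.masks[key]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def area(self, key: str) -> int:
        return int(self.masks[key].sum())

    def copy(self) -> "ComponentSet":
        return ComponentSet(
            {k: v.copy() for k, v in self.masks.items()}, dict(self.provenance)
        )


@dataclass
class LeafSample:
    """An RGB leaf photograph with its component masks and identity."""

    image: np.ndarray  # uint8 (H, W, 3)
    components: ComponentSet
    leaf_id: str = "leaf"
    orientation: str = "positive"  # adaxial ("positive") or abaxial ("back")
    pixel_scale: float = 4.785e-2  # mm per pixel

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.components.shape:
            raise ValueError(
                f"image shape {self.image.shape[:2]} does not match "
                f"mask shape {self.components.shape}"
            )
        if self.orientation not in ("positive", "back"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def copy(self) -> "LeafSample":
        return replace(self, image=self.image.copy(),
                       components=self.components.copy())


def derive_venation(mr: np.ndarray, vs: np.ndarray) -> np.ndarray:
    """Venation is the pixel-wise union of mid-rib and second-order veins."""
    if mr.shape != vs.shape:
        raise ValueError(f"shape mismatch: MR {mr.shape} vs VS {vs.shape}")
    return mr | vs


def derive_marginal_zone(bd: np.ndarray, vv: np.ndarray,
                         lm: np.ndarray) -> np.ndarray:
    """Marginal zone is the blade minus venation minus laminas."""
    if not (bd.shape == vv.shape == lm.shape):
        raise ValueError("BD/VV/LM shapes differ")
    return bd & ~vv & ~lm


def complete_component_set(masks: Mapping[str, np.ndarray]) -> ComponentSet:
    """Build a full six-component set, deriving VV and MZ when absent."""
    out = {k: np.asarray(v, dtype=bool) for k, v in masks.items()}
    provenance = {k: "annotated" for k in out}
    missing = [k for k in ANNOTATED_KEYS if k not in out]
    if missing:
        raise ValueError(f"annotated components missing: {missing}")
    if "VV" not in out:
        out["VV"] = derive_venation(out["MR"], out["VS"])
        provenance["VV"] = "derived"
    if "MZ" not in out:
        out["MZ"] = derive_marginal_zone(out["BD"], out["VV"], out["LM"])
        provenance["MZ"] = "derived"
    return ComponentSet(out, provenance)


def _read_mask(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    if arr.max(initial=0) <= 1:  # 0/1-valued file: any nonzero is foreground
        return arr > 0
    return arr > FOREGROUND_THRESHOLD


def load_component_set(paths: Mapping[str, Path | str]) -> ComponentSet:
    """Load component masks from 8-bit PNGs, deriving missing VV/MZ.

    Any pixel value above :data:`FOREGROUND_THRESHOLD` is foreground, so
    0/1- and 0/255-valued files load identically.  All masks of one leaf
    must share dimensions; a mismatch raises naming both files.
    """
    masks: dict[str, np.ndarray] = {}
    ref_key = ref_path = None
    for key, path in paths.items():
        mask = _read_mask(Path(path))
        if ref_key is None:
            ref_key, ref_path = key, path
        elif mask.shape != masks[ref_key].shape:
            raise ValueError(
                f"dimension mismatch: {ref_path} is {masks[ref_key].shape}, "
                f"{path} is {mask.shape}"
            )
        masks[key] = mask
    return complete_component_set(masks)


def save_component_set(cs: ComponentSet, out_dir: Path | str,
                       leaf_id: str) -> dict[str, Path]:
    """Write each mask as `<id>_<KEY>.png` (8-bit, 0/255)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for key in COMPONENT_KEYS:
        path = out_dir / f"{leaf_id}_{key}.png"
        Image.fromarray(cs[key].astype(np.uint8) * 255, mode="L").save(path)
        written[key] = path
    return written


@dataclass
class AreaIndicators:
    """Area-ratio and area-overlap indicators, in percent.

    Component-to-blade ratios (``*_A_Ratio``) live in [0, 100]; the
    ``EVA_*`` indicators measure by how much two components' summed area
    exceeds a reference component (0 when the pair partitions it).  An
    indicator whose denominator component is empty is ``None`` —
    undefined, never coerced to 0.
    """

    MR_A_Ratio: float | None
    VS_A_Ratio: float | None
    VV_A_Ratio: float | None
    LM_A_Ratio: float | None
    MZ_A_Ratio: float | None
    MR_VS_A_Ratio: float | None
    MR_VV_A_Ratio: float | None
    VS_VV_A_Ratio: float | None
    EVA_MR_VS_2_VV: float | None
    EVA_LM_VV_2_BD: float | None
    EVA_MZ_LM_2_BD: float | None

    def as_dict(self) -> dict[str, float | None]:
        return dict(vars(self))


def excess_area(x: int, y: int, z: int) -> float | None:
    """Excess of |X|+|Y| over the reference |Z|, as a percentage of |Z|.

    Zero when X and Y exactly partition Z; positive overlap between X
    and Y (inside Z) pushes the value up.
    """
    if z == 0:
        return None
    return 100.0 * (x + y - z) / z


def area_indicators(cs: ComponentSet) -> AreaIndicators:
    """Compute the eight area-ratio and three overlap indicators."""
    a = {k: cs.area(k) for k in COMPONENT_KEYS}
    if a["BD"] == 0:
        raise ValueError("blade mask is empty; area ratios undefined")

    def ratio(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    return AreaIndicators(
        MR_A_Ratio=ratio(a["MR"], a["BD"]),
        VS_A_Ratio=ratio(a["VS"], a["BD"]),
        VV_A_Ratio=ratio(a["VV"], a["BD"]),
        LM_A_Ratio=ratio(a["LM"], a["BD"]),
        MZ_A_Ratio=ratio(a["MZ"], a["BD"]),
        MR_VS_A_Ratio=ratio(a["MR"], a["VS"]),
        MR_VV_A_Ratio=ratio(a["MR"], a["VV"]),
        VS_VV_A_Ratio=ratio(a["VS"], a["VV"]),
        EVA_MR_VS_2_VV=excess_area(a["MR"], a["VS"], a["VV"]),
        EVA_LM_VV_2_BD=excess_area(a["LM"], a["VV"], a["BD"]),
        EVA_MZ_LM_2_BD=excess_area(a["MZ"], a["LM"], a["BD"]),
    )
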