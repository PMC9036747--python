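"""End-to-end orchestration: masks in, trait table and reports out.

Stages per leaf: load masks → derive VV/MZ → normalize (upright + fixed
width) → canonical flip → skeletonize → vein architecture → 266 traits.
Per-leaf failures are logged and skipped, never fatal; leaves that fail
structural screening (no laminas, fragmented mid-rib) are flagged
``invalid`` rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .architecture import (
    DEFAULT_ADJACENCY_RADIUS,
    DEFAULT_DP_TOLERANCE,
    DEFAULT_MIN_LAMINA_AREA,
    analyze_architecture,
    midrib_main_path,
    skeletonize_component,
    split_left_right,
)
from .components import ANNOTATED_KEYS, COMPONENT_KEYS, LeafSample, load_component_set
from .normalization import DEFAULT_WIDTH, flip_to_canonical, normalize
from .traits import DEFAULT_PIXEL_SCALE, extract_traits, trait_names, trait_schema

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of a phenotyping run.

    The config is serialized next to every output for provenance.
    """

    normalized_width: int = DEFAULT_WIDTH
    dp_tolerance: float = DEFAULT_DP_TOLERANCE
    adjacency_radius: int = DEFAULT_ADJACENCY_RADIUS
    min_lamina_area: int = DEFAULT_MIN_LAMINA_AREA
    pixel_scale: float = DEFAULT_PIXEL_SCALE  # mm per pixel
    seed: int = 0
    flip_backs: bool = True
    linkage: str = "ward"
    k: int = 4

    def __post_init__(self) -> None:
        for name in ("normalized_width", "dp_tolerance", "adjacency_radius",
                     "min_lamina_area", "pixel_scale", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path: Path | str) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class LeafResult:
    leaf_id: str
    orientation: str
    traits: dict | None
    architecture: dict | None
    valid: bool
    error: str | None = None
    timings: dict[str, float] = field(default_factory=dict)


def process_leaf(sample: LeafSample,
                 config: PipelineConfig | None = None) -> LeafResult:
    """Run the full per-leaf pipeline on an in-memory sample."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    norm = normalize(sample, width=config.normalized_width)
    if config.flip_backs:
        norm = flip_to_canonical(norm)
    timings["normalize"] = time.perf_counter() - t0

    cs = norm.sample.components
    t0 = time.perf_counter()
    arch = analyze_architecture(cs, dp_tolerance=config.dp_tolerance,
                                radius=config.adjacency_radius,
                                min_area=config.min_lamina_area)
    mr_path = midrib_main_path(cs["MR"])
    vv_skel = skeletonize_component(cs["VV"])
    vs_skel = skeletonize_component(cs["VS"])
    timings["architecture"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    lm_split = split_left_right(cs["LM"], mr_path)
    bd_split = split_left_right(cs["BD"], mr_path)
    traits = extract_traits(norm.sample.image, cs, norm.scaling_factor,
                            arch, vv_skel, vs_skel, lm_split, bd_split)
    timings["traits"] = time.perf_counter() - t0

    valid = arch.LM_N > 0
    if not valid:
        logger.warning("leaf %s: no laminas found, flagged invalid",
                       sample.leaf_id)
    return LeafResult(leaf_id=sample.leaf_id, orientation=sample.orientation,
                      traits=traits, architecture=arch.as_dict(),
                      valid=valid, timings=timings)


def discover_leaves(input_dir: Path | str) -> list[str]:
    """Leaf ids in a directory, recognized by their `<id>_BD.png` mask."""
    input_dir = Path(input_dir)
    return sorted(p.name[: -len("_BD.png")]
                  for p in input_dir.glob("*_BD.png"))


def load_leaf(input_dir: Path | str, leaf_id: str,
              pixel_scale: float = DEFAULT_PIXEL_SCALE) -> LeafSample:
    """Load one leaf's masks (+ optional RGB photo) from disk."""
    input_dir = Path(input_dir)
    paths = {}
    for key in COMPONENT_KEYS:
        p = input_dir / f"{leaf_id}_{key}.png"
        if p.exists():
            paths[key] = p
    missing = [k for k in ANNOTATED_KEYS if k not in paths]
    if missing:
        raise FileNotFoundError(f"{leaf_id}: missing masks {missing}")
    cs = load_component_set(paths)
    rgb_path = input_dir / f"{leaf_id}_rgb.png"
    if rgb_path.exists():
        image = np.asarray(Image.open(rgb_path).convert("RGB"))
    else:
        image = np.zeros((*cs.shape, 3), dtype=np.uint8)
    orientation = "back" if leaf_id.endswith("_back") else "positive"
    return LeafSample(image=image, components=cs, leaf_id=leaf_id,
                      orientation=orientation, pixel_scale=pixel_scale)


def run_pipeline(config: PipelineConfig, input_dir: Path | str,
                 out_dir: Path | str) -> pd.DataFrame:
    """Phenotype every leaf in a directory; write CSV, reports and config.

    Returns the trait table.  The exit status contract (number of failed
    leaves) is left to the CLI; failures are recorded in `failures.json`.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    leaf_ids = discover_leaves(input_dir)
    if not leaf_ids:
        raise ValueError(f"no `<id>_BD.png` masks found in {input_dir}")
    rows, failures = [], []
    for leaf_id in leaf_ids:
        try:
            sample = load_leaf(input_dir, leaf_id, config.pixel_scale)
            result = process_leaf(sample, config)
        except Exception as exc:  # per-leaf failures are not fatal
            logger.warning("leaf %s failed: %s", leaf_id, exc)
            failures.append({"leaf_id": leaf_id, "error": str(exc)})
            continue
        row = {"leaf_id": result.leaf_id, "orientation": result.orientation,
               "valid": result.valid}
        row.update(result.traits)
        rows.append(row)
        (out_dir / f"{leaf_id}_arch.json").write_text(
            json.dumps(result.architecture, indent=1))
    table = pd.DataFrame(rows,
                         columns=["leaf_id", "orientation", "valid",
                                  *trait_names()])
    table.to_csv(out_dir / "traits.csv", index=False)
    (out_dir / "traits_schema.json").write_text(
        json.dumps(trait_schema(), indent=1))
    config.save(out_dir / "config.json")
    (out_dir / "failures.json").write_text(json.dumps(failures, indent=1))
    logger.info("phenotyped %d/%d leaves", len(rows), len(leaf_ids))
    return table
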