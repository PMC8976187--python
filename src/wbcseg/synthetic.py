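"""Seeded synthetic blood-smear scenes with pixel-exact WBC ground truth.

Scenes emulate the visual structure the segmentation cascade assumes in
stained single-cell smear crops: pale elliptical erythrocytes (RBCs) with
lighter centers scattered on a light pinkish field, and one or more white
blood cells (WBCs) whose basophilic stain renders them dark purple.  The
default 257 x 257 canvas matches the single-WBC crop geometry of public ALL
screening datasets.  Degradations — multiplicative illumination gradient,
Gaussian blur and additive sensor noise — are applied to the *image only*;
the ground-truth mask is the exact pre-degradation union of rendered WBC
interiors.

The default palette is chosen so the half-degree hue plane is well separated:
background and RBC hues sit around 9-17, WBC cytoplasm/nucleus hues around
127-135, with no class near the circular hue wrap (noise cannot flip a pixel
across 0/180).  All palette entries are overridable through the config.

*Healthy* WBCs render as round cells with a compact round nucleus; *ALL*
(acute lymphoblastic leukemia) cells render with an irregular lobed boundary
and a higher nucleus-to-cell ratio, mimicking lymphoblast morphology.  This
is deliberately not a cytomorphology simulator — it provides controllable,
reproducible fixtures with exact ground truth, nothing more.

RBCs may overlap each other and may touch WBCs (WBCs are painted last);
WBCs never overlap each other.  Everything is deterministic per seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.draw import disk as _disk, ellipse as _ellipse, polygon as _polygon

from .errors import GenerationError, ParameterError
from .io_color import BinaryMask, RasterImage, write_image, write_mask

__all__ = [
    "DEFAULT_PALETTE",
    "SmearSceneConfig",
    "CellSpec",
    "SmearScene",
    "generate_scene",
    "generate_dataset",
]

#: RGB palette; hue layout documented in the module docstring.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (232, 216, 196),
    "rbc": (228, 160, 130),
    "rbc_center": (238, 186, 164),
    "cytoplasm_healthy": (170, 140, 200),
    "nucleus_healthy": (90, 60, 150),
    "cytoplasm_all": (160, 130, 195),
    "nucleus_all": (70, 50, 130),
}


@dataclass
class SmearSceneConfig:
    """Parameters of one synthetic scene (all lengths in pixels)."""

    image_size: tuple[int, int] = (257, 257)
    n_wbc: int = 1
    n_rbc: int = 15
    wbc_radius_range: tuple[float, float] = (36.0, 52.0)
    rbc_radius_range: tuple[float, float] = (14.0, 24.0)
    wbc_class: str = "healthy"  # "healthy" | "ALL"
    illumination_gradient: float = 0.15
    blur_sigma: float = 1.0
    noise_sd: float = 4.0
    seed: int = 0
    palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ParameterError("image_size must be positive")
        if self.n_wbc < 0 or self.n_rbc < 0:
            raise ParameterError("cell counts must be nonnegative")
        for name in ("wbc_radius_range", "rbc_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ParameterError(f"{name} must satisfy 0 < lo <= hi")
            if hi >= min(h, w) / 2:
                raise ParameterError(f"{name} radii must stay below min(H, W)/2")
        if self.wbc_class not in ("healthy", "ALL"):
            raise ParameterError("wbc_class must be 'healthy' or 'ALL'")
        if self.illumination_gradient < 0 or self.blur_sigma < 0 or self.noise_sd < 0:
            raise ParameterError("degradation strengths must be nonnegative")
        missing = set(DEFAULT_PALETTE) - set(self.palette)
        if missing:
            raise ParameterError(f"palette missing entries: {sorted(missing)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        d["wbc_radius_range"] = list(self.wbc_radius_range)
        d["rbc_radius_range"] = list(self.rbc_radius_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SmearSceneConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown scene config key(s): {sorted(unknown)}")
        data = dict(data)
        for key in ("image_size", "wbc_radius_range", "rbc_radius_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "SmearSceneConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"scene config {path!r} must be a YAML mapping")
        return cls.from_dict(data)


@dataclass
class CellSpec:
    """Ground-truth description of one rendered cell."""

    center: tuple[float, float]  # (row, col)
    radius: float
    cell_type: str  # "wbc" | "rbc"
    cell_class: str | None  # "healthy"/"ALL" for WBCs, None for RBCs


@dataclass
class SmearScene:
    """A rendered scene, its exact WBC mask and its generating description."""

    image: RasterImage
    wbc_mask: BinaryMask
    cells: list[CellSpec]
    label: str
    config: SmearSceneConfig


def _lobed_polygon(
    center: tuple[float, float],
    radius: float,
    rng: np.random.Generator,
    amplitude: float = 0.12,
    shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize an irregular lobed blob around *center* (ALL morphology)."""
    k = int(rng.integers(3, 6))
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    theta = np.linspace(0.0, 2 * np.pi, 180, endpoint=False)
    r = radius * (
        1.0
        + amplitude * np.sin(k * theta + phase1)
        + 0.6 * amplitude * np.sin((k + 2) * theta + phase2)
    )
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return _polygon(rows, cols, shape=shape)


def _paint(canvas: np.ndarray, rr: np.ndarray, cc: np.ndarray, color) -> None:
    canvas[rr, cc] = np.asarray(color, dtype=np.float64)


def generate_scene(config: SmearSceneConfig | None = None) -> SmearScene:
    """Render one scene; deterministic for a fixed config (incl. seed)."""
    if config is None:
        config = SmearSceneConfig()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    pal = config.palette
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = np.asarray(pal["background"], dtype=np.float64)
    cells: list[CellSpec] = []

    # erythrocytes first; they may overlap each other freely
    for _ in range(config.n_rbc):
        a = rng.uniform(*config.rbc_radius_range)
        b = a * rng.uniform(0.7, 1.0)
        angle = rng.uniform(0, np.pi)
        cy = rng.uniform(a, h - a)
        cx = rng.uniform(a, w - a)
        rr, cc = _ellipse(cy, cx, a, b, shape=(h, w), rotation=angle)
        _paint(canvas, rr, cc, pal["rbc"])
        rr, cc = _ellipse(cy, cx, 0.55 * a, 0.55 * b, shape=(h, w), rotation=angle)
        _paint(canvas, rr, cc, pal["rbc_center"])
        cells.append(CellSpec((cy, cx), float(a), "rbc", None))

    # leukocytes last (painted over RBCs); mutually non-overlapping
    wbc_mask = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []
    for _ in range(config.n_wbc):
        for attempt in range(200):
            radius = rng.uniform(*config.wbc_radius_range)
            margin = radius * 1.2 + 2
            if 2 * margin >= min(h, w):
                continue
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(
                np.hypot(cy - py, cx - px) > radius + pr + 4 for py, px, pr in placed
            ):
                break
        else:
            raise GenerationError(
                f"could not place {config.n_wbc} non-overlapping WBCs on a "
                f"{h}x{w} canvas after 200 attempts"
            )
        placed.append((cy, cx, radius))
        is_all = config.wbc_class == "ALL"
        if is_all:
            rr, cc = _lobed_polygon((cy, cx), radius, rng, amplitude=0.12, shape=(h, w))
        else:
            rr, cc = _disk((cy, cx), radius, shape=(h, w))
        cell_bool = np.zeros((h, w), dtype=bool)
        cell_bool[rr, cc] = True
        _paint(canvas, rr, cc, pal["cytoplasm_all" if is_all else "cytoplasm_healthy"])
        if is_all:  # large, lobed nucleus
            nr, nc = _lobed_polygon((cy, cx), 0.85 * radius, rng, amplitude=0.15, shape=(h, w))
        else:  # compact round nucleus, slightly offset
            off = rng.uniform(-0.15 * radius, 0.15 * radius, size=2)
            nr, nc = _disk((cy + off[0], cx + off[1]), 0.6 * radius, shape=(h, w))
        nucleus_bool = np.zeros((h, w), dtype=bool)
        nucleus_bool[nr, nc] = True
        nucleus_bool &= cell_bool  # nucleus never pokes out of its cell
        canvas[nucleus_bool] = np.asarray(
            pal["nucleus_all" if is_all else "nucleus_healthy"], dtype=np.float64
        )
        wbc_mask |= cell_bool
        cells.append(CellSpec((cy, cx), float(radius), "wbc", config.wbc_class))

    # degradations: image only, never the mask
    if config.illumination_gradient > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        shade = 1.0 - config.illumination_gradient * 0.5 * (yy / max(h - 1, 1) + xx / max(w - 1, 1))
        canvas *= shade[:, :, np.newaxis]
    if config.blur_sigma > 0:
        canvas = ndimage.gaussian_filter(
            canvas, sigma=(config.blur_sigma, config.blur_sigma, 0.0), mode="reflect"
        )
    if config.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, config.noise_sd, size=canvas.shape)
    image = RasterImage(np.clip(np.rint(canvas), 0, 255).astype(np.uint8), "RGB")
    return SmearScene(image, BinaryMask(wbc_mask), cells, config.wbc_class, config)


def _split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    n_train = round(n * fractions[0])
    n_val = round(n * fractions[1])
    return n_train, n_val, n - n_train - n_val


def generate_dataset(
    n_scenes: int,
    base_config: SmearSceneConfig | None = None,
    class_balance: float = 0.5,
    outdir: str | os.PathLike | None = None,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> tuple[list[SmearScene], pd.DataFrame]:
    """Generate a labelled scene collection with a reproducible manifest.

    ``class_balance`` is the healthy fraction (exact to rounding).  Scenes get
    per-scene seeds drawn from the master seed (``base_config.seed``) and a
    deterministic shuffled train/validation/test split; the default fractions
    reproduce the canonical 208/26/26 split at 260 scenes.  When *outdir* is
    given, images, masks and ``manifest.csv`` are written there.
    """
    if n_scenes < 1:
        raise ParameterError("n_scenes must be >= 1")
    if not 0.0 <= class_balance <= 1.0:
        raise ParameterError(f"class_balance must be in [0, 1], got {class_balance}")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ParameterError("split_fractions must sum to 1")
    if base_config is None:
        base_config = SmearSceneConfig()
    rng = np.random.default_rng(base_config.seed)
    n_healthy = round(n_scenes * class_balance)
    labels = np.array(["healthy"] * n_healthy + ["ALL"] * (n_scenes - n_healthy))
    rng.shuffle(labels)
    n_train, n_val, n_test = _split_counts(n_scenes, split_fractions)
    splits = np.array(["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
    rng.shuffle(splits)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_scenes)

    scenes: list[SmearScene] = []
    rows = []
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
    for i in range(n_scenes):
        cfg = replace(base_config, seed=int(scene_seeds[i]), wbc_class=str(labels[i]))
        scene = generate_scene(cfg)
        scenes.append(scene)
        image_path = f"scene_{i:04d}.png"
        mask_path = f"scene_{i:04d}_mask.png"
        if outdir is not None:
            write_image(scene.image, os.path.join(outdir, image_path))
            write_mask(scene.wbc_mask, os.path.join(outdir, mask_path))
        rows.append(
            {
                "scene_id": f"scene_{i:04d}",
                "image_path": image_path,
                "mask_path": mask_path,
                "label": str(labels[i]),
                "split": str(splits[i]),
                "seed": int(scene_seeds[i]),
            }
        )
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return scenes, manifest
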