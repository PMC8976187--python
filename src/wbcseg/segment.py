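"""Triple-thresholding WBC segmentation.

The pipeline isolates white blood cells in a stained blood-smear image by
working entirely in the hue plane, where the purple/basophilic nucleus stain
is well separated from the pale red of erythrocytes and plasma:

1. convert RGB -> HSV and extract the H plane (half-degree units, [0, 180));
2. run ``n_passes`` (default 3) rounds of Gaussian smoothing followed by Otsu
   thresholding; each round removes one population (erythrocytes, their
   boundaries, residual clutter) and restricts the next round's histogram to
   the surviving pixels;
3. clean up with a morphological opening (13 x 13 square, two iterations by
   default) and, optionally, a minimum-object-area filter.

Otsu's criterion is implemented from its definition: the returned threshold
``t`` is the smallest maximizer of the between-class variance

    sigma_b^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2

where class 0 holds pixels ``<= t``.  Ties break toward the smallest ``t``;
a constant plane returns its constant with variance 0, so blank fields
degrade gracefully instead of raising.

Keep-side rule
--------------
Each round must decide which side of the threshold to keep.  ``"auto"``
(default) keeps the **higher-mean-hue** side in round 1 — nuclei are the
high-hue minority against a low-hue background — and the **majority** side in
later rounds: once the background is gone, subsequent rounds remove small
contaminant populations (cell-boundary blends, erythrocyte remnants), which
are the minority of the surviving pixels and, because purple-to-pink blends
sweep through the magenta hue sector, need not lie below the nucleus hue.
Each round can be forced with ``"above"``, ``"below"``, ``"higher"`` or
``"majority"``.

A round whose optimal split separates the class means by less than
``min_class_separation`` hue units is *degenerate*: there is no second
population left to remove.  A degenerate first round yields an empty mask
(no distinct high-hue population means no WBC in the field); a degenerate
later round is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy import ndimage

from .errors import ParameterError, SemanticError
from .io_color import BinaryMask, ChannelImage, RasterImage, extract_channel, rgb_to_hsv

__all__ = [
    "OtsuResult",
    "SegmentationConfig",
    "ContourSet",
    "PassRecord",
    "gaussian_filter",
    "otsu_threshold",
    "apply_threshold",
    "morphological_open",
    "triple_threshold_segment",
    "extract_contours",
    "draw_contours",
]

_KEEP_CHOICES = ("auto", "above", "below", "higher", "majority")


@dataclass(frozen=True)
class OtsuResult:
    """Outcome of Otsu threshold selection on an 8-bit histogram."""

    threshold: int
    between_class_variance: float
    histogram: np.ndarray

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ParameterError(f"threshold {self.threshold} outside [0, 255]")
        if self.between_class_variance < 0:
            raise ParameterError("between-class variance must be nonnegative")


@dataclass
class SegmentationConfig:
    """Tunable parameters of the triple-thresholding cascade.

    Defaults reproduce the published pipeline settings: three passes, a
    13 x 13 opening element applied for two (staged) iterations.  The Gaussian
    kernel size defaults to 5 with sigma derived from the kernel as
    ``0.3 * ((kernel - 1) * 0.5 - 1) + 0.8``.
    """

    gaussian_kernel: int = 5
    gaussian_sigma: float | None = None  # None => derived from kernel
    opening_kernel: int = 13
    opening_iterations: int = 2
    n_passes: int = 3
    min_object_area: int = 0
    histogram_mode: str = "masked"  # "masked" | "full"
    keep_side: str | tuple[str, ...] = "auto"
    opening_element: str = "square"  # "square" | "ellipse"
    opening_mode: str = "staged"  # "staged" | "repeated"
    min_class_separation: float = 10.0  # hue units; degenerate-split guard

    def __post_init__(self) -> None:
        if self.gaussian_kernel < 1 or self.gaussian_kernel % 2 == 0:
            raise ParameterError(f"gaussian_kernel must be odd >= 1, got {self.gaussian_kernel}")
        if self.gaussian_sigma is not None and self.gaussian_sigma <= 0:
            raise ParameterError("gaussian_sigma must be positive")
        if self.opening_kernel < 1:
            raise ParameterError("opening_kernel must be >= 1")
        if self.opening_iterations < 1:
            raise ParameterError("opening_iterations must be >= 1")
        if self.n_passes < 1:
            raise ParameterError("n_passes must be >= 1")
        if self.min_object_area < 0:
            raise ParameterError("min_object_area must be >= 0")
        if self.histogram_mode not in ("masked", "full"):
            raise ParameterError(f"histogram_mode must be masked|full, got {self.histogram_mode}")
        sides = (self.keep_side,) if isinstance(self.keep_side, str) else tuple(self.keep_side)
        for s in sides:
            if s not in _KEEP_CHOICES:
                raise ParameterError(f"keep_side {s!r} not in {_KEEP_CHOICES}")
        if self.opening_element not in ("square", "ellipse"):
            raise ParameterError("opening_element must be square|ellipse")
        if self.opening_mode not in ("staged", "repeated"):
            raise ParameterError("opening_mode must be staged|repeated")
        if self.min_class_separation < 0:
            raise ParameterError("min_class_separation must be >= 0")

    @property
    def sigma(self) -> float:
        """Effective Gaussian sigma (derived from the kernel when unset)."""
        if self.gaussian_sigma is not None:
            return float(self.gaussian_sigma)
        return 0.3 * ((self.gaussian_kernel - 1) * 0.5 - 1) + 0.8

    def keep_side_for(self, round_index: int) -> str:
        """Keep-side tag for a 0-based round index."""
        if isinstance(self.keep_side, str):
            return self.keep_side
        sides = tuple(self.keep_side)
        return sides[round_index] if round_index < len(sides) else sides[-1]

    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["keep_side"], str):
            d["keep_side"] = list(d["keep_side"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SegmentationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown segmentation config key(s): {sorted(unknown)}")
        data = dict(data)
        if isinstance(data.get("keep_side"), list):
            data["keep_side"] = tuple(data["keep_side"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "SegmentationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"segmentation config {path!r} must be a YAML mapping")
        return cls.from_dict(data)


@dataclass
class ContourSet:
    """Ordered closed boundary polygons, one per 8-connected component.

    Vertices are 0-based ``(row, col)`` pixel coordinates of actual boundary
    pixels; single-pixel objects degenerate to their own pixel repeated.
    """

    contours: list[np.ndarray]
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        h, w = self.image_shape
        for poly in self.contours:
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ParameterError("each contour must be an (n>=3) x 2 vertex array")
            if poly.min() < 0 or poly[:, 0].max() >= h or poly[:, 1].max() >= w:
                raise ParameterError("contour vertex outside image bounds")

    def __len__(self) -> int:
        return len(self.contours)


@dataclass
class PassRecord:
    """Debug record of one Gaussian+Otsu round (the per-round figure analogue)."""

    round_index: int  # 1-based
    threshold: int
    between_class_variance: float
    keep: str | None  # "above"/"below", or None for a degenerate (skipped) round
    mask: BinaryMask  # surviving pixels after this round


def gaussian_filter(channel: ChannelImage, kernel: int, sigma: float) -> ChannelImage:
    """Smooth a plane with a normalized, truncated Gaussian (reflect borders)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError(f"Gaussian kernel must be odd >= 1, got {kernel}")
    if sigma <= 0:
        raise ParameterError(f"Gaussian sigma must be positive, got {sigma}")
    radius = (kernel - 1) // 2
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    w = np.exp(-(x**2) / (2.0 * sigma**2))
    w /= w.sum()
    out = channel.pixels.astype(np.float64)
    out = ndimage.correlate1d(out, w, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, w, axis=1, mode="reflect")
    return ChannelImage(np.clip(out, 0.0, 255.0), channel.source_channel)


def _otsu_from_values(values: np.ndarray) -> OtsuResult:
    values = np.rint(np.clip(values, 0, 255)).astype(np.int64).ravel()
    if values.size == 0:
        raise ParameterError("Otsu thresholding needs at least one pixel")
    hist = np.bincount(values, minlength=256)
    vmin, vmax = int(values.min()), int(values.max())
    if vmin == vmax:  # constant plane: its own value, zero variance
        return OtsuResult(vmin, 0.0, hist)
    # Exact integer arithmetic: sigma_b^2(t) = (S*c0 - N*s0)^2 / (N^2 c0 (N - c0))
    # with cumulative count c0 and cumulative sum s0.  Ties between thresholds
    # are frequently *exact*, so the smallest-maximizer rule needs fraction
    # comparison (cross-multiplication), not floating-point cumsums.
    counts = [int(c) for c in hist]
    total_n = int(values.size)
    total_s = int(values.sum())
    best_t, best_num, best_den = 0, 0, 1
    c0 = s0 = 0
    for t in range(256):
        c0 += counts[t]
        s0 += t * counts[t]
        if c0 == 0 or c0 == total_n:
            continue
        num = (total_s * c0 - total_n * s0) ** 2
        den = c0 * (total_n - c0)
        if num * best_den > best_num * den:  # strictly greater: first max wins
            best_t, best_num, best_den = t, num, den
    variance = best_num / (best_den * total_n**2)
    return OtsuResult(best_t, float(variance), hist)


def otsu_threshold(channel: ChannelImage | np.ndarray) -> OtsuResult:
    """Smallest threshold maximizing between-class variance on [0, 255].

    Accepts a :class:`ChannelImage` or a bare array of intensities (the
    masked-histogram mode of the cascade passes pixel subsets directly).
    """
    values = channel.pixels if isinstance(channel, ChannelImage) else np.asarray(channel)
    return _otsu_from_values(values)


def apply_threshold(channel: ChannelImage, t: int, keep: str = "above") -> BinaryMask:
    """Binarize: foreground is ``pixel > t`` (above) or ``pixel <= t`` (below)."""
    if not 0 <= int(t) <= 255 or int(t) != t:
        raise ParameterError(f"threshold must be an integer in [0, 255], got {t}")
    if keep not in ("above", "below"):
        raise ParameterError(f"keep must be 'above' or 'below', got {keep!r}")
    above = channel.pixels > t
    return BinaryMask(above if keep == "above" else ~above)


def _footprint(kernel_size: int, element: str) -> np.ndarray:
    if element == "square":
        return np.ones((kernel_size, kernel_size), dtype=bool)
    # filled ellipse (disk) inscribed in the kernel_size square
    radius = (kernel_size - 1) / 2.0
    yy, xx = np.mgrid[:kernel_size, :kernel_size]
    return (yy - radius) ** 2 + (xx - radius) ** 2 <= radius**2 + 1e-9


def morphological_open(
    mask: BinaryMask,
    kernel_size: int,
    iterations: int = 1,
    element: str = "square",
    mode: str = "staged",
) -> BinaryMask:
    """Erosion then dilation; removes objects smaller than the element.

    ``mode="staged"`` (default) erodes ``iterations`` times then dilates
    ``iterations`` times — the staged reading of "two iterations" of opening.
    ``mode="repeated"`` applies a full open ``iterations`` times (idempotent,
    so equivalent to a single open).
    """
    if kernel_size < 1:
        raise ParameterError(f"kernel_size must be >= 1, got {kernel_size}")
    if iterations < 1:
        raise ParameterError(f"iterations must be >= 1, got {iterations}")
    if element not in ("square", "ellipse"):
        raise ParameterError(f"element must be square|ellipse, got {element!r}")
    if mode not in ("staged", "repeated"):
        raise ParameterError(f"mode must be staged|repeated, got {mode!r}")
    fp = _footprint(kernel_size, element)
    fg = mask.bool
    if mode == "staged":
        out = ndimage.binary_erosion(fg, structure=fp, iterations=iterations)
        out = ndimage.binary_dilation(out, structure=fp, iterations=iterations)
    else:
        out = fg
        for _ in range(iterations):
            out = ndimage.binary_erosion(out, structure=fp)
            out = ndimage.binary_dilation(out, structure=fp)
    return BinaryMask(out)


def _resolve_keep(tag: str, round_index: int, q: np.ndarray, hi: np.ndarray, lo: np.ndarray) -> str:
    """Map a keep-side tag to 'above'/'below' for this round's split."""
    if tag == "auto":
        tag = "higher" if round_index == 0 else "majority"
    if tag in ("above", "below"):
        return tag
    if tag == "higher":  # class with higher mean hue (above by construction)
        return "above" if q[hi].mean() >= q[lo].mean() else "below"
    # majority: side retaining more pixels; ties keep the higher-hue side
    n_hi, n_lo = int(hi.sum()), int(lo.sum())
    if n_hi > n_lo:
        return "above"
    if n_lo > n_hi:
        return "below"
    return "above"


def triple_threshold_segment(
    image: RasterImage,
    config: SegmentationConfig | None = None,
    return_intermediates: bool = False,
) -> BinaryMask | tuple[BinaryMask, list[PassRecord]]:
    """Segment WBCs with the cascaded Gaussian + Otsu pipeline.

    Deterministic for a fixed image and config.  With
    ``return_intermediates=True`` also returns the per-round
    :class:`PassRecord` list (the per-round debugging figure analogue).
    """
    if config is None:
        config = SegmentationConfig()
    if image.channel_order != "RGB":
        raise SemanticError(
            f"triple_threshold_segment needs an RGB image, got {image.channel_order}"
        )
    hue = extract_channel(rgb_to_hsv(image), "H")
    active = np.ones(hue.shape, dtype=bool)
    smoothed = hue
    records: list[PassRecord] = []
    for round_index in range(config.n_passes):
        smoothed = gaussian_filter(smoothed, config.gaussian_kernel, config.sigma)
        q = np.rint(smoothed.pixels)
        q = np.where(q >= 180, q - 180, q)  # guard the hue wrap after rounding
        if not active.any():
            records.append(PassRecord(round_index + 1, 0, 0.0, None, BinaryMask(active)))
            continue
        pool = q[active] if config.histogram_mode == "masked" else q
        res = _otsu_from_values(pool)
        above = q > res.threshold
        hi = active & above
        lo = active & ~above
        significant = (
            res.between_class_variance > 0
            and hi.any()
            and lo.any()
            and (q[hi].mean() - q[lo].mean()) >= config.min_class_separation
        )
        if not significant:
            if round_index == 0:
                # no distinct high-hue population in the field => no WBC
                active = np.zeros_like(active)
            records.append(
                PassRecord(round_index + 1, res.threshold, res.between_class_variance,
                           None, BinaryMask(active.copy()))
            )
            continue
        side = _resolve_keep(config.keep_side_for(round_index), round_index, q, hi, lo)
        active = hi if side == "above" else lo
        records.append(
            PassRecord(round_index + 1, res.threshold, res.between_class_variance,
                       side, BinaryMask(active.copy()))
        )
    if active.any():
        opened = morphological_open(
            BinaryMask(active),
            config.opening_kernel,
            config.opening_iterations,
            config.opening_element,
            config.opening_mode,
        )
        active = opened.bool
    if config.min_object_area > 0 and active.any():
        labels, n = ndimage.label(active, structure=np.ones((3, 3), dtype=int))
        areas = ndimage.sum_labels(active, labels, index=np.arange(1, n + 1))
        for comp_id, area in enumerate(areas, start=1):
            if area < config.min_object_area:
                active[labels == comp_id] = False
    mask = BinaryMask(active)
    return (mask, records) if return_intermediates else mask


# ---------------------------------------------------------------------------
# contours

_MOORE_OFFSETS = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_MOORE_INDEX = {off: k for k, off in enumerate(_MOORE_OFFSETS)}


def _moore_trace(component: np.ndarray) -> np.ndarray:
    """Ordered outer-boundary pixels of one filled component (Moore tracing).

    Starts at the raster-first pixel (whose west neighbor is background) and
    walks the Moore neighborhood clockwise; terminates when the (pixel,
    backtrack) state recurs, which closes the boundary even on spurs.
    """
    rows, cols = np.nonzero(component)
    start = (int(rows[0]), int(cols[0]))
    n_pix = rows.size
    if n_pix == 1:
        return np.array([start, start, start], dtype=np.int64)
    h, w = component.shape
    boundary: list[tuple[int, int]] = []
    current, back = start, 0  # back: neighbor index of the backtrack pixel (west)
    initial_state = (current, back)
    for _ in range(8 * n_pix + 8):
        if not boundary or boundary[-1] != current:
            boundary.append(current)
        found = None
        for k in range(1, 9):
            idx = (back + k) % 8
            dr, dc = _MOORE_OFFSETS[idx]
            nb = (current[0] + dr, current[1] + dc)
            if 0 <= nb[0] < h and 0 <= nb[1] < w and component[nb]:
                found = (idx, nb)
                break
        if found is None:  # isolated pixel (handled above), defensive
            break
        idx, nb = found
        prev_dr, prev_dc = _MOORE_OFFSETS[(idx - 1) % 8]
        prev_pixel = (current[0] + prev_dr, current[1] + prev_dc)
        back = _MOORE_INDEX[(prev_pixel[0] - nb[0], prev_pixel[1] - nb[1])]
        current = nb
        if (current, back) == initial_state:
            break
    if boundary and len(boundary) > 1 and boundary[0] == boundary[-1]:
        boundary.pop()
    while len(boundary) < 3:
        boundary.append(boundary[-1])
    return np.array(boundary, dtype=np.int64)


def extract_contours(mask: BinaryMask) -> ContourSet:
    """One closed outer boundary polygon per 8-connected component.

    Inner holes are ignored (components are hole-filled before tracing);
    components are ordered by raster position of their first pixel.
    """
    fg = mask.bool
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    polys: list[np.ndarray] = []
    for comp_id in range(1, n + 1):
        component = ndimage.binary_fill_holes(labels == comp_id)
        polys.append(_moore_trace(component))
    return ContourSet(polys, mask.shape)


def draw_contours(
    image: RasterImage,
    contours: ContourSet,
    color: tuple[int, int, int] = (0, 255, 0),
    thickness: int = 1,
) -> RasterImage:
    """Overlay contour polygons on a copy of *image* (input unmodified)."""
    from skimage.draw import line as _line

    if contours.image_shape != image.shape:
        raise SemanticError(
            f"contour shape {contours.image_shape} != image shape {image.shape}"
        )
    if image.channels != 3:
        raise SemanticError("draw_contours needs a 3-channel image")
    if thickness < 1:
        raise ParameterError(f"thickness must be >= 1, got {thickness}")
    canvas = np.zeros(image.shape, dtype=bool)
    for poly in contours.contours:
        n = len(poly)
        for i in range(n):
            r0, c0 = poly[i]
            r1, c1 = poly[(i + 1) % n]
            rr, cc = _line(int(r0), int(c0), int(r1), int(c1))
            canvas[rr, cc] = True
    if thickness > 1:
        canvas = ndimage.binary_dilation(canvas, np.ones((thickness, thickness), bool))
    out = image.pixels.copy()
    out[canvas] = np.asarray(color, dtype=out.dtype)
    return RasterImage(out, image.channel_order)
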