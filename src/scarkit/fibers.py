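"""Collagen fiber organization analysis on Masson's-trichrome images.

Masson's trichrome renders collagen blue and cytoplasm/muscle red, so collagen
is located by the per-pixel blue/red intensity ratio.  Fiber orientation at a
collagen pixel is then estimated by weighted vector summation: every other
collagen pixel within a disk contributes a unit vector at twice the angle of
the connecting segment (angles of undirected fibers live on the half-circle,
so doubling maps them to the full circle where ordinary circular statistics
apply), weighted by its collagen signal strength.  Organization is summarized
as directional variance

    V = 1 - |sum w * exp(2i * theta)| / sum w,

the weighted circular variance of the doubled angles: V = 0 for perfectly
aligned fibers and V -> 1 for uniformly random orientations.

Four region-level metrics are produced: overall directional variance, mean
local directional variance (within a 50 px disk of each pixel), fiber density
(collagen-mask fraction), and mean blue intensity over collagen — evaluated in
the scar zone and in four flanking 500 x 500 px boxes (left/right x
distant/proximal), plus pooled distal and proximal pairs.

Angle convention: degrees, axial domain [0, 180), measured from the image
x-axis (columns) toward increasing rows; origin top-left, row-major pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.draw import polygon2mask

#: Below this total neighbour weight an orientation/variance is undefined.
CERTAINTY_FLOOR = 1e-9

#: Guard against division by zero in the blue/red ratio.
RATIO_EPS = 1e-6


class UndefinedMetricError(ValueError):
    """A statistic is undefined (zero total weight / no defined pixels)."""


# ---------------------------------------------------------------------------
# containers

@dataclass
class TrichromeImage:
    """RGB raster with channels normalized to [0, 1].

    Parameters
    ----------
    pixels : (H, W, 3) float array, values in [0, 1].
    pixel_size_um : physical size of one pixel in micrometres, if known.
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("expected an H x W x 3 RGB array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("channel values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @classmethod
    def from_file(cls, path: str | Path, pixel_size_um: float | None = None) -> "TrichromeImage":
        raw = iio.imread(path)
        if raw.ndim == 3 and raw.shape[2] == 4:  # drop alpha
            raw = raw[..., :3]
        arr = raw.astype(float)
        if raw.dtype == np.uint8:
            arr /= 255.0
        elif raw.dtype == np.uint16:
            arr /= 65535.0
        return cls(arr, pixel_size_um=pixel_size_um)

    def to_file(self, path: str | Path) -> None:
        iio.imwrite(path, (np.clip(self.pixels, 0, 1) * 255).round().astype(np.uint8))


@dataclass
class CollagenMap:
    """Collagen location (boolean mask) and signal strength (weights in [0, 1])."""

    mask: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.mask.shape != self.weight.shape:
            raise ValueError("mask and weight shapes differ")
        if np.any(self.weight[~self.mask] != 0):
            raise ValueError("weights must be zero off the mask")
        if self.weight.min() < 0 or self.weight.max() > 1:
            raise ValueError("weights must lie in [0, 1]")


@dataclass
class OrientationField:
    """Per-pixel axial orientation (deg, [0, 180)) with certainty in [0, 1].

    ``theta_deg`` and ``certainty`` are NaN where no orientation is defined;
    ``defined`` marks the valid pixels and ``weight`` carries the collagen
    signal strength used when pooling pixels into variance statistics.
    """

    theta_deg: np.ndarray
    certainty: np.ndarray
    defined: np.ndarray
    weight: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta_deg.shape


@dataclass(frozen=True)
class Box:
    """Axis-aligned half-open pixel box [row, row+height) x [col, col+width)."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("box must have positive size")
        if self.row < 0 or self.col < 0:
            raise ValueError("box anchor must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row + self.height), slice(self.col, self.col + self.width)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.row + self.height > shape[0] or self.col + self.width > shape[1]:
            raise ValueError("box exceeds image bounds")
        m = np.zeros(shape, dtype=bool)
        m[self.slices] = True
        return m

    def overlaps(self, other: "Box") -> bool:
        return not (
            self.row + self.height <= other.row
            or other.row + other.height <= self.row
            or self.col + self.width <= other.col
            or other.col + other.width <= self.col
        )


Region = Box | np.ndarray  # a Box, a boolean mask, or an (n, 2) polygon (row, col)

BOX_NAMES = ("LD", "LP", "RD", "RP")


@dataclass
class RegionLayout:
    """The five standard analysis regions of a section.

    ``boxes`` holds the four flanking squares LD (left distant), LP (left
    proximal), RD (right distant), RP (right proximal); ``scar`` is the scar
    zone as a box or polygon.  Boxes are square with side ``box_size``
    (500 px in the standard layout) and must not overlap pairwise.
    """

    scar: Region
    boxes: dict[str, Box]
    box_size: int = 500

    def __post_init__(self) -> None:
        missing = set(BOX_NAMES) - set(self.boxes)
        if missing:
            raise ValueError(f"layout missing boxes: {sorted(missing)}")
        for name, box in self.boxes.items():
            if box.height != self.box_size or box.width != self.box_size:
                raise ValueError(
                    f"box {name} is {box.height}x{box.width}, expected "
                    f"{self.box_size}x{self.box_size}"
                )
        names = list(self.boxes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if self.boxes[a].overlaps(self.boxes[b]):
                    raise ValueError(f"boxes {a} and {b} overlap")

    def region_mask(self, name: str, shape: tuple[int, int]) -> np.ndarray:
        if name == "S":
            return region_to_mask(self.scar, shape)
        return self.boxes[name].to_mask(shape)

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        for name in ("S",) + BOX_NAMES:
            self.region_mask(name, shape)


def region_to_mask(region: Region, shape: tuple[int, int]) -> np.ndarray:
    """Normalize a region (Box, boolean mask, or polygon vertices) to a mask."""
    if isinstance(region, Box):
        return region.to_mask(shape)
    arr = np.asarray(region)
    if arr.dtype == bool:
        if arr.shape != shape:
            raise ValueError("region mask shape differs from image shape")
        return arr
    if arr.ndim == 2 and arr.shape[1] == 2:  # polygon vertices (row, col)
        return polygon2mask(shape, arr)
    raise TypeError("region must be a Box, boolean mask, or (n, 2) polygon")


@dataclass(frozen=True)
class FiberParams:
    """Tunable parameters of the fiber pipeline (defaults per the analysis protocol)."""

    ratio_threshold: float = 1.0
    window_radius_px: int = 12
    local_radius_px: int = 50
    line_of_sight: bool = True
    certainty_power: float = 3.0


@dataclass
class FiberMetrics:
    """The four region-level organization metrics, all in [0, 1]."""

    region: str
    overall_directional_variance: float
    mean_local_directional_variance: float
    fiber_density: float
    blue_intensity: float
    n_pixels: int = 0


# ---------------------------------------------------------------------------
# operations

def segment_collagen(image: TrichromeImage, ratio_threshold: float = 1.0) -> CollagenMap:
    """Locate collagen by the per-pixel blue/red intensity ratio.

    A pixel is collagen when ``blue / (red + eps) > ratio_threshold`` (strict,
    so neutral gray is excluded at the default threshold of 1).  The weight is
    the blue-minus-red excess clipped to [0, 1], zero off the mask.
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be positive")
    red = image.pixels[..., 0]
    blue = image.pixels[..., 2]
    mask = blue / (red + RATIO_EPS) > ratio_threshold
    weight = np.clip(blue - red, 0.0, 1.0)
    weight[~mask] = 0.0
    return CollagenMap(mask=mask, weight=weight)


def _disk_offsets(radius: int) -> np.ndarray:
    rng = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(rng, rng, indexing="ij")
    return (dy * dy + dx * dx <= radius * radius)


def _shift(arr: np.ndarray, dy: int, dx: int, fill) -> np.ndarray:
    """arr translated so that out[c] = arr[c + (dy, dx)], edges filled."""
    out = np.full_like(arr, fill)
    h, w = arr.shape
    src_y = slice(max(0, dy), min(h, h + dy))
    src_x = slice(max(0, dx), min(w, w + dx))
    dst_y = slice(max(0, -dy), min(h, h - dy))
    dst_x = slice(max(0, -dx), min(w, w - dx))
    out[dst_y, dst_x] = arr[src_y, src_x]
    return out


def segment_cells(dy: int, dx: int) -> list[tuple[tuple[int, int], ...]]:
    """Interior lattice cells crossed by the segment (0,0) -> (dy,dx).

    The segment is sampled once per unit step of its dominant axis; each
    sample yields a group of one cell, or of the two tied cells when the
    minor coordinate falls exactly on a half-integer.  A group counts as
    occupied if any of its cells is (so 1-px diagonals see themselves).
    The construction commutes with the 8 axis symmetries, which keeps the
    orientation field exactly invariant under right-angle rotations.
    """
    n = max(abs(dy), abs(dx))
    groups: list[tuple[tuple[int, int], ...]] = []
    for k in range(1, n):
        y, x = k * dy / n, k * dx / n
        cells_y = _near_int(y)
        cells_x = _near_int(x)
        group = tuple((yy, xx) for yy in cells_y for xx in cells_x)
        groups.append(group)
    return groups


def _near_int(v: float, eps: float = 1e-9) -> tuple[int, ...]:
    r = round(v)
    if abs(v - r) < 0.5 - eps:
        return (int(r),)
    return (int(np.floor(v)), int(np.ceil(v)))


@lru_cache(maxsize=8)
def _offset_table(radius: int) -> tuple:
    """All disk offsets (center excluded) with phase and visibility groups."""
    entries = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            r2 = dy * dy + dx * dx
            if r2 == 0 or r2 > radius * radius:
                continue
            phase = complex(np.exp(2j * np.arctan2(dy, dx)))
            entries.append((dy, dx, phase, tuple(segment_cells(dy, dx))))
    return tuple(entries)


def estimate_orientation_field(
    cmap: CollagenMap,
    window_radius_px: int = 12,
    line_of_sight: bool = True,
    certainty_power: float = 3.0,
) -> OrientationField:
    """Axial orientation per collagen pixel by weighted vector summation.

    For collagen pixel ``c``, every other collagen pixel ``j`` within the
    disk of radius ``window_radius_px`` contributes a unit vector at twice
    the angle of the segment c->j, scaled by j's collagen weight.  With
    ``line_of_sight`` (default), j contributes only if the discrete segment
    from c to j lies entirely on the collagen mask; this blocks the spurious
    perpendicular signal of parallel fibers that pass near c without
    touching it, which otherwise inflates the measured variance of dense
    aligned fields.  The axial orientation is half the angle of the
    resultant; the certainty is the resultant length normalized by the total
    contributing weight.

    The field's statistical pooling weight is the collagen weight times
    ``certainty ** certainty_power``, so that pixels whose neighbourhood is
    orientationally ambiguous (fiber crossings, interiors of merged bundles)
    carry little weight in the variance statistics.
    """
    if window_radius_px < 1:
        raise ValueError("window_radius_px must be >= 1")
    if certainty_power < 0:
        raise ValueError("certainty_power must be non-negative")
    h, w = cmap.mask.shape
    theta = np.full((h, w), np.nan)
    certainty = np.full((h, w), np.nan)
    if not cmap.mask.any():
        return OrientationField(theta, certainty, np.zeros((h, w), bool), np.zeros((h, w)))

    mask = cmap.mask
    wmap = cmap.weight
    s_acc = np.zeros((h, w), dtype=complex)
    total = np.zeros((h, w))
    for dy, dx, phase, groups in _offset_table(window_radius_px):
        wj = _shift(wmap, dy, dx, 0.0)
        if line_of_sight and groups:
            vis = np.ones((h, w), dtype=bool)
            for group in groups:
                occupied = _shift(mask, *group[0], False)
                for cell in group[1:]:
                    occupied |= _shift(mask, *cell, False)
                vis &= occupied
            wj = wj * vis
        s_acc += phase * wj
        total += wj

    defined = mask & (total > CERTAINTY_FLOOR)
    r = np.clip(np.abs(s_acc) / np.maximum(total, CERTAINTY_FLOOR), 0.0, 1.0)
    certainty = np.where(defined, r, np.nan)
    theta = np.where(defined, np.degrees(np.angle(s_acc)) / 2.0 % 180.0, np.nan)
    weight_out = np.where(defined, wmap * r ** certainty_power, 0.0)
    return OrientationField(theta, certainty, defined, weight_out)


def directional_variance(orientations_deg, weights=None) -> float:
    """Weighted circular variance of axial angles on the doubled circle.

    ``V = 1 - |sum w exp(2i theta)| / sum w``; 0 for identical angles, 1 for
    an antipodal-on-the-doubled-circle (e.g. orthogonal equal-weight) pair or
    the uniform limit.

    Raises
    ------
    UndefinedMetricError
        If the total weight is zero (no data).
    """
    theta = np.radians(np.asarray(orientations_deg, dtype=float))
    if weights is None:
        w = np.ones_like(theta)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != theta.shape:
            raise ValueError("orientations and weights must have equal length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    total = w.sum()
    if not total > 0:
        raise UndefinedMetricError("directional variance undefined: zero total weight")
    resultant = np.abs(np.sum(w * np.exp(2j * theta))) / total
    return float(np.clip(1.0 - resultant, 0.0, 1.0))


def local_directional_variance(
    field: OrientationField, radius_px: int = 50
) -> tuple[np.ndarray, float]:
    """Directional variance within a disk around every defined pixel.

    Disks are truncated at image borders; normalization uses the weights that
    are actually inside.  Returns the per-pixel map (NaN where undefined) and
    its mean over defined pixels.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if not field.defined.any():
        raise UndefinedMetricError("no defined orientations in field")
    disk = _disk_offsets(radius_px).astype(float)
    theta = np.where(field.defined, np.radians(field.theta_deg), 0.0)
    w = np.where(field.defined, field.weight, 0.0)
    u = w * np.exp(2j * theta)
    num = np.abs(
        fftconvolve(u.real, disk, mode="same") + 1j * fftconvolve(u.imag, disk, mode="same")
    )
    den = fftconvolve(w, disk, mode="same")
    valid = field.defined & (den > CERTAINTY_FLOOR)
    vmap = np.full(field.shape, np.nan)
    vmap[valid] = np.clip(1.0 - num[valid] / den[valid], 0.0, 1.0)
    if not valid.any():
        raise UndefinedMetricError("no pixel has positive neighbourhood weight")
    return vmap, float(np.nanmean(vmap[valid]))


def overall_directional_variance(field: OrientationField, region: Region | None = None) -> float:
    """Single directional variance pooled over all defined pixels of a region."""
    sel = field.defined
    if region is not None:
        sel = sel & region_to_mask(region, field.shape)
    if not sel.any():
        raise UndefinedMetricError("region contains no defined orientations")
    return directional_variance(field.theta_deg[sel], field.weight[sel])


def fiber_density(cmap: CollagenMap, region: Region | None = None) -> float:
    """Collagen-mask pixel fraction of a region."""
    sel = (
        np.ones(cmap.mask.shape, bool)
        if region is None
        else region_to_mask(region, cmap.mask.shape)
    )
    n = int(sel.sum())
    if n == 0:
        raise ValueError("empty region")
    return float(cmap.mask[sel].mean())


def blue_intensity(
    image: TrichromeImage, cmap: CollagenMap, region: Region | None = None
) -> float:
    """Mean normalized blue-channel value over collagen pixels of a region."""
    sel = cmap.mask if region is None else cmap.mask & region_to_mask(region, cmap.mask.shape)
    if not sel.any():
        raise UndefinedMetricError("region contains no collagen pixels")
    return float(image.pixels[..., 2][sel].mean())


def _region_metrics(
    name: str,
    sel: np.ndarray,
    image: TrichromeImage,
    cmap: CollagenMap,
    field: OrientationField,
    local_map: np.ndarray,
) -> FiberMetrics:
    defined = field.defined & sel
    if not defined.any():
        raise UndefinedMetricError(f"region {name} contains no defined orientations")
    overall = directional_variance(field.theta_deg[defined], field.weight[defined])
    local_vals = local_map[defined]
    return FiberMetrics(
        region=name,
        overall_directional_variance=overall,
        mean_local_directional_variance=float(np.nanmean(local_vals)),
        fiber_density=float(cmap.mask[sel].mean()),
        blue_intensity=float(image.pixels[..., 2][cmap.mask & sel].mean()),
        n_pixels=int(sel.sum()),
    )


def analyze_section(
    image: TrichromeImage,
    layout: RegionLayout,
    params: FiberParams = FiberParams(),
) -> pd.DataFrame:
    """Full fiber pipeline over the five standard regions of a section.

    Segments collagen, estimates the orientation field and the local-variance
    map once over the whole image, then reports the four metrics for S, LD,
    LP, RD, RP plus the pooled distal (RD&LD) and proximal (RP&LP) pairs.
    Pooled rows concatenate per-pixel data of the two boxes; they are not
    averages of per-box metrics.
    """
    layout.validate_bounds(image.shape)
    cmap = segment_collagen(image, params.ratio_threshold)
    field = estimate_orientation_field(
        cmap, params.window_radius_px, params.line_of_sight, params.certainty_power
    )
    local_map, _ = local_directional_variance(field, params.local_radius_px)

    masks = {name: layout.region_mask(name, image.shape) for name in ("S",) + BOX_NAMES}
    masks["RD&LD"] = masks["RD"] | masks["LD"]
    masks["RP&LP"] = masks["RP"] | masks["LP"]
    rows = [
        _region_metrics(name, masks[name], image, cmap, field, local_map)
        for name in ("S", "LD", "LP", "RD", "RP", "RD&LD", "RP&LP")
    ]
    return pd.DataFrame([vars(m) for m in rows])


def metrics_to_csv(metrics: pd.DataFrame, path: str | Path) -> None:
    metrics.to_csv(path, index=False)


def load_layout(path: str | Path) -> RegionLayout:
    """Read a region layout from JSON.

    Expected shape::

        {"box_size": 500,
         "boxes": {"LD": [row, col], "LP": [...], "RD": [...], "RP": [...]},
         "scar": {"box": [row, col, height, width]}}

    ``scar`` may instead hold ``{"polygon": [[row, col], ...]}``.
    """
    import json

    with open(path) as fh:
        cfg = json.load(fh)
    size = int(cfg.get("box_size", 500))
    boxes = {
        name: Box(int(rc[0]), int(rc[1]), size, size) for name, rc in cfg["boxes"].items()
    }
    scar_cfg = cfg["scar"]
    if "box" in scar_cfg:
        r, c, h, w = (int(v) for v in scar_cfg["box"])
        scar: Region = Box(r, c, h, w)
    else:
        scar = np.asarray(scar_cfg["polygon"], dtype=float)
    return RegionLayout(scar=scar, boxes=boxes, box_size=size)
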