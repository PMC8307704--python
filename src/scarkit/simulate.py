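"""Seeded synthetic inputs with known ground truth.

No raw data from the source study were deposited, so every downstream stage
is exercised on simulations that state their own truth:

* **Fiber phantoms** — straight anti-aliased segments on a red/pink
  background, with axial orientations drawn from a doubled-angle von Mises
  distribution.  The concentration ``kappa`` fixes the theoretical
  directional variance ``1 - I1(kappa)/I0(kappa)`` in closed form, which is
  what the image pipeline must recover.
* **Section phantoms** — a composite image whose scar and four flanking
  boxes each carry their own orientation structure.
* **Morphometry tables** — truncated-Gaussian draws whose default moments
  are the study's printed group means ± SD.
* **Scar time-series** — exponential decay of area/length/width with
  lognormal noise over the 11 photographic observation days (the study gives
  no time-course model; this is acknowledged plumbing with a configurable
  early-healing effect for the 0.03 % NAC group).
* **Rater scores** — truth plus Gaussian noise, clipped to the scale and
  quantized to the 0.1 visual-analog-scale increment.

All generators take explicit seeds; identical spec + seed gives identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from skimage.draw import line_aa

from . import reference
from .fibers import BOX_NAMES, Box, RegionLayout, TrichromeImage
from .planimetry import OBSERVATION_DAYS, WIDTH_REGIONS, PlanimetryRecord

#: Collagen pixel color is (0.2, 0.3, blue_level); background is
#: (background_red_level, 0.4, 0.4).  The defaults put the blue = red
#: crossover of a blended boundary pixel exactly at coverage 0.5, so the
#: generator's density ground truth and the blue/red segmentation agree.
COLLAGEN_RG = (0.2, 0.3)
BACKGROUND_GB = (0.4, 0.4)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic trichrome field."""

    image_height_px: int = 384
    image_width_px: int = 384
    n_fibers: int = 700
    mean_orientation_deg: float = 90.0
    kappa: float = 2.0
    target_density: float = 0.35
    blue_level: float = 0.72
    background_red_level: float = 0.92
    fiber_thickness_px: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px < 64 or self.image_width_px < 64:
            raise ValueError("phantom images must be at least 64 px on a side")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not 0.0 <= self.target_density <= 1.0:
            raise ValueError("target_density must lie in [0, 1]")
        if self.fiber_thickness_px < 1:
            raise ValueError("fiber_thickness_px must be >= 1")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be non-negative")
        if self.n_fibers == 0 and self.target_density > 0:
            raise ValueError("cannot reach a positive density with zero fibers")
        if not 0.0 <= self.mean_orientation_deg < 180.0:
            raise ValueError("mean_orientation_deg must lie in [0, 180)")


@dataclass
class PhantomTruth:
    """Generator-side ground truth of a fiber phantom."""

    orientations_deg: np.ndarray
    realized_density: float
    theoretical_directional_variance: float
    collagen_mask: np.ndarray


def theoretical_directional_variance(kappa: float) -> float:
    """Closed-form circular variance of a von Mises sample: 1 - I1(k)/I0(k).

    Equals 1 at kappa = 0 (uniform orientations) and tends to 0 as kappa
    grows (perfect alignment).
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return float(1.0 - special.i1e(kappa) / special.i0e(kappa))


def _clip_segment(y0, x0, y1, x1, h, w):
    """Liang-Barsky clipping of a segment to [0, h-1] x [0, w-1]; None if outside."""
    dy, dx = y1 - y0, x1 - x0
    t0, t1 = 0.0, 1.0
    for p, q in ((-dy, y0), (dy, (h - 1) - y0), (-dx, x0), (dx, (w - 1) - x0)):
        if p == 0:
            if q < 0:
                return None
        else:
            t = q / p
            if p < 0:
                if t > t1:
                    return None
                t0 = max(t0, t)
            else:
                if t < t0:
                    return None
                t1 = min(t1, t)
    return (y0 + t0 * dy, x0 + t0 * dx, y0 + t1 * dy, x0 + t1 * dx)


def _render_fibers(h, w, centers, phis_rad, length, thickness):
    """Anti-aliased coverage map (max-combined) of equal-length fibers."""
    cov = np.zeros((h, w))
    if length <= 0 or len(phis_rad) == 0:
        return cov
    half = length / 2.0
    dirs_y, dirs_x = np.sin(phis_rad), np.cos(phis_rad)
    offsets = np.arange(thickness) - (thickness - 1) / 2.0
    for (yc, xc), dy, dx in zip(centers, dirs_y, dirs_x):
        ny, nx = dx, -dy  # unit normal
        for o in offsets:
            oy, ox = yc + o * ny, xc + o * nx
            seg = _clip_segment(oy - half * dy, ox - half * dx,
                                oy + half * dy, ox + half * dx, h, w)
            if seg is None:
                continue
            rr, cc, val = line_aa(
                int(round(seg[0])), int(round(seg[1])),
                int(round(seg[2])), int(round(seg[3])),
            )
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            rr, cc, val = rr[ok], cc[ok], val[ok]
            cov[rr, cc] = np.maximum(cov[rr, cc], val)
    return cov


def sample_axial_orientations(
    n: int, mean_deg: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Axial angles in [0, 180): von Mises on the doubled circle, halved back."""
    psi = rng.vonmises(np.radians(2.0 * mean_deg), kappa, size=n)
    return np.degrees(psi / 2.0) % 180.0


def generate_fiber_phantom(spec: PhantomSpec) -> tuple[TrichromeImage, PhantomTruth]:
    """Render a fiber phantom and its ground truth.

    Fiber length is solved from the target density through the Boolean-model
    coverage formula ``p = 1 - exp(-n L t / (H W))`` and refined by a few
    deterministic re-renders, so the realized collagen fraction (pixels with
    coverage > 0.5) lands within ~0.005 of the target.
    """
    h, w = spec.image_height_px, spec.image_width_px
    rng = np.random.default_rng(spec.seed)
    phis_deg = sample_axial_orientations(spec.n_fibers, spec.mean_orientation_deg,
                                         spec.kappa, rng)
    phis_rad = np.radians(phis_deg)
    centers = rng.uniform([0, 0], [h - 1, w - 1], size=(spec.n_fibers, 2))

    p, t = spec.target_density, spec.fiber_thickness_px
    if p > 0 and spec.n_fibers > 0:
        length = -np.log1p(-min(p, 0.999)) * h * w / (spec.n_fibers * t)
        length = float(np.clip(length, 2.0, np.hypot(h, w)))
    else:
        length = 0.0

    cov = _render_fibers(h, w, centers, phis_rad, length, t)
    realized = float((cov > 0.5).mean())
    for _ in range(4):
        if p <= 0 or abs(realized - p) <= 0.005 or not 0 < realized < 1:
            break
        length = float(np.clip(length * np.log1p(-min(p, 0.999)) / np.log1p(-realized),
                               2.0, np.hypot(h, w)))
        cov = _render_fibers(h, w, centers, phis_rad, length, t)
        realized = float((cov > 0.5).mean())

    # Color blending uses a sharpened alpha so that edge pixels inside the
    # mask stay close to the pure collagen color (keeps the mean blue
    # intensity of the mask within a few percent of blue_level) while the
    # blue = red crossover still falls exactly at coverage 0.5, where the
    # density ground truth is defined.
    a = np.clip((cov - 0.35) / 0.3, 0.0, 1.0)[..., None]
    collagen = np.array([COLLAGEN_RG[0], COLLAGEN_RG[1], spec.blue_level])
    background = np.array([spec.background_red_level, *BACKGROUND_GB])
    pixels = a * collagen + (1.0 - a) * background
    truth = PhantomTruth(
        orientations_deg=phis_deg,
        realized_density=realized,
        theoretical_directional_variance=theoretical_directional_variance(spec.kappa),
        collagen_mask=cov > 0.5,
    )
    return TrichromeImage(pixels), truth


# ---------------------------------------------------------------------------
# section phantom

def standard_section_layout(box_size: int = 500, gap: int = 20) -> RegionLayout:
    """LD, LP, scar, RP, RD laid out left to right with uniform gaps."""
    row = gap
    cols = {name: gap + i * (box_size + gap)
            for i, name in enumerate(("LD", "LP", "S", "RP", "RD"))}
    boxes = {n: Box(row, cols[n], box_size, box_size) for n in BOX_NAMES}
    return RegionLayout(scar=Box(row, cols["S"], box_size, box_size),
                        boxes=boxes, box_size=box_size)


def section_layout_shape(layout: RegionLayout) -> tuple[int, int]:
    """Smallest symmetric canvas that holds every region of a layout."""
    regions = [layout.boxes[n] for n in BOX_NAMES]
    if isinstance(layout.scar, Box):
        regions.append(layout.scar)
    pad_r = min(b.row for b in regions)
    pad_c = min(b.col for b in regions)
    return (max(b.row + b.height for b in regions) + pad_r,
            max(b.col + b.width for b in regions) + pad_c)


def generate_section_phantom(
    region_specs: dict[str, PhantomSpec],
    layout: RegionLayout,
    image_shape: tuple[int, int] | None = None,
) -> tuple[TrichromeImage, dict[str, PhantomTruth]]:
    """Composite section in which each region carries its own fiber structure.

    ``region_specs`` maps region names (S, LD, LP, RD, RP) to phantom specs;
    the spec image size is overridden by the region's box size.  The scar
    region must be a box for generation.
    """
    if not region_specs:
        raise ValueError("empty region map")
    unknown = set(region_specs) - {"S", *BOX_NAMES}
    if unknown:
        raise ValueError(f"unknown regions: {sorted(unknown)}")
    if not isinstance(layout.scar, Box):
        raise ValueError("section generation requires a box scar region")
    shape = image_shape or section_layout_shape(layout)
    layout.validate_bounds(shape)

    first = next(iter(region_specs.values()))
    background = np.array([first.background_red_level, *BACKGROUND_GB])
    pixels = np.broadcast_to(background, (*shape, 3)).copy()
    truths: dict[str, PhantomTruth] = {}
    for name, spec in region_specs.items():
        box = layout.scar if name == "S" else layout.boxes[name]
        sub = replace(spec, image_height_px=box.height, image_width_px=box.width)
        img, truth = generate_fiber_phantom(sub)
        pixels[box.slices] = img.pixels
        truths[name] = truth
    return TrichromeImage(pixels), truths


# ---------------------------------------------------------------------------
# morphometry tables

@dataclass
class MorphometrySimSpec:
    """Truncated-Gaussian sampler for the ten wound-geometry measurements.

    ``moments`` maps (group, day) to {measurement: (mean, sd)}.  Defaults come
    from the study's printed group summaries (:mod:`scarkit.reference`):
    CONT from the control column, NAC15/NAC45 from the pooled-NAC column, and
    NAC30 from its own day-7 column (pooled column at days 14/60, where no
    separate NAC30 summary was printed).  Values are truncated at zero;
    measurements are sampled independently (only marginal moments are known).
    """

    moments: dict[tuple[str, int], dict[str, tuple[float, float]]] = field(
        default_factory=lambda: default_morphometry_moments()
    )
    n_per_group: int = 6
    seed: int = 0
    enforce_depth_leq_dermis: bool = False

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        for cell, params in self.moments.items():
            for name, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {name} in {cell}")


def default_morphometry_moments() -> dict[tuple[str, int], dict[str, tuple[float, float]]]:
    src = reference.MEASUREMENT_MOMENTS
    out: dict[tuple[str, int], dict[str, tuple[float, float]]] = {}
    for day in reference.MORPHOMETRY_DAYS:
        for group in reference.STUDY_GROUPS:
            if group == "CONT":
                cell = ("CONT", day)
            elif group == "NAC30" and day == 7:
                cell = ("NAC30", 7)
            else:
                cell = ("gNAC", day)
            out[(group, day)] = dict(src[cell])
    return out


def _truncated_normal(mean, sd, size, rng):
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_morphometry_table(spec: MorphometrySimSpec) -> pd.DataFrame:
    """Long-format measurement table (animal, group, day, ten measurements)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for (group, day), params in sorted(spec.moments.items()):
        draws = {
            name: _truncated_normal(*params[name], size=spec.n_per_group, rng=rng)
            for name in reference.MEASUREMENTS
            if name in params
        }
        if spec.enforce_depth_leq_dermis and "D" in draws and "N" in draws:
            draws["D"] = np.minimum(draws["D"], draws["N"])
        for i in range(spec.n_per_group):
            row = {"animal": f"{group}-d{day}-{i:03d}", "group": group, "day": day}
            row.update({name: float(v[i]) for name, v in draws.items()})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scar time-series

@dataclass(frozen=True)
class ScarDecayParams:
    """Exponential-decay model of one group's scar dimensions.

    Initial values reflect a fresh 1.5 cm dorsal incision (area ~60 mm^2,
    length 15 mm, width ~4 mm); rates are per day and must be positive.
    """

    area0_mm2: float = 60.0
    length0_mm: float = 15.0
    width0_mm: float = 4.0
    area_rate: float = 0.05
    length_rate: float = 0.005
    width_rate: float = 0.05
    noise_sd: float = 0.15
    n_wounds: int = 6

    def __post_init__(self) -> None:
        if min(self.area_rate, self.length_rate, self.width_rate) <= 0:
            raise ValueError("decay rates must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_wounds < 1:
            raise ValueError("need at least one wound")


def default_group_params(nac30_boost: float = 1.6) -> dict[str, ScarDecayParams]:
    """Group decay parameters with a faster early decay for the 0.03 % group."""
    base = ScarDecayParams()
    fast = ScarDecayParams(
        area_rate=base.area_rate * nac30_boost,
        width_rate=base.width_rate * nac30_boost,
    )
    return {"CONT": base, "NAC15": base, "NAC30": fast, "NAC45": base}


def generate_scar_timeseries(
    group_params: dict[str, ScarDecayParams] | None = None,
    seed: int = 0,
    days: tuple[int, ...] = OBSERVATION_DAYS,
) -> list[PlanimetryRecord]:
    """Per-wound scar dimensions over the photographic observation days.

    Each dimension follows ``value0 * exp(-rate * day)`` times lognormal
    noise (exact closed form at ``noise_sd = 0``).
    """
    if not days:
        raise ValueError("empty day list")
    params = group_params if group_params is not None else default_group_params()
    rng = np.random.default_rng(seed)
    records: list[PlanimetryRecord] = []
    for group in sorted(params):
        gp = params[group]
        for i in range(gp.n_wounds):
            site = WIDTH_REGIONS[i % len(WIDTH_REGIONS)]
            for day in days:
                noise = np.exp(rng.normal(0.0, gp.noise_sd, size=3)) if gp.noise_sd > 0 \
                    else np.ones(3)
                records.append(PlanimetryRecord(
                    animal=f"{group}-{i:02d}",
                    site=site,
                    group=group,
                    day=day,
                    area_mm2=gp.area0_mm2 * np.exp(-gp.area_rate * day) * noise[0],
                    length_mm=gp.length0_mm * np.exp(-gp.length_rate * day) * noise[1],
                    width_mm=gp.width0_mm * np.exp(-gp.width_rate * day) * noise[2],
                ))
    return records


# ---------------------------------------------------------------------------
# rater scores

def generate_rater_scores(
    truth: pd.DataFrame,
    n_raters: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    scale: tuple[float, float] = (0.0, 3.0),
) -> pd.DataFrame:
    """Blinded-rater visual-analog scores: truth + noise, clipped, 0.1 steps.

    ``truth`` needs columns ``sample``, ``parameter``, ``value`` (an optional
    ``stain`` column is carried through).
    """
    if n_raters < 1:
        raise ValueError("need at least one rater")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    lo, hi = scale
    if not lo < hi:
        raise ValueError("scale range must be non-degenerate")
    required = {"sample", "parameter", "value"}
    if not required.issubset(truth.columns):
        raise ValueError(f"truth table needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in truth.iterrows():
        for rater in range(1, n_raters + 1):
            raw = rec["value"] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            score = round(float(np.clip(raw, lo, hi)), 1)
            row = {
                "sample": rec["sample"],
                "parameter": rec["parameter"],
                "rater": f"R{rater}",
                "score": score,
            }
            if "stain" in truth.columns:
                row["stain"] = rec["stain"]
            rows.append(row)
    return pd.DataFrame(rows)
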