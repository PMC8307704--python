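"""End-to-end orchestration: simulate -> fiber analysis -> morphometry ->
planimetry -> scores -> statistics, reproducibly per seed.

`run_all` produces a run directory of CSV tables (fiber metrics per region,
index tables, planimetry time-series, score summaries, decision-pipeline
results) plus a JSON log carrying the configuration, its hash, and stage
timings.  All randomness flows from the single config seed through fixed
per-stage offsets; no global random state is touched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import planimetry, scoring, simulate, stats
from . import morphometry as morpho
from .fibers import FiberParams, analyze_section
from .reference import MEASUREMENTS

INDEX_NAMES = ("SCI", "DCI", "WSI", "GCI", "GHI", "RHI", "MRI", "GRI")


@dataclass
class RunConfig:
    """Configuration of one full synthetic run."""

    seed: int = 0
    out_dir: str = "results/run"
    # fiber stage
    fiber: FiberParams = field(default_factory=FiberParams)
    box_size: int = 500
    gap: int = 20
    scar_kappa: float = 0.5
    flank_kappa: float = 5.0
    phantom_density: float = 0.35
    n_fibers: int = 700
    # morphometry stage
    n_per_group: int = 6
    # planimetry stage
    nac30_boost: float = 1.6
    # statistics
    alpha: float = 0.05
    # outputs
    write_images: bool = False
    write_heatmaps: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "fiber" in raw:
            raw["fiber"] = FiberParams(**raw["fiber"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _fiber_stage(cfg: RunConfig, out: Path) -> None:
    layout = simulate.standard_section_layout(box_size=cfg.box_size, gap=cfg.gap)
    base = dict(
        image_height_px=cfg.box_size, image_width_px=cfg.box_size,
        n_fibers=cfg.n_fibers, target_density=cfg.phantom_density,
    )
    specs = {}
    for i, name in enumerate(("S", "LD", "LP", "RD", "RP")):
        kappa = cfg.scar_kappa if name == "S" else cfg.flank_kappa
        specs[name] = simulate.PhantomSpec(
            **base, kappa=kappa, mean_orientation_deg=0.0, seed=cfg.seed + i
        )
    image, truths = simulate.generate_section_phantom(specs, layout)
    metrics = analyze_section(image, layout, cfg.fiber)
    metrics.to_csv(out / "fiber_metrics.csv", index=False)
    truth_rows = [
        {
            "region": name,
            "kappa": specs[name].kappa,
            "theoretical_directional_variance": t.theoretical_directional_variance,
            "realized_density": t.realized_density,
        }
        for name, t in truths.items()
    ]
    pd.DataFrame(truth_rows).to_csv(out / "fiber_truth.csv", index=False)
    if cfg.write_images:
        image.to_file(out / "section_phantom.png")
    if cfg.write_heatmaps:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .fibers import estimate_orientation_field, local_directional_variance, segment_collagen

        cmap = segment_collagen(image, cfg.fiber.ratio_threshold)
        fld = estimate_orientation_field(
            cmap, cfg.fiber.window_radius_px,
            cfg.fiber.line_of_sight, cfg.fiber.certainty_power,
        )
        vmap, _ = local_directional_variance(fld, cfg.fiber.local_radius_px)
        fig, axes = plt.subplots(2, 1, figsize=(10, 5))
        axes[0].imshow(vmap, vmin=0, vmax=1, cmap="magma")
        axes[0].set_title("local directional variance")
        axes[1].imshow(cmap.mask, cmap="gray")
        axes[1].set_title("collagen mask")
        for ax in axes:
            ax.axis("off")
        fig.savefig(out / "heatmaps.png", dpi=100)
        plt.close(fig)


def _morphometry_stage(cfg: RunConfig, out: Path) -> None:
    spec = simulate.MorphometrySimSpec(n_per_group=cfg.n_per_group, seed=cfg.seed + 101)
    table = simulate.generate_morphometry_table(spec)
    table.to_csv(out / "measurements.csv", index=False)
    per_sample, summary = morpho.index_table(table)
    per_sample.to_csv(out / "indices_per_sample.csv", index=False)
    summary.to_csv(out / "indices_summary.csv", index=False)
    merged = table.merge(per_sample, on=["animal", "group", "day"])
    results = stats.run_table(merged, list(MEASUREMENTS) + list(INDEX_NAMES), alpha=cfg.alpha)
    results.to_csv(out / "morphometry_stats.csv", index=False)


def _planimetry_stage(cfg: RunConfig, out: Path) -> None:
    records = simulate.generate_scar_timeseries(
        simulate.default_group_params(cfg.nac30_boost), seed=cfg.seed + 202
    )
    frame = planimetry.records_to_frame(records)
    frame.to_csv(out / "planimetry_records.csv", index=False)
    planimetry.build_timeseries(frame).to_csv(out / "planimetry_timeseries.csv", index=False)
    rows = []
    for day, day_df in frame.groupby("day"):
        for col in ("area_mm2", "length_mm", "width_mm"):
            sub = day_df[["group", col]].rename(columns={col: "value"})
            res = stats.run_endpoint(sub, alpha=cfg.alpha, endpoint=col, day=int(day))
            rows.append(res.to_row())
    pd.DataFrame(rows).to_csv(out / "planimetry_stats.csv", index=False)


def _scoring_stage(cfg: RunConfig, out: Path) -> None:
    rng = np.random.default_rng(cfg.seed + 303)
    samples = [f"S{i:02d}" for i in range(8)]
    truth = pd.DataFrame([
        {"sample": s, "parameter": p, "value": float(np.round(rng.uniform(0.5, 2.5), 1))}
        for s in samples
        for p in scoring.SCORE_PARAMETERS
    ])
    scores = simulate.generate_rater_scores(truth, noise_sd=0.2, seed=cfg.seed + 304)
    scores.to_csv(out / "scores.csv", index=False)
    scoring.aggregate_scores(scores).to_csv(out / "scores_summary.csv", index=False)


STAGES = {
    "fibers": _fiber_stage,
    "morphometry": _morphometry_stage,
    "planimetry": _planimetry_stage,
    "scores": _scoring_stage,
}


def run_all(config: RunConfig) -> Path:
    """Run every stage into ``config.out_dir``; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": config.to_dict(), "config_hash": config.digest(), "stages": {}}
    for name, stage in STAGES.items():
        t0 = time.perf_counter()
        try:
            stage(config, out)
        except Exception as exc:  # label failures with their stage
            log["stages"][name] = {"status": "error", "error": str(exc)}
            (out / "run_log.json").write_text(json.dumps(log, indent=1))
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        log["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return out
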