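"""Generate the synthetic study: section phantoms, morphometry tables,
scar time-series, and rater scores, all with known ground truth.

Writes results/analysis/inputs/ with one section phantom per harvest day
(scar disorder decreasing over days 3 -> 60 to mimic remodeling), a
measurement table sampled from the published group moments, the 11-day
planimetric series with the faster-healing 0.03% NAC group, and VAS scores
from three simulated raters.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scarkit import planimetry, scoring, simulate

OUT = Path("results/analysis/inputs")
SEED = 20210714  # study publication date, used as the base seed

#: scar disorder (von Mises kappa on doubled angles) per harvest day:
#: early scars are nearly random, day-60 scars partially reorganized.
SCAR_KAPPA = {3: 0.2, 7: 0.3, 14: 0.5, 60: 1.5}
FLANK_KAPPA = 5.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # --- section phantoms, one per harvest day -------------------------------
    layout = simulate.standard_section_layout()
    truth_rows = []
    for day_i, (day, kappa) in enumerate(sorted(SCAR_KAPPA.items())):
        specs = {}
        for i, name in enumerate(("S", "LD", "LP", "RD", "RP")):
            specs[name] = simulate.PhantomSpec(
                image_height_px=500, image_width_px=500,
                kappa=kappa if name == "S" else FLANK_KAPPA,
                mean_orientation_deg=0.0,
                seed=SEED + 10 * day_i + i,
            )
        image, truths = simulate.generate_section_phantom(specs, layout)
        image.to_file(OUT / f"section_day{day:02d}.png")
        for name, t in truths.items():
            truth_rows.append({
                "day": day, "region": name, "kappa": specs[name].kappa,
                "theory_directional_variance": t.theoretical_directional_variance,
                "realized_density": t.realized_density,
            })
    pd.DataFrame(truth_rows).to_csv(OUT / "section_truth.csv", index=False)
    print(f"wrote {len(SCAR_KAPPA)} section phantoms "
          f"(scar kappa {min(SCAR_KAPPA.values())}..{max(SCAR_KAPPA.values())})")

    # --- morphometry measurements -------------------------------------------
    table = simulate.generate_morphometry_table(
        simulate.MorphometrySimSpec(n_per_group=6, seed=SEED + 100))
    table.to_csv(OUT / "measurements.csv", index=False)
    print(f"wrote measurement table: {len(table)} sections "
          f"({table.group.nunique()} groups x {table.day.nunique()} days x 6)")

    # --- planimetric time-series --------------------------------------------
    records = simulate.generate_scar_timeseries(
        simulate.default_group_params(nac30_boost=1.6), seed=SEED + 200)
    planimetry.records_to_frame(records).to_csv(OUT / "planimetry_records.csv",
                                                index=False)
    print(f"wrote planimetry records: {len(records)} wound-days")

    # --- rater scores ---------------------------------------------------------
    rng = np.random.default_rng(SEED + 300)
    samples = [f"{g}-d{d}" for g in ("CONT", "NAC15", "NAC30", "NAC45")
               for d in (3, 7, 14, 60)]
    truth = pd.DataFrame([
        {"sample": s, "parameter": p, "value": float(np.round(rng.uniform(0.5, 2.5), 1))}
        for s in samples for p in scoring.SCORE_PARAMETERS
    ])
    scores = simulate.generate_rater_scores(truth, n_raters=3, noise_sd=0.2,
                                            seed=SEED + 301)
    scores.to_csv(OUT / "scores.csv", index=False)
    print(f"wrote {len(scores)} rater scores for {len(samples)} samples")


if __name__ == "__main__":
    main()
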