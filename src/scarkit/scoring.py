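"""Aggregation of blinded-rater visual-analog histology scores.

Three blinded raters scored each section for a panel of wound-healing
parameters (acute/chronic inflammation, granulation, fibroblast maturity,
collagen deposition, collagen orientation/morphology/maturity,
epithelialization, neovascularization) on a continuous 0–3 visual-analog
extension of the ordinal Abramov grades, quantized to 0.1; complete wound
closure was a separate binary call.  The human scoring act is out of scope —
this module validates, aggregates, and summarizes the score tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_SCALE = (0.0, 3.0)

SCORE_PARAMETERS = (
    "acute inflammation",
    "chronic inflammation",
    "granulation",
    "fibroblast maturity",
    "collagen deposition",
    "collagen orientation",
    "collagen morphology",
    "collagen maturity",
    "epithelialization",
    "neovascularization",
)


def validate_scores(
    scores: pd.DataFrame, scale: tuple[float, float] = DEFAULT_SCALE
) -> pd.DataFrame:
    """Check range and 0.1 quantization of a (sample, parameter, rater, score) table."""
    required = {"sample", "parameter", "rater", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    vals = scores["score"].to_numpy(dtype=float)
    lo, hi = scale
    if vals.size and (vals.min() < lo - 1e-9 or vals.max() > hi + 1e-9):
        raise ValueError("scores outside the scale range")
    if vals.size and not np.allclose(vals * 10, np.round(vals * 10), atol=1e-6):
        raise ValueError("scores must be quantized to 0.1 increments")
    return scores


def aggregate_scores(
    scores: pd.DataFrame, scale: tuple[float, float] = DEFAULT_SCALE
) -> pd.DataFrame:
    """Per-sample per-parameter mean ± SD across raters (rater count reported).

    Missing raters are tolerated; a single rater yields SD = NaN.
    """
    if scores.empty:
        raise ValueError("empty score table")
    validate_scores(scores, scale)
    out = (
        scores.groupby(["sample", "parameter"])["score"]
        .agg(mean="mean", sd="std", n_raters="count")
        .reset_index()
    )
    return out


def closure_rate(calls: pd.DataFrame, group_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Fraction of samples judged closed, by majority vote across raters.

    ``calls`` needs columns ``sample``, ``rater``, ``closed`` (bool).  Exact
    rater ties are unresolved: excluded from the rate with a warning.  If
    ``group_of`` maps sample ids to groups, one rate per group is returned;
    otherwise a single overall row labelled ``"all"``.
    """
    required = {"sample", "rater", "closed"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"closure table missing columns: {sorted(missing)}")
    if calls.empty:
        raise ValueError("empty closure table")

    votes = calls.groupby("sample")["closed"].agg(["sum", "count"])
    closed = votes["sum"] * 2 > votes["count"]
    open_ = votes["sum"] * 2 < votes["count"]
    tied = ~closed & ~open_
    if tied.any():
        warnings.warn(
            f"{int(tied.sum())} sample(s) with tied closure votes excluded", stacklevel=2
        )
    resolved = votes.index[~tied]
    rows = []
    groups = (
        pd.Series({s: group_of.get(s, "all") for s in resolved})
        if group_of
        else pd.Series("all", index=resolved)
    )
    for group in sorted(groups.unique()):
        samples = groups.index[groups == group]
        if len(samples) == 0:
            raise ValueError(f"group {group} has no resolved samples")
        rows.append({
            "group": group,
            "fraction_closed": float(closed.loc[samples].mean()),
            "n_samples": int(len(samples)),
            "n_unresolved": int(tied.reindex(samples, fill_value=False).sum()),
        })
    return pd.DataFrame(rows)
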