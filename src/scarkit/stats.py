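"""The study's group-pooling statistical decision pipeline.

For every endpoint and day the procedure is:

1. **Normality gate** — Shapiro–Wilk per group; the parametric branch is
   taken only if every compared group passes (p > alpha).
2. **Three-way comparison** of the NAC concentration groups (NAC15, NAC30,
   NAC45): one-way ANOVA with post-hoc Tukey when parametric, Kruskal–Wallis
   otherwise.
3. **Pooling rule** — if the three concentrations do not differ (omnibus
   p > alpha, strict), they are pooled into a single ``gNAC`` group.
4. **Final comparison** — pooled: gNAC vs CONT by two-sided t-test (or
   Mann–Whitney U); not pooled: NAC30 vs CONT by Tukey over all four groups
   (or Mann–Whitney U).

alpha = 0.05 throughout, matching the study; no correction across endpoints
or days is applied by default (a Benjamini–Hochberg helper is provided but
deliberately off, as the study applied none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_DEFAULT = 0.05
NAC_GROUPS = ("NAC15", "NAC30", "NAC45")
ALL_GROUPS = ("CONT",) + NAC_GROUPS


class DegenerateDataError(ValueError):
    """All values identical: test statistics are undefined."""


@dataclass
class ComparisonResult:
    """Full record of one endpoint-day decision path."""

    endpoint: str
    day: int | None
    branch: str                      # "parametric" | "nonparametric"
    three_group_p: float
    pooled: bool
    alpha: float
    tukey_p: dict[str, float] = field(default_factory=dict)
    gnac_vs_cont_p: float | None = None
    nac30_vs_cont_p: float | None = None

    def to_row(self) -> dict:
        return {
            "endpoint": self.endpoint, "day": self.day, "branch": self.branch,
            "three_group_p": self.three_group_p, "pooled": self.pooled,
            "gnac_vs_cont_p": self.gnac_vs_cont_p,
            "nac30_vs_cont_p": self.nac30_vs_cont_p, "alpha": self.alpha,
        }


def _as_groups(table: pd.DataFrame, value_col: str = "value") -> dict[str, np.ndarray]:
    return {
        g: sub[value_col].to_numpy(dtype=float)
        for g, sub in table.groupby("group")
    }


def normality_gate(groups: dict[str, np.ndarray], alpha: float = ALPHA_DEFAULT) -> str:
    """Shapiro–Wilk on each group; parametric only if every group passes.

    Groups with n < 3 cannot be tested: the nonparametric branch is taken
    with a warning.
    """
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3:
            warnings.warn(
                f"group {name} has n={len(vals)} < 3; falling back to the "
                "nonparametric branch", stacklevel=2,
            )
            return "nonparametric"
        if np.ptp(vals) == 0:  # Shapiro undefined on constants
            return "nonparametric"
        if sps.shapiro(vals).pvalue <= alpha:
            return "nonparametric"
    return "parametric"


def compare_nac_groups(
    groups: dict[str, np.ndarray], branch: str
) -> tuple[float, dict[str, float]]:
    """Omnibus comparison of the three NAC groups.

    Returns the omnibus p (ANOVA or Kruskal–Wallis) and, on the parametric
    branch, pairwise Tukey p-values keyed ``"A|B"``.
    """
    missing = [g for g in NAC_GROUPS if g not in groups or len(groups[g]) == 0]
    if missing:
        raise ValueError(f"missing NAC groups: {missing}")
    samples = [np.asarray(groups[g], dtype=float) for g in NAC_GROUPS]
    if np.ptp(np.concatenate(samples)) == 0:
        raise DegenerateDataError("all NAC values identical; omnibus test undefined")
    if branch == "parametric":
        omnibus = float(sps.f_oneway(*samples).pvalue)
        tk = sps.tukey_hsd(*samples)
        pairs = {
            f"{NAC_GROUPS[i]}|{NAC_GROUPS[j]}": float(tk.pvalue[i, j])
            for i in range(3) for j in range(i + 1, 3)
        }
        return omnibus, pairs
    omnibus = float(sps.kruskal(*samples).pvalue)
    return omnibus, {}


def pool_decision(omnibus_p: float, alpha: float = ALPHA_DEFAULT) -> bool:
    """Pool the NAC concentrations into gNAC iff omnibus p > alpha (strict)."""
    if not 0.0 <= omnibus_p <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    return omnibus_p > alpha


def pool_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Relabel NAC15/NAC30/NAC45 as gNAC."""
    out = table.copy()
    out.loc[out["group"].isin(NAC_GROUPS), "group"] = "gNAC"
    return out


def compare_two_groups(x: np.ndarray, y: np.ndarray, branch: str) -> float:
    """Two-sided t-test (Student, pooled variance) or Mann–Whitney U p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    if branch == "parametric":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("t-test needs n >= 2 per group")
        if np.ptp(np.concatenate([x, y])) == 0:
            raise DegenerateDataError("all values identical; t-test undefined")
        return float(sps.ttest_ind(x, y, equal_var=True).pvalue)
    if np.ptp(np.concatenate([x, y])) == 0:
        raise DegenerateDataError("all values identical; Mann–Whitney undefined")
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def run_endpoint(
    table: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    endpoint: str = "",
    day: int | None = None,
    value_col: str = "value",
) -> ComparisonResult:
    """Execute gate -> three-group test -> pool decision -> final comparison.

    ``table`` is long with columns ``group`` (CONT/NAC15/NAC30/NAC45) and
    ``value``.  Deterministic given the table.
    """
    groups = _as_groups(table, value_col)
    missing = [g for g in ALL_GROUPS if g not in groups]
    if missing:
        raise ValueError(f"missing groups: {missing}")
    branch = normality_gate(groups, alpha)
    omnibus, tukey_nac = compare_nac_groups(groups, branch)
    pooled = pool_decision(omnibus, alpha)
    result = ComparisonResult(
        endpoint=endpoint, day=day, branch=branch, three_group_p=omnibus,
        pooled=pooled, alpha=alpha, tukey_p=tukey_nac,
    )
    if pooled:
        gnac = np.concatenate([groups[g] for g in NAC_GROUPS])
        result.gnac_vs_cont_p = compare_two_groups(gnac, groups["CONT"], branch)
    else:
        if branch == "parametric":
            tk = sps.tukey_hsd(*(groups[g] for g in ALL_GROUPS))
            i30 = ALL_GROUPS.index("NAC30")
            result.nac30_vs_cont_p = float(tk.pvalue[0, i30])
            result.tukey_p.update({
                f"{ALL_GROUPS[i]}|{ALL_GROUPS[j]}": float(tk.pvalue[i, j])
                for i in range(4) for j in range(i + 1, 4)
            })
        else:
            result.nac30_vs_cont_p = compare_two_groups(
                groups["NAC30"], groups["CONT"], branch
            )
    return result


def run_table(
    table: pd.DataFrame,
    endpoints: list[str],
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Apply :func:`run_endpoint` to every endpoint column x day of a wide table."""
    rows = []
    for day, day_df in table.groupby("day"):
        for endpoint in endpoints:
            sub = day_df[["group", endpoint]].rename(columns={endpoint: "value"}).dropna()
            res = run_endpoint(sub, alpha=alpha, endpoint=endpoint, day=int(day))
            rows.append(res.to_row())
    return pd.DataFrame(rows)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; the study applied no correction)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out
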