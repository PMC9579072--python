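"""Descriptive biomass summaries: prey totals, feeding-threshold
exceedance, dominance rankings, and zone x period mean +/- CI tables.

Thresholds default to 60, 100 and 200 g/m2 wet weight: 60 g/m2 is the rough
minimum amphipod biomass for gray-whale feeding, 200 g/m2 captures extreme
concentrations.  Exceedance is computed over replicate-level values by
default (station-mean mode available), matching how replicate bubbles are
usually plotted.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .ancova import total_prey_table
from .simulate import PREY_GROUPS

__all__ = [
    "total_prey",
    "cutoff_percentages",
    "rank_dominants",
    "group_summary_ci",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (60.0, 100.0, 200.0)


def total_prey(table: pd.DataFrame) -> pd.DataFrame:
    """Per-grab total prey biomass (sum of the six diet groups).

    Echinoidea and the residual category are excluded by definition; a grab
    missing an explicit (possibly zero) row for any prey group is an error.
    """
    return total_prey_table(table)


def cutoff_percentages(
    table: pd.DataFrame,
    group: str = "Amphipoda",
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    level: str = "replicate",
) -> pd.DataFrame:
    """Percent of biomass values exceeding each threshold, by period x zone.

    ``level`` is "replicate" (default) or "station" (station means first).
    Returns rows (period, zone, design, threshold_g_per_m2,
    percent_exceeding, n_values); empty cells are omitted with a warning.
    """
    if any(t <= 0 for t in thresholds) or list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be positive and sorted ascending")
    if level not in ("replicate", "station"):
        raise ValueError(f"unknown level {level!r}")
    sub = table[table["taxon_group"] == group]
    if sub.empty:
        warnings.warn(f"no rows for group {group!r}", stacklevel=2)
        return pd.DataFrame(
            columns=["period", "zone", "design", "threshold_g_per_m2",
                     "percent_exceeding", "n_values"]
        )
    if level == "station":
        sub = (
            sub.groupby(["period", "zone", "design", "station_id"], observed=True,
                        as_index=False)["biomass_wet_g_per_m2"].mean()
        )
    rows = []
    for (period, zone, design), cell in sub.groupby(
        ["period", "zone", "design"], observed=True
    ):
        vals = cell["biomass_wet_g_per_m2"].to_numpy()
        if vals.size == 0:
            warnings.warn(f"empty cell ({period}, {zone}, {design}) omitted",
                          stacklevel=2)
            continue
        for t in thresholds:
            rows.append(
                {
                    "period": period,
                    "zone": zone,
                    "design": design,
                    "threshold_g_per_m2": t,
                    "percent_exceeding": 100.0 * float(np.mean(vals > t)),
                    "n_values": int(vals.size),
                }
            )
    out = pd.DataFrame(rows)
    # nested events: exceedance cannot increase with the threshold
    for _, cell in out.groupby(["period", "zone", "design"], observed=True):
        pct = cell.sort_values("threshold_g_per_m2")["percent_exceeding"].to_numpy()
        assert np.all(np.diff(pct) <= 1e-12)
    return out


def rank_dominants(
    table: pd.DataFrame,
    n: int = 5,
    design: str | None = "grid",
) -> pd.DataFrame:
    """Top-n taxon groups by mean biomass per period x zone, with SDs.

    Means and SDs are over replicate-level values; ties in the mean are
    broken alphabetically.  ``design`` restricts to one design type
    (default the detailed grid); pass None to pool.
    """
    sub = table if design is None else table[table["design"] == design]
    if sub["taxon_group"].nunique() < n:
        raise ValueError(
            f"table has {sub['taxon_group'].nunique()} groups; need >= {n}"
        )
    agg = (
        sub.groupby(["period", "zone", "taxon_group"], observed=True)[
            "biomass_wet_g_per_m2"
        ]
        .agg(mean_biomass="mean", sd_biomass=lambda x: x.std(ddof=1))
        .reset_index()
    )
    out = []
    for (period, zone), cell in agg.groupby(["period", "zone"], observed=True):
        top = cell.sort_values(
            ["mean_biomass", "taxon_group"], ascending=[False, True]
        ).head(n)
        top = top.assign(rank=np.arange(1, len(top) + 1))
        out.append(top)
    return pd.concat(out, ignore_index=True)[
        ["period", "zone", "rank", "taxon_group", "mean_biomass", "sd_biomass"]
    ]


def group_summary_ci(
    table: pd.DataFrame,
    group: str,
    level: float = 0.95,
) -> pd.DataFrame:
    """Mean and t-based CI of untransformed biomass per period x zone x design.

    ``group`` may be a taxon group or "total_prey".  Cells with a single
    value report the mean with an undefined (NaN) CI.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if group == "total_prey":
        sub = total_prey_table(table)
    else:
        sub = table[table["taxon_group"] == group]
        if sub.empty:
            raise ValueError(f"no rows for group {group!r}")
    rows = []
    for (period, zone, design), cell in sub.groupby(
        ["period", "zone", "design"], observed=True
    ):
        vals = cell["biomass_wet_g_per_m2"].to_numpy()
        n = vals.size
        mean = float(np.mean(vals))
        if n >= 2:
            half = float(
                stats.t.ppf(0.5 + level / 2.0, n - 1) * np.std(vals, ddof=1) / math.sqrt(n)
            )
            lo, hi, defined = mean - half, mean + half, True
        else:
            lo = hi = float("nan")
            defined = False
        rows.append(
            {
                "period": period,
                "zone": zone,
                "design": design,
                "n": n,
                "mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "ci_defined": defined,
            }
        )
    return pd.DataFrame(rows)
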