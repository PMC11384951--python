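"""Distribution-comparison and outcome statistics.

Two-sample Kolmogorov-Smirnov statistic and Hellinger distance compare the
arms' exit-day distributions; daily exit curves and per-day medians of the
last recorded severity score summarize outcomes; a two-factor (arm, time)
Type-2 ANOVA on the last recorded severity of alive leavers tests the arm
effect while adjusting for exit timing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .cohort import EXIT_ALIVE, EXIT_DEAD, EXIT_IN_STUDY

DEFAULT_DAY_CUTOFF = 11


def ks_statistic(sample_a, sample_b) -> float:
    """Two-sample KS statistic: sup |F_a(x) - F_b(x)| over the pooled sample."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(sps.ks_2samp(a, b, method="asymp").statistic)


def hellinger_distance(density_f, density_g) -> float:
    """Hellinger distance between two binned densities on a shared grid.

    ``D_H = sqrt(0.5 * sum_i (sqrt(f_i) - sqrt(g_i))^2)`` for probability
    masses summing to 1; bounded in [0, 1], attaining 1 exactly on disjoint
    supports and 0 on identical densities.
    """
    f = np.asarray(density_f, dtype=float)
    g = np.asarray(density_g, dtype=float)
    if f.shape != g.shape:
        raise ValueError("densities must share one bin grid")
    if np.any(f < 0) or np.any(g < 0):
        raise ValueError("densities must be nonnegative")
    for name, d in (("f", f), ("g", g)):
        if not np.isclose(d.sum(), 1.0, atol=1e-6):
            raise ValueError(f"density {name} must sum to 1 (got {d.sum()!r})")
    return float(np.sqrt(0.5 * np.sum((np.sqrt(f) - np.sqrt(g)) ** 2)))


def patient_exits(states: pd.DataFrame) -> pd.DataFrame:
    """Per-patient exit summary from a wide state-vector table."""
    last = states.sort_values("day").groupby("patient_id").tail(1)
    out = last[["patient_id", "arm", "day", "exit_status", "sofa_total"]].rename(
        columns={"day": "exit_day", "sofa_total": "last_sofa"}
    )
    max_day = int(states["day"].max())
    bad = out[(out["exit_status"] == EXIT_IN_STUDY) & (out["exit_day"] < max_day)]
    if len(bad):
        raise ValueError(
            f"patients with no exit record and no max-day truncation: "
            f"{sorted(bad['patient_id'])[:5]}"
        )
    return out.reset_index(drop=True)


def exit_curves(states: pd.DataFrame) -> pd.DataFrame:
    """Daily and cumulative alive/dead exit counts per arm.

    One row per (arm, day) over the full day range with daily exit counts
    and cumulative curves; feeds the KS / Hellinger comparison of exit-day
    distributions.
    """
    exits = patient_exits(states)
    max_day = int(states["day"].max())
    grid = pd.MultiIndex.from_product(
        [sorted(exits["arm"].unique()), range(1, max_day + 1)],
        names=["arm", "day"],
    )
    rows = []
    for status, name in ((EXIT_ALIVE, "alive"), (EXIT_DEAD, "dead")):
        sub = exits[exits["exit_status"] == status]
        counts = sub.groupby(["arm", "exit_day"]).size()
        counts.index.names = ["arm", "day"]
        rows.append(counts.reindex(grid, fill_value=0).rename(f"exits_{name}"))
    curve = pd.concat(rows, axis=1).reset_index()
    for name in ("alive", "dead"):
        curve[f"cum_{name}"] = curve.groupby("arm")[f"exits_{name}"].cumsum()
    return curve


def exit_day_samples(
    states: pd.DataFrame, status: str = EXIT_ALIVE
) -> dict[str, np.ndarray]:
    """Per-arm exit-day samples for a given exit status."""
    exits = patient_exits(states)
    sub = exits[exits["exit_status"] == status]
    return {
        arm: group["exit_day"].to_numpy(dtype=float)
        for arm, group in sub.groupby("arm")
    }


def binned_density(sample, bin_edges) -> np.ndarray:
    """Histogram of a sample as probability masses on the given bins."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("cannot bin an empty sample")
    counts, _ = np.histogram(sample, bins=bin_edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("sample lies entirely outside the bin grid")
    return counts / total


def compare_exit_distributions(
    states: pd.DataFrame, status: str = EXIT_ALIVE
) -> dict:
    """KS and Hellinger comparison of the two arms' exit-day distributions.

    Exit days are per-patient samples; the Hellinger density uses integer-day
    bins spanning the union support.
    """
    samples = exit_day_samples(states, status)
    if len(samples) != 2:
        raise ValueError("need exits in exactly two arms to compare")
    (arm_a, a), (arm_b, b) = sorted(samples.items())
    lo = int(min(a.min(), b.min()))
    hi = int(max(a.max(), b.max()))
    edges = np.arange(lo - 0.5, hi + 1.5, 1.0)
    return {
        "status": status,
        "arms": [arm_a, arm_b],
        "n": [int(a.size), int(b.size)],
        "ks": ks_statistic(a, b),
        "hellinger": hellinger_distance(
            binned_density(a, edges), binned_density(b, edges)
        ),
    }


def last_sofa_by_day(
    states: pd.DataFrame,
    status: str = EXIT_ALIVE,
    day_cutoff: int = DEFAULT_DAY_CUTOFF,
) -> pd.DataFrame:
    """Median last-recorded severity total per (arm, exit day) for leavers.

    Days before the cutoff with no leavers keep an explicit null median.
    """
    exits = patient_exits(states)
    sub = exits[(exits["exit_status"] == status) & (exits["exit_day"] < day_cutoff)]
    grid = pd.MultiIndex.from_product(
        [sorted(exits["arm"].unique()), range(1, day_cutoff)],
        names=["arm", "day"],
    )
    med = (
        sub.groupby(["arm", "exit_day"])["last_sofa"]
        .median()
        .rename("median_last_sofa")
    )
    med.index.names = ["arm", "day"]
    counts = sub.groupby(["arm", "exit_day"]).size().rename("n")
    counts.index.names = ["arm", "day"]
    out = pd.concat([med.reindex(grid), counts.reindex(grid, fill_value=0)], axis=1)
    return out.reset_index()


def anova_group_time(
    records: pd.DataFrame,
    typ: int = 2,
    time_as_category: bool = False,
) -> pd.DataFrame:
    """Two-factor ANOVA of last severity on arm and exit day via OLS.

    Fits the additive model ``last_sofa ~ group + time`` by ordinary least
    squares and decomposes variance with Type-2 sums of squares (each factor
    adjusted for the other); Type 1 (sequential) is available via ``typ``.
    Time enters as a continuous covariate by default.

    ``records`` needs columns group, day, last_sofa.
    """
    df = records.rename(columns={"arm": "group", "exit_day": "day"}).copy()
    for col in ("group", "day", "last_sofa"):
        if col not in df.columns:
            raise ValueError(f"records missing column {col!r}")
    if df["group"].nunique() < 2:
        raise ValueError("factor 'group' has a single level")
    if df["day"].nunique() < 2:
        raise ValueError("factor 'time' has a single level")
    time_term = "C(day)" if time_as_category else "day"
    model = smf.ols(f"last_sofa ~ C(group) + {time_term}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=typ)
    table = table.rename(
        index={"C(group)": "group", "C(day)": "time", "day": "time"}
    )
    return table
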