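"""Statistical battery on subject-level metric tables.

* Bonferroni-corrected paired t-tests between adjacent postures at one
  timepoint (family = the four contrasts within a tissue/channel: baseline↔
  walk, walk↔stand, stand↔end-supine, baseline↔end-supine).
* Two-way repeated-measures ANOVA (tissue × bed rest) on a kinetic metric,
  with Bonferroni pairwise post hocs only when the interaction is
  significant.  With two 2-level within factors sphericity holds
  automatically, so no epsilon correction is applied.
* Ordinary least-squares simple regression (slope, r²).

Tables are long-format DataFrames with columns ``subject, timepoint,
tissue, channel, metric, value`` (one row per combination).  Paired
analyses drop subjects missing either member of a pair and log the drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .protocol import ADJACENT_TRANSITIONS

log = logging.getLogger("nirskinetics")

TABLE_COLUMNS = ("subject", "timepoint", "tissue", "channel", "metric", "value")


@dataclass(frozen=True)
class StatResult:
    """One hypothesis test with raw and familywise-adjusted p-values."""

    comparison: str
    n: int
    mean_difference: float | None
    statistic: float
    p_raw: float
    p_adjusted: float
    family_size: int
    method: str


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"metric table missing columns {sorted(missing)}")
    keys = ["subject", "timepoint", "tissue", "channel", "metric"]
    dup = table.duplicated(subset=keys)
    if dup.any():
        raise ValueError(f"metric table has {int(dup.sum())} duplicate rows over {keys}")
    return table


def _bonferroni(p: float, family: int) -> float:
    return float(min(1.0, p * family))


def paired_adjacent_tests(
    table: pd.DataFrame, timepoint: str = "PRE"
) -> list[StatResult]:
    """Paired t-tests between adjacent postures, Bonferroni family of four.

    Expects per-segment plateau metrics named ``plateau_<segment>`` in the
    table (last-minute means, baseline-referenced or not — paired
    differences are invariant to a common reference).
    """
    validate_table(table)
    sub = table[table["timepoint"] == timepoint]
    results: list[StatResult] = []
    family = len(ADJACENT_TRANSITIONS)
    for (tissue, channel), grp in sub.groupby(["tissue", "channel"], sort=True):
        wide = grp.pivot(index="subject", columns="metric", values="value")
        for seg_a, seg_b in ADJACENT_TRANSITIONS:
            cols = (f"plateau_{seg_a}", f"plateau_{seg_b}")
            if not all(c in wide.columns for c in cols):
                continue
            pair = wide[list(cols)].dropna()
            n_dropped = len(wide) - len(pair)
            if n_dropped:
                log.info(
                    "%s/%s %s->%s: dropped %d subjects missing a pair member",
                    tissue, channel, seg_a, seg_b, n_dropped,
                )
            if len(pair) < 2:
                log.warning(
                    "%s/%s %s->%s skipped: fewer than 2 complete pairs",
                    tissue, channel, seg_a, seg_b,
                )
                continue
            diff = pair[cols[1]] - pair[cols[0]]
            if np.allclose(diff, 0):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = sps.ttest_rel(pair[cols[1]], pair[cols[0]])
            results.append(
                StatResult(
                    comparison=f"{tissue}/{channel}: {seg_a} vs {seg_b}",
                    n=len(pair),
                    mean_difference=float(diff.mean()),
                    statistic=float(t_stat),
                    p_raw=float(p),
                    p_adjusted=_bonferroni(float(p), family),
                    family_size=family,
                    method="paired t, Bonferroni",
                )
            )
    return results


def rm_anova_tissue_by_bedrest(
    table: pd.DataFrame, metric: str, alpha: float = 0.05
) -> dict[str, StatResult]:
    """Two-way repeated-measures ANOVA (tissue × bed rest) on one metric.

    Subjects without the complete 2×2 cell set are dropped (logged).
    Returns the two main effects and the interaction; Bonferroni-adjusted
    pairwise post hocs are added under ``"posthoc:<label>"`` keys only when
    the interaction p-value is below ``alpha``.
    """
    validate_table(table)
    sub = table[table["metric"] == metric].copy()
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present in table")
    counts = sub.groupby("subject")["value"].count()
    complete = counts[counts == 4].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        log.info("rm_anova %s: dropped incomplete subjects %s", metric, dropped)
    sub = sub[sub["subject"].isin(complete)]
    if sub["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects with complete 2x2 data")

    if np.ptp(sub["value"].to_numpy()) == 0:
        # degenerate: no variation anywhere, every effect is exactly null
        return {
            key: StatResult(
                comparison=f"{metric}: {key}", n=int(sub["subject"].nunique()),
                mean_difference=None, statistic=0.0, p_raw=1.0, p_adjusted=1.0,
                family_size=1, method="two-way RM-ANOVA",
            )
            for key in ("tissue", "bed_rest", "interaction")
        }

    aov = pg.rm_anova(
        data=sub, dv="value", within=["tissue", "timepoint"],
        subject="subject", detailed=True,
    )
    def _p(row) -> float:
        return float(row["p_unc"] if "p_unc" in row else row["p-unc"])

    out: dict[str, StatResult] = {}
    labels = {"tissue": "tissue", "timepoint": "bed_rest",
              "tissue * timepoint": "interaction"}
    for _, row in aov.iterrows():
        key = labels.get(row["Source"])
        if key is None:
            continue
        out[key] = StatResult(
            comparison=f"{metric}: {key}",
            n=int(sub["subject"].nunique()),
            mean_difference=None,
            statistic=float(row["F"]),
            p_raw=_p(row),
            p_adjusted=_p(row),  # omnibus: no family correction
            family_size=1,
            method="two-way RM-ANOVA",
        )
    if out["interaction"].p_raw < alpha:
        ph = pg.pairwise_tests(
            data=sub, dv="value", within=["tissue", "timepoint"],
            subject="subject", padjust="bonf",
        )
        inter = ph[ph["Contrast"].str.contains("\\*")]
        family = max(len(inter), 1)
        for _, row in inter.iterrows():
            level = row.get("tissue", row.get("timepoint", ""))
            label = f"posthoc:{level} {row['A']} vs {row['B']}"
            p_corr = row.get("p_corr", np.nan)
            p_adj = float(p_corr) if pd.notna(p_corr) else _p(row)
            out[label] = StatResult(
                comparison=f"{metric}: {label}",
                n=int(sub["subject"].nunique()),
                mean_difference=None,
                statistic=float(row["T"]),
                p_raw=_p(row),
                p_adjusted=p_adj,
                family_size=family,
                method="paired t post hoc, Bonferroni",
            )
    return out


def pre_post_tests(table: pd.DataFrame, metric: str) -> list[StatResult]:
    """Plain paired t-tests PRE vs POST within each tissue for one metric."""
    validate_table(table)
    sub = table[table["metric"] == metric]
    results = []
    for (tissue, channel), grp in sub.groupby(["tissue", "channel"], sort=True):
        wide = grp.pivot(index="subject", columns="timepoint", values="value").dropna()
        if len(wide) < 2 or not {"PRE", "POST"} <= set(wide.columns):
            continue
        t_stat, p = sps.ttest_rel(wide["POST"], wide["PRE"])
        results.append(
            StatResult(
                comparison=f"{tissue}/{channel}/{metric}: POST vs PRE",
                n=len(wide),
                mean_difference=float((wide["POST"] - wide["PRE"]).mean()),
                statistic=float(t_stat),
                p_raw=float(p),
                p_adjusted=float(p),
                family_size=1,
                method="paired t",
            )
        )
    return results


def simple_regression(x, y) -> tuple[float, float]:
    """OLS slope and coefficient of determination of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need at least 3 finite (x, y) pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)
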