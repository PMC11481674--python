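"""Hierarchical aggregation and the significance-test battery.

Cells are averaged within biological replicates, replicate means within
conditions; the replicate means — not the cells — are the observations of
the one-way ANOVA (cells within one culture are pseudoreplicates).
Normality (Shapiro-Wilk) and variance homogeneity (Levene) are checked
before the ANOVA; pairwise differences use Tukey's honestly significant
difference (Tukey-Kramer for unequal replicate counts), mapped to the
conventional star labels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("cortiquant")

STAR_LEVELS = [(0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*")]


@dataclass
class TestReport:
    """Outcome of one statistical test."""

    name: str
    statistic: float
    df: tuple | None
    pvalue: float
    pairwise: pd.DataFrame | None = None    # Tukey: pair, diff, p_adj, stars
    notes: list[str] = field(default_factory=list)


def aggregate(
    measurements: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    parameter: str = "pm_cytosol_ratio",
    channel: str | None = None,
) -> pd.DataFrame:
    """Per-replicate summaries of a per-cell parameter.

    ``measurements`` is a measurement table; ``annotations`` maps
    field_id -> (condition, replicate) when those columns are not already
    present. Cells flagged degenerate and cells with a non-finite
    parameter (e.g. the +inf ratio sentinel) are excluded with a logged
    count. Returns one row per (condition, replicate): n_cells,
    mean/sd of the parameter and mean cell area.
    """
    df = measurements.copy()
    if annotations is not None:
        df = df.merge(annotations, on="field_id", how="left",
                      suffixes=("", "_ann"))
        for c in ("condition", "replicate"):
            if c + "_ann" in df.columns:
                df[c] = df[c].fillna(df.pop(c + "_ann")) if c in df else \
                    df.pop(c + "_ann")
    if "condition" not in df.columns or "replicate" not in df.columns:
        raise ValueError("measurements must carry condition and replicate "
                         "annotations")
    if channel is not None:
        df = df[df["channel"] == channel]
    if "degenerate" in df.columns:
        df = df[~df["degenerate"].astype(bool)]
    n0 = len(df)
    df = df[np.isfinite(df[parameter])]
    if len(df) < n0:
        logger.info("aggregate: excluded %d cells with non-finite %s",
                    n0 - len(df), parameter)
    if df.empty:
        raise ValueError("no cells left to aggregate")

    rows = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        rows.append({
            "condition": cond, "replicate": rep, "n_cells": len(grp),
            "mean_ratio": float(grp[parameter].mean()),
            "sd_ratio": float(grp[parameter].std(ddof=1)) if len(grp) > 1
            else 0.0,
            "mean_area": float(grp["area_um2"].mean())
            if "area_um2" in grp else float("nan"),
        })
    return pd.DataFrame(rows)


def condition_summary(replicate_summaries: pd.DataFrame) -> pd.DataFrame:
    """Condition mean +/- SD over *replicate means* (the plotted statistic)."""
    rows = []
    for cond, grp in replicate_summaries.groupby("condition", sort=True):
        rows.append({
            "condition": cond,
            "n_replicates": len(grp),
            "n_cells": int(grp["n_cells"].sum()),
            "mean_ratio": float(grp["mean_ratio"].mean()),
            "sd_ratio": float(grp["mean_ratio"].std(ddof=1))
            if len(grp) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def shapiro_wilk(sample) -> TestReport:
    """Shapiro-Wilk normality test (Royston approximation), 3 <= n <= 50."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 50:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 50, got n={len(x)}")
    res = sps.shapiro(x)
    return TestReport("shapiro-wilk", float(res.statistic), None,
                      float(res.pvalue))


def levene(groups, center: str = "mean") -> TestReport:
    """Levene's homogeneity-of-variance test.

    ``center="mean"`` is the classic Levene test (one-way ANOVA on
    absolute deviations from the group mean); ``center="median"`` is the
    Brown-Forsythe variant.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Levene needs >= 2 groups with n >= 2 each")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    k = len(groups)
    N = sum(len(g) for g in groups)
    centers = [np.mean(g) if center == "mean" else np.median(g)
               for g in groups]
    if all(np.allclose(g, c) for g, c in zip(groups, centers)):
        # no within-group spread at all: trivially homogeneous
        return TestReport("levene", 0.0, (k - 1, N - k), 1.0)
    stat, p = sps.levene(*groups, center=center)
    return TestReport("levene", float(stat), (k - 1, N - k), float(p))


def one_way_anova(groups) -> TestReport:
    """One-way fixed-effects ANOVA; observations are replicate means."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with n >= 2 each")
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups)
    if np.allclose(grand, grand[0]):
        # identical constant groups: no between-group signal
        return TestReport("one-way-anova", 0.0, (k - 1, N - k), 1.0)
    stat, p = sps.f_oneway(*groups)
    return TestReport("one-way-anova", float(stat), (k - 1, N - k), float(p))


def tukey_hsd(groups, labels: list[str] | None = None) -> TestReport:
    """All-pairwise Tukey HSD after one-way ANOVA.

    Adjusted p-values come from the studentized-range distribution;
    unequal group sizes use the Tukey-Kramer form. The report's pairwise
    table carries the mean difference, adjusted p and star label per pair.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Tukey HSD needs >= 2 groups with n >= 2 each")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    res = sps.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        p = float(res.pvalue[i, j])
        rows.append({
            "group_a": labels[i], "group_b": labels[j],
            "mean_diff": float(np.mean(groups[j]) - np.mean(groups[i])),
            "p_adj": p, "stars": significance_stars(p),
        })
    pairwise = pd.DataFrame(rows)
    p_min = float(pairwise["p_adj"].min())
    return TestReport("tukey-hsd", float("nan"), None, p_min,
                      pairwise=pairwise)


def significance_stars(p: float) -> str:
    """Conventional star label with inclusive thresholds.

    '****' for p <= 1e-4, '***' for p <= 1e-3, '**' for p <= 0.01,
    '*' for p <= 0.05, 'ns' above.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    for thr, label in STAR_LEVELS:
        if p <= thr:
            return label
    return "ns"


def run_battery(
    replicate_summaries: pd.DataFrame,
    parameter: str = "mean_ratio",
    alpha: float = 0.05,
    levene_center: str = "mean",
) -> list[TestReport]:
    """The full test battery on replicate means grouped by condition.

    Shapiro-Wilk per condition, Levene across conditions, one-way ANOVA,
    Tukey HSD. When a gate test (normality/homoscedasticity) fails at
    ``alpha`` the ANOVA still runs but the report carries a warning note —
    the gate outcome is reported rather than silently switching tests.
    """
    conds = sorted(replicate_summaries["condition"].unique())
    groups = [replicate_summaries.loc[replicate_summaries["condition"] == c,
                                      parameter].to_numpy() for c in conds]
    reports: list[TestReport] = []
    gate_notes: list[str] = []
    for c, g in zip(conds, groups):
        rep = shapiro_wilk(g)
        rep.name = f"shapiro-wilk[{c}]"
        if rep.pvalue <= alpha:
            gate_notes.append(f"normality rejected for {c} "
                              f"(p={rep.pvalue:.3g})")
        reports.append(rep)
    lev = levene(groups, center=levene_center)
    if lev.pvalue <= alpha:
        gate_notes.append(f"equal variance rejected (p={lev.pvalue:.3g})")
    reports.append(lev)
    anova = one_way_anova(groups)
    anova.notes = list(gate_notes)
    for note in gate_notes:
        logger.warning("test battery gate: %s", note)
    reports.append(anova)
    reports.append(tukey_hsd(groups, labels=conds))
    return reports


def reports_to_frame(reports: list[TestReport]) -> pd.DataFrame:
    """Flatten a battery into one tidy CSV-ready table."""
    rows = []
    for r in reports:
        rows.append({"test": r.name, "statistic": r.statistic,
                     "df1": r.df[0] if r.df else float("nan"),
                     "df2": r.df[1] if r.df else float("nan"),
                     "pvalue": r.pvalue,
                     "comparison": "", "stars": "",
                     "notes": "; ".join(r.notes)})
        if r.pairwise is not None:
            for _, pr in r.pairwise.iterrows():
                rows.append({"test": r.name, "statistic": pr["mean_diff"],
                             "df1": float("nan"), "df2": float("nan"),
                             "pvalue": pr["p_adj"],
                             "comparison": f"{pr['group_a']} vs "
                                           f"{pr['group_b']}",
                             "stars": pr["stars"], "notes": ""})
    return pd.DataFrame(rows)
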