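"""Statistical comparisons for the experiment and the landscape survey.

Community percent cover is arcsine-square-root transformed before testing.
Soil-treatment differences use a one-way fixed-effects ANOVA on plot-level
community totals, with Tukey HSD pairwise comparisons summarised as a compact
letter display.  The survey uses a site-blocked two-way fixed-effects ANOVA
(origin x distance) on transect means averaged over years, with paired
per-distance contrasts; this replaces the original random-effects formulation,
which is not separately estimable from the averaged, balanced design.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .generate import DISTANCE_CLASSES
from .species import community_members

logger = logging.getLogger(__name__)

ALPHA = 0.05


def transform_cover(cover_percent):
    """Arcsine-square-root transform of percent cover; returns radians.

    Maps [0, 100] onto [0, pi/2] and is strictly monotone, so group rank
    order is preserved.
    """
    arr = np.asarray(cover_percent, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("cover must lie in [0, 100]")
    out = np.arcsin(np.sqrt(arr / 100.0))
    return float(out) if out.ndim == 0 else out


@dataclass
class AnovaResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    group_means: dict[str, float]  # back-transformed mean percent cover per soil
    letters: dict[str, str]  # compact letter display at alpha
    n_per_group: dict[str, int]


@dataclass
class DistanceContrast:
    difference: float  # native - non-native, transformed scale
    p_value: float
    significant: bool


@dataclass
class SurveyTestResult:
    interaction_f: float
    df_num: int
    df_den: int
    interaction_p: float
    contrasts: dict[int, DistanceContrast]


def compact_letter_display(
    groups: list[str], significant: set[frozenset[str]]
) -> dict[str, str]:
    """Assign letters so that two groups share a letter iff they are not
    significantly different in any pairwise test separating them.

    `groups` must be pre-ordered (descending mean); letters are assigned in
    that order.  Uses the insert-and-absorb algorithm.
    """
    def absorb(cols: list[set[str]]) -> list[set[str]]:
        out: list[set[str]] = []
        for c in cols:
            if any(c < other for other in cols) or c in out:
                continue
            out.append(c)
        return out

    columns: list[set[str]] = [set(groups)]
    for pair in sorted(significant, key=sorted):
        a, b = sorted(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend(new for new in (col - {a}, col - {b}) if new)
        columns = absorb(columns)
    # order letters by the first (highest-mean) group they contain
    columns.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


def soil_treatment_anova(
    plots: pd.DataFrame, community: str, alpha: float = ALPHA, adjust: str = "tukey"
) -> AnovaResult:
    """One-way fixed-effects ANOVA of transformed community totals across soils.

    adjust: "tukey" (Tukey-Kramer HSD) or "none" (unadjusted pairwise t-tests)
    for the pairwise comparisons behind the letter display.
    """
    members = list(community_members(community))
    sub = plots[plots["community"] == community].copy()
    sub["total"] = sub[members].sum(axis=1)
    counts = sub.groupby("soil_type")["total"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"soil types with < 2 plots: {bad}")
    sub["y"] = transform_cover(sub["total"].to_numpy())

    groups = (
        sub.groupby("soil_type")["y"].mean().sort_values(ascending=False).index.tolist()
    )
    samples = [sub.loc[sub["soil_type"] == g, "y"].to_numpy() for g in groups]
    group_means = {
        g: float(np.sin(s.mean()) ** 2 * 100.0) for g, s in zip(groups, samples)
    }
    n_per_group = {g: int(len(s)) for g, s in zip(groups, samples)}

    grand = sub["y"].to_numpy()
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    ss_between = sum(len(s) * (s.mean() - grand.mean()) ** 2 for s in samples)
    df_num, df_den = len(groups) - 1, len(grand) - len(groups)

    if ss_within <= 1e-14 * max(1.0, abs(grand).max()) ** 2:
        if ss_between <= 1e-14:
            # degenerate noise-free case: nothing varies at all
            return AnovaResult(0.0, df_num, df_den, 1.0, group_means,
                               {g: "a" for g in groups}, n_per_group)
        raise ValueError("zero within-group variance; F is undefined")

    f = (ss_between / df_num) / (ss_within / df_den)
    p = float(sps.f.sf(f, df_num, df_den))

    significant: set[frozenset[str]] = set()
    if adjust == "tukey":
        res = sps.tukey_hsd(*samples)
        for i, j in itertools.combinations(range(len(groups)), 2):
            if res.pvalue[i, j] < alpha:
                significant.add(frozenset((groups[i], groups[j])))
    elif adjust == "none":
        for i, j in itertools.combinations(range(len(groups)), 2):
            if sps.ttest_ind(samples[i], samples[j]).pvalue < alpha:
                significant.add(frozenset((groups[i], groups[j])))
    else:
        raise ValueError(f"unknown adjust {adjust!r}")

    letters = compact_letter_display(groups, significant)
    return AnovaResult(float(f), df_num, df_den, p, group_means, letters, n_per_group)


def survey_origin_by_distance(
    records: pd.DataFrame, alpha: float = ALPHA
) -> SurveyTestResult:
    """Origin x distance interaction test on the survey, blocked by site.

    Records are averaged within site x distance across years, reshaped to one
    row per site x distance x origin, transformed, and fit with
    y ~ site + origin * distance (all fixed effects).  Per-distance contrasts
    are paired t-tests (native - non-native) across sites.
    """
    if records["site_id"].nunique() < 2:
        raise ValueError("need records from >= 2 sites")
    cell = (
        records.groupby(["site_id", "distance_m"])[["native_cover", "nonnative_cover"]]
        .mean()
        .reset_index()
    )
    complete = cell.groupby("site_id")["distance_m"].nunique()
    incomplete = complete[complete < len(DISTANCE_CLASSES)].index.tolist()
    if incomplete:
        logger.warning("dropping sites missing distance classes: %s", incomplete)
        cell = cell[~cell["site_id"].isin(incomplete)]
    if cell["site_id"].nunique() < 2:
        raise ValueError("fewer than 2 complete sites")

    long = cell.melt(
        id_vars=["site_id", "distance_m"],
        value_vars=["native_cover", "nonnative_cover"],
        var_name="origin", value_name="cover",
    )
    long["origin"] = long["origin"].map(
        {"native_cover": "native", "nonnative_cover": "non-native"}
    )
    long["y"] = transform_cover(long["cover"].to_numpy())

    model = ols("y ~ C(site_id) + C(origin) * C(distance_m)", data=long).fit()
    table = anova_lm(model, typ=2)
    inter = table.loc["C(origin):C(distance_m)"]
    resid = table.loc["Residual"]
    df_num, df_den = int(inter["df"]), int(resid["df"])
    if resid["sum_sq"] <= 1e-14:
        f, p = (0.0, 1.0) if inter["sum_sq"] <= 1e-14 else (np.inf, 0.0)
    else:
        f, p = float(inter["F"]), float(inter["PR(>F)"])

    contrasts: dict[int, DistanceContrast] = {}
    wide = long.pivot_table(index=["site_id", "distance_m"], columns="origin", values="y")
    for dist in DISTANCE_CLASSES:
        d = wide.xs(dist, level="distance_m")
        diffs = (d["native"] - d["non-native"]).to_numpy()
        mean_diff = float(diffs.mean())
        if np.allclose(diffs, diffs[0]):
            pval = 1.0 if abs(mean_diff) <= 1e-14 else 0.0
        else:
            pval = float(sps.ttest_rel(d["native"], d["non-native"]).pvalue)
        contrasts[dist] = DistanceContrast(mean_diff, pval, pval < alpha)
    return SurveyTestResult(f, df_num, df_den, p, contrasts)
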