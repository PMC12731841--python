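"""Damaged-area quantification, group statistics and reporting.

Group comparisons follow the design of the underlying study: one-way
ANOVA per feature with the effect size R^2 = SS_between / SS_total,
followed by Bonferroni-adjusted pooled-variance pairwise t tests
(adjusted p = min(1, raw p x number of pairs), significance at 0.05 by
default). All pairs are compared unless a restricted pair list is given.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_preprocess import ROIMask

logger = logging.getLogger("histotex")

TABLE_COLUMNS = ("subject", "group", "feature", "value")


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    raw_p: float
    bonferroni_p: float
    significant: bool


@dataclass
class GroupComparisonResult:
    feature: str
    f_stat: float
    anova_p: float
    r_squared: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def damaged_fraction(damaged: ROIMask, tumor: ROIMask) -> float:
    """|damaged ∩ tumor| / |tumor|; damage outside the tumor is ignored."""
    if tumor.n_pixels == 0:
        raise ValueError("empty tumor mask")
    if damaged.mask.shape != tumor.mask.shape:
        raise ValueError("mask shapes differ")
    inter = int((damaged.mask & tumor.mask).sum())
    return inter / tumor.n_pixels


def make_group_table(rows: list[tuple[str, str, str, float]]) -> pd.DataFrame:
    """Long-format table with columns (subject, group, feature, value)."""
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    dup = df.duplicated(subset=["subject", "feature"])
    if dup.any():
        raise ValueError("duplicate (subject, feature) rows in group table")
    return df


def _group_values(table: pd.DataFrame, feature: str) -> dict[str, np.ndarray]:
    sub = table[table["feature"] == feature]
    if sub.empty:
        raise ValueError(f"feature {feature!r} not in table")
    groups = {g: grp["value"].to_numpy(dtype=float)
              for g, grp in sub.groupby("group", sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    return groups


def one_way_anova(table: pd.DataFrame, feature: str) -> GroupComparisonResult:
    """One-way ANOVA with R^2 = SS_between / SS_total.

    A table with zero variance everywhere reports F = 0 with a warning
    (0/0 degenerate case) instead of erroring.
    """
    groups = _group_values(table, feature)
    values = [v for v in groups.values()]
    allv = np.concatenate(values)
    grand = allv.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in values)
    ss_total = float(((allv - grand) ** 2).sum())
    if ss_total == 0.0:
        logger.warning("feature %r: all values identical; reporting F = 0",
                       feature)
        return GroupComparisonResult(feature=feature, f_stat=0.0,
                                     anova_p=1.0, r_squared=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = sps.f_oneway(*values)
    r2 = ss_between / ss_total
    return GroupComparisonResult(feature=feature, f_stat=float(f_stat),
                                 anova_p=float(p), r_squared=float(r2))


def bonferroni_pairwise(table: pd.DataFrame, feature: str,
                        alpha: float = 0.05,
                        pairs: list[tuple[str, str]] | None = None
                        ) -> list[PairwiseResult]:
    """Pooled-variance pairwise t tests with Bonferroni adjustment.

    The multiplier is the number of compared pairs; a pair of identical,
    zero-variance groups gets raw p = 1.
    """
    groups = _group_values(table, feature)
    if pairs is None:
        pairs = list(combinations(sorted(groups), 2))
    else:
        for a, b in pairs:
            if a not in groups or b not in groups:
                raise ValueError(f"pair ({a}, {b}) not in table groups")
    n_pairs = len(pairs)
    out: list[PairwiseResult] = []
    for a, b in pairs:
        va, vb = groups[a], groups[b]
        if va.std() == 0.0 and vb.std() == 0.0:
            raw = 1.0 if va.mean() == vb.mean() else 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                raw = float(sps.ttest_ind(va, vb, equal_var=True).pvalue)
            if np.isnan(raw):
                raw = 1.0
        adj = min(1.0, raw * n_pairs)
        out.append(PairwiseResult(group_a=a, group_b=b, raw_p=raw,
                                  bonferroni_p=adj,
                                  significant=adj < alpha))
    return out


def compare_all_features(table: pd.DataFrame, alpha: float = 0.05,
                         pairs: list[tuple[str, str]] | None = None
                         ) -> list[GroupComparisonResult]:
    """ANOVA + post hoc for every feature of a long-format table.

    Features whose values are not finite for every subject are skipped
    with a warning (texture-derivative entries can be missing by design).
    """
    results: list[GroupComparisonResult] = []
    for feature in sorted(table["feature"].unique()):
        sub = table[table["feature"] == feature]
        if not np.isfinite(sub["value"].to_numpy(dtype=float)).all():
            logger.warning("feature %r has missing values; skipped", feature)
            continue
        res = one_way_anova(table, feature)
        res.pairwise = bonferroni_pairwise(table, feature, alpha=alpha,
                                           pairs=pairs)
        results.append(res)
    return results


def report(tables: dict[str, pd.DataFrame],
           results: dict[str, list[GroupComparisonResult]],
           outdir: str | Path) -> list[Path]:
    """Write one CSV per analysis tier plus a significance summary.

    Output is deterministically ordered, so identical inputs produce
    byte-identical files.
    """
    if not results or all(len(r) == 0 for r in results.values()):
        raise ValueError("no results to report")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {outdir}: {exc}")
    paths: list[Path] = []
    for tier in sorted(tables):
        df = tables[tier].sort_values(["feature", "group", "subject"],
                                      kind="stable").reset_index(drop=True)
        path = outdir / f"{tier}_values.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        paths.append(path)
    summary_rows = []
    for tier in sorted(results):
        for res in results[tier]:
            for pw in res.pairwise:
                summary_rows.append({
                    "tier": tier, "feature": res.feature,
                    "f_stat": res.f_stat, "anova_p": res.anova_p,
                    "r_squared": res.r_squared,
                    "group_a": pw.group_a, "group_b": pw.group_b,
                    "raw_p": pw.raw_p, "bonferroni_p": pw.bonferroni_p,
                    "significant": pw.significant,
                })
    summary = pd.DataFrame(summary_rows).sort_values(
        ["tier", "feature", "group_a", "group_b"],
        kind="stable").reset_index(drop=True)
    spath = outdir / "significance_summary.csv"
    summary.to_csv(spath, index=False, float_format="%.10g")
    paths.append(spath)
    return paths


def group_boxplot(table: pd.DataFrame, feature: str, path: str | Path) -> None:
    """Per-group boxplot of one feature, saved to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = _group_values(table, feature)
    names = sorted(groups)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([groups[g] for g in names], tick_labels=names)
    ax.set_ylabel(feature)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
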