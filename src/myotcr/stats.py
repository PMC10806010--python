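"""Nonparametric group comparisons and clinical-covariate correlations.

Two groups are compared with a two-sided Mann-Whitney U test (exact for
small tie-free samples, normal approximation with tie correction
otherwise); three or more with a Kruskal-Wallis omnibus test followed by
pairwise Mann-Whitney tests under Bonferroni adjustment. Associations
between repertoire metrics and clinical markers use Pearson correlation
with a two-sided t-test on n-2 degrees of freedom. Group descriptives
are medians with interquartile ranges throughout.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class AssociationResult:
    """Pearson correlation of one metric with one covariate."""

    metric: str
    covariate: str
    pearson_r: float
    p_value: float
    n: int


@dataclass
class GroupComparison:
    """Result of a two-or-more-group nonparametric comparison."""

    test: str  # mann_whitney | kruskal_wallis
    statistic: float
    p_value: float
    descriptives: pd.DataFrame = field(repr=False)  # group, n, median, q1, q3
    pairwise: pd.DataFrame = field(repr=False)  # group_a, group_b, statistic, p_raw, p_adjusted


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: multiply by the family size, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)


def _descriptives(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, x in groups.items():
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        rows.append({"group": name, "n": len(x), "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    min_n: int = 2,
) -> GroupComparison:
    """Compare two or more groups of observations nonparametrically.

    Groups with fewer than ``min_n`` observations are excluded with a
    warning. Two usable groups give a two-sided Mann-Whitney U test;
    three or more give Kruskal-Wallis followed by all pairwise
    Mann-Whitney tests with Bonferroni-adjusted p-values (the family is
    the set of pairs).
    """
    groups: "dict[str, np.ndarray]" = {}
    for name, vals in values_by_group.items():
        x = np.asarray(list(vals), dtype=float)
        if len(x) < min_n:
            log.warning("group %r has %d < %d observations; excluded", name, len(x), min_n)
            continue
        groups[str(name)] = x
    if len(groups) < 2:
        raise ValueError("need at least two groups with enough observations")
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    pair_rows = []
    for a, b in pairs:
        u, p = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided", method="auto")
        pair_rows.append({"group_a": a, "group_b": b, "statistic": float(u), "p_raw": float(p)})
    pairwise = pd.DataFrame(pair_rows)
    pairwise["p_adjusted"] = bonferroni(pairwise["p_raw"]) if len(pairs) > 1 else pairwise["p_raw"]
    pairwise["family_size"] = len(pairs) if len(pairs) > 1 else 1
    if len(groups) == 2:
        return GroupComparison(
            test="mann_whitney",
            statistic=float(pairwise.loc[0, "statistic"]),
            p_value=float(pairwise.loc[0, "p_raw"]),
            descriptives=_descriptives(groups),
            pairwise=pairwise,
        )
    h, p_omni = sps.kruskal(*groups.values())
    return GroupComparison(
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p_omni),
        descriptives=_descriptives(groups),
        pairwise=pairwise,
    )


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    metric: str = "x",
    covariate: str = "y",
) -> AssociationResult:
    """Pearson correlation with two-sided p-value from the t-distribution.

    Pairs where either value is missing (NaN/None) are dropped and
    logged; at least 3 complete pairs are required, and both variables
    must vary.
    """
    xa = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    ya = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(xa) & np.isfinite(ya)
    dropped = int((~keep).sum())
    if dropped:
        log.info("correlate(%s, %s): dropped %d incomplete pair(s)", metric, covariate, dropped)
    xa, ya = xa[keep], ya[keep]
    n = len(xa)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(xa, ya)
    return AssociationResult(metric, covariate, float(r), float(p), n)


METRICS = ("gini", "shannon", "simpson")
COVARIATES = ("ck_u_per_l", "mmt_score")


def association_panel(
    profiles: pd.DataFrame,
    meta: pd.DataFrame,
    metrics: Sequence[str] = METRICS,
    covariates: Sequence[str] = COVARIATES,
    log10_ck: bool = False,
) -> pd.DataFrame:
    """Correlate repertoire metrics with clinical markers per compartment.

    ``profiles`` is the per-sample metrics table (``subject_id``,
    ``compartment`` and the metric columns); ``meta`` is indexed by
    subject with the covariate columns. Patients only (controls carry no
    clinical markers). Produces the metrics x covariates x compartments
    grid of Pearson r, p and n; with ``log10_ck`` CK values are
    log10-transformed first.
    """
    if not isinstance(meta.index, pd.Index) or meta.index.name != "subject_id":
        meta = meta.set_index("subject_id")
    rows = []
    for compartment, chunk in profiles.groupby("compartment", sort=True):
        merged = chunk.join(meta, on="subject_id", how="left")
        if "group" in merged.columns:
            merged = merged[merged["group"] == "patient"]
        for metric in metrics:
            for cov in covariates:
                y = merged[cov].astype(float)
                if cov == "ck_u_per_l" and log10_ck:
                    y = np.log10(y)
                try:
                    res = correlate(merged[metric], y, metric=metric, covariate=cov)
                except ValueError as exc:
                    log.warning("panel cell (%s, %s, %s) skipped: %s", compartment, metric, cov, exc)
                    continue
                rows.append(
                    {
                        "compartment": compartment,
                        "metric": metric,
                        "covariate": cov,
                        "n": res.n,
                        "pearson_r": res.pearson_r,
                        "p_value": res.p_value,
                        "significant": res.p_value < ALPHA,
                    }
                )
    return pd.DataFrame(rows)
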