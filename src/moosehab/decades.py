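"""Decade-wise refits and the extra-sum-of-squares comparison.

The parsimonious model chosen on the full study period is refit
independently to each decade's regional table. Whether a pair of decades
shares one regression (common intercept and slopes) is tested with the
extra-sum-of-squares F test on the pooled pair: the reduced model fits one
line through both decades, the full model adds a decade indicator and
indicator × predictor interactions, and

    F = [(RSS_red − RSS_full)/Δdf] / [RSS_full/df_full].

``scope='joint'`` tests intercept and slopes together (one P per pair, the
default); ``scope='slopes'`` allows separate intercepts under the reduced
model and tests the slopes alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from collections.abc import Mapping

import pandas as pd
import scipy.stats

from .regression import RSS_FLOOR, FitResult, ModelSpec, fit_ols

__all__ = ["ExtraSSTest", "DecadeComparison", "fit_decades", "extra_ss_test", "compare_decades"]


@dataclass
class ExtraSSTest:
    pair: tuple[str, str]
    scope: str
    f_stat: float
    df1: int
    df2: int
    p_value: float
    rss_reduced: float
    rss_full: float


@dataclass
class DecadeComparison:
    fits: dict[str, FitResult]
    tests: pd.DataFrame  # pair_a, pair_b, scope, F, df1, df2, p


def fit_decades(tables: Mapping[str, pd.DataFrame], spec: ModelSpec) -> dict[str, FitResult]:
    """Independent OLS fits of the same spec to each decade table."""
    region_sets = {lab: frozenset(t["region_id"]) for lab, t in tables.items() if "region_id" in t}
    if len(set(region_sets.values())) > 1:
        raise ValueError("decade tables cover different region sets")
    return {lab: fit_ols(t, spec) for lab, t in tables.items()}


def _with_interactions(pooled: pd.DataFrame, spec: ModelSpec, pair: tuple[str, str],
                       group_col: str) -> tuple[pd.DataFrame, str, list[str]]:
    sub = pooled[pooled[group_col].isin(pair)].copy()
    if sub[group_col].nunique() != 2:
        raise ValueError(f"pooled table must contain both groups of {pair}")
    ind = f"_is_{pair[1]}"
    sub[ind] = (sub[group_col] == pair[1]).astype(float)
    inter = []
    for pred in spec.predictors:
        col = f"{ind}:{pred}"
        sub[col] = sub[ind] * sub[pred].astype(float)
        inter.append(col)
    return sub, ind, inter


def extra_ss_test(
    pooled: pd.DataFrame,
    spec: ModelSpec,
    pair: tuple[str, str],
    group_col: str = "period_label",
    scope: str = "joint",
) -> ExtraSSTest:
    """Extra-sum-of-squares F test for equality of two decades' regressions.

    A numerically exact full fit (RSS below the degeneracy floor while the
    reduced model is not) is flagged as F = inf, p = 0.
    """
    sub, ind, inter = _with_interactions(pooled, spec, pair, group_col)
    full = fit_ols(sub, ModelSpec(spec.response, (*spec.predictors, ind, *inter)))
    if scope == "joint":
        reduced = fit_ols(sub, spec.__class__(spec.response, spec.predictors))
    elif scope == "slopes":
        reduced = fit_ols(sub, ModelSpec(spec.response, (*spec.predictors, ind)))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    df1 = full.p - reduced.p
    df2 = full.n - full.p - 1
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom in the full model")
    if full.rss <= RSS_FLOOR:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = max(0.0, (reduced.rss - full.rss) / df1) / (full.rss / df2)
        p = float(scipy.stats.f.sf(f_stat, df1, df2))
    return ExtraSSTest(pair, scope, f_stat, df1, df2, p, reduced.rss, full.rss)


def compare_decades(
    tables: Mapping[str, pd.DataFrame],
    spec: ModelSpec,
    group_col: str = "period_label",
) -> DecadeComparison:
    """Per-decade fits plus all pairwise joint and slope-only tests."""
    fits = fit_decades(tables, spec)
    frames = []
    for lab, t in tables.items():
        t = t.copy()
        t[group_col] = lab
        frames.append(t)
    pooled = pd.concat(frames, ignore_index=True)
    rows = []
    for a, b in itertools.combinations(tables.keys(), 2):
        for scope in ("joint", "slopes"):
            t = extra_ss_test(pooled, spec, (a, b), group_col=group_col, scope=scope)
            rows.append((a, b, scope, t.f_stat, t.df1, t.df2, t.p_value))
    tests = pd.DataFrame(rows, columns=["decade_a", "decade_b", "scope", "f_stat", "df1", "df2", "p_value"])
    return DecadeComparison(fits, tests)
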