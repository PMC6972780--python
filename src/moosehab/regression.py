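"""Best-subsets OLS with BIC ranking, collinearity screening, VIF and
residual diagnostics.

The model-selection workflow: screen candidate predictors (Pearson matrix;
average-linkage clustering of the bioclimatic variables on 1 − squared
Spearman correlation, keeping one representative per tight cluster),
exhaustively enumerate predictor subsets ranked by BIC, then check the
chosen model's variance inflation factors (VIF < 10) and the spatial
structure of its residuals with an empirical semivariogram.

Conventions (documented because they differ across software): BIC is
n·ln(RSS/n) + k·ln(n) with k = p + 1 (intercept counted, error variance
not); absolute BIC therefore carries an arbitrary additive constant and
only ΔBIC between models on the same data is meaningful. RMSE uses the n
denominator, √(RSS/n).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from scipy.spatial.distance import squareform

__all__ = [
    "ModelSpec",
    "FitResult",
    "SubsetSearchResult",
    "CollinearityReport",
    "Semivariogram",
    "fit_ols",
    "bic",
    "best_subsets",
    "screen_collinearity",
    "vif",
    "predict_residuals",
    "residual_semivariogram",
]

#: Below this RSS a model interpolates the data to numerical precision and
#: the log term of BIC is meaningless; such fits get BIC = −inf and ranking
#: falls back to parsimony (fewer predictors first).
RSS_FLOOR = 1e-20


@dataclass(frozen=True)
class ModelSpec:
    response: str
    predictors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("duplicate predictors in model spec")

    @classmethod
    def from_formula(cls, formula: str) -> "ModelSpec":
        """Parse ``"y ~ x1 + x2"`` (``"y ~ 1"`` for intercept-only)."""
        lhs, _, rhs = formula.partition("~")
        preds = tuple(p.strip() for p in rhs.split("+") if p.strip() and p.strip() != "1")
        return cls(lhs.strip(), preds)

    def formula(self) -> str:
        return f"{self.response} ~ " + (" + ".join(self.predictors) or "1")


@dataclass
class FitResult:
    spec: ModelSpec
    params: pd.Series  # 'const' + slopes
    bse: pd.Series
    rss: float
    n: int
    p: int
    r2: float
    r2_adj: float
    rmse: float
    bic: float
    fitted: np.ndarray
    residuals: np.ndarray


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name the columns involved in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    arr = np.asarray(X, dtype=float)
    _, R, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
    dependent = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    return dependent


def fit_ols(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Ordinary least squares of ``spec.response`` on ``spec.predictors``.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    missing = [c for c in (spec.response, *spec.predictors) if c not in table.columns]
    if missing:
        raise ValueError(f"columns absent from table: {missing}")
    y = table[spec.response].to_numpy(dtype=float)
    X = sm.add_constant(table[list(spec.predictors)].astype(float), has_constant="add")
    n, k = X.shape
    p = k - 1
    if n <= k:
        raise ValueError(f"n = {n} too small for {p} predictors")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise ValueError(f"rank-deficient design; collinear columns: {_collinear_columns(X)}")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return FitResult(
        spec=spec,
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        rss=rss,
        n=n,
        p=p,
        r2=r2,
        r2_adj=r2_adj,
        rmse=math.sqrt(rss / n),
        bic=bic(rss=rss, n=n, p=p),
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
    )


def bic(fit: FitResult | None = None, *, rss: float | None = None,
        n: int | None = None, p: int | None = None) -> float:
    """BIC = n·ln(RSS/n) + (p + 1)·ln(n); −inf for an (effectively) exact fit."""
    if fit is not None:
        rss, n, p = fit.rss, fit.n, fit.p
    if rss is None or n is None or p is None:
        raise ValueError("need rss, n and p")
    if rss < 0:
        raise ValueError("negative RSS")
    if rss <= RSS_FLOOR:
        return float("-inf")
    return n * math.log(rss / n) + (p + 1) * math.log(n)


@dataclass
class SubsetModel:
    spec: ModelSpec
    fit: FitResult
    delta_bic: float


@dataclass
class SubsetSearchResult:
    models: list[SubsetModel] = field(default_factory=list)

    @property
    def best(self) -> SubsetModel:
        return self.models[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictors": [" + ".join(m.spec.predictors) or "(intercept)" for m in self.models],
                "n_predictors": [m.fit.p for m in self.models],
                "bic": [m.fit.bic for m in self.models],
                "delta_bic": [m.delta_bic for m in self.models],
                "r2_adj": [m.fit.r2_adj for m in self.models],
                "rmse": [m.fit.rmse for m in self.models],
            }
        )


def best_subsets(
    table: pd.DataFrame,
    response: str,
    candidates: list[str],
    max_size: int | None = None,
) -> SubsetSearchResult:
    """Exhaustive subset enumeration up to ``max_size``, ranked by BIC.

    The intercept is always included. Ties (including exact fits flagged
    BIC = −inf) break toward fewer predictors, then lexicographic names.
    Rank-deficient subsets (duplicated columns) are skipped.
    """
    missing = [c for c in candidates if c not in table.columns]
    if missing:
        raise ValueError(f"candidates absent from table: {missing}")
    if max_size is None:
        max_size = len(candidates)
    if max_size > len(candidates):
        raise ValueError("max_size exceeds number of candidates")
    models: list[SubsetModel] = []
    for size in range(max_size + 1):
        for combo in itertools.combinations(candidates, size):
            spec = ModelSpec(response, combo)
            try:
                fit = fit_ols(table, spec)
            except ValueError as err:
                if "rank-deficient" in str(err):
                    continue
                raise
            models.append(SubsetModel(spec, fit, 0.0))
    models.sort(key=lambda m: (m.fit.bic, m.fit.p, m.spec.predictors))
    best_bic = models[0].fit.bic
    for m in models:
        if math.isinf(m.fit.bic) and math.isinf(best_bic):
            m.delta_bic = 0.0
        else:
            m.delta_bic = m.fit.bic - best_bic
    return SubsetSearchResult(models)


@dataclass
class CollinearityReport:
    pearson: pd.DataFrame
    spearman_sq: pd.DataFrame
    linkage: np.ndarray | None
    clusters: dict[int, list[str]]
    retained: list[str]


def screen_collinearity(
    table: pd.DataFrame,
    candidates: list[str],
    cluster_columns: list[str] | None = None,
    threshold: float = 0.5,
) -> CollinearityReport:
    """Pearson matrix plus Spearman²-based cluster pruning.

    ``cluster_columns`` (default: all candidates) are clustered by
    average linkage on distance 1 − ρ²_Spearman and cut where similarity
    ρ² ≥ ``threshold``; within each multi-member cluster only the first
    column in candidate order is retained. Non-clustered candidates are
    always retained. Constant columns make the correlations undefined and
    are rejected.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidates")
    sub = table[candidates].astype(float)
    constant = [c for c in candidates if sub[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant columns have undefined correlation: {constant}")
    pearson = sub.corr(method="pearson")
    spearman_sq = sub.corr(method="spearman") ** 2
    if cluster_columns is None:
        cluster_columns = list(candidates)
    clusters: dict[int, list[str]] = {}
    linkage = None
    if len(cluster_columns) >= 2:
        d = 1.0 - spearman_sq.loc[cluster_columns, cluster_columns].to_numpy()
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        linkage = sch.linkage(squareform(d, checks=False), method="average")
        labels = sch.fcluster(linkage, t=1.0 - threshold, criterion="distance")
        for col, lab in zip(cluster_columns, labels):
            clusters.setdefault(int(lab), []).append(col)
    dropped: set[str] = set()
    for members in clusters.values():
        dropped.update(members[1:])  # keep the first in candidate order
    retained = [c for c in candidates if c not in dropped]
    return CollinearityReport(pearson, spearman_sq, linkage, clusters, retained)


def vif(table: pd.DataFrame, predictors: list[str]) -> pd.Series:
    """Variance inflation factor 1/(1 − R²_j) per predictor.

    R²_j regresses predictor j on the remaining predictors (with
    intercept). Perfect collinearity yields inf.
    """
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    if len(table) <= len(predictors) + 1:
        raise ValueError("too few rows for VIF")
    out = {}
    for j in predictors:
        others = [c for c in predictors if c != j]
        y = table[j].to_numpy(dtype=float)
        X = sm.add_constant(table[others].astype(float), has_constant="add")
        res = sm.OLS(y, X).fit()
        r2j = float(res.rsquared)
        out[j] = float("inf") if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
    return pd.Series(out, name="vif")


def predict_residuals(fit: FitResult, table: pd.DataFrame) -> pd.DataFrame:
    """Predicted response and residuals for each row of ``table``."""
    missing = [c for c in fit.spec.predictors if c not in table.columns]
    if missing:
        raise ValueError(f"predictor columns absent: {missing}")
    X = sm.add_constant(table[list(fit.spec.predictors)].astype(float), has_constant="add")
    pred = X.to_numpy() @ fit.params.loc[X.columns].to_numpy()
    out = pd.DataFrame({"predicted": pred})
    if "region_id" in table.columns:
        out.insert(0, "region_id", table["region_id"].to_numpy())
    if fit.spec.response in table.columns:
        out["residual"] = table[fit.spec.response].to_numpy(dtype=float) - pred
    return out


@dataclass
class Semivariogram:
    bin_mid: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray


def _pair_distances(coords: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        from scipy.spatial.distance import pdist

        return pdist(coords)
    if metric == "greatcircle":
        lon = np.radians(coords[:, 0])
        lat = np.radians(coords[:, 1])
        i, j = np.triu_indices(len(coords), k=1)
        dlat = lat[j] - lat[i]
        dlon = lon[j] - lon[i]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat[i]) * np.cos(lat[j]) * np.sin(dlon / 2) ** 2
        return 6371.0 * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    raise ValueError(f"unknown metric {metric!r}")


def residual_semivariogram(
    residuals: np.ndarray,
    coords: np.ndarray,
    n_bins: int = 10,
    metric: str = "euclidean",
    max_dist: float | None = None,
) -> Semivariogram:
    """Empirical semivariogram γ(h) = mean over pairs in bin of (zᵢ−zⱼ)²/2.

    ``coords`` is (n, 2); with ``metric='greatcircle'`` columns are
    (lon, lat) in degrees and distances are km.
    """
    z = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(z) < 2:
        raise ValueError("need at least two points")
    d = _pair_distances(coords, metric)
    if not d.max() > 0:
        raise ValueError("all points coincident")
    i, j = np.triu_indices(len(z), k=1)
    sq = (z[i] - z[j]) ** 2 / 2
    top = max_dist if max_dist is not None else d.max() * (1 + 1e-12)
    edges = np.linspace(0.0, top, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    inside = d <= top
    gamma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = inside & (idx == b)
        counts[b] = int(sel.sum())
        if counts[b]:
            gamma[b] = float(sq[sel].mean())
    return Semivariogram((edges[:-1] + edges[1:]) / 2, gamma, counts)
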