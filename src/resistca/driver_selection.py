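"""Exploratory statistics for choosing resistance drivers.

Continuous candidate drivers are screened by Pearson correlation against the
confirmed-resistance indicator (|r| > 0.2 flags importance), by principal
component analysis on the correlation matrix (retain the smallest set of PCs
whose cumulative explained variance exceeds 80%, then keep drivers loading
above 0.25 in absolute value on any retained PC), and reduced by
average-linkage hierarchical clustering at correlation distance 1 - |r| (one
representative per cluster, the member most correlated with the outcome).
Categorical drivers are screened by a chi-square test of association
(significant below p = 0.05, no continuity correction). The Kaiser criterion
(eigenvalue > 1) is reported for context but not enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CorrelationResult",
    "ChiSquareResult",
    "SelectionReport",
    "pearson_r",
    "chi_square",
    "pca_select",
    "cluster_drivers",
    "select_drivers",
]

IMPORTANCE_R = 0.2
VAR_THRESHOLD = 0.80
LOADING_THRESHOLD = 0.25
ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    important: bool  # |r| > 0.2


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class SelectionReport:
    """Full provenance of a driver-selection run."""

    eigenvalues: np.ndarray | None = None
    proportion: np.ndarray | None = None
    cumulative: np.ndarray | None = None
    retained_pc_count: int | None = None
    kaiser: np.ndarray | None = None  # eigenvalue > 1 flags, reported only
    loadings: pd.DataFrame | None = None
    retained_drivers: list[str] = field(default_factory=list)
    correlations: dict[str, CorrelationResult] = field(default_factory=dict)
    chi_square_results: dict[str, ChiSquareResult] = field(default_factory=dict)
    clusters: dict[str, int] = field(default_factory=dict)
    cluster_representatives: list[str] = field(default_factory=list)
    final_drivers: list[str] = field(default_factory=list)


def _check_vector(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.ptp(v) == 0:
        raise ValueError(f"{name} is constant; correlation undefined")
    return v


def pearson_r(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the |r| > 0.2 importance flag."""
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n=len(x), important=abs(r) > IMPORTANCE_R)


def chi_square(table) -> ChiSquareResult:
    """Chi-square test of association on a contingency table.

    Expected counts are the product-of-marginals estimate; the statistic is
    the plain sum of (O - E)^2 / E with no continuity correction and
    df = (rows - 1)(cols - 1).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("contingency counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        observed=obs,
        expected=np.asarray(res.expected_freq),
    )


def _correlation_matrix(X: np.ndarray, names: Sequence[str]) -> np.ndarray:
    for k, name in enumerate(names):
        if np.ptp(X[:, k]) == 0:
            raise ValueError(f"driver {name!r} is constant")
    return np.corrcoef(X, rowvar=False)


def pca_select(
    X,
    driver_names: Sequence[str] | None = None,
    var_threshold: float = VAR_THRESHOLD,
    loading_threshold: float = LOADING_THRESHOLD,
) -> SelectionReport:
    """PCA retention on standardized drivers (correlation-matrix eigenbasis).

    Retains the smallest leading set of PCs whose cumulative explained
    variance strictly exceeds ``var_threshold``, then keeps every driver
    whose loading (eigenvector coefficient) exceeds ``loading_threshold`` in
    absolute value on at least one retained PC.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a samples x drivers matrix with >= 2 drivers")
    names = list(driver_names) if driver_names else [f"d{k}" for k in range(X.shape[1])]
    corr = _correlation_matrix(X, names)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude coefficient of each PC positive
    for k in range(evecs.shape[1]):
        pivot = np.argmax(np.abs(evecs[:, k]))
        if evecs[pivot, k] < 0:
            evecs[:, k] = -evecs[:, k]

    proportion = evals / evals.sum()
    cumulative = np.cumsum(proportion)
    # strict "> threshold" with a hair of slack so an exact tie (e.g. equal
    # eigenvalues summing to 0.80) is not promoted by float round-off
    retained = int(np.argmax(cumulative > var_threshold + 1e-9)) + 1
    loadings = pd.DataFrame(
        evecs, index=names, columns=[f"PC{k + 1}" for k in range(len(evals))]
    )
    keep = [
        name
        for name in names
        if np.abs(loadings.loc[name].to_numpy()[:retained]).max() > loading_threshold
    ]
    return SelectionReport(
        eigenvalues=evals,
        proportion=proportion,
        cumulative=cumulative,
        retained_pc_count=retained,
        kaiser=evals > 1.0,
        loadings=loadings,
        retained_drivers=keep,
    )


def cluster_drivers(
    X,
    driver_names: Sequence[str] | None = None,
    height: float = 0.5,
) -> tuple[np.ndarray, dict[str, int]]:
    """Agglomerative clustering of drivers at distance 1 - |r|, average linkage.

    Returns the scipy linkage matrix (for dendrograms) and a flat cluster
    assignment cut at ``height``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a samples x drivers matrix with >= 2 drivers")
    names = list(driver_names) if driver_names else [f"d{k}" for k in range(X.shape[1])]
    corr = _correlation_matrix(X, names)
    dist = np.clip(1.0 - np.abs(corr), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    flat = fcluster(Z, t=height, criterion="distance")
    return Z, dict(zip(names, (int(c) for c in flat)))


def select_drivers(
    X,
    y,
    driver_names: Sequence[str] | None = None,
    categorical_tables: Mapping[str, np.ndarray] | None = None,
    cluster_height: float = 0.5,
) -> SelectionReport:
    """Combine PCA retention, correlation screening, chi-square flags and
    cluster reduction into one selection.

    A continuous driver makes the final list when it is PCA-retained, its
    correlation with the confirmed-resistance indicator ``y`` exceeds 0.2 in
    absolute value, and it is its cluster's representative (the member with
    max |r| against ``y``; ties break lexicographically on name). Categorical
    drivers join when their contingency table against ``y`` is significant at
    p < 0.05.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a samples x drivers matrix")
    names = list(driver_names) if driver_names else [f"d{k}" for k in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("driver_names length does not match X columns")

    correlations = {name: pearson_r(X[:, k], y) for k, name in enumerate(names)}

    if X.shape[1] >= 2:
        report = pca_select(X, driver_names=names)
        _, clusters = cluster_drivers(X, driver_names=names, height=cluster_height)
    else:  # single driver: PCA/clustering degenerate, driver stands alone
        report = SelectionReport(retained_drivers=list(names))
        clusters = {names[0]: 1}
    report.correlations = correlations
    report.clusters = clusters

    reps: list[str] = []
    for cid in sorted(set(clusters.values())):
        members = [n for n, c in clusters.items() if c == cid]
        best = max(abs(correlations[n].r) for n in members)
        # tie-break: lexicographically first among the maximally correlated
        reps.append(min(n for n in members if abs(correlations[n].r) == best))
    report.cluster_representatives = reps

    final = [
        n
        for n in names
        if n in report.retained_drivers and correlations[n].important and n in reps
    ]
    for name, table in (categorical_tables or {}).items():
        res = chi_square(table)
        report.chi_square_results[name] = res
        if res.significant:
            final.append(name)
    report.final_drivers = final
    return report
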