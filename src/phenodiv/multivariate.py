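"""Correlation, principal components, and hierarchical clustering of
genotype adjusted means.

Traits are standardised (zero mean, unit sample variance) before PCA and
before Euclidean distances are formed, since trait scales differ by orders
of magnitude. PCA is the eigendecomposition of the trait correlation
matrix; components with eigenvalue >= 1 are flagged as retained (Kaiser
rule). Clustering is agglomerative on the standardised Euclidean distance
matrix with complete (default), average or Ward linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import DomainError

__all__ = [
    "CorrelationResult",
    "PcaResult",
    "ClusteringResult",
    "correlation_matrix",
    "pca",
    "biplot_coordinates",
    "hierarchical_cluster",
    "cluster_traits",
    "correlation_star",
]

_LINKAGES = ("complete", "average", "ward")


def correlation_star(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class CorrelationResult:
    r: pd.DataFrame  # symmetric Pearson correlations
    p: pd.DataFrame  # two-sided p-values (t reference, df = n - 2)
    stars: pd.DataFrame
    n: int
    constant_traits: tuple[str, ...] = ()


@dataclass(frozen=True)
class PcaResult:
    eigenvalues: np.ndarray  # descending; sums to the trait count
    proportion: np.ndarray  # percent variance per component
    cumulative: np.ndarray  # cumulative percent
    loadings: pd.DataFrame  # unit-norm eigenvectors (traits x components)
    scores: pd.DataFrame  # genotypes x components
    n_retained: int  # Kaiser rule: eigenvalue >= 1
    reduced_rank: bool = False


@dataclass(frozen=True)
class ClusteringResult:
    distances: pd.DataFrame  # square Euclidean distance matrix
    linkage_matrix: np.ndarray  # scipy merge tree
    assignments: pd.Series  # genotype -> cluster label 1..K
    cluster_means: pd.DataFrame  # K x traits, original scale
    linkage: str
    k: int


def _complete_cases(means: pd.DataFrame) -> pd.DataFrame:
    return means.dropna(axis=0, how="any")


def _standardize(means: pd.DataFrame) -> pd.DataFrame:
    std = means.std(ddof=1)
    return (means - means.mean()) / std


def correlation_matrix(means: pd.DataFrame, traits: list[str] | None = None) -> CorrelationResult:
    """Pairwise Pearson correlations over complete cases, with t-based
    two-sided p-values and the ***/**/* star convention."""
    data = _complete_cases(means[traits] if traits else means)
    n = len(data)
    if n < 3:
        raise DomainError(f"need at least 3 complete genotypes, got {n}")
    std = data.std(ddof=1)
    constant = tuple(std.index[std == 0.0])
    r = data.corr()  # pandas leaves NaN for constant columns
    with np.errstate(divide="ignore", invalid="ignore"):
        rv = r.to_numpy(dtype=float)
        t = rv * np.sqrt((n - 2) / np.clip(1.0 - rv**2, 1e-300, None))
        pv = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(pv, 0.0)
    p = pd.DataFrame(pv, index=r.index, columns=r.columns)
    stars = p.map(correlation_star).where(r.notna(), "")
    return CorrelationResult(r=r, p=p, stars=stars, n=n, constant_traits=constant)


def pca(means: pd.DataFrame) -> PcaResult:
    """PCA of the trait correlation matrix.

    Sign convention: each eigenvector's largest-magnitude loading is made
    positive, so results are reproducible across LAPACK implementations.
    """
    data = _complete_cases(means)
    n, p = data.shape
    if p < 2 or n < 3:
        raise DomainError(f"need >= 2 traits and >= 3 genotypes, got {p} x {n}")
    std = data.std(ddof=1)
    if (std == 0).any():
        raise DomainError(f"constant trait(s): {list(std.index[std == 0])}")
    z = _standardize(data)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    reduced = bool(np.any(w < 1e-10))
    w = np.clip(w, 0.0, None)
    # deterministic sign: largest |loading| positive per component
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    v = v * flip
    comp_names = [f"PC{i + 1}" for i in range(p)]
    loadings = pd.DataFrame(v, index=data.columns, columns=comp_names)
    scores = pd.DataFrame(z.to_numpy() @ v, index=data.index, columns=comp_names)
    proportion = 100.0 * w / p
    return PcaResult(
        eigenvalues=w,
        proportion=proportion,
        cumulative=np.cumsum(proportion),
        loadings=loadings,
        scores=scores,
        n_retained=int(np.sum(w >= 1.0)),
        reduced_rank=reduced,
    )


def biplot_coordinates(
    result: PcaResult, components: tuple[int, int] = (1, 2)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype points (scores) and trait arrows (loadings scaled by sqrt(lambda))
    for a pair of 1-based component indices."""
    p = len(result.eigenvalues)
    for comp in components:
        if not 1 <= comp <= p:
            raise DomainError(f"component {comp} out of range 1..{p}")
    cols = [f"PC{c}" for c in components]
    points = result.scores[cols].copy()
    lam = result.eigenvalues[[c - 1 for c in components]]
    arrows = result.loadings[cols] * np.sqrt(lam)
    return points, arrows


def hierarchical_cluster(
    means: pd.DataFrame,
    k: int,
    linkage: str = "complete",
    metric: str = "euclidean",
    standardize: bool = True,
) -> ClusteringResult:
    """Agglomerative clustering of genotypes on standardised traits.

    Genotypes are sorted lexicographically before distances are formed so the
    result is invariant to input row order; cluster labels 1..K follow the
    order of first appearance in that sorted list. Cluster means are reported
    on the original trait scale.
    """
    if linkage not in _LINKAGES:
        raise DomainError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    data = _complete_cases(means).loc[sorted(_complete_cases(means).index)]
    n = len(data)
    if k < 1 or k > n:
        raise DomainError(f"K must be in 1..{n}, got {k}")
    z = _standardize(data).fillna(0.0) if standardize else data  # constant traits add no distance
    condensed = pdist(z.to_numpy(), metric=metric)
    tree = hierarchy.linkage(condensed, method=linkage)
    raw = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    # relabel clusters 1..K by first appearance over the sorted genotypes
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[i] = relabel[lab]
    assignments = pd.Series(labels, index=data.index, name="cluster")
    cluster_means = data.groupby(assignments).mean()
    cluster_means.index.name = "cluster"
    dist = pd.DataFrame(squareform(condensed), index=data.index, columns=data.index)
    return ClusteringResult(
        distances=dist,
        linkage_matrix=tree,
        assignments=assignments,
        cluster_means=cluster_means,
        linkage=linkage,
        k=int(assignments.nunique()),
    )


def cluster_traits(means: pd.DataFrame, k: int, linkage: str = "complete") -> ClusteringResult:
    """Cluster the traits by their standardised genotype profiles (the
    transposed matrix), as in a two-way clustered heatmap."""
    z = _standardize(_complete_cases(means))
    return hierarchical_cluster(z.T, k=k, linkage=linkage, standardize=False)
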