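"""Multi-trait genotype-ideotype distance index (MGIDI).

Pipeline:

1. **Rescale** each trait to [0, 100] in the direction of desirability:
   for a trait to be increased, r = 100 (x - min) / (max - min); for a trait
   to be decreased, r = 100 (max - x) / (max - min). The ideotype scores 100
   on every trait by construction.
2. **Factor analysis** of the correlation matrix of the rescaled traits:
   retain f factors with eigenvalue >= 1 (Kaiser), initial loadings
   L = V_f diag(sqrt(lambda_f)), varimax rotation (orthogonal, no row
   normalisation), communalities = row sums of squared rotated loadings.
3. **Scores** by ordinary least squares: F = Z A (A'A)^-1, where Z is the
   column-standardised rescaled matrix and A the rotated loadings; the
   ideotype row is standardised by the genotypes' means and SDs.
4. **Index**: MGIDI_i = sqrt( sum_j (gamma_ij - gamma_j)^2 ), the Euclidean
   distance between genotype i's factor scores and the ideotype's. Lower is
   closer to the ideotype; genotypes are ranked ascending and the best
   round(alpha * t) are selected (round half up; alpha defaults to 0.20).

Per-factor contributions omega_ij = (gamma_ij - gamma_j)^2 / MGIDI_i^2 show
which factors keep a genotype away from the ideotype; per-trait selection
differentials compare the selected set's mean with the population mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "RescaledMatrix",
    "FactorModel",
    "MgidiResult",
    "rescale",
    "varimax",
    "factor_analysis",
    "mgidi_index",
    "select",
    "selection_differentials",
    "run_mgidi",
]


@dataclass(frozen=True)
class RescaledMatrix:
    data: pd.DataFrame  # genotypes x traits, each entry in [0, 100]
    ideotype: pd.Series  # 100 for every kept trait
    trait_min: pd.Series  # original-scale minima
    trait_max: pd.Series
    goals: dict[str, str]
    dropped: tuple[str, ...] = ()  # constant traits excluded with a warning


@dataclass(frozen=True)
class FactorModel:
    eigenvalues: np.ndarray
    n_factors: int
    loadings_initial: pd.DataFrame  # traits x factors, eigenvector * sqrt(lambda)
    loadings: pd.DataFrame  # varimax-rotated
    communalities: pd.Series
    uniquenesses: pd.Series
    scores: pd.DataFrame  # genotypes x factors (gamma_ij)
    ideotype_scores: pd.Series  # gamma_j


@dataclass(frozen=True)
class MgidiResult:
    mgidi: pd.Series  # per genotype, ascending = better
    ranking: pd.Series  # rank 1 = closest to ideotype; ties by genotype id
    contributions: pd.DataFrame  # omega_ij, rows sum to 1
    model: FactorModel


def rescale(means: pd.DataFrame, goals: dict[str, str] | None = None) -> RescaledMatrix:
    """Goal-directed 0-100 rescaling; the best observed value maps to 100."""
    goals = dict(goals or {})
    data = means.dropna(axis=0, how="any")
    kept, dropped = [], []
    out = {}
    for trait in data.columns:
        col = data[trait].astype(float)
        lo, hi = float(col.min()), float(col.max())
        if hi <= lo:
            dropped.append(trait)
            warnings.warn(f"trait {trait!r} is constant; excluded from MGIDI rescaling")
            continue
        goal = goals.get(trait, "increase")
        if goal not in ("increase", "decrease"):
            raise DomainError(f"trait {trait!r}: unknown goal {goal!r}")
        if goal == "increase":
            out[trait] = 100.0 * (col - lo) / (hi - lo)
        else:
            out[trait] = 100.0 * (hi - col) / (hi - lo)
        kept.append(trait)
    if len(kept) < 2:
        raise DomainError(f"need at least 2 non-constant traits, got {len(kept)}")
    df = pd.DataFrame(out)[kept]
    return RescaledMatrix(
        data=df,
        ideotype=pd.Series(100.0, index=kept),
        trait_min=data[kept].min(),
        trait_max=data[kept].max(),
        goals={t: goals.get(t, "increase") for t in kept},
        dropped=tuple(dropped),
    )


def varimax(loadings: np.ndarray, tol: float = 1e-6, max_iter: int = 1000) -> np.ndarray:
    """Orthogonal varimax rotation (no Kaiser row normalisation).

    Deterministic: starts from the identity rotation of the given loadings.
    Returns the rotated loading matrix; the rotation is orthogonal, so row
    communalities are preserved exactly up to floating point.
    """
    L = np.asarray(loadings, dtype=float)
    p, f = L.shape
    if f < 2:
        return L.copy()
    R = np.eye(f)
    var_old = 0.0
    for _ in range(max_iter):
        A = L @ R
        u, s, vt = np.linalg.svd(L.T @ (A**3 - A @ np.diag(np.sum(A**2, axis=0)) / p))
        R = u @ vt
        var_new = float(np.sum(s))
        if var_new <= var_old * (1.0 + tol):
            break
        var_old = var_new
    return L @ R


def factor_analysis(rescaled: RescaledMatrix) -> FactorModel:
    """Kaiser-retained, varimax-rotated factor model of the rescaled traits,
    with OLS factor scores for the genotypes and the ideotype."""
    X = rescaled.data
    n, p = X.shape
    if p < 2 or n < 3:
        raise DomainError(f"need >= 2 traits and >= 3 genotypes, got {p} x {n}")
    mu, sd = X.mean(), X.std(ddof=1)
    if (sd == 0).any():
        raise DomainError(f"constant rescaled trait(s): {list(sd.index[sd == 0])}")
    Z = ((X - mu) / sd).to_numpy()
    corr = np.corrcoef(Z, rowvar=False)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0.0, None), v[:, order]
    f = int(np.sum(w >= 1.0))
    if f == 0:
        raise DomainError("no eigenvalue >= 1; factor analysis needs correlated traits")
    # deterministic sign on eigenvectors before scaling
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    v = v * flip
    L0 = v[:, :f] * np.sqrt(w[:f])
    A = varimax(L0)
    # orient each rotated factor so its largest-magnitude loading is positive
    flip = np.sign(A[np.argmax(np.abs(A), axis=0), np.arange(f)])
    flip[flip == 0] = 1.0
    A = A * flip
    comm = np.sum(A**2, axis=1)
    factor_names = [f"FA{j + 1}" for j in range(f)]
    # OLS scores: F = Z A (A'A)^{-1}
    AtA_inv_At = np.linalg.solve(A.T @ A, A.T)
    scores = Z @ AtA_inv_At.T
    z_ideo = ((rescaled.ideotype - mu) / sd).to_numpy()
    ideo_scores = AtA_inv_At @ z_ideo
    return FactorModel(
        eigenvalues=w,
        n_factors=f,
        loadings_initial=pd.DataFrame(L0, index=X.columns, columns=factor_names),
        loadings=pd.DataFrame(A, index=X.columns, columns=factor_names),
        communalities=pd.Series(comm, index=X.columns, name="communality"),
        uniquenesses=pd.Series(1.0 - comm, index=X.columns, name="uniqueness"),
        scores=pd.DataFrame(scores, index=X.index, columns=factor_names),
        ideotype_scores=pd.Series(ideo_scores, index=factor_names, name="ideotype"),
    )


def mgidi_index(model: FactorModel) -> MgidiResult:
    """Genotype-ideotype distances, ascending ranking and factor contributions."""
    diff = model.scores - model.ideotype_scores
    sq = diff**2
    mgidi = np.sqrt(sq.sum(axis=1))
    mgidi.name = "MGIDI"
    denom = sq.sum(axis=1)
    contrib = sq.div(denom.where(denom > 0), axis=0)
    contrib = contrib.fillna(1.0 / model.n_factors)  # exact ideotype match: flat profile
    order = sorted(mgidi.index, key=lambda g: (mgidi[g], g))
    ranking = pd.Series(
        np.arange(1, len(order) + 1), index=pd.Index(order, name=mgidi.index.name), name="rank"
    )
    return MgidiResult(mgidi=mgidi, ranking=ranking, contributions=contrib, model=model)


def select(result: MgidiResult, intensity: float = 0.20) -> list[str]:
    """The round(intensity * t) genotypes closest to the ideotype (round half up)."""
    if not 0 < intensity <= 1:
        raise DomainError(f"selection intensity must be in (0, 1], got {intensity}")
    t = len(result.mgidi)
    n_sel = int(math.floor(intensity * t + 0.5))
    n_sel = max(n_sel, 1)
    return list(result.ranking.index[:n_sel])


def selection_differentials(
    means: pd.DataFrame,
    selected: list[str],
    h2_percent: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-trait mean(selected) - mean(all), also in percent of the overall
    mean; optionally the expected gain SD% x h2 when heritabilities are given."""
    pop = means.dropna(axis=0, how="any")
    sel = pop.loc[[g for g in selected if g in pop.index]]
    mean_all = pop.mean()
    sd = sel.mean() - mean_all
    with np.errstate(divide="ignore", invalid="ignore"):
        sd_pct = 100.0 * sd / mean_all
    out = pd.DataFrame(
        {
            "mean_all": mean_all,
            "mean_selected": sel.mean(),
            "SD": sd,
            "SD_pct": sd_pct,
        }
    )
    if h2_percent is not None:
        out["expected_gain_pct"] = out["SD_pct"] * h2_percent.reindex(out.index) / 100.0
    out.index.name = "trait"
    return out


def run_mgidi(
    means: pd.DataFrame,
    goals: dict[str, str] | None = None,
    intensity: float = 0.20,
) -> tuple[MgidiResult, list[str], pd.DataFrame]:
    """Rescale -> factor analysis -> index -> selection, in one call."""
    resc = rescale(means, goals)
    model = factor_analysis(resc)
    result = mgidi_index(model)
    chosen = select(result, intensity)
    diffs = selection_differentials(means, chosen)
    return result, chosen, diffs
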