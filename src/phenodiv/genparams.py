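"""Quantitative-genetic variability parameters and descriptive statistics.

From the treatment-adjusted ANOVA of each trait:

* error variance         sigma2_e = residual mean square (MSE)
* genotypic variance     sigma2_g = max(0, MSG - MSE)   (MSG = accession MS)
* phenotypic variance    sigma2_p = sigma2_g + sigma2_e
* GCV / PCV (%)          100 * sigma_g / mean,  100 * sigma_p / mean
* heritability h2 (%)    100 * sigma2_g / sigma2_p  (broad sense)
* genetic advance        GA = k * h2 * sigma_p  (h2 as a fraction),
  GAM (%) = 100 * GA / mean

The selection constant k is the standardised selection differential of
truncation selection; the default 2.063 corresponds to selecting the best
5 % of a normal population. Coefficient-of-variation and genetic-advance
percentages are banded low/medium/high at <10 / 10-20 / >20 (the
Sivasubramanian-Madhavamenon convention) and heritability at 0-30 / 30-60 /
>60.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import AdjustedMeans, AnovaTable, adjust_entry_means, anova_treatment_adjusted
from .errors import DomainError
from .trial import AugmentedTrial

__all__ = [
    "DEFAULT_SELECTION_K",
    "VarianceComponents",
    "VariabilityEstimates",
    "DescriptiveStats",
    "variance_components",
    "coefficient_of_variation",
    "heritability",
    "heritability_category",
    "genetic_advance",
    "categorize_cv",
    "descriptive_stats",
    "variability_estimates",
    "variability_table",
    "descriptive_table",
]

#: Standardised selection differential at a 5 % selected fraction.
DEFAULT_SELECTION_K = 2.063


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float
    sigma2_p: float
    sigma2_e: float
    floored: bool  # True when MSG < MSE and sigma2_g was floored at 0


@dataclass(frozen=True)
class VariabilityEstimates:
    """One trait's full Table-of-genetic-parameters row."""

    trait: str
    mean: float
    sigma2_g: float
    sigma2_p: float
    sigma2_e: float
    gcv: float
    pcv: float
    h2: float  # percent
    ga: float
    gam: float
    categories: dict[str, str]  # {"GCV","PCV","h2","GAM"} -> {"L","M","H"}
    floored: bool = False
    degenerate: bool = False


@dataclass(frozen=True)
class DescriptiveStats:
    trait: str
    max: float
    min: float
    mean: float
    std: float  # sample SD (n-1)
    cv: float  # percent
    degenerate: bool = False


def variance_components(msg: float, mse: float) -> VarianceComponents:
    """Moment estimators from the accession and residual mean squares.

    A negative MSG - MSE difference is floored at zero (and flagged), the
    standard convention for method-of-moments variance components.
    """
    sigma2_e = float(mse)
    diff = float(msg) - float(mse)
    floored = diff < 0
    sigma2_g = max(diff, 0.0)
    return VarianceComponents(sigma2_g, sigma2_g + sigma2_e, sigma2_e, floored)


def coefficient_of_variation(variance: float, mean: float) -> float:
    """100 * sqrt(variance) / mean."""
    if mean <= 0:
        raise DomainError(f"coefficient of variation needs a positive mean, got {mean}")
    if variance < 0:
        raise DomainError(f"variance must be non-negative, got {variance}")
    return 100.0 * math.sqrt(variance) / mean


def heritability(sigma2_g: float, sigma2_p: float) -> float:
    """Broad-sense heritability in percent; NaN-free but flags sigma2_p = 0."""
    if sigma2_p <= 0:
        raise DomainError("heritability undefined for sigma2_p <= 0 (degenerate trait)")
    return 100.0 * sigma2_g / sigma2_p


def categorize_cv(value: float) -> str:
    """L (<10), M (10-20), H (>20); applied to GCV, PCV and GAM percentages."""
    if value < 0:
        raise DomainError(f"negative coefficient {value}")
    if value < 10.0:
        return "L"
    if value <= 20.0:
        return "M"
    return "H"


def heritability_category(h2_percent: float) -> str:
    """L (0-30), M (30-60), H (>60)."""
    if h2_percent <= 30.0:
        return "L"
    if h2_percent <= 60.0:
        return "M"
    return "H"


def genetic_advance(
    h2_fraction: float,
    sigma_p: float,
    k: float = DEFAULT_SELECTION_K,
    mean: float | None = None,
) -> tuple[float, float]:
    """Expected gain under truncation selection: GA = k * h2 * sigma_p.

    Returns (GA in trait units, GAM in percent of the mean). ``mean`` is
    required (and must be positive) for GAM.
    """
    if sigma_p < 0:
        raise DomainError(f"sigma_p must be non-negative, got {sigma_p}")
    if k <= 0:
        raise DomainError(f"selection constant k must be positive, got {k}")
    ga = k * h2_fraction * sigma_p
    if mean is None:
        return ga, float("nan")
    if mean <= 0:
        raise DomainError(f"GAM needs a positive mean, got {mean}")
    return ga, 100.0 * ga / mean


def descriptive_stats(adjusted: AdjustedMeans | pd.Series, trait: str | None = None) -> DescriptiveStats:
    """Min/max/mean/sample-SD/CV% over the genotype adjusted means."""
    if isinstance(adjusted, AdjustedMeans):
        series = adjusted.as_series()
        trait = trait or adjusted.trait
    else:
        series = adjusted.dropna()
        trait = trait or str(adjusted.name)
    x = series.to_numpy(dtype=float)
    if len(x) < 2:
        return DescriptiveStats(trait, float("nan"), float("nan"), float("nan"), float("nan"), float("nan"), degenerate=True)
    std = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    cv = 100.0 * std / mean if mean > 0 else float("nan")
    return DescriptiveStats(trait, float(np.max(x)), float(np.min(x)), mean, std, cv)


def variability_estimates(
    anova: AnovaTable,
    mean: float,
    k: float = DEFAULT_SELECTION_K,
) -> VariabilityEstimates:
    """Assemble the full per-trait parameter row from an ANOVA table and the
    mean of the adjusted genotype means."""
    vc = variance_components(anova.ms_accession, anova.ms_residual)
    if vc.sigma2_p <= 0 or anova.degenerate:
        return VariabilityEstimates(
            trait=anova.trait, mean=mean, sigma2_g=vc.sigma2_g, sigma2_p=vc.sigma2_p,
            sigma2_e=vc.sigma2_e, gcv=float("nan"), pcv=float("nan"), h2=float("nan"),
            ga=float("nan"), gam=float("nan"), categories={}, floored=vc.floored, degenerate=True,
        )
    gcv = coefficient_of_variation(vc.sigma2_g, mean)
    pcv = coefficient_of_variation(vc.sigma2_p, mean)
    h2 = heritability(vc.sigma2_g, vc.sigma2_p)
    ga, gam = genetic_advance(h2 / 100.0, math.sqrt(vc.sigma2_p), k=k, mean=mean)
    return VariabilityEstimates(
        trait=anova.trait,
        mean=mean,
        sigma2_g=vc.sigma2_g,
        sigma2_p=vc.sigma2_p,
        sigma2_e=vc.sigma2_e,
        gcv=gcv,
        pcv=pcv,
        h2=h2,
        ga=ga,
        gam=gam,
        categories={
            "GCV": categorize_cv(gcv),
            "PCV": categorize_cv(pcv),
            "h2": heritability_category(h2),
            "GAM": categorize_cv(gam),
        },
        floored=vc.floored,
    )


def variability_table(
    trial: AugmentedTrial,
    k: float = DEFAULT_SELECTION_K,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Per-trait genetic-parameter table (PV, GV, GCV, PCV, h2, GA, GAM with
    category letters), computed from scratch for every trait of the trial."""
    rows = []
    for t in traits or trial.trait_abbreviations:
        anova = anova_treatment_adjusted(trial, t)
        adj = adjust_entry_means(trial, t)
        mean = float(np.mean(list(adj.values.values())))
        est = variability_estimates(anova, mean, k=k)
        rows.append(
            {
                "trait": est.trait,
                "mean": est.mean,
                "PV": est.sigma2_p,
                "GV": est.sigma2_g,
                "EV": est.sigma2_e,
                "GCV": est.gcv,
                "GCV_cat": est.categories.get("GCV", ""),
                "PCV": est.pcv,
                "PCV_cat": est.categories.get("PCV", ""),
                "h2": est.h2,
                "h2_cat": est.categories.get("h2", ""),
                "GA": est.ga,
                "GAM": est.gam,
                "GAM_cat": est.categories.get("GAM", ""),
                "floored": est.floored,
                "degenerate": est.degenerate,
            }
        )
    return pd.DataFrame(rows)


def descriptive_table(trial: AugmentedTrial, traits: list[str] | None = None) -> pd.DataFrame:
    """Max/Min/Mean/Std/CV table over adjusted genotype means, one row per trait."""
    rows = []
    for t in traits or trial.trait_abbreviations:
        d = descriptive_stats(adjust_entry_means(trial, t))
        rows.append(
            {"trait": d.trait, "max": d.max, "min": d.min, "mean": d.mean, "std": d.std, "CV": d.cv}
        )
    return pd.DataFrame(rows)
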