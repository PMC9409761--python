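"""Genotype-ideotype distance index: rescaling, factor analysis, the index
itself and truncation selection, pinned by a brute-force toy oracle."""

import numpy as np
import pandas as pd
import pytest

from phenodiv.anova import adjusted_means_frame
from phenodiv.errors import DomainError
from phenodiv.mgidi import (
    factor_analysis,
    mgidi_index,
    rescale,
    run_mgidi,
    select,
    selection_differentials,
    varimax,
)


def toy_means(n=10, p=4, seed=0):
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n, 2))
    load = rng.standard_normal((2, p))
    x = latent @ load + 0.3 * rng.standard_normal((n, p))
    return pd.DataFrame(
        x, index=[f"G{i:02d}" for i in range(n)], columns=[f"T{j}" for j in range(p)]
    )


# --- rescaling --------------------------------------------------------------

def test_rescale_bounds_and_directions():
    means = toy_means()
    goals = {"T0": "increase", "T1": "decrease"}
    resc = rescale(means, goals)
    assert ((resc.data >= 0) & (resc.data <= 100)).all().all()
    best_up = means["T0"].idxmax()
    assert resc.data.loc[best_up, "T0"] == pytest.approx(100.0)
    best_down = means["T1"].idxmin()
    assert resc.data.loc[best_down, "T1"] == pytest.approx(100.0)
    assert (resc.ideotype == 100.0).all()


def test_rescale_midpoint_linearity():
    means = pd.DataFrame(
        {"A": [0.0, 5.0, 10.0], "B": [2.0, 3.0, 4.0]}, index=["g1", "g2", "g3"]
    )
    resc = rescale(means, {"A": "increase", "B": "increase"})
    assert resc.data.loc["g2", "A"] == pytest.approx(50.0)


def test_rescale_drops_constant_trait():
    means = toy_means()
    means["T3"] = 7.0
    with pytest.warns(UserWarning, match="constant"):
        resc = rescale(means, {})
    assert resc.dropped == ("T3",)
    assert "T3" not in resc.data.columns


# --- varimax / factor analysis ---------------------------------------------

def test_varimax_preserves_communalities():
    rng = np.random.default_rng(1)
    L = rng.standard_normal((17, 5))
    A = varimax(L)
    assert np.allclose((A**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-8)


def test_varimax_criterion_nondecreasing():
    """The varimax objective (variance of squared loadings per factor) never
    decreases from the unrotated start."""

    def criterion(M, p):
        sq = M**2
        return float(np.sum(sq**2) - np.sum(sq.sum(axis=0) ** 2) / p)

    rng = np.random.default_rng(2)
    means = pd.DataFrame(
        rng.standard_normal((103, 17)) + rng.standard_normal((103, 1)),
        index=[f"G{i:03d}" for i in range(103)],
        columns=[f"T{j}" for j in range(17)],
    )
    model = factor_analysis(rescale(means, {}))
    L0 = model.loadings_initial.to_numpy()
    A = model.loadings.to_numpy()
    assert criterion(A, L0.shape[0]) >= criterion(L0, L0.shape[0]) - 1e-10


def test_two_perfectly_correlated_traits_single_factor():
    base = np.linspace(0.0, 1.0, 20)
    means = pd.DataFrame(
        {"A": base, "B": 2 * base + 1}, index=[f"G{i:02d}" for i in range(20)]
    )
    model = factor_analysis(rescale(means, {}))
    assert model.n_factors == 1
    assert np.allclose(model.communalities, 1.0, atol=1e-8)


def test_factor_model_invariants(study_trial):
    means = adjusted_means_frame(study_trial)
    model = factor_analysis(rescale(means, {}))
    assert 1 <= model.n_factors < means.shape[1]
    comm = model.communalities
    assert ((comm >= -1e-9) & (comm <= 1 + 1e-9)).all()
    # rotation preserves the communality of every trait
    init_comm = (model.loadings_initial**2).sum(axis=1)
    assert np.allclose(comm, init_comm, atol=1e-8)


# --- index ------------------------------------------------------------------

def test_ideotype_equal_genotype_has_zero_distance():
    rng = np.random.default_rng(3)
    means = toy_means(n=12, seed=3)
    # make one genotype the best on every trait
    means.loc["G00"] = means.max() + 1.0
    resc = rescale(means, {})
    assert np.allclose(resc.data.loc["G00"], 100.0)
    model = factor_analysis(resc)
    result = mgidi_index(model)
    assert result.mgidi["G00"] == pytest.approx(0.0, abs=1e-8)
    assert result.ranking.index[0] == "G00"
    # its factor-contribution row still sums to 1 (flat by convention)
    assert result.contributions.loc["G00"].sum() == pytest.approx(1.0)


def test_contributions_sum_to_one(study_trial):
    means = adjusted_means_frame(study_trial)
    goals = {t.abbreviation: t.goal for t in study_trial.traits}
    result, chosen, _ = run_mgidi(means, goals=goals)
    assert np.allclose(result.contributions.sum(axis=1), 1.0, atol=1e-9)
    assert (result.mgidi >= 0).all()


def test_single_factor_ranking_is_absolute_score_distance():
    base = np.linspace(0.0, 1.0, 15)
    rng = np.random.default_rng(4)
    means = pd.DataFrame(
        {"A": base, "B": 2 * base + 0.01 * rng.standard_normal(15)},
        index=[f"G{i:02d}" for i in range(15)],
    )
    model = factor_analysis(rescale(means, {}))
    assert model.n_factors == 1
    result = mgidi_index(model)
    dist = (model.scores.iloc[:, 0] - model.ideotype_scores.iloc[0]).abs()
    expected_order = sorted(dist.index, key=lambda g: (dist[g], g))
    assert list(result.ranking.index) == expected_order


def test_mgidi_bruteforce_oracle():
    """End-to-end recomputation on a 10 x 4 toy matrix with independent
    numpy code (explicit eigendecomposition, rotation via the package's
    varimax on the same loadings, explicit OLS scores)."""
    means = toy_means(n=10, p=4, seed=7)
    goals = {"T0": "increase", "T1": "decrease", "T2": "increase", "T3": "increase"}
    result, _, _ = run_mgidi(means, goals=goals)

    # independent route
    data = means.copy()
    resc = pd.DataFrame(index=data.index, columns=data.columns, dtype=float)
    for trait in data.columns:
        lo, hi = data[trait].min(), data[trait].max()
        if goals[trait] == "increase":
            resc[trait] = 100 * (data[trait] - lo) / (hi - lo)
        else:
            resc[trait] = 100 * (hi - data[trait]) / (hi - lo)
    mu, sd = resc.mean(), resc.std(ddof=1)
    Z = ((resc - mu) / sd).to_numpy()
    corr = np.corrcoef(Z, rowvar=False)
    w, v = np.linalg.eigh(corr)
    idx = np.argsort(w)[::-1]
    w, v = w[idx], v[:, idx]
    f = int(np.sum(w >= 1.0))
    L = v[:, :f] * np.sqrt(w[:f])
    A = varimax(L)
    scores = Z @ A @ np.linalg.inv(A.T @ A)
    ideo = ((pd.Series(100.0, index=data.columns) - mu) / sd).to_numpy()
    ideo_scores = np.linalg.inv(A.T @ A) @ A.T @ ideo
    expected = np.sqrt(((scores - ideo_scores) ** 2).sum(axis=1))
    assert np.allclose(result.mgidi.to_numpy(), expected, atol=1e-8)


def test_scale_invariance():
    """Multiplying a trait by a positive constant does not change the index."""
    means = toy_means(seed=8)
    a, _, _ = run_mgidi(means, goals={})
    scaled = means.copy()
    scaled["T2"] = scaled["T2"] * 37.5
    b, _, _ = run_mgidi(scaled, goals={})
    assert np.allclose(a.mgidi, b.mgidi, atol=1e-8)


# --- selection --------------------------------------------------------------

def test_selection_count_round_half_up(study_trial):
    means = adjusted_means_frame(study_trial)
    result, _, _ = run_mgidi(means, goals={})
    assert len(select(result, 0.20)) == 21  # 103 * 0.20 = 20.6 -> 21
    assert len(select(result, 1.0)) == 103
    with pytest.raises(DomainError):
        select(result, 0.0)


def test_full_intensity_zero_differential():
    means = toy_means(seed=9)
    result, _, _ = run_mgidi(means, goals={})
    diffs = selection_differentials(means, select(result, 1.0))
    assert np.allclose(diffs["SD"], 0.0, atol=1e-12)


def test_dominant_genotype_selected_with_positive_differential():
    rng = np.random.default_rng(10)
    means = toy_means(n=20, seed=10)
    means["YIELD"] = rng.normal(10.0, 0.5, 20)
    means.loc["G00", means.columns] = means.max() + 2.0  # dominant everywhere
    result, chosen, diffs = run_mgidi(means, goals={}, intensity=0.2)
    assert "G00" in chosen
    assert diffs.loc["YIELD", "SD_pct"] > 0


def test_goal_reversal_flips_differential_direction():
    """On data where one trait increases monotonically with overall merit,
    flipping its goal flips the sign of its selection differential."""
    n = 30
    merit = np.linspace(0.0, 1.0, n)
    rng = np.random.default_rng(11)
    means = pd.DataFrame(
        {
            "A": merit + 0.05 * rng.standard_normal(n),
            "B": merit + 0.05 * rng.standard_normal(n),
            "C": merit + 0.05 * rng.standard_normal(n),
        },
        index=[f"G{i:02d}" for i in range(n)],
    )
    up = run_mgidi(means, goals={"A": "increase", "B": "increase", "C": "increase"})
    down = run_mgidi(means, goals={"A": "decrease", "B": "decrease", "C": "decrease"})
    assert up[2].loc["A", "SD"] > 0
    assert down[2].loc["A", "SD"] < 0
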