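"""Correlation, PCA and hierarchical clustering of genotype means."""

import numpy as np
import pandas as pd
import pytest

from phenodiv.anova import adjusted_means_frame
from phenodiv.errors import DomainError
from phenodiv.multivariate import (
    biplot_coordinates,
    cluster_traits,
    correlation_matrix,
    correlation_star,
    hierarchical_cluster,
    pca,
)


@pytest.fixture(scope="module")
def study_means(study_trial):
    return adjusted_means_frame(study_trial)


def random_means(n=40, p=5, seed=0, corr=None):
    rng = np.random.default_rng(seed)
    if corr is None:
        x = rng.standard_normal((n, p))
    else:
        chol = np.linalg.cholesky(corr)
        x = rng.standard_normal((n, p)) @ chol.T
    return pd.DataFrame(x, index=[f"G{i:03d}" for i in range(n)], columns=[f"T{j}" for j in range(p)])


# --- correlation ------------------------------------------------------------

def test_correlation_basics():
    means = random_means(seed=1)
    means["T1"] = 2.0 * means["T0"]  # exact linear dependence
    res = correlation_matrix(means)
    assert np.allclose(np.diag(res.r), 1.0)
    assert res.r.loc["T0", "T1"] == pytest.approx(1.0)
    assert res.p.loc["T0", "T1"] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.r, res.r.T)
    assert np.allclose(res.p, res.p.T)
    assert (np.abs(res.r.to_numpy()) <= 1 + 1e-12).all()


def test_correlation_sampling_distribution():
    """r-hat over repeated bivariate normal samples (rho=0.7, n=103)
    averages to 0.70 within 0.01."""
    rho = 0.7
    corr = np.array([[1.0, rho], [rho, 1.0]])
    rs = []
    for seed in range(300):
        means = random_means(n=103, p=2, seed=seed, corr=corr)
        rs.append(correlation_matrix(means).r.iloc[0, 1])
    assert np.mean(rs) == pytest.approx(rho, abs=0.01)


def test_correlation_psd(study_means):
    res = correlation_matrix(study_means)
    eig = np.linalg.eigvalsh(res.r.to_numpy())
    assert eig.min() > -1e-10


def test_constant_trait_flagged():
    means = random_means(seed=2)
    means["T4"] = 3.14
    res = correlation_matrix(means)
    assert res.constant_traits == ("T4",)
    assert res.r["T4"].drop("T4").isna().all()


def test_correlation_stars():
    assert correlation_star(0.0005) == "***"
    assert correlation_star(0.005) == "**"
    assert correlation_star(0.03) == "*"
    assert correlation_star(0.5) == ""


# --- PCA --------------------------------------------------------------------

def test_pca_two_trait_closed_form():
    """For two standardised traits with correlation r the eigenvalues are
    1+r and 1-r."""
    rho = 0.6
    means = random_means(n=500, p=2, seed=3, corr=np.array([[1, rho], [rho, 1]]))
    res = pca(means)
    r_hat = np.corrcoef(means.T)[0, 1]
    assert res.eigenvalues == pytest.approx([1 + r_hat, 1 - r_hat], abs=1e-10)


def test_pca_identity_correlation():
    means = random_means(n=2000, p=4, seed=4)
    res = pca(means)
    assert np.all(np.abs(res.eigenvalues - 1.0) < 0.15)


def test_pca_invariants(study_means):
    res = pca(study_means)
    p = study_means.shape[1]
    assert res.eigenvalues.sum() == pytest.approx(p, abs=1e-8)
    assert res.cumulative[-1] == pytest.approx(100.0, abs=1e-8)
    v = res.loadings.to_numpy()
    assert np.allclose(v.T @ v, np.eye(p), atol=1e-8)
    # reconstruction: scores @ loadings' == standardised data
    z = (study_means - study_means.mean()) / study_means.std(ddof=1)
    recon = res.scores.to_numpy() @ v.T
    assert np.allclose(recon, z.to_numpy(), atol=1e-8)
    assert res.n_retained == int(np.sum(res.eigenvalues >= 1.0))


def test_biplot_geometry():
    """Perfectly correlated traits give parallel arrows; anti-correlated
    traits point to opposite sides of the origin."""
    rng = np.random.default_rng(5)
    base = rng.standard_normal(60)
    means = pd.DataFrame(
        {
            "A": base,
            "B": 3.0 * base + 1.0,
            "C": -2.0 * base + 5.0,
            "D": rng.standard_normal(60),
        },
        index=[f"G{i:02d}" for i in range(60)],
    )
    res = pca(means)
    points, arrows = biplot_coordinates(res, (1, 2))
    assert list(points.columns) == ["PC1", "PC2"]
    a, b, c = arrows.loc["A"], arrows.loc["B"], arrows.loc["C"]
    cos_ab = a @ b / np.sqrt((a @ a) * (b @ b))
    cos_ac = a @ c / np.sqrt((a @ a) * (c @ c))
    assert cos_ab == pytest.approx(1.0, abs=1e-6)  # 0 degrees
    assert cos_ac == pytest.approx(-1.0, abs=1e-6)  # opposite sides
    with pytest.raises(DomainError):
        biplot_coordinates(res, (1, 99))


def test_biplot_reproduces_score_columns(study_means):
    res = pca(study_means)
    points, _ = biplot_coordinates(res, (2, 3))
    assert points.equals(res.scores[["PC2", "PC3"]])


# --- clustering -------------------------------------------------------------

def test_distance_matrix_matches_bruteforce(study_means):
    res = hierarchical_cluster(study_means, k=6)
    z = (study_means - study_means.mean()) / study_means.std(ddof=1)
    z = z.loc[res.distances.index]
    ids = list(z.index)
    for i in (0, 17, 50):
        for j in (3, 44, 102):
            d = np.sqrt(((z.iloc[i] - z.iloc[j]) ** 2).sum())
            assert res.distances.loc[ids[i], ids[j]] == pytest.approx(d, abs=1e-10)
    assert np.allclose(res.distances, res.distances.T)
    assert np.allclose(np.diag(res.distances), 0.0)


def test_identical_genotypes_merge_first():
    means = random_means(n=10, p=3, seed=6)
    means.iloc[1] = means.iloc[0]
    res = hierarchical_cluster(means, k=9)
    assert res.distances.iloc[0, 1] == 0.0
    # the pair shares a cluster even at K = n-1
    assert res.assignments.iloc[0] == res.assignments.iloc[1]


def test_k_equals_n(study_means):
    res = hierarchical_cluster(study_means, k=len(study_means))
    assert res.assignments.nunique() == len(study_means)
    for g in study_means.index[:5]:
        lab = res.assignments[g]
        assert np.allclose(res.cluster_means.loc[lab], study_means.loc[g])


def test_cluster_order_invariance(study_means):
    shuffled = study_means.sample(frac=1.0, random_state=0)
    a = hierarchical_cluster(study_means, k=6)
    b = hierarchical_cluster(shuffled, k=6)
    assert a.assignments.sort_index().equals(b.assignments.sort_index())


def test_cluster_means_recompose_grand_mean(study_means):
    res = hierarchical_cluster(study_means, k=6)
    sizes = res.assignments.value_counts().sort_index()
    weighted = (res.cluster_means.mul(sizes, axis=0)).sum() / sizes.sum()
    assert np.allclose(weighted, study_means.mean(), atol=1e-9)


def test_linkage_heights_monotone(study_means):
    for method in ("complete", "average", "ward"):
        res = hierarchical_cluster(study_means, k=6, linkage=method)
        heights = res.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-10)


def test_k_out_of_range(study_means):
    with pytest.raises(DomainError):
        hierarchical_cluster(study_means, k=0)
    with pytest.raises(DomainError):
        hierarchical_cluster(study_means, k=len(study_means) + 1)


def test_trait_dendrogram(study_means):
    res = cluster_traits(study_means, k=4)
    assert set(res.assignments.index) == set(study_means.columns)
    assert res.assignments.nunique() == 4
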