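"""Synthetic augmented trials and qualitative tables with known ground truth.

The generative model mirrors the additive structure the downstream analysis
assumes: for a test entry *i* in block *j*,

    y_ij = mu + g_i + beta_j + eps_ij

with genotypic effects g ~ MVN(0, Sigma_g) (tests only; checks carry fixed
deviations), block effects beta_j ~ N(0, sigma_b^2) iid per trait, and plot
errors eps ~ MVN(0, Sigma_e). Because every quantity is drawn with known
variances, every downstream estimator has a recoverable target.

The default configuration emulates a cucumber landrace characterisation
trial: 4 blocks, 3 replicated check varieties, 100 unreplicated test
entries (112 plots), and 17 correlated quantitative traits whose means,
genotypic variances, error variances and block variances are set to the
published summary statistics of that trial. Seventeen qualitative
descriptors are simulated as multinomial draws at the published state
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .trial import (
    AugmentedTrial,
    PlotRecord,
    QualitativeDescriptorSpec,
    QualitativeTable,
    TraitSpec,
)

__all__ = [
    "SimulationConfig",
    "TrueParams",
    "simulate_augmented_trial",
    "simulate_qualitative",
    "paper_like_fixture",
    "default_trait_specs",
    "default_simulation_config",
    "default_qualitative_frequencies",
]

# ---------------------------------------------------------------------------
# Default trait panel: 17 quantitative traits of a cucumber landrace trial.
# Columns: abbreviation, full name, units, selection goal, trial mean,
# genotypic variance, error variance, block mean square.
# Variances derive from the trial's variance-component analysis
# (sigma2_g = accession MS - residual MS, floored at 0; sigma2_e = residual MS).
# ---------------------------------------------------------------------------
_TRAIT_TABLE = [
    # abbr, name, units, goal, mean, sigma2_g, sigma2_e, ms_block
    ("PH", "Vine length", "cm", "increase", 221.00, 1423.59, 84.28, 5.14),
    ("BPP", "Primary branches per plant", "", "increase", 4.60, 0.39, 0.08, 0.13),
    ("DI", "Internode length", "cm", "increase", 7.44, 3.93, 0.34, 0.37),
    ("DM", "Days to first male flower", "d", "decrease", 39.11, 4.75, 6.31, 10.97),
    ("DFM", "Days to first female flower", "d", "decrease", 47.59, 0.0, 18.42, 4.75),
    ("NMF", "Node of first male flower", "", "increase", 5.78, 0.31, 0.95, 0.58),
    ("NMFF", "Node of first female flower", "", "increase", 9.91, 0.64, 1.08, 0.24),
    ("LN", "Leaf length", "cm", "increase", 14.01, 4.28, 0.91, 0.56),
    ("LW", "Leaf width", "cm", "increase", 17.38, 6.06, 1.55, 2.37),
    ("FFH", "Days to first fruit harvest", "d", "decrease", 59.76, 0.0, 14.92, 10.33),
    ("FL", "Fruit length", "cm", "increase", 17.53, 11.49, 1.62, 1.10),
    ("FD", "Fruit width", "cm", "increase", 5.91, 0.65, 0.23, 0.11),
    ("FW", "Fruit weight", "g", "increase", 298.60, 7551.91, 482.59, 413.80),
    ("NFP", "Fruits per plant", "", "increase", 5.41, 2.06, 0.37, 0.14),
    ("DH", "Days to mature fruit harvest", "d", "decrease", 85.59, 15.07, 2.97, 4.31),
    ("YP", "Yield per plant", "kg", "increase", 1.93, 0.35, 0.04, 0.01),
    ("HSW", "Hundred-seed weight", "g", "increase", 2.68, 0.11, 0.03, 0.18),
]

# Trait groups with correlated genetic effects (phenology, vigour/yield,
# fruit size, leaf architecture), matching the grouping the trait dendrogram
# of such trials typically shows.
_TRAIT_GROUPS = [
    ("DH", "FFH", "DFM", "DM", "NMFF", "NMF"),
    ("PH", "YP", "NFP", "BPP"),
    ("HSW", "FL", "FD", "FW"),
    ("LN", "LW", "DI"),
]
_RHO_WITHIN, _RHO_BETWEEN = 0.6, 0.1


def default_trait_specs() -> list[TraitSpec]:
    return [TraitSpec(abbreviation=a, name=n, units=u, goal=g) for a, n, u, g, *_ in _TRAIT_TABLE]


def _default_genetic_correlation() -> np.ndarray:
    abbrs = [row[0] for row in _TRAIT_TABLE]
    group_of = {t: gi for gi, grp in enumerate(_TRAIT_GROUPS) for t in grp}
    p = len(abbrs)
    corr = np.full((p, p), _RHO_BETWEEN)
    for i in range(p):
        for j in range(p):
            if group_of[abbrs[i]] == group_of[abbrs[j]]:
                corr[i, j] = _RHO_WITHIN
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated augmented trial."""

    b: int = 4
    c: int = 3
    n: int = 100
    traits: list[TraitSpec] = field(default_factory=default_trait_specs)
    trait_means: np.ndarray | None = None  # mu per trait
    genetic_cov: np.ndarray | None = None  # Sigma_g, PSD
    error_cov: np.ndarray | None = None  # Sigma_e, PD
    block_sd: np.ndarray | float = 0.0  # sigma_b per trait (scalar broadcast)
    check_effects: np.ndarray | None = None  # c x p fixed deviations
    seed: int = 0

    def __post_init__(self):
        p = len(self.traits)
        if self.trait_means is None:
            self.trait_means = np.zeros(p)
        self.trait_means = np.asarray(self.trait_means, dtype=float)
        if self.genetic_cov is None:
            self.genetic_cov = np.eye(p)
        if self.error_cov is None:
            self.error_cov = np.eye(p)
        self.genetic_cov = np.asarray(self.genetic_cov, dtype=float)
        self.error_cov = np.asarray(self.error_cov, dtype=float)
        self.block_sd = np.broadcast_to(np.asarray(self.block_sd, dtype=float), (p,)).copy()
        if self.check_effects is None:
            self.check_effects = np.zeros((self.c, p))
        self.check_effects = np.asarray(self.check_effects, dtype=float)
        self.validate()

    def validate(self) -> None:
        p = len(self.traits)
        if self.b < 2 or self.c < 2 or self.n < 1:
            raise ConfigError(f"need b >= 2, c >= 2, n >= 1; got b={self.b}, c={self.c}, n={self.n}")
        for name, mat, strict in (("genetic_cov", self.genetic_cov, False), ("error_cov", self.error_cov, True)):
            if mat.shape != (p, p):
                raise ConfigError(f"{name} must be {p}x{p}, got {mat.shape}")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ConfigError(f"{name} must be symmetric")
            eig = np.linalg.eigvalsh(mat)
            floor = 1e-10 * max(1.0, abs(eig[-1]))
            if strict and eig[0] <= 0:
                raise ConfigError(f"{name} must be positive definite (min eigenvalue {eig[0]:.3g})")
            if not strict and eig[0] < -floor:
                raise ConfigError(f"{name} must be positive semidefinite (min eigenvalue {eig[0]:.3g})")
        if self.trait_means.shape != (p,):
            raise ConfigError(f"trait_means must have length {p}")
        if np.any(self.block_sd < 0):
            raise ConfigError("block_sd must be non-negative")
        if self.check_effects.shape != (self.c, p):
            raise ConfigError(f"check_effects must be {self.c}x{p}, got {self.check_effects.shape}")


@dataclass(frozen=True)
class TrueParams:
    """Per-trait ground truth for parameter-recovery tests."""

    traits: tuple[str, ...]
    sigma2_g: np.ndarray
    sigma2_e: np.ndarray
    sigma2_b: np.ndarray
    h2_true: np.ndarray  # sigma2_g / (sigma2_g + sigma2_e), in [0, 1]
    genetic_correlation: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": list(self.traits),
                "sigma2_g": self.sigma2_g,
                "sigma2_e": self.sigma2_e,
                "sigma2_b": self.sigma2_b,
                "h2_true": self.h2_true,
            }
        )


def _mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """Draws via symmetric eigendecomposition; tolerates PSD (rank-deficient) cov."""
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((size, cov.shape[0]))
    return z @ root.T


def simulate_augmented_trial(config: SimulationConfig) -> tuple[AugmentedTrial, TrueParams]:
    """Simulate one augmented-RCBD trial under ``config``.

    Test entries are assigned to blocks as evenly as possible in a seeded
    random order; identical config (including seed) gives an identical trial.
    """
    rng = np.random.default_rng(config.seed)
    p = len(config.traits)
    abbrs = [t.abbreviation for t in config.traits]
    b, c, n = config.b, config.c, config.n

    g = _mvn(rng, config.genetic_cov, n)  # n x p genotypic effects (tests)
    beta = rng.standard_normal((b, p)) * config.block_sd  # b x p block effects
    order = rng.permutation(n)
    test_block = np.empty(n, dtype=int)
    test_block[order] = np.arange(n) % b  # balanced assignment in random order

    block_ids = [f"B{j + 1}" for j in range(b)]
    check_ids = [f"C{i + 1}" for i in range(c)]
    test_ids = [f"G{i + 1:03d}" for i in range(n)]

    records: list[PlotRecord] = []
    eps_c = _mvn(rng, config.error_cov, c * b).reshape(c, b, p)
    for i, gid in enumerate(check_ids):
        for j, blk in enumerate(block_ids):
            y = config.trait_means + config.check_effects[i] + beta[j] + eps_c[i, j]
            records.append(PlotRecord(blk, gid, "check", dict(zip(abbrs, y))))
    eps_t = _mvn(rng, config.error_cov, n)
    for i, gid in enumerate(test_ids):
        j = test_block[i]
        y = config.trait_means + g[i] + beta[j] + eps_t[i]
        records.append(PlotRecord(block_ids[j], gid, "test", dict(zip(abbrs, y))))

    trial = AugmentedTrial(
        traits=list(config.traits),
        blocks=block_ids,
        checks=check_ids,
        tests=test_ids,
        records=records,
    )
    s2g = np.diag(config.genetic_cov).copy()
    s2e = np.diag(config.error_cov).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(s2g + s2e > 0, s2g / (s2g + s2e), 0.0)
    d = np.sqrt(np.clip(s2g, 1e-300, None))
    gcorr = config.genetic_cov / np.outer(d, d)
    np.fill_diagonal(gcorr, 1.0)
    truth = TrueParams(
        traits=tuple(abbrs),
        sigma2_g=s2g,
        sigma2_e=s2e,
        sigma2_b=config.block_sd**2,
        h2_true=h2,
        genetic_correlation=gcorr,
    )
    return trial, truth


# ---------------------------------------------------------------------------
# Qualitative simulation
# ---------------------------------------------------------------------------

def simulate_qualitative(
    frequencies: dict[str, dict[int, float] | list[float]],
    n_genotypes: int,
    seed: int = 0,
    genotype_ids: list[str] | None = None,
    state_labels: dict[str, dict[int, str]] | None = None,
) -> QualitativeTable:
    """IID multinomial draws per genotype at the given state probabilities.

    ``frequencies`` maps descriptor name to either a list of probabilities
    (codes assigned 1..k) or an explicit {code: probability} map. The
    probabilities per descriptor must sum to 1 within 1e-9.
    """
    rng = np.random.default_rng(seed)
    if genotype_ids is None:
        genotype_ids = [f"G{i + 1:03d}" for i in range(n_genotypes)]
    if len(genotype_ids) != n_genotypes:
        raise ConfigError("genotype_ids length must equal n_genotypes")

    descriptors: list[QualitativeDescriptorSpec] = []
    data: dict[str, np.ndarray] = {}
    for name, probs in frequencies.items():
        if isinstance(probs, dict):
            codes = list(probs.keys())
            pvec = np.array([probs[c] for c in codes], dtype=float)
        else:
            codes = list(range(1, len(probs) + 1))
            pvec = np.asarray(probs, dtype=float)
        if np.any(pvec < 0):
            raise ConfigError(f"descriptor {name!r}: negative probability")
        if abs(pvec.sum() - 1.0) > 1e-9:
            raise ConfigError(f"descriptor {name!r}: probabilities sum to {pvec.sum()!r}, not 1")
        labels = (state_labels or {}).get(name, {})
        states = tuple((int(c), labels.get(c, f"state_{c}")) for c in codes)
        descriptors.append(QualitativeDescriptorSpec(name=name, states=states))
        draws = rng.choice(len(codes), size=n_genotypes, p=pvec)
        data[name] = np.array([codes[i] for i in draws], dtype=int)

    obs = pd.DataFrame(data, index=pd.Index(genotype_ids, name="genotype"))
    return QualitativeTable(descriptors=descriptors, observations=obs)


# Observed state counts of the 17 qualitative descriptors in the reference
# collection of 103 accessions (counts / 103 give the sampling probabilities).
_QUALITATIVE_COUNTS: dict[str, list[tuple[str, int]]] = {
    "Plant growth type": [("Indeterminate", 103)],
    "Plant growth habit": [("Viny", 94), ("Intermediate", 9)],
    "Stem colour": [("Light green", 4), ("Green", 73), ("Dark green", 26)],
    "Stem pubescence density": [("Dense", 61), ("Intermediate", 42)],
    "Leaf intensity of green colour": [("Light green", 53), ("Medium green", 41), ("Dark green", 9)],
    "Leaf blade shape": [("Orbicular", 103)],
    "Leaf apex shape": [("Obtuse", 72), ("Rounded", 31)],
    "Leaf pubescence density": [("Dense", 103)],
    "Flower colour": [("Yellow", 103)],
    "Sex type": [("Monoecious", 103)],
    "Stem end fruit shape": [("Necked", 1), ("Acute", 30), ("Obtuse", 72)],
    "Blossom end fruit shape": [("Flat", 100), ("Deep raised", 3)],
    "Fruit skin texture": [("Smooth", 31), ("Wrinkled", 72)],
    "Fruit shape": [("Oblong", 87), ("Oval", 5), ("Ellipsoid", 4), ("Ovate", 7)],
    "Fruit skin colour at table maturity": [
        ("Light green", 67), ("Green", 15), ("Dark green", 4), ("Yellowish green", 13),
        ("Greenish yellow", 2), ("Blackish green", 1), ("Whitish green", 1),
    ],
    "Fruit skin colour at mature harvest": [("Brown", 72), ("Yellow", 31)],
    "Seed colour": [("White", 43), ("Cream", 60)],
}


def default_qualitative_frequencies() -> tuple[dict[str, list[float]], dict[str, dict[int, str]]]:
    """State probabilities (counts/103) and labels of the default 17 descriptors."""
    freqs: dict[str, list[float]] = {}
    labels: dict[str, dict[int, str]] = {}
    for name, counts in _QUALITATIVE_COUNTS.items():
        total = sum(c for _, c in counts)
        freqs[name] = [c / total for _, c in counts]
        labels[name] = {i + 1: lab for i, (lab, _) in enumerate(counts)}
    return freqs, labels


def default_simulation_config(seed: int = 0) -> SimulationConfig:
    """The reference trial conditions: b=4, c=3, n=100, 17 correlated traits."""
    means = np.array([row[4] for row in _TRAIT_TABLE])
    s2g = np.array([row[5] for row in _TRAIT_TABLE])
    s2e = np.array([row[6] for row in _TRAIT_TABLE])
    ms_block = np.array([row[7] for row in _TRAIT_TABLE])
    c = 3
    sd_g = np.sqrt(s2g)
    genetic_cov = _default_genetic_correlation() * np.outer(sd_g, sd_g)
    error_cov = np.diag(s2e)
    # checks-based block MS has expectation sigma2_e + c * sigma2_b
    block_sd = np.sqrt(np.clip((ms_block - s2e) / c, 0.0, None))
    return SimulationConfig(
        b=4,
        c=c,
        n=100,
        traits=default_trait_specs(),
        trait_means=means,
        genetic_cov=genetic_cov,
        error_cov=error_cov,
        block_sd=block_sd,
        seed=seed,
    )


def paper_like_fixture(seed: int = 0) -> tuple[AugmentedTrial, QualitativeTable]:
    """A full 103-genotype / 17-trait / 17-descriptor synthetic study."""
    trial, _ = simulate_augmented_trial(default_simulation_config(seed))
    freqs, labels = default_qualitative_frequencies()
    qual = simulate_qualitative(
        freqs,
        n_genotypes=len(trial.genotypes),
        seed=seed + 1,
        genotype_ids=trial.genotypes,
        state_labels=labels,
    )
    return trial, qual
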