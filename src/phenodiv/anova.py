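"""Federer-style analysis of an augmented RCBD: block effects estimated from
the replicated checks, adjusted entry means, and the treatment-adjusted ANOVA.

Block effects come from the checks alone (block check mean minus grand check
mean); a test entry's adjusted value is its observation minus its block's
effect, and a check's adjusted value is the mean of its replicated plots
(block effects cancel there by construction).

The ANOVA decomposes the treatment sum of squares (eliminating blocks) into
Check, Accession (test entries) and Accession-vs-Check components. All
treatment sums of squares are exact least-squares hypothesis sums of squares
from the fixed-effects model ``y = block + genotype``: the residual then has
(b-1)(c-1) degrees of freedom and equals the check x block interaction, the
Check component coincides with the classical b * sum((check mean - grand
check mean)^2), and the F-tests against the residual are exact under
normality. (The textbook shortcut that sums squared deviations of adjusted
test values overstates the accession mean square by roughly
sigma2_e * (n/b)(b-1) / (c(n-1)) because adjusted values sharing a block are
positively correlated; the exact partition has no such inflation.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AdjustmentError, DomainError
from .trial import AugmentedTrial

__all__ = [
    "BlockEffects",
    "AdjustedMeans",
    "AnovaRow",
    "AnovaTable",
    "estimate_block_effects",
    "adjust_entry_means",
    "anova_treatment_adjusted",
    "adjusted_means_frame",
    "significance_code",
]

_DEGENERATE_TOL = 1e-12


def significance_code(p: float) -> str:
    """Two-star convention: ** for p <= 0.01, * for p <= 0.05, ns otherwise."""
    if not math.isfinite(p):
        return "ns"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class BlockEffects:
    trait: str
    effects: dict[str, float]  # block_id -> effect (trait units); sums to 0
    grand_check_mean: float

    def __getitem__(self, block_id: str) -> float:
        return self.effects[block_id]


@dataclass(frozen=True)
class AdjustedMeans:
    trait: str
    values: dict[str, float]  # genotype_id -> adjusted mean
    roles: dict[str, str]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.trait)


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float
    f: float  # NaN for the residual row / degenerate tables
    p: float
    significance: str


@dataclass(frozen=True)
class AnovaTable:
    trait: str
    rows: tuple[AnovaRow, ...]
    r: int  # replication count of the checks (= number of blocks)
    degenerate: bool = False

    def row(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    @property
    def ms_accession(self) -> float:
        return self.row("Accession").ms

    @property
    def ms_residual(self) -> float:
        return self.row("Residual").ms

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [r.source for r in self.rows],
                "df": [r.df for r in self.rows],
                "ss": [r.ss for r in self.rows],
                "ms": [r.ms for r in self.rows],
                "F": [r.f for r in self.rows],
                "p": [r.p for r in self.rows],
                "sig": [r.significance for r in self.rows],
            }
        )


# ---------------------------------------------------------------------------
# Layout extraction
# ---------------------------------------------------------------------------

def _trait_arrays(trial: AugmentedTrial, trait: str):
    """Non-missing plot data for one trait as flat arrays.

    Returns (y, block_idx, geno_idx, geno_ids, is_test, check_matrix) where
    check_matrix is the c x b table of check observations (NaN if missing).
    """
    if trait not in trial.trait_abbreviations:
        raise KeyError(f"unknown trait {trait!r}")
    blocks = {blk: j for j, blk in enumerate(trial.blocks)}
    genos = {g: i for i, g in enumerate(trial.genotypes)}
    c, b = len(trial.checks), len(trial.blocks)
    y, bidx, gidx = [], [], []
    check_mat = np.full((c, b), np.nan)
    for rec in trial.records:
        v = rec.value(trait)
        if math.isnan(v):
            continue
        y.append(v)
        bidx.append(blocks[rec.block_id])
        gi = genos[rec.genotype_id]
        gidx.append(gi)
        if rec.role == "check":
            check_mat[gi, blocks[rec.block_id]] = v
    return (
        np.asarray(y, dtype=float),
        np.asarray(bidx, dtype=int),
        np.asarray(gidx, dtype=int),
        trial.genotypes,
        np.asarray([g in set(trial.tests) for g in trial.genotypes]),
        check_mat,
    )


def estimate_block_effects(trial: AugmentedTrial, trait: str) -> BlockEffects:
    """Block effect = (mean of check plots in the block) - (grand check mean)."""
    _, _, _, _, _, check_mat = _trait_arrays(trial, trait)
    if np.isnan(check_mat).any():
        ci, bj = np.argwhere(np.isnan(check_mat))[0]
        raise AdjustmentError(
            f"trait {trait!r}: check {trial.checks[ci]!r} has no observation in "
            f"block {trial.blocks[bj]!r}; block effects are not estimable"
        )
    grand = check_mat.mean()
    effects = check_mat.mean(axis=0) - grand
    effects = effects - effects.mean()  # exact zero-sum against float drift
    return BlockEffects(
        trait=trait,
        effects={blk: float(e) for blk, e in zip(trial.blocks, effects)},
        grand_check_mean=float(grand),
    )


def adjust_entry_means(trial: AugmentedTrial, trait: str) -> AdjustedMeans:
    """Adjusted mean: test = observation - block effect; check = mean of its plots."""
    be = estimate_block_effects(trial, trait)
    check_set = set(trial.checks)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for rec in trial.records:
        v = rec.value(trait)
        if math.isnan(v):
            continue
        if rec.genotype_id in check_set:
            adj = v  # block effects cancel in the mean over all b blocks
        else:
            adj = v - be[rec.block_id]
        sums[rec.genotype_id] = sums.get(rec.genotype_id, 0.0) + adj
        counts[rec.genotype_id] = counts.get(rec.genotype_id, 0) + 1
    values = {g: sums[g] / counts[g] for g in trial.genotypes if g in sums}
    roles = {g: ("check" if g in check_set else "test") for g in values}
    return AdjustedMeans(trait=trait, values=values, roles=roles)


def adjusted_means_frame(trial: AugmentedTrial, traits: list[str] | None = None) -> pd.DataFrame:
    """Genotype x trait matrix of adjusted means (index sorted; trial order for columns)."""
    traits = traits or trial.trait_abbreviations
    cols = {t: adjust_entry_means(trial, t).as_series() for t in traits}
    df = pd.DataFrame(cols)
    return df.loc[sorted(df.index)]


# ---------------------------------------------------------------------------
# Exact least-squares ANOVA
# ---------------------------------------------------------------------------

class _LayoutProjectors:
    """Orthonormal column bases of the nested design matrices of one layout.

    RSS under a model with basis Q is ||y||^2 - ||Q^T y||^2; caching per
    layout makes repeated ANOVA on the same design (Monte-Carlo loops, the
    17 traits of one trial) cheap.
    """

    def __init__(self, bidx: np.ndarray, gidx: np.ndarray, is_test_geno: np.ndarray):
        n_obs = len(bidx)
        b = bidx.max() + 1
        n_gen = gidx.max() + 1

        def onehot(idx, k):
            m = np.zeros((n_obs, k))
            m[np.arange(n_obs), idx] = 1.0
            return m

        Xb = onehot(bidx, b)
        Xg = onehot(gidx, n_gen)
        role = is_test_geno[gidx].astype(int)
        # checks merged / tests merged relabelings
        check_ids = np.flatnonzero(~is_test_geno)
        test_ids = np.flatnonzero(is_test_geno)
        remap_cm = np.empty(n_gen, dtype=int)  # checks -> one group, tests keep identity
        remap_cm[check_ids] = 0
        remap_cm[test_ids] = 1 + np.arange(len(test_ids))
        remap_tm = np.empty(n_gen, dtype=int)  # tests -> one group, checks keep identity
        remap_tm[check_ids] = np.arange(len(check_ids))
        remap_tm[test_ids] = len(check_ids)

        def basis(X):
            q, r = np.linalg.qr(X)
            keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(np.diag(r)).max())
            return q[:, keep]

        self.q_block = basis(Xb)
        self.q_full = basis(np.hstack([Xb, Xg]))
        self.q_checks_merged = basis(np.hstack([Xb, onehot(remap_cm[gidx], 1 + len(test_ids))]))
        self.q_tests_merged = basis(np.hstack([Xb, onehot(remap_tm[gidx], 1 + len(check_ids))]))
        self.q_role = basis(np.hstack([Xb, onehot(role, 2)]))
        self.df_residual = n_obs - self.q_full.shape[1]

    def rss(self, which: str, y: np.ndarray) -> float:
        q = getattr(self, f"q_{which}")
        proj = q.T @ y
        return float(max(y @ y - proj @ proj, 0.0))


_PROJECTOR_CACHE: dict[tuple, _LayoutProjectors] = {}


def _projectors(bidx: np.ndarray, gidx: np.ndarray, is_test_geno: np.ndarray) -> _LayoutProjectors:
    key = (bidx.tobytes(), gidx.tobytes(), is_test_geno.tobytes())
    proj = _PROJECTOR_CACHE.get(key)
    if proj is None:
        if len(_PROJECTOR_CACHE) > 64:
            _PROJECTOR_CACHE.clear()
        proj = _PROJECTOR_CACHE[key] = _LayoutProjectors(bidx, gidx, is_test_geno)
    return proj


def anova_treatment_adjusted(trial: AugmentedTrial, trait: str) -> AnovaTable:
    """Treatment-adjusted ANOVA with Check / Accession / Accession-vs-Check rows.

    Raises :class:`DomainError` when the residual has no degrees of freedom.
    A table whose total sum of squares is (numerically) zero is returned with
    ``degenerate=True`` and NaN F statistics instead of propagating NaNs.
    """
    y, bidx, gidx, _, is_test_geno, check_mat = _trait_arrays(trial, trait)
    if np.isnan(check_mat).any():
        estimate_block_effects(trial, trait)  # raises with a precise message
    b, c = len(trial.blocks), len(trial.checks)
    n_tests = int(np.sum(is_test_geno[gidx]))
    df_res = (b - 1) * (c - 1)
    if df_res < 1:
        raise DomainError(f"residual df (b-1)(c-1) = {df_res}; design too small")

    proj = _projectors(bidx, gidx, is_test_geno)
    yc = y - y.mean()  # centring improves conditioning; SS are centred anyway
    rss_full = proj.rss("full", yc)
    ss_block = float(
        c * np.sum((check_mat.mean(axis=0) - check_mat.mean()) ** 2)
    )  # checks-based block SS, df b-1
    ss_treat = proj.rss("block", yc) - rss_full
    ss_check = proj.rss("checks_merged", yc) - rss_full
    ss_acc = proj.rss("tests_merged", yc) - rss_full
    ss_avc = max(ss_treat - ss_check - ss_acc, 0.0)

    total_ss = float(np.sum(yc**2))
    degenerate = total_ss <= _DEGENERATE_TOL * max(1.0, float(np.sum(y**2)))
    ms_res = rss_full / df_res

    def mkrow(source, df, ss):
        ms = ss / df if df > 0 else float("nan")
        if degenerate or source == "Residual" or ms_res <= 0:
            f = p = float("nan")
        else:
            f = ms / ms_res
            p = float(stats.f.sf(f, df, df_res))
        return AnovaRow(source, df, float(ss), float(ms), float(f), float(p), significance_code(p))

    rows = (
        mkrow("Block", b - 1, ss_block),
        mkrow("Treatment", c + n_tests - 1, ss_treat),
        mkrow("Check", c - 1, ss_check),
        mkrow("Accession", n_tests - 1, ss_acc),
        mkrow("Accession vs Check", 1, ss_avc),
        mkrow("Residual", df_res, rss_full),
    )
    return AnovaTable(trait=trait, rows=rows, r=b, degenerate=degenerate)
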