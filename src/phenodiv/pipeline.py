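"""End-to-end orchestration: ANOVA -> variability -> diversity ->
multivariate -> MGIDI, with one TSV per result table and a run manifest.

The pipeline is deterministic: the same inputs and configuration produce
byte-identical outputs. On any stage failure every file already written to
the output directory by this run is removed before the error propagates.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from ._tsv import write_tsv
from .anova import adjusted_means_frame, anova_treatment_adjusted
from .diversity import diversity_report
from .errors import PhenodivError
from .genparams import DEFAULT_SELECTION_K, descriptive_table, variability_table
from .mgidi import run_mgidi
from .multivariate import correlation_matrix, hierarchical_cluster, pca
from .trial import AugmentedTrial, QualitativeTable, read_qualitative, read_trial

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    trial_path: str
    trait_dictionary: str
    out_dir: str
    qualitative_path: str | None = None
    descriptor_dictionary: str | None = None
    selection_k: float = DEFAULT_SELECTION_K
    n_clusters: int = 6
    linkage: str = "complete"
    mgidi_intensity: float = 0.20
    goals: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    round_digits: int | None = None

    def content_hash(self) -> str:
        # hash of the analysis-determining fields only (not the output path)
        relevant = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = repr(sorted(relevant.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class _StageError(PhenodivError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: PipelineConfig) -> dict[str, str]:
    """Run every stage and write the result tables; returns {name: path}."""
    os.makedirs(config.out_dir, exist_ok=True)
    written: list[str] = []
    meta = {
        "phenodiv_version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
    }

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = os.path.join(config.out_dir, name)
        write_tsv(df, path, meta=meta, index=index, round_digits=config.round_digits)
        written.append(path)

    stage = "read_trial"
    try:
        trial = read_trial(config.trial_path, config.trait_dictionary)

        stage = "anova"
        tables = [anova_treatment_adjusted(trial, t).as_frame().assign(trait=t) for t in trial.trait_abbreviations]
        emit("anova.tsv", pd.concat(tables, ignore_index=True)[["trait", "source", "df", "ss", "ms", "F", "p", "sig"]])

        stage = "variability"
        emit("variability.tsv", variability_table(trial, k=config.selection_k))
        emit("descriptives.tsv", descriptive_table(trial))
        means = adjusted_means_frame(trial)
        emit("adjusted_means.tsv", means, index=True)

        if config.qualitative_path is not None:
            stage = "diversity"
            qual = read_qualitative(config.qualitative_path, config.descriptor_dictionary)
            div, mean_h = diversity_report(qual)
            emit("diversity.tsv", div.assign(mean_H_norm=mean_h))

        stage = "multivariate"
        corr = correlation_matrix(means)
        emit("correlation.tsv", corr.r, index=True)
        pc = pca(means)
        eigen = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(pc.eigenvalues))],
                "eigenvalue": pc.eigenvalues,
                "proportion_pct": pc.proportion,
                "cumulative_pct": pc.cumulative,
                "retained": [i < pc.n_retained for i in range(len(pc.eigenvalues))],
            }
        )
        emit("pca_eigen.tsv", eigen)
        emit("pca_loadings.tsv", pc.loadings, index=True)
        emit("pca_scores.tsv", pc.scores, index=True)
        clus = hierarchical_cluster(means, k=config.n_clusters, linkage=config.linkage)
        emit("clusters.tsv", clus.assignments.to_frame(), index=True)
        emit("cluster_means.tsv", clus.cluster_means, index=True)

        stage = "mgidi"
        goals = {t.abbreviation: t.goal for t in trial.traits}
        goals.update(config.goals)
        result, chosen, diffs = run_mgidi(means, goals=goals, intensity=config.mgidi_intensity)
        ranking = pd.DataFrame(
            {
                "genotype": result.ranking.index,
                "rank": result.ranking.to_numpy(),
                "MGIDI": result.mgidi.loc[result.ranking.index].to_numpy(),
                "selected": [g in set(chosen) for g in result.ranking.index],
            }
        )
        emit("mgidi_ranking.tsv", ranking)
        emit("factor_loadings.tsv", result.model.loadings, index=True)
        emit("contributions.tsv", result.contributions, index=True)
        emit("selection_differential.tsv", diffs, index=True)

        stage = "manifest"
        manifest = dict(meta)
        manifest.update(
            {
                "n_genotypes": len(trial.genotypes),
                "n_blocks": len(trial.blocks),
                "n_checks": len(trial.checks),
                "n_tests": len(trial.tests),
                "n_traits": len(trial.traits),
                "outputs": sorted(os.path.basename(p) for p in written),
            }
        )
        manifest_path = os.path.join(config.out_dir, "manifest.yaml")
        with open(manifest_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        written.append(manifest_path)
    except Exception as exc:
        for path in written:
            try:
                os.remove(path)
            except OSError:
                pass
        raise _StageError(stage, exc) from exc

    return {os.path.basename(p): p for p in written}
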