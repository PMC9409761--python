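"""Data model and file I/O for augmented trials and qualitative descriptors.

An augmented randomised complete block design (augmented RCBD) replicates a
small set of *check* varieties in every block while each unreplicated *test*
entry appears in exactly one block. The replicated checks provide the error
and block-effect information that lets the unreplicated entries be adjusted
and compared.

Quantitative plot data arrive as a CSV/TSV with columns ``block``,
``genotype``, ``role`` plus one column per trait abbreviation; a YAML
dictionary maps abbreviations to full names, units and the direction of
desirability used later by the selection index. Qualitative observations
arrive as one coded row per genotype plus a YAML dictionary defining the
admissible states of each descriptor.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import FormatError, LayoutError, ValidationError

__all__ = [
    "TraitSpec",
    "QualitativeDescriptorSpec",
    "PlotRecord",
    "AugmentedTrial",
    "QualitativeTable",
    "read_trial",
    "write_trial",
    "read_trait_dictionary",
    "write_trait_dictionary",
    "read_qualitative",
    "write_qualitative",
    "read_descriptor_dictionary",
    "write_descriptor_dictionary",
]

_GOALS = ("increase", "decrease")


@dataclass(frozen=True)
class TraitSpec:
    """A quantitative trait: short code, display name, units and the
    direction of desirability (used for genotype-ideotype rescaling)."""

    abbreviation: str
    name: str = ""
    units: str = ""
    goal: str = "increase"

    def __post_init__(self):
        if self.goal not in _GOALS:
            raise ValidationError(
                f"trait {self.abbreviation!r}: goal must be one of {_GOALS}, got {self.goal!r}"
            )


@dataclass(frozen=True)
class QualitativeDescriptorSpec:
    """A coded qualitative descriptor with its ordered set of defined states.

    The number of *defined* states ``k`` (not merely the states observed in a
    given collection) is what normalises the Shannon-Weaver index.
    """

    name: str
    states: tuple[tuple[int, str], ...]  # (code, label)

    def __post_init__(self):
        if len(self.states) < 1:
            raise ValidationError(f"descriptor {self.name!r}: needs at least one defined state")
        codes = [c for c, _ in self.states]
        if len(set(codes)) != len(codes):
            raise ValidationError(f"descriptor {self.name!r}: duplicate state codes {codes}")

    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.states)

    def label(self, code: int) -> str:
        for c, lab in self.states:
            if c == code:
                return lab
        raise KeyError(code)


@dataclass
class PlotRecord:
    """One experimental plot: a block, a genotype, its role and the measured
    trait values (missing values allowed, stored as absent keys or NaN)."""

    block_id: str
    genotype_id: str
    role: str  # "check" | "test"
    values: dict[str, float] = field(default_factory=dict)

    def value(self, trait: str) -> float:
        v = self.values.get(trait, float("nan"))
        return float("nan") if v is None else float(v)


@dataclass
class AugmentedTrial:
    traits: list[TraitSpec]
    blocks: list[str]
    checks: list[str]
    tests: list[str]
    records: list[PlotRecord]

    def __post_init__(self):
        self.validate()

    # -- layout invariants -------------------------------------------------
    def validate(self) -> None:
        b, c = len(self.blocks), len(self.checks)
        if b < 2 or c < 2:
            raise LayoutError(
                f"need b >= 2 blocks and c >= 2 checks for positive residual df; got b={b}, c={c}"
            )
        abbrs = [t.abbreviation for t in self.traits]
        if len(set(abbrs)) != len(abbrs):
            raise LayoutError(f"duplicate trait abbreviations: {abbrs}")
        overlap = set(self.checks) & set(self.tests)
        if overlap:
            raise LayoutError(f"genotypes cannot be both check and test: {sorted(overlap)}")
        known_blocks = set(self.blocks)
        seen_check: dict[tuple[str, str], int] = {}
        seen_test: dict[str, list[str]] = {}
        for rec in self.records:
            if rec.block_id not in known_blocks:
                raise LayoutError(f"record references unknown block {rec.block_id!r}")
            for trait, v in rec.values.items():
                if v is not None and not (isinstance(v, float) and math.isnan(v)):
                    if not math.isfinite(float(v)):
                        raise ValidationError(
                            f"non-finite value for trait {trait!r} in plot "
                            f"({rec.genotype_id!r}, {rec.block_id!r})"
                        )
            if rec.genotype_id in self.checks:
                if rec.role != "check":
                    raise LayoutError(f"genotype {rec.genotype_id!r} listed as check but role={rec.role!r}")
                key = (rec.genotype_id, rec.block_id)
                seen_check[key] = seen_check.get(key, 0) + 1
            elif rec.genotype_id in self.tests:
                if rec.role != "test":
                    raise LayoutError(f"genotype {rec.genotype_id!r} listed as test but role={rec.role!r}")
                seen_test.setdefault(rec.genotype_id, []).append(rec.block_id)
            else:
                raise LayoutError(f"record references unknown genotype {rec.genotype_id!r}")
        for g in self.checks:
            for blk in self.blocks:
                n = seen_check.get((g, blk), 0)
                if n != 1:
                    raise LayoutError(
                        f"check {g!r} must occur exactly once in block {blk!r}; found {n}"
                    )
        for g in self.tests:
            blocks = seen_test.get(g, [])
            if len(blocks) != 1:
                raise LayoutError(
                    f"test entry {g!r} must occur exactly once in exactly one block; "
                    f"found in {blocks or 'no block'}"
                )

    # -- convenience -------------------------------------------------------
    @property
    def genotypes(self) -> list[str]:
        return list(self.checks) + list(self.tests)

    @property
    def trait_abbreviations(self) -> list[str]:
        return [t.abbreviation for t in self.traits]

    def trait_spec(self, abbreviation: str) -> TraitSpec:
        for t in self.traits:
            if t.abbreviation == abbreviation:
                return t
        raise KeyError(abbreviation)

    def to_frame(self) -> pd.DataFrame:
        """Plot-level table with block/genotype/role plus one trait column each,
        rows sorted by (block, role, genotype) so serialisation is canonical."""
        rows = []
        for rec in self.records:
            row = {"block": rec.block_id, "genotype": rec.genotype_id, "role": rec.role}
            for t in self.trait_abbreviations:
                row[t] = rec.value(t)
            rows.append(row)
        df = pd.DataFrame(rows)
        return df.sort_values(["block", "role", "genotype"], kind="mergesort").reset_index(drop=True)


@dataclass
class QualitativeTable:
    """Genotype x descriptor table of coded states."""

    descriptors: list[QualitativeDescriptorSpec]
    observations: pd.DataFrame  # index genotype_id, columns descriptor names, int codes

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate descriptor names: {names}")
        missing = [n for n in names if n not in self.observations.columns]
        if missing:
            raise FormatError(f"observations missing descriptor columns: {missing}")
        for d in self.descriptors:
            observed = set(int(v) for v in self.observations[d.name].dropna())
            bad = observed - set(d.codes)
            if bad:
                raise ValidationError(
                    f"descriptor {d.name!r}: observed codes {sorted(bad)} are not among "
                    f"defined states {list(d.codes)}"
                )

    def descriptor(self, name: str) -> QualitativeDescriptorSpec:
        for d in self.descriptors:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def genotypes(self) -> list[str]:
        return list(self.observations.index)


# ---------------------------------------------------------------------------
# YAML dictionaries
# ---------------------------------------------------------------------------

def read_trait_dictionary(path: str | os.PathLike) -> list[TraitSpec]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "traits" not in doc:
        raise FormatError(f"{path}: trait dictionary must have a top-level 'traits' list")
    specs = []
    for entry in doc["traits"]:
        try:
            specs.append(
                TraitSpec(
                    abbreviation=str(entry["abbreviation"]),
                    name=str(entry.get("name", "")),
                    units=str(entry.get("units", "")),
                    goal=str(entry.get("goal", "increase")),
                )
            )
        except KeyError as exc:
            raise FormatError(f"{path}: trait entry missing key {exc}") from exc
    return specs


def write_trait_dictionary(traits: list[TraitSpec], path: str | os.PathLike) -> None:
    doc = {
        "traits": [
            {"abbreviation": t.abbreviation, "name": t.name, "units": t.units, "goal": t.goal}
            for t in traits
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_descriptor_dictionary(path: str | os.PathLike) -> list[QualitativeDescriptorSpec]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "descriptors" not in doc:
        raise FormatError(f"{path}: descriptor dictionary must have a top-level 'descriptors' list")
    specs = []
    for entry in doc["descriptors"]:
        try:
            states = tuple((int(s["code"]), str(s["label"])) for s in entry["states"])
            specs.append(QualitativeDescriptorSpec(name=str(entry["name"]), states=states))
        except KeyError as exc:
            raise FormatError(f"{path}: descriptor entry missing key {exc}") from exc
    return specs


def write_descriptor_dictionary(
    descriptors: list[QualitativeDescriptorSpec], path: str | os.PathLike
) -> None:
    doc = {
        "descriptors": [
            {"name": d.name, "states": [{"code": c, "label": lab} for c, lab in d.states]}
            for d in descriptors
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("block", "genotype", "role")


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    # comma/tab sniffed from the header line; round-trip float parsing
    try:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
        return pd.read_csv(
            path,
            sep=sep,
            comment="#",
            dtype={"block": str, "genotype": str},
            float_precision="round_trip",
        )
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_trial(path: str | os.PathLike, trait_dictionary: str | os.PathLike | list[TraitSpec]) -> AugmentedTrial:
    """Read a plot-level augmented-trial table plus its trait dictionary.

    Row order in the file never affects downstream results: the layout is
    reconstructed from the (block, genotype, role) triples alone.
    """
    traits = (
        trait_dictionary
        if isinstance(trait_dictionary, list)
        else read_trait_dictionary(trait_dictionary)
    )
    df = _read_table(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    missing_traits = [t.abbreviation for t in traits if t.abbreviation not in df.columns]
    if missing_traits:
        raise FormatError(f"{path}: missing trait column(s) {missing_traits}")
    bad_roles = set(df["role"]) - {"check", "test"}
    if bad_roles:
        raise FormatError(f"{path}: unknown role value(s) {sorted(bad_roles)}")

    checks = sorted(df.loc[df["role"] == "check", "genotype"].unique())
    tests = sorted(df.loc[df["role"] == "test", "genotype"].unique())
    blocks = sorted(df["block"].astype(str).unique())
    records = []
    for _, row in df.iterrows():
        values = {t.abbreviation: float(row[t.abbreviation]) for t in traits}
        records.append(
            PlotRecord(
                block_id=str(row["block"]),
                genotype_id=str(row["genotype"]),
                role=str(row["role"]),
                values=values,
            )
        )
    return AugmentedTrial(traits=traits, blocks=blocks, checks=checks, tests=tests, records=records)


def write_trial(trial: AugmentedTrial, path: str | os.PathLike) -> None:
    """Write the canonical plot-level TSV (full float precision, round-trip safe)."""
    trial.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_qualitative(
    path: str | os.PathLike,
    dictionary: str | os.PathLike | list[QualitativeDescriptorSpec],
) -> QualitativeTable:
    """Read a genotype x descriptor table of coded states plus its dictionary."""
    descriptors = (
        dictionary
        if isinstance(dictionary, list)
        else read_descriptor_dictionary(dictionary)
    )
    df = _read_table(path)
    if "genotype" not in df.columns:
        raise FormatError(f"{path}: missing required column 'genotype'")
    obs = df.set_index("genotype")
    missing = [d.name for d in descriptors if d.name not in obs.columns]
    if missing:
        raise FormatError(f"{path}: missing descriptor column(s) {missing}")
    obs = obs[[d.name for d in descriptors]].astype(int)
    return QualitativeTable(descriptors=descriptors, observations=obs)


def write_qualitative(table: QualitativeTable, path: str | os.PathLike) -> None:
    out = table.observations.copy()
    out.insert(0, "genotype", out.index)
    out.to_csv(path, sep="\t", index=False)
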