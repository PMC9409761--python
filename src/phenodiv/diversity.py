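"""Qualitative-descriptor frequency tables and the Shannon-Weaver index.

For a descriptor observed in states with relative frequencies p_i
(p_i = count_i / n over the observed states),

    H_raw  = -sum_i p_i ln p_i          (0 ln 0 := 0)
    H_norm = H_raw / ln(k)

where k is the number of states *defined* in the descriptor dictionary, not
merely those observed in the collection at hand. H_norm lies in [0, 1]: 0
for a monomorphic descriptor and 1 when all k defined states are equally
frequent. Higher values mean more diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError
from .trial import QualitativeDescriptorSpec, QualitativeTable

__all__ = [
    "FrequencyTable",
    "DiversityResult",
    "frequency_table",
    "shannon_weaver",
    "diversity_report",
]


@dataclass(frozen=True)
class FrequencyTable:
    descriptor: str
    counts: dict[int, int]  # state code -> count (observed states only)
    n: int

    @property
    def percentages(self) -> dict[int, float]:
        return {code: 100.0 * cnt / self.n for code, cnt in self.counts.items()}

    def as_frame(self, spec: QualitativeDescriptorSpec | None = None) -> pd.DataFrame:
        rows = []
        for code in sorted(self.counts):
            rows.append(
                {
                    "state_code": code,
                    "state": spec.label(code) if spec is not None else str(code),
                    "count": self.counts[code],
                    "frequency_pct": 100.0 * self.counts[code] / self.n,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DiversityResult:
    descriptor: str
    h_raw: float  # nats
    k: int  # defined states
    h_norm: float  # in [0, 1]


def frequency_table(table: QualitativeTable, descriptor: str) -> FrequencyTable:
    """Counts and relative frequencies of the observed states of one descriptor."""
    spec = table.descriptor(descriptor)  # KeyError for unknown descriptor
    col = table.observations[spec.name].dropna().astype(int)
    counts = {int(code): int(cnt) for code, cnt in col.value_counts().items()}
    return FrequencyTable(descriptor=spec.name, counts=counts, n=int(col.size))


def shannon_weaver(
    frequencies: FrequencyTable, spec: QualitativeDescriptorSpec
) -> DiversityResult:
    """Normalised Shannon-Weaver index of one descriptor.

    Proportions are computed from integer counts (never from pre-rounded
    percentages). A single-state dictionary (k = 1) defines H_norm = 0.
    """
    if frequencies.n < 1:
        raise DomainError(f"descriptor {frequencies.descriptor!r}: no observations")
    h_raw = 0.0
    for cnt in frequencies.counts.values():
        if cnt > 0:
            p = cnt / frequencies.n
            h_raw -= p * math.log(p)
    h_raw = max(h_raw, 0.0)
    k = spec.k
    h_norm = 0.0 if k <= 1 else h_raw / math.log(k)
    return DiversityResult(descriptor=frequencies.descriptor, h_raw=h_raw, k=k, h_norm=h_norm)


def diversity_report(table: QualitativeTable) -> tuple[pd.DataFrame, float]:
    """One diversity row per descriptor (input order) and the mean H_norm."""
    rows = []
    for spec in table.descriptors:
        ft = frequency_table(table, spec.name)
        res = shannon_weaver(ft, spec)
        rows.append(
            {
                "descriptor": spec.name,
                "n": ft.n,
                "k_defined": res.k,
                "n_observed_states": len(ft.counts),
                "H_raw": res.h_raw,
                "H_norm": res.h_norm,
            }
        )
    df = pd.DataFrame(rows)
    mean_h = float(df["H_norm"].mean()) if len(df) else float("nan")
    return df, mean_h
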