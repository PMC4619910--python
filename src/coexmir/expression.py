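"""Gene-level expression matrix with a two-condition design.

Values are assumed normalized, log2-scale (microarray-style).  Conditions
are labeled ``null`` (control) and ``mir142`` (overexpression) by default,
but any two labels work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("null", "mir142")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix plus a sample -> condition label map."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.isna().any().any():
            raise ValueError("missing values are not supported")
        missing = [s for s in self.values.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        counts = self.sample_counts()
        for cond, n in counts.items():
            if n < 3:
                raise ValueError(f"condition {cond!r} has {n} samples; need >= 3")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    def sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.values.columns:
            counts[self.conditions[s]] = counts.get(self.conditions[s], 0) + 1
        return counts

    def condition_samples(self, condition: str) -> list[str]:
        cols = [s for s in self.values.columns if self.conditions[s] == condition]
        if not cols:
            raise ValueError(f"no samples with condition {condition!r}")
        return cols

    def condition_values(self, condition: str) -> pd.DataFrame:
        """Genes x samples sub-matrix restricted to one condition."""
        return self.values[self.condition_samples(condition)]

    def group_arrays(self, condition_a: str, condition_b: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.condition_values(condition_a).to_numpy(float),
            self.condition_values(condition_b).to_numpy(float),
        )

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        genes: list[str],
        samples: list[str],
        conditions: Mapping[str, str],
    ) -> "ExpressionMatrix":
        frame = pd.DataFrame(values, index=genes, columns=samples)
        frame.index.name = "gene"
        return cls(values=frame, conditions=dict(conditions))
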