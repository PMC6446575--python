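"""Feature-by-sample count matrices with condition labels.

Shared container for per-enhancer ATAC fragment counts and per-gene RNA
counts; thin wrapper over a pandas DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """Non-negative integer counts (features x samples) plus a condition
    label per sample."""

    counts: pd.DataFrame  # index = feature ids, columns = sample ids
    conditions: pd.Series  # index = sample ids, values = condition labels

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        self.conditions = self.conditions.loc[self.counts.columns]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        sel = self.conditions[self.conditions == condition]
        if sel.empty:
            raise KeyError(f"unknown condition {condition!r}")
        return list(sel.index)

    def subset(self, conditions: list[str]) -> "CountMatrix":
        samples = [s for s in self.sample_ids if self.conditions[s] in conditions]
        return CountMatrix(self.counts[samples], self.conditions.loc[samples])

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, counts_path: str | Path, sheet_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
        sheet = pd.DataFrame(
            {"sample_id": self.sample_ids, "condition": self.conditions.values}
        )
        sheet.to_csv(sheet_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, sheet_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts = counts.astype(np.int64)
        sheet = pd.read_csv(sheet_path, sep="\t", dtype={"sample_id": str})
        conditions = pd.Series(
            sheet["condition"].values, index=sheet["sample_id"].values
        )
        return cls(counts, conditions)
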