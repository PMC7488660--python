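"""Age-bin schemes used throughout the package.

The analyses work on ages >= 25 grouped into bins; two schemes are shipped:
5-year bins (25-29, 30-34, ..., 90-94, 95+) used for selectivity analysis
and age standardization, and 10-year bins (25-34, ..., 85+) used for the
population-description table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AgeBinScheme", "FIVE_YEAR_BINS", "TEN_YEAR_BINS"]


@dataclass(frozen=True)
class AgeBinScheme:
    """Partition of ages >= `min_age` into contiguous bins, open-ended at top.

    ``lower_edges`` are the inclusive lower bounds of each bin; the last bin
    has no upper bound.
    """

    lower_edges: tuple[int, ...]
    min_age: int = 25

    def __post_init__(self) -> None:
        if list(self.lower_edges) != sorted(set(self.lower_edges)):
            raise ValueError("lower_edges must be strictly increasing")
        if self.lower_edges[0] != self.min_age:
            raise ValueError("first bin must start at min_age")

    @property
    def n_bins(self) -> int:
        return len(self.lower_edges)

    @property
    def labels(self) -> list[str]:
        out = []
        edges = self.lower_edges
        for i, lo in enumerate(edges):
            if i + 1 < len(edges):
                out.append(f"{lo}-{edges[i + 1] - 1}")
            else:
                out.append(f"{lo}+")
        return out

    def assign_index(self, ages: np.ndarray) -> np.ndarray:
        """Bin index per age; raises on ages below min_age."""
        ages = np.asarray(ages)
        if np.any(ages < self.min_age):
            raise ValueError(f"ages below {self.min_age} cannot be binned")
        return np.searchsorted(np.asarray(self.lower_edges), ages, side="right") - 1

    def assign_labels(self, ages) -> pd.Categorical:
        """Bin label per age, as an ordered categorical."""
        idx = self.assign_index(np.asarray(ages))
        labels = self.labels
        return pd.Categorical.from_codes(idx, categories=labels, ordered=True)


FIVE_YEAR_BINS = AgeBinScheme(tuple(range(25, 96, 5)))
TEN_YEAR_BINS = AgeBinScheme((25, 35, 45, 55, 65, 75, 85))
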