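"""Age-group schemas used throughout the pipeline.

The standard output schema partitions ages into fourteen groups: thirteen
5-year groups (0-4, 5-9, ..., 60-64) and an open-ended final group for ages
65 and over.  A finer 17-group schema (up to an open 80+ group) is used for
between-round sensitivity comparisons of survey data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class AgeSchema:
    """An ordered partition of ages ``0..inf`` into contiguous bins.

    Parameters
    ----------
    lower_edges
        Lower bound (inclusive) of each bin, starting at 0 and strictly
        increasing.  The last bin is open-ended.
    labels
        One text code per bin, e.g. ``A0004`` ... ``A65PL``.
    """

    lower_edges: tuple[int, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if len(self.lower_edges) < 2:
            raise ValueError("schema needs at least two bins")
        if self.lower_edges[0] != 0:
            raise ValueError("first bin must start at age 0")
        if any(b <= a for a, b in zip(self.lower_edges, self.lower_edges[1:])):
            raise ValueError("lower_edges must be strictly increasing")
        if not self.labels:
            object.__setattr__(self, "labels", tuple(self._default_labels()))
        if len(self.labels) != len(self.lower_edges):
            raise ValueError("labels and lower_edges length mismatch")

    def _default_labels(self):
        edges = self.lower_edges
        labels = []
        for i, lo in enumerate(edges):
            if i + 1 < len(edges):
                labels.append(f"A{lo:02d}{edges[i + 1] - 1:02d}")
            else:
                labels.append(f"A{lo:02d}PL")
        return labels

    @property
    def n_bins(self) -> int:
        return len(self.lower_edges)

    @property
    def open_lower(self) -> int:
        """Lower bound of the open-ended top bin."""
        return self.lower_edges[-1]

    def bin_of_age(self, age: int) -> int:
        """Index of the bin containing integer ``age`` (>= 0)."""
        if age < 0:
            raise ValueError(f"negative age {age}")
        for i in range(self.n_bins - 1, -1, -1):
            if age >= self.lower_edges[i]:
                return i
        raise AssertionError("unreachable")

    def interval(self, i: int) -> tuple[int, float]:
        """Half-open interval ``[lo, hi)`` of bin ``i`` (``hi`` may be inf)."""
        lo = self.lower_edges[i]
        hi = self.lower_edges[i + 1] if i + 1 < self.n_bins else math.inf
        return lo, hi


#: The standard 14-group schema: A0004 ... A6064, A65PL.
STANDARD_14 = AgeSchema(lower_edges=tuple(range(0, 66, 5)))

#: Finer 17-group schema used for survey-round comparisons: <5 ... 80+.
FINE_17 = AgeSchema(lower_edges=tuple(range(0, 81, 5)))

#: Column order of the standardised per-unit table.
STANDARD_COLUMNS = ["NAME", "ADM_NAME", "MPROP", "FPROP", *STANDARD_14.labels]

#: Tolerance (percentage points) on table sum checks; absorbs 1-decimal
#: rounding of up to 16 addends.
SUM_TOLERANCE = 0.15
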