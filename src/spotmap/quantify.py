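"""Per-sample read quantification: total and relative gene counts."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpotTable, select_roi

__all__ = ["CountMatrix", "total_counts"]


@dataclass
class CountMatrix:
    """Samples × genes counts with a companion per-sample frequency matrix.

    Each frequency row sums to 1 unless the sample has zero reads, in which
    case the row is all zeros (with a warning at construction time).
    """

    counts: pd.DataFrame
    frequencies: pd.DataFrame

    def to_csv(self, prefix: str) -> None:
        self.counts.to_csv(f"{prefix}.counts.csv")
        self.frequencies.to_csv(f"{prefix}.frequencies.csv")


def total_counts(
    spots: SpotTable,
    *,
    by_sample: bool = True,
    rois: dict[str, tuple[float, float, float, float]] | None = None,
) -> CountMatrix:
    """Count reads of each gene per sample (or per named ROI).

    The output gene panel is the union of genes across samples, sorted
    lexicographically so column order is reproducible.  frequency[s, g] =
    counts[s, g] / row total.
    """
    if len(spots) == 0:
        raise ValueError("no reads to count")
    if rois is not None:
        parts = []
        for name, rect in rois.items():
            sub = select_roi(spots, rect).data.assign(sample=name)
            parts.append(sub)
        df = pd.concat(parts, ignore_index=True)
    else:
        df = spots.data if by_sample else spots.data.assign(sample="all")
    counts = (
        df.groupby(["sample", "gene"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    counts = counts.reindex(columns=sorted(counts.columns), fill_value=0).astype(int)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        warnings.warn("sample(s) with zero reads: frequency rows set to 0")
    freq = counts.div(totals.replace(0, 1), axis=0).astype(float)
    freq[totals == 0] = 0.0
    return CountMatrix(counts=counts, frequencies=freq)
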