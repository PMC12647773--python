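"""Sample × feature abundance containers shared across the pipeline."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "CLRMatrix"]

logger = logging.getLogger(__name__)


@dataclass
class AbundanceTable:
    """Relative abundances (samples × features) plus sample metadata.

    ``data`` holds non-negative entries (NaN = missing); ``meta`` is indexed
    like ``data`` and carries at least ``individual`` and ``day`` columns.
    Rows are compositional: when expressed as percentages they sum to
    100 ± 0.5 (checked by :meth:`validate`, renormalizable with
    :meth:`closed`).
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.data.index.equals(self.meta.index):
            self.meta = self.meta.reindex(self.data.index)
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValueError("abundance entries must be non-negative")

    @property
    def samples(self):
        return list(self.data.index)

    @property
    def features(self):
        return list(self.data.columns)

    def validate(self, total: float = 100.0, tol: float = 0.5) -> None:
        sums = np.nansum(self.data.to_numpy(dtype=float), axis=1)
        bad = np.where(np.abs(sums - total) > tol)[0]
        if bad.size:
            raise ValueError(
                f"rows not closed to {total}: {[self.samples[i] for i in bad]}"
            )

    def closed(self, total: float = 100.0) -> "AbundanceTable":
        """Renormalize every row to sum to ``total`` (NaN-aware)."""
        arr = self.data.to_numpy(dtype=float)
        sums = np.nansum(arr, axis=1, keepdims=True)
        if (sums <= 0).any():
            raise ValueError("cannot close an all-zero sample")
        return AbundanceTable(
            pd.DataFrame(arr / sums * total, index=self.data.index, columns=self.data.columns),
            self.meta.copy(),
        )


@dataclass
class CLRMatrix:
    """Center-log-ratio transformed table (samples × features).

    With ``gamma`` = 0, every row sums to zero; ``gamma`` > 0 adds one
    Normal(0, γ²) scale-uncertainty draw per sample to all entries of that
    row (seeded).  All clustering and correlation downstream happens in
    this space.
    """

    data: pd.DataFrame
    gamma: float = 0.0
    seed: Optional[int] = None
    meta: Optional[pd.DataFrame] = None

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)
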