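"""Staged gene x sample expression container.

The analysis moves a single matrix through four stages — raw counts,
depth-normalized counts, log2 values, and batch-adjusted log2 values —
and several contracts only make sense at a particular stage (e.g. the
expressed-gene filter operates on normalized counts, batch adjustment on
log2 values).  ``ExpressionMatrix`` carries the stage tag and enforces
that transitions happen in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed stages, in pipeline order.
STAGES = ("raw", "normalized", "log2", "batch_adjusted")


class StageError(ValueError):
    """Raised when an operation is applied to a matrix at the wrong stage."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a processing-stage tag.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
    stage
        One of :data:`STAGES`.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        if self.stage in ("raw", "normalized") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values not allowed at stage {self.stage!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"operation requires stage {' or '.join(map(repr, stages))}, "
                f"matrix is at stage {self.stage!r}"
            )

    def advance(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        """Return a new matrix at ``stage``, checking the transition is forward."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise StageError(f"cannot move from stage {self.stage!r} back to {stage!r}")
        return ExpressionMatrix(values, stage=stage)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), stage=self.stage)
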