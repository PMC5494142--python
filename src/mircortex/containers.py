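"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a feature-by-sample grid of
non-negative expression values with an explicit missingness mask (NaN),
a feature class (miRNA, lincRNA or mRNA), per-sample batch labels and a
processing-state tag that only advances in pipeline order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("mirna", "lincrna", "mrna")

#: processing states in pipeline order
STATES = ("raw", "background_adjusted", "filtered", "normalized", "batch_adjusted")


class PipelineOrderError(RuntimeError):
    """Raised when an operation is applied to a matrix in the wrong state."""


@dataclass
class ExpressionMatrix:
    """Feature x sample expression values with missingness encoded as NaN.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
        ``NaN`` entries are missing measurements.
    feature_class
        One of ``"mirna"``, ``"lincrna"``, ``"mrna"``.
    batch
        Optional per-sample batch (cartridge) labels, aligned to columns.
    state
        Processing-state tag; advances through :data:`STATES`.
    """

    values: pd.DataFrame
    feature_class: str = "mirna"
    batch: Optional[pd.Series] = None
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.values = self.values.astype(float)
        if self.batch is not None:
            self.batch = pd.Series(self.batch).reindex(self.values.columns)
            if self.batch.isna().any():
                raise ValueError("batch labels missing for some samples")

    # -- basic views ------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the measurement is present."""
        return self.values.notna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise PipelineOrderError(
                f"operation requires state in {allowed}, matrix is {self.state!r}"
            )

    def evolve(self, values: pd.DataFrame | None = None, state: str | None = None,
               batch: pd.Series | None = None) -> "ExpressionMatrix":
        """Return a copy with selected fields replaced; never mutates self."""
        new_values = self.values.copy() if values is None else values
        new_batch = self.batch
        if batch is not None:
            new_batch = batch
        elif self.batch is not None:
            new_batch = self.batch.reindex(new_values.columns)
        return ExpressionMatrix(
            values=new_values,
            feature_class=self.feature_class,
            batch=new_batch,
            state=self.state if state is None else state,
        )

    def __eq__(self, other: object) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        same_batch = (
            (self.batch is None and other.batch is None)
            or (self.batch is not None and other.batch is not None
                and self.batch.astype(str).equals(other.batch.astype(str)))
        )
        return (
            self.feature_class == other.feature_class
            and self.state == other.state
            and same_batch
            and self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and np.array_equal(self.values.to_numpy(), other.values.to_numpy(),
                               equal_nan=True)
        )


@dataclass
class FilterStep:
    """Record of one filtering step: what was removed and why."""

    name: str
    axis: str                       # "feature" or "sample"
    threshold: float
    n_before: int
    n_after: int
    removed: list = field(default_factory=list)

    def reconciles(self) -> bool:
        return self.n_before - self.n_after == len(self.removed)


@dataclass
class FilterReport:
    """Accumulated record of QC filtering, one entry per step."""

    steps: list = field(default_factory=list)

    def add(self, step: FilterStep) -> None:
        if not step.reconciles():
            raise AssertionError("filter step counts do not reconcile")
        self.steps.append(step)

    def removed_features(self) -> list:
        out: list = []
        for s in self.steps:
            if s.axis == "feature":
                out.extend(s.removed)
        return out

    def removed_samples(self) -> list:
        out: list = []
        for s in self.steps:
            if s.axis == "sample":
                out.extend(s.removed)
        return out

    def to_dict(self) -> dict:
        return {"steps": [dataclasses.asdict(s) for s in self.steps]}


# Covariates used throughout: the demographic/technical adjustment set.
COVARIATES = ("age", "sex", "study", "nnls", "pmi", "rin")
OUTCOMES = ("np", "nft", "ad")
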