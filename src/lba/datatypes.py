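"""Core in-memory containers shared across the pipeline stages.

The containers are thin, validated wrappers around pandas/numpy objects:
a :class:`ResponseSet` of open-ended answers, an :class:`EmbeddingMatrix`
of per-response feature vectors, a :class:`RatingScaleData` item table,
the :class:`PredictionResult` of a cross-validated model, and the
:class:`TrainingConfig` that parametrises the training scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidInputError, InvalidParameterError

CONSTRUCTS = ("hil", "swl")
FORMATS = ("words", "text")

RESPONSE_COLUMNS = ["participant_id", "construct", "format", "response"]


# ---------------------------------------------------------------------------
# Responses


@dataclass(frozen=True)
class ResponseSet:
    """Open-ended responses, one row per participant x construct x format.

    ``frame`` has columns ``participant_id, construct, format, response``.
    Within one (construct, format) block each participant appears at most
    once; the row order of a block is the participant order used for all
    downstream matrices.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RESPONSE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise InvalidInputError(f"response table is missing columns: {missing}")
        bad_construct = set(self.frame["construct"]) - set(CONSTRUCTS)
        if bad_construct:
            raise InvalidInputError(f"unknown construct values: {sorted(bad_construct)}")
        bad_format = set(self.frame["format"]) - set(FORMATS)
        if bad_format:
            raise InvalidInputError(f"unknown format values: {sorted(bad_format)}")
        dup = self.frame.duplicated(subset=["participant_id", "construct", "format"])
        if dup.any():
            ids = self.frame.loc[dup, "participant_id"].tolist()[:5]
            raise InvalidInputError(f"duplicate (participant, construct, format) rows, e.g. {ids}")

    def __len__(self) -> int:
        return len(self.frame)

    def select(self, construct: str | None = None, format: str | None = None) -> "ResponseSet":
        """Subset to one construct and/or one response format, order preserved."""
        mask = pd.Series(True, index=self.frame.index)
        if construct is not None:
            mask &= self.frame["construct"] == construct
        if format is not None:
            mask &= self.frame["format"] == format
        return ResponseSet(self.frame.loc[mask].reset_index(drop=True))

    @property
    def participant_ids(self) -> list[str]:
        return [str(p) for p in self.frame["participant_id"]]

    @property
    def texts(self) -> list[str]:
        return [str(t) for t in self.frame["response"]]

    def iter_records(self) -> Iterator[tuple[str, str, str, str]]:
        for row in self.frame.itertuples(index=False):
            yield str(row.participant_id), row.construct, row.format, str(row.response)

    def blocks(self) -> Iterator[tuple[str, str, "ResponseSet"]]:
        """Iterate over the non-empty (construct, format) blocks."""
        for construct in CONSTRUCTS:
            for fmt in FORMATS:
                block = self.select(construct, fmt)
                if len(block):
                    yield construct, fmt, block

    @classmethod
    def concat(cls, parts: Sequence["ResponseSet"]) -> "ResponseSet":
        return cls(pd.concat([p.frame for p in parts], ignore_index=True))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResponseSet":
        return cls(pd.read_csv(path, dtype={"participant_id": str}))


# ---------------------------------------------------------------------------
# Embeddings


@dataclass(frozen=True)
class EmbeddingMatrix:
    """An N x D numeric feature matrix with provenance metadata.

    ``mode`` records the extraction regime: ``contextual`` (tokens embedded
    in their sentence context), ``decontextual`` (each word embedded as its
    own one-word document), ``synthetic`` (simulator output) or ``mixed``
    (column-wise combination of several sources).
    """

    values: np.ndarray
    row_ids: tuple[str, ...]
    mode: str
    layer: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidInputError(f"embedding values must be 2-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("embedding matrix contains non-finite entries")
        if len(self.row_ids) != values.shape[0]:
            raise AlignmentError(
                f"{len(self.row_ids)} row ids for {values.shape[0]} embedding rows"
            )
        if self.mode not in ("contextual", "decontextual", "synthetic", "mixed"):
            raise InvalidParameterError(f"unknown embedding mode {self.mode!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", tuple(str(r) for r in self.row_ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def reorder(self, ids: Sequence[str]) -> "EmbeddingMatrix":
        """Rows re-ordered to ``ids`` (which must be a permutation subset)."""
        index = {r: i for i, r in enumerate(self.row_ids)}
        missing = [i for i in ids if str(i) not in index]
        if missing:
            raise AlignmentError(f"ids absent from embedding matrix: {missing[:5]}")
        rows = [index[str(i)] for i in ids]
        return replace(self, values=self.values[rows], row_ids=tuple(str(i) for i in ids))


# ---------------------------------------------------------------------------
# Rating scales


@dataclass(frozen=True)
class RatingScaleData:
    """Item responses of one rating scale.

    ``items`` is indexed by participant id with one column per item. Item
    values must lie inside ``scale_range`` (inclusive); simulated
    pre-rounding items may be real-valued but still within range.
    """

    items: pd.DataFrame
    scale_range: tuple[int, int] = (1, 7)
    scale_name: str = ""

    def __post_init__(self) -> None:
        if self.items.shape[1] < 2:
            raise InvalidInputError("a rating scale needs at least 2 items")
        lo, hi = self.scale_range
        if lo >= hi:
            raise InvalidParameterError(f"scale_range must be increasing, got {self.scale_range}")
        vals = self.items.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError(f"{self.scale_name or 'scale'}: non-finite item values")
        if vals.min() < lo or vals.max() > hi:
            raise InvalidInputError(
                f"{self.scale_name or 'scale'}: item values outside range {self.scale_range}"
            )

    @property
    def k(self) -> int:
        return self.items.shape[1]

    @property
    def n(self) -> int:
        return self.items.shape[0]

    @property
    def participant_ids(self) -> list[str]:
        return [str(p) for p in self.items.index]

    @property
    def values(self) -> np.ndarray:
        return self.items.to_numpy(dtype=float)

    @property
    def total(self) -> np.ndarray:
        """Scale total: the row sum over items."""
        return self.values.sum(axis=1)

    def reorder(self, ids: Sequence[str]) -> "RatingScaleData":
        idx = [str(i) for i in ids]
        missing = [i for i in idx if i not in set(self.participant_ids)]
        if missing:
            raise AlignmentError(f"ids absent from {self.scale_name or 'scale'}: {missing[:5]}")
        items = self.items.copy()
        items.index = items.index.map(str)
        return replace(self, items=items.loc[idx])

    def to_csv(self, path) -> None:
        self.items.rename_axis("participant_id").to_csv(path)

    @classmethod
    def from_csv(cls, path, scale_range=(1, 7), scale_name="") -> "RatingScaleData":
        frame = pd.read_csv(path, dtype={"participant_id": str}).set_index("participant_id")
        return cls(items=frame, scale_range=scale_range, scale_name=scale_name)


# ---------------------------------------------------------------------------
# Training configuration and results


def default_penalty_grid() -> np.ndarray:
    """The ridge penalty search grid: 10^-16 ... 10^16 in steps of x10."""
    return 10.0 ** np.arange(-16, 17)


@dataclass(frozen=True)
class TrainingConfig:
    """Parameters of the nested cross-validated ridge scheme.

    Ten outer folds, stratified on 4 quantile bins of the outcome; inside
    each outer training set a single stratified 75/25 analysis/assessment
    split selects the penalty from a 33-point grid spanning 32 orders of
    magnitude.
    """

    n_folds: int = 10
    n_strat_bins: int = 4
    inner_analysis_fraction: float = 0.75
    penalty_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(default_penalty_grid())
    )
    standardize_features: bool = True
    selection_rule: str = "min_rmse_1se"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise InvalidParameterError("n_folds must be >= 2")
        if not 0.0 < self.inner_analysis_fraction < 1.0:
            raise InvalidParameterError("inner_analysis_fraction must be in (0, 1)")
        if self.n_strat_bins < 1:
            raise InvalidParameterError("n_strat_bins must be >= 1")
        if self.selection_rule not in ("min_rmse", "min_rmse_1se"):
            raise InvalidParameterError(f"unknown selection_rule {self.selection_rule!r}")
        grid = np.asarray(self.penalty_grid, dtype=float)
        if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise InvalidParameterError("penalty_grid must be strictly positive and increasing")
        object.__setattr__(self, "penalty_grid", tuple(float(x) for x in grid))

    def grid(self) -> np.ndarray:
        return np.asarray(self.penalty_grid, dtype=float)


@dataclass(frozen=True)
class PredictionResult:
    """Out-of-fold predictions of one model for one outcome.

    ``accuracy_r`` is the Pearson correlation between the observed outcome
    and the pooled out-of-fold predictions, ``accuracy_p`` its two-sided
    p-value; every observation is predicted exactly once by a model that
    never saw it in training.
    """

    y_observed: np.ndarray
    y_predicted: np.ndarray
    fold_assignment: np.ndarray
    fold_penalties: tuple[float, ...]
    accuracy_r: float
    accuracy_p: float
    outcome_name: str = "outcome"
    model_name: str = ""

    def __post_init__(self) -> None:
        y = np.asarray(self.y_observed, dtype=float)
        yhat = np.asarray(self.y_predicted, dtype=float)
        folds = np.asarray(self.fold_assignment, dtype=int)
        if not (len(y) == len(yhat) == len(folds)):
            raise AlignmentError("observed, predicted and fold vectors differ in length")
        object.__setattr__(self, "y_observed", y)
        object.__setattr__(self, "y_predicted", yhat)
        object.__setattr__(self, "fold_assignment", folds)
        object.__setattr__(self, "fold_penalties", tuple(float(p) for p in self.fold_penalties))

    @property
    def n(self) -> int:
        return len(self.y_observed)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "outcome_name": self.outcome_name,
            "accuracy_r": float(self.accuracy_r),
            "accuracy_p": float(self.accuracy_p),
            "fold_penalties": list(self.fold_penalties),
            "y_observed": self.y_observed.tolist(),
            "y_predicted": self.y_predicted.tolist(),
            "fold_assignment": self.fold_assignment.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionResult":
        return cls(
            y_observed=np.asarray(d["y_observed"], dtype=float),
            y_predicted=np.asarray(d["y_predicted"], dtype=float),
            fold_assignment=np.asarray(d["fold_assignment"], dtype=int),
            fold_penalties=tuple(d["fold_penalties"]),
            accuracy_r=float(d["accuracy_r"]),
            accuracy_p=float(d["accuracy_p"]),
            outcome_name=d.get("outcome_name", "outcome"),
            model_name=d.get("model_name", ""),
        )
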