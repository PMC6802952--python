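"""Stimulus design: the fragment grid and the predictor RDMs derived from it.

The condition space is a full factorial grid of natural-scene fragments:
``n_scenes_per_type`` indoor and as many outdoor scenes, each cut into a
``n_vertical`` x ``n_horizontal`` grid of fragments. The default grid
(3 scenes per type, 3 vertical levels, 2 horizontal levels) yields
36 conditions: 6 scenes x 6 fragments.

Canonical condition order is scene-major: indoor scenes first
(``scene_id`` 1..n), then outdoor (n+1..2n); within a scene the vertical
level varies first (1 = top .. bottom), then the horizontal level
(1 = left, 2 = right). Every matrix in the package is index-aligned to
this order, and the diagonal of every RDM is stored as NaN ("empty"),
never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from ._utils import check_square_symmetric

INDOOR = "indoor"
OUTDOOR = "outdoor"

RdmKind = Literal[
    "vertical", "horizontal", "category", "vertical_euclidean", "custom"
]


class InvalidDesignError(ValueError):
    """Raised when a stimulus-design request is degenerate (e.g. zero counts)."""


@dataclass(frozen=True)
class Condition:
    """One scene fragment: which scene it comes from and where it sits in it."""

    scene_id: int
    scene_type: str  # "indoor" | "outdoor"
    vertical: int  # 1 = top .. n_vertical = bottom
    horizontal: int  # 1 = left .. n_horizontal = right


@dataclass(frozen=True)
class StimulusSet:
    """Ordered set of conditions; the shared index space of all RDMs."""

    conditions: tuple[Condition, ...]

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self) -> Iterator[Condition]:
        return iter(self.conditions)

    def __getitem__(self, i: int) -> Condition:
        return self.conditions[i]

    @property
    def scene_id(self) -> np.ndarray:
        return np.array([c.scene_id for c in self.conditions])

    @property
    def scene_type(self) -> np.ndarray:
        return np.array([c.scene_type for c in self.conditions])

    @property
    def vertical(self) -> np.ndarray:
        return np.array([c.vertical for c in self.conditions])

    @property
    def horizontal(self) -> np.ndarray:
        return np.array([c.horizontal for c in self.conditions])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_index": np.arange(len(self)),
                "scene_id": self.scene_id,
                "scene_type": self.scene_type,
                "vertical": self.vertical,
                "horizontal": self.horizontal,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StimulusSet":
        frame = frame.sort_values("condition_index")
        conditions = tuple(
            Condition(int(r.scene_id), str(r.scene_type), int(r.vertical), int(r.horizontal))
            for r in frame.itertuples()
        )
        return cls(conditions)

    def subset(self, indices: Sequence[int]) -> "StimulusSet":
        return StimulusSet(tuple(self.conditions[i] for i in indices))


@dataclass
class ModelRDM:
    """Predictor/model dissimilarity matrix over a StimulusSet's order.

    ``values`` is square and symmetric with a NaN diagonal. Binary kinds
    (vertical, horizontal, category) contain only {0, 1} off the diagonal.
    """

    values: np.ndarray
    kind: str = "custom"
    name: str = ""

    def __post_init__(self) -> None:
        self.values = check_square_symmetric(self.values, "ModelRDM")
        np.fill_diagonal(self.values, np.nan)
        if not self.name:
            self.name = self.kind

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]


@dataclass
class PairMask:
    """Symmetric boolean inclusion mask over unordered condition pairs.

    Self-pairs are never included (the diagonal is always False).
    """

    include: np.ndarray
    name: str = "mask"

    def __post_init__(self) -> None:
        inc = np.asarray(self.include, dtype=bool)
        if inc.ndim != 2 or inc.shape[0] != inc.shape[1]:
            raise ValueError("PairMask.include must be square")
        if not np.array_equal(inc, inc.T):
            raise ValueError("PairMask.include must be symmetric")
        np.fill_diagonal(inc, False)
        self.include = inc

    @property
    def n_pairs(self) -> int:
        """Number of retained unordered pairs."""
        return int(np.tril(self.include, -1).sum())


def build_stimulus_set(
    n_scenes_per_type: int = 3, n_vertical: int = 3, n_horizontal: int = 2
) -> StimulusSet:
    """Build the full factorial fragment grid in canonical scene-major order.

    The default (3, 3, 2) reproduces the 36-condition design: 6 scenes
    (3 indoor + 3 outdoor) x 6 fragments (3 vertical x 2 horizontal).
    """
    if min(n_scenes_per_type, n_vertical, n_horizontal) < 1:
        raise InvalidDesignError(
            "all design counts must be >= 1, got "
            f"({n_scenes_per_type}, {n_vertical}, {n_horizontal})"
        )
    conditions = []
    for scene_id in range(1, 2 * n_scenes_per_type + 1):
        scene_type = INDOOR if scene_id <= n_scenes_per_type else OUTDOOR
        for vertical in range(1, n_vertical + 1):
            for horizontal in range(1, n_horizontal + 1):
                conditions.append(Condition(scene_id, scene_type, vertical, horizontal))
    return StimulusSet(tuple(conditions))


def _binary_rdm(levels: np.ndarray) -> np.ndarray:
    values = (levels[:, None] != levels[None, :]).astype(float)
    np.fill_diagonal(values, np.nan)
    return values


def build_location_rdm(
    stimulus_set: StimulusSet, axis: Literal["vertical", "horizontal"] = "vertical"
) -> ModelRDM:
    """Binary location predictor: 0 if a pair shares the level on ``axis``, else 1."""
    if len(stimulus_set) == 0:
        raise InvalidDesignError("stimulus set is empty")
    if axis not in ("vertical", "horizontal"):
        raise ValueError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")
    levels = stimulus_set.vertical if axis == "vertical" else stimulus_set.horizontal
    return ModelRDM(_binary_rdm(levels), kind=axis)


def build_category_rdm(stimulus_set: StimulusSet) -> ModelRDM:
    """Binary category predictor: 0 if both fragments stem from the same scene."""
    if len(stimulus_set) == 0:
        raise InvalidDesignError("stimulus set is empty")
    return ModelRDM(_binary_rdm(stimulus_set.scene_id), kind="category")


def build_vertical_euclidean_rdm(stimulus_set: StimulusSet) -> ModelRDM:
    """Graded vertical predictor: |vertical_i - vertical_j| on the ordinal axis."""
    if len(stimulus_set) == 0:
        raise InvalidDesignError("stimulus set is empty")
    v = stimulus_set.vertical.astype(float)
    values = np.abs(v[:, None] - v[None, :])
    np.fill_diagonal(values, np.nan)
    return ModelRDM(values, kind="vertical_euclidean")


def build_cross_type_mask(stimulus_set: StimulusSet) -> PairMask:
    """Mask retaining only comparisons between indoor and outdoor scenes.

    Every pair within the same scene type is removed; on the default design
    this keeps 18 x 18 = 324 unordered pairs. A single-type set produces an
    empty mask with a warning.
    """
    types = stimulus_set.scene_type
    include = types[:, None] != types[None, :]
    if not include.any():
        warnings.warn(
            "stimulus set contains a single scene type; cross-type mask is empty",
            RuntimeWarning,
            stacklevel=2,
        )
    return PairMask(include, name="cross_type")


def default_predictor_rdms(stimulus_set: StimulusSet) -> dict[str, ModelRDM]:
    """The three standard predictors: vertical, horizontal and category."""
    return {
        "vertical": build_location_rdm(stimulus_set, "vertical"),
        "horizontal": build_location_rdm(stimulus_set, "horizontal"),
        "category": build_category_rdm(stimulus_set),
    }
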