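"""Experimental design primitives: task dimensions, stimuli and response mappings.

The paradigm is a four-task cued switching design.  Every stimulus is a
conjunction of four binary features -- colour (red/green), shape
(circle/triangle), vertical position (up/down) and horizontal position
(left/right) -- so exactly 16 distinct stimuli exist.  On each trial one
dimension is cued as relevant and the stimulus is classified on that
dimension with one of two response keys.  All four tasks share the same two
keys, which is what makes irrelevant dimensions act as *competitor*
stimulus-response rules whenever their activated rule points at the other
key.

Features and keys are coded as integers 0/1 throughout; human-readable
labels live in :data:`FEATURE_LABELS` and :data:`KEYS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

DIMENSIONS: tuple[str, ...] = ("colour", "shape", "vertical", "horizontal")
SPATIAL_DIMENSIONS: tuple[str, ...] = ("vertical", "horizontal")

#: label of feature code 0 and 1 on each dimension
FEATURE_LABELS: dict[str, tuple[str, str]] = {
    "colour": ("red", "green"),
    "shape": ("circle", "triangle"),
    "vertical": ("up", "down"),
    "horizontal": ("left", "right"),
}

KEYS: tuple[str, str] = ("key1", "key2")

N_STIMULI = 16
N_MAPPINGS = 8


class InvalidDesignError(ValueError):
    """Raised when a requested design is structurally impossible."""


class InvalidTaskError(ValueError):
    """Raised when an unknown task dimension is referenced."""


def _check_dimension(name: str) -> None:
    if name not in DIMENSIONS:
        raise InvalidTaskError(f"unknown task dimension: {name!r}")


@dataclass(frozen=True)
class Stimulus:
    """One of the 16 stimuli, as four binary feature codes."""

    colour: int
    shape: int
    vertical: int
    horizontal: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            if getattr(self, dim) not in (0, 1):
                raise ValueError(f"feature {dim} must be 0 or 1")

    def feature(self, dimension: str) -> int:
        _check_dimension(dimension)
        return getattr(self, dimension)

    @classmethod
    def from_labels(cls, **labels: str) -> "Stimulus":
        """Build a stimulus from feature labels, e.g. colour='green'."""
        codes = {}
        for dim, lab in labels.items():
            _check_dimension(dim)
            codes[dim] = FEATURE_LABELS[dim].index(lab)
        return cls(**codes)

    def labels(self) -> dict[str, str]:
        return {dim: FEATURE_LABELS[dim][self.feature(dim)] for dim in DIMENSIONS}


def all_stimuli() -> Iterator[Stimulus]:
    """Iterate over the full 2**4 stimulus set."""
    for code in range(N_STIMULI):
        yield Stimulus(
            colour=code & 1,
            shape=(code >> 1) & 1,
            vertical=(code >> 2) & 1,
            horizontal=(code >> 3) & 1,
        )


@dataclass(frozen=True)
class ResponseMapping:
    """One of the 8 counterbalanced stimulus-response mappings.

    Each dimension's two features map to the two keys; the mapping is fully
    described by one *flip* bit per dimension: key = feature XOR flip.
    The canonical set mirrors the counterbalancing of the experiment:
    'up' is always on key1 (the upper key of either keyboard arrangement),
    the horizontal assignment follows the arrangement, and the colour and
    shape assignments vary freely, yielding 2 x 2 x 2 = 8 mappings.
    """

    mapping_id: int
    flips: tuple[int, int, int, int]  # order follows DIMENSIONS

    @classmethod
    def standard(cls, mapping_id: int) -> "ResponseMapping":
        if not 1 <= mapping_id <= N_MAPPINGS:
            raise InvalidDesignError(f"mapping_id must be 1..{N_MAPPINGS}")
        bits = mapping_id - 1
        colour_flip = bits & 1
        shape_flip = (bits >> 1) & 1
        horizontal_flip = (bits >> 2) & 1
        return cls(mapping_id, (colour_flip, shape_flip, 0, horizontal_flip))

    def flip(self, dimension: str) -> int:
        _check_dimension(dimension)
        return self.flips[DIMENSIONS.index(dimension)]

    def key_for(self, dimension: str, feature: int) -> int:
        """Response key (0/1) dictated by one stimulus-response rule."""
        if feature not in (0, 1):
            raise ValueError("feature must be 0 or 1")
        return feature ^ self.flip(dimension)

    @property
    def rule_table(self) -> dict[tuple[str, str], str]:
        """Mapping from (dimension, feature label) to key label."""
        return {
            (dim, FEATURE_LABELS[dim][f]): KEYS[self.key_for(dim, f)]
            for dim in DIMENSIONS
            for f in (0, 1)
        }


def all_mappings() -> list[ResponseMapping]:
    return [ResponseMapping.standard(i) for i in range(1, N_MAPPINGS + 1)]


def correct_response(stimulus: Stimulus, task: str, mapping: ResponseMapping) -> int:
    """Correct key (0/1) for classifying `stimulus` on the cued `task`."""
    _check_dimension(task)
    return mapping.key_for(task, stimulus.feature(task))
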