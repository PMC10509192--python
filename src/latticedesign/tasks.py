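"""Design tasks: a target conformation within an exact ensemble, plus constraints."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .lattice import Conformation, EnsembleModel


@dataclass(frozen=True)
class DesignConstraints:
    """Fixed-position constraints and the position visit order for decoding.

    ``fixed`` pins residues (0-based position -> required symbol), the
    mechanism used to conserve active-site or otherwise essential residues
    during redesign. ``order`` is the permutation in which the decoder
    visits positions; ``None`` means identity (left to right).
    """

    fixed: tuple[tuple[int, str], ...] = ()
    order: tuple[int, ...] | None = None

    @classmethod
    def create(
        cls,
        fixed: Mapping[int, str] | None = None,
        order: Sequence[int] | None = None,
    ) -> "DesignConstraints":
        fixed_items = tuple(sorted((int(p), s) for p, s in (fixed or {}).items()))
        return cls(fixed_items, None if order is None else tuple(int(i) for i in order))

    @property
    def fixed_map(self) -> dict[int, str]:
        return dict(self.fixed)

    def resolve_order(self, length: int) -> tuple[int, ...]:
        if self.order is None:
            return tuple(range(length))
        return self.order

    def validate_for(self, model: EnsembleModel) -> None:
        for pos, sym in self.fixed:
            if not 0 <= pos < model.length:
                raise ValidationError(f"fixed position {pos} outside [0, {model.length})")
            model.alphabet.index(sym)  # raises on unknown symbol
        if self.order is not None and sorted(self.order) != list(range(model.length)):
            raise ValidationError("decode order must be a permutation of all positions")


def random_order(length: int, rng: np.random.Generator) -> tuple[int, ...]:
    """A seeded random decoding permutation (some structure-conditioned decoders randomize visit order)."""
    return tuple(int(i) for i in rng.permutation(length))


@dataclass(frozen=True)
class DesignTask:
    """An ensemble model, a designated native conformation, and constraints."""

    model: EnsembleModel
    native_index: int
    constraints: DesignConstraints = field(default_factory=DesignConstraints)

    def __post_init__(self) -> None:
        if not 0 <= self.native_index < self.model.n_conformations:
            raise ValidationError(
                f"native index {self.native_index} outside ensemble of size "
                f"{self.model.n_conformations}"
            )
        self.constraints.validate_for(self.model)

    @property
    def native(self) -> Conformation:
        return self.model.conformations[self.native_index]

    @classmethod
    def from_native(
        cls,
        model: EnsembleModel,
        native: Conformation,
        constraints: DesignConstraints | None = None,
    ) -> "DesignTask":
        try:
            idx = model.conformations.index(native)
        except ValueError:
            raise ValidationError("native conformation not found in the ensemble") from None
        return cls(model, idx, constraints or DesignConstraints())
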