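"""Probabilistic stability and conformational-specificity metrics.

Stability is the total Boltzmann weight of a folded set F of conformations,
p(F | s); conformational specificity is how strongly the native structure X
dominates within that folded set, p(X | s) / p(F | s). Their product is
exactly the Boltzmann objective,

    p(X | s) = specificity(s) * stability(s),

so both chemical properties are factors of the single design objective.
The folded set itself is configurable: just the native state, an explicit
index list, or the lowest-energy quantile of the ensemble under the
sequence being scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import InfiniteFreeEnergyGapError, ValidationError
from .lattice import conformation_distribution
from .tasks import DesignTask

NATIVE_ONLY = "native_only"
EXPLICIT = "explicit"
ENERGY_QUANTILE = "energy_quantile"


@dataclass(frozen=True)
class FoldedSet:
    """The set of conformations counted as 'folded', with its derivation rule."""

    member_indices: frozenset[int]
    rule: str

    def __post_init__(self) -> None:
        if not self.member_indices:
            raise ValidationError("folded set must be non-empty")

    def sorted_indices(self) -> list[int]:
        return sorted(self.member_indices)


def folded_set(
    task: DesignTask,
    sequence: str,
    rule: str = NATIVE_ONLY,
    *,
    indices: Iterable[int] | None = None,
    q: float | None = None,
) -> FoldedSet:
    """Derive the folded set for a sequence under one of three rules.

    ``native_only`` (default) collapses stability onto the Boltzmann
    objective. ``explicit`` takes a caller-supplied index list, which must
    contain the native state. ``energy_quantile`` keeps the
    ceil(q * |ensemble|) lowest-energy conformations under this sequence
    (ties broken by ensemble order), always forcing the native state in.
    """
    model = task.model
    model.validate_sequence(sequence)
    if rule == NATIVE_ONLY:
        return FoldedSet(frozenset({task.native_index}), NATIVE_ONLY)
    if rule == EXPLICIT:
        if indices is None:
            raise ValidationError("explicit rule requires an index list")
        members = frozenset(int(i) for i in indices)
        if any(not 0 <= i < model.n_conformations for i in members):
            raise ValidationError("explicit folded-set index outside the ensemble")
        if task.native_index not in members:
            raise ValidationError("folded set must contain the native conformation")
        return FoldedSet(members, EXPLICIT)
    if rule == ENERGY_QUANTILE:
        if q is None or not 0 < q <= 1:
            raise ValidationError("energy_quantile rule requires 0 < q <= 1")
        energies = model.sequence_energies(sequence)
        k = max(1, math.ceil(q * model.n_conformations))
        keep = set(np.argsort(energies, kind="stable")[:k].tolist())
        keep.add(task.native_index)
        return FoldedSet(frozenset(int(i) for i in keep), f"energy_quantile({q})")
    raise ValidationError(f"unknown folded-set rule {rule!r}")


def stability(task: DesignTask, sequence: str, fset: FoldedSet) -> float:
    """p(folded | s): total Boltzmann probability of the folded set."""
    probs = conformation_distribution(task.model, sequence)
    return float(probs[fset.sorted_indices()].sum())


def free_energy_gap(task: DesignTask, sequence: str, fset: FoldedSet) -> float:
    """Two-state folding free energy, dG = -kT ln(p(F|s) / (1 - p(F|s))).

    Negative when folding is favorable (p > 1/2). Diverges when the folded
    set carries all or none of the probability mass, which is signalled
    explicitly rather than returned as inf.
    """
    p = stability(task, sequence, fset)
    if p <= 0.0 or p >= 1.0:
        raise InfiniteFreeEnergyGapError(
            f"folding probability {p} gives an infinite two-state gap"
        )
    return float(-task.model.kT * math.log(p / (1.0 - p)))


def conformational_specificity(task: DesignTask, sequence: str, fset: FoldedSet) -> float:
    """p(X | s) / p(F | s): preference for the native state within the folded set."""
    probs = conformation_distribution(task.model, sequence)
    p_folded = float(probs[fset.sorted_indices()].sum())
    if p_folded <= 0.0:
        raise ValidationError("folded set has zero probability; specificity undefined")
    return float(probs[task.native_index] / p_folded)


class Decomposition(NamedTuple):
    boltzmann: float
    stability: float
    specificity: float
    residual: float


def decomposition_check(task: DesignTask, sequence: str, fset: FoldedSet) -> Decomposition:
    """Verify the exact factorization p(X|s) = specificity * stability."""
    probs = conformation_distribution(task.model, sequence)
    p_native = float(probs[task.native_index])
    p_folded = float(probs[fset.sorted_indices()].sum())
    spec = p_native / p_folded
    return Decomposition(p_native, p_folded, spec, abs(p_native - spec * p_folded))


def metrics_report(
    task: DesignTask,
    sequences: Iterable[str],
    rule: str = NATIVE_ONLY,
    *,
    indices: Iterable[int] | None = None,
    q: float | None = None,
) -> pd.DataFrame:
    """One row per sequence: Boltzmann, stability, specificity, dG, rule used."""
    rows = []
    for seq in sequences:
        fset = folded_set(task, seq, rule, indices=indices, q=q)
        p_fold = stability(task, seq, fset)
        try:
            gap = free_energy_gap(task, seq, fset)
        except InfiniteFreeEnergyGapError:
            gap = float("nan")
        rows.append(
            {
                "sequence": seq,
                "boltzmann": float(
                    conformation_distribution(task.model, seq)[task.native_index]
                ),
                "stability": p_fold,
                "specificity": conformational_specificity(task, seq, fset),
                "delta_g_kT": gap,
                "folded_set_rule": fset.rule,
            }
        )
    return pd.DataFrame(rows)
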