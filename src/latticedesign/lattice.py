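"""Exactly enumerable 2D lattice-protein ensembles.

A chain of ``L`` monomers is a self-avoiding walk (SAW) on the square
lattice. The complete set of canonical walks of a given length is the
conformational ensemble; with a symmetric contact potential this gives an
exactly computable Boltzmann distribution p(conformation | sequence),

    p(C | s) = exp(-G(C, s) / kT) / sum_C' exp(-G(C', s) / kT),

where G(C, s) is the sum of pairwise contact energies over all lattice
contacts of C. Because the ensemble is enumerated exhaustively, every
probability in this module is exact up to floating point, which is what
makes the module usable as a ground-truth oracle for sequence design.

Symmetry convention: conformations are quotiented by lattice translations,
rotations and reflections, but *not* by chain reversal -- residue indices
are chemically directional (N- to C-terminus). The canonical representative
starts at the origin, takes its first step in the +x direction, and makes
its first turn (if any) in the +y direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property, lru_cache
from typing import TYPE_CHECKING, Iterable

import numpy as np
from scipy.special import log_softmax

from .exceptions import EnsembleTooLargeError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .tasks import DesignTask

Point = tuple[int, int]

#: Hard cap on exhaustive SAW enumeration. The canonical ensemble grows
#: roughly as 2.64**L; at L = 14 it holds 110188 conformations, which is the
#: largest size that stays comfortably interactive on one CPU.
MAX_CHAIN_LENGTH = 14

# Trial order right, up, left, down fixes the lexicographic ordering of the
# enumerated step strings.
_DIRECTIONS: tuple[Point, ...] = ((1, 0), (0, 1), (-1, 0), (0, -1))


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet; the ordering defines tie-breaking rank."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValidationError("alphabet needs at least two symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError("alphabet symbols must be unique")
        if any(len(s) != 1 for s in self.symbols):
            raise ValidationError("alphabet symbols must be single characters")

    @classmethod
    def from_string(cls, symbols: str) -> "Alphabet":
        return cls(tuple(symbols))

    @property
    def size(self) -> int:
        return len(self.symbols)

    @cached_property
    def _index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise ValidationError(
                f"symbol {symbol!r} not in alphabet {''.join(self.symbols)!r}"
            ) from None

    def encode(self, sequence: str) -> np.ndarray:
        return np.array([self.index(c) for c in sequence], dtype=np.intp)

    def __str__(self) -> str:
        return "".join(self.symbols)


@dataclass(frozen=True)
class Conformation:
    """A self-avoiding walk; monomer ``i`` sits at ``coords[i]``."""

    coords: tuple[Point, ...]

    def __post_init__(self) -> None:
        if not self.coords:
            raise ValidationError("conformation needs at least one monomer")
        for (x0, y0), (x1, y1) in zip(self.coords, self.coords[1:]):
            if abs(x1 - x0) + abs(y1 - y0) != 1:
                raise ValidationError("consecutive monomers must be unit lattice steps")
        if len(set(self.coords)) != len(self.coords):
            raise ValidationError("walk revisits a lattice site (not self-avoiding)")

    @property
    def length(self) -> int:
        return len(self.coords)

    def steps(self) -> tuple[Point, ...]:
        return tuple(
            (x1 - x0, y1 - y0) for (x0, y0), (x1, y1) in zip(self.coords, self.coords[1:])
        )

    def is_canonical(self) -> bool:
        return canonicalize(self.coords) == self


def canonicalize(coords: Iterable[Point]) -> Conformation:
    """Map an arbitrary SAW onto its canonical symmetry representative.

    Translation puts the first monomer at the origin; the unique rotation
    sends the first step to (+1, 0); of the two remaining mirror images the
    one whose first non-collinear step has positive y is kept. Chain
    reversal is deliberately not quotiented.
    """
    pts = tuple((int(x), int(y)) for x, y in coords)
    walk = Conformation(pts)  # validates SAW-ness
    if walk.length == 1:
        return Conformation(((0, 0),))

    sx, sy = walk.steps()[0]
    # The four proper rotations of the square lattice.
    rotations = (
        lambda x, y: (x, y),
        lambda x, y: (y, -x),
        lambda x, y: (-x, -y),
        lambda x, y: (-y, x),
    )
    rot = next(r for r in rotations if r(sx, sy) == (1, 0))

    def rebuild(transform) -> tuple[Point, ...]:
        steps = [transform(*rot(dx, dy)) for dx, dy in walk.steps()]
        out = [(0, 0)]
        for dx, dy in steps:
            x, y = out[-1]
            out.append((x + dx, y + dy))
        return tuple(out)

    upright = rebuild(lambda x, y: (x, y))
    for dx, dy in Conformation(upright).steps():
        if dy != 0:  # first non-collinear step decides the mirror
            if dy < 0:
                upright = rebuild(lambda x, y: (x, -y))
            break
    return Conformation(upright)


@lru_cache(maxsize=None)
def enumerate_conformations(length: int) -> tuple[Conformation, ...]:
    """All canonical SAWs of ``length`` monomers, in lexicographic step order.

    The DFS emits only canonical walks directly: the first step is forced to
    +x and the first turn, if any, to +y, so no post-hoc deduplication is
    needed. Order is lexicographic over step strings with direction rank
    right < up < left < down, and is stable across runs.
    """
    if length < 1:
        raise ValidationError("chain length must be at least 1")
    if length > MAX_CHAIN_LENGTH:
        raise EnsembleTooLargeError(
            f"exhaustive ensemble for L={length} exceeds the cap "
            f"L <= {MAX_CHAIN_LENGTH}"
        )
    if length == 1:
        return (Conformation(((0, 0),)),)

    results: list[Conformation] = []
    path: list[Point] = [(0, 0), (1, 0)]
    occupied = {(0, 0), (1, 0)}

    def dfs(turned: bool) -> None:
        if len(path) == length:
            results.append(Conformation(tuple(path)))
            return
        x, y = path[-1]
        candidates = _DIRECTIONS if turned else ((1, 0), (0, 1))
        for dx, dy in candidates:
            nxt = (x + dx, y + dy)
            if nxt in occupied:
                continue
            path.append(nxt)
            occupied.add(nxt)
            dfs(turned or dy != 0)
            occupied.remove(nxt)
            path.pop()

    dfs(False)
    return tuple(results)


def contacts(conformation: Conformation) -> list[tuple[int, int]]:
    """Topological contacts: pairs (i, j), i + 1 < j, at unit lattice distance."""
    where = {pt: i for i, pt in enumerate(conformation.coords)}
    found: list[tuple[int, int]] = []
    for i, (x, y) in enumerate(conformation.coords):
        for dx, dy in _DIRECTIONS:
            j = where.get((x + dx, y + dy))
            if j is not None and j > i + 1:
                found.append((i, j))
    return sorted(found)


@dataclass(frozen=True)
class ContactPotential:
    """Symmetric pairwise contact energies in units of kT per contact."""

    alphabet: Alphabet
    energies: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        n = self.alphabet.size
        if len(self.energies) != n or any(len(row) != n for row in self.energies):
            raise ValidationError("energy matrix must be |alphabet| x |alphabet|")
        for i in range(n):
            for j in range(i + 1, n):
                if self.energies[i][j] != self.energies[j][i]:
                    raise ValidationError("contact energies must be symmetric")

    @classmethod
    def from_matrix(cls, alphabet: Alphabet, matrix) -> "ContactPotential":
        return cls(alphabet, tuple(tuple(float(v) for v in row) for row in matrix))

    @classmethod
    def hp(cls, e_hh: float = -1.0) -> "ContactPotential":
        """The classic HP potential: H-H contacts attract, everything else is inert."""
        return cls.from_matrix(Alphabet.from_string("HP"), [[e_hh, 0.0], [0.0, 0.0]])

    @cached_property
    def matrix(self) -> np.ndarray:
        return np.array(self.energies, dtype=float)


def energy(conformation: Conformation, sequence: str, potential: ContactPotential) -> float:
    """Contact energy G(C, s) = sum over contacts (i, j) of E(s_i, s_j)."""
    if len(sequence) != conformation.length:
        raise ValidationError(
            f"sequence length {len(sequence)} != chain length {conformation.length}"
        )
    idx = potential.alphabet.encode(sequence)
    return float(sum(potential.matrix[idx[i], idx[j]] for i, j in contacts(conformation)))


@dataclass(frozen=True)
class EnsembleModel:
    """Complete conformational ensemble plus energetics: the exact oracle.

    Holds every canonical conformation of the given length together with a
    contact potential and a temperature factor kT (dimensionless; energies
    are expressed in kT units, kT defaults to 1).
    """

    length: int
    alphabet: Alphabet
    conformations: tuple[Conformation, ...]
    potential: ContactPotential
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise ValidationError("kT must be positive")
        if self.potential.alphabet != self.alphabet:
            raise ValidationError("potential alphabet differs from model alphabet")
        if self.conformations != enumerate_conformations(self.length):
            raise ValidationError(
                "ensemble must be the complete canonical ensemble for its length"
            )

    @classmethod
    def build(
        cls,
        length: int,
        alphabet: Alphabet,
        potential: ContactPotential,
        kT: float = 1.0,
    ) -> "EnsembleModel":
        return cls(length, alphabet, enumerate_conformations(length), potential, kT)

    @property
    def n_conformations(self) -> int:
        return len(self.conformations)

    @cached_property
    def _contact_arrays(self) -> tuple[tuple[np.ndarray, np.ndarray], ...]:
        out = []
        for conf in self.conformations:
            pairs = contacts(conf)
            if pairs:
                i, j = zip(*pairs)
            else:
                i, j = (), ()
            out.append((np.array(i, dtype=np.intp), np.array(j, dtype=np.intp)))
        return tuple(out)

    def validate_sequence(self, sequence: str) -> np.ndarray:
        if len(sequence) != self.length:
            raise ValidationError(
                f"sequence length {len(sequence)} != chain length {self.length}"
            )
        return self.alphabet.encode(sequence)

    def sequence_energies(self, sequence: str) -> np.ndarray:
        """G(C, s) for every conformation C in ensemble order."""
        idx = self.validate_sequence(sequence)
        mat = self.potential.matrix
        return np.array(
            [mat[idx[i], idx[j]].sum() if i.size else 0.0 for i, j in self._contact_arrays]
        )


def log_conformation_distribution(
    model: EnsembleModel, sequence: str, energy_offset: float = 0.0
) -> np.ndarray:
    """log p(C | s) over the ensemble, via a stable log-softmax.

    ``energy_offset`` adds a constant to G(C, s) for every conformation; it
    exists to make the gauge invariance of the Boltzmann distribution under
    uniform energy shifts directly testable.
    """
    g = model.sequence_energies(sequence) + energy_offset
    return log_softmax(-g / model.kT)


def conformation_distribution(
    model: EnsembleModel, sequence: str, energy_offset: float = 0.0
) -> np.ndarray:
    """Exact Boltzmann distribution p(C | s) over the ensemble."""
    return np.exp(log_conformation_distribution(model, sequence, energy_offset))


def boltzmann_probability(task: "DesignTask", sequence: str) -> float:
    """p(structure = native | seq), the Boltzmann probability of the target fold."""
    return float(conformation_distribution(task.model, sequence)[task.native_index])


def log_boltzmann_probability(task: "DesignTask", sequence: str) -> float:
    return float(log_conformation_distribution(task.model, sequence)[task.native_index])
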