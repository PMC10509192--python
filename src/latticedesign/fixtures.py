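"""Seeded generation of randomized design tasks.

The generator draws symmetric contact potentials, sequence priors, and
native target conformations from a recorded seed, producing fully
validated DesignTask/JointModel pairs. Defaults are chosen to emulate a
designable lattice-protein study: contact energies are attractive (drawn
uniformly from [-2, 0] kT, bracketing the classic HP value of -1 kT), and
the native state is by default the most-contacted conformation of its
ensemble, i.e. a compact, designable target rather than an arbitrary open
coil.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .lattice import Alphabet, ContactPotential, EnsembleModel, contacts
from .models import JointModel, SequencePrior
from .tasks import DesignTask

UNIFORM_NATIVE = "uniform"
MAX_CONTACTS_NATIVE = "max_contacts"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible batch of random design tasks."""

    seed: int
    n_tasks: int = 1
    lengths: tuple[int, int] = (6, 6)  # inclusive range sampled uniformly
    alphabet: str = "HP"
    energy_range: tuple[float, float] = (-2.0, 0.0)
    prior_kind: str = "uniform"  # "uniform" | "markov1" (random Dirichlet rows)
    native_rule: str = MAX_CONTACTS_NATIVE
    kT: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.lengths
        if not 2 <= lo <= hi:
            raise ValidationError("length range must satisfy 2 <= min <= max")
        if self.n_tasks < 1:
            raise ValidationError("need at least one task")
        if self.prior_kind not in ("uniform", "markov1"):
            raise ValidationError(f"unknown prior kind {self.prior_kind!r}")
        if self.native_rule not in (UNIFORM_NATIVE, MAX_CONTACTS_NATIVE):
            raise ValidationError(f"unknown native rule {self.native_rule!r}")


def random_potential(
    alphabet: Alphabet, rng: np.random.Generator, energy_range=(-2.0, 0.0)
) -> ContactPotential:
    """A symmetric contact matrix with i.i.d. uniform upper-triangle entries."""
    n = alphabet.size
    lo, hi = energy_range
    m = rng.uniform(lo, hi, size=(n, n))
    m = np.triu(m) + np.triu(m, 1).T
    return ContactPotential.from_matrix(alphabet, m)


def random_prior(
    alphabet: Alphabet, kind: str, rng: np.random.Generator
) -> SequencePrior:
    """Uniform, or a first-order Markov prior with Dirichlet(1) rows."""
    if kind == "uniform":
        return SequencePrior.uniform(alphabet)
    n = alphabet.size
    return SequencePrior.markov1(
        alphabet, rng.dirichlet(np.ones(n)), [rng.dirichlet(np.ones(n)) for _ in range(n)]
    )


def pick_native(model: EnsembleModel, rule: str, rng: np.random.Generator) -> int:
    """Select a native conformation index: uniform, or the most-contacted one."""
    if rule == UNIFORM_NATIVE:
        return int(rng.integers(model.n_conformations))
    n_contacts = [len(contacts(c)) for c in model.conformations]
    return int(np.argmax(n_contacts))  # ties -> lowest ensemble index


def generate_fixtures(spec: FixtureSpec) -> list[tuple[DesignTask, JointModel]]:
    """Deterministically expand a FixtureSpec into validated task/joint pairs."""
    rng = np.random.default_rng(spec.seed)
    alphabet = Alphabet.from_string(spec.alphabet)
    out = []
    for _ in range(spec.n_tasks):
        length = int(rng.integers(spec.lengths[0], spec.lengths[1] + 1))
        potential = random_potential(alphabet, rng, spec.energy_range)
        model = EnsembleModel.build(length, alphabet, potential, kT=spec.kT)
        prior = random_prior(alphabet, spec.prior_kind, rng)
        task = DesignTask(model, pick_native(model, spec.native_rule, rng))
        out.append((task, JointModel(prior, model)))
    return out
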