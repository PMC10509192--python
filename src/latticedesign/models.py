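"""Exact autoregressive sequence models over the lattice joint distribution.

The joint distribution is p(s, C) = p0(s) * p(C | s): a sequence prior
(uniform or first-order Markov) times the exact Boltzmann distribution of
the ensemble. From it two autoregressive models are derived by brute-force
marginalization over unassigned positions:

* the structure conditional p(s_i | s_assigned, X), the role a
  structure-conditioned inverse-folding network plays;
* the marginal p(s_i | s_assigned), the role a protein language model
  plays. Because sum_C p(C | s) = 1 for every sequence, this marginal is
  identically the prior's own conditional -- a fact the test suite verifies
  by explicit summation.

A mismatched marginal (a different prior standing in for the true one)
models the practically important scenario where the conditional and
marginal networks were trained on different sequence distributions, e.g.
crystal-structure sequences versus a broad sequence database.
"""

from __future__ import annotations

import abc
import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import log_softmax, logsumexp

from .exceptions import FeasibilityError, ValidationError
from .lattice import Alphabet, EnsembleModel, log_conformation_distribution
from .tasks import DesignTask

#: Refuse brute-force enumeration when the number of sequence completions
#: exceeds this; exactness is only honest at desk scale.
MAX_ENUMERATION = 10**6

Prefix = "str | Mapping[int, str]"


@dataclass(frozen=True)
class SequencePrior:
    """p0(s): uniform or first-order Markov over the alphabet."""

    alphabet: Alphabet
    kind: str  # "uniform" | "markov1"
    initial: tuple[float, ...] | None = None
    transition: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        n = self.alphabet.size
        if self.kind == "uniform":
            if self.initial is not None or self.transition is not None:
                raise ValidationError("uniform prior takes no parameters")
        elif self.kind == "markov1":
            if self.initial is None or self.transition is None:
                raise ValidationError("markov1 prior needs initial and transition")
            if len(self.initial) != n or len(self.transition) != n:
                raise ValidationError("prior dimensions must match the alphabet")
            if any(p < 0 for p in self.initial) or abs(sum(self.initial) - 1) > 1e-12:
                raise ValidationError("initial distribution must be a probability vector")
            for row in self.transition:
                if len(row) != n:
                    raise ValidationError("transition matrix must be square")
                if any(p < 0 for p in row) or abs(sum(row) - 1) > 1e-12:
                    raise ValidationError("transition rows must sum to 1")
        else:
            raise ValidationError(f"unknown prior kind {self.kind!r}")

    @classmethod
    def uniform(cls, alphabet: Alphabet) -> "SequencePrior":
        return cls(alphabet, "uniform")

    @classmethod
    def markov1(cls, alphabet: Alphabet, initial, transition) -> "SequencePrior":
        return cls(
            alphabet,
            "markov1",
            tuple(float(p) for p in initial),
            tuple(tuple(float(p) for p in row) for row in transition),
        )

    @property
    def log_initial(self) -> np.ndarray:
        if self.kind == "uniform":
            return np.full(self.alphabet.size, -np.log(self.alphabet.size))
        with np.errstate(divide="ignore"):
            return np.log(np.array(self.initial))

    @property
    def log_transition(self) -> np.ndarray:
        if self.kind == "uniform":
            n = self.alphabet.size
            return np.full((n, n), -np.log(n))
        with np.errstate(divide="ignore"):
            return np.log(np.array(self.transition))


def prior_logprob(prior: SequencePrior, sequence: str) -> float:
    """log p0(s) under the prior's factorization."""
    idx = prior.alphabet.encode(sequence)
    if idx.size == 0:
        return 0.0
    total = float(prior.log_initial[idx[0]])
    lt = prior.log_transition
    for a, b in zip(idx, idx[1:]):
        total += float(lt[a, b])
    return total


def prior_next_logprobs(prior: SequencePrior, prev_symbol: str | None) -> np.ndarray:
    """The prior's next-symbol conditional after a contiguous prefix."""
    if prev_symbol is None:
        return prior.log_initial.copy()
    return prior.log_transition[prior.alphabet.index(prev_symbol)].copy()


@dataclass(frozen=True)
class JointModel:
    """p(s, C) = p0(s) * p(C | s) over a complete lattice ensemble."""

    prior: SequencePrior
    ensemble: EnsembleModel

    def __post_init__(self) -> None:
        if self.prior.alphabet != self.ensemble.alphabet:
            raise ValidationError("prior alphabet differs from ensemble alphabet")


def _as_assignment(prefix, length: int) -> dict[int, str]:
    if isinstance(prefix, str):
        assigned = dict(enumerate(prefix))
    else:
        assigned = {int(p): s for p, s in prefix.items()}
    for pos in assigned:
        if not 0 <= pos < length:
            raise ValidationError(f"assigned position {pos} outside [0, {length})")
    return assigned


def _pick_position(assigned: dict[int, str], length: int, position: int | None) -> int:
    if position is None:
        free = [i for i in range(length) if i not in assigned]
        if not free:
            raise ValidationError("no unassigned position left to decode")
        return free[0]
    if position in assigned:
        raise ValidationError(f"position {position} is already assigned")
    if not 0 <= position < length:
        raise ValidationError(f"position {position} outside [0, {length})")
    return position


class AutoregressiveModel(abc.ABC):
    """Contract: a deterministic next-symbol log-probability distribution.

    ``prefix`` is either a contiguous string (positions 0..k-1) or a
    mapping from position to symbol for arbitrary partial assignments;
    ``position`` selects the position being decoded (default: first
    unassigned). The returned vector is over the alphabet, normalized
    (exponentiates and sums to 1 within 1e-9), and identical for identical
    inputs.
    """

    @property
    @abc.abstractmethod
    def alphabet(self) -> Alphabet:
        ...

    @abc.abstractmethod
    def next_symbol_logprobs(
        self,
        prefix,
        *,
        position: int | None = None,
        task: DesignTask | None = None,
    ) -> np.ndarray:
        ...


def _check_enumeration_cap(n_symbols: int, n_open: int) -> None:
    if n_symbols**n_open > MAX_ENUMERATION:
        raise FeasibilityError(
            f"brute-force enumeration of {n_symbols}**{n_open} completions exceeds "
            f"the cap of {MAX_ENUMERATION}"
        )


def _enumerated_next_logprobs(
    prior: SequencePrior,
    assigned: dict[int, str],
    position: int,
    length: int,
    loglik=None,
) -> np.ndarray:
    """Marginalize p0(s) (* optional structure likelihood) over open positions."""
    symbols = prior.alphabet.symbols
    free = [i for i in range(length) if i not in assigned and i != position]
    _check_enumeration_cap(len(symbols), len(free) + 1)
    template = [""] * length
    for pos, sym in assigned.items():
        template[pos] = sym
    out = np.empty(len(symbols))
    for ai, a in enumerate(symbols):
        template[position] = a
        terms = []
        for combo in itertools.product(symbols, repeat=len(free)):
            for pos, sym in zip(free, combo):
                template[pos] = sym
            seq = "".join(template)
            lp = prior_logprob(prior, seq)
            if loglik is not None:
                lp += loglik(seq)
            terms.append(lp)
        out[ai] = logsumexp(terms)
    return log_softmax(out)


class PriorModel(AutoregressiveModel):
    """Exact marginal p(s_i | s_assigned): the sequence prior's own conditional.

    Contiguous prefixes use the closed Markov form; arbitrary assignments
    fall back to brute-force marginalization (which needs the chain length,
    taken from ``length`` or from ``task``).
    """

    def __init__(self, prior: SequencePrior, length: int | None = None):
        self.prior = prior
        self.length = length

    @property
    def alphabet(self) -> Alphabet:
        return self.prior.alphabet

    def next_symbol_logprobs(self, prefix, *, position=None, task=None) -> np.ndarray:
        length = self.length
        if length is None and task is not None:
            length = task.model.length
        if isinstance(prefix, str) and length is None:
            length = max(len(prefix) + 1, (position or 0) + 1)
        if length is None:
            raise ValidationError("PriorModel needs a chain length for mapping prefixes")
        assigned = _as_assignment(prefix, length)
        position = _pick_position(assigned, length, position)
        if set(assigned) == set(range(position)):
            prev = assigned[position - 1] if position > 0 else None
            return prior_next_logprobs(self.prior, prev)
        return _enumerated_next_logprobs(self.prior, assigned, position, length)


class ExactConditionalModel(AutoregressiveModel):
    """Exact structure conditional p(s_i | s_assigned, X) by suffix enumeration.

    p(s_i = a | s_assigned, X) is proportional to the sum over all
    completions s of p0(s) * p(X | s). Per-sequence structure likelihoods
    and per-(assignment, position) output vectors are memoized, so teacher
    forcing many sequences of one task shares nearly all the work.
    """

    def __init__(self, joint: JointModel, task: DesignTask):
        if task.model != joint.ensemble:
            raise ValidationError("task ensemble differs from the joint model's ensemble")
        self.joint = joint
        self.task = task
        self._loglik_cache: dict[str, float] = {}
        self._vector_cache: dict[tuple, np.ndarray] = {}

    @property
    def alphabet(self) -> Alphabet:
        return self.joint.prior.alphabet

    def _log_structure_likelihood(self, sequence: str) -> float:
        cached = self._loglik_cache.get(sequence)
        if cached is None:
            cached = float(
                log_conformation_distribution(self.joint.ensemble, sequence)[
                    self.task.native_index
                ]
            )
            self._loglik_cache[sequence] = cached
        return cached

    def next_symbol_logprobs(self, prefix, *, position=None, task=None) -> np.ndarray:
        if task is not None and task != self.task:
            raise ValidationError("model was built for a different design task")
        length = self.joint.ensemble.length
        assigned = _as_assignment(prefix, length)
        position = _pick_position(assigned, length, position)
        key = (tuple(sorted(assigned.items())), position)
        cached = self._vector_cache.get(key)
        if cached is None:
            cached = _enumerated_next_logprobs(
                self.joint.prior,
                assigned,
                position,
                length,
                loglik=self._log_structure_likelihood,
            )
            self._vector_cache[key] = cached
        return cached.copy()


def exact_conditional(
    joint: JointModel, task: DesignTask, prefix, *, position: int | None = None
) -> np.ndarray:
    """One-shot p(s_i | s_assigned, X); see :class:`ExactConditionalModel`."""
    return ExactConditionalModel(joint, task).next_symbol_logprobs(
        prefix, position=position
    )


def exact_marginal(
    joint: JointModel, prefix, *, position: int | None = None
) -> np.ndarray:
    """One-shot p(s_i | s_assigned) under the joint's own prior."""
    return PriorModel(joint.prior, joint.ensemble.length).next_symbol_logprobs(
        prefix, position=position
    )


def mismatched_marginal(
    joint: JointModel, alt_prior: SequencePrior, prefix, *, position: int | None = None
) -> np.ndarray:
    """Marginal under a *different* prior than the one inside the joint.

    Models a marginal network trained on another sequence distribution than
    the conditional network; plugging this into ratio decoding quantifies
    the cost of that miscalibration.
    """
    if alt_prior.alphabet != joint.prior.alphabet:
        raise ValidationError("mismatched prior must share the joint's alphabet")
    return PriorModel(alt_prior, joint.ensemble.length).next_symbol_logprobs(
        prefix, position=position
    )
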