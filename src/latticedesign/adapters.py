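"""Adapter contract for external neural conditional/marginal models.

No network code ships with this package. This module documents exactly
what an external model (e.g. a structure-conditioned inverse-folding
network standing in for p(seq | structure), or a protein language model
standing in for p(seq)) must implement so that the decoders in
:mod:`latticedesign.decode` can drive it in place of the exact toy models.

Contract (see :class:`latticedesign.models.AutoregressiveModel`):

1. ``alphabet`` -- the residue alphabet the model scores, as a
   :class:`latticedesign.lattice.Alphabet`. Its symbol ordering defines
   tie-breaking; decoders resolve score ties toward the lowest index.
2. ``next_symbol_logprobs(prefix, *, position=None, task=None)`` -- a
   NumPy vector of log-probabilities over the alphabet for the symbol at
   ``position``, conditioned on the partial assignment ``prefix`` (a
   contiguous string or a {position: symbol} mapping) and, for
   conditional models, on the target structure carried by ``task``.
   Marginal models must ignore the structure. The vector must
   exponentiate and sum to 1 within 1e-9 and be byte-identical for
   identical inputs (no sampling, no stateful caches that change
   results). Return log-probabilities, never logits.
3. The model must tolerate arbitrary visit orders: decoders may request
   positions in any permutation, with fixed (constrained) residues
   already present in ``prefix``.

An adapter that satisfies this contract can be passed directly as the
``cond`` or ``marg`` argument of ``greedy_decode`` / ``beam_decode``; the
ratio objective, constraint handling, tie-breaking, and result reporting
are then identical to the exact-model path.
"""

from __future__ import annotations

from .models import AutoregressiveModel


class NeuralModelAdapter(AutoregressiveModel):
    """Abstract base for external model adapters; implement the contract above."""

    @property
    def alphabet(self):  # pragma: no cover - documentation stub
        raise NotImplementedError("adapters must expose their residue alphabet")

    def next_symbol_logprobs(self, prefix, *, position=None, task=None):  # pragma: no cover
        raise NotImplementedError(
            "adapters must return a normalized log-probability vector; "
            "see the module docstring for the full contract"
        )
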