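# Methods

## Model

`latticedesign` studies inverse protein folding in a setting where every
probability can be computed exactly. A "protein" is a chain of `L` monomers
over a finite residue alphabet, a "structure" is a self-avoiding walk (SAW)
on the 2D square lattice, and the conformational ensemble `C` is the
*complete* set of canonical SAWs of length `L`. The energy of a sequence
`s` in a conformation `C` is the standard lattice-contact form

    G(C, s) = sum over contacts (i, j) of E(s_i, s_j),

where a contact is a residue pair non-adjacent in the chain (`i + 1 < j`)
at unit lattice distance, and `E` is a symmetric matrix in units of kT per
contact. The equilibrium (Boltzmann) probability of a conformation is

    p(C | s) = exp(-G(C, s) / kT) / sum_{C'} exp(-G(C', s) / kT).

Because the ensemble is enumerated exhaustively, the partition sum is
exact; this is the package's entire reason for using a lattice model. The
contact-sum energy is a design choice: it is the simplest form that makes
the Boltzmann sum exactly computable while still coupling sequence to
structure. `kT` is dimensionless and defaults to 1.0 (energies are
expressed in kT units); it is configurable everywhere.

### Symmetry and enumeration conventions

Conformations are quotiented by translation, rotation, and reflection, but
**not** by chain reversal: residue indices are chemically directional. The
canonical representative starts at the origin, takes its first step in +x,
and makes its first turn (if any) in +y. The enumerator emits canonical
walks directly (first step forced, first turn forced) in lexicographic
step-string order with direction rank right < up < left < down, so
ensemble indices and probability vectors are reproducible across runs. The
test suite independently re-derives the ensemble by enumerating *all*
walks and counting symmetry orbits under the full 8-element lattice point
group.

Exhaustive enumeration grows exponentially (~2.64^L canonical walks);
chains longer than `MAX_CHAIN_LENGTH = 14` (110,188 conformations) are
refused with an explicit error rather than silently truncated.

## Stability and conformational specificity

For a folded set `F` of conformations (which must contain the native
structure `X`):

* **stability** = p(F | s), the total Boltzmann weight of the folded set;
* **conformational specificity** = p(X | s) / p(F | s), the preference for
  the native state among folded conformations;
* their product is identically the Boltzmann objective,
  p(X | s) = specificity x stability. The identity is exact by
  construction; the tests require the residual to stay below 1e-12 across
  random tasks, sequences, and folded-set rules, which pins down that both
  chemical properties are factors of the single design objective.

The folded set is configurable because "folded" has no canonical
definition in a discrete toy ensemble: `native_only` (default; stability
then *is* the Boltzmann objective), an `explicit` index list, or
`energy_quantile(q)` (the `ceil(q * |C|)` lowest-energy conformations
under the scored sequence, native forced in, ties broken by ensemble
order). A two-state free-energy gap is also provided,

    dG = -kT ln( p(F|s) / (1 - p(F|s)) ),

negative when folding is favorable; p(F|s) of exactly 0 or 1 raises an
explicit infinite-gap error instead of returning inf.

## Exact autoregressive models

The joint distribution is p(s, C) = p0(s) p(C | s) with a sequence prior
p0 that is either uniform or first-order Markov (initial vector +
row-stochastic transition matrix). Two autoregressive models are derived
from it by brute-force marginalization over unassigned positions:

* **structure conditional** p(s_i = a | s_assigned, X), proportional to
  the sum over all completions of p0(s) p(X | s) — the role a
  structure-conditioned inverse-folding network plays;
* **marginal** p(s_i = a | s_assigned) — the role an unconditional protein
  language model plays. Since sum_C p(C | s) = 1, this marginal equals the
  prior's own conditional; the tests verify that by explicitly summing the
  joint over every conformation and suffix.

Both satisfy a single model contract (normalized log-probability vector,
deterministic, arbitrary visit orders with partial assignments), which is
also the documented adapter surface for plugging in external neural
models (`latticedesign/adapters.py`). Enumeration refuses to run when the
completion count `|A|^(L - assigned)` exceeds 1e6, keeping exactness
honest. A **mismatched marginal** — the conditional of a *different* prior
— models conditional and marginal networks trained on different sequence
corpora; ratio decoding against it quantifies the cost of that
miscalibration.

## Decoding

By Bayes' rule, argmax_s p(X | s) = argmax_s p(s | X) / p0(s): the dropped
evidence p(X) does not depend on the sequence. The decoders maximize the
per-position log-ratio log p(a | context, X) - log p(a | context):

* **greedy**: positions visited in the constraint order (identity by
  default; a seeded random permutation is available since some
  structure-conditioned decoders use randomized orders); fixed positions
  take their required symbol but still extend the context; ties resolve to
  the lowest alphabet index. Passing no marginal gives the
  conditional-only baseline, argmax p(s | X).
* **beam**: standard beam search over the same score; width 1 reproduces
  greedy exactly, width `|A|^L` is exhaustive.
* **brute force**: exhaustive scan of every constraint-respecting
  sequence under the ratio, conditional-only, or direct Boltzmann
  objective. The ratio and conditional objectives are scored through the
  same teacher-forced autoregressive chain the decoders use, so the
  brute-force oracle exercises the full Bayes machinery end to end rather
  than a closed-form shortcut.

Only argmax-style decoders are provided: the ratio objective is defined
through an argmax, and sampling from it would require renormalizing the
ratio, so stochastic decoding is an explicit non-goal.

### Numerical choices

All scoring is in log domain; probabilities are never multiplied in linear
domain. Conformation distributions use a log-sum-exp softmax.

Exact toy ensembles produce *genuinely tied* sequence classes — e.g. when
the native structure's contacts touch only a subset of positions, every
sequence agreeing on those positions has identical p(X | s). Different
float paths to the same mathematical score (a teacher-forced chain sum
versus a direct log-softmax entry) disagree at ~1e-14 on such classes, so
the brute-force and beam maximizers treat log-score differences below
`TIE_TOLERANCE = 1e-9` as exact ties and break them lexicographically by
alphabet order. This keeps all maximizers deterministic and mutually
consistent; with continuous random potentials, genuine score gaps below
1e-9 essentially never occur.

## Synthetic task generator

`FixtureSpec`/`generate_fixtures` draw validated tasks from a recorded
seed: symmetric contact matrices with i.i.d. uniform entries on [-2, 0] kT
(attractive contacts bracketing the classic HP value of -1 kT), uniform or
random-Dirichlet first-order Markov priors, and a native structure that is
by default the most-contacted conformation of its ensemble — a compact,
designable target (at L = 4 this is always the unique "hook" with one
contact). Verification sweeps use binary (HP) alphabets at L = 4–6, where
exhaustive sequence scans (<= 64 sequences) and ensembles (<= 36
conformations) make every oracle exact and the full suite runs in seconds;
batch sizes of 50 (argmax/beam/reduction checks) and 200 (dominance) give
stable means.

What the generator does *not* emulate: 20-letter chemistry, 3D lattices or
off-lattice geometry, structure-dependent model error (the exact
conditional is perfectly calibrated to the ensemble by construction), and
solubility or any other property outside the Boltzmann ensemble. Passing
tests therefore certify the *logic* of ratio decoding — that it recovers
the Boltzmann maximizer when its two models are exact and matched — not
that any particular neural instantiation is accurate on real proteins.

## Known limitations

* The finite, discrete conformational ensemble is a concretization; for
  real proteins the state space is continuous and the partition sum is
  intractable, which is precisely why neural surrogates are used there.
* Cross-objective dominance (each greedy decoder winning on its own
  objective) is asserted at the batch mean; individual tasks can violate
  it because greedy decoding is not exhaustive, and the per-task violation
  rate is reported alongside the means (typically ~5% at L = 6).
* The mismatched-marginal comparison is likewise a mean-level statement;
  a particular mismatched prior can happen to help on a particular task.
* `energy_quantile` folded sets depend on the scored sequence, so folded
  sets are not comparable across sequences under that rule; the metrics
  report records the rule used for exactly this reason.
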