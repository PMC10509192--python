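"""Greedy/beam ratio decoding, brute-force oracle, constraints, and dominance."""

import itertools

import numpy as np
import pytest

import latticedesign as ld
from conftest import fixture_batch


def _models(task, joint, matched=True):
    cond = ld.ExactConditionalModel(joint, task)
    marg = ld.PriorModel(joint.prior, task.model.length) if matched else None
    return cond, marg


class TestGreedy:
    def test_all_positions_fixed_returns_fixed_sequence(self, hook_task, hook_joint):
        cons = ld.DesignConstraints.create({0: "P", 1: "H", 2: "P", 3: "H"})
        cond, marg = _models(hook_task, hook_joint)
        result = ld.greedy_decode(cond, marg, hook_task, cons)
        assert result.sequence == "PHPH"

    def test_hook_task_decodes_all_h(self, hook_task, hook_joint):
        """Positions 0 and 3 prefer H (they form the only contact); positions
        1 and 2 tie and resolve to H, the lower alphabet index."""
        cond, marg = _models(hook_task, hook_joint)
        result = ld.greedy_decode(cond, marg, hook_task)
        assert result.sequence == "HHHH"
        assert result.objective_name == "bayes_ratio"
        assert result.objective_total == pytest.approx(
            sum(result.per_position_scores), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_uniform_prior_reduction(self, seed):
        """With a uniform prior the marginal term is a constant per position,
        so Bayes decoding and conditional-only decoding coincide exactly."""
        task, joint = fixture_batch(seed + 100, 1, length=6, prior_kind="uniform")[0]
        cond, marg = _models(task, joint)
        bayes = ld.greedy_decode(cond, marg, task)
        conditional = ld.greedy_decode(cond, None, task)
        assert bayes.sequence == conditional.sequence

    def test_fixed_positions_respected_and_extend_context(self, hook_task, hook_joint):
        cons = ld.DesignConstraints.create({1: "P"})
        cond, marg = _models(hook_task, hook_joint)
        result = ld.greedy_decode(cond, marg, hook_task, cons)
        assert result.sequence[1] == "P"
        assert len(result.per_position_scores) == 4

    def test_unknown_constraint_symbol_rejected(self, hook_task, hook_joint):
        cond, marg = _models(hook_task, hook_joint)
        with pytest.raises(ld.ValidationError):
            ld.greedy_decode(
                cond, marg, hook_task, ld.DesignConstraints.create({0: "X"})
            )

    def test_determinism(self):
        task, joint = fixture_batch(7, 1)[0]
        runs = [
            ld.greedy_decode(*_models(task, joint), task) for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_random_decode_order_total_matches_identity_order(self, hook_task, hook_joint):
        """Teacher-forced chain totals are visit-order invariant (chain rule
        factorizes in any order), even though greedy choices may differ."""
        cond, marg = _models(hook_task, hook_joint)
        order = ld.random_order(4, np.random.default_rng(3))
        seq = ld.greedy_decode(cond, marg, hook_task).sequence
        t_identity = sum(ld.teacher_forced_scores(cond, marg, hook_task, seq))
        t_permuted = sum(
            ld.teacher_forced_scores(
                cond, marg, hook_task, seq, ld.DesignConstraints.create(order=order)
            )
        )
        assert t_identity == pytest.approx(t_permuted, abs=1e-10)


class TestBeam:
    @pytest.mark.parametrize("seed", range(10))
    def test_width_one_equals_greedy(self, seed):
        task, joint = fixture_batch(seed + 200, 1)[0]
        cond, marg = _models(task, joint)
        assert ld.beam_decode(cond, marg, task, width=1) == ld.greedy_decode(
            cond, marg, task
        )

    def test_widening_never_decreases_objective(self):
        task, joint = fixture_batch(42, 1)[0]
        cond, marg = _models(task, joint)
        totals = [
            ld.beam_decode(cond, marg, task, width=w).objective_total
            for w in (1, 2, 4, 8, 16, 64)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_exhaustive_width_equals_brute_force(self, seed):
        task, joint = fixture_batch(seed + 300, 1)[0]
        cond, marg = _models(task, joint)
        exhaustive = ld.beam_decode(cond, marg, task, width=2 ** task.model.length)
        oracle = ld.brute_force_argmax(task, joint, ld.BAYES_RATIO)
        assert exhaustive.sequence == oracle.sequence
        assert exhaustive.objective_total == pytest.approx(
            oracle.objective_total, abs=1e-12
        )

    def test_invalid_width(self, hook_task, hook_joint):
        cond, marg = _models(hook_task, hook_joint)
        with pytest.raises(ld.ValidationError):
            ld.beam_decode(cond, marg, hook_task, width=0)


class TestBruteForce:
    def test_single_free_position_scans_alphabet(self, hook_task, hook_joint):
        cons = ld.DesignConstraints.create({0: "H", 1: "H", 3: "H"})
        best = ld.brute_force_argmax(hook_task, hook_joint, ld.BOLTZMANN, cons)
        scans = {
            seq: ld.boltzmann_probability(hook_task, seq)
            for seq in ("HHHH", "HHPH")
        }
        assert best.sequence == max(sorted(scans), key=lambda s: scans[s])

    def test_boltzmann_maximizer_places_h_at_contact(self, hook_task, hook_joint):
        best = ld.brute_force_argmax(hook_task, hook_joint, ld.BOLTZMANN)
        assert best.sequence[0] == "H" and best.sequence[3] == "H"

    @pytest.mark.parametrize("seed", range(10))
    def test_matched_prior_ratio_equals_boltzmann_argmax(self, seed):
        """The Bayes derivation drops only sequence-independent factors, so
        the exhaustive ratio maximizer is the exhaustive Boltzmann maximizer."""
        task, joint = fixture_batch(seed + 400, 1, length=5)[0]
        ratio = ld.brute_force_argmax(task, joint, ld.BAYES_RATIO)
        boltz = ld.brute_force_argmax(task, joint, ld.BOLTZMANN)
        assert ratio.sequence == boltz.sequence

    def test_search_space_cap(self):
        alphabet = ld.Alphabet.from_string("ACDEFGHIKLMNPQRSTVWY")
        model = ld.EnsembleModel.build(
            6, alphabet, ld.ContactPotential.from_matrix(alphabet, np.zeros((20, 20)))
        )
        task = ld.DesignTask(model, 0)
        joint = ld.JointModel(ld.SequencePrior.uniform(alphabet), model)
        with pytest.raises(ld.FeasibilityError):
            ld.brute_force_argmax(task, joint, ld.BOLTZMANN)


class TestScoring:
    def test_ratio_minus_log_boltzmann_is_constant(self, hook_task, hook_joint):
        """log_ratio(s) - log p(X|s) is the same for all 16 HP sequences."""
        offsets = []
        for s in itertools.product("HP", repeat=4):
            seq = "".join(s)
            scores = ld.score_sequence(hook_task, hook_joint, seq)
            offsets.append(scores.log_ratio - np.log(scores.boltzmann))
        assert np.ptp(offsets) < 1e-9

    def test_uniform_prior_conditional_is_shifted_ratio(self, hook_task, hook_joint):
        diffs = []
        for s in itertools.product("HP", repeat=4):
            scores = ld.score_sequence(hook_task, hook_joint, "".join(s))
            diffs.append(scores.log_conditional - scores.log_ratio)
        assert np.ptp(diffs) < 1e-12  # constant log p0(s) = -4 log 2

    def test_argmax_beats_random_sequences_on_own_objective(self):
        task, joint = fixture_batch(9, 1)[0]
        best = ld.brute_force_argmax(task, joint, ld.BAYES_RATIO)
        best_score = ld.score_sequence(task, joint, best.sequence).log_ratio
        rng = np.random.default_rng(9)
        for _ in range(100):
            seq = "".join(rng.choice(list("HP")) for _ in range(task.model.length))
            assert best_score >= ld.score_sequence(task, joint, seq).log_ratio - 1e-10


class TestCompareDecoders:
    def test_uniform_batch_identical_decoders(self):
        table, summary = ld.compare_decoders(
            fixture_batch(55, 10, prior_kind="uniform")
        )
        wide = table.pivot(index="task", columns="decoder", values="sequence")
        assert (wide["bayes_greedy"] == wide["conditional_greedy"]).all()
        assert summary["ratio_gap"] == pytest.approx(0.0, abs=1e-12)
        assert summary["conditional_gap"] == pytest.approx(0.0, abs=1e-12)

    def test_markov_batch_dominance_at_mean(self):
        """Each greedy decoder wins on its own objective at the batch mean."""
        _, summary = ld.compare_decoders(fixture_batch(66, 40, prior_kind="markov1"))
        assert summary["ratio_gap"] >= 0
        assert summary["conditional_gap"] >= 0
        assert summary["dominance_holds"]

    def test_brute_force_weakly_dominates_on_ratio_objective(self):
        table, _ = ld.compare_decoders(
            fixture_batch(77, 8, prior_kind="markov1"), include_brute_force=True
        )
        wide = table.pivot(index="task", columns="decoder", values="log_ratio")
        for decoder in ("bayes_greedy", "conditional_greedy"):
            assert (wide["brute_force_ratio"] >= wide[decoder] - 1e-9).all()

    def test_mismatched_marginal_never_helps_at_mean(self):
        """Decoding against a marginal from the wrong sequence distribution
        cannot improve the achieved Boltzmann probability on average."""
        batch = fixture_batch(88, 60, prior_kind="markov1")
        rng = np.random.default_rng(89)
        alts = [
            ld.random_prior(batch[0][0].model.alphabet, "markov1", rng)
            for _ in batch
        ]
        table, _ = ld.compare_decoders(batch, mismatched_priors=alts)
        means = table.groupby("decoder")["boltzmann"].mean()
        assert means["bayes_greedy"] >= means["bayes_greedy_mismatched"]
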