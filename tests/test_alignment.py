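import math

import numpy as np
import pytest

from eradev.alignment import (
    ERAConfig,
    PreferencePair,
    build_preference_pairs,
    closed_form_optimal_policy,
    dpo_pair_loss,
    era_pair_divergence,
    parametric_preference_probability,
    target_preference_probability,
    train_policy_dpo,
    train_policy_era,
)
from eradev.landscapes import (
    FitnessLandscape,
    SyntheticSpec,
    generate_synthetic_landscape,
    scale_landscape,
)
from eradev.policy import FactorizedPolicy, JointPolicy, snapshot_reference
from eradev.synthetic_fixtures import make_biased_reference_policy


def _kl(p_log, q_log):
    return float(np.sum(np.exp(p_log) * (p_log - q_log)))


def _tv(p, q):
    return 0.5 * float(np.abs(p - q).sum())


def _pair(uy=0.0, uyp=0.0, ref_lr=0.0):
    return PreferencePair("AA", "AC", uy, uyp, ref_lr)


class TestBuildPairs:
    @pytest.mark.parametrize("n,expected", [(96, 4560), (1, 0), (3, 3)])
    def test_pair_counts(self, n, expected):
        l = generate_synthetic_landscape(SyntheticSpec(n_positions=3, alphabet_size=5, seed=0))
        ref = FactorizedPolicy.for_landscape(l)
        sl = scale_landscape(l)
        records = [(v, sl.energy[v]) for v in l.variants()[:n]]
        assert len(build_preference_pairs(records, ref)) == expected

    def test_canonical_orientation(self):
        l = generate_synthetic_landscape(SyntheticSpec(n_positions=2, alphabet_size=3, seed=0))
        ref = FactorizedPolicy.for_landscape(l)
        sl = scale_landscape(l)
        pairs = build_preference_pairs([(v, sl.energy[v]) for v in l.variants()], ref)
        assert all(q.U_y <= q.U_y_prime for q in pairs)

    def test_duplicate_records_error(self):
        l = generate_synthetic_landscape(SyntheticSpec(n_positions=2, alphabet_size=3, seed=0))
        ref = FactorizedPolicy.for_landscape(l)
        v = l.variants()[0]
        with pytest.raises(ValueError, match="duplicate"):
            build_preference_pairs([(v, 0.1), (v, 0.2)], ref)

    def test_ref_logratio_from_snapshot(self, small_epistatic, biased_reference):
        pairs = build_preference_pairs(
            [(v, small_epistatic.energy[v]) for v in small_epistatic.variants()[:4]],
            biased_reference,
        )
        for q in pairs:
            want = biased_reference.loglik(biased_reference.encode([q.y, q.y_prime]))
            assert q.ref_logratio == pytest.approx(float(want[0] - want[1]))


class TestPreferenceProbabilities:
    def test_equal_likelihoods_give_half(self):
        p = FactorizedPolicy.uniform([1, 2], "ACD")
        assert parametric_preference_probability(_pair(), p) == pytest.approx(0.5)

    def test_logratio_ln3_gives_three_quarters(self):
        # pi(AA)/pi(CA) = 0.75/0.25 = 3 -> sigma(ln 3) = 3/4
        logits = np.log(np.array([[0.75, 0.25, 0.0], [1.0, 0.0, 0.0]]) + 1e-300)
        p = FactorizedPolicy([1, 2], "ACD", logits)
        q = PreferencePair("AA", "CA", 0.0, 0.0, 0.0)
        assert parametric_preference_probability(q, p) == pytest.approx(0.75, abs=1e-9)

    def test_orientation_sums_to_one(self, small_epistatic, biased_reference):
        pairs = build_preference_pairs(
            [(v, small_epistatic.energy[v]) for v in small_epistatic.variants()[:5]],
            biased_reference,
        )
        for q in pairs:
            a = parametric_preference_probability(q, biased_reference)
            b = parametric_preference_probability(q.swapped(), biased_reference)
            assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_target_neutral_pair_is_half(self):
        assert target_preference_probability(_pair(), ERAConfig()) == pytest.approx(0.5)

    def test_target_direct_evaluation(self):
        # gamma=0, beta=1, U(y)=0, U(y')=ln 2 -> sigma(ln 2) = 2/3
        cfg = ERAConfig(beta=1.0, gamma=0.0)
        got = target_preference_probability(_pair(uy=0.0, uyp=math.log(2)), cfg)
        assert got == pytest.approx(2 / 3, abs=1e-12)

    def test_target_large_gamma_follows_reference(self):
        cfg = ERAConfig(beta=1.0, gamma=1e9)
        q = _pair(uy=0.0, uyp=5.0, ref_lr=math.log(3))
        assert target_preference_probability(q, cfg) == pytest.approx(0.75, abs=1e-6)

    def test_as_printed_coefficient(self):
        cfg = ERAConfig(beta=2.0, gamma=0.5, logratio_coefficient_mode="as_printed")
        assert cfg.logratio_coefficient == pytest.approx(0.25)
        cfg2 = ERAConfig(beta=2.0, gamma=0.5)
        assert cfg2.logratio_coefficient == pytest.approx(1 / 3)


class TestDivergences:
    def test_kl_zero_at_match(self):
        p = FactorizedPolicy.uniform([1, 2], "ACD")
        assert era_pair_divergence(_pair(), p, ERAConfig()) == pytest.approx(0.0, abs=1e-12)

    def test_kl_direct_value(self):
        # p_gamma=0.5 vs p_theta=0.75: 0.5 ln(0.5/0.75) + 0.5 ln(0.5/0.25)
        want = 0.5 * math.log(4 / 3)
        logits = np.log(np.array([[0.75, 0.25, 0.0], [1.0, 0.0, 0.0]]) + 1e-300)
        p = FactorizedPolicy([1, 2], "ACD", logits)
        q = PreferencePair("AA", "CA", 0.0, 0.0, 0.0)  # p_theta = 3/4, p_gamma = 1/2
        assert era_pair_divergence(q, p, ERAConfig()) == pytest.approx(want, abs=1e-9)

    def test_kl_nonnegative_random_pairs(self):
        rng = np.random.default_rng(0)
        p = FactorizedPolicy([1, 2], "ACD", rng.normal(size=(2, 3)))
        cfg = ERAConfig(beta=1.3, gamma=0.4)
        for _ in range(200):
            q = _pair(uy=rng.exponential(), uyp=rng.exponential(), ref_lr=rng.normal())
            assert era_pair_divergence(q, p, cfg) >= -1e-15

    def test_mean_loss_orientation_invariant(self, small_epistatic, biased_reference):
        cfg = ERAConfig(beta=1.0, gamma=0.3)
        pairs = build_preference_pairs(
            [(v, small_epistatic.energy[v]) for v in small_epistatic.variants()[:6]],
            biased_reference,
        )
        a = np.mean([era_pair_divergence(q, biased_reference, cfg) for q in pairs])
        b = np.mean([era_pair_divergence(q.swapped(), biased_reference, cfg) for q in pairs])
        assert a == pytest.approx(b, abs=1e-12)


class TestDPOLoss:
    def test_at_reference_is_ln2(self):
        p = FactorizedPolicy.uniform([1, 2], "ACD")
        q = PreferencePair("AA", "AC", 0.0, 1.0, 0.0)
        assert dpo_pair_loss(q, p, beta_dpo=1.0) == pytest.approx(math.log(2), abs=1e-12)

    def test_winner_advantage_drives_loss_to_zero(self):
        logits = np.array([[40.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        p = FactorizedPolicy([1, 2], "ACD", logits)
        q = PreferencePair("AA", "CA", 0.0, 1.0, 0.0)  # winner AA hugely likelier
        assert dpo_pair_loss(q, p, beta_dpo=1.0) < 1e-9

    def test_direct_evaluation_ln3_advantage(self):
        logits = np.log(np.array([[0.75, 0.25, 0.0], [1.0, 0.0, 0.0]]) + 1e-300)
        p = FactorizedPolicy([1, 2], "ACD", logits)
        q = PreferencePair("AA", "CA", 0.0, 1.0, 0.0)
        assert dpo_pair_loss(q, p, beta_dpo=1.0) == pytest.approx(-math.log(0.75), abs=1e-9)

    def test_tie_skipped(self):
        p = FactorizedPolicy.uniform([1, 2], "ACD")
        assert dpo_pair_loss(PreferencePair("AA", "AC", 1.0, 1.0, 0.0), p) is None

    def test_trainer_counts_ties(self, small_epistatic, biased_reference):
        pairs = build_preference_pairs(
            [(v, small_epistatic.energy[v]) for v in small_epistatic.variants()[:4]],
            biased_reference,
        )
        tied = [PreferencePair(q.y, q.y_prime, 1.0, 1.0, q.ref_logratio) for q in pairs[:2]]
        p = FactorizedPolicy.for_landscape(small_epistatic.base)
        res = train_policy_dpo(p, pairs[2:] + tied, ERAConfig(epochs=2))
        assert res.skipped_ties == 2


class TestClosedForm:
    def test_gamma_limit_recovers_reference(self, small_epistatic, biased_reference):
        cfg = ERAConfig(beta=1.0, gamma=1e12)
        opt = closed_form_optimal_policy(small_epistatic, biased_reference, cfg)
        ref_ll = biased_reference.loglik(biased_reference.encode(opt.variants))
        assert _tv(np.exp(opt.log_prob_vector()), np.exp(ref_ll)) < 1e-9

    def test_gamma_zero_is_boltzmann(self, small_epistatic, biased_reference):
        cfg = ERAConfig(beta=2.0, gamma=0.0)
        opt = closed_form_optimal_policy(small_epistatic, biased_reference, cfg)
        U = np.array([small_epistatic.energy[v] for v in opt.variants])
        boltz = np.exp(-cfg.beta * U)
        boltz /= boltz.sum()
        assert _tv(np.exp(opt.log_prob_vector()), boltz) < 1e-12

    def test_two_variant_direct(self):
        l = FitnessLandscape(
            positions=(1,), parent="A", alphabet="AC", table={"A": 1.0, "C": 0.5}
        )
        sl = scale_landscape(l)  # U = (0, ln 2)
        ref = FactorizedPolicy.uniform([1], "AC")
        opt = closed_form_optimal_policy(sl, ref, ERAConfig(beta=1.0, gamma=0.0))
        probs = {v: math.exp(x) for v, x in zip(opt.variants, opt.log_prob_vector())}
        assert probs["A"] == pytest.approx(2 / 3, abs=1e-12)
        assert probs["C"] == pytest.approx(1 / 3, abs=1e-12)

    def test_fixed_point_of_preferences(self, small_epistatic, biased_reference):
        """Defining property: pi* makes parametric == target for every pair."""
        cfg = ERAConfig(beta=1.7, gamma=0.6)
        opt = closed_form_optimal_policy(small_epistatic, biased_reference, cfg)
        pairs = build_preference_pairs(
            [(v, small_epistatic.energy[v]) for v in small_epistatic.variants()],
            biased_reference,
        )
        for q in pairs:
            assert parametric_preference_probability(q, opt) == pytest.approx(
                target_preference_probability(q, cfg), abs=1e-9
            )

    def test_beta_monotone_expected_fitness(self, small_epistatic, biased_reference):
        """Increasing beta never lowers expected scaled fitness under pi*."""
        f = np.array([small_epistatic.scaled[v] for v in small_epistatic.variants()])
        prev = -np.inf
        for beta in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
            opt = closed_form_optimal_policy(
                small_epistatic, biased_reference, ERAConfig(beta=beta, gamma=0.3)
            )
            ef = float(np.exp(opt.log_prob_vector()) @ f)
            assert ef >= prev - 1e-12
            prev = ef


class TestTraining:
    def test_stationary_at_optimum(self, small_epistatic, biased_reference):
        cfg = ERAConfig(beta=1.0, gamma=0.2, epochs=10, learning_rate=0.5)
        opt = closed_form_optimal_policy(small_epistatic, biased_reference, cfg)
        pairs = build_preference_pairs(
            [(v, small_epistatic.energy[v]) for v in small_epistatic.variants()],
            biased_reference,
        )
        start = np.exp(opt.log_prob_vector()).copy()
        res = train_policy_era(opt.copy(), pairs, cfg)
        assert res.loss_trace[0] < 1e-15
        assert _tv(np.exp(res.policy.log_prob_vector()), start) < 1e-6

    def test_joint_converges_to_closed_form(self, small_epistatic, biased_reference):
        cfg = ERAConfig(beta=1.0, gamma=0.1, epochs=500, learning_rate=1.0)
        pairs = build_preference_pairs(
            [(v, small_epistatic.energy[v]) for v in small_epistatic.variants()],
            biased_reference,
        )
        p = JointPolicy.uniform_over(small_epistatic)
        train_policy_era(p, pairs, cfg)
        opt = closed_form_optimal_policy(small_epistatic, biased_reference, cfg)
        assert _kl(opt.log_prob_vector(), p.loglik(p.encode(opt.variants))) < 1e-3

    def test_factorized_converges_when_energy_additive(self):
        l = generate_synthetic_landscape(
            SyntheticSpec(
                n_positions=2, alphabet_size=3, pairwise_scale=0.0,
                higher_order_scale=0.0, noise_sd=0.0, seed=5,
            )
        )
        sl = scale_landscape(l)
        ref = make_biased_reference_policy(l, bias=0.2, seed=6)
        cfg = ERAConfig(beta=1.0, gamma=0.1, epochs=500, learning_rate=1.0)
        pairs = build_preference_pairs([(v, sl.energy[v]) for v in l.variants()], ref)
        p = FactorizedPolicy.for_landscape(l)
        train_policy_era(p, pairs, cfg)
        opt = closed_form_optimal_policy(sl, ref, cfg)
        assert _kl(opt.log_prob_vector(), p.loglik(p.encode(opt.variants))) < 1e-3

    def test_large_gamma_stays_near_reference(self, small_epistatic, biased_reference):
        cfg = ERAConfig(beta=1.0, gamma=1e6, epochs=300, learning_rate=1.0)
        pairs = build_preference_pairs(
            [(v, small_epistatic.energy[v]) for v in small_epistatic.variants()],
            biased_reference,
        )
        p = biased_reference.copy()
        p.logits = p.logits.copy()
        train_policy_era(p, pairs, cfg)
        ref_probs = np.exp(
            biased_reference.loglik(
                biased_reference.encode(small_epistatic.variants())
            )
        )
        got = np.exp(p.loglik(p.encode(small_epistatic.variants())))
        assert _tv(got, ref_probs) < 1e-2

    def test_loss_trace_decreases(self, small_epistatic, biased_reference):
        cfg = ERAConfig(beta=1.0, gamma=0.1, epochs=50, learning_rate=0.5)
        pairs = build_preference_pairs(
            [(v, small_epistatic.energy[v]) for v in small_epistatic.variants()],
            biased_reference,
        )
        res = train_policy_era(JointPolicy.uniform_over(small_epistatic), pairs, cfg)
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_minibatch_training_runs(self, small_epistatic, biased_reference):
        cfg = ERAConfig(epochs=5, learning_rate=0.2, pair_batch_size=8, seed=3)
        pairs = build_preference_pairs(
            [(v, small_epistatic.energy[v]) for v in small_epistatic.variants()],
            biased_reference,
        )
        res = train_policy_era(JointPolicy.uniform_over(small_epistatic), pairs, cfg)
        assert len(res.loss_trace) == cfg.epochs + 1


def test_pair_table_export(tmp_path, small_epistatic, biased_reference):
    from eradev.alignment import write_pair_table

    pairs = build_preference_pairs(
        [(v, small_epistatic.energy[v]) for v in small_epistatic.variants()[:4]],
        biased_reference,
    )
    f = tmp_path / "pairs.tsv"
    write_pair_table(pairs, f)
    lines = f.read_text().strip().split("\n")
    assert lines[0].split("\t") == ["combo_y", "combo_yprime", "U_y", "U_yprime", "ref_logratio"]
    assert len(lines) == 1 + 6
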