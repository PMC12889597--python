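"""Energy rank alignment (ERA): preference pairs, targets, losses, training.

Given a batch of assayed variants, every unordered pair ``(y, y')`` becomes a
preference labeled by the energies ``U = -log f`` of its members.  The policy
is trained so that its parametric preference probability

    p_theta(y > y') = sigmoid(log pi_theta(y) - log pi_theta(y'))

matches an entropy-regularized Gibbs-Boltzmann target

    p_gamma(y > y') = sigmoid( beta/(1+gamma) * (U(y') - U(y))
                               + c_gamma * [log pi_ref(y) - log pi_ref(y')] )

by minimizing the mean Bernoulli KL divergence ``D(p_gamma || p_theta)`` over
pairs.  The minimizer is the tilted distribution

    pi*(y)  propto  pi_ref(y)^(gamma/(1+gamma)) * exp(-beta U(y) / (1+gamma)),

i.e. a Boltzmann distribution at inverse temperature ``beta/(1+gamma)``
regularized toward the reference policy.  With ``c_gamma = gamma/(1+gamma)``
(the default, ``self_consistent`` mode) this fixed point is exact: plugging
``pi*`` into the parametric preference reproduces the target for every pair.
An alternative ``as_printed`` mode with ``c_gamma = gamma/beta`` is retained
for comparison experiments; it does not share the closed-form minimizer
except where the two coefficients coincide.

A rank-only direct-preference-optimization (DPO) baseline loss is included:
it uses only the ordering of each pair, not the energy gap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, log_expit, logsumexp, xlogy

from .landscapes import ScaledLandscape, Variant
from .policy import (
    FactorizedPolicy,
    JointPolicy,
    Policy,
    pseudo_log_likelihood,
)

__all__ = [
    "PreferencePair",
    "ERAConfig",
    "TrainResult",
    "build_preference_pairs",
    "parametric_preference_probability",
    "target_preference_probability",
    "era_pair_divergence",
    "dpo_pair_loss",
    "train_policy_era",
    "train_policy_dpo",
    "closed_form_optimal_policy",
    "write_pair_table",
]


@dataclass(frozen=True)
class PreferencePair:
    """An unordered preference pair stored in canonical orientation.

    ``y`` is the lower-energy (higher-fitness) member when energies differ;
    all downstream quantities are invariant to the orientation.
    ``ref_logratio`` is ``log pi_ref(y) - log pi_ref(y')`` under the frozen
    reference snapshot.
    """

    y: Variant
    y_prime: Variant
    U_y: float
    U_y_prime: float
    ref_logratio: float

    def __post_init__(self) -> None:
        if self.y == self.y_prime:
            raise ValueError(f"preference pair members must differ, got {self.y!r} twice")
        if not (np.isfinite(self.U_y) and np.isfinite(self.U_y_prime)):
            raise ValueError("pair energies must be finite")

    def swapped(self) -> "PreferencePair":
        return PreferencePair(
            self.y_prime, self.y, self.U_y_prime, self.U_y, -self.ref_logratio
        )


@dataclass(frozen=True)
class ERAConfig:
    """Hyperparameters of the alignment objective and its trainer.

    ``beta`` is the inverse temperature of the Gibbs-Boltzmann target
    (larger beta -> lower-entropy, greedier target); ``gamma`` regularizes
    toward the reference policy (gamma -> infinity recovers the reference,
    gamma = 0 the pure Boltzmann distribution).  ``epochs`` defaults to 25,
    a budget chosen so the training loss has converged; the default
    ``learning_rate`` is sized for tabular logits so that full-batch descent
    actually reaches that plateau within the epoch budget (the pair-gradient
    coefficients are bounded by 1, so these steps remain stable).
    ``pair_batch_size`` of None means full-batch gradient descent.
    """

    beta: float = 1.0
    gamma: float = 0.1
    epochs: int = 25
    learning_rate: float = 2.0
    pair_batch_size: int | None = None
    seed: int = 0
    logratio_coefficient_mode: str = "self_consistent"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.logratio_coefficient_mode not in ("self_consistent", "as_printed"):
            raise ValueError(
                f"unknown logratio_coefficient_mode {self.logratio_coefficient_mode!r}"
            )

    @property
    def energy_coefficient(self) -> float:
        return self.beta / (1.0 + self.gamma)

    @property
    def logratio_coefficient(self) -> float:
        if self.logratio_coefficient_mode == "self_consistent":
            return self.gamma / (1.0 + self.gamma)
        return self.gamma / self.beta


def build_preference_pairs(
    records: Sequence[tuple[Variant, float]],
    ref: Policy,
) -> list[PreferencePair]:
    """All N(N-1)/2 unordered pairs from assayed (variant, energy) records.

    Each pair is stored once, oriented with the lower-energy member first;
    reference log-ratios are computed from the given reference snapshot.
    """
    variants = [v for v, _ in records]
    if len(set(variants)) != len(variants):
        seen: set[Variant] = set()
        dup = next(v for v in variants if v in seen or seen.add(v))
        raise ValueError(f"duplicate variant in records: {dup!r}")
    ll = ref.loglik(ref.encode(variants))
    pairs: list[PreferencePair] = []
    for (i, (y, uy)), (j, (yp, uyp)) in itertools.combinations(enumerate(records), 2):
        if uyp < uy:  # canonical orientation: lower energy first
            i, j, y, yp, uy, uyp = j, i, yp, y, uyp, uy
        pairs.append(
            PreferencePair(y, yp, float(uy), float(uyp), float(ll[i] - ll[j]))
        )
    return pairs


def parametric_preference_probability(pair: PreferencePair, p: Policy) -> float:
    """sigmoid of the policy's log-likelihood ratio for the pair."""
    s = pseudo_log_likelihood(p, pair.y) - pseudo_log_likelihood(p, pair.y_prime)
    return float(expit(s))


def target_preference_probability(pair: PreferencePair, cfg: ERAConfig) -> float:
    """The entropy-regularized Gibbs-Boltzmann preference target."""
    s = cfg.energy_coefficient * (pair.U_y_prime - pair.U_y)
    s += cfg.logratio_coefficient * pair.ref_logratio
    return float(expit(s))


def _bernoulli_kl(p: np.ndarray, logit_q: np.ndarray) -> np.ndarray:
    """D(Bern(p) || Bern(sigmoid(logit_q))), numerically safe at p in {0,1}."""
    return (
        xlogy(p, p)
        + xlogy(1.0 - p, 1.0 - p)
        - p * log_expit(logit_q)
        - (1.0 - p) * log_expit(-logit_q)
    )


def era_pair_divergence(pair: PreferencePair, p: Policy, cfg: ERAConfig) -> float:
    """Bernoulli KL from the target preference to the parametric one."""
    p_gamma = target_preference_probability(pair, cfg)
    s = pseudo_log_likelihood(p, pair.y) - pseudo_log_likelihood(p, pair.y_prime)
    return float(_bernoulli_kl(np.float64(p_gamma), np.float64(s)))


def dpo_pair_loss(
    pair: PreferencePair, p: Policy, beta_dpo: float = 0.1
) -> float | None:
    """Rank-only DPO loss for one pair; None for energy ties (skipped).

    The winner is the lower-energy member.  Only the difference of the
    policy-vs-reference log-ratios between winner and loser enters, so the
    stored pairwise ``ref_logratio`` suffices.
    """
    if pair.U_y == pair.U_y_prime:
        return None
    pr = pair if pair.U_y < pair.U_y_prime else pair.swapped()
    s = pseudo_log_likelihood(p, pr.y) - pseudo_log_likelihood(p, pr.y_prime)
    return float(-log_expit(beta_dpo * (s - pr.ref_logratio)))


@dataclass
class TrainResult:
    """Outcome of a training run: the policy (trained in place), the
    per-epoch loss trace, and the number of tied pairs skipped (DPO only)."""

    policy: Policy
    loss_trace: list[float] = field(default_factory=list)
    skipped_ties: int = 0


def _encode_pairs(p: Policy, pairs: Sequence[PreferencePair]):
    enc_y = p.encode([q.y for q in pairs])
    enc_yp = p.encode([q.y_prime for q in pairs])
    return enc_y, enc_yp


def train_policy_era(
    p: Policy, pairs: Sequence[PreferencePair], cfg: ERAConfig
) -> TrainResult:
    """Gradient-descent minimization of the mean pairwise ERA divergence.

    Full-batch by default; with ``pair_batch_size`` set, pairs are shuffled
    each epoch under the config seed.  The per-epoch trace records the
    full-batch loss before each epoch's updates plus the final loss.  The
    reference enters only through the frozen ``ref_logratio`` stored on the
    pairs, so the snapshot is untouched.
    """
    if not pairs:
        raise ValueError("need at least one preference pair")
    enc_y, enc_yp = _encode_pairs(p, pairs)
    p_gamma = np.array([target_preference_probability(q, cfg) for q in pairs])
    rng = np.random.default_rng(cfg.seed)
    m = len(pairs)

    def full_loss() -> float:
        s = p.loglik(enc_y) - p.loglik(enc_yp)
        return float(_bernoulli_kl(p_gamma, s).mean())

    trace: list[float] = []
    for _ in range(cfg.epochs):
        loss = full_loss()
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite ERA loss {loss} — reduce the learning rate or check energies"
            )
        trace.append(loss)
        if cfg.pair_batch_size is None or cfg.pair_batch_size >= m:
            batches = [np.arange(m)]
        else:
            perm = rng.permutation(m)
            batches = np.array_split(perm, int(np.ceil(m / cfg.pair_batch_size)))
        for idx in batches:
            by, byp = enc_y[idx], enc_yp[idx]
            s = p.loglik(by) - p.loglik(byp)
            coeff = (expit(s) - p_gamma[idx]) / len(idx)
            p.step(p.pair_gradient(by, byp, coeff), cfg.learning_rate)
    trace.append(full_loss())
    return TrainResult(policy=p, loss_trace=trace)


def train_policy_dpo(
    p: Policy,
    pairs: Sequence[PreferencePair],
    cfg: ERAConfig,
    beta_dpo: float = 0.1,
) -> TrainResult:
    """Gradient descent on the mean rank-only DPO loss.

    Energy ties carry no ranking signal and are skipped; the skipped count is
    reported on the result.
    """
    oriented = []
    ties = 0
    for q in pairs:
        if q.U_y == q.U_y_prime:
            ties += 1
        else:
            oriented.append(q if q.U_y < q.U_y_prime else q.swapped())
    if not oriented:
        raise ValueError("no strictly ordered pairs to train on")
    enc_w, enc_l = _encode_pairs(p, oriented)
    ref_lr = np.array([q.ref_logratio for q in oriented])
    rng = np.random.default_rng(cfg.seed)
    m = len(oriented)

    def full_loss() -> float:
        s = beta_dpo * ((p.loglik(enc_w) - p.loglik(enc_l)) - ref_lr)
        return float(-log_expit(s).mean())

    trace: list[float] = []
    for _ in range(cfg.epochs):
        loss = full_loss()
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite DPO loss {loss}")
        trace.append(loss)
        if cfg.pair_batch_size is None or cfg.pair_batch_size >= m:
            batches = [np.arange(m)]
        else:
            perm = rng.permutation(m)
            batches = np.array_split(perm, int(np.ceil(m / cfg.pair_batch_size)))
        for idx in batches:
            bw, bl = enc_w[idx], enc_l[idx]
            s = beta_dpo * ((p.loglik(bw) - p.loglik(bl)) - ref_lr[idx])
            coeff = -beta_dpo * expit(-s) / len(idx)
            p.step(p.pair_gradient(bw, bl, coeff), cfg.learning_rate)
    trace.append(full_loss())
    return TrainResult(policy=p, loss_trace=trace, skipped_ties=ties)


def closed_form_optimal_policy(
    l: ScaledLandscape, ref: Policy, cfg: ERAConfig
) -> JointPolicy:
    """The exact minimizer of the ERA objective over an enumerable landscape.

    ``pi*(y) propto pi_ref(y)^(gamma/(1+gamma)) * exp(-beta U(y)/(1+gamma))``,
    equivalently ``pi_ref^(gamma/(1+gamma)) * f_y^(beta/(1+gamma))`` with
    ``f_y`` the scaled fitness.  Returned as a joint policy because the
    optimum need not factorize even when the reference does.
    """
    from .landscapes import DEFAULT_SIZE_CAP

    if len(l) > DEFAULT_SIZE_CAP:
        raise ValueError(f"landscape size {len(l)} exceeds enumeration cap")
    variants = l.variants()
    ref_ll = ref.loglik(ref.encode(variants))
    U = np.array([l.energy[v] for v in variants])
    g = cfg.gamma
    log_unnorm = (g / (1.0 + g)) * ref_ll - cfg.energy_coefficient * U
    log_probs = log_unnorm - logsumexp(log_unnorm)
    return JointPolicy(
        l.positions, l.alphabet, variants, log_probs, name="era-optimal"
    )


def write_pair_table(pairs: Iterable[PreferencePair], path: str | Path) -> None:
    """Export pairs as TSV: combo_y, combo_yprime, U_y, U_yprime, ref_logratio."""
    with open(path, "w") as fh:
        fh.write("combo_y\tcombo_yprime\tU_y\tU_yprime\tref_logratio\n")
        for q in pairs:
            fh.write(
                f"{q.y}\t{q.y_prime}\t{q.U_y:.10g}\t{q.U_y_prime:.10g}\t{q.ref_logratio:.10g}\n"
            )
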