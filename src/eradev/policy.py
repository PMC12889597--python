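"""Sequence policies over the mutated positions of a landscape.

A policy is a probability distribution over variants.  Two tabular forms are
provided:

* :class:`FactorizedPolicy` — one categorical distribution per mutated
  position, combined as a product.  This mirrors the simultaneous-unmasking
  scheme of masked protein language models, where all masked positions are
  filled independently given the fixed parent context and the generation
  pseudo-likelihood is the product of the per-position probabilities.
* :class:`JointPolicy` — an explicit categorical distribution over an
  enumerated variant space.  The closed-form alignment optimum is in general
  not factorized, so the joint form is needed as an exact oracle.

Both expose the same minimal contract a real protein-language-model adapter
would satisfy: pseudo-log-likelihoods, constrained sampling, a frozen
reference snapshot, and a gradient step on their logits.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .landscapes import DEFAULT_SIZE_CAP, FitnessLandscape, ScaledLandscape, Variant, hamming

__all__ = [
    "FactorizedPolicy",
    "JointPolicy",
    "SamplingConstraints",
    "VariantDistribution",
    "pseudo_log_likelihood",
    "enumerate_distribution",
    "sample_variants",
    "snapshot_reference",
    "save_policy",
    "load_policy",
]


@dataclass
class SamplingConstraints:
    """Restrictions applied while sampling variants.

    ``excluded`` removes specific variants (duplicates and previously assayed
    sequences); ``fixed`` pins residues at given 1-based parent positions;
    ``max_hamming`` keeps samples within a Hamming radius of a reference set
    of variants; ``allow_repeats`` permits duplicate draws (used only to
    reproduce the mode-collapse concession made for the rank-only baseline).
    """

    excluded: frozenset[Variant] = frozenset()
    fixed: Mapping[int, str] = field(default_factory=dict)
    max_hamming: tuple[int, frozenset[Variant]] | None = None
    allow_repeats: bool = False
    #: optional support restriction (e.g. the landscape's variant table when
    #: the policy's sample space is larger than the assayable space)
    allowed: frozenset[Variant] | None = None

    def __post_init__(self) -> None:
        self.excluded = frozenset(self.excluded)
        if self.allowed is not None:
            self.allowed = frozenset(self.allowed)
        if self.max_hamming is not None:
            radius, refs = self.max_hamming
            if radius < 0:
                raise ValueError("Hamming radius must be >= 0")
            self.max_hamming = (int(radius), frozenset(refs))

    def admits(self, v: Variant, positions: Sequence[int], alphabet: str) -> bool:
        if v in self.excluded:
            return False
        if self.allowed is not None and v not in self.allowed:
            return False
        for pos, res in self.fixed.items():
            if res not in alphabet:
                raise ValueError(f"fixed residue {res!r} not in alphabet")
            try:
                i = list(positions).index(pos)
            except ValueError:
                raise ValueError(f"fixed position {pos} is not a mutated position") from None
            if v[i] != res:
                return False
        if self.max_hamming is not None:
            radius, refs = self.max_hamming
            if not any(hamming(v, r) <= radius for r in refs):
                return False
        return True


class _TabularPolicy:
    """Shared machinery for tabular policies parameterized by logits."""

    positions: tuple[int, ...]
    alphabet: str
    logits: np.ndarray
    name: str

    def _check_symbols(self, v: Variant) -> None:
        bad = set(v) - set(self.alphabet)
        if bad:
            raise ValueError(f"variant {v!r} uses symbols outside alphabet: {sorted(bad)}")

    def freeze(self) -> None:
        self.logits.setflags(write=False)

    @property
    def frozen(self) -> bool:
        return not self.logits.flags.writeable

    def step(self, gradient: np.ndarray, learning_rate: float) -> None:
        """In-place gradient-descent step on the logits."""
        if self.frozen:
            raise ValueError("cannot train a frozen reference snapshot")
        self.logits -= learning_rate * gradient


class FactorizedPolicy(_TabularPolicy):
    """Product of independent per-position categorical distributions.

    ``logits`` has shape ``(n_positions, alphabet_size)``; per-position
    probabilities are softmax rows and the joint probability of a variant is
    the product across positions.
    """

    def __init__(
        self,
        positions: Sequence[int],
        alphabet: str,
        logits: np.ndarray | None = None,
        name: str = "factorized",
    ) -> None:
        self.positions = tuple(positions)
        self.alphabet = alphabet
        n, A = len(self.positions), len(alphabet)
        if logits is None:
            logits = np.zeros((n, A))
        logits = np.array(logits, dtype=float)
        if logits.shape != (n, A):
            raise ValueError(f"logits shape {logits.shape} != ({n}, {A})")
        self.logits = logits
        self.name = name

    @classmethod
    def uniform(cls, positions: Sequence[int], alphabet: str) -> "FactorizedPolicy":
        return cls(positions, alphabet, name="uniform")

    @classmethod
    def for_landscape(cls, l: FitnessLandscape | ScaledLandscape) -> "FactorizedPolicy":
        return cls(l.positions, l.alphabet, name=f"uniform-{getattr(l, 'name', '')}")

    def log_prob_matrix(self) -> np.ndarray:
        return self.logits - logsumexp(self.logits, axis=1, keepdims=True)

    # -- encoding / vectorized likelihoods ---------------------------------
    def encode(self, variants: Sequence[Variant]) -> np.ndarray:
        """Residue-index matrix of shape (m, n_positions)."""
        lut = {a: k for k, a in enumerate(self.alphabet)}
        try:
            return np.array([[lut[a] for a in v] for v in variants], dtype=np.intp).reshape(
                len(variants), len(self.positions)
            )
        except KeyError as e:
            raise ValueError(f"residue {e.args[0]!r} not in alphabet") from None

    def loglik(self, enc: np.ndarray) -> np.ndarray:
        lp = self.log_prob_matrix()
        return lp[np.arange(lp.shape[0]), enc].sum(axis=1)

    def pair_gradient(
        self, enc_y: np.ndarray, enc_yp: np.ndarray, coeff: np.ndarray
    ) -> np.ndarray:
        """Gradient of ``sum_k coeff_k * (loglik(y_k) - loglik(y'_k))``.

        The softmax-Jacobian terms cancel between the two members of each
        pair, leaving signed one-hot accumulations.
        """
        g = np.zeros_like(self.logits)
        for i in range(g.shape[0]):
            np.add.at(g[i], enc_y[:, i], coeff)
            np.add.at(g[i], enc_yp[:, i], -coeff)
        return g

    def copy(self, name: str | None = None) -> "FactorizedPolicy":
        return FactorizedPolicy(
            self.positions, self.alphabet, self.logits.copy(), name or self.name
        )

    # -- sampling ----------------------------------------------------------
    def propose(self, n: int, rng: np.random.Generator) -> list[Variant]:
        p = np.exp(self.log_prob_matrix())
        cols = [rng.choice(len(self.alphabet), size=n, p=p[i]) for i in range(p.shape[0])]
        mat = np.stack(cols, axis=1)
        return ["".join(self.alphabet[k] for k in row) for row in mat]

    def space_size(self) -> int:
        return len(self.alphabet) ** len(self.positions)

    def enumerate_space(self):
        for tup in itertools.product(self.alphabet, repeat=len(self.positions)):
            yield "".join(tup)


class JointPolicy(_TabularPolicy):
    """Explicit categorical distribution over an enumerated variant space."""

    def __init__(
        self,
        positions: Sequence[int],
        alphabet: str,
        variants: Sequence[Variant],
        logits: np.ndarray | None = None,
        name: str = "joint",
    ) -> None:
        self.positions = tuple(positions)
        self.alphabet = alphabet
        self.variants = list(variants)
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("duplicate variants in joint support")
        self.index = {v: i for i, v in enumerate(self.variants)}
        if logits is None:
            logits = np.zeros(len(self.variants))
        logits = np.array(logits, dtype=float)
        if logits.shape != (len(self.variants),):
            raise ValueError("logits must be one value per variant")
        self.logits = logits
        self.name = name

    @classmethod
    def uniform_over(cls, l: FitnessLandscape | ScaledLandscape) -> "JointPolicy":
        base = l.base if isinstance(l, ScaledLandscape) else l
        return cls(base.positions, base.alphabet, base.variants(), name="uniform-joint")

    @classmethod
    def from_log_probs(
        cls,
        positions: Sequence[int],
        alphabet: str,
        log_probs: Mapping[Variant, float],
        name: str = "joint",
    ) -> "JointPolicy":
        variants = list(log_probs)
        return cls(positions, alphabet, variants, np.array([log_probs[v] for v in variants]), name)

    def log_prob_vector(self) -> np.ndarray:
        return self.logits - logsumexp(self.logits)

    def encode(self, variants: Sequence[Variant]) -> np.ndarray:
        try:
            return np.array([self.index[v] for v in variants], dtype=np.intp)
        except KeyError as e:
            raise ValueError(f"variant {e.args[0]!r} not in joint support") from None

    def loglik(self, enc: np.ndarray) -> np.ndarray:
        return self.log_prob_vector()[enc]

    def pair_gradient(
        self, enc_y: np.ndarray, enc_yp: np.ndarray, coeff: np.ndarray
    ) -> np.ndarray:
        g = np.zeros_like(self.logits)
        np.add.at(g, enc_y, coeff)
        np.add.at(g, enc_yp, -coeff)
        return g

    def copy(self, name: str | None = None) -> "JointPolicy":
        return JointPolicy(
            self.positions, self.alphabet, self.variants, self.logits.copy(), name or self.name
        )

    def propose(self, n: int, rng: np.random.Generator) -> list[Variant]:
        p = np.exp(self.log_prob_vector())
        p = p / p.sum()
        idx = rng.choice(len(self.variants), size=n, p=p)
        return [self.variants[i] for i in idx]

    def space_size(self) -> int:
        return len(self.variants)

    def enumerate_space(self):
        return iter(self.variants)


Policy = FactorizedPolicy | JointPolicy


def pseudo_log_likelihood(p: Policy, v: Variant) -> float:
    """Log-probability of a variant in nats.

    For a factorized policy this is the sum of per-position log-probabilities
    (the simultaneous-unmasking pseudo-likelihood); for a joint policy it is
    a table lookup.
    """
    if len(v) != len(p.positions):
        raise ValueError(f"variant {v!r} has wrong length for {len(p.positions)} positions")
    p._check_symbols(v)
    return float(p.loglik(p.encode([v]))[0])


class VariantDistribution(dict):
    """``variant -> probability`` map with a renormalization flag.

    ``renormalized`` records whether the values were rescaled to sum to one
    over the given landscape; when a factorized policy is restricted to an
    incomplete landscape without renormalization, the values are the raw
    joint probabilities and need not sum to one.
    """

    def __init__(self, probs: Mapping[Variant, float], renormalized: bool) -> None:
        super().__init__(probs)
        self.renormalized = renormalized


def enumerate_distribution(
    p: Policy,
    l: FitnessLandscape | ScaledLandscape,
    renormalize: bool = False,
    cap: int = DEFAULT_SIZE_CAP,
) -> VariantDistribution:
    """Probabilities of every variant in the landscape under the policy.

    Over a complete landscape the values sum to one and no renormalization is
    needed.  Over an incomplete landscape the factorized joint probabilities
    are unnormalized unless ``renormalize`` is set.
    """
    base = l.base if isinstance(l, ScaledLandscape) else l
    if len(base) > cap:
        raise ValueError(f"landscape size {len(base)} exceeds enumeration cap {cap}")
    variants = base.variants()
    ll = p.loglik(p.encode(variants))
    complete = base.is_complete()
    did_renorm = False
    if renormalize or (isinstance(p, JointPolicy) and not complete):
        ll = ll - logsumexp(ll)
        did_renorm = True
    probs = np.exp(ll)
    return VariantDistribution(dict(zip(variants, probs)), renormalized=did_renorm or complete)


def _admissible_count(p: Policy, c: SamplingConstraints, cap: int) -> int | None:
    """Exact number of constraint-admissible variants, or None if too large."""
    if c.allowed is not None:
        return sum(1 for v in c.allowed if c.admits(v, p.positions, p.alphabet))
    size = p.space_size()
    if c.max_hamming is None and not c.fixed:
        relevant = sum(1 for v in c.excluded if len(v) == len(p.positions))
        return size - relevant
    if size > cap:
        return None
    return sum(1 for v in p.enumerate_space() if c.admits(v, p.positions, p.alphabet))


def sample_variants(
    p: Policy,
    n: int,
    c: SamplingConstraints | None = None,
    seed: int | np.random.Generator = 0,
    proposal_budget_factor: int = 1000,
) -> list[Variant]:
    """Draw ``n`` variants from the policy subject to constraints.

    Unless ``allow_repeats`` is set, draws are mutually distinct and disjoint
    from the excluded set; uniqueness is enforced by rejection sampling with
    a proposal budget (default ``1000 * n``) so the same code path works for
    adapters that cannot enumerate their sample space.  Deterministic under
    the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    c = c or SamplingConstraints()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if not c.allow_repeats:
        count = _admissible_count(p, c, DEFAULT_SIZE_CAP)
        if count is not None and count < n:
            raise ValueError(
                f"only {count} admissible variants exist but {n} were requested "
                f"(shortfall of {n - count})"
            )

    out: list[Variant] = []
    taken: set[Variant] = set()
    budget = proposal_budget_factor * n
    spent = 0
    while len(out) < n:
        batch = min(max(n - len(out), 64), budget - spent)
        if batch <= 0:
            raise RuntimeError(
                f"rejection budget of {budget} proposals exhausted with "
                f"{len(out)}/{n} samples drawn; the policy may be too "
                "concentrated on excluded variants — review constraints or "
                "increase policy entropy"
            )
        for v in p.propose(batch, rng):
            if len(out) >= n:
                break
            if not c.admits(v, p.positions, p.alphabet):
                continue
            if not c.allow_repeats and v in taken:
                continue
            out.append(v)
            taken.add(v)
        spent += batch
    return out


def snapshot_reference(p: Policy) -> Policy:
    """Deep, frozen copy whose log-likelihoods never change under training.

    Idempotent: a snapshot of a snapshot is an equal frozen copy.
    """
    snap = p.copy(name=f"{p.name}-ref")
    snap.freeze()
    return snap


# ---------------------------------------------------------------------------
# Serialization


def save_policy(p: Policy, path: str | Path) -> None:
    """Write a policy as JSON (alphabet order, positions, logit arrays)."""
    doc = {
        "kind": "factorized" if isinstance(p, FactorizedPolicy) else "joint",
        "name": p.name,
        "positions": list(p.positions),
        "alphabet": p.alphabet,
        "logits": np.asarray(p.logits).tolist(),
    }
    if isinstance(p, JointPolicy):
        doc["variants"] = p.variants
    Path(path).write_text(json.dumps(doc, indent=1))


def load_policy(path: str | Path) -> Policy:
    """Load a policy written by :func:`save_policy`, validating normalization."""
    doc = json.loads(Path(path).read_text())
    if doc["kind"] == "factorized":
        p: Policy = FactorizedPolicy(
            doc["positions"], doc["alphabet"], np.array(doc["logits"]), doc["name"]
        )
        probs = np.exp(p.log_prob_matrix())
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("loaded factorized policy rows do not normalize")
    else:
        p = JointPolicy(
            doc["positions"], doc["alphabet"], doc["variants"], np.array(doc["logits"]), doc["name"]
        )
        if not math.isclose(float(np.exp(p.log_prob_vector()).sum()), 1.0, abs_tol=1e-9):
            raise ValueError("loaded joint policy does not normalize")
    return p
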