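"""Combinatorial multi-site fitness landscapes.

A landscape maps every variant — an assignment of residues to a small set of
mutated positions in a parent protein — to a non-negative experimental
fitness.  Benchmark landscapes of this kind (e.g. three or four positions
mutated combinatorially over the 20 canonical amino acids) are the substrate
for simulated directed-evolution campaigns: the assay is a table lookup.

Fitness enters the alignment objective through an energy
``U(y) = -log f_y`` where ``f_y`` is fitness rescaled to the unit interval
by the landscape maximum; :func:`scale_landscape` performs that rescaling
with a configurable floor so that dead (zero-activity) variants receive a
finite, large energy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "CANONICAL_AA",
    "FitnessLandscape",
    "ScaledLandscape",
    "SyntheticSpec",
    "load_landscape_table",
    "write_landscape_table",
    "write_mutant_fasta",
    "scale_landscape",
    "single_mutation_neighbors",
    "generate_synthetic_landscape",
]

#: The 20 canonical amino acids, in the conventional alphabetical order.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Hard cap on enumerable landscape size (alphabet_size ** n_positions).
DEFAULT_SIZE_CAP = 10**6

Variant = str  # ordered residue string, one uppercase symbol per mutated position


def hamming(u: Variant, v: Variant) -> int:
    """Number of positions at which two equal-length variants differ."""
    if len(u) != len(v):
        raise ValueError(f"variants have different lengths: {u!r} vs {v!r}")
    return sum(a != b for a, b in zip(u, v))


@dataclass(frozen=True)
class FitnessLandscape:
    """A map from residue combinations at fixed positions to raw fitness.

    Parameters
    ----------
    positions
        1-based residue indices into ``parent``, strictly increasing.
    parent
        Full-length parent amino-acid sequence.
    alphabet
        Ordered residue alphabet; defaults to the 20 canonical amino acids.
    table
        ``variant -> raw fitness`` with raw fitness >= 0.
    name
        Free-form identifier used in logs and file headers.
    """

    positions: tuple[int, ...]
    parent: str
    table: Mapping[Variant, float]
    alphabet: str = CANONICAL_AA
    name: str = "landscape"

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.positions)
        object.__setattr__(self, "positions", pos)
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"positions must be strictly increasing: {pos}")
        if pos and (pos[0] < 1 or pos[-1] > len(self.parent)):
            raise ValueError(
                f"positions {pos} out of range for parent of length {len(self.parent)}"
            )
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet contains duplicate symbols")
        object.__setattr__(self, "table", dict(self.table))
        allowed = set(self.alphabet)
        for combo, fit in self.table.items():
            if len(combo) != len(pos):
                raise ValueError(
                    f"combo {combo!r} has length {len(combo)}, expected {len(pos)}"
                )
            bad = set(combo) - allowed
            if bad:
                raise ValueError(f"combo {combo!r} uses symbols outside alphabet: {sorted(bad)}")
            if not math.isfinite(fit) or fit < 0:
                raise ValueError(f"fitness for {combo!r} must be finite and >= 0, got {fit}")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, v: Variant) -> bool:
        return v in self.table

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.table)

    def variants(self) -> list[Variant]:
        return list(self.table)

    def is_complete(self) -> bool:
        """True when the table covers the full combinatorial space."""
        return len(self.table) == len(self.alphabet) ** self.n_positions

    def mutant_sequence(self, v: Variant) -> str:
        """Full-length parent sequence with ``v`` substituted at the positions."""
        seq = list(self.parent)
        for p, a in zip(self.positions, v):
            seq[p - 1] = a
        return "".join(seq)

    def argmax(self) -> Variant:
        """Variant with the highest raw fitness (ties broken lexicographically)."""
        best = max(self.table.values())
        return min(v for v, f in self.table.items() if f == best)

    def optimum_set(self, rel_tol: float = 0.0) -> frozenset[Variant]:
        """All variants whose raw fitness ties the maximum (within ``rel_tol``)."""
        best = max(self.table.values())
        return frozenset(v for v, f in self.table.items() if f >= best * (1.0 - rel_tol))


@dataclass(frozen=True)
class ScaledLandscape:
    """A landscape with unit-interval fitness and its induced energies.

    ``scaled = max(raw / raw_max, floor)`` so scaled values lie in
    ``[floor, 1]`` and attain exactly 1 at the raw argmax;
    ``energy = -log(scaled)`` in nats, so the global optimum has energy 0.
    """

    base: FitnessLandscape
    scaled: Mapping[Variant, float]
    energy: Mapping[Variant, float]
    floor: float

    @property
    def positions(self) -> tuple[int, ...]:
        return self.base.positions

    @property
    def alphabet(self) -> str:
        return self.base.alphabet

    def __len__(self) -> int:
        return len(self.base)

    def __contains__(self, v: Variant) -> bool:
        return v in self.base

    def variants(self) -> list[Variant]:
        return self.base.variants()

    def argmax(self) -> Variant:
        return self.base.argmax()

    def optimum_set(self, rel_tol: float = 0.0) -> frozenset[Variant]:
        return self.base.optimum_set(rel_tol)


def scale_landscape(l: FitnessLandscape, floor: float = 1e-6) -> ScaledLandscape:
    """Rescale raw fitness by the landscape maximum and attach energies.

    The floor is applied after division so zero-activity variants get the
    finite energy ``-log(floor)`` rather than an infinity.

    Raises
    ------
    ValueError
        If every raw fitness is zero (no scaling reference) or the floor is
        not in (0, 1].
    """
    if not 0 < floor <= 1:
        raise ValueError(f"floor must be in (0, 1], got {floor}")
    raw_max = max(l.table.values(), default=0.0)
    if raw_max <= 0:
        raise ValueError("cannot scale an all-zero landscape: no positive fitness reference")
    scaled = {v: max(f / raw_max, floor) for v, f in l.table.items()}
    energy = {v: -math.log(s) for v, s in scaled.items()}
    return ScaledLandscape(base=l, scaled=scaled, energy=energy, floor=floor)


def single_mutation_neighbors(v: Variant, l: FitnessLandscape | ScaledLandscape) -> set[Variant]:
    """All variants present in ``l`` at Hamming distance exactly 1 from ``v``."""
    base = l.base if isinstance(l, ScaledLandscape) else l
    if v not in base:
        raise KeyError(f"variant {v!r} is not in the landscape")
    out: set[Variant] = set()
    for i in range(len(v)):
        for a in base.alphabet:
            if a == v[i]:
                continue
            u = v[:i] + a + v[i + 1 :]
            if u in base:
                out.add(u)
    return out


# ---------------------------------------------------------------------------
# CSV / FASTA I/O


def load_landscape_table(
    path: str | Path,
    positions: Sequence[int],
    parent: str,
    alphabet: str = CANONICAL_AA,
    name: str | None = None,
) -> FitnessLandscape:
    """Read a ``combo,fitness`` CSV into a :class:`FitnessLandscape`.

    Combo strings list residues in ascending position order and are
    upper-cased on read.  Duplicate combos, symbols outside the alphabet and
    negative fitness are hard errors.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, dtype={"combo": str}, float_precision="round_trip")
    missing = {"combo", "fitness"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    table: dict[Variant, float] = {}
    for combo, fit in zip(df["combo"].str.upper(), df["fitness"].astype(float)):
        if combo in table:
            raise ValueError(f"{path}: duplicate combo {combo!r}")
        table[combo] = fit
    return FitnessLandscape(
        positions=tuple(positions),
        parent=parent,
        table=table,
        alphabet=alphabet,
        name=name or path.stem,
    )


def write_landscape_table(l: FitnessLandscape, path: str | Path) -> None:
    """Write the landscape as a ``combo,fitness`` CSV (same dialect as the reader)."""
    # repr() round-trips float64 exactly, unlike default float formatting
    with open(path, "w") as fh:
        fh.write("combo,fitness\n")
        for v, f in l.table.items():
            fh.write(f"{v},{f!r}\n")


def write_mutant_fasta(l: FitnessLandscape, path: str | Path) -> None:
    """Export every variant as a full-length mutant sequence in FASTA.

    Record ids are the combo strings; sequences are the parent with the
    combo's residues substituted at the mutated positions.
    """
    with open(path, "w") as fh:
        for v in l.table:
            fh.write(f">{v}\n{l.mutant_sequence(v)}\n")


# ---------------------------------------------------------------------------
# Synthetic landscape generation


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a rugged, epistatic synthetic landscape.

    The latent score of a variant is a sum of independent Gaussian additive
    effects (one per position/residue), pairwise couplings (one per position
    pair and residue pair, the tunable-ruggedness term), an optional
    idiosyncratic higher-order term (one draw per variant, a
    house-of-cards-style contribution), and measurement noise.  The score is
    mapped to non-negative fitness by an exponential link
    ``exp(score - max score)`` (default; the scaled maximum is exactly 1), a
    logistic link, or a linear link ``score - min(score)``.  Only the linear
    link preserves additivity of the score in fitness space; the monotone
    exponential and logistic links preserve rank structure (local optima,
    effect signs) but introduce magnitude epistasis.
    """

    n_positions: int = 3
    alphabet_size: int = 8
    additive_scale: float = 1.0
    pairwise_scale: float = 0.5
    higher_order_scale: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    link: str = "exponential"
    size_cap: int = DEFAULT_SIZE_CAP

    def __post_init__(self) -> None:
        if self.n_positions < 2:
            raise ValueError("n_positions must be >= 2")
        if not 2 <= self.alphabet_size <= 20:
            raise ValueError("alphabet_size must be in [2, 20]")
        if self.link not in ("exponential", "logistic", "linear"):
            raise ValueError(f"unknown link {self.link!r}")
        for nm in ("additive_scale", "pairwise_scale", "higher_order_scale", "noise_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")


def _latent_scores(spec: SyntheticSpec) -> np.ndarray:
    """Latent score tensor of shape (A,)*n, deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    n, A = spec.n_positions, spec.alphabet_size
    shape = (A,) * n
    score = np.zeros(shape)
    # Additive per-position effects
    for i in range(n):
        eff = rng.normal(0.0, spec.additive_scale, size=A)
        ax = [1] * n
        ax[i] = A
        score = score + eff.reshape(ax)
    # Pairwise couplings between every position pair
    for i, j in itertools.combinations(range(n), 2):
        coup = rng.normal(0.0, spec.pairwise_scale, size=(A, A))
        ax = [1] * n
        ax[i] = A
        ax[j] = A
        score = score + coup.reshape(ax)
    if spec.higher_order_scale > 0:
        score = score + rng.normal(0.0, spec.higher_order_scale, size=shape)
    if spec.noise_sd > 0:
        score = score + rng.normal(0.0, spec.noise_sd, size=shape)
    return score


def generate_synthetic_landscape(spec: SyntheticSpec) -> FitnessLandscape:
    """Build a complete synthetic landscape from a :class:`SyntheticSpec`.

    The landscape covers all ``alphabet_size ** n_positions`` variants over a
    prefix of the canonical amino-acid alphabet.  With zero coupling, zero
    higher-order term and zero noise the landscape is purely additive.
    """
    size = spec.alphabet_size**spec.n_positions
    if size > spec.size_cap:
        raise ValueError(f"landscape size {size} exceeds cap {spec.size_cap}")
    alphabet = CANONICAL_AA[: spec.alphabet_size]
    score = _latent_scores(spec)
    if spec.link == "exponential":
        fitness = np.exp(score - score.max())
    elif spec.link == "logistic":
        fitness = 1.0 / (1.0 + np.exp(-score))
    else:
        # small positive offset keeps the minimum above the scaling floor,
        # so the affine map preserves additivity exactly after rescaling
        fitness = score - score.min() + 0.01 * np.ptp(score)
    table: dict[Variant, float] = {}
    for idx in itertools.product(range(spec.alphabet_size), repeat=spec.n_positions):
        combo = "".join(alphabet[k] for k in idx)
        table[combo] = float(fitness[idx])
    parent = alphabet[0] * spec.n_positions
    positions = tuple(range(1, spec.n_positions + 1))
    return FitnessLandscape(
        positions=positions,
        parent=parent,
        table=table,
        alphabet=alphabet,
        name=f"synthetic-n{spec.n_positions}-a{spec.alphabet_size}-s{spec.seed}",
    )
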