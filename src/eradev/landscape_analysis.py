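"""Ruggedness, navigability, and epistasis diagnostics for complete landscapes.

Operational definitions follow the standard fitness-landscape literature:

* **Local optima ratio (LOR)** — fraction of variants with no strictly
  fitter single-mutation neighbor (plateaus therefore count as optima).
* **Roughness-slope (R-S) ratio** — root-mean-square residual of the best
  additive (one-hot per position, with intercept) least-squares fit, divided
  by the mean absolute fitted additive effect; zero for perfectly additive
  landscapes, growing with deviation from additivity.
* **Neutrality index** — fraction of single-mutation neighbor pairs whose
  scaled-fitness difference is within a small ``delta``.
* **Global optimum accessibility (GOA)** — fraction of non-optimal variants
  from which the global optimum is reachable by a strictly fitness-increasing
  path of single mutations, computed by reverse traversal from the optimum.
* **Epistasis classes** — every square (two positions, two substitutions, one
  background) is additive, magnitude, sign, or reciprocal-sign epistatic
  depending on whether neither, one, or both single-mutation effect signs
  flip across backgrounds.  A zero marginal effect is treated as
  sign-consistent with either sign, so squares with a zero margin but a
  nonzero interaction classify as magnitude.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass

import numpy as np

from .landscapes import ScaledLandscape, Variant

__all__ = [
    "EpistasisSquare",
    "EpistasisPrevalence",
    "LandscapeReport",
    "classify_square",
    "classify_epistasis_square",
    "epistasis_prevalence",
    "local_optima_ratio",
    "roughness_slope_ratio",
    "neutrality_index",
    "global_optimum_accessibility",
    "analyze_landscape",
]

DEFAULT_GAP_TOL = 1e-9
DEFAULT_NEUTRAL_DELTA = 1e-3


@dataclass(frozen=True)
class EpistasisSquare:
    """A 2x2 sub-landscape: two substitutions on a fixed background.

    ``w00`` is the background fitness, ``w10``/``w01`` carry one substitution
    each, ``w11`` both.  Scaled fitnesses are expected but any reals work.
    """

    background: Variant
    position_pair: tuple[int, int]
    substitutions: tuple[str, str]
    w00: float
    w10: float
    w01: float
    w11: float

    def __post_init__(self) -> None:
        if self.position_pair[0] == self.position_pair[1]:
            raise ValueError("the two positions of a square must differ")


def classify_square(
    w00: float, w10: float, w01: float, w11: float, tol: float = DEFAULT_GAP_TOL
) -> tuple[str, int]:
    """Classify one square; returns (label, sign of the interaction gap).

    The gap is ``w11 - w10 - w01 + w00``.  With effects
    ``d1 = w10 - w00``, ``d1' = w11 - w01`` (first substitution on either
    background) and ``d2 = w01 - w00``, ``d2' = w11 - w10``: no sign flip in
    either effect pair -> magnitude; exactly one flip -> sign; both ->
    reciprocal_sign.  A flip requires strictly opposite signs (``d * d' < 0``).
    """
    gap = w11 - w10 - w01 + w00
    if abs(gap) <= tol:
        return "additive", 0
    flip1 = (w10 - w00) * (w11 - w01) < 0
    flip2 = (w01 - w00) * (w11 - w10) < 0
    sgn = 1 if gap > 0 else -1
    if flip1 and flip2:
        return "reciprocal_sign", sgn
    if flip1 or flip2:
        return "sign", sgn
    return "magnitude", sgn


def classify_epistasis_square(
    s: EpistasisSquare, tol: float = DEFAULT_GAP_TOL
) -> tuple[str, int]:
    return classify_square(s.w00, s.w10, s.w01, s.w11, tol)


def _to_grid(l: ScaledLandscape) -> np.ndarray:
    """Scaled fitness as an ndarray of shape (A,)*n; requires completeness."""
    base = l.base
    if not base.is_complete():
        raise ValueError("analysis requires a complete landscape")
    A = len(base.alphabet)
    n = base.n_positions
    lut = {a: k for k, a in enumerate(base.alphabet)}
    W = np.empty((A,) * n)
    for v, f in l.scaled.items():
        W[tuple(lut[a] for a in v)] = f
    return W


@dataclass(frozen=True)
class EpistasisPrevalence:
    magnitude: float
    sign: float
    reciprocal_sign: float
    n_squares: int
    n_epistatic: int

    @property
    def no_epistasis(self) -> bool:
        return self.n_epistatic == 0


def epistasis_prevalence(
    l: ScaledLandscape, tol: float = DEFAULT_GAP_TOL
) -> EpistasisPrevalence:
    """Class fractions over all epistatic (non-additive) squares.

    Enumerates every square once: each unordered position pair, each
    unordered substitution pair at both positions, each background over the
    remaining positions.  Fractions sum to 1 whenever any epistatic square
    exists; an all-additive landscape yields zeros with ``no_epistasis`` set.
    """
    W = _to_grid(l)
    n = W.ndim
    A = W.shape[0]
    pairs = np.array(list(itertools.combinations(range(A), 2)))  # (P, 2)
    a1, a2 = pairs[:, 0], pairs[:, 1]
    counts = {"magnitude": 0, "sign": 0, "reciprocal_sign": 0}
    n_additive = 0
    for i, j in itertools.combinations(range(n), 2):
        Wij = np.moveaxis(W, (i, j), (0, 1)).reshape(A, A, -1)
        # first axis indexes the substitution pair at position i, second at j
        w00 = Wij[a1[:, None], a1[None, :], :]
        w10 = Wij[a2[:, None], a1[None, :], :]
        w01 = Wij[a1[:, None], a2[None, :], :]
        w11 = Wij[a2[:, None], a2[None, :], :]
        gap = w11 - w10 - w01 + w00
        additive = np.abs(gap) <= tol
        flip1 = (w10 - w00) * (w11 - w01) < 0
        flip2 = (w01 - w00) * (w11 - w10) < 0
        epi = ~additive
        recip = epi & flip1 & flip2
        sign_cls = epi & (flip1 ^ flip2)
        mag = epi & ~flip1 & ~flip2
        counts["magnitude"] += int(mag.sum())
        counts["sign"] += int(sign_cls.sum())
        counts["reciprocal_sign"] += int(recip.sum())
        n_additive += int(additive.sum())
    n_epi = sum(counts.values())
    total = n_epi + n_additive
    if n_epi == 0:
        return EpistasisPrevalence(0.0, 0.0, 0.0, total, 0)
    return EpistasisPrevalence(
        counts["magnitude"] / n_epi,
        counts["sign"] / n_epi,
        counts["reciprocal_sign"] / n_epi,
        total,
        n_epi,
    )


def local_optima_ratio(l: ScaledLandscape) -> float:
    """Fraction of variants with no strictly fitter single-mutation neighbor."""
    W = _to_grid(l)
    is_opt = np.ones(W.shape, dtype=bool)
    for i in range(W.ndim):
        is_opt &= W >= W.max(axis=i, keepdims=True)
    return float(is_opt.sum() / W.size)


def roughness_slope_ratio(l: ScaledLandscape) -> float:
    """RMS residual of the additive least-squares fit over the mean absolute
    additive effect.  Zero for additive landscapes; errors on flat ones."""
    base = l.base
    variants = base.variants()
    y = np.array([l.scaled[v] for v in variants])
    A = len(base.alphabet)
    n = base.n_positions
    lut = {a: k for k, a in enumerate(base.alphabet)}
    # Intercept + drop-first one-hot per position
    X = np.ones((len(variants), 1 + n * (A - 1)))
    for r, v in enumerate(variants):
        row = X[r]
        row[1:] = 0.0
        for i, a in enumerate(v):
            k = lut[a]
            if k > 0:
                row[1 + i * (A - 1) + (k - 1)] = 1.0
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    roughness = float(np.sqrt(np.mean(resid**2)))
    slope = float(np.mean(np.abs(coef[1:])))
    if slope < 1e-12:
        raise ValueError("flat landscape: additive slope is zero, ratio undefined")
    return roughness / slope


def neutrality_index(
    l: ScaledLandscape, delta: float = DEFAULT_NEUTRAL_DELTA
) -> float:
    """Fraction of single-mutation neighbor pairs with |fitness change| <= delta."""
    W = _to_grid(l)
    A = W.shape[0]
    pairs = list(itertools.combinations(range(A), 2))
    neutral = 0
    total = 0
    for i in range(W.ndim):
        Wi = np.moveaxis(W, i, 0).reshape(A, -1)
        for a1, a2 in pairs:
            diff = np.abs(Wi[a1] - Wi[a2])
            neutral += int((diff <= delta).sum())
            total += diff.size
    return neutral / total


def _neighbors_idx(idx: tuple[int, ...], A: int):
    for i in range(len(idx)):
        for k in range(A):
            if k != idx[i]:
                yield idx[:i] + (k,) + idx[i + 1 :]


def global_optimum_accessibility(
    l: ScaledLandscape, optimum: frozenset[Variant] | None = None
) -> float:
    """Fraction of non-optimal variants that can climb to the global optimum.

    Reverse breadth-first traversal from the optimum set over strictly
    fitness-decreasing edges; a variant is accessible iff it is visited.
    A single-variant landscape is vacuously fully accessible.
    """
    W = _to_grid(l)
    A = W.shape[0]
    base = l.base
    lut = {a: k for k, a in enumerate(base.alphabet)}
    if optimum is None:
        optimum = base.optimum_set()
    opt_idx = {tuple(lut[a] for a in v) for v in optimum}
    n_non_opt = W.size - len(opt_idx)
    if n_non_opt == 0:
        return 1.0
    visited: set[tuple[int, ...]] = set(opt_idx)
    queue = deque(opt_idx)
    while queue:
        cur = queue.popleft()
        f_cur = W[cur]
        for nb in _neighbors_idx(cur, A):
            if nb not in visited and W[nb] < f_cur:
                visited.add(nb)
                queue.append(nb)
    accessible = len(visited) - len(opt_idx)
    return accessible / n_non_opt


@dataclass(frozen=True)
class LandscapeReport:
    """The ruggedness/navigability panel for one landscape."""

    name: str
    size: int
    lor: float
    rs_ratio: float
    neutrality: float
    goa: float
    epistasis: EpistasisPrevalence

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "size": self.size,
            "local_optima_ratio": self.lor,
            "roughness_slope_ratio": self.rs_ratio,
            "neutrality_index": self.neutrality,
            "global_optimum_accessibility": self.goa,
            "epistasis_magnitude": self.epistasis.magnitude,
            "epistasis_sign": self.epistasis.sign,
            "epistasis_reciprocal_sign": self.epistasis.reciprocal_sign,
            "n_squares": self.epistasis.n_squares,
            "n_epistatic_squares": self.epistasis.n_epistatic,
        }


def analyze_landscape(
    l: ScaledLandscape,
    tol: float = DEFAULT_GAP_TOL,
    delta: float = DEFAULT_NEUTRAL_DELTA,
) -> LandscapeReport:
    """Compute the full diagnostic panel for a complete landscape."""
    return LandscapeReport(
        name=l.base.name,
        size=len(l),
        lor=local_optima_ratio(l),
        rs_ratio=roughness_slope_ratio(l),
        neutrality=neutrality_index(l, delta),
        goa=global_optimum_accessibility(l),
        epistasis=epistasis_prevalence(l, tol),
    )
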