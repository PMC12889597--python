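"""Distributional diagnostics of a sequence policy over a landscape.

These summarize how concentrated ("mode-seeking") a policy is, how well its
log-likelihoods track experimental activity, how alignment moves probability
mass toward high-activity sequences, and which residues the policy favors at
each position (a policy-weighted position frequency matrix, the tabular form
of a likelihood-weighted multiple sequence alignment).

Entropy and KL are reported in nats, so entropy + KL-to-uniform = ln(M) for
a landscape of M variants — a useful internal consistency identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .landscapes import ScaledLandscape, Variant
from .policy import (
    Policy,
    SamplingConstraints,
    enumerate_distribution,
    sample_variants,
)

__all__ = [
    "DistributionSummary",
    "PositionFrequencyMatrix",
    "distribution_summary",
    "loglik_fitness_correlation",
    "probability_mass_fold_change",
    "weighted_position_frequency_matrix",
    "residue_count_change",
    "write_pfm_tsv",
]


@dataclass(frozen=True)
class DistributionSummary:
    """Mode-seeking diagnostics of an enumerated policy distribution.

    ``redundancy`` is the duplicate fraction in a seeded batch sampled with
    repeats allowed — the policy's natural collision rate.
    """

    entropy: float
    kl_to_uniform: float
    top_k_coverage: float
    redundancy: float
    k: int
    batch: int
    landscape_size: int


def distribution_summary(
    p: Policy,
    l: ScaledLandscape,
    k: int = 5,
    batch: int = 1000,
    seed: int = 0,
) -> DistributionSummary:
    """Entropy, KL to uniform, top-k coverage and sampling redundancy."""
    dist = enumerate_distribution(p, l)
    probs = np.array(list(dist.values()))
    M = len(probs)
    if k > M:
        raise ValueError(f"k={k} exceeds landscape size {M}")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(np.maximum(probs, 1e-300)), 0.0)
    entropy = float(-plogp.sum())
    kl = float(np.log(M) - entropy)
    topk = float(np.sort(probs)[-k:].sum())
    draws = sample_variants(
        p, batch, SamplingConstraints(allow_repeats=True), seed=seed
    )
    redundancy = (batch - len(set(draws))) / batch
    return DistributionSummary(entropy, kl, topk, redundancy, k, batch, M)


def loglik_fitness_correlation(
    p: Policy, l: ScaledLandscape, use_scaled: bool = False
) -> float:
    """Pearson r between log-likelihood and experimental activity.

    Raw activity by default (as plotted against log-probabilities in the
    benchmark analyses); ``use_scaled`` switches to unit-interval fitness.
    """
    variants = l.variants()
    if len(variants) < 2:
        raise ValueError("need at least two variants for a correlation")
    ll = p.loglik(p.encode(variants))
    y = np.array(
        [l.scaled[v] if use_scaled else l.base.table[v] for v in variants]
    )
    if np.ptp(ll) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(ll, y).statistic)


def probability_mass_fold_change(
    before: Policy,
    after: Policy,
    l: ScaledLandscape,
    thresholds: Sequence[float],
    use_scaled: bool = True,
) -> dict[float, float | None]:
    """Per-threshold ratio of high-activity probability mass after vs before.

    For each threshold t the masses sum policy probability over variants with
    fitness strictly above t.  A threshold where the before-policy assigns no
    mass is reported as None (undefined) rather than raising.
    """
    dist_b = enumerate_distribution(before, l)
    dist_a = enumerate_distribution(after, l)
    variants = l.variants()
    fit = np.array([l.scaled[v] if use_scaled else l.base.table[v] for v in variants])
    pb = np.array([dist_b[v] for v in variants])
    pa = np.array([dist_a[v] for v in variants])
    out: dict[float, float | None] = {}
    for t in thresholds:
        mask = fit > t
        mass_b = float(pb[mask].sum())
        mass_a = float(pa[mask].sum())
        out[t] = (mass_a / mass_b) if mass_b > 0 else None
    return out


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Policy-weighted per-position residue frequencies.

    ``matrix`` has shape (alphabet_size, n_positions); each column sums to 1.
    This is the tabular content of a likelihood-weighted MSA/sequence logo.
    """

    alphabet: str
    positions: tuple[int, ...]
    matrix: np.ndarray

    def frequency(self, position: int, residue: str) -> float:
        i = self.positions.index(position)
        return float(self.matrix[self.alphabet.index(residue), i])


def weighted_position_frequency_matrix(
    p: Policy, l: ScaledLandscape
) -> PositionFrequencyMatrix:
    """Per-position residue frequencies weighted by policy probability."""
    dist = enumerate_distribution(p, l, renormalize=True)
    A = len(l.alphabet)
    n = len(l.positions)
    lut = {a: k for k, a in enumerate(l.alphabet)}
    mat = np.zeros((A, n))
    for v, prob in dist.items():
        for i, a in enumerate(v):
            mat[lut[a], i] += prob
    col = mat.sum(axis=0)
    mat = mat / np.where(col > 0, col, 1.0)
    return PositionFrequencyMatrix(l.alphabet, l.positions, mat)


@dataclass(frozen=True)
class ResidueCountChange:
    """Percent change of one residue's count at one position between batches."""

    position: int
    residue: str
    count_before: int
    count_after: int
    percent_change: float
    newly_appeared: bool


def residue_count_change(
    samples_before: Sequence[Variant],
    samples_after: Sequence[Variant],
    positions: Sequence[int],
    alphabet: str,
) -> list[ResidueCountChange]:
    """Per-(position, residue) percent change in generated-residue counts.

    ``100 * (after - before) / max(before, 1)``; residues absent before but
    present after are additionally flagged as newly appeared.
    """
    if not samples_before or not samples_after:
        raise ValueError("both sample lists must be non-empty")
    out: list[ResidueCountChange] = []
    for i, pos in enumerate(positions):
        cb = {a: 0 for a in alphabet}
        ca = {a: 0 for a in alphabet}
        for v in samples_before:
            cb[v[i]] += 1
        for v in samples_after:
            ca[v[i]] += 1
        for a in alphabet:
            if cb[a] == 0 and ca[a] == 0:
                continue
            pct = 100.0 * (ca[a] - cb[a]) / max(cb[a], 1)
            out.append(
                ResidueCountChange(
                    position=pos,
                    residue=a,
                    count_before=cb[a],
                    count_after=ca[a],
                    percent_change=pct,
                    newly_appeared=cb[a] == 0 and ca[a] > 0,
                )
            )
    return out


def write_pfm_tsv(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    """TSV export: rows = residues in alphabet order, columns = positions."""
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(str(p) for p in pfm.positions) + "\n")
        for k, a in enumerate(pfm.alphabet):
            vals = "\t".join(f"{x:.6g}" for x in pfm.matrix[k])
            fh.write(f"{a}\t{vals}\n")
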