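"""Deterministic fixtures with planted, checkable structure.

These tie the modules together for tests and demos: landscapes whose global
optimum and fitness gap are known by construction, and reference policies
whose entropy/mode statistics are dialed by a single bias knob (emulating the
range from a spread-out prior to a strongly mode-seeking one).  Everything is
byte-reproducible under its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .landscapes import (
    CANONICAL_AA,
    FitnessLandscape,
    ScaledLandscape,
    SyntheticSpec,
    Variant,
    generate_synthetic_landscape,
    scale_landscape,
    write_landscape_table,
)
from .policy import FactorizedPolicy

__all__ = [
    "make_planted_optimum_landscape",
    "make_biased_reference_policy",
    "FixtureSuite",
    "default_suite",
]

# Logit magnitude at bias=1: the target residue carries >= 0.998 of each
# per-position distribution even for a 20-letter alphabet.
_POINT_MASS_LOGIT = 16.0


def make_planted_optimum_landscape(
    n_positions: int = 3,
    alphabet_size: int = 4,
    gap: float = 0.2,
    seed: int = 0,
) -> FitnessLandscape:
    """Complete random landscape with one designated, gapped global optimum.

    All non-optimal variants get fitness uniform in ``(0, 1 - gap]`` and a
    randomly chosen variant gets fitness 1, so after scaling the runner-up is
    at most ``1 - gap`` below the unique optimum.
    """
    if not 0 < gap < 1:
        raise ValueError("gap must be in (0, 1)")
    rng = np.random.default_rng(seed)
    import itertools

    alphabet = CANONICAL_AA[:alphabet_size]
    combos = ["".join(t) for t in itertools.product(alphabet, repeat=n_positions)]
    fitness = rng.uniform(0.0, 1.0 - gap, size=len(combos))
    opt_idx = int(rng.integers(len(combos)))
    table = dict(zip(combos, fitness))
    table[combos[opt_idx]] = 1.0
    return FitnessLandscape(
        positions=tuple(range(1, n_positions + 1)),
        parent=alphabet[0] * n_positions,
        table=table,
        alphabet=alphabet,
        name=f"planted-n{n_positions}-a{alphabet_size}-g{gap}-s{seed}",
    )


def make_biased_reference_policy(
    l: FitnessLandscape | ScaledLandscape,
    bias: float,
    seed: int = 0,
) -> FactorizedPolicy:
    """Factorized reference with tunable concentration.

    ``bias=0`` is uniform (entropy ``n * ln A``); ``bias=1`` is a near point
    mass on a randomly chosen variant; intermediate values interpolate the
    per-position logits linearly, sweeping from a spread-out prior to a
    mode-seeking one.
    """
    if not 0 <= bias <= 1:
        raise ValueError("bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alphabet = l.alphabet
    positions = l.positions
    n, A = len(positions), len(alphabet)
    target = rng.integers(A, size=n)
    logits = np.zeros((n, A))
    logits[np.arange(n), target] = bias * _POINT_MASS_LOGIT
    # small seeded jitter so intermediate biases are not exactly symmetric
    logits += bias * rng.normal(0.0, 0.1, size=(n, A))
    return FactorizedPolicy(positions, alphabet, logits, name=f"biased-{bias}-s{seed}")


@dataclass
class FixtureSuite:
    """Named (landscape, reference policy, expected-property manifest) triples.

    The manifest records coarse properties (size, optimum, entropy bounds)
    that the analysis modules must reproduce when run on the fixture; suites
    regenerate byte-identically under the same master seed.
    """

    master_seed: int = 0
    entries: dict[str, tuple[FitnessLandscape, FactorizedPolicy, dict]] = field(
        default_factory=dict
    )

    def add(
        self, name: str, landscape: FitnessLandscape, policy: FactorizedPolicy, manifest: dict
    ) -> None:
        if name in self.entries:
            raise ValueError(f"duplicate fixture name {name!r}")
        self.entries[name] = (landscape, policy, manifest)

    def export(self, out_dir: str | Path) -> None:
        """Write each fixture's landscape CSV and manifest JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, (landscape, _, manifest) in self.entries.items():
            write_landscape_table(landscape, out / f"{name}.csv")
            (out / f"{name}.manifest.json").write_text(json.dumps(manifest, indent=1))


def default_suite(master_seed: int = 0) -> FixtureSuite:
    """The standard small-fixture suite: caps at 4 positions x 8 letters so
    every brute-force oracle (path enumeration, exhaustive squares, full
    enumeration) runs in seconds."""
    suite = FixtureSuite(master_seed=master_seed)

    additive = generate_synthetic_landscape(
        SyntheticSpec(
            n_positions=3,
            alphabet_size=4,
            pairwise_scale=0.0,
            higher_order_scale=0.0,
            noise_sd=0.0,
            seed=master_seed,
            link="linear",  # additive in fitness space, not just latent score
        )
    )
    suite.add(
        "additive",
        additive,
        make_biased_reference_policy(additive, bias=0.0, seed=master_seed),
        {"size": 64, "epistatic_squares": 0, "roughness": 0.0, "goa": 1.0},
    )

    rugged = generate_synthetic_landscape(
        SyntheticSpec(
            n_positions=3,
            alphabet_size=8,
            pairwise_scale=1.0,
            higher_order_scale=0.5,
            seed=master_seed + 1,
        )
    )
    suite.add(
        "rugged",
        rugged,
        make_biased_reference_policy(rugged, bias=0.3, seed=master_seed + 1),
        {"size": 512, "scaled_max": 1.0},
    )

    planted = make_planted_optimum_landscape(
        n_positions=3, alphabet_size=4, gap=0.2, seed=master_seed + 2
    )
    suite.add(
        "planted",
        planted,
        make_biased_reference_policy(planted, bias=0.0, seed=master_seed + 2),
        {"size": 64, "gap": 0.2, "optimum": planted.argmax()},
    )
    return suite
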