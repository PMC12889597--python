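# Methods

## Model and procedure

`eradev` simulates preference-optimization-driven directed evolution on
enumerable combinatorial fitness landscapes. The components:

**Landscape.** A complete (or nearly complete) table mapping residue
combinations at *n* designated positions of a parent sequence to a
non-negative experimental fitness. Fitness is rescaled by the landscape
maximum to (0, 1] and floored at ε (default 1e−6) before taking
*U = −log f*, so dead variants receive the finite energy −log ε ≈ 13.8 nats
instead of an infinity. Benchmark-mode scaling uses the known full-landscape
maximum (the evaluation protocol for complete datasets); for a real campaign
where the global maximum is unknown, the caller can rescale by the maximum
observed so far instead — scaling is a pure function of the table, so this
is a one-line variation.

**Policy.** Two tabular forms. A `FactorizedPolicy` holds one categorical
distribution per mutated position and mirrors the simultaneous-unmasking
scheme of masked language models: all positions are filled independently
given the fixed parent context, and the generation pseudo-likelihood is the
product of per-position probabilities. A `JointPolicy` is an explicit
categorical over the enumerated variant space; it exists because the
alignment optimum is in general *not* factorized on epistatic landscapes.
Either satisfies the minimal contract a real protein-language-model adapter
would implement: pseudo-log-likelihoods, constrained sampling, a frozen
reference snapshot, and a gradient step on its logits. Autoregressive or
permuted unmasking orders and structure/function conditioning are out of
scope.

**Alignment objective.** For a pair (y, y′) with energies U(y), U(y′), the
parametric preference is σ(log π<sub>θ</sub>(y) − log π<sub>θ</sub>(y′)) and
the target is

σ( β/(1+γ)·(U(y′) − U(y)) + c<sub>γ</sub>·(log π<sub>ref</sub>(y) − log π<sub>ref</sub>(y′)) ).

The loss is the mean Bernoulli KL from target to parametric over all pairs.
With c<sub>γ</sub> = γ/(1+γ) (default, `self_consistent` mode) the unique
minimizer is the tilted distribution
π\* ∝ π<sub>ref</sub>^{γ/(1+γ)}·exp(−βU/(1+γ)), and substituting π\* into
the parametric preference reproduces the target exactly — the package's
central invariant, tested to 1e−9. An alternative `as_printed` mode with
c<sub>γ</sub> = γ/β is retained for comparison; it does not share that fixed
point except where the coefficients coincide, and is not the default
precisely because testability demands a self-consistent target.

**Trainer.** Plain full-batch gradient descent on the logits. For both
policy forms the gradient has a closed form: the log-softmax Jacobian
cancels between the two members of each pair, leaving signed one-hot
accumulations weighted by (p<sub>θ</sub> − p<sub>γ</sub>)/m per pair. These
coefficients are bounded by 1, which keeps large steps stable. Optional
minibatching shuffles pairs per epoch under the config seed. Training aborts
on a non-finite loss. The DPO baseline trains the rank-only loss
−log σ(β<sub>dpo</sub>·[policy-vs-reference log-ratio advantage of the
winner]); energy ties carry no ranking signal and are skipped with a
reported count.

**Campaign loop.** Round 0 samples from the untrained reference. Each round
draws N admissible variants (distinct, disjoint from all previous rounds,
and within the landscape's assayable support), assays them by table lookup,
rebuilds the full pairwise dataset over every variant evaluated so far, and
trains for the configured epochs. Likelihoods of previously sampled
variants are recomputed under each newly trained policy and logged. The
reference anchor for the target is snapshotted once before any training and
reused every round; per-round re-anchoring is available behind a config
flag but is not the default, since the target is defined against a fixed
reference and nothing in the protocol requires moving it. After the
training rounds an optional final batch is sampled without further
training. Exhaustion of the admissible pool terminates a replicate early
with a flag rather than an exception.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| β | 1.0 | inverse temperature of the Gibbs-Boltzmann target; larger → greedier target, lower-entropy π\* |
| γ | 0.1 | regularization toward π_ref; γ→∞ recovers the reference, γ=0 the pure Boltzmann distribution |
| epochs | 25 | training budget per round, chosen so the loss has converged at the default learning rate |
| learning rate | 2.0 | full-batch step on tabular logits; sized so the 25-epoch schedule reaches the loss plateau (at 0.1 the loss is still far from converged after 25 epochs, which silently degrades campaigns) |
| round size N | 96 | assays per round; the benchmark protocol is 4×96 + final 96 = 480 |
| fitness floor ε | 1e−6 | finite energy for dead variants; −log ε ≈ 13.8 nats |
| epistasis gap tol | 1e−9 | |gap| below this is additive |
| neutrality δ | 1e−3 | scaled-fitness difference considered neutral |

β and γ are exposed rather than fixed because the appropriate greediness
depends on landscape ruggedness and assay budget; the defaults are a mildly
greedy, lightly regularized setting that performs well across the synthetic
fixtures.

## Synthetic landscapes

The generator draws independent Gaussian additive effects (one per
position/residue, scale 1.0), pairwise couplings (one per position pair and
residue pair — the tunable epistasis knob), an optional idiosyncratic
per-variant term (house-of-cards-style), and measurement noise, then maps
the latent score to non-negative fitness through a link. The exponential
link exp(score − max) is the default: it produces the heavy-tailed,
single-dominant-peak fitness profiles typical of activity assays and makes
the scaled maximum exactly 1. A logistic link gives saturating assays. A
linear link (score − min, plus a 1% offset so the floor never binds) is the
only one that preserves additivity of the score in *fitness* space; the
purely additive fixtures use it, because monotone links preserve effect
signs, local optima and accessibility but introduce magnitude epistasis and
curvature that an additive least-squares fit registers as roughness.

What the generator emulates: ruggedness spanning smooth/additive to heavily
epistatic, a known global optimum, fitness spanning several orders of
magnitude, and (via the fixture policies) reference priors from spread-out
to mode-seeking — the biased reference used in campaign experiments is
calibrated to an entropy ratio H/ln M ≈ 0.7, the spread-prior regime in
which 3-site benchmark campaigns operate. What it does not emulate: real
assay noise structure, measurement censoring, phylogenetic correlation
between positions, insertions/deletions, or anything about actual protein
biophysics. Passing tests therefore demonstrate algorithmic correctness and
qualitative behavior (aligned campaigns beat random screening; likelihoods
become correlated with fitness), not quantitative transfer to any
particular experimental landscape.

## Landscape metrics — operational definitions

The literature admits variant definitions; these are the ones implemented.
Local optima use the non-strict definition (no *strictly* fitter neighbor),
so plateaus count as optima. The roughness-slope ratio is the RMS residual
of the intercept-plus-drop-first-one-hot least-squares fit divided by the
mean absolute non-intercept coefficient; it errors on flat landscapes
(zero slope). Neutrality is the fraction of single-mutation edges with
|Δf| ≤ δ. Global optimum accessibility is computed by reverse breadth-first
traversal from the optimum over strictly decreasing edges and equals forward
per-variant path enumeration (tested exhaustively on small landscapes). In
an epistasis square, a marginal effect of exactly zero is treated as
sign-consistent with either sign, so squares with a zero margin but nonzero
interaction classify as magnitude — this avoids spurious sign-epistasis
calls from ties. Because published landscape panels depend on each tool's
tolerances and path conventions, values computed here are comparable across
landscapes analyzed with this package but not bit-comparable to other
implementations.

## Numerical choices

Probabilities are kept in log space; normalization uses log-sum-exp; the
Bernoulli KL uses `xlogy`/`log_expit` so endpoints p ∈ {0, 1} are exact.
Pair orientation is canonicalized (lower energy first) purely for
readability — the loss is orientation-invariant, which is tested.
Uniqueness during sampling is enforced by rejection with a proposal budget
(default 1000·n) rather than enumeration, so the same code path works for
adapters that cannot enumerate; when the admissible pool is countable the
shortfall is detected exactly before sampling. Replicate and round seeds
derive deterministically from the master seed and are logged; identical
seeds give identical campaigns.

## Known limitations

- The factorized policy cannot represent π\* on epistatic landscapes; the
  trainer then converges to the best factorized approximation (exact
  convergence to π\* is guaranteed, and tested, when the energy is additive
  and the reference factorizes).
- Full enumeration caps at 10⁶ variants; the landscape-analysis grid
  operations are vectorized but hold O(C(A,2)² · A^{n−2}) intermediates per
  position pair, so 4-position × 20-letter panels are near the practical
  memory limit.
- The campaign assumes a noiseless assay (table lookup). Assay noise would
  enter the energies and hence the target preferences; nothing in the loss
  requires noiseless labels, but no noise model is provided.
- Problem sizes in the test and acceptance runs are desk-scale (≤ 4096
  variants, dozens of replicates), chosen so every oracle — path
  enumeration, exhaustive squares, exact optima — is computed exactly
  rather than approximated.
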