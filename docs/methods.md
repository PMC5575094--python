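# Methods

## Model and assumptions

The simulator implements an aspiration-based reinforcement-learning
model of the Dictator Game in a well-mixed population. Agents are
characterised by two coupled quantities on `[0, Φ]`: an aspiration `A`
(the donation they expect to receive as recipients, and equivalently the
amount they insist on keeping as dictators) and a donation `D`. The
population has no spatial or network structure; every agent plays
exactly one game per time step.

Per step: a uniform random perfect matching forms `N/2` pairs, roles are
assigned by independent fair coin flips within each pair, and each
recipient is updated from the payoff `π` (its dictator's current
donation) in a fixed order:

1. stimulus `s = (π − A)/(Φ − A)` (0 if `A = Φ`), clamped to `[−1, 1]`;
2. aspiration update `A′ = A + (Φ − A)·l·s` for `s ≥ 0`,
   `A′ = A + A·l·s` for `s < 0`;
3. donation habituation `D′ = (1 − h)·D + h·π`;
4. aspiration bound `D′ ← max(0, min(D′, Φ − A′))` — against the *new*
   aspiration, which is what couples donations to expectations;
5. optional trembling hand `D′ ← clip(D′·(1 + ε), 0, Φ)`,
   `ε ~ N(0, δ)`;
6. optional envy cap `D′ ← min(D′, Φ/2)` for inequity-averse agents;
7. final clip to `[0, Φ]`.

Dictators never change within a round. Frozen free-riders skip the
whole update (their donation and aspiration are constants) but their
donations do reach other agents as payoffs.

Key modelling choices where the design was genuinely open:

- **Stimulus clamping.** The raw stimulus can fall below −1 whenever
  `A > Φ/2` and `π` is small; left unclamped it would drive aspirations
  negative. We clamp to `[−1, 1]`, which preserves both the nominal
  stimulus range and `A ∈ [0, Φ]`.
- **Order of noise, bound and cap.** The aspiration bound is applied
  before the noise (the bound is a statement about intended behaviour
  and holds exactly only in the noiseless model); the envy cap is an
  absolute ceiling and is applied last.
- **Matching semantics.** A full perfect matching per step (rather than
  a single random pair) so that each agent plays one game per step;
  with single-pair steps each agent would play only ~10 games within a
  10⁴-step transient, far too few for the learning dynamics to settle.
- **Envy as a trait.** Inequity aversion is a persistent label drawn
  once per agent (`Bernoulli(0.05)` by default), not a per-round event.
- **Noise parameter.** The configurable quantity is the standard
  deviation `δ` of the multiplicative perturbation; the predefined
  conditions use `δ ∈ {0, 0.01, 0.1}`.

## Parameters

| name | meaning | default | range |
| --- | --- | --- | --- |
| `endowment` (Φ) | pie size per game (money units) | 1 | > 0 |
| `learning_rate` (l) | stimulus weight in aspiration update | grid | [0, 1] |
| `habituation` (h) | payoff weight in donation update | grid | [0, 1] |
| `noise_scale` (δ) | SD of trembling-hand factor | 0 | ≥ 0 |
| `envy_probability` | P(agent is inequity-averse) | 0 | [0, 1] |
| `n_free_riders` | frozen zero-donors | 0 | ≤ N |
| `n_agents` (N) | population size | 1000 | even, ≥ 2 |

The *general regime* is `l, h ∈ [0.2, 0.8]`; the limiting values
`{0, 1}` switch off one of the two learning channels and behave
qualitatively differently, so the predefined sweeps use the grid
`{0.2, 0.4, 0.6, 0.8}`.

## Initialisation, stationarity and replication

Aspirations are i.i.d. `U[0, Φ]` and donations start at `Φ − A` (the
model's own consistency condition). After a transient (default 10⁴
steps) the run proceeds in 1000-step windows; after each window an OLS
line is fitted to the per-step population-mean donation within the
window and the run stops when `|slope| < 10⁻⁴` (strict). A `max_steps`
guard (default 2·10⁵) returns a flagged partial result instead of
looping forever. Replications use RNG streams spawned as
`SeedSequence(base_seed, spawn_key=(cell, rep))`, making every sweep
bit-reproducible from one root seed.

## Measurement

Distributions are reported on 11 bins: bin `n` covers
`n·Φ/10 ≤ v < (n+1)·Φ/10`, with `v = Φ` assigned to bin 10. Bin edges
are computed by true division (`k/10`) so that literal boundary values
compare exactly. Pooled statistics are computed on the concatenation of
final-state vectors (not time averages) over all grid cells and
replications:

- `mean_donation` — arithmetic mean;
- `concentration_G` — the standard sample Gini coefficient of the
  11 histogram *frequencies*. This is the headline heterogeneity
  statistic: if all agents occupy one bin the frequency vector is one 1
  and ten 0s and `G = 10/11 ≈ 0.91` ("close to 1"), regardless of which
  bin it is — an all-selfish population scores just as high as an
  all-generous one, because both represent a universally followed norm;
- `equality_index = 1 − Gini(values)` and the raw value Gini, as
  complementary value-based measures (these *distinguish* the selfish
  and generous homogeneous states).

The Gini uses the sorted-vector identity for the mean absolute
difference over twice the mean; an all-zero vector (Gini undefined) is
treated as perfectly homogeneous with a logged warning.

## Problem sizes

Full-scale conditions (N = 1000, 100 replications × 16 cells, ≥ 10⁴
steps each) are what the predefined conditions encode; the package's
standard desk scale (`scaled("small")`, used by the test suite and
`scripts/acceptance.py`) is N = 200, 10 replications, transient 5000.
In a well-mixed population the stationary distributions are insensitive
to N at this level, so the reduction costs only sampling precision —
with one exception: conditions with frozen free-riders. A single frozen
agent is an O(1/N) perturbation, and the speed at which it erodes the
donation norm scales with its interaction frequency, so shrinking N
changes the measured pooled mean, not just its noise. Free-rider
conditions therefore keep N = 1000 and the full transient at desk scale
and reduce only the replication count (to 5).

## What the simulations do and do not show

The model generates its own data; there is no empirical input. Pooled
over the general-regime grid, the noiseless model concentrates donations
in the 30–40% bins with strongly correlated aspirations, moderate noise
(δ = 0.1) widens the distribution and produces a zero-donation fraction
at high habituation, and a single obstinate free-rider collapses the
norm except at the lowest habituation. These are statements about the
model's stationary states under the stated initialisation and stopping
rule — the stationary value in free-rider conditions in particular
reflects where the slope criterion halts a slowly decaying mean, not a
true fixed point. Nothing here validates the learning rule against
human-subject data; the simulator only establishes what the rule
implies.

## Numerical notes

- All agent updates are vectorised over the `N/2` recipients of a step;
  a scalar single-agent path (`recipient_update`) exists and is held
  equal to the vectorised path by test.
- Donations and aspirations are hard-clipped to `[0, Φ]` after noise;
  without noise the update rules keep them in range analytically.
- The stationarity slope is fitted on raw per-step means (no
  smoothing), and the comparison is strict (`<`), so a series drifting
  at exactly the threshold keeps running.
- Degenerate inputs: empty value vectors raise; all-zero donation
  vectors yield `equality_index = 1` with a warning; `n_free_riders`
  may equal N (a fully frozen population never changes).

## Known limitations

- Role assignment is a fresh coin flip each round; there is no
  alternation or balancing, so an agent can be dictator several rounds
  in a row.
- The stationarity criterion watches only the mean donation; a
  distribution could in principle keep reshaping at constant mean.
- No networked or spatial interaction topologies, no strategy-update
  rules other than the reinforcement rule above, and no statistical
  comparison against experimental human data.
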