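# normsim

An agent-based simulator of how a *donation norm* emerges in the
Dictator Game (DG) when agents learn their expectations by
reinforcement.

## The model

`N` agents each carry an **aspiration** `A_i ∈ [0, Φ]` — the share of
the endowment `Φ` they expect to receive as recipient — and a
**donation** `D_i ∈ [0, Φ]` — what they give away when acting as
dictator. Every time step a uniform random perfect matching pairs all
agents; within each pair one agent is the dictator (coin flip) and
donates `D` to the other. Only the recipient updates (a Bush–Mosteller
style rule):

1. **Stimulus** `s = (π − A) / (Φ − A)` (0 if `A = Φ`, clamped to
   `[−1, 1]`), where `π` is the donation received;
2. **Aspiration learning** with rate `l ∈ [0, 1]`:
   `A ← A + (Φ − A)·l·s` if `s ≥ 0`, else `A ← A + A·l·s`;
3. **Habituation** with weight `h ∈ [0, 1]`:
   `D ← (1 − h)·D + h·π`;
4. **Aspiration bound**: `D ← max(0, min(D, Φ − A))` — a dictator never
   keeps less than she aspires to.

Optional ingredients: multiplicative **trembling-hand noise**
`D ← D·(1 + ε)`, `ε ~ N(0, δ)` (clipped to `[0, Φ]`); **inequity-averse
agents** (probability 0.05) whose donations are capped at `Φ/2`; and
frozen **free-riders** that always donate 0 and never learn.

Aspirations start uniform on `[0, Φ]` with `D_i = Φ − A_i`. A run is
stationary once the OLS slope of the population-mean donation over a
1000-step window falls below 10⁻⁴ (after a transient).

Two pooled statistics summarise a parameter sweep:

- **mean donation** `⟨d⟩` of all final-state donations, and
- the **norm-concentration index** `G`: the Gini coefficient of the
  11-bin donation histogram (bin `n` counts `n/10 ≤ D < (n+1)/10`).
  `G → 10/11 ≈ 0.91` when the entire population sits in one bin — a
  universally shared norm, generous or selfish alike — and drops as the
  distribution spreads.

## Worked example

```bash
normsim run --condition deterministic --scale small --seed 1 --out out/det
```

runs the noiseless model on the grid `l, h ∈ {0.2, 0.4, 0.6, 0.8}`
(N = 200, 10 replications per cell, transient 5000 steps) and prints

```
condition        : deterministic
runs             : 160 (N=200)
mean donation    : 0.373
concentration G  : 0.866
equality index   : 0.951 (raw Gini 0.049)
mean aspiration  : 0.373
mean convergence : 6000 steps
```

Read: pooled over all cells and replications the population settles on
donating ≈ 37% of the pie, and aspirations converge to the same value —
expectations align with behaviour; `G = 0.87` says nearly all mass sits
in a single histogram bin, i.e. a strong shared norm of generosity (the
value-based equality index 0.95 agrees); and every run reached the
stationarity criterion on its first post-transient window. `out/det/`
contains `histograms.csv` (per-cell binned distributions of donations
and aspirations with across-replication SDs), `convergence.csv` and
`summary.json`. `normsim list-conditions` shows the other predefined
conditions (trembling-hand noise 0.1 and 0.01, envy, free-rider, each
with/without noise); `normsim plot out/det` renders the histogram grid.

With noise `δ = 0.1` (`--condition stochastic`) the distribution widens
(`⟨d⟩ ≈ 0.24`, `G ≈ 0.67`, including a visible zero-donation fraction at
high habituation), while a single frozen free-rider collapses the norm
to near-universal selfishness (`⟨d⟩ ≈ 0.05`) for all but the lowest
habituation values.

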