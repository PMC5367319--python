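# Methods

## Model and assumptions

- Each island hosts a well-mixed population; within-island polymorphism is
  ignored. The state of a locus is which islands share its fixed allele.
- Incompatibility is symmetric and additive across loci: the genetic distance
  `z` between two islands is the fraction of the `l` incompatibility loci
  fixed for different alleles, and a pair is reproductively isolated exactly
  when `z > z_c` (a distance *equal* to the threshold leaves the bond open).
- Mutation-and-fixation of a novel allele is a Poisson stream of rate `u` per
  locus per island. A novel allele is always incompatible with everything
  else, so fixation moves the locus to the configuration in which that island
  stands alone.
- Successful migration events on the directed bond `alpha -> beta` arrive as
  a Poisson process of rate `m_ab`. At an event, each locus at which the two
  islands differ independently fixes the migrant allele with probability
  `epsilon`; the destination island adopts the source island's allele, which
  determines the configuration transition (e.g. under `A -> B`, a locus in
  (A)(BC) moves to (C)(AB)). One event therefore moves a Binomial(`count`,
  `epsilon`) number of loci per eligible configuration — the within-event
  correlation that distinguishes this model from per-locus gene flow.
- Bond closure is re-evaluated every step and is reversible while all three
  islands still form one species (set `irreversible_bonds=True` to keep a
  bond closed forever). Once the migration graph disconnects, the severed
  bonds are permanently removed (`m = 0` on them): the split populations no
  longer exchange genes even if their distance later drifts below `z_c`.
  `tau2` is the first disconnection time, `tau3` the first time all three
  bonds are closed.

## Parameters

| name      | meaning                                                    | typical |
|-----------|------------------------------------------------------------|---------|
| `l`       | number of incompatibility loci (may be `inf`)              | 20–100  |
| `u`       | per-locus mutation-fixation rate per generation            | 7.5e-5  |
| `epsilon` | expected fraction of differing loci fixed per migration    | 0.01    |
| `m`       | successful-migration rate per directed bond per generation | 0.01    |
| `z_c`     | incompatibility threshold on the distance                  | 0.3     |

`epsilon` above 0.25 triggers a warning: a migrant group that replaces more
than a quarter of the gene pool stretches the rare-migration assumptions.
Times are in generations throughout.

## Diffusion approximation

Between events the five configuration fractions `z1..z5` change by many small
jumps, so the package propagates their first two moments as an
Euler–Maruyama step of length `dt`:

- each mutation flow (9 of them, e.g. `z1 -> z2` at rate `u z1`) contributes
  mean `u z_i dt` and variance `u z_i dt / l`, and the *same* Gaussian
  realization is subtracted from the source and added to the target, so the
  fractions sum to 1 exactly, step by step;
- each open directed bond contributes three flows (e.g. `A -> B` moves
  `z2 -> z4`, `z3 -> z1`, `z5 -> z4`) that share one timing noise per bond
  (the compound-Poisson fluctuation, variance `m dt (eps z_i)(eps z_k)`
  between flows of the same bond) plus independent binomial-thinning noise
  of variance `m z_i eps (1 - eps) dt / l` per flow. With `l = inf` only the
  timing noise survives.

`increment_moments` returns the analytic mean and 5x5 covariance of one
increment; the moments are exact for the jump process in the `dt -> 0` limit
and were validated against the exact simulator (below) at 10^5–10^6
replicates at `dt = 1`.

The two-island model is the scalar special case
`dz = [2u(1-z) - 2 m eps z] dt + sqrt(2u(1-z)/l + 2m[(eps z)^2 +
z eps(1-eps)/l]) dW` with balance point `z* = u/(u + m eps)`.

## Exact jump oracle

`gcspec.jump_oracle` simulates the underlying per-locus process with no time
discretization: exponential waiting times between events (total mutation rate
`3 u l`, plus `m_ab` per open bond), and at a migration event each eligible
locus flips with probability `epsilon`. It is the ground truth for the SDE
coefficients (`moment_probe` measures one-interval increment moments on an
exactly representable state, i.e. every `l * z_i` integral) and follows the
same bond-closure policy, so trajectories and waiting times are directly
comparable. Its cost grows with `u*l` and `m`, which confines it to small
`l`; the SDE engine is the production path.

## Numerical choices

- `dt = 1` generation by default; a warning fires when `u dt` or `m dt`
  exceeds 0.1. The Euler scheme is O(dt) in the mean; the acceptance tests
  verified the O(dt) error is far below sampling noise at the parameters
  used.
- After each step the fractions are clipped to `[0, 1]`; flows that would
  overdraw a configuration within one step are rescaled proportionally to
  the available mass (`sum z_i = 1` is preserved exactly). The two-island
  `z` is clipped to `[0, 1]`.
- First-passage estimators run all replicates in lock-step vectorized
  batches; a replicate that has not crossed by `t_max` is reported as
  censored (NaN), never averaged in silently. Summaries report mean,
  standard error, and censored counts.
- Seeding: a master seed plus `SeedSequence(master, spawn_key=(k,))` per
  work unit gives bit-for-bit reproducibility and independently
  re-runnable replicates.
- The threshold sweep uses horizons long enough that no replicate is
  censored at the default grids; the fixed-product sweep (`m * eps`
  constant) uses a threshold (`z_c = 0.35` in the acceptance suite) chosen
  above the common deterministic balance point so the waiting time is
  fluctuation-driven and the effect of `epsilon` is well separated at
  modest replicate counts.
- The ratio experiment reports `mean(tau3)/mean(tau2)` per rate combination
  and an unweighted ordinary least-squares fit (with intercept, via
  `scipy.stats.linregress`) of the ratio against the population standard
  deviation of the three undirected bond rates.

## Limitations

- The diffusion propagates first and second moments only; rare-event tails
  (very high thresholds, very small `m eps`) are better served by the exact
  oracle, which in turn is limited to modest `l`.
- Fixation is instantaneous: the model has no within-island polymorphism,
  no selection coefficients, and no standing genetic variation.
- Migration rates are constant per bond (no geometry or distance decay);
  closing and severing are threshold rules, not a gradual loss of hybrid
  fitness.
- The Euler step freezes bond status within a step, so closure times are
  resolved to `dt`.
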