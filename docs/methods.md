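# Methods

This note records the modeling assumptions, numerical choices and known
limitations of `rfmnet`, in the spirit of a model-documentation page: what
the simulator computes, what its defaults mean, and what a passing test does
and does not establish.

## Model

### Single chain (RFM / RFMIO)

An ORF of `K` codons is partitioned into `n + 1` pieces: the first piece has
`q − 1 = 9` codons (late initiation steps), pieces 2..n have `q = 10` codons
(one ribosome footprint per site), and the last piece keeps the remainder,
held within `[q/2, 3q/2]` by half-up rounding of the piece count.  Half-up
rounding is the unique convention consistent with both worked partitions we
use as oracles (`K = 146 → n = 14` with a 7-codon last piece; `K = 239 →
n = 23` with a 10-codon last piece); at the boundary it prefers the shorter
last piece plus one extra site.

Site occupancies follow the mean-field exclusion dynamics given in the
README.  The flow `λ_i·x_i·(1 − x_{i+1})` makes the chain a tridiagonal
cooperative system: for constant positive input it has a unique steady state
in the open unit cube that attracts every initial condition, and the unit
cube is forward-invariant.  Both facts are exercised as property tests, not
assumed.

### Rates

* `λ_i = 1/Σ τ_k` over piece `i + 1` (decoding times `τ` in s/codon).
* `λ0 = 1/(p⁻¹ + Σ_{k=1}^{q−1} τ_k)` — the gene's initiation rate `p` in
  series with decoding of the first piece.
* Decoding-time tables are rescaled by a single constant so the **median
  per-gene elongation rate** `K_g/Σ τ` equals 6.4 codons/s.  The alternative
  per-codon reading (median of `1/τ` over the 61 codons) is available as
  `normalize_decoding_times(..., per_codon=True)`; the per-gene reading is
  the default because the calibration target is a property of mRNAs, not of
  the codon alphabet.
* Initiation rates can be estimated from data as ribosome density per mRNA
  copy, rescaled to median 0.8 /s.  No floor or ceiling is applied to
  extreme values.
* Median conventions: for an even number of values the *lower* middle order
  statistic is matched (determinism; no interpolation).

### Pooled network (RFMNP)

Chains are coupled through the free pool `z` via `u_j = G(z) = tanh(z/c)`
(`G(z) = z/c` available).  Copy numbers enter as per-chain weights `w_j`
multiplying both pool-coupling terms; this is exact mean-field collapse of
`w_j` identical copies with identical inputs (tested against explicitly
duplicated chains).  The conserved total
`H = z + Σ_j w_j Σ_i x_i` is a *linear* invariant, so Runge-Kutta and
multistep integrators preserve it to roundoff; conservation tests at 1e-6
relative drift are therefore a sanity check on the implementation, not on
integrator tuning.

The scale `c` is not taken from data: it is calibrated by bisection (in
log c, over `c ∈ [10⁻⁶, 10³]·H0`) so the unforced steady state leaves a
target percentage `z̄` of ribosomes free, to within 0.1 percentage points.
`z̄(c)` is strictly increasing (weaker binding leaves more ribosomes free),
which the tests assert on a grid.  Targets outside the reachable band raise
an error carrying the achievable bracket.

## Steady states

Single chain: at steady state every inter-site flow equals the through-flow
`R`, so the profile back-substitutes in closed form from `e_n = R/λn`, and
the initiation residual `λ0·u·(1 − e_1) − R` is strictly decreasing in `R`.
The solver bisects `R` on `(0, min(λ0·u, λ_1..λ_n))` to ~1e-14 relative — no
Jacobian, no convergence basin, deterministic.  An independent ODE-relaxation
solver (`steady_state_by_integration`, LSODA at rtol 1e-10) is kept as the
dual oracle; the two agree to 1e-8 on random chains up to n = 12.

Network: at a steady pool level `z` every chain is at its own steady profile
for input `G(z)`, and chain in/out flows balance, so the only remaining
equation is ribosome conservation `z + bound(z) = H0` with `bound`
strictly increasing.  Brent's method on `[0, H0]` finds the root; uniqueness
is re-checked by relaxing the ODE network from random splits of `H0`.

## Forcing and entrainment

A gene with nominal level `L` and amplitude `A` is represented by two chains
sharing its elongation rates: a baseline chain of weight `β1 = L(1 − A)` and
a modulated chain of weight `β2 − β1 = 2AL` whose initiation is multiplied by
`m(t) = (1 + sin(2πt/T + φ))/2`, so the initiation-weighted copy count equals
`ℓ(t) = L(1 + A sin(2πt/T + φ))` identically.  Gating initiation (rather than
varying copy weights in time) keeps `H` conserved: removing mRNA copies
outright would strand their bound ribosomes.  Within the modulated chain all
copies share one mean-field state — an approximation for heterogeneous copy
histories that is exact in the slow-modulation limit and is the natural
counterpart of the copy-collapse used everywhere else.

Entrainment: integration starts from the steady state of the network with
every modulation frozen at its mean (1/2) and proceeds period by period; the
period-map residual is `max(|Δx|_∞, |Δz|/H0)` (the pool term is normalized
by `H0` because `z` is O(10³–10⁵) while occupancies are O(1)).  Default
tolerance 1e-6, cap 200 periods, 128 samples on the converged period.
Convergence is geometric in practice (~30–60 periods at desk scale); the
residual history is returned so tests can verify the tail decreases, which
guards against limit cycles longer than `T`.  The integrator is RK45 at
rtol 1e-8 / atol 1e-10: at the calibrated rates (λ ≈ 0.3–7 /s) the network
is non-stiff, explicit RK is several times faster than implicit multistep at
these tolerances, and it preserves the linear invariant `H` exactly; LSODA
remains available through the `method` argument for stiffer rate sets.

Changing the forcing period re-entrains the network at the new period (the
response's fundamental frequency follows `1/T`); the response *waveform* is
not invariant under time rescaling, because chain relaxation times are fixed
by the rates.

## Amplitude statistics

Amplitude = half peak-to-peak on the 128-point converged period; for
sinusoidal responses this agrees with the first Fourier coefficient to grid
error (tested).  All statistics are percentages on the 0–100 scale:
`z̄ = 100·mean(z)/H0`, `z_a = 100·amp(z)/mean(z)`, per-gene
`R_a = 100·amp(R)/mean(R)` and likewise for mean density; gene-wise averages
and *population* variances (divide by m).  By default the oscillating genes
are excluded, so the numbers quantify the pool-mediated effect on the rest
of the transcriptome; `exclude=frozenset()` includes everything.
`normalize_per_unit` divides a statistic by the oscillating gene's level in
percent of the mRNA pool (the per-600-mRNAs normalization when the pool is
60,000).

## Synthetic world

The generator's defaults state a fixed world and are not tuned:

* **Economy**: 200,000 ribosomes and 60,000 mRNAs; desk-scale genomes of m
  genes shrink both by `m/6310`, preserving ribosomes-per-mRNA.
* **ORF lengths**: log-uniform on [25, 4911] codons — only the range and a
  heavy right tail are stated facts; log-uniform reproduces both at any
  gene count.
* **Codons**: uniform over the 61 sense codons (no codon-usage bias).
* **Decoding times**: i.i.d. log-normal, log-sd 0.5, rescaled to median rate
  6.4 codons/s.
* **mRNA levels**: log-normal, log-sd 1.5 (expression spans roughly four
  orders of magnitude), rescaled to the mRNA pool.
* **Initiation rates**: log-normal, log-sd 0.5 (about one order of spread),
  rescaled to median 0.8 /s.
* **Reporter**: 239 sense codons, uniform, initiation 0.8 /s.

What the synthetic world does *not* emulate: codon-usage bias and slow-codon
clustering (jams in endogenous genes), correlations between expression
level, ORF length and initiation efficiency, and the empirical gene-length
histogram beyond its range.  A green test on this world establishes a
property of the model and implementation, not agreement with measured yeast
numbers — the headline whole-genome amplitude values depend on the real
parameterization and are out of desk-scale reach by design.

## Known limitations

* **Relative translation-rate amplitudes track the pool amplitude across
  free-pool fractions.**  In the synthetic world, chains are dilute (mean
  occupancy ~0.03 at the stated economy and length range), so the calibrated
  pool response sits deep in the linear region of `tanh` at every `z̄`
  target; the elasticity `G′z/G ≈ 1` then ties each gene's relative rate
  amplitude to the pool's relative amplitude, and `R̄a` varies across a
  `z̄ ∈ {10..30}%` sweep by the same ~3× factor as `z_a` instead of staying
  nearly constant.  Near-constant `R̄a` requires a sub-population of dense,
  input-insensitive (jammed) chains, which a uniform-codon genome does not
  produce.  The corresponding check is left failing rather than relaxed.
* The variant designers' printed steady-state values for the original GFP
  cannot be reproduced without the published codon decoding-time table and
  the GFP coding sequence; the real-data ingestion path is implemented and
  tested on synthetic stand-ins only.
* The increasing DTM weight profile is a linear ramp with mean 1 (pluggable);
  published scores computed under a different monotone profile will differ.
* No stochasticity (TASEP), ribosome drop-off, or mRNA decay dynamics; a
  single shared phase and amplitude per forcing experiment; no phase-lag
  statistics.
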