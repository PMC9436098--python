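# Methods

## The process being modelled

The rDNA locus of *Saccharomyces cerevisiae* is a tandem array of 35S rRNA
gene repeats whose copy number (normally ~125–250, viable range ~40–350) is
matched to cell volume by a feedback circuit: the upstream activator factor
(UAF) binds rDNA promoters with high affinity, and its *free* nucleoplasmic
pool — large when repeats are scarce relative to cell volume — represses
*SIR2*. Low Sir2 activity permits unequal sister chromatid recombination
(USCR) at the locus, and in this system USCR is directional: one daughter
chromatid gains repeats while the other keeps the parental count. A cell
with too few repeats for its volume therefore amplifies its array, one
division at a time, until the enlarged array titrates the free UAF pool,
*SIR2* is derepressed, and recombination stops. The question the simulators
address is purely population-dynamical: given that per-division rule, how
many generations does a population need to move from the founder copy
number to the cap, and how do bottlenecks, a graded (rather than binary)
Sir2 switch, replicative aging, and copy-number-dependent growth rates
change that number?

## Models

All models share a state space of integer copy numbers `c` in
`[c_start, c_max]` and a division rule parameterized by **Delta**, the mean
copy-number gain of the amplified daughter. A non-integral Delta is
realized as a floor/ceil mixture preserving the mean (Delta = 1.3: 70 %
gain +1, 30 % gain +2). Jumps that would overshoot the cap are clamped to
`c_max`, which makes the cap absorbing for the asymmetric rule.

**Model A1 (exact recursion, binary switch).** Every sub-cap cell divides
into one cell with the parental copy number and one amplified cell; cells
at the cap divide into two unchanged cells. The population doubles every
generation, so the engine tracks relative frequencies and renormalizes each
step (absolute counts after 175 doublings would overflow anything; no
reported statistic needs them). While the distribution is far from the cap
the mean rises by exactly Delta/2 per generation. A run stops at the first
generation where the cap frequency reaches `saturation_frac` (default
0.98). Defaults (125 → 220, Delta 1.3) give 176 generations.

**Model A2 (linear Sir2 ramp).** As A1, except a copy-number-dependent
fraction `p_noamp(c)` of divisions amplifies nothing (both offspring keep
`c`): 0 at `c_start`, 1 % one copy above it, rising linearly to 100 % at
the cap. This slows amplification progressively. A caveat discovered during
implementation: with *integral* Delta the reachable states form a lattice
`c_start + k·Delta`, and the saturation time is dominated by the silencing
probability at the last lattice state below the cap — which makes
generations-to-saturation non-monotone in Delta (e.g. Delta 8 saturates
faster than Delta 9 or 10). `fit_delta_a2` therefore always returns the
full candidate table along with the smallest in-window candidate; under the
defaults and the observed 160–180 generation window that candidate is 8.

**Model A3 (bottlenecked counts).** The same division rules with integer
cell counts and binomially sampled amplification outcomes; every
`reseed_interval` (12) generations the grown population (~4.1 × 10⁷ cells)
is resampled multinomially down to `n0` (10000) cells, mimicking daily
re-inoculation. Sampling is with replacement; at a ~4000:1 source-to-sample
ratio the hypergeometric correction is negligible. The bottleneck turns out
to be nearly neutral: over 10 seeded runs the mean saturation generation
differs from Model A1 by well under one generation.

**Model B (asynchronous, growth-rate selection).** Division time is affine
in copy number, `t(c) = t0 + gti·(c − c_start)`, with `t0` = 5820 s (the
97-minute division time measured for the 125-copy strain) and `gti` the
seconds added (+) or removed (−) per extra copy; ±9 s/copy spans ±855 s
(±15 % growth rate) across the 95-copy range. The engine is a discrete
event simulation over *cohorts* — cells sharing (copy number, lineage
division count, next division time) are one queue entry — which keeps the
queue at thousands of entries for populations of tens of millions. Each
offspring schedules its next division its own `t(c')` after birth.
Event times are quantized to 1 µs for exact cohort merging; simultaneous
cohorts are processed in a fixed sorted order so runs are bit-reproducible
from (params, seed).

Two conventions matter and were fixed as follows:

* **Bottleneck trigger and phase.** The population is reseeded to `n0`
  whenever the population-mean division count crosses a multiple of
  `reseed_interval` — the only reading that degenerates exactly to Model A3
  at `gti = 0`. Sampled cells keep their scheduled division times
  (sampling a cell does not reset its cell cycle); an optional
  `reset_clocks_on_reseed` restarts every sampled cell's clock instead,
  which weakens the selection effect by a few percent.
* **What a "generation" is.** The headline `generations` is elapsed
  simulated time divided by `t0` — the number of base division periods,
  which is how a serial-dilution experiment counts generations and is
  identical to the synchronous generation counter when `gti = 0`. The
  population-mean division count is also reported (`mean_divisions`); it
  under-weights the time dimension of selection and gives systematically
  weaker GTI effects. With the time-based metric the published fits
  reproduce closely: 80 → 150 copies at (Delta 2.0, GTI −6 s) gives 83.1
  generations (published fit 82.7); 35 → 80 at (Delta 1.90, GTI −9 s)
  gives 60.0 (published 59.7). At Delta 1.3 the ±9 s slope shifts the
  125 → 220 saturation time by −13.9 % / +13.8 % over 10 runs — close to,
  and slightly above, the ±12–13 % the source experiments report.

**Aging cap.** Optionally a mother retires after `aging_cap` divisions
(the unamplified offspring is taken to be the continuing mother, the
amplified one a newborn daughter); retired cells stay in the population.
A biologically realistic cap (~25) changes predictions by less than run
noise; a cap of 1 stalls amplification and surfaces as an explicit
non-convergence error. `aging_cap=None` is the unlimited baseline.

**Symmetric counterfactual.** Classical USCR would transfer repeats between
sisters: one daughter gains δ, the other loses the same δ, clamped to a
viability floor (default 40 copies) and the cap, with no absorbing state.
The copy-number increment per generation is then ±δ with equal probability,
a driftless random walk: the variance grows as `g·E[δ²]` (Delta 1.3:
1.9 per generation) while the mean stays flat; with a growth-rate penalty
on high-copy cells (`gti > 0`, via the Model B engine) the mean declines.
Neither reaches 98 % at the cap on the observed ~175-generation horizon —
the directional, one-sided rule is essential to the amplification.

## Growth-rate arithmetic

The strain table calculus: `DR = F · GR_app`, `GR_actual = GR_app − DR`,
generation time `ln 2 / GR`. The early *cln3* row (GR 0.45 h⁻¹, F 4.4 %)
gives GR_actual 0.43 h⁻¹ and a 96.7 ≈ 97-minute generation time — the
`t0` used throughout. Printed values are rounded half-up to two decimals;
one published row (0.37 h⁻¹, F 1.4 %) computes to 0.365 → 0.36 but is
printed as 0.37 in the source table; the package reports the arithmetic
result and a test records the discrepancy.

## Numerical choices

* Frequencies conserve total mass to 1e−9 per step (exact up to float
  rounding; verified by property tests).
* Stochastic engines use `numpy.random.default_rng(seed)`; every run is
  exactly reproducible from (params, seed). Replicate runners use seeds
  `base_seed .. base_seed + n − 1` and sample SD (n−1).
* Populations above 10⁸ cells are multinomially thinned back to 10⁸; the
  default 12-generation bottleneck cycle peaks at 4.1 × 10⁷, so thinning
  only engages in degenerate settings (e.g. bottlenecks disabled).
* Saturation is evaluated after completing each generation (synchronous
  models) or after each event batch (Model B).
* `ModelParams` validates all invariants at construction, including that
  the generation time stays positive across the whole state range.

## Problem sizes used in tests and the acceptance script

Stochastic results are averaged over 10 seeded runs (matching the 10-run
summaries the original analyses report). The agent-based oracle that
cross-checks the recursions uses 200 cells × 15 generations × 40
replicates. The symmetric-selection demonstration uses a 2000-cell
inoculum over 60 mean generations; its conclusions are directionally
identical at larger sizes.

## What the simulators do not model

Wet-lab quantities enter only as parameters (t0, GTI span, inoculum size,
copy-number ranges). There is no molecular model of UAF/Sir2 binding, no
cell-volume dynamics, no nutrient or spatial structure, no repeat loss by
intrachromatid recombination or ecDNA extrusion, and no attempt to fit
(Delta, GTI) to new datasets beyond grid scans. Agreement of the
simulators with the published generation counts shows the population
arithmetic is faithful; it does not by itself validate the underlying
molecular circuit.
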