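# Methods

## Model

The limbal stem-cell niche is idealised as a one-dimensional ring of `n`
cells from two selectively neutral populations (blue/white). The real
limbus is a narrow two-dimensional annulus; collapsing it to a ring gives
every cell exactly two neighbours and makes patch counts equivalent to
corneal stripe counts. Generations are discrete. Each generation applies,
to every living cell independently:

1. **Replacement** (probability `p_replace` per cell): the cell's label is
   overwritten by the pre-update label of its left or right neighbour,
   chosen with probability ½ each. The update is synchronous — every cell
   reads the configuration at the start of the generation. A replacement
   may copy a same-coloured neighbour; it is then invisible in the labels
   but is still a replacement event. Cell number is conserved.
2. **Loss** (probability `p_loss` per cell): the cell is removed and not
   replaced; survivors close ranks preserving circular order, and the
   cell's original position is recorded as permanently lost.

With loss disabled this is a synchronous voter model on a cycle: the blue
cell count is a martingale, fixation (loss of mosaicism) is absorbing, and
interfaces between patches perform annihilating random walks. Replacement
sub-steps precede loss within a generation; at the probabilities studied
(≤ 50% replacement, ≤ 20% loss per generation) the ordering effect is
second-order.

Design choices made where the behaviour was genuinely open:

* **Synchronous vs sequential update.** Real divisions are not
  synchronous; the generation-stepped bookkeeping is. We compared the
  synchronous rule against sequential-sweep and "push" (invasion-process)
  variants on small rings via the exact 2⁶-state Markov chain and
  Monte-Carlo: fixation-time medians differ by ~10–20% between schemes and
  no scheme is clearly more faithful, so the simplest reproducible rule
  (synchronous pull) was kept. Synchronous updating is also what produces
  the fine-grained alternating patterns seen at replacement probabilities
  above 50%, including exact checkerboard inversion at 100%.
* **Neighbour choice** is symmetric (½ left, ½ right).
* **Degenerate rings.** On a 2-cell ring both neighbours are the other
  cell; on a 1-cell ring replacement is a no-op; an empty ring is legal and
  all statistics on it are undefined.

## Initial arrays

Random arrays place `round(n·p_blue)` blue cells in a uniformly random
circular arrangement; clumped arrays place `round(n/k·p_blue)` monochrome
blue groups of size `k` (modelling multicellular coherent clones) in
uniformly random group order. Compositions are exact by construction —
equivalent to rejection-sampling independent draws until the target
percentage is hit, but without wasted draws. Fractional targets round to
nearest, ties away from zero.

## Statistics

* **Patch counts.** Circular run-length counting; on a mosaic ring blue
  and white patch counts are equal and their total is even. A monochrome
  ring counts as one patch (uncorrected stripe number 1).
* **Corrected stripe number.** `B/(1−p) + W/p` with `p` the blue
  proportion *observed at that generation*, not the configured target.
  The labelled-population correction `1/(1−p)` is the expected number of
  adjacent labelled coherent clones per labelled patch; the symmetric
  two-population total is the unique natural form whose G0 mean equals the
  cell count on random arrays at every `p` (calibration: within 2% of `n`
  for `n=120`, and of the clone count `n/k` for clumped arrays, over 1,000
  draws). Undefined when `p` ∈ {0,1}.
* **Exclusion rules.** A fixed (single-population) replicate reports
  % blue 0 or 100 and uncorrected stripe number 1 but no corrected stripe
  number; an emptied replicate reports nothing. Undefined values are
  excluded from ensemble means, never imputed.
* **Half-life.** First generation `t ≥ 1` with value ≤ half the G0 value;
  undefined entries cannot trigger the threshold. Computed for the
  ensemble-mean series (`t½`) and per replicate against each replicate's
  own baseline (`t½(i)`). The same definition applies to corrected and
  uncorrected stripe numbers and to cell number, and to external
  longitudinal CSV tables.
* **Ensembles.** Default 20 replicates per condition, each from an
  independent child stream (`SeedSequence(seed, spawn_key=(i,))`) of one
  master seed; separate conditions use separate master seeds. Error bars
  are two-sided 95% Student-t intervals over the replicates contributing a
  defined value at each generation.
* **Survival of mosaicism.** Event time = first generation with one
  population gone; censored at the horizon. Median survival is the
  empirical half-count median (the `⌈n/2⌉`-th event time, or `> horizon`
  when more than half are censored); a Kaplan-Meier median is available
  behind a switch and coincides except on exact-0.5 ties, which it resolves
  to the next event time. Log-rank comparisons (two-sample, multivariate,
  and trend via the Cox score test on an ordinal group score) are
  delegated to lifelines and smoke-tested only.

## Synthetic data and what the tests show

All inputs are generated by the simulator itself; there is no external
data beyond an optional longitudinal stripe-count CSV for the half-life
estimator. The generator's defaults are the study conditions: 20
replicates, balanced (50% blue) or unbalanced (80%) arrays, 120 random
cells (matching the ~124 coherent clones inferred for the young mouse
limbus) or clumped arrays of 240–480 cells in groups of 2–4, 5–10% loss or
10–50% replacement per generation, horizons of 50–1000 generations. What
the model deliberately omits — two-dimensional niche geometry, more than
two neighbours, uneven circumferential density, staining-intensity
variation, cell-cycle asynchrony beyond the generation clock — limits what
passing tests say about real limbal biology: they validate the drift
arithmetic, not the tissue.

## Numerical and reproducibility choices

* Random draws are consumed in a fixed order per generation (replacement
  uniforms, neighbour directions, loss uniforms; a disabled sub-step
  consumes none), so traces are bit-reproducible from (config, seed).
* CSV outputs use a fixed dialect (comma, dot decimal, UTF-8, header row);
  undefined statistics are written as empty fields; floats are written at
  full precision and re-read with round-trip parsing, so read(write(x))
  is exact. The lost-cell sentinel in the state matrix is −1.
* Raster export renders one column per generation with lost cells handled
  in three modes (compact/inline/grouped); it is a static PNG, not a
  replica of the original interactive display.

## Problem sizes

Ensemble checks in the test suite use the study's own scales (20 replicates
per condition; 200 where a tighter estimate of a median is wanted; up to
480 cells × 500 generations, and 1000-generation survival horizons), which
keeps the full suite in the low minutes on a single core.

## Known limitations

* The per-figure choice between `t½` and `t½(i)` in the original study is
  not fully recoverable; presets default to the ensemble-mean `t½` and
  also record all `t½(i)`.
* The original summary table's exact 12 parameter names are unavailable;
  the summary CSV's 12 columns (generation, cell counts, % blue, patch
  counts, stripe numbers, correction factor, mosaic flag, cumulative lost
  cells) are this package's equivalents, and the mapping is provisional.
* Fixation-time medians on very small rings depend at the ~10–20% level on
  the (undocumented) update scheme; see the synchronous-update note above.
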