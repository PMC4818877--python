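# Methods

## Model and procedure

The package treats a sequencing lane as a matrix of integer read counts,
one row per distinct barcode sequence, one column per multiplexed sample
(technical replicate). The central assumption is that an individual
PCR/sequencing error — a specific daughter sequence of a specific mother —
recurs at a near-constant rate relative to its mother across all samples of
a lane, while the rate for the *same* error may differ (up to roughly
ten-fold) between lanes. Clean-up is therefore strictly per-lane.

For an ordered candidate pair (mother more prevalent than daughter), with
per-sample counts `m_i` and `c_i`:

- `r = Σc_i / Σm_i` estimates the per-error rate and predicts `r·m_i`
  daughter reads in sample `i`.
- The scatter of `c_i` around `r·m_i` is overdispersed relative to a
  binomial, and is modelled as beta-binomial with trials `n = m_i` and
  shape fixed via `mu = r`, `rho = r/10` (`mu = α/(α+β)`,
  `rho = 1/(1+α+β)`). Fixing the shape rather than estimating it keeps the
  score a pure measure of predictability; `rho = r/10` makes the density
  unimodal with its peak at the expected read number.
- The score `l` is the mean natural-log density over qualifying samples
  (those with `m_i ≥ 200` or `c_i ≥ 200`; below that, chance reversals of
  mother and daughter would corrupt the score). `l` is compared with the
  line `a·log10(Σc_i) + b`: deeper daughters are held to a stricter
  (more negative is easier; the slope is negative) standard because their
  densities are intrinsically flatter.

A pair is a mother-daughter pair iff `d_L ≤ 4`, `r ≤ 0.05`, `l` is defined
and `l > a·log10(Σc_i)+b` with defaults `a = −2`, `b = −1`. The greedy loop
processes barcodes in descending lane-total order (ties broken
lexicographically on the sequence, for determinism and row-order
independence), removing every qualifying daughter of the current mother;
removed barcodes are never reconsidered as mothers, so a granddaughter is
only removed if it qualifies against a retained ancestor. Retained counts
are bit-identical to the input.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_dist` | 4 | maximal Levenshtein distance for a pair |
| `max_ratio` | 0.05 | maximal total-frequency ratio `r` |
| `slope_a`, `offset_b` | −2, −1 | score threshold line vs `log10(Σc_i)` |
| `min_total_reads` | 100 | prefilter on lane-total reads |
| `min_sample_reads` | 200 | per-sample qualification for the score |
| `rho_divisor` | 10 | overdispersion `rho = r / rho_divisor` |

All are exposed in `CleanupParams` and serializable to flat YAML. The
divisor of 10 is the weakest-justified of these; it is exposed precisely
because it is a modelling convention rather than a measured quantity.

## Numerical choices

- Beta-binomial log densities are computed with log-gamma functions.
  Impossible outcomes (`c_i > m_i`, including `m_i = 0` with `c_i > 0`) and
  astronomically small masses are floored at `ln(1e-300) ≈ −690.8`: a
  single such sample still (correctly) destroys a pair's score without
  producing non-finite arithmetic.
- An undefined score (no qualifying sample, or degenerate ratio `r = 0` or
  `r ≥ 1`) can never qualify a pair: acceptance requires positive evidence.
- Pair criteria are evaluated cheapest-first; a pair failing on distance is
  reported without ratio/score. The reported failure reason is the first
  failing criterion in the order distance, ratio, score.
- Subsampled lanes are rescaled to the original grand total with
  round-half-to-even (deterministic, unbiased).
- Rescue from a multi-lane library re-applies the prefilter, so every
  filtering method operates on the same universe of barcodes; library
  membership is exact-sequence, with no fuzzy matching.
- Demultiplexing anchors on the leftmost exact occurrence of the primer
  constant; index matching is exact (index errors are out of scope by
  design and are best addressed by index design, not correction).
  Quality scores are ignored.

## What the simulator emulates

`simulate_experiment` reproduces the training design the method was
calibrated on, at read-count resolution:

- **Mothers:** 20 clones, two-fold geometric series from 10 cells
  (~5·10^5-fold range), as relative read fractions. Sequences are drawn with
  pairwise distance ≥ 5 so that every simulated daughter has an unambiguous
  mother. Per replicate group the clone fractions receive lognormal jitter
  (σ = 0.3 decades) shared by both technical replicates; each replicate's
  mother counts are multinomial at 2.5·10^7 reads/sample over 24 samples.
- **Error daughters:** 10 per mother at distances 1–4 (70/15/10/5%,
  matching the observed ~1.6 ± 1.0 differences for true pairs), each with a
  per-error rate log-uniform on (10^−5, 10^−1.3); counts are beta-binomial
  around `rate · m_i` with `rho = rate/10`. With multiple lanes, each
  error's rate is divided by a per-lane factor log-uniform on [1, 10]
  (downward-only, keeping rates within the configured range while giving
  up-to-ten-fold lane differences).
- **Noise tail:** 180 rare variants per mother (1–30 reads, scattered
  proportionally to the mother's profile), emulating the fact that the
  vast majority of *distinct* observed sequences are one-off errors far
  below any usable threshold. This tail is what makes the randomization
  control meaningful at simulation scale.
- **Replicate-specific artifacts:** early-PCR variants and physical
  contaminants appear in one technical replicate only.

Deliberately *not* emulated: cell-sampling bottlenecks at low dilutions
(the real training data lost 1 of its 20 clones this way; the generator
works at read resolution so the full clone series stays observable),
read-level errors along the amplicon, index hopping, and between-lane
correlations beyond the shared error identities. Passing tests on this
generator therefore demonstrate the algorithm's behaviour under its own
model assumptions plus a realistic abundance design — not performance on
any particular real data set, where additional error processes (e.g.
unpredictable high-frequency artifacts) occur.

Simulation problem sizes used in the test-suite experiments (24 samples,
~3,800 distinct barcodes, ~6.5·10^8 reads per lane; 10 lanes for the
truth-recovery check) were chosen as the smallest design that exhibits all
the qualitative phenomena of interest — heterogeneous clone sizes straddling
the noise, a prefilter-dominated noise tail, and enough samples for the
score to discriminate.

## Known limitations

- Daughters whose realized ratio lands just above `max_ratio = 0.05`
  (their rate sits at the top of the configured range) escape removal; on
  the default design this is the dominant residual error class, typically
  one or two barcodes per lane.
- Single-replicate artifacts score poorly against any mother and are
  retained; the intended remedy is a separate replicate-discordance filter,
  which is out of scope here (the replicate-pair metadata supports adding
  one).
- The method needs multiple samples per lane with shared barcodes at
  sufficient depth; with very few samples the score is often undefined and
  precision degrades, as the subsampling experiment shows.
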