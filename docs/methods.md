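# Methods

## The analysis model

The screen compares one treatment lane (query-gene knockdown) against
one control lane, with no replicates. All inference therefore rests on
two design features: (a) each lane's counts are normalized to the lane's
*average* read count, so only relative abundances matter; and (b) each
sub-library module carries 21 negative-control constructs (targeting
Luciferase, absent from the genome) whose log2 treatment/control ratios
sample the screen's null noise. The per-module sample SD (denominator
n−1) of those control ratios, computed only from controls that pass the
read floor, is the noise estimate; depletion and enrichment calls are
strict threshold crossings at ±1 SD of the construct's own module.

Gene calls are a deterministic vote, not a test: a gene is synthetic
lethal when the depleted fraction of its constructs reaches the vote
threshold (default ≥ 1/2), rescue symmetrically on enrichment. Two
ambiguities in the published rule are exposed as switches rather than
resolved silently: *strict vs. non-strict majority* ("more than half" vs
"at least half" appear in different places; default non-strict, flag
`strict_majority`), and the *vote denominator* (constructs passing the
read floor, the default, vs. all constructs targeting the gene, flag
`denominator="total"`). The reproduction report computes the candidate
count under both majority variants so the matching one can be
documented. Genes with constructs in both modules pool their votes,
each construct judged against its own module's threshold. If both
directions pass the threshold the larger fraction wins; an exact tie is
refused (NEUTRAL with a warning) since the rule does not define it.

Enrichment is the hypergeometric upper tail over the *library* universe
(the genes the screen could have called), not the pathway-annotation
union; set memberships are intersected with that universe before K is
counted. FDR adjustment is Benjamini–Hochberg (the standard reading of
"FDR corrected"; Benjamini–Yekutieli behind `method="by"`). Redundancy
pruning walks the (q, p, name)-sorted list and removes a set when the
fraction of its *candidate* members already covered by kept sets'
candidate members exceeds the overlap threshold (strictly more than
50 % by default; exactly 50 % survives). Jaccard and full-membership
variants of the overlap metric are available (`metric=` on
`prune_overlapping`); the candidate-coverage reading is the default
because it is the one under which partially shared members across
several kept pathways remain coherent.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_reads` | 100 reads | control-lane floor; strict "less than" excludes |
| `zero_guard` | 1 read | pseudo-count when treatment count is 0 (pre-normalization) |
| `vote_threshold` | 0.5 | fraction of construct votes needed for a gene call |
| `noise_sigma` | 0.17 log2 units | generative ratio noise; the 0.16–0.19 band observed in the emulated screen |
| `effect_log2` | −2 | planted abundance shift for SL carriers (+2 for rescue) |
| `efficacy_constructs` | 3 of 5 | constructs of an affected gene that carry the effect |
| `baseline_sigma` | 0.5 (ln units) | log-normal spread of baseline construct abundance |
| `reads_per_lane` | 5·10⁵ | lane depth of the default simulation |
| `overlap_threshold` | 0.5 | pruning bound, strict "more than" removes |

## The simulator: what it emulates and what it does not

`simulate` reproduces the *count-and-ratio structure* the analysis
consumes: a two-module library (default 1,000 genes × 5 constructs,
round-robin module assignment, 21 controls per module — the real
design at 1/10 scale so a full screen runs in seconds), log-normal
baseline abundances, multiplicative (additive-in-log2) planted effects
with partial per-construct efficacy, Gaussian ratio noise, and
fixed-depth multinomial sampling per lane. Multinomial rather than
independent Poisson sampling matches fixed lane depth; the two are
asymptotically equivalent. Rescue is the exact mirror of lethality
(+|effect| on the treatment lane), matching its symmetric definition.

Not modeled: MOI/infection statistics, PCR jackpotting, growth dynamics
across passages, sequencing error (barcode counting is exact-match by
design), or correlated off-target structure among hairpins. Passing
tests therefore demonstrate the pipeline's statistical behavior under
its own assumptions — calibrated thresholds, vote operating
characteristics, enrichment arithmetic — not robustness to those
real-data artifacts.

Planted fractions default to 3 % SL and 1 % rescue, the order of the
candidate rate the vote rule yields on a null screen, so simulated
screens exercise both directions without dominating the library.

At the default 1/10-scale depth each construct averages ~100 reads, so
counting (shot) noise contributes visibly to observed ratio SDs: by the
delta method a construct with m reads per lane adds
(1/ln 2)²·(2/m) to the log2-ratio variance. `expected_control_ratio_sd`
returns both the generative SD and this inflated observed SD, and
calibration tests target the observed value. For the same reason the
absolute 100-read floor is scaled to 10 reads when analyzing simulated
screens at this depth — the floor tracks depth, keeping the excluded
fraction in the same few-percent regime as the full-depth screen.

## Numerical choices

- Hypergeometric tails are evaluated through the survival function of
  `scipy.stats.hypergeom` (log-space internally); agreement with exact
  rational tail sums is better than 10⁻¹² relative across the library-
  scale grid the tests check, and `k = 0` returns exactly 1.
- Threshold crossings and the pruning bound are strict inequalities, so
  boundary values (a ratio exactly at −σ, an overlap of exactly 50 %)
  resolve to the conservative side (NEUTRAL, kept).
- Normalization uses the mean, not the median, following the source
  procedure; per-condition normalization spans both modules (they were
  sequenced in one lane per condition), with a per-module mode as a
  config switch since the alternative reading is defensible.
- Normalization happens before the read-floor exclusion; the order is a
  documented choice (the source is silent) and is configurable only in
  the sense that the floor operates on raw control counts, so the two
  orders differ only through the lane means.
- Ties in enrichment sorting break by (q, p, set name) so output files
  are byte-deterministic; `prune_overlapping` enforces sorted input.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawns, making library generation and
  count sampling independently reproducible.

## Expected operating characteristics

Under an all-null screen with m = 5 constructs/gene and ±1 *known*-SD
thresholds, a construct votes depleted with p₁ = Φ(−1) ≈ 0.1587 and a
gene is falsely called SL with BinomialTail(5, p₁, 3) ≈ 0.0310. With
thresholds *estimated* from 21 controls, σ̂/σ ~ √(χ²₂₀/20), and
integrating the binomial tail over that law raises the expected rate to
≈ 0.038 — the analytic twin of the ~3 % candidate rate such screens
report. The acceptance suite checks simulated null screens against this
integrated value within 3 Monte-Carlo SE over 20 seeds.

The control-SD calibration check uses the 99 % chi-square band
(20 degrees of freedom) around the expected *observed* SD and requires
≥ 95 % of 200 module estimates inside it; a 95 % band would make the
95 %-coverage requirement a coin flip by construction.

## Limitations

- Exact-match barcode counting undercounts in proportion to sequencing
  error; with 18-nt barcodes and ~0.1–1 % per-base error a few percent
  of reads land in the unassigned tally. That loss is nearly uniform
  across constructs and cancels in the ratios.
- With a single screen (no replicates) the ±1 SD rule controls nothing
  like an FDR at the gene level; it is a noise-calibrated effect-size
  cut, and the candidate list should be read as enriched-for-signal, not
  error-controlled.
- The vote treats constructs as exchangeable; it does not weight by
  knockdown efficiency or read depth.
- `reproduce_screen_stats` needs raw per-construct counts; a table
  carrying only precomputed log2 ratios cannot re-derive exclusion
  percentages and is rejected.
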