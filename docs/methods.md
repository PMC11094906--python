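# Methods

## Guide selection

Candidates arrive as one scored record per transcript position (an
external quality predictor is assumed; the simulator stands in with
Uniform(0, 1) scores). Scores are bucketed into quartiles **per
transcript** using linear-interpolation percentiles; ties at a boundary
resolve upward, and transcripts with fewer than four candidates place
every candidate in the top quartile. Selection is a staged greedy:

- **strict** — top-quartile candidates, zero overlap, up to
  `target_per_transcript` (default 10);
- **relaxed_q3** — quartile ≥ 3, still zero overlap, entered only when the
  strict stage yields fewer than `min_guides` (default 5);
- **relaxed_overlap** — quartile ≥ 3 with pairwise interval overlap up to
  `relax_overlap_max_nt` (default 10 nt, reading the tolerated
  "5–10 nt" band as its upper bound).

The first stage that reaches `min_guides` wins; if none does, the most
permissive stage's result is kept and flagged `below_minimum` (transcripts
with a single usable guide are retained rather than dropped). Greedy order
is (score descending, start ascending, sequence lexicographic) — a total
order, so the output is invariant to input permutation. The greedy is
verified against an independent brute-force reimplementation on random
instances.

Two consequences worth knowing: selection per transcript is capped at 10
always, and adding a candidate can change the outcome *through the
quartile boundaries* even when its score is lowest — monotonicity of the
greedy holds only at fixed quartile labels, which is how the property is
tested.

Redundancy removal operates on the emitted spacers: identical spacers from
transcripts of the same gene collapse to the best-scoring record; a spacer
that appears in two different genes is removed outright, since its
knockdown signal would be unattributable. Spacers are stored as the
target-site (protospacer) sequence; a config switch emits the reverse
complement (the physical crRNA spacer) instead at oligo time. Flank
sequences are config-supplied and default to empty strings in the design
config; the simulator and counter default to a Cas13d direct-repeat 5′
anchor and a pol III terminator 3′ tail. Coordinates are 0-based
half-open throughout.

## Off-target search

The filter treats "coverage" as a contiguous (ungapped) guide substring:
a qualifying placement aligns ≥ ceil(0.9·L) consecutive guide bases
(21 of 23) against a reference window with Hamming distance ≤ 2.
Genomic references are scanned on both strands; transcriptome scans are
forward-only because Cas13d binds the sense transcript. Ambiguous bases
(N) always count as mismatches. Placements overlapping the guide's own
gene intervals are excluded; co-located placements (same reference, start
and strand) collapse to the longest, then fewest mismatches.

Two implementations share only the output bookkeeping. The brute-force
oracle enumerates every (guide substring, window, strand) placement via a
windowed comparison and cumulative sums — exhaustive by construction.
The production scanner indexes reference k-mers (k = 7 =
floor(21 / (2 + 1)), the largest pigeonhole-safe seed: any ≥ 21-nt
placement with ≤ 2 mismatches splits into 3 blocks of ≥ 7 nt of which one
is exact) and verifies only seeded diagonals. The suite asserts exact
hit-set equality on hundreds of randomized 50 kb instances with planted
mutated copies. The contract is correctness at ≤ 100 Mb scale, not
genome-scale throughput.

## Counting and QC

Reads are assigned by locating the first exact occurrence of the 5′ flank
and matching the following L bases literally against the library; reads
with a missing flank, a truncated spacer or any spacer mismatch are
discarded and tallied (mismatch rescue would inflate noise, not counts).
Assigned + discarded = total, and a FASTQ produced by the simulator
round-trips to its exact input counts.

Library evenness uses the Gini index
G = (2·Σᵢ i·x₍ᵢ₎)/(n·Σx) − (n+1)/n (x ascending), equal to the mean
absolute pairwise difference over twice the mean; replicate agreement is
pairwise Pearson correlation on log2(count + 1). Normalization is
median-of-ratios against the per-guide geometric mean over guides nonzero
in every sample, with size factors rescaled to geometric mean 1 — the
rescaling leaves normalized columns identical up to a common constant and
makes the operation exactly idempotent, which plain median-of-ratios is
not.

## Hit calling

The test follows the published negative-binomial + robust-rank-aggregation
scheme for pooled screens, reimplemented and calibrated by simulation
rather than benchmarked against any external binary.

- **Variance model.** On normalized baseline replicates, least squares of
  log(max(σ̂² − μ̂, 0.01)) on log μ̂ gives σ²(μ) = μ + exp(a)·μᵇ, never
  below the Poisson floor. Poisson data drive the overdispersion term to
  ~0; quadratic overdispersion (σ² = μ + 0.1 μ²) is recovered with
  b ∈ [1.8, 2.2] at 10⁴ guides.
- **Guide test.** The summed treatment count of each guide (sum of
  normalized replicate values, evaluated at the enclosing integers) is
  tested against NB(mean = n·μ, var = n·σ²(μ)) in both tails; guides with
  zero baseline mean are excluded and flagged. Treatment replicates are
  summed (unpaired design: the baseline is a common plasmid/day-0 pool).
- **Gene score.** Guides are ranked per direction by (p, crRNA_id) — the
  lexicographic tie-break makes results deterministic — and ρ = rank/m.
  The α-RRA score is min over j of BetaCDF(ρ₍ⱼ₎; j, n_g − j + 1) over
  guides with ρ ≤ α (default 0.25); genes with no guide in the top α
  score exactly 1.
- **Inference.** Permutation p-values resample n_g ranks without
  replacement from the observed pool (10,000 rounds per distinct gene
  size, vectorized; p = (1 + #{perm ≤ obs})/(n_perm + 1)), BH adjusts per
  direction, and genes pass at FDR ≤ 0.3 as positive (enriched) or
  negative (depleted); when both directions pass, the smaller permutation
  p wins and the gene is flagged ambiguous. Gene lfc is the median guide
  lfc; guide-level "differentially represented" flags use |lfc| > 0.1 and
  tail p < 0.05. `rerun_after_filter` repeats the whole pipeline on the
  off-target-filtered library and reports genes whose class changed.

**Calibration.** Under a global null the continuous part of the gene
p-value distribution is uniform (fraction p < 0.05 measured 0.044–0.048
at 500 genes) and guide log-fold-changes show no gene-shared structure
(one-way ANOVA F ≈ 0.95). The distribution necessarily carries an atom at
p = 1 of mass (1 − α)^n_g (0.75¹⁰ ≈ 0.056 for ten-guide genes): genes
with no guide in the top α fraction. A Kolmogorov–Smirnov statistic
against the uniform therefore cannot fall below ≈ 0.056 for ten-guide
genes no matter how well calibrated the method is; uniformity should be
judged on the continuous part. Occasionally a null gene beats all
permutations (p = 1/(n_perm + 1), BH FDR ≈ m/(n_perm·k)), which can
produce isolated null hits at FDR ≤ 0.3; raising n_perm shrinks this
floor. Power at the reference simulation (200 genes, 10% positive and 10%
negative at δ = 2, Beta(5, 2) efficacy, 3 replicates, coverage 300, depth
2×10⁵) is recall = precision = 1.0 at FDR ≤ 0.3.

## Downstream statistics

**Half-life.** ln(abundance) is regressed on time with a free intercept
(the intercept absorbs normalization scale; forcing it through 0 at t = 0
would discard the t = 0 replicate's noise structure), k = −slope,
t½ = ln 2/k, with non-positive k flagged non-decaying (t½ = ∞). Noiseless
exponential input inverts exactly (relative error < 1e-9). Precision
under noise depends on how much decay the sampling window captures: with
harvests at 0, 3, 4, 8, 12 h and log-noise sd 0.1, first-order
propagation gives a median relative t½ error of 0.674·sd/(k·√Sxx) ≈ 0.06
for a 6 h half-life but ≈ 0.115 for 11 h — the window only spans one
half-life of the slower allele. The allele comparison reports
t½(risk)/t½(protective); the defaults (6 h vs 11 h) give 0.545.

**Pull-down.** Per protein, a two-sided one-sample t-test of the
replicate log2 ratios against 0 (the test variant on summed-abundance
ratios is interpreted as one-sample on the ratios; a paired test against
the control channel would need the raw channel intensities, which are out
of scope). The pass filter is the conjunction n_peptides ≥ 5 ∧ mean
log2FC > 2 ∧ p < 0.05; zero-variance proteins with nonzero mean get a
machine-floor p and a flag; passers are ranked by mean fold-change
descending.

## Synthetic data: what it emulates and what it does not

The screen generator reproduces the experiment's geometry: baseline
natural-log guide abundance aᵢ ~ N(0, σ_lib²) shared across samples (the
plasmid pool), gene effect classes assigned by exact counts of the
configured fractions with signed effect ±δ (controls forced null), guide
efficacy uᵢ ~ Beta(5, 2) so realized guide effects are uᵢ·δ (the
efficacy model is the package's own choice — screens need heterogeneous
guide potency for realistic power), final expected proportions ∝
exp(aᵢ)·2^(uᵢ·δ). Baseline replicates are independent
Multinomial(depth) draws of the shared pool; each final replicate first
samples the surviving cell population (Multinomial(coverage·n_guides) —
the transduction bottleneck, default 1000 cells/guide) and then the
sequencer (Multinomial(depth)). Not modeled: PCR jackpotting, sequencing
errors, cell-division stochasticity, multiple infection, or Cas13d
collateral activity — so passing recovery tests demonstrates the
statistics, not robustness to those artifacts.

σ_lib defaults to 0.15: no plasmid-pool dispersion is published, and this
value is chosen so the full-scale screen satisfies the reported evenness
bound. Both QC metrics move with sequencing depth because counting noise
is not scale-free: at the screen's real depth (20 M reads over 18,248
guides, ≈ 1100 reads/guide) the generator gives Gini ≈ 0.085 and minimum
replicate correlation ≈ 0.96, matching the reported bounds (< 0.1 and
> 0.9); at a 1:100 desk-scale depth of 2 M reads (≈ 110 reads/guide)
Poisson noise contributes ≈ 1/110 of log-scale variance against a signal
variance of 0.15², pushing the Gini to ≈ 0.100 and the correlation down
to ≈ 0.70. The QC acceptance test therefore runs at the real screen
depth (cheap — a multinomial draw), while desk-scale defaults (200 genes
× 10 guides, depth 2×10⁵) are used where the whole pipeline must run.

Decay defaults follow the measured system: alleles at 11 h (protective)
and 6 h (risk), harvests at 0/3/4/8/12 h, multiplicative log-normal noise
(sd 0.1 default). Pull-down tables draw replicate log2 ratios
N(μ, noise_sd²) with μ = enrich_log2fc for planted binders (default 3.0,
safely above the 2.0 filter) and 0 otherwise, peptide counts uniform
1–30 with planted binders forced ≥ 5.

## Numerical and interface choices

- Pseudocount 1 wherever logs of counts are taken (lfc, correlations).
- Guide lfc = log2((treat_norm_mean + 1)/(base_norm_mean + 1)).
- NB tails are evaluated at floor(x) / ceil(x) − 1 so that both tails
  include an integer observation (p_low + p_high ≥ 1 at the mode).
- Permutation sampling uses rejection of duplicate indices — vectorized
  and exactly reproducible from the seed; each direction uses its own
  derived seed.
- Ranks, greedy selection and table row orders all carry explicit total
  tie-breaks; fixed seeds give byte-identical output tables.
- All tabular I/O is TSV with headers; intervals are BED-style 0-based
  half-open; FASTQ is written with constant quality 'I'.

## Known limitations

- Off-target matching is ungapped; a BLAST-style gapped notion of 90%
  coverage would admit more hits.
- The hit caller assumes an unpaired baseline common to replicates;
  paired designs and MLE effect-size estimation are out of scope.
- The p = 1 atom in α-RRA limits distribution-level uniformity tests (see
  Calibration) and makes gene p-values conservative for genes with few
  guides.
- Exact-match counting undercounts libraries sequenced with high error
  rates; there is no mismatch rescue or UMI handling.
- Half-life estimates for transcripts whose t½ exceeds the sampling
  window carry relative errors of order 10–15% at realistic qPCR noise.
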