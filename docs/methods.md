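# Methods

## The assay being modelled

A pooled protein-fragment complementation screen: each diploid strain
carries a bait and a prey construct fused to complementary fragments of
murine DHFR, plus a chromosomal *double barcode* (two adjacent 38-bp
random barcodes, one inherited from each haploid parent, joined across a
loxP scar). Under a low dose of methotrexate, reconstituted mDHFR gives a
growth advantage proportional to the amount of functional reporter, so
interaction strength maps to relative fitness. The pool is grown in
serial batch culture, diluted 1:8 every ~3 generations, and the double
barcodes are amplicon-sequenced at generations 0, 3, 6, 9 and 12 in each
of three replicate cultures per environment.

## Read processing

Reads are parsed at fixed offsets (configurable `AmpliconLayout`; default
`tag1 | barcode1 | loxP | barcode2 | tag2` with 6-nt sample tags, matching
the synthetic reads the simulator emits — real amplicon designs differ
only in offsets). A read is kept when (i) the mean Phred quality over each
barcode region is strictly greater than 30, and (ii) each region matches
its structural pattern: a one-mismatch-tolerant 4-nt flank, four random
segments of 4–7 nt, and exact internal `AA…AA…TT` spacers. The first
region alternatively matches a fixed flank literal
(`GTACTAACGGCTAATTTGGTGCC[.?]CA`; the published form of this alternative
contains a stray separator character, which we accept as zero or one
arbitrary character). Degenerate positions are treated as "any
nucleotide".

Parsed pairs are assigned to the designed library by unique-best Hamming
distance over the 76-bp concatenation, at most 2 mismatches. Hamming
rather than edit distance because the regions are fixed-length; ties are
deliberately unassigned rather than arbitrarily broken. Every rejection is
tallied per sample by reason (`quality_fail`, `pattern1_fail`,
`pattern2_fail`, `tag_fail`, `no_match`, `ambiguous`, `malformed_read`) so
that matched + rejected = reads processed, exactly.

## Chimera correction

PCR chimeras re-pair barcode halves from different templates. Under
random re-pairing the expected chimeric reads on pair (i, j) in one
sequencing sample are ε·R<sub>i·</sub>R<sub>·j</sub>/R<sub>··</sub>
(half-barcode marginals within that sample). The rate ε is estimated from
*off-target* pairs — both halves designed, the combination not — as
ε̂ = off-target reads / ((1 − inside)·total), where *inside* is the
probability a random re-pairing lands on a designed pair. When the
library is a complete cross of all halves (as in the 50×50 pilot design),
*inside* ≈ 1 and ε is unidentifiable from counts; the code then raises
explicitly and the pipeline takes ε from configuration (default 0.002).
Corrected counts are `round(max(0, raw − expected))`: integers, floored
at zero, never exceeding raw. At uniform marginals the per-pair
expectation (~0.1 read) vanishes under rounding; the correction bites
exactly where it matters — pairs with large marginal products, where
chimeras visibly distort trajectories — and bookkeeping invariants are
therefore stated on the pre-rounding expectation.

## Fitness inference

Model: φ<sub>l</sub>(t) = f<sub>l</sub>·exp(s<sub>l</sub>t − x̄(t)),
R<sub>l,t</sub> ~ Poisson(D<sub>t</sub>φ<sub>l</sub>(t)). Pure Poisson
counting noise is assumed throughout: in this assay the dominant error
source is finite read depth, and the bottlenecks are large enough
(~10⁶ cells) that drift is secondary.

Numerics. For fixed s the optimal initial frequency is closed-form,
f = ΣR / Σ<sub>t</sub>D<sub>t</sub>e<sup>st−x̄</sup>, and the profile
score in s reduces to matching the μ-weighted mean generation to the
read-weighted mean generation — a monotone scalar equation. We solve it
for all lineages simultaneously by 52 vectorized bisection steps on
s ∈ [−2, 2] (machine precision on that interval), rather than running a
per-lineage quasi-Newton optimizer; the optimum is identical and the
whole 2,500-lineage pool fits in well under a second. The mean-fitness
curve is a fixed point, x̄(t) ← ln Σ<sub>l</sub>f<sub>l</sub>e<sup>s<sub>l</sub>t</sup>,
anchored at x̄(0) = 0 and iterated until max|Δx̄| < 10⁻⁴ (cap 100;
typically < 10 iterations). Note the model has a linear gauge freedom —
adding c·t to x̄ and c to every s changes nothing observable — which is
fixed downstream by zeroing on the reporter-negative controls (their mean
fitness is subtracted from every estimate, making the control mean
exactly 0). Standard errors come from the observed Fisher information in
(ln f, s). Trajectories extinct after t = 0 pin s at the lower bound (the
data only bound the decay); all-zero trajectories return NaN and are
never used.

Fit quality is reported as the mean per-time-point log-likelihood of the
fitted model minus the saturated model (0 = perfect). The `used` flag
requires this score ≥ −0.9, a threshold calibrated once on
experiment-scale simulated pools so that fewer than 5% of well-behaved
trajectories are flagged (measured 5th percentile ≈ −0.84; −0.9 flags
~4%). The threshold is a keyword argument everywhere it is consumed.

## Interaction calling

Per genotype pair and environment, the usable fitness estimates
(~25 barcodes × 3 replicates) are tested against the pooled control
estimates with a one-sided (greater) t-test, Bonferroni ×500, α = 0.05.
Welch's unequal-variance form is the default — group sizes and variances
differ — with `equal_var=True` available for exact pooled-variance
replication. Controls are pooled across barcodes and replicates (their
per-culture mean is pinned to zero by the normalization, which if
anything makes the test slightly conservative). Dynamic calls compare a
pair's fitness sample in each perturbation against the permissive (DMSO)
environment, two-sided, Bonferroni ×400. Summary fractions use
"detected" = significant vs control in ≥ 1 environment. The known
adaptive-mutation outlier pair is handled as a user-supplied blacklist,
not hard-coded. The two orthogonal validation scores are implemented as
published: OD-curve AUC (sum of readings before 32 h) differenced against
the control strain and normalized to the vehicle condition, and the
luminescence condition/vehicle ratio (log₂ reported alongside).

## Simulator

Per cycle: deterministic exponential growth — frequency of lineage l is
multiplied by exp(g·(ln2 + s<sub>l</sub>)), i.e. neutral lineages double
once per generation and s is the natural-log per-generation frequency
advantage, the *same* parameterization the estimator infers, so recovery
is well-posed — then a multinomial bottleneck of 1.3×10⁶ cells (a 70 μl
transfer of saturated culture at ~1.9×10⁷ cells/ml) and a multinomial
sequencing draw of fixed depth. A Binomial(depth, ε) number of reads are
chimeric: their halves are drawn independently from the half-barcode
marginal frequencies; landings on designed pairs inflate those counts,
landings outside are kept in an off-target ledger. Per-sample totals
always equal the configured depth. `sampling="expected"` replaces every
draw by its expectation for closed-form tests. Growth noise within a
cycle (birth–death) is not modelled: at these population sizes the
bottleneck multinomial dominates drift.

Defaults mirror the real assay: 10×10 genotypes (index 0 = control half)
× 5×5 barcodes = 2,500 lineages; generations 0/3/6/9/12; 67 reads/barcode
per sample; ε = 0.002; 1:8 dilution coupled to 3 doublings. True genotype
fitnesses span the observed range: the 81 non-control pairs take evenly
spaced values on [0, 0.4]; pairs with one control half carry a single
reporter fragment and get s = 0. What the simulator does **not** emulate:
sequencing substitution errors inside barcodes, PCR amplification bias,
adaptive mutation within lineages, plate/batch covariates, and
non-exponential growth phases — so passing tests demonstrate correctness
of the inference under counting + bottleneck noise, not robustness to
every artefact of real libraries.

## Accuracy and its limit

On the default configuration, true-vs-inferred fitness correlates at
Pearson r = 0.9855 ± 0.0005 across seeds (computed over used
trajectories; `scripts/acceptance.py` recomputes it). This is read-depth
limited, not estimator limited: removing bottleneck drift entirely
(10⁹-cell bottlenecks) raises r only to ~0.989, while tenfold read depth
reaches r = 0.996. Accuracy is best for high-fitness lineages, whose
trajectories never fall into the low-count regime — reflected in their
smaller standard errors.

## Other design choices

- Time is measured in generations; fitness is per generation
  (dimensionless log advantage). The 1:8 dilution ↔ 3 doublings coupling
  is enforced as a default (warning if broken).
- The chimera rate is estimated globally by default (pooled across
  samples); per-sample estimation is available but noisier.
- Problem sizes in the test suite are chosen so the full suite runs in
  ~10 s: small 3×3-genotype pools for structural checks, the full
  2,500-lineage configuration for recovery, calibration (family-wise
  error over 8 neutral experiments, power over 5 planted-effect
  experiments) and concordance checks.

## Known limitations

- The Poisson model ignores overdispersion from bottleneck drift; with
  the default bottleneck this inflates quality scores only slightly
  (absorbed by the −0.9 flag calibration), but much smaller bottlenecks
  would need an explicit overdispersion term.
- Hamming matching does not handle indels inside barcodes (out of scope
  by design: regions are fixed-length).
- With a complete-cross library the chimera rate cannot be estimated
  from the data; it must come from configuration or a spike-in.
- `reproduce_reference_analysis` assumes the published flat
  per-trajectory schema; idiosyncratic control labels must be passed via
  `control_pairs`.
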