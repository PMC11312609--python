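# Methods

This note documents the models behind each `trapseq` stage, the
assumptions they make, the tunable parameters with their defaults, what
the synthetic generator does and does not emulate, and the numerical
choices made where the design was genuinely open. No empirical claim is
made here that the test suite or `scripts/acceptance.py` does not
itself compute.

## Experimental design assumed

Samples carry three factors: **fraction** (total intimal mRNA from a
Trizol-style flush; ribosome-bound mRNA from a TRAP pulldown;
optionally the unbound flow-through), **condition** (low/disturbed flow
vs. the contralateral normal-flow artery), and **genotype** (wild type
vs. an endothelial-specific knockout). `pair_id` may link the two
arteries of one animal; all tests here nonetheless treat samples as
independent (see *Delta statistic* below).

## Differential expression (`diffexpr`)

Counts are modelled as NB(μ, α) with `var = μ + αμ²`, log link, and a
two-group design per contrast.

- **Size factors.** Median-of-ratios: `s_j = median_g count_gj /
  geomean_g`, over genes with a positive geometric mean, rescaled to
  geometric mean 1. This estimator assumes most genes are unchanged;
  with strongly asymmetric differential expression it absorbs part of
  the common shift (a property shared with all median-of-ratios
  pipelines, quantified in the recovery test's balanced design).
- **Dispersion.** Per-gene method of moments on normalized counts with
  within-group pooled variance (ddof = 1): `α̂ = (v − m)/m²`, floored
  at 1e-8; a trend `α(μ) = a₀ + a₁/μ` is fit by least squares to the
  positive raw estimates; the working dispersion is the 50/50
  arithmetic average of the floored per-gene estimate and the trend.
  This replaces empirical-Bayes machinery with something small and
  testable; its type-I error at n = 6 vs 6 is measured, not assumed
  (acceptance band 0.03–0.07).
- **GLM.** IRLS on the 2-parameter design with `log s_j` offsets,
  vectorized across genes; `se(β)` from the inverse Fisher information;
  Wald `z = β/se`, two-sided normal p, BH across tested genes. Genes
  with an all-zero group get a 0.5-count continuity correction
  (flagged) so reported LFCs stay finite; non-converged genes (after
  100 iterations) get p = NA and leave the BH m. No LFC shrinkage is
  applied anywhere: thresholds on reported LFCs (e.g. ±0.5) act on raw
  MLEs.
- **TpM floor.** Where a mean-TpM ≥ 100 floor is used (the top-N delta
  ranking), it is applied before testing and before BH.

## Translational shift and concordance (`translatome`)

- **Delta statistic.** `Δ = β_ribo − β_total` for the same condition
  contrast in the two fractions; `se_Δ = √(se_r² + se_t²)` treats the
  contrasts as independent, which is conservative-to-neutral when
  different animals feed the two library types; `z = Δ/se_Δ`, normal p,
  BH. Ranking is by signed delta with deterministic gene-id tie-breaks.
- **Concordance.** Flow-responsive genes are selected from the WT TRAP
  contrast at a p (default) or padj threshold and split by LFC sign;
  within each sign the reported fraction is the share whose
  knockout-vs-WT TRAP LFC lies beyond ±0.5 in the same direction.
  Genes between the thresholds stay in the denominator and are reported
  as their own category; the Fisher exact test uses only the
  beyond-threshold 2×2 table. Two facts keep the recovered fraction
  below the planted one even when everything works: the knockout
  estimate must clear the 0.5 threshold (≈ 95% for a planted shift of
  1 at n = 5/arm), and p-threshold selection admits null false
  positives whose knockout LFC is near 0. The parameter-recovery test
  therefore selects at padj < 0.05 (the `use_padj` flag) and expects
  ≈ 0.73 for a planted 0.8.
- **ORA.** Upper-tail hypergeometric `P(X ≥ k)` per set, BH across
  sets; verified against exact integer enumeration.

## Splicing (`splicing`)

- **Clustering.** Junctions sharing a donor or acceptor coordinate
  (transitively, per chrom/strand) form a cluster; clusters with fewer
  than 50 split reads summed over all samples are dropped, as are
  junctions sharing no boundary (nothing alternative to quantify).
- **PSI.** `ψ = ((i1+i2)/2) / ((i1+i2)/2 + e)`; the mean of the two
  inclusion junctions is the standard skipped-exon estimator and is
  symmetric in i1/i2. Per-sample ψ is NA below a coverage of 10 (the
  `min_coverage` default; prevents 0/0 and wild low-coverage values).
- **ΔPSI test.** Per sample, inclusion successes `round((i1+i2)/2)` out
  of successes + e trials; beta-binomial likelihood with inclusion
  probability ψ and intra-class correlation ρ shared across groups. ρ
  is estimated once by **Cox–Reid adjusted profiling** of the
  within-group likelihood (the adjustment — subtracting half the
  log-determinant of the observed information in ψ — repays the degrees
  of freedom the group means consume) and then held fixed in both the
  common-ψ and group-ψ fits, so the LRT compares models differing only
  in ψ (1 df, χ² reference). Alternatives were measured and rejected:
  per-model free ρ inflates null type-I error to ~0.10 at n = 6 vs 6,
  and ρ profiled under the null absorbs real group differences and
  attenuates Δψ̂ by ~15%. `ρ = 0` is available as an exact binomial
  limit with closed-form MLEs (used by the oracle test).
  A beta-binomial LRT on a binary inclusion/exclusion choice is the
  two-outcome special case of Dirichlet-multinomial intron-cluster
  models; per-intron effects within larger clusters are out of scope.
- **Z-scores.** Per event across samples, ddof = 1; constant rows are
  zeroed and flagged; NA propagates.

## Motif enrichment (`motifscan`)

- **Flanks.** 200 bp immediately up/downstream of the cassette exon in
  transcript orientation (minus-strand windows reverse-complemented),
  clipped at contig bounds and flagged. Flanks are not clipped at the
  neighbouring exons by default; the exons here are ≥ 500 bp apart in
  the generator, and for real annotations a caller can pre-trim.
- **Counting.** Overlapping 6-mer windows; windows containing N are
  excluded from both counts and positions, so occurrences over all 4096
  6-mers always sum to positions.
- **Background.** Unregulated exons matched on mean junction coverage
  (the detectability axis available before any sequence is read) by
  quantile bins of the foreground levels, sampled without replacement
  at a 3:1 ratio with a fixed seed; candidates outside the foreground's
  level range are ineligible; deficits are logged, not silently padded.
- **Test.** Position-level 2×2 per 6-mer (occurrences vs. other scanned
  positions, foreground vs. background), two-sided Fisher exact p, BH
  across all emitted 6-mers; odds ratios take a 0.5 Haldane correction
  when any cell is zero. Occurrence-level counting is more powerful in
  short windows than per-event presence/absence; a `presence` mode is
  provided for repeat-heavy inputs. Per-RBP scores: minimum member q
  (primary), mean −log10 p (secondary), alphabetical tie-break.

## Synthetic data (`simulate`)

The generator's defaults are the stated world of the emulated study
design: 5 replicates per arm, NB dispersion α = 0.1, log-uniform
baselines over ~8–2048 expected counts, log-normal size factors
(σ = 0.15), contamination mixed at the mean level (10% into total, 1%
into the TRAP fraction) as a convex combination with a contaminant
profile concentrated on marker genes, cassette exons with coverage
T ~ NB(100, 0.1), beta-binomial overdispersion ρ = 0.05, planted
Δψ = 0.4, and an AU-rich 6-mer inserted into 60% of regulated-exon
flanks on uniform i.i.d. DNA (background 6-mer frequency ≈ 4⁻⁶, which
makes enrichment power analytically predictable).

Two modelling points deserve emphasis:

- **ψ is transcript-level.** An included transcript contributes two
  inclusion-junction reads, a skipped one a single exclusion read, so
  inclusion *reads* are drawn at fraction `2ψ/(1+ψ)`; the standard PSI
  estimator then recovers the planted ψ unbiasedly. Drawing reads at
  fraction ψ directly would make a planted ψ = 0.5 read out as 1/3.
- **Recovery worlds plant effects among unchanged genes.** Median-of-
  ratios normalization is only consistent when DE is a minority or
  balanced; the DE-recovery acceptance world plants 250 up + 250 down
  unit LFCs among 2000 genes for this reason, and measures
  direction-corrected recovery.

Not emulated: read-level data (FASTQ), positional/GC bias,
isoform-level expression, genuinely paired within-animal correlation,
library-composition artifacts beyond the size factors, and non-uniform
genomic sequence composition. A green recovery test therefore
establishes correctness of the estimators under the stated model — not
robustness to alignment artifacts or annotation error.

## Determinism and numerics

Every stochastic step draws from `numpy.random.default_rng` seeded from
the config (`[seed, stream]` spawn keys separate the count and splicing
streams); `run_all` writes a manifest of SHA-256 hashes and reruns are
byte-identical. IRLS stops at 1e-8 coordinate change or 100 iterations;
beta-binomial fits use L-BFGS-B with ψ, ρ bounded away from 0/1 (1e-6)
and two ρ starts; the CR profile uses bounded scalar minimization
(xatol 1e-6), which leaves a ~1e-3 asymmetry under group relabeling —
tests account for it. BH is implemented directly (step-up with NA
exclusion); Fisher and hypergeometric p-values come from scipy and are
verified exhaustively against integer enumeration for small tables.

## Known limitations

- Two-group contrasts only; the ribo-vs-total interaction is the delta
  statistic, not a multi-factor GLM.
- The NB Wald test is modestly anticonservative at very small n for
  strongly dispersed genes, as all Wald-type count tests are; the
  calibration test bounds this at the design's n.
- Fisher enrichment treats 6-mer occurrences as independent across
  positions; overlapping occurrences of self-similar motifs (e.g.
  homopolymers) violate this mildly.
- The beta-binomial ΔPSI test assumes a shared ρ across groups.
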