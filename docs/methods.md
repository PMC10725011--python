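# Methods

## The model

A transposon mutant library screen reads out gene fitness through insertion
representation: if disrupting a gene is costly under a condition, mutants
carrying insertions in that gene are depleted from the pool, and sequencing
recovers fewer reads at fewer distinct insertion sites inside it.

tndiva treats each gene as an ecological community. Its "species" are the
unique insertion sites in the gene (a site is the genomic coordinate the 5'
end of a read maps to; strand is not tracked, so coincident sites on
opposite strands collapse). Its "individuals" are the reads at each site.
For the positive count vector `c_1..c_S` of a gene in one replicate, with
proportions `p_i = c_i / Σc`:

- Shannon index `H' = −Σ p_i ln p_i` (nats; natural log is forced by the
  exponential inverse below),
- effective number of sites `'D = exp(H')` — the Hill number of order 1,
  the count of equally abundant sites with the same index. Unlike `H'` it
  satisfies the doubling property, so ratios of `'D` between conditions are
  interpretable,
- effective density `ED = 'D / L`, with `L` the gene length.

Lower ED under a condition means insertions in that gene are
under-represented there, i.e. the gene contributes to fitness in that
condition.

Conventions and edge cases:

- A gene with no insertions has `H' = 0` and `'D := 0` (not `exp(0) = 1`):
  the empty sum would otherwise report one effective site where there are
  none, and never-hit genes must rank as minimal diversity.
- `L` defaults to the full annotated gene length; `length_mode="trimmed"`
  divides by the trimmed core length instead (the region that actually
  hosts the counted sites). The two differ by the constant factor 1/0.6, so
  within-run comparisons are unaffected by the choice.
- Summation is ordinary double precision; vectors longer than 10^4 sites
  use compensated (`fsum`) summation.

## Pre-processing

**Replicate QC.** A replicate is kept only if more than 80% of its reads
mapped to the target genome (strict inequality; exactly 0.8 fails).
Replicates without a recorded mapped fraction pass with a warning. Each
condition must keep at least two replicates, or QC raises an error
(`strict=False` relaxes this for fold-change-only use).

**Coding-sequence trimming.** `floor(0.2 · L)` nucleotides are removed from
each end of every gene before sites are collected; only the central ~60%
counts. This guards against mis-annotated start codons (5') and tolerated
truncations (3'). The floor rule is a deterministic integer choice that
keeps short genes' cores non-empty; trimming is symmetric, so strand never
matters. Site membership uses the closed interval; a site inside two
overlapping genes counts for both.

**Normalization.** Median-of-ratios size factors are estimated on
gene-level summed retained counts (site-level rows are too sparse for the
estimator) and applied to site-level counts. Because a per-sample scalar
cannot change within-gene proportions, `H'`, `'D` and `ED` are provably
invariant to this step — a property asserted by the test suite. The step is
kept on by default so normalized totals are available for reporting;
`pseudo_reference=True` uses per-gene positive entries only, for sparse
data where no gene is covered in every sample.

## The three tests and consensus

With condition means `ED_A` (reference) and `ED_B` (treatment) per gene:

1. **log2 fold change** `log2(ED_A / ED_B)`, flagged when strictly
   `|log2FC| > 1` (more than two-fold). One zero mean gives a signed
   infinity (a hit); two zero means give 0 (no hit).
2. **Regression + Cook's distance.** OLS of `ED_B` on `ED_A` with
   intercept; Cook's distance from the closed leverage form
   `D_g = r_g² h_g / (2·MSE·(1−h_g)²)`, influential iff `D_g > 4/n` with
   `n` the number of genes entering the regression. Genes with an infinite
   fold change are excluded from the fit but kept, flagged, in the output.
   The regression orientation (treatment on reference) is a configuration
   choice; the influence flags are robust to swapping it.
3. **Welch's t-test** on per-replicate ED, two-sided, Satterthwaite degrees
   of freedom, flagged at raw `p ≤ 0.05` and `p ≤ 0.01`. Genes with zero
   variance in both conditions are degenerate: equal means report `t = 0,
   p = 1`, unequal means `p = 0`, both marked in a `degenerate` column.
   Benjamini–Hochberg adjusted p-values are reported alongside but drive no
   flag.

The consensus set is the intersection of the three hit sets; the
Cook's ∩ Welch and log2FC ∩ Cook's intersections are reported as well.
Replicate-subset reruns (`run_subset_analyses`) repeat the whole comparison
on named sample subsets — e.g. with and without an anomalously shallow
replicate — and report pairwise hit-set overlaps and Jaccard distances per
method.

All statistics are computed from explicit closed forms in this package;
scipy's t-test, statsmodels' OLS influence measures, and pydeseq2's
median-of-ratios normalization serve as independent cross-checks in the
test suite only.

## The synthetic-data generator

`simulate_experiment` emulates the screen's data-generating process, not
its biology: genes laid left-to-right on two replicons with intergenic
gaps; insertion sites uniform at `sites_per_kb` (a `ta_sites` switch
restricts sites to a regular grid, for mariner-style TA-only libraries);
per-site mutant abundances lognormal(σ = 1.5), giving the heavy-tailed
count distributions real libraries show; per-replicate reads drawn
multinomially from the abundance vector, so read totals are conserved
exactly. A depleted gene's site abundances are multiplied by the depletion
factor `d` in the treatment condition before sampling — the simplest model
of a gene-level fitness cost. Contaminant reads (default 5%) go to a decoy
replicon and lower the recorded mapped fraction to exactly `1 − f`.
Per-sample depth multipliers create shallow replicates. Each sample has its
own random stream derived from the master seed and the sample id, so
removing one sample never changes another's data.

Default design: 500 genes (lengths uniform 300–2400 bp), 4 vs 4
replicates, 200 000 reads each, 25 genes depleted at `d = 0.25`. Site
density and depth are set so sequencing runs at ≈2.5 reads per unique site
— the sampling-limited regime of real dense Tn5 screens (which sequence a
few reads per unique site), and the regime in which depletion visibly
removes effective sites. In a saturated regime (many reads per site)
uniform depletion leaves within-gene proportions, and hence ED, almost
unchanged; detection genuinely depends on depth, and the simulator makes
that explicit. `expected_effective_sites` gives the Monte-Carlo expectation
of observed `'D` at a given depth for calibrating expectations.

What the generator does **not** emulate: sequence-dependent insertion bias,
PCR jackpot duplicates beyond the lognormal tail, growth dynamics (the
depletion factor subsumes generations of selection), mixed fitness effects
within one gene, or annotation errors. Passing tests therefore show the
statistical machinery behaves correctly under a faithful sampling model,
not that any particular biological dataset will separate as cleanly.

## Test-bed problem sizes and frozen bands

- Null calibration: 20 simulations of 1000 genes, 4 vs 4, no depleted
  genes, 50 000 reads per replicate; mean fraction of genes at `p ≤ 0.05`
  required in 0.05 ± 0.02. (Observed ≈ 0.04: ED is not Gaussian, and with
  n = 4 + 4 the t-test runs slightly conservative.)
- Recovery: the default design at one frozen seed; ≥ 80% of truly depleted
  genes must be flagged by at least one method and their median |log2FC|
  must exceed the null genes' 95th percentile.
- Subset sensitivity: five seeded simulations with one treatment replicate
  at a quarter depth, depletion `d = 0.1`. The strong depletion puts the
  fold-change hit set (~20 genes) comfortably past the two-fold cutoff, the
  regime in which the comparison is meaningful; at `d = 0.25` the set holds
  only a handful of borderline genes and its Jaccard distance is noise. The
  required property is that removing the shallow replicate moves the Welch
  hit set more (mean Jaccard distance) than the fold-change hit set —
  Welch's variance estimate reacts to a noisy replicate much more strongly
  than condition means do.

## Known limitations

- ED depends on sequencing depth through the number of observed sites;
  comparing EDs across samples of very different depth conflates fitness
  with depth. The subset machinery exists precisely to measure that
  sensitivity; no explicit rarefaction or coverage standardization is
  provided.
- Only the order-1 Hill number is implemented; no other diversity orders,
  and no permutation or resampling tests.
- Raw p-values drive the significance flags by design; users wanting FDR
  control should filter on the reported `p_adj` column instead.
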