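# Methods

## The frequency regression

A pool of *h* known haplotypes mixed at frequencies *b* is sequenced; at
each retained bi-allelic SNP *m* the pooled allele frequency is
*Y_m* = (reads supporting the coded-1 allele) / (total reads). Since a read
drawn from the pool carries haplotype *i*'s allele with probability *b_i*,
E[*Y_m*] = Σ_i *b_i*·*h_{i,m}* with *h_{i,m}* ∈ {0,1}, i.e. the linear model
*Y* = Σ *b_i X_i* holds with the regression coefficients equal to the
haplotype frequencies. The estimator is ordinary least squares via
`numpy.linalg.lstsq`:

* **No intercept.** An intercept would absorb coding bias and destroy the
  sum-to-one diagnostic; the model has none.
* **No constraints.** Nonnegativity and Σb = 1 are true of the estimand but
  are *not* imposed. The deviations of the raw solution from them —
  `sum_deviation` = |Σb̂ − 1| and `negative_mass` = Σ|b̂_i| over negative
  coefficients — are the quality-control signal: a well-specified pool
  satisfies both approximately, while copy-number variation, library
  duplication or mapping bias shows up as a violation. `qc_check` flags
  `pass`/`warn`/`fail` with default warn thresholds (0.05, 0.05), loose
  enough not to trip on sampling noise at the ~1–2% error level of a
  well-behaved pool; both thresholds are overridable. The raw b̂ is never
  clipped or renormalised; `FrequencyEstimate.normalized()` is an explicitly
  derived simplex projection for reporting only.
* **Rank deficiency** returns the minimum-norm solution plus a warning
  rather than failing, mirroring the trivial-gene treatment on the RNA-seq
  side. Estimation requires at least as many SNPs as haplotypes.

**Allele coding.** One allele per locus is coded 1 by a fair coin flip —
never the major/minor allele, because "major" would be judged from the
noisy pool itself and systematically selects the allele whose observed
frequency exceeds its truth. The RNG protocol is fixed and documented (one
`integers(0,2)` draw per locus in locus sort order from
`default_rng(seed)`), so a coding is exactly replayable from its seed.

**Why collinearity is benign here.** Complementary haplotypes such as
(0,0,0,1) and (1,1,1,0) are perfectly anti-correlated, but an allele coded 0
contributes nothing to Σ *b_i X_i*, so their coefficients cannot trade off
against each other as correlated regressors normally do; recovery on a
noiseless pool of exactly that pair is exact (asserted in the tests).

**Error metric.** `mean_absolute_error` = (1/h)·Σ|b̂_i − b_i|, the mean over
haplotypes of the absolute frequency error. This is the only error statistic
reported.

## Informative-SNP selection

With per-SNP coded-1 allele counts *c_m* among the *h* haplotypes, the mean
pairwise difference over a SNP set S is

    D̄(S) = Σ_{m∈S} c_m (h − c_m) / ( C(h,2) · |S| ),

which depends on the allele counts only — not on how alleles are arranged
across haplotypes. Its per-column maximum, max_k k(h−k)/C(h,2), equals
h/(2(h−1)) for even *h* and (h+1)/(2h) for odd *h* (allele frequency ½ is
infeasible for odd *h*; the implementation maximises over integer counts).
Both the closed form and a brute-force pair enumeration are implemented and
asserted equal — the closed form is the fast path, the enumeration its
oracle.

A high mean does not prevent a single pair of haplotypes from being almost
identical on S, which is the actual conditioning risk, so the selection
criterion is the **minimum** pairwise difference. The search:

1. `candidate_filter` keeps SNPs with coded-1 frequency in [0.4, 0.6]
   (inclusive) among the haplotypes.
2. Each restart starts from a seeded uniform random *n*-subset; repeatedly
   the worst pair (ties: lexicographically first) is found, one selected
   SNP where that pair *agrees* is removed (uniform choice) and one outside
   candidate where it *differs* is added (uniform choice).
3. The swap is accepted iff no pair's difference falls below the previous
   global minimum; the worst pair's own difference strictly increases by
   construction, so the global minimum is non-decreasing along accepted
   swaps and strictly increases whenever the tie at the minimum has been
   cleared. Requiring a strict global-minimum increase on every accepted
   swap would stall whenever several pairs tie at the minimum, which is the
   typical state for h = 34 (561 pairs).
4. Every proposal, accepted or not, counts toward `max_iterations`
   (default 10,000). A restart stops at `target_min` (default 0.45) or the
   cap; up to 20 restarts guard against local maxima, stopping early once
   one restart converges (further restarts cannot improve a met target).
   Across restarts the largest achieved minimum wins (ties: larger mean,
   then first found).

Pair-difference counts are maintained incrementally as an h×h matrix
(O(h²) per proposal); the returned min/mean are recomputed from scratch on
the final subset. Quality-based pre-filtering (mapping quality, coverage
windows) is left to the caller; only the allele-frequency window is built in.

## The pool simulator

* **Panels** (`synthetic_panel`): per SNP, a target frequency f ~ U[0.4,0.6]
  (defaults) and round(f·h) carriers chosen uniformly; degenerate draws
  (0 or h carriers) are redrawn, so every SNP is polymorphic.
* **Frequencies** (`random_frequencies`): flat Dirichlet(1,…,1) on the
  simplex — maximally uninformative given that only "random frequencies"
  are specified; `user_supplied` mode covers fixed designs.
* **Coverage** (`simulate_coverage`): independent per-SNP draws from a
  normal, rounded and truncated below at 1. Rounding adds ~1/12
  quantization variance, so the underlying normal uses
  sd' = √max(sd² − 1/12, 0) so the **realized integer coverages** achieve
  the requested SD (at mean 2 / SD 0.5 the realized SD is ≈ 0.47;
  SDs below the quantization floor ≈ 0.29 are unattainable with integers).
  sd = 0 yields exactly round(mean) everywhere. Coverage is interpreted as
  the per-SNP mean depth of the pool.
* **Pools** (`simulate_pool`): at each SNP, the coverage is allocated to
  source haplotypes by one multinomial(b) draw; the coded-1 count follows.
  Read length and linkage between neighbouring SNPs on one read are
  deliberately ignored — per-SNP independence is the model's working
  assumption. An optional per-read allele-flip `error_rate` (default 0)
  emulates sequencing error; duplication/CNV artefacts are not modelled,
  which is precisely why the QC diagnostics exist for real data.
* **Protocol** (`run_experiment`): per replicate (default 30) draw b, draw
  coverage, simulate the pool on the selected SNPs, infer, score the mean
  absolute error and QC; report per-replicate values and their mean. All
  streams are spawned from `config.seed` (`SeedSequence.spawn`), so runs
  are exactly reproducible.

What the simulator does **not** emulate: linkage disequilibrium between
SNPs in real panels, mapping/SNP-calling error, library duplication and
structural variation. Passing simulations therefore demonstrate the
estimator's statistical behaviour under its own assumptions, not robustness
to those real-data artefacts (the QC flags are the run-time guard there).

## RNA-seq sub-function

Isoform abundances within one gene reduce to the same regression with exon
membership playing the role of alleles. Processing steps:

* **Segmentation** (`segment_gene_model`): all exon boundaries of all
  isoforms are projected onto the genome; segments are the
  boundary-delimited intervals inside the exon union, and membership is 1
  iff the segment lies entirely inside some exon of the isoform. Abutting
  exons within an isoform are merged on ingestion (a boundary with no
  membership change is meaningless), which makes the construction equal to
  the per-base membership-signature oracle asserted in the tests.
  GFF3/GTF 1-based closed coordinates become 0-based half-open at the I/O
  boundary only.
* **Terminal trimming** (`trim_terminal_segments`): the gene's first and
  last segment (pseudo-exons included) are dropped from the regression
  unless strictly longer than `factor`×`read_length` (default 5×, tunable;
  with 76 bp reads, 380 bp is trimmed and 381 bp kept). Applied once, at
  gene level, not per isoform and not iteratively.
* **Trivial genes**: if the retained membership matrix has rank below the
  isoform count (e.g. two isoforms identical after trimming), frequencies
  are unidentifiable; the gene is excluded and reported.
* **Inference** (`infer_isoform_frequencies`): per-base mean depth per
  retained segment is regressed on membership without constraints; the
  coefficient a_i absorbs the expression level and b̂_i = a_i/Σa_j is the
  relative abundance. Raw a, Σa and negative mass are kept for QC; |Σa| ≤
  1e-9 is an inference failure. Mean per-base depth (not read count) is the
  observation so segment length does not confound membership.
* **Frequency semantics**: b is the **per-base-coverage share** of an
  isoform — the direct analogue of the genomic model, where b_i is the
  share of reads at a SNP. No transcript-length correction to molecule
  counts is applied; users wanting molar fractions must reweight by
  effective transcript length themselves. Consistently, the simulator
  (`simulate_rnaseq`) allocates reads to isoforms with probability
  ∝ b_i·(L_i − read_length + 1), so each isoform's expected interior
  per-base depth is ∝ b_i and the regression estimand equals the simulated
  b. Read starts are uniform on the spliced transcript and coverage is
  projected back through the exon structure, so the terminal coverage
  falloff that motivates trimming emerges from read geometry rather than
  being injected. The expected gene-average depth over the exon union
  equals `total_coverage`.
* **Synthetic gene models** (`synthetic_gene_models`): stand-ins for curated
  plant annotations, labelled synthetic. Terminal exons 1,200–2,000 bp and
  shared by all isoforms (so the terminal falloff stays inside long shared
  segments, biasing means by ≲2–3%), interior exons 400–1,200 bp included
  per isoform at random, introns 100–500 bp; in half the genes one
  isoform's last exon is extended 100–300 bp, creating a terminal
  pseudo-exon that the trimming rule removes. Draws are rejected until the
  retained membership has full rank.

## Reference problem sizes

The benchmark settings used by `scripts/acceptance.py` and the end-to-end
tests: 34 haplotypes; 5,000 candidate SNPs (20,000 for the high-coverage
arm) with allele frequencies in [0.4, 0.6]; 1,000 selected SNPs at 2× mean
coverage and 10,000 at 20×, coverage SD 0.5; 30 random-frequency replicates
per cell; RNA-seq: 20 three-isoform genes, 50× coverage, 76 bp reads,
5×-read-length trimming, 30 replicates per gene. These complete in seconds
on one CPU.

## Numerical and degenerate-input choices

* OLS via `lstsq` (SVD): minimum-norm on rank deficiency, reported.
* Closed-form/enumeration agreement asserted to 1e-12; noiseless recovery
  asserted to 1e-10 per coefficient.
* Pool counts exceeding coverage, off-simplex frequency vectors (beyond
  1e-9), third alleles in pool files, non-bi-allelic panel loci and
  heterozygous diploid panel genotypes are rejected with named loci/counts;
  zero-coverage SNPs are dropped and listed, never silently.
* Transcripts shorter than the read length are rejected for simulation.
* Ties in the greedy search (worst pair, best restart) are broken
  deterministically so a master seed fixes the entire run.

## Known limitations

* Rare haplotypes (frequency ≪ 1/n_SNPs-scale noise) are hard to pin down;
  nothing special is done for them.
* No constrained/penalised regression variants are offered, by design.
* Indels and multi-allelic sites are out of scope; pools observing a third
  allele at a panel locus are rejected rather than reconciled.
* The haplotype-unknown problem (inferring the panel itself) is not
  addressed.
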