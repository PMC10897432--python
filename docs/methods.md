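# Methods

This note documents the models, rules and numerical choices behind
`nascentarch`, in the order the pipeline runs them, and states what the
synthetic-data generator does and does not emulate.

## Coordinates and signal model

All internal coordinates are 0-based, half-open; conversion happens only at
the GFF3 boundary (1-based, closed). For a gene the TSS is `start` on the
plus strand and `end − 1` on the minus strand; the TTS is the opposite
terminus. Signal is a per-base, per-strand map of 5′ read-start counts (raw)
or normalized signal; minus-strand values are stored as magnitudes, strand
identity being carried by the file (one bedGraph per strand). Oriented
windows such as a promoter (−400, +100) always count upstream/downstream in
transcription orientation.

## Peak metrics

* **Summit** — position of maximal pileup within the peak; ties broken
  leftmost so outputs are reproducible (any deterministic rule would do;
  leftmost is the simplest).
* **Width** — length of the smallest contiguous window containing at least
  ⌈f·N⌉ of the N read starts in the peak, f = 0.8 by default. The ceiling
  is used because "80% of read starts" on a discrete count must be rounded
  somewhere, and rounding up makes the window a true ≥80% container. Among
  equal-length minima the leftmost is returned. Found by a two-pointer scan
  (O(L)); tests compare against an all-windows O(L²) enumeration.

## TMM normalization

Between-library normalization re-implements the trimmed mean of M-values:
the reference is the sample whose upper quartile of library-size-scaled
counts is closest to the mean upper quartile; for each sample, M (log₂
ratio) and A (average log abundance) are computed on scaled counts over
features nonzero in both libraries, the top/bottom 30% of M and 5% of A are
trimmed (rank windows with average-tie ranks), and the factor is 2 to the
variance-weighted mean of the surviving M values, with weights the inverse
approximate asymptotic (delta-method) variance. Factors are rescaled to
geometric mean 1, and CPM = count / (library size × factor) × 10⁶.

The implementation agrees with the R reference implementation to < 1e-12 on
random matrices (cross-checked in the test suite). One caveat documented
here because it is easy to assume otherwise: TMM is *not* exactly invariant
to multiplying one library by a constant. M and A values are, but the
precision weights depend on absolute counts, so factors shift at the ~1%
level; the reference implementation shifts identically. Proportional
libraries do yield factors of exactly 1 (the M-values are all zero).

## TSS assignment and categories

A peak is assigned (by summit) to a same-strand transcript when any of
three rules hold: (a) inside the annotated 5′ UTR; (b) within 500 bp
upstream to 200 bp downstream of the annotated TSS; (c) within the first
25% of the transcript length. "5′ region" is read as the annotated 5′ UTR
when one exists and empty otherwise — rules (b) and (c) carry the
assignment in annotations without UTRs; this was a genuinely open reading
and is deliberately not a silent fixed window. Among multiple matches the
nearest annotated TSS wins, ties going to the lexicographically smallest
gene id.

Categories: assigned peaks map through the gene biotype (protein_coding →
mRNA; the long-non-coding list → lncRNA; the small-RNA list → otherNcRNA;
anything else → otherNcRNA with a warning). Unassigned peaks become
putativeLncRNA when a reconstructed transcript's 5′ end lies within 50 bp
of the summit, else unstable. Transcript candidates are pre-filtered: length
≥ 200 bp, 5′ end within 50 bp of a same-strand peak summit, and same-strand
overlaps resolved keep-longest (the source analysis required a
non-overlapping set without stating the rule; keep-longest is deterministic
and favors better-supported models).

## ACR annotation ladder

ACRs are labelled by summit through ordered rules where later rules
overwrite: Intergenic → Intragenic (inside a gene detected in the
initiation data, i.e. with ≥1 assigned peak) → TE (inside a
transposable-element interval) → Promoter (inside the oriented (−400, +100)
window of any detected TSS).

## Antisense architecture

A non-coding peak whose summit lies opposite-strand within a protein-coding
gene body extended 200 bp past the TTS is antisense to that gene; summits
in several bodies resolve to the gene with the nearest TSS. Each gene is
represented by its highest-expressed assigned sense peak (max CPM over
time-course samples). Proximal requires *strictly* less than half the gene
body from the TSS and *strictly* more than 1 kb from the TTS; boundary
equalities are distal (configurable). Position is measured at the summit.
Ratios are max-CPM(sense)/max-CPM(antisense) over the non-mutant samples;
correlations are sample Pearson r over the same samples, undefined (and
excluded downstream) when either vector is constant. Cluster enrichment of
antisense TSSs compares observed counts to (global antisense fraction ×
cluster size) with a χ² statistic on k−1 degrees of freedom.

## Bidirectional promoters

A candidate is a minus-strand summit m and plus-strand summit p with m ≤ p
(head-to-head, transcribing apart; m = p allowed) and p − m ≤ 500 bp;
inter-TSS distance is summit-to-summit. Peaks join at most one pair via
greedy matching by ascending distance (ties: leftmost minus member). Types
come from member categories (mRNA → pc, all else → nc). The
correlation-vs-distance table enumerates all candidates up to 2 kb without
the 500 bp cut, one row per candidate; smoothing belongs to plotting. Pairs
are grouped by correlation at ±0.25 (strict inequalities; undefined r →
other), group log₂ max-CPM-ratio distributions compared by two-sided
rank-sum tests with Holm correction.

## Enhancers

Candidates are nc–nc bidirectional promoters (region spanning both summits,
grown symmetrically to ≥500 bp) and intergenic unidirectional ncTSSs
(500 bp centered on the summit). The per-case curation step that prevented
overlap with protein-coding promoters is automated as a deterministic rule:
subtract all detected pc promoter windows (−400, +100) from the candidate,
keep the longest remainder, drop it if < 500 bp — manual edits are not
reproducible, this rule is. Activity per sample is the summed
TMM-normalized signal of both strands over the region. Genes are linked
within 5 kb measured edge-to-summit (0 if the pc summit lies inside the
region). The null distribution draws uniform inter-chromosomal
(enhancer, pcTSS) pairs with a caller-supplied seed and draw count (both
unstated in the source analysis, hence configuration values). Targets are
genes with any link at r ≥ 0.5. Ranking (top/bottom n by activity) uses the
named sample only — "total signal intensity" could also be read as summed
across samples; within-sample is the default and configurable. n is capped
at ⌊count/2⌋ so the sets stay disjoint.

## Exosome sensitivity

Positive log₂FC means higher in the mutant. Sensitive: log₂FC ≥ +2 and
q < 0.05 — upregulation-only, since the defining phenotype is stabilization
in the mutant; a |log₂FC| ≥ 2 downregulation is left unclassified.
Insensitive: |log₂FC| < 1, q > 0.05 and max expression > 1 CPM (initiation
assay) or > 0.1 TPM (steady-state assay). q = 0.05 exactly satisfies
neither gate. Mutant-overlap significance is the upper-tail hypergeometric
probability P(X ≥ overlap).

## Heatmap matrices

Per anchored window and strand, values are capped at the window's 90th
percentile, min–max rescaled to [0, 1] (all-equal windows, including
all-zero, map to zeros), and the row is sense minus antisense, hence in
[−1, 1]. The percentile is per-window, not per-heatmap (the trim is applied
"for each window"). Minus-strand windows are reversed so downstream is
rightward; off-chromosome windows are zero-padded and flagged. Note that on
very sparse windows (>90% zero positions) the cap is 0 and the row
degenerates to zeros; dense binned tracks avoid this.

## Synthetic-data generator

The generator emulates the *structure* of a germination-style study: a
six-time-point developmental course plus two exosome-mutant samples taken
at the seedling stage, a small multi-chromosome genome, and planted
instances of every feature class above, with truth tables.

* **Layout** — features are built as independent "units" (a gene with an
  antisense TSS, a divergent promoter, an nc–nc pair with or without a
  linked gene 1.2–3.5 kb away, a convergent decoy pair, TE and decoy ACRs,
  …), each padded by 600 bp, randomly mirrored, shuffled, and packed onto
  chromosomes with 500 bp gaps. Packing infeasibility is detected before
  any output. The padding/gap sizes guarantee that no cross-unit geometry
  (500 bp pairing windows, 700 bp assignment windows, 200 bp TTS
  extensions) can create unplanned interactions.
* **Read starts** — P(offset d from summit) ∝ p^|d| with p = 0.75
  (two-sided geometric): sharp summits with a realistic few-bp 80%-width.
  No sequencing-read model is used; the sources publish no generative
  model, and the pipeline consumes only per-base start counts. Background
  noise adds Poisson read starts at 2 per kb per strand per sample.
* **Expression** — each feature has a mean level (lognormal, median e⁶ ≈
  400 reads) modulated by one of six unimodal stage profiles
  (mean-normalized Gaussian bumps, width 0.9 stages); counts are negative
  binomial with dispersion 0.1. Mutant samples reuse the seedling-stage
  mean, scaled by 2^lfc for planted exosome-sensitive features. Antisense
  amplitudes are sense/8 (median), matching the observed scale of antisense
  initiation.
* **Correlation planting** — a partner with target r is built from the
  standardized log counts of its base feature plus independent Gaussian
  noise mixed at weight r, exponentiated into a mean profile; the realized
  count-level correlation is checked and redrawn up to 10 times (best draw
  kept) because r estimates at n = 6 are individually very noisy. Planted
  divergent-pair correlations decay with inter-TSS distance
  (r = 0.8·e^−(d−80)/600); nc–nc members and enhancer–gene links are
  planted at r = 0.8; pc–pc pairs are independent. The six stage profiles
  are near-orthogonal after standardization, which keeps the mean
  correlation of random feature pairs — and hence the inter-chromosomal
  null — near zero.
* **Defaults** — the default configuration *is* the "mini" study genome
  used throughout the tests and the acceptance script: 3 × 500 kb
  chromosomes, 150 protein-coding genes, 30 proximal + 30 distal antisense,
  40 divergent promoters, 10 pc–pc pairs, 20 nc–nc pairs, 20 intergenic
  unidirectional ncTSSs, 10 convergent decoys, 20 enhancer–gene links, 30
  exosome-sensitive features, plus annotated lncRNA/small-RNA genes, TEs
  and decoy ACRs. These sizes keep a full simulation + pipeline run under
  ~10 s while every class retains ≥20 instances.

**What passing tests do and do not show.** The generator plants features in
isolation with clean geometry; real genomes have overlapping gene models,
nested and tandem TSSs, mappability artifacts, and assignment ambiguities
the layout deliberately avoids. Recovery of 100% of planted classes
therefore validates the *rules* (windows, boundaries, tie-breaks,
partitions) and the statistical machinery, not performance on messy real
annotation. Correlation-based results (enhancer links ≥90% recovered at
r ≥ 0.5) are bounded by estimation noise at six samples regardless of
implementation quality.

## Degenerate inputs and tie-breaking (summary)

Zero-signal peaks are dropped with their ids reported; constant expression
vectors give undefined correlations (NaN) and fall into "other"/unlinked
groups; zero denominators flag ratios as undefined rather than raising;
all tie-breaks (summit, width window, assignment, matching, ranking) are
leftmost/lexicographic so that every output is permutation-invariant and
byte-reproducible under a fixed seed.

## Known limitations

* Peak calling, alignment, differential testing and transcript assembly are
  consumed, not performed; their quality bounds everything downstream.
* The proximal/distal antisense rule and the 500 bp bidirectional cut are
  hard thresholds; features near boundaries are sensitive to summit
  placement at the ±few-bp level.
* The exosome gates leave a deliberate gap (1 ≤ |log₂FC| < 2, or
  intermediate q); "unclassified" is a real output class, not an error.
* The enhancer null assumes inter-chromosomal pairs share no biology;
  trans-acting co-regulation violates this and would widen the null.
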