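# Methods

## Model and procedure

`homeophase` phases an allopolyploid genome into two pseudo-parental
subgenomes without a progenitor reference, using only compositional
contrasts between the two copies of each homoeologous gene pair, and then
quantifies homoeolog expression bias on top of the phased labels.

**dGC profiles.** For a pair with copies on chromosomes X and X′,
dGC_X = GC_X / ((GC_X + GC_X′)/2); the pair's two values sum to 2 exactly.
GC is computed on the coding sequence only, with N bases excluded from both
numerator and denominator so assembly gaps cannot bias composition. dGC3 is
the same ratio over third codon positions of complete codons (a trailing
partial codon is dropped with a warning). Pairs are ordered by the
appearance of their X-copy gene along chromosome X — transposed pairs
simply enter the X-ordered series — and smoothed with a centered simple
moving average (default window 11 genes).

**Assignment and flip-overs.** The polarity of each position is the sign of
(smoothed ratio − 1). The majority polarity sets the default label of each
physical chromosome (the high side is Fso_h); maximal runs of opposite
polarity at least `min_flip_run` genes long (default 20, comfortably above
the smoothing window) whose mean |smoothed ratio − 1| reaches
`min_flip_effect` (default 0.01) become flip segments, interpreted as
post-hybridization crossovers, and their gene labels are swapped. Shorter
or weaker reversals are treated as noise. Chromosomes with fewer pairs than
`min_flip_run` and mixed polarity are labelled by mean ratio and flagged
low-confidence. Positions with ratio exactly 1 carry polarity 0 and inherit
the majority label.

By default the segmentation runs on the smoothed **dGC3** series. When
divergence between subgenomes is synonymous, the full-CDS dGC is simply the
third-position contrast diluted three-fold, so the two series agree in
polarity essentially everywhere while dGC3 has three times the effect size;
the default `min_flip_effect` is calibrated to the dGC3 scale. Passing
`use_dgc3=False` segments on full-CDS dGC with identical logic.

**Codon-usage PCA.** Codon counts of homoeologous genes are summed per
chromosome copy (optionally per segment or subgenome), converted to per-mil
frequencies — removing chromosome-length effects — standardized per codon,
and eigendecomposed via the correlation matrix. Loadings are eigenvector
elements × √eigenvalue, so squared loadings per component sum to the
eigenvalue and eigenvalues sum to the number of retained (non-constant)
codon columns. Eigenvector signs are arbitrary, so they are fixed for
reproducibility: PC1 so its mean loading is negative, PC2 so the mean score
of Fso_h-labelled observations is at least that of Fso_l observations, any
remaining component so its largest-magnitude loading is positive. Stop
codons stay among the 64 variables. Segment-level PCA adds the
whole-chromosome units of every pairing as context so the gene-content
axis stays on PC1 and segments project onto the subgenome axis.

**Chromosome summary and fractionation.** Per chromosome pair the package
tabulates predicted, homoeologous and non-homoeologous (singleton) gene
counts for the Fso_h and Fso_l sides, with percentages reported to two
decimals, round-half-up. Pairs with flip segments additionally get one
sub-row per dGC-homogeneous segment, H/L re-keyed by segment polarity; the
fractionation sign test (exact binomial, two-sided, ties dropped) uses the
segment-summed counts for such chromosomes, since physical-chromosome
totals would mix the two subgenomes. The packaged table
`data/fsolaris_chromosomes.tsv` carries the published chromosome-level
counts for *F. solaris* (42 chromosome pairs, 9007 homoeologous gene pairs,
Chr10 segment sub-rows) and was validated at transcription time against the
per-row identity predicted = homoeologous + non-homoeologous.

**Expression bias.** Pairs with both copies below the expressed threshold
(RPKM 1) at every time point are removed before analysis. At each time
point a pair is biased toward the copy with RPKM at least `fold` times its
partner's (default 2, inclusive: ratio exactly 2 counts), or toward the
only expressed copy (the silenced case, flagged and tallied separately).
log2 fold changes are oriented positive-toward-Fso_h. Consistency over time
points is strict: the same non-neutral direction at every evaluated time
point; a pair biased twice and neutral once is `mixed`; time points where
the pair is unexpressed are dropped and flagged rather than silently
discarded. Synchrony offers two labelled methods — sign concordance of
consecutive RPKM changes (zero changes are wildcards, flagged degenerate)
and Pearson correlation with a configurable threshold (default 0.8); the
method tag travels with every output row, and neither is claimed to
reproduce published synchrony percentages whose exact definition lives in
earlier work. RPKM strata membership uses the larger of the two copies'
values (configurable to the mean). Pathway/GO association uses the 2×2
(term vs background) × (toward a direction vs not) table, Fisher exact when
any expected cell is below 5 and Pearson chi-square otherwise, with
Benjamini–Hochberg correction across rows; pairs whose copies localise to
different compartments are excluded when a compartment table is supplied.

**Promoter motifs.** Promoters are the 500 bp immediately upstream of the
TSS on the gene's strand (clipped and flagged at chromosome ends).
User-supplied IUPAC motifs are scanned with overlapping matches allowed, on
the sense strand by default (`--both-strands` adds the opposite strand).
Subgenome-biased distribution is a per-motif Fisher exact test on
(subgenome) × (present/absent) with BH correction — an exact-test
substitution for ranking-based motif-enrichment tools. Motif-conditional
bias splits pairs by which copy carries the motif (both / only Fso_h / only
Fso_l) and compares toward-h vs toward-l biased counts with Welch's t-test
using time points as replicates (n = 3 by default); a closed-form Welch
implementation guards the zero-variance corner (equal constant samples
give t = 0, p = 1). De-novo motif discovery and motif annotation are out of
scope.

## The synthetic allopolyploid

The generator emulates the statistical structure the pipeline exploits;
every stochastic choice is emitted as a truth sidecar.

* **Defaults as study conditions**: 10 chromosome pairs × 300 gene slots ×
  400 codons, subgenome GC3 targets 49.2% / 47.9%, fractionation rate 0.08
  with probability 0.65 that a retained singleton sits on the Fso_h copy,
  one crossover (breakpoint at least 50 genes from either end), three time
  points, 61% of retained pairs biased (of which a 0.05 share is realised
  as one-copy silencing), 15.6% of pairs all-silent, log2 noise sd 0.3.
  The dataset-level scale (10 pairs rather than 42) keeps a full pipeline
  run at a few seconds while leaving ≥ 10⁶ third positions per subgenome
  for compositional checks.
* **Synonymous-only divergence.** Both copies of a pair share one
  amino-acid sequence. Codons are grouped into synonymous **boxes**
  (codons of one amino acid sharing their first two bases); the pair
  shares the box at every position, and at a `divergent_codon_fraction`
  (default 0.3, motivated by the ~75% nucleotide homology between the real
  subgenomes) of positions each copy independently redraws the third base.
  This concentrates the compositional signal in third positions, keeps
  positions 1–2 identical within a pair, and makes per-gene dGC exactly the
  scaled dGC3 — matching the observed near-perfect polarity agreement of
  the two series. Inter-box codon preferences (differences at codon
  positions 1–2 between subgenomes) are not modelled.
* **Exact GC3 calibration.** The third-base GC-vs-AT split is solved in
  closed form per chromosome pair and subgenome so that the expected GC3
  of a whole gene (start codon, content-weighted middle positions, stop
  box) equals the target; on divergent positions the split is amplified by
  1/ρ so the marginal expectation is preserved despite the shared
  positions. The truth sidecar stores the exact expected 64-codon
  distribution given the realized sequences, and a chi-square
  goodness-of-fit test confirms the sampler follows it.
* **Codon-usage signatures** come from Dirichlet-perturbed within-subset
  third-base weights per subgenome (`codon_profile_divergence`, default
  0.15 ≈ concentration 6.7). The value was chosen so that chromosome-level
  codon usage separates all pairs on the subgenome axis while remaining a
  small perturbation of a shared profile.
* **Gene-content gradient.** Real chromosomes differ strongly in gene
  content, which dominates PC1 of codon-usage PCA. The generator mimics
  this with a one-dimensional amino-acid composition gradient across
  chromosome pairs (`chrom_content_sd`, default 0.8), shared by both
  copies of a pair. Without it, the subgenome contrast would sit on PC1
  instead of PC2.
* **Expression.** Retained pairs draw a lognormal base level plus per-time
  point shifts; biased pairs get a |log2 fold change| of 1.5 + Exp(1)
  toward their designated subgenome, consistent across time points for a
  0.7 share and direction-flipped at one random time point otherwise;
  silenced copies draw uniform below the expressed threshold; the base
  level is floored so that truly retained pairs stay expressed, making
  noiseless recovery exact by construction. Gaussian log2 noise is added
  per gene and time point. The minimum offset sits half a unit above the
  two-fold call threshold so that the realized ≥ two-fold fraction tracks
  `bias_fraction` under the default noise.

What the generator does **not** emulate: real intergenic sequence,
introns, indels, amino-acid divergence between homoeologs, phylogenetic
structure, length variation between genes, tandem duplications, or
count-based expression noise (RPKM values are treated as given, as the
pipeline consumes them). Passing tests therefore demonstrate that the
algorithms recover the compositional and expression structure they target
at realistic signal-to-noise, not that they are robust to assembly or
annotation artefacts in real data.

## Numerical conventions and edge cases

* Moving-average edges use truncated centered windows (the mean over the
  part of the window inside the series), keeping output aligned with gene
  positions; flips are judged on run length and are insensitive to the
  edge convention. For a linear-in-index series the centro-symmetric
  weights preserve the series mean at any window.
* Percentages are rounded half-up to two decimals via decimal arithmetic,
  matching conventional table formatting.
* Fisher's exact test (scipy) is cross-checked in the test suite against
  exhaustive hypergeometric enumeration over all 2×2 tables with margins
  ≤ 12; the chi-square GOF's type-I error is verified by 10,000-replicate
  Monte-Carlo at α = 0.05.
* Correlation-matrix PCA drops constant columns before standardization
  (logged); observation-order invariance and exact reconstruction are
  property-tested against an independent SVD oracle.
* Usage ratios flag codons absent from both tables (undefined) and
  zero-denominator codons (+inf) instead of erroring.
* A chromosome-level assignment is scored against the truth's majority
  label; when a crossover falls almost exactly mid-chromosome the majority
  is intrinsically ambiguous, and per-gene accuracy is the meaningful
  metric.

## Known limitations

* With synonymous-only divergence the full-CDS dGC effect is one third of
  the dGC3 effect; segmentation thresholds tuned for one series should not
  be reused on the other without rescaling.
* The sign-concordance synchrony rule is coarse for three time points
  (two change signs); the Pearson variant needs more time points to be
  statistically meaningful.
* The motif enrichment test conditions on presence/absence only; match
  counts and positions are reported but unused by the test.
* The fractionation sign test treats chromosome pairs as exchangeable;
  very short chromosomes contribute the same weight as long ones.
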