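# homeophase

Reference-free subgenome phasing and homoeolog expression bias analysis for
allopolyploid genomes.

An allopolyploid carries two chromosome sets inherited from divergent
progenitor species. When no progenitor reference genome exists — the
situation for the oleaginous diatom *Fistulifera solaris*, the first
allopolyploid microalga — the two pseudo-parental subgenomes can still be
separated from the genome's own sequence, because each progenitor left a
distinct compositional signature. `homeophase` implements that strategy as
a reusable pipeline for anyone analysing an allopolyploid with only a draft
genome, a homoeologous gene-pair table, and an RPKM expression matrix.

## The method

For each homoeologous gene pair on a chromosome pair (X, X′), the GC
content of each copy is expressed relative to the pair mean:

```
dGC_X  = GC_X  / ((GC_X + GC_X′) / 2)
dGC_X′ = GC_X′ / ((GC_X + GC_X′) / 2)
```

so dGC_X + dGC_X′ = 2 and the copy with dGC > 1 is the GC-richer one.
Plotted in gene order along chromosome X and smoothed with an 11-gene
moving average, the high-dGC copies of nearly all pairs lie on one physical
chromosome: that chromosome is assigned to subgenome **Fso_h** and its
counterpart to **Fso_l**. The same ratio computed only over third codon
positions (dGC3) carries roughly twice the signal when the progenitors'
divergence is largely synonymous. Extended runs of reversed polarity
(at least 20 genes long with a distinctive mean effect) are called
**flip-over segments** — post-hybridization intergenomic crossovers — and
their genes receive the opposite label.

Three independent lines of evidence corroborate the phasing:

* **Codon-usage PCA** — 64-codon per-mil frequencies per chromosome copy,
  standardized, decomposed on the correlation matrix. Loadings are
  eigenvector elements scaled by the component standard deviation. PC1
  captures gene-content variation between chromosomes; PC2 separates the
  two members of every chromosome pair, the Fso_h copy scoring higher.
* **Fractionation asymmetry** — post-polyploidization gene loss is biased:
  most chromosome pairs carry more non-homoeologous (singleton) genes on
  their Fso_h side (exact sign test).
* **Homoeolog expression bias** — per pair and time point, a copy with
  RPKM at least two-fold its partner's (or the only copy expressed at
  RPKM ≥ 1) is called biased toward its subgenome; calls are tracked for
  direction consistency across time points, expression synchrony, RPKM
  strata, and pathway/GO enrichment (Fisher exact / chi-square, BH-FDR).
  Promoter motifs (IUPAC strings, e.g. `TABASTA`) can be scanned 500 bp
  upstream of the TSS and tested for subgenome-biased distribution.

Because the real genome and RNA-seq are not bundled, the package includes a
**synthetic allopolyploid generator** (`simulate_genome`,
`simulate_expression`) that emulates the relevant statistical structure —
two subgenomes with GC3 49.2% vs 47.9%, Dirichlet-perturbed synonymous
codon profiles, fractionated singletons biased toward Fso_h, one terminal
crossover segment, and a 3-time-point RPKM matrix with 61% biased pairs —
with every stochastic choice written to a truth sidecar, so each stage is
scored against known labels.

## Worked example

```python
import numpy as np
import homeophase as hp

params = hp.SimulationParams()                      # the default study conditions
genome = hp.simulate_genome(params, seed=1)
profiles = hp.compute_dgc_profiles(genome.genes, genome.pairs,
                                   genome.pairings, window=11)
assignment = hp.assign_subgenomes(genome.pairings, profiles)

truth = genome.truth.gene_subgenome
acc = np.mean([assignment.labels[g] == truth[g] for g in assignment.labels])
print(f"per-gene label accuracy: {100 * acc:.2f}%")

for name, pa in assignment.pairings.items():
    for seg in pa.flip_segments:
        print(f"{name}: flip segment at pair positions "
              f"{seg.start_index}-{seg.end_index} "
              f"(true breakpoint {genome.truth.breakpoints[name][0]})")

tables = hp.chromosome_usage(genome.genes, genome.pairs)
labels, unit_pairing = hp.chromosome_units(assignment, genome.pairings)
pca = hp.pca_correlation(hp.usage_matrix(tables), orient_groups=labels)
sep = hp.separation_check(pca, labels, unit_pairing)
print(f"chromosome pairs separated on PC2: {sep.fraction_separated:.0%}")

expr, _ = hp.simulate_expression(params, genome, seed=2)
retained, removed = hp.filter_expressed_pairs(expr, genome.pairs)
calls = hp.call_bias_table(expr, retained, assignment.labels)
biased = calls["direction"].isin(["toward_h", "toward_l"]).mean()
print(f"removed {len(removed)} all-silent pairs; "
      f"{100 * biased:.1f}% of pair x timepoint calls biased")

frac = hp.fractionation_bias(hp.load_fsolaris_chromosome_counts())
print(f"F. solaris: more singletons on the Fso_h side in "
      f"{frac.n_greater_h} of 42 chromosome pairs "
      f"(sign test p = {frac.p_value:.2g})")
```

prints

```
per-gene label accuracy: 99.86%
chrpair03: flip segment at pair positions 170-272 (true breakpoint 174)
chromosome pairs separated on PC2: 100%
removed 442 all-silent pairs; 63.2% of pair x timepoint calls biased
F. solaris: more singletons on the Fso_h side in 38 of 42 chromosome pairs (sign test p = 5.7e-08)
```

The phasing recovers every chromosome-level assignment, localises the
injected crossover within four gene positions, and every chromosome pair
separates by subgenome on PC2. On the packaged *F. solaris* chromosome
table (42 homoeologous chromosome pairs, 9007 pairs of homoeologous genes),
fractionation is significantly skewed toward the high-dGC subgenome, with
chromosomes 27, 38, 41 and 42 the only exceptions.

## Command line

A thin CLI wraps the same functions:

```bash
homeophase simulate  --seed 1 --out-dir sim/
homeophase phase     --cds sim/cds.fasta --genes sim/genes.tsv \
                     --pairs sim/pairs.tsv --pairings sim/pairings.tsv \
                     --out-dir phase/
homeophase codon-pca --cds sim/cds.fasta --genes sim/genes.tsv \
                     --pairs sim/pairs.tsv --out-dir pca/
homeophase bias      --expr sim/expression.tsv --pairs sim/pairs.tsv \
                     --assignment phase/assignment.tsv --out-dir bias/
homeophase motifs    --genome genome.fasta --tss tss.tsv --motif TABASTA \
                     --assignment phase/assignment.tsv --out-dir motifs/
```

Outputs are TSV tables with a commented provenance header (pipeline version
and configuration hash) plus JSON for machine consumption.

## Scope

Read mapping and RPKM computation, gene annotation, tRNA gene prediction
and de-novo motif discovery are upstream of this package: it consumes their
outputs (FASTA, TSV tables, IUPAC motif strings). See `docs/methods.md` for
the model, parameter defaults, numerical conventions and limitations.
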