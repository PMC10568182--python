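# Methods

## Scope and model

cernakit implements the desk half of a two-region nerve-injury
transcriptome study: everything downstream of a gene-level count matrix.
Upstream steps (trimming, alignment, transcript assembly, browser tracks)
and the hosted annotation services (DAVID, STRING, GeneCards, CTD) are out
of scope; their products enter as plain files — a count matrix with biotype
and length, a miRNA→target table, GMT gene sets, and a PPI edge list.

## Expression and differential expression

RPKM is computed self-contained: the "total mapped reads" N_s is the column
sum of the supplied matrix (global by default, per-biotype switchable).
This makes the result order-independent and reproducible from the matrix
alone; whether an upstream mapper would have counted multi-mapping reads
differently is unknowable from a count matrix and therefore not modelled.
Length normalization is applied uniformly to all biotypes, including
miRNA-sized genes, where it is biologically moot but harmless.

The DE statistic is Welch's unequal-variance t on log₂(RPKM + pseudocount)
(default pseudocount 1 RPKM), with the fold change taken on pseudocounted
group means.  The headline filter is the classic joint rule p ≤ 0.05 AND
fold change ≥ 2 (i.e. |log₂FC| ≥ 1), uncorrected — BH q-values are emitted
as an extra column but do not gate anything.  Conventions: both groups
constant and equal → p = 1; both constant and different → p = 0 (the Welch
limit); fewer than two replicates in a group → p missing, the gene cannot be
significant.  Because the fold-change arm is strictly extra, the joint
filter's null rate sits well below the nominal 0.05.

The qPCR 2^−ΔΔCt ratio is provided as a pure function for validation
arithmetic: 2^−[(Ct_target,case − Ct_ref,case) − (Ct_target,ctrl − Ct_ref,ctrl)].

## Over-representation and set accounting

Annotation enrichment and the sponge statistic share one primitive, the
upper hypergeometric tail P(X ≥ k) with P(X ≥ 0) = 1.  For annotation ORA
the universe is, by default, all genes appearing in at least one supplied
set (overridable); the test is one-sided over-representation only.  BH is
standard step-up with monotone enforcement.

Category percentages use the region's significant DEG count (all biotypes;
mRNA-only switchable) as the denominator.  Published reports of this design
are not always consistent about their own DEG totals (abstract, results and
proportion figures can disagree by a few genes or even swap the two
regions), so no attempt is made to reproduce any reported percentage; the
denominator here is simply stated and configurable.

Top-k class tables rank significant genes within a class by |log₂FC|
descending, ties broken by smaller p then gene id.  Hub selection ranks the
DEG-induced PPI subgraph by plain unweighted degree ("correlation degree"
is read as connection degree), ties again by |log₂FC| then id; an optional
minimum-score filter accommodates weighted STRING exports.

## ceRNA inference

Candidates are ordered pairs (ceRNA ∈ {lncRNA, circRNA}, mRNA), both
significant in the region's DE table, sharing at least one miRNA in the
target map.  Three filters:

1. **Shared-miRNA over-representation.**  M = distinct miRNAs in the map,
   K = miRNAs targeting the ceRNA, n = miRNAs targeting the mRNA,
   k = shared; pass at P(X ≥ k) ≤ 0.05.  M is deliberately the smallest
   self-contained universe (the supplied map); restricting miRNAs to a
   DE-miRNA list is optional and off by default, because the provenance of
   miRNA differential expression in such designs is typically unspecified.
2. **Expression correlation.**  Pearson r of the pair's log₂(RPKM+1)
   profiles across the region's pooled samples, after subtracting each
   condition's mean (a partial correlation given condition; p from
   t = r·√(df/(1−r²)) with df = n_samples − 3).  Pass at r ≥ 0.5 and
   p ≤ 0.05.  Centering matters: without it, every pair of concordantly
   injury-regulated genes correlates through the shared group shift, and
   the filter would wave through essentially all concordant DE pairs.
   Centered, it measures sample-level co-expression — which is what shared
   miRNA sequestration predicts — and holds the null candidate pass rate
   below 1%.  (The scalar helper `pearson_with_p` is the plain statistic
   with df = n − 2; `call_pairs` uses the centered variant.)
3. **Direction concordance** — same DE direction, as a sponge model
   predicts.

With fewer than 4 samples in a region the correlation is undefined
(df < 1); the caller then degrades to filters 1 + 3 and flags the output —
the "two groups without replication" regime.

Passing pairs form a tripartite network: ceRNA degree = distinct passing
mRNA partners (and symmetrically), miRNA degree = passing pairs whose
shared-miRNA evidence contains it.  Top lists (default top-10 ceRNAs,
top-2 miRNAs) rank by degree, ties by best hypergeometric p then id.
lncRNA- and circRNA-flavoured networks can be read off the node `kind`
column; both are emitted together.

## Synthetic data generator

The generator emulates the study design — 2 regions × 2 conditions ×
r replicates (default 3, matching pooled samples of 3 animals from 9 per
group) — over a scaled-down transcriptome (defaults: 800 mRNA, 400 lncRNA,
300 circRNA, 100 miRNA).  Counts are negative binomial with log-normal
baselines:

- baseline mean μ_g ~ LogNormal(ln 200, 1.0);
- per-sample biological factor exp(0.3·ε), ε ~ N(0,1) (≈ 35 % CV, pooled
  inbred animals);
- NB dispersion 0.05 (var = μ + 0.05 μ²) — mid-range for bulk RNA-seq of
  genetically identical animals, further justified by the 3-animal pooling;
- gene lengths uniform on 200–10,000 bp.

Planted DE genes (default 200, half up / half down) have their CCI-condition
mean in the target region multiplied by 2^±log2fc (default |log₂FC| = 2).
Planted sponge triplets give the ceRNA and mRNA a shared per-sample latent
log factor with loading √|ρ| each, so the pair's latent correlation is
exactly ρ; ρ is the requested Pearson r (default 0.8) divided by the
analytic attenuation σ_t²/(σ_t² + α + 1/√(μ_c μ_m)) from counting noise,
with per-gene log sd σ_t = 0.65 — the smallest value at which r ≈ 0.8
remains attainable.  Three deliberate design choices make the planted
signal recoverable and defensible:

- **sponge members are drawn from the expressed stratum** (baseline clamped
  to the median): an effective ceRNA must be abundant enough to titrate
  miRNAs, and low-expression transcripts are filtered before ceRNA analysis
  in practice;
- **each sponge pair is mediated by 3 miRNAs** (one ground-truth triplet
  record per miRNA): a pair sharing a single miRNA has tail probability
  ≈ K·n/M, which no realistic target-map density brings under 0.05 — the
  shared-miRNA statistic is only powered by multiple shared response
  elements, as in the biology;
- **the latent factor is mean-centered within each design cell**: it models
  condition-independent co-regulation, so it is constructed not to perturb
  the planted fold changes (otherwise both members' fold-change errors move
  together and whole pairs drop out of the DE filter).

Both sponge members are planted DE in the same direction.  miRNA counts are
emitted in the same matrix by the same model — a stated simplification,
since small-RNA quantification really needs its own protocol.

The target map plants the two edges of every triplet and adds, per miRNA,
a fixed number of background targets (default 20) sampled uniformly from
the non-miRNA genes; duplicates collapse with a warning.  Gene sets are
built from fresh-gene blocks so that requested sizes and (multi-way)
overlaps are exact; the PPI edge list is uniform over unordered mRNA pairs.

All randomness flows from one integer seed through `numpy.random.SeedSequence`
substreams; a fixed seed reproduces every written file byte for byte.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: library-size and GC biases, correlated
background co-expression modules, count-dependent dispersion trends,
isoform structure, and real miRNA-target specificity.  Recovery results on
this generator validate the *pipeline logic and statistics*, not the
biological discovery rate of any particular dataset.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use fixtures the package
generates itself: 2,000 genes with 100 planted |log₂FC| = 2 genes at
9 replicates/cell for DE recovery and null calibration; 20 planted sponge
pairs (r ≈ 0.8) among ≥ 1,500 random DE candidate pairs for ceRNA recovery;
medians over 5 seeds.  Exactness checks enumerate all hypergeometric
configurations up to M = 12 and 1,000 random BH vectors.  These sizes give
stable Monte-Carlo estimates while keeping the whole suite in the
seconds-to-minutes range on one CPU.

At the default 3 replicates/cell — the real study's depth — DE sensitivity
for 4-fold changes is only ≈ 0.66 with FDR ≈ 0.2, and the ceRNA correlation
filter (df = 3, critical r ≈ 0.88) rejects nearly everything.  That is a
property of the raw-threshold design at n = 3, faithfully reproduced, and
the main practical caveat for interpreting studies of this shape.

## Known limitations

- The DE test is a per-gene Welch t on log RPKM; no shrinkage, dispersion
  modelling, or paired designs.
- ceRNA inference takes miRNA targets as given; no sequence-based target
  prediction, and strictly PPC ≥ 0.5 (occasional negative-correlation
  sponges reported elsewhere are not admitted).
- Enrichment is plain ORA; no topology-aware or ranked (GSEA-style) tests.
- Outputs are tables; no figure rendering.
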