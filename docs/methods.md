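# Methods

This note documents the models, parameter choices and numerical decisions
behind `orthosilence`, in the order the pipeline runs them.

## Synthetic cohorts

The generator produces everything a comparative H3K9me3 study consumes, as a
deterministic function of one seed.

**Genomes and chains.** Each chromosome starts as a uniform-random ancestor
sequence; two descendants are produced independently by per-base
substitutions (default rate 0.01, the approximate human–chimpanzee
divergence) and indels (default rate 1e-4 per base, geometric lengths with
mean 3 bp, insertions and deletions equally likely). Because both lineages
descend from the same ancestor, the pairwise chain is computed exactly: runs
of ancestor positions retained contiguously in both descendants become
aligned blocks, and the reverse-direction chain is the exact inversion.
Chains use the UCSC chain format throughout; all simulated chains are
plus/plus.

**TE annotations.** TEs carry a class/family/type hierarchy drawn from a
small catalogue covering the five main classes (LINE, SINE, LTR, DNA, SVA)
with class weights defaulting to 0.35/0.35/0.18/0.10/0.02 — roughly the
composition of a primate genome. Lengths are lognormal around class-typical
means (SINE 300 bp, LINE 600 bp, LTR 400 bp, DNA 250 bp, SVA 1,200 bp);
milliDiv (substitutions per kilobase vs the family consensus) is a truncated
normal on [0, 400] with class-dependent means, shifted 60 per-mil lower for
silenced instances so the divergence contrast between silenced and
unsilenced TEs is recoverable. A configurable fraction of TEs (default 0.1)
exists in a single genome; half of those carry a species-restricted type
name (the species-specific set, analogous to SVA_E being annotated only in
human), half a shared name (plain non-orthologous instances). Orthologous
TEs sit on ancestor segments aligned contiguously in both genomes, so their
two coordinate sets correspond exactly under the chains.

**Silencing ground truth.** Each TE is silenced with a class-dependent prior
(defaults SVA 0.5 > LTR 0.2 > LINE 0.05 > SINE 0.025 > DNA 0.0125 — the
qualitative class ordering seen in pluripotent cells, scaled so the silenced
set packs into a megabase-scale genome). Among silenced orthologous TEs the
shared / species-specific split is assigned by stratified quota: exactly
`round(shared_fraction * n)` TEs (default 0.8) are shared, the rest split as
evenly as possible between the two directions, with a random permutation
deciding which TE receives which label. Quota assignment keeps the realized
truth fraction at the configured value up to rounding, so end-to-end
recovery checks measure the pipeline rather than label-sampling noise; the
per-class priors and the orthology split remain Bernoulli.

**Domain isolation.** Silenced TEs are placed first, with at least 2 kb
between silenced-TE midpoints, and all other TEs keep a 300 bp halo around
silenced loci. This makes each silenced locus its own H3K9me3 domain, so
per-TE ground truth is identifiable at desk scale. Real genomes contain
nested repeats and multi-TE heterochromatin domains spanning tens of
kilobases; the generator deliberately does not model them, which means
passing tests demonstrate correct statistics and interval plumbing, not
robustness to entangled domain structure. TE sequence content is likewise
not written into the genomes (annotations are coordinates only), so
mappability of simulated genomes is essentially 1 everywhere; the
mappability filter is exercised separately on genomes with planted
duplications.

**ChIP fragments.** Input fragments are uniform; ChIP fragments mix a
uniform background (default 3 fragments/kb) with enrichment over silenced
TEs: each contributes NB-distributed counts (dispersion `alpha`, default
0.2, between-individual) around `mean_frag_per_region` (default 50)
fragments per individual, multiplied by `2**species_effect_log2fc` (default
2, i.e. four-fold) in the favored species for species-specific labels.
Per-individual depths are lognormal (sigma 0.15). Fragments are 200 bp,
mirroring typical ChIP size selection; window counting uses fragment
midpoints. The default cohort is 10 + 7 individuals.

**Expression.** Gene counts are NB with lognormal baselines. A gene whose
upstream window (default 10 kb) contains a species-specifically silenced
orthologous TE receives a true species effect of
`expression_coupling x direction`; all other genes draw their effect from a
centred normal (sd 0.3). The default coupling is 0: no true relationship
between silencing divergence and expression divergence, which the
association stage must recover as a calibrated null without bias.

## Peak calling and orthologous regions

The broad-domain caller tiles each genome in fixed windows, takes the
expected window count as `max(depth-scaled Input, genome-wide ChIP mean)`,
computes an upper-tail Poisson p-value per window, BH-adjusts across all
windows, and merges significant windows separated by at most `gap` bases;
merged domains report their minimum q. The function defaults (1 kb windows,
3 kb gap, q <= 0.1) suit gigabase genomes with sparse multi-kilobase
domains. The pipeline configuration instead defaults to 250 bp windows and
gaps: on a compressed megabase cohort whose silenced domains are TE-sized,
kilobase windows would fuse distinct loci and swallow unsilenced neighbours.
This is a scale-matching choice, not a change of contract — the q <= 0.1
broad-calling semantics are identical.

Per-individual peaks must survive a reciprocal, unique lift: at least 70% of
an interval's bases inside aligned blocks of exactly one qualifying chain,
the round trip overlapping the original by at least the same fraction (the
round-trip fraction is not separately specified anywhere authoritative; we
reuse `min_match` and expose it). Surviving peaks from all individuals of
both species are union-merged in genome-A coordinates (merge genome
configurable), lifted once to genome B, and dropped unless mean 50-mer
mappability exceeds 0.8 in both genomes. Mappability is exact k-mer
occurrence counting on both strands (1 / occurrences per base; the trailing
k-1 bases inherit the last full k-mer's score); approximate-match
mappability is out of scope.

Fragment counting is by >= 1 bp overlap of the fragment span, each fragment
at most once per region, species-A individuals counted on the A interval and
species-B on the B interval. Regions without a nonzero count in strictly
more than half of all individuals (with 17 individuals: more than 8) are
removed before testing.

## The NB differential engine

One engine serves ChIP regions, gene-window silencing sums and RNA counts.
Practitioners often reach for separate frameworks for ChIP and RNA (a
NB-GLM package for the former, a precision-weighted linear-model pipeline
for the latter); using a single NB engine for both is a deliberate design
simplification — a rank-based alternative was considered and rejected
because it cannot produce the per-feature effect sizes the downstream
analyses need.

- Size factors: median-of-ratios over features positive in every individual.
- Dispersions: per-feature method-of-moments `(var - mu) / mu^2` on
  normalized counts, averaged over the two species (floor 1e-8); a trend
  `alpha(mu) = a1/mu + a0` fitted by least squares (a0 floored, a1 clipped
  non-negative); final dispersion `exp(w log raw + (1-w) log trend)` with
  fixed weight w = 0.5 in place of empirical-Bayes machinery.
- Per-feature NB regression `log mu = log s_j + beta0 + beta_sp x_j` fitted
  by vectorized IRLS (working weights `mu/(1+alpha mu)`, linear predictor
  clipped at +-30, max 100 iterations, convergence 1e-8); Wald z from the
  weighted information matrix, two-sided normal p. Non-converged or
  degenerate features are flagged untested and count as `shared` in category
  proportions, keeping denominators equal to the retained feature set.
- Independent filtering: BH is applied at each base-mean quantile threshold
  in a grid (default 0 to 0.5); the threshold maximizing rejections at the
  working alpha wins, ties to the smallest threshold. A grid of {0} is plain
  BH.
- No effect-size shrinkage is applied; log2 fold changes are raw MLEs.

Generic tests: the rank-sum test enumerates all group assignments (midranks,
so ties are exact) when the combined n is at most 12 and uses the
tie-corrected normal approximation otherwise; chi-squared is Pearson's
without continuity correction; the permutation correlation reports
`(1 + #{|r*| >= |r|}) / (n_perm + 1)`.

## TE orthology and silencing classification

Orthologous TEs: lift A instances to B (70% match), keep those overlapping a
same-name B instance by >= 50% of the lifted span (measured against the
lifted span, not the annotated instance; largest-overlap then
smallest-start tie-break), lift back to A; repeat seeded from B; intersect
the two sets in A coordinates requiring >= 50% reciprocal overlap of the
shorter span, emitting the A-seeded pair and de-duplicating by A instance.
Non-orthologous instances are the per-species complement; species-specific
instances are non-orthologous instances whose type name is absent from the
other species' table. Orthologous TE length and milliDiv are reported from
the A instance.

A TE is H3K9me3-marked when >= 50% of its length (genome-A coordinates;
configurable) is covered by the union of retained orthologous regions; it
inherits the category and log2FC of the single region with the largest base
overlap (ties to the smaller region id). The within-species orthology
comparison uses each species' own peak set, with empty cells reported as
missing rather than zero. The length-matched control extends
non-overlapping TEs symmetrically to a target median (odd leftover base to
a random side, clipped at chromosome ends) and re-applies the same rule.
The effect-size split for property contrasts is |log2FC| >= 1 (two-fold);
the alternative reading (log2FC >= 2) is available via the
`split_threshold` argument. TSS distance is 0 for a TE containing a TSS,
otherwise the gap between nearest edges (a TE ending 1 bp before a TSS is
at distance 1).

## Gene-level association

The representative TSS is the 5'-most transcript start for sense-strand
genes and the 3'-most for antisense genes. Upstream windows (1/10/20/40 kb)
exclude the TSS base and are clipped at chromosome ends. A gene's silencing
count sums, once each, the distinct orthologous regions assigned to TEs
overlapping its window; genes whose window has TEs but no marked region are
carried with zero counts but excluded from differential silencing, and
genes without any TE in the window are excluded entirely. TE membership in
a window uses >= 1 bp overlap (the stricter full-containment reading would
discard TEs straddling the window edge for no analytical gain).

Expression counts are filtered to genes nonzero in more than 10/17 of
individuals (the ratio generalizes, rounding the threshold down), quantile
normalized (columns' order statistics mapped to the cross-column mean
vector, ties by average rank), and reported as log2 CPM with pseudocount 1;
differential testing always runs on the raw filtered counts. The
association report contains the expression-divergence distributions per
silencing category with pairwise rank-sum tests, the silencing-by-DE-status
cross-tabulation with a chi-squared test, the Pearson correlation of the
two per-gene log2FCs with a permutation p-value, and counts of
opposite-sign vs same-sign gene pairs beyond a +-1 log2FC threshold.
TE-type expression uses `RPKM = reads x 1e9 / (agglomerated length x total
exonic reads)` with a strict > 1 expressed threshold. For the
non-orthologous TE analysis, genome-B TSSs come from lifting the 1 bp TSS
(retained only when its 1 kb context lifts reciprocally), and a gene is
`silent` only if every non-orthologous TE in its window is marked.

## Problem sizes and determinism

Default simulated cohorts are two 1 Mb chromosomes, 5,000 TEs and 10 + 7
individuals — sizes chosen so a complete end-to-end analysis runs in well
under a minute on one CPU while every stage still has hundreds of truth
events to estimate from. The null-association calibration uses 100
replicate cohorts of 250 kb each. Every artifact and every reported number
is a deterministic function of the configured seed; reruns are
byte-identical.

## Known limitations

- The generator writes no TE sequence content and no multi-TE domain
  structure; conclusions about entangled heterochromatin domains or
  sequence-driven mappability artifacts are outside what the tests show.
- The windowed Poisson caller is a deliberately simple stand-in for a
  production broad-peak caller; it preserves the broad-domain q <= 0.1
  contract but not local-lambda refinements or duplicate handling.
- Dispersion shrinkage uses a fixed geometric weight rather than
  empirical-Bayes estimation; at very small replicate numbers the Wald test
  is mildly anti-conservative (the null simulations bound this at roughly
  half a percentage point at alpha = 0.05).
- Only plus/plus chains are generated and invertible; negative-strand query
  chains are parsed and lifted but untested against real liftOver output.
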