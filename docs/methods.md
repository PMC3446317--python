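# Methods

`tevland` analyses transposable-element variants (TEVs): TE insertions that
are polymorphic among inbred strains. This note records the models the
package implements, the defaults it ships, and the choices made where the
design was genuinely open.

## Coordinates and conventions

All coordinates are 0-based, half-open. A TEV is reduced to a point at its
5' base on the reference genome wherever position matters (GC windows,
proximity profiles, randomization tests): reference-lineage insertions have
a measurable span on the reference while non-reference insertions do not,
and the 5'-base convention treats the two sides identically. Strain
distribution patterns encode a reference-lineage TEV (`B6plus`) as `1`
(same as reference) / `DEL` (absent), and a non-reference TEV (`B6minus`)
as `0` / `INS`.

## Read-pair caller

Non-reference insertions are discovered from *anchor reads*: confidently
mapped ends of read pairs whose mates hit TE sequence. The caller:

1. keeps anchors with mapping quality >= 30 whose mates were assigned a TE
   family (mate-to-probe alignment at >= 80% identity over >= 36 bp is an
   upstream step; the table arrives with families assigned);
2. chains anchors closer than 450 bp and discards clusters with fewer than
   10 supporting pairs;
3. scans cluster positions for a breakpoint `bp` with >= 10 forward
   anchors in `(bp-450, bp]`, >= 10 reverse anchors in `[bp, bp+450)`, and
   a last-forward-to-first-reverse gap under 120 bp, reporting the
   leftmost qualifying position (ties are otherwise arbitrary);
4. requires the cluster's total forward and reverse support to balance to
   better than 2:1. The balance is assessed on cluster totals rather than
   per scanned position: per-position counting would let an imbalanced
   cluster qualify at an interior position that silently drops the excess
   anchors, which defeats the filter;
5. rejects calls within 50 bp of an annotated reference repeat
   (SINE/LINE/ERV, simple repeat, low complexity), since anchors abutting
   existing repeats are enriched for mapping artefacts;
6. genotypes every panel strain +/-300 bp around each accepted breakpoint:
   present iff >= 5 forward anchors upstream and >= 5 reverse downstream.

Per-strain calls within 100 bp merge into one non-redundant site (median
breakpoint, majority family vote). Genotyping is monotone in evidence by
construction. The long-insert size classifier applies the spanning-pair
rule literally: more than two 3 kb-library pairs spanning the breakpoint
=> class `> 3 kb`. The physical direction of this rule is debatable (a
spanned breakpoint can equally be read as the element fitting within the
insert); `CallerParams.spanning_literal=False` selects the opposite
reading.

Reference-side (`B6plus`) classification types an SV deletion against
repeat annotation: accepted only if TE sequence lies within 50 bp of an SV
breakpoint and forms a single element; structures are solo-LTR, provirus
(LTR-internal-LTR, internal rows suffixed `-int`), LTR-internal only,
pseudoelement (partial LTR / poly-A), and their hybrid variants when
subfamilies mix within one element; LINEs shorter than 5 kb are fragments
(canonical full length ~6.4 kb). Deletions containing simple repeats or
multiple independent elements are rejected as complex, with reasons
logged; every input SV lands in exactly one output table.

The trio false-negative estimator assumes three near-identical substrains
are monomorphic for every TEV: at sites called in two of the three, the
missing call is counted as a false negative. The denominator is trio
*calls* (three per qualifying site); the alternative (sites) is not used.

## Phylogenetics

Presence/absence columns are discrete characters under Dollo parsimony:
one gain per character (a TE insertion at an orthologous site is
effectively unique and irreversible), any number of losses. The gain sits
at the LCA of the carriers; the cost is the number of maximal observed-
absent subtrees under the gained lineage; missing genotypes (NA) do not
constrain the fit. This is a deliberate substitution for the generic
mixed-parsimony program the original workflow used: only topology-level
agreement is contracted.

Search is stepwise addition followed by NNI hill-climbing; for <= 7
strains the point estimate enumerates all rooted topologies (the same
enumeration is the test oracle). Identical presence patterns are collapsed
into weighted characters first, which bounds the work at 2^n patterns.
Bootstrap resamples characters (multinomially over the collapsed
patterns), runs the heuristic search per replicate, and reports the
majority-rule consensus of rooted clades with supports on the 0-100
scale. Each TEV is mapped to the LCA of its carriers; single-carrier TEVs
map to terminal branches (private insertions).

## Selection statistics

* **Orientation bias** = sense / (sense + antisense) among intronic TEVs;
  0.5 under neutrality. Assuming antisense insertions are neutral, the
  fraction of sense insertions purged is `1 - bias/(1-bias)` (clipped at
  zero).
* **Contingency tests** are Pearson chi-square without continuity
  correction; this choice reproduces the published desk-scale p-values at
  their printed precision.
* **Male insertion bias**: `alpha = (3r - 4)/(2 - 3r)` with `r` the
  GC-accounted X/autosome density ratio; `r <= 2/3` means exclusively male
  (`alpha = inf`), `r = 1` means no sex bias. The 95% CI is a
  nonparametric bootstrap over TEV chromosome labels (percentile method,
  nearest-rank so infinite upper bounds survive); results with `r`
  outside (2/3, 4/3) are flagged rather than raised.
* **Solo-LTR half-life**: `lambda = Y ln(1/2) / ln(Z)` for divergence `Y`
  (My) and proviral fraction `Z`, assuming constant recombination rate and
  proviral insertion. `fit_half_life` additionally fits `lambda` by 1-D
  maximum likelihood over per-event ages and end states, which stays
  defined when an age group's observed fraction hits 0 or 1.
* **Chromosome-level polymorphism/fixation contrast** adapts the
  McDonald-Kreitman idea: per chromosome, the TEV count expected from the
  fixed-TE distribution is compared by a G-test (chromosome vs rest of
  genome, df = 1), BH-corrected at FDR 0.1%. A TEV deficit against the
  fixed background (direction -1) marks candidate positive selection for
  retention.
* **GC profiles** take the mean GC of the 20 kb window centred on each
  TEV's 5' base (window-track resolution) and report per-family ECDFs;
  windows running off a chromosome end are truncated and flagged.

## Randomization enrichment

TE insertion rates vary strongly with GC, so overlap tests must condition
on composition. Each chromosome's isochore windows are partitioned into
GC-quantile strata (default 8 strata over 20 kb windows; neither number is
canonical, both are configurable); every TEV point is re-placed uniformly
within its own (chromosome, stratum) cell, default 10,000 times. The
empirical p doubles the tail in the observed direction (floor
`2/(n_samples+1)`), and q-values are BH across each batch of annotations.
Compartments (exon > intron > 5 kb flank > intergenic, by precedence on
the union gene model) and gene-category tables are wrappers over the same
core; the merge-QTL analysis is this test applied to supplied intervals.

Proximity profiles count TEV 5' bases in Fibonacci-scaled distance bins
(base x 1, 2, 3, 5, 8, ...) from gene or exon boundaries, each gene's
usable span stopping half-way to its neighbour; densities are per
available base and reported relative to the global TEV density, stratified
by sense/antisense (unknown orientation dropped). Intron position strata
are indexed in transcript orientation; a one-intron gene contributes
"first", a two-intron gene "first" and "last"; heterogeneity across strata
is a chi-square on the sense/antisense x stratum table.

## Expression association

Counts are normalized by median-of-ratios size factors (rescaled to median
1); genes with no counts anywhere are dropped. The resampled DE procedure
draws, per resampling (default 100), two carrier and two non-carrier
strains without replacement, pairs each tested gene with a random TEV-free
gene, tests the 4-vs-4 tables, applies BH at FDR 10% across the whole
table, and calls a gene when significant in at least ceil(100/3) = 34
resamplings. Sampling without replacement is a choice; the exact table
construction for >2 carriers is not canonical.

The inner test is authored in-package: a two-sided conditional
negative-binomial test with pooled method-of-moments dispersion
(exact-style tail summation over splits of the grand total), reducing to
the conditional Poisson/binomial test as dispersion -> 0. The resampling
wrapper is agnostic to the inner test, which is swappable.

The CTCF test measures ln(upstream/downstream expression) of the genes
flanking each intergenic TEV (up/down assignment randomized upstream) and
compares carrier vs non-carrier variance by a robust Brown-Forsythe ANOVA
on absolute deviations from group medians — "analysis of variance" alone
does not pin down the form, and the robust variance version is the choice
here. The empirical p is the fraction of (default) 10,000 equally sized
random samples of non-CTCF TEVs with a smaller ANOVA p, floored at
`1/(n_perm+1)`.

## Synthetic data generator

The generator produces the conditions the analyses assume, with truth
files for every recoverable parameter. Insertions arise as a Poisson
process per tree branch and family; carriers are exactly the leaves below
the branch (no homoplasy). Defaults: an 18-strain tree with 2 My to the
deepest split (wild-derived strains deep, laboratory strains shallow, a
trio of near-identical 129-like substrains); 3 autosomes + X of 20 Mb
each; 20 kb isochore windows with smoothly varying GC in [0.30, 0.65];
300 non-overlapping multi-exon genes with category labels.

* Family rates default to 150 (SINE), 200 (LINE) and 150 total across four
  ERV families per My — no canonical per-family rates exist, and these are
  arbitrary scale choices that give a few thousand events on the default
  tree.
* GC preference: windows sampled with weight `exp(w * GC)`, one weight per
  family (positive for SINE and MuLV, negative for LINE); this
  single-parameter form reproduces stochastically ordered family ECDFs.
* Male bias: X-window weights are scaled by `r(alpha) = (2a+4)/(3(a+1))`,
  the inverse of the alpha estimator, so the realized X/A density ratio
  matches the target (2/3 at alpha = inf). Default alpha 7.5, near the
  estimates the statistics recover.
* Selection: sense-orientated intronic insertions are purged instantly at
  insertion with class-specific probability (defaults 0.5 for ERV, 1/3
  for LINE and SINE, matching the purged fractions the orientation bias
  implies). Purging is modelled as instantaneous, not as drift: the
  analyses only see the end state.
* Decay: ERVs insert as proviruses and are solo LTRs with probability
  `1 - (1/2)^(age/lambda)`; event age is measured from the branch
  midpoint (unbiased under uniform placement along a branch). Default
  half-lives: IAP 0.7, MuLV/MaLR 0.8, ETn 2.0 My.
* Evidence: each flank of a true breakpoint receives Poisson(read_depth)
  anchors (default 30) within 450 bp, ~90% at mapping quality 60; noise
  pairs are scattered at 0.5/Mb/strain. Reference-side events emit SV
  deletions plus RepeatMasker-like annotation; nested elements are
  skipped, as they do not resolve into independent deletions.
* Expression: negative-binomial counts (default mean 500, dispersion
  0.05, lognormal gene effects), two replicates per strain; 10% of genic
  TEVs multiply carrier means by 4; CTCF-flagged intergenic TEVs (5%)
  multiply both flanking genes by lognormal noise (sd 0.8) in carriers.

One seed in `SimulationConfig` fixes everything; module sub-streams are
derived by fixed offsets, so outputs are bit-identical across runs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence-level artefacts (alignability,
segmental duplication, PCR bias), incomplete lineage sorting and
homoplasy, insertion-site sequence preferences beyond window GC,
population-level segregation within strains, linked causal variants in the
expression model, and overlapping/nested element resolution. Recovery
results certify the estimators under their own assumptions, not caller
performance on real sequencing data.

## Problem sizes and numerical notes

Tests and the acceptance script run the generator at reduced scale —
genomes of tens of Mb, 10^3-10^4 events, 100 bootstrap/resampling
replicates, 200-10,000 randomizations — chosen so the full suite
completes in minutes while keeping Monte-Carlo error well inside the
asserted tolerances. Empirical p-values are floored at their resolution
and never reported as zero. The half-life MLE optimizes over
log(lambda) in [1e-3, 1e3] My; G-test terms use the 0 ln 0 = 0
convention; BH is a single shared implementation (statsmodels) tested
against a brute-force reference.

## Known limitations

* Dollo parsimony assumes no homoplasy; recurrent insertion at hot spots
  would inflate losses and can distort supports.
* The alpha CI resamples chromosome labels only; spatial clustering of
  insertions would make it anti-conservative.
* The caller abstraction has no per-base coverage, so the published
  low-coverage breakpoint scan is folded into the anchor-window criteria.
* Orientation of non-reference calls comes from the simulated/mate
  orientation field; records without it are excluded from orientation
  statistics rather than recovered by local assembly.
* The trio false-negative estimator conflates genuine trio polymorphism
  with caller misses unless the trio really is monomorphic.
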