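# Methods

## The subtraction model

The pipeline assumes a binary functional trait (here: competence for
arbuscular-mycorrhizal symbiosis) that partitions species into
trait-positive dicots (group A), trait-positive monocots (group B) and
trait-negative species (group C), and that genes required for the trait are
under purifying selection only where the trait exists. Two observable
signatures follow: a trait gene's orthocluster may lack group-C members
entirely (gene loss), or its group-C homologues may be measurably more
diverged than its group-A/B homologues (relaxed constraint). The stages
target these signatures in order of stringency.

**Presence/absence filters.** Orthology clusters arrive as one Newick tree
per line with `<code>_<protein_id>` leaves; only leaf sets matter — inner
labels and branch lengths are ignored. Species are resolved by the longest
registered code that prefixes the label followed by an underscore, because
protein ids themselves may contain underscores. `TaskX` retains clusters
with ≥ X *distinct* trait-positive clustered species (paralogs never
inflate the count, matching a per-species presence reading) and zero
trait-negative members; `Task9` retains clusters present in every clustered
species. Task results nest (Task6 ⊆ Task5 ⊆ Task4 ⊆ Task3) by
construction; the test suite asserts this against a brute-force membership
scan on random clusters. Cluster ids are `<provenance>_<ordinal>` in file
order and stable across runs.

**Expression gate.** Probesets ending in `_x_at`/`_s_at` (non-unique or
cross-hybridizing probes) and probesets with genome identity strictly below
70 % are discarded; exactly 70 is retained. Induction for a criterion is
mean(test columns) / mean(control columns), replicate test columns averaged
before the ratio, with the control mean floored at ε = 0.01 on the
intensity scale so zero controls give large finite ratios instead of
infinities. A gene passes when *any* of its curated probesets reaches the
threshold (inclusive ≥ 3 by default, from the "at least 3-fold" reading);
genes with no curated probeset are absent from the table rather than
counted as failures. The phosphate-repression criterion reads low-phosphate
control roots as test and high-phosphate roots as control, so a ratio ≥ 3
means repression by phosphate. The Venn partition assigns each gene to the
unique region matching its exact pass pattern over the selected criteria;
phosphate repression is reported as an orthogonal per-region count rather
than a region of its own.

**Scale-score standardization and co-expression.** Y = (X − μ)/ρ with
X = ln(x), μ and ρ the per-treatment mean and *population* standard
deviation over all probesets (the descriptive statistic; at atlas scale the
n vs n−1 difference is immaterial, but the convention is fixed so the
−1/+1 two-point identity holds exactly). Constant columns are an error
(ρ = 0). Clustering is average-linkage on the Pearson-correlation distance
d = 1 − r across treatments (scipy's `pdist`/`linkage`); zero-variance rows
are excluded with a warning since their correlation is undefined, and flat
groups come from a configurable distance cut (default 0.3).

## The conservation-ratio statistic

Per candidate cluster, a consensus query (per column the most frequent
non-gap residue over the trait-positive members, gap-majority columns
dropped, residue ties broken alphabetically) is searched against all
proteomes; hit tables are 12-column BLAST tabular with the E-value in
column 11. Multiple hits per proteome are reduced to the per-species
minimum E — the profile should reflect the closest homologue per species.
Group averages are arithmetic means over species *with* hits; absent
species are excluded rather than zero-filled, and an entirely absent group
is undefined. The conservation ratio is

    ratio_CX = log10(Ē_C) − log10(Ē_X),

i.e. log10 of the ratio of averaged E-values. The alternative reading as a
quotient of logs cannot produce the three behaviours the statistic must
have — values far above 100 for trait-biased clusters, negative values for
housekeeping clusters, and zero when the groups are equidistant — so the
log-difference is used. E-values are floored at E_MIN = 1e-180 before
logs; clusters whose raw group average is exactly 0 are flagged because the
reference-band selection excludes them verbatim. The statistic is
antisymmetric and strictly monotone in both arguments (property-tested).

**Divergence gate.** Group divergence is tested by a two-sided Wilcoxon
rank-sum on the per-species best-hit E-values (C vs A, C vs B). Being rank
based, any monotone transform of E gives the same p — asserted as a
property. Ties take mid-ranks; for pooled n ≤ 12 the null is enumerated
exactly over all C(n, n₁) group assignments (at most 924), above that a
tie-corrected normal approximation with continuity correction is used. The
gate is p < 0.05 uncorrected, exactly as applied in practice for this
screen; a Benjamini–Hochberg column is emitted for reference but does not
gate. Whether the original screen compared per-species best hits or all
hits per group is not recoverable; best-hit-per-species is adopted because
it keeps the samples independent across species.

**Classes and ranking.** Each record is classed `NaN_in_C` (no group-C hit
— maximal specificity), `ratio>threshold` (ratio_CA above 100),
`significant`, or `nonsignificant`. Candidates are ranked NaN class first,
then descending ratio_CA, with flags for either or both ratios above the
threshold. The housekeeping reference band takes Task9 records, drops
zero-E and monocot-undefined records, ranks the rest by Ē_A and keeps the
n = 150 records straddling the median — "intermediate E-values" has no
stated quantile bounds, so the median-centered window is the neutral
operationalization. With fewer than n eligible records the band takes all
of them with a warning (the default synthetic bundle has 80).

## Promoter statistics

Promoters are 2 kb upstream slices, position 1 farthest upstream; shorter
sequences are scanned at their true length with per-promoter trial counts.
Scanning is exact IUPAC matching via overlap-tolerant regex lookahead; `N`
in the sequence never matches. Perfect palindromes (pattern equals its
reverse complement) are scanned on one strand only — the other strand
carries the identical sites — and a one-strand scan is exactly half of a
naive two-strand scan (tested). Odd-length palindromes allow exactly one
free center base, the structure of the Myc2 element. Non-palindromic
elements are scanned in both orientations, each orientation reported as a
distinct record.

Overrepresentation is the exact upper binomial tail
P[Bin(trials, p) ≥ observed] with trials = scanned positions and p the
product of per-position base frequencies under the background composition
(empirical composition of the "all promoters" sample by default; uniform by
flag; doubled for pooled-orientation scans of non-palindromes). Occurrence
counts feed the binomial; *relative frequencies* (% of promoters with ≥ 1
site) feed the fold enrichment, since the samples being compared differ in
size. Positional bias bins hits by distance to the start codon
(d = L − start − |pattern| + 2, 500-bp bins) and tests the proximal bin
against the uniform per-hit probability.

The discovery stage replaces EM-based motif search with an exhaustive and
therefore fully reproducible alternative: every foreground k-mer
(k = 6..14 by default) classified palindromic is scored by the exact
binomial tail of its foreground count against the background occurrence
rate, with a BH column across the enumerated k-mers. A k-mer absent from
the background gets a continuity floor of 0.5/background-trials so the
expected rate stays in (0, 1).

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes, at
roughly 1 % of genome scale: 16 species (6 trait-positive dicots, 7
trait-positive monocots, 3 trait-negative), 9 of them clustered, and 200
gene families in four classes — 80 ubiquitous (all clustered species,
log10 E ~ N(−110, 5) in every group), 40 trait-specific (trait-positive
members only, *no* group-C hit rows), 40 trait-biased (trait-positive
clusters, group C present but weak: C ~ N(−10, 2) vs A, B ~ N(−130, 5)),
and 40 negative-only. Member sequences share a random 120-aa family core
with 10 % point substitutions so external aligners behave sanely; a 10 %
paralog rate and a per-species dropout (10 %, floor of 3 present) exercise
the distinct-species counting and the Task3–6 gradient. Hit tables are
emitted under the cluster ids the pipeline itself will assign (the
generator runs the same deterministic parse-and-filter), with decoy
secondary hits at 10¹–10⁵ × the best E.

Expression: 254 treatment columns (the named contrast columns first,
fillers after), per-probeset lognormal baselines (ln-mean 4, ln-sd 1),
multiplicative lognormal cell noise σ = 0.2, and a 4-fold planted
induction on the test columns of each induced criterion; 30 % of trait
families are induced, and the AM and phosphate-repression criteria are
never planted together because the repression control column doubles as
the AM control — planting both would mechanically cancel the AM ratio.
About 10 % of probesets are made unreliable (suffix or identity < 70) to
exercise curation. Promoters are 2000 nt at composition A/T = 0.3,
C/G = 0.2; the four named elements are planted at rate 0.3 into promoters
of induced genes, `GCCGGC` restricted to the proximal 500 nt and the
extended CTTC element in either orientation.

A single integer seed drives everything through per-stage substreams, so
identical configs give byte-identical bundles and stages can be
regenerated independently.

**What passing tests do and do not show.** The generator plants the *effect
structure* (presence/absence, E-value separation, fold induction, motif
occurrence) but not realistic protein evolution, probe cross-hybridization
beyond id suffixes, correlated treatments, or genomic base-composition
heterogeneity. Recovery on the bundle demonstrates that the statistics
separate the planted classes at the configured effect sizes; it does not
certify sensitivity on real proteomes, where orthology errors and
database incompleteness dominate.

## Numerical and calibration notes

- Exact Wilcoxon enumeration is limited to pooled n ≤ 12; the per-cluster
  group sizes in this design (3 vs 6, 3 vs 7) always fall inside it.
- A fully separated 3-vs-6 configuration has p = 2/84 ≈ 0.024 — below the
  0.05 gate — but 3-vs-4 bottoms out at 2/35 ≈ 0.057: with fewer than five
  group-A species the gate is unreachable no matter the data, which is why
  group coverage matters more than effect size for the significance class.
- The exact binomial null is discrete: with an expected site count below 1,
  P(p = 1) is large and null p-values are super-uniform (conservative), not
  uniform. Null calibration is therefore checked as *validity* — a
  one-sided Kolmogorov–Smirnov test that the null p-values are not
  stochastically smaller than uniform — rather than as literal uniformity,
  which no exact discrete test can satisfy.
- At a planted fold exactly at 3.5 with σ = 0.2 cell noise, per-probeset
  sensitivity at the 3-fold gate is analytically ≈ Φ(ln(3.5/3)/0.245) ≈
  0.77; high recovery (≥ 0.9) is a property of folds comfortably above the
  gate, and the recovery test uses the generator's default 4-fold
  condition (analytic ≈ 0.91).
- Dendrogram merge order is deterministic: scipy's linkage resolves equal
  distances by cluster index, and all inputs are generated in fixed order.
- Ambiguous-residue letters (B, Z, J, U, O) are tolerated on FASTA input
  but never produced by the generator.

## Limitations

- Consensus building implements majority rule only; computing the multiple
  alignments themselves is out of scope (alignments are inputs).
- Running homology searches is out of scope; E-value tables are inputs,
  and a species present only with hits above the search tool's reporting
  cutoff is indistinguishable from a truly absent species — such cases
  feed the NaN class.
- The headline counts of any real screen depend on database release and
  search parameters; this package reproduces the *method*, with
  correctness argued through oracles and planted-truth recovery, not
  through matching historical counts.
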