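# Methods

`coexmir` implements an integrative analysis of a miRNA-overexpression
microarray experiment with two conditions and three replicates each: a
control (`null`) and a miR-142-overexpressing (`mir142`) condition.  The
pipeline combines three independent evidence layers — condition-specific
coexpression, miRNA seed-site presence in 3′ UTRs, and differential
expression — and intersects them to nominate genes most plausibly
repressed by the overexpressed miRNA.

## Seed mapping

Each miR-142 arm contributes a 7-nt seed (miR-142-5p `AUAAAGU`,
miR-142-3p `GUAGUGU`).  A transcript is a predicted target when its 3′ UTR
contains the seed's *site*: the DNA reverse complement of the seed read
5′→3′ on the UTR sense strand (`ACTTTAT` and `ACACTAC` for the defaults).
Because miRNA–target pairing tolerates single mismatches, the scanner also
searches the sites of all 3 × 7 = 21 one-base mutants per arm ("inexact"
sites), 44 site strings in total.  Scanning is plain overlapping 7-mer
matching on the sense strand only (mRNA is single-stranded); positions are
1-based; windows containing `N` never match; no flanking context, site-type
taxonomy (7mer-m8/8mer), conservation or free-energy model is applied.

Per-gene classification collapses hits over all of a gene's transcripts
(logical OR) into one of seven mutually exclusive classes.  Exact hits
take precedence over inexact hits, and arms combine to `both`:
`exact-5p`, `exact-3p`, `exact-both`, `inexact-5p`, `inexact-3p`,
`inexact-both`, `none`.  The precedence rule is a design choice made so
that class counts partition the gene set; for the default seeds the two
arms' site sets (exact + mutants) are disjoint, so no single window can
ever count for both arms.  Mutant labels (`1a` … `7c`) enumerate the
substituted base in fixed A<C<G<U order; the label convention is
deterministic but carries no biology.

## Coexpression networks

For each condition separately, Pearson correlations are computed over all
gene pairs (zero-variance genes dropped with a logged count) and an
undirected simple graph is built from the retained pairs.  Only positive
correlations are retained, modelling coexpression as a positive effect.
Two retention modes exist:

* **`r-threshold`** (default, `r_min = 0.9998`) — retain `r ≥ r_min`.
  This is the reproduction mode: the threshold is the correlation at
  which a three-replicate design reaches 80% power at one-sided
  α = 0.01 under the Fisher-z approximation (see *Power* below), and the
  minimum retained correlation is logged.
* **`adjusted-p`** — retain positive pairs with adjusted p ≤ α, with
  Bonferroni/Holm/Hochberg/BH adjustment (statsmodels implementations
  behind one façade).  With n = 3 the correlation t-test has df = 1 and
  its two-sided p cannot fall below ≈ 0.0127 even at r = 0.9998
  (closed form at df = 1: p = 1 − (2/π)·arctan|t|), so this mode is
  essentially powerless after genome-scale correction; it is provided for
  completeness and for larger designs.

Correlation p-values use the exact-under-normality transform
t = r·√((n−2)/(1−r²)) on n − 2 df, two-sided, with p(|r| = 1) = 0 by
convention.  Network statistics are node count, edge count and edge
density E/(N(N−1)/2) (reported as 0 with a degeneracy flag for N < 2);
network comparison reports shared nodes/edges and Jaccard indices.

**Small-sample caveat.**  With three samples the null distribution of r
has density (1/π)(1−r²)^(−1/2): about 0.64% of *independent* gene pairs
exceed 0.9998.  Planted-clique recall at the threshold is therefore
essentially perfect (near-1 correlations survive deterministically), but
exact recovery — the network containing *only* planted structure — and
exact zero overlap between condition networks are probabilistic events
whose probability decreases with gene count.  The test suite checks exact
recovery and zero overlap on a small clique-only configuration at the
generator's default seed, and checks the seed-independent guarantees
(complete clique recall, positive-only retention, threshold monotonicity)
everywhere else.  On real data this tail implies that an r-threshold
network from a 3v3 design always carries some noise edges.

## Differential expression

Two tests suited to three-per-group designs, both authored here:

* **Pooled-variance t-test** — textbook two-sample t with
  df = n_A + n_B − 2.  Degenerate conventions: zero pooled variance with
  equal means → p = 1; with unequal means → p = 0.  (A moderated
  empirical-Bayes fit would share variance information across genes; the
  pooled t keeps the per-gene test self-contained and exactly auditable.)
* **Exact Wilcoxon rank-sum** — the rank-sum W of group A with midranks
  for ties, with the exact two-sided p obtained by enumerating all
  C(n_A+n_B, n_A) assignments of the observed pooled values:
  p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).  The doubling rule is one of
  several two-sided conventions; it is stated here and matches scipy's
  exact method on tie-free data.  Enumeration is capped at 50 000
  assignments (about 8 per group).

For tie-free 3v3 data the exact two-sided WRS p has a hard floor of
2/C(6,3) = **0.1**.  Consequently BH adjustment of many WRS tests can
only leave calls at the 0.1 threshold if essentially every test sits at
the floor, so the DE stage defaults to raw-p filtering
(`adjust="none"`) at α = 0.1 for the rank-sum test; BH adjustment is the
default for the t-test and available everywhere.  Direction: `down`
means lower mean in `mir142` than in `null`; `log2fc` is the difference
of group means (values are assumed log2-scale, so a mean difference is a
log fold change).

## Contingency statistics and power

`pearson_chisq` is the uncorrected Pearson chi-square test of
independence (scipy's `chi2_contingency` with `correction=False`); for
df = 2 the upper-tail p equals exp(−χ²/2), asserted in tests to 1e−12.
The package ships the published summary counts of the GSE50133 study
(`coexmir.reference`) and the two 3×2 cross-tabulations derived from
them — arm (5p/3p/both) × mapping quality (exact/inexact) over network
nodes, and arm × regulation direction (down/up) over seed-mapped DE
genes.  These reproduce the study's printed statistics (χ² = 13.6125,
p = 0.0011; χ² = 2.49, p = 0.2878) to < 0.01, which validates both the
statistic and the reconstruction; the tables are fixtures, not runtime
inferences, because the raw data is out of scope.

Sample size for correlation detection uses the standard Fisher-z
approximation n = ((z_α + z_β)/C(ρ))² + 3 with C(ρ) = arctanh(ρ).  At
ρ = 0.9998, one-sided α = 0.01, power 0.8 the formula gives 3.47 —
ceil-rounding yields 4, nearest-rounding 3.  Both conventions are
exposed (`rounding="ceil"|"round"`) because neither is canonical, and
the Fisher-z standard error 1/√(n−3) is itself undefined at n = 3; the
result dict always records which convention produced it.

## Integration

Nodes of both networks are annotated with seed class and DE status.
Export encodes the display conventions as strings:
color ∈ {dark-red, pink, dark-green, light-green, blue, plain} for
{exact-5p, inexact-5p, exact-3p, inexact-3p, inexact-both, none} (the
never-observed exact-both maps to "dark-red+dark-green"), and shape
∈ {down-arrow, up-arrow, ellipse} for {down, up, ns}.  Interchange
formats are SIF plus a node-attribute TSV (simplest faithful Cytoscape
import) and GraphML (single-file alternative).  The **triad** selection
is the deterministic conjunction: member of the overexpression network ∧
seed class ≠ none ∧ DE-down, ordered by gene id.

## Synthetic data

The generator emulates the statistical structure the analysis assumes —
not microarray physics.  Defaults (chosen once as a realistic small
study, used by tests and the acceptance script):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genome-scale enough for multiple-testing behavior, fast enough for CI |
| `n_per_group` | 3 | the study design |
| `modules_null` / `modules_mir142` | (8, 6) / (7, 5) | planted clique sizes per condition, disjoint memberships |
| `clique_noise_sd` | 1e-4 | per-member noise around the shared latent profile (r ≈ 1 − O(noise²)) |
| `background_sd` | 0.5 | i.i.d. log2-scale background around `baseline_mean` = 8, a typical microarray spread |
| `n_de_genes` / `de_shift` | 10 / 5.0 | planted DE genes; the shift fully separates groups so the exact WRS floor is attained |
| `utr_length_range` | (200, 400) | short-but-realistic 3′ UTRs |

Cliques use a latent-profile model — one shared profile per clique per
condition plus independent noise — rather than an explicit covariance
matrix: it is simpler and guarantees within-clique correlations → 1 as
the noise → 0.  DE planting is an additive shift on the log2 scale,
consistent with log2fc = difference of group means.  The first two DE
genes are drawn from the first `mir142` clique and planted with exact 5p
sites, so triad genes exist by construction (a constant between-condition
shift does not perturb within-condition correlation).

UTR backgrounds are *guaranteed* site-free: sequence is sampled
uniformly and any window matching one of the 44 forbidden site strings is
resampled in place (only unprotected bases) until no match remains —
rejection at window granularity, which converges quickly and preserves
planted sites exactly.  Planted sites are written at recorded 1-based
positions with at least one free base between sites so no fully protected
forbidden window can arise.  The generator re-scans its own output and
refuses to return if the scan differs from the manifest.  All randomness
flows from one `numpy` Generator seeded with `rng_seed`; outputs are
byte-reproducible under a fixed seed.

What the generator does **not** model: probe-level summarization,
normalization artifacts, batch effects, correlated background structure,
realistic UTR base composition, or multiple transcripts per gene.
Passing tests therefore demonstrate correctness of the algorithms under
the idealized model, not robustness to microarray artifacts.

## Problem sizes and numerical choices

The test suite runs the full pipeline at 2000 genes (seconds on one
core); unit and property tests use 5–400 genes.  Pair correlation uses
one `numpy.corrcoef` call per condition with r clipped to [−1, 1]; ties
in adjusted-p ranking are resolved by the underlying stable step
procedures plus a stable (p, gene-pair) sort at edge retention.
Degenerate inputs are defined rather than erroneous wherever a convention
exists (empty network → density 0 with flag; |r| = 1 → p 0; constant
groups → p 1; Jaccard of two empty sets → 1).

## Known limitations

* The `adjusted-p` network mode is powerless at n = 3 (df = 1); it exists
  for larger designs.
* The r-threshold network at n = 3 inevitably includes a ~0.6% background
  pair tail (see caveat above).
* The exact WRS is enumeration-only; no normal approximation is provided,
  so groups beyond ~8 per side are rejected.
* Gene-level UTR handling assumes one record per gene in the synthetic
  path; multi-transcript genes are supported in the scanner and
  classifier but not generated.
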