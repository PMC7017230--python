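# Methods

## The calling rule

For each reference position the read stack is summarised as four counts
(A, C, G, T) with depth *n*. With parameters (*m*, *k*, *f*, *M*) — minimum
depth, subsample size, required agreement, maximum depth — the rule is: N
when *n* < *m* or *n* > *M*; otherwise, when *n* ≥ *k*, draw *k* reads
uniformly **without replacement** and call the base supported by at least
*f* of them (else N); when *f* ≤ *n* < *k*, use all reads under the same
agreement rule. Defaults are *m* = 2, *k* = 3, *f* = 2, *M* unbounded.

Design points:

* Subsampling is without replacement — each mapped read contributes one
  observation — so the subsample composition is multivariate hypergeometric
  in the stack counts. The implementation draws it with a chained
  vectorised hypergeometric (four sequential conditional draws), which the
  test suite checks against exact *k*-subset enumeration for every stack of
  depth ≤ 8.
* Ties cannot occur when 2*f* > *k* (two bases cannot both reach *f*); for
  parameterisations with 2*f* ≤ *k* a tie conservatively yields N.
* Sites above the depth cap are N even when the call would be
  deterministic: excessive depth flags collapsed repeats and mismapping,
  and the cap is a mask, not a convenience.
* The depth cap is derived from the empirical coverage distribution of
  covered sites: the percentile (default 0.95) is taken as the order
  statistic at 0-based rank ⌈p·(n−1)⌉ (the "higher" convention, so the top
  tail is always excluded), and the cap is the largest integer strictly
  below that value. The published pipeline's exact interpolation rule is
  not documented; this convention is one defensible reading and is pinned
  by tests. A cap below *m* is possible for degenerate depth distributions
  and is reported as a warning by the CLI (which then masks everything
  deeper while keeping the run valid).
* One seeded generator drives a whole run; outputs are byte-reproducible
  at fixed seed.

## The error model

Equal base composition; errors equally likely across all substitution types
(the sequencing-error analogue of the one-parameter JC69 substitution
model). A single global error rate Pg summarises the machine; an error
reports any base with probability Pe = Pg/4 (possibly the original base).
Hence single-read correct-observation probabilities Phom = (1 − Pg) + Pe
and Phet = (1 − Pg) + 2 Pe. The 2-of-3 consensus outcome probabilities
{correct, N, incorrect} come from exact enumeration of the 4³ ordered
triples; the closed forms (e.g. p_error = 3[3Pe²(1−Pe) + Pe³] homozygous,
2[·] heterozygous) are kept in the tests as an independent check on the
enumeration, not used by the implementation.

The fold-reduction in error relative to single-read sampling defaults to
the **per-site** ratio, which is algebraically identical for homozygous and
heterozygous genotypes (both reduce to Pg/(4E), E = 3Pe²(1−Pe) + Pe³); the
implementation asserts that identity against the enumeration at call time.
A `per_called_base=True` variant conditions the consensus error on a call
being made (the consensus can emit N, one random read cannot); the
conditional homozygous ratio agrees with the per-site ratio to well within
two significant figures at realistic error rates (133.5 vs 133.6 at
Pg = 1%), but its heterozygous counterpart drifts as Pg grows because the
no-call probability at heterozygous sites is O(Pe) rather than O(Pe²) —
which is precisely why per-site is the default and the genotype-equality
claim is attached to it.

Minor-allele sampling uses the large-stack binomial model (each of 3
sampled reads carries the allele independently with its stack frequency p),
giving 3p²(1−p) + p³ — 0.352 at p = 0.4 against the single-read comparator
p. A finite-stack hypergeometric variant is exposed for cross-checks
against the caller.

## Alignment reduction and distances

Individual pseudohaploid genomes are stacked per scaffold and every column
with an N in any individual is dropped, so all comparisons share one site
set. Filter order is fixed — missing-data exclusion, variability,
transition/singleton filters — because singleton counts depend on the
surviving columns. The consensus-sequence distance treatment uses all sites
(transitions included); transition and singleton removal exist as options
for comparison with single-read pipelines, not as defaults.

JC69 distances d = −(3/4)·ln(1 − (4/3)p are computed from p-distances;
p ≥ 3/4 is outside the model's range and yields a flagged infinite distance
rather than an exception. Neighbour joining is delegated to scikit-bio's
Saitou–Nei implementation behind this package's interface, with a post-pass
that clamps negative branch lengths to zero and moves the deficit to the
adjacent branch (logged); optional rooting bisects the outgroup's terminal
edge. PCoA is classical metric scaling (scikit-bio), eigenvalues reported
in decreasing order and coordinates restricted to positive-eigenvalue axes.
Both are cross-checked in the tests against additive-matrix exactness,
distance-preservation oracles, and R's ape package.

## D statistic and jackknife

With individuals ordered (((P1, P2), P3), P4-outgroup), the outgroup base
is ancestral; strictly biallelic columns with derived-allele sharing
{P2, P3} count as ABBA and {P1, P3} as BABA; BBAA, private-derived and
multi-state columns are uninformative. D = (nABBA − nBABA)/(nABBA + nBABA).
Transition exclusion is available but off by default for consensus input.

Significance uses a weighted block jackknife over fixed-width windows
(default 5 Mb, anchored at position 1, half-open), blocks weighted by their
informative-site counts. The variance formula is pinned to the delete-m_j
estimator of Busing, Meijer & van der Leeden (1999):

    D_J = g·D − Σ_j (1 − m_j/n)·D_{−j},    h_j = n/m_j
    var = (1/g) Σ_j (h_j·D − (h_j − 1)·D_{−j} − D_J)² / (h_j − 1)

which reduces exactly to the unweighted delete-one jackknife under equal
weights (test-verified). Blocks without informative sites carry no weight
and are dropped; if all delete-one estimates coincide the variance is zero
and the result carries a degenerate-variance flag. |Z| > 3 is the
conventional significance cutoff.

## The simulator

The caller consumes counts, so data are emulated at count level. Per site:
depth ~ Poisson(mean coverage); each read draws its source allele uniformly
from the diploid genotype, then its observed base from the single-read
error model; deamination is a uniform per-read excess probability δ that a
read over a true C reports T (and G reports A). Modelling δ as
position-independent rather than decaying from fragment ends is a stated
simplification: the caller never sees read coordinates, and the downstream
artefact is driven by the asymmetric C→T excess, which is preserved. The
default "ancient" treatment uses δ = 0.1, roughly the read-average of a
0.3-at-the-ends exponentially decaying profile on ~35 bp fragments, with
Pg = 0.001 matching a 0.1% global misincorporation rate.

Quartets (((P1, P2), P3), P4) mutate an ancestral sequence independently
down each branch (substitution probability 1 − exp(−b), new base uniform
over the other three — Jukes–Cantor-consistent), then apply admixture as
instantaneous site replacement of a Bernoulli(α) subset of P2's sites by
P3's state. Individuals are homozygous for their lineage state. There is no
coalescent machinery: ABBA/BABA-informative sites arise from homoplasy and
sequencing error, not incomplete lineage sorting. Default branch lengths
(0.15 terminal, 0.05 internal, 0.2 to P3, 0.3 to the outgroup, on a 1 Mb
genome at 3× coverage) are sized so a replicate yields ≳10⁴ informative
sites, the regime the jackknife calibration experiments assume; they
describe a moderately diverged species quartet, not any particular
empirical system.

What passing tests show — and what they do not: the simulator validates the
calling rule, the analytic error model, the jackknife calibration and the
differential-error artefact *mechanism*. It does not model mapping bias,
fragment-length effects, reference bias, or real demographic history, so
quantitative D values from real palaeogenomes are outside its reach.

## Numerical and scale choices

* Test and example problem sizes (10⁵-site error-model concordance runs,
  1 Mb quartets, 100 kb jackknife blocks, 50-replicate null calibration)
  are chosen as the smallest scales at which the binomial/jackknife
  tolerances are meaningful; the 5 Mb block default remains the
  genome-scale setting.
* Stochastic test tolerances are 3σ for single comparisons and 4.5σ within
  large batteries (≈2.5k comparisons), keeping family-wise false-alarm
  rates negligible without loosening any single check.
* Zero-coverage sites are absent from pos/counts files by construction;
  gzip is detected from magic bytes, never file names; coordinates are
  1-based throughout, matching the pos dialect.

## Known limitations

* Consensus calling preferentially samples the majority allele at
  unbalanced heterozygous stacks (0.352 vs 0.4 above), so it amplifies
  reference bias when mapping to an ingroup reference; mapping to an
  outgroup reference is the recommended usage.
* The error model assumes equal base composition and symmetric errors;
  empirical deamination is neither, and the model is used for expectations
  and validation, not for correcting data.
* At very low coverage (< 2–3×) few sites reach the minimum depth and the
  method's site yield drops sharply; the single-read parameterisation
  (m = k = f = 1) is provided for exactly that regime.
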