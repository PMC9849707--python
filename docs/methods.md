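# Methods

## The resampling test of temporal frequency change

For each haplotype *h* and each non-reference temporal period *p*, the
test asks whether the observed count of *h* in *p* is compatible with
random sampling from the haplotype frequencies of a reference period
(by default the most recent one). The null distribution is
Binomial(*n_p*, *f_h*) with *n_p* the period sample size and *f_h* the
reference-period frequency. `resampling_test` estimates both tail
probabilities, P(X ≤ obs) and P(X ≥ obs), from `replicates` Monte-Carlo
draws (default 100,000 per cell); `exact_test_oracle` computes the same
quantities from the binomial CDF. The two agree to Monte-Carlo error by
construction and the test suite asserts agreement within three standard
errors on every cell of the packaged table.

**Substitute frequency.** A haplotype never seen in the reference sample
has an estimated frequency of zero, under which any later observation
would be impossible. Such haplotypes instead receive the frequency *f*
solving (1 − *f*)^*n_ref* = α, i.e. the frequency at which absence from
a reference sample of size *n_ref* has exactly probability α. For
*n_ref* = 128 and α = 0.05 this is 0.023132. The substitute applies only
to reference-period absences; observed zeros in the tested periods need
no adjustment.

**Tail rules.** "Observed outside 95% of the null mass" is ambiguous for
a discrete distribution, so two readings are implemented.
`two_tailed_2p5` (default) flags a cell when either tail probability is
below α/2. `outside_95_mass` flags an observation outside the
equal-tailed [α/2, 1 − α/2] quantile interval of the null (empirical
quantiles of the draws for the Monte-Carlo test, binomial quantiles for
the oracle). On the packaged table both rules flag the identical seven
cells, so the headline result is insensitive to the choice.

**Size of the test.** Because the null is discrete, the attainable size
of a two-tailed rule is below the nominal α: over the non-substitute
cells of the packaged table the exact size averages ≈1.6% (cell-wise
range 0.2–4.2%) at α = 0.05. The calibration test therefore checks two
things on null-simulated tables: the empirical flag rate never exceeds
α, and it matches the analytically computed attainable size within
Monte-Carlo error. A discrete test cannot be made to reject at exactly
5% without randomised rejection, which would be unreproducible and is
not used.

**Per-cell RNG streams** are derived from (seed, haplotype index, period
index) via numpy's SeedSequence, so results are independent of iteration
order and bit-reproducible.

**Multiple testing.** No per-cell correction is applied; instead
`meta_binomial` treats the cells as independent Bernoulli(α) trials and
reports the expected number of chance significances (n·α) and
P(X ≥ observed) for X ~ Binomial(n, α). The cells are not strictly
independent (counts within a period are multinomially coupled), so the
meta-test is approximate — the same approximation the descriptive
headline makes. An information-only Bonferroni column is written to the
per-cell output.

## Haplotype collapsing and masking

Sequences are collapsed by exact string identity. Under
`gap_fifth_state` the gap character is a fifth symbol, so length
variants are distinct haplotypes (the policy used for network-style
datasets). Under `strict_remove`, any sequence carrying an IUPAC
ambiguity code at a column that is polymorphic among the unambiguous
sequences is excluded, with the offending columns recorded (the policy
used for phylogeny-style datasets). Labels are assigned by decreasing
total frequency with first-occurrence tie-break; historical label maps
can be applied downstream since the catalog is an explicit object.

`mask_unreplicated` implements replicate-aware damage masking for museum
sequence: at a column that is unreplicated for a record and where the
record's base differs from the base shared by all other replicated,
unambiguous records, the base is replaced by the two-state IUPAC code
covering both. Columns that are genuinely polymorphic among the other
records are left alone — a private base there may be a real variant, not
damage. The operation is idempotent and a no-op for fully replicated
records; the replication mask defaults to all-true when the metadata
lacks the column, so modern data pass through unchanged.

**Simple indel coding.** Each distinct maximal gap interval (identical
start and end across sequences) becomes one binary character; a sequence
scores present with exactly that gap, absent with residues in the
interval, and missing when one of its own gaps strictly contains the
interval (the longer deletion makes the shorter event unobservable).
Partially overlapping, non-nested gaps are coded as separate characters
scored absent for each other's carriers — the simple-coding convention;
no attempt is made to infer homology between overlapping gaps.

## The minimum-spanning network

Pairwise distances count differing columns, with '-' a fifth state
(`fifth_state`) or with gapped columns skipped (`ignore`). The network
is the union of all minimum spanning trees of the complete distance
graph, computed by the cycle property: an edge belongs to some MST iff
its endpoints lie in different components of the subgraph of strictly
lighter edges. This is deterministic, order-invariant, and testable
against exhaustive spanning-tree enumeration on small catalogs (the
suite does both). Edges that merely tie an alternative connection are
reported in `tie_edges`. Unobserved intermediate haplotypes appear as
edge weights > 1 rather than as synthetic median nodes, and an optional
maximum connection weight can cut long edges to emulate a connection
limit. No statistical-parsimony connection probability is computed: the
network is used descriptively.

## Rarefaction and diversity

Expected richness at subsample size *m* ≤ *n* uses the hypergeometric
(Hurlbert) form Ŝ(m) = Σ_h [1 − C(n − n_h, m)/C(n, m)], evaluated in
log-space. Extrapolation beyond *n* follows the Chao1-anchored
exponential form Ŝ(n + m*) = S_obs + f̂₀[1 − (1 − f₁/(n f̂₀ + f₁))^m*],
where f̂₀ is the bias-corrected Chao1 estimate of undetected richness
(f₁²/2f₂, or f₁(f₁ − 1)/2 when no doubletons exist). Confidence bounds
are percentile bootstrap over individuals resampled with replacement,
200 replicates by default. Haplotype diversity is the unbiased
h = n/(n − 1)(1 − Σp²); nucleotide diversity π is the mean per-site
pairwise difference weighted by haplotype counts, with gap columns
handled per the chosen gap mode.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with defaults mirroring the motivating study system:

- **census trajectory**: piecewise-linear through (1890, 1000),
  (1985, 140), (2011, 425) — roughly a thousand animals before the
  20th-century crash, a low well under 150 in the mid-1980s, and ~425
  today. Illustrative, not an estimate.
- **female effective size**: census × a single fraction (default 0.25),
  since mtDNA drifts at the number of breeding matrilines and no
  published conversion exists for the system; one transparent knob.
- **generations**: 11 years, a typical phocid generation time; years are
  stepped in whole generations from the first anchor.
- **drift**: haploid Wright–Fisher — each generation's haplotype counts
  are one multinomial draw of size N_f(t) from the previous frequencies.
  The suite checks the closed-form heterozygosity decay
  E[H_t] = H₀(1 − 1/N_f)^t at N_f ∈ {25, 100}.
- **sampling**: per-period multinomial draws at the frequencies of the
  generation nearest the period midpoint, with the five-period grouping
  (1894–1939, 1960–1979, 1980–1989, 1990–1999, 2000–2011) and sample
  sizes (23, 33, 81, 56, 128) as defaults.
- **sequences**: a star genealogy — each haplotype carries an
  independent Poisson number of substitutions (mean 2, minimum 1) on a
  common root of default length 663, with uniqueness enforced; one
  lineage may carry a contiguous deletion (the 64-bp deletion case)
  rendered as '-' columns. Collapsing the emitted alignment recovers the
  simulated truth exactly on clean data, which the suite asserts over
  100 seeds.
- **damage**: each (record, column) independently becomes a two-state
  ambiguity code with a configurable rate and is marked unreplicated,
  mimicking single-read museum miscalls.

What the generator does **not** model: coalescent genealogies (the star
tree has no shared internal branches), recombination, selection,
spatial substructure, recurrent/parallel mutation, or heterogeneous
per-site rates. Passing round-trip tests therefore demonstrates that the
bookkeeping, collapsing, network, and test machinery are correct under
the stated null — not that the pipeline is robust to realistic
genealogical correlation or alignment error in field data.

## Numerical and design notes

- Gap intervals and column indices are half-open 0-based internally;
  user-facing reports print 1-based inclusive coordinates.
- Years in the 1940–1959 gap of the default grouping are legal input;
  such samples are dropped from the count table with a warning, since
  the grouping defines no bin for them.
- Chi-square homogeneity uses the Pearson statistic without continuity
  correction and flags results where more than 20% of expected cells
  fall below 5 (strictly greater than 20%).
- Problem sizes in the test suite (replicate counts, numbers of seeds,
  simulated table counts) are chosen so the entire suite runs in well
  under a minute on one CPU while keeping Monte-Carlo error far below
  the asserted tolerances; the headline resampling comparison still uses
  the full 100,000 replicates per cell.
- Random draws everywhere go through `numpy.random.default_rng` seeded
  from explicit integers; two runs with the same configuration and seed
  produce byte-identical outputs (asserted for the CLI).
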