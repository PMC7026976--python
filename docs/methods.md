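# Methods

## The SPECS statistic

For a feature with observations Y_di (i = 1..n_d) in state d, the score for
state d is the prevalence-weighted exceedance probability

    p̂_d = Σ_{k≠d} P̂_kd · w_k,
    P̂_kd = (1 / n_k n_d) Σ_i Σ_j 1{Y_ki < Y_dj},

the two-sample AUC (Mann–Whitney) statistic aggregated over all off-target
states. Two conventions matter and are fixed throughout the package:

**Strict ties.** The indicator is strict; tied pairs contribute 0, not 0.5.
Consequences: a feature constant across all samples scores 0 for every state,
and a feature that is all-zero in the target state against positive values
elsewhere scores exactly 0 (the "specifically absent" extreme). The flip side
is a systematic downward bias for tie-heavy features: for low-count genes
with many zeros the null score sits below 0.5 (the complement identity
p(A→B) + p(B→A) = 1 − P(tie) loses the tie mass). The permutation-null
center of 0.5 holds for continuous-valued features, and empirically for
counts large enough that ties are rare. This asymmetry is intentional — it
is what makes near-zero noise genes land in the "absent" tail rather than
drifting toward apparent presence.

**Off-target weight renormalization.** The weights w_k are the prevalences
π_k renormalized to sum to 1 over k ≠ d (equilibrated mode: w_k = 1/(m−1)).
Without renormalization the maximum attainable score would be 1 − π_d; with
it, a perfectly separated target group scores exactly 1 for any prevalence
vector, which is the behavior the score's users rely on when thresholding at
0.95. Population prevalences can be supplied to weight specific off-target
states more heavily; equilibrated mode removes the influence of unbalanced
group sizes entirely.

### Fast path

The double sum is never evaluated directly for matrices. For each (k, d)
block the strictly-below count is obtained from min-ranks:
rank_min of Y_dj within the pooled k∪d block equals 1 + #(pooled < Y_dj),
and within the d block alone 1 + #(d-values < Y_dj); the difference counts
exactly the k-values strictly below Y_dj, which is correct under arbitrary
ties. This gives O(m² · G · n log n) for G genes, m states, and is validated
against the brute-force double sum (tolerance 1e−12) in the tests and the
acceptance script. Single-feature calls use sort + binary search instead.

### Classification

Strict thresholds: present when p̂_d > 0.95, absent when p̂_d < 0.05; a
feature crossing a threshold in several states is labelled for all of them
(multi-state specificity). Scores of exactly 0.95/0.05 are deliberately not
labelled. All-zero genes are scored (0 everywhere), never dropped — any
expression filter is the caller's job.

## Comparator metrics

z-score, Gini, Tau, TSI and the JSD score are computed from per-state
arithmetic-mean profiles (replicate collapsing is precisely what these
metrics do; SPECS alone consumes raw replicates). Numerical conventions the
formulas leave open:

- **z-score** uses the sample (n−1) standard deviation by default; `ddof` is
  a parameter. Constant profiles yield NaN for every state.
- **JSD** uses base-2 entropy so the Jensen–Shannon divergence, and hence
  the score 1 − √JS, stays in [0, 1]. The per-state score compares the
  normalized profile with a one-hot reference; the overall specificity is the
  maximum over states. Cross-checked in tests against
  `scipy.spatial.distance.jensenshannon`.
- **Gini** follows the sorted-weights formula (equivalent to the
  mean-absolute-difference form, which the tests use as an independent
  oracle); its one-hot maximum is (n−1)/n, not 1.
- All ratio-based metrics return NaN on all-zero profiles; NaN propagates to
  the metric table and ranks last, never silently zeroed.

## Normalization and background selection

Size factors are DESeq-style median-of-ratios: reference genes are those with
strictly positive counts in every sample; each sample's factor is the median
ratio of its counts to the per-gene geometric means. If no reference gene
exists the function raises rather than falling back to a pseudo-reference
silently. Factors are defined up to the geometric-mean convention, so only
ratios between samples are meaningful invariants. The implementation is
cross-checked against DESeq2's `estimateSizeFactorsForMatrix` in the test
suite.

The benchmark background set is the `size` (default 1000) genes whose overall
mean normalized count lies strictly between the bounds (default 0.1–10,
exclusive — genes at exactly a bound are excluded, an arbitrary but
deterministic choice) with the smallest standard deviation computed across
per-state means. Computing the dispersion on per-state means rather than on
all samples pooled matches the goal of *between-tissue* stability; the
alternative pooled reading would conflate within-tissue noise with
between-tissue drift. Ties break by gene id.

## Spike-in benchmark

Specificity is induced on normalized counts (the scoring substrate) for a
random subset of background genes in one random tissue per cycle:

- **multiply** scales the target block by a factor — zero counts stay zero,
  so residual overlap with other tissues survives moderate factors;
- **add** shifts the block by a constant — a pure location shift that
  removes zeros and preserves the variance.
- **variance inflation** (add mode) maps each targeted entry v to
  m + √f·(v − m) around the post-shift per-gene mean m, clipping at 0 and
  rounding when the input is integral. This multiplies the variance by
  exactly f while preserving the mean; the mechanism is this package's own
  construction, since only the factor range, not the procedure, is specified
  in the literature the benchmark mirrors.

Each metric's scores are converted to ranks over all background genes
(rank 1 = most specific; average ties; NaN last; per-tissue metrics ranked on
the target-state component). Metrics are compared by the summed ranks of the
induced genes across cycles (one-way ANOVA), and by the Spearman correlation
between a gene's rank-sum overlap (sum of the target samples' descending
expression ranks over all samples; minimum n_d(n_d+1)/2 means no overlap)
and its score rank. The correlation is computed within each cycle and
averaged — rank sums from cycles with different target tissues live on
different scales, so pooling them across cycles would corrupt the ordering.

Randomness is driven by a single user seed expanded into independent
per-cycle streams (`numpy.random.SeedSequence.spawn`); identical seeds
reproduce runs bit-for-bit.

## Synthetic data

The generator emulates the statistical shape of the benchmark substrate, not
any real tissue biology: negative-binomial counts with per-gene means drawn
log-uniformly from 0.1–10 (the background-set band), a shared dispersion
α = 0.4 (variance μ + αμ², the strong overdispersion typical of counts
pooled across heterogeneous donors), identical means across groups (no
intrinsic specificity), and 10 groups with sizes log-spaced 11–490 — the
unbalanced design the score must tolerate. A configurable number of
high-mean (100–1000), low-dispersion (α = 0.05) "housekeeping" genes is
appended (default 50): real matrices always contain stable high expressors,
and they provide the all-positive reference genes median-of-ratios
normalization needs. A `scale` factor shrinks the group-size preset for fast
runs; tests and the acceptance script use 5 groups of 11–100 samples,
200-gene backgrounds, 10 induced genes and 3 cycles — the same structure at
desk scale.

What passing tests on this generator do **not** show: behavior under
gene–gene correlation, batch effects, library-composition bias, or real
tissue expression structure. The benchmark claims are qualitative orderings
(which metric tracks overlap, which detects weak additive signal), not
reproductions of any particular dataset's p-values.

## Known limitations

- No post-selection (empirical-Bayes) correction of extreme scores; the
  thresholding is raw.
- The strict-tie convention biases tie-heavy low-count features downward;
  comparisons of SPECS values across features with very different zero
  fractions should be made on ranks, as the benchmark does.
- Scores are O(m²) in the number of states per gene; very large state counts
  (hundreds) will be slow.
- Matrix orientation is fixed genes-in-rows; transposed input is rejected,
  not auto-detected.
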