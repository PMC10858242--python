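# Methods

This note documents the models, estimators, numerical choices and known
limitations of `hlapop`. Notation: a locus has alleles with sample
frequencies `p_i` over `2n` scored gene copies from `n` diploid samples;
`k` is the number of distinct alleles.

## Allele nomenclature and G groups

Allele names are parsed as `LOCUS*F1[:F2[:F3[:F4]]][suffix]`,
case-insensitively and with or without the `HLA-` prefix; leading zeros in
fields are preserved so parsing and formatting round-trip exactly. All
analyses run at two-field resolution; `trim_to_two_fields` keeps the
expression suffix and drops the G flag when truncation removes the
G-bearing third field.

Two comparison rules coexist deliberately:

* **Allele equality** is literal at two-field resolution, including the
  expression suffix (`01:01 ≠ 01:01N`): expression variants are distinct
  products.
* **G-group containment** ignores expression suffixes on both sides: group
  membership encodes identity of the antigen-recognition-site exons, which
  a null variant shares with its expressed counterpart, so a group whose
  listed member is `01:01:02N` still covers a caller's plain `01:01`.

Missing calls are a single distinguished token; the readers map `""`,
`NA`, `-`, `.` onto it. Group definitions are read from the
`hla_nom_g.txt` dialect (three `;`-separated columns, `#` comments; an
empty third column is a lone allele, not a group).

## Consensus calling

`evaluate_tool` scores a caller against the gold standard per locus as
matched / comparable alleles, using the maximum bipartite matching between
the two called and two gold alleles under the match rule (two-field
equality or G-group containment either way). Missing alleles reduce the
comparable denominator (`min(#called non-missing, #gold non-missing)`) and
cannot match; a homozygous gold genotype counts as two comparable alleles.

`combine_by_af` merges two callers' pairs into exactly two alleles:

1. cross-caller agreements (under the match rule) are selected first, the
   more specific name winning when a group name agrees with a plain name;
2. cross-caller pairs sharing the first field but differing at the second
   contribute the member with the higher reference frequency (pairs are
   processed in descending max-AF order when more than one exists);
3. remaining slots fill from unconsumed candidates in descending reference
   AF; ties break toward the designated priority tool, then
   lexicographically;
4. if only one allele was ever selected (single concordant allele), it is
   doubled.

Design choices that were genuinely open: the reference AF of a G-group
candidate is the group name's own entry if the table has one, else the
maximum over the group's two-field members (a group aggregates
indistinguishable alleles); alleles absent from the reference table get
AF 0 so rare or novel alleles stay selectable but rank last; how to fill
the second slot after a first-field match resolves is not dictated by the
rule set, and we fill it by descending AF among what remains; the
priority tool for ties is the caller with the higher standalone accuracy
at that locus. `select_policy` adopts, per locus, whichever of
{tool 1, tool 2, vote} validated best, ties favouring the vote and then
tool order; `apply_policy` dispatches per locus, falling back to the other
caller when one lacks a locus entirely.

## Locus statistics

* Frequencies: `p_i = count_i / 2n`, missing alleles excluded from
  numerator and denominator; homozygotes contribute two copies.
* Heterozygosity: observed = fraction of fully scored genotypes that are
  heterozygous; expected = `1 − Σ p_i²`, also reported with the unbiased
  small-sample factor `2n/(2n−1)` (both emitted).
* **Hardy–Weinberg exact test.** Conditional on the allele counts, the
  probability of a genotype table `{n_ij}` is
  `n! ∏_i n_i! 2^H / ((2n)! ∏_{i≤j} n_ij!)` with `H` the heterozygote
  total. The p-value sums probabilities of tables no more probable than
  observed (tie tolerance 1e-9 relative). For `k = 2`, and for `k = 3`
  with a modest table-count bound (≤ 2·10⁵), the table set is enumerated
  exactly. Otherwise a Markov chain runs on the explicit vector of n
  allele pairs: a step picks two individuals and one gene-copy slot each
  and swaps them. Single swaps leave the uniform distribution over slot
  assignments invariant, and a uniform assignment induces exactly the
  conditional null above, so the always-accepted chain targets the right
  distribution. Defaults: 10⁵ steps after 10⁴ burn-in, seeded; the
  Monte-Carlo standard error comes from 50 batch means, which absorbs the
  chain's autocorrelation. Monomorphic loci short-circuit to p = 1.
* **Ewens–Watterson test.** `F_obs = Σ p_i²` is referred to the neutral
  null conditional on `(2n, k)`, which is free of the diversity parameter
  θ. Null draws use the Feller-coupling representation of the Ewens
  sampling formula: independent indicators `ξ_i ~ Bernoulli(θ/(θ+i−1))`,
  with the allele configuration given exactly by the spacings between
  successive ones (closed at position 2n+1) and `k = Σξ`. Replicates with
  the wrong k are rejected; θ is tuned by Newton iterations on
  `E[K] = Σ θ/(θ+i−1) = k`, which only optimises the acceptance rate. The
  sampler is validated against exact enumeration of the conditional
  configuration distribution at small 2n in the test suite. Reported:
  `E[F]`, `Var[F]`, `Fnd = (F_obs − E[F])/√Var[F]`, and both tail
  probabilities (`Pr(F ≤ F_obs)` small under balancing selection,
  `Pr(F ≥ F_obs)` small under homozygosity excess). Default 10⁵
  replicates keeps the Monte-Carlo error on Fnd near the fourth decimal.
  Degenerate cases: `k = 1` returns F = 1 with no test; `k = 2n` is a
  conditional point mass, so Fnd is undefined (NaN) and both tails are 1.
* Fisher's exact 2×2 test (two-sided, hypergeometric tail sum) backs both
  the per-allele WGS-vs-WES comparison (allele count vs all-other count by
  platform, with per-platform frequencies and their difference) and the
  ROH-stratum homozygosity comparison.

Note the exact tests are discrete: their achievable level at nominal
α = 0.05 is below 0.05 (≈ 0.036 for two equifrequent alleles at n = 50),
which is the correct behaviour of a conservative exact test, not a
calibration defect.

## EM haplotype estimation

Samples missing any requested locus are dropped listwise (count reported).
Each kept genotype expands into its compatible unordered haplotype pairs
(the first heterozygous locus is held fixed, halving the enumeration); a
configurable cap (default 10⁵ pairs total) guards against exponential
blow-up and advises locus subsetting. The E-step distributes each sample's
unit weight over pairs `∝ f(h1)f(h2)` (×2 when distinct); the M-step
renormalises expected counts. Initialisation is the linkage-equilibrium
product of single-locus frequencies with ±5% seeded multiplicative jitter
and 3 restarts (the unjittered product is a saddle point for symmetric
double heterozygotes); the best-likelihood run is kept. Convergence: max
|Δf| < 1e-7 or 1000 iterations; haplotypes below 1e-6 are pruned with
renormalisation between iterations, so the log-likelihood is asserted
non-decreasing up to a 1e-6 relative slack that pruning can introduce.

## Population panels

`harmonize` trims reported names (including G-group names) to two fields
and sums duplicate alleles within a population; populations failing the
`n > 95` or Gold-typing filters are flagged, and dropped only when
filtering is requested. Frequencies are not renormalised after
trim-and-sum: the input rows are already per-study frequencies and
summing preserves their scale.

Pairwise differentiation over a locus set L, for populations with
frequency vectors `p₁, p₂` and sample sizes `n₁, n₂`:

* Gst (uncorrected): `Hs = mean(1 − Σp₁², 1 − Σp₂²)`,
  `Ht = 1 − Σ x̄²` with `x̄ = (p₁+p₂)/2`, aggregated as
  `Σ_L (Ht − Hs) / Σ_L Ht` (sum-of-components, not mean of ratios).
* Corrected Fst: unbiased within-population diversity
  `h_j = 2n_j/(2n_j−1) (1 − Σ p_j²)`, `Hs = (h₁+h₂)/2`,
  `Ht = 1 − Σx̄² + Hs/(4ñ)` with ñ the harmonic mean of n₁, n₂. This is a
  Nei–Chesser-style estimator restricted to what frequency panels contain
  — the observed-heterozygosity term needs genotypes and is omitted — and
  other software's "corrected" variant may differ in that term. The
  corrected numerator can be marginally negative for near-identical
  populations; the final ratio is clamped to [0, 1], so "distance 0"
  includes statistically indistinguishable pairs, whereas uncorrected Gst
  is 0 exactly iff the frequency vectors coincide.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion with deterministic tie-breaking by label order; negative
branch lengths are clamped to zero with the excess moved to the sibling
branch, and the last three nodes join on an unrooted trifurcation.
Additive matrices are recovered exactly. PCA column-centres the frequency
matrix without unit-variance scaling (frequencies share a scale; scaling
would up-weight rare alleles) and fixes each component's sign by making
its largest-magnitude loading positive. The heatmap preparation removes
allele columns with variance < 0.001 (population variance, ddof = 0)
first, then populations whose remaining frequency sum is < 0.9, and
orders rows and columns by average-linkage clustering of Euclidean
distances.

## ROH stratification

The autosomal ROH fraction divides the summed ROH length by the GRCh38
autosome total (2,875,001,522 bp summed over chr1–22, shipped as a
constant; any other build's total can be passed in). 2-means runs on
z-scored (total length, segment count) — the raw scales differ by orders
of magnitude — with 10 seeded restarts; the cluster with the larger mean
total length is labelled high-ROH. The stratum comparison tests each
locus's 2×2 homozygote/heterozygote × stratum table two-sided; the
choice of Fisher's exact test here is this package's own (the underlying
comparison is routinely reported without a named test).

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 570 samples
(WGS fraction 142/570, the rest WES), 8 classical loci with 15 alleles
each, a 36-sample error-free gold subset, and heavy-tailed allele spectra
from a symmetric Dirichlet with concentration 0.5. Haplotypes are pooled
(default 60, Dirichlet(1) weights) with per-locus alleles drawn from the
target spectrum, which induces linkage disequilibrium; each sample draws
two pool haplotypes, and with probability F (per stratum: 0 low, 0.10
high, 30% of samples high) the second copies the first —
identity-by-descent inbreeding. Caller noise corrupts each allele copy
independently at the tool's per-locus rate; the replacement is uniform
over other alleles by default, or directed at the locus's lowest- or
highest-frequency other allele. The directed modes exist because they
bracket the voting strategy's behaviour: miscalls to near-zero-AF alleles
are rescued by AF voting (the vote beats both callers), while miscalls to
the top-AF allele defeat it (the vote inherits the worse caller's
errors); `policy_scenario_config` uses them to construct a cohort whose
best per-locus policy is, by design, vote at A/DRB1 and caller 2 at
B/C/DQB1/DPB1. Caller 2 reports G-group names with configurable
probability (a synthetic group file accompanies the namespace); calls
drop to missing independently. ROH summaries are lognormal per stratum
(means 40 Mb/350 Mb and 25/90 segments, σ = 0.25 log units), separated
far beyond the clustering's resolution limit.

What the generator does **not** emulate: read-level errors (miscalls are
allele-exchangeable, real callers err toward sequence-similar alleles),
recombination or coalescent genealogy (LD comes only from the finite
pool), population substructure, and locus-specific missingness patterns.
Passing tests therefore certify the algorithms and their statistical
calibration, not caller behaviour on real reads.

## Problem sizes in tests and the acceptance script

The suite uses reduced but statistically adequate sizes chosen as such:
HWE Markov-chain cross-checks at 6·10⁴ steps against exact enumeration;
conditional-ESF validation at 2n ≤ 10 by full partition enumeration;
neutral-Fnd calibration at 2n = 60–80 with 20,000-replicate nulls cached
per k; EM recovery at n = 1000 from an 8-haplotype pool; policy-pattern
construction at n = 300 with a 120-sample gold subset (margins large
enough that the pattern is seed-robust). The acceptance script runs the
same computations end to end in well under a minute.

## Known limitations

* Consensus operates strictly at two-field resolution; three/four-field
  and allele-ambiguity (NMDP) inputs are out of scope, as are P-groups.
* The EM estimator returns maximum-likelihood frequencies, not per-sample
  phases, and has no ambiguity-string support.
* The corrected-Fst variant is one member of a family; see above.
* The ROH module consumes per-sample summaries; calling ROH segments from
  variant data is upstream of this package.
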