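# Methods

## Single-sample pathway activity (ssGSEA)

For one sample with N genes, genes are sorted by decreasing expression
(ties broken by stable input order — deterministic, and measure-zero for
continuous data). With rank weight ρ_g = N + 1 − position(g), the score of
gene set S is

    score(S) = Σ_p [ P_in(p) − P_out(p) ],
    P_in(p)  = Σ_{g∈S, pos≤p} ρ_g^α / Σ_{g∈S} ρ_g^α,
    P_out(p) = #{g∉S, pos≤p} / #{g∉S}.

Defaults: α = 0.25 and matrix-wide range normalization (divide all scores
by global max − min) **on**. Neither is dictated by the method's published
uses we target, so both are configurable; they follow the conventional
single-sample enrichment defaults. Normalization is a single global
positive factor, so it can rescale but never re-order within-sample
differences — the pairwise indicators downstream are provably unaffected
(tested, not assumed). Genes missing from the expression matrix are dropped
from a set with a log record; a set retaining fewer than `min_genes` (2)
genes is an error rather than a silent drop.

## Pairwise signatures and the differential screen

Pairs are enumerated for catalog indices i < j (lexicographic), ids written
`"idA-idB"`; pathway ids therefore must not contain `-`. The ordering
indicator maps a tie (MP_i = MP_j) to +1, matching the I(x ≥ 0) convention
of the original formulation. Both the continuous difference and the
indicator are stored, because published coefficient tables are ambiguous
about which representation they apply to.

The screen uses Pearson's chi-square on the 2×2 ordering-by-group table
with **no Yates continuity correction**: the uncorrected test is the one
that reproduces the published worked example (gender counts 288/200 vs
282/205 → p = 0.725) that anchors this implementation. Holm's step-down
adjustment runs across all testable pairs; a pair whose ordering is
constant in every sample (zero column margin) carries no information and is
excluded from the Holm family instead of being assigned p = 1 — including
it would only deflate the correction for real tests. Default flagging
threshold: adjusted p < 0.01.

## Consensus NMF subtyping

Input is the flagged-pair submatrix restricted to case samples, passed
through e^x to make it positive (default representation: continuous
differences; the ±1 indicators are supported and give the two-valued matrix
{e⁻¹, e}). Factorization is multiplicative-update NMF on generalized
KL divergence, the update family whose objective is provably
non-increasing; the per-iteration trace is kept and asserted in tests.
Initialization: W, H ~ i.i.d. Uniform(0,1) × mean(V), floored at 1e-12;
stopping at relative objective change < 1e-6 or 2000 iterations.

Each of `nrun` (default 10) restarts assigns samples to the argmax row of
H; the mean of the run connectivity matrices is the consensus. Per rank k
we report:

- cophenetic correlation between the condensed 1 − consensus distances and
  the cophenetic distances of their average-linkage tree (1.0 when the
  consensus is perfectly hierarchical; defined as 1.0 in the degenerate
  all-equal-distance case),
- dispersion (1/n²) Σ 4(c − ½)² (1.0 iff the consensus is binary),
- mean silhouette of the final assignments on 1 − consensus.

Rank selection: smallest k attaining the maximum cophenetic coefficient,
ties broken by higher dispersion, then higher silhouette, then smaller k.

Final assignments cut the average-linkage tree of 1 − consensus into k
clusters. (The common R implementation reports the best single run's argmax
instead; the consensus-tree cut is the convention of consensus clustering,
is what the silhouette is computed on, and is stable across restarts.)
Labels are canonicalized by decreasing cluster size, so subtype S1 is
always the larger group.

## Hub network

Flagged pairs are unweighted undirected edges (test-statistic magnitudes
are deliberately ignored; maximal clique centrality is topology-only).
Maximal cliques are enumerated exactly with Bron–Kerbosch pivoting — at
most 84 pathway nodes, so worst-case exponential enumeration is a
non-issue. MCC(v) sums (|C|−1)! over maximal cliques containing v; an
isolated node scores 0, and a triangle-free node's score equals its degree.
The hub subnetwork is the induced subgraph on the top-n ranked nodes plus
their first neighbors.

## Risk scoring and training

The score is linear: intercept + Σ coef_i × value_i, values from the
model's representation. Model pair ids are orientation-normalized — a model
entry `B-A` scored against a matrix that stores `A-B` uses the negated row
(for indicators the negation is exact except at ties, which cannot be
reconstructed from the reversed row). The published 13-pair model ships
with intercept 0 and representation "continuous"; the source formula calls
the signature an "activity", but the discrete reading is supported by a
flag rather than guessed away.

Training interprets "repeated selection" as bootstrap resampling of the
stratified 70% training split: each of `n_iter` (default 1000) resamples is
fit with L1-penalized logistic regression, the penalty chosen by internal
stratified cross-validation (default 10-fold) at minimum CV deviance; pairs
with nonzero coefficients in ≥ `freq_threshold` (default 0.8) of resamples
form the final set, refit once on the full training split. The fitted
intercept is reported separately so the intercept-free published form stays
reproducible; AUC is intercept-invariant. A bootstrap draw that loses a
class is redrawn (up to 10 times, logged). If no pair survives selection
the model is empty and scores every sample 0 — the honest null, which
evaluates to AUC 0.5.

## Evaluation

AUC is the Mann–Whitney rank statistic with half credit for ties; its 95%
CI uses DeLong's structural-components estimator (deterministic, standard;
published intervals we compare against may use other methods, so the CI
method is a documented choice, not a claim of equivalence).
Threshold-dependent metrics (recall/precision/F1) use the Youden-optimal
threshold estimated on training scores only. Cross-validation is
stratified k-fold with per-repeat pooling; samples are put in canonical
(sorted-id) order before splitting so fold assignment is invariant to input
column order given the seed.

## Synthetic worlds

The generator draws log-scale expression from an additive Gaussian model:
gene baseline μ_g ~ N(μ0, σ0²), plus the pathway-arm shifts of an effect
table, plus optional batch intercepts, plus N(0, σ²) noise. Pathways occupy
disjoint gene blocks. Defaults: μ0 = 6, σ0 = 1 (log2-microarray-like),
σ = 0.5, 10 pathways × 30 genes + 300 background genes, 60 controls and
40 + 30 cases split into subtypes S1/S2 — sized for seconds-scale tests
with stable contingency counts. Effects may target the case group, one
subtype, or the control group; the control arm is needed to plant a genuine
ordering *flip* (pathway above its peers in controls, below them in cases),
since an unshifted pair ordering is a coin flip driven by baseline noise.

A pair is a ground-truth pair when its planted ordering contrast — the
case-vs-control difference of (shift_i − shift_j), cases averaging the two
subtypes by size — is nonzero. Four frozen scenario presets state the
worlds used for validation: a null world (no effects), a flip world (±1.0 =
2σ on one pathway), a subtype world (opposing ±1.5 = 3σ shifts on two
pathways between S1 and S2), and a classification world (+1.0 = 2σ
case-only shifts on five pathways).

What a green recovery test establishes — and what it does not: the additive
Gaussian model carries the assumed structure (pathway-coherent shifts,
rank-stable orderings) but none of the messiness of real cohorts:
no probe-level artifacts, no heavy-tailed or count noise, no correlated
background genes, no overlapping pathway membership, and batch effects only
as optional intercepts with no correction implemented. Recovery on these
worlds validates the statistics' implementation, not their field
performance.

Null calibration runs the full activity → pairs → screen chain on
replicated null cohorts and reports the pooled fraction of raw p < α
(per-test type-I error) and the fraction of replicates with any
Holm-adjusted p < threshold (familywise error).

## Numerical and scale choices

- Chi-square and Holm go through scipy/statsmodels; hand-computed values
  remain the test oracles.
- NMF floors W, H at 1e-12; KL terms with V = 0 contribute only +WH.
- Acceptance-scale reductions for runtime: recovery tests use 20 bootstrap
  training iterations (not the production default of 1000 — the selection
  frequencies are coarser but the planted signal is strong), NMF rank
  search 2–4, and 50 null replicates. These reduce Monte-Carlo resolution,
  not the tested logic.
- All randomness flows from explicit integer seeds; substreams derive from
  `numpy.random.SeedSequence(entropy=seed, spawn_key=...)`.

## Known limitations

- ssGSEA is the only activity kernel; no permutation significance of
  single-set scores.
- The screen is the count test only (no Fisher exact or continuous-valued
  alternatives).
- The classifier interface is pluggable but only L1-logistic is shipped.
- Published cohort-level numbers (significant-pair counts, cohort AUCs)
  depend on data this package does not download and are not reproduction
  targets.
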