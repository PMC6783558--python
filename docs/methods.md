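# Methods

This note records the models, estimators, numerical choices and known
limitations behind `ripresil`, in the order the pipeline applies them.

## Study design assumed by the package

All analyses assume a space-for-time design: each sample belongs to one
study area and to exactly one of three disturbance groups (reference,
flooding, recovery). Group membership is a metadata fact supplied by the
user — typically assigned from elevation relative to the water level
(never-flooded sites are reference; sites below water at sampling are
flooding; previously flooded, re-exposed sites are recovery). The package
validates the labels case-insensitively and requires every analysed sample
to carry a metadata row. Time is collapsed into the three groups; the
package does not model multi-timepoint recovery trajectories.

## Resistance and resilience indices

For a per-sample variable x, group means are unweighted arithmetic means
over the samples in (area, group). With C₀, P₀, Pₓ the reference,
flooding and recovery means and Cₓ = C₀ (the space-for-time convention:
the unflooded reference sites stand in for the undisturbed state at both
times),

    RS = 1 − 2|C₀ − P₀| / (C₀ + |C₀ − P₀|)
    RL = 2|C₀ − P₀| / (|C₀ − P₀| + |Cₓ − Pₓ|) − 1.

Properties the tests verify: both indices lie in [−1, +1]; RS = +1 iff
P₀ = C₀; RS is strictly decreasing in the displacement |C₀ − P₀| and tends
to −1 as the disturbed value diverges; RL = +1 iff Pₓ = C₀ given a nonzero
displacement; both are invariant to rescaling (C₀, P₀, Pₓ) by any k > 0,
which justifies applying them to copy numbers and proportions alike.

Degenerate cases, decided here and flagged at run time:

- C₀ = P₀ = 0 → RS = 1 (nothing changed), with a logged note;
- C₀ = P₀ → RL is *undefined* and reported as NA, rather than the raw
  formula's limit of −1: without displacement, "recovery" has no meaning.

Report tables round both indices to 2 decimal places; full precision is
kept internally. Because published tables are typically computed from
unrounded group means, re-deriving an index from the *rounded* printed
means can differ in the second decimal (e.g. printed means of
8.6×10⁸/1.9×10⁹ give RS = −0.095 where the source data rounded to −0.10);
agreement is therefore asserted at rounded precision only.

Taxon-level indices use relative abundances (consistent with how taxon
results are quoted as percentages); diversity indices are computed on the
rarefied table, matching the rarefaction-first workflow.

## Rarefaction and alpha diversity

Rarefaction draws, for each sample, a multivariate-hypergeometric
subsample (without replacement) to a common depth — by default the
shallowest sample's total. A single draw with a fixed seed is used (an
optional iteration grid supports rarefaction curves); the per-taxon
expectation is the hypergeometric mean, which a Monte-Carlo test checks.
Samples shallower than the target raise an error unless `drop_shallow`
removes them with a logged warning.

Alpha diversity follows the standard definitions: Shannon H = −Σ pᵢ ln pᵢ
(natural log by default, base configurable), bias-corrected Chao1
S_obs + F₁(F₁−1)/(2(F₂+1)) (classic F₁²/(2F₂) form by flag; the corrected
form is defined at F₂ = 0), and Pielou evenness H / ln S_obs, undefined
(NaN) for single-taxon samples. Bray–Curtis dissimilarity is
1 − 2Σmin(Aᵢ,Bᵢ)/(ΣA+ΣB), clipped to [0, 1] against floating-point
round-off.

## Group comparisons

ANOSIM is implemented from scratch: all n(n−1)/2 pairwise distances are
ranked with average ranks on ties, and R = (r̄_between − r̄_within) /
(n(n−1)/4). Significance is a one-sided label-permutation test (large R =
separation) with the +1 convention p = (1 + #{R_perm ≥ R_obs}) / (1 + N),
which never returns 0 and is bounded below by 1/(N+1); N defaults to 999
with an explicit seed. Pairwise group comparisons subset the precomputed
distance matrix rather than recomputing distances per pair — the rank
structure differs from recomputation only through the excluded pairs, and
subsetting keeps the pairwise tests consistent with the full-matrix
distances.

Kruskal–Wallis (tie-corrected H, chi-square p on k−1 df) and Mann–Whitney
U (two-sided; the smaller of the two U statistics is reported) are
delegated to scipy.stats behind the module interface. Exact Mann–Whitney
enumeration is used when n_a·n_b ≤ 400 and the pooled data are tie-free;
with ties the tie- and continuity-corrected normal approximation is used
at any size, since exact enumeration is not defined under ties. The
all-values-identical corner returns H = 0, p = 1. No multiple-testing
correction is applied by default; a Benjamini–Hochberg adjustment can be
applied by the user downstream (statsmodels' `multipletests` works
directly on the output columns).

## Co-occurrence networks

Correlations are Spearman's ρ computed as Pearson on average-ranked data,
with a two-sided p from the t approximation on n−2 df. Taxa constant
across the selected samples have undefined correlations; they are emitted
as NaN with a warning and never form edges. An edge joins taxa i, j iff
|ρᵢⱼ| > 0.6 AND pᵢⱼ < 0.01 — strict inequalities on both thresholds.
Nodes without edges stay in the node set flagged `isolated` (a
`drop_isolated` view supports the convention that counts only connected
nodes). Node selection before correlation is prevalence-based (detected
in ≥ 1/3 of samples by default, plus an optional mean-relative-abundance
floor); the filter is fully configurable because no single convention
exists for which genera enter a network.

Topology: avgK = 2E/N; average path length and diameter are computed on
the largest connected component of the unweighted graph (thresholded
networks are routinely disconnected); the clustering coefficient is the
mean local coefficient with degree-<2 nodes contributing 0; modularity is
the best Louvain Q on the sign-ignored, unweighted graph with a fixed
seed (negative-edge-aware modularity is out of scope). Exports: GEXF,
GraphML (node attributes phylum/degree, edge attributes rho/p/sign) and a
plain edge-list TSV.

Plain Spearman correlation on relative abundances is used deliberately —
compositionality-aware estimators (SparCC-style) are a different method
family and out of scope — so the closure-induced coupling discussed below
applies to real analyses as much as to the generator.

## Synthetic data generator

The generator emulates the two-area, three-group design: areas NA and AA,
4/13/7 reference/flooding/recovery samples per area, 24 archaeal genera,
and fixed-depth counts at 20,826 reads per sample (every column sums to
the depth exactly).

Mechanism, per sample:

1. expected genus proportions = shared rank-abundance baseline
   (exp(−0.45·rank), dominant genus ≈ 0.36) times (area, group) fold
   changes, renormalised;
2. per-genus log-normal perturbation exp(σz − σ²/2) with σ = 0.3 by
   default; planted genus pairs share a latent factor with loading λ
   (default 0.8), giving latent correlation ±λ²;
3. counts ~ Multinomial(depth, renormalised perturbed proportions);
4. total abundance ~ log-normal with the configured (area, group) mean
   and CV (default 0.5).

Every sample draws from its own deterministic substream of the global
seed, so datasets are bit-reproducible and insensitive to generation
order. Ground truth (expected RS/RL per variable and area, planted
correlation signs) is pure arithmetic on the configured means — no
sampling.

Default effect sizes encode the study motif: methanogen genera ×10 and
ammonia oxidisers ×0.08 under flooding in both areas; recovery returns
close to baseline in NA (×2 / ×0.8) but stays displaced in AA (×5 /
×0.3). Default abundance means are the published group means
(NA 8.6×10⁸ / 1.9×10⁹ / 4.6×10⁸; AA 3.2×10⁸ / 1.2×10⁹ / 2.1×10⁸
copies/g). The genus log-sd default of 0.3 keeps the logistic-normal
closure bias on group-mean proportions small (the renormalisation makes
E[xᵢ/Σx] differ from the configured pᵢ by a factor ≈ 1 − (e^{σ²}−1)(pᵢ −
Σp²); at σ = 0.3 this is under one percentage point for the dominant
genus), so the analytic ground truth is a faithful target. The abundance
CV default of 0.5 is a choice in the realistic range for qPCR copy
numbers across field replicates.

What the generator does *not* emulate: sequencing-read error, chimeras,
PCR bias, overdispersion beyond the logistic-normal, spatial
autocorrelation along the elevation transect, and genuinely sparse
zero-inflated taxa. Passing tests therefore demonstrate correctness of
the estimators under a clean compositional model, not robustness to those
artefacts.

Detectability of planted correlations has two intrinsic limits worth
knowing when designing benchmarks with it. First, group fold-changes
induce strong common variation across mixed-group samples (every genus's
proportion moves when the methanogens bloom), which can dominate a latent
planted factor; planting is therefore best validated with group effects
silenced. Second, a genus drawing only a handful of reads per sample
cannot express a rank correlation — multinomial noise attenuates the
latent signal roughly by var_latent/(var_latent + var_counting) — so
plants belong on genera with tens of reads or more at the chosen depth.
The test suite's planted-recovery checks follow both rules, and the
network-recovery fixture uses loading 0.95 with ~100 samples so the
planted latent correlation clears the |ρ| > 0.6 edge threshold with
margin.

## Pipeline and reproducibility

`run_pipeline` composes: load (or simulate) → rarefy → alpha diversity →
per-area RS/RL (total abundance, Shannon, Chao1, evenness, and the k = 4
most abundant taxa by mean relative abundance) → per-area pairwise ANOSIM
(3 comparisons for 3 groups) → per-area genus network + topology. One
global seed deterministically derives the rarefaction, permutation and
modularity seeds; the manifest records them with all thresholds and
input/output checksums. Two runs from the same config and seed produce
byte-identical tables (the GEXF format embeds a last-modified date and is
excluded from checksum comparison). Any stage failure aborts with the
stage name and the offending entity.

Problem sizes used by the test suite and acceptance script are chosen to
keep the full run in the tens-of-seconds range: the parameter-recovery
checks scale the 4/13/7 design by ×20 and average estimates over five
replicate datasets (the mean over replicates is the quantity that
converges; a single draw retains sampling noise comparable to the 0.05
tolerance), the ANOSIM oracle compares exhaustive enumeration over all
720 label orders of a 6-sample toy with a 10⁵-draw Monte-Carlo estimate,
and pipeline tests run at reduced depth and 99–199 permutations.
Statistical conclusions are unchanged at larger sizes.

## Known limitations

- RS/RL are mean-based; no uncertainty (bootstrap/jackknife) is attached
  to the indices.
- ANOSIM assumes exchangeability of samples under the null; transect
  autocorrelation would inflate significance, as in any field design.
- Spearman networks inherit compositional closure effects; edge signs
  between dominant taxa should be interpreted with that in mind.
- The BIOM reader covers the JSON dialect only (HDF5 BIOM is out of
  scope).
- Louvain modularity is stochastic across seeds; the seed is fixed and
  the observed cross-seed spread on fixtures is < 0.05, but Q is not a
  deterministic functional of the graph.
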