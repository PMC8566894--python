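# Methods

`commassembly` implements the standard inference stack for partitioning
microbial community assembly into stochastic and deterministic processes,
together with a generative model of communities whose assembly regime is
known exactly. This note records the models, the parameter choices that
matter, and the design decisions taken where the methods literature leaves
room.

## The generative model

All validation rests on synthetic communities with ground truth, emulating
the statistical structure of a marker-gene survey (on the order of 100–200
OTUs after clustering, samples rarefied to a common read depth, strong
dominance by a few taxa).

**Metacommunity.** Regional relative abundances γ are lognormal,
`γ_i ∝ exp(N(0, σ_ln²))`, normalised. Default `σ_ln = 2.0`: amplicon
communities of a single functional guild are strongly dominance-skewed, and
this value gives per-sample richness around 30–60 % of the regional pool at
the default read depth — the occupancy structure the null models are
typically applied to. (At σ_ln ≤ 1.5 nearly every taxon occurs in nearly
every sample, which no marker-gene survey looks like.)

**Phylogeny and niche trait.** A pure-birth (Yule) tree with unit birth
rate; a niche-optimum trait evolves along it by Brownian motion with rate
`σ²_BM = 1` from a root value placed at the centre of the environmental
axis. BM is the calibration model of Blomberg's K (expected K = 1), so
selection on this trait leaves a phylogenetically structured footprint.

**Neutral local communities.** A Moran death–replacement process: a
community of fixed size `N` (default 1000) is initialised as a multinomial
draw from γ; each of `generations × N` steps (default 50 generations) kills
one uniformly chosen individual and replaces it with an immigrant drawn
from γ with probability `m`, otherwise with the offspring of a uniformly
chosen surviving local individual. This is exactly the birth–death process
whose stationary abundance distribution the Sloan model approximates.

**Selected local communities.** Gaussian environmental filtering:
sampling weight `w_i = γ_i · exp(−(t_i − env)² / 2σ_w²)` with niche
optimum `t_i` and breadth `σ_w`.

* *Variable selection*: two equal sample groups at optima `t̄ ± 2·sd(t)`,
  each sample a multinomial draw from the filtered weights.
* *Homogeneous selection*: one optimum (the trait mean) for all samples,
  but each sample is a **Moran community drifting on the filtered
  metacommunity** (immigration `m` from the filtered pool) rather than a
  fresh multinomial draw. This matters: with deterministic filtering, any
  two samples share the same dominant taxa, and shared taxa contribute
  zero to βMNTD under both the observed data and the tip-shuffling null
  (their nearest neighbour in the other sample is themselves). The
  footprint homogeneous selection leaves in real data — samples dominated
  by *different but closely related* members of the favoured clade — only
  appears when local drift can act within the filtered pool.
* Both selection regimes mix in a fraction `background_m` (default 0.05)
  of individuals drawn from the **unfiltered** metacommunity. Real surveys
  contain maladapted immigrants at low abundance; without them, strong
  selection leaves only the selected clade in the observed matrix, the
  null model's regional pool is itself phylogenetically clustered, and
  homogeneous selection becomes undetectable in principle.

**Sequencing.** Multinomial subsampling of each community to a fixed read
depth (default 1000) — reads with replacement, distinct from rarefaction
(without replacement, multivariate hypergeometric).

What the generator does **not** emulate: spatially explicit dispersal,
temporal autocorrelation, PCR/primer bias, chimeras and clustering
artefacts, overdispersed (beyond-multinomial) sequencing noise. Passing
calibrations therefore demonstrate correctness of the inference machinery
under the stated assembly models, not robustness to these artefacts.

## Neutral community model

Occurrence frequency is predicted from metacommunity mean relative
abundance as `freq(p) = 1 − I_d(Nm·p, Nm·(1−p))` (regularised incomplete
beta function; detection limit `d`, default one read, `1/N̄`). `Nm` is
estimated by bounded nonlinear least squares on (p, freq) points
(`Nm ∈ (10⁻³, 10·N̄]`, optimised in log space); `R²` is computed about the
mean observed frequency.

**Migration probability.** The per-death immigration probability is
reported as `m = Nm / (N̄ − 1 + Nm)`, inverting the Moran/Hubbell
correspondence `I = m(N−1)/(1−m)` between the fitted beta-scale parameter
and the mechanistic immigration probability. The widely used `Nm/N̄`
(reported as `m_sloan`) coincides with it for small m but exceeds 1 on
strongly immigration-dominated data; on Moran simulations with
`m_true = 0.5, N = 1000` the corrected form recovers 0.49–0.55 across
seeds while `Nm/N̄` gives ≈ 1.0–1.3.

**Taxon partition.** A taxon is `within` the neutral expectation when the
predicted frequency falls inside the 95 % Wilson score interval computed
from its observed frequency (n = number of samples); `above`/`below`
otherwise. The interval is computed from the observed, not the predicted,
frequency: a band centred on the prediction collapses at the boundaries
(a taxon predicted at 0.9996 is observed at exactly 150/150 and would be
misclassified), under-covering badly (≈ 0.74 measured vs 0.95 nominal),
whereas the inverted form achieves 0.95–0.97 coverage on self-consistent
data.

## βMNTD, βNTI, RC_Bray and process classification

βMNTD between samples k, l is the abundance-weighted mean distance from
each taxon to its nearest taxon in the other sample,
`½[Σ_i f_ik·min_j d_ij + Σ_j f_jl·min_i d_ij]`, with patristic distances
d. Abundance weighting is the default (uniform weights over present taxa
behind a flag). Agreement with `picante::comdistnt` is exact (both
variants, cross-checked during development and frozen into tests).

βNTI standardises βMNTD against a null that permutes taxon labels across
the distance matrix of the **whole regional pool** (all taxa present in
the matrix), 999 randomisations by default. Pairs whose null has zero
variance (e.g. samples with identical taxon sets) are reported NaN,
counted, and excluded from fractions.

RC_Bray compares observed Bray–Curtis with nulls that preserve each
sample's richness and total count: taxa drawn without replacement with
probability ∝ regional occurrence frequency (Gumbel top-k), one read
seated per drawn taxon, the remainder allocated multinomially ∝ regional
relative abundance. Seating one read preserves realized richness, the
standard Raup–Crick convention. Null realizations are generated **per
sample** (999 each) and paired i-with-i across samples — distributionally
identical to per-pair generation because realizations are independent, at
O(S·n) rather than O(S²·n) cost. `RC = 2·[(#null < obs) + ½(#null = obs)]/n − 1`,
ties at half weight (tolerance 10⁻¹²).

Classification per pair: βNTI > +2 → variable selection; βNTI < −2 →
homogeneous selection; otherwise RC > +0.95 → dispersal limitation;
RC < −0.95 → homogenizing dispersal; else undominated. Thresholds are
strict inequalities; fractions are computed over defined pairs and sum
to 1.

## Normalized stochasticity ratio

Two null algorithms mirror the two metric families:
`incidence_prop_fixed` (fix richness, presence ∝ occurrence frequency) and
`abundance_prop_prop` (additionally fix totals, allocate ∝ regional
abundance). For each pair, with observed dissimilarity D and null
expectation Ē (mean over 999 randomisations), the normalized selection
strength is `(D−Ē)/(1−Ē)` when D ≥ Ē and `(Ē−D)/Ē` otherwise (bounds
D_max = 1, D_min = 0; the 0/0 cases at Ē ∈ {0,1} resolve to 0 and are
logged). `NST = 1 − mean(NSS)` over within-group pairs; 50 % is the
stochastic/deterministic boundary. The "permutation distribution" reported
as mean ± sd contains one NST value per randomisation, obtained by using
that single randomisation's dissimilarities as the expectation — the
convention behind table-style ± values; it quantifies null-model spread,
not sampling error of the data.

The group comparison (`nst_panova`) holds per-pair D and Ē fixed, permutes
group labels, and re-partitions pairs; the statistic is |NST_A − NST_B|
and `p = (1 + #{perm ≥ obs})/(1 + n_perm)`. Type-I error measured at
0.05–0.07 at α = 0.05 over 200 identical-pool replicates.

Two properties of the mean-based NSS normalisation are worth knowing.
First, downward deviations are divided by Ē, so when Ē is small the
statistic is harsh on below-expectation pairs; the fully-stochastic limit
NST → 1 is reached only when the null dissimilarity distribution is tight
relative to Ē and 1−Ē (many taxa, dense occupancy). Second, when extreme
dominance makes the null presence-draw bimodal (the dominant taxon in or
out), every single draw is far from the mean Ē and NST is depressed even
for data generated by the null itself. The self-null calibration is
therefore run in a dense-occupancy configuration (12 samples × 100 taxa,
σ_ln = 0.6, depth 5000), where it yields NST ≥ 0.93 for both metric
families.

## Phylogenetic signal

A taxon's realized niche is its abundance-weighted mean environment,
`t_i = Σ_s (x_is/Σ_s' x_is') · env_s`. Blomberg's K uses the BM tip
covariance matrix V: `K = (MSE0/MSE) · (n−1)/(tr V − n/(1ᵀV⁻¹1))` with the
GLS root estimate â; agreement with `picante::Kcalc` to 7+ digits (frozen
oracles). Exactly constant traits return K = 0 with a warning.
Significance is one-sided on the variance of phylogenetically independent
contrasts against tip reshuffles (999 by default; contrasts are pruned for
all permutations in one vectorised pass; `p = (1+#{null ≤ obs})/(1+n_perm)`).
PIC requires a bifurcating tree; polytomies raise an error rather than
being silently resolved. On a 64-tip Yule tree, mean K over 200 BM
replicates is 0.97–1.06, BM traits are detected ≥ 95 % of the time, and
tip-shuffled traits are rejected at ≈ 5 %.

## Diversity indices and dissimilarities

Alpha: richness, bias-corrected Chao1, ACE (rare cutoff 10; when every
rare taxon is a singleton ACE is undefined and bias-corrected Chao1 is
substituted, the EstimateS recommendation), Shannon in nats (so Pielou
J = H/ln S), Gini–Simpson `1 − Σp²` ("Simpson diversity" is ambiguous in
the literature; the complement form is the common ecology-package
default). Dissimilarities are the [0,1]-bounded family required by the
stochasticity normalisation: Bray–Curtis, quantitative Jaccard (Ružička,
`2B/(1+B)`; classical `(b+c)/(a+b+c)` for incidence), Kulczynski,
Canberra (averaged over taxa present in at least one sample of the pair),
range-standardised Gower and maximum-standardised Manhattan (per-taxon
across-sample range/maximum as divisor, zero-range taxa contribute 0 —
the names alone do not fix a scaling, and NST needs bounded metrics).

## Drivers

Mantel (Spearman or Pearson, two-sided on |r|) and one-way PERMANOVA
(pseudo-F, label permutation) are delegated to scikit-bio; both honour the
permutation floor `1/(n_perm+1)` and were calibrated here (type-I 0.03–0.06
at α = 0.05 over 500 null replicates). The co-occurrence network computes
Spearman correlations among taxa with total count > 10 and numeric
environmental variables, keeping edges with |r| > 0.5 and raw p < 0.05
(two-sided t-approximation). No multiple-testing correction by default —
the raw-p rule is the common field practice and is kept for comparability,
with a Benjamini–Hochberg flag available; note that over thousands of
pairs the raw rule admits spurious edges at roughly the nominal rate.
Betweenness is reported unnormalized; closeness and eigenvector centrality
are computed within connected components (isolated nodes get 0).

## Orchestration, seeds, problem sizes

The pipeline fans a single global seed out per stage via CRC32 of the
stage name (`(seed ^ crc32(stage)) & 0x7fffffff`), so stages can be rerun
in isolation and a full run is byte-reproducible. Defaults mirror standard
practice: 999 nulls/permutations for βNTI, RC, NST and the signal test,
9999 PERMANOVA permutations, thresholds ±2 (βNTI), ±0.95 (RC), 0.5 (NST),
|r| > 0.5 & p < 0.05 (network).

Calibration problem sizes were chosen so each check has clear resolution
at desk scale: 150 samples × 500 taxa for neutral-model self-consistency,
150 Moran communities of N = 1000 for mechanistic recovery, 20 samples ×
100 taxa with 999 nulls for the βNTI/RC calibrations, 200 replicates for
rejection-rate estimates. The high-immigration ("homogenizing dispersal")
condition uses N = 5000 and depth 250: a large local community suppresses
drift so replicates are near-identical, and the moderate depth keeps
per-sample richness well below the pool size, which is where the
Raup–Crick null has discriminating variance.

## Known limitations

* The Moran simulator is O(generations × N) per sample; very large
  communities (N ≫ 10⁵) are slow in pure Python.
* RC_Bray holds all per-sample null realizations in memory
  (S × n_null × T); hundreds of samples with 999 nulls need ~1 GB.
* βNTI's tip-shuffling null assumes the regional pool spans the tree;
  datasets consisting of a single selected clade (no immigrants) yield
  near-zero signal by construction — a property of the method, not of
  this implementation.
* The NST normalisation is convention-dependent (documented above);
  absolute NST values should be compared only within a convention.
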