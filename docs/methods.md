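# Methods

This note documents the statistical procedures `riverwq` implements, the
assumptions behind them, the defaults it ships, and what its synthetic
test data can and cannot demonstrate.

## Monitoring data model

All stages operate on a samples × parameters matrix, one row per
(site, date), over the fixed 11-parameter vocabulary pH, WT (°C), DO
(mg/L), EC (µS/cm), TSS (mg/L), TP (µg/L), TN (mg/L), BOD (mg/L), COD
(mg/L), CHL-a (µg/L), TCB (MPN/100 mL). Two unit conventions matter:

- TP is carried in µg/L and TN in mg/L, so the TN/TP mass ratio is
  formed after converting TN to µg/L. A ratio above 20 is read as
  phosphorus limitation of algal growth.
- TCB is a count (most probable number per 100 mL) and is treated as a
  concentration-like abundance everywhere.

Calendar months drive the monsoon stratification: January–June is
premonsoon, July–August monsoon, September–December postmonsoon. Weir
periods default to pre-weir ≤ 2011-12-31 and post-weir ≥ 2013-01-01,
with the construction year between them labelled "transition" and
excluded from pre/post contrasts by default, because impoundment and
treatment-plant upgrades were commissioned in the same year and cannot
be separated. Both boundaries are configurable.

Duplicate (site, date, parameter) observations are averaged rather than
rejected — monthly replicates are common in agency exports — and gaps
are carried as missing values with per-stage handling (listwise deletion
for factor analysis and DA, pairwise-complete pairs for correlation
networks, renormalised weights for the WQI).

## Water Quality Index

The weighted-arithmetic index uses unit weights W_n = K/S_n with
K = 1/Σ(1/S_n), sub-indices Q_n = (V_n − V_0)/(S_n − V_0)·100 and
WQI = ΣW_nQ_n/ΣW_n. Ideal values V_0 are zero except pH (7) and DO
(14.6 mg/L, saturation); for DO the denominator is negative, so
sub-saturation oxygen correctly raises the index. WT is excluded.

The standards table S_n is an explicit, editable configuration. The
shipped defaults (pH 8.5, DO 5, EC 300, TSS 25, TP 100, TN 1.5, BOD 5,
COD 7, CHL-a 30, TCB 5000, in parameter units) are assembled from the
same pollution-screening thresholds used by the classification module;
they are a documented stand-in, not a regulatory table, and any
jurisdictional table can be supplied instead. Missing parameters
renormalise the weights over the present set, which keeps the unity
constraint meaningful per sample at the cost of comparability between
samples with different coverage. Band edges are closed on the upper
edge: 0–25 excellent, >25–50 good, >50–75 poor, >75–100 very poor,
>100 unsuitable.

## Receptor model (PMF)

The receptor model factorises X ≈ GF with G ≥ 0 (samples × p source
contributions) and F ≥ 0 (p × parameters source profiles) by minimising
Q = Σ[(x_ij − Σ_k g_ik f_kj)/u_ij]². Uncertainties follow the standard
convention u = sqrt((EF·x)² + (0.5·MDL)²) above the detection limit and
u = (5/6)·MDL below it. Defaults: error fraction EF = 0.1 for every
parameter and MDL = 1% of the parameter's median, both overridable per
parameter; runs should state these explicitly since apportionment is
sensitive to relative weighting.

The minimiser is three-phase, and Q is non-increasing throughout:

1. multiplicative updates for weighted non-negative factorisation
   (weights 1/u²), run from seeded random starts (default 10) until the
   relative drop in Q falls below 1e-9 or 2000 iterations;
2. exact alternating weighted-NNLS sweeps (each row of G, then each
   column of F, solved to optimality), which tighten convergence where
   multiplicative updates slow to a crawl;
3. a single joint bounded trust-region (Gauss–Newton with analytic
   sparse Jacobian) polish of the best start, which finishes the descent
   — alternating schemes converge only linearly and stall many orders
   of magnitude above the attainable optimum on exactly factorable
   data.

Scale indeterminacy is resolved by normalising each factor to mean
contribution 1 over samples, pushing units into F so f_kj reads directly
as the mean concentration of parameter j attributed to source k; factor
order is total explained concentration, descending, which makes output
deterministic. The apportionment table reports, per parameter, each
factor's mean concentration contribution (mean over samples of
g_ik·f_kj), its percentage share (rows sum to 100), and the R² between
observed and reconstructed series as a per-variable fit diagnostic.

pH is excluded from the fit by default (bounded, non-extensive; a
logarithmic acidity measure has no source-mixture semantics). DO can be
excluded the same way; it is kept by default so its typically poor R²
remains visible as a diagnostic. Multi-start matters in practice:
on noisy data distinct local minima with nearly equal Q can differ
visibly in profile geometry, and five or more starts are recommended
for production fits.

## Mann–Kendall trend test

S = Σ_{i<j} sgn(x_j − x_i) with the tie-corrected variance
Var(S) = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18 and the classical
continuity correction Z = (S∓1)/√Var(S). Series shorter than 4 are
rejected, and below 8 a warning flags the rough normal approximation.
Monthly per-site series are the default granularity; annual means are a
flag. No multiple-testing correction is applied by default when many
(site, parameter) series are scanned — matching common practice in
monitoring reports — but a Benjamini–Hochberg option exists and the
report logs the number of tests. Seasonal Mann–Kendall and Sen slopes
are out of scope.

## Clustering and discriminant analysis

Sites are clustered on Bray–Curtis dissimilarity of per-site mean
parameter vectors, with UPGMA (average) linkage by default and the
dendrogram cut at 60% similarity. Bray–Curtis has abundance semantics,
so the input is deliberately unstandardised raw concentrations; this
means large-unit parameters (EC, TCB) dominate the metric, which is
also true of the common desktop-software workflow this mirrors. A
range-normalisation flag is provided (off by default) for users who
want unit-free site comparisons.

Discriminant analysis has standard (all variables) and stepwise modes.
Stepwise selection uses Wilks' Λ = det(W)/det(T) on the candidate
subset, entering the variable with the largest partial
F = ((Λ_p/Λ_{p+1}) − 1)(n − g − p)/(g − 1) when it reaches f_enter
(default 3.84) and removing entered variables whose partial F drops
below f_remove (default 2.71) — the familiar SPSS convention.
Classification uses Fisher linear classification functions with equal
priors and resubstitution counting; an empty stepwise model (nothing
met f_enter) classifies by priors and is flagged. Resubstitution
accuracy is optimistic by construction; cross-validated error is a
non-goal here.

## Factor analysis

PCA runs on the correlation matrix after listwise deletion; loadings
are eigenvector·√λ, retention is Kaiser (λ > 1) or a fixed count, and
percent variance per factor is 100·λ/p. The table presentation keeps
unrotated eigenvalues and their percent-variance accounting alongside
varimax-rotated loadings, the convention of varifactor tables (that
convention is why a rotated table's per-factor percentages can disagree
slightly with sums of squared rotated loadings). Varimax runs on
Kaiser-normalised rows and preserves communalities; each rotated factor
is sign-flipped so its largest-|loading| entry is positive, making
output deterministic. Loadings classify as strong (|l| > 0.70) or
moderate (0.5 ≤ |l| ≤ 0.7).

Suitability diagnostics: KMO = Σr²/(Σr² + Σq²) over off-diagonal
entries, with partial correlations q from the inverse correlation
matrix, and Bartlett sphericity χ² = −(n − 1 − (2p+5)/6)·ln det R with
df = p(p−1)/2.

## Correlation networks and empirical regressions

Network edges keep parameter pairs with two-sided p < 0.05 from
t = r√((n−2)/(1−r²)), computed on pairwise-complete observations, with
the sign recorded (the green/red plotting convention). The per-edge
false-positive rate is therefore ≈ α under independence, and with 55
pairs a handful of spurious edges is expected — the optional Bonferroni
flag addresses this when edge lists feed downstream decisions.

Driver–response regressions (CHL-a ~ TP, TCB ~ BOD, …) default to OLS
on log10-transformed pairs, the standard form for these empirical
limnological models; the transform is explicit in the output. Fold
changes between weir periods are reported as ratios ≥ 1 with a
direction label ("2.74-fold decrease"), i.e. mean(pre)/mean(post) for
decreases and the inverse for increases.

## Synthetic data generator

The generator defines the study conditions under which every recovery
claim is made: 16 sites split 2/5/9 into highly/moderately/less
polluted tiers, monthly sampling over 15 years, and concentrations from
a 3-source non-negative mixture — point-source effluent (heavy in
BOD/COD/TP/TN/CHL-a), agriculture/livestock (TP/TN/TCB/BOD) and
background/ionic (EC/DO) — with tier-dependent mean source activities
(the point source dominating at highly polluted sites). Monsoon months
multiply TP/TN/EC by 0.7 (dilution) and TSS/TCB by 2.0/1.5 (runoff
enrichment); linear annual multipliers drift COD and CHL-a up (+2%/yr)
and TP/TN/BOD down (−3/−2/−2%/yr), the impoundment-era pattern; noise
is multiplicative lognormal (CV 0.2) so concentrations stay positive
and right-skewed. Per-sample source activities vary lognormally
(CV 0.3) around tier means, which is what gives the data its rank-3
structure. pH is drawn outside the mixture, normal around 7.75 and
clipped to [0, 14]. Optional left-censoring reports values below a
supplied MDL at MDL/2 and flags them. Everything is deterministic under
the config seed.

Magnitudes were chosen once so site means land in realistic river
ranges (TP ~80–500 µg/L, EC ~250–1100 µS/cm, TCB up to tens of
thousands MPN/100 mL across tiers).

What the generator does **not** emulate: hydrological dynamics (flow,
residence time), spatial autocorrelation along the river network,
serial autocorrelation within months, non-stationary seasonality, or
correlated measurement error. Passing recovery tests therefore shows
the estimators work when their structural assumptions hold — factor
recovery with three true sources, trend detection on genuinely monotone
drifts, tier recovery when tiers are separated — not that real
monitoring data satisfies those assumptions.

Named fixtures scale the same machinery down: "tiny" (2 sites × 12
months), "separated-tiers" (3×3 sites with ×3 concentration steps
between tiers, giving between-tier Bray–Curtis similarity ≈ 0.5 <
0.6 < within-tier similarity), "trended" (±8%/yr drifts against 5%
noise), and "rank3-noiseless" (exact mixture for the Q → 0 check).

## Numerical choices and problem sizes

- PMF floors iterates at 1e-12 during multiplicative updates so zeros
  are never absorbed; convergence is relative ΔQ < 1e-9 (updates),
  1e-8 (NNLS sweeps), and trust-region tolerances 1e-14.
- The noiseless-fixture check asserts Q below 1e-6 per cell in absolute
  units — with concentrations up to ~2×10⁴ this demands relative
  residuals near 1e-10, which is what the trust-region polish is for.
- Recovery experiments in the test suite and acceptance script use the
  full default generator (2880 samples × 10 parameters) with 5 dataset
  seeds and 5 solver starts for the receptor model, 2000 replicates for
  the trend test's type-I rate, and 50 label permutations for the DA
  null; these sizes keep the whole suite in a few minutes on one CPU
  while leaving Monte-Carlo noise well inside the asserted tolerances.
- Ties in classification scores resolve to the first group in label
  order; dendrogram group ids are renumbered by order of first
  appearance so output is stable across runs.

## Known limitations

- The WQI standards table is a package default, not a regulatory
  appendix; index values are only comparable across studies that share
  a standards table.
- PMF rotational ambiguity is unquantified: no bootstrap or
  displacement diagnostics, only multi-start Q and per-variable R².
- Stepwise selection inherits the usual caveats (greedy, inflated
  in-sample separation); the classification matrices are
  resubstitution, not cross-validated.
- The Bray–Curtis cut at 60% similarity is a convention, not a
  significance test (no SIMPROF equivalent).
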