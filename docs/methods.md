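# Methods

## Model and procedure

The pipeline treats each city's daily pollutant series as one node of a
dynamic system and asks, for every ordered pair, whether the history of
one city improves prediction of another beyond that city's own history.
For a pair (x, y) and lag order p it fits two OLS regressions — y on a
constant and its own lags 1..p, and the same plus x's lags 1..p — and
forms the joint F statistic on the added block,
F = [(SSR_r − SSR_u)/p] / [SSR_u/(T − 2p − 1)], referred to the
F(p, T − 2p − 1) distribution. The test assumes stationary inputs and
residuals that are serially uncorrelated once the own-lag block is
included; it is a *bivariate* test, so edges reflect predictive
association, not structural causality (see “Limitations”).

Each ordered pair is tested at every lag order in `lag_min..lag_max`
(default 1–10 days: pollution transport and dispersion play out over
days, and a band of lags guards against the arbitrariness of any single
choice). Per-lag rejections at level `alpha` (default 0.10) are
combined into one edge call by an aggregation rule: `any` (at least one
lag rejects), `majority` (more than half; the default — robust both to
a single lucky lag and to a single unlucky one), or `all`. By
construction the three rules produce nested edge sets. Directed edges
are kept one-way (i → j means i helps predict j) so that out- versus
in-degree bookkeeping, and with it the spillover/receiver role of a
city, remains meaningful; a reciprocal-only mode (edge kept only when
both directions reject) is available. No multiple-testing correction is
applied across the n(n−1) pairs by default — the network is defined by
the per-pair rule — but Bonferroni and Benjamini–Hochberg options
exist.

### Preprocessing

Missing daily values are filled with the mean of the nearest valid
observation before and after the gap (a run of missing days receives a
constant fill). A rule phrased as averaging fixed-offset neighbours
cannot be applied near series boundaries in a ~2.4-year window, so the
nearest-neighbour mean is the default interpretation; it is idempotent
and never alters observed values. Series endpoints must be observed.

Stationarity is screened per series with the augmented Dickey–Fuller
test — regression with constant, no trend; lag order chosen by AIC up
to ⌊12·(T/100)^0.25⌋ (the conventional Schwert cap). While p ≥ alpha
(default 0.05) and fewer than `max_diffs` (default 2) differences have
been taken, the series is first-differenced and retested; every test is
recorded in a ledger. Within a pair, both series are aligned at the max
of their two differencing orders so the two regressions are balanced.

### Network statistics

On the resulting binary directed graph: density = edges / n(n−1);
Krackhardt efficiency and connectedness are computed on the underlying
undirected graph (efficiency = 1 − (L − V)/(M − V) with V = Σ(n_k − 1),
M = Σ n_k(n_k−1)/2 over components, defined as 1 when M = V;
connectedness = fraction of unordered pairs joined by a path); average
distance and the cohesion (compactness) index use directed geodesics —
unreachable pairs are excluded from the former (NaN when no pair is
reachable) and contribute 0 to the latter, the two conventions that
keep both statistics defined on disconnected graphs. Degree centrality
is the percentage of the other n−1 cities adjacent in either direction
(so its printable maximum is 100); betweenness is Freeman betweenness
on the directed graph, normalized to [0, 1]. A city with out-degree
greater than in-degree is classified “spillover”, the converse
“receiver”, ties “equivalent”.

### CONCOR

Each node's profile is its adjacency row concatenated with its column
(the standard treatment of directed data). The node-by-node Pearson
correlation matrix of profiles is repeatedly replaced by the
correlation matrix of its own columns until every off-diagonal entry is
within `tolerance` (default 1e−6) of ±1 or `max_iterations` (200) is
reached; the sign pattern of the first row gives a bisection, applied
recursively to `depth` (default 2, cap 4 — deeper splits of a ~35-node
network produce degenerate slivers). Numerical guards: the iterate is
re-symmetrized with unit diagonal each step; a zero-variance (constant)
profile cannot be correlated and is set aside to the larger sibling
block with a warning; an all-positive correlation pattern marks an
indivisible block, left as a leaf; non-convergence is reported and the
last iterate's signs used. Subgroup labels come from aggregate flow:
with member out/in totals O and I, a block is “spillover” when
O > λI, “receiver” when I > λO, else “intermediary”; λ (default 1.2)
sets how lopsided the balance must be before a block is called
one-sided, and is deliberately configurable because any sharp threshold
on a continuous balance is a judgement call.

### QAP

Matrices over the same node set are compared on their off-diagonal
cells (self-association is undefined). The observed statistic is an
ordinary OLS fit of vec(Y) on an intercept and vec(X_1)..vec(X_k); R²
and adjusted R² use the n(n−1) cell count and k predictors. Inference
permutes the *node labels* of Y — rows and columns jointly, never
separately, preserving each dyad — and refits; with B draws the
p-value is (count + 1)/(B + 1) (never exactly 0), counting permutation
statistics as or more extreme in the observed direction (a two-sided
option exists). For n ≤ 7 an exhaustive mode enumerates all n!
permutations and reports count/n! (the identity is included, so p > 0).
Plain Y-permutation is the default because it is the procedure's
literal form; Dekker-style double semi-partialing (permuting the
residual of Y on the remaining predictors) is available for
collinearity-robust coefficient tests. The default design regresses the
AQI network on the six pollutant networks, 5000 permutations.

## Synthetic data generator

City AQI anomalies follow a VAR: a_t = φ·a_{t−1} + c·Wᵀa_{t−lag} + ε_t,
with W the planted binary network (W[i,j]=1: city i drives city j),
own-lag φ = 0.5, coupling c per edge, Gaussian innovations, and a
200-step burn-in. The companion-matrix spectral radius is checked and
an explosive configuration rejected. Observed AQI adds a baseline
(default 80) and an annual sinusoid peaking in mid-January (default
amplitude 20), reproducing the high-in-winter / low-in-summer pattern;
a coupling written on raw levels instead of anomalies would compound
the baseline through the recursion, which is why the generator couples
anomalies. Non-AQI pollutants are w·(AQI signal) + an idiosyncratic
AR(1), with default weights ordered PM2.5 (0.90) > PM10 (0.70) > NO2
(0.55) > O3 (0.45) > CO (0.40) > SO2 (0.30), so the particulate
networks resemble the AQI network most and a QAP regression has a
planted coefficient ordering to recover. Missing cells are removed
completely at random — exactly ⌊rate·N⌋ of them, never a series
endpoint, so two-sided imputation always applies. Two planted-network
families are provided: a stochastic block model (ground truth for
subgroup recovery) and a random directed matching (disjoint
source→sink pairs).

What the generator does **not** emulate: real AQI marginal
distributions (values can be negative), heteroskedasticity, spatial
coordinates or meteorology, heavy tails, and measurement error. Passing
tests therefore demonstrate that the *methods* recover known structure
under clean conditions, not that any particular real-world network is
correct.

### Benchmark design: why recovery runs are unseasonal

A seasonal cycle shared by all cities is a common deterministic driver:
lagged values of any city then genuinely improve prediction of any
other, and the pairwise test — correctly — rejects. Measured on
35-city panels (alpha = 0.10, majority aggregation), the false-positive
rate against the planted network is ≈ 0.59 with seasonal amplitude 20
versus ≈ 0.09 with amplitude 0. Planted-edge sensitivity and
false-positive rate are therefore measured on unseasonal panels, where
the planted network is the only cross-city dependence; the same
reasoning selects the directed *matching* as the recovery ground truth,
since chains or common drivers inside the planted graph would make
two-step “false” positives genuine predictive associations. This is
also why association networks estimated from real, strongly seasonal
panels tend to be near-saturated, and why their density should be read
as predictive association rather than direct transport.

## Problem sizes used in the checks

Oracle-equivalence checks run 10,000 random graphs of 2–5 nodes against
a matrix-power path-enumeration oracle, and 100 random Granger inputs
against a normal-equation oracle (agreement to 10 significant digits).
Calibration and recovery use 200 AR(1) replicate pairs at T = 879; one
35 × 879 panel with 16 planted edges (coupling 0.8); 200 QAP replicates
of 20-node matrices at 999 permutations; and 100 stochastic-block-model
seeds (36 nodes, 4 blocks, p_within = 0.9, p_between = 0.05). The
end-to-end determinism check runs the full pipeline twice at 8 cities ×
160 days and compares artifacts byte for byte.

## Limitations

* Pairwise Granger networks conflate direct and mediated influence;
  conditional (multivariate) tests are out of scope.
* The F test's nominal size assumes homoskedastic, serially
  uncorrelated errors given the included lags; heavy-tailed or
  conditionally heteroskedastic pollution data will distort it.
* CONCOR is a bisection heuristic with no objective function; on weak
  block structure different profile orderings can flip assignments.
* QAP Y-permutation tests coefficients under the full-exchangeability
  null; with strongly collinear predictors, prefer the DSP option.
* Half-year summaries split the calendar at 1 July; partial halves are
  averaged over available days and flagged, not rescaled.
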