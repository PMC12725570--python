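# Methods

This note records the models, numerical conventions, and design choices
behind `fcnflow`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Network model and delineation

A drainage is a forest of in-trees: each confluence-to-confluence reach has
at most one downstream neighbour, and a table may hold several independent
drainages (hydrological disconnects are real features of arid study areas).
Validation rejects duplicate ids, dangling pointers, cycles, and
non-positive lengths or drainage areas; decreasing drainage area along a
downstream pointer is only a warning, because real hydrography contains
divergences and permissive ingestion with logged provenance beats silent
repair. Braided (multi-downstream) networks are out of scope — input must
be pre-resolved to a dendritic structure. Reaches draining less than
2.5 km² are dropped before analysis to control for variable drainage
density; because drainage area is monotone downstream, the dropped set is
upstream-closed, and any pointer severed by a monotonicity violation simply
becomes a new terminus (logged).

Functionally connected networks are the connected components of the
undirected reach graph after deleting, for every active barrier on reach
*r*, the edge between *r* and its downstream neighbour; *r* stays with the
upstream patch. This is computed with a union-find, so results cannot
depend on iteration order; the test suite checks equivalence against an
independent graph-components oracle on a thousand random forests. Barriers
on terminus reaches cut nothing (logged no-op), and co-located barriers
collapse to a single cut — both situations the delineation definition
leaves open, resolved here in the least surprising way. Patch ids are the
smallest member reach id, making outputs reproducible. The historical
scenario uses waterfalls that are complete barriers; the current scenario
adds dams of every passability class (complete, partial, unknown). Barriers
flagged removed, off-network, or with anadromous fish observed upstream are
excluded from both.

## Habitat classes and diversity metrics

Each reach gets one composite class: stream size (drainage-area thresholds;
defaults 25 / 100 / 518 / 2,590 / 10,000 km² separating headwater, creek,
small, medium, large, great river), thermal regime (August temperature;
defaults 16 / 21 °C separating cold, cool, warm), and the categorical
gradient, flow-regime, and confinement labels carried by the input. Every
dimension is optional, and the thresholds ship as an editable schema
(regional classifications differ; the defaults are round numbers in the
range such systems use, not a calibration). Waterbody classes
(ocean/estuary, natural lake, artificial lake) are standalone. A reach with
a missing categorical value falls into a sentinel class with a logged
count; a missing temperature is an error unless the schema names a fallback
label.

Per patch, a stream class is present when its summed length is at least
1 km (boundary inclusive); waterbodies need only be present. Richness
counts all present classes, waterbodies included (configurable).
Rarity-weighted richness is `Σ_h 1/n_h` over present classes, with `n_h`
the number of patches in the same scenario × ecoregion group containing
class *h*; summing it over a group therefore returns exactly the number of
distinct classes present anywhere in the group — an identity the tests
enforce and a useful audit on real data. Because the current period has
more (hence smaller) patches, raw RWR is not comparable across periods;
values are z-scored within ecoregion × scenario using the sample (n−1)
standard deviation, with zero-spread groups mapped to z = 0 plus a warning
rather than NaN. Z-scoring is a blunt instrument — it aligns the first two
moments and nothing else — but it is the only correction implemented.

## Watershed linkage

Several patches can intersect one HUC-12; the subwatershed is characterized
by the longest (total stream km, not reach count) historical and current
patch intersecting it, each chosen independently — no containment between
the two is enforced, and ties break to the smaller patch id with a log
entry. Habitat change enters as `100 × (current − historic)/historic` per
class (negative = loss), with the undefined gained-from-zero case left
missing and the signal carried by the −1/0/+1 presence-change variable;
this keeps loss and gain distinguishable where a boolean delta would not.
Current condition is summarized per HUC-12: watershed health (HWI) and
local hydrologic regulation as length-weighted means over the HUC-12's
reaches (missing values skipped, weights renormalized, never silently
zero), and upstream dam density/storage read at the HUC-12 outlet (largest
drainage area, ties to the smallest reach id).

## Temporal beta-diversity

With per-site counts *a* (shared), *b* (lost), *c* (gained), the Sorensen
dissimilarity `D = (b+c)/(2a+b+c)` decomposes exactly into loss
`B = b/(2a+b+c)` and gain `C = c/(2a+b+c)`. Sites empty in both periods are
undefined and excluded from means and dominance tests with a logged count.

The per-site significance test is Monte-Carlo: the reference method is
cited in the literature without an algorithmic specification, so the
permutation scheme here is explicit and pluggable. The default shuffles
each species column independently across sites, separately within each
period matrix — the null of assemblages that could have been observed at
the site given the regional per-species occupancy rates. An alternative
pools the two periods' rows before shuffling each column (exchanging
occupancy between periods as well as sites). P-values use the add-one
estimator `(1 + #{D* ≥ D_obs})/(1 + n_perm)` with ties counted as
exceedances, so p is never zero and the test errs conservative; the suite
verifies agreement with exhaustive enumeration of the full permutation
group on a tiny instance and a near-nominal type-I error rate at α = 0.05
in a 1,000-replicate null simulation. Default 9,999 permutations, batched
internally (256 rounds at a time) to bound memory at large site counts.

Loss-gain dominance across sites is a sign-flip permutation of the paired
differences B − C (two-sided on the t statistic; zero-variance differences
map to t = 0 or ±∞ with inf-ties counted as exceedances). Per-species
change uses the paired-t sign-flip permutation on the site-wise occupancy
differences, one shared flip matrix across species per round (valid
marginally, and it lets the permuted statistics be computed by a single
matrix product because the sum of squared differences is flip-invariant).
Multiple testing defaults to Holm — a correction is required but
unspecified upstream, and Holm controls FWER without independence
assumptions; Bonferroni and Benjamini-Hochberg are selectable. Occupancy
percent changes are reported rounded half away from zero to one decimal,
the convention of published species-decline tables (−81.25 → −81.3).

## Spatial random forest

Predictor screening drops zero-variance columns, then resolves every pair
with |Pearson r| > 0.75 by keeping the member more |Spearman|-correlated
with the response, then enforces VIF ≤ 5 by forward selection in
response-relevance order, admitting a predictor only while the selected
set's maximum VIF stays within threshold. The forward pass matters: the
total-length percent change is nearly a linear combination of the per-class
percent changes, so a naive backward VIF loop can end up deleting the
aggregate — the single most informative fragmentation variable — after all
its parts have individually fallen below threshold. VIFs are the diagonal
of the inverse correlation matrix (identical to the regression definition
with intercept; cross-checked against an independent implementation in the
tests), with singular matrices treated as infinite.

Spatial weights are inverse-distance, truncated at a threshold and
row-normalized; the threshold ladder defaults to the quartiles of the
pairwise-distance distribution because the appropriate distances are
dataset-specific. Moran's I uses the standard cross-product form with
expectation −1/(n−1) and a permutation p-value (ties as exceedances,
one-sided for positive autocorrelation). Moran eigenvector maps are the
positive-eigenvalue eigenvectors of the double-centered symmetric weight
matrix, ordered by the Moran's I they attain under the row-normalized
weights (which differs slightly from eigenvalue order precisely because the
testing weights are row-normalized).

The fit proceeds: non-spatial forest (scikit-learn defaults, 100 trees —
tuning was explored upstream and found unnecessary, and the package keeps
that choice); if residual Moran's I is significant (p ≤ 0.05) at any
threshold, MEMs from the most-autocorrelated threshold are added one at a
time, refitting, until residuals are quiet at every threshold or the
candidate budget (20) is exhausted, in which case a warning is mandatory.
The final design is refit `n_runs = 30` times with distinct seeds,
recording out-of-bag R² and out-of-bag permutation importance (increase in
OOB MSE when one column is shuffled, computed from the public per-tree
bootstrap indices, clipped at zero). Partial dependence holds the other
predictors at their medians (0.5 quantiles) and averages predictions over
all 30 runs. A repeated 75/25 train/test R² routine is provided for
reporting but is not part of the core fit. A minimum of 30 sites is
enforced — below that a forest's OOB estimates are noise.

## Synthetic landscapes

The generator exists so every stage is testable without data downloads, and
its defaults are the package's study conditions: 2,500 reaches in 20
independent drainages, 500 HUC-12s, 30 waterfalls and 100 dams (dams
sampled ∝ drainage area, mirroring the mainstem bias of real dam siting;
waterfalls uniform), 40 species. Reach topology is a random recursive
in-forest (every new reach attaches downstream to a uniformly random
earlier reach), which makes drainage accumulation a single reverse sweep
and guarantees area monotonicity. Lengths are log-normal with median 2 km
(typical of confluence-to-confluence reaches); August temperature falls and
gradient steepens toward the headwaters; HUC-12s are contiguous blocks of
the per-tree depth-first order, so several patches can intersect one
HUC-12 and the longest-patch linkage rule is genuinely exercised; site
coordinates come from a planar random-walk embedding of each tree, giving
mild, realistic spatial autocorrelation.

Communities: each species draws a minimum patch-length requirement spanning
the observed range of longest-patch lengths; a species historically
occupies the HUC-12s whose longest historical patch meets its requirement
(with 10% haphazard absence). Between periods each occurrence is lost
independently with probability `logistic(β0 + β1·frag + β2·cond)`, where
`frag` is the site's fractional loss of longest-patch length between
scenarios and `cond` its length-weighted HWI. Defaults β0 = −2.5 (baseline
loss ≈ 8%), β1 = 3 (the planted fragmentation effect: loss probability
roughly quadruples over the frag range), β2 = −2 (better condition, fewer
losses). Dynamics are loss-only by default, matching the loss-dominated
regime the method targets; a gain rate exists solely to exercise the
dominance test's gain branch.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: real hydrographic geometry and flow
routing; observation error and uneven survey effort in occurrence records;
species dispersal limits, biotic interactions, and translocations;
correlated condition gradients (HWI here varies smoothly with elevation
only); and water availability in arid networks, where physical connection
need not mean hydrological connection. Tests on these landscapes establish
that the machinery is correct and that a planted fragmentation→loss signal
of realistic strength is recovered, not that any particular real-world
effect size will be.

## Problem sizes and determinism

Default analysis sizes (500 sites, 2,500 reaches, 9,999 permutations, 30
forest runs) were chosen as a desk-scale configuration that exercises every
code path with stable statistics. All randomness flows through explicit
integer seeds into numpy Generators; reruns with the same configuration are
bit-identical for every deterministic stage, and the suite asserts
reproducibility of the Monte-Carlo stages given a seed.

## Known limitations

* Presence–absence understates change relative to abundance data; no
  abundance-based dissimilarity is implemented.
* The longest-FCN linkage is a coarse proxy for the habitat actually
  available to low-dispersal species.
* Partial passability is binary here (a dam either cuts or it does not);
  probabilistic connectivity models are out of scope.
* Z-scoring RWR aligns moments, not shapes, across periods.
* The MEM selection heuristic (single worst threshold, Moran-ordered
  forward addition) is deliberately simple; specialised spatial-RF packages
  implement richer search strategies.
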