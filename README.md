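# fcnflow

River networks are dendritic: every dam or impassable waterfall splits a
drainage into smaller, isolated habitat patches. `fcnflow` quantifies what a
century of that fragmentation does to freshwater fish communities. It is
aimed at freshwater ecologists and conservation planners who have (a) a
reach-based hydrography table (NHDPlus-style: one confluence-to-confluence
reach per row with a downstream pointer), (b) barrier inventories, and
(c) two-period fish presence–absence data at the subwatershed (HUC-12)
scale — or who want to study the method itself on fully synthetic
landscapes, which the package can generate.

## What it computes

1. **Functionally connected networks (FCNs).** Given a barrier scenario
   (*historical* = complete-barrier waterfalls only; *current* = waterfalls
   plus dams of any passability), the reach forest is cut at each barrier
   (the barrier reach stays with the upstream patch) and partitioned into
   connected patches. Per ecoregion the package reports patch counts, mean
   lengths, and percent change between periods.

2. **Habitat diversity per patch.** Each reach gets a composite physical
   habitat class (stream size × thermal regime × gradient × flow regime ×
   valley confinement, all configurable) plus standalone waterbody classes.
   A class is *present* in a patch when it spans ≥ 1 km (waterbodies by mere
   presence). Per patch: richness = number of classes present, and
   rarity-weighted richness

   `RWR = Σ_{h present} 1 / n_h`,

   where `n_h` counts the patches (same scenario × ecoregion) containing
   class *h*; RWR is z-scored within ecoregion × scenario so the two periods
   are comparable despite different patch counts.

3. **Temporal beta-diversity (TBI).** For each HUC-12 with species counts
   *a* (shared), *b* (lost), *c* (gained) between periods,

   `D = (b + c) / (2a + b + c) = B + C`,  `B = b/(2a+b+c)`, `C = c/(2a+b+c)`,

   the Sorensen dissimilarity split exactly into loss and gain components.
   Site-level significance comes from a seeded Monte-Carlo permutation test
   (default 9,999 permutations), loss-vs-gain dominance from a sign-flip
   test of the paired B − C differences, and per-species change from
   paired-t sign-flip permutation tests with Holm correction.

4. **Attribution.** HUC-12s are characterized by their longest historical
   and current FCN; habitat change enters as per-class percent changes and
   presence changes, alongside current condition scores (length-weighted
   watershed health index and hydrologic regulation, outlet dam
   density/storage). After correlation (|r| ≤ 0.75) and VIF (≤ 5)
   screening, a random forest predicts TBI; Moran eigenvector maps are added
   until residual spatial autocorrelation (Moran's I over a ladder of
   distance thresholds) is non-significant, and the final model is rerun 30
   times for out-of-bag R² and permutation-importance distributions and
   partial dependence curves.

## Worked example

Generate a synthetic landscape with a planted fragmentation→loss effect and
run the full pipeline:

```bash
fcnflow simulate --seed 7 --out demo_inputs
cat > demo.yaml <<EOF
reaches: demo_inputs/reaches.csv
barriers: demo_inputs/barriers.csv
community_historical: demo_inputs/community_historical.csv
community_current: demo_inputs/community_current.csv
centroids: demo_inputs/centroids.csv
out_dir: demo_out
tbi_n_perm: 999
EOF
fcnflow run --config demo.yaml
python - <<'PY'
import json
r = json.load(open("demo_out/report.json"))
d, t = r["delineate"], r["tbi"]
print(f"FCNs: {d['historical_fcn_count']} -> {d['current_fcn_count']} "
      f"({d['fcn_count_pct_change']:+.0f}%)")
print(f"mean FCN length change: {d['mean_length_pct_change']:+.0f}%")
print(f"mean TBI {t['mean_D']:.3f} = loss {t['mean_B']:.3f} + gain {t['mean_C']:.3f}; "
      f"dominance: {t['dominance_direction']} (p={t['dominance_p']:.4f})")
PY
```

which prints (seed 7):

```
FCNs: 50 -> 150 (+200%)
mean FCN length change: -67%
mean TBI 0.116 = loss 0.116 + gain 0.000; dominance: loss (p=0.0010)
```

Dam construction tripled the number of habitat patches and cut mean patch
length by two thirds; the fish communities changed (mean TBI 0.116) entirely
through species loss — the gain component is zero because the generator's
default dynamics are loss-only, and the dominance test flags that asymmetry
at the smallest p attainable with 999 sign flips.

The same stages are available as library calls (`fcnflow.delineate_fcns`,
`fcnflow.tbi_permutation_test`, `fcnflow.SpatialRandomForest(...).fit()`,
…) for notebook use; `SpatialRandomForest` follows the familiar
model/results pattern with a `summary()` on the results object.

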