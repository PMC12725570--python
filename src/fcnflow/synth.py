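"""Seeded synthetic dendritic networks, barriers, and two-period fish communities.

The generator produces a full input bundle for the pipeline without any
external data: a forest of random recursive reach trees with accumulated
drainage areas and depth-structured habitat attributes, waterfall and dam
barriers, contiguous-subtree HUC-12 blocks with planar centroids, and
historical/current presence–absence matrices in which species losses follow
a site-level logistic model

    P(loss) = logistic(β0 + β1 · frag_s + β2 · cond_s)

with frag_s the fractional loss of longest-FCN length at site s between the
historical and current barrier scenarios, and cond_s the site's
length-weighted habitat condition (HWI). β1 > 0 plants the
fragmentation→loss effect the downstream attribution stage should recover;
dynamics are loss-only by default (an optional gain rate exists to exercise
the gain branch of the dominance test). Everything is deterministic given
the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .delineation import (
    CURRENT,
    HISTORICAL,
    Barrier,
    delineate_fcns,
    select_barriers,
    write_barrier_table,
)
from .linkage import length_weighted_condition, longest_fcn_per_huc12
from .network import RiverNetwork, write_reach_table
from .tbi import CommunityPair

logger = logging.getLogger(__name__)

GRADIENT_CLASSES = ("low_gradient", "moderate_gradient", "high_gradient")
FLOW_CLASSES = ("stable_baseflow", "runoff_flashy", "intermittent")
CONFINEMENT_CLASSES = ("confined", "unconfined")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a desk-scale landscape: 2,500 reaches across 20
    independent drainages partitioned into 500 subwatersheds, fragmented by
    30 waterfalls and 100 dams (dams biased toward high-drainage mainstems),
    with 40 species whose losses respond to fragmentation (β1 = 3 on the
    [0, 1] fractional length-loss scale) and to habitat condition
    (β2 = −2 on the [0, 1] HWI scale) around a baseline loss odds of
    β0 = −2.5.
    """

    n_reaches: int = 2500
    n_outlets: int = 20
    n_waterfalls: int = 30
    n_dams: int = 100
    dam_size_bias: float = 1.0
    n_species: int = 40
    richness_gradient: float = 1.0
    loss_intercept: float = -2.5
    loss_frag_coef: float = 3.0
    loss_condition_coef: float = -2.0
    gain_rate: float = 0.0
    n_huc12: int = 500
    n_ecoregions: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_reaches <= self.n_waterfalls + self.n_dams:
            raise ValueError("need n_waterfalls + n_dams < n_reaches")
        if min(self.n_reaches, self.n_outlets, self.n_species, self.n_huc12) < 1:
            raise ValueError("counts must be positive")
        if self.n_outlets > self.n_reaches:
            raise ValueError("more outlets than reaches")


@dataclass
class SynthDataset:
    """The generated bundle plus the generating truth for recovery tests."""

    network: RiverNetwork
    barriers: list[Barrier]
    centroids: pd.DataFrame
    communities: CommunityPair
    truth: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_reach_table(self.network, out / "reaches.csv")
        write_barrier_table(self.barriers, out / "barriers.csv")
        self.centroids.to_csv(out / "centroids.csv")
        t1 = pd.DataFrame(self.communities.t1.astype(int),
                          index=self.communities.sites, columns=self.communities.species)
        t2 = pd.DataFrame(self.communities.t2.astype(int),
                          index=self.communities.sites, columns=self.communities.species)
        t1.to_csv(out / "community_historical.csv", index_label="site_id")
        t2.to_csv(out / "community_current.csv", index_label="site_id")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------- #
def generate_network(cfg: SynthConfig, rng: np.random.Generator | None = None) -> tuple[RiverNetwork, pd.DataFrame]:
    """Random recursive reach forest with attributes; returns (network, centroids).

    Reach i > n_outlets attaches downstream to a uniformly random earlier
    reach, so parents always precede children and drainage accumulation is a
    single reverse sweep (monotone by construction). August temperature
    falls and gradient steepens with distance from the outlet; HUC-12s are
    contiguous blocks of the per-tree depth-first order, each with the
    centroid of its member reach positions in a random planar embedding.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_reaches, cfg.n_outlets
    downstream = np.full(n, -1, dtype=int)
    for i in range(k, n):
        downstream[i] = rng.integers(0, i)

    length = rng.lognormal(mean=np.log(2.0), sigma=0.6, size=n)
    local_area = rng.lognormal(mean=np.log(1.5), sigma=0.8, size=n) + 0.5
    acc = local_area.copy()
    for i in range(n - 1, k - 1, -1):
        acc[downstream[i]] += acc[i]

    depth = np.zeros(n, dtype=int)
    pos = np.zeros((n, 2))
    root_of = np.zeros(n, dtype=int)
    grid = int(np.ceil(np.sqrt(k)))
    for r in range(k):
        pos[r] = (100.0 * (r % grid), 100.0 * (r // grid))
        root_of[r] = r
    for i in range(k, n):
        d = downstream[i]
        depth[i] = depth[d] + 1
        root_of[i] = root_of[d]
        pos[i] = pos[d] + rng.normal(0.0, 2.0, size=2)

    max_depth = np.zeros(k)
    for i in range(n):
        max_depth[root_of[i]] = max(max_depth[root_of[i]], depth[i])
    frac = depth / np.maximum(max_depth[root_of], 1)

    temp = 24.0 - 12.0 * frac + rng.normal(0.0, 0.8, size=n)
    grad_p = np.clip(np.column_stack([0.7 - 0.6 * frac, np.full(n, 0.25), 0.05 + 0.6 * frac]), 0.01, None)
    grad_p /= grad_p.sum(axis=1, keepdims=True)
    gradient = np.array([rng.choice(GRADIENT_CLASSES, p=p) for p in grad_p])
    flow = rng.choice(FLOW_CLASSES, size=n, p=(0.45, 0.35, 0.2))
    confinement = rng.choice(CONFINEMENT_CLASSES, size=n, p=(0.55, 0.45))

    waterbody = np.full(n, "none", dtype=object)
    waterbody[:k] = np.where(rng.random(k) < 0.5, "ocean_estuary", "none")
    lakes = rng.random(n) < 0.02
    lakes[:k] = False
    waterbody[lakes] = np.where(rng.random(int(lakes.sum())) < 0.5, "natural_lake", "artificial_lake")

    hwi = np.clip(0.35 + 0.4 * frac + rng.normal(0.0, 0.15, size=n), 0.0, 1.0)
    hydro_reg = np.clip(0.3 + 0.5 * frac + rng.normal(0.0, 0.15, size=n), 0.0, 1.0)

    # HUC-12s: contiguous chunks of the per-tree DFS order, apportioned by size
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(k, n):
        children[downstream[i]].append(i)
    huc = np.empty(n, dtype=object)
    tree_sizes = np.bincount(root_of, minlength=k)
    quota = np.maximum(1, np.round(cfg.n_huc12 * tree_sizes / n).astype(int))
    hid = 0
    for r in range(k):
        order: list[int] = []
        stack = [r]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(sorted(children[node], reverse=True))
        blocks = np.array_split(np.array(order), min(quota[r], len(order)))
        for blk in blocks:
            huc[blk] = f"H{hid:04d}"
            hid += 1
    ecoregion = np.array([f"E{root_of[i] % cfg.n_ecoregions:02d}" for i in range(n)])

    ids = np.array([f"R{i:05d}" for i in range(n)])
    df = pd.DataFrame(
        {
            "reach_id": ids,
            "downstream_id": [None if downstream[i] < 0 else ids[downstream[i]] for i in range(n)],
            "length_km": length,
            "drainage_area_km2": acc,
            "ecoregion_id": ecoregion,
            "huc12_id": huc,
            "aug_temp_c": temp,
            "gradient_class": gradient,
            "flow_class": flow,
            "confinement_class": confinement,
            "waterbody_type": waterbody,
            "hwi": hwi,
            "local_hydro_reg": hydro_reg,
            "upstream_dam_density": 0.0,
            "upstream_dam_storage": 0.0,
        }
    )
    net = RiverNetwork(df)
    cent = (
        pd.DataFrame({"huc12_id": huc, "x": pos[:, 0], "y": pos[:, 1]})
        .groupby("huc12_id")
        .mean()
        .sort_index()
    )
    return net, cent


def place_barriers(net: RiverNetwork, cfg: SynthConfig, rng: np.random.Generator | None = None) -> list[Barrier]:
    """Waterfalls uniform, dams drainage-area-biased; one barrier per reach."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    df = net.frame
    # non-terminus reaches above the standard drainage-area analysis cutoff,
    # so barriers survive the small-reach filter downstream
    eligible = [
        rid
        for rid in net.reach_ids
        if net.downstream[rid] is not None and df.at[rid, "drainage_area_km2"] >= 2.5
    ]
    if len(eligible) < cfg.n_waterfalls + cfg.n_dams:
        raise ValueError("not enough non-terminus reaches for requested barrier counts")
    eligible = np.array(eligible)
    falls = rng.choice(eligible, size=cfg.n_waterfalls, replace=False)
    remaining = np.setdiff1d(eligible, falls)
    w = df.loc[remaining, "drainage_area_km2"].to_numpy(dtype=float) ** cfg.dam_size_bias
    dams = rng.choice(remaining, size=cfg.n_dams, replace=False, p=w / w.sum())
    barriers = [
        Barrier(f"WF{i:04d}", rid, "waterfall", "complete") for i, rid in enumerate(sorted(falls))
    ]
    passability = rng.choice(("complete", "partial", "unknown"), size=cfg.n_dams, p=(0.6, 0.25, 0.15))
    barriers += [
        Barrier(f"DAM{i:04d}", rid, "dam", p)
        for i, (rid, p) in enumerate(zip(sorted(dams), passability))
    ]
    return barriers


def attach_dam_metrics(net: RiverNetwork, barriers, rng: np.random.Generator) -> RiverNetwork:
    """Recompute upstream dam density/storage from the placed dams.

    Density = upstream dam count per upstream km²; storage = summed upstream
    reservoir volumes (lognormal per dam, scaled by dam-reach drainage area).
    """
    df = net.to_frame()
    dam_reaches = [b.reach_id for b in barriers if b.barrier_type == "dam"]
    storage = {
        rid: float(rng.lognormal(np.log(5.0), 1.0) * df.at[rid, "drainage_area_km2"])
        for rid in dam_reaches
    }
    count = pd.Series(0.0, index=df.index)
    stor = pd.Series(0.0, index=df.index)
    for rid in dam_reaches:
        # a dam affects its own reach and everything downstream of it
        node: str | None = rid
        while node is not None:
            count[node] += 1
            stor[node] += storage[rid]
            node = net.downstream[node]
    df["upstream_dam_density"] = count / df["drainage_area_km2"]
    df["upstream_dam_storage"] = stor
    return RiverNetwork(df)


def simulate_communities(
    net: RiverNetwork,
    fcns_hist,
    fcns_curr,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CommunityPair, dict]:
    """Two-period occupancy with a logistic fragmentation→loss mechanism.

    Historically a species occupies the HUC-12s whose longest historical FCN
    meets its (lognormally drawn) minimum-length requirement; currently each
    historical occurrence is retained unless lost with the logistic
    probability described in the module docstring. Returns the community
    pair and the per-site truth record (frag_s, cond_s, parameters).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    fcn_len_h = {f.fcn_id: f.total_length_km for f in fcns_hist}
    fcn_len_c = {f.fcn_id: f.total_length_km for f in fcns_curr}
    long_h = longest_fcn_per_huc12(fcns_hist, net)
    long_c = longest_fcn_per_huc12(fcns_curr, net)
    sites = sorted(long_h)
    lh = np.array([fcn_len_h[long_h[s]] for s in sites])
    lc = np.array([fcn_len_c[long_c[s]] for s in sites])
    frag = np.clip((lh - lc) / lh, 0.0, 1.0)
    cond = np.array([length_weighted_condition(net, s, ("hwi",))["hwi"] for s in sites])

    # species length requirements spanning the observed FCN-length range
    lo, hi = np.quantile(lh, (0.05, 0.95))
    req = np.exp(rng.uniform(np.log(max(lo, 0.5)), np.log(max(hi, 1.0)), size=cfg.n_species))
    req = req ** cfg.richness_gradient
    t1 = (lh[:, None] >= req[None, :]) & (rng.random((len(sites), cfg.n_species)) < 0.9)

    logit = cfg.loss_intercept + cfg.loss_frag_coef * frag + cfg.loss_condition_coef * cond
    p_loss = 1.0 / (1.0 + np.exp(-logit))
    t2 = t1 & (rng.random(t1.shape) >= p_loss[:, None])
    if cfg.gain_rate > 0:
        t2 |= (~t1) & (rng.random(t1.shape) < cfg.gain_rate)

    species = [f"SP{j:03d}" for j in range(cfg.n_species)]
    pair = CommunityPair(sites=sites, species=species,
                         t1=t1.astype(int), t2=t2.astype(int))
    truth = {
        "params": {k: v for k, v in asdict(cfg).items()},
        "sites": sites,
        "frag": frag.tolist(),
        "cond": cond.tolist(),
        "loss_prob": p_loss.tolist(),
        "species_length_req_km": req.tolist(),
    }
    return pair, truth


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """End-to-end bundle generation (network → barriers → communities)."""
    rng = np.random.default_rng(cfg.seed)
    net, centroids = generate_network(cfg, rng)
    barriers = place_barriers(net, cfg, rng)
    net = attach_dam_metrics(net, barriers, rng)
    fcns_hist = delineate_fcns(net, select_barriers(barriers, HISTORICAL), "historical")
    fcns_curr = delineate_fcns(net, select_barriers(barriers, CURRENT), "current")
    communities, truth = simulate_communities(net, fcns_hist, fcns_curr, cfg, rng)
    return SynthDataset(
        network=net,
        barriers=barriers,
        centroids=centroids,
        communities=communities,
        truth=truth,
    )
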