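"""Temporal beta-diversity (TBI) with Sorensen decomposition and permutation tests.

For each site (HUC-12) with presence–absence rows ``t1`` (historical) and
``t2`` (current):

* a = species shared, b = losses (present only at t1), c = gains (only t2);
* D = (b + c) / (2a + b + c)  — the Sorensen dissimilarity between periods,
  decomposed exactly as D = B + C with B = b/(2a+b+c) (loss component) and
  C = c/(2a+b+c) (gain component).

Significance per site comes from a Monte-Carlo permutation test of D against
assemblages that could have been observed at that site: by default every
species column is permuted independently across sites, separately within
each period matrix, and D is recomputed each round. The p-value uses the
add-one estimator (1 + #{D* ≥ D_obs}) / (1 + n_perm); permuted values tied
with the observed count as exceedances (conservative), and p is never 0.

Also provided: a loss-vs-gain dominance test over sites (sign-flip
permutation of the paired B − C differences), per-species paired t
permutation tests with multiple-testing correction, and occupancy-change
accounting per species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .delineation import round_half_away
from .errors import ShapeMismatchError, TooFewSitesError

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12

PERMUTATION_SCHEMES = ("columns_within_period", "columns_pooled_periods")


@dataclass
class CommunityPair:
    """Aligned site × species binary matrices for two periods."""

    sites: list
    species: list
    t1: np.ndarray
    t2: np.ndarray

    def __post_init__(self):
        self.t1 = np.asarray(self.t1)
        self.t2 = np.asarray(self.t2)
        if self.t1.shape != self.t2.shape:
            raise ShapeMismatchError(
                f"period matrices differ in shape: {self.t1.shape} vs {self.t2.shape}"
            )
        if self.t1.shape != (len(self.sites), len(self.species)):
            raise ShapeMismatchError(
                "matrix shape does not match sites × species labels"
            )
        for name, m in (("t1", self.t1), ("t2", self.t2)):
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} must be binary (0/1)")
        self.t1 = self.t1.astype(bool)
        self.t2 = self.t2.astype(bool)

    @classmethod
    def from_dataframes(cls, d1: pd.DataFrame, d2: pd.DataFrame) -> "CommunityPair":
        """Align two site × species tables on shared index/columns (sorted)."""
        sites = sorted(set(d1.index) & set(d2.index))
        species = sorted(set(d1.columns) & set(d2.columns))
        if not sites or not species:
            raise ShapeMismatchError("no shared sites or species between periods")
        lost = (len(d1.index) - len(sites), len(d2.index) - len(sites))
        if any(lost):
            logger.info("dropped %s sites not shared between periods", lost)
        return cls(
            sites=list(map(str, sites)),
            species=list(map(str, species)),
            t1=d1.loc[sites, species].to_numpy(),
            t2=d2.loc[sites, species].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path1, path2) -> "CommunityPair":
        read = lambda p: pd.read_csv(p, index_col=0)
        return cls.from_dataframes(read(path1), read(path2))

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)


# ---------------------------------------------------------------------- #
def _abc(t1: np.ndarray, t2: np.ndarray):
    """Shared / lost / gained species counts along the last axis."""
    a = (t1 & t2).sum(axis=-1)
    b = (t1 & ~t2).sum(axis=-1)
    c = (~t1 & t2).sum(axis=-1)
    return a, b, c


def _decompose(a, b, c):
    denom = 2 * a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.where(denom > 0, b / denom, np.nan)
        C = np.where(denom > 0, c / denom, np.nan)
    return B, C, B + C, denom


def tbi_components(pair: CommunityPair) -> pd.DataFrame:
    """Per-site Sorensen decomposition (no p-values).

    Sites empty in both periods (denominator 2a+b+c = 0) get NaN components
    and are flagged ``undefined``.
    """
    a, b, c = _abc(pair.t1, pair.t2)
    B, C, D, denom = _decompose(a, b, c)
    n_undef = int((denom == 0).sum())
    if n_undef:
        logger.info("%d sites empty in both periods; TBI undefined there", n_undef)
    return pd.DataFrame(
        {
            "site_id": pair.sites,
            "a": a,
            "b": b,
            "c": c,
            "denom": denom,
            "B": B,
            "C": C,
            "D": D,
        }
    ).set_index("site_id")


def _permuted_columns(m: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    """``n`` copies of ``m`` with every species column independently shuffled
    across sites. Shape (n, sites, species)."""
    idx = np.argsort(rng.random((n,) + m.shape), axis=1)
    return np.take_along_axis(np.broadcast_to(m, (n,) + m.shape), idx, axis=1)


def tbi_permutation_test(
    pair: CommunityPair,
    n_perm: int = 9999,
    seed: int | None = None,
    alpha: float = 0.05,
    scheme: str = "columns_within_period",
    batch_size: int = 256,
) -> pd.DataFrame:
    """Per-site TBI with Monte-Carlo permutation p-values.

    ``scheme`` selects the null-assemblage generator:

    * ``columns_within_period`` (default) — each species column permuted
      across sites independently in t1 and in t2;
    * ``columns_pooled_periods`` — columns permuted across the pooled
      2n-row (site, period) matrix, then split back, exchanging occupancy
      between periods as well as sites.

    Deterministic given ``seed``. Results carry ``p_value`` and
    ``significant`` (p ≤ alpha) columns; undefined sites keep NaN p.
    """
    if scheme not in PERMUTATION_SCHEMES:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    res = tbi_components(pair)
    d_obs = res["D"].to_numpy()
    rng = np.random.default_rng(seed)
    exceed = np.zeros(pair.n_sites, dtype=np.int64)
    done = 0
    while done < n_perm:
        nb = min(batch_size, n_perm - done)
        if scheme == "columns_within_period":
            p1 = _permuted_columns(pair.t1, rng, nb)
            p2 = _permuted_columns(pair.t2, rng, nb)
        else:
            pooled = np.concatenate([pair.t1, pair.t2], axis=0)
            perm = _permuted_columns(pooled, rng, nb)
            p1, p2 = perm[:, : pair.n_sites], perm[:, pair.n_sites :]
        a, b, c = _abc(p1, p2)
        _, _, d_perm, _ = _decompose(a, b, c)
        with np.errstate(invalid="ignore"):
            exceed += np.nansum(d_perm >= d_obs[None, :] - _TIE_EPS, axis=0).astype(np.int64)
        done += nb
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[~np.isfinite(d_obs)] = np.nan
    res["p_value"] = p
    res["significant"] = res["p_value"] <= alpha
    return res


# ---------------------------------------------------------------------- #
def _paired_t(diff: np.ndarray):
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
        # zero-variance, nonzero-mean differences: infinitely extreme t
        t = np.where((sd == 0) & (m != 0), np.sign(m) * np.inf, t)
        t = np.where((sd == 0) & (m == 0), 0.0, t)
    return t, m


def dominance_test(
    results: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Are temporal changes dominated by losses (B) or gains (C) across sites?

    Paired comparison of the per-site loss and gain components via sign-flip
    permutation of the differences B − C (two-sided p). Undefined sites are
    excluded with a logged count.
    """
    defined = results.dropna(subset=["B", "C"])
    n_excl = len(results) - len(defined)
    if n_excl:
        logger.info("dominance test excludes %d undefined sites", n_excl)
    if len(defined) < 2:
        raise TooFewSitesError("dominance test needs >= 2 sites with defined TBI")
    diff = (defined["B"] - defined["C"]).to_numpy()[:, None]
    t_obs, _ = _paired_t(diff)
    t_obs = float(t_obs[0])
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, len(diff)))
    t_perm, _ = _paired_t((signs * diff[:, 0]).T)
    with np.errstate(invalid="ignore"):
        exceed = int(np.sum(np.abs(t_perm) >= abs(t_obs) - _TIE_EPS))
    p = (1.0 + exceed) / (1.0 + n_perm)
    mean_b = float(defined["B"].mean())
    mean_c = float(defined["C"].mean())
    if p <= alpha:
        direction = "loss" if mean_b > mean_c else "gain"
    else:
        direction = "none"
    return {
        "direction": direction,
        "mean_B": mean_b,
        "mean_C": mean_c,
        "mean_D": float(defined["D"].mean()),
        "statistic": t_obs,
        "p": float(p),
        "n_sites": int(len(defined)),
    }


def species_paired_tests(
    pair: CommunityPair,
    n_perm: int = 9999,
    seed: int | None = None,
    correction: str = "holm",
    alpha: float = 0.05,
    range_types: dict | None = None,
) -> pd.DataFrame:
    """Per-species paired-t permutation tests of occupancy change.

    For each species, the t statistic of the site-wise differences t2 − t1 is
    compared with its sign-flip permutation distribution (two-sided; one set
    of flips shared across species per round, which preserves the marginal
    validity of each test). Species whose differences are all zero get p = 1.
    P-values are corrected with Holm by default (``bonferroni`` and
    ``fdr_bh`` selectable).
    """
    if pair.n_sites < 2:
        raise TooFewSitesError("paired tests need >= 2 sites")
    diff = pair.t2.astype(np.int8) - pair.t1.astype(np.int8)
    t_obs, m_obs = _paired_t(diff.astype(float))
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, pair.n_sites))
    n = pair.n_sites
    ss = (diff.astype(float) ** 2).sum(axis=0)  # invariant under sign flips
    m_perm = signs @ diff.astype(float) / n
    var_perm = (ss - n * m_perm**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = m_perm / np.sqrt(var_perm / n)
        t_perm = np.where((var_perm <= 0) & (m_perm != 0), np.sign(m_perm) * np.inf, t_perm)
        t_perm = np.where((var_perm <= 0) & (m_perm == 0), 0.0, t_perm)
    with np.errstate(invalid="ignore"):
        exceed = np.sum(np.abs(t_perm) >= np.abs(t_obs)[None, :] - _TIE_EPS, axis=0)
    p_raw = (1.0 + exceed) / (1.0 + n_perm)
    unchanged = (diff == 0).all(axis=0)
    p_raw[unchanged] = 1.0
    p_adj = multipletests(p_raw, method=correction)[1]

    occ = occupancy_change(pair, range_types)
    occ["p_raw"] = p_raw
    occ["p_adj"] = p_adj
    occ["significant"] = occ["p_adj"] <= alpha
    return occ


def occupancy_change(pair: CommunityPair, range_types: dict | None = None) -> pd.DataFrame:
    """Per-species occupancy counts and percent change between periods.

    Percent change is rounded half away from zero to one decimal (the
    reporting convention for species-decline tables); species absent
    historically get NaN percent change.
    """
    n_hist = pair.t1.sum(axis=0).astype(int)
    n_curr = pair.t2.sum(axis=0).astype(int)
    delta = n_curr - n_hist
    pct = np.array(
        [
            round_half_away(100.0 * d / h, 1) if h > 0 else np.nan
            for d, h in zip(delta, n_hist)
        ]
    )
    df = pd.DataFrame(
        {
            "species_id": pair.species,
            "n_hist": n_hist,
            "n_curr": n_curr,
            "delta": delta,
            "pct_change": pct,
        }
    ).set_index("species_id")
    if range_types is not None:
        df["range_type"] = [range_types.get(s) for s in pair.species]
    return df
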