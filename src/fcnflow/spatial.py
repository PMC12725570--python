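"""Spatially explicit random-forest attribution of community change.

Workflow, mirroring standard spatial-RF practice:

1. screen predictors — drop zero-variance columns, then iteratively remove
   one member of every pair with |r| above a correlation threshold (keeping
   the predictor more rank-correlated with the response) and predictors with
   variance inflation factor above a VIF threshold;
2. fit a non-spatial random forest and measure Moran's I of its residuals at
   a series of distance thresholds;
3. if residual autocorrelation is significant at any threshold, add Moran
   eigenvector map (MEM) columns — eigenvectors of the double-centered
   spatial weight matrix with positive eigenvalues, in decreasing Moran's I
   order — one at a time until residuals are non-significant at every
   threshold (or candidates are exhausted, with a warning);
4. repeat the final model many times with different seeds to obtain the
   distribution of out-of-bag R² and out-of-bag permutation importances.

The model/results split follows the usual estimator convention:
``SpatialRandomForest(y, X, coords).fit(...)`` returns a
:class:`SpatialRandomForestResults` carrying estimates, diagnostics,
``summary()`` and ``partial_dependence()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor

from .errors import NoPredictorsError, TooFewSitesError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------- #
@dataclass
class SpatialWeights:
    """Inverse-distance spatial weights truncated at a distance threshold.

    ``weights`` is the row-normalized matrix used for Moran's I;
    ``raw`` keeps the symmetric, unnormalized 1/d matrix used for MEM
    construction. Sites with no neighbour inside the threshold are flagged.
    """

    threshold: float
    weights: np.ndarray
    raw: np.ndarray
    isolated: np.ndarray

    @classmethod
    def from_coords(cls, coords: np.ndarray, threshold: float) -> "SpatialWeights":
        coords = np.asarray(coords, dtype=float)
        d = squareform(pdist(coords))
        with np.errstate(divide="ignore"):
            raw = np.where((d > 0) & (d <= threshold), 1.0 / np.where(d > 0, d, 1.0), 0.0)
        np.fill_diagonal(raw, 0.0)
        rowsum = raw.sum(axis=1)
        isolated = rowsum == 0
        if isolated.any():
            logger.warning("%d sites have no neighbour within %.3g", int(isolated.sum()), threshold)
        w = raw / np.where(rowsum > 0, rowsum, 1.0)[:, None]
        return cls(threshold=float(threshold), weights=w, raw=raw, isolated=isolated)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def default_thresholds(coords: np.ndarray, quantiles=(0.25, 0.5, 0.75)) -> list[float]:
    """Distance thresholds at quartiles of the pairwise-distance distribution."""
    d = pdist(np.asarray(coords, dtype=float))
    return [float(q) for q in np.quantile(d, quantiles)]


@dataclass
class MoranResult:
    variable: str
    threshold: float
    I: float
    expected_I: float
    p_value: float | None


def morans_i(
    x: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    variable: str = "x",
    alternative: str = "greater",
) -> MoranResult:
    """Global Moran's I with a permutation p-value.

    I = (n/S0) · Σ_ij w_ij z_i z_j / Σ_i z_i², z = x − mean(x), S0 = Σ w_ij.
    The permutation null shuffles x over sites; its expectation is
    −1/(n−1). ``alternative`` is ``greater`` (positive autocorrelation,
    default) or ``two-sided``. ``n_perm=0`` skips the test (p is None).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise TooFewSitesError("Moran's I needs >= 3 sites")
    z = x - x.mean()
    zz = float(z @ z)
    if zz == 0:
        raise ValueError("Moran's I undefined for zero-variance input")
    W = weights.weights
    s0 = float(W.sum())
    factor = n / (s0 * zz)
    i_obs = float(factor * (z @ W @ z))
    expected = -1.0 / (n - 1)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        i_perm = np.empty(n_perm)
        for k in range(n_perm):
            zp = z[rng.permutation(n)]
            i_perm[k] = factor * (zp @ W @ zp)
        if alternative == "greater":
            exceed = int(np.sum(i_perm >= i_obs - 1e-12))
        else:
            exceed = int(np.sum(np.abs(i_perm - expected) >= abs(i_obs - expected) - 1e-12))
        p = (1.0 + exceed) / (1.0 + n_perm)
    return MoranResult(variable=variable, threshold=weights.threshold, I=i_obs,
                       expected_I=expected, p_value=p)


def mem_spatial_predictors(weights: SpatialWeights, tol: float = 1e-10) -> pd.DataFrame:
    """Moran eigenvector maps from a spatial weight matrix.

    Eigenvectors of Ω = H A H (A the symmetric raw weights, H the centering
    projector) with positive eigenvalues, ordered by decreasing Moran's I —
    which for symmetric A coincides with decreasing eigenvalue order. Columns
    are named mem_1, mem_2, …; eigenvalues are stored in ``df.attrs``.
    """
    a = 0.5 * (weights.raw + weights.raw.T)
    n = a.shape[0]
    h = np.eye(n) - np.ones((n, n)) / n
    omega = h @ a @ h
    omega = 0.5 * (omega + omega.T)
    vals, vecs = np.linalg.eigh(omega)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > tol * max(abs(vals[0]), 1.0)
    if not keep.any():
        raise ValueError("degenerate weight matrix: no positive MEM eigenvalues")
    vals, vecs = vals[keep], vecs[:, keep]
    # order by the Moran's I each vector attains under the row-normalized
    # weights actually used in testing (matches eigenvalue order only when
    # the weights are symmetric)
    scores = np.array([morans_i(vecs[:, k], weights, n_perm=0).I for k in range(vecs.shape[1])])
    order = np.argsort(-scores)
    vals, vecs = vals[order], vecs[:, order]
    df = pd.DataFrame(vecs, columns=[f"mem_{i+1}" for i in range(vecs.shape[1])])
    df.attrs["eigenvalues"] = vals
    df.attrs["moran_i"] = scores[order]
    return df


# ---------------------------------------------------------------------- #
def compute_vifs(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors (intercept included).

    Computed as the diagonal of the inverse correlation matrix, which equals
    the regression definition 1/(1 − R²_j) for standardized predictors. A
    singular correlation matrix (exact collinearity) yields +inf for the
    involved predictors.
    """
    r = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    r = np.atleast_2d(r)
    try:
        inv = np.linalg.inv(r)
        vifs = np.diag(inv).copy()
        if (vifs < 0.999).any():  # numerically broken inverse
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        eig = np.linalg.eigvalsh(r)
        if eig.min() < 1e-10 * max(eig.max(), 1.0):
            vifs = np.full(r.shape[0], np.inf)
        else:
            vifs = np.diag(np.linalg.pinv(r)).copy()
    return pd.Series(np.where(np.isfinite(vifs), np.maximum(vifs, 1.0), np.inf),
                     index=X.columns)


def prune_predictors(
    X: pd.DataFrame,
    y: np.ndarray,
    cor_threshold: float = 0.75,
    vif_threshold: float = 5.0,
) -> tuple[list[str], pd.DataFrame]:
    """Multicollinearity screening: correlation then VIF pruning.

    Zero-variance predictors are dropped first. While any pair exceeds
    ``cor_threshold`` in |Pearson r|, the member less rank-correlated
    (|Spearman|) with the response is removed. Then, while any variance
    inflation factor exceeds ``vif_threshold``, the violating predictor
    least rank-correlated with the response is removed. Returns the kept
    names and a removal log (predictor, reason, detail).
    """
    X = X.astype(float)
    log_rows = []
    kept = list(X.columns)

    for c in list(kept):
        if X[c].nunique(dropna=False) <= 1 or X[c].std(ddof=0) == 0:
            kept.remove(c)
            log_rows.append({"predictor": c, "reason": "ZV", "detail": "zero variance"})
    if not kept:
        raise NoPredictorsError("all predictors have zero variance")

    y = np.asarray(y, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        relevance = {
            c: abs(spearmanr(X[c].to_numpy(), y).statistic) for c in kept
        }
    relevance = {c: (0.0 if not np.isfinite(v) else v) for c, v in relevance.items()}

    def drop_weaker(c1: str, c2: str, reason: str, detail: str):
        # drop the less response-relevant member; ties drop the later name
        if (relevance[c1], c2) < (relevance[c2], c1):
            victim = c1
        else:
            victim = c2
        kept.remove(victim)
        log_rows.append({"predictor": victim, "reason": reason, "detail": detail})

    full_corr = X[kept].corr().abs()
    while len(kept) > 1:
        corr = full_corr.loc[kept, kept].to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= cor_threshold:
            break
        drop_weaker(kept[i], kept[j], "COR", f"|r|={corr[i, j]:.3f}")

    # VIF stage: forward selection in response-relevance order, admitting a
    # predictor only while the selected set's max VIF stays within threshold.
    # This keeps the most relevant member of every multicollinear set (the
    # pairwise rule above, generalized to sets).
    if len(kept) > 1 and compute_vifs(X[kept]).max() > vif_threshold:
        order = sorted(kept, key=lambda c: (-relevance[c], c))
        selected = [order[0]]
        for c in order[1:]:
            trial = selected + [c]
            if compute_vifs(X[trial]).max() <= vif_threshold:
                selected.append(c)
            else:
                log_rows.append(
                    {"predictor": c, "reason": "VIF", "detail": "raises max VIF above threshold"}
                )
        kept = [c for c in kept if c in selected]

    if not kept:
        raise NoPredictorsError("pruning removed every predictor")
    return kept, pd.DataFrame(log_rows, columns=["predictor", "reason", "detail"])


# ---------------------------------------------------------------------- #
def _oob_masks(forest: RandomForestRegressor, n: int) -> list[np.ndarray]:
    masks = []
    for sample_idx in forest.estimators_samples_:
        m = np.ones(n, dtype=bool)
        m[sample_idx] = False
        masks.append(m)
    return masks


def _oob_predict(forest, X: np.ndarray, masks) -> np.ndarray:
    n = X.shape[0]
    pred = np.zeros(n)
    count = np.zeros(n)
    for tree, m in zip(forest.estimators_, masks):
        if m.any():
            pred[m] += tree.predict(X[m])
            count[m] += 1
    with np.errstate(invalid="ignore"):
        out = pred / count
    out[count == 0] = np.nan
    return out


def oob_permutation_importance(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Increase in out-of-bag MSE when each predictor column is permuted.

    Negative increases are clipped to zero (importances are reported as
    nonnegative scores).
    """
    n = X.shape[0]
    masks = _oob_masks(forest, n)
    base = _oob_predict(forest, X, masks)
    ok = np.isfinite(base)
    mse0 = float(np.mean((y[ok] - base[ok]) ** 2))
    imps = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = Xp[rng.permutation(n), j]
        pred = _oob_predict(forest, Xp, masks)
        okj = np.isfinite(pred)
        imps[j] = np.mean((y[okj] - pred[okj]) ** 2) - mse0
    return np.clip(imps, 0.0, None)


class SpatialRandomForest:
    """Random-forest model of a site-level response with spatial diagnostics.

    Parameters
    ----------
    y : array-like (n_sites,)
        Response (e.g. per-site temporal beta-diversity).
    X : pandas.DataFrame (n_sites × p)
        Screened predictor table (no missing values; prune first).
    coords : array-like (n_sites, 2)
        Planar site coordinates for the Euclidean distance matrix.
    thresholds : sequence of float, optional
        Distance thresholds for the Moran diagnostics; default = quartiles of
        the pairwise-distance distribution.
    min_sites : int
        Refuse to fit below this many sites (default 30).
    """

    def __init__(
        self,
        y,
        X: pd.DataFrame,
        coords,
        thresholds=None,
        min_sites: int = 30,
        alpha: float = 0.05,
        max_spatial_predictors: int | None = 20,
        rf_params: dict | None = None,
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = X.astype(float).reset_index(drop=True)
        self.coords = np.asarray(coords, dtype=float)
        if len(self.y) < min_sites:
            raise TooFewSitesError(
                f"{len(self.y)} sites < minimum {min_sites} for a stable forest"
            )
        if self.X.isna().any().any():
            raise ValueError("X contains missing values; impute upstream")
        self.thresholds = (
            list(thresholds) if thresholds is not None else default_thresholds(self.coords)
        )
        self.alpha = alpha
        self.max_spatial_predictors = max_spatial_predictors
        # library defaults are sufficient; only concurrency/seed handled here
        self.rf_params = {"n_estimators": 100, "n_jobs": 1}
        if rf_params:
            self.rf_params.update(rf_params)
        self._weights = [SpatialWeights.from_coords(self.coords, t) for t in self.thresholds]

    # -------------------------------------------------------------- #
    def _forest(self, seed: int) -> RandomForestRegressor:
        return RandomForestRegressor(
            oob_score=True, random_state=int(seed), **self.rf_params
        )

    def _residual_moran(self, resid: np.ndarray, n_perm: int, rng) -> list[MoranResult]:
        return [
            morans_i(resid, w, n_perm=n_perm,
                     seed=int(rng.integers(2**31 - 1)), variable="residuals")
            for w in self._weights
        ]

    def fit(
        self,
        n_runs: int = 30,
        seed: int | None = None,
        n_perm_moran: int = 999,
    ) -> "SpatialRandomForestResults":
        """Fit the spatial RF and repeat the final model ``n_runs`` times."""
        rng = np.random.default_rng(seed)
        design = self.X.copy()

        forest = self._forest(rng.integers(2**31 - 1))
        forest.fit(design.to_numpy(), self.y)
        resid = self.y - forest.oob_prediction_
        moran0 = self._residual_moran(resid, n_perm_moran, rng)

        spatial_used: list[str] = []
        moran_final = moran0
        if any(m.p_value is not None and m.p_value <= self.alpha for m in moran0):
            worst = min(moran0, key=lambda m: m.p_value)
            w = self._weights[self.thresholds.index(worst.threshold)]
            mems = mem_spatial_predictors(w)
            limit = self.max_spatial_predictors or mems.shape[1]
            for k in range(min(limit, mems.shape[1])):
                design[mems.columns[k]] = mems.iloc[:, k].to_numpy()
                spatial_used.append(mems.columns[k])
                forest = self._forest(rng.integers(2**31 - 1))
                forest.fit(design.to_numpy(), self.y)
                resid = self.y - forest.oob_prediction_
                moran_final = self._residual_moran(resid, n_perm_moran, rng)
                if all(m.p_value > self.alpha for m in moran_final):
                    break
            else:
                warnings.warn(
                    "spatial predictors exhausted with residual autocorrelation "
                    "still significant", stacklevel=2,
                )

        cols = list(design.columns)
        Xmat = design.to_numpy()
        oob_r2 = np.empty(n_runs)
        importances = np.empty((n_runs, len(cols)))
        models = []
        for r in range(n_runs):
            f = self._forest(rng.integers(2**31 - 1))
            f.fit(Xmat, self.y)
            oob_r2[r] = f.oob_score_
            importances[r] = oob_permutation_importance(f, Xmat, self.y, rng)
            models.append(f)

        return SpatialRandomForestResults(
            model=self,
            predictors=cols,
            spatial_predictors_used=spatial_used,
            design=design,
            oob_r2=oob_r2,
            importances=pd.DataFrame(importances, columns=cols),
            residual_moran=moran_final,
            nonspatial_moran=moran0,
            models=models,
        )


@dataclass
class SpatialRandomForestResults:
    """Fit results: OOB R² distribution, importances, spatial diagnostics."""

    model: SpatialRandomForest
    predictors: list[str]
    spatial_predictors_used: list[str]
    design: pd.DataFrame
    oob_r2: np.ndarray
    importances: pd.DataFrame
    residual_moran: list[MoranResult]
    nonspatial_moran: list[MoranResult]
    models: list = field(repr=False, default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.oob_r2)

    def median_importance(self) -> pd.Series:
        return self.importances.median().sort_values(ascending=False)

    def importance_rank(self, predictor: str) -> int:
        """1-based rank of a predictor by median importance."""
        order = list(self.median_importance().index)
        return order.index(predictor) + 1

    def partial_dependence(self, predictor: str, grid_size: int = 25) -> pd.DataFrame:
        """Partial dependence with other predictors held at their medians.

        Predictions are averaged across all repeated runs; the grid spans the
        predictor's observed range.
        """
        if predictor not in self.predictors:
            raise KeyError(f"unknown predictor {predictor!r}")
        col = self.design[predictor].to_numpy()
        grid = np.linspace(col.min(), col.max(), grid_size)
        ref = self.design.median().to_numpy()
        Xg = np.tile(ref, (grid_size, 1))
        j = self.predictors.index(predictor)
        Xg[:, j] = grid
        preds = np.mean([m.predict(Xg) for m in self.models], axis=0)
        return pd.DataFrame({predictor: grid, "prediction": preds})

    def summary(self) -> str:
        med = float(np.median(self.oob_r2))
        mad = float(np.median(np.abs(self.oob_r2 - med)))
        lines = [
            "Spatial random forest results",
            "=" * 34,
            f"sites:               {len(self.model.y)}",
            f"predictors:          {len(self.predictors)} "
            f"(incl. {len(self.spatial_predictors_used)} spatial)",
            f"runs:                {self.n_runs}",
            f"OOB R2 median (MAD): {med:.3f} ({mad:.3f})",
            "",
            "Residual Moran's I by distance threshold:",
        ]
        for m in self.residual_moran:
            lines.append(
                f"  d<={m.threshold:>10.3f}  I={m.I:+.4f}  E[I]={m.expected_I:+.4f}"
                f"  p={m.p_value:.4f}"
            )
        lines += ["", "Top predictors by median OOB permutation importance:"]
        for name, v in self.median_importance().head(8).items():
            lines.append(f"  {name:<32s} {v:.5f}")
        return "\n".join(lines)


def train_test_r2(
    results: SpatialRandomForestResults,
    test_fraction: float = 0.25,
    n_splits: int = 30,
    seed: int | None = None,
) -> np.ndarray:
    """Optional evaluation: R² over repeated random train/test splits."""
    from sklearn.metrics import r2_score
    from sklearn.model_selection import train_test_split

    rng = np.random.default_rng(seed)
    X = results.design.to_numpy()
    y = results.model.y
    out = np.empty(n_splits)
    for k in range(n_splits):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_fraction, random_state=int(rng.integers(2**31 - 1))
        )
        f = RandomForestRegressor(
            random_state=int(rng.integers(2**31 - 1)), **results.model.rf_params
        ).fit(Xtr, ytr)
        out[k] = r2_score(yte, f.predict(Xte))
    return out


def spearman_screen(X: pd.DataFrame, y) -> pd.DataFrame:
    """Reporting routine: Spearman correlation of each predictor with y."""
    y = np.asarray(y, dtype=float)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in X.columns:
            r = spearmanr(X[c].to_numpy(dtype=float), y)
            rows.append({"predictor": c, "spearman_r": r.statistic, "p_value": r.pvalue})
    return pd.DataFrame(rows).set_index("predictor")
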