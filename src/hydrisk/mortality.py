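"""Drought-mortality occurrence models.

Species-level models relate hydraulic safety margins to recorded mortality
(binomial occurrence and Poisson event counts) on balanced resamples of
no-mortality species. Assemblage-level models relate per-pixel risk metrics
to mortality presence against equal-sized random background draws, repeated
and averaged. Evaluation uses Nagelkerke pseudo-R^2 and cross-validated
AUC; spatial autocorrelation of residuals is checked with a Mantel
permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.spatial.distance import pdist
from sklearn.metrics import roc_auc_score

__all__ = [
    "dedup_events",
    "fit_glm",
    "species_mortality_models",
    "assemblage_mortality_models",
    "evaluate_glm",
    "mantel_residual_test",
    "per_level_trends",
    "nagelkerke_r2",
]


# --------------------------------------------------------------------------
# record thinning
# --------------------------------------------------------------------------

def dedup_events(points: pd.DataFrame, cell_size: float) -> pd.DataFrame:
    """Keep one record per occupied cell of a square grid of ``cell_size``.

    The grid origin is anchored at the lower-left corner of the data
    bounding box; within a cell the first record in file order is retained.
    The number retained equals the number of distinct occupied cells, so the
    count is tie-break-invariant.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    if points.empty:
        return points.copy()
    x0, y0 = points["x"].min(), points["y"].min()
    cx = np.floor((points["x"] - x0) / cell_size).astype(int)
    cy = np.floor((points["y"] - y0) / cell_size).astype(int)
    key = pd.Series(list(zip(cx, cy)), index=points.index)
    keep = ~key.duplicated(keep="first")
    out = points[keep].copy()
    out.attrs["n_input"] = len(points)
    out.attrs["n_retained"] = int(keep.sum())
    return out


# --------------------------------------------------------------------------
# GLM core
# --------------------------------------------------------------------------

_FAMILIES = {
    "binomial": sm.families.Binomial,
    "poisson": sm.families.Poisson,
}


def fit_glm(X: np.ndarray | pd.DataFrame, y: np.ndarray, family: str = "binomial"):
    """Canonical-link GLM by IRLS; aliased columns dropped and reported.

    Returns a statsmodels results object with extra attributes
    ``dropped_columns`` and ``separation_flag`` (binomial fits whose
    coefficients diverge are returned with a warning rather than rejected).
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {sorted(_FAMILIES)}")
    X = pd.DataFrame(X).copy()
    y = np.asarray(y, dtype=float)
    dropped: list[str] = []
    # drop aliased (linearly dependent) columns, keeping the earliest set
    arr = X.to_numpy(dtype=float)
    keep: list[int] = []
    for j in range(arr.shape[1]):
        cand = arr[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(str(X.columns[j]))
    if dropped:
        warnings.warn(f"dropped aliased columns: {dropped}")
        X = X.iloc[:, keep]
    model = sm.GLM(y, X, family=_FAMILIES[family]())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(tol=1e-8, maxiter=200)
    res.dropped_columns = dropped
    res.separation_flag = bool(np.abs(res.params).max() > 30) and family == "binomial"
    if res.separation_flag:
        warnings.warn("possible complete separation: coefficients diverging")
    return res


def nagelkerke_r2(res) -> float:
    """Nagelkerke pseudo-R^2 from a fitted binary GLM."""
    n = res.nobs
    ll1 = res.llf
    ll0 = res.llnull
    cox = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    denom = 1.0 - np.exp((2.0 / n) * ll0)
    return float(cox / denom) if denom > 0 else np.nan


def mcfadden_r2(res) -> float:
    return float(1.0 - res.llf / res.llnull)


def _anova_sequential(formula: str, data: pd.DataFrame, family: str) -> pd.DataFrame:
    """Sequential (type-I) likelihood-ratio tests per formula term."""
    from scipy import stats as sps

    fam = _FAMILIES[family]()
    full = smf.glm(formula, data, family=fam).fit()
    terms = [t for t in full.model.data.design_info.term_names if t != "Intercept"]
    rows = []
    prev_dev, prev_df = None, None
    for i in range(len(terms) + 1):
        sub = "1" if i == 0 else " + ".join(terms[:i])
        lhs = formula.split("~")[0].strip()
        res = smf.glm(f"{lhs} ~ {sub}", data, family=fam).fit()
        if i > 0:
            ddev = prev_dev - res.deviance
            ddf = prev_df - res.df_resid
            p = sps.chi2.sf(ddev, ddf) if ddf > 0 else np.nan
            rows.append({"term": terms[i - 1], "deviance": ddev, "df": ddf, "p": p})
        prev_dev, prev_df = res.deviance, res.df_resid
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def evaluate_glm(
    formula: str,
    data: pd.DataFrame,
    family: str = "binomial",
    train_fraction: float = 0.8,
    reps: int = 10,
    seed: int | np.random.Generator = 0,
    pseudo_r2: str = "nagelkerke",
) -> dict:
    """Nagelkerke pseudo-R^2 of the full fit plus repeated hold-out AUC.

    Per repetition the rows are split at ``train_fraction``; the model is
    refit on the training part and AUC (rank statistic, tie-corrected)
    computed on the test part. Single-class test splits are skipped and
    counted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fam = _FAMILIES[family]()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.glm(formula, data, family=fam).fit()
    r2 = nagelkerke_r2(full) if pseudo_r2 == "nagelkerke" else mcfadden_r2(full)
    aucs, skipped = [], 0
    n = len(data)
    lhs = formula.split("~")[0].strip()
    for _ in range(reps):
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        train, test = data.iloc[perm[:n_train]], data.iloc[perm[n_train:]]
        y_test = test[lhs].to_numpy()
        if family == "poisson":  # AUC on the any-event indicator
            y_test = (y_test > 0).astype(float)
        if len(np.unique(y_test)) < 2:
            skipped += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.glm(formula, train, family=fam).fit()
                score = res.predict(test)
        except Exception:
            skipped += 1
            continue
        aucs.append(roc_auc_score(y_test, score))
    return {
        "pseudo_r2": r2,
        "auc_mean": float(np.mean(aucs)) if aucs else np.nan,
        "auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        "reps_done": len(aucs),
        "reps_skipped": skipped,
        "fit": full,
    }


def mantel_residual_test(
    residuals: np.ndarray,
    coordinates: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mantel test of residual structure against geographic distance.

    r is the Pearson correlation between the off-diagonal entries of the
    |r_i - r_j| matrix and the Euclidean distance matrix; p is the one-sided
    permutation probability (1 + #{r_perm >= r_obs}) / (n_perm + 1).
    """
    residuals = np.asarray(residuals, dtype=float)
    coordinates = np.asarray(coordinates, dtype=float)
    if len(residuals) < 4:
        raise ValueError("need at least 4 pixels")
    if np.ptp(residuals) == 0:
        warnings.warn("constant residuals: Mantel r undefined")
        return np.nan, np.nan
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geo = pdist(coordinates)
    n = len(residuals)

    def corr(res_vec: np.ndarray) -> float:
        rd = pdist(res_vec[:, None], metric="cityblock")
        return float(np.corrcoef(rd, geo)[0, 1])

    r_obs = corr(residuals)
    count = 0
    for _ in range(n_perm):
        if corr(residuals[rng.permutation(n)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, p


def per_level_trends(
    fit, data: pd.DataFrame, metric: str, factor: str
) -> pd.DataFrame:
    """Within-level slope of ``metric`` from a metric x factor interaction fit.

    The slope for each factor level is the linear combination of
    coefficients given by differencing the design row at metric = 1 and
    metric = 0 (other covariates at their means); its standard error comes
    from the delta method on the coefficient covariance.
    """
    from patsy import build_design_matrices
    from scipy import stats as sps

    design_info = fit.model.data.design_info
    cov = fit.cov_params()
    if isinstance(cov, pd.DataFrame):
        cov = cov.to_numpy()
    params = np.asarray(fit.params)
    levels = sorted(pd.unique(data[factor]))
    base = {}
    for col in data.columns:
        if pd.api.types.is_numeric_dtype(data[col]):
            base[col] = data[col].mean()
        else:
            base[col] = data[col].iloc[0]
    rows = []
    for lev in levels:
        sub = data[data[factor] == lev]
        if sub[metric].nunique() <= 1 and len(sub) > 0:
            rows.append({"level": lev, "slope": np.nan, "se": np.nan, "z": np.nan, "p": np.nan})
            continue
        lo, hi = dict(base), dict(base)
        lo[factor] = hi[factor] = lev
        lo[metric], hi[metric] = 0.0, 1.0
        frame = pd.DataFrame([lo, hi])
        (mat,) = build_design_matrices([design_info], frame)
        contrast = np.asarray(mat)[1] - np.asarray(mat)[0]
        slope = float(contrast @ params)
        se = float(np.sqrt(contrast @ cov @ contrast))
        z = slope / se if se > 0 else np.nan
        p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"level": lev, "slope": slope, "se": se, "z": z, "p": p})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# resampled model ensembles
# --------------------------------------------------------------------------

@dataclass
class EnsembleSummary:
    """Averaged summaries of a resampled GLM design."""

    coefficients: pd.DataFrame
    pseudo_r2: float
    auc: float
    anova: pd.DataFrame | None
    iterations: int
    extra: dict = _field(default_factory=dict)


def _average_frames(frames: list[pd.DataFrame]) -> pd.DataFrame:
    stacked = pd.concat(frames)
    return stacked.groupby(stacked.index, sort=False).mean()


def species_mortality_models(
    species_table: pd.DataFrame,
    reps: int = 100,
    seed: int = 0,
    hsm_column: str = "hsm",
    clade_interaction: bool = False,
    eval_reps: int = 5,
) -> dict[str, EnsembleSummary]:
    """Balanced resampling of species without mortality; binomial + Poisson.

    ``species_table`` needs ``mortality`` (0/1), ``n_events`` (counts) and
    the HSM column (plus ``clade`` when the interaction is requested). Per
    repetition all mortality species are joined by an equal-sized random
    sample of no-mortality species (count response 0); both families are
    fitted and all summaries averaged over repetitions.
    """
    rng = np.random.default_rng(seed)
    pos = species_table[species_table["mortality"] == 1]
    neg = species_table[species_table["mortality"] == 0]
    if len(pos) < 2:
        raise ValueError("need at least 2 species with mortality")
    if len(neg) == 0:
        raise ValueError("no species without mortality to sample")
    rhs = f"{hsm_column} * clade" if clade_interaction else hsm_column
    out: dict[str, list] = {"binomial": [], "poisson": []}
    evals: dict[str, list] = {"binomial": [], "poisson": []}
    for _ in range(reps):
        take = rng.choice(neg.index, size=min(len(pos), len(neg)), replace=False)
        sample = pd.concat([pos, neg.loc[take]])
        for family, resp in (("binomial", "mortality"), ("poisson", "n_events")):
            ev = evaluate_glm(
                f"{resp} ~ {rhs}", sample, family=family, reps=eval_reps, seed=rng
            )
            res = ev["fit"]
            coefs = pd.DataFrame(
                {"estimate": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
            )
            out[family].append(coefs)
            evals[family].append((ev["pseudo_r2"], ev["auc_mean"]))
    summaries = {}
    for family in ("binomial", "poisson"):
        r2s, aucs = zip(*evals[family])
        summaries[family] = EnsembleSummary(
            coefficients=_average_frames(out[family]),
            pseudo_r2=float(np.nanmean(r2s)),
            auc=float(np.nanmean(aucs)),
            anova=None,
            iterations=reps,
        )
    return summaries


def assemblage_mortality_models(
    metrics_table: pd.DataFrame,
    presence_cells: np.ndarray,
    formula_rhs: str,
    reps: int = 100,
    seed: int = 0,
    eval_reps: int = 5,
    coordinates: pd.DataFrame | None = None,
    mantel_perms: int = 0,
) -> EnsembleSummary:
    """Background-resampled binomial GLM of mortality presence on metrics.

    ``metrics_table`` is indexed by cell id with metric/factor columns;
    presences with undefined metrics are dropped (reported in ``extra``).
    Per repetition, backgrounds are sampled uniformly (without replacement)
    from defined-metric cells with no observed mortality, matching the
    presence count; the binomial fit of ``mortality ~ formula_rhs`` and its
    summaries are averaged over repetitions.
    """
    rng = np.random.default_rng(seed)
    used_cols = [c for c in metrics_table.columns]
    defined = metrics_table.dropna(subset=[c for c in used_cols]).index
    presence_cells = np.asarray(presence_cells)
    pres = pd.Index(np.unique(presence_cells))
    pres_ok = pres.intersection(defined)
    dropped = len(pres) - len(pres_ok)
    candidates = defined.difference(pres)
    if len(candidates) < len(pres_ok):
        raise ValueError("fewer candidate background pixels than presences")
    coef_frames, r2s, aucs, anovas = [], [], [], []
    mantels = []
    for _ in range(reps):
        bg = rng.choice(candidates, size=len(pres_ok), replace=False)
        rows = metrics_table.loc[list(pres_ok) + list(bg)].copy()
        rows["mortality"] = np.r_[np.ones(len(pres_ok)), np.zeros(len(bg))]
        ev = evaluate_glm(
            f"mortality ~ {formula_rhs}", rows, family="binomial",
            reps=eval_reps, seed=rng,
        )
        res = ev["fit"]
        coef_frames.append(
            pd.DataFrame(
                {"estimate": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
            )
        )
        r2s.append(ev["pseudo_r2"])
        aucs.append(ev["auc_mean"])
        anovas.append(_anova_sequential(f"mortality ~ {formula_rhs}", rows, "binomial").set_index("term"))
        if mantel_perms and coordinates is not None:
            resid = np.asarray(res.resid_deviance)
            coords = coordinates.loc[rows.index].to_numpy()
            r, p = mantel_residual_test(resid, coords, n_perm=mantel_perms, seed=rng)
            mantels.append((r, p))
    extra = {"presences_dropped": dropped, "n_presence": int(len(pres_ok))}
    if mantels:
        extra["mantel_r"] = float(np.nanmean([m[0] for m in mantels]))
        extra["mantel_p"] = float(np.nanmean([m[1] for m in mantels]))
    return EnsembleSummary(
        coefficients=_average_frames(coef_frames),
        pseudo_r2=float(np.nanmean(r2s)),
        auc=float(np.nanmean(aucs)),
        anova=_average_frames(anovas),
        iterations=reps,
        extra=extra,
    )
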