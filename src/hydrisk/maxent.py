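"""Presence/background maximum-entropy occurrence model with hinge features.

The model is the Gibbs distribution q_lambda(x) = exp(lambda . f(x)) / Z
over the background sample, fitted by maximizing the L1-penalized mean
presence log-likelihood. Features are forward/reverse hinges on an
equally-spaced knot grid per continuous variable (scaled to [0, 1]) plus
one-hot indicators for factors. The penalty per feature is
reg_multiplier * 0.5 * sd_presence(feature) / sqrt(n_presence), the hinge
schedule of the reference tool family. The solver is FISTA with
soft-thresholding and adaptive restart; convergence is certified by the
L1 subgradient (KKT) condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score

__all__ = [
    "FeatureMap",
    "MaxentModel",
    "build_features",
    "fit_maxent",
    "predict_maxent",
    "training_auc",
    "select_uncorrelated_vars",
    "jackknife_contribution",
    "permutation_importance",
    "evaluate_repeated",
    "run_model_suite",
]

HINGE_BETA_BASE = 0.5


@dataclass
class FeatureMap:
    """Hinge + indicator feature expansion of a variable table."""

    continuous: dict[str, tuple[np.ndarray, float, float]]  # var -> (knots, min, max)
    factors: dict[str, list]  # var -> levels
    feature_names: list[str] = field(default_factory=list)
    feature_variable: list[str] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return list(self.continuous) + list(self.factors)

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in data.columns]
        if missing:
            raise KeyError(f"rows are missing model variables: {missing}")
        cols: list[np.ndarray] = []
        for var, (knots, lo, hi) in self.continuous.items():
            x = data[var].to_numpy(dtype=float)
            if not np.isfinite(x).all():
                raise ValueError(f"non-finite values in variable {var!r}")
            for k in knots[:-1]:  # forward hinges: max(0, x - k) / (max - k)
                cols.append(np.clip((x - k) / (hi - k), 0.0, 1.0))
            for k in knots[1:]:  # reverse hinges: max(0, k - x) / (k - min)
                cols.append(np.clip((k - x) / (k - lo), 0.0, 1.0))
        for var, levels in self.factors.items():
            x = data[var].to_numpy()
            for lev in levels:
                cols.append((x == lev).astype(float))
        return np.column_stack(cols) if cols else np.empty((len(data), 0))

    def restricted_to(self, variables: Sequence[str]) -> "FeatureMap":
        keep = set(variables)
        fm = FeatureMap(
            {v: k for v, k in self.continuous.items() if v in keep},
            {v: lv for v, lv in self.factors.items() if v in keep},
        )
        fm._name_features()
        return fm

    def _name_features(self) -> None:
        names, owner = [], []
        for var, (knots, lo, hi) in self.continuous.items():
            for k in knots[:-1]:
                names.append(f"{var}:fwd@{k:.6g}")
                owner.append(var)
            for k in knots[1:]:
                names.append(f"{var}:rev@{k:.6g}")
                owner.append(var)
        for var, levels in self.factors.items():
            for lev in levels:
                names.append(f"{var}=={lev}")
                owner.append(var)
        self.feature_names, self.feature_variable = names, owner


def build_features(
    data: pd.DataFrame,
    factors: Sequence[str] = (),
    n_knots: int = 50,
) -> tuple[FeatureMap, np.ndarray]:
    """Feature map from observed variable ranges, plus the design values.

    Knots are ``n_knots`` equally spaced values across each continuous
    variable's observed range; constant variables are excluded with a
    warning. Factor columns are one-hot encoded per observed level.
    """
    continuous: dict[str, tuple[np.ndarray, float, float]] = {}
    fac: dict[str, list] = {}
    for col in data.columns:
        if col in factors:
            fac[col] = sorted(pd.unique(data[col]).tolist())
            continue
        x = data[col].to_numpy(dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo <= 0:
            warnings.warn(f"constant variable {col!r} excluded from features")
            continue
        continuous[col] = (np.linspace(lo, hi, n_knots), lo, hi)
    fm = FeatureMap(continuous, fac)
    fm._name_features()
    return fm, fm.transform(data)


@dataclass
class MaxentModel:
    feature_map: FeatureMap
    coefficients: np.ndarray  # lambda
    reg_weights: np.ndarray  # beta per feature
    log_z: float  # log background normalizer
    entropy: float  # entropy of q over the training background
    presence_means: np.ndarray
    training_gain: float
    n_background: int
    converged: bool
    n_iter: int


def _objective(lam, Fp_mean, Fb, beta):
    log_z = logsumexp(Fb @ lam)
    smooth = -(Fp_mean @ lam - log_z)
    return smooth + np.abs(lam) @ beta, log_z


def _grad_smooth(lam, Fp_mean, Fb):
    eta = Fb @ lam
    w = np.exp(eta - logsumexp(eta))
    return -(Fp_mean - w @ Fb)


def fit_maxent(
    presence: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
    feature_map: FeatureMap | None = None,
    reg_multiplier: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 20000,
) -> MaxentModel:
    """L1-penalized maxent fit over a background sample.

    ``presence``/``background`` are variable tables (a feature map is built
    from the background if not given) or pre-transformed feature matrices
    when ``feature_map`` is provided and inputs are arrays. The training
    gain is the penalized mean presence log-probability plus
    log(n_background), zero for the uniform model.
    """
    if feature_map is None:
        stack = pd.concat([pd.DataFrame(background), pd.DataFrame(presence)])
        feature_map, _ = build_features(stack)
    if isinstance(presence, pd.DataFrame):
        Fp = feature_map.transform(presence)
        Fb = feature_map.transform(background)
    else:
        Fp, Fb = np.asarray(presence, float), np.asarray(background, float)
    if not (np.isfinite(Fp).all() and np.isfinite(Fb).all()):
        raise ValueError("non-finite feature values")
    m, d = Fp.shape
    if m < 1 or Fb.shape[0] < 2:
        raise ValueError("need >= 1 presence and >= 2 background rows")
    Fp_mean = Fp.mean(axis=0)
    # presence sd sets the per-feature penalty scale; floored so features
    # that happen to be constant over presences cannot escape regularization
    sd = np.maximum(Fp.std(axis=0), 0.05)
    beta = reg_multiplier * HINGE_BETA_BASE * sd / np.sqrt(m)
    if reg_multiplier <= 0:
        beta = np.zeros(d)

    lam = np.zeros(d)
    zlam = lam.copy()
    t_mom = 1.0
    L = 1.0
    f_prev, _ = _objective(lam, Fp_mean, Fb, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = _grad_smooth(zlam, Fp_mean, Fb)
        # backtracking on the smooth majorizer
        while True:
            cand = np.sign(zlam - g / L) * np.maximum(np.abs(zlam - g / L) - beta / L, 0.0)
            diff = cand - zlam
            smooth_z = _objective(zlam, Fp_mean, Fb, np.zeros(d))[0]
            smooth_c = _objective(cand, Fp_mean, Fb, np.zeros(d))[0]
            if smooth_c <= smooth_z + g @ diff + 0.5 * L * diff @ diff + 1e-12:
                break
            L *= 2.0
        f_new, _ = _objective(cand, Fp_mean, Fb, beta)
        if f_new > f_prev:  # adaptive restart
            zlam, t_mom = lam.copy(), 1.0
            continue
        t_next = (1 + np.sqrt(1 + 4 * t_mom**2)) / 2
        zlam = cand + ((t_mom - 1) / t_next) * (cand - lam)
        lam, t_mom, f_prev = cand, t_next, f_new
        L = max(L * 0.9, 1e-3)
        # KKT / subgradient check
        if it % 10 == 0 or it == max_iter:
            gl = _grad_smooth(lam, Fp_mean, Fb)
            viol = np.where(
                lam == 0.0,
                np.maximum(np.abs(gl) - beta, 0.0),
                np.abs(gl + beta * np.sign(lam)),
            )
            if viol.max() <= tol:
                converged = True
                break
    if not converged:
        warnings.warn(f"maxent solver hit max_iter={max_iter} before tol={tol}")
    log_z = logsumexp(Fb @ lam)
    q = np.exp(Fb @ lam - log_z)
    entropy = float(-(q * np.log(np.maximum(q, 1e-300))).sum())
    gain = float(Fp_mean @ lam - log_z - np.abs(lam) @ beta + np.log(Fb.shape[0]))
    return MaxentModel(
        feature_map, lam, beta, float(log_z), entropy, Fp_mean, gain,
        Fb.shape[0], converged, it,
    )


def predict_maxent(
    model: MaxentModel, rows: pd.DataFrame, output: str = "cloglog"
) -> np.ndarray:
    """Suitability of new rows.

    raw: q_lambda normalized over the model's training background (raw
    values over that background sum to 1). cloglog: 1 - exp(-exp(H) * raw)
    with H the entropy of q over the background — a strictly increasing
    transform of raw bounded in (0, 1).
    """
    F = model.feature_map.transform(rows)
    # exponent clipped: a feature with support only among presences makes
    # the unpenalized direction unbounded and coefficients can be huge
    raw = np.exp(np.clip(F @ model.coefficients - model.log_z, -700.0, 700.0))
    if output == "raw":
        return raw
    if output == "cloglog":
        return 1.0 - np.exp(-np.exp(model.entropy) * raw)
    raise ValueError(f"unknown output {output!r}")


def training_auc(model: MaxentModel, presence: pd.DataFrame, background: pd.DataFrame) -> float:
    score = np.r_[
        predict_maxent(model, presence, "raw"), predict_maxent(model, background, "raw")
    ]
    y = np.r_[np.ones(len(presence)), np.zeros(len(background))]
    return float(roc_auc_score(y, score))


# --------------------------------------------------------------------------
# variable screening, contribution, importance
# --------------------------------------------------------------------------

def _single_variable_gain(
    presence: pd.DataFrame, background: pd.DataFrame, var: str,
    feature_map: FeatureMap, reg_multiplier: float, tol: float,
) -> float:
    fm = feature_map.restricted_to([var])
    model = fit_maxent(presence, background, fm, reg_multiplier, tol=tol)
    return model.training_gain


def select_uncorrelated_vars(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    variables: Sequence[str],
    threshold: float = 0.75,
    feature_map: FeatureMap | None = None,
    reg_multiplier: float = 1.0,
    tol: float = 1e-4,
) -> list[str]:
    """Greedy screen: order by single-variable training gain, keep a variable
    iff |Pearson r| < threshold against every already-kept variable (r over
    the pooled presence + background rows)."""
    if not len(variables):
        raise ValueError("need at least one candidate variable")
    if feature_map is None:
        feature_map, _ = build_features(
            pd.concat([background[list(variables)], presence[list(variables)]])
        )
    gains = {
        v: _single_variable_gain(presence, background, v, feature_map, reg_multiplier, tol)
        for v in variables
    }
    order = sorted(variables, key=lambda v: -gains[v])
    pooled = pd.concat([presence[list(variables)], background[list(variables)]])
    kept: list[str] = []
    for v in order:
        ok = all(
            abs(np.corrcoef(pooled[v], pooled[u])[0, 1]) < threshold for u in kept
        )
        if ok:
            kept.append(v)
    return kept


def jackknife_contribution(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    variables: Sequence[str] | None = None,
    feature_map: FeatureMap | None = None,
    reg_multiplier: float = 1.0,
    tol: float = 1e-4,
    factors: Sequence[str] = (),
    n_knots: int = 50,
) -> pd.Series:
    """Percent contribution: single-variable training gain, floored at 0,
    normalized to sum 100."""
    if feature_map is None:
        feature_map, _ = build_features(
            pd.concat([background, presence]), factors=factors, n_knots=n_knots
        )
    variables = list(variables) if variables is not None else feature_map.variables
    gains = np.array([
        max(
            _single_variable_gain(presence, background, v, feature_map, reg_multiplier, tol),
            0.0,
        )
        for v in variables
    ])
    total = gains.sum()
    if total <= 0:
        warnings.warn("all single-variable gains are 0; contributions undefined")
        return pd.Series(np.nan, index=variables)
    return pd.Series(100.0 * gains / total, index=variables)


def permutation_importance(
    model: MaxentModel,
    presence: pd.DataFrame,
    background: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Normalized drop in training AUC when one variable is shuffled across
    the pooled presence + background rows (coefficients held fixed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    auc0 = training_auc(model, presence, background)
    m = len(presence)
    pooled = pd.concat([presence, background], ignore_index=True)
    drops = {}
    for var in model.feature_map.variables:
        shuffled = pooled.copy()
        shuffled[var] = rng.permutation(shuffled[var].to_numpy())
        auc = training_auc(model, shuffled.iloc[:m], shuffled.iloc[m:])
        drops[var] = max(auc0 - auc, 0.0)
    s = pd.Series(drops)
    total = s.sum()
    return 100.0 * s / total if total > 0 else s * 0.0


def evaluate_repeated(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    reps: int = 100,
    train_fraction: float = 0.8,
    seed: int | np.random.Generator = 0,
    factors: Sequence[str] = (),
    n_knots: int = 50,
    reg_multiplier: float = 1.0,
    tol: float = 1e-4,
) -> dict:
    """Repeated stratified evaluation: presences and backgrounds are split
    separately at ``train_fraction``; the model is fit on the training
    parts and AUC computed on the held-out parts; mean and sd over reps."""
    if len(presence) < 5:
        raise ValueError("need at least 5 presences")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aucs, skipped = [], 0
    for _ in range(reps):
        pi = rng.permutation(len(presence))
        bi = rng.permutation(len(background))
        np_tr = int(round(train_fraction * len(presence)))
        nb_tr = int(round(train_fraction * len(background)))
        p_tr, p_te = presence.iloc[pi[:np_tr]], presence.iloc[pi[np_tr:]]
        b_tr, b_te = background.iloc[bi[:nb_tr]], background.iloc[bi[nb_tr:]]
        if len(p_te) == 0 or len(b_te) == 0:
            skipped += 1
            continue
        fm, _ = build_features(
            pd.concat([b_tr, p_tr]), factors=factors, n_knots=n_knots
        )
        model = fit_maxent(p_tr, b_tr, fm, reg_multiplier, tol=tol)
        aucs.append(training_auc(model, p_te, b_te))
    return {
        "auc_mean": float(np.mean(aucs)) if aucs else np.nan,
        "auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        "reps_done": len(aucs),
        "reps_skipped": skipped,
    }


def run_model_suite(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    factor_vars: Sequence[str],
    continuous_vars: Sequence[str],
    hydraulic_vars: Sequence[str],
    reps: int = 20,
    seed: int = 0,
    n_knots: int = 50,
    reg_multiplier: float = 1.0,
    tol: float = 1e-4,
    projection_rows: pd.DataFrame | None = None,
) -> dict:
    """The a/b/c model suite on shared presences and backgrounds.

    a: factors only. b: factors + continuous edaphoclimatic variables.
    c: b with its two lowest-contribution continuous variables replaced by
    the two hydraulic metrics, keeping b and c at equal predictor counts.
    Reports per type the repeated-split test AUC, jackknife contributions,
    permutation importances, and (optionally) a projection.
    """
    hydraulic_vars = list(hydraulic_vars)
    continuous_vars = list(continuous_vars)
    if len(hydraulic_vars) != 2:
        raise ValueError("suite expects exactly two hydraulic metrics")
    for col in list(factor_vars) + continuous_vars + hydraulic_vars:
        for frame, label in ((presence, "presence"), (background, "background")):
            if col not in frame.columns:
                raise KeyError(f"layer {col!r} missing from {label} rows")
    rng = np.random.default_rng(seed)
    contrib_b = jackknife_contribution(
        presence, background, continuous_vars,
        factors=factor_vars, n_knots=n_knots,
        reg_multiplier=reg_multiplier, tol=tol,
    )
    lowest_two = list(contrib_b.sort_values().index[:2])
    kept = [v for v in continuous_vars if v not in lowest_two]
    suites = {
        "a": list(factor_vars),
        "b": list(factor_vars) + continuous_vars,
        "c": list(factor_vars) + kept + hydraulic_vars,
    }
    out: dict = {"replaced": lowest_two, "variables": suites}

    # paired evaluation: every repetition draws one stratified 80/20 split
    # shared by all three model types, so split noise cancels from the
    # between-type AUC comparison
    aucs: dict[str, list[float]] = {name: [] for name in suites}
    for _ in range(reps):
        pi = rng.permutation(len(presence))
        bi = rng.permutation(len(background))
        np_tr = int(round(0.8 * len(presence)))
        nb_tr = int(round(0.8 * len(background)))
        for name, cols in suites.items():
            facs = [f for f in factor_vars if f in cols]
            p_tr = presence[cols].iloc[pi[:np_tr]]
            p_te = presence[cols].iloc[pi[np_tr:]]
            b_tr = background[cols].iloc[bi[:nb_tr]]
            b_te = background[cols].iloc[bi[nb_tr:]]
            fm, _ = build_features(
                pd.concat([b_tr, p_tr]), factors=facs, n_knots=n_knots
            )
            model = fit_maxent(p_tr, b_tr, fm, reg_multiplier, tol=tol)
            aucs[name].append(training_auc(model, p_te, b_te))

    for name, cols in suites.items():
        pres, bg = presence[cols], background[cols]
        facs = [f for f in factor_vars if f in cols]
        fm, _ = build_features(pd.concat([bg, pres]), factors=facs, n_knots=n_knots)
        model = fit_maxent(pres, bg, fm, reg_multiplier, tol=tol)
        arr = np.asarray(aucs[name])
        report = {
            "model": model,
            "test_auc_mean": float(arr.mean()),
            "test_auc_sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "contribution": jackknife_contribution(
                pres, bg, feature_map=fm, reg_multiplier=reg_multiplier, tol=tol
            ),
            "permutation_importance": permutation_importance(model, pres, bg, rng),
        }
        if projection_rows is not None:
            report["projection"] = predict_maxent(model, projection_rows[cols])
        out[name] = report
    return out
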