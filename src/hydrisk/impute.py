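"""Trait imputation: iterative random-forest completion of a mixed table,
repeated cross-validation over predictor sets, ensemble imputation with
uncertainty, and hydraulic safety margins.

The imputer follows the classic iterative random-forest scheme: initialize
missing numerics with the column mean (categoricals with the mode), then
cycle over columns in order of increasing missingness, refitting a random
forest on the currently-completed other columns and re-predicting the
missing entries, until the change statistic first increases; the previous
iterate is returned. Observed values are never altered by any path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = [
    "ImputationSpec",
    "missforest_impute",
    "cross_validate_specs",
    "impute_traits_ensemble",
    "compute_hsm",
    "species_uncertainty",
]

TRAITS = ("p_min", "p50", "p88")


@dataclass(frozen=True)
class ImputationSpec:
    """A predictor set + RF settings for joint trait imputation."""

    name: str
    phylo_axes: int = 5
    env_components: int = 5
    include_clade: bool = True
    traits: tuple[str, ...] = ("p_min", "p50")
    n_trees: int = 100
    max_iter: int = 10

    def predictor_columns(self, table: pd.DataFrame) -> list[str]:
        cols = [f"axis{i + 1}" for i in range(self.phylo_axes)]
        cols += [f"pc{i + 1}" for i in range(self.env_components)]
        if self.include_clade:
            cols.append("clade")
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise KeyError(f"predictor columns absent from table: {missing}")
        return cols

    def columns(self, table: pd.DataFrame) -> list[str]:
        if not self.traits:
            raise ValueError("spec must impute at least one trait")
        return self.predictor_columns(table) + list(self.traits)


def _rf_seed(seed: int, iteration: int, col_index: int) -> int:
    return (int(seed) + 7919 * iteration + 104729 * col_index) % (2**31 - 1)


def missforest_impute(
    data: pd.DataFrame,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
    max_features: str | float = "sqrt",
) -> tuple[pd.DataFrame, dict]:
    """Iteratively complete a mixed numeric/categorical table with RFs.

    Numeric columns are float dtype; anything else is treated as
    categorical. The stopping statistic is sum((new-old)^2)/sum(new^2) over
    imputed numeric cells and the mismatch fraction over imputed categorical
    cells; iteration stops when every applicable statistic stops decreasing
    (or at ``max_iter``), and the previous iterate is returned.
    """
    data = data.copy()
    numeric = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    categorical = [c for c in data.columns if c not in numeric]
    miss = data.isna()
    if (miss.all(axis=0)).any():
        bad = list(data.columns[miss.all(axis=0)])
        raise ValueError(f"columns with no observed values: {bad}")

    cur = data.copy()
    for c in numeric:
        cur[c] = cur[c].fillna(data[c].mean())
    for c in categorical:
        cur[c] = cur[c].fillna(data[c].mode().iloc[0])

    targets = [c for c in data.columns if miss[c].any()]
    targets.sort(key=lambda c: miss[c].mean())
    if not targets:
        return cur, {"n_iter": 0, "num_stat": [], "cat_stat": []}

    def encode(frame: pd.DataFrame) -> np.ndarray:
        return pd.get_dummies(frame, columns=[c for c in frame.columns if c in categorical]).to_numpy(dtype=float)

    num_hist: list[float] = []
    cat_hist: list[float] = []
    n_done = 0
    for it in range(1, max_iter + 1):
        new = cur.copy()
        for j, col in enumerate(targets):
            obs = ~miss[col]
            predictors = [c for c in data.columns if c != col]
            X = encode(new[predictors])
            # per-column seed, constant across iterations: refitting with
            # unchanged inputs is then idempotent and the loop can converge
            rs = _rf_seed(seed, 0, j)
            if col in numeric:
                model = RandomForestRegressor(
                    n_estimators=n_trees, max_features=max_features, random_state=rs
                )
                model.fit(X[obs.to_numpy()], new.loc[obs, col].to_numpy(dtype=float))
                new.loc[miss[col], col] = model.predict(X[miss[col].to_numpy()])
            else:
                model = RandomForestClassifier(
                    n_estimators=n_trees, max_features=max_features, random_state=rs
                )
                model.fit(X[obs.to_numpy()], new.loc[obs, col].to_numpy())
                new.loc[miss[col], col] = model.predict(X[miss[col].to_numpy()])
        num_cols = [c for c in targets if c in numeric]
        cat_cols = [c for c in targets if c in categorical]
        worse = []
        if num_cols:
            num_new = np.concatenate([new.loc[miss[c], c].to_numpy(dtype=float) for c in num_cols])
            num_old = np.concatenate([cur.loc[miss[c], c].to_numpy(dtype=float) for c in num_cols])
            denom = (num_new**2).sum()
            stat = ((num_new - num_old) ** 2).sum() / denom if denom > 0 else 0.0
            worse.append(bool(num_hist) and stat >= num_hist[-1])
            num_hist.append(stat)
        if cat_cols:
            pairs = [(new.loc[miss[c], c].to_numpy(), cur.loc[miss[c], c].to_numpy()) for c in cat_cols]
            n_cells = sum(len(a) for a, _ in pairs)
            stat = sum((a != b).sum() for a, b in pairs) / n_cells
            worse.append(bool(cat_hist) and stat >= cat_hist[-1])
            cat_hist.append(stat)
        if worse and all(worse) and it > 1:
            # statistic increased: keep the previous iterate
            return cur, {"n_iter": n_done, "num_stat": num_hist, "cat_stat": cat_hist}
        cur = new
        n_done = it
        converged = (not num_cols or num_hist[-1] == 0.0) and (
            not cat_cols or cat_hist[-1] == 0.0
        )
        if converged:
            break
    return cur, {"n_iter": n_done, "num_stat": num_hist, "cat_stat": cat_hist}


def _r_squared(truth: np.ndarray, pred: np.ndarray, kind: str = "pearson") -> float:
    if kind == "pearson":
        if np.std(truth) == 0 or np.std(pred) == 0:
            return np.nan
        return float(np.corrcoef(truth, pred)[0, 1] ** 2)
    if kind == "sse":
        sst = ((truth - truth.mean()) ** 2).sum()
        return float(1.0 - ((truth - pred) ** 2).sum() / sst) if sst > 0 else np.nan
    raise ValueError(kind)


def cross_validate_specs(
    table: pd.DataFrame,
    specs: Sequence[ImputationSpec],
    test_fractions: Sequence[float] = (0.1,),
    reps: int = 10,
    seed: int = 0,
    r2_kind: str = "pearson",
) -> pd.DataFrame:
    """Repeated hold-out cross-validation of imputation predictor sets.

    Per repetition a random ``test_fraction`` of the *observed* values of
    each trait is hidden, the spec's table is imputed, and R^2 (squared
    Pearson correlation by default) between the held-out truth and the
    imputations is recorded. Returns a tidy frame (spec, trait, fraction,
    mean_r2, sd_r2, reps_done, reps_skipped); the best spec is the one with
    the highest mean R^2. Ten-fold CV is the special case fraction = 0.1.
    """
    for f in test_fractions:
        if not (0 < f < 1):
            raise ValueError("test fractions must be in (0, 1)")
    rows = []
    for spec in specs:
        cols = spec.columns(table)
        base = table[cols]
        for frac in test_fractions:
            scores: dict[str, list[float]] = {t: [] for t in spec.traits}
            skipped = 0
            for rep in range(reps):
                # hold-out masks depend only on (seed, fraction, rep) so that
                # competing specs are scored on identical held-out cells — a
                # paired design that sharpens spec ranking
                rng = np.random.default_rng(
                    np.random.SeedSequence((seed, int(frac * 1000), rep))
                )
                work = base.copy()
                held: dict[str, pd.Index] = {}
                ok = True
                for t in spec.traits:
                    obs_idx = base.index[base[t].notna()]
                    n_test = max(int(round(frac * len(obs_idx))), 1)
                    test_idx = pd.Index(rng.choice(obs_idx, size=n_test, replace=False))
                    if len(obs_idx) - n_test < 1 or n_test < 3:
                        ok = False
                    held[t] = test_idx
                    work.loc[test_idx, t] = np.nan
                if not ok:
                    skipped += 1
                    continue
                completed, _ = missforest_impute(
                    work, n_trees=spec.n_trees, max_iter=spec.max_iter,
                    seed=_rf_seed(seed, rep, 0),
                )
                for t in spec.traits:
                    truth = base.loc[held[t], t].to_numpy(dtype=float)
                    pred = completed.loc[held[t], t].to_numpy(dtype=float)
                    scores[t].append(_r_squared(truth, pred, r2_kind))
            for t in spec.traits:
                arr = np.asarray(scores[t], dtype=float)
                rows.append(
                    {
                        "spec": spec.name,
                        "trait": t,
                        "test_fraction": frac,
                        "mean_r2": float(np.nanmean(arr)) if arr.size else np.nan,
                        "sd_r2": float(np.nanstd(arr, ddof=1)) if arr.size > 1 else 0.0,
                        "reps_done": int(arr.size),
                        "reps_skipped": skipped,
                    }
                )
    return pd.DataFrame(rows)


def best_spec(report: pd.DataFrame, specs: Sequence[ImputationSpec]) -> ImputationSpec:
    """Spec with the highest mean R^2 averaged over traits and fractions."""
    ranking = report.groupby("spec")["mean_r2"].mean().sort_values(ascending=False)
    by_name = {s.name: s for s in specs}
    return by_name[ranking.index[0]]


def impute_traits_ensemble(
    table: pd.DataFrame,
    spec: ImputationSpec,
    n_iter: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Ensemble imputation: n_iter runs with sub-seeds seed+i.

    Observed values are kept verbatim; imputed cells get the ensemble mean
    and standard deviation (sd 0 with a flag when n_iter == 1).
    """
    cols = spec.columns(table)
    stacks: dict[str, list[np.ndarray]] = {t: [] for t in spec.traits}
    for i in range(n_iter):
        completed, _ = missforest_impute(
            table[cols], n_trees=spec.n_trees, max_iter=spec.max_iter, seed=seed + i
        )
        for t in spec.traits:
            stacks[t].append(completed[t].to_numpy(dtype=float))
    out = table.copy()
    for t in spec.traits:
        arr = np.stack(stacks[t])
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1) if n_iter > 1 else np.zeros(arr.shape[1])
        observed = table[t].notna().to_numpy()
        out[t] = np.where(observed, table[t].to_numpy(dtype=float), mean)
        out[f"{t}_sd"] = np.where(observed, 0.0, sd)
        out[f"{t}_source"] = np.where(observed, "observed", "imputed")
    out.attrs["n_iter"] = n_iter
    out.attrs["sd_degenerate"] = n_iter == 1
    return out


def compute_hsm(traits: pd.DataFrame, mode: str = "standard") -> pd.DataFrame:
    """Hydraulic safety margins.

    standard: HSM = P_min - P50 for every species (column ``hsm``).
    fifty_eighty_eight: gymnosperms use P50, angiosperms use P88 (column
    ``hsm_50_88``; requires the clade column). Missing inputs propagate to
    missing HSM, never zero.
    """
    out = traits.copy()
    if mode == "standard":
        out["hsm"] = out["p_min"] - out["p50"]
        return out
    if mode == "fifty_eighty_eight":
        if "clade" not in out.columns:
            raise KeyError("clade column required for the 50/88 variant")
        resist = out["p50"].where(out["clade"] == "gymnosperm", out["p88"])
        out["hsm_50_88"] = out["p_min"] - resist
        return out
    raise ValueError(f"unknown mode {mode!r}")


def species_uncertainty(
    table: pd.DataFrame,
    spec: ImputationSpec,
    exclude_fraction: float = 0.2,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Second uncertainty tier: sensitivity to the identity of training species.

    Per repetition, a random ``exclude_fraction`` of species with observed
    data have their trait values masked before refitting; the per-species
    standard deviation of predictions across repetitions is returned
    (columns ``<trait>_excl_sd``).
    """
    cols = spec.columns(table)
    preds: dict[str, list[np.ndarray]] = {t: [] for t in spec.traits}
    rng = np.random.default_rng(seed)
    for rep in range(reps):
        work = table[cols].copy()
        for t in spec.traits:
            obs_idx = table.index[table[t].notna()]
            n_drop = int(round(exclude_fraction * len(obs_idx)))
            if len(obs_idx) - n_drop < 10:
                raise ValueError("too few observed species to exclude a fraction")
            drop = rng.choice(obs_idx, size=n_drop, replace=False)
            work.loc[drop, t] = np.nan
        completed, _ = missforest_impute(
            work, n_trees=spec.n_trees, max_iter=spec.max_iter, seed=seed + rep
        )
        for t in spec.traits:
            preds[t].append(completed[t].to_numpy(dtype=float))
    out = pd.DataFrame(index=table.index)
    for t in spec.traits:
        arr = np.stack(preds[t])
        out[f"{t}_excl_sd"] = arr.std(axis=0, ddof=1) if reps > 1 else 0.0
    return out
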