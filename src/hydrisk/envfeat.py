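"""Environmental niche features: range means, normalizing transforms,
maximum vapour pressure deficit, and principal components.

Species' edaphoclimatic affiliations are summarized as the mean of each
environmental layer over the species' occupied cells, optionally transformed
towards normality, then compressed with a PCA whose leading components feed
the trait imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import EnvLayerStack

__all__ = [
    "EnvScores",
    "extract_species_env",
    "svp",
    "vpd_max",
    "normalize_transform",
    "env_pca",
]


@dataclass
class EnvScores:
    """Species x component coordinates with loadings and variance shares."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def extract_species_env(env: EnvLayerStack, ranges) -> pd.DataFrame:
    """Mean of every layer over each species' occupied, non-missing cells.

    Species with an empty range (or all-missing cells) are excluded and
    reported via warning.
    """
    flat = env.flat()
    rows: dict[str, np.ndarray] = {}
    empty: list[str] = []
    cells = ranges.cells if hasattr(ranges, "cells") else dict(ranges)
    for sp in sorted(cells):
        occ = np.asarray(cells[sp], dtype=int)
        if occ.size == 0:
            empty.append(sp)
            continue
        vals = flat[:, occ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(vals, axis=1)
        if np.isnan(means).all():
            empty.append(sp)
            continue
        rows[sp] = means
    if empty:
        warnings.warn(f"{len(empty)} species with empty range excluded: {empty[:10]}")
    return pd.DataFrame.from_dict(rows, orient="index", columns=env.names).rename_axis(
        "species"
    )


def svp(temp_c: np.ndarray | float) -> np.ndarray | float:
    """Saturation vapour pressure (kPa) after Murray (1967).

    e_s(hPa) = 6.1078 * exp(17.2693882 * (T - 273.16) / (T - 35.86)), T in K.
    """
    T = np.asarray(temp_c, dtype=float) + 273.16
    es_hpa = 6.1078 * np.exp(17.2693882 * (T - 273.16) / (T - 35.86))
    return es_hpa / 10.0  # hPa -> kPa


def vpd_max(t_max: np.ndarray, vapour_pressure: np.ndarray) -> float:
    """Maximum monthly vapour pressure deficit (kPa).

    VPD_m = SVP(t_max,m) - e_a,m per month; the result is the maximum over
    months. Negative monthly VPD (actual vapour pressure above saturation)
    is clamped to 0 with a warning. Inputs implausible for kPa are flagged.
    """
    t_max = np.asarray(t_max, dtype=float)
    ea = np.asarray(vapour_pressure, dtype=float)
    if t_max.shape != ea.shape:
        raise ValueError("t_max and vapour_pressure must be aligned by month")
    if np.nanmax(np.abs(ea)) > 50:
        warnings.warn("vapour pressure values look implausible for kPa (unit mismatch?)")
    vpd = svp(t_max) - ea
    if (vpd < 0).any():
        warnings.warn("negative monthly VPD clamped to 0")
        vpd = np.clip(vpd, 0.0, None)
    return float(np.max(vpd))


def normalize_transform(
    table: pd.DataFrame, skew_threshold: float = 1.0
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-variable normality transform with a recorded log.

    |skewness| > threshold and min > 0 -> natural log; min >= 0 -> square
    root; otherwise identity (negative-valued skewed variables are left
    untouched with a warning).
    """
    out = table.copy()
    log: dict[str, str] = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        sk = stats.skew(x[~np.isnan(x)])
        if abs(sk) > skew_threshold and np.nanmin(x) > 0:
            out[col] = np.log(x)
            log[col] = "log"
        elif abs(sk) > skew_threshold and np.nanmin(x) >= 0:
            out[col] = np.sqrt(x)
            log[col] = "sqrt"
        else:
            if abs(sk) > skew_threshold:
                warnings.warn(
                    f"variable {col!r} is skewed but has negative values; left untransformed"
                )
            log[col] = "identity"
    return out, log


def apply_transform_log(table: pd.DataFrame, log: dict[str, str]) -> pd.DataFrame:
    """Re-apply a recorded transform log to a raw table."""
    out = table.copy()
    for col, kind in log.items():
        if kind == "log":
            out[col] = np.log(out[col])
        elif kind == "sqrt":
            out[col] = np.sqrt(out[col])
    return out


def env_pca(table: pd.DataFrame, n_components: int = 5, scale: bool = True) -> EnvScores:
    """PCA of the species x variable table.

    Variables are standardized to mean 0, sd 1 by default (correlation PCA;
    the variables mix units), then eigendecomposed via SVD. Species with any
    missing value are excluded and reported. Requesting more components than
    variables returns all with a warning.
    """
    complete = table.dropna()
    if len(complete) < len(table):
        warnings.warn(
            f"{len(table) - len(complete)} species with missing env values excluded"
        )
    X = complete.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    Xc = X - mu
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    n, p = Xc.shape
    if n_components > p:
        warnings.warn(f"requested {n_components} components but only {p} variables")
        n_components = p
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / (n - 1)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    k = n_components
    scores = pd.DataFrame(
        (U[:, :k] * S[:k]),
        index=complete.index,
        columns=[f"pc{j + 1}" for j in range(k)],
    )
    loadings = pd.DataFrame(
        Vt[:k].T, index=table.columns, columns=scores.columns
    )
    ratio = eigvals[:k] / eigvals.sum()
    return EnvScores(scores, loadings, ratio)
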