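"""Compositional preprocessing and diversity statistics.

Relative-abundance glycomics data are compositional: only ratios carry
information, so Euclidean statistics on raw percentages are biased.  The
standard remedy is the centered log-ratio (CLR) transform, optionally with
a scale-uncertainty perturbation γ that acknowledges that the total is not
observed.  The preprocessing pipeline here is Winsorize → impute →
re-close → CLR(γ), after which ordinary multivariate statistics apply
(Aitchison geometry).

Diversity: Shannon entropy, Simpson's index and observed richness within
samples; ANOSIM (rank-based permutation test on a distance matrix) between
groups; Mann-Whitney U with two-stage Benjamini-Hochberg correction for
two-group feature screens.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, CLRMatrix

__all__ = [
    "winsorize",
    "impute",
    "clr",
    "preprocess",
    "alpha_diversity",
    "aitchison_distance",
    "anosim",
    "group_compare",
    "two_stage_bh",
]


def two_stage_bh(pvals, alpha: float = 0.05) -> np.ndarray:
    """Two-stage (adaptive) Benjamini-Hochberg q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, alpha=alpha, method="fdr_tsbh")[1]


# ---------------------------------------------------------------------------
# preprocessing


def winsorize(data: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Two-sided per-feature Winsorization at ``fraction`` on each tail.

    Clips each feature's most extreme values to the corresponding
    percentiles; NaNs are left in place. Rank order within a feature is
    preserved (ties are introduced at the tails).
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("winsor fraction must be in [0, 0.5)")
    if fraction == 0:
        return data.copy()
    out = data.copy().astype(float)
    for col in out.columns:
        v = out[col].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() < 2:
            continue
        lo, hi = np.quantile(v[ok], [fraction, 1 - fraction])
        out[col] = np.clip(v, lo, hi)
    return out


def impute(
    data: pd.DataFrame,
    method: str = "half_min",
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Replace zeros / missing values by strictly positive estimates.

    ``"half_min"`` (deterministic): half the smallest positive observed
    value of the feature.  ``"forest"``: iterative imputation with a
    tree-ensemble regressor over features (a MissForest-style strategy),
    seeded; results are clipped to (0, feature maximum].
    """
    arr = data.to_numpy(dtype=float).copy()
    arr[arr == 0] = np.nan
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cols checked below
        col_max = np.nanmax(arr, axis=0)
        col_min = np.nanmin(arr, axis=0)
    if np.isnan(col_max).any():
        missing = [data.columns[i] for i in np.where(np.isnan(col_max))[0]]
        raise ValueError(f"features missing in all samples: {missing}")
    if method == "half_min":
        fill = col_min / 2.0
        idx = np.where(np.isnan(arr))
        arr[idx] = fill[idx[1]]
    elif method == "forest":
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.ensemble import ExtraTreesRegressor
        from sklearn.impute import IterativeImputer

        imp = IterativeImputer(
            estimator=ExtraTreesRegressor(n_estimators=10, random_state=seed),
            random_state=seed,
            max_iter=5,
            keep_empty_features=False,
        )
        arr = imp.fit_transform(arr)
        floor = np.minimum(col_min / 2.0, np.nanmin(col_min) / 2.0)
        arr = np.clip(arr, floor[None, :], col_max[None, :])
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return pd.DataFrame(arr, index=data.index, columns=data.columns)


def clr(
    data: pd.DataFrame,
    gamma: float = 0.0,
    seed: Optional[int] = None,
    meta: Optional[pd.DataFrame] = None,
) -> CLRMatrix:
    """Centered log-ratio transform with optional γ scale perturbation.

    γ = 0: x → log x − mean(log x) per row (rows sum to zero; invariant to
    per-sample rescaling).  γ > 0: one Normal(0, γ²) draw per sample is
    added to every entry of that row, modeling uncertainty in the unseen
    total; ``seed`` makes the draws reproducible.
    """
    arr = data.to_numpy(dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("CLR requires strictly positive entries; impute first")
    logs = np.log(arr)
    out = logs - logs.mean(axis=1, keepdims=True)
    if gamma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, gamma, size=(arr.shape[0], 1))
    return CLRMatrix(
        pd.DataFrame(out, index=data.index, columns=data.columns),
        gamma=gamma,
        seed=seed,
        meta=meta,
    )


def preprocess(
    table: AbundanceTable,
    winsor_fraction: float = 0.05,
    gamma: float = 0.1,
    seed: Optional[int] = None,
    impute_method: str = "half_min",
) -> CLRMatrix:
    """Winsorize → impute → re-close → CLR(γ), the standard pipeline."""
    w = winsorize(table.data, winsor_fraction)
    filled = impute(w, method=impute_method, seed=seed)
    closed = filled.div(filled.sum(axis=1), axis=0)
    return clr(closed, gamma=gamma, seed=seed, meta=table.meta)


# ---------------------------------------------------------------------------
# alpha diversity

_INDICES = ("shannon", "simpson", "observed_richness")


def alpha_diversity(values, index: str = "shannon") -> pd.Series:
    """Per-sample diversity of non-negative quantities.

    shannon = −Σ p ln p; simpson = 1 − Σ p²; observed_richness = number of
    positive features. Input rows are normalized to proportions first.
    """
    if index not in _INDICES:
        raise ValueError(f"index must be one of {_INDICES}")
    df = values.data if isinstance(values, AbundanceTable) else pd.DataFrame(values)
    arr = np.nan_to_num(df.to_numpy(dtype=float))
    if (arr < 0).any():
        raise ValueError("diversity requires non-negative values")
    totals = arr.sum(axis=1)
    if (totals <= 0).any():
        bad = [df.index[i] for i in np.where(totals <= 0)[0]]
        raise ValueError(f"all-zero samples: {bad}")
    p = arr / totals[:, None]
    if index == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    elif index == "simpson":
        out = 1.0 - np.sum(p**2, axis=1)
    else:
        out = (arr > 0).sum(axis=1).astype(float)
    return pd.Series(out, index=df.index, name=index)


# ---------------------------------------------------------------------------
# beta diversity


def aitchison_distance(clr_matrix: CLRMatrix) -> np.ndarray:
    """Euclidean distance between CLR rows (the Aitchison metric)."""
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(clr_matrix.values, metric="euclidean"))


def anosim(
    dist: np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: Optional[int] = None,
):
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2 ranks over all pairs; R ∈ [−1, 1].  The p-value is the
    seeded permutation tail probability
    (1 + #{permuted R ≥ observed}) / (1 + n_permutations).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("dist must be square symmetric with zero diagonal")
    labels = np.asarray(groups)
    if labels.shape[0] != n:
        raise ValueError("labels length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("singleton groups are not allowed in ANOSIM")

    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d[iu])
    M = ranks.size

    def r_stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2.0)

    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(labels)) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return observed, p


# ---------------------------------------------------------------------------
# two-group feature screen


def group_compare(values: pd.DataFrame, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature two-tailed Mann-Whitney U between two groups, with
    two-stage Benjamini-Hochberg q-values.

    Returns a DataFrame indexed by feature with columns U, p, q.
    """
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("group_compare requires exactly two groups")
    a_idx, b_idx = labels == uniq[0], labels == uniq[1]
    if a_idx.sum() < 3 or b_idx.sum() < 3:
        raise ValueError("each group needs at least 3 values")
    rows = []
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        res = stats.mannwhitneyu(v[a_idx], v[b_idx], alternative="two-sided")
        rows.append((col, res.statistic, res.pvalue))
    out = pd.DataFrame(rows, columns=["feature", "U", "p"]).set_index("feature")
    out["q"] = two_stage_bh(out["p"].to_numpy(), alpha=alpha)
    return out
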