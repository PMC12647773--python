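"""Glycome-metabolome integration.

Cross-omics association on CLR-transformed compositions: Spearman
cross-correlation with t-test significance and two-stage
Benjamini-Hochberg masking (correlation of log-ratio-transformed data
mitigates compositional artifacts); regularized partial correlations
(Spearman ρ of ridge-regression residuals) that strip "bystander"
correlations and enrich for direct links; per-modality informativeness
(how well each modality's Ward clustering recovers lactation timepoints,
optionally after PCA denoising); and the correlation of the two
modalities' first principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge

from .compositional import two_stage_bh
from .dynamics import ClusterScore, cluster_samples, clustering_scores
from .tables import CLRMatrix

__all__ = [
    "CrossCorrelationResult",
    "PartialCorrelationResult",
    "ModalityReport",
    "cross_correlate",
    "regularized_partial_correlation",
    "modality_informativeness",
    "pc1_link",
]


def _check_shared_samples(a: CLRMatrix, b: CLRMatrix, min_n: int = 4):
    ia, ib = list(a.data.index), list(b.data.index)
    if ia != ib:
        only_a = sorted(set(ia) - set(ib))
        only_b = sorted(set(ib) - set(ia))
        raise ValueError(
            f"sample mismatch between modalities; only in first: {only_a}; "
            f"only in second: {only_b}; order must also agree"
        )
    if len(ia) < min_n:
        raise ValueError(f"need at least {min_n} shared samples, got {len(ia)}")


def _rho_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed t-test on Spearman ρ with n − 2 degrees of freedom."""
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


@dataclass
class CrossCorrelationResult:
    rho: pd.DataFrame  # motifs × metabolites Spearman ρ
    q: pd.DataFrame
    mask: pd.DataFrame  # True where q < alpha
    alpha: float = 0.05

    def significant_pairs(self) -> pd.DataFrame:
        """Long-format list of significant (motif, metabolite, ρ, q) rows."""
        rows = [
            (m, c, self.rho.loc[m, c], self.q.loc[m, c])
            for m in self.rho.index
            for c in self.rho.columns
            if self.mask.loc[m, c]
        ]
        return pd.DataFrame(rows, columns=["motif", "metabolite", "rho", "q"])


def cross_correlate(
    clr_motifs: CLRMatrix,
    clr_metabolites: CLRMatrix,
    alpha: float = 0.05,
) -> CrossCorrelationResult:
    """Spearman ρ for every (motif, metabolite) pair on CLR data, with
    two-tailed t-tests and a two-stage Benjamini-Hochberg mask at
    q < ``alpha``."""
    _check_shared_samples(clr_motifs, clr_metabolites)
    A, B = clr_motifs.data, clr_metabolites.data
    n = A.shape[0]
    ra = np.apply_along_axis(stats.rankdata, 0, A.to_numpy(dtype=float))
    rb = np.apply_along_axis(stats.rankdata, 0, B.to_numpy(dtype=float))
    ra = (ra - ra.mean(axis=0)) / ra.std(axis=0)
    rb = (rb - rb.mean(axis=0)) / rb.std(axis=0)
    rho = (ra.T @ rb) / n
    p = _rho_pvalues(rho, n)
    q = two_stage_bh(p.ravel(), alpha=alpha).reshape(p.shape)
    rho_df = pd.DataFrame(rho, index=A.columns, columns=B.columns)
    q_df = pd.DataFrame(q, index=A.columns, columns=B.columns)
    return CrossCorrelationResult(rho_df, q_df, q_df < alpha, alpha)


@dataclass
class PartialCorrelationResult:
    pair: tuple
    rho_partial: float
    p: float
    penalty: float


def regularized_partial_correlation(
    clr_joint: CLRMatrix,
    pair: tuple,
    penalty: Optional[float] = None,
) -> PartialCorrelationResult:
    """Spearman ρ of ridge residuals: each member of ``pair`` is regressed
    on all remaining features with an L2 penalty, and the residual vectors
    are correlated.  Default penalty 0.1 × (number of remaining features).

    Large penalties shrink the regressions to intercept-only, so the
    partial correlation converges to the marginal Spearman ρ.
    """
    df = clr_joint.data
    a, b = pair
    for f in (a, b):
        if f not in df.columns:
            raise KeyError(f"feature {f!r} not in matrix")
    if df.shape[0] < 5:
        raise ValueError("need at least 5 samples for partial correlation")
    rest = [c for c in df.columns if c not in (a, b)]
    if penalty is None:
        penalty = 0.1 * max(len(rest), 1)
    if penalty < 0:
        raise ValueError("penalty must be non-negative")

    def residuals(target):
        y = df[target].to_numpy(dtype=float)
        if not rest:
            return y - y.mean()
        X = df[rest].to_numpy(dtype=float)
        model = Ridge(alpha=penalty).fit(X, y)
        return y - model.predict(X)

    res = stats.spearmanr(residuals(a), residuals(b))
    return PartialCorrelationResult((a, b), float(res.statistic), float(res.pvalue), penalty)


@dataclass
class ModalityReport:
    scores: dict  # modality name → ClusterScore
    denoised: Optional[dict] = None
    retained_components: Optional[dict] = None


def _denoise(arr: np.ndarray, components) -> tuple[np.ndarray, int]:
    if components == "auto":
        full = PCA().fit(arr)
        ncomp = int(np.searchsorted(np.cumsum(full.explained_variance_ratio_), 0.8) + 1)
    else:
        ncomp = int(components)
    ncomp = max(1, min(ncomp, min(arr.shape) - 1))
    pca = PCA(n_components=ncomp)
    return pca.fit_transform(arr), ncomp


def modality_informativeness(
    modalities: dict,
    labels,
    k: int,
    denoise_components=None,
) -> ModalityReport:
    """Score how well each modality (and their concatenation, reported as
    ``"combined"``) recovers the reference labels when Ward-clustered into
    ``k`` flat clusters.  With ``denoise_components`` (an integer or
    ``"auto"`` = 80% cumulative variance) the data are first projected onto
    leading principal components."""
    names = list(modalities)
    mats = {m: modalities[m].data for m in names}
    index = mats[names[0]].index
    for m in names[1:]:
        if not mats[m].index.equals(index):
            raise ValueError(f"modality {m!r} has mismatched samples")
    combined = pd.concat([mats[m] for m in names], axis=1)
    all_mats = {**mats, "combined": combined}

    def score(df):
        result = cluster_samples(CLRMatrix(df), k=k)
        return clustering_scores(result.labels.to_numpy(), labels)

    scores = {m: score(df) for m, df in all_mats.items()}
    report = ModalityReport(scores)
    if denoise_components is not None:
        report.denoised, report.retained_components = {}, {}
        for m, df in all_mats.items():
            proj, ncomp = _denoise(df.to_numpy(dtype=float), denoise_components)
            proj_df = pd.DataFrame(proj, index=df.index)
            report.denoised[m] = score(proj_df)
            report.retained_components[m] = ncomp
    return report


def pc1_link(clr_A: CLRMatrix, clr_B: CLRMatrix, days=None):
    """First-principal-component linkage of two modalities.

    PCA (column-centered, unscaled) per modality; returns (variance share
    of PC1 in A, in B, Pearson r of the PC1 score vectors, two-tailed
    t-test p).  When ``days`` is given each PC1 is oriented to correlate
    positively with lactation day (sign convention).
    """
    _check_shared_samples(clr_A, clr_B, min_n=3)

    def pc1(df):
        arr = df.to_numpy(dtype=float)
        if np.allclose(arr.std(axis=0), 0):
            raise ValueError("constant matrix has no principal components")
        pca = PCA().fit(arr)
        scores = pca.transform(arr)[:, 0]
        share = float(pca.explained_variance_ratio_[0])
        if days is not None:
            d = np.asarray(days, dtype=float)
            if np.corrcoef(scores, d)[0, 1] < 0:
                scores = -scores
        return scores, share

    sa, share_a = pc1(clr_A.data)
    sb, share_b = pc1(clr_B.data)
    res = stats.pearsonr(sa, sb)
    return share_a, share_b, float(res.statistic), float(res.pvalue)
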