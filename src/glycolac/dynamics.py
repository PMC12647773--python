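"""Temporal analysis of the lactation glycome.

Samples (individual × lactation day) are clustered on CLR-transformed
abundances with Ward's variance-minimization linkage and scored against
the known timepoints with ARI/NMI; glycan clusters (Early / Stable / Late)
are summarized as trajectories; motif differences between clusters are
tested by one-way ANOVA with Tukey HSD post-hocs and two-stage
Benjamini-Hochberg correction; motif time courses are fit with a degree-1
polynomial; and the sulfation-branching hypothesis (sulfated GlcNAc is
extended less often than unmodified GlcNAc at matched structure sizes) is
tested with a Wilcoxon signed-rank test over size strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .compositional import two_stage_bh
from .structures import GlycanStructure
from .tables import AbundanceTable, CLRMatrix

__all__ = [
    "ClusteringResult",
    "ClusterScore",
    "MotifAnovaRow",
    "TimeSeriesFit",
    "cluster_samples",
    "clustering_scores",
    "cluster_trajectories",
    "motif_anova",
    "timeseries_fit",
    "sulfation_branching_test",
]


@dataclass
class ClusteringResult:
    labels: pd.Series  # flat cluster labels in 1..k
    linkage: np.ndarray
    k: int
    method: str


@dataclass
class ClusterScore:
    ari: float
    nmi: float


def cluster_samples(
    clr: CLRMatrix,
    k: int,
    method: str = "ward",
    rows: str = "samples",
    z_score_rows: bool = False,
) -> ClusteringResult:
    """Agglomerative clustering of CLR rows (or of glycans, with
    ``rows="glycans"``, on the transposed matrix) cut into ``k`` flat
    clusters.

    ``z_score_rows`` standardizes each clustered row first (useful when
    clustering glycans whose CLR levels differ in scale but share shape).
    """
    df = clr.data if isinstance(clr, CLRMatrix) else pd.DataFrame(clr)
    if rows == "glycans":
        df = df.T
    elif rows != "samples":
        raise ValueError("rows must be 'samples' or 'glycans'")
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > df.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {df.shape[0]}")
    arr = df.to_numpy(dtype=float)
    if z_score_rows:
        sd = arr.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        arr = (arr - arr.mean(axis=1, keepdims=True)) / sd
    Z = hierarchy.linkage(pdist(arr, metric="euclidean"), method=method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusteringResult(pd.Series(flat, index=df.index), Z, k, method)


def clustering_scores(labels, reference) -> ClusterScore:
    """Adjusted Rand index and arithmetic-mean-normalized mutual
    information between two partitions of the same samples."""
    a = np.asarray(labels)
    b = np.asarray(reference)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return ClusterScore(
        ari=float(adjusted_rand_score(b, a)),
        nmi=float(normalized_mutual_info_score(b, a, average_method="arithmetic")),
    )


def cluster_trajectories(
    table: AbundanceTable,
    glycan_clusters: dict,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-cluster abundance trajectory over lactation days.

    For each (cluster, day): the summed abundance of the cluster's glycans
    per sample, averaged over individuals, with a t-distribution confidence
    interval.  Summing the cluster trajectories at any day recovers the
    mean total abundance (100 for percentage tables).
    """
    clusters = {}
    for g, c in glycan_clusters.items():
        clusters.setdefault(c, []).append(g)
    for c, gs in clusters.items():
        missing = [g for g in gs if g not in table.data.columns]
        if missing:
            raise KeyError(f"cluster {c!r} references unknown glycans {missing}")
        if not gs:
            raise ValueError(f"cluster {c!r} is empty")
    unassigned = set(table.data.columns) - set(glycan_clusters)
    if unassigned:
        raise ValueError(f"glycans without cluster assignment: {sorted(unassigned)}")

    days = table.meta["day"]
    rows = []
    for c, gs in sorted(clusters.items(), key=lambda kv: str(kv[0])):
        totals = table.data[gs].sum(axis=1)
        for day, vals in totals.groupby(days):
            v = vals.to_numpy(dtype=float)
            mean = v.mean()
            if v.size > 1 and v.std(ddof=1) > 0:
                half = stats.t.ppf((1 + ci) / 2, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
            else:
                half = 0.0
            rows.append((c, day, mean, mean - half, mean + half, v.size))
    return pd.DataFrame(rows, columns=["cluster", "day", "mean", "ci_low", "ci_high", "n"])


@dataclass
class MotifAnovaRow:
    motif: str
    F: float
    p: float
    q: float = np.nan
    tukey: Optional[pd.DataFrame] = None  # pair, mean difference, adjusted p


def motif_anova(
    motif_table: AbundanceTable | CLRMatrix,
    groups,
    alpha: float = 0.05,
    tukey_on: str = "significant",
) -> list:
    """One-way ANOVA per motif across groups, Tukey HSD post-hocs on
    significant motifs, two-stage Benjamini-Hochberg q-values across motifs."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = motif_table.data
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = [u for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups with fewer than 2 observations: {small}")

    rows = []
    for motif in df.columns:
        v = df[motif].to_numpy(dtype=float)
        samples = [v[labels == u] for u in uniq]
        if np.ptp(v) == 0:
            F, p = 0.0, 1.0
        else:
            F, p = stats.f_oneway(*samples)
            if np.isnan(F):
                F, p = 0.0, 1.0
        rows.append(MotifAnovaRow(motif, float(F), float(p)))
    qs = two_stage_bh([r.p for r in rows], alpha=alpha)
    for r, q in zip(rows, qs):
        r.q = float(q)
        if tukey_on == "all" or (tukey_on == "significant" and r.q < alpha):
            res = pairwise_tukeyhsd(df[r.motif].to_numpy(dtype=float), labels, alpha=alpha)
            r.tukey = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
    return rows


@dataclass
class TimeSeriesFit:
    motif: str
    beta: float
    intercept: float
    p: float
    q: float = np.nan


def timeseries_fit(motif_table: AbundanceTable | CLRMatrix, times=None) -> list:
    """Degree-1 polynomial fit of each motif's (CLR-scale) time series.

    All individuals are pooled; ``beta`` is the least-squares slope per
    day, ``p`` the regression ANOVA p-value, ``q`` the two-stage
    Benjamini-Hochberg correction across motifs.
    """
    df = motif_table.data
    if times is None:
        meta = motif_table.meta
        if meta is None or "day" not in meta:
            raise ValueError("no time values given and no 'day' metadata")
        times = meta["day"]
    t = np.asarray(times, dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct time values")
    fits = []
    for motif in df.columns:
        y = df[motif].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            fits.append(TimeSeriesFit(motif, 0.0, float(y[0]), 1.0))
            continue
        res = stats.linregress(t, y)
        p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
        fits.append(TimeSeriesFit(motif, float(res.slope), float(res.intercept), p))
    qs = two_stage_bh([f.p for f in fits])
    for f, q in zip(fits, qs):
        f.q = float(q)
    return fits


def sulfation_branching_test(structures, min_strata: int = 5):
    """Does 6-O-sulfation of GlcNAc suppress chain extension?

    Structures are stratified by residue count (controlling for length).
    Within each stratum the extension rate (fraction of nodes that carry a
    child) is computed separately for GlcNAc6S and unmodified GlcNAc
    residues; strata containing both kinds are paired and compared with a
    two-sided Wilcoxon signed-rank test.  Returns (W, p, direction) where
    direction is the sign of the median paired difference
    (sulfated − unsulfated rate; negative = sulfated extended less often).
    """
    per_stratum: dict[int, dict[bool, list[bool]]] = {}
    for g in structures:
        if not isinstance(g, GlycanStructure):
            raise TypeError("sulfation test needs fully structured glycans")
        size = len(g)
        for nid, res in g.nodes.items():
            if res.base != "GlcNAc":
                continue
            sulfated = (6, "S") in res.modifications
            extended = bool(g.children[nid])
            per_stratum.setdefault(size, {True: [], False: []})[sulfated].append(extended)

    diffs = []
    for size in sorted(per_stratum):
        d = per_stratum[size]
        if d[True] and d[False]:
            diffs.append(float(np.mean(d[True])) - float(np.mean(d[False])))
    if len(diffs) < min_strata:
        raise ValueError(
            f"only {len(diffs)} informative size strata (need >= {min_strata})"
        )
    diffs = np.asarray(diffs)
    direction = int(np.sign(np.median(diffs)))
    if np.all(diffs == 0):
        return 0.0, 1.0, 0
    W, p = stats.wilcoxon(diffs, alternative="two-sided")
    return float(W), float(p), direction
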