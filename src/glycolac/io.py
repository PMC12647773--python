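"""Readers, writers, configuration and the end-to-end pipeline.

All formats are plain text: delimited abundance tables (sample_id,
individual, day, then feature columns), glycan-list files (one
IUPAC-condensed string per line, ``#`` comments, optional tab-separated
name), motif-library TSV (name, pattern variants ``;``-separated,
constraint), newick trees and a JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import compositional, dynamics, multiomics, phylo
from .motifs import MotifDefinition, MotifLibrary, builtin_library, quantify_motifs, terminal_motifs
from .structures import GlycanStructure, parse_iupac, write_iupac
from .tables import AbundanceTable, CLRMatrix

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_glycan_list",
    "write_glycan_list",
    "read_motif_library",
    "write_motif_library",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_META_COLS = ("sample_id", "individual", "day")


def read_abundance_table(path, total: float = 100.0, tol: float = 0.01) -> AbundanceTable:
    """Read a delimited abundance table (comma default, tab auto-detected).

    Rows whose sums deviate measurably (beyond ``tol``) from ``total`` are
    renormalized with a logged warning; duplicate sample ids are an error
    reporting the offending line numbers.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing metadata columns {missing} in {path}")
    dup = df["sample_id"].duplicated(keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in np.where(dup)[0]]  # header is line 1
        raise ValueError(f"duplicate sample_id at lines {lines} in {path}")
    df = df.set_index("sample_id")
    meta = df[["individual", "day"]]
    data = df.drop(columns=["individual", "day"]).astype(float)
    sums = np.nansum(data.to_numpy(), axis=1)
    off = np.abs(sums - total) > tol
    if off.any():
        logger.warning(
            "renormalizing %d rows of %s whose sums deviate from %s",
            int(off.sum()), path, total,
        )
        data.loc[off] = data.loc[off].div(sums[off], axis=0) * total
    return AbundanceTable(data, meta.copy())


def write_abundance_table(table: AbundanceTable, path, sep: str = ",") -> None:
    out = table.meta.copy()
    out.insert(0, "sample_id", table.data.index)
    out = pd.concat([out.reset_index(drop=True),
                     table.data.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=sep, index=False)


def read_glycan_list(path) -> dict:
    """Glycan-list file → ordered mapping name → GlycanStructure.

    One structure per line; an optional second tab-separated column names
    the structure (default: the canonical string itself)."""
    out: dict[str, GlycanStructure] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        g = parse_iupac(parts[0])
        name = parts[1].strip() if len(parts) > 1 and parts[1].strip() else write_iupac(g)
        out[name] = g
    return out


def write_glycan_list(structures: dict, path) -> None:
    lines = [f"{write_iupac(g)}\t{name}" for name, g in structures.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_motif_library(path) -> MotifLibrary:
    """Motif-library TSV: name <tab> pattern[;variant...] <tab> constraint."""
    defs = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed motif line {line!r}")
        name, patterns = fields[0], fields[1].split(";")
        constraint = fields[2] if len(fields) > 2 else "anywhere"
        defs.append(MotifDefinition(name, patterns, constraint))
    return MotifLibrary(defs)


def write_motif_library(library: MotifLibrary, path) -> None:
    lines = [
        "\t".join((d.name, ";".join(d.patterns), d.terminal_constraint))
        for d in library
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    ``glycan_table`` / ``metabolite_table`` are paths to delimited tables
    (the metabolome is optional); ``glycan_list`` maps feature columns to
    structures.  One pipeline seed drives every randomized stage through
    deterministically derived per-stage seeds.
    """

    glycan_table: object = None  # path or AbundanceTable
    glycan_list: object = None  # path or dict name → structure
    metabolite_table: object = None  # path or AbundanceTable or None
    motif_library: object = None  # path or MotifLibrary (default built-in)
    gamma: float = 0.1
    winsor_fraction: float = 0.05
    impute_method: str = "half_min"
    k: int = 4
    feature_sets: tuple = ("known", "size_branch")
    seed: Optional[int] = None
    output_dir: Optional[str] = None

    def stage_seed(self, stage: str) -> Optional[int]:
        if self.seed is None:
            return None
        import zlib

        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _load(obj, reader):
    if obj is None or not isinstance(obj, (str, Path)):
        return obj
    return reader(obj)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run parse → motifs → preprocess → diversity → cluster/score →
    ANOVA → time series → cross-omics, writing artifacts when
    ``output_dir`` is set; returns the machine-readable summary."""
    table = _load(config.glycan_table, read_abundance_table)
    if table is None:
        raise ValueError("pipeline needs a glycan abundance table")
    structures = _load(config.glycan_list, read_glycan_list)
    if structures is None:
        structures = getattr(table, "_structures", None)
        if structures is None:
            raise ValueError("pipeline needs structures for the glycan columns")
    library = _load(config.motif_library, read_motif_library) or builtin_library()

    summary: dict = {"seed": config.seed, "gamma": config.gamma, "k": config.k}

    # motifs
    motif_table = quantify_motifs(table, structures, library, feature_sets=config.feature_sets)

    # preprocess (γ as configured for the summary statistics; clustering and
    # correlation use the same matrix so the summary is self-consistent)
    clr_glyco = compositional.preprocess(
        table,
        winsor_fraction=config.winsor_fraction,
        gamma=config.gamma,
        seed=config.stage_seed("clr"),
        impute_method=config.impute_method,
    )
    present = motif_table.data.loc[:, (motif_table.data.fillna(0) > 0).any(axis=0)]
    clr_motifs = compositional.preprocess(
        AbundanceTable(present, motif_table.meta).closed(),
        winsor_fraction=config.winsor_fraction,
        gamma=0.0,
        seed=config.stage_seed("clr-motifs"),
        impute_method=config.impute_method,
    )

    # diversity
    shannon = compositional.alpha_diversity(table, "shannon")
    summary["alpha_diversity_shannon_mean"] = float(shannon.mean())
    dist = compositional.aitchison_distance(clr_glyco)
    R, p_anosim = compositional.anosim(
        dist, table.meta["day"].to_numpy(), seed=config.stage_seed("anosim")
    )
    summary["anosim_R"] = float(R)
    summary["anosim_p"] = float(p_anosim)

    # clustering + scores against timepoints
    clustering = dynamics.cluster_samples(clr_glyco, k=config.k)
    score = dynamics.clustering_scores(
        clustering.labels.to_numpy(), table.meta["day"].to_numpy()
    )
    summary["timepoint_ari"] = score.ari
    summary["timepoint_nmi"] = score.nmi

    # glycan-row clusters and trajectories
    glycan_clust = dynamics.cluster_samples(clr_glyco, k=config.k, rows="glycans")
    assignments = {g: int(c) for g, c in glycan_clust.labels.items()}
    trajectories = dynamics.cluster_trajectories(table, assignments)

    # per-motif ANOVA across sample clusters and time-series fits
    anova_rows = dynamics.motif_anova(clr_motifs, clustering.labels.to_numpy())
    summary["n_cluster_specific_motifs_q05"] = int(sum(r.q < 0.05 for r in anova_rows))
    fits = dynamics.timeseries_fit(clr_motifs)
    summary["n_temporal_motifs_q05"] = int(sum(f.q < 0.05 for f in fits))

    # glyco-phylogeny over individuals' mean motif profiles
    profiles = motif_table.data.groupby(table.meta["individual"]).mean()
    profiles = profiles.loc[:, (profiles > 0).any(axis=0)]
    tree = phylo.upgma(phylo.cosine_distance_matrix(profiles))
    newick = phylo.to_newick(tree)
    summary["tree_newick"] = newick

    # cross-omics (optional)
    metab = _load(config.metabolite_table, read_abundance_table)
    if metab is not None:
        clr_metab = compositional.preprocess(
            metab,
            winsor_fraction=config.winsor_fraction,
            gamma=config.gamma,
            seed=config.stage_seed("clr-metab"),
            impute_method=config.impute_method,
        )
        xc = multiomics.cross_correlate(clr_motifs, clr_metab)
        summary["n_significant_cross_correlations"] = int(xc.mask.to_numpy().sum())
        share_a, share_b, r, p = multiomics.pc1_link(
            clr_glyco, clr_metab, days=table.meta["day"].to_numpy()
        )
        summary["pc1_variance_share_glycome"] = share_a
        summary["pc1_variance_share_metabolome"] = share_b
        summary["pc1_pearson_r"] = r
        summary["pc1_p"] = p
    else:
        logger.info("no metabolome table given; cross-omics stage skipped")

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_abundance_table(motif_table, out / "motif_table.csv")
        clr_glyco.data.to_csv(out / "clr_glycome.csv")
        trajectories.to_csv(out / "cluster_trajectories.csv", index=False)
        (out / "glyco_tree.nwk").write_text(newick + "\n", encoding="utf-8")
        anova_df = pd.DataFrame(
            [(r.motif, r.F, r.p, r.q) for r in anova_rows],
            columns=["motif", "F", "p", "q"],
        )
        anova_df.to_csv(out / "motif_anova.csv", index=False)
        fit_df = pd.DataFrame(
            [(f.motif, f.beta, f.p, f.q) for f in fits],
            columns=["motif", "beta", "p", "q"],
        )
        fit_df.to_csv(out / "timeseries_fits.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
        )
    return summary
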