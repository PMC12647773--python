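"""Synthetic study-design generator with recorded ground truth.

Emulates the longitudinal seal-milk study design — five individuals
sampled at four lactation timepoints (days 2, 7, 13 and 17/18/19, coded as
18) — so that every pipeline stage can be exercised and scored against a
known truth without external data:

* **structures** from a lactose-core grammar: lactose is extended with
  type-2 LacNAc units (GlcNAcβ1-3 + Galβ1-4), branched with GlcNAcβ1-6 +
  Galβ1-4 at eligible galactoses, and decorated (Fucα1-2 on Gal, Fucα1-3
  on GlcNAc, Neu5Acα2-3/α2-6 caps, 6-O-sulfation of GlcNAc, LacdiNAc
  caps); sulfated GlcNAc may be capped/extended with a different
  probability than unmodified GlcNAc, planting the sulfation-branching
  effect when the two probabilities differ;
* **glycome cohorts** with planted temporal clusters (Early glycans
  present only in the first timepoint, Late glycans rising through
  lactation, Stable glycans flat, Sporadic glycans intermittent),
  individual-level lognormal random effects and Dirichlet sampling noise,
  closed to percentages;
* **paired metabolomes** driven by a shared latent day factor, with a
  configurable number of direct glycan→metabolite links planted on top.

Identical seeds give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .structures import GlycanStructure, Linkage, Monosaccharide, write_iupac
from .tables import AbundanceTable

__all__ = [
    "GrammarParams",
    "CohortDesign",
    "GroundTruth",
    "simulate_structures",
    "simulate_cohort",
    "simulate_metabolome",
    "simulate_motif_timeseries",
]

#: temporal abundance multipliers per glycan cluster, one per timepoint
DEFAULT_MULTIPLIERS = {
    "Early": (1.0, 0.0, 0.0, 0.0),
    "Stable": (1.0, 1.0, 1.0, 1.0),
    "Late": (0.0, 0.5, 1.0, 1.5),
}


@dataclass
class GrammarParams:
    """Probabilities of the lactose-core extension/branching/decoration
    grammar.  ``max_size`` bounds the backbone residue count; decorations
    (Fuc, Neu5Ac) may exceed it by construction."""

    p_extend: float = 0.5  # terminal Gal gains a LacNAc unit, per round
    p_branch: float = 0.25  # eligible internal Gal gains a β1-6 LacNAc branch
    p_fuc2_gal: float = 0.3  # Fucα1-2 on terminal Gal
    p_fuc3_glcnac: float = 0.2  # Fucα1-3 on GlcNAc
    p_neu5ac_a3: float = 0.15  # Neu5Acα2-3 cap on terminal Gal
    p_neu5ac_a6: float = 0.15  # Neu5Acα2-6 cap on terminal Gal (if no α2-3)
    p_sulf6_glcnac: float = 0.15  # 6-O-sulfation of a new GlcNAc
    p_cap: float = 1.0  # unmodified GlcNAc is capped (extended) with Gal
    p_cap_sulfated: Optional[float] = None  # sulfated GlcNAc cap probability
    p_lacdinac: float = 0.1  # cap is GalNAc (LacdiNAc) instead of Gal
    max_size: int = 14
    seed: Optional[int] = None

    def __post_init__(self):
        probs = [
            self.p_extend, self.p_branch, self.p_fuc2_gal, self.p_fuc3_glcnac,
            self.p_neu5ac_a3, self.p_neu5ac_a6, self.p_sulf6_glcnac,
            self.p_cap, self.p_lacdinac,
        ]
        if self.p_cap_sulfated is not None:
            probs.append(self.p_cap_sulfated)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("grammar probabilities must lie in [0, 1]")
        if self.max_size < 2:
            raise ValueError("max_size must be at least 2 (the lactose core)")

    @property
    def cap_sulfated(self) -> float:
        return self.p_cap if self.p_cap_sulfated is None else self.p_cap_sulfated


def _grow_structure(rng: np.random.Generator, p: GrammarParams) -> GlycanStructure:
    g = GlycanStructure()
    glc = g.add_node(Monosaccharide("Glc"))
    gal = g.add_node(Monosaccharide("Gal"))
    g.add_edge(gal, glc, Linkage("β", 1, 4))
    g.root = glc

    def backbone_size():
        return sum(1 for r in g.nodes.values() if r.base in ("Glc", "Gal", "GlcNAc", "GalNAc"))

    def add_glcnac(parent, parent_carbon):
        sulf = rng.random() < p.p_sulf6_glcnac
        mods = frozenset({(6, "S")}) if sulf else frozenset()
        node = g.add_node(Monosaccharide("GlcNAc", mods))
        g.add_edge(node, parent, Linkage("β", 1, parent_carbon))
        # capping = chain extension past this GlcNAc; sulfation may suppress it
        cap_p = p.cap_sulfated if sulf else p.p_cap
        if backbone_size() + 1 <= p.max_size and rng.random() < cap_p:
            base = "GalNAc" if rng.random() < p.p_lacdinac else "Gal"
            cap = g.add_node(Monosaccharide(base))
            g.add_edge(cap, node, Linkage("β", 1, 4))

    # growth: each site gets one chance per appearance; new Gal caps created
    # by an extension are offered their own chance in the next round
    frontier_changed = True
    tried_extend: set[int] = set()
    tried_branch: set[int] = set()
    while frontier_changed:
        frontier_changed = False
        for n in list(g.nodes):
            res = g.nodes[n]
            if res.base != "Gal":
                continue
            kids = g.children[n]
            if not kids and n not in tried_extend:
                tried_extend.add(n)
                if backbone_size() + 1 <= p.max_size and rng.random() < p.p_extend:
                    add_glcnac(n, 3)
                    frontier_changed = True
            pcs = {g.linkage(c).parent_carbon for c in g.children[n]}
            if 3 in pcs and 6 not in pcs and n not in tried_branch:
                tried_branch.add(n)
                if backbone_size() + 1 <= p.max_size and rng.random() < p.p_branch:
                    add_glcnac(n, 6)
                    frontier_changed = True

    # decoration pass (order fixed for reproducibility)
    for n in list(g.nodes):
        res = g.nodes[n]
        if res.base == "Gal" and not g.children[n]:
            if rng.random() < p.p_fuc2_gal:
                fuc = g.add_node(Monosaccharide("Fuc"))
                g.add_edge(fuc, n, Linkage("α", 1, 2))
            if rng.random() < p.p_neu5ac_a3:
                sia = g.add_node(Monosaccharide("Neu5Ac"))
                g.add_edge(sia, n, Linkage("α", 2, 3))
            elif rng.random() < p.p_neu5ac_a6:
                sia = g.add_node(Monosaccharide("Neu5Ac"))
                g.add_edge(sia, n, Linkage("α", 2, 6))
        elif res.base == "GlcNAc":
            blocked = {g.linkage(c).parent_carbon for c in g.children[n]}
            if 3 not in blocked and rng.random() < p.p_fuc3_glcnac:
                fuc = g.add_node(Monosaccharide("Fuc"))
                g.add_edge(fuc, n, Linkage("α", 1, 3))
    return g


def simulate_structures(n: int, params: Optional[GrammarParams] = None) -> list:
    """Draw ``n`` structures from the grammar (seeded via ``params.seed``)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    p = params or GrammarParams()
    rng = np.random.default_rng(p.seed)
    return [_grow_structure(rng, p) for _ in range(n)]


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortDesign:
    """The study design: individuals × timepoints, a glycan panel with
    planted temporal clusters, individual random effects and Dirichlet
    sampling noise."""

    n_individuals: int = 5
    days: tuple = (2, 7, 13, 18)  # day 17/18/19 collapsed to 18
    panel_size: int = 60
    cluster_probs: dict = field(
        default_factory=lambda: {"Early": 0.2, "Stable": 0.4, "Late": 0.2, "Sporadic": 0.2}
    )
    multipliers: dict = field(default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    sporadic_presence: float = 0.3  # Bernoulli presence per (glycan, timepoint)
    individual_sigma: float = 0.2  # lognormal σ of individual × glycan effects
    dirichlet_concentration: float = 200.0
    grammar: Optional[GrammarParams] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.panel_size < 2:
            raise ValueError("panel must contain at least 2 glycans")
        if any(m < 0 for ms in self.multipliers.values() for m in ms):
            raise ValueError("temporal multipliers must be non-negative")


@dataclass
class GroundTruth:
    """Everything needed to score recovery: cluster assignments, planted
    effects, planted direct cross-omics pairs and latent loadings."""

    cluster_assignments: dict = field(default_factory=dict)
    structures: dict = field(default_factory=dict)  # glycan name → IUPAC string
    base_levels: dict = field(default_factory=dict)
    multipliers: dict = field(default_factory=dict)
    direct_pairs: list = field(default_factory=list)  # (glycan, metabolite, strength)
    latent_loadings: dict = field(default_factory=dict)
    planted_slopes: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), default=str, **kw)


def simulate_cohort(design: Optional[CohortDesign] = None):
    """Generate the cohort abundance table and its ground truth.

    Expected abundance of glycan g in sample (individual i, day d) =
    base_g × multiplier(cluster_g, d) × lognormal individual effect; the
    observed row is a Dirichlet draw around the expected composition,
    expressed as percentages (exact zeros stay zero).
    """
    design = design or CohortDesign()
    rng = np.random.default_rng(design.seed)

    grammar = design.grammar or GrammarParams(seed=int(rng.integers(2**31)))
    structures = simulate_structures(design.panel_size * 3, grammar)
    names, struct_map = [], {}
    for s in structures:
        key = write_iupac(s)
        if key not in struct_map:
            struct_map[key] = s
            names.append(key)
        if len(names) == design.panel_size:
            break
    if len(names) < design.panel_size:
        names = names[: len(names)]
    if len(names) < 2:
        raise ValueError("grammar produced fewer than 2 distinct glycans")

    clusters = list(design.cluster_probs)
    probs = np.array([design.cluster_probs[c] for c in clusters], dtype=float)
    probs = probs / probs.sum()
    assignment = {g: clusters[i] for g, i in zip(names, rng.choice(len(clusters), len(names), p=probs))}
    # guarantee every non-sporadic cluster is populated
    for i, c in enumerate(c for c in clusters if c != "Sporadic"):
        assignment[names[i]] = c

    base = {g: float(np.exp(rng.normal(0.0, 1.0))) for g in names}
    n_days = len(design.days)
    mult = {}
    for g in names:
        c = assignment[g]
        if c == "Sporadic":
            pres = (rng.random(n_days) < design.sporadic_presence).astype(float)
            if not pres.any():  # every glycan must appear somewhere
                pres[rng.integers(n_days)] = 1.0
            mult[g] = tuple(pres)
        else:
            mult[g] = tuple(design.multipliers[c][:n_days])

    individuals = [chr(ord("A") + i) for i in range(design.n_individuals)]
    ind_effect = {
        (i, g): float(np.exp(rng.normal(0.0, design.individual_sigma)))
        for i in individuals
        for g in names
    }

    rows, meta_rows, index = [], [], []
    for ind in individuals:
        for di, day in enumerate(design.days):
            expected = np.array(
                [base[g] * mult[g][di] * ind_effect[(ind, g)] for g in names]
            )
            if expected.sum() <= 0:
                raise ValueError("a sample has zero expected abundance everywhere")
            pos = expected > 0
            comp = np.zeros(len(names))
            alpha = design.dirichlet_concentration * expected[pos] / expected[pos].sum()
            comp[pos] = rng.dirichlet(alpha)
            rows.append(comp * 100.0)
            index.append(f"{ind}_d{day}")
            meta_rows.append((ind, day))

    data = pd.DataFrame(rows, index=index, columns=names)
    meta = pd.DataFrame(meta_rows, index=index, columns=["individual", "day"])
    truth = GroundTruth(
        cluster_assignments=assignment,
        structures={g: g for g in names},
        base_levels=base,
        multipliers={g: list(mult[g]) for g in names},
        seed=design.seed,
    )
    table = AbundanceTable(data, meta)
    table._structures = struct_map  # convenience: name → parsed structure
    return table, truth


# ---------------------------------------------------------------------------
# paired metabolome


def simulate_metabolome(
    cohort: AbundanceTable,
    truth: GroundTruth,
    n_metabolites: Optional[int] = None,
    n_direct_links: int = 3,
    noise_scale: float = 0.3,
    latent_sigma: float = 1.0,
    link_strength: float = 1.0,
    seed: Optional[int] = None,
):
    """Generate a paired metabolome for an existing cohort.

    A latent day factor (standardized lactation day) drives the bystander
    metabolites through log-scale loadings that are balanced to sum to
    zero; ``n_direct_links`` metabolites are instead tied directly to the
    CLR value of a specific glycan.  Individual effects and measurement
    noise scale with ``noise_scale`` (exactly zero noise leaves a direct
    link's Spearman ρ at 1 after CLR).  Output closed to percentages.
    Defaults to ~5× as many metabolites as glycans, mirroring typical
    metabolome/glycome feature ratios.
    """
    rng = np.random.default_rng(seed)
    glycans = list(cohort.data.columns)
    if n_metabolites is None:
        n_metabolites = 5 * len(glycans)
    if not 0 <= n_direct_links <= n_metabolites:
        raise ValueError("n_direct_links must lie in [0, n_metabolites]")
    if noise_scale < 0 or latent_sigma < 0:
        raise ValueError("scales must be non-negative")

    days = cohort.meta["day"].to_numpy(dtype=float)
    f = (days - days.mean()) / (days.std() if days.std() > 0 else 1.0)
    n_samples = len(cohort.data)

    # CLR of the glycome (deterministic: half-minimum imputation, γ=0)
    from .compositional import clr, impute

    glyco_clr = clr(
        impute(cohort.data, method="half_min").div(
            impute(cohort.data, method="half_min").sum(axis=1), axis=0
        )
    ).data

    # plant links on glycans observed in every sample (a direct metabolic
    # coupling to a glycan absent from most samples is not representable),
    # preferring those whose abundance actually varies across samples
    always_present = [g for g in glycans if (cohort.data[g] > 0).all()]
    candidates = always_present if len(always_present) >= n_direct_links else glycans
    candidates = sorted(
        candidates, key=lambda g: -float(np.var(np.log(cohort.data[g].clip(lower=1e-9))))
    )
    pool = candidates[: max(n_direct_links, len(candidates) // 3)]
    link_partners = [pool[i] for i in rng.choice(len(pool), n_direct_links, replace=False)]
    n_bystanders = n_metabolites - n_direct_links
    loadings = rng.normal(0.0, latent_sigma, n_bystanders)
    if n_bystanders:
        loadings = loadings - loadings.mean()  # balanced: closure-safe links

    individuals = cohort.meta["individual"].to_numpy()
    uniq_ind = list(dict.fromkeys(individuals))
    log_m = np.empty((n_samples, n_metabolites))
    met_names = []
    for j in range(n_direct_links):
        partner = link_partners[j]
        log_m[:, j] = link_strength * glyco_clr[partner].to_numpy() + rng.normal(
            0.0, noise_scale, n_samples
        )
        met_names.append(f"met_link_{j}")
    for j in range(n_bystanders):
        ind_eff = {i: rng.normal(0.0, 0.3 * noise_scale) for i in uniq_ind}
        log_m[:, n_direct_links + j] = (
            loadings[j] * f
            + np.array([ind_eff[i] for i in individuals])
            + rng.normal(0.0, noise_scale, n_samples)
        )
        met_names.append(f"met_{j}")

    raw = np.exp(log_m)
    data = pd.DataFrame(
        raw / raw.sum(axis=1, keepdims=True) * 100.0,
        index=cohort.data.index,
        columns=met_names,
    )
    out_truth = GroundTruth(
        cluster_assignments=dict(truth.cluster_assignments),
        direct_pairs=[
            (link_partners[j], f"met_link_{j}", link_strength) for j in range(n_direct_links)
        ],
        latent_loadings={f"met_{j}": float(loadings[j]) for j in range(n_bystanders)},
        seed=seed,
    )
    return AbundanceTable(data, cohort.meta.copy()), out_truth


def simulate_motif_timeseries(
    slope: float,
    intercept: float = 0.0,
    noise_sd: float = 0.2,
    n_individuals: int = 5,
    days: tuple = (2, 7, 13, 18),
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """CLR-scale motif values that follow a planted linear day trend, one
    row per individual × day (columns: individual, day, value)."""
    rng = np.random.default_rng(seed)
    rows = [
        (chr(ord("A") + i), d, intercept + slope * d + rng.normal(0.0, noise_sd))
        for i in range(n_individuals)
        for d in days
    ]
    return pd.DataFrame(rows, columns=["individual", "day", "value"])
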