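"""Seeded synthetic ontologies, cohorts and count tables with planted structure.

The generator emulates the products of a marine metagenomic annotation
pipeline for a Hawaii-Ocean-Time-series-like depth transect (and, for the
cross-environment workflows, a river-versus-marine contrast):

* a GO-like DAG embedding a fixed worked-example fragment (cellular
  metabolic process over photosynthesis and methanogenesis, the binding /
  ion binding / cation binding family, an oxidoreductase branch) plus a
  seeded random DAG;
* an NCBITaxon-like ranked tree embedding the *Prochlorococcus* and
  *Synechococcus* genera with named low-light-adapted strains, the
  OMZ-affiliated phyla, and seeded random taxa below them;
* a small ENVO-like vocabulary of water-body classes and measurable
  parameters (depth, dissolved oxygen, phosphate, dissolved inorganic
  carbon);
* per-sample metadata, pipeline statistics and multinomial count tables.

Counts follow a logistic-normal / multinomial model: term weights are
``exp(a_f + b_f * z_j + eps)`` where ``z_j`` is the sample's standardized
covariate (depth or group), ``a_f`` a seeded log-normal baseline, ``b_f``
a planted effect, and ``eps`` per-(sample, term) Gaussian overdispersion;
the multinomial total is the sample's read/ORF count.  Every planted
effect, per-sample total and expected abundance needed by a test oracle is
recorded in the run ledger.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ontology import OntologyGraph, OntologyTerm, parse_obo, write_obo
from .store import (
    FeatureCountTable,
    SampleRecord,
    SampleStats,
    Store,
    read_count_table,
    read_sample_metadata,
    read_sample_stats,
    write_sample_metadata,
    write_sample_stats,
)

__all__ = [
    "PlantedEffect",
    "SimulationDesign",
    "make_go_like_ontology",
    "make_taxonomy",
    "make_env_ontology",
    "simulate_dataset",
    "write_fixture_bundle",
    "load_bundle",
]

# CURIEs for measurable parameters
DEPTH = "ENVO:3100031"
OXYGEN = "ENVO:3100011"
PHOSPHATE = "ENVO:3100026"
DIC = "PMO:00000142"

MESOPELAGIC = "ENVO:00000213"
SEA_SURFACE = "ENVO:01001581"
MARINE_WATER_BODY = "ENVO:00001999"
RIVER = "ENVO:00000022"

CATION_BINDING = "GO:0043169"
PHOTOSYNTHESIS = "GO:0015979"
METHANOGENESIS = "GO:0015948"
CO_DEHYDROGENASE = "GO:0018492"
PROCHLOROCOCCUS = "NCBITaxon:1218"
MIT0801 = "NCBITaxon:1501269"
LOW_LIGHT_STRAINS = (
    "NCBITaxon:167555",
    "NCBITaxon:59920",
    "NCBITaxon:93059",
    "NCBITaxon:167539",
)


def _term(tid, label, parents=(), rank="no rank"):
    return OntologyTerm(
        id=tid, label=label, parent_ids=frozenset(parents), rank=rank
    )


# ---------------------------------------------------------------------------
# ontologies

_GO_FIXED = [
    ("GO:0003673", "gene ontology", ()),
    ("GO:0008150", "biological process", ("GO:0003673",)),
    ("GO:0003674", "molecular function", ("GO:0003673",)),
    ("GO:0044237", "cellular metabolic process", ("GO:0008150",)),
    ("GO:0015979", "photosynthesis", ("GO:0044237",)),
    ("GO:0015947", "methane metabolic process", ("GO:0044237",)),
    ("GO:0015948", "methanogenesis", ("GO:0015947",)),
    ("GO:0009061", "anaerobic respiration", ("GO:0044237",)),
    ("GO:0006547", "histidine metabolic process", ("GO:0044237",)),
    ("GO:0005488", "binding", ("GO:0003674",)),
    ("GO:0043167", "ion binding", ("GO:0005488",)),
    ("GO:0043169", "cation binding", ("GO:0043167",)),
    ("GO:0043168", "anion binding", ("GO:0043167",)),
    ("GO:0042301", "phosphate ion binding", ("GO:0043168",)),
    ("GO:0005509", "calcium ion binding", ("GO:0043169",)),
    ("GO:0016151", "nickel cation binding", ("GO:0043169",)),
    ("GO:0008199", "ferric iron binding", ("GO:0043169",)),
    ("GO:0008198", "ferrous iron binding", ("GO:0043169",)),
    ("GO:0034618", "arginine binding", ("GO:0043169",)),
    ("GO:0031072", "heat shock protein binding", ("GO:0005488",)),
    ("GO:0009058", "biosynthetic process", ("GO:0008150",)),
    ("GO:0006750", "glutathione biosynthetic process", ("GO:0009058",)),
    ("GO:0016052", "carbohydrate catabolic process", ("GO:0008150",)),
    ("GO:0045493", "xylan catabolic process", ("GO:0016052",)),
    ("GO:0016491", "oxidoreductase activity", ("GO:0003674",)),
    ("GO:0018492", "carbon monoxide dehydrogenase (acceptor) activity", ("GO:0016491",)),
    ("GO:0042279", "nitrite reductase (cytochrome, ammonia-forming) activity", ("GO:0016491",)),
]

# extra leaves of the queried cation binding family (seventeen leaves total,
# the size of the worked gene-vs-gradient query)
_N_EXTRA_CATION = 12


def make_go_like_ontology(seed: int, n_terms: int = 60) -> OntologyGraph:
    """GO-like DAG: the fixed worked-example fragment plus random terms.

    Random terms get 1-3 parents drawn from already-created terms, which
    guarantees acyclicity and a single root.  Same seed, same graph.
    """
    if n_terms < 20:
        raise ValueError("n_terms must be >= 20")
    rng = np.random.default_rng(seed)
    terms: dict[str, OntologyTerm] = {}
    for tid, label, parents in _GO_FIXED:
        terms[tid] = _term(tid, label, parents)
    for i in range(_N_EXTRA_CATION):
        tid = f"GO:88000{i:02d}"
        terms[tid] = _term(tid, f"cation binding activity {i}", (CATION_BINDING,))
    # random terms attach below internal fixed nodes only, so the fixed
    # leaves stay leaves (they are the planted count categories)
    with_children = {p for t in terms.values() for p in t.parent_ids}
    pool = sorted(with_children)
    for i in range(n_terms):
        tid = f"GO:9{i:06d}"
        k = int(rng.integers(1, 4))
        parents = rng.choice(pool, size=min(k, len(pool)), replace=False)
        terms[tid] = _term(tid, f"random process {i}", tuple(parents))
        pool.append(tid)
    g = OntologyGraph(terms=terms)
    g.validate_acyclic()
    return g


_RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species", "strain"]

_TAX_FIXED = [
    ("NCBITaxon:1", "root", (), "no rank"),
    ("NCBITaxon:131567", "cellular organisms", ("NCBITaxon:1",), "no rank"),
    ("NCBITaxon:2", "Bacteria", ("NCBITaxon:131567",), "domain"),
    ("NCBITaxon:2157", "Archaea", ("NCBITaxon:131567",), "domain"),
    ("NCBITaxon:1117", "Cyanobacteria", ("NCBITaxon:2",), "phylum"),
    ("NCBITaxon:1224", "Proteobacteria", ("NCBITaxon:2",), "phylum"),
    ("NCBITaxon:976", "Bacteroidetes", ("NCBITaxon:2",), "phylum"),
    ("NCBITaxon:1239", "Firmicutes", ("NCBITaxon:2",), "phylum"),
    ("NCBITaxon:203682", "Planctomycetes", ("NCBITaxon:2",), "phylum"),
    ("NCBITaxon:74201", "Verrucomicrobia", ("NCBITaxon:2",), "phylum"),
    ("NCBITaxon:28211", "Alphaproteobacteria", ("NCBITaxon:1224",), "class"),
    ("NCBITaxon:1236", "Gammaproteobacteria", ("NCBITaxon:1224",), "class"),
    ("NCBITaxon:28221", "Deltaproteobacteria", ("NCBITaxon:1224",), "class"),
    ("NCBITaxon:29547", "Epsilonproteobacteria", ("NCBITaxon:1224",), "class"),
    ("NCBITaxon:1890424", "Synechococcales", ("NCBITaxon:1117",), "order"),
    ("NCBITaxon:1213", "Prochloraceae", ("NCBITaxon:1890424",), "family"),
    ("NCBITaxon:1890426", "Synechococcaceae", ("NCBITaxon:1890424",), "family"),
    ("NCBITaxon:1218", "Prochlorococcus", ("NCBITaxon:1213",), "genus"),
    ("NCBITaxon:1129", "Synechococcus", ("NCBITaxon:1890426",), "genus"),
    ("NCBITaxon:1219", "Prochlorococcus marinus", ("NCBITaxon:1218",), "species"),
    ("NCBITaxon:1501269", "Prochlorococcus sp. MIT 0801", ("NCBITaxon:1218",), "species"),
    ("NCBITaxon:167555", "Prochlorococcus marinus str. NATL1A", ("NCBITaxon:1219",), "strain"),
    ("NCBITaxon:59920", "Prochlorococcus marinus str. NATL2A", ("NCBITaxon:1219",), "strain"),
    ("NCBITaxon:93059", "Prochlorococcus marinus str. MIT 9211", ("NCBITaxon:1219",), "strain"),
    ("NCBITaxon:167539", "Prochlorococcus marinus subsp. marinus str. CCMP1375", ("NCBITaxon:1219",), "strain"),
    ("NCBITaxon:32046", "Synechococcus elongatus", ("NCBITaxon:1129",), "species"),
    ("NCBITaxon:1140", "Synechococcus elongatus PCC 7942", ("NCBITaxon:32046",), "strain"),
    ("NCBITaxon:1846278", "Candidatus Nitrosotenuis aquarius", ("NCBITaxon:2157",), "species"),
    ("NCBITaxon:2268451", "Candidatus Pelagibacter sp. FZCC0015", ("NCBITaxon:28211",), "species"),
]


def make_taxonomy(seed: int, n_terms: int = 40) -> OntologyGraph:
    """NCBITaxon-like ranked tree with the fixed cyanobacterial skeleton.

    Every node except the root has exactly one parent, and every child's
    rank is strictly finer than its parent's.  Random genera, species and
    strains are attached below seeded picks of the existing internal nodes.
    """
    if n_terms < 30:
        raise ValueError("n_terms must be >= 30")
    rng = np.random.default_rng(seed)
    terms: dict[str, OntologyTerm] = {}
    for tid, label, parents, rank in _TAX_FIXED:
        terms[tid] = _term(tid, label, parents, rank)
    # fixed species stay out of the pool so their strain sets are stable
    fixed_species = {tid for tid, _, _, r in _TAX_FIXED if r == "species"}
    attachable = [
        tid
        for tid, t in terms.items()
        if t.rank in _RANKS and t.rank != "strain" and tid not in fixed_species
    ]
    for i in range(n_terms):
        parent = str(rng.choice(attachable))
        p_rank = terms[parent].rank
        rank = _RANKS[_RANKS.index(p_rank) + 1]
        tid = f"NCBITaxon:9{i:06d}"
        terms[tid] = _term(tid, f"synthetic {rank} {i}", (parent,), rank)
        if rank != "strain":
            attachable.append(tid)
    g = OntologyGraph(terms=terms)
    g.validate_acyclic()
    return g


_ENV_FIXED = [
    ("ENVO:00000000", "environmental entity", (), ""),
    ("ENVO:00000063", "water body", ("ENVO:00000000",), ""),
    ("ENVO:00001999", "marine water body", ("ENVO:00000063",), ""),
    ("ENVO:00000022", "river", ("ENVO:00000063",), ""),
    ("ENVO:00000015", "ocean", ("ENVO:00001999",), ""),
    ("ENVO:02000049", "coastal water body", ("ENVO:00001999",), ""),
    ("ENVO:01001581", "sea surface layer", ("ENVO:00001999",), ""),
    ("ENVO:01000061", "marine wind mixed layer", ("ENVO:01001581",), ""),
    ("ENVO:00000213", "marine mesopelagic zone", ("ENVO:00001999",), ""),
    ("ENVO:01000324", "measurable environmental parameter", ("ENVO:00000000",), ""),
    ("ENVO:3100031", "depth of water", ("ENVO:01000324",), ""),
    ("ENVO:3100011", "concentration of dioxygen in liquid water", ("ENVO:01000324",), ""),
    ("ENVO:3100026", "concentration of phosphate in liquid water", ("ENVO:01000324",), ""),
    ("PMO:00000142", "dissolved inorganic carbon", ("ENVO:01000324",), ""),
]


def make_env_ontology() -> OntologyGraph:
    """Fixed ENVO-like vocabulary of environments and parameters."""
    terms = {
        tid: _term(tid, label, parents) for tid, label, parents, _ in _ENV_FIXED
    }
    g = OntologyGraph(terms=terms)
    g.validate_acyclic()
    return g


# ---------------------------------------------------------------------------
# simulation design


@dataclass(frozen=True)
class PlantedEffect:
    term: str
    covariate: str  # "depth" | "group" (anoxia) | "river"
    strength: float  # log-scale slope against the standardized covariate


def _default_function_effects() -> list[PlantedEffect]:
    return [
        PlantedEffect(PHOTOSYNTHESIS, "depth", -2.0),
        PlantedEffect(METHANOGENESIS, "depth", 2.0),
        PlantedEffect("GO:0042301", "depth", -1.5),
        # the planted cation binding gradient terms recovered by the
        # gene-vs-gradient workflow; moderate slopes keep these genes out
        # of the top-variance band while per-term overdispersion keeps
        # them informative jointly rather than mutually redundant
        PlantedEffect("GO:0016151", "depth", -1.1),
        PlantedEffect("GO:0008199", "depth", -0.9),
        PlantedEffect("GO:0008198", "depth", 1.0),
        PlantedEffect("GO:0034618", "depth", 0.9),
        PlantedEffect("GO:0005509", "depth", -1.0),
        # river-vs-marine differential genes for the cross-environment
        # workflows (plant-derived xylan degradation in the river, marine
        # osmotic-stress glutathione synthesis)
        PlantedEffect("GO:0045493", "river", 1.2),
        PlantedEffect("GO:0006750", "river", -1.2),
    ]


def _default_taxon_effects() -> list[PlantedEffect]:
    eff = [PlantedEffect(MIT0801, "depth", 1.6)]
    for s, b in zip(LOW_LIGHT_STRAINS, (1.5, 1.7, 1.4, 1.6)):
        eff.append(PlantedEffect(s, "depth", b))
    eff.append(PlantedEffect("NCBITaxon:1140", "depth", -1.8))
    eff.append(PlantedEffect("NCBITaxon:1846278", "river", 1.3))
    eff.append(PlantedEffect("NCBITaxon:2268451", "river", -1.2))
    return eff


@dataclass
class SimulationDesign:
    """Study conditions for a synthetic cohort.

    Defaults emulate the corpus the workflows were built for: a 64-sample
    depth transect from 5 to 1000 m with ~1e7 QC reads and ~1e6 ORFs per
    sample.  ``scale`` shrinks the sequencing totals (1e-3 for quick runs);
    every other condition is untouched by it.
    """

    n_samples: int = 64
    depth_min: float = 5.0
    depth_max: float = 1000.0
    n_function_terms: int = 60   # random GO terms beyond the fixed fragment
    n_taxon_terms: int = 40      # random taxa beyond the fixed skeleton
    function_effects: list[PlantedEffect] = field(default_factory=_default_function_effects)
    taxon_effects: list[PlantedEffect] = field(default_factory=_default_taxon_effects)
    # perfect anoxic indicators: one in the metabolic-process family, one in
    # the oxidoreductase family (both question shapes are exercised)
    indicator_terms: list[str] = field(
        default_factory=lambda: [CO_DEHYDROGENASE, "GO:0006547"]
    )
    reads_qc_scale: float = 1e7
    orfs_scale: float = 1e6
    scale: float = 1.0
    overdispersion_sd: float = 0.8
    measurement_noise_sd: float = 0.05  # relative sd on physicochemical values
    anoxic_oxygen_threshold: float = 20.0  # umol/kg
    n_housekeeping: int = 6  # high-abundance stable terms per table
    project_id: str = "HOT_224_283"
    river_fraction: float = 0.0  # fraction of samples from a river project
    planted_qc_failures: dict[int, str] = field(default_factory=dict)  # index -> reason
    qc_min_raw_reads: float | None = None  # default: 0.5 * scaled reads
    qc_min_unique_taxa: int | None = None  # default: half the taxon categories
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.depth_max <= self.depth_min:
            raise ValueError("depth_max must exceed depth_min")
        for eff in list(self.function_effects) + list(self.taxon_effects):
            if eff.covariate not in ("depth", "group", "river"):
                raise ValueError(f"unknown covariate: {eff.covariate}")
            if not np.isfinite(eff.strength):
                raise ValueError("planted strengths must be finite")
        for i, reason in self.planted_qc_failures.items():
            if not 0 <= i < max(self.n_samples, 1):
                raise ValueError(f"planted failure index {i} out of range")
            if reason not in ("reads", "taxa"):
                raise ValueError(f"unknown QC failure reason: {reason}")


# ---------------------------------------------------------------------------
# dataset generation


def _leaves(g: OntologyGraph) -> list[str]:
    idx = g.children_index()
    return sorted(t for t in g.non_obsolete() if not idx[t])


def _oxygen_profile(depth: np.ndarray) -> np.ndarray:
    # OMZ-like: well-oxygenated surface, oxycline near 300 m, suboxic
    # (< ~20 umol/kg) below ~450 m
    return 230.0 / (1.0 + np.exp((depth - 300.0) / 60.0)) + 3.0


def _phosphate_profile(depth: np.ndarray) -> np.ndarray:
    return 0.1 + 2.8 * depth / (depth + 300.0)


def _simulate_counts(
    rng: np.random.Generator,
    terms: list[str],
    z_depth: np.ndarray,
    z_group: np.ndarray,
    z_river: np.ndarray,
    effects: list[PlantedEffect],
    indicator_terms: list[str],
    housekeeping: list[str],
    totals: np.ndarray,
    overdispersion_sd: float,
    restrict_rows: dict[int, np.ndarray],
    baseline_overrides: dict[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, dict]:
    """Multinomial counts for one table; returns (matrix, oracle record)."""
    p = len(terms)
    n = len(z_depth)
    t_idx = {t: j for j, t in enumerate(terms)}
    a = rng.normal(-1.0, 0.8, size=p)  # log-normal baselines
    for t in housekeeping:
        a[t_idx[t]] = rng.normal(3.0, 0.2)
    for t, (mu, sd) in (baseline_overrides or {}).items():
        if t in t_idx:
            a[t_idx[t]] = rng.normal(mu, sd)
    b = {c: np.zeros(p) for c in ("depth", "group", "river")}
    for eff in effects:
        if eff.term not in t_idx:
            raise ValueError(f"planted term {eff.term} not a count category")
        b[eff.covariate][t_idx[eff.term]] = eff.strength

    log_w = (
        a[None, :]
        + np.outer(z_depth, b["depth"])
        + np.outer(z_group, b["group"])
        + np.outer(z_river, b["river"])
    )
    log_w = log_w + rng.normal(0.0, overdispersion_sd, size=(n, p))
    w = np.exp(log_w)
    for t in indicator_terms:
        j = t_idx[t]
        w[z_group <= 0, j] = 0.0  # exclusive to the positive (anoxic) group
        w[z_group > 0, j] = np.exp(1.5)  # solidly present where it occurs
    for i, mask in restrict_rows.items():
        w[i] = w[i] * mask
    probs = w / w.sum(axis=1, keepdims=True)
    counts = np.empty((n, p), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(int(totals[i]), probs[i])
    record = {
        "terms": terms,
        "baselines": a.tolist(),
        "expected_probs_planted": {
            eff.term: probs[:, t_idx[eff.term]].tolist() for eff in effects
        },
        "planted_effects": [asdict(e) for e in effects],
        "indicator_terms": indicator_terms,
        "housekeeping": housekeeping,
    }
    return counts, record


def _long(kind: str, samples: list[str], terms: list[str], mat: np.ndarray) -> FeatureCountTable:
    rows = []
    for i, s in enumerate(samples):
        nz = np.nonzero(mat[i])[0]
        for j in nz:
            rows.append((s, terms[j], int(mat[i, j])))
    df = pd.DataFrame(rows, columns=["sample_id", "term_id", "count"])
    if df.empty:
        df = pd.DataFrame({"sample_id": [], "term_id": [], "count": []})
    return FeatureCountTable(kind=kind, data=df)


def simulate_dataset(
    design: SimulationDesign,
) -> tuple[list[SampleRecord], dict[str, SampleStats], FeatureCountTable, FeatureCountTable, dict]:
    """Generate a full synthetic cohort from a design.

    Returns (records, stats, function table, taxon table, ledger).  The
    ledger carries everything a downstream oracle needs: planted effects,
    expected abundances of planted terms, per-sample totals, group labels,
    planted QC failures and the thresholds that expose them.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_samples

    go = make_go_like_ontology(design.seed, design.n_function_terms)
    tax = make_taxonomy(design.seed, design.n_taxon_terms)

    depth = np.linspace(design.depth_min, design.depth_max, n) if n else np.array([])
    n_river = int(round(design.river_fraction * n))
    is_river = np.zeros(n, dtype=bool)
    if n_river:
        is_river[:n_river] = True
        depth = depth.copy()
        depth[is_river] = np.linspace(2.0, 25.0, n_river)  # surface river samples

    noise = design.measurement_noise_sd
    oxygen = _oxygen_profile(depth) * np.exp(rng.normal(0, noise, n)) if n else depth
    phosphate = _phosphate_profile(depth) * np.exp(rng.normal(0, noise, n)) if n else depth
    dic = np.where(is_river, 180.0, 2050.0) * np.exp(rng.normal(0, noise, n)) if n else depth
    anoxic = oxygen < design.anoxic_oxygen_threshold if n else np.zeros(0, bool)

    z_depth = (depth - depth.mean()) / depth.std() if n > 1 and depth.std() > 0 else np.zeros(n)
    z_group = np.where(anoxic, 1.0, -1.0) if n else np.zeros(0)
    z_river = np.where(is_river, 1.0, -1.0) if n else np.zeros(0)

    samples = [f"S{i:04d}" for i in range(n)]
    reads_qc = (
        np.maximum(
            (design.reads_qc_scale * design.scale * np.exp(rng.normal(0, 0.1, n))).astype(np.int64),
            1,
        )
        if n
        else np.array([], dtype=np.int64)
    )
    orfs = (
        np.maximum(
            (design.orfs_scale * design.scale * np.exp(rng.normal(0, 0.1, n))).astype(np.int64),
            1,
        )
        if n
        else np.array([], dtype=np.int64)
    )
    reads_raw = (reads_qc / 0.85).astype(np.int64)

    min_raw = design.qc_min_raw_reads
    if min_raw is None:
        min_raw = 0.5 * design.reads_qc_scale * design.scale / 0.85

    # taxon categories: species/strain leaves plus genus-level internal nodes,
    # exercising Kraken2-style internal assignments
    tax_leaves = _leaves(tax)
    genus_nodes = sorted(
        t for t, term in tax.terms.items() if term.rank == "genus"
    )
    taxon_categories = sorted(set(tax_leaves) | set(genus_nodes))
    go_leaves = _leaves(go)

    min_taxa = design.qc_min_unique_taxa
    if min_taxa is None:
        min_taxa = len(taxon_categories) // 2

    restrict_taxa: dict[int, np.ndarray] = {}
    for i, reason in design.planted_qc_failures.items():
        if reason == "reads":
            reads_raw[i] = int(min_raw * 0.8)
            reads_qc[i] = min(reads_qc[i], reads_raw[i])
        else:  # concentrate the sample on a few taxa so richness collapses
            mask = np.zeros(len(taxon_categories))
            keep = rng.choice(len(taxon_categories), size=max(min_taxa // 4, 1), replace=False)
            mask[keep] = 1.0
            restrict_taxa[i] = mask

    hk_go = [t for t in go_leaves if t.startswith("GO:9")][: design.n_housekeeping]
    hk_tax = [t for t in tax_leaves if t.startswith("NCBITaxon:9")][: design.n_housekeeping]

    # planted gradient genes sit at modest baseline abundance while the
    # unplanted members of the queried family are abundant and stable, so
    # the high-variance exclusion step removes housekeeping-like genes
    # rather than the gradient signal — the regime the workflow assumes
    overrides: dict[str, tuple[float, float]] = {
        eff.term: (-2.0, 0.2) for eff in design.function_effects
    }
    for j in range(_N_EXTRA_CATION):
        overrides[f"GO:88000{j:02d}"] = (0.5, 0.3)
    func_counts, func_record = _simulate_counts(
        rng, go_leaves, z_depth, z_group, z_river,
        design.function_effects, design.indicator_terms, hk_go,
        orfs, design.overdispersion_sd, {}, overrides,
    )
    overrides_tax = {eff.term: (-2.0, 0.2) for eff in design.taxon_effects}
    taxon_counts, taxon_record = _simulate_counts(
        rng, taxon_categories, z_depth, z_group, z_river,
        design.taxon_effects, [], hk_tax,
        reads_qc, design.overdispersion_sd, restrict_taxa, overrides_tax,
    )

    func_table = _long("function", samples, go_leaves, func_counts)
    taxon_table = _long("taxon", samples, taxon_categories, taxon_counts)

    records = []
    stats = {}
    for i, s in enumerate(samples):
        env = frozenset(
            {RIVER}
            if is_river[i]
            else {MARINE_WATER_BODY, SEA_SURFACE if depth[i] < 200 else MESOPELAGIC}
        )
        meas = {
            DEPTH: (float(depth[i]), "m"),
            OXYGEN: (float(oxygen[i]), "umol/kg"),
            PHOSPHATE: (float(phosphate[i]), "umol/kg"),
            DIC: (float(dic[i]), "umol/kg"),
        }
        records.append(
            SampleRecord(
                sample_id=s,
                project_id="Amazon_River" if is_river[i] else design.project_id,
                env_classes=env,
                measurements=meas,
                depth_m=float(depth[i]),
                latitude=22.75 if not is_river[i] else -3.1,
                longitude=-158.0 if not is_river[i] else -60.0,
                collected_at=f"2020-01-{(i % 28) + 1:02d}T00:00:00Z",
            )
        )
        stats[s] = SampleStats(
            sample_id=s,
            n_reads_raw=int(reads_raw[i]),
            n_reads_qc=int(reads_qc[i]),
            n_orfs=int(orfs[i]),
            n_unique_taxa=int((taxon_counts[i] > 0).sum()),
            n_unique_go=int((func_counts[i] > 0).sum()),
        )

    anoxic_idx = np.where(anoxic)[0]
    indicator_occupancy = {
        t: float((func_counts[anoxic_idx, go_leaves.index(t)] > 0).mean())
        if len(anoxic_idx)
        else 0.0
        for t in design.indicator_terms
    }
    ledger = {
        "seed": design.seed,
        "scale": design.scale,
        "n_samples": n,
        "samples": samples,
        "depth_m": depth.tolist(),
        "oxygen": oxygen.tolist(),
        "phosphate": phosphate.tolist(),
        "dic": dic.tolist(),
        "anoxic": anoxic.astype(bool).tolist(),
        "anoxic_oxygen_threshold": design.anoxic_oxygen_threshold,
        "totals": {"n_reads_qc": reads_qc.tolist(), "n_orfs": orfs.tolist(),
                   "n_reads_raw": reads_raw.tolist()},
        "function": func_record,
        "taxon": taxon_record,
        "planted_qc_failures": {samples[i]: r for i, r in design.planted_qc_failures.items()},
        "qc_min_raw_reads": float(min_raw),
        "qc_min_unique_taxa": int(min_taxa),
        "indicator_occupancy_anoxic": indicator_occupancy,
    }
    return records, stats, func_table, taxon_table, ledger


# ---------------------------------------------------------------------------
# fixture bundles on disk


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(directory, design: SimulationDesign) -> dict:
    """Write ontologies, tables, metadata, stats and the ledger to a
    directory; returns a manifest of file SHA-256 hashes.

    The bundle is exactly what :func:`load_bundle` (and the CLI) consume,
    and what the store readers validate.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records, stats, func_table, taxon_table, ledger = simulate_dataset(design)
    go = make_go_like_ontology(design.seed, design.n_function_terms)
    tax = make_taxonomy(design.seed, design.n_taxon_terms)
    env = make_env_ontology()

    write_obo(go, directory / "go.obo")
    write_obo(tax, directory / "taxonomy.obo")
    write_obo(env, directory / "env.obo")
    func_table.data.to_csv(directory / "functions.tsv", sep="\t", index=False)
    taxon_table.data.to_csv(directory / "taxa.tsv", sep="\t", index=False)
    write_sample_metadata(records, directory / "metadata.tsv")
    write_sample_stats(stats, directory / "stats.tsv")
    (directory / "ledger.json").write_text(json.dumps(ledger, indent=1, sort_keys=True))

    files = ["go.obo", "taxonomy.obo", "env.obo", "functions.tsv", "taxa.tsv",
             "metadata.tsv", "stats.tsv", "ledger.json"]
    manifest = {f: _sha256(directory / f) for f in files}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def load_bundle(directory) -> tuple[Store, dict[str, OntologyGraph], dict]:
    """Load a fixture bundle into a Store plus its ontologies and ledger."""
    directory = Path(directory)
    with open(directory / "go.obo") as fh:
        go = parse_obo(fh)
    with open(directory / "taxonomy.obo") as fh:
        tax = parse_obo(fh)
    with open(directory / "env.obo") as fh:
        env = parse_obo(fh)
    records = read_sample_metadata(directory / "metadata.tsv", env_ontology=env)
    stats = read_sample_stats(directory / "stats.tsv")
    func = read_count_table(directory / "functions.tsv", "function")
    taxa = read_count_table(directory / "taxa.tsv", "taxon")
    store = Store(
        records={r.sample_id: r for r in records},
        stats=stats,
        tables={"function": func, "taxon": taxa},
    )
    ledger = json.loads((directory / "ledger.json").read_text())
    return store, {"function": go, "taxon": tax, "env": env}, ledger
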