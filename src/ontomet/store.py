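"""Sample store: count tables, pipeline statistics, metadata, QC and queries.

The store holds the three products of an upstream annotation pipeline for a
cohort of metagenomic samples:

* per-sample **feature count tables** — Kraken2-style taxon read counts
  keyed by NCBITaxon CURIEs, and Pfam/InterProScan-derived gene counts keyed
  by GO CURIEs;
* per-sample **pipeline statistics** — raw reads, reads surviving quality
  control (the denominator for taxon relativization), predicted ORFs (the
  denominator for gene relativization) and annotation richness;
* per-sample **metadata** — project membership, ENVO environment classes,
  physicochemical measurements keyed by parameter CURIEs, depth and
  coordinates.

Its central operation is the intersection :func:`query`: the recursive
subclass closure of an ontology class is intersected with the terms present
in the data, restricted to the samples that satisfy every metadata
constraint.  The store can be exported as RDF N-Triples realizing a minimal
FAIR vocabulary, so the same intersections can be posed to any SPARQL
engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyGraph, UnknownTermError, descendants, is_curie

__all__ = [
    "SampleRecord",
    "SampleStats",
    "FeatureCountTable",
    "QueryConstraints",
    "QueryResult",
    "QcReport",
    "Store",
    "StoreError",
    "read_count_table",
    "read_sample_metadata",
    "read_sample_stats",
    "write_sample_metadata",
    "qc_filter_samples",
    "annotation_richness",
    "query",
    "export_ntriples",
]

MIN_RAW_READS = 5_000_000
MIN_UNIQUE_TAXA = 10_000

ONTOMET_NS = "https://w3id.org/ontomet/"
OBO_NS = "http://purl.obolibrary.org/obo/"
RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
XSD = "http://www.w3.org/2001/XMLSchema#"


class StoreError(Exception):
    pass


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    project_id: str
    env_classes: frozenset[str] = frozenset()
    measurements: Mapping[str, tuple[float, str]] = field(default_factory=dict)
    depth_m: float | None = None
    latitude: float | None = None
    longitude: float | None = None
    collected_at: str | None = None

    def __post_init__(self):
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise StoreError(
                f"sample {self.sample_id}: latitude {self.latitude} out of [-90, 90]"
            )
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise StoreError(
                f"sample {self.sample_id}: longitude {self.longitude} out of [-180, 180]"
            )
        if self.depth_m is not None and self.depth_m < 0:
            raise StoreError(f"sample {self.sample_id}: negative depth {self.depth_m}")


@dataclass(frozen=True)
class SampleStats:
    sample_id: str
    n_reads_raw: int
    n_reads_qc: int
    n_orfs: int
    n_unique_taxa: int = 0
    n_unique_go: int = 0

    def __post_init__(self):
        for f in ("n_reads_raw", "n_reads_qc", "n_orfs", "n_unique_taxa", "n_unique_go"):
            if getattr(self, f) < 0:
                raise StoreError(f"sample {self.sample_id}: negative {f}")
        if self.n_reads_qc > self.n_reads_raw:
            raise StoreError(
                f"sample {self.sample_id}: n_reads_qc > n_reads_raw"
            )


@dataclass
class FeatureCountTable:
    """Sparse sample x term table, long format.

    ``data`` has columns ``sample_id``, ``term_id``, ``count`` with no
    duplicate (sample, term) keys.  ``normalized`` is False for raw integer
    counts and True for relativized real abundances in [0, 1].
    """

    kind: str  # "function" | "taxon"
    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        if self.kind not in ("function", "taxon"):
            raise StoreError(f"bad table kind: {self.kind}")
        expected = ["sample_id", "term_id", "count"]
        if list(self.data.columns) != expected:
            raise StoreError(f"table columns must be {expected}")

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))

    @property
    def terms(self) -> list[str]:
        return sorted(set(self.data["term_id"]))

    def value(self, sample_id: str, term_id: str) -> float:
        sel = self.data[
            (self.data["sample_id"] == sample_id) & (self.data["term_id"] == term_id)
        ]
        return float(sel["count"].iloc[0]) if len(sel) else 0.0

    def sample_total(self, sample_id: str) -> float:
        return float(self.data.loc[self.data["sample_id"] == sample_id, "count"].sum())

    def restrict_samples(self, keep: Iterable[str]) -> "FeatureCountTable":
        keep = set(keep)
        return replace(self, data=self.data[self.data["sample_id"].isin(keep)].reset_index(drop=True))

    def restrict_terms(self, keep: Iterable[str]) -> "FeatureCountTable":
        keep = set(keep)
        return replace(self, data=self.data[self.data["term_id"].isin(keep)].reset_index(drop=True))

    def to_matrix(
        self, samples: Sequence[str] | None = None, terms: Sequence[str] | None = None
    ) -> tuple[list[str], list[str], np.ndarray]:
        """Densify to (samples, terms, values); absent entries are 0."""
        samples = list(samples) if samples is not None else self.samples
        terms = list(terms) if terms is not None else self.terms
        mat = np.zeros((len(samples), len(terms)))
        s_idx = {s: i for i, s in enumerate(samples)}
        t_idx = {t: j for j, t in enumerate(terms)}
        for s, t, c in self.data.itertuples(index=False):
            if s in s_idx and t in t_idx:
                mat[s_idx[s], t_idx[t]] = c
        return samples, terms, mat


@dataclass
class Store:
    records: dict[str, SampleRecord] = field(default_factory=dict)
    stats: dict[str, SampleStats] = field(default_factory=dict)
    tables: dict[str, FeatureCountTable] = field(default_factory=dict)

    def table_for(self, kind: str) -> FeatureCountTable:
        try:
            return self.tables[kind]
        except KeyError:
            raise StoreError(f"store has no {kind} table") from None


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path, kind: str) -> FeatureCountTable:
    """Read a TSV of (sample_id, term_id, count) into a count table.

    Duplicate (sample, term) rows are summed with a warning — parallelized
    annotation runs can legitimately shard a term across files.  Non-integer
    counts and malformed CURIEs raise with the 1-based data line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "term_id", "count"]
    if list(df.columns[:3]) != required:
        raise StoreError(f"count table must start with columns {required}")
    counts = np.empty(len(df), dtype=np.int64)
    for i, (term, raw) in enumerate(zip(df["term_id"], df["count"])):
        line = i + 2  # header is line 1
        if not is_curie(term):
            raise StoreError(f"line {line}: malformed CURIE {term!r}")
        try:
            counts[i] = int(raw)
        except ValueError:
            raise StoreError(f"line {line}: non-integer count {raw!r}") from None
        if counts[i] < 0:
            raise StoreError(f"line {line}: negative count {raw!r}")
    out = df[["sample_id", "term_id"]].copy()
    out["count"] = counts
    dup = out.duplicated(["sample_id", "term_id"])
    if dup.any():
        n = int(dup.sum())
        warnings.warn(f"{n} duplicate (sample, term) rows summed", stacklevel=2)
        out = out.groupby(["sample_id", "term_id"], as_index=False, sort=False)["count"].sum()
    return FeatureCountTable(kind=kind, data=out.reset_index(drop=True))


def _opt_float(cell: str) -> float | None:
    return None if cell == "" else float(cell)


_META_FIXED = [
    "sample_id",
    "project_id",
    "env_classes",
    "depth_m",
    "latitude",
    "longitude",
    "collected_at",
]


def read_sample_metadata(
    path, env_ontology: OntologyGraph | None = None
) -> list[SampleRecord]:
    """Read sample metadata TSV into :class:`SampleRecord` objects.

    Measurement columns are named ``CURIE[unit]`` (e.g.
    ``ENVO:3100011[umol/kg]``); ``env_classes`` is a pipe-separated CURIE
    list.  If ``env_ontology`` is given, every environment class and
    parameter CURIE must resolve in it; offenders are listed in the error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_FIXED if c not in df.columns]
    if missing:
        raise StoreError(f"metadata missing columns: {missing}")
    meas_cols: list[tuple[str, str, str]] = []  # (column, curie, unit)
    for col in df.columns:
        if col in _META_FIXED:
            continue
        if "[" in col and col.endswith("]"):
            curie, _, unit = col[:-1].partition("[")
            if not is_curie(curie):
                raise StoreError(f"metadata column {col!r}: malformed CURIE")
            meas_cols.append((col, curie, unit))

    if env_ontology is not None:
        bad = sorted(
            {c for _, c, _ in meas_cols if c not in env_ontology}
            | {
                c
                for cell in df["env_classes"]
                for c in cell.split("|")
                if c and c not in env_ontology
            }
        )
        if bad:
            raise StoreError(f"CURIEs not in environment ontology: {', '.join(bad)}")

    records = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        env = frozenset(c for c in row["env_classes"].split("|") if c)
        for c in env:
            if not is_curie(c):
                raise StoreError(f"sample {row['sample_id']}: malformed env class {c!r}")
        meas = {}
        for col, curie, unit in meas_cols:
            v = _opt_float(row[col])
            if v is not None:
                meas[curie] = (v, unit)
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                project_id=row["project_id"],
                env_classes=env,
                measurements=meas,
                depth_m=_opt_float(row["depth_m"]),
                latitude=_opt_float(row["latitude"]),
                longitude=_opt_float(row["longitude"]),
                collected_at=row["collected_at"] or None,
            )
        )
    return records


def write_sample_metadata(records: Sequence[SampleRecord], path) -> None:
    meas_cols = sorted(
        {(curie, unit) for r in records for curie, (_, unit) in r.measurements.items()}
    )
    cols = _META_FIXED + [f"{c}[{u}]" for c, u in meas_cols]
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "project_id": r.project_id,
            "env_classes": "|".join(sorted(r.env_classes)),
            "depth_m": "" if r.depth_m is None else repr(r.depth_m),
            "latitude": "" if r.latitude is None else repr(r.latitude),
            "longitude": "" if r.longitude is None else repr(r.longitude),
            "collected_at": r.collected_at or "",
        }
        for c, u in meas_cols:
            got = r.measurements.get(c)
            row[f"{c}[{u}]"] = "" if got is None or got[1] != u else repr(got[0])
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


_STATS_COLS = ["sample_id", "n_reads_raw", "n_reads_qc", "n_orfs", "n_unique_taxa", "n_unique_go"]


def read_sample_stats(path) -> dict[str, SampleStats]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _STATS_COLS if c not in df.columns]
    if missing:
        raise StoreError(f"stats missing columns: {missing}")
    out = {}
    for row in df.itertuples(index=False):
        s = SampleStats(
            sample_id=str(row.sample_id),
            n_reads_raw=int(row.n_reads_raw),
            n_reads_qc=int(row.n_reads_qc),
            n_orfs=int(row.n_orfs),
            n_unique_taxa=int(row.n_unique_taxa),
            n_unique_go=int(row.n_unique_go),
        )
        out[s.sample_id] = s
    return out


def write_sample_stats(stats: Mapping[str, SampleStats], path) -> None:
    rows = [
        {c: getattr(stats[s], c) for c in _STATS_COLS} for s in stats
    ]
    pd.DataFrame(rows, columns=_STATS_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC


@dataclass
class QcReport:
    removed: dict[str, list[str]]  # sample -> reasons
    retained: list[str]


def annotation_richness(table: FeatureCountTable, sample_id: str) -> int:
    """Number of distinct terms with a positive value for the sample."""
    if sample_id not in set(table.data["sample_id"]):
        raise StoreError(f"unknown sample: {sample_id}")
    sel = table.data[table.data["sample_id"] == sample_id]
    return int((sel["count"] > 0).sum())


def qc_filter_samples(
    tables: Mapping[str, FeatureCountTable],
    stats: Mapping[str, SampleStats],
    min_raw_reads: int = MIN_RAW_READS,
    min_unique_taxa: int = MIN_UNIQUE_TAXA,
) -> tuple[dict[str, FeatureCountTable], dict[str, SampleStats], QcReport]:
    """Remove low-coverage / low-richness samples from all tables and stats.

    A sample fails if its raw read count is below ``min_raw_reads`` (default
    5,000,000) or its unique taxon annotation richness is below
    ``min_unique_taxa`` (default 10,000).  Boundary values are retained.
    Order of retained samples is preserved; the report lists every removal
    with its reasons.
    """
    table_samples: list[str] = []
    for t in tables.values():
        for s in t.samples:
            if s not in table_samples:
                table_samples.append(s)
    missing = [s for s in table_samples if s not in stats]
    if missing:
        raise StoreError(f"samples missing from stats: {', '.join(missing)}")

    removed: dict[str, list[str]] = {}
    for s in stats:
        reasons = []
        if stats[s].n_reads_raw < min_raw_reads:
            reasons.append("min_raw_reads")
        if stats[s].n_unique_taxa < min_unique_taxa:
            reasons.append("min_unique_taxa")
        if reasons:
            removed[s] = reasons
    keep = [s for s in stats if s not in removed]
    new_tables = {k: t.restrict_samples(keep) for k, t in tables.items()}
    new_stats = {s: stats[s] for s in keep}
    return new_tables, new_stats, QcReport(removed=removed, retained=keep)


# ---------------------------------------------------------------------------
# intersection query


@dataclass(frozen=True)
class QueryConstraints:
    project_id: str | None = None
    env_class: str | None = None
    expand_env: bool = True
    required_measurements: frozenset[str] = frozenset()
    depth_range: tuple[float, float] | None = None  # half-open [lo, hi)
    measurement_range: Mapping[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class QueryResult:
    samples: list[str]
    terms: list[str]
    counts: np.ndarray  # len(samples) x len(terms)
    measurements: dict[str, list[float | None]]

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _sample_matches(
    rec: SampleRecord,
    c: QueryConstraints,
    env_closure: set[str] | None,
) -> bool:
    if c.project_id is not None and rec.project_id != c.project_id:
        return False
    if c.env_class is not None:
        allowed = env_closure if env_closure is not None else {c.env_class}
        if not (rec.env_classes & allowed):
            return False
    for m in c.required_measurements:
        if m not in rec.measurements:
            return False
    if c.depth_range is not None:
        lo, hi = c.depth_range
        if rec.depth_m is None or not (lo <= rec.depth_m < hi):
            return False
    for m, (lo, hi) in c.measurement_range.items():
        if m not in rec.measurements or not (lo <= rec.measurements[m][0] < hi):
            return False
    return True


def query(
    store: Store,
    ontologies: Mapping[str, OntologyGraph],
    feature_class: str,
    constraints: QueryConstraints = QueryConstraints(),
) -> QueryResult:
    """Intersect an ontology subclass closure with the store.

    ``ontologies`` maps ``"function"``/``"taxon"`` to the respective graphs
    and optionally ``"env"`` to the environment ontology used for subclass
    expansion of the ``env_class`` constraint.  The feature table is chosen
    by the prefix of ``feature_class`` (GO -> function, otherwise taxon).

    Returns the samples satisfying every constraint (and possessing every
    required measurement), the descendant terms of ``feature_class`` that
    have at least one nonzero entry among those samples, the dense count
    submatrix, and measurement vectors aligned to the sample order (missing
    values explicit ``None``).
    """
    kind = "function" if feature_class.startswith("GO:") else "taxon"
    graph = ontologies.get(kind)
    if graph is None or feature_class not in graph:
        raise UnknownTermError(f"feature class {feature_class} not in {kind} ontology")
    closure = descendants(graph, feature_class, include_self=True)

    env_closure = None
    if constraints.env_class is not None:
        env_graph = ontologies.get("env")
        if env_graph is None or constraints.env_class not in env_graph:
            raise UnknownTermError(
                f"environment class {constraints.env_class} not in environment ontology"
            )
        if constraints.expand_env:
            env_closure = descendants(env_graph, constraints.env_class, include_self=True)
        else:
            env_closure = {constraints.env_class}

    matched = [
        s
        for s, rec in store.records.items()
        if _sample_matches(rec, constraints, env_closure)
    ]
    table = store.table_for(kind)
    sub = table.data[
        table.data["sample_id"].isin(set(matched))
        & table.data["term_id"].isin(closure)
        & (table.data["count"] > 0)
    ]
    terms = sorted(set(sub["term_id"]))
    _, _, counts = table.restrict_samples(matched).to_matrix(matched, terms)
    wanted = set(constraints.required_measurements) | set(constraints.measurement_range)
    meas = {
        m: [
            store.records[s].measurements[m][0]
            if m in store.records[s].measurements
            else None
            for s in matched
        ]
        for m in sorted(wanted)
    }
    return QueryResult(samples=matched, terms=terms, counts=counts, measurements=meas)


# ---------------------------------------------------------------------------
# RDF export


def _iri(term: str) -> str:
    return OBO_NS + term.replace(":", "_") if is_curie(term) else ONTOMET_NS + term


def _esc(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _num_literal(v: float | int, integer: bool) -> str:
    if integer:
        return f'"{int(v)}"^^<{XSD}integer>'
    return f'"{_esc(repr(float(v)))}"^^<{XSD}double>'


def export_ntriples(store: Store, path) -> int:
    """Export the store as N-Triples; returns the triple count.

    Vocabulary (minimal FAIR mapping, documented in the package docs):
    samples are typed ``ontomet:Sample`` and linked with ``from_project``,
    ``has_env_class``, ``has_count`` and ``has_measurement``; each count or
    measurement node is typed by the OBO PURL of its term and carries a
    ``count`` (xsd:integer) or ``value`` (xsd:double) literal.  Triples are
    emitted sorted, so repeated exports are byte-identical.
    """
    ns = ONTOMET_NS
    lines: list[str] = []

    def add(s: str, p: str, o: str) -> None:
        lines.append(f"<{s}> <{p}> {o} .")

    def ref(iri: str) -> str:
        return f"<{iri}>"

    for sid, rec in store.records.items():
        s_iri = f"{ns}sample/{sid}"
        add(s_iri, RDF_TYPE, ref(ns + "Sample"))
        add(s_iri, ns + "from_project", ref(f"{ns}project/{rec.project_id}"))
        for env in rec.env_classes:
            add(s_iri, ns + "has_env_class", ref(_iri(env)))
        for param, (value, _unit) in rec.measurements.items():
            node = f"{ns}sample/{sid}/measurement/{param.replace(':', '_')}"
            add(s_iri, ns + "has_measurement", ref(node))
            add(node, RDF_TYPE, ref(_iri(param)))
            add(node, ns + "value", _num_literal(value, integer=False))

    for table in store.tables.values():
        for s, t, c in table.data.itertuples(index=False):
            node = f"{ns}sample/{s}/count/{t.replace(':', '_')}"
            s_iri = f"{ns}sample/{s}"
            add(s_iri, ns + "has_count", ref(node))
            add(node, RDF_TYPE, ref(_iri(t)))
            add(node, ns + "count", _num_literal(c, integer=not table.normalized))

    lines = sorted(set(lines))
    with open(path, "w", encoding="utf-8") as fh:
        for ln in lines:
            fh.write(ln + "\n")
    return len(lines)
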