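"""Normalization, aggregation, filtering and compositional transforms.

Metagenomic annotation counts are relative by construction: a sample's gene
counts scale with how many ORFs were predicted, its taxon counts with how
many reads survived quality control.  The preprocessing layer therefore
relativizes by those per-sample denominators, optionally sums relativized
counts over taxonomic clades (every read is assigned to exactly one node,
so a subtree sum does not double-count), restricts taxa to species and
strain level, removes rare features by a counts-per-million prevalence
rule, and finally applies the Aitchison centered log-ratio (CLR) transform

    clr_i(x) = ln x_i - (1/k) * sum_j ln x_j

so that downstream Euclidean statistics respect the compositional geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .ontology import OntologyGraph, UnknownTermError, descendants
from .store import FeatureCountTable, SampleStats, StoreError

__all__ = [
    "NormalizedMatrix",
    "BinAssignment",
    "PreprocessError",
    "relativize_functions",
    "relativize_taxa",
    "aggregate_clade",
    "filter_species_level",
    "prevalence_filter",
    "clr_transform",
    "variance_filter",
    "bin_values",
]


class PreprocessError(Exception):
    pass


@dataclass
class NormalizedMatrix:
    """Dense samples x terms real matrix with a transform tag.

    ``transform_tag`` is ``"relabund"`` (values in [0, 1]) or ``"clr"``
    (rows sum to zero within 1e-9).
    """

    samples: list[str]
    terms: list[str]
    values: np.ndarray
    transform_tag: str = "relabund"

    def __post_init__(self):
        if self.values.shape != (len(self.samples), len(self.terms)):
            raise PreprocessError("matrix shape does not match sample/term labels")

    def column(self, term: str) -> np.ndarray:
        return self.values[:, self.terms.index(term)]

    def restrict_terms(self, keep: Sequence[str]) -> "NormalizedMatrix":
        idx = [self.terms.index(t) for t in keep]
        return replace(self, terms=list(keep), values=self.values[:, idx])


@dataclass
class BinAssignment:
    labels_by_sample: dict[str, str | None]
    thresholds: list[float]
    labels: list[str]

    def groups(self) -> dict[str, str]:
        """Assigned samples only (nulls dropped)."""
        return {s: g for s, g in self.labels_by_sample.items() if g is not None}


def _dense(table: FeatureCountTable) -> tuple[list[str], list[str], np.ndarray]:
    return table.to_matrix()


def _relativize(
    table: FeatureCountTable,
    stats: Mapping[str, SampleStats],
    kind: str,
    denom_field: str,
    samples=None,
    terms=None,
) -> NormalizedMatrix:
    if table.kind != kind:
        raise PreprocessError(f"expected a {kind} table, got {table.kind}")
    if table.normalized:
        raise PreprocessError("table is already normalized")
    samples, terms, mat = table.to_matrix(samples, terms)
    denom = np.empty(len(samples))
    for i, s in enumerate(samples):
        if s not in stats:
            raise StoreError(f"sample {s} missing from stats")
        d = getattr(stats[s], denom_field)
        if d <= 0:
            if mat[i].sum() > 0:
                raise PreprocessError(
                    f"sample {s}: zero {denom_field} with nonzero counts"
                )
            d = 1  # all-zero row stays all-zero
        denom[i] = d
    return NormalizedMatrix(samples, terms, mat / denom[:, None], "relabund")


def relativize_functions(
    table: FeatureCountTable,
    stats: Mapping[str, SampleStats],
    samples=None,
    terms=None,
) -> NormalizedMatrix:
    """Divide each sample's gene (GO) counts by its number of ORFs.

    ``samples``/``terms`` fix the row/column order of the result (defaults
    to the table's own order).
    """
    return _relativize(table, stats, "function", "n_orfs", samples, terms)


def relativize_taxa(
    table: FeatureCountTable,
    stats: Mapping[str, SampleStats],
    samples=None,
    terms=None,
) -> NormalizedMatrix:
    """Divide each sample's taxon counts by its post-QC read count."""
    return _relativize(table, stats, "taxon", "n_reads_qc", samples, terms)


def aggregate_clade(
    norm: NormalizedMatrix, taxonomy: OntologyGraph, clade_root: str
) -> dict[str, float]:
    """Per-sample sum of relativized abundance over a clade's subtree.

    Includes the clade root itself and everything below it; counts assigned
    to ancestors of the root are excluded.  This is how genus-level depth
    profiles are built: the genus node plus all species/strains beneath it.
    """
    if norm.transform_tag != "relabund":
        raise PreprocessError("clade aggregation requires relative abundances")
    if clade_root not in taxonomy:
        raise UnknownTermError(f"unknown clade root: {clade_root}")
    clade = descendants(taxonomy, clade_root, include_self=True)
    idx = [j for j, t in enumerate(norm.terms) if t in clade]
    sums = norm.values[:, idx].sum(axis=1) if idx else np.zeros(len(norm.samples))
    return dict(zip(norm.samples, sums.tolist()))


_SPECIES_RANK = "species"


def filter_species_level(table, taxonomy: OntologyGraph):
    """Keep only species- and strain-level taxa.

    Retains terms whose rank is "species" or that are descendants of a
    species-ranked term (strains, subspecies); drops everything coarser.
    Accepts a :class:`FeatureCountTable` or :class:`NormalizedMatrix`.
    """
    species = {
        t.id
        for t in taxonomy.terms.values()
        if t.rank == _SPECIES_RANK and not t.obsolete
    }
    below: set[str] = set()
    for s in species:
        below |= descendants(taxonomy, s, include_self=True)

    if isinstance(table, NormalizedMatrix):
        keep = [t for t in table.terms if t in below]
        return table.restrict_terms(keep)
    return table.restrict_terms([t for t in table.terms if t in below])


def prevalence_filter(
    table: FeatureCountTable,
    min_cpm: float = 1.0,
    min_fraction: float = 0.05,
) -> tuple[FeatureCountTable, list[str]]:
    """Drop rare features: retain a term iff it reaches ``min_cpm``
    counts-per-million in at least ``min_fraction`` of samples.

    CPM is relative to the per-sample total of this table.  Samples with a
    zero total cannot express prevalence and are excluded from the
    denominator with a warning.  Returns (filtered table, removed terms).
    """
    if table.normalized:
        raise PreprocessError("prevalence filter operates on raw counts")
    samples, terms, mat = _dense(table)
    totals = mat.sum(axis=1)
    usable = totals > 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} zero-total samples excluded from prevalence",
            stacklevel=2,
        )
    if not usable.any():
        return table.restrict_terms([]), list(terms)
    cpm = mat[usable] / totals[usable, None] * 1e6
    frac = (cpm >= min_cpm).mean(axis=0)
    keep = [t for t, f in zip(terms, frac) if f >= min_fraction]
    removed = [t for t in terms if t not in set(keep)]
    return table.restrict_terms(keep), removed


def clr_transform(
    matrix, zero_policy: str = "pseudocount", pseudocount: float | None = None
) -> NormalizedMatrix:
    """Aitchison centered log-ratio transform, row-wise.

    ``zero_policy``:

    * ``"pseudocount"`` — add ``pseudocount`` to every entry before taking
      logs; the default (``pseudocount=None``) is half the smallest nonzero
      value of the matrix, a standard compositional choice.
    * ``"multiplicative_replacement"`` — replace zeros with 65% of the
      row's smallest nonzero value and rescale nonzero parts so the row
      total is preserved.

    Accepts a :class:`NormalizedMatrix` (relabund) or a raw
    :class:`FeatureCountTable`; CLR is scale-invariant so both give the
    same answer on zero-free data.  A row that is entirely zero has no
    compositional information and raises.
    """
    if isinstance(matrix, FeatureCountTable):
        samples, terms, vals = matrix.to_matrix()
    else:
        samples, terms, vals = matrix.samples, matrix.terms, matrix.values
    vals = np.asarray(vals, dtype=float)
    if (vals < 0).any():
        raise PreprocessError("CLR requires nonnegative values")
    zero_rows = [samples[i] for i in np.where(vals.sum(axis=1) == 0)[0]]
    if zero_rows:
        raise PreprocessError(
            f"entirely-zero samples have no composition: {', '.join(zero_rows)}"
        )

    if zero_policy == "pseudocount":
        if (vals == 0).any():
            if pseudocount is None:
                nz = vals[vals > 0]
                pseudocount = 0.5 * nz.min()
            x = vals + pseudocount
        else:
            x = vals  # zero-free compositions are transformed exactly
    elif zero_policy == "multiplicative_replacement":
        x = vals.copy()
        for i in range(x.shape[0]):
            row = x[i]
            zeros = row == 0
            if zeros.any():
                delta = 0.65 * row[~zeros].min()
                total = row.sum()
                row[zeros] = delta
                row[~zeros] *= (total - delta * zeros.sum()) / total
    else:
        raise PreprocessError(f"unknown zero policy: {zero_policy}")

    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return NormalizedMatrix(list(samples), list(terms), clr, "clr")


def variance_filter(
    matrix: NormalizedMatrix, drop_fraction: float = 0.30
) -> tuple[NormalizedMatrix, list[str]]:
    """Drop the highest-variance features.

    Ranks features by across-sample variance and removes
    ``ceil(drop_fraction * n_features)`` of the largest; variance ties are
    broken by term id so the removed set is deterministic.  Returns
    (filtered matrix, removed terms).
    """
    if not 0 <= drop_fraction < 1:
        raise PreprocessError("drop_fraction must be in [0, 1)")
    if len(matrix.samples) < 2:
        raise PreprocessError("variance filter needs at least 2 samples")
    n_drop = math.ceil(drop_fraction * len(matrix.terms))
    var = matrix.values.var(axis=0)
    order = sorted(
        range(len(matrix.terms)), key=lambda j: (-var[j], matrix.terms[j])
    )
    dropped = {matrix.terms[j] for j in order[:n_drop]}
    keep = [t for t in matrix.terms if t not in dropped]
    return matrix.restrict_terms(keep), sorted(dropped)


def bin_values(
    values: Mapping[str, float | None],
    thresholds: Sequence[float],
    labels: Sequence[str],
) -> BinAssignment:
    """Assign each sample to a half-open bin.

    Value v receives label i when thresholds[i-1] <= v < thresholds[i]
    (with virtual infinite ends), so a value exactly on a cut point falls
    in the upper bin.  Null values are left unassigned.
    """
    thresholds = list(thresholds)
    labels = list(labels)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise PreprocessError("thresholds must be strictly increasing")
    if len(labels) != len(thresholds) + 1:
        raise PreprocessError("need exactly one more label than thresholds")
    out: dict[str, str | None] = {}
    for s, v in values.items():
        if v is None:
            out[s] = None
        else:
            out[s] = labels[int(np.searchsorted(thresholds, v, side="right"))]
    return BinAssignment(labels_by_sample=out, thresholds=thresholds, labels=labels)
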