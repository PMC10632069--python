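"""Packaged analysis workflows (query -> preprocess -> analyze).

Each recipe reproduces one of the system's case-study question shapes over
a loaded store bundle:

* ``gene-vs-gradient`` — which genes of a GO family change most along a
  physicochemical gradient (elastic net, gaussian; depth by default), plus
  a PERMANOVA and dispersion test across gradient bins;
* ``species-vs-species`` — which taxa of a clade have abundance profiles
  most resembling a target taxon (elastic net, gaussian);
* ``omz-species`` — which taxa of a clade increase as dissolved oxygen
  decreases in mesopelagic samples (elastic net, gaussian; z-scaled
  negative coefficients ranked);
* ``anoxic-indicators`` — which genes of a GO family indicate anoxic
  samples (oxygen binning + IndVal permutation test on raw counts);
* ``cross-env-taxa`` / ``cross-env-genes`` — which taxa / genes separate
  high- from low-DIC (marine vs river) samples (elastic net, binomial).

A recipe is a pure function of (bundle, config): the JSON manifest written
next to each result captures every parameter and seed, so re-runs are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .ontology import OntologyGraph
from .preprocess import (
    bin_values,
    clr_transform,
    filter_species_level,
    prevalence_filter,
    relativize_functions,
    relativize_taxa,
    variance_filter,
)
from .simulate import DEPTH, DIC, MESOPELAGIC, OXYGEN
from .store import QueryConstraints, Store, query
from .stats import (
    dispersion_test,
    elastic_net_select,
    indval,
    permanova,
    zscale_coefficients,
)

__all__ = ["RecipeConfig", "RecipeError", "EmptyQueryError", "RECIPES", "run_recipe"]


class RecipeError(Exception):
    pass


class EmptyQueryError(RecipeError):
    """The query matched no samples or no terms."""


@dataclass
class RecipeConfig:
    """Parameters shared by the packaged workflows.

    Bin boundaries are configuration with documented defaults (the depth
    bins are this package's convention; oxic/anoxic and DIC cutoffs follow
    common literature values for marine suboxia and marine vs river DIC).
    """

    feature_class: str | None = None
    response_term: str | None = None       # species-vs-species target
    project_id: str | None = None
    env_class: str | None = None
    expand_env: bool = True
    depth_range: tuple[float, float] | None = None
    gradient: str = DEPTH                  # parameter CURIE for regressions
    alpha: float = 1.0
    n_folds: int = 10
    n_perm: int = 999
    variance_drop: float = 0.30
    clr_zero_policy: str = "pseudocount"
    depth_bins: tuple[float, float] = (200.0, 600.0)
    depth_bin_labels: tuple[str, str, str] = ("shallow", "intermediate", "deep")
    anoxic_threshold: float = 20.0         # umol/kg dissolved oxygen
    dic_threshold: float = 1000.0          # umol/kg, river vs marine
    seed: int = 0

    def manifest(self) -> dict[str, Any]:
        out = {k: v for k, v in self.__dict__.items()}
        out["version"] = __version__
        return out


def _require_nonempty(result, name: str) -> None:
    if result.n_samples == 0 or not result.terms:
        raise EmptyQueryError(
            f"recipe {name}: query returned "
            f"{result.n_samples} samples x {len(result.terms)} terms"
        )


def _resolve_config_curies(
    config: RecipeConfig, ontologies: Mapping[str, OntologyGraph]
) -> None:
    """Fail before any computation if a configured CURIE does not resolve."""
    checks = []
    if config.feature_class:
        kind = "function" if config.feature_class.startswith("GO:") else "taxon"
        checks.append((config.feature_class, kind))
    if config.response_term:
        checks.append((config.response_term, "taxon"))
    if config.env_class:
        checks.append((config.env_class, "env"))
    checks.append((config.gradient, "env"))
    bad = [c for c, kind in checks if c not in ontologies.get(kind, {})]
    if bad:
        raise RecipeError(f"unresolved CURIEs in config: {', '.join(bad)}")


def _query_counts(store, ontologies, config, required, name):
    constraints = QueryConstraints(
        project_id=config.project_id,
        env_class=config.env_class,
        expand_env=config.expand_env,
        required_measurements=frozenset(required),
        depth_range=config.depth_range,
    )
    result = query(store, ontologies, config.feature_class, constraints)
    _require_nonempty(result, name)
    return result

def _sub_table(table, result):
    return table.restrict_samples(result.samples).restrict_terms(result.terms)


def _relabund_for(result, store, kind):
    # row order pinned to the query's sample order so measurement vectors align
    table = _sub_table(store.table_for(kind), result)
    if kind == "function":
        return relativize_functions(table, store.stats, result.samples, result.terms)
    return relativize_taxa(table, store.stats, result.samples, result.terms)


def _gene_vs_gradient(store, ontologies, config: RecipeConfig) -> dict:
    result = _query_counts(store, ontologies, config, {config.gradient}, "gene-vs-gradient")
    norm = _relabund_for(result, store, "function")
    filtered, dropped = variance_filter(norm, config.variance_drop)
    clr = clr_transform(filtered, config.clr_zero_policy)
    y = np.asarray(result.measurements[config.gradient], dtype=float)
    enet = elastic_net_select(
        clr.values, y, features=clr.terms, family="gaussian",
        alpha=config.alpha, n_folds=config.n_folds, seed=config.seed,
    )
    bins = bin_values(
        dict(zip(result.samples, y)),
        list(config.depth_bins), list(config.depth_bin_labels),
    )
    groups = [bins.labels_by_sample[s] for s in result.samples]
    perma = disp = None
    sizes = pd.Series(groups).value_counts()
    if len(sizes) >= 2 and (sizes >= 2).all():
        all_clr = clr_transform(norm, config.clr_zero_policy)
        perma = permanova(all_clr.values, groups, config.n_perm, config.seed)
        disp = dispersion_test(all_clr.values, groups, config.n_perm, config.seed)
    return {
        "query": result, "enet": enet, "dropped_by_variance": dropped,
        "permanova": perma, "dispersion": disp, "bins": bins,
    }


def _species_vs_species(store, ontologies, config: RecipeConfig) -> dict:
    result = _query_counts(store, ontologies, config, set(), "species-vs-species")
    table = _sub_table(store.table_for("taxon"), result)
    table = filter_species_level(table, ontologies["taxon"])
    table, removed = prevalence_filter(table)
    if config.response_term is None:
        raise RecipeError("species-vs-species needs a response_term")
    norm = relativize_taxa(table, store.stats, result.samples)
    if config.response_term not in norm.terms:
        raise EmptyQueryError(f"response term {config.response_term} absent after filtering")
    # response and predictors share one CLR composition so the regression
    # compares log-ratio profiles, not raw fractions
    clr_all = clr_transform(norm, config.clr_zero_policy)
    y = clr_all.column(config.response_term)
    predictors = [t for t in clr_all.terms if t != config.response_term]
    clr = clr_all.restrict_terms(predictors)
    enet = elastic_net_select(
        clr.values, y, features=clr.terms, family="gaussian",
        alpha=config.alpha, n_folds=config.n_folds, seed=config.seed,
    )
    return {"query": result, "enet": enet, "removed_by_prevalence": removed}


def _omz_species(store, ontologies, config: RecipeConfig) -> dict:
    result = _query_counts(store, ontologies, config, {OXYGEN}, "omz-species")
    table = _sub_table(store.table_for("taxon"), result)
    table = filter_species_level(table, ontologies["taxon"])
    table, _ = prevalence_filter(table)
    norm = relativize_taxa(table, store.stats, result.samples)
    filtered, _ = variance_filter(norm, config.variance_drop)
    clr = clr_transform(filtered, config.clr_zero_policy)
    y = np.asarray(result.measurements[OXYGEN], dtype=float)
    enet = elastic_net_select(
        clr.values, y, features=clr.terms, family="gaussian",
        alpha=config.alpha, n_folds=config.n_folds, seed=config.seed,
    )
    ztable = None
    if len(enet.selected) >= 2:
        ztable = zscale_coefficients(enet)
    return {"query": result, "enet": enet, "zscores": ztable}


def _anoxic_indicators(store, ontologies, config: RecipeConfig) -> dict:
    result = _query_counts(
        store, ontologies, config, {OXYGEN, DEPTH}, "anoxic-indicators"
    )
    oxy = dict(zip(result.samples, result.measurements[OXYGEN]))
    bins = bin_values(oxy, [config.anoxic_threshold], ["anoxic", "oxic"])
    groups = [bins.labels_by_sample[s] for s in result.samples]
    # indicator analysis runs on the raw (unnormalized) counts
    res = indval(
        result.counts, groups, features=result.terms,
        n_perm=config.n_perm, seed=config.seed,
    )
    return {"query": result, "indval": res, "bins": bins}


def _cross_env(kind: str):
    def run(store, ontologies, config: RecipeConfig) -> dict:
        name = f"cross-env-{'taxa' if kind == 'taxon' else 'genes'}"
        result = _query_counts(store, ontologies, config, {DIC}, name)
        dic_pre = dict(zip(result.samples, result.measurements[DIC]))
        pre_bins = bin_values(dic_pre, [config.dic_threshold], ["river", "marine"])
        sizes = pd.Series(list(pre_bins.groups().values())).value_counts()
        if len(sizes) < 2 or (sizes < 2).any():
            raise EmptyQueryError(
                f"{name}: need at least 2 samples in each DIC group, got "
                f"{sizes.to_dict()}"
            )
        table = _sub_table(store.table_for(kind), result)
        if kind == "taxon":
            table = filter_species_level(table, ontologies["taxon"])
            table, _ = prevalence_filter(table)
        norm = (
            relativize_taxa(table, store.stats, result.samples)
            if kind == "taxon"
            else relativize_functions(table, store.stats, result.samples)
        )
        filtered, _ = variance_filter(norm, config.variance_drop)
        clr = clr_transform(filtered, config.clr_zero_policy)
        dic = dict(zip(result.samples, result.measurements[DIC]))
        bins = bin_values(dic, [config.dic_threshold], ["river", "marine"])
        y = np.asarray(
            [1.0 if bins.labels_by_sample[s] == "marine" else 0.0 for s in result.samples]
        )
        if len(np.unique(y)) < 2:
            raise EmptyQueryError(f"{name}: only one DIC group present")
        enet = elastic_net_select(
            clr.values, y, features=clr.terms, family="binomial",
            alpha=config.alpha, n_folds=min(config.n_folds, int(min(np.bincount(y.astype(int))))),
            seed=config.seed,
        )
        return {"query": result, "enet": enet, "bins": bins}

    return run


RECIPES = {
    "gene-vs-gradient": _gene_vs_gradient,
    "species-vs-species": _species_vs_species,
    "omz-species": _omz_species,
    "anoxic-indicators": _anoxic_indicators,
    "cross-env-taxa": _cross_env("taxon"),
    "cross-env-genes": _cross_env("function"),
}

_DEFAULTS: dict[str, dict] = {
    "gene-vs-gradient": {"feature_class": "GO:0043169"},
    "species-vs-species": {
        "feature_class": "NCBITaxon:1117",
        "response_term": "NCBITaxon:1501269",
    },
    "omz-species": {
        "feature_class": "NCBITaxon:1117",
        "env_class": MESOPELAGIC,
        "depth_range": (300.0, 600.0),
    },
    "anoxic-indicators": {
        "feature_class": "GO:0044237",
        "env_class": MESOPELAGIC,
        "depth_range": (300.0, 600.0),
    },
    "cross-env-taxa": {"feature_class": "NCBITaxon:2", "depth_range": (0.0, 30.0)},
    "cross-env-genes": {"feature_class": "GO:0008150", "depth_range": (0.0, 30.0)},
}


def default_config(name: str, **overrides) -> RecipeConfig:
    if name not in RECIPES:
        raise RecipeError(f"unknown recipe: {name}")
    params = dict(_DEFAULTS.get(name, {}))
    params.update(overrides)
    return RecipeConfig(**params)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _write_outputs(name: str, out: dict, config: RecipeConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"recipe": name, "config": config.manifest()}
    if out.get("enet") is not None:
        e = out["enet"]
        df = pd.DataFrame(
            {
                "feature": e.coefficients.index,
                "coefficient": [_fmt(v) for v in e.coefficients],
                "selected": [f in set(e.selected) for f in e.coefficients.index],
            }
        )
        df.to_csv(outdir / "coefficients.tsv", sep="\t", index=False)
        summary["enet"] = {
            "selected": e.selected,
            "lambda_min": e.lambda_min,
            "lambda_1se": e.lambda_1se,
            "n_features": len(e.coefficients),
            "intercept": e.intercept,
        }
    if out.get("indval") is not None:
        t = out["indval"].table.copy()
        for c in ("A", "B", "stat", "p"):
            t[c] = t[c].map(_fmt)
        t.to_csv(outdir / "indicators.tsv", sep="\t", index=False)
        summary["indval"] = {"n_features": len(t), "absent": out["indval"].absent}
    if out.get("zscores") is not None:
        z = out["zscores"].copy().reset_index(names="feature")
        z.to_csv(outdir / "zscores.tsv", sep="\t", index=False, float_format="%.12g")
    if out.get("permanova") is not None:
        pm, dp = out["permanova"], out["dispersion"]
        summary["permanova"] = {"pseudo_F": pm.pseudo_F, "R2": pm.R2, "p": pm.p}
        summary["dispersion"] = {"F": dp.F, "p": dp.p}
    q = out["query"]
    summary["query"] = {"n_samples": q.n_samples, "n_terms": len(q.terms)}
    (outdir / "manifest.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def run_recipe(
    name: str,
    store: Store,
    ontologies: Mapping[str, OntologyGraph],
    config: RecipeConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute a named workflow; optionally write result TSVs + manifest.

    Returns the in-memory result dict (query, analysis results, bins).
    Raises :class:`EmptyQueryError` when the query matches nothing, and
    :class:`RecipeError` before any computation when a configured CURIE
    does not resolve against the loaded ontologies.
    """
    if name not in RECIPES:
        raise RecipeError(f"unknown recipe: {name}")
    if config is None:
        config = default_config(name)
    _resolve_config_curies(config, ontologies)
    out = RECIPES[name](store, ontologies, config)
    if outdir is not None:
        out["summary"] = _write_outputs(name, out, config, Path(outdir))
    return out
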