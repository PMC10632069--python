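"""Normalization, clade aggregation, filters, CLR, binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ontomet.preprocess import (
    NormalizedMatrix,
    PreprocessError,
    aggregate_clade,
    bin_values,
    clr_transform,
    filter_species_level,
    prevalence_filter,
    relativize_functions,
    relativize_taxa,
    variance_filter,
)
from ontomet.store import FeatureCountTable, SampleStats

from conftest import build_graph


def _table(kind, entries):
    df = pd.DataFrame(entries, columns=["sample_id", "term_id", "count"])
    return FeatureCountTable(kind=kind, data=df)


def _stats(**per_sample):
    return {
        s: SampleStats(s, int(2e7), int(v["reads"]), int(v["orfs"]), 10, 10)
        for s, v in per_sample.items()
    }


class TestRelativize:
    def test_function_quotient(self):
        t = _table("function", [("S1", "GO:1", 5)])
        stats = _stats(S1={"reads": 1e7, "orfs": 100})
        m = relativize_functions(t, stats)
        assert m.values[0, 0] == pytest.approx(0.05)
        assert m.transform_tag == "relabund"

    def test_taxon_quotient(self):
        t = _table("taxon", [("S1", "NCBITaxon:5", 1000)])
        stats = _stats(S1={"reads": 1e7, "orfs": 100})
        m = relativize_taxa(t, stats)
        assert m.values[0, 0] == pytest.approx(1e-4)

    def test_missing_stats_errors(self):
        t = _table("taxon", [("S1", "NCBITaxon:5", 1)])
        with pytest.raises(Exception, match="S1"):
            relativize_taxa(t, {})

    def test_zero_denominator_with_counts_errors(self):
        t = _table("function", [("S1", "GO:1", 5)])
        stats = {"S1": SampleStats("S1", 10, 10, 0, 1, 1)}
        with pytest.raises(PreprocessError, match="S1"):
            relativize_functions(t, stats)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_fixture_matches_elementwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(6)]
        terms = [f"GO:{j}" for j in range(9)]
        counts = rng.integers(0, 50, size=(6, 9))
        entries = [
            (s, t, int(counts[i, j]))
            for i, s in enumerate(samples)
            for j, t in enumerate(terms)
            if counts[i, j]
        ]
        orfs = rng.integers(100, 1000, size=6)
        stats = _stats(**{s: {"reads": 1e6, "orfs": orfs[i]} for i, s in enumerate(samples)})
        m = relativize_functions(_table("function", entries), stats, samples, terms)
        assert np.allclose(m.values, counts / orfs[:, None])


TAXONOMY = build_graph(
    {
        "NCBITaxon:2": set(),
        "NCBITaxon:1117": {"NCBITaxon:2"},
        "NCBITaxon:1218": {"NCBITaxon:1117"},
        "NCBITaxon:1219": {"NCBITaxon:1218"},
        "NCBITaxon:167555": {"NCBITaxon:1219"},
        "NCBITaxon:59920": {"NCBITaxon:1219"},
        "NCBITaxon:1129": {"NCBITaxon:1117"},
        "NCBITaxon:32046": {"NCBITaxon:1129"},
    },
    ranks={
        "NCBITaxon:2": "domain",
        "NCBITaxon:1117": "phylum",
        "NCBITaxon:1218": "genus",
        "NCBITaxon:1219": "species",
        "NCBITaxon:167555": "strain",
        "NCBITaxon:59920": "strain",
        "NCBITaxon:1129": "genus",
        "NCBITaxon:32046": "species",
    },
)


class TestAggregateClade:
    def _matrix(self):
        terms = ["NCBITaxon:1218", "NCBITaxon:167555", "NCBITaxon:59920", "NCBITaxon:32046"]
        vals = np.array([[0.01, 0.02, 0.03, 0.4], [0.0, 0.1, 0.0, 0.2]])
        return NormalizedMatrix(["S1", "S2"], terms, vals, "relabund")

    def test_genus_sums_node_and_strains(self):
        v = aggregate_clade(self._matrix(), TAXONOMY, "NCBITaxon:1218")
        assert v["S1"] == pytest.approx(0.06)
        assert v["S2"] == pytest.approx(0.1)

    def test_leaf_clade_equals_leaf_value(self):
        v = aggregate_clade(self._matrix(), TAXONOMY, "NCBITaxon:167555")
        assert v["S1"] == pytest.approx(0.02)

    def test_additive_over_disjoint_clades(self):
        m = self._matrix()
        pro = aggregate_clade(m, TAXONOMY, "NCBITaxon:1218")
        syn = aggregate_clade(m, TAXONOMY, "NCBITaxon:1129")
        both = aggregate_clade(m, TAXONOMY, "NCBITaxon:1117")
        for s in m.samples:
            assert pro[s] + syn[s] == pytest.approx(both[s])

    def test_matches_subtree_sum_oracle(self):
        from ontomet.ontology import descendants

        rng = np.random.default_rng(9)
        m = self._matrix()
        root = "NCBITaxon:1117"
        expected = {
            s: sum(
                m.values[i, j]
                for j, t in enumerate(m.terms)
                if t in descendants(TAXONOMY, root, include_self=True)
            )
            for i, s in enumerate(m.samples)
        }
        assert aggregate_clade(m, TAXONOMY, root) == pytest.approx(expected)


class TestSpeciesFilter:
    def test_keeps_species_and_strains_only(self):
        t = _table(
            "taxon",
            [("S1", "NCBITaxon:1218", 5), ("S1", "NCBITaxon:1219", 3),
             ("S1", "NCBITaxon:167555", 2), ("S1", "NCBITaxon:1117", 9)],
        )
        out = filter_species_level(t, TAXONOMY)
        assert set(out.terms) == {"NCBITaxon:1219", "NCBITaxon:167555"}

    def test_only_coarse_ranks_gives_empty(self):
        t = _table("taxon", [("S1", "NCBITaxon:1117", 5)])
        assert filter_species_level(t, TAXONOMY).terms == []


class TestPrevalenceFilter:
    def _make(self, cpm_rows):
        # 20 samples with total exactly 1e6 each -> count == CPM
        probe_total = {s: 0 for s in range(20)}
        entries = []
        for term, pairs in cpm_rows.items():
            for s, cpm in pairs:
                entries.append((f"S{s}", term, cpm))
                probe_total[s] += cpm
        for s in range(20):
            entries.append((f"S{s}", "GO:pad", 1_000_000 - probe_total[s]))
        return _table("function", entries)

    def test_two_cpm_in_ten_percent_retained(self):
        t = self._make({"GO:a": [(0, 2), (1, 2)]})
        out, removed = prevalence_filter(t)
        assert "GO:a" in out.terms and "GO:a" not in removed

    def test_sub_cpm_everywhere_removed(self):
        t = self._make({"GO:b": [(s, 0) for s in range(20)]})
        # zero counts are below 1 CPM in every sample
        out, removed = prevalence_filter(t)
        assert "GO:b" in removed

    def test_exact_boundary_one_cpm_one_sample_of_twenty(self):
        # 1 sample of 20 = 5% exactly -> retained (>= on both clauses)
        t = self._make({"GO:c": [(0, 1)]})
        out, _ = prevalence_filter(t)
        assert "GO:c" in out.terms

    def test_absent_term_removed(self):
        out, removed = prevalence_filter(self._make({}))
        assert removed == []
        assert out.terms == ["GO:pad"]


class TestClr:
    def test_uniform_row_is_zero(self):
        m = NormalizedMatrix(["S1"], list("abcd"), np.full((1, 4), 0.25), "relabund")
        out = clr_transform(m)
        assert np.allclose(out.values, 0.0)

    def test_closed_form_two_parts(self):
        m = NormalizedMatrix(["S1"], ["a", "b"], np.array([[1.0, 3.0]]), "relabund")
        out = clr_transform(m)
        expected = 0.5 * np.log(3.0)
        assert out.values[0] == pytest.approx([-expected, expected])

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.random((10, 7))
        vals[2, 3] = 0.0  # exercise the pseudocount path
        m = NormalizedMatrix([f"S{i}" for i in range(10)], list("abcdefg"), vals, "relabund")
        out = clr_transform(m)
        assert np.abs(out.values.sum(axis=1)).max() < 1e-9
        assert out.transform_tag == "clr"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8),
        st.floats(0.1, 50.0),
    )
    def test_scale_invariance(self, row, lam):
        vals = np.array([row])
        a = clr_transform(NormalizedMatrix(["S"], [f"t{i}" for i in range(len(row))], vals, "relabund"), pseudocount=0.0)
        b = clr_transform(NormalizedMatrix(["S"], [f"t{i}" for i in range(len(row))], lam * vals, "relabund"), pseudocount=0.0)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_all_zero_row_errors(self):
        m = NormalizedMatrix(["S1", "S2"], ["a", "b"], np.array([[1.0, 2.0], [0.0, 0.0]]), "relabund")
        with pytest.raises(PreprocessError, match="S2"):
            clr_transform(m)

    def test_multiplicative_replacement_preserves_row_total(self):
        m = NormalizedMatrix(["S1"], list("abc"), np.array([[0.0, 0.3, 0.7]]), "relabund")
        out = clr_transform(m, zero_policy="multiplicative_replacement")
        assert np.abs(out.values.sum()) < 1e-9

    def test_matches_skbio_on_zero_free_rows(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(5)
        vals = rng.random((4, 6)) + 0.05
        m = NormalizedMatrix([f"S{i}" for i in range(4)], list("abcdef"), vals, "relabund")
        ours = clr_transform(m, pseudocount=0.0)
        theirs = skbio_comp.clr(vals)
        assert np.allclose(ours.values, theirs, atol=1e-10)


class TestVarianceFilter:
    def _matrix(self, vals):
        vals = np.asarray(vals, dtype=float)
        terms = [f"GO:{j}" for j in range(vals.shape[1])]
        return NormalizedMatrix([f"S{i}" for i in range(vals.shape[0])], terms, vals, "relabund")

    def test_drop_count_is_ceil(self):
        rng = np.random.default_rng(1)
        m = self._matrix(rng.random((5, 10)))
        out, removed = variance_filter(m, 0.30)
        assert len(removed) == 3 and len(out.terms) == 7

    def test_constant_feature_survives(self):
        vals = np.c_[np.ones(5), np.random.default_rng(2).random((5, 3))]
        out, removed = variance_filter(self._matrix(vals), 0.5)
        assert "GO:0" in out.terms

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.random((8, 12))
        m = self._matrix(vals)
        _, removed = variance_filter(m, 0.25)
        var = vals.var(axis=0)
        order = sorted(range(12), key=lambda j: (-var[j], m.terms[j]))
        assert set(removed) == {m.terms[j] for j in order[:3]}

    def test_bad_fraction(self):
        with pytest.raises(PreprocessError):
            variance_filter(self._matrix(np.ones((3, 3))), 1.0)


class TestBinValues:
    def test_boundary_goes_to_upper_bin(self):
        out = bin_values({"S1": 20.0}, [20.0], ["anoxic", "oxic"])
        assert out.labels_by_sample["S1"] == "oxic"

    def test_three_depth_bins(self):
        out = bin_values(
            {"a": 50.0, "b": 500.0, "c": 1500.0},
            [200.0, 1000.0],
            ["shallow", "intermediate", "deep"],
        )
        assert [out.labels_by_sample[s] for s in "abc"] == ["shallow", "intermediate", "deep"]

    def test_nulls_unassigned(self):
        out = bin_values({"a": None}, [1.0], ["lo", "hi"])
        assert out.labels_by_sample["a"] is None
        assert out.groups() == {}

    def test_empty_input(self):
        assert bin_values({}, [1.0], ["lo", "hi"]).labels_by_sample == {}

    def test_non_monotone_thresholds(self):
        with pytest.raises(PreprocessError):
            bin_values({"a": 1.0}, [2.0, 1.0], ["x", "y", "z"])


def test_species_filter_commutes_with_prevalence_and_clr():
    """The taxonomic pipeline's filters commute when applied either order."""
    rng = np.random.default_rng(7)
    terms = ["NCBITaxon:1218", "NCBITaxon:1219", "NCBITaxon:167555",
             "NCBITaxon:59920", "NCBITaxon:32046", "NCBITaxon:1117"]
    entries = [
        (f"S{i}", t, int(rng.integers(1, 2000)))
        for i in range(20)
        for t in terms
    ]
    t = _table("taxon", entries)

    a, _ = prevalence_filter(filter_species_level(t, TAXONOMY))
    b = filter_species_level(prevalence_filter(t)[0], TAXONOMY)
    # identical surviving term sets and entries
    pd.testing.assert_frame_equal(
        a.data.sort_values(["sample_id", "term_id"]).reset_index(drop=True),
        b.data[a.data.columns].sort_values(["sample_id", "term_id"]).reset_index(drop=True),
    )
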