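"""Sample store: readers, QC, intersection queries, RDF export."""

import io

import numpy as np
import pytest

from ontomet.ontology import UnknownTermError
from ontomet.simulate import (
    DEPTH,
    OXYGEN,
    MESOPELAGIC,
    MARINE_WATER_BODY,
    SimulationDesign,
    make_env_ontology,
    simulate_dataset,
)
from ontomet.store import (
    FeatureCountTable,
    QueryConstraints,
    SampleRecord,
    SampleStats,
    Store,
    StoreError,
    annotation_richness,
    export_ntriples,
    qc_filter_samples,
    query,
    read_count_table,
    read_sample_metadata,
)

from conftest import build_graph


def _tsv(text: str) -> io.StringIO:
    return io.StringIO(text.replace("|", "\t"))


class TestReadCountTable:
    def test_small_table(self):
        t = read_count_table(
            _tsv("sample_id|term_id|count\nS1|GO:1|3\nS1|GO:2|0\nS2|GO:1|7\n"),
            "function",
        )
        assert len(t.data) == 3
        assert t.value("S2", "GO:1") == 7
        assert annotation_richness(t, "S1") == 1

    def test_duplicate_rows_summed_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            t = read_count_table(
                _tsv("sample_id|term_id|count\nS1|GO:1|3\nS1|GO:1|4\n"), "taxon"
            )
        assert t.value("S1", "GO:1") == 7
        assert len(t.data) == 1

    def test_header_only_is_empty(self):
        t = read_count_table(_tsv("sample_id|term_id|count\n"), "function")
        assert len(t.data) == 0 and t.terms == []

    def test_non_integer_count_names_line(self):
        with pytest.raises(StoreError, match="line 3"):
            read_count_table(
                _tsv("sample_id|term_id|count\nS1|GO:1|3\nS1|GO:2|3.5\n"), "function"
            )

    def test_malformed_curie_rejected(self):
        with pytest.raises(StoreError, match="CURIE"):
            read_count_table(_tsv("sample_id|term_id|count\nS1|nocolon|3\n"), "function")


class TestReadSampleMetadata:
    HEADER = "sample_id|project_id|env_classes|depth_m|latitude|longitude|collected_at|ENVO:3100011[umol/kg]"

    def test_full_row(self):
        recs = read_sample_metadata(
            _tsv(self.HEADER + "\nS1|HOT|ENVO:00000213|450|22.75|-158|2020-01-01T00:00:00Z|2.5\n"),
            env_ontology=make_env_ontology(),
        )
        (r,) = recs
        assert r.env_classes == {"ENVO:00000213"}
        assert r.measurements[OXYGEN] == (2.5, "umol/kg")
        assert r.depth_m == 450

    def test_empty_optionals_are_null(self):
        (r,) = read_sample_metadata(_tsv(self.HEADER + "\nS1|HOT|||||\t\n"))
        assert r.depth_m is None and r.latitude is None and r.collected_at is None
        assert r.measurements == {}

    def test_latitude_out_of_range(self):
        with pytest.raises(StoreError, match="latitude"):
            read_sample_metadata(_tsv(self.HEADER + "\nS1|HOT||10|95|0||1\n"))

    def test_unresolvable_curie_listed(self):
        with pytest.raises(StoreError, match="ENVO:77"):
            read_sample_metadata(
                _tsv(self.HEADER + "\nS1|HOT|ENVO:77|||||\n"),
                env_ontology=make_env_ontology(),
            )


def _stats(sid, raw=6_000_000, qc=None, orfs=500_000, taxa=12_000):
    qc = min(raw, 5_000_000) if qc is None else qc
    return SampleStats(sid, raw, qc, orfs, taxa, 100)


def _table(kind, entries):
    import pandas as pd

    df = pd.DataFrame(entries, columns=["sample_id", "term_id", "count"])
    return FeatureCountTable(kind=kind, data=df)


class TestQcFilter:
    def test_below_read_threshold_removed_at_boundary(self):
        stats = {
            "A": _stats("A", raw=4_999_999),
            "B": _stats("B", raw=5_000_000, taxa=10_000),
        }
        tables = {"taxon": _table("taxon", [("A", "NCBITaxon:5", 1), ("B", "NCBITaxon:5", 1)])}
        _, new_stats, report = qc_filter_samples(tables, stats)
        assert report.removed == {"A": ["min_raw_reads"]}
        assert list(new_stats) == ["B"]

    def test_richness_threshold_boundary_inclusive(self):
        stats = {"A": _stats("A", taxa=9_999), "B": _stats("B", taxa=10_000)}
        _, new_stats, report = qc_filter_samples({}, stats)
        assert report.removed == {"A": ["min_unique_taxa"]}
        assert "B" in new_stats

    def test_missing_stats_is_error(self):
        tables = {"taxon": _table("taxon", [("Z", "NCBITaxon:5", 1)])}
        with pytest.raises(StoreError, match="Z"):
            qc_filter_samples(tables, {})

    def test_planted_failures_exactly_removed(self):
        """Generator-planted QC violations are removed, nothing else."""
        design = SimulationDesign(
            seed=4, n_samples=20, scale=1e-3,
            planted_qc_failures={2: "reads", 5: "taxa", 7: "reads",
                                 11: "taxa", 13: "reads", 17: "taxa"},
        )
        _, stats, _, taxa, ledger = simulate_dataset(design)
        tables = {"taxon": taxa}
        _, _, report = qc_filter_samples(
            tables, stats,
            min_raw_reads=int(ledger["qc_min_raw_reads"]),
            min_unique_taxa=int(ledger["qc_min_unique_taxa"]),
        )
        assert set(report.removed) == set(ledger["planted_qc_failures"])
        assert len(report.retained) == 14


def _mini_store():
    env = make_env_ontology()
    fn = build_graph({"GO:1": set(), "GO:2": {"GO:1"}, "GO:3": {"GO:1"}, "GO:4": set()})
    records = {
        "S1": SampleRecord("S1", "HOT", frozenset({MESOPELAGIC}),
                           {DEPTH: (450.0, "m"), OXYGEN: (5.0, "umol/kg")}, 450.0),
        "S2": SampleRecord("S2", "HOT", frozenset({"ENVO:01001581"}),
                           {DEPTH: (25.0, "m")}, 25.0),
        "S3": SampleRecord("S3", "Tara", frozenset({MESOPELAGIC}),
                           {DEPTH: (500.0, "m"), OXYGEN: (3.0, "umol/kg")}, 500.0),
    }
    table = _table("function", [
        ("S1", "GO:2", 5), ("S1", "GO:4", 1),
        ("S2", "GO:2", 2), ("S2", "GO:3", 4),
        ("S3", "GO:3", 9),
    ])
    store = Store(records=records, tables={"function": table})
    return store, {"function": fn, "env": env}


class TestQuery:
    def test_closure_intersection_and_alignment(self):
        store, onts = _mini_store()
        res = query(store, onts, "GO:1",
                    QueryConstraints(required_measurements=frozenset({OXYGEN})))
        assert res.samples == ["S1", "S3"]
        assert res.terms == ["GO:2", "GO:3"]  # GO:4 outside closure, GO:1 absent
        assert res.counts.tolist() == [[5.0, 0.0], [0.0, 9.0]]
        assert res.measurements[OXYGEN] == [5.0, 3.0]

    def test_env_subclass_expansion_toggle(self):
        store, onts = _mini_store()
        expanded = query(store, onts, "GO:1",
                         QueryConstraints(env_class=MARINE_WATER_BODY))
        assert expanded.samples == ["S1", "S2", "S3"]
        exact = query(store, onts, "GO:1",
                      QueryConstraints(env_class=MARINE_WATER_BODY, expand_env=False))
        assert exact.samples == []

    def test_depth_range_half_open(self):
        store, onts = _mini_store()
        res = query(store, onts, "GO:1", QueryConstraints(depth_range=(450.0, 500.0)))
        assert res.samples == ["S1"]  # 500 excluded, 450 included

    def test_empty_store(self):
        _, onts = _mini_store()
        res = query(Store(tables={"function": _table("function", [])}), onts, "GO:1")
        assert res.samples == [] and res.terms == []

    def test_unknown_feature_class(self):
        store, onts = _mini_store()
        with pytest.raises(UnknownTermError):
            query(store, onts, "GO:999")

    def test_monotone_in_constraints(self, cohort):
        store, onts, _, _ = cohort
        base = query(store, onts, "GO:0043169", QueryConstraints())
        tighter = query(
            store, onts, "GO:0043169",
            QueryConstraints(depth_range=(0.0, 300.0),
                             required_measurements=frozenset({OXYGEN})),
        )
        assert set(tighter.samples) <= set(base.samples)

    def test_root_query_returns_all_terms_present(self, cohort):
        store, onts, _, _ = cohort
        res = query(store, onts, "GO:0003673", QueryConstraints())
        assert set(res.terms) == set(store.table_for("function").terms)

    def test_matches_brute_force_oracle(self, cohort):
        """Independent double loop over samples x predicates."""
        from ontomet.ontology import descendants

        store, onts, _, _ = cohort
        constraints = QueryConstraints(
            project_id="HOT_224_283",
            env_class=MESOPELAGIC,
            required_measurements=frozenset({OXYGEN}),
            depth_range=(300.0, 800.0),
        )
        res = query(store, onts, "GO:0044237", constraints)

        env_closure = descendants(onts["env"], MESOPELAGIC, include_self=True)
        expected_samples = []
        for sid, rec in store.records.items():
            if rec.project_id != "HOT_224_283":
                continue
            if not rec.env_classes & env_closure:
                continue
            if OXYGEN not in rec.measurements:
                continue
            if rec.depth_m is None or not (300.0 <= rec.depth_m < 800.0):
                continue
            expected_samples.append(sid)
        assert res.samples == expected_samples

        closure = descendants(onts["function"], "GO:0044237", include_self=True)
        table = store.table_for("function")
        expected_terms = sorted(
            {
                t
                for (s, t, c) in table.data.itertuples(index=False)
                if s in set(expected_samples) and t in closure and c > 0
            }
        )
        assert res.terms == expected_terms
        for i, s in enumerate(res.samples):
            for j, t in enumerate(res.terms):
                assert res.counts[i, j] == table.value(s, t)


class TestRichness:
    def test_counts_positive_entries_only(self):
        t = _table("function", [("S1", "GO:1", 3), ("S1", "GO:2", 0), ("S1", "GO:3", 1)])
        assert annotation_richness(t, "S1") == 2

    def test_unknown_sample(self):
        t = _table("function", [("S1", "GO:1", 3)])
        with pytest.raises(StoreError):
            annotation_richness(t, "S9")

    def test_matches_stats_ledger(self, cohort):
        store, _, _, _ = cohort
        taxa = store.table_for("taxon")
        for sid in list(store.stats)[:5]:
            assert annotation_richness(taxa, sid) == store.stats[sid].n_unique_taxa


class TestExportNtriples:
    def _one_sample_store(self):
        records = {
            "S1": SampleRecord("S1", "HOT", frozenset({MESOPELAGIC}),
                               {DEPTH: (450.0, "m")}, 450.0)
        }
        table = _table("function", [("S1", "GO:0015979", 5), ("S1", "GO:0015948", 2)])
        return Store(records=records, tables={"function": table})

    def test_triple_count_closed_form(self, tmp_path):
        # 3 per count entry + 3 per measurement + (type + project + env) per sample
        store = self._one_sample_store()
        n = export_ntriples(store, tmp_path / "out.nt")
        assert n == 3 * 2 + 3 * 1 + (1 + 1 + 1)

    def test_reparse_recovers_counts_and_measurements(self, tmp_path):
        import rdflib

        store = self._one_sample_store()
        path = tmp_path / "out.nt"
        export_ntriples(store, path)
        g = rdflib.Graph()
        g.parse(path, format="nt")
        ns = "https://w3id.org/ontomet/"
        counts = {}
        for s, p, o in g.triples((None, rdflib.URIRef(ns + "count"), None)):
            (term_type,) = [
                str(t) for t in g.objects(s, rdflib.RDF.type)
            ]
            counts[term_type.rsplit("/", 1)[-1]] = int(o)
        assert counts == {"GO_0015979": 5, "GO_0015948": 2}
        values = [float(o) for _, _, o in g.triples((None, rdflib.URIRef(ns + "value"), None))]
        assert values == [450.0]

    def test_export_deterministic(self, tmp_path):
        store = self._one_sample_store()
        export_ntriples(store, tmp_path / "a.nt")
        export_ntriples(store, tmp_path / "b.nt")
        assert (tmp_path / "a.nt").read_bytes() == (tmp_path / "b.nt").read_bytes()

    def test_empty_store_zero_triples(self, tmp_path):
        assert export_ntriples(Store(), tmp_path / "e.nt") == 0
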