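"""Retrieval functions: URL building, pagination, partitioning, per-row queries."""

import datetime

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skiff import (
    ExtractionSpec,
    MockFhirServer,
    NotFoundError,
    SearchQuery,
    SkiffError,
    build_search_url,
    partition_time_span,
    request_history,
    sail_through_search_space,
    steal_bundles,
    steal_bundles_to_dataframe,
    trade_rows_for_bundles,
    trade_rows_for_dataframe,
)
from skiff.errors import ExtractionError
from skiff.synthetic import ResourceStore, scattered_observation_store

from conftest import make_session, tiny_patient_store

D = datetime.date


class TestBuildSearchUrl:
    def test_token_code_without_system(self, session):
        url = build_search_url(session, SearchQuery("Condition", {"code": "C50"}))
        assert url.endswith("/Condition?code=C50&_count=100")

    def test_empty_params_only_count(self, session):
        url = build_search_url(session, SearchQuery("Patient"))
        assert url.endswith("/Patient?_count=100")

    def test_repeated_date_keys_in_order(self, session):
        query = SearchQuery(
            "Observation", {"date": ["ge2020-01-01", "lt2020-02-01"]}
        )
        url = build_search_url(session, query)
        assert "date=ge2020-01-01&date=lt2020-02-01" in url

    def test_history_form(self, session):
        url = build_search_url(
            session, SearchQuery("Patient", include_history=True)
        )
        assert "/Patient/_history?" in url

    def test_invalid_query_rejected(self):
        with pytest.raises(SkiffError):
            SearchQuery("")
        with pytest.raises(SkiffError):
            SearchQuery("Patient", {"": "x"})


class TestStealBundles:
    def test_pagination_ceil_rule(self):
        server = MockFhirServer(tiny_patient_store(5))
        session = make_session(server)
        result = steal_bundles(session, SearchQuery("Patient", page_size=2))
        assert len(result.bundles) == 3
        assert result.total_entries == 5

    def test_no_matches_single_empty_bundle(self):
        server = MockFhirServer(tiny_patient_store(5))
        session = make_session(server)
        result = steal_bundles(
            session, SearchQuery("Patient", {"gender": "other"})
        )
        assert len(result.bundles) == 1
        assert result.total_entries == 0

    def test_max_bundles_truncates(self):
        server = MockFhirServer(tiny_patient_store(5))
        session = make_session(server)
        result = steal_bundles(
            session, SearchQuery("Patient", page_size=2), max_bundles=1
        )
        assert result.total_entries == 2

    @pytest.mark.parametrize("page_size", [1, 2, 3, 7, 100])
    def test_pagination_invariance(self, store, server, session, page_size):
        result = steal_bundles(
            session, SearchQuery("Patient", page_size=page_size)
        )
        assert result.total_entries == len(store.all("Patient"))


class TestPartitionTimeSpan:
    def test_equal_division(self):
        part = partition_time_span(D(2020, 1, 1), D(2020, 1, 11), 5)
        assert len(part.spans) == 5
        assert all((b - a).days == 2 for a, b in part.spans)

    def test_remainder_to_earliest_spans(self):
        part = partition_time_span(D(2020, 1, 1), D(2020, 1, 11), 3)
        assert [(b - a).days for a, b in part.spans] == [4, 3, 3]

    def test_capped_at_day_count(self):
        part = partition_time_span(D(2020, 1, 1), D(2020, 1, 3), 10)
        assert [(b - a).days for a, b in part.spans] == [1, 1]

    def test_degenerate_range_rejected(self):
        with pytest.raises(SkiffError):
            partition_time_span(D(2020, 1, 2), D(2020, 1, 2), 3)

    @given(
        start_offset=st.integers(0, 3000),
        length=st.integers(1, 800),
        n=st.integers(1, 12),
    )
    @settings(max_examples=200, deadline=None)
    def test_partition_properties(self, start_offset, length, n):
        """Spans are disjoint, ordered, cover [start, end), lengths differ <= 1."""
        start = D(2015, 1, 1) + datetime.timedelta(days=start_offset)
        end = start + datetime.timedelta(days=length)
        part = partition_time_span(start, end, n)
        assert len(part.spans) == min(n, length)
        assert part.spans[0][0] == start and part.spans[-1][1] == end
        for (a1, b1), (a2, b2) in zip(part.spans, part.spans[1:]):
            assert b1 == a2 and a1 < b1
        lengths = [(b - a).days for a, b in part.spans]
        assert max(lengths) - min(lengths) <= 1
        assert lengths == sorted(lengths, reverse=True)


def _scattered_session(dates):
    server = MockFhirServer(scattered_observation_store(dates))
    return server, make_session(server)


class TestSailThroughSearchSpace:
    def test_equivalent_to_single_query(self):
        import random

        rng = random.Random(7)
        start, end = D(2020, 1, 1), D(2021, 1, 1)
        dates = [
            start + datetime.timedelta(days=rng.randrange(366)) for _ in range(20)
        ]
        server, session = _scattered_session(dates)
        query = SearchQuery("Observation", page_size=7)
        single = steal_bundles(
            session,
            query.with_params(
                [("date", f"ge{start}"), ("date", f"lt{end}")]
            ),
        )
        for n_procs in (1, 2, 4):
            sailed = sail_through_search_space(
                session, query, "date", start, end, n_procs=n_procs
            )
            assert sorted(sailed.resource_ids()) == sorted(single.resource_ids())

    def test_boundary_dated_resources_appear_exactly_once(self):
        start, end = D(2020, 1, 1), D(2020, 1, 11)
        part = partition_time_span(start, end, 4)
        boundary_dates = [a for a, _ in part.spans[1:]]  # interior boundaries
        server, session = _scattered_session(boundary_dates)
        sailed = sail_through_search_space(
            session, SearchQuery("Observation"), "date", start, end, n_procs=4
        )
        ids = sailed.resource_ids()
        assert len(ids) == len(boundary_dates)
        assert len(set(ids)) == len(ids)

    def test_degenerate_single_process_matches_explicit_params(self):
        server, session = _scattered_session(["2020-03-01", "2020-06-01"])
        start, end = D(2020, 1, 1), D(2021, 1, 1)
        sailed = sail_through_search_space(
            session, SearchQuery("Observation"), "date", start, end, n_procs=1
        )
        explicit = steal_bundles(
            session,
            SearchQuery("Observation").with_params(
                [("date", f"ge{start}"), ("date", f"lt{end}")]
            ),
        )
        assert sailed.resource_ids() == explicit.resource_ids()


class TestTradeRowsForBundles:
    def test_per_row_studies_match_subject(self, store, server, session):
        patients = [
            s["subject"]["reference"].split("/")[1]
            for s in store.all("ImagingStudy")
        ][:3]
        table = pd.DataFrame({"pid": sorted(set(patients))[:3]})
        results = trade_rows_for_bundles(
            session, table, SearchQuery("ImagingStudy"), {"pid": "subject"}
        )
        assert len(results) == len(table)
        for index, bundles in results:
            expected = sorted(
                s["id"]
                for s in store.all("ImagingStudy")
                if s["subject"]["reference"] == f"Patient/{table.at[index, 'pid']}"
            )
            assert sorted(bundles.resource_ids()) == expected

    def test_empty_table(self, session):
        results = trade_rows_for_bundles(
            session, pd.DataFrame({"pid": []}), SearchQuery("Patient"), {"pid": "_id"}
        )
        assert list(results) == [] and results.skipped == []

    def test_system_prefix_builds_token_value(self, store, server, session):
        # LOINC-system-qualified cell value must match system|code server-side
        table = pd.DataFrame({"loinc": ["16112-5"]})
        results = trade_rows_for_bundles(
            session,
            table,
            SearchQuery("Observation"),
            {"loinc": ("code", "http://loinc.org")},
        )
        expected = [
            o["id"]
            for o in store.all("Observation")
            if any(
                c.get("system") == "http://loinc.org" and c.get("code") == "16112-5"
                for c in o["code"]["coding"]
            )
        ]
        assert sorted(results[0][1].resource_ids()) == sorted(expected)
        requested = [url for _, url in server.request_log if "Observation" in url]
        assert any("code=http%3A%2F%2Floinc.org%7C16112-5" in url for url in requested)

    def test_missing_cells_skipped_and_reported(self, session):
        table = pd.DataFrame({"pid": ["p0", None, ""]})
        results = trade_rows_for_bundles(
            session, table, SearchQuery("Patient"), {"pid": "_id"}
        )
        assert [index for index, _ in results] == [0]
        assert results.skipped == [1, 2]

    def test_absent_constraint_column_raises(self, session):
        with pytest.raises(KeyError):
            trade_rows_for_bundles(
                session, pd.DataFrame({"x": [1]}), SearchQuery("Patient"), {"pid": "_id"}
            )

    def test_row_union_equivalence(self, store, server, session):
        """Per-row trade equals the union of sequential single queries."""
        table = pd.DataFrame({"pid": sorted(store.patient_ids())[:8]})
        traded = trade_rows_for_bundles(
            session, table, SearchQuery("Observation"), {"pid": "subject"}, n_procs=3
        )
        union = []
        for pid in table["pid"]:
            union.extend(
                steal_bundles(
                    session, SearchQuery("Observation", {"subject": pid})
                ).resource_ids()
            )
        traded_ids = [rid for _, bundles in traded for rid in bundles.resource_ids()]
        assert traded_ids == union

    def test_concurrency_determinism(self, store, session):
        table = pd.DataFrame({"pid": sorted(store.patient_ids())[:6]})
        outputs = []
        for n_procs in (1, 2, 4):
            result = trade_rows_for_bundles(
                session, table, SearchQuery("Observation"), {"pid": "subject"}, n_procs
            )
            outputs.append([(i, b.resource_ids()) for i, b in result])
        assert outputs[0] == outputs[1] == outputs[2]

    def test_default_worker_count_is_one(self):
        import inspect

        for fn in (trade_rows_for_bundles, sail_through_search_space):
            assert inspect.signature(fn).parameters["n_procs"].default == 1


class TestRequestHistory:
    def test_planted_versions_newest_first(self, session, server):
        store = server.store
        patient = store.all("Patient")[0]
        history = request_history(session, "Patient", patient["id"])
        assert history.total_entries == 2
        versions = [r["meta"]["versionId"] for r in history.resources()]
        assert versions == ["2", "1"]

    def test_three_planted_versions(self):
        store = tiny_patient_store(1)
        base = store.all("Patient")[0]
        store.versions[("Patient", "p0")] = [
            {**base, "meta": {"versionId": str(v)}} for v in (3, 2, 1)
        ]
        session = make_session(MockFhirServer(store))
        history = request_history(session, "Patient", "p0")
        assert history.total_entries == 3

    def test_unversioned_resource_single_entry(self, store, session):
        unversioned = store.all("Patient")[5]["id"]
        assert request_history(session, "Patient", unversioned).total_entries == 1

    def test_unknown_id_not_found(self, session):
        with pytest.raises(NotFoundError):
            request_history(session, "Patient", "no-such-id")


class TestFacades:
    def test_identity_extraction(self):
        server = MockFhirServer(tiny_patient_store(5))
        session = make_session(server)
        frame = steal_bundles_to_dataframe(
            session, SearchQuery("Patient"), ExtractionSpec.paths([("id", "id")])
        )
        assert list(frame.columns) == ["id"]
        assert sorted(frame["id"]) == [f"p{i}" for i in range(5)]

    def test_with_columns_propagates_source_row(self, store, session):
        table = pd.DataFrame(
            {"pid": sorted(store.patient_ids())[:3], "icd_code": ["C50", "C78.0", "C34"]}
        )
        frame = trade_rows_for_dataframe(
            session,
            table,
            SearchQuery("Observation"),
            {"pid": "subject"},
            ExtractionSpec.paths([("obs_id", "id"), ("subject", "subject.reference")]),
            with_columns=["icd_code"],
        )
        for _, row in frame.iterrows():
            pid = row["subject"].split("/")[1]
            source = table[table["pid"] == pid].iloc[0]
            assert row["icd_code"] == source["icd_code"]

    def test_alternate_mode_aborts_before_next_fetch(self):
        server = MockFhirServer(tiny_patient_store(6))
        session = make_session(server)

        def explode_on_p2(bundle):
            for entry in bundle.get("entry", []):
                if entry["resource"]["id"] == "p2":
                    raise ValueError("filtering schema violated")
            return [{"id": e["resource"]["id"]} for e in bundle.get("entry", [])]

        with pytest.raises(ExtractionError):
            steal_bundles_to_dataframe(
                session,
                SearchQuery("Patient", page_size=2),
                ExtractionSpec.processing(explode_on_p2),
                alternate=True,
            )
        searches = [url for _, url in server.request_log if "/Patient?" in url]
        assert len(searches) == 2  # bundle 3 was never fetched

    def test_facade_equals_composition(self, store, session):
        from skiff import bundles_to_table

        query = SearchQuery("Condition", {"code": "C50"})
        spec = ExtractionSpec.paths([("id", "id"), ("onset", "onsetDateTime")])
        direct = steal_bundles_to_dataframe(session, query, spec)
        composed = bundles_to_table(steal_bundles(session, query), spec)
        pd.testing.assert_frame_equal(direct, composed)
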