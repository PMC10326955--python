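"""Flattening, processing functions, merge-on-key, and the table writers."""

import pandas as pd
import pytest

from skiff import (
    CohortConfig,
    ExtractionSpec,
    MockFhirServer,
    SearchQuery,
    SkiffError,
    bundles_to_table,
    flatten_resource,
    generate_cohort,
    merge_rows,
    read_csv,
    steal_bundles,
    write_csv,
)
from skiff.errors import ExtractionError

from conftest import make_session

PATIENT = {"resourceType": "Patient", "id": "p1", "name": [{"family": "Smith"}]}


def bundle_of(*resources):
    return {
        "resourceType": "Bundle",
        "type": "searchset",
        "entry": [{"resource": r} for r in resources],
    }


class TestFlattenResource:
    def test_scalar_cells(self):
        spec = ExtractionSpec.paths([("pid", "id"), ("fam", "name.family")])
        assert flatten_resource(PATIENT, spec) == {"pid": "p1", "fam": "Smith"}

    def test_multi_valued_path_becomes_list_cell(self):
        resource = {"resourceType": "Patient", "name": [{"given": ["Anna", "B"]}]}
        spec = ExtractionSpec.paths([("given", "name.given")])
        assert flatten_resource(resource, spec) == {"given": ["Anna", "B"]}

    def test_empty_collection_becomes_missing(self):
        spec = ExtractionSpec.paths([("x", "name.nickname")])
        assert flatten_resource(PATIENT, spec) == {"x": None}

    def test_full_dump_dot_and_index_names(self):
        record = flatten_resource(PATIENT, ExtractionSpec.full_dump())
        assert record == {
            "resourceType": "Patient",
            "id": "p1",
            "name.0.family": "Smith",
        }

    def test_duplicate_alias_first_nonempty_path_wins(self):
        spec = ExtractionSpec.paths(
            [("pid", "Patient.id"), ("pid", "subject.reference")]
        )
        assert [alias for alias, _ in spec.columns] == ["pid"]
        assert flatten_resource(PATIENT, spec) == {"pid": "p1"}
        study = {"resourceType": "ImagingStudy", "subject": {"reference": "Patient/p1"}}
        assert flatten_resource(study, spec) == {"pid": "Patient/p1"}

    def test_bad_path_annotated_with_alias(self):
        spec = ExtractionSpec.paths([("n", "id.replace('a', 'b')")])
        with pytest.raises(ExtractionError, match="'n'"):
            flatten_resource({"resourceType": "X", "id": 7}, spec)


class TestBundlesToTable:
    def test_row_per_entry(self):
        bundles = [bundle_of(*({"resourceType": "P", "id": f"r{i}{j}"} for j in range(2)))
                   for i in range(3)]
        frame = bundles_to_table(bundles, ExtractionSpec.paths([("id", "id")]))
        assert len(frame) == 6
        assert list(frame["id"]) == [f"r{i}{j}" for i in range(3) for j in range(2)]

    def test_empty_input_keeps_spec_columns(self):
        frame = bundles_to_table([], ExtractionSpec.paths([("id", "id"), ("x", "a.b")]))
        assert list(frame.columns) == ["id", "x"]
        assert len(frame) == 0

    def test_blood_pressure_components_one_column_per_display_name(self, store):
        """Component display names become headers, quantities the values,
        units an extra column; one row per Observation."""

        def get_blood_panel_info(bundle):
            rows = []
            for entry in bundle.get("entry", []):
                resource = entry["resource"]
                record = {"id": resource["id"]}
                for component in resource.get("component", []):
                    name = component["code"]["text"]
                    record[name] = component["valueQuantity"]["value"]
                    record[f"{name} unit"] = component["valueQuantity"]["unit"]
                rows.append(record)
            return rows

        session = make_session(MockFhirServer(store))
        bundles = steal_bundles(
            session, SearchQuery("Observation", {"code": "85354-9"})
        )
        n_panels = bundles.total_entries
        assert n_panels > 0
        frame = bundles_to_table(bundles, ExtractionSpec.processing(get_blood_panel_info))
        assert len(frame) == n_panels
        assert "Systolic blood pressure" in frame.columns
        assert "Diastolic blood pressure" in frame.columns
        assert "Systolic blood pressure unit" in frame.columns
        assert set(frame["Systolic blood pressure unit"]) == {"mmHg"}
        assert all(isinstance(v, int) for v in frame["Systolic blood pressure"])

    def test_processing_error_wrapped_with_bundle_index(self):
        def boom(bundle):
            raise RuntimeError("nope")

        with pytest.raises(ExtractionError, match="bundle 0"):
            bundles_to_table([bundle_of(PATIENT)], ExtractionSpec.processing(boom))

    @pytest.mark.parametrize("n_procs", [2, 4])
    def test_worker_count_does_not_change_output(self, store, n_procs):
        bundles = [bundle_of(*store.all("Observation")[i : i + 5]) for i in range(0, 30, 5)]
        spec = ExtractionSpec.paths(
            [("id", "id"), ("code", "code.coding.code"), ("when", "effectiveDateTime")]
        )
        pd.testing.assert_frame_equal(
            bundles_to_table(bundles, spec, n_procs=1),
            bundles_to_table(bundles, spec, n_procs=n_procs),
        )

    def test_row_conservation(self, store):
        """Rows out equals entries in for both non-merge modes."""
        resources = store.all("Condition")
        bundles = [bundle_of(*resources[i : i + 4]) for i in range(0, len(resources), 4)]
        n_entries = sum(len(b["entry"]) for b in bundles)
        for spec in (ExtractionSpec.paths([("id", "id")]), ExtractionSpec.full_dump()):
            assert len(bundles_to_table(bundles, spec)) == n_entries

    def test_full_dump_projection_reproduces_scalar_paths(self, store):
        """Cross-mode oracle on navigation-only scalar attributes."""
        bundles = [bundle_of(*store.all("Patient"))]
        spec = ExtractionSpec.paths(
            [("id", "id"), ("gender", "gender"), ("birthDate", "birthDate")]
        )
        via_paths = bundles_to_table(bundles, spec)
        via_dump = bundles_to_table(bundles, ExtractionSpec.full_dump())
        for col in ("id", "gender", "birthDate"):
            assert list(via_paths[col]) == list(via_dump[col])


class TestMergeRows:
    def test_include_bundle_merges_study_and_patient_rows(self):
        store = generate_cohort(
            CohortConfig(n_patients=8, seed=11, studies_per_patient=("fixed", 1))
        )
        session = make_session(MockFhirServer(store))
        spec = ExtractionSpec.paths(
            [
                ("patient_id", "ImagingStudy.subject.reference.replace('Patient/', '')"),
                ("patient_id", "Patient.id"),
                ("study_id", "ImagingStudy.id"),
                ("gender", "Patient.gender"),
                ("birth_date", "Patient.birthDate"),
            ]
        )
        table = bundles_to_table(steal_bundles(session, SearchQuery("ImagingStudy", {"_include": "ImagingStudy:subject"})), spec)
        n_studies = len(store.all("ImagingStudy"))
        assert len(table) > n_studies  # study rows plus included patient rows
        merged = merge_rows(table, "patient_id")
        assert len(merged) == n_studies  # one study per patient here
        assert merged["gender"].notna().all()
        assert merged["study_id"].notna().all()

    def test_all_distinct_keys_is_identity(self):
        table = pd.DataFrame(
            {"k": ["a", "b"], "v": [1, 2]}, dtype=object
        )
        pd.testing.assert_frame_equal(merge_rows(table, "k"), table)

    def test_conflicting_scalars_collected_into_list(self):
        table = pd.DataFrame({"k": ["a", "a"], "c": ["x", "y"]}, dtype=object)
        merged = merge_rows(table, "k")
        assert len(merged) == 1
        assert merged["c"].iloc[0] == ["x", "y"]

    def test_agreeing_scalars_stay_scalar(self):
        table = pd.DataFrame({"k": ["a", "a"], "c": ["x", "x"]}, dtype=object)
        assert merge_rows(table, "k")["c"].iloc[0] == "x"

    def test_missing_values_lose_to_values(self):
        table = pd.DataFrame({"k": ["a", "a"], "c": [None, "x"]}, dtype=object)
        assert merge_rows(table, "k")["c"].iloc[0] == "x"

    def test_missing_key_rows_kept_unmerged(self):
        table = pd.DataFrame(
            {"k": ["a", None, "a", None], "c": [1, 2, 3, 4]}, dtype=object
        )
        merged = merge_rows(table, "k")
        # one merged 'a' row + two untouched missing-key rows
        assert len(merged) == 3
        assert list(merged["c"])[1:] == [2, 4]

    def test_row_count_rule(self, store):
        """Output rows = distinct non-missing keys + missing-key rows."""
        table = pd.DataFrame(
            {
                "k": ["a", "b", None, "a", "c", None, "b"],
                "v": list(range(7)),
            },
            dtype=object,
        )
        assert len(merge_rows(table, "k")) == 3 + 2

    def test_absent_key_column_raises(self):
        with pytest.raises(KeyError):
            merge_rows(pd.DataFrame({"a": [1]}), "nope")


class TestWriters:
    def test_csv_round_trip_with_list_cells(self, tmp_path):
        table = pd.DataFrame(
            {
                "id": ["r1", "r2"],
                "given": [["Anna", "B"], None],
                "n": [3, None],
            },
            dtype=object,
        )
        path = tmp_path / "t.csv"
        write_csv(table, path)
        text = path.read_text()
        assert '"[""Anna"", ""B""]"' in text  # JSON array quoted per RFC 4180
        back = read_csv(path)
        assert list(back.columns) == ["id", "given", "n"]
        assert back["given"].iloc[0] == ["Anna", "B"]
        assert back["given"].iloc[1] is None

    def test_spec_invariants_enforced(self):
        with pytest.raises(SkiffError):
            ExtractionSpec(columns=[("a", []), ("a", [])])
        with pytest.raises(SkiffError):
            ExtractionSpec(mode="processing_function")
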