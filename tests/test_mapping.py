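import random

import pytest

from fhirtab.errors import (
    MappingContractError,
    RowMappingError,
    TemplateNotFoundError,
)
from fhirtab.mapping import (
    DEFAULT_REGISTRY,
    MappingTemplate,
    TemplateEntry,
    count_template_tags,
    drf_run,
    map_resource,
    registry_from_dict,
    registry_to_dict,
    resource_template,
)
from fhirtab.model import (
    ReferenceView,
    ResourceType,
    parse_resource,
    read_resource_collection,
    walk_path,
)
from fhirtab.source import open_source
from fhirtab.store import SCHEMA_TABLES, create_schema, table_counts


class TestTemplateRegistry:
    def test_patient_template_covers_demographics(self):
        template = resource_template(ResourceType.PATIENT)
        paths = [e.source_path for e in template.entries]
        for needed in ("identifier", "name", "telecom", "address", "gender", "birthDate"):
            assert any(p.startswith(needed) for p in paths), needed

    def test_appointment_template_covers_scheduling_elements(self):
        template = resource_template(ResourceType.APPOINTMENT)
        columns = {e.target_column for e in template.entries}
        assert {"status", "appointment_type", "priority"} <= columns

    @pytest.mark.parametrize(
        "rtype,needed",
        [
            (ResourceType.CONDITION, {"clinical_status", "category", "code_display"}),
            (ResourceType.ALLERGY_INTOLERANCE, {"clinical_status", "code_display"}),
            (ResourceType.PRACTITIONER, {"family", "qualification"}),
            (ResourceType.SERVICE_REQUEST, {"status", "category", "requester_ref", "based_on_ref"}),
            (ResourceType.DIAGNOSTIC_REPORT, {"status", "category", "code_display", "based_on_ref"}),
        ],
    )
    def test_minimum_registry_coverage(self, rtype, needed):
        columns = {e.target_column for e in resource_template(rtype).entries}
        assert needed <= columns

    def test_every_template_has_id_and_subject_where_applicable(self):
        subject_bearing = {
            ResourceType.ALLERGY_INTOLERANCE,
            ResourceType.CONDITION,
            ResourceType.SERVICE_REQUEST,
            ResourceType.DIAGNOSTIC_REPORT,
            ResourceType.APPOINTMENT,
        }
        for rtype, template in DEFAULT_REGISTRY.items():
            columns = {e.target_column for e in template.entries}
            assert "logical_id" in columns
            if rtype in subject_bearing:
                assert "patient_ref" in columns

    def test_unregistered_type_errors(self):
        with pytest.raises(TemplateNotFoundError):
            resource_template("Medication")

    def test_duplicate_source_paths_rejected(self):
        with pytest.raises(MappingContractError):
            MappingTemplate(
                ResourceType.PATIENT,
                [
                    TemplateEntry("id", "patient", "logical_id"),
                    TemplateEntry("id", "patient", "identifier"),
                ],
            )

    def test_registry_dict_round_trip(self):
        again = registry_from_dict(registry_to_dict(DEFAULT_REGISTRY))
        assert again == DEFAULT_REGISTRY


class TestCountTemplateTags:
    def test_counts_entries(self):
        template = MappingTemplate(
            ResourceType.PATIENT,
            [TemplateEntry("id", "patient", "logical_id")]
            + [
                TemplateEntry(f"f{i}", "patient", f"c{i}")
                for i in range(4)
            ],
        )
        assert count_template_tags(template) == 5

    def test_matches_mapped_columns_across_tables(self):
        # recount through the schema registry: every entry lands in a declared column
        for template in DEFAULT_REGISTRY.values():
            n = 0
            for entry in template.entries:
                spec = SCHEMA_TABLES[entry.target_table]
                columns = {c for c, _ in spec.columns}
                if entry.transform == "reference_to_key":
                    base = entry.target_column[:-4]
                    assert {f"{base}_key", f"{base}_ref_id"} <= columns
                else:
                    assert entry.target_column in columns
                n += 1
            assert count_template_tags(template) == n


class TestMapResource:
    def test_patient_gender_lands_in_column(self):
        env = parse_resource('{"resourceType":"Patient","id":"1","gender":"male"}')
        batch = map_resource(env, resource_template(ResourceType.PATIENT))
        assert batch.tables["patient"][0]["gender"] == "male"
        assert batch.tables["patient"][0]["logical_id"] == "1"
        assert batch.provenance == (ResourceType.PATIENT, "1")

    def test_two_telecoms_yield_two_child_rows(self):
        env = parse_resource(
            '{"resourceType":"Patient","id":"1","telecom":'
            '[{"system":"phone","value":"a"},{"system":"email","value":"b"}]}'
        )
        batch = map_resource(env, resource_template(ResourceType.PATIENT))
        assert len(batch.tables["patient"]) == 1
        rows = batch.tables["patient_telecom"]
        assert [(r["system"], r["value"]) for r in rows] == [
            ("phone", "a"),
            ("email", "b"),
        ]
        assert all(r["patient_logical_id"] == "1" for r in rows)

    def test_allergy_reference_and_label(self):
        env = parse_resource(
            '{"resourceType":"AllergyIntolerance","id":"5",'
            '"patient":{"reference":"Patient/7"},'
            '"code":{"coding":[{"display":"Latex"}]}}'
        )
        batch = map_resource(env, resource_template(ResourceType.ALLERGY_INTOLERANCE))
        row = batch.tables["allergy"][0]
        assert row["code_display"] == "Latex"
        assert row["patient_ref"] == ReferenceView(ResourceType.PATIENT, "7")

    def test_absent_elements_map_to_null(self):
        env = parse_resource('{"resourceType":"Patient","id":"1"}')
        batch = map_resource(env, resource_template(ResourceType.PATIENT))
        assert batch.tables["patient"][0]["gender"] is None
        assert batch.tables["patient_telecom"] == []

    def test_type_mismatch_is_contract_error(self):
        env = parse_resource('{"resourceType":"Patient","id":"1"}')
        with pytest.raises(MappingContractError):
            map_resource(env, resource_template(ResourceType.CONDITION))

    def test_bad_reference_is_row_error(self):
        env = parse_resource(
            '{"resourceType":"AllergyIntolerance","id":"5",'
            '"patient":{"reference":"not-a-reference"}}'
        )
        with pytest.raises(RowMappingError):
            map_resource(env, resource_template(ResourceType.ALLERGY_INTOLERANCE))


class TestValueFidelity:
    def test_stored_value_matches_raw_json_walk(self, fixture_dir, loaded):
        """50 random (resource, scalar entry) pairs: stored == raw JSON walk."""
        schema, _ = loaded
        rng = random.Random(42)
        envelopes = {
            t: list(read_resource_collection(fixture_dir / f"{t.value}.ndjson"))
            for t in ResourceType
        }
        for _ in range(50):
            rtype = rng.choice(list(ResourceType))
            env = rng.choice(envelopes[rtype])
            template = resource_template(rtype)
            scalars = [
                e
                for e in template.entries
                if e.cardinality == "scalar"
                and e.transform in ("identity", "date_normalize")
            ]
            entry = rng.choice(scalars)
            expected = walk_path(env.elements, entry.source_path)
            stored = schema.conn.execute(
                f'SELECT "{entry.target_column}" FROM "{template.primary_table}" '
                "WHERE logical_id = ?",
                (env.logical_id,),
            ).fetchone()[0]
            assert stored == expected, (rtype, entry.source_path, env.logical_id)


class TestDrfRun:
    def test_full_run_reads_700_zero_skipped(self, loaded):
        _, report = loaded
        assert report.total_read == 700
        assert report.resources_read == {t: 100 for t in ResourceType}
        assert report.skipped == []

    def test_conservation_rows_equal_read_minus_skipped(self, loaded):
        schema, report = loaded
        counts = table_counts(schema)
        primary = {
            ResourceType.PATIENT: "patient",
            ResourceType.ALLERGY_INTOLERANCE: "allergy",
            ResourceType.PRACTITIONER: "practitioner",
            ResourceType.CONDITION: "condition",
            ResourceType.SERVICE_REQUEST: "service_request",
            ResourceType.DIAGNOSTIC_REPORT: "diagnostic_report",
            ResourceType.APPOINTMENT: "appointment",
        }
        skipped_by_type = {}
        for type_name, _, _ in report.skipped:
            skipped_by_type[type_name] = skipped_by_type.get(type_name, 0) + 1
        for rtype, table in primary.items():
            assert counts[table] == report.resources_read[rtype] - skipped_by_type.get(
                rtype.value, 0
            )

    def test_rerun_is_idempotent(self, fixture_dir, loaded):
        schema, _ = loaded
        before = table_counts(schema)
        drf_run(open_source(str(fixture_dir)), list(ResourceType), schema)
        assert table_counts(schema) == before

    def test_empty_source_all_zero_report(self, tmp_path):
        for t in ResourceType:
            (tmp_path / f"{t.value}.ndjson").write_text("")
        schema = create_schema(":memory:")
        report = drf_run(open_source(str(tmp_path)), list(ResourceType), schema)
        assert report.total_read == 0
        assert all(n == 0 for n in table_counts(schema).values())

    def test_order_independence_of_type_streams(self, fixture_dir):
        """Loading children before parents yields the same resolved contents."""
        forward = create_schema(":memory:")
        drf_run(open_source(str(fixture_dir)), list(ResourceType), forward)
        backward = create_schema(":memory:")
        drf_run(
            open_source(str(fixture_dir)), list(reversed(ResourceType)), backward
        )
        for table in SCHEMA_TABLES:
            columns = [c for c, _ in SCHEMA_TABLES[table].columns]
            select = f'SELECT {", ".join(columns)} FROM "{table}"'
            a = sorted(map(tuple, forward.conn.execute(select).fetchall()))
            b = sorted(map(tuple, backward.conn.execute(select).fetchall()))
            assert a == b, table
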