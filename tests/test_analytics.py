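import pytest

from fhirtab.analytics import (
    allergy_cohort_counts,
    apportion_percentages,
    patients_by_gender,
    patients_by_year,
    run_workflow,
    test_order_distribution as order_distribution,
    test_orders_by_year as orders_by_year,
)
from fhirtab.mapping import map_resource, resource_template
from fhirtab.model import ResourceType, parse_resource
from fhirtab.store import create_schema, load_rows, resolve_references


def _load(schema, raw):
    env = parse_resource(raw)
    load_rows(schema, map_resource(env, resource_template(env.resource_type)))


def _patient(pid, gender="male", birth="1980-01-01"):
    return (
        f'{{"resourceType":"Patient","id":"{pid}","gender":"{gender}",'
        f'"birthDate":"{birth}"}}'
    )


def _allergy(aid, patient, label):
    return (
        f'{{"resourceType":"AllergyIntolerance","id":"{aid}",'
        f'"patient":{{"reference":"Patient/{patient}"}},'
        f'"code":{{"coding":[{{"display":"{label}"}}]}}}}'
    )


class TestApportionPercentages:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([50, 50], [50, 50]),
            ([1, 1, 1], [34, 33, 33]),  # hand-enumerated: tie goes to index 0
            ([2, 1], [67, 33]),
            ([16, 15, 15, 14, 12, 10, 9, 9], [16, 15, 15, 14, 12, 10, 9, 9]),
        ],
    )
    def test_known_apportionments(self, counts, expected):
        assert apportion_percentages(counts) == expected

    def test_identity_when_counts_sum_to_100(self):
        counts = [40, 35, 25]
        assert apportion_percentages(counts) == counts

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            apportion_percentages([0, 0])


class TestGenderDistribution:
    def test_default_fixture_split(self, loaded):
        schema, _ = loaded
        result = patients_by_gender(schema)
        assert result.as_dict() == {"male": 55, "female": 45}
        assert result.total == 100

    def test_empty_store_total_zero(self):
        result = patients_by_gender(create_schema(":memory:"))
        assert result.total == 0 and result.rows == []

    def test_null_gender_reported_as_unknown(self):
        schema = create_schema(":memory:")
        _load(schema, '{"resourceType":"Patient","id":"1"}')
        assert patients_by_gender(schema).as_dict() == {"unknown": 1}


class TestRegistrationsByYear:
    def test_default_fixture_fixed_cells(self, loaded):
        schema, _ = loaded
        rows = patients_by_year(schema, 1950, 2021).as_dict()
        assert {y: rows[y] for y in ("1950", "1952", "2021")} == {
            "1950": 3,
            "1952": 3,
            "2021": 2,
        }

    def test_sum_over_full_range_conserves_patients(self, loaded):
        schema, _ = loaded
        assert patients_by_year(schema, 1950, 2021).total == 100

    def test_future_range_is_empty(self, loaded):
        schema, _ = loaded
        result = patients_by_year(schema, 2050, 2060)
        assert result.rows == [] and result.total == 0

    def test_zero_years_omitted_unless_flagged(self):
        schema = create_schema(":memory:")
        _load(schema, _patient("1", birth="1980-05-05"))
        sparse = patients_by_year(schema, 1979, 1981)
        assert [r.label for r in sparse.rows] == ["1980"]
        dense = patients_by_year(schema, 1979, 1981, include_empty_years=True)
        assert [(r.label, r.count) for r in dense.rows] == [
            ("1979", 0),
            ("1980", 1),
            ("1981", 0),
        ]

    def test_undated_patients_flagged_or_excluded(self):
        schema = create_schema(":memory:")
        _load(schema, '{"resourceType":"Patient","id":"1","gender":"male"}')
        excluded = patients_by_year(schema, 1950, 2021)
        assert excluded.total == 0
        assert excluded.parameters["undated_excluded"] == 1
        included = patients_by_year(schema, 1950, 2021, include_undated=True)
        assert included.as_dict() == {"undated": 1}

    def test_partial_birth_year_counts(self):
        # FHIR permits YYYY-only dates; the year is the first four characters
        schema = create_schema(":memory:")
        _load(schema, _patient("1", birth="1999"))
        assert patients_by_year(schema, 1950, 2021).as_dict() == {"1999": 1}

    def test_invalid_range_rejected(self, loaded):
        schema, _ = loaded
        with pytest.raises(ValueError):
            patients_by_year(schema, 2000, 1990)


class TestAllergyCohorts:
    def test_default_fixture_rows(self, loaded):
        schema, _ = loaded
        result = allergy_cohort_counts(schema)
        counts = result.as_dict()
        assert counts["Shellfish"] == 9
        assert counts["Neomycin"] == 12
        assert counts["IV Dye"] == 1
        assert len(counts) == 17

    def test_ordered_by_descending_count_then_label(self, loaded):
        schema, _ = loaded
        rows = allergy_cohort_counts(schema).rows
        keys = [(-r.count, r.label) for r in rows]
        assert keys == sorted(keys)

    def test_same_patient_same_label_counts_once(self):
        schema = create_schema(":memory:")
        _load(schema, _patient("1"))
        _load(schema, _allergy("1", "1", "Latex"))
        _load(schema, _allergy("2", "1", "Latex"))
        resolve_references(schema)
        assert allergy_cohort_counts(schema).as_dict() == {"Latex": 1}

    def test_orphan_allergies_excluded_and_reported(self):
        schema = create_schema(":memory:")
        _load(schema, _patient("1"))
        _load(schema, _allergy("1", "1", "Latex"))
        _load(schema, _allergy("2", "404", "Latex"))
        resolve_references(schema)
        result = allergy_cohort_counts(schema)
        assert result.as_dict() == {"Latex": 1}
        assert result.parameters["orphans_excluded"] == 1


class TestTestOrderDistribution:
    def test_default_fixture_percentages(self, loaded):
        schema, _ = loaded
        result = order_distribution(schema)
        percents = result.percents()
        assert percents["HIV"] == 16
        assert percents["SGPT"] == 9
        assert sum(percents.values()) == 100

    def test_counts_equal_percents_at_total_100(self, loaded):
        schema, _ = loaded
        result = order_distribution(schema)
        assert all(r.percent == r.count for r in result.rows)

    def test_zero_orders_empty_result(self):
        result = order_distribution(create_schema(":memory:"))
        assert result.rows == [] and result.total == 0


class TestOrdersByYear:
    def test_default_fixture_fixed_cells(self, loaded):
        schema, _ = loaded
        rows = orders_by_year(schema, 1950, 2021).as_dict()
        assert rows["2019"] == 6
        assert rows["2010"] == 5

    def test_sum_over_full_range_conserves_orders(self, loaded):
        schema, _ = loaded
        assert orders_by_year(schema, 1950, 2021).total == 100

    def test_empty_range_total_zero(self, loaded):
        schema, _ = loaded
        assert orders_by_year(schema, 2050, 2060).total == 0


class TestWorkflowResultContract:
    @pytest.mark.parametrize(
        "workflow_id",
        [
            "gender_distribution",
            "registrations_by_year",
            "allergy_cohorts",
            "test_order_distribution",
            "test_orders_by_year",
        ],
    )
    def test_counts_sum_to_total_and_percents_to_100(self, loaded, workflow_id):
        schema, _ = loaded
        result = run_workflow(schema, workflow_id)
        assert sum(r.count for r in result.rows) == result.total
        percents = [r.percent for r in result.rows if r.percent is not None]
        if percents:
            assert sum(percents) == 100

    def test_unknown_workflow_rejected(self, loaded):
        schema, _ = loaded
        with pytest.raises(ValueError):
            run_workflow(schema, "nope")

    def test_csv_export_shape(self, loaded, tmp_path):
        schema, _ = loaded
        result = patients_by_gender(schema)
        path = tmp_path / "gender.csv"
        result.write_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "label,count,percent"
        assert lines[1].startswith("male,55")
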