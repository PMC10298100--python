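"""Deterministic synthetic FHIR dataset generator.

The generator emits one NDJSON file per resource type whose *marginal
distributions are fully specified by configuration*: categorical attributes
(gender, birth year, allergy label, test name, order year) are assigned by
exact quota rather than sampled, so every configured marginal holds with
equality on every run.  The seed controls only assignment shuffling and the
synthesis of free-text fields (names, telecoms, addresses).

The default configuration reproduces a 700-resource demonstration dataset:
100 resources of each of the seven types, a 55/45 male/female split, birth
years over 1950-2021 with eight fixed year counts, seventeen allergy labels
with fixed patient counts summing to 100, eight laboratory test names whose
order counts equal their integer percentages (total 100), and order years
over 1950-2021 with eight fixed counts.  Year counts not fixed explicitly
are spread round-robin in ascending year order so that totals stay exact.

Every clinical resource references a generated Patient (and, for orders, a
generated Practitioner), so the dataset is referentially closed by
construction.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigValidationError
from .model import ResourceType

DEFAULT_SEED = 1729
YEAR_START, YEAR_END = 1950, 2021

# Small word pools for free-text synthesis (seed-controlled, cosmetic only).
_GIVEN_NAMES = [
    "Aaliyah", "Bilal", "Chen", "Dana", "Elif", "Farah", "Gabriel", "Hana",
    "Ibrahim", "Jun", "Kofi", "Leila", "Marco", "Nadia", "Omar", "Priya",
    "Quinn", "Rosa", "Sami", "Tara", "Umar", "Vera", "Wei", "Yusuf",
]
_FAMILY_NAMES = [
    "Abbas", "Brown", "Costa", "Diallo", "Ekwueme", "Fischer", "Garcia",
    "Haddad", "Ivanov", "Jensen", "Khan", "Lim", "Mensah", "Novak", "Okafor",
    "Park", "Qureshi", "Rossi", "Santos", "Tanaka", "Ueda", "Varga", "Wong",
    "Yilmaz",
]
_STREETS = ["Cedar St", "Maple Ave", "Oak Rd", "Pine Ln", "Elm Dr", "Birch Way"]
_CITIES = ["Springfield", "Riverton", "Lakeview", "Fairmont", "Hillcrest", "Brookside"]
_COUNTRY = "Utopia"
_QUALIFICATIONS = ["MBBS", "MD", "RN", "DO", "PharmD"]
_APPOINTMENT_TYPES = ["ROUTINE", "FOLLOWUP", "CHECKUP", "EMERGENCY", "WALKIN"]
_CONDITION_CODES = [
    "Hypertension", "Type 2 diabetes", "Asthma", "Migraine", "Osteoarthritis",
    "Anemia", "Gastritis", "Sinusitis",
]

DEFAULT_BIRTH_YEAR_CELLS = {
    1950: 3, 1951: 1, 1952: 3, 1953: 2, 1955: 1, 2013: 3, 2018: 1, 2021: 2,
}
DEFAULT_ALLERGY_TABLE = {
    "Shellfish": 9, "Glyburide": 8, "Latex": 5, "Coal Tar": 6, "Neomycin": 12,
    "Codeine": 8, "IVP Dye": 10, "Caffeine": 5, "Levaquin": 5, "Seafood": 6,
    "Rifampin": 3, "Norco": 6, "Penicillium": 5, "Benztropine": 6,
    "Watermelon": 3, "Metoprolol": 2, "IV Dye": 1,
}
DEFAULT_TEST_TABLE = {
    "HIV": 16, "CBC": 15, "CT SCAN": 15, "X-Ray Ankle": 14, "MRI": 12,
    "Blood Culture": 10, "COVID": 9, "SGPT": 9,
}
DEFAULT_ORDER_YEAR_CELLS = {
    1951: 4, 1952: 4, 1953: 3, 1955: 2, 2010: 5, 2015: 3, 2019: 6, 2020: 5,
}


@dataclass
class FixtureConfig:
    """Full specification of a synthetic dataset's marginal distributions."""

    counts_per_type: dict[ResourceType, int]
    gender_quota: dict[str, int]
    birth_year_histogram: dict[int, int]
    allergy_table: dict[str, int]
    test_table: dict[str, int]
    order_year_histogram: dict[int, int]
    link_policy: str = "uniform"
    use_registration_extension: bool = False
    seed: int = DEFAULT_SEED


@dataclass
class DatasetManifest:
    """What a generation run produced: files, counts, seed, config digest."""

    out_dir: str
    files: dict[str, str]
    counts: dict[str, int]
    seed: int
    config_digest: str

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "out_dir": self.out_dir,
                    "files": self.files,
                    "counts": self.counts,
                    "seed": self.seed,
                    "config_digest": self.config_digest,
                },
                fh,
                indent=2,
            )
            fh.write("\n")


def spread_over_years(
    fixed_cells: dict[int, int],
    total: int,
    start: int = YEAR_START,
    end: int = YEAR_END,
) -> dict[int, int]:
    """Complete a sparse year histogram to a given total.

    The fixed cells are kept exact; the remaining mass is distributed
    round-robin over the non-fixed years in ascending order, one unit per
    pass, so the result is deterministic and sums to ``total``.
    """
    if sum(fixed_cells.values()) > total:
        raise ValueError("fixed year cells exceed the requested total")
    hist = dict(fixed_cells)
    others = [y for y in range(start, end + 1) if y not in fixed_cells]
    remaining = total - sum(fixed_cells.values())
    i = 0
    while remaining > 0 and others:
        y = others[i % len(others)]
        hist[y] = hist.get(y, 0) + 1
        remaining -= 1
        i += 1
    return {y: hist[y] for y in sorted(hist)}


def default_fixture_config(seed: int = DEFAULT_SEED) -> FixtureConfig:
    """The replica configuration: 700 resources with the fixed marginals above."""
    return FixtureConfig(
        counts_per_type={t: 100 for t in ResourceType},
        gender_quota={"male": 55, "female": 45},
        birth_year_histogram=spread_over_years(DEFAULT_BIRTH_YEAR_CELLS, 100),
        allergy_table=dict(DEFAULT_ALLERGY_TABLE),
        test_table=dict(DEFAULT_TEST_TABLE),
        order_year_histogram=spread_over_years(DEFAULT_ORDER_YEAR_CELLS, 100),
        seed=seed,
    )


def validate_config(config: FixtureConfig) -> list[str]:
    """Return the list of violated invariants (empty when the config is valid)."""
    v: list[str] = []
    counts = config.counts_per_type
    for t in ResourceType:
        if counts.get(t, 0) < 0:
            v.append(f"counts_per_type[{t.value}] is negative")
    n_pat = counts.get(ResourceType.PATIENT, 0)
    n_all = counts.get(ResourceType.ALLERGY_INTOLERANCE, 0)
    n_sr = counts.get(ResourceType.SERVICE_REQUEST, 0)
    if sum(config.gender_quota.values()) != n_pat:
        v.append(
            f"gender_quota sums to {sum(config.gender_quota.values())}, "
            f"expected counts_per_type[Patient]={n_pat}"
        )
    if sum(config.birth_year_histogram.values()) != n_pat:
        v.append(
            f"birth_year_histogram sums to "
            f"{sum(config.birth_year_histogram.values())}, expected {n_pat}"
        )
    if sum(config.allergy_table.values()) != n_all:
        v.append(
            f"allergy_table sums to {sum(config.allergy_table.values())}, "
            f"expected counts_per_type[AllergyIntolerance]={n_all}"
        )
    for label, c in config.allergy_table.items():
        if c > n_pat:
            v.append(
                f"allergy_table[{label!r}]={c} exceeds the patient count {n_pat}"
            )
        if c < 0:
            v.append(f"allergy_table[{label!r}] is negative")
    if sum(config.test_table.values()) != n_sr:
        v.append(
            f"test_table sums to {sum(config.test_table.values())}, "
            f"expected counts_per_type[ServiceRequest]={n_sr}"
        )
    if sum(config.order_year_histogram.values()) != n_sr:
        v.append(
            f"order_year_histogram sums to "
            f"{sum(config.order_year_histogram.values())}, expected {n_sr}"
        )
    dependent = (
        n_all,
        counts.get(ResourceType.CONDITION, 0),
        n_sr,
        counts.get(ResourceType.DIAGNOSTIC_REPORT, 0),
        counts.get(ResourceType.APPOINTMENT, 0),
    )
    if any(dependent) and n_pat == 0:
        v.append("clinical resources configured but no patients to reference")
    if n_sr > 0 and counts.get(ResourceType.PRACTITIONER, 0) == 0:
        v.append("ServiceRequest resources configured but no practitioners")
    if (
        counts.get(ResourceType.DIAGNOSTIC_REPORT, 0) > 0
        and n_sr == 0
    ):
        v.append("DiagnosticReport resources configured but no service requests")
    return v


# --------------------------------------------------------------------------
# Config (de)serialization — YAML or JSON mirroring the field names.


def config_to_dict(config: FixtureConfig) -> dict[str, Any]:
    return {
        "counts_per_type": {t.value: n for t, n in config.counts_per_type.items()},
        "gender_quota": dict(config.gender_quota),
        "birth_year_histogram": {int(y): n for y, n in config.birth_year_histogram.items()},
        "allergy_table": dict(config.allergy_table),
        "test_table": dict(config.test_table),
        "order_year_histogram": {int(y): n for y, n in config.order_year_histogram.items()},
        "link_policy": config.link_policy,
        "use_registration_extension": config.use_registration_extension,
        "seed": config.seed,
    }


def config_from_dict(data: dict[str, Any]) -> FixtureConfig:
    return FixtureConfig(
        counts_per_type={
            ResourceType(t): int(n) for t, n in data["counts_per_type"].items()
        },
        gender_quota={str(g): int(n) for g, n in data["gender_quota"].items()},
        birth_year_histogram={
            int(y): int(n) for y, n in data["birth_year_histogram"].items()
        },
        allergy_table={str(a): int(n) for a, n in data["allergy_table"].items()},
        test_table={str(t): int(n) for t, n in data["test_table"].items()},
        order_year_histogram={
            int(y): int(n) for y, n in data["order_year_histogram"].items()
        },
        link_policy=str(data.get("link_policy", "uniform")),
        use_registration_extension=bool(data.get("use_registration_extension", False)),
        seed=int(data.get("seed", DEFAULT_SEED)),
    )


def load_config(path: str | Path) -> FixtureConfig:
    """Load a FixtureConfig from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)  # YAML is a JSON superset
    return config_from_dict(data)


def config_digest(config: FixtureConfig) -> str:
    canonical = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


# --------------------------------------------------------------------------
# Generation


def _expand_quota(quota: dict, rng: random.Random) -> list:
    """Expand {label: count} to a shuffled list of labels."""
    out = []
    for label, count in quota.items():
        out.extend([label] * count)
    rng.shuffle(out)
    return out


def _date_in_year(year: int, rng: random.Random) -> str:
    return f"{year:04d}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"


def _human_name(rng: random.Random) -> dict[str, Any]:
    return {
        "family": rng.choice(_FAMILY_NAMES),
        "given": [rng.choice(_GIVEN_NAMES)],
    }


def _make_patients(config: FixtureConfig, rng: random.Random) -> list[dict]:
    n = config.counts_per_type.get(ResourceType.PATIENT, 0)
    genders = _expand_quota(config.gender_quota, rng)
    years = _expand_quota(
        {y: c for y, c in sorted(config.birth_year_histogram.items())}, rng
    )
    patients = []
    for i in range(n):
        pid = str(i + 1)
        name = _human_name(rng)
        resource: dict[str, Any] = {
            "resourceType": "Patient",
            "id": pid,
            "identifier": [{"system": "urn:fhirtab:mrn", "value": pid}],
            "name": [name],
            "telecom": [
                {"system": "phone", "value": f"+1-555-{rng.randint(1000, 9999)}"},
                {
                    "system": "email",
                    "value": f"{name['given'][0].lower()}.{name['family'].lower()}"
                    f".{pid}@example.org",
                },
            ],
            "address": [
                {
                    "line": [f"{rng.randint(1, 999)} {rng.choice(_STREETS)}"],
                    "city": rng.choice(_CITIES),
                    "country": _COUNTRY,
                }
            ],
            "gender": genders[i],
            "birthDate": _date_in_year(years[i], rng),
        }
        if config.use_registration_extension:
            resource["extension"] = [
                {
                    "url": "urn:fhirtab:registration-date",
                    "valueDate": _date_in_year(rng.randint(YEAR_START, YEAR_END), rng),
                }
            ]
        patients.append(resource)
    return patients


def _make_practitioners(config: FixtureConfig, rng: random.Random) -> list[dict]:
    n = config.counts_per_type.get(ResourceType.PRACTITIONER, 0)
    out = []
    for i in range(n):
        pid = str(i + 1)
        out.append(
            {
                "resourceType": "Practitioner",
                "id": pid,
                "identifier": [{"system": "urn:fhirtab:npi", "value": pid}],
                "name": [_human_name(rng)],
                "address": [{"city": rng.choice(_CITIES), "country": _COUNTRY}],
                "qualification": [{"code": {"text": rng.choice(_QUALIFICATIONS)}}],
            }
        )
    return out


def _make_allergies(
    config: FixtureConfig, patient_ids: list[str], rng: random.Random
) -> list[dict]:
    # One allergy label per resource; each label attached to `count` distinct
    # patients, so "patients per label" equals "resources per label" exactly.
    pairs: list[tuple[str, str]] = []
    for label, count in config.allergy_table.items():
        for pid in rng.sample(patient_ids, count):
            pairs.append((label, pid))
    rng.shuffle(pairs)
    out = []
    for i, (label, pid) in enumerate(pairs):
        aid = str(i + 1)
        out.append(
            {
                "resourceType": "AllergyIntolerance",
                "id": aid,
                "identifier": [{"system": "urn:fhirtab:allergy", "value": aid}],
                "clinicalStatus": {
                    "coding": [
                        {
                            "system": "http://terminology.hl7.org/CodeSystem/"
                            "allergyintolerance-clinical",
                            "code": "active",
                        }
                    ]
                },
                "code": {"coding": [{"system": "", "display": label}]},
                "patient": {"reference": f"Patient/{pid}"},
            }
        )
    return out


def _make_service_requests(
    config: FixtureConfig,
    patient_ids: list[str],
    practitioner_ids: list[str],
    rng: random.Random,
) -> list[dict]:
    tests = _expand_quota(config.test_table, rng)
    years = _expand_quota(
        {y: c for y, c in sorted(config.order_year_histogram.items())}, rng
    )
    out = []
    for i, (test, year) in enumerate(zip(tests, years)):
        sid = str(i + 1)
        out.append(
            {
                "resourceType": "ServiceRequest",
                "id": sid,
                "identifier": [{"system": "urn:fhirtab:order", "value": sid}],
                "status": "completed",
                "intent": "order",
                "category": [{"coding": [{"system": "", "code": "laboratory"}]}],
                "code": {"coding": [{"system": "", "display": test}]},
                "authoredOn": _date_in_year(year, rng),
                "subject": {"reference": f"Patient/{rng.choice(patient_ids)}"},
                "requester": {
                    "reference": f"Practitioner/{rng.choice(practitioner_ids)}"
                },
            }
        )
    return out


def _make_diagnostic_reports(
    config: FixtureConfig, service_requests: list[dict], rng: random.Random
) -> list[dict]:
    n = config.counts_per_type.get(ResourceType.DIAGNOSTIC_REPORT, 0)
    out = []
    for i in range(n):
        did = str(i + 1)
        sr = service_requests[i % len(service_requests)]
        out.append(
            {
                "resourceType": "DiagnosticReport",
                "id": did,
                "identifier": [{"system": "urn:fhirtab:report", "value": did}],
                "basedOn": [{"reference": f"ServiceRequest/{sr['id']}"}],
                "status": "final",
                "category": [{"coding": [{"system": "", "code": "LAB"}]}],
                "code": sr["code"],  # mirrors the order's test label
                "subject": sr["subject"],
            }
        )
    return out


def _make_conditions(
    config: FixtureConfig, patient_ids: list[str], rng: random.Random
) -> list[dict]:
    n = config.counts_per_type.get(ResourceType.CONDITION, 0)
    out = []
    for i in range(n):
        cid = str(i + 1)
        out.append(
            {
                "resourceType": "Condition",
                "id": cid,
                "identifier": [{"system": "urn:fhirtab:condition", "value": cid}],
                "clinicalStatus": {
                    "coding": [
                        {
                            "system": "http://terminology.hl7.org/CodeSystem/"
                            "condition-clinical",
                            "code": "active",
                        }
                    ]
                },
                "category": [
                    {"coding": [{"system": "", "code": "encounter-diagnosis"}]}
                ],
                "code": {"coding": [{"system": "", "display": rng.choice(_CONDITION_CODES)}]},
                "subject": {"reference": f"Patient/{rng.choice(patient_ids)}"},
            }
        )
    return out


def _make_appointments(
    config: FixtureConfig, patient_ids: list[str], rng: random.Random
) -> list[dict]:
    n = config.counts_per_type.get(ResourceType.APPOINTMENT, 0)
    out = []
    for i in range(n):
        aid = str(i + 1)
        out.append(
            {
                "resourceType": "Appointment",
                "id": aid,
                "identifier": [{"system": "urn:fhirtab:appt", "value": aid}],
                "status": rng.choice(["booked", "fulfilled", "cancelled"]),
                "appointmentType": {
                    "coding": [{"system": "", "code": rng.choice(_APPOINTMENT_TYPES)}]
                },
                "priority": rng.randint(0, 9),
                "participant": [
                    {
                        "actor": {"reference": f"Patient/{rng.choice(patient_ids)}"},
                        "status": "accepted",
                    }
                ],
            }
        )
    return out


def generate_dataset(config: FixtureConfig, out_dir: str | Path) -> DatasetManifest:
    """Write one ``<ResourceType>.ndjson`` per type plus ``manifest.json``.

    Two runs with the same (config, seed) produce byte-identical output.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigValidationError(violations)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)

    patients = _make_patients(config, rng)
    practitioners = _make_practitioners(config, rng)
    patient_ids = [p["id"] for p in patients]
    practitioner_ids = [p["id"] for p in practitioners]
    allergies = _make_allergies(config, patient_ids, rng)
    service_requests = _make_service_requests(
        config, patient_ids, practitioner_ids, rng
    )
    reports = _make_diagnostic_reports(config, service_requests, rng)
    conditions = _make_conditions(config, patient_ids, rng)
    appointments = _make_appointments(config, patient_ids, rng)

    by_type: dict[ResourceType, list[dict]] = {
        ResourceType.PATIENT: patients,
        ResourceType.ALLERGY_INTOLERANCE: allergies,
        ResourceType.PRACTITIONER: practitioners,
        ResourceType.CONDITION: conditions,
        ResourceType.SERVICE_REQUEST: service_requests,
        ResourceType.DIAGNOSTIC_REPORT: reports,
        ResourceType.APPOINTMENT: appointments,
    }
    files: dict[str, str] = {}
    counts: dict[str, int] = {}
    for rtype, resources in by_type.items():
        path = out / f"{rtype.value}.ndjson"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for resource in resources:
                fh.write(json.dumps(resource, ensure_ascii=False))
                fh.write("\n")
        files[rtype.value] = str(path)
        counts[rtype.value] = len(resources)

    manifest = DatasetManifest(
        out_dir=str(out),
        files=files,
        counts=counts,
        seed=config.seed,
        config_digest=config_digest(config),
    )
    manifest.write(out / "manifest.json")
    return manifest
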