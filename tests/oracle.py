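"""Brute-force workflow oracles computed directly on raw NDJSON.

These deliberately use only the json module — no fhirtab imports — so they
stay independent of the pipeline they check (parser, templates, relational
store, SQL)."""

import json
from collections import Counter
from pathlib import Path


def _load(fixture_dir, type_name):
    path = Path(fixture_dir) / f"{type_name}.ndjson"
    if not path.exists():
        return []
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(json.loads(line))
    return out


def gender_counts(fixture_dir):
    c = Counter()
    for p in _load(fixture_dir, "Patient"):
        c[p.get("gender", "unknown") or "unknown"] += 1
    return dict(c)


def birth_year_counts(fixture_dir, start=1950, end=2021):
    c = Counter()
    for p in _load(fixture_dir, "Patient"):
        bd = p.get("birthDate")
        if isinstance(bd, str) and len(bd) >= 4:
            year = int(bd[:4])
            if start <= year <= end:
                c[str(year)] += 1
    return dict(c)


def allergy_patient_counts(fixture_dir):
    patients_per_label = {}
    for a in _load(fixture_dir, "AllergyIntolerance"):
        label = a["code"]["coding"][0]["display"]
        ref = a["patient"]["reference"]
        patients_per_label.setdefault(label, set()).add(ref)
    return {label: len(refs) for label, refs in patients_per_label.items()}


def test_label_counts(fixture_dir):
    c = Counter()
    for sr in _load(fixture_dir, "ServiceRequest"):
        c[sr["code"]["coding"][0]["display"]] += 1
    return dict(c)


def order_year_counts(fixture_dir, start=1950, end=2021):
    c = Counter()
    for sr in _load(fixture_dir, "ServiceRequest"):
        authored = sr.get("authoredOn")
        if isinstance(authored, str) and len(authored) >= 4:
            year = int(authored[:4])
            if start <= year <= end:
                c[str(year)] += 1
    return dict(c)


def resource_counts(fixture_dir):
    return {
        t: len(_load(fixture_dir, t))
        for t in (
            "Patient",
            "AllergyIntolerance",
            "Practitioner",
            "Condition",
            "ServiceRequest",
            "DiagnosticReport",
            "Appointment",
        )
    }
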