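"""Deterministic synthetic FHIR stores and in-process mock servers.

This module makes every other part of skiff testable offline.  It provides:

* :func:`generate_cohort` — a seeded generator producing a referentially
  consistent store of Patients, Conditions (ICD-10 coded, e.g. C50 breast
  cancer / C78.0 pulmonary metastases), Observations (LOINC-coded receptor
  markers, TNM staging, component-bearing blood-pressure panels),
  DiagnosticReports (base64-encoded free text with planted positive /
  excluded sentences), and ImagingStudies backed by a planted DICOM
  instance store.
* :class:`MockFhirServer` / :class:`MockDicomWeb` — request handlers that
  speak enough of the FHIR search API (token / date / reference parameters,
  ``_count`` paging with next links, ``_include``, ``_history``) and of
  QIDO-RS/WADO-RS to exercise the real client code paths.  They run
  in-process through :class:`InProcessTransport` (no sockets) and can also
  be mounted on a real local HTTP server via :func:`mount_http`.
* :func:`example_results_pipeline` — an end-to-end cohort build: patients
  carrying both ICD codes, demographics, four LOINC observations restricted
  to ±30 days around the metastasis diagnosis, and thorax CT studies under
  the same window, merged into one table.

Identical (config, seed) always yields a byte-identical store.
"""

from __future__ import annotations

import base64
import copy
import datetime
import hashlib
import io
import json
import random
import threading
import urllib.parse
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SkiffError, TransportError
from .session import Transport, TransportResponse

ICD10 = "http://hl7.org/fhir/sid/icd-10"
LOINC = "http://loinc.org"
DCM = "http://dicom.nema.org/resources/ontology/DCM"

UID_ROOT = "1.2.826.0.1.3680043.10.1405"


class UnsupportedParameterError(SkiffError):
    """A search parameter the mock server does not index (maps to HTTP 400)."""


# ---------------------------------------------------------------------------
# Configuration


def _draw(rng: random.Random, spec) -> int:
    """Draw from an integer distribution spec: ('fixed', k),
    ('uniform_int', lo, hi) or ('poisson', lam)."""
    kind = spec[0]
    if kind == "fixed":
        return int(spec[1])
    if kind == "uniform_int":
        return rng.randint(int(spec[1]), int(spec[2]))
    if kind == "poisson":
        # Knuth's method; lambda is tiny here.
        lam = float(spec[1])
        limit = pow(2.718281828459045, -lam)
        k, p = 0, 1.0
        while True:
            p *= rng.random()
            if p <= limit:
                return k
            k += 1
    raise SkiffError(f"unknown distribution spec {spec!r}")


DEFAULT_CONDITION_CODES = [
    (ICD10, "C50", 0.6),    # breast cancer
    (ICD10, "C78.0", 0.5),  # pulmonary metastases
]

DEFAULT_OBSERVATION_CODES = [
    (LOINC, "16112-5", ("coded", ["Positive", "Negative"])),  # ER
    (LOINC, "16113-3", ("coded", ["Positive", "Negative"])),  # PR
    (LOINC, "48676-1", ("coded", ["Positive", "Negative"])),  # HER-2
    (LOINC, "21908-9", ("string", ["T1 N0 M0", "T2 N1 M0", "T3 N1 M1", "T4 N2 M1"])),
]


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort generator.

    Defaults emulate a metastatic-breast-cancer cohort: two ICD-10 condition
    codes whose joint carriers form the cohort, the four LOINC observation
    codes (ER / PR / HER-2 receptor status and TNM stage), one year of
    activity, a modest imaging and document volume per patient, and roughly
    one positive (pattern-bearing) document in three.
    """

    n_patients: int = 40
    seed: int = 0
    condition_codes: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_CONDITION_CODES)
    )
    observation_codes: list[tuple[str, str, tuple]] = field(
        default_factory=lambda: list(DEFAULT_OBSERVATION_CODES)
    )
    date_range: tuple[datetime.date, datetime.date] = (
        datetime.date(2020, 1, 1),
        datetime.date(2021, 1, 1),
    )
    studies_per_patient: tuple = ("uniform_int", 0, 2)
    docs_per_patient: tuple = ("uniform_int", 1, 3)
    positive_doc_fraction: float = 0.3
    blood_pressure_fraction: float = 0.5

    def __post_init__(self) -> None:
        for _, code, prevalence in self.condition_codes:
            if not 0.0 <= prevalence <= 1.0:
                raise SkiffError(f"prevalence for {code} outside [0, 1]: {prevalence}")
        for frac_name in ("positive_doc_fraction", "blood_pressure_fraction"):
            value = getattr(self, frac_name)
            if not 0.0 <= value <= 1.0:
                raise SkiffError(f"{frac_name} outside [0, 1]: {value}")
        if self.n_patients < 0:
            raise SkiffError("n_patients must be >= 0")
        if self.date_range[0] >= self.date_range[1]:
            raise SkiffError("date_range must be a non-empty half-open interval")


# ---------------------------------------------------------------------------
# Resource store


@dataclass
class ResourceStore:
    """All generated resources plus version history and the DICOM listing.

    ``dicom`` maps study UID → series UID → ordered SOP instance UIDs; the
    actual part-10 instances are rebuilt deterministically on demand from the
    UIDs, so a saved store is plain text.
    """

    resources: dict[str, list[dict]] = field(default_factory=dict)
    versions: dict[tuple[str, str], list[dict]] = field(default_factory=dict)
    dicom: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    doc_labels: dict[str, str] = field(default_factory=dict)

    def add(self, resource: dict) -> None:
        self.resources.setdefault(resource["resourceType"], []).append(resource)

    def all(self, resource_type: str) -> list[dict]:
        return self.resources.get(resource_type, [])

    def get(self, resource_type: str, resource_id: str) -> dict | None:
        for resource in self.all(resource_type):
            if resource.get("id") == resource_id:
                return resource
        return None

    def patient_ids(self) -> list[str]:
        return [p["id"] for p in self.all("Patient")]

    def history(self, resource_type: str, resource_id: str) -> list[dict] | None:
        """Versions of one resource, newest first; None if unknown."""
        planted = self.versions.get((resource_type, resource_id))
        if planted is not None:
            return planted
        current = self.get(resource_type, resource_id)
        return None if current is None else [current]

    def build_instance(self, study_uid: str, series_uid: str, sop_uid: str):
        """Deterministically rebuild one minimal valid part-10 CT instance."""
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = int(sop_uid.rsplit(".", 1)[-1]) if "." in sop_uid else 1
        ds.Rows = 4
        ds.Columns = 4
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = hashlib.sha256(sop_uid.encode()).digest()  # 32 B = 4x4x2
        return ds

    def instance_bytes(self, study_uid: str, series_uid: str, sop_uid: str) -> bytes:
        import pydicom

        buffer = io.BytesIO()
        ds = self.build_instance(study_uid, series_uid, sop_uid)
        pydicom.dcmwrite(buffer, ds, enforce_file_format=True)
        return buffer.getvalue()

    def check_integrity(self) -> None:
        """Exhaustive referential-integrity check; raises on any violation."""
        patients = set(self.patient_ids())
        for rtype in ("Condition", "Observation", "DiagnosticReport", "ImagingStudy"):
            for resource in self.all(rtype):
                ref = resource.get("subject", {}).get("reference", "")
                if not ref.startswith("Patient/") or ref[len("Patient/"):] not in patients:
                    raise SkiffError(
                        f"{rtype}/{resource.get('id')} references unknown {ref!r}"
                    )
        for study in self.all("ImagingStudy"):
            uid = study_uid_of(study)
            if uid not in self.dicom:
                raise SkiffError(
                    f"ImagingStudy/{study.get('id')} study UID {uid} not in DICOM store"
                )

    # -- text persistence (newline-delimited JSON per resource type) -------

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for rtype in sorted(self.resources):
            with open(directory / f"{rtype}.ndjson", "w", encoding="utf-8") as fh:
                for resource in self.resources[rtype]:
                    fh.write(json.dumps(resource, sort_keys=True) + "\n")
        with open(directory / "versions.json", "w", encoding="utf-8") as fh:
            serializable = {f"{t}/{i}": v for (t, i), v in self.versions.items()}
            json.dump(serializable, fh, sort_keys=True, indent=1)
        with open(directory / "dicom.json", "w", encoding="utf-8") as fh:
            json.dump(self.dicom, fh, sort_keys=True, indent=1)
        with open(directory / "doc_labels.json", "w", encoding="utf-8") as fh:
            json.dump(self.doc_labels, fh, sort_keys=True, indent=1)
        return directory

    @classmethod
    def load(cls, directory) -> "ResourceStore":
        directory = Path(directory)
        store = cls()
        for path in sorted(directory.glob("*.ndjson")):
            rtype = path.stem
            with open(path, encoding="utf-8") as fh:
                store.resources[rtype] = [json.loads(line) for line in fh if line.strip()]
        versions_path = directory / "versions.json"
        if versions_path.exists():
            raw = json.loads(versions_path.read_text())
            store.versions = {
                tuple(key.split("/", 1)): value for key, value in raw.items()
            }
        dicom_path = directory / "dicom.json"
        if dicom_path.exists():
            store.dicom = json.loads(dicom_path.read_text())
        labels_path = directory / "doc_labels.json"
        if labels_path.exists():
            store.doc_labels = json.loads(labels_path.read_text())
        return store


def study_uid_of(study: dict) -> str | None:
    for identifier in study.get("identifier", []):
        value = identifier.get("value", "")
        if value.startswith("urn:oid:"):
            return value[len("urn:oid:"):]
        if value:
            return value
    return None


# ---------------------------------------------------------------------------
# Generator

_FILLER_SENTENCES = [
    "The lungs are clear without focal consolidation.",
    "Heart size is within normal limits.",
    "No pleural effusion is identified.",
    "Degenerative changes are noted in the thoracic spine.",
    "The visualized upper abdomen is unremarkable.",
    "No acute osseous abnormality is seen.",
]

_POSITIVE_SENTENCE = "There is evidence of sarcoma in the left lower lobe."
_EXCLUDED_SENTENCE = "Findings are compatible with the known osteosarcoma."


def _iso(day: datetime.date) -> str:
    return day.isoformat()


def _random_date(rng: random.Random, start: datetime.date, end: datetime.date) -> datetime.date:
    return start + datetime.timedelta(days=rng.randrange((end - start).days))


def generate_cohort(config: CohortConfig | None = None) -> ResourceStore:
    """Generate a referentially consistent store from ``config``.

    Deterministic: the same (config, seed) yields a byte-identical store.
    """
    config = config or CohortConfig()
    rng = random.Random(config.seed)
    store = ResourceStore()
    start, end = config.date_range

    # Patients -------------------------------------------------------------
    for i in range(config.n_patients):
        pid = f"pat-{i:03d}"
        birth = datetime.date(1930 + rng.randrange(60), rng.randrange(1, 13), rng.randrange(1, 29))
        patient = {
            "resourceType": "Patient",
            "id": pid,
            "gender": "female" if rng.random() < 0.85 else "male",
            "birthDate": _iso(birth),
            "name": [{"family": f"Synth{i:03d}", "given": ["Case"]}],
        }
        store.add(patient)

    patient_ids = store.patient_ids()

    # Conditions -----------------------------------------------------------
    carriers: dict[str, set[str]] = {}
    onsets: dict[tuple[str, str], datetime.date] = {}
    cond_n = 0
    for system, code, prevalence in config.condition_codes:
        carriers[code] = set()
        for pid in patient_ids:
            if rng.random() >= prevalence:
                continue
            carriers[code].add(pid)
            onset = _random_date(rng, start, end)
            onsets[(pid, code)] = onset
            store.add(
                {
                    "resourceType": "Condition",
                    "id": f"cond-{cond_n:04d}",
                    "code": {"coding": [{"system": system, "code": code}]},
                    "subject": {"reference": f"Patient/{pid}"},
                    "onsetDateTime": _iso(onset),
                }
            )
            cond_n += 1

    # Vital status: deaths always postdate every recorded diagnosis so the
    # survival times the example pipeline derives are non-negative.
    for patient in store.all("Patient"):
        if rng.random() >= 0.3:
            continue
        patient_onsets = [
            day for (pid, _), day in onsets.items() if pid == patient["id"]
        ]
        anchor = max(patient_onsets) if patient_onsets else _random_date(rng, start, end)
        died = anchor + datetime.timedelta(days=rng.randint(30, 500))
        patient["deceasedDateTime"] = _iso(died)

    cohort_codes = [code for _, code, _ in config.condition_codes[:2]]
    cohort = set(patient_ids)
    for code in cohort_codes:
        cohort &= carriers.get(code, set())
    metastasis_code = cohort_codes[-1] if cohort_codes else None

    # Observations ---------------------------------------------------------
    obs_n = 0

    def add_observation(pid: str, system: str, code: str, value_spec, day: datetime.date):
        nonlocal obs_n
        obs: dict = {
            "resourceType": "Observation",
            "id": f"obs-{obs_n:04d}",
            "status": "final",
            "code": {"coding": [{"system": system, "code": code}]},
            "subject": {"reference": f"Patient/{pid}"},
            "effectiveDateTime": _iso(day),
        }
        kind = value_spec[0]
        if kind == "coded":
            obs["valueCodeableConcept"] = {"text": rng.choice(value_spec[1])}
        elif kind == "string":
            obs["valueString"] = rng.choice(value_spec[1])
        elif kind == "quantity":
            lo, hi, unit = value_spec[1], value_spec[2], value_spec[3]
            obs["valueQuantity"] = {"value": rng.randint(lo, hi), "unit": unit}
        else:
            raise SkiffError(f"unknown observation value spec {value_spec!r}")
        store.add(obs)
        obs_n += 1

    for pid in patient_ids:
        in_cohort = pid in cohort
        anchor = onsets.get((pid, metastasis_code)) if metastasis_code else None
        for system, code, value_spec in config.observation_codes:
            if in_cohort and anchor is not None:
                day = anchor + datetime.timedelta(days=rng.randint(-45, 45))
                add_observation(pid, system, code, value_spec, day)
            elif rng.random() < 0.3:
                add_observation(pid, system, code, value_spec, _random_date(rng, start, end))

    # Blood-pressure panels with components (for column-per-component runs)
    for pid in patient_ids:
        if rng.random() >= config.blood_pressure_fraction:
            continue
        store.add(
            {
                "resourceType": "Observation",
                "id": f"obs-{obs_n:04d}",
                "status": "final",
                "code": {"coding": [{"system": LOINC, "code": "85354-9"}]},
                "subject": {"reference": f"Patient/{pid}"},
                "effectiveDateTime": _iso(_random_date(rng, start, end)),
                "component": [
                    {
                        "code": {
                            "coding": [{"system": LOINC, "code": "8480-6"}],
                            "text": "Systolic blood pressure",
                        },
                        "valueQuantity": {"value": rng.randint(100, 180), "unit": "mmHg"},
                    },
                    {
                        "code": {
                            "coding": [{"system": LOINC, "code": "8462-4"}],
                            "text": "Diastolic blood pressure",
                        },
                        "valueQuantity": {"value": rng.randint(60, 110), "unit": "mmHg"},
                    },
                ],
            }
        )
        obs_n += 1

    # DiagnosticReports with planted text ----------------------------------
    doc_n = 0
    for pid in patient_ids:
        for _ in range(_draw(rng, config.docs_per_patient)):
            body = rng.sample(_FILLER_SENTENCES, k=3)
            roll = rng.random()
            if roll < config.positive_doc_fraction:
                label = "positive"
                body.insert(rng.randrange(len(body) + 1), _POSITIVE_SENTENCE)
            elif roll < config.positive_doc_fraction + 0.2:
                label = "excluded"
                body.insert(rng.randrange(len(body) + 1), _EXCLUDED_SENTENCE)
            else:
                label = "negative"
            text = (
                "Clinical information: outpatient follow-up examination. "
                "Findings: " + " ".join(body)
            )
            report_id = f"doc-{doc_n:04d}"
            store.add(
                {
                    "resourceType": "DiagnosticReport",
                    "id": report_id,
                    "status": "final",
                    "code": {"coding": [{"system": LOINC, "code": "18748-4"}]},
                    "subject": {"reference": f"Patient/{pid}"},
                    "effectiveDateTime": _iso(_random_date(rng, start, end)),
                    "presentedForm": [
                        {
                            "contentType": "text/plain",
                            "data": base64.b64encode(text.encode()).decode(),
                        }
                    ],
                }
            )
            store.doc_labels[report_id] = label
            doc_n += 1

    # ImagingStudies + DICOM listing ---------------------------------------
    img_n = 0
    for pid in patient_ids:
        n_studies = _draw(rng, config.studies_per_patient)
        in_cohort = pid in cohort
        anchor = onsets.get((pid, metastasis_code)) if metastasis_code else None
        if in_cohort and n_studies == 0:
            n_studies = 1  # the example cohort always has imaging to fetch
        for k in range(n_studies):
            if in_cohort and anchor is not None and k == 0:
                started = anchor + datetime.timedelta(days=rng.randint(-20, 20))
            else:
                started = _random_date(rng, start, end)
            study_uid = f"{UID_ROOT}.{config.seed}.{img_n + 1}"
            series_map: dict[str, list[str]] = {}
            series_entries = []
            for s in range(1, rng.randint(1, 3) + 1):
                series_uid = f"{study_uid}.{s}"
                sops = [f"{series_uid}.{j}" for j in range(1, rng.randint(1, 3) + 1)]
                series_map[series_uid] = sops
                series_entries.append(
                    {
                        "uid": series_uid,
                        "number": s,
                        "modality": {"system": DCM, "code": "CT"},
                        "numberOfInstances": len(sops),
                    }
                )
            store.dicom[study_uid] = series_map
            store.add(
                {
                    "resourceType": "ImagingStudy",
                    "id": f"img-{img_n:04d}",
                    "identifier": [{"system": "urn:dicom:uid", "value": f"urn:oid:{study_uid}"}],
                    "status": "available",
                    "subject": {"reference": f"Patient/{pid}"},
                    "started": _iso(started),
                    "modality": [{"system": DCM, "code": "CT"}],
                    "description": "CT Thorax",
                    "numberOfSeries": len(series_entries),
                    "numberOfInstances": sum(len(v) for v in series_map.values()),
                    "series": series_entries,
                }
            )
            img_n += 1

    # Planted version history on the first two patients ---------------------
    for patient in store.all("Patient")[:2]:
        current = copy.deepcopy(patient)
        current.setdefault("meta", {})["versionId"] = "2"
        older = copy.deepcopy(patient)
        older.setdefault("meta", {})["versionId"] = "1"
        older["name"] = [{"family": "Unlinked", "given": ["Record"]}]
        patient.setdefault("meta", {})["versionId"] = "2"
        store.versions[("Patient", patient["id"])] = [current, older]

    return store


def scattered_observation_store(
    dates: Sequence[datetime.date | str],
    code: str = "94531-1",
) -> ResourceStore:
    """A minimal store with one patient and one Observation per given date.

    Useful for exercising time partitioning with exact (e.g. boundary) dates.
    """
    store = ResourceStore()
    store.add({"resourceType": "Patient", "id": "pat-000", "gender": "female"})
    for i, day in enumerate(dates):
        day_iso = day if isinstance(day, str) else day.isoformat()
        store.add(
            {
                "resourceType": "Observation",
                "id": f"obs-{i:04d}",
                "status": "final",
                "code": {"coding": [{"system": LOINC, "code": code}]},
                "subject": {"reference": "Patient/pat-000"},
                "effectiveDateTime": day_iso,
            }
        )
    return store


# ---------------------------------------------------------------------------
# Search semantics

_CONTROL_PARAMS = {"_count", "_page", "_include"}

_TOKEN_FIELDS = {
    ("Condition", "code"): "code",
    ("Observation", "code"): "code",
    ("DiagnosticReport", "code"): "code",
}

_DATE_FIELDS = {
    ("Observation", "date"): "effectiveDateTime",
    ("DiagnosticReport", "date"): "effectiveDateTime",
    ("Condition", "onset-date"): "onsetDateTime",
    ("ImagingStudy", "started"): "started",
    ("Patient", "birthdate"): "birthDate",
    ("Patient", "death-date"): "deceasedDateTime",
}

_REFERENCE_PARAMS = {"subject", "patient"}
_DATE_PREFIXES = ("ge", "gt", "le", "lt", "eq")


def _token_matches(codings: Iterable[dict], value: str) -> bool:
    if "|" in value:
        system, code = value.split("|", 1)
        return any(
            c.get("system") == system and c.get("code") == code for c in codings
        )
    return any(c.get("code") == value for c in codings)


def _date_matches(raw: str | None, value: str) -> bool:
    if not raw:
        return False
    prefix = value[:2] if value[:2] in _DATE_PREFIXES else "eq"
    literal = value[2:] if value[:2] in _DATE_PREFIXES else value
    try:
        actual = datetime.date.fromisoformat(raw[:10])
        bound = datetime.date.fromisoformat(literal[:10])
    except ValueError:
        return False
    if prefix == "ge":
        return actual >= bound
    if prefix == "gt":
        return actual > bound
    if prefix == "le":
        return actual <= bound
    if prefix == "lt":
        return actual < bound
    return actual == bound


def _param_matches(resource_type: str, resource: dict, key: str, value: str) -> bool:
    if key == "_id":
        return resource.get("id") == value
    if (resource_type, key) in _TOKEN_FIELDS:
        fld = _TOKEN_FIELDS[(resource_type, key)]
        return _token_matches(resource.get(fld, {}).get("coding", []), value)
    if resource_type == "Patient" and key == "gender":
        return resource.get("gender") == value
    if resource_type == "ImagingStudy" and key == "modality":
        return _token_matches(resource.get("modality", []), value)
    if (resource_type, key) in _DATE_FIELDS:
        return _date_matches(resource.get(_DATE_FIELDS[(resource_type, key)]), value)
    if key in _REFERENCE_PARAMS:
        ref = resource.get("subject", {}).get("reference")
        return ref == value or ref == f"Patient/{value}"
    raise UnsupportedParameterError(
        f"search parameter {key!r} is not supported for {resource_type}"
    )


def _filter_store(
    store: ResourceStore,
    resource_type: str,
    pairs: Sequence[tuple[str, str]],
    lenient: bool,
) -> list[dict]:
    matches = sorted(store.all(resource_type), key=lambda r: r.get("id", ""))
    for key, value in pairs:
        if key in _CONTROL_PARAMS:
            continue
        try:
            matches = [
                r for r in matches if _param_matches(resource_type, r, key, value)
            ]
        except UnsupportedParameterError:
            if not lenient:
                raise
    return matches


def mock_search(
    store: ResourceStore,
    query,
    page_token: str | int | None = None,
    base_url: str = "http://mock.local/fhir",
    lenient: bool = False,
) -> dict:
    """One page of search results as a FHIR searchset Bundle.

    Supports token (``code=C50`` / ``code=system|code``), date-prefixed
    (ge/gt/le/lt), and reference (``subject=Patient/<id>``) parameters,
    ``_count`` paging with next links, and ``_include`` of referenced
    Patients.  Match order is deterministic (sorted by id).
    """
    pairs = query.pairs()
    rtype = query.resource_type
    matches = _filter_store(store, rtype, pairs, lenient)
    offset = int(page_token or 0)
    count = query.page_size
    page = matches[offset : offset + count]

    entries = [
        {
            "fullUrl": f"{base_url}/{rtype}/{r.get('id')}",
            "resource": r,
            "search": {"mode": "match"},
        }
        for r in page
    ]
    include_targets = [v for k, v in pairs if k == "_include"]
    if include_targets:
        seen: list[str] = []
        for resource in page:
            ref = resource.get("subject", {}).get("reference", "")
            if ref.startswith("Patient/") and ref not in seen:
                seen.append(ref)
        for ref in seen:
            patient = store.get("Patient", ref[len("Patient/"):])
            if patient is not None:
                entries.append(
                    {
                        "fullUrl": f"{base_url}/{ref}",
                        "resource": patient,
                        "search": {"mode": "include"},
                    }
                )

    self_qs = urllib.parse.urlencode(pairs + [("_page", str(offset))])
    links = [{"relation": "self", "url": f"{base_url}/{rtype}?{self_qs}"}]
    if offset + count < len(matches):
        next_qs = urllib.parse.urlencode(pairs + [("_page", str(offset + count))])
        links.append({"relation": "next", "url": f"{base_url}/{rtype}?{next_qs}"})
    return {
        "resourceType": "Bundle",
        "type": "searchset",
        "total": len(matches),
        "link": links,
        "entry": entries,
    }


# ---------------------------------------------------------------------------
# In-process servers and transport


def _json_response(status: int, payload) -> tuple[int, dict, bytes]:
    return (
        status,
        {"Content-Type": "application/fhir+json"},
        json.dumps(payload).encode("utf-8"),
    )


def _error_response(status: int, message: str) -> tuple[int, dict, bytes]:
    outcome = {
        "resourceType": "OperationOutcome",
        "issue": [{"severity": "error", "diagnostics": message}],
    }
    return _json_response(status, outcome)


class MockFhirServer:
    """In-process FHIR endpoint over a :class:`ResourceStore`.

    Handles search (with paging, ``_include``, ``_history``), resource reads,
    and a token endpoint (``POST {base}/token`` form exchange, ``POST
    {base}/token/refresh`` bearer rotation).  Failure scripting: statuses
    pushed onto ``fail_queue`` are served (and consumed) before real
    handling; ``reject_refresh`` forces the refresh route to 401 so clients
    must fall back to reauthentication.
    """

    def __init__(
        self,
        store: ResourceStore,
        base_url: str = "http://mock.local/fhir",
        require_auth: str | None = None,
        username: str = "user",
        password: str = "pass",
        lenient: bool = False,
    ):
        self.store = store
        self.base_url = base_url.rstrip("/")
        self.require_auth = require_auth
        self.username = username
        self.password = password
        self.lenient = lenient
        self.request_log: list[tuple[str, str]] = []
        self.fail_queue: list[int] = []
        self.reject_refresh = False
        self.valid_tokens: set[str] = set()
        self._token_counter = 0

    # -- token lifecycle ---------------------------------------------------

    def _new_token(self) -> str:
        self._token_counter += 1
        token = f"tok-{self._token_counter:04d}"
        self.valid_tokens = {token}  # rotation invalidates older tokens
        return token

    def _issue_token(self, body: bytes | None) -> tuple[int, dict, bytes]:
        form = dict(urllib.parse.parse_qsl((body or b"").decode("utf-8")))
        if form.get("username") != self.username or form.get("password") != self.password:
            return _error_response(401, "invalid credentials")
        return _json_response(200, {"access_token": self._new_token(), "expires_in": 300})

    def _refresh_token(self, headers: Mapping[str, str]) -> tuple[int, dict, bytes]:
        presented = _bearer_of(headers)
        if self.reject_refresh or presented not in self.valid_tokens:
            return _error_response(401, "refresh rejected")
        return _json_response(200, {"access_token": self._new_token(), "expires_in": 300})

    def _authorized(self, headers: Mapping[str, str]) -> bool:
        if self.require_auth is None:
            return True
        auth = _header(headers, "Authorization")
        if self.require_auth == "token":
            return _bearer_of(headers) in self.valid_tokens
        if self.require_auth == "basic":
            expected = base64.b64encode(
                f"{self.username}:{self.password}".encode()
            ).decode()
            return auth == f"Basic {expected}"
        return False

    # -- request handling --------------------------------------------------

    def handles(self, url: str) -> bool:
        return url == self.base_url or url.startswith(self.base_url + "/") or url.startswith(
            self.base_url + "?"
        )

    def handle(
        self,
        method: str,
        url: str,
        headers: Mapping[str, str] | None = None,
        body: bytes | None = None,
    ) -> tuple[int, dict, bytes]:
        headers = headers or {}
        self.request_log.append((method, url))
        parsed = urllib.parse.urlparse(url)
        base_path = urllib.parse.urlparse(self.base_url).path
        if not parsed.path.startswith(base_path):
            return _error_response(404, f"not under {base_path}")
        parts = [p for p in parsed.path[len(base_path):].split("/") if p]
        pairs = urllib.parse.parse_qsl(parsed.query, keep_blank_values=True)

        if parts == ["token"]:
            if method != "POST":
                return _error_response(405, "POST required")
            return self._issue_token(body)
        if parts == ["token", "refresh"]:
            if method != "POST":
                return _error_response(405, "POST required")
            return self._refresh_token(headers)
        if not self._authorized(headers):
            return _error_response(401, "unauthorized")
        if self.fail_queue:
            status = self.fail_queue.pop(0)
            return _error_response(status, "scripted failure")

        if method != "GET":
            return _error_response(405, "read-only mock")
        if len(parts) == 1:
            return self._search(parts[0], pairs)
        if len(parts) == 2:
            resource = self.store.get(parts[0], parts[1])
            if resource is None:
                return _error_response(404, f"{parts[0]}/{parts[1]} not found")
            return _json_response(200, resource)
        if len(parts) == 3 and parts[2] == "_history":
            return self._history(parts[0], parts[1])
        return _error_response(404, "unknown route")

    def _search(self, resource_type: str, pairs) -> tuple[int, dict, bytes]:
        from .query import SearchQuery

        count = 100
        offset = 0
        params: dict[str, list[str]] = {}
        for key, value in pairs:
            if key == "_count":
                count = max(1, int(value))
            elif key == "_page":
                offset = int(value)
            else:
                params.setdefault(key, []).append(value)
        query = SearchQuery(resource_type, params, page_size=count)
        try:
            bundle = mock_search(
                self.store,
                query,
                page_token=offset,
                base_url=self.base_url,
                lenient=self.lenient,
            )
        except UnsupportedParameterError as exc:
            return _error_response(400, str(exc))
        return _json_response(200, bundle)

    def _history(self, resource_type: str, resource_id: str):
        versions = self.store.history(resource_type, resource_id)
        if versions is None:
            return _error_response(404, f"{resource_type}/{resource_id} not found")
        bundle = {
            "resourceType": "Bundle",
            "type": "history",
            "total": len(versions),
            "entry": [
                {
                    "fullUrl": f"{self.base_url}/{resource_type}/{resource_id}",
                    "resource": version,
                }
                for version in versions
            ],
        }
        return _json_response(200, bundle)


class MockDicomWeb:
    """In-process DICOMweb endpoint (QIDO-RS listings, WADO-RS instances).

    ``transport_faults`` maps a series UID to ``'transport'`` (simulated
    connection drop while fetching its instances) or ``'not_found'``.
    """

    def __init__(self, store: ResourceStore, base_url: str = "http://mock.local/dicomweb"):
        self.store = store
        self.base_url = base_url.rstrip("/")
        self.transport_faults: dict[str, str] = {}
        self.request_log: list[tuple[str, str]] = []

    def handles(self, url: str) -> bool:
        return url == self.base_url or url.startswith(self.base_url + "/")

    def handle(self, method, url, headers=None, body=None):
        self.request_log.append((method, url))
        parsed = urllib.parse.urlparse(url)
        base_path = urllib.parse.urlparse(self.base_url).path
        parts = [p for p in parsed.path[len(base_path):].split("/") if p]
        if method != "GET" or not parts or parts[0] != "studies":
            return _error_response(404, "unknown route")
        dicom = self.store.dicom
        if len(parts) == 3 and parts[2] == "series":
            study = parts[1]
            if study not in dicom:
                return _error_response(404, f"study {study} not found")
            payload = [
                {"0020000E": {"vr": "UI", "Value": [series_uid]}}
                for series_uid in sorted(dicom[study])
            ]
            return _json_response(200, payload)
        if len(parts) == 5 and parts[2] == "series" and parts[4] == "instances":
            study, series = parts[1], parts[3]
            self._check_fault(series)
            if study not in dicom or series not in dicom[study]:
                return _error_response(404, f"series {series} not found")
            payload = [
                {"00080018": {"vr": "UI", "Value": [sop]}}
                for sop in dicom[study][series]
            ]
            return _json_response(200, payload)
        if len(parts) == 6 and parts[2] == "series" and parts[4] == "instances":
            study, series, sop = parts[1], parts[3], parts[5]
            self._check_fault(series)
            if (
                study not in dicom
                or series not in dicom[study]
                or sop not in dicom[study][series]
            ):
                return _error_response(404, f"instance {sop} not found")
            data = self.store.instance_bytes(study, series, sop)
            return (200, {"Content-Type": "application/dicom"}, data)
        return _error_response(404, "unknown route")

    def _check_fault(self, series_uid: str) -> None:
        fault = self.transport_faults.get(series_uid)
        if fault == "transport":
            raise TransportError(f"scripted connection drop for series {series_uid}")


class InProcessTransport(Transport):
    """Routes requests to in-process mock apps; no sockets involved."""

    def __init__(self, *apps):
        self.apps = list(apps)

    def request(self, method, url, headers=None, body=None, timeout=30.0):
        for app in self.apps:
            if app.handles(url):
                status, resp_headers, data = app.handle(method, url, headers, body)
                return TransportResponse(status, resp_headers, data)
        return TransportResponse(404, {}, b'{"error": "no mock app mounted here"}')


def _header(headers: Mapping[str, str], name: str) -> str | None:
    for key, value in headers.items():
        if key.lower() == name.lower():
            return value
    return None


def _bearer_of(headers: Mapping[str, str]) -> str | None:
    auth = _header(headers, "Authorization") or ""
    return auth[len("Bearer "):] if auth.startswith("Bearer ") else None


@contextmanager
def mount_http(*apps):
    """Serve mock apps on a real localhost HTTP server.

    Each app's ``base_url`` is rewritten to the bound address (its path
    prefix is preserved); the original is restored on exit.  Yields the
    ``http://127.0.0.1:<port>`` root.
    """
    from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

    class Handler(BaseHTTPRequestHandler):
        def _dispatch(self):
            host = self.server.server_address
            url = f"http://127.0.0.1:{host[1]}{self.path}"
            length = int(self.headers.get("Content-Length") or 0)
            body = self.rfile.read(length) if length else None
            for app in apps:
                if app.handles(url):
                    try:
                        status, headers, data = app.handle(
                            self.command, url, dict(self.headers), body
                        )
                    except TransportError:
                        self.connection.close()
                        return
                    self.send_response(status)
                    for key, value in headers.items():
                        self.send_header(key, value)
                    self.send_header("Content-Length", str(len(data)))
                    self.end_headers()
                    self.wfile.write(data)
                    return
            self.send_response(404)
            self.end_headers()

        do_GET = _dispatch
        do_POST = _dispatch

        def log_message(self, *args):  # silence stderr chatter
            pass

    server = ThreadingHTTPServer(("127.0.0.1", 0), Handler)
    port = server.server_address[1]
    originals = [app.base_url for app in apps]
    for app in apps:
        prefix = urllib.parse.urlparse(app.base_url).path
        app.base_url = f"http://127.0.0.1:{port}{prefix}"
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    try:
        yield f"http://127.0.0.1:{port}"
    finally:
        server.shutdown()
        server.server_close()
        for app, original in zip(apps, originals):
            app.base_url = original


# ---------------------------------------------------------------------------
# End-to-end example pipeline


_MARKER_COLUMNS = [
    ("16112-5", "er", "valueCodeableConcept.text"),
    ("16113-3", "pr", "valueCodeableConcept.text"),
    ("48676-1", "her2", "valueCodeableConcept.text"),
    ("21908-9", "tnm", "valueString"),
]

OBSERVATION_WINDOW_DAYS = 30


def example_results_pipeline(store: ResourceStore, session, n_procs: int = 1) -> pd.DataFrame:
    """Build the metastatic-breast-cancer cohort table end to end.

    Steps: (1) patients carrying both the C50 and C78.0 Conditions;
    (2) demographics and death dates; (3) the four LOINC observations
    restricted to at most ±30 days around the metastasis diagnosis;
    (4) thorax CT ImagingStudies under the same window.  All merged into one
    row per patient, sorted by patient id.  Deterministic for any
    ``n_procs``.
    """
    from .query import SearchQuery, steal_bundles_to_dataframe, trade_rows_for_dataframe
    from .tabulator import ExtractionSpec

    cond_spec = ExtractionSpec.paths(
        [
            ("patient_id", "subject.reference.replace('Patient/', '')"),
            ("onset", "onsetDateTime"),
        ]
    )
    c50 = steal_bundles_to_dataframe(
        session, SearchQuery("Condition", {"code": "C50"}), cond_spec
    )
    c78 = steal_bundles_to_dataframe(
        session, SearchQuery("Condition", {"code": "C78.0"}), cond_spec
    )
    cohort_ids = sorted(set(c50["patient_id"]) & set(c78["patient_id"]))
    onset_by_patient = (
        c78[c78["patient_id"].isin(cohort_ids)].groupby("patient_id")["onset"].min()
        if cohort_ids
        else pd.Series(dtype=object)
    )
    cohort = pd.DataFrame(
        {
            "patient_id": cohort_ids,
            "metastasis_date": [onset_by_patient[pid] for pid in cohort_ids],
        },
        dtype=object,
    )
    window = datetime.timedelta(days=OBSERVATION_WINDOW_DAYS)
    cohort["date_ge"] = [
        "ge" + (datetime.date.fromisoformat(d[:10]) - window).isoformat()
        for d in cohort["metastasis_date"]
    ]
    cohort["date_le"] = [
        "le" + (datetime.date.fromisoformat(d[:10]) + window).isoformat()
        for d in cohort["metastasis_date"]
    ]

    demographics = trade_rows_for_dataframe(
        session,
        cohort,
        SearchQuery("Patient"),
        {"patient_id": "_id"},
        ExtractionSpec.paths(
            [
                ("gender", "gender"),
                ("birth_date", "birthDate"),
                ("death_date", "deceasedDateTime"),
            ]
        ),
        n_procs=n_procs,
        with_columns=["patient_id"],
    )
    cohort = cohort.merge(demographics, on="patient_id", how="left")

    for loinc_code, column, value_path in _MARKER_COLUMNS:
        observations = trade_rows_for_dataframe(
            session,
            cohort,
            SearchQuery("Observation", {"code": f"{LOINC}|{loinc_code}"}),
            {
                "patient_id": ("subject", None),
                "date_ge": ("date", None),
                "date_le": ("date", None),
            },
            ExtractionSpec.paths([(column, value_path)]),
            n_procs=n_procs,
            with_columns=["patient_id"],
        )
        observations = observations.dropna(subset=[column])
        if len(observations):
            first = observations.groupby("patient_id", as_index=False, sort=True).first()
            cohort = cohort.merge(
                first[["patient_id", column]], on="patient_id", how="left"
            )
        else:
            cohort[column] = pd.array([None] * len(cohort), dtype=object)

    studies = trade_rows_for_dataframe(
        session,
        cohort,
        SearchQuery("ImagingStudy", {"modality": "CT"}),
        {
            "patient_id": ("subject", None),
            "date_ge": ("started", None),
            "date_le": ("started", None),
        },
        ExtractionSpec.paths(
            [("study_uid", "identifier.value.replace('urn:oid:', '')")]
        ),
        n_procs=n_procs,
        with_columns=["patient_id"],
    )
    studies = studies.dropna(subset=["study_uid"])
    if len(studies):
        uid_lists = studies.groupby("patient_id", sort=True)["study_uid"].apply(list)
        cohort["study_uids"] = pd.array(
            [uid_lists.get(pid) for pid in cohort["patient_id"]], dtype=object
        )
    else:
        cohort["study_uids"] = pd.array([None] * len(cohort), dtype=object)
    cohort["n_studies_in_window"] = pd.array(
        [len(v) if isinstance(v, list) else 0 for v in cohort["study_uids"]],
        dtype=object,
    )

    cohort = cohort.drop(columns=["date_ge", "date_le"])
    cohort = cohort.sort_values("patient_id", kind="stable").reset_index(drop=True)
    return cohort.astype(object)
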