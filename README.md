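# skiff

FHIR cohort extraction for data science: query FHIR servers with full
search-parameter control, flatten arbitrarily nested resources into pandas
DataFrames via FHIRPath expressions, triage clinical free text with regular
expressions, and bulk-download the DICOM studies a cohort references — with
a deterministic synthetic FHIR/DICOMweb mock so the whole stack runs and is
tested offline.

## The problem

Modern hospitals expose electronic health records through HL7 FHIR: every
entity — a patient, a diagnosis, a lab value, an imaging study, a written
report — is a typed, arbitrarily nested JSON *resource* behind a REST search
API. That shape is excellent for interoperability and poor for analysis,
which wants flat tables. Researchers assembling a study cohort therefore
keep rewriting the same boilerplate: paginate search Bundles, walk nested
JSON, cross-reference patients, grep report text, fetch pixel data from the
PACS. skiff packages that pipeline for people building cohorts and
machine-learning datasets from a FHIR server, while deliberately keeping the
FHIR search vocabulary (token parameters like `code=http://loinc.org|16112-5`,
date prefixes like `date=ge2020-06-01`, `_include`, `_count`) in the user's
hands rather than abstracting it away.

## What is in the box

| module | role |
| --- | --- |
| `skiff.session` | authenticated HTTP context (none / basic / bearer token with proactive + reactive refresh), retrying JSON GET |
| `skiff.query` | the retrieval verbs: `steal_bundles` (one query, full pagination), `sail_through_search_space` (time-partitioned parallel retrieval over disjoint half-open date spans), `trade_rows_for_bundles` (one constrained query per DataFrame row), `request_history`, and their `*_to_dataframe` facades |
| `skiff.fhirpath` | a small FHIRPath engine (member navigation, `[i]`, `where(x = 'lit')`, `exists/empty/count/first`, `replace`, `join`) with collection semantics: every step maps a collection to a collection, lists flatten one level, missing members yield the empty collection |
| `skiff.tabulator` | Bundle → DataFrame: one row per resource, FHIRPath columns or full recursive dumps or per-Bundle processing functions, plus `merge_rows` to consolidate `_include`d resources sharing a key |
| `skiff.miner` | regex triage of documents: header stripping, deterministic sentence segmentation, main/exclusion pattern matching with per-document reports |
| `skiff.dicom` | QIDO-RS/WADO-RS bulk download of the DICOM series referenced by ImagingStudy resources, returning paired success/failure ledgers |
| `skiff.synthetic` | seeded synthetic FHIR + DICOM stores, in-process mock servers (also mountable on localhost HTTP), and an end-to-end example cohort pipeline |

A `skiff` CLI (`query`, `mine`, `download`, `fixtures`) wraps the library
for shell use.

## Worked example

Build a metastatic-breast-cancer cohort against the in-process mock server:
patients carrying both the ICD-10 `C50` (breast cancer) and `C78.0`
(pulmonary metastases) Conditions, their demographics and survival dates,
the ER / PR / HER-2 receptor markers (LOINC 16112-5, 16113-3, 48676-1) and
TNM stage (21908-9) restricted to at most 30 days before or after the
metastasis diagnosis, and the thorax CT studies under the same window:

```python
import skiff

store = skiff.generate_cohort(skiff.CohortConfig(n_patients=40, seed=1))
server = skiff.MockFhirServer(store)
session = skiff.create_session(
    skiff.ServerConfig(base_url=server.base_url),
    transport=skiff.InProcessTransport(server),
)
cohort = skiff.example_results_pipeline(store, session)
print(cohort.head(5).to_string(index=False))
print("cohort size:", len(cohort))
```

```
patient_id metastasis_date gender death_date       er       pr     her2      tnm n_studies_in_window
   pat-000      2020-10-21 female 2021-03-11      NaN Negative Negative T3 N1 M1                   1
   pat-003      2020-06-01 female       None      NaN Positive Positive T2 N1 M0                   1
   pat-010      2020-10-14 female       None      NaN      NaN Positive T3 N1 M1                   1
   pat-012      2020-04-21 female       None Positive Positive Positive T3 N1 M1                   1
   pat-015      2020-12-26 female       None Negative Negative Positive      NaN                   1
cohort size: 11
```

One row per cohort patient. A missing marker cell (`NaN`) means no matching
Observation fell inside the ±30-day window around `metastasis_date` — e.g.
an ER result recorded 31 days after diagnosis is deliberately excluded.
`death_date` is absent for censored patients; `n_studies_in_window` counts
the thorax CT ImagingStudies whose `started` date lies in the window (their
StudyInstanceUIDs, in the `study_uids` column, feed straight into
`skiff.dicom.download_data_from_dataframe`).

The same store can be mined for report text:

```python
import base64, pandas as pd
reports = store.all("DiagnosticReport")
table = pd.DataFrame({"data": [r["presentedForm"][0]["data"] for r in reports]})
config = skiff.MinerConfig(
    main_pattern="sarcoma", exclusion_pattern="osteosarcoma",
    header_keyword="Findings", text_column="data",
    decode_fn=lambda raw: base64.b64decode(raw).decode(),
)
mined = skiff.nlp_on_dataframe(table, config)
```

Sentences mentioning osteosarcoma match the main pattern but are dropped by
the exclusion pattern and counted in `excluded_count`.

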