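"""Turn Bundles into tabular datasets.

The default schema is one row per Bundle entry (one row ≈ one resource).
Three extraction modes are supported:

``fhir_paths``
    Each column is produced by a FHIRPath expression.  An alias may carry
    several candidate paths (useful with resource-type-qualified paths over
    mixed ``_include`` bundles: ``Patient.id`` and
    ``ImagingStudy.subject.reference.replace('Patient/', '')`` can feed the
    same ``patient_id`` column); the first path yielding a non-empty
    collection wins.  Empty → missing cell, singleton → scalar, multiple
    values → an ordered list cell (rows are never exploded).

``full_dump``
    Recursive flattening of the whole resource with dot-and-index column
    names (``name.0.family``).

``processing_function``
    A user callable ``Bundle -> list[dict]``, run once per Bundle; the row
    schema is then entirely caller-defined.

:func:`merge_rows` consolidates rows sharing a key (e.g. ImagingStudy rows
and ``_include``-imported Patient rows sharing ``patient_id``) into one row
per key; conflicting scalars are kept losslessly as ordered list cells.
"""

from __future__ import annotations

import csv
import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import pandas as pd

from . import fhirpath
from .errors import ExtractionError, SkiffError
from .fhirpath import PathExpression, parse_path

MISSING = None

MODES = ("fhir_paths", "full_dump", "processing_function")


@dataclass
class ExtractionSpec:
    """Column recipe for flattening resources.

    ``columns`` maps each unique alias to an ordered list of candidate
    parsed paths (first non-empty result wins).
    """

    columns: list[tuple[str, list[PathExpression]]] = field(default_factory=list)
    mode: str = "fhir_paths"
    processing_fn: Callable[[dict], list[dict]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise SkiffError(f"unknown extraction mode {self.mode!r}")
        if self.mode == "full_dump" and self.columns:
            raise SkiffError("full_dump mode takes no columns")
        if self.mode == "processing_function" and self.processing_fn is None:
            raise SkiffError("processing_function mode requires processing_fn")
        aliases = [alias for alias, _ in self.columns]
        if len(aliases) != len(set(aliases)):
            raise SkiffError("ExtractionSpec aliases must be unique")

    @classmethod
    def paths(
        cls,
        columns: Mapping[str, str] | Sequence[tuple[str, str]],
    ) -> "ExtractionSpec":
        """Build a ``fhir_paths`` spec from (alias, expression) pairs.

        Repeated aliases merge into one column with multiple candidate paths.
        """
        pairs = list(columns.items()) if isinstance(columns, Mapping) else list(columns)
        merged: dict[str, list[PathExpression]] = {}
        order: list[str] = []
        for alias, expr in pairs:
            parsed = expr if isinstance(expr, PathExpression) else parse_path(expr)
            if alias not in merged:
                merged[alias] = []
                order.append(alias)
            merged[alias].append(parsed)
        return cls(columns=[(alias, merged[alias]) for alias in order])

    @classmethod
    def full_dump(cls) -> "ExtractionSpec":
        return cls(mode="full_dump")

    @classmethod
    def processing(cls, fn: Callable[[dict], list[dict]]) -> "ExtractionSpec":
        return cls(mode="processing_function", processing_fn=fn)

    @property
    def aliases(self) -> list[str]:
        return [alias for alias, _ in self.columns]


def _flatten_full(node: Any, prefix: str, record: dict) -> None:
    if isinstance(node, dict):
        for key, value in node.items():
            _flatten_full(value, f"{prefix}.{key}" if prefix else key, record)
    elif isinstance(node, list):
        for idx, value in enumerate(node):
            _flatten_full(value, f"{prefix}.{idx}" if prefix else str(idx), record)
    else:
        record[prefix] = node


def flatten_resource(resource: dict, spec: ExtractionSpec) -> dict:
    """Flatten one resource into a record according to ``spec``.

    Only valid for ``fhir_paths`` and ``full_dump`` modes.
    """
    if spec.mode == "full_dump":
        record: dict = {}
        _flatten_full(resource, "", record)
        return record
    if spec.mode != "fhir_paths":
        raise SkiffError("flatten_resource requires fhir_paths or full_dump mode")
    record = {}
    for alias, paths in spec.columns:
        values: list = []
        for path in paths:
            try:
                values = fhirpath.evaluate(path, resource)
            except SkiffError as exc:
                raise ExtractionError(f"column {alias!r}: {exc}") from exc
            if values:
                break
        if not values:
            record[alias] = MISSING
        elif len(values) == 1:
            record[alias] = values[0]
        else:
            record[alias] = list(values)
    return record


def _records_to_frame(records: list[dict], leading: Sequence[str]) -> pd.DataFrame:
    columns = list(leading)
    seen = set(columns)
    for record in records:
        for key in record:
            if key not in seen:
                seen.add(key)
                columns.append(key)
    data = {
        col: [record.get(col, MISSING) for record in records] for col in columns
    }
    return pd.DataFrame(data, columns=columns, dtype=object)


def bundles_to_table(
    bundles,
    spec: ExtractionSpec,
    n_procs: int = 1,
) -> pd.DataFrame:
    """Flatten every entry of every bundle into a DataFrame.

    ``bundles`` is a BundleSet or any iterable of Bundle JSON trees.  Output
    is identical for every ``n_procs``; workers only parallelize the
    per-resource flattening, never reorder rows.
    """
    bundle_list = list(getattr(bundles, "bundles", bundles))
    if spec.mode == "processing_function":
        records: list[dict] = []
        for idx, bundle in enumerate(bundle_list):
            try:
                produced = spec.processing_fn(bundle)
            except Exception as exc:
                raise ExtractionError(f"processing function failed on bundle {idx}: {exc}") from exc
            records.extend(produced)
        return _records_to_frame(records, leading=[])

    resources = [
        entry["resource"]
        for bundle in bundle_list
        for entry in bundle.get("entry", [])
        if "resource" in entry
    ]
    if n_procs > 1 and len(resources) > 1:
        with ThreadPoolExecutor(max_workers=n_procs) as pool:
            records = list(pool.map(lambda r: flatten_resource(r, spec), resources))
    else:
        records = [flatten_resource(resource, spec) for resource in resources]
    frame = _records_to_frame(records, leading=spec.aliases)
    frame.attrs["provenance"] = [
        (resource.get("resourceType"), resource.get("id")) for resource in resources
    ]
    return frame


def _is_missing(value: Any) -> bool:
    if isinstance(value, (list, dict)):
        return False
    return pd.isna(value)


def merge_rows(table: pd.DataFrame, key_column: str) -> pd.DataFrame:
    """Merge rows that share a value in ``key_column`` into single rows.

    Non-missing values win over missing; distinct conflicting scalars are
    collected into an ordered list cell.  Rows with a missing key stay
    unmerged.  Output order is first-appearance order of keys.
    """
    if key_column not in table.columns:
        raise KeyError(key_column)
    groups: dict[Any, list[int]] = {}
    order: list[tuple[str, Any]] = []  # ("key", k) or ("row", index)
    for pos in range(len(table)):
        key = table[key_column].iloc[pos]
        if _is_missing(key):
            order.append(("row", pos))
        else:
            if key not in groups:
                groups[key] = []
                order.append(("key", key))
            groups[key].append(pos)

    other_cols = [col for col in table.columns if col != key_column]
    records: list[dict] = []
    for kind, ref in order:
        if kind == "row":
            records.append({col: table[col].iloc[ref] for col in table.columns})
            continue
        positions = groups[ref]
        record = {key_column: ref}
        for col in other_cols:
            seen: list = []
            for pos in positions:
                value = table[col].iloc[pos]
                if _is_missing(value):
                    continue
                if not any(_cell_equal(value, prior) for prior in seen):
                    seen.append(value)
            if not seen:
                record[col] = MISSING
            elif len(seen) == 1:
                record[col] = seen[0]
            else:
                record[col] = seen
        records.append(record)
    return pd.DataFrame(records, columns=list(table.columns), dtype=object)


def _cell_equal(a: Any, b: Any) -> bool:
    try:
        return bool(a == b)
    except ValueError:  # e.g. comparing arrays
        return False


# ---------------------------------------------------------------------------
# Readers / writers


def _serialize_cell(value: Any) -> str:
    if _is_missing(value):
        return ""
    if isinstance(value, (list, dict)):
        return json.dumps(value, ensure_ascii=False, separators=(", ", ": "))
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def write_csv(table: pd.DataFrame, path) -> None:
    """Write ``table`` as RFC 4180 CSV (UTF-8, CRLF, lists as JSON arrays)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(table.columns))
        for pos in range(len(table)):
            writer.writerow(
                [_serialize_cell(table[col].iloc[pos]) for col in table.columns]
            )


def write_jsonl(table: pd.DataFrame, path) -> None:
    """Write one JSON object per row (missing cells omitted)."""
    with open(path, "w", encoding="utf-8") as fh:
        for pos in range(len(table)):
            record = {
                col: table[col].iloc[pos]
                for col in table.columns
                if not _is_missing(table[col].iloc[pos])
            }
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_csv(path) -> pd.DataFrame:
    """Re-ingest a CSV written by :func:`write_csv` (or any constraint table).

    Cells holding JSON arrays/objects are parsed back into Python values;
    empty cells become missing.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        return pd.DataFrame(dtype=object)
    header, body = rows[0], rows[1:]
    parsed_rows = []
    for row in body:
        parsed = []
        for cell in row:
            if cell == "":
                parsed.append(MISSING)
            elif cell[:1] in "[{":
                try:
                    parsed.append(json.loads(cell))
                except ValueError:
                    parsed.append(cell)
            else:
                parsed.append(cell)
        parsed_rows.append(parsed)
    return pd.DataFrame(parsed_rows, columns=header, dtype=object)
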