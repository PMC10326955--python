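"""Bulk retrieval of DICOM series from a DICOMweb endpoint.

An ImagingStudy resource references a DICOM study (StudyInstanceUID) which
contains one or more series (SeriesInstanceUID); the pixel data itself lives
on a DICOMweb server, reached here through a minimal client speaking
QIDO-RS (series/instance queries, JSON) and WADO-RS (instance retrieval,
``application/dicom``).

Bulk runs never die on one bad series: every resolved (study, series) pair
lands in exactly one of the two ledger tables — successes (with folder and
instance count) or failures (with an error category: not_found, transport,
write, corrupt).
"""

from __future__ import annotations

import io
import logging
import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import pydicom

from .errors import (
    CorruptSeriesError,
    HttpError,
    NotFoundError,
    SkiffError,
    TransportError,
    WriteError,
)
from .session import Session, Transport, UrllibTransport, normalize_base_url

logger = logging.getLogger(__name__)

_UID_RE = re.compile(r"^\d+(\.\d+)*$")

SERIES_UID_TAG = "0020000E"
SOP_UID_TAG = "00080018"


def _valid_uid(uid: str) -> bool:
    return bool(uid) and bool(_UID_RE.match(uid)) and len(uid) <= 64


@dataclass
class DownloadRequest:
    """One row of work: a study, optionally narrowed to one series."""

    study_uid: str
    series_uid: str | None = None

    def __post_init__(self) -> None:
        if not _valid_uid(self.study_uid):
            raise SkiffError(f"invalid StudyInstanceUID: {self.study_uid!r}")
        if self.series_uid is not None and not _valid_uid(self.series_uid):
            raise SkiffError(f"invalid SeriesInstanceUID: {self.series_uid!r}")


SUCCESS_COLUMNS = ["study_uid", "series_uid", "folder", "instance_count"]
FAILURE_COLUMNS = ["study_uid", "series_uid", "error_category", "message"]


@dataclass
class DownloadLedger:
    """Paired success/failure tables for one bulk run."""

    successes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SUCCESS_COLUMNS, dtype=object)
    )
    failures: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=FAILURE_COLUMNS, dtype=object)
    )

    def write_csv(self, directory) -> tuple[Path, Path]:
        from .tabulator import write_csv

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ok_path = directory / "download_successes.csv"
        bad_path = directory / "download_failures.csv"
        write_csv(self.successes, ok_path)
        write_csv(self.failures, bad_path)
        return ok_path, bad_path


class DicomWebClient:
    """Minimal QIDO-RS / WADO-RS client.

    ``transport`` defaults to the stdlib HTTP transport; tests inject the
    in-process mock transport.  A :class:`~skiff.session.Session` may be
    passed to reuse its transport and auth headers.
    """

    def __init__(
        self,
        base_url: str,
        transport: Transport | None = None,
        headers: dict | None = None,
        session: Session | None = None,
        timeout: float = 60.0,
    ):
        self.base_url = normalize_base_url(base_url)
        if session is not None:
            transport = transport or session.transport
            headers = dict(session.headers) | (headers or {})
        self.transport = transport or UrllibTransport()
        self.headers = headers or {}
        self.timeout = timeout

    def _get(self, url: str, accept: str) -> bytes:
        headers = dict(self.headers)
        headers["Accept"] = accept
        resp = self.transport.request("GET", url, headers=headers, timeout=self.timeout)
        if resp.status == 404:
            raise NotFoundError(url)
        if resp.status >= 300:
            raise HttpError(resp.status, url, resp.data.decode("utf-8", "replace"))
        return resp.data

    def _get_json(self, url: str) -> list:
        import json

        return json.loads(self._get(url, "application/dicom+json").decode("utf-8"))

    def series_for_study(self, study_uid: str) -> list[str]:
        """QIDO-RS: SeriesInstanceUIDs of one study, in server order."""
        url = f"{self.base_url}/studies/{study_uid}/series"
        return [item[SERIES_UID_TAG]["Value"][0] for item in self._get_json(url)]

    def instances_for_series(self, study_uid: str, series_uid: str) -> list[str]:
        """QIDO-RS: SOPInstanceUIDs of one series."""
        url = f"{self.base_url}/studies/{study_uid}/series/{series_uid}/instances"
        return [item[SOP_UID_TAG]["Value"][0] for item in self._get_json(url)]

    def fetch_instance(
        self, study_uid: str, series_uid: str, sop_uid: str
    ) -> pydicom.Dataset:
        """WADO-RS: retrieve one instance as a parsed DICOM dataset."""
        url = (
            f"{self.base_url}/studies/{study_uid}/series/{series_uid}"
            f"/instances/{sop_uid}"
        )
        data = self._get(url, "application/dicom")
        return pydicom.dcmread(io.BytesIO(data))

    def fetch_series(self, study_uid: str, series_uid: str) -> list[pydicom.Dataset]:
        return [
            self.fetch_instance(study_uid, series_uid, sop)
            for sop in self.instances_for_series(study_uid, series_uid)
        ]


def resolve_series(client: DicomWebClient, request: DownloadRequest) -> list[str]:
    """Series UIDs covered by ``request``.

    With an explicit series_uid, verifies it exists and returns a singleton;
    otherwise returns the endpoint's full series listing for the study.
    """
    listing = client.series_for_study(request.study_uid)
    if request.series_uid is None:
        return listing
    if request.series_uid not in listing:
        raise NotFoundError(
            f"{client.base_url}/studies/{request.study_uid}"
            f"/series/{request.series_uid}"
        )
    return [request.series_uid]


def store_series(
    instances: Sequence[pydicom.Dataset],
    output_dir,
    hierarchical: bool = True,
    naming: str = "uid",
) -> Path:
    """Write one series to disk as DICOM part-10 files; returns its folder.

    ``hierarchical=True`` nests ``<out>/<study_uid>/<series_uid>/``;
    otherwise a flat ``<out>/<study_uid>_<series_uid>/`` folder is used.
    Re-running is idempotent (the folder is rebuilt deterministically), and a
    failed write removes the partial folder before raising.
    """
    if naming not in ("uid", "sequential"):
        raise SkiffError(f"naming must be 'uid' or 'sequential', got {naming!r}")
    if not instances:
        raise CorruptSeriesError("series has no instances; nothing written")
    study_uid = str(instances[0].StudyInstanceUID)
    series_uid = str(instances[0].SeriesInstanceUID)
    output_dir = Path(output_dir)
    if hierarchical:
        folder = output_dir / study_uid / series_uid
    else:
        folder = output_dir / f"{study_uid}_{series_uid}"
    try:
        if folder.exists():
            shutil.rmtree(folder)
        folder.mkdir(parents=True)
        for number, dataset in enumerate(instances, start=1):
            if naming == "uid":
                name = f"{dataset.SOPInstanceUID}.dcm"
            else:
                name = f"{number:06d}.dcm"
            dataset.save_as(folder / name, enforce_file_format=True)
    except OSError as exc:
        shutil.rmtree(folder, ignore_errors=True)
        raise WriteError(f"failed to store series {series_uid}: {exc}") from exc
    return folder


def download_data_from_dataframe(
    client: DicomWebClient,
    table: pd.DataFrame,
    study_col: str = "study_uid",
    series_col: str | None = None,
    output_dir=".",
    hierarchical: bool = True,
    naming: str = "uid",
) -> DownloadLedger:
    """Download every study/series referenced by ``table``.

    Per-series errors are recorded and processing continues; only
    configuration errors (missing columns) raise.  Ledger row order follows
    the input rows, expanded by resolved series.
    """
    if study_col not in table.columns:
        raise KeyError(f"study column {study_col!r} not in table")
    if series_col is not None and series_col not in table.columns:
        raise KeyError(f"series column {series_col!r} not in table")

    successes: list[dict] = []
    failures: list[dict] = []
    output_dir = Path(output_dir)

    def fail(study, series, category, message):
        failures.append(
            {
                "study_uid": study,
                "series_uid": series,
                "error_category": category,
                "message": str(message)[:300],
            }
        )

    for pos in range(len(table)):
        study_raw = table[study_col].iloc[pos]
        series_raw = table[series_col].iloc[pos] if series_col else None
        if series_raw is not None and (
            not isinstance(series_raw, str) and pd.isna(series_raw)
        ):
            series_raw = None
        try:
            request = DownloadRequest(str(study_raw), series_raw)
        except SkiffError as exc:
            fail(study_raw, series_raw, "corrupt", exc)
            continue
        try:
            series_uids = resolve_series(client, request)
        except NotFoundError as exc:
            fail(request.study_uid, request.series_uid, "not_found", exc)
            continue
        except (TransportError, HttpError) as exc:
            fail(request.study_uid, request.series_uid, "transport", exc)
            continue
        for series_uid in series_uids:
            try:
                instances = client.fetch_series(request.study_uid, series_uid)
                folder = store_series(
                    instances, output_dir, hierarchical=hierarchical, naming=naming
                )
            except NotFoundError as exc:
                fail(request.study_uid, series_uid, "not_found", exc)
            except (TransportError, HttpError) as exc:
                fail(request.study_uid, series_uid, "transport", exc)
            except WriteError as exc:
                fail(request.study_uid, series_uid, "write", exc)
            except CorruptSeriesError as exc:
                fail(request.study_uid, series_uid, "corrupt", exc)
            else:
                successes.append(
                    {
                        "study_uid": request.study_uid,
                        "series_uid": series_uid,
                        "folder": str(folder.relative_to(output_dir)),
                        "instance_count": len(instances),
                    }
                )
    ledger = DownloadLedger(
        successes=pd.DataFrame(successes, columns=SUCCESS_COLUMNS, dtype=object),
        failures=pd.DataFrame(failures, columns=FAILURE_COLUMNS, dtype=object),
    )
    logger.info(
        "download complete: %d series stored, %d failed",
        len(ledger.successes),
        len(ledger.failures),
    )
    return ledger
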