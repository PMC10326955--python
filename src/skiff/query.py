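"""FHIR search retrieval: single queries, pagination, time-partitioned and
per-row parallel queries, and their DataFrame facades.

Concurrency here is a *contract*, not a mechanism: for any number of worker
processes the result equals sequential execution (up to bundle order inside
a partition, which is itself fixed by span order).  Workers are threads —
the workload is network-bound — and the default worker count is one.
"""

from __future__ import annotations

import datetime
import logging
import urllib.parse
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import MalformedBundleError, SkiffError
from .session import Session
from .tabulator import ExtractionSpec, bundles_to_table, _is_missing

logger = logging.getLogger(__name__)

DEFAULT_PAGE_SIZE = 100


@dataclass
class SearchQuery:
    """One FHIR search: a resource type plus a request-parameter multimap.

    ``request_params`` values may be scalars or lists (repeated keys are sent
    as repeated ``key=value`` pairs, which FHIR reads as AND).  Serialization
    is deterministic: parameters keep their given order, and ``_count`` is
    appended from ``page_size`` unless explicitly present.
    """

    resource_type: str
    request_params: Mapping[str, Any] = field(default_factory=dict)
    page_size: int = DEFAULT_PAGE_SIZE
    include_history: bool = False

    def __post_init__(self) -> None:
        if not self.resource_type:
            raise SkiffError("resource_type must be non-empty")
        if self.page_size < 1:
            raise SkiffError("page_size must be >= 1")
        for key in self.request_params:
            if not key:
                raise SkiffError("request_params keys must be non-empty strings")

    def pairs(self) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        has_count = False
        for key, value in self.request_params.items():
            if key == "_count":
                has_count = True
            if isinstance(value, (list, tuple)):
                out.extend((key, str(v)) for v in value)
            else:
                out.append((key, str(value)))
        if not has_count:
            out.append(("_count", str(self.page_size)))
        return out

    def with_params(self, extra: Sequence[tuple[str, str]]) -> "SearchQuery":
        """A copy with ``extra`` pairs appended to the multimap."""
        params: dict[str, Any] = {}
        for key, value in self.request_params.items():
            params[key] = list(value) if isinstance(value, (list, tuple)) else [value]
        for key, value in extra:
            params.setdefault(key, []).append(value)
        return replace(self, request_params=params)


@dataclass
class BundleSet:
    """Ordered Bundles returned by one logical query, with a retrieval log."""

    bundles: list[dict]
    source_query: SearchQuery | None = None
    retrieval_log: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def total_entries(self) -> int:
        return sum(len(b.get("entry", [])) for b in self.bundles)

    def entries(self) -> Iterator[dict]:
        for bundle in self.bundles:
            yield from bundle.get("entry", [])

    def resources(self) -> Iterator[dict]:
        for entry in self.entries():
            if "resource" in entry:
                yield entry["resource"]

    def resource_ids(self) -> list[str]:
        return [r.get("id") for r in self.resources()]


@dataclass
class RowConstraints:
    """Column → (search parameter, optional system prefix) mapping.

    A system prefix turns each cell into a token value ``system|code``.
    """

    mapping: Mapping[str, tuple[str, str | None]]

    @classmethod
    def of(cls, mapping: Mapping[str, Any]) -> "RowConstraints":
        norm: dict[str, tuple[str, str | None]] = {}
        for col, spec in mapping.items():
            if isinstance(spec, str):
                norm[col] = (spec, None)
            else:
                param, system = spec
                norm[col] = (param, system)
        return cls(norm)


@dataclass
class TimePartition:
    """Disjoint half-open date spans covering ``[start, end)``."""

    start: datetime.date
    end: datetime.date
    spans: list[tuple[datetime.date, datetime.date]]
    date_param: str | None = None


# ---------------------------------------------------------------------------
# URL building and pagination


def build_search_url(session: Session, query: SearchQuery) -> str:
    base = session.config.base_url
    path = f"/{query.resource_type}"
    if query.include_history:
        path += "/_history"
    qs = urllib.parse.urlencode(query.pairs())
    return f"{base}{path}?{qs}" if qs else f"{base}{path}"


def _next_link(bundle: dict) -> str | None:
    for link in bundle.get("link", []):
        if link.get("relation") == "next":
            return link.get("url")
    return None


def _iter_bundles(
    session: Session,
    query: SearchQuery,
    max_bundles: int | None,
    log: list[tuple[str, int, int]],
) -> Iterator[dict]:
    url: str | None = build_search_url(session, query)
    base_host = urllib.parse.urlparse(session.config.base_url).netloc
    fetched = 0
    while url is not None:
        if max_bundles is not None and fetched >= max_bundles:
            return
        bundle = session.get_json(url)
        if bundle.get("resourceType") != "Bundle":
            raise MalformedBundleError(
                f"expected a Bundle from {url}, got "
                f"{bundle.get('resourceType')!r}"
            )
        log.append((url, 200, len(bundle.get("entry", []))))
        fetched += 1
        yield bundle
        url = _next_link(bundle)
        if url is not None and urllib.parse.urlparse(url).netloc != base_host:
            logger.warning("following next link on a different host: %s", url)


def steal_bundles(
    session: Session,
    query: SearchQuery,
    max_bundles: int | None = None,
) -> BundleSet:
    """Run one query and follow ``next`` links until done (or ``max_bundles``)."""
    log: list[tuple[str, int, int]] = []
    bundles = list(_iter_bundles(session, query, max_bundles, log))
    return BundleSet(bundles, source_query=query, retrieval_log=log)


# ---------------------------------------------------------------------------
# Time partitioning


def partition_time_span(
    start: datetime.date,
    end: datetime.date,
    n: int,
    date_param: str | None = None,
) -> TimePartition:
    """Split ``[start, end)`` into at most ``n`` half-open spans.

    Span lengths differ by at most one day, with the longer spans first; the
    number of spans is capped at the number of days so no span is empty.
    """
    if start >= end:
        raise SkiffError(f"start must precede end, got [{start}, {end})")
    if n < 1:
        raise SkiffError("n must be >= 1")
    total_days = (end - start).days
    n_spans = min(n, total_days)
    base, remainder = divmod(total_days, n_spans)
    spans: list[tuple[datetime.date, datetime.date]] = []
    cursor = start
    for i in range(n_spans):
        length = base + (1 if i < remainder else 0)
        nxt = cursor + datetime.timedelta(days=length)
        spans.append((cursor, nxt))
        cursor = nxt
    assert cursor == end
    return TimePartition(start=start, end=end, spans=spans, date_param=date_param)


def _run_concurrent(tasks: Sequence[Callable[[], Any]], n_procs: int) -> list:
    """Run tasks preserving order; the first failure propagates (fail fast)."""
    if n_procs <= 1 or len(tasks) <= 1:
        return [task() for task in tasks]
    with ThreadPoolExecutor(max_workers=n_procs) as pool:
        futures = [pool.submit(task) for task in tasks]
        return [future.result() for future in futures]


def sail_through_search_space(
    session: Session,
    query: SearchQuery,
    date_param: str,
    start: datetime.date,
    end: datetime.date,
    n_procs: int = 1,
) -> BundleSet:
    """Time-partitioned retrieval: one sub-query per span, run concurrently.

    Each span contributes ``date_param=ge<start_i>`` and ``date_param=lt<end_i>``;
    half-open spans guarantee boundary-dated resources appear exactly once.
    Results are concatenated in span order.  Fails fast on any sub-query error.
    """
    partition = partition_time_span(start, end, n_procs, date_param)
    tasks = [
        (
            lambda span=span: steal_bundles(
                session,
                query.with_params(
                    [(date_param, f"ge{span[0].isoformat()}"),
                     (date_param, f"lt{span[1].isoformat()}")]
                ),
            )
        )
        for span in partition.spans
    ]
    results = _run_concurrent(tasks, n_procs)
    merged = BundleSet([], source_query=query)
    for sub in results:
        merged.bundles.extend(sub.bundles)
        merged.retrieval_log.extend(sub.retrieval_log)
    return merged


# ---------------------------------------------------------------------------
# Per-row constrained queries


class RowBundles(list):
    """``list[(row_index, BundleSet)]`` plus the indices of skipped rows."""

    def __init__(self, *args):
        super().__init__(*args)
        self.skipped: list[Any] = []


def _row_query(
    query: SearchQuery,
    constraints: RowConstraints,
    row: Mapping[str, Any],
) -> SearchQuery | None:
    extra: list[tuple[str, str]] = []
    for col, (param, system) in constraints.mapping.items():
        value = row[col]
        if _is_missing(value) or value == "":
            return None
        text = str(value)
        if system:
            text = f"{system}|{text}"
        extra.append((param, text))
    return query.with_params(extra)


def trade_rows_for_bundles(
    session: Session,
    table: pd.DataFrame,
    query: SearchQuery,
    constraints: RowConstraints | Mapping[str, Any],
    n_procs: int = 1,
) -> RowBundles:
    """One constrained sub-query per table row, run concurrently.

    Rows with a missing/empty value in any constrained column are skipped
    (logged and listed in the result's ``skipped`` attribute).  Output order
    equals input row order; transport errors fail fast.
    """
    if not isinstance(constraints, RowConstraints):
        constraints = RowConstraints.of(constraints)
    for col in constraints.mapping:
        if col not in table.columns:
            raise KeyError(f"constraint column {col!r} not in table")
    result = RowBundles()
    planned: list[tuple[Any, SearchQuery]] = []
    for pos in range(len(table)):
        index = table.index[pos]
        row = {col: table[col].iloc[pos] for col in constraints.mapping}
        sub = _row_query(query, constraints, row)
        if sub is None:
            logger.warning("row %r skipped: missing constraint value", index)
            result.skipped.append(index)
            continue
        planned.append((index, sub))
    outputs = _run_concurrent(
        [(lambda q=sub: steal_bundles(session, q)) for _, sub in planned], n_procs
    )
    result.extend((index, bundles) for (index, _), bundles in zip(planned, outputs))
    return result


def request_history(
    session: Session, resource_type: str, resource_id: str
) -> BundleSet:
    """Fetch the edit history of one resource (versions, newest first)."""
    if not resource_id:
        raise SkiffError("resource_id must be non-empty")
    url = f"{session.config.base_url}/{resource_type}/{resource_id}/_history"
    bundle = session.get_json(url)
    if bundle.get("resourceType") != "Bundle":
        raise MalformedBundleError(f"expected a history Bundle from {url}")
    log = [(url, 200, len(bundle.get("entry", [])))]
    return BundleSet([bundle], retrieval_log=log)


# ---------------------------------------------------------------------------
# DataFrame facades


def _tabulate(
    bundle_iter: Iterable[dict],
    spec: ExtractionSpec,
    alternate: bool,
    n_procs: int,
) -> pd.DataFrame:
    if alternate:
        # Build per bundle as it arrives; an extraction failure aborts the
        # run before the next bundle is fetched.
        frames = [bundles_to_table([bundle], spec) for bundle in bundle_iter]
        frames = [f for f in frames if len(f.columns)]
        if not frames:
            return bundles_to_table([], spec)
        return pd.concat(frames, ignore_index=True).astype(object)
    return bundles_to_table(list(bundle_iter), spec, n_procs=n_procs)


def steal_bundles_to_dataframe(
    session: Session,
    query: SearchQuery,
    spec: ExtractionSpec,
    max_bundles: int | None = None,
    n_procs: int = 1,
    alternate: bool = False,
) -> pd.DataFrame:
    """Facade: :func:`steal_bundles` composed with :func:`bundles_to_table`.

    ``alternate=True`` interleaves retrieval and table building so the run
    stops at the first extraction failure.
    """
    log: list[tuple[str, int, int]] = []
    return _tabulate(_iter_bundles(session, query, max_bundles, log), spec, alternate, n_procs)


def sail_through_search_space_to_dataframe(
    session: Session,
    query: SearchQuery,
    spec: ExtractionSpec,
    date_param: str,
    start: datetime.date,
    end: datetime.date,
    n_procs: int = 1,
    alternate: bool = False,
) -> pd.DataFrame:
    bundles = sail_through_search_space(session, query, date_param, start, end, n_procs)
    return _tabulate(bundles.bundles, spec, alternate, n_procs)


def trade_rows_for_dataframe(
    session: Session,
    table: pd.DataFrame,
    query: SearchQuery,
    constraints: RowConstraints | Mapping[str, Any],
    spec: ExtractionSpec,
    n_procs: int = 1,
    with_columns: Sequence[str] | None = None,
    alternate: bool = False,
) -> pd.DataFrame:
    """Facade over :func:`trade_rows_for_bundles`.

    With ``with_columns``, the named columns of each originating row are
    copied into every output row it produced.
    """
    row_bundles = trade_rows_for_bundles(session, table, query, constraints, n_procs)
    frames: list[pd.DataFrame] = []
    for index, bundles in row_bundles:
        frame = _tabulate(bundles.bundles, spec, alternate, n_procs=1)
        if with_columns:
            for col in with_columns:
                frame[col] = [table.at[index, col]] * len(frame)
        frames.append(frame)
    if not frames:
        columns = list(spec.aliases) + list(with_columns or [])
        return pd.DataFrame(columns=columns, dtype=object)
    return pd.concat(frames, ignore_index=True).astype(object)
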