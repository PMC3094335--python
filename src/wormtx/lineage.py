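"""Gene-identifier lineage tracking across genome annotation releases.

C. elegans gene annotations change between WormBase releases: gene models
are merged, split, killed, created, renamed and occasionally resurrected.
A gene list published against one release therefore cannot be compared
directly with data annotated against another.  This module replays the
recorded lineage events to convert identifier lists forward in release
time, reports every change (merges, splits, deaths, unresolved names),
and can guess the release a list most likely came from.

The stable unit of identity is the gene-level WB ID (``WBGene...``);
sequence names, public names and transcript names are resolved to it
through per-release correspondence tables.  Conversion is forward-only:
merges destroy information, so newer-to-older conversion is refused.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

EVENT_TYPES = frozenset({"merge", "split", "kill", "create", "rename", "resurrect"})

OUTPUT_FORMATS = ("wbid", "sequence_name", "public_name")


class LineageError(ValueError):
    """Base class for lineage-conversion errors."""


class UnknownReleaseError(LineageError):
    pass


class UnsupportedFormatError(LineageError):
    """Raised for transcript-name output: lineage is recorded at gene level,
    so a gene list cannot be converted into transcript names."""


class BackwardConversionError(LineageError):
    """Merges are not invertible, so newer-to-older conversion is refused."""


class NoDetectionError(LineageError):
    pass


@dataclass(frozen=True, order=True)
class ReleaseTag:
    """An annotation release label and its position in release order."""

    ordinal: int
    name: str


@dataclass
class GeneRecord:
    wbid: str
    sequence_name: str = ""
    public_name: str = ""
    transcript_names: tuple[str, ...] = ()
    status: str = "live"

    def __post_init__(self) -> None:
        if not self.wbid:
            raise LineageError("GeneRecord requires a non-empty wbid")
        if self.status not in ("live", "dead"):
            raise LineageError(f"bad status {self.status!r} for {self.wbid}")


@dataclass
class LineageEvent:
    """A recorded change in gene structure, effective from one release on.

    Cardinality rules follow curation practice: a merge folds two or more
    genes into one survivor; a split keeps (or, rarely, drops) the parent
    and creates new daughters, so it has one source and two or more
    targets; kill removes genes; create and resurrect introduce genes.
    A rename keeps the WB ID and only changes names.
    """

    effective_release: str
    event_type: str
    source_wbids: tuple[str, ...]
    target_wbids: tuple[str, ...]
    note: str = ""

    def __post_init__(self) -> None:
        self.source_wbids = tuple(self.source_wbids)
        self.target_wbids = tuple(self.target_wbids)
        t = self.event_type
        ns, nt = len(self.source_wbids), len(self.target_wbids)
        if t not in EVENT_TYPES:
            raise LineageError(f"unknown event_type {t!r}")
        ok = {
            "merge": ns >= 2 and nt == 1,
            "split": ns == 1 and nt >= 2,
            "kill": ns >= 1 and nt == 0,
            "create": ns == 0 and nt >= 1,
            "rename": ns == 1 and nt == 1,
            "resurrect": ns == 0 and nt >= 1,
        }[t]
        if not ok:
            raise LineageError(
                f"{t} event has {ns} source(s) and {nt} target(s), "
                "violating its cardinality rule"
            )


@dataclass
class ConversionReport:
    """Full accounting of one list conversion.

    Every input identifier lands in exactly one bucket: unresolved (no
    WB ID in the source release), killed, merged (its WB ID changed by a
    merge), split (its gene was split; the modified parent survives), or
    passthrough.  Split daughters appended to the output are listed in
    ``split_added``.
    """

    resolved: dict[str, str] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)
    killed: list[tuple[str, str]] = field(default_factory=list)  # (input, release)
    merged: dict[str, str] = field(default_factory=dict)  # source wbid -> survivor
    split_added: list[str] = field(default_factory=list)
    split_sources: list[str] = field(default_factory=list)
    passthrough: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "input": len(self.unresolved) + len(self.resolved),
            "resolved": len(self.resolved),
            "unresolved": len(self.unresolved),
            "killed": len(self.killed),
            "merged": len(self.merged),
            "split": len(self.split_sources),
            "passthrough": len(self.passthrough),
            "split_added": len(self.split_added),
        }

    def to_dict(self) -> dict:
        d = {
            "resolved": dict(self.resolved),
            "unresolved": list(self.unresolved),
            "killed": [list(k) for k in self.killed],
            "merged": dict(self.merged),
            "split_added": list(self.split_added),
            "split_sources": list(self.split_sources),
            "passthrough": list(self.passthrough),
            "counts": self.counts,
        }
        return d


@dataclass
class ReleaseHistory:
    """Ordered releases, per-release gene tables and the events between them."""

    releases: list[ReleaseTag]
    tables: dict[str, dict[str, GeneRecord]]
    events: list[LineageEvent] = field(default_factory=list)
    patches: list[LineageEvent] = field(default_factory=list)
    inconsistencies: list[str] = field(default_factory=list)
    repaired: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.releases]
        if len(set(names)) != len(names):
            raise LineageError("duplicate release names")
        ords = [r.ordinal for r in self.releases]
        if ords != sorted(ords) or len(set(ords)) != len(ords):
            raise LineageError("release ordinals must be strictly increasing")
        self._ordinal = {r.name: r.ordinal for r in self.releases}
        for ev in list(self.events) + list(self.patches):
            if ev.effective_release not in self._ordinal:
                raise LineageError(
                    f"event references unknown release {ev.effective_release!r}"
                )
        # stable chronological order, patches interleaved
        self._all_events = sorted(
            list(self.events) + list(self.patches),
            key=lambda e: self._ordinal[e.effective_release],
        )
        self._indexes: dict[str, dict[str, dict[str, str]]] = {}

    def ordinal(self, release: str) -> int:
        try:
            return self._ordinal[release]
        except KeyError:
            raise UnknownReleaseError(f"unknown release {release!r}") from None

    @property
    def release_names(self) -> list[str]:
        return [r.name for r in self.releases]

    def table(self, release: str) -> dict[str, GeneRecord]:
        self.ordinal(release)
        return self.tables[release]

    def events_between(self, from_release: str, to_release: str) -> list[LineageEvent]:
        """Events with ``from < effective_release <= to``, in release order."""
        lo, hi = self.ordinal(from_release), self.ordinal(to_release)
        return [
            e for e in self._all_events if lo < self._ordinal[e.effective_release] <= hi
        ]

    # -- identifier resolution ------------------------------------------------

    def _index(self, release: str) -> dict[str, dict[str, str]]:
        """Lookup maps (exact and casefolded) from each identifier kind to
        the live WB ID carrying it in ``release``."""
        if release in self._indexes:
            return self._indexes[release]
        maps: dict[str, dict[str, str]] = {
            k: {}
            for k in (
                "wbid",
                "sequence_name",
                "public_name",
                "transcript",
                "wbid_ci",
                "sequence_name_ci",
                "public_name_ci",
                "transcript_ci",
            )
        }
        for rec in self.table(release).values():
            if rec.status != "live":
                continue
            maps["wbid"][rec.wbid] = rec.wbid
            maps["wbid_ci"].setdefault(rec.wbid.casefold(), rec.wbid)
            if rec.sequence_name:
                maps["sequence_name"][rec.sequence_name] = rec.wbid
                maps["sequence_name_ci"].setdefault(rec.sequence_name.casefold(), rec.wbid)
            if rec.public_name:
                maps["public_name"][rec.public_name] = rec.wbid
                maps["public_name_ci"].setdefault(rec.public_name.casefold(), rec.wbid)
            for tn in rec.transcript_names:
                maps["transcript"][tn] = rec.wbid
                maps["transcript_ci"].setdefault(tn.casefold(), rec.wbid)
        self._indexes[release] = maps
        return maps


# ---------------------------------------------------------------------------
# resolution

_KIND_ORDER = ("wbid", "sequence_name", "public_name", "transcript")


def resolve_identifiers(
    ids: Sequence[str], release: str, history: ReleaseHistory
) -> list[tuple[str, str | None]]:
    """Resolve a heterogeneous identifier list to WB IDs in one release.

    Each input is tried, in order, as a WB ID, a sequence name, a public
    name and finally a transcript name (which resolves to its parent
    gene).  Exact matches take precedence over case-insensitive ones,
    which are logged.  Unresolved inputs are reported as ``None`` rather
    than dropped.
    """
    if not ids:
        raise LineageError("empty identifier list")
    maps = history._index(release)
    out: list[tuple[str, str | None]] = []
    for ident in ids:
        wbid = None
        for kind in _KIND_ORDER:
            if ident in maps[kind]:
                wbid = maps[kind][ident]
                break
        if wbid is None:
            cf = ident.casefold()
            for kind in _KIND_ORDER:
                if cf in maps[kind + "_ci"]:
                    wbid = maps[kind + "_ci"][cf]
                    logger.info(
                        "case-insensitive fallback: %r -> %s (%s, %s)",
                        ident, wbid, kind, release,
                    )
                    break
        out.append((ident, wbid))
    return out


# ---------------------------------------------------------------------------
# conversion

def _check_span(history: ReleaseHistory, from_release: str, to_release: str) -> None:
    lo, hi = history.ordinal(from_release), history.ordinal(to_release)
    if lo > hi:
        raise BackwardConversionError(
            f"cannot convert {from_release} -> {to_release}: merges are not "
            "invertible, so only forward conversion is supported"
        )


def _render(wbids: Sequence[str], release: str, history: ReleaseHistory, fmt: str) -> list[str]:
    if fmt == "transcript":
        raise UnsupportedFormatError(
            "gene lists cannot be converted to transcript names: lineage is "
            "recorded at the gene (WB ID) level"
        )
    if fmt not in OUTPUT_FORMATS:
        raise LineageError(f"unknown output format {fmt!r}")
    if fmt == "wbid":
        return list(wbids)
    table = history.table(release)
    out = []
    for w in wbids:
        rec = table.get(w)
        name = getattr(rec, fmt, "") if rec is not None else ""
        out.append(name or (rec.sequence_name if rec else "") or w)
    return out


@dataclass
class _GeneState:
    input_id: str | None  # None for split daughters spawned during replay
    current: str | None  # live wbid, or None while dead
    last: str  # last wbid held (for resurrect lookups)
    merged_into: str | None = None
    split: bool = False
    killed_at: str | None = None
    spawn_key: tuple[int, str] | None = None  # (event index, wbid at creation)


def convert_list(
    ids: Sequence[str],
    from_release: str,
    to_release: str,
    history: ReleaseHistory,
    output_format: str = "wbid",
) -> tuple[list[str], ConversionReport]:
    """Convert a gene list forward between releases, reporting every change.

    All events effective after ``from_release`` and up to ``to_release``
    are replayed over the resolved genes in chronological order.  Merged
    genes map to the surviving gene (deduplicated in the output); split
    daughters are appended at the end of the output; killed genes are
    omitted and reported with the release at which they died.

    This is the indexed single-pass implementation; ``convert_list_naive``
    is an intentionally simple per-gene rescan with the identical contract,
    kept as an independent cross-check.
    """
    _check_span(history, from_release, to_release)
    if output_format == "transcript":
        raise UnsupportedFormatError(
            "gene lists cannot be converted to transcript names"
        )

    resolved_pairs = resolve_identifiers(ids, from_release, history)
    report = ConversionReport()
    states: list[_GeneState] = []
    daughters: list[_GeneState] = []
    holders: dict[str, list[_GeneState]] = {}
    for ident, wbid in resolved_pairs:
        if wbid is None:
            report.unresolved.append(ident)
            continue
        report.resolved[ident] = wbid
        st = _GeneState(input_id=ident, current=wbid, last=wbid)
        states.append(st)
        holders.setdefault(wbid, []).append(st)

    dead_index: dict[str, list[_GeneState]] = {}

    for ev_idx, ev in enumerate(history.events_between(from_release, to_release)):
        if ev.event_type == "merge":
            target = ev.target_wbids[0]
            for src in ev.source_wbids:
                if src == target or src not in holders:
                    continue
                moved = holders.pop(src)
                for st in moved:
                    st.current = target
                    st.last = target
                    st.merged_into = target
                holders.setdefault(target, []).extend(moved)
        elif ev.event_type == "split":
            src = ev.source_wbids[0]
            if src not in holders:
                continue
            for st in holders[src]:
                st.split = True
            # daughters become tracked lineages of their own, so later
            # merges/kills/splits affect them like any held gene
            for t in sorted(x for x in ev.target_wbids if x != src):
                d = _GeneState(
                    input_id=None, current=t, last=t, spawn_key=(ev_idx, t)
                )
                daughters.append(d)
                holders.setdefault(t, []).append(d)
            if src not in ev.target_wbids:
                # curation inconsistency: modified parent dropped without a
                # formal kill; the gene stays held until a (patch) kill event
                logger.warning(
                    "split of %s at %s does not retain the parent",
                    src, ev.effective_release,
                )
        elif ev.event_type == "kill":
            for src in ev.source_wbids:
                if src not in holders:
                    continue
                for st in holders.pop(src):
                    st.current = None
                    st.killed_at = ev.effective_release
                    dead_index.setdefault(st.last, []).append(st)
        elif ev.event_type == "resurrect":
            for tgt in ev.target_wbids:
                for st in dead_index.pop(tgt, []):
                    st.current = tgt
                    st.killed_at = None
                    holders.setdefault(tgt, []).append(st)
        # create and rename do not move gene identity

    # partition (priority killed > merged > split > passthrough) and output
    main_out: list[str] = []
    seen: set[str] = set()
    for st in states:
        if st.current is None:
            report.killed.append((st.input_id, st.killed_at or to_release))
            continue
        if st.merged_into is not None:
            report.merged[report.resolved[st.input_id]] = st.current
        elif st.split:
            report.split_sources.append(st.input_id)
        else:
            report.passthrough.append(st.input_id)
        if st.current not in seen:
            seen.add(st.current)
            main_out.append(st.current)

    appended: list[str] = []
    for d in sorted(daughters, key=lambda s: s.spawn_key):
        if d.current is not None and d.current not in seen:
            seen.add(d.current)
            appended.append(d.current)
    report.split_added = appended
    out_wbids = main_out + appended
    return _render(out_wbids, to_release, history, output_format), report


def convert_list_naive(
    ids: Sequence[str],
    from_release: str,
    to_release: str,
    history: ReleaseHistory,
    output_format: str = "wbid",
) -> tuple[list[str], ConversionReport]:
    """Reference conversion: one gene at a time, one linear event scan each.

    Same contract as :func:`convert_list`; exists solely so the two
    independent code paths can be checked against each other.
    """
    _check_span(history, from_release, to_release)
    if output_format == "transcript":
        raise UnsupportedFormatError(
            "gene lists cannot be converted to transcript names"
        )
    events = history.events_between(from_release, to_release)
    resolved_pairs = resolve_identifiers(ids, from_release, history)
    report = ConversionReport()

    def trace(wbid: str, start_idx: int):
        """Follow one lineage through events[start_idx:]; returns the final
        live wbid (or None), the release of death, the merge target, the
        split flag and the daughters spawned as (event index, wbid)."""
        cur: str | None = wbid
        last = wbid
        merged_into: str | None = None
        was_split = False
        killed_at: str | None = None
        spawns: list[tuple[int, str]] = []
        for idx in range(start_idx, len(events)):
            ev = events[idx]
            if ev.event_type == "merge" and cur is not None:
                if cur in ev.source_wbids and cur != ev.target_wbids[0]:
                    cur = last = merged_into = ev.target_wbids[0]
            elif ev.event_type == "split" and cur is not None:
                if cur == ev.source_wbids[0]:
                    was_split = True
                    for t in sorted(x for x in ev.target_wbids if x != cur):
                        spawns.append((idx, t))
            elif ev.event_type == "kill" and cur is not None:
                if cur in ev.source_wbids:
                    cur, killed_at = None, ev.effective_release
            elif ev.event_type == "resurrect" and cur is None:
                if last in ev.target_wbids:
                    cur, killed_at = last, None
        return cur, killed_at, merged_into, was_split, spawns

    finals: list[tuple[str, str]] = []  # (input, final wbid) for survivors
    pending: list[tuple[int, str]] = []  # daughter lineages yet to trace
    for ident, wbid in resolved_pairs:
        if wbid is None:
            report.unresolved.append(ident)
            continue
        report.resolved[ident] = wbid
        cur, killed_at, merged_into, was_split, spawns = trace(wbid, 0)
        pending.extend(spawns)
        if cur is None:
            report.killed.append((ident, killed_at or to_release))
            continue
        if merged_into is not None:
            report.merged[wbid] = cur
        elif was_split:
            report.split_sources.append(ident)
        else:
            report.passthrough.append(ident)
        finals.append((ident, cur))

    # follow every spawned daughter (and any daughters of daughters)
    daughter_finals: list[tuple[tuple[int, str], str]] = []
    k = 0
    while k < len(pending):
        ev_idx, wbid = pending[k]
        k += 1
        cur, _, _, _, spawns = trace(wbid, ev_idx + 1)
        pending.extend(spawns)
        if cur is not None:
            daughter_finals.append(((ev_idx, wbid), cur))

    main_out: list[str] = []
    seen: set[str] = set()
    for _, w in finals:
        if w not in seen:
            seen.add(w)
            main_out.append(w)
    appended: list[str] = []
    for _, w in sorted(daughter_finals, key=lambda kv: kv[0]):
        if w not in seen:
            seen.add(w)
            appended.append(w)
    report.split_added = appended
    out_wbids = main_out + appended
    return _render(out_wbids, to_release, history, output_format), report


# ---------------------------------------------------------------------------
# release detection

def detect_release(
    ids: Sequence[str], history: ReleaseHistory
) -> tuple[ReleaseTag, dict[str, float]]:
    """Guess the release an identifier list was annotated against.

    Scores each release by the fraction of inputs it can resolve and
    returns the argmax; ties are broken toward the most recent release,
    on the grounds that users are more likely to work with current data.
    """
    if not ids:
        raise LineageError("empty identifier list")
    scores: dict[str, float] = {}
    for tag in history.releases:
        pairs = resolve_identifiers(ids, tag.name, history)
        scores[tag.name] = sum(1 for _, w in pairs if w is not None) / len(ids)
    best = max(history.releases, key=lambda t: (scores[t.name], t.ordinal))
    if scores[best.name] == 0.0:
        raise NoDetectionError("no input identifier resolves in any release")
    return best, scores


# ---------------------------------------------------------------------------
# file I/O

_CORR_COLUMNS = ["wbid", "sequence_name", "public_name", "transcript_names", "status"]
_EVENT_COLUMNS = ["effective_release", "event_type", "source_wbids", "target_wbids", "note"]


class ParseError(LineageError):
    pass


def _read_tsv(path, columns) -> list[dict[str, str]]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != columns:
            raise ParseError(f"{path}:1: expected header {columns}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(row)}"
                )
            rows.append(dict(zip(columns, row)))
    return rows


def _split_ids(s: str) -> tuple[str, ...]:
    return tuple(x for x in (p.strip() for p in s.split(",")) if x)


def load_events(path) -> list[LineageEvent]:
    events = []
    for row in _read_tsv(path, _EVENT_COLUMNS):
        events.append(
            LineageEvent(
                effective_release=row["effective_release"].strip(),
                event_type=row["event_type"].strip(),
                source_wbids=_split_ids(row["source_wbids"]),
                target_wbids=_split_ids(row["target_wbids"]),
                note=row["note"],
            )
        )
    return events


def load_history(
    correspondence_paths: Mapping[str, str] | Sequence[tuple[str, str]],
    event_log_path,
    patch_path=None,
) -> ReleaseHistory:
    """Load a release history from correspondence tables and an event log.

    ``correspondence_paths`` maps release name to its table path, in
    release order.  Patches use the event-log schema and are merged in
    before the load-time consistency check, so a patch can repair a
    recorded inconsistency (e.g. declare the kill implied by a split that
    dropped its parent).  Remaining inconsistencies are logged, not fatal.
    """
    items = list(correspondence_paths.items()) if isinstance(
        correspondence_paths, Mapping
    ) else list(correspondence_paths)
    releases = [ReleaseTag(ordinal=i, name=name) for i, (name, _) in enumerate(items)]
    tables: dict[str, dict[str, GeneRecord]] = {}
    for name, path in items:
        table: dict[str, GeneRecord] = {}
        for row in _read_tsv(path, _CORR_COLUMNS):
            rec = GeneRecord(
                wbid=row["wbid"].strip(),
                sequence_name=row["sequence_name"].strip(),
                public_name=row["public_name"].strip(),
                transcript_names=_split_ids(row["transcript_names"]),
                status=row["status"].strip() or "live",
            )
            if rec.wbid in table:
                raise ParseError(f"duplicate wbid {rec.wbid} in {path}")
            table[rec.wbid] = rec
        tables[name] = table

    events = load_events(event_log_path)
    patches = load_events(patch_path) if patch_path else []

    base = ReleaseHistory(releases=releases, tables=tables, events=events)
    incons_before = check_consistency(base)
    hist = ReleaseHistory(
        releases=releases, tables=tables, events=events, patches=patches
    )
    incons_after = check_consistency(hist)
    hist.inconsistencies = incons_after
    hist.repaired = [m for m in incons_before if m not in incons_after]
    for msg in hist.repaired:
        logger.info("inconsistency repaired by patch: %s", msg)
    for msg in incons_after:
        logger.warning("history inconsistency: %s", msg)
    return hist


def check_consistency(history: ReleaseHistory) -> list[str]:
    """Replay all events forward and compare predicted live sets with the
    per-release tables; returns human-readable mismatch descriptions."""
    msgs: list[str] = []
    if not history.releases:
        return msgs
    first = history.releases[0].name
    live = {w for w, r in history.table(first).items() if r.status == "live"}
    for prev, cur in zip(history.releases, history.releases[1:]):
        for ev in history.events_between(prev.name, cur.name):
            if ev.event_type == "merge":
                tgt = ev.target_wbids[0]
                live -= {s for s in ev.source_wbids if s != tgt}
                live.add(tgt)
            elif ev.event_type == "split":
                src = ev.source_wbids[0]
                if src not in ev.target_wbids:
                    # "split from" should retain a modified parent; a dropped
                    # parent is only legitimate with an accompanying kill
                    has_kill = any(
                        e.event_type == "kill"
                        and e.effective_release == ev.effective_release
                        and src in e.source_wbids
                        for e in history._all_events
                    )
                    if not has_kill:
                        msgs.append(
                            f"{ev.effective_release}: split of {src} drops the "
                            "parent without a formal kill"
                        )
                    live.discard(src)
                live |= set(ev.target_wbids)
            elif ev.event_type == "kill":
                live -= set(ev.source_wbids)
            elif ev.event_type in ("create", "resurrect"):
                live |= set(ev.target_wbids)
        table_live = {
            w for w, r in history.table(cur.name).items() if r.status == "live"
        }
        for w in sorted(live - table_live):
            msgs.append(f"{cur.name}: {w} expected live from events but absent/dead in table")
        for w in sorted(table_live - live):
            msgs.append(f"{cur.name}: {w} live in table but not predicted by events")
        live = table_live
    return msgs


def write_history(history: ReleaseHistory, directory) -> dict[str, str]:
    """Write correspondence tables and the event log as TSV; returns the
    path layout (used by the simulator CLI and round-trip tests)."""
    import os

    os.makedirs(directory, exist_ok=True)
    layout: dict[str, str] = {}
    for tag in history.releases:
        path = os.path.join(directory, f"correspondence_{tag.name}.tsv")
        layout[tag.name] = path
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(_CORR_COLUMNS)
            for rec in history.table(tag.name).values():
                w.writerow(
                    [
                        rec.wbid,
                        rec.sequence_name,
                        rec.public_name,
                        ",".join(rec.transcript_names),
                        rec.status,
                    ]
                )
    ev_path = os.path.join(directory, "events.tsv")
    layout["events"] = ev_path
    with open(ev_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_EVENT_COLUMNS)
        for ev in history.events:
            w.writerow(
                [
                    ev.effective_release,
                    ev.event_type,
                    ",".join(ev.source_wbids),
                    ",".join(ev.target_wbids),
                    ev.note,
                ]
            )
    return layout
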