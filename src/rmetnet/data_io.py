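"""Readers and writers for forced-choice response data.

Handles three tabular inputs — the participant response table, the item
answer key, and the optional participant trait table — plus graph export of
built response networks (GEXF, GraphML, or a plain edge-list CSV).

All word matching is exact string equality after Unicode NFC normalization
and whitespace trimming; there is no fuzzy matching, since answer keys are
authored files and a silent near-match would corrupt the network.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

#: Distinguished token for a trial where no choice was made within the
#: display window.  Raw CSVs may encode it as an empty cell or the literal
#: string "NR"; both are normalized to this token on read.
NO_RESPONSE = "NR"

#: Emotion-polarity tags an item may carry.
VALENCES = ("negative", "neutral", "positive")

#: Stimulus display window in milliseconds.  A response cannot be logged
#: after the item has left the screen, so any recorded reaction time must
#: not exceed this bound.
DISPLAY_WINDOW_MS = 8000.0

RESPONSE_COLUMNS = ("participant_id", "group", "item_id", "choice", "rt_ms")
KEY_COLUMNS = ("item_id", "target", "d1", "d2", "d3", "valence")


class ValidationError(ValueError):
    """Malformed or internally inconsistent input data."""


def normalize_word(word: str) -> str:
    """NFC-normalize and trim an answer word for exact comparison."""
    return unicodedata.normalize("NFC", str(word)).strip()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemSpec:
    """One test item: the correct answer word, its three distractors, and
    the emotion polarity of the target word."""

    item_id: int
    target: str
    distractors: tuple[str, str, str]
    valence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", normalize_word(self.target))
        object.__setattr__(
            self, "distractors", tuple(normalize_word(w) for w in self.distractors)
        )
        if len(self.distractors) != 3:
            raise ValidationError(
                f"item {self.item_id}: expected exactly 3 distractors, "
                f"got {len(self.distractors)}"
            )
        if self.valence not in VALENCES:
            raise ValidationError(
                f"item {self.item_id}: unknown valence {self.valence!r} "
                f"(expected one of {VALENCES})"
            )
        words = self.words
        if len(set(words)) != 4:
            raise ValidationError(
                f"item {self.item_id}: the four answer words must be pairwise "
                f"distinct, got {words}"
            )
        if any(not w for w in words):
            raise ValidationError(f"item {self.item_id}: empty answer word")

    @property
    def words(self) -> tuple[str, str, str, str]:
        """The four candidate answer words, target first."""
        return (self.target,) + self.distractors

    @property
    def answer_categories(self) -> tuple[str, str, str, str, str]:
        """The five answer categories: four words plus no-response."""
        return self.words + (NO_RESPONSE,)


@dataclass(frozen=True)
class AnswerKey:
    """Ordered collection of items with a recorded valence partition."""

    items: tuple[ItemSpec, ...]
    _by_id: Mapping[int, ItemSpec] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValidationError("answer key contains no items")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate item_id in answer key")
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise ValidationError(
                "item_ids must be unique and contiguous starting at 1, "
                f"got {sorted(ids)[:5]}..."
            )
        object.__setattr__(
            self, "items", tuple(sorted(self.items, key=lambda it: it.item_id))
        )
        object.__setattr__(self, "_by_id", {it.item_id: it for it in self.items})

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def item(self, item_id: int) -> ItemSpec:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise ValidationError(f"unknown item_id {item_id}") from None

    def valence_counts(self) -> dict[str, int]:
        """Number of items per valence, in canonical order."""
        counts = {v: 0 for v in VALENCES}
        for it in self.items:
            counts[it.valence] += 1
        return counts

    def items_for_valence(self, valence: str) -> tuple[ItemSpec, ...]:
        if valence not in VALENCES:
            raise ValidationError(f"unknown valence {valence!r}")
        return tuple(it for it in self.items if it.valence == valence)


@dataclass(frozen=True)
class ResponseRecord:
    """One participant's answer (or timeout) on one item."""

    participant_id: str
    group: str
    item_id: int
    choice: str
    rt_ms: float | None

    def __post_init__(self) -> None:
        if self.choice == NO_RESPONSE:
            if self.rt_ms is not None:
                raise ValidationError(
                    f"participant {self.participant_id}, item {self.item_id}: "
                    "a no-response trial cannot carry a reaction time"
                )
        else:
            if self.rt_ms is None:
                raise ValidationError(
                    f"participant {self.participant_id}, item {self.item_id}: "
                    "a responded trial must carry a reaction time"
                )
            if not (0.0 <= self.rt_ms <= DISPLAY_WINDOW_MS):
                raise ValidationError(
                    f"participant {self.participant_id}, item {self.item_id}: "
                    f"rt_ms={self.rt_ms} outside [0, {DISPLAY_WINDOW_MS:.0f}] "
                    "display window"
                )

    @property
    def is_no_response(self) -> bool:
        return self.choice == NO_RESPONSE


@dataclass(frozen=True)
class TraitRecord:
    """Trait questionnaire scores for one participant.

    ``aq`` maps AQ subscale names to scores; ``adir`` maps ADI-R subscale
    names to scores.  Either map may be empty (e.g. ADI-R is typically
    administered to the clinical group only).
    """

    participant_id: str
    group: str
    aq: Mapping[str, float]
    adir: Mapping[str, float]


# ---------------------------------------------------------------------------
# Answer key I/O
# ---------------------------------------------------------------------------


def read_answer_key(path: str | Path) -> AnswerKey:
    """Read an answer key from CSV (``item_id,target,d1,d2,d3,valence``) or
    an equivalent JSON list of item objects."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text(encoding="utf-8"))
        items = []
        for obj in raw:
            items.append(
                ItemSpec(
                    item_id=int(obj["item_id"]),
                    target=obj["target"],
                    distractors=tuple(obj["distractors"]),
                    valence=obj["valence"],
                )
            )
        return AnswerKey(items=tuple(items))

    df = pd.read_csv(path, dtype=str)
    missing = set(KEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"answer key missing columns: {sorted(missing)}")
    items = []
    for row in df.itertuples(index=False):
        distractors = tuple(
            "" if pd.isna(w) else str(w) for w in (row.d1, row.d2, row.d3)
        )
        if any(not normalize_word(w) for w in distractors):
            raise ValidationError(
                f"item {row.item_id}: fewer than 3 distractors provided"
            )
        items.append(
            ItemSpec(
                item_id=int(row.item_id),
                target=str(row.target),
                distractors=distractors,  # type: ignore[arg-type]
                valence=str(row.valence).strip().lower(),
            )
        )
    return AnswerKey(items=tuple(items))


def write_answer_key(key: AnswerKey, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [
            {
                "item_id": it.item_id,
                "target": it.target,
                "distractors": list(it.distractors),
                "valence": it.valence,
            }
            for it in key
        ]
        path.write_text(json.dumps(payload, indent=1, ensure_ascii=False), "utf-8")
        return
    df = pd.DataFrame(
        [
            {
                "item_id": it.item_id,
                "target": it.target,
                "d1": it.distractors[0],
                "d2": it.distractors[1],
                "d3": it.distractors[2],
                "valence": it.valence,
            }
            for it in key
        ]
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Response table I/O
# ---------------------------------------------------------------------------


def read_responses(path: str | Path, key: AnswerKey) -> list[ResponseRecord]:
    """Read and validate a response table against an answer key.

    Every row is checked: the item must exist in the key, the choice must be
    one of the item's five legal answer categories, and the reaction time
    must be present within the display window exactly when a choice was
    made.  Duplicate (participant, item) rows are rejected.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "group": str, "choice": str})
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"response table missing columns: {sorted(missing)}")

    records: list[ResponseRecord] = []
    seen: set[tuple[str, int]] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            item_id = int(row.item_id)
        except (TypeError, ValueError):
            raise ValidationError(f"row {pos}: non-integer item_id {row.item_id!r}")
        try:
            item = key.item(item_id)
        except ValidationError:
            raise ValidationError(f"row {pos}: unknown item_id {item_id}")

        raw_choice = row.choice
        if pd.isna(raw_choice) or normalize_word(raw_choice) in ("", NO_RESPONSE):
            choice = NO_RESPONSE
        else:
            choice = normalize_word(raw_choice)
            if choice not in item.words:
                raise ValidationError(
                    f"row {pos}: choice {choice!r} is not a legal answer for "
                    f"item {item_id} (expected one of {item.words} or "
                    f"{NO_RESPONSE!r})"
                )

        rt = None if pd.isna(row.rt_ms) else float(row.rt_ms)
        pid = str(row.participant_id)
        dup_key = (pid, item_id)
        if dup_key in seen:
            raise ValidationError(
                f"row {pos}: duplicate record for participant {pid!r}, item {item_id}"
            )
        seen.add(dup_key)
        try:
            rec = ResponseRecord(
                participant_id=pid,
                group=str(row.group),
                item_id=item_id,
                choice=choice,
                rt_ms=rt,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {pos}: {exc}") from None
        records.append(rec)
    return records


def write_responses(records: Iterable[ResponseRecord], path: str | Path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "group": r.group,
            "item_id": r.item_id,
            "choice": "" if r.is_no_response else r.choice,
            "rt_ms": "" if r.rt_ms is None else f"{r.rt_ms:.1f}",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trait table I/O
# ---------------------------------------------------------------------------


def read_traits(
    path: str | Path, known_ids: set[str] | None = None
) -> list[TraitRecord]:
    """Read a trait table.

    Columns prefixed ``aq_`` and ``adir_`` become the AQ and ADI-R subscale
    maps (empty cells are simply absent from the map).  If ``known_ids`` is
    given, every participant must appear in it.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "group": str})
    for col in ("participant_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"trait table missing column {col!r}")
    aq_cols = [c for c in df.columns if c.startswith("aq_")]
    adir_cols = [c for c in df.columns if c.startswith("adir_")]
    records = []
    for row in df.itertuples(index=False):
        pid = str(row.participant_id)
        if known_ids is not None and pid not in known_ids:
            raise ValidationError(
                f"trait table participant {pid!r} not present in response table"
            )
        values = row._asdict()
        aq = {
            c[len("aq_") :]: float(values[c]) for c in aq_cols if pd.notna(values[c])
        }
        adir = {
            c[len("adir_") :]: float(values[c])
            for c in adir_cols
            if pd.notna(values[c])
        }
        records.append(
            TraitRecord(participant_id=pid, group=str(row.group), aq=aq, adir=adir)
        )
    return records


def write_traits(records: Sequence[TraitRecord], path: str | Path) -> None:
    aq_names = sorted({name for r in records for name in r.aq})
    adir_names = sorted({name for r in records for name in r.adir})
    rows = []
    for r in records:
        row: dict[str, object] = {"participant_id": r.participant_id, "group": r.group}
        for name in aq_names:
            row[f"aq_{name}"] = r.aq.get(name, "")
        for name in adir_names:
            row[f"adir_{name}"] = r.adir.get(name, "")
        rows.append(row)
    cols = ["participant_id", "group"]
    cols += [f"aq_{n}" for n in aq_names] + [f"adir_{n}" for n in adir_names]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

GRAPH_FORMATS = ("gexf", "graphml", "edge_csv")


def export_graph(net, path: str | Path, fmt: str = "gexf") -> None:
    """Write a built response network to disk.

    ``gexf`` and ``graphml`` carry full node attributes (role, word,
    item_id) and integer edge weights; ``edge_csv`` is a plain
    ``source,target,weight`` list keyed by stable node-id strings.
    """
    from .network import to_networkx  # deferred: avoid import cycle

    if fmt not in GRAPH_FORMATS:
        raise ValidationError(
            f"unknown graph format {fmt!r} (expected one of {GRAPH_FORMATS})"
        )
    path = Path(path)
    graph = to_networkx(net)
    if fmt == "gexf":
        nx.write_gexf(graph, path)
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        rows = [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, index=False
        )


def read_graph(path: str | Path, fmt: str = "gexf") -> nx.DiGraph:
    """Read back an exported graph file (round-trip check / downstream use)."""
    if fmt not in GRAPH_FORMATS:
        raise ValidationError(
            f"unknown graph format {fmt!r} (expected one of {GRAPH_FORMATS})"
        )
    path = Path(path)
    if fmt == "gexf":
        return nx.DiGraph(nx.read_gexf(path))
    if fmt == "graphml":
        return nx.DiGraph(nx.read_graphml(path))
    df = pd.read_csv(path)
    graph = nx.DiGraph()
    for row in df.itertuples(index=False):
        graph.add_edge(str(row.source), str(row.target), weight=int(row.weight))
    return graph
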