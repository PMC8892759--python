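"""Directed response-distribution network construction.

Each test item contributes one *target node* (the item's correct answer,
standing for the photograph).  The five answer categories a participant can
produce — the four candidate words plus the no-response condition — are
*source nodes*, and every observed choice adds weight to a directed edge
from its source node into the item's target node.  Choosing the correct
word also creates an edge (from the target word's shared source-word
identity into the item-scoped target node), so an item's in-degree can
reach the full ceiling of 5 when every answer category is observed.

Node identity conventions:

* target nodes are item-scoped (one per item);
* source-word nodes are shared across items and keyed by the word string,
  so two items offering the same distractor share one source node;
* no-response nodes are item-scoped by default, with a ``global`` mode
  collapsing them into a single node (both conventions are defensible for
  this family of networks, so the choice is a configuration switch).

Only observed choices instantiate nodes and edges: there are no
zero-weight edges, and the two groups' networks built from identical
stimuli generally differ in node and edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .data_io import NO_RESPONSE, AnswerKey, ResponseRecord, ValidationError

NrNodeMode = Literal["per-item", "global"]

#: Order of the five answer-category slots in a binary-matrix row.
CATEGORY_SLOTS = ("target", "d1", "d2", "d3", "no_response")


@dataclass(frozen=True)
class NodeRef:
    """Identity of one network node.

    ``role`` is ``target``, ``source_word`` or ``no_response``.  ``word``
    is empty for no-response nodes; ``item_id`` is set for item-scoped
    nodes (targets and per-item no-response) and ``None`` for shared
    source-word nodes and the global no-response node.
    """

    role: str
    word: str = ""
    item_id: int | None = None

    def node_id(self) -> str:
        """Stable string id used in graph exports."""
        if self.role == "target":
            return f"item{self.item_id:03d}:{self.word}"
        if self.role == "source_word":
            return f"word:{self.word}"
        if self.item_id is None:
            return "no_response"
        return f"no_response:item{self.item_id:03d}"


def _sort_key(ref: NodeRef) -> tuple:
    # deterministic node order: item-scoped first by item_id, then word
    return (ref.item_id if ref.item_id is not None else -1, ref.word, ref.role)


@dataclass(frozen=True)
class ResponseNetwork:
    """One group's aggregated choice network.

    ``edges`` maps (source NodeRef, target NodeRef) to a positive integer
    weight — the number of participants in the group who produced that
    answer category for that item.  ``item_index`` maps each item_id to
    ``(target_node, candidate_nodes)`` where ``candidate_nodes`` are the
    five possible source nodes for the item in slot order.
    """

    group: str
    n_participants: int
    nr_node: NrNodeMode
    edges: Mapping[tuple[NodeRef, NodeRef], int]
    item_index: Mapping[int, tuple[NodeRef, tuple[NodeRef, ...]]]
    nodes: frozenset[NodeRef] = field(init=False, compare=False)

    def __post_init__(self) -> None:
        observed: set[NodeRef] = set()
        for (src, tgt), w in self.edges.items():
            if w < 1:
                raise ValidationError("zero-weight edge in response network")
            observed.add(src)
            observed.add(tgt)
        object.__setattr__(self, "nodes", frozenset(observed))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_items(self) -> int:
        return len(self.item_index)

    @property
    def total_weight(self) -> int:
        return sum(self.edges.values())

    def in_edges(self, item_id: int) -> dict[NodeRef, int]:
        """Source node -> weight for all edges into an item's target node."""
        try:
            target, _ = self.item_index[item_id]
        except KeyError:
            raise ValidationError(f"unknown item_id {item_id}") from None
        return {src: w for (src, tgt), w in self.edges.items() if tgt == target}


def build_binary_matrix(
    records: Iterable[ResponseRecord],
    key: AnswerKey,
    group: str,
) -> dict[int, np.ndarray]:
    """Aggregate one group's raw choices into per-item count vectors.

    Returns, for every item, a length-5 integer vector counting choices of
    (target, d1, d2, d3, no-response).  Each vector sums to the number of
    participants in the group: every participant either answers or times
    out on every item, and a coverage hole is an error.
    """
    group_records = [r for r in records if r.group == group]
    if not group_records:
        raise ValidationError(f"no records for group {group!r}")
    participants = {r.participant_id for r in group_records}
    n = len(participants)

    counts = {it.item_id: np.zeros(5, dtype=int) for it in key}
    for rec in group_records:
        item = key.item(rec.item_id)
        slot = item.answer_categories.index(rec.choice)
        counts[rec.item_id][slot] += 1

    for item_id, vec in counts.items():
        total = int(vec.sum())
        if total == 0:
            raise ValidationError(
                f"group {group!r}: no responses recorded for item {item_id}"
            )
        if total != n:
            raise ValidationError(
                f"group {group!r}, item {item_id}: {total} responses for "
                f"{n} participants (incomplete or duplicated coverage)"
            )
    return counts


def build_response_network(
    records: Iterable[ResponseRecord],
    key: AnswerKey,
    group: str,
    nr_node: NrNodeMode = "per-item",
) -> ResponseNetwork:
    """Build the group's directed network from validated responses.

    One edge per observed (answer category -> item target) pair, weighted
    by the number of participants who made that choice.  Total edge weight
    therefore equals participants x items, exactly.
    """
    if nr_node not in ("per-item", "global"):
        raise ValidationError(f"unknown nr_node mode {nr_node!r}")
    records = list(records)
    counts = build_binary_matrix(records, key, group)
    n_participants = len({r.participant_id for r in records if r.group == group})

    edges: dict[tuple[NodeRef, NodeRef], int] = {}
    item_index: dict[int, tuple[NodeRef, tuple[NodeRef, ...]]] = {}
    for item in key:
        target_node = NodeRef(role="target", word=item.target, item_id=item.item_id)
        nr_ref = NodeRef(
            role="no_response",
            item_id=item.item_id if nr_node == "per-item" else None,
        )
        candidates = tuple(
            NodeRef(role="source_word", word=w) for w in item.words
        ) + (nr_ref,)
        item_index[item.item_id] = (target_node, candidates)

        vec = counts[item.item_id]
        for slot, src in enumerate(candidates):
            if vec[slot] > 0:
                edges[(src, target_node)] = int(vec[slot])

    return ResponseNetwork(
        group=group,
        n_participants=n_participants,
        nr_node=nr_node,
        edges=edges,
        item_index=item_index,
    )


def to_networkx(net: ResponseNetwork) -> nx.DiGraph:
    """Convert to a networkx DiGraph with deterministic node order.

    Node attributes: ``role``, ``word`` (label), and ``item_id`` for
    item-scoped nodes.  Edge attribute: integer ``weight``.
    """
    graph = nx.DiGraph()
    graph.graph["group"] = net.group
    graph.graph["n_participants"] = net.n_participants
    for ref in sorted(net.nodes, key=_sort_key):
        attrs = {"role": ref.role, "word": ref.word}
        if ref.item_id is not None:
            attrs["item_id"] = ref.item_id
        graph.add_node(ref.node_id(), **attrs)
    for (src, tgt), w in sorted(
        net.edges.items(), key=lambda kv: (_sort_key(kv[0][1]), _sort_key(kv[0][0]))
    ):
        graph.add_edge(src.node_id(), tgt.node_id(), weight=int(w))
    return graph
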