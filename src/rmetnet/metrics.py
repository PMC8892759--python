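"""Network indices and behavioral measures.

Two item-level network indices summarize how spread-out a group's choices
are:

* **in-degree** — the number of distinct answer categories the group
  produced for an item, i.e. distinct in-edges to the item's target node.
  Ranges from 1 (everyone picked the same answer) to 5 (all four words and
  the no-response condition were observed).
* **item density** — realized connections among the item's five candidate
  nodes divided by the 10 potential unordered pairs.  Under the
  source-to-target topology used here the realized connections are exactly
  the in-edges, so item density is in-degree / 10 and is capped at 0.5;
  the denominator of 10 is kept as the definitional convention.

The whole-network density uses the directed-graph convention
``e / (n * (n - 1))`` and is reported rounded half-even to 3 decimals.

Behavioral measures are percent accuracy (no-response counts as incorrect
— a non-answer cannot be correct) and mean reaction time over responded
trials.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .data_io import VALENCES, AnswerKey, ResponseRecord, ValidationError
from .network import ResponseNetwork

#: Unordered pairs among an item's five candidate nodes.
POTENTIAL_ITEM_CONNECTIONS = 10


def round_half_even(x: float, digits: int = 3) -> float:
    """Banker's rounding as used for reported density values."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


def item_in_degree(net: ResponseNetwork, item_id: int) -> int:
    """Distinct in-edges to the item's target node (1..5 with any data)."""
    return len(net.in_edges(item_id))


def item_density(net: ResponseNetwork, item_id: int) -> float:
    """Realized connections for the item over its 10 potential ones."""
    return item_in_degree(net, item_id) / POTENTIAL_ITEM_CONNECTIONS


def density_from_counts(n_nodes: int, n_edges: int) -> float:
    """Directed density ``e / (n (n-1))`` from printed node/edge counts."""
    if n_nodes < 2:
        raise ValidationError(
            f"density undefined for n_nodes={n_nodes} (need at least 2)"
        )
    if n_edges < 0:
        raise ValidationError("negative edge count")
    return n_edges / (n_nodes * (n_nodes - 1))


def network_density(net: ResponseNetwork, digits: int | None = None) -> float:
    """Whole-network density; pass ``digits`` for the reporting rounding."""
    dens = density_from_counts(net.n_nodes, net.n_edges)
    return dens if digits is None else round_half_even(dens, digits)


def in_degree_vector(
    net: ResponseNetwork,
    key: AnswerKey,
    valence: str | None = None,
) -> list[int]:
    """Per-item in-degrees in item_id order, optionally one valence stratum."""
    if valence is not None and valence not in VALENCES:
        raise ValidationError(f"unknown valence filter {valence!r}")
    return [
        item_in_degree(net, it.item_id)
        for it in key
        if valence is None or it.valence == valence
    ]


def participant_accuracy(
    records: Iterable[ResponseRecord],
    key: AnswerKey,
    participant_id: str,
) -> float:
    """Percent of items answered correctly; timeouts count as incorrect."""
    mine = [r for r in records if r.participant_id == participant_id]
    if not mine:
        raise ValidationError(f"unknown participant {participant_id!r}")
    if len(mine) != key.n_items:
        raise ValidationError(
            f"participant {participant_id!r} has {len(mine)} records for "
            f"{key.n_items} items"
        )
    correct = sum(1 for r in mine if r.choice == key.item(r.item_id).target)
    return 100.0 * correct / key.n_items


def participant_mean_rt(
    records: Iterable[ResponseRecord],
    participant_id: str,
) -> float | None:
    """Mean reaction time (ms) over responded trials; None if all timed out."""
    mine = [r for r in records if r.participant_id == participant_id]
    if not mine:
        raise ValidationError(f"unknown participant {participant_id!r}")
    rts = [r.rt_ms for r in mine if r.rt_ms is not None]
    if not rts:
        warnings.warn(
            f"participant {participant_id!r} made no responses; mean RT undefined",
            stacklevel=2,
        )
        return None
    return float(sum(rts) / len(rts))


def per_item_table(net: ResponseNetwork, key: AnswerKey) -> pd.DataFrame:
    """Tidy per-item metrics: item_id, valence, in_degree, item_density, group."""
    rows = [
        {
            "item_id": it.item_id,
            "valence": it.valence,
            "in_degree": item_in_degree(net, it.item_id),
            "item_density": item_density(net, it.item_id),
            "group": net.group,
        }
        for it in key
    ]
    return pd.DataFrame(rows)


def network_summary(net: ResponseNetwork, digits: int = 3) -> pd.DataFrame:
    """One-row whole-network summary with the reported (rounded) density."""
    return pd.DataFrame(
        [
            {
                "group": net.group,
                "n_participants": net.n_participants,
                "n_nodes": net.n_nodes,
                "n_edges": net.n_edges,
                "network_density": network_density(net, digits=digits),
            }
        ]
    )
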