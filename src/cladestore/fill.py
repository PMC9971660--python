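"""Summarise raw values and propagate estimates through the taxonomy.

Every taxon with raw measurements for an attribute gets a single
reported value chosen by the attribute's ordered summary rules (first
applicable statistic wins).  Missing values are then inferred on the
tree in two passes:

* **UP** (post-order): an internal node without its own measurement
  receives the ancestor-summary statistic (median for numeric, mode for
  keyword by default) of its children's direct or descendant-derived
  values — never of ancestor-derived values, which would be circular.
  Provenance: ``descendant`` (orange).
* **DOWN** (pre-order): any node still without a value copies the value
  of its nearest informative ancestor (fewest edges; the backbone has no
  branch lengths).  Provenance: ``ancestor`` (red), with the source
  taxon recorded.

Direct summaries are never overwritten.  Traversal can be barred by a
clade (the named node and its whole subtree are untouched and leak no
values) or by a rank (nodes more inclusive than the limit rank are
barred), in both directions.
"""

from __future__ import annotations

import logging
import statistics
from typing import Optional

from .ingest import AttributeDefinition
from .taxonomy import AttributeSlot, Estimate, Store, Summary, rank_level

logger = logging.getLogger("cladestore")

__all__ = ["summarise", "refresh_summary", "fill_attribute", "fill_all", "reported"]

_NUMERIC = ("integer", "float")


def _flatten(values: list) -> list:
    out = []
    for v in values:
        out.extend(v) if isinstance(v, list) else out.append(v)
    return out


def _mode(values: list, enum: Optional[list]) -> object:
    """Most frequent value; ties broken by enum priority, then ascending."""
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    tied = [v for v, c in counts.items() if c == top]
    if enum:
        labels = [str(e).casefold() for e in enum]

        def enum_key(v):
            lv = str(v).casefold()
            return labels.index(lv) if lv in labels else len(labels)

        return min(tied, key=lambda v: (enum_key(v), str(v)))
    try:
        return min(tied)
    except TypeError:
        return min(tied, key=str)


def _median(values: list, numeric: bool):
    if numeric:
        return statistics.median(values)
    # non-averageable types (dates as ISO strings): lower middle
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def summarise(
    values: list,
    rules: list[str],
    enum: Optional[list] = None,
    source_priority: Optional[list] = None,
    sources: Optional[list] = None,
    value_type: str = "float",
) -> Summary:
    """Reduce a non-empty list of typed values to one reported value.

    The first rule in *rules* applicable to the value type decides the
    statistic.  ``min``/``max`` fields are recorded for numeric and
    ordered-keyword (by enum position) attributes; ``count`` is the
    number of raw values.
    """
    if not values:
        raise ValueError("summarise requires a non-empty value list")
    numeric = value_type in _NUMERIC
    ordered = value_type == "ordered_keyword"
    flat = _flatten(values)

    def enum_pos(v):
        labels = [str(e).casefold() for e in enum]
        return len(labels) - labels.index(str(v).casefold())

    chosen = None
    value = None
    for rule in rules:
        if rule in ("min", "max") and (numeric or ordered or value_type == "date"):
            if ordered:
                pick = min if rule == "min" else max
                value = pick(flat, key=enum_pos)
            else:
                value = (min if rule == "min" else max)(flat)
        elif rule == "mean" and numeric:
            value = statistics.fmean(flat)
        elif rule == "median" and (numeric or value_type == "date"):
            value = _median(flat, numeric)
        elif rule == "mode":
            value = _mode(flat, enum)
        elif rule == "list":
            value = sorted(set(flat), key=str)
        elif rule == "priority-by-enum":
            if not enum:
                raise ValueError("priority-by-enum requires an ordered enum")
            value = max(flat, key=enum_pos)
        elif rule == "priority-by-source":
            if not source_priority or not sources:
                raise ValueError("priority-by-source requires source_priority and sources")
            order = {s: i for i, s in enumerate(source_priority)}
            idx = min(
                range(len(values)),
                key=lambda i: order.get(sources[i], len(order)),
            )
            value = values[idx]
        else:
            continue
        chosen = rule
        break
    if chosen is None:
        raise ValueError(f"no applicable summary rule in {rules} for type {value_type}")

    lo = hi = None
    if numeric or value_type == "date":
        lo, hi = min(flat), max(flat)
    elif ordered:
        lo, hi = min(flat, key=enum_pos), max(flat, key=enum_pos)
    return Summary(value=value, statistic=chosen, count=len(values), min=lo, max=hi)


def refresh_summary(slot: AttributeSlot, definition: AttributeDefinition) -> None:
    """Recompute a slot's summary from its raw values (direct provenance)."""
    if not slot.raw:
        slot.summary = None
        return
    slot.summary = summarise(
        [rv.value for rv in slot.raw],
        definition.summary_rules or ["median", "mode", "list"],
        enum=definition.enum or None,
        source_priority=definition.source_priority,
        sources=[rv.source_name for rv in slot.raw],
        value_type=definition.value_type,
    )
    slot.estimate = Estimate(slot.summary.value, "direct")


def _ancestor_statistic(definition: AttributeDefinition) -> str:
    if definition.traverse.statistic:
        return definition.traverse.statistic
    return "median" if definition.value_type in _NUMERIC else "mode"


def _apply_statistic(stat: str, values: list, definition: AttributeDefinition):
    enum = definition.enum or None
    numeric = definition.value_type in _NUMERIC
    if stat == "median":
        return _median(values, numeric)
    if stat == "mode":
        return _mode(values, enum)
    if stat == "mean":
        return statistics.fmean(values)
    if stat == "min":
        if definition.value_type == "ordered_keyword":
            return min(values, key=definition.enum_position)
        return min(values)
    if stat == "max":
        if definition.value_type == "ordered_keyword":
            return max(values, key=definition.enum_position)
        return max(values)
    raise ValueError(f"unsupported ancestor-summary statistic {stat!r}")


def _blocked_nodes(store: Store, definition: AttributeDefinition) -> set[str]:
    limit = definition.traverse.limit
    if not limit:
        return set()
    blocked: set[str] = set()
    if "clade" in limit:
        label = str(limit["clade"])
        anchors = [label] if label in store.taxa else store.taxa_named(label)
        for a in anchors:
            blocked |= store.descendants(a, include_self=True)
    if "rank" in limit:
        cutoff = rank_level(str(limit["rank"]))
        if cutoff is None:
            raise ValueError(f"unknown barrier rank {limit['rank']!r}")
        for tid, doc in store.taxa.items():
            lvl = rank_level(doc.rank)
            if lvl is not None and lvl < cutoff:
                blocked.add(tid)
    return blocked


def fill_attribute(store: Store, attribute: str) -> int:
    """Infer missing values for one taxon-index attribute.

    Returns the number of descendant/ancestor estimates newly written or
    changed (a rerun on unchanged data returns 0).  Stale estimates are
    cleared.  Raises on unknown attributes, assembly-index attributes,
    and attributes whose traverse direction is ``none``.
    """
    if attribute not in store.attributes:
        raise KeyError(f"unknown attribute {attribute!r}")
    definition: AttributeDefinition = store.attributes[attribute]
    if definition.index != "taxon":
        raise ValueError(f"fill applies to the taxon index only, not {attribute!r}")
    direction = definition.traverse.direction
    if direction == "none":
        raise ValueError(f"attribute {attribute!r} has traverse.direction none")
    if definition.value_type == "list":
        raise ValueError("list attributes have no ancestor-summary statistic; set traverse none")

    blocked = _blocked_nodes(store, definition)
    stat = _ancestor_statistic(definition)

    # refresh direct summaries (idempotent) and seed available values
    values: dict[str, object] = {}
    provenance: dict[str, str] = {}
    for tid, doc in store.taxa.items():
        slot = doc.attributes.get(attribute)
        if slot and slot.raw:
            refresh_summary(slot, definition)
            values[tid] = slot.summary.value
            provenance[tid] = "direct"

    if direction in ("up", "both"):
        for node in store.postorder():
            if node in blocked or node in values:
                continue
            child_vals = [
                values[c]
                for c in store.sorted_children(node)
                if c not in blocked and c in values
            ]
            if child_vals:
                values[node] = _apply_statistic(stat, child_vals, definition)
                provenance[node] = "descendant"

    ancestor_src: dict[str, str] = {}
    if direction in ("down", "both"):
        carry: dict[str, Optional[tuple]] = {store.root_id: None}
        for node in store.preorder():
            inherited = carry.get(node)
            if node in blocked:
                payload = None
            elif node in values:
                payload = (values[node], node)
            else:
                payload = inherited
                if inherited is not None:
                    values[node] = inherited[0]
                    provenance[node] = "ancestor"
                    ancestor_src[node] = inherited[1]
            for c in store.children.get(node, []):
                carry[c] = payload

    # write estimates, counting changes
    changed = 0
    for tid, doc in store.taxa.items():
        slot = doc.attributes.get(attribute)
        if slot and slot.raw:
            continue  # direct; refresh_summary already set the estimate
        prov = provenance.get(tid)
        if prov is None:
            if slot and slot.estimate is not None:
                slot.estimate = None  # stale
            continue
        est = Estimate(values[tid], prov, ancestor_src.get(tid))
        if slot is None:
            slot = store.taxa[tid].attributes[attribute] = AttributeSlot()
        if slot.estimate != est:
            slot.estimate = est
            changed += 1
    return changed


def fill_all(store: Store) -> dict[str, int]:
    """Fill every eligible attribute (taxon index, traverse != none).

    Attributes are processed in name order; per-attribute failures are
    logged and reported without aborting the batch.
    """
    counts: dict[str, int] = {}
    for name in sorted(store.attributes):
        definition = store.attributes[name]
        if definition.index != "taxon" or definition.traverse.direction == "none":
            continue
        try:
            counts[name] = fill_attribute(store, name)
        except Exception as e:  # noqa: BLE001 - batch reports, does not abort
            logger.error("fill failed for %s: %s", name, e)
            counts[name] = -1
    return counts


def reported(slot: Optional[AttributeSlot], include_estimates: bool = True):
    """The (value, provenance) pair a query sees for a slot, or None.

    With ``include_estimates=False`` only direct and descendant-derived
    values are visible; ancestor-derived values are hidden.
    """
    if slot is None or slot.estimate is None:
        return None
    est = slot.estimate
    if not include_estimates and est.provenance == "ancestor":
        return None
    return est.value, est.provenance
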