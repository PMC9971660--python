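"""Aggregation reports over query results.

Five report types: per-rank counts (``xPerRank``), subset ratios
(``arc``), binned value distributions (``histogram``), paired-value
plots that degrade to heatmaps above a size threshold (``scatter``),
and annotated minimal spanning subtrees (``tree``) exportable as
Newick, PhyloXML or TSV.

Bin boundaries are half-open, lower-inclusive; values equal to the top
edge are clamped into the last bin so totals conserve.  Log binning is
base 10.  Documents matching the query but lacking a value are never
silently dropped: they are counted in an explicit ``no_value``
remainder.
"""

from __future__ import annotations

import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional

from .fill import reported
from .query import QueryExpression, SearchOptions, evaluate, parse_query
from .taxonomy import Store, sort_key

__all__ = [
    "HistogramReport",
    "ScatterReport",
    "TreeNode",
    "TreeReport",
    "report_arc",
    "report_histogram",
    "report_scatter",
    "report_tree",
    "report_xPerRank",
    "DEFAULT_RANKS",
    "DEFAULT_SCATTER_THRESHOLD",
    "PROVENANCE_COLORS",
]

DEFAULT_RANKS = [
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
]

DEFAULT_SCATTER_THRESHOLD = 10_000

PROVENANCE_COLORS = {"direct": "green", "descendant": "orange", "ancestor": "red"}


def _as_ast(query, store) -> QueryExpression:
    if isinstance(query, QueryExpression):
        return query
    return parse_query(query, registry=store.attributes)


# ---------------------------------------------------------------------------
# xPerRank


def report_xPerRank(
    query,
    store: Store,
    ranks: Optional[list] = None,
    options: Optional[SearchOptions] = None,
) -> dict:
    """Number of matching documents at each requested rank."""
    ranks = list(ranks) if ranks else list(DEFAULT_RANKS)
    options = options or SearchOptions()
    docs = evaluate(_as_ast(query, store), store, options)
    counts = {r: 0 for r in ranks}
    for doc in docs:
        rank = doc.rank if hasattr(doc, "rank") else store.taxa[doc.taxon_id].rank
        if rank in counts:
            counts[rank] += 1
    return {
        "report_type": "xPerRank",
        "queries": [_render(query)],
        "total": len(docs),
        "per_rank": counts,
    }


def _render(query) -> str:
    return query.render() if isinstance(query, QueryExpression) else str(query)


# ---------------------------------------------------------------------------
# arc


def report_arc(query_x, query_y, store: Store, options: Optional[SearchOptions] = None) -> dict:
    """Count of query x as a subset of query y, with their ratio.

    The ratio is reported as None when y matches nothing.
    """
    from .query import count as _count

    options = options or SearchOptions()
    x = _count(_as_ast(query_x, store), store, options)
    y = _count(_as_ast(query_y, store), store, options)
    return {
        "report_type": "arc",
        "queries": [_render(query_x), _render(query_y)],
        "x_count": x,
        "y_count": y,
        "ratio": (x / y) if y else None,
    }


# ---------------------------------------------------------------------------
# histogram


@dataclass
class HistogramReport:
    report_type: str
    queries: list
    attribute: str
    bins: list  # (lo, hi) edges in raw units
    counts: list
    per_category: dict  # category label -> per-bin counts
    no_value: int
    unbinnable: int
    total: int


def _bin_edges(values, binning: Optional[dict]):
    """Half-open [lo, hi) edges from a width or count specification."""
    binning = binning or {}
    log = bool(binning.get("log"))
    xs = [math.log10(v) for v in values] if log else list(values)
    lo, hi = min(xs), max(xs)
    if "width" in binning:
        w = float(binning["width"])
        start = math.floor(lo / w) * w
        n = max(1, math.ceil((hi - start) / w + 1e-9))
        if start + n * w <= hi:
            n += 1
        edges = [start + i * w for i in range(n + 1)]
    else:
        n = int(binning.get("count", 10))
        if hi == lo:
            hi = lo + 1
        w = (hi - lo) / n
        edges = [lo + i * w for i in range(n + 1)]
    if log:
        edges = [10**e for e in edges]
    return edges


def _bin_index(value, edges, log) -> Optional[int]:
    x = value
    if x < edges[0] or x > edges[-1]:
        return None
    for i in range(len(edges) - 1):
        if edges[i] <= x < edges[i + 1]:
            return i
    return len(edges) - 2  # value == top edge clamps into last bin


def report_histogram(
    query,
    attribute: str,
    store: Store,
    binning: Optional[dict] = None,
    category: Optional[str] = None,
    options: Optional[SearchOptions] = None,
) -> HistogramReport:
    """Binned distribution of an attribute over a query result.

    *binning* is ``{"width": w}`` or ``{"count": n}``, optionally with
    ``"log": True`` for base-10 log-scaled bins (positive values only;
    non-positive values land in the ``unbinnable`` remainder).  With a
    *category* attribute, per-category stacks sum to the bin totals.
    """
    options = options or SearchOptions()
    definition = store.attributes.get(attribute)
    if definition is None or definition.value_type not in ("integer", "float", "date"):
        raise ValueError(f"attribute {attribute!r} is not binnable")
    if definition.value_type == "date":
        raise NotImplementedError("date histograms: convert dates upstream")
    docs = evaluate(_as_ast(query, store), store, options)
    log = bool((binning or {}).get("log"))

    pairs = []  # (value, category label)
    no_value = 0
    unbinnable = 0
    for doc in docs:
        rep = reported(doc.attributes.get(attribute), options.include_estimates)
        if rep is None:
            no_value += 1
            continue
        value = rep[0]
        if log and value <= 0:
            unbinnable += 1
            continue
        cat = "all"
        if category:
            crep = reported(doc.attributes.get(category), options.include_estimates)
            cat = str(crep[0]) if crep else "none"
        pairs.append((float(value), cat))

    if pairs:
        edges = _bin_edges([v for v, _ in pairs], binning)
        nbins = len(edges) - 1
        counts = [0] * nbins
        per_cat: dict[str, list] = {}
        for value, cat in pairs:
            i = _bin_index(value, edges, log)
            counts[i] += 1
            per_cat.setdefault(cat, [0] * nbins)[i] += 1
        bins = [(edges[i], edges[i + 1]) for i in range(nbins)]
    else:
        bins, counts, per_cat = [], [], {}
    return HistogramReport(
        report_type="histogram",
        queries=[_render(query)],
        attribute=attribute,
        bins=bins,
        counts=counts,
        per_category=per_cat,
        no_value=no_value,
        unbinnable=unbinnable,
        total=len(docs),
    )


# ---------------------------------------------------------------------------
# scatter


@dataclass
class ScatterReport:
    report_type: str
    queries: list
    attributes: list
    points: Optional[list]  # (doc_id, x, y[, category]) when under threshold
    cells: Optional[list]  # (xlo, xhi, ylo, yhi, count) heatmap otherwise
    point_count: int
    no_value: int
    total: int
    per_category: dict = field(default_factory=dict)


def report_scatter(
    query,
    attr_x: str,
    attr_y: str,
    store: Store,
    threshold: int = DEFAULT_SCATTER_THRESHOLD,
    binning: Optional[dict] = None,
    category: Optional[str] = None,
    options: Optional[SearchOptions] = None,
) -> ScatterReport:
    """Paired attribute values, or a 2-D heatmap above *threshold* points.

    Documents contribute one point when both values are present; the
    heatmap's cell counts sum to the point count.
    """
    options = options or SearchOptions()
    docs = evaluate(_as_ast(query, store), store, options)
    points = []
    no_value = 0
    per_category: dict[str, int] = {}
    for doc in docs:
        rx = reported(doc.attributes.get(attr_x), options.include_estimates)
        ry = reported(doc.attributes.get(attr_y), options.include_estimates)
        if rx is None or ry is None:
            no_value += 1
            continue
        doc_id = doc.taxon_id if hasattr(doc, "scientific_name") else doc.assembly_id
        cat = None
        if category:
            crep = reported(doc.attributes.get(category), options.include_estimates)
            cat = str(crep[0]) if crep else "none"
            per_category[cat] = per_category.get(cat, 0) + 1
        points.append((doc_id, float(rx[0]), float(ry[0]), cat))

    if len(points) <= threshold:
        return ScatterReport(
            "scatter",
            [_render(query)],
            [attr_x, attr_y],
            points,
            None,
            len(points),
            no_value,
            len(docs),
            per_category,
        )
    xs = [p[1] for p in points]
    ys = [p[2] for p in points]
    log = bool((binning or {}).get("log"))
    if log:
        positive = [p for p in points if p[1] > 0 and p[2] > 0]
        dropped = len(points) - len(positive)
        no_value += dropped
        points = positive
        xs = [p[1] for p in points]
        ys = [p[2] for p in points]
    xedges = _bin_edges(xs, binning)
    yedges = _bin_edges(ys, binning)
    grid: dict[tuple, int] = {}
    for _, x, y, _cat in points:
        i = _bin_index(x, xedges, log)
        j = _bin_index(y, yedges, log)
        grid[(i, j)] = grid.get((i, j), 0) + 1
    cells = [
        (xedges[i], xedges[i + 1], yedges[j], yedges[j + 1], c)
        for (i, j), c in sorted(grid.items())
    ]
    return ScatterReport(
        "scatter",
        [_render(query)],
        [attr_x, attr_y],
        None,
        cells,
        len(points),
        no_value,
        len(docs),
        per_category,
    )


# ---------------------------------------------------------------------------
# tree


@dataclass
class TreeNode:
    taxon_id: str
    scientific_name: str
    rank: str
    children: list = field(default_factory=list)
    matched_descendants: int = 0
    value: object = None
    provenance: Optional[str] = None
    color: Optional[str] = None


@dataclass
class TreeReport:
    report_type: str
    queries: list
    attribute: Optional[str]
    root: TreeNode
    node_count: int
    matched_count: int

    def node_index(self) -> dict[str, TreeNode]:
        out = {}
        stack = [self.root]
        while stack:
            n = stack.pop()
            out[n.taxon_id] = n
            stack.extend(n.children)
        return out


def report_tree(
    query,
    store: Store,
    attribute: Optional[str] = None,
    options: Optional[SearchOptions] = None,
) -> TreeReport:
    """Minimal spanning subtree of the matched taxa, up to their MRCA.

    Node annotations: count of matched taxa at-or-below the node, the
    reported attribute value (if requested) and its traffic-light
    provenance class.  Taxon-level only; assembly-index queries error.
    """
    options = options or SearchOptions()
    if options.index != "taxon":
        raise ValueError("tree reports are taxon-level; use the taxon index")
    docs = evaluate(_as_ast(query, store), store, options)
    if not docs:
        raise ValueError("tree report requires a query matching at least one taxon")
    matched = {d.taxon_id for d in docs}

    # MRCA: deepest node on every matched taxon's self-inclusive root path
    paths = []
    for tid in matched:
        doc = store.taxa[tid]
        paths.append([tid] + [a.taxon_id for a in doc.lineage])
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    mrca = next(t for t in paths[0] if t in common)

    node_ids: set[str] = set()
    for p in paths:
        for t in p:
            node_ids.add(t)
            if t == mrca:
                break

    nodes: dict[str, TreeNode] = {}
    for tid in node_ids:
        doc = store.taxa[tid]
        n = TreeNode(tid, doc.scientific_name, doc.rank)
        if attribute:
            rep = reported(doc.attributes.get(attribute), options.include_estimates)
            if rep:
                n.value, n.provenance = rep
                n.color = PROVENANCE_COLORS[rep[1]]
        nodes[tid] = n
    for tid, n in nodes.items():
        if tid == mrca:
            continue
        parent = store.taxa[tid].parent_id
        nodes[parent].children.append(n)
    for n in nodes.values():
        n.children.sort(key=lambda c: sort_key(c.taxon_id))

    # matched descendant counts (self-inclusive) bottom-up
    def fill_counts(n: TreeNode) -> int:
        c = (1 if n.taxon_id in matched else 0) + sum(fill_counts(ch) for ch in n.children)
        n.matched_descendants = c
        return c

    fill_counts(nodes[mrca])
    return TreeReport(
        "tree", [_render(query)], attribute, nodes[mrca], len(nodes), len(matched)
    )


# -- exports ----------------------------------------------------------------

_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _newick_label(name: str) -> str:
    if _SAFE_LABEL.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def to_newick(tree: TreeReport) -> str:
    """Newick with scientific-name labels (quoted when needed), no branch lengths."""

    def emit(n: TreeNode) -> str:
        label = _newick_label(n.scientific_name)
        if not n.children:
            return label
        return "(" + ",".join(emit(c) for c in n.children) + ")" + label

    return emit(tree.root) + ";"


def to_phyloxml(tree: TreeReport) -> str:
    """PhyloXML export; attribute summaries are carried as property elements."""
    NS = "http://www.phyloxml.org"
    ET.register_namespace("", NS)
    root = ET.Element(f"{{{NS}}}phyloxml")
    phylogeny = ET.SubElement(root, f"{{{NS}}}phylogeny", rooted="true")

    def emit(n: TreeNode, parent) -> None:
        clade = ET.SubElement(parent, f"{{{NS}}}clade")
        ET.SubElement(clade, f"{{{NS}}}name").text = n.scientific_name
        props = {
            "taxon_id": n.taxon_id,
            "rank": n.rank,
            "matched_descendants": n.matched_descendants,
        }
        if n.value is not None:
            props[tree.attribute] = n.value
            props["provenance"] = n.provenance
        for ref, val in props.items():
            p = ET.SubElement(
                clade,
                f"{{{NS}}}property",
                ref=f"cladestore:{ref}",
                datatype="xsd:string",
                applies_to="clade",
            )
            p.text = str(val)
        for c in n.children:
            emit(c, clade)

    emit(tree.root, phylogeny)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def to_tsv(tree: TreeReport) -> str:
    lines = ["taxon_id\tscientific_name\trank\tmatched_descendants\tvalue\tprovenance"]
    stack = [tree.root]
    while stack:
        n = stack.pop()
        value = "" if n.value is None else n.value
        lines.append(
            f"{n.taxon_id}\t{n.scientific_name}\t{n.rank}\t{n.matched_descendants}"
            f"\t{value}\t{n.provenance or ''}"
        )
        stack.extend(reversed(n.children))
    return "\n".join(lines) + "\n"
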