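"""Backbone taxonomy store.

Loads an NCBI-style taxdump (``nodes.dmp`` + ``names.dmp``) into an
in-process store of taxon documents, each carrying its full ordered
lineage (immediate parent first, root last) so that clade-scoped queries
reduce to lineage-membership tests.  Genome assemblies are held in a
separate collection, one document per assembly, inheriting the lineage
of their owning taxon.

Off-backbone taxa (e.g. species on a project target list that NCBI does
not yet know) can be grafted onto the tree at the nearest resolvable
anchor rank (genus, family, ...), receiving synthetic negative IDs.

Free-text name resolution follows a three-tier cascade: exact matches on
any name class, then prefix matches, then fuzzy matches within edit
distance 2.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Optional

import edlib

__all__ = [
    "AncestorRef",
    "AssemblyDocument",
    "AttributeSlot",
    "Estimate",
    "LookupResult",
    "Name",
    "RawValue",
    "Store",
    "Summary",
    "TaxonDocument",
    "TaxdumpError",
    "AnchorError",
    "load_taxdump",
    "insert_taxon",
    "lookup",
    "RANK_ORDER",
    "rank_level",
]

# Most-inclusive first.  Ranks absent from this list ("no rank", clade,
# etc.) have undefined level and never act as rank barriers or anchors
# ordered by specificity.
RANK_ORDER = [
    "superkingdom",
    "kingdom",
    "subkingdom",
    "superphylum",
    "phylum",
    "subphylum",
    "superclass",
    "class",
    "subclass",
    "infraclass",
    "cohort",
    "superorder",
    "order",
    "suborder",
    "infraorder",
    "parvorder",
    "superfamily",
    "family",
    "subfamily",
    "tribe",
    "subtribe",
    "genus",
    "subgenus",
    "section",
    "species group",
    "species subgroup",
    "species",
    "subspecies",
    "varietas",
    "forma",
]

_RANK_LEVEL = {r: i for i, r in enumerate(RANK_ORDER)}

SCIENTIFIC_NAME = "scientific name"


def rank_level(rank: str) -> Optional[int]:
    """Position of *rank* in the canonical order (0 = most inclusive)."""
    return _RANK_LEVEL.get(rank)


class TaxdumpError(ValueError):
    """Structural problem in a taxdump: cycles, dangling parents, duplicates."""


class AnchorError(ValueError):
    """An insertion anchor could not be resolved (missing or ambiguous)."""

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason  # "no-taxon-match" | "ambiguous-match"


# ---------------------------------------------------------------------------
# document model


@dataclass
class Name:
    name: str
    name_class: str = SCIENTIFIC_NAME


@dataclass
class AncestorRef:
    taxon_id: str
    rank: str
    scientific_name: str
    depth: int  # edges from the focal taxon; immediate parent == 1


@dataclass
class RawValue:
    """A sourced, directly measured attribute observation."""

    value: object
    source_name: str = ""
    source_url: Optional[str] = None
    imported_at: Optional[str] = None  # ISO date

    def key(self):
        return (_freeze(self.value), self.source_name)


def _freeze(v):
    return tuple(v) if isinstance(v, list) else v


@dataclass
class Summary:
    """Single reported value derived from raw values by a configured statistic."""

    value: object
    statistic: str
    count: int
    min: object = None
    max: object = None


@dataclass
class Estimate:
    """Reported value with traffic-light provenance.

    ``direct`` (green): summarised from the taxon's own raw values;
    ``descendant`` (orange): inferred bottom-up from values below;
    ``ancestor`` (red): copied from the nearest informative ancestor.
    """

    value: object
    provenance: str  # direct | descendant | ancestor
    source_taxon_id: Optional[str] = None


@dataclass
class AttributeSlot:
    raw: list[RawValue] = field(default_factory=list)
    summary: Optional[Summary] = None
    estimate: Optional[Estimate] = None


@dataclass
class TaxonDocument:
    taxon_id: str
    parent_id: Optional[str]
    rank: str
    scientific_name: str
    names: list[Name] = field(default_factory=list)
    lineage: list[AncestorRef] = field(default_factory=list)
    attributes: dict[str, AttributeSlot] = field(default_factory=dict)


@dataclass
class AssemblyDocument:
    assembly_id: str
    taxon_id: str
    identifiers: list[dict] = field(default_factory=list)  # {id, class}
    lineage: list[AncestorRef] = field(default_factory=list)
    attributes: dict[str, AttributeSlot] = field(default_factory=dict)


@dataclass
class LookupResult:
    match_tier: str  # exact | prefix | fuzzy
    doc_id: str
    index: str  # taxon | assembly
    matched_name: str
    name_class: str
    rank: Optional[str] = None
    parent_name: Optional[str] = None


# ---------------------------------------------------------------------------
# store


class Store:
    """In-process taxon + assembly document store with secondary indexes."""

    def __init__(self) -> None:
        self.taxa: dict[str, TaxonDocument] = {}
        self.assemblies: dict[str, AssemblyDocument] = {}
        self.attributes: dict[str, object] = {}  # name -> AttributeDefinition
        self.root_id: Optional[str] = None
        self.children: dict[str, list[str]] = {}
        # lowercase name -> list of (doc_id, stored name, name_class)
        self._taxon_names: dict[str, list[tuple[str, str, str]]] = {}
        self._assembly_names: dict[str, list[tuple[str, str, str]]] = {}
        self._next_synthetic = 1

    # -- registration ------------------------------------------------------

    def add_taxon(self, doc: TaxonDocument, index_names: Optional[Iterable[Name]] = None) -> None:
        if doc.taxon_id in self.taxa:
            raise TaxdumpError(f"duplicate taxon_id {doc.taxon_id!r}")
        self.taxa[doc.taxon_id] = doc
        self.children.setdefault(doc.taxon_id, [])
        if doc.parent_id is not None:
            self.children.setdefault(doc.parent_id, []).append(doc.taxon_id)
        for nm in (doc.names if index_names is None else index_names):
            self._taxon_names.setdefault(nm.name.casefold(), []).append(
                (doc.taxon_id, nm.name, nm.name_class)
            )

    def add_assembly(self, doc: AssemblyDocument) -> None:
        if doc.assembly_id in self.assemblies:
            raise ValueError(f"duplicate assembly_id {doc.assembly_id!r}")
        if doc.taxon_id not in self.taxa:
            raise ValueError(
                f"assembly {doc.assembly_id!r} references unknown taxon {doc.taxon_id!r}"
            )
        if not any(ident["id"] == doc.assembly_id for ident in doc.identifiers):
            doc.identifiers.insert(0, {"id": doc.assembly_id, "class": "assembly_id"})
        doc.lineage = self._assembly_lineage(doc.taxon_id)
        self.assemblies[doc.assembly_id] = doc
        for ident in doc.identifiers:
            self._assembly_names.setdefault(ident["id"].casefold(), []).append(
                (doc.assembly_id, ident["id"], ident["class"])
            )

    def _assembly_lineage(self, taxon_id: str) -> list[AncestorRef]:
        owner = self.taxa[taxon_id]
        self_ref = AncestorRef(owner.taxon_id, owner.rank, owner.scientific_name, 0)
        return [self_ref] + [
            AncestorRef(a.taxon_id, a.rank, a.scientific_name, a.depth) for a in owner.lineage
        ]

    # -- traversal ---------------------------------------------------------

    def sorted_children(self, taxon_id: str) -> list[str]:
        return sorted(self.children.get(taxon_id, []), key=sort_key)

    def descendants(self, taxon_id: str, include_self: bool = True) -> set[str]:
        out = {taxon_id} if include_self else set()
        stack = list(self.children.get(taxon_id, []))
        while stack:
            t = stack.pop()
            out.add(t)
            stack.extend(self.children.get(t, []))
        return out

    def postorder(self) -> Iterator[str]:
        """Iterative post-order over the whole tree, children in id order."""
        if self.root_id is None:
            return
        stack: list[tuple[str, bool]] = [(self.root_id, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(self.sorted_children(node)):
                    stack.append((c, False))

    def preorder(self) -> Iterator[str]:
        if self.root_id is None:
            return
        stack = [self.root_id]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.sorted_children(node)))

    # -- name resolution ---------------------------------------------------

    def taxa_named(self, name: str, name_class: Optional[str] = None) -> list[str]:
        hits = self._taxon_names.get(name.casefold(), [])
        if name_class is not None:
            hits = [h for h in hits if h[2] == name_class]
        return sorted({h[0] for h in hits}, key=sort_key)

    def taxa_with_rank_and_name(self, rank: str, name: str) -> list[str]:
        return [
            t
            for t in self.taxa_named(name, SCIENTIFIC_NAME)
            if self.taxa[t].rank == rank
        ]

    def new_synthetic_id(self) -> str:
        tid = f"-{self._next_synthetic}"
        self._next_synthetic += 1
        return tid

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        from .ingest import AttributeDefinition  # local import to avoid cycle

        return {
            "root_id": self.root_id,
            "next_synthetic": self._next_synthetic,
            "taxa": {t: asdict(d) for t, d in self.taxa.items()},
            "assemblies": {a: asdict(d) for a, d in self.assemblies.items()},
            "attributes": {n: d.to_dict() for n, d in self.attributes.items()},
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, data: dict) -> "Store":
        from .ingest import AttributeDefinition

        store = cls()
        store.root_id = data["root_id"]
        store._next_synthetic = data.get("next_synthetic", 1)
        for tdata in data["taxa"].values():
            doc = TaxonDocument(
                taxon_id=tdata["taxon_id"],
                parent_id=tdata["parent_id"],
                rank=tdata["rank"],
                scientific_name=tdata["scientific_name"],
                names=[Name(**n) for n in tdata["names"]],
                lineage=[AncestorRef(**a) for a in tdata["lineage"]],
                attributes=_slots_from_dict(tdata["attributes"]),
            )
            store.add_taxon(doc)
        for adata in data["assemblies"].values():
            doc = AssemblyDocument(
                assembly_id=adata["assembly_id"],
                taxon_id=adata["taxon_id"],
                identifiers=list(adata["identifiers"]),
                attributes=_slots_from_dict(adata["attributes"]),
            )
            store.add_assembly(doc)
        for name, ad in data["attributes"].items():
            store.attributes[name] = AttributeDefinition.from_dict(ad)
        return store

    @classmethod
    def load(cls, path) -> "Store":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _slots_from_dict(data: dict) -> dict[str, AttributeSlot]:
    out = {}
    for name, s in data.items():
        out[name] = AttributeSlot(
            raw=[RawValue(**r) for r in s["raw"]],
            summary=Summary(**s["summary"]) if s["summary"] else None,
            estimate=Estimate(**s["estimate"]) if s["estimate"] else None,
        )
    return out


def sort_key(doc_id: str):
    """Natural order: numeric ids numerically, others lexicographically."""
    try:
        return (0, int(doc_id), "")
    except ValueError:
        return (1, 0, doc_id)


# ---------------------------------------------------------------------------
# taxdump parsing


def _parse_dmp(path) -> Iterator[list[str]]:
    """Yield field lists from a .dmp file.

    Accepts the classic NCBI dialect (fields separated by "\\t|\\t", rows
    terminated "\\t|") and a plain-TSV fallback.
    """
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t|" in line:
                if line.endswith("\t|"):
                    line = line[: -len("\t|")]
                yield line.split("\t|\t")
            else:
                yield line.split("\t")


def load_taxdump(nodes_path, names_path) -> Store:
    """Load ``nodes.dmp`` + ``names.dmp`` into a :class:`Store`.

    Only nodes.dmp columns 1-3 (taxid, parent, rank) and names.dmp
    columns 1, 2, 4 (taxid, name, name class) are consumed.

    Raises :class:`TaxdumpError` on duplicate ids, dangling parent
    pointers, parent cycles, or a root count other than one.
    """
    nodes: dict[str, tuple[str, str]] = {}
    root_id: Optional[str] = None
    for fields_ in _parse_dmp(nodes_path):
        if len(fields_) < 3:
            raise TaxdumpError(f"nodes.dmp row with <3 fields: {fields_!r}")
        tid, parent, rank = (f.strip() for f in fields_[:3])
        if tid in nodes:
            raise TaxdumpError(f"duplicate taxon_id {tid!r} in nodes.dmp")
        nodes[tid] = (parent, rank)
        if parent == tid:
            if root_id is not None:
                raise TaxdumpError(f"multiple roots: {root_id!r} and {tid!r}")
            root_id = tid
    if root_id is None:
        raise TaxdumpError("no root node (node whose parent is itself)")
    for tid, (parent, _) in nodes.items():
        if parent not in nodes:
            raise TaxdumpError(f"dangling parent_id {parent!r} for taxon {tid!r}")

    names: dict[str, list[Name]] = {}
    for fields_ in _parse_dmp(names_path):
        if len(fields_) < 4:
            raise TaxdumpError(f"names.dmp row with <4 fields: {fields_!r}")
        tid = fields_[0].strip()
        nm = fields_[1].strip()
        cls_ = fields_[3].strip()
        names.setdefault(tid, []).append(Name(nm, cls_))

    # lineage by memoised parent walk; detects cycles
    lineages: dict[str, list[str]] = {root_id: []}

    def lineage_ids(tid: str) -> list[str]:
        chain: list[str] = []
        seen: set[str] = set()
        cur = tid
        while cur not in lineages:
            if cur in seen:
                cycle = " -> ".join(chain + [cur])
                raise TaxdumpError(f"cycle in parent pointers: {cycle}")
            seen.add(cur)
            chain.append(cur)
            cur = nodes[cur][0]
        for node in reversed(chain):
            parent = nodes[node][0]
            lineages[node] = [parent] + lineages[parent]
        return lineages[tid]

    store = Store()
    store.root_id = root_id
    for tid in nodes:
        lineage_ids(tid)
    for tid, (parent, rank) in nodes.items():
        nm_list = names.get(tid, [])
        sci = [n for n in nm_list if n.name_class == SCIENTIFIC_NAME]
        if len(sci) != 1:
            raise TaxdumpError(
                f"taxon {tid!r} has {len(sci)} scientific names (exactly one required)"
            )
        lin = [
            AncestorRef(aid, nodes[aid][1], "", depth)
            for depth, aid in enumerate(lineages[tid], start=1)
        ]
        doc = TaxonDocument(
            taxon_id=tid,
            parent_id=None if tid == root_id else parent,
            rank=rank,
            scientific_name=sci[0].name,
            names=nm_list,
            lineage=lin,
        )
        store.add_taxon(doc)
    # second pass: fill ancestor scientific names now all docs exist
    for doc in store.taxa.values():
        for ref in doc.lineage:
            ref.scientific_name = store.taxa[ref.taxon_id].scientific_name
    return store


# ---------------------------------------------------------------------------
# off-backbone insertion


def insert_taxon(name: str, rank: str, anchor: dict[str, str], store: Store) -> str:
    """Graft a new taxon under the most specific resolvable anchor.

    *anchor* maps rank labels to names, e.g. ``{"genus": "Drosophila",
    "family": "Drosophilidae"}``.  Anchors are tried from most to least
    specific; the first whose (rank, name) pair matches exactly one
    backbone taxon becomes the parent.  An anchor name occurring at two
    taxa of the same rank is ambiguous and rejected outright.

    Returns the synthetic taxon_id (negative-signed, reserved namespace).
    Raises :class:`AnchorError` when no anchor resolves or an anchor is
    ambiguous.  Inserted taxa are indexed under their scientific name only.
    """
    ordered = sorted(
        anchor.items(),
        key=lambda kv: -(rank_level(kv[0]) if rank_level(kv[0]) is not None else -1),
    )
    parent_doc = None
    for arank, aname in ordered:
        hits = store.taxa_with_rank_and_name(arank, aname)
        if len(hits) > 1:
            raise AnchorError(
                f"anchor {arank}={aname!r} is ambiguous ({len(hits)} taxa)",
                "ambiguous-match",
            )
        if len(hits) == 1:
            parent_doc = store.taxa[hits[0]]
            break
    if parent_doc is None:
        raise AnchorError(
            f"no anchor in {sorted(anchor)} resolves to a backbone taxon",
            "no-taxon-match",
        )
    tid = store.new_synthetic_id()
    lineage = [
        AncestorRef(parent_doc.taxon_id, parent_doc.rank, parent_doc.scientific_name, 1)
    ] + [
        AncestorRef(a.taxon_id, a.rank, a.scientific_name, a.depth + 1)
        for a in parent_doc.lineage
    ]
    doc = TaxonDocument(
        taxon_id=tid,
        parent_id=parent_doc.taxon_id,
        rank=rank,
        scientific_name=name,
        names=[Name(name, SCIENTIFIC_NAME)],
        lineage=lineage,
    )
    store.add_taxon(doc)
    return tid


# ---------------------------------------------------------------------------
# lookup


def _edit_distance(a: str, b: str, k: int = 2) -> int:
    res = edlib.align(a, b, task="distance", k=k)
    d = res["editDistance"]
    return d if d >= 0 else k + 1


def lookup(query: str, store: Store, limit: int = 10) -> list[LookupResult]:
    """Resolve a free-text name to taxa or assemblies.

    Tier cascade: case-insensitive exact matches (any name class) win;
    failing that, prefix matches; failing that, fuzzy matches within edit
    distance 2.  Within a tier, shorter matched names sort first, then
    lexicographically.  Results always carry rank and parent name so
    callers can disambiguate homonyms; equal-tier homonyms are never
    auto-picked.
    """
    q = query.casefold()
    if not q:
        return []

    def emit(doc_id: str, index: str, name: str, name_class: str, tier: str) -> LookupResult:
        if index == "taxon":
            doc = store.taxa[doc_id]
            parent = store.taxa[doc.parent_id].scientific_name if doc.parent_id else None
            return LookupResult(tier, doc_id, index, name, name_class, doc.rank, parent)
        doc = store.assemblies[doc_id]
        owner = store.taxa[doc.taxon_id]
        return LookupResult(tier, doc_id, index, name, name_class, owner.rank, owner.scientific_name)

    def collect(pred, tier: str) -> list[LookupResult]:
        hits: list[tuple[tuple, LookupResult]] = []
        for table, index in ((store._taxon_names, "taxon"), (store._assembly_names, "assembly")):
            for key, entries in table.items():
                if not pred(key):
                    continue
                for doc_id, name, name_class in entries:
                    r = emit(doc_id, index, name, name_class, tier)
                    hits.append(((len(name), name.casefold(), sort_key(doc_id)), r))
        hits.sort(key=lambda x: x[0])
        # one result per document per tier (best-sorting name)
        seen: set[tuple[str, str]] = set()
        out = []
        for _, r in hits:
            if (r.index, r.doc_id) in seen:
                continue
            seen.add((r.index, r.doc_id))
            out.append(r)
        return out[:limit]

    exact = collect(lambda key: key == q, "exact")
    if exact:
        return exact
    prefix = collect(lambda key: key.startswith(q), "prefix")
    if prefix:
        return prefix
    return collect(lambda key: _edit_distance(q, key) <= 2, "fuzzy")


def today_iso() -> str:
    return _dt.date.today().isoformat()
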