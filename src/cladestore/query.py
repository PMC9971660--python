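"""Taxon/attribute search language over the store.

A query is a conjunction of terms joined by ``AND``.  Taxon terms use
ENA-portal-style functions with a ``tax_`` prefix — ``tax_eq`` (by id),
``tax_name`` (by name, with optional name-class prefix and ``*``
wildcards), ``tax_tree`` (the named taxa plus all descendants),
``tax_rank``, ``tax_depth`` (relative to the query's taxon anchor) and
``tax_lineage`` (root path of a single taxon).  Attribute terms compare
the reported value with ``< <= = >= > !=``, test existence with a bare
attribute name, or apply ``min()``/``max()`` (summary range) and
``length()`` (raw-value list cardinality) modifiers.  Comma-joined
values are OR-ed; a ``!`` prefix negates.  General OR/NOT connectives
are deliberately not part of the user grammar.

Ordering comparisons are defined for numeric attributes, ISO dates and
ordered keywords (by declared enum position, best label greatest);
plain keywords support only ``=``/``!=``.
"""

from __future__ import annotations

import csv
import datetime as _dt
import fnmatch
import io
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from .fill import reported
from .ingest import AttributeDefinition
from .taxonomy import Store, sort_key

__all__ = [
    "AttributeTerm",
    "NotFoundError",
    "QueryExpression",
    "QueryParseError",
    "SearchOptions",
    "TaxonArg",
    "TaxonTerm",
    "count",
    "evaluate",
    "format_results",
    "get_record",
    "parse_query",
    "render_query",
]

TAX_FUNCTIONS = ("tax_eq", "tax_name", "tax_tree", "tax_rank", "tax_depth", "tax_lineage")
OPERATORS = ("<=", ">=", "!=", "==", "=", "<", ">")
MODIFIERS = ("min", "max", "length")


logger = logging.getLogger("cladestore")


class QueryParseError(ValueError):
    def __init__(self, message: str, position: int = 0):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class NotFoundError(KeyError):
    pass


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class TaxonArg:
    pattern: str
    name_class: Optional[str] = None
    negated: bool = False

    def render(self) -> str:
        cls = f"{self.name_class}:" if self.name_class else ""
        return f"{'!' if self.negated else ''}{cls}{self.pattern}"


@dataclass(frozen=True)
class TaxonTerm:
    function: str
    arguments: tuple[TaxonArg, ...]

    def render(self) -> str:
        return f"{self.function}({','.join(a.render() for a in self.arguments)})"


@dataclass(frozen=True)
class AttributeTerm:
    attribute: str
    modifier: str = "none"  # none | min | max | length
    operator: str = "exists"
    values: tuple[str, ...] = ()
    negated: bool = False

    def render(self) -> str:
        bang = "!" if self.negated else ""
        name = self.attribute if self.modifier == "none" else f"{self.modifier}({self.attribute})"
        if self.operator == "exists":
            return f"{bang}{name}"
        return f"{bang}{name}{self.operator}{','.join(self.values)}"


@dataclass(frozen=True)
class QueryExpression:
    terms: tuple = ()

    def render(self) -> str:
        return " AND ".join(t.render() for t in self.terms)


def render_query(ast: QueryExpression) -> str:
    """Canonical text form; ``parse_query(render_query(q)) == q``."""
    return ast.render()


# ---------------------------------------------------------------------------
# parsing


_AND_RE = re.compile(r"\bAND\b", re.IGNORECASE)
_TAXTERM_RE = re.compile(r"^(tax_[A-Za-z_]*)\s*\(\s*(.*?)\s*\)$", re.DOTALL)
_ATTRTERM_RE = re.compile(
    r"^(!)?\s*(?:(min|max|length)\s*\(\s*([A-Za-z_][\w.]*)\s*\)|([A-Za-z_][\w.]*))"
    r"\s*(?:(<=|>=|!=|==|=|<|>)\s*(.*))?$",
    re.DOTALL,
)


def _split_top_level(text: str) -> list[tuple[int, str]]:
    """Split on AND outside parentheses; returns (offset, chunk) pairs."""
    depth = 0
    cuts: list[tuple[int, int]] = []  # (start, end) of AND tokens at depth 0
    for m in _AND_RE.finditer(text):
        d = 0
        for ch in text[: m.start()]:
            if ch == "(":
                d += 1
            elif ch == ")":
                d -= 1
        if d == 0:
            cuts.append((m.start(), m.end()))
    chunks: list[tuple[int, str]] = []
    prev = 0
    for s, e in cuts:
        chunks.append((prev, text[prev:s]))
        prev = e
    chunks.append((prev, text[prev:]))
    return chunks


def _check_balance(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise QueryParseError("unbalanced parentheses", i)
    if depth != 0:
        raise QueryParseError("unbalanced parentheses", len(text))


def _parse_taxon_term(body: str, fn: str, offset: int) -> TaxonTerm:
    if fn not in TAX_FUNCTIONS:
        raise QueryParseError(f"unknown tax_ function {fn!r}", offset)
    args = []
    for raw in body.split(","):
        raw = raw.strip()
        if not raw:
            raise QueryParseError(f"empty argument in {fn}()", offset)
        negated = raw.startswith("!")
        if negated:
            raw = raw[1:].strip()
        name_class = None
        if fn in ("tax_name", "tax_tree") and ":" in raw:
            name_class, raw = (p.strip() for p in raw.split(":", 1))
        args.append(TaxonArg(raw, name_class, negated))
    if fn == "tax_depth":
        if len(args) != 1 or not args[0].pattern.isdigit():
            raise QueryParseError("tax_depth takes a single integer", offset)
    return TaxonTerm(fn, tuple(args))


def _parse_attribute_term(
    chunk: str, offset: int, registry: Optional[dict] = None
) -> AttributeTerm:
    m = _ATTRTERM_RE.match(chunk)
    if not m:
        raise QueryParseError(f"cannot parse term {chunk!r}", offset)
    bang, modifier, mod_attr, bare_attr, op, value_text = m.groups()
    attribute = mod_attr or bare_attr
    modifier = modifier or "none"
    if op is None:
        term = AttributeTerm(attribute, modifier, "exists", (), bool(bang))
    else:
        if op == "==":
            op = "="
        values = tuple(v.strip() for v in value_text.split(","))
        if any(not v for v in values):
            raise QueryParseError(f"empty comparison value in {chunk!r}", offset)
        term = AttributeTerm(attribute, modifier, op, values, bool(bang))
    if registry is not None:
        _validate_attribute_term(term, registry, offset)
    return term


def _validate_attribute_term(term: AttributeTerm, registry: dict, offset: int) -> None:
    definition: Optional[AttributeDefinition] = registry.get(term.attribute)
    if definition is None:
        raise QueryParseError(f"unknown attribute {term.attribute!r}", offset)
    if term.operator in ("<", "<=", ">=", ">") and term.modifier != "length":
        orderable = definition.value_type in ("integer", "float", "date", "ordered_keyword")
        if not orderable:
            raise QueryParseError(
                f"ordering operator {term.operator!r} on unordered attribute"
                f" {term.attribute!r}",
                offset,
            )


def parse_query(text: str, registry: Optional[dict] = None) -> QueryExpression:
    """Parse a search string into a :class:`QueryExpression`.

    With a *registry* of attribute definitions, ordering operators on
    unordered keyword attributes are rejected at parse time.  Errors
    carry the character position of the offending term.
    """
    _check_balance(text)
    if not text.strip():
        return QueryExpression(())
    terms = []
    has_anchor = False
    has_depth = False
    for offset, chunk in _split_top_level(text):
        stripped = chunk.strip()
        if not stripped:
            raise QueryParseError("empty term", offset)
        m = _TAXTERM_RE.match(stripped)
        if m or stripped.startswith("tax_"):
            if not m:
                raise QueryParseError(f"malformed taxon term {stripped!r}", offset)
            term = _parse_taxon_term(m.group(2), m.group(1), offset)
            if term.function in ("tax_eq", "tax_name", "tax_tree", "tax_lineage"):
                has_anchor = True
            if term.function == "tax_depth":
                has_depth = True
            terms.append(term)
        else:
            terms.append(_parse_attribute_term(stripped, offset, registry))
    if has_depth and not has_anchor:
        raise QueryParseError("tax_depth requires an anchoring taxon term", 0)
    return QueryExpression(tuple(terms))


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class SearchOptions:
    index: str = "taxon"  # taxon | assembly
    include_estimates: bool = True
    ranks: Optional[set] = None  # restrict result docs to these ranks
    fields: Optional[list] = None  # attribute columns for formatting


def _glob_match(pattern: str, name: str) -> bool:
    return fnmatch.fnmatchcase(name.casefold(), pattern.casefold())


def _name_matches(store: Store, pattern: str, name_class: Optional[str]) -> set[str]:
    """Taxa whose indexed names match a (possibly wildcard) pattern."""
    out = set()
    if "*" not in pattern and "?" not in pattern:
        candidates = store._taxon_names.get(pattern.casefold(), [])
        for tid, _name, cls_ in candidates:
            if name_class is None or cls_ == name_class:
                out.add(tid)
        return out
    for entries in store._taxon_names.values():
        for tid, name, cls_ in entries:
            if name_class is not None and cls_ != name_class:
                continue
            if _glob_match(pattern, name):
                out.add(tid)
    return out


def _resolve_anchor_taxa(store: Store, arg: TaxonArg) -> set[str]:
    """Taxa named by a tree/eq argument: id verbatim, else name match."""
    if arg.name_class is None and arg.pattern in store.taxa:
        return {arg.pattern}
    return _name_matches(store, arg.pattern, arg.name_class)


class _Evaluator:
    def __init__(self, store: Store, options: SearchOptions):
        self.store = store
        self.options = options
        self.anchors: set[str] = set()  # for tax_depth
        self.depth_terms: list[int] = []

    # taxon-id sets ------------------------------------------------------

    def taxon_term_ids(self, term: TaxonTerm) -> set[str]:
        pos: set[str] = set()
        neg: set[str] = set()
        for arg in term.arguments:
            target = neg if arg.negated else pos
            target |= self._arg_taxa(term.function, arg)
            if arg.negated:
                neg = target
            else:
                pos = target
        return pos - neg

    def _arg_taxa(self, fn: str, arg: TaxonArg) -> set[str]:
        store = self.store
        if fn == "tax_eq":
            hit = {arg.pattern} if arg.pattern in store.taxa else set()
            if not arg.negated:
                self.anchors |= hit
            return hit
        if fn == "tax_name":
            hits = _name_matches(store, arg.pattern, arg.name_class)
            if not arg.negated:
                self.anchors |= hits
            return hits
        if fn == "tax_tree":
            anchors = _resolve_anchor_taxa(store, arg)
            if not arg.negated:
                self.anchors |= anchors
            out: set[str] = set()
            for a in anchors:
                out |= store.descendants(a, include_self=True)
            return out
        if fn == "tax_rank":
            return {t for t, d in store.taxa.items() if _glob_match(arg.pattern, d.rank)}
        if fn == "tax_lineage":
            anchors = _resolve_anchor_taxa(store, arg)
            if len(anchors) != 1:
                raise NotFoundError(
                    f"tax_lineage requires a single taxon; {arg.pattern!r} "
                    f"matched {len(anchors)}"
                )
            (a,) = anchors
            return {a} | {ref.taxon_id for ref in store.taxa[a].lineage}
        raise QueryParseError(f"unknown tax_ function {fn!r}")

    def term_doc_ids(self, term) -> Optional[set[str]]:
        """Matching doc ids in the active index; None = deferred (tax_depth)."""
        store, opts = self.store, self.options
        if isinstance(term, TaxonTerm):
            if term.function == "tax_depth":
                self.depth_terms.append(int(term.arguments[0].pattern))
                return None
            taxa = self.taxon_term_ids(term)
            if opts.index == "taxon":
                return taxa
            return {a for a, doc in store.assemblies.items() if doc.taxon_id in taxa}
        return self.attribute_term_ids(term)

    # attribute terms ----------------------------------------------------

    def attribute_term_ids(self, term: AttributeTerm) -> set[str]:
        store, opts = self.store, self.options
        definition = store.attributes.get(term.attribute)
        if definition is None:
            raise NotFoundError(f"unknown attribute {term.attribute!r}")
        _validate_attribute_term(term, store.attributes, 0)
        docs = store.taxa if opts.index == "taxon" else store.assemblies
        base = {
            doc_id
            for doc_id, doc in docs.items()
            if self._attr_positive(doc, term, definition)
        }
        if term.negated ^ (term.operator == "!="):
            return set(docs) - base
        return base

    def _attr_positive(self, doc, term: AttributeTerm, definition) -> bool:
        """Does the doc satisfy the un-negated, equality form of the term?"""
        slot = doc.attributes.get(term.attribute)
        operator = "=" if term.operator == "!=" else term.operator

        if term.modifier == "length":
            if slot is None:
                length = 0
            elif definition.value_type == "list":
                # a list cell may carry several labels; count distinct members
                members = set()
                for rv in slot.raw:
                    members.update(rv.value if isinstance(rv.value, list) else [rv.value])
                length = len(members)
            else:
                length = len(slot.raw)
            return all_or_any_compare(operator, length, term.values, "integer", None)
        if term.modifier in ("min", "max"):
            if slot is None or slot.summary is None:
                return False
            bound = slot.summary.min if term.modifier == "min" else slot.summary.max
            if bound is None:
                return False
            if operator == "exists":
                return True
            return all_or_any_compare(
                operator, bound, term.values, definition.value_type, definition
            )

        rep = reported(slot, self.options.include_estimates)
        if rep is None:
            return False
        if operator == "exists":
            return True
        value = rep[0]
        if definition.value_type == "list" or isinstance(value, list):
            members = value if isinstance(value, list) else [value]
            return any(
                any(str(m).casefold() == v.casefold() for m in members)
                for v in term.values
            )
        return all_or_any_compare(
            operator, value, term.values, definition.value_type, definition
        )

    # query --------------------------------------------------------------

    def run(self, ast: QueryExpression) -> list[str]:
        store, opts = self.store, self.options
        docs = store.taxa if opts.index == "taxon" else store.assemblies
        functions = {t.function for t in ast.terms if isinstance(t, TaxonTerm)}
        if "tax_rank" in functions and not functions & {"tax_eq", "tax_name", "tax_tree"}:
            logger.info("tax_rank without an anchoring taxon term scans the whole index")
        matched: Optional[set[str]] = None
        for term in ast.terms:
            ids = self.term_doc_ids(term)
            if ids is None:
                continue
            matched = ids if matched is None else matched & ids
        if matched is None:
            matched = set(docs)
        for limit in self.depth_terms:
            matched = {d for d in matched if self._depth_ok(d, limit)}
        if opts.ranks:
            if opts.index == "taxon":
                matched = {d for d in matched if store.taxa[d].rank in opts.ranks}
            else:
                matched = {
                    d
                    for d in matched
                    if store.taxa[store.assemblies[d].taxon_id].rank in opts.ranks
                }
        return sorted(matched, key=sort_key)

    def _depth_ok(self, doc_id: str, limit: int) -> bool:
        store, opts = self.store, self.options
        if opts.index == "taxon":
            doc = store.taxa[doc_id]
            if doc.taxon_id in self.anchors:
                return True
            depths = [a.depth for a in doc.lineage if a.taxon_id in self.anchors]
        else:
            doc = store.assemblies[doc_id]
            depths = [a.depth for a in doc.lineage if a.taxon_id in self.anchors]
        return bool(depths) and min(depths) <= limit


def _typed_literal(text: str, value_type: str, definition):
    if value_type in ("integer", "float"):
        # numeric comparison even for fractional literals on integer attributes
        return float(text)
    if value_type == "date":
        _dt.date.fromisoformat(text)  # validation; dates compare as ISO strings
        return text
    if value_type == "ordered_keyword":
        return definition.enum_position(text)
    return text.casefold()


def _comparable(value, value_type: str, definition):
    if value_type == "ordered_keyword":
        return definition.enum_position(value)
    if value_type in ("integer", "float"):
        return float(value)
    if value_type == "date":
        return str(value)
    return str(value).casefold()


def all_or_any_compare(operator, value, literals, value_type, definition) -> bool:
    """Comma list = OR: the comparison holds for at least one literal."""
    try:
        left = _comparable(value, value_type, definition)
    except (TypeError, ValueError):
        return False
    for lit in literals:
        try:
            right = _typed_literal(lit, value_type, definition)
            if value_type in ("integer", "float"):
                right = float(right)
        except (TypeError, ValueError):
            continue
        if operator == "=" and left == right:
            return True
        if operator == "<" and left < right:
            return True
        if operator == "<=" and left <= right:
            return True
        if operator == ">=" and left >= right:
            return True
        if operator == ">" and left > right:
            return True
    return False


def evaluate(ast: QueryExpression, store: Store, options: Optional[SearchOptions] = None):
    """Evaluate a parsed query; returns matching documents in id order."""
    options = options or SearchOptions()
    ev = _Evaluator(store, options)
    ids = ev.run(ast)
    docs = store.taxa if options.index == "taxon" else store.assemblies
    return [docs[i] for i in ids]


def count(ast: QueryExpression, store: Store, options: Optional[SearchOptions] = None) -> int:
    """Number of matches, computed without materialising field payloads."""
    options = options or SearchOptions()
    return len(_Evaluator(store, options).run(ast))


def get_record(doc_id: str, store: Store):
    """Full taxon or assembly document by id."""
    if doc_id in store.taxa:
        return store.taxa[doc_id]
    if doc_id in store.assemblies:
        return store.assemblies[doc_id]
    raise NotFoundError(f"no taxon or assembly with id {doc_id!r}")


# ---------------------------------------------------------------------------
# formatting


def _identity_columns(doc) -> dict:
    if hasattr(doc, "scientific_name"):
        return {
            "taxon_id": doc.taxon_id,
            "scientific_name": doc.scientific_name,
            "rank": doc.rank,
        }
    return {"assembly_id": doc.assembly_id, "taxon_id": doc.taxon_id}


def _render_value(value) -> str:
    if isinstance(value, list):
        return ";".join(str(v) for v in value)
    if isinstance(value, float) and value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return str(value)


def format_results(
    results: list,
    format: str = "tsv",
    mode: str = "summary",
    fields: Optional[list] = None,
    include_estimates: bool = True,
) -> str:
    """Serialise result documents.

    ``summary``: one row per document, one column per requested field.
    ``tidy``: one (document, attribute, value, provenance, source) row
    per reported value.  ``raw``: tidy restricted to direct raw values.
    Formats: ``json``, ``csv`` (RFC-4180 quoting) and ``tsv``.
    """
    if fields is None:
        seen: list[str] = []
        for doc in results:
            for a in doc.attributes:
                if a not in seen:
                    seen.append(a)
        fields = sorted(seen)

    rows: list[dict] = []
    if mode == "summary":
        for doc in results:
            row = _identity_columns(doc)
            for attr in fields:
                rep = reported(doc.attributes.get(attr), include_estimates)
                row[attr] = _render_value(rep[0]) if rep else ""
            rows.append(row)
    elif mode == "tidy":
        for doc in results:
            for attr in fields:
                slot = doc.attributes.get(attr)
                rep = reported(slot, include_estimates)
                if rep is None:
                    continue
                value, provenance = rep
                if provenance == "direct":
                    source = ";".join(sorted({rv.source_name for rv in slot.raw}))
                elif provenance == "ancestor":
                    source = slot.estimate.source_taxon_id or ""
                else:
                    source = ""
                rows.append(
                    dict(
                        _identity_columns(doc),
                        attribute=attr,
                        value=_render_value(value),
                        provenance=provenance,
                        source=source,
                    )
                )
    elif mode == "raw":
        for doc in results:
            for attr in fields:
                slot = doc.attributes.get(attr)
                if slot is None:
                    continue
                for rv in slot.raw:
                    rows.append(
                        dict(
                            _identity_columns(doc),
                            attribute=attr,
                            value=_render_value(rv.value),
                            provenance="direct",
                            source=rv.source_name,
                        )
                    )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    fmt = format.lower()
    if fmt == "json":
        return json.dumps(rows, indent=1)
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    cols: list[str] = []
    for r in rows:
        for k in r:
            if k not in cols:
                cols.append(k)
    buf = io.StringIO()
    writer = csv.DictWriter(
        buf,
        fieldnames=cols,
        delimiter="\t" if fmt == "tsv" else ",",
        quoting=csv.QUOTE_MINIMAL,
        lineterminator="\n",
    )
    writer.writeheader()
    writer.writerows(rows)
    return buf.getvalue()
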