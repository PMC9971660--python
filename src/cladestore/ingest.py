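"""Declarative tabular import (configuration as code).

A data source is a delimited table (one taxon or one assembly per row)
paired with a YAML import specification that declares which columns fill
which attributes, how cell values are transformed and translated, how
rows are matched to backbone taxa, and where the data came from.

Attribute semantics (value type, constraints, summary rules, fill
behaviour) live in a registry of :class:`AttributeDefinition` entries,
declared inline in import specs.  Row-level problems never abort an
import: bad cells or unmatched rows become :class:`ExceptionRecord`
entries written to an exceptions file, while matches inferred through
anything weaker than an explicit taxon id or a unique scientific name
are logged to a review file.

YAML layout (keys map 1:1 onto :class:`ImportSpec`)::

    file: {path: data.tsv, delimiter: "\\t"}
    attributes:                # inline AttributeDefinition declarations
      genome_size:
        type: float
        constraints: {min: 0}
        summary: [median]
        traverse: {direction: both}
    columns:                   # column -> attribute mapping
      c_value: {attribute: genome_size, transform: {multiply: 978000000.0}}
    taxonomy: {taxon_id: ncbi_id, scientific_name: species, family: family}
    assembly: {assembly_id: accession}     # assembly-index sources only
    options: {allow_synonyms: true, create_missing_taxa: false}
    source: {name: kew, url: "https://...", date: 2020-11-30}
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .taxonomy import (
    SCIENTIFIC_NAME,
    AnchorError,
    AssemblyDocument,
    AttributeSlot,
    RawValue,
    Store,
    _edit_distance,
    insert_taxon,
    rank_level,
)

logger = logging.getLogger("cladestore")

__all__ = [
    "AttributeDefinition",
    "ColumnSpec",
    "ExceptionRecord",
    "ImportSpec",
    "ImportSpecError",
    "IndexResult",
    "Traverse",
    "apply_transform",
    "coerce_value",
    "index_directory",
    "index_file",
    "match_row_to_taxon",
    "parse_import_spec",
    "DEFAULT_MISSING",
    "PG_TO_BP",
]

# Dolezel et al. conversion: 1 pg of DNA = 0.978e9 bp.  Used by fixture
# specs for C-value columns; any multiply-constant may be configured.
PG_TO_BP = 0.978e9

DEFAULT_MISSING = ("", "NA", "None", "-")

VALUE_TYPES = {"integer", "float", "date", "keyword", "ordered_keyword", "list"}
SUMMARY_RULES = {
    "min",
    "max",
    "mean",
    "median",
    "mode",
    "list",
    "priority-by-enum",
    "priority-by-source",
}
TRANSFORMS = {"multiply", "add", "template", "lowercase", "uppercase", "date"}


class ImportSpecError(ValueError):
    """Invalid YAML import specification or attribute declaration."""


@dataclass
class Traverse:
    direction: str = "none"  # up | down | both | none
    limit: Optional[dict] = None  # {"clade": name-or-id} or {"rank": label}
    statistic: Optional[str] = None  # ancestor-summary override


@dataclass
class AttributeDefinition:
    name: str
    index: str = "taxon"  # taxon | assembly
    value_type: str = "float"
    constraints: dict = field(default_factory=dict)  # min, max, enum
    summary_rules: list = field(default_factory=list)
    traverse: Traverse = field(default_factory=Traverse)
    display_group: Optional[str] = None
    units: Optional[str] = None
    source_priority: Optional[list] = None
    list_separator: str = ","

    def __post_init__(self):
        if isinstance(self.traverse, dict):
            self.traverse = Traverse(**self.traverse)
        if self.index not in ("taxon", "assembly"):
            raise ImportSpecError(f"{self.name}: index must be taxon|assembly")
        if self.value_type not in VALUE_TYPES:
            raise ImportSpecError(f"{self.name}: unknown value_type {self.value_type!r}")
        if self.traverse.direction not in ("up", "down", "both", "none"):
            raise ImportSpecError(
                f"{self.name}: traverse.direction must be up|down|both|none"
            )
        if self.value_type == "ordered_keyword" and not self.enum:
            raise ImportSpecError(f"{self.name}: ordered_keyword requires a non-empty enum")
        unknown = set(self.summary_rules) - SUMMARY_RULES
        if unknown:
            raise ImportSpecError(f"{self.name}: unknown summary rules {sorted(unknown)}")
        if self.traverse.direction != "none" and not self.summary_rules:
            raise ImportSpecError(
                f"{self.name}: traversable attributes need non-empty summary_rules"
            )

    @property
    def enum(self) -> list:
        """Ordered allowed labels, best first (e.g. complete genome > ... > contig)."""
        return self.constraints.get("enum") or []

    def enum_position(self, label) -> int:
        """Comparable magnitude of an enum label: larger = higher priority."""
        labels = [str(e).casefold() for e in self.enum]
        return len(labels) - labels.index(str(label).casefold())

    def conflicts_with(self, other: "AttributeDefinition") -> bool:
        return asdict(self) != asdict(other)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AttributeDefinition":
        data = dict(data)
        data["traverse"] = Traverse(**data["traverse"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, name: str, data: dict) -> "AttributeDefinition":
        data = dict(data)
        vtype = data.pop("type", data.pop("value_type", "float"))
        rules = data.pop("summary", data.pop("summary_rules", []))
        if isinstance(rules, str):
            rules = [rules]
        return cls(name=name, value_type=vtype, summary_rules=list(rules), **data)


@dataclass
class ColumnSpec:
    attribute: str
    transform: Optional[dict] = None
    translate: Optional[dict] = None


@dataclass
class ImportSpec:
    file_path: Path
    delimiter: str = "\t"
    index: str = "taxon"
    attribute_columns: dict[str, ColumnSpec] = field(default_factory=dict)
    taxonomy_columns: dict[str, str] = field(default_factory=dict)
    assembly_id_column: Optional[str] = None
    allow_fuzzy: bool = False
    allow_synonyms: bool = False
    create_missing_taxa: bool = False
    missing_markers: tuple = DEFAULT_MISSING
    source_name: str = ""
    source_url: Optional[str] = None
    source_date: Optional[str] = None


@dataclass
class ExceptionRecord:
    row: dict
    reason: str  # no-taxon-match | ambiguous-match | constraint-violation | type-error
    detail: str = ""


@dataclass
class IndexResult:
    indexed: int = 0
    inferred: int = 0
    exceptions: int = 0
    raw_values: int = 0
    cell_exceptions: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# spec parsing


def parse_import_spec(
    yaml_path, registry: Optional[dict[str, AttributeDefinition]] = None
) -> tuple[ImportSpec, list[AttributeDefinition]]:
    """Parse and validate one YAML import specification.

    Inline attribute declarations are returned (and may be registered by
    the caller); a declaration conflicting with an existing registry
    entry is a hard error rather than a silent merge.
    """
    yaml_path = Path(yaml_path)
    data = yaml.safe_load(yaml_path.read_text())
    if not isinstance(data, dict):
        raise ImportSpecError(f"{yaml_path}: top level must be a mapping")
    if "file" not in data or "path" not in (data["file"] or {}):
        raise ImportSpecError(f"{yaml_path}: missing required 'file.path'")

    defs: list[AttributeDefinition] = []
    known: dict[str, AttributeDefinition] = dict(registry or {})
    for name, decl in (data.get("attributes") or {}).items():
        ad = AttributeDefinition.from_yaml(name, decl or {})
        if name in known and known[name].conflicts_with(ad):
            raise ImportSpecError(
                f"{yaml_path}: attribute {name!r} conflicts with existing registry entry"
            )
        known[name] = ad
        defs.append(ad)

    columns: dict[str, ColumnSpec] = {}
    for col, cdata in (data.get("columns") or {}).items():
        if isinstance(cdata, str):
            cdata = {"attribute": cdata}
        if "attribute" not in cdata:
            raise ImportSpecError(f"{yaml_path}: column {col!r} lacks an attribute")
        attr = cdata["attribute"]
        if attr not in known:
            raise ImportSpecError(
                f"{yaml_path}: column {col!r} references undeclared attribute {attr!r}"
            )
        transform = cdata.get("transform")
        if transform is not None:
            bad = set(transform) - TRANSFORMS
            if bad:
                raise ImportSpecError(
                    f"{yaml_path}: unknown transform name(s) {sorted(bad)} on column {col!r}"
                )
        columns[col] = ColumnSpec(attr, transform, cdata.get("translate"))
    if not columns:
        raise ImportSpecError(f"{yaml_path}: no attribute columns declared")

    taxonomy = dict(data.get("taxonomy") or {})
    if "taxon_id" not in taxonomy:
        higher = [k for k in taxonomy if k not in ("taxon_id", "scientific_name")]
        if "scientific_name" not in taxonomy or not higher:
            raise ImportSpecError(
                f"{yaml_path}: taxonomy needs taxon_id or scientific_name plus >=1 higher rank"
            )

    assembly = data.get("assembly") or {}
    index = "assembly" if assembly else "taxon"
    options = data.get("options") or {}
    source = data.get("source") or {}
    spec = ImportSpec(
        file_path=yaml_path.parent / data["file"]["path"],
        delimiter=data["file"].get("delimiter", "\t"),
        index=index,
        attribute_columns=columns,
        taxonomy_columns=taxonomy,
        assembly_id_column=assembly.get("assembly_id"),
        allow_fuzzy=bool(options.get("allow_fuzzy", False)),
        allow_synonyms=bool(options.get("allow_synonyms", False)),
        create_missing_taxa=bool(options.get("create_missing_taxa", False)),
        missing_markers=tuple(options.get("missing", DEFAULT_MISSING)),
        source_name=str(source.get("name", yaml_path.stem)),
        source_url=source.get("url"),
        source_date=str(source["date"]) if source.get("date") else None,
    )
    if index == "assembly" and not spec.assembly_id_column:
        raise ImportSpecError(f"{yaml_path}: assembly sources need assembly.assembly_id")
    return spec, defs


# ---------------------------------------------------------------------------
# value transforms and coercion


def apply_transform(value, spec: Optional[dict], row: Optional[dict] = None):
    """Apply one declared transform to a cell value.

    Supported: ``multiply`` / ``add`` by a constant, ``template`` string
    join over row columns (``{column}`` placeholders), ``lowercase`` /
    ``uppercase``, and ``date`` normalisation to ISO-8601.
    Raises ValueError on non-numeric input to an arithmetic transform;
    callers turn that into a row-level exception, never a fatal error.
    """
    if not spec:
        return value
    for name, arg in spec.items():
        if name == "multiply":
            value = float(value) * float(arg)
        elif name == "add":
            value = float(value) + float(arg)
        elif name == "template":
            value = str(arg).format(**(row or {}))
        elif name == "lowercase":
            value = str(value).lower()
        elif name == "uppercase":
            value = str(value).upper()
        elif name == "date":
            value = normalise_date(str(value))
        else:
            raise ImportSpecError(f"unknown transform {name!r}")
    return value


_DATE_FORMATS = ("%Y-%m-%d", "%Y/%m/%d", "%d/%m/%Y", "%d-%m-%Y", "%Y%m%d", "%Y-%m", "%Y")


def normalise_date(text: str) -> str:
    text = text.strip()
    for fmt in _DATE_FORMATS:
        try:
            return _dt.datetime.strptime(text, fmt).date().isoformat()
        except ValueError:
            continue
    raise ValueError(f"unrecognised date {text!r}")


def coerce_value(value, definition: AttributeDefinition):
    """Coerce a transformed cell to the attribute's declared type.

    Dates are held as ISO strings (which compare chronologically);
    ordered-keyword labels are canonicalised against the enum.  A list
    cell may hold several separator-joined values and coerces to a list.
    """
    vt = definition.value_type
    if vt == "integer":
        f = float(value)
        if f != int(f):
            raise ValueError(f"{value!r} is not an integer")
        return int(f)
    if vt == "float":
        return float(value)
    if vt == "date":
        return normalise_date(str(value))
    if vt == "list":
        parts = [p.strip() for p in str(value).split(definition.list_separator)]
        return [p for p in parts if p]
    label = str(value).strip()
    if vt == "ordered_keyword":
        for e in definition.enum:
            if str(e).casefold() == label.casefold():
                return str(e)
        raise ValueError(f"{label!r} not in enum {definition.enum}")
    return label


def check_constraints(value, definition: AttributeDefinition) -> Optional[str]:
    """Return a violation message or None.  Runs after transforms."""
    cons = definition.constraints
    values = value if isinstance(value, list) else [value]
    for v in values:
        if "min" in cons and not isinstance(v, str) and v < cons["min"]:
            return f"{v!r} < min {cons['min']}"
        if "max" in cons and not isinstance(v, str) and v > cons["max"]:
            return f"{v!r} > max {cons['max']}"
        if cons.get("enum") and definition.value_type in ("keyword", "list"):
            labels = [str(e).casefold() for e in cons["enum"]]
            if str(v).casefold() not in labels:
                return f"{v!r} not in enum"
    return None


# ---------------------------------------------------------------------------
# taxon matching


def _cell(row: dict, col: Optional[str], markers) -> Optional[str]:
    if not col:
        return None
    v = str(row.get(col, "")).strip()
    return None if v in markers else v


def match_row_to_taxon(row: dict, store: Store, spec: ImportSpec):
    """Resolve one data row to a backbone taxon.

    Tier order: (1) explicit taxon_id verbatim; (2) unique scientific
    name; (3) name disambiguated by higher-rank columns; (4) synonym
    match if allowed; (5) fuzzy match if allowed; (6) insertion of a new
    taxon if ``create_missing_taxa``.  Returns ``(taxon_id, tier)``;
    tiers 3-6 are "inferred" and should be routed to the review file.
    Unresolvable rows return an :class:`ExceptionRecord`.
    """
    markers = spec.missing_markers
    cols = spec.taxonomy_columns
    tid = _cell(row, cols.get("taxon_id"), markers)
    if tid is not None and tid in store.taxa:
        return tid, 1

    name = _cell(row, cols.get("scientific_name"), markers)
    if name is None:
        return ExceptionRecord(row, "no-taxon-match", "no taxon_id or name in row")

    higher = {
        rank: _cell(row, col, markers)
        for rank, col in cols.items()
        if rank not in ("taxon_id", "scientific_name")
    }
    higher = {r: n for r, n in higher.items() if n}

    def congruent(candidates: list[str]) -> list[str]:
        if not higher:
            return candidates
        out = []
        for cand in candidates:
            lin = {(a.rank, a.scientific_name.casefold()) for a in store.taxa[cand].lineage}
            if all((r, n.casefold()) in lin for r, n in higher.items()):
                out.append(cand)
        return out

    exact = store.taxa_named(name, SCIENTIFIC_NAME)
    if len(exact) == 1:
        return exact[0], 2
    if len(exact) > 1:
        kept = congruent(exact)
        if len(kept) == 1:
            return kept[0], 3
        return ExceptionRecord(
            row, "ambiguous-match", f"{name!r} matches {len(exact)} taxa"
        )

    if spec.allow_synonyms:
        syn = congruent(store.taxa_named(name))
        if len(syn) == 1:
            return syn[0], 4
        if len(syn) > 1:
            return ExceptionRecord(row, "ambiguous-match", f"synonym {name!r} ambiguous")

    if spec.allow_fuzzy:
        best: list[str] = []
        best_d = 3
        for key, entries in store._taxon_names.items():
            d = _edit_distance(name.casefold(), key)
            if d < best_d:
                best_d, best = d, sorted({e[0] for e in entries})
            elif d == best_d:
                best = sorted(set(best) | {e[0] for e in entries})
        kept = congruent(best)
        if len(kept) == 1:
            return kept[0], 5
        if len(kept) > 1:
            return ExceptionRecord(row, "ambiguous-match", f"fuzzy {name!r} ambiguous")

    if spec.create_missing_taxa and higher:
        try:
            return insert_taxon(name, "species", higher, store), 6
        except AnchorError as e:
            return ExceptionRecord(row, e.reason, str(e))

    return ExceptionRecord(row, "no-taxon-match", f"{name!r} not found")


# ---------------------------------------------------------------------------
# indexing


def _ensure_slot(doc, attribute: str) -> AttributeSlot:
    if attribute not in doc.attributes:
        doc.attributes[attribute] = AttributeSlot()
    return doc.attributes[attribute]


def index_file(
    spec: ImportSpec,
    store: Store,
    exceptions_path=None,
    inferred_path=None,
) -> IndexResult:
    """Import one TSV/CSV per its spec, appending raw values to the store.

    One RawValue per non-empty attribute cell per matched row; a bad
    cell voids only that cell.  Re-importing the identical file is
    idempotent: duplicates on (document, attribute, value, source) are
    skipped.  Summaries of touched slots are refreshed in place.
    """
    if not Path(spec.file_path).exists():
        raise FileNotFoundError(spec.file_path)
    for col, cspec in spec.attribute_columns.items():
        if cspec.attribute not in store.attributes:
            raise ImportSpecError(
                f"attribute {cspec.attribute!r} (column {col!r}) not registered"
            )

    result = IndexResult()
    exceptions: list[ExceptionRecord] = []
    inferred: list[tuple[dict, str, int]] = []
    with open(spec.file_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=spec.delimiter)
        for row in reader:
            row_indexed = _index_row(spec, store, row, result, exceptions, inferred)
            if row_indexed:
                result.indexed += 1
            else:
                result.exceptions += 1
    result.inferred = len(inferred)

    if exceptions_path and exceptions:
        _write_rows(
            exceptions_path,
            [dict(e.row, reason=e.reason, detail=e.detail) for e in exceptions],
        )
    if inferred_path and inferred:
        _write_rows(
            inferred_path,
            [dict(r, matched_taxon_id=t, match_tier=tier) for r, t, tier in inferred],
        )
    logger.info(
        "indexed %s: %d rows indexed, %d inferred matches, %d exceptions, %d raw values",
        spec.file_path,
        result.indexed,
        result.inferred,
        result.exceptions,
        result.raw_values,
    )
    return result


def _index_row(spec, store, row, result, exceptions, inferred) -> bool:
    from .fill import refresh_summary

    match = match_row_to_taxon(row, store, spec)
    if isinstance(match, ExceptionRecord):
        exceptions.append(match)
        result.cell_exceptions.append(match)
        return False
    taxon_id, tier = match
    if tier >= 3:
        inferred.append((row, taxon_id, tier))

    if spec.index == "assembly":
        aid = _cell(row, spec.assembly_id_column, spec.missing_markers)
        if aid is None:
            rec = ExceptionRecord(row, "no-taxon-match", "missing assembly_id")
            exceptions.append(rec)
            result.cell_exceptions.append(rec)
            return False
        if aid not in store.assemblies:
            store.add_assembly(AssemblyDocument(assembly_id=aid, taxon_id=taxon_id))
        target = store.assemblies[aid]
    else:
        target = store.taxa[taxon_id]

    wrote_any = False
    attempted = 0
    for col, cspec in spec.attribute_columns.items():
        cell = _cell(row, col, spec.missing_markers)
        if cell is None:
            continue
        attempted += 1
        definition: AttributeDefinition = store.attributes[cspec.attribute]
        try:
            value = cell
            if cspec.translate:
                value = cspec.translate.get(str(value), value)
            value = apply_transform(value, cspec.transform, row)
            value = coerce_value(value, definition)
        except (ValueError, KeyError) as e:
            rec = ExceptionRecord(row, "type-error", f"{col}: {e}")
            exceptions.append(rec)
            result.cell_exceptions.append(rec)
            continue
        violation = check_constraints(value, definition)
        if violation:
            rec = ExceptionRecord(row, "constraint-violation", f"{col}: {violation}")
            exceptions.append(rec)
            result.cell_exceptions.append(rec)
            continue
        slot = _ensure_slot(target, cspec.attribute)
        rv = RawValue(
            value=value,
            source_name=spec.source_name,
            source_url=spec.source_url,
            imported_at=spec.source_date or _dt.date.today().isoformat(),
        )
        if any(existing.key() == rv.key() for existing in slot.raw):
            wrote_any = True  # row still counts as indexed on re-import
            continue
        slot.raw.append(rv)
        refresh_summary(slot, definition)
        result.raw_values += 1
        wrote_any = True
    # a matched row with no non-empty attribute cells is vacuously processed
    return wrote_any or attempted == 0


def _write_rows(path, rows: list[dict]) -> None:
    cols: list[str] = []
    for r in rows:
        for k in r:
            if k not in cols:
                cols.append(k)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def index_directory(directory, store: Store, write_logs: bool = True) -> dict[str, IndexResult]:
    """Scan a directory for ``*.yaml`` import specs and index each one.

    Mirrors directory-level import semantics: every YAML with a sibling
    data file is processed; exceptions/review files are written next to
    the spec as ``<stem>.exceptions.tsv`` / ``<stem>.inferred.tsv``.
    """
    directory = Path(directory)
    results: dict[str, IndexResult] = {}
    for yml in sorted(directory.glob("*.yaml")):
        spec, defs = parse_import_spec(yml, registry=store.attributes)
        for ad in defs:
            store.attributes[ad.name] = ad
        results[yml.name] = index_file(
            spec,
            store,
            exceptions_path=(yml.with_suffix(".exceptions.tsv") if write_logs else None),
            inferred_path=(yml.with_suffix(".inferred.tsv") if write_logs else None),
        )
    return results
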