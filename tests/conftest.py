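"""Shared fixtures and independent oracles.

Oracles here deliberately re-derive results by the most naive route
available (explicit recursion, per-document scans, textbook DP) so they
stay independent of the engine's indexed implementations.
"""

from __future__ import annotations

import statistics

import numpy as np
import pytest

from cladestore.taxonomy import (
    AncestorRef,
    Name,
    RawValue,
    Store,
    TaxonDocument,
    rank_level,
)
from cladestore.ingest import AttributeDefinition, Traverse
from cladestore.fill import refresh_summary


# ---------------------------------------------------------------------------
# store builders


def make_store(nodes):
    """Build a Store from (taxon_id, parent_id, rank, name) rows.

    The first row whose parent equals its own id is the root.  Lineages
    are derived by per-node parent walks.
    """
    parent = {tid: pid for tid, pid, _, _ in nodes}
    meta = {tid: (rank, name) for tid, _, rank, name in nodes}
    store = Store()
    root = next(tid for tid, pid, _, _ in nodes if pid == tid)
    store.root_id = root
    for tid, pid, rank, name in nodes:
        lineage = []
        cur, depth = tid, 0
        while cur != root:
            cur = parent[cur]
            depth += 1
            lineage.append(AncestorRef(cur, meta[cur][0], meta[cur][1], depth))
        store.add_taxon(
            TaxonDocument(
                taxon_id=tid,
                parent_id=None if tid == root else pid,
                rank=rank,
                scientific_name=name,
                names=[Name(name)],
                lineage=lineage,
            )
        )
    return store


def register(store, name, **kwargs):
    kwargs.setdefault("summary_rules", ["median", "mode", "list"])
    ad = AttributeDefinition(name=name, **kwargs)
    store.attributes[name] = ad
    return ad


def add_value(store, doc_id, attr, value, source="src", index="taxon"):
    from cladestore.taxonomy import AttributeSlot

    doc = store.taxa[doc_id] if index == "taxon" else store.assemblies[doc_id]
    slot = doc.attributes.setdefault(attr, AttributeSlot())
    slot.raw.append(RawValue(value=value, source_name=source, imported_at="2022-11-16"))
    refresh_summary(slot, store.attributes[attr])
    return slot


@pytest.fixture
def chain_store():
    """root -> A -> B -> C."""
    return make_store(
        [
            ("1", "1", "no rank", "root"),
            ("2", "1", "family", "A"),
            ("3", "2", "genus", "B"),
            ("4", "3", "species", "C"),
        ]
    )


def random_tree_nodes(rng: np.random.Generator, n: int):
    """Random single-root tree as (tid, parent, rank, name) rows."""
    rows = [("1", "1", "no rank", "root")]
    for i in range(2, n + 1):
        parent = str(int(rng.integers(1, i)))
        rows.append((str(i), parent, "clade", f"node {i}"))
    return rows


# ---------------------------------------------------------------------------
# naive oracles


def naive_levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def naive_parent_walk(parent_of: dict, tid: str, root: str) -> list[str]:
    out = []
    cur = tid
    while cur != root:
        cur = parent_of[cur]
        out.append(cur)
    return out


def _naive_stat(stat, values, defn):
    if stat == "median":
        ordered = sorted(values)
        n = len(ordered)
        if defn.value_type in ("integer", "float"):
            mid = n // 2
            return (ordered[mid - 1] + ordered[mid]) / 2 if n % 2 == 0 else ordered[mid]
        return ordered[(n - 1) // 2]
    if stat == "mode":
        freq = {}
        for v in values:
            freq[v] = freq.get(v, 0) + 1
        best = max(freq.values())
        tied = [v for v, c in freq.items() if c == best]
        enum = defn.enum
        if enum:
            labels = [str(e).casefold() for e in enum]
            return min(
                tied,
                key=lambda v: (
                    labels.index(str(v).casefold()) if str(v).casefold() in labels else len(labels),
                    str(v),
                ),
            )
        return min(tied)
    if stat == "mean":
        return statistics.fmean(values)
    if stat == "min":
        return min(values)
    if stat == "max":
        return max(values)
    raise ValueError(stat)


def naive_fill_expectation(store, attr):
    """Expected (value, provenance, source) per taxon, by explicit recursion.

    Descendant values: recursive bottom-up recomputation.  Ancestor
    values: nearest-informative-ancestor search up the lineage, cut by
    blocked nodes.  Independent of the engine's iterative passes.
    """
    defn = store.attributes[attr]
    direction = defn.traverse.direction
    stat = defn.traverse.statistic or (
        "median" if defn.value_type in ("integer", "float") else "mode"
    )

    blocked = set()
    limit = defn.traverse.limit or {}
    if "clade" in limit:
        label = str(limit["clade"])
        seeds = [label] if label in store.taxa else [
            t for t, d in store.taxa.items()
            if any(nm.name.casefold() == label.casefold() for nm in d.names)
        ]

        def collect(t):
            blocked.add(t)
            for c in store.children.get(t, []):
                collect(c)

        for s in seeds:
            collect(s)
    if "rank" in limit:
        cut = rank_level(limit["rank"])
        for t, d in store.taxa.items():
            lvl = rank_level(d.rank)
            if lvl is not None and lvl < cut:
                blocked.add(t)

    direct = {}
    for tid, doc in store.taxa.items():
        slot = doc.attributes.get(attr)
        if slot and slot.raw:
            direct[tid] = slot.summary.value

    import sys

    sys.setrecursionlimit(10000)
    memo = {}

    def avail(tid):
        """Direct or descendant-derived value, or None."""
        if tid in memo:
            return memo[tid]
        if tid in blocked:
            memo[tid] = None
            return None
        if tid in direct:
            memo[tid] = direct[tid]
            return direct[tid]
        result = None
        if direction in ("up", "both"):
            vals = [avail(c) for c in sorted(store.children.get(tid, []), key=int)]
            vals = [v for v in vals if v is not None]
            if vals:
                result = _naive_stat(stat, vals, defn)
        memo[tid] = result
        return result

    expected = {}
    for tid, doc in store.taxa.items():
        if tid in direct:
            expected[tid] = (direct[tid], "direct", None)
            continue
        if tid in blocked:
            expected[tid] = None
            continue
        v = avail(tid)
        if v is not None:
            expected[tid] = (v, "descendant", None)
            continue
        if direction in ("down", "both"):
            found = None
            for anc in doc.lineage:
                if anc.taxon_id in blocked:
                    break
                av = avail(anc.taxon_id)
                if av is not None:
                    found = (av, "ancestor", anc.taxon_id)
                    break
            expected[tid] = found
        else:
            expected[tid] = None
    return expected


# ---------------------------------------------------------------------------
# naive per-document query matcher


def _nm_glob(pattern, text):
    import fnmatch

    return fnmatch.fnmatchcase(text.casefold(), pattern.casefold())


_nm_cache: dict = {}


def _nm_names(store, pattern, name_class):
    """Taxa whose names match, by full scan over every document's name list.

    Resolutions are memoised per store so the per-document oracle stays
    usable on 10^4-document fixtures; each entry is still computed by a
    full scan.
    """
    key = (id(store), pattern, name_class)
    if key in _nm_cache:
        return _nm_cache[key]
    out = set()
    for tid, doc in store.taxa.items():
        for nm in doc.names:
            if name_class is not None and nm.name_class != name_class:
                continue
            if _nm_glob(pattern, nm.name):
                out.add(tid)
    _nm_cache[key] = out
    return out


def _nm_anchor(store, pattern, name_class):
    """tax_tree/tax_lineage anchor: a verbatim taxon id wins, else names."""
    if name_class is None and pattern in store.taxa:
        return {pattern}
    return _nm_names(store, pattern, name_class)


def _nm_reported(slot, include_estimates):
    if slot is None or slot.estimate is None:
        return None
    if not include_estimates and slot.estimate.provenance == "ancestor":
        return None
    return slot.estimate


def _nm_compare(op, left, rights, defn):
    def conv(x):
        if defn is None or defn.value_type in ("integer", "float"):
            return float(x)
        if defn.value_type == "ordered_keyword":
            labels = [str(e).casefold() for e in defn.enum]
            return len(labels) - labels.index(str(x).casefold())
        if defn.value_type == "date":
            return str(x)
        return str(x).casefold()

    for r in rights:
        try:
            lv, rv = conv(left), conv(r)
        except (ValueError, TypeError):
            continue
        if (
            (op == "=" and lv == rv)
            or (op == "<" and lv < rv)
            or (op == "<=" and lv <= rv)
            or (op == ">=" and lv >= rv)
            or (op == ">" and lv > rv)
        ):
            return True
    return False


def naive_match_doc(doc, ast, store, index="taxon", include_estimates=True):
    """Term-by-term matcher applied to a single document."""
    from cladestore.query import AttributeTerm, TaxonTerm

    if index == "taxon":
        own = doc.taxon_id
        path = [own] + [a.taxon_id for a in doc.lineage]
        own_rank = doc.rank
    else:
        own = doc.taxon_id  # owning taxon
        path = [a.taxon_id for a in doc.lineage]
        own_rank = store.taxa[own].rank

    anchors = set()
    for term in ast.terms:
        if not isinstance(term, TaxonTerm):
            continue
        for arg in term.arguments:
            if arg.negated:
                continue
            if term.function == "tax_eq" and arg.pattern in store.taxa:
                anchors.add(arg.pattern)
            elif term.function == "tax_name":
                anchors |= _nm_names(store, arg.pattern, arg.name_class)
            elif term.function == "tax_tree":
                anchors |= _nm_anchor(store, arg.pattern, arg.name_class)

    for term in ast.terms:
        if isinstance(term, TaxonTerm):
            fn = term.function
            if fn == "tax_depth":
                n = int(term.arguments[0].pattern)
                depths = [d for d, t in enumerate(path) if t in anchors]
                if not depths or min(depths) > n:
                    return False
                continue

            def arg_hits(arg):
                if fn == "tax_eq":
                    return own == arg.pattern
                if fn == "tax_name":
                    return own in _nm_names(store, arg.pattern, arg.name_class)
                if fn == "tax_tree":
                    targets = _nm_anchor(store, arg.pattern, arg.name_class)
                    return bool(targets & set(path))
                if fn == "tax_rank":
                    return _nm_glob(arg.pattern, own_rank)
                if fn == "tax_lineage":
                    targets = _nm_anchor(store, arg.pattern, arg.name_class)
                    assert len(targets) == 1
                    (t,) = targets
                    tpath = [t] + [a.taxon_id for a in store.taxa[t].lineage]
                    return own in tpath
                raise AssertionError(fn)

            pos = [a for a in term.arguments if not a.negated]
            neg = [a for a in term.arguments if a.negated]
            if not any(arg_hits(a) for a in pos):
                return False
            if any(arg_hits(a) for a in neg):
                return False
        else:
            assert isinstance(term, AttributeTerm)
            defn = store.attributes[term.attribute]
            slot = doc.attributes.get(term.attribute)
            op = "=" if term.operator == "!=" else term.operator
            if term.modifier == "length":
                if slot is None:
                    n_raw = 0
                elif defn.value_type == "list":
                    flat = set()
                    for rv in slot.raw:
                        flat.update(rv.value if isinstance(rv.value, list) else [rv.value])
                    n_raw = len(flat)
                else:
                    n_raw = len(slot.raw)
                ok = _nm_compare(op, n_raw, term.values, None)
            elif term.modifier in ("min", "max"):
                if slot is None or slot.summary is None:
                    ok = False
                else:
                    bound = slot.summary.min if term.modifier == "min" else slot.summary.max
                    if bound is None:
                        ok = False
                    elif op == "exists":
                        ok = True
                    else:
                        ok = _nm_compare(op, bound, term.values, defn)
            else:
                est = _nm_reported(slot, include_estimates)
                if est is None:
                    ok = False
                elif op == "exists":
                    ok = True
                elif isinstance(est.value, list) or defn.value_type == "list":
                    members = est.value if isinstance(est.value, list) else [est.value]
                    ok = any(
                        str(m).casefold() == v.casefold()
                        for m in members
                        for v in term.values
                    )
                else:
                    ok = _nm_compare(op, est.value, term.values, defn)
            if term.negated ^ (term.operator == "!="):
                ok = not ok
            if not ok:
                return False
    return True


def naive_evaluate(ast, store, index="taxon", include_estimates=True):
    from cladestore.taxonomy import sort_key

    docs = store.taxa if index == "taxon" else store.assemblies
    return sorted(
        (
            doc_id
            for doc_id, doc in docs.items()
            if naive_match_doc(doc, ast, store, index, include_estimates)
        ),
        key=sort_key,
    )


# ---------------------------------------------------------------------------
# random query generation (from the grammar)


def random_query(rng, store, index="taxon"):
    """Random QueryExpression drawn from the search grammar.

    Values are sampled from the store so queries have non-trivial hit
    rates; operator choice respects attribute orderability.
    """
    from cladestore.query import AttributeTerm, QueryExpression, TaxonArg, TaxonTerm

    taxon_ids = sorted(store.taxa, key=lambda t: int(t))
    attrs = [
        a
        for a, d in store.attributes.items()
        if d.index == index
    ]
    terms = []

    def rand_taxon():
        return store.taxa[taxon_ids[int(rng.integers(0, len(taxon_ids)))]]

    def taxon_term():
        kind = rng.choice(["tree", "tree_neg", "rank", "eq", "name", "lineage"])
        if kind == "tree":
            return TaxonTerm("tax_tree", (TaxonArg(rand_taxon().scientific_name),))
        if kind == "tree_neg":
            a, b = rand_taxon(), rand_taxon()
            return TaxonTerm(
                "tax_tree",
                (TaxonArg(a.scientific_name), TaxonArg(b.taxon_id, negated=True)),
            )
        if kind == "rank":
            rank = rng.choice(["species", "genus", "family", "order", "class"])
            return TaxonTerm("tax_rank", (TaxonArg(str(rank)),))
        if kind == "eq":
            return TaxonTerm("tax_eq", (TaxonArg(rand_taxon().taxon_id),))
        if kind == "name":
            name = rand_taxon().scientific_name
            if rng.random() < 0.5 and " " in name:
                name = name.split(" ")[0] + " *"
            return TaxonTerm("tax_name", (TaxonArg(name),))
        return TaxonTerm("tax_lineage", (TaxonArg(rand_taxon().taxon_id),))

    def attribute_term():
        attr = str(rng.choice(sorted(attrs)))
        defn = store.attributes[attr]
        docs = store.taxa if index == "taxon" else store.assemblies
        pool = []
        for doc in docs.values():
            slot = doc.attributes.get(attr)
            if slot and slot.estimate is not None:
                v = slot.estimate.value
                pool.extend(v if isinstance(v, list) else [v])
            if len(pool) > 50:
                break
        if not pool or rng.random() < 0.1:
            return AttributeTerm(attr)  # existence filter
        pivot = pool[int(rng.integers(0, len(pool)))]
        orderable = defn.value_type in ("integer", "float", "date", "ordered_keyword")
        modifier = "none"
        r = rng.random()
        if r < 0.15:
            modifier = "length"
            pivot = int(rng.integers(0, 3))
            op = str(rng.choice([">", "=", "<="]))
        elif r < 0.3 and defn.value_type in ("integer", "float", "date"):
            modifier = str(rng.choice(["min", "max"]))
            op = str(rng.choice(["<", "<=", "=", ">=", ">"]))
        elif orderable:
            op = str(rng.choice(["<", "<=", "=", ">=", ">", "!="]))
        else:
            op = str(rng.choice(["=", "!="]))
        values = [str(pivot)]
        if rng.random() < 0.25 and pool:
            values.append(str(pool[int(rng.integers(0, len(pool)))]))
        return AttributeTerm(attr, modifier, op, tuple(values))

    n_terms = int(rng.integers(1, 4))
    for _ in range(n_terms):
        if attrs and rng.random() < 0.55:
            terms.append(attribute_term())
        else:
            terms.append(taxon_term())
    if rng.random() < 0.15:
        # anchored depth restriction
        anchor = rand_taxon()
        terms.append(TaxonTerm("tax_tree", (TaxonArg(anchor.taxon_id),)))
        terms.append(TaxonTerm("tax_depth", (TaxonArg(str(int(rng.integers(1, 5)))),)))
    return QueryExpression(tuple(terms))


# ---------------------------------------------------------------------------
# full synthetic pipeline store (session-scoped; shared by query/report tests)


@pytest.fixture(scope="session")
def pipeline_store(tmp_path_factory):
    """~10k-document store built from seeded fixtures through the full pipeline."""
    from cladestore.fill import fill_all
    from cladestore.ingest import index_directory
    from cladestore.synth import FixtureSpec, synth_all

    tmp = tmp_path_factory.mktemp("pipeline")
    spec = FixtureSpec(n_species=5000, homonyms=10, synonyms=40)
    _, data_dir, store = synth_all(spec, seed=20220, out_dir=tmp)
    index_directory(data_dir, store, write_logs=False)
    fill_all(store)
    return store
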