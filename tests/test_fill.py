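"""Summary statistics and tree-based propagation of estimates."""

import copy

import numpy as np
import pytest

from cladestore.fill import fill_all, fill_attribute, summarise
from cladestore.ingest import Traverse

from conftest import (
    add_value,
    make_store,
    naive_fill_expectation,
    random_tree_nodes,
    register,
)

LEVELS = ["complete genome", "chromosome", "scaffold", "contig"]


class TestSummarise:
    def test_priority_by_enum_prefers_higher_level(self):
        s = summarise(
            ["scaffold", "chromosome"],
            ["priority-by-enum"],
            enum=LEVELS,
            value_type="ordered_keyword",
        )
        assert s.value == "chromosome"
        assert (s.min, s.max) == ("scaffold", "chromosome")

    def test_median_with_range(self):
        s = summarise([10, 20], ["median"], value_type="integer")
        assert (s.value, s.min, s.max, s.count) == (15, 10, 20, 2)

    @pytest.mark.parametrize(
        "values, expected",
        [([2, 2, 3], 2), ([2, 3], 2), ([5, 5, 1, 1], 1)],
    )
    def test_mode_with_ascending_tiebreak(self, values, expected):
        # oracle: frequency count over the list, ties to the smaller value
        freq = {v: values.count(v) for v in values}
        best = max(freq.values())
        assert expected == min(v for v, c in freq.items() if c == best)
        assert summarise(values, ["mode"], value_type="integer").value == expected

    def test_first_applicable_rule_wins(self):
        s = summarise(["a", "b", "b"], ["mean", "median", "mode"], value_type="keyword")
        assert s.statistic == "mode" and s.value == "b"

    def test_priority_by_source(self):
        s = summarise(
            [1.0, 2.0],
            ["priority-by-source"],
            source_priority=["curated", "bulk"],
            sources=["bulk", "curated"],
        )
        assert s.value == 2.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarise([], ["median"])

    def test_ordered_priority_without_enum_rejected(self):
        with pytest.raises(ValueError, match="enum"):
            summarise(["a"], ["priority-by-enum"], value_type="keyword")


STAR = [
    ("1", "1", "no rank", "root"),
    ("2", "1", "species", "a"),
    ("3", "1", "species", "b"),
    ("4", "1", "species", "c"),
]


class TestFillAttribute:
    def test_star_tree_two_pass(self):
        """Children {10, 20} give the parent a descendant median of 15,
        which then fills the value-less third child as an ancestor copy."""
        store = make_store(STAR)
        register(store, "gs", value_type="float", traverse=Traverse(direction="both"))
        add_value(store, "2", "gs", 10.0)
        add_value(store, "3", "gs", 20.0)
        fill_attribute(store, "gs")
        parent = store.taxa["1"].attributes["gs"].estimate
        assert (parent.value, parent.provenance) == (15.0, "descendant")
        orphan = store.taxa["4"].attributes["gs"].estimate
        assert (orphan.value, orphan.provenance, orphan.source_taxon_id) == (
            15.0,
            "ancestor",
            "1",
        )

    def test_single_direct_value_unchanged(self):
        store = make_store([("1", "1", "no rank", "root")])
        register(store, "gs", value_type="float", traverse=Traverse(direction="both"))
        add_value(store, "1", "gs", 7.0)
        assert fill_attribute(store, "gs") == 0
        est = store.taxa["1"].attributes["gs"].estimate
        assert (est.value, est.provenance) == (7.0, "direct")

    def test_direction_up_only_leaves_tips_empty(self):
        store = make_store(STAR)
        register(store, "gs", value_type="float", traverse=Traverse(direction="up"))
        add_value(store, "2", "gs", 10.0)
        fill_attribute(store, "gs")
        assert store.taxa["1"].attributes["gs"].estimate.provenance == "descendant"
        assert "gs" not in store.taxa["4"].attributes

    def test_clade_barrier_blocks_estimates_inside(self):
        """No taxon inside the barrier clade receives any estimate, and
        values inside the clade never leak above it."""
        store = make_store(
            [
                ("1", "1", "no rank", "root"),
                ("2", "1", "clade", "Plants"),
                ("3", "2", "species", "plant one"),
                ("4", "1", "clade", "Animals"),
                ("5", "4", "species", "animal one"),
                ("6", "4", "species", "animal two"),
            ]
        )
        register(
            store,
            "plastid_span",
            value_type="float",
            traverse=Traverse(direction="both", limit={"clade": "Animals"}),
        )
        add_value(store, "3", "plastid_span", 150000.0)
        add_value(store, "5", "plastid_span", 99.0)  # inside barrier; must not leak
        fill_attribute(store, "plastid_span")
        for blocked in ("4", "6"):
            slot = store.taxa[blocked].attributes.get("plastid_span")
            assert slot is None or slot.estimate is None
        assert store.taxa["1"].attributes["plastid_span"].estimate.value == 150000.0

    def test_assembly_attribute_rejected(self):
        store = make_store(STAR)
        register(store, "span", index="assembly", traverse=Traverse(direction="both"))
        with pytest.raises(ValueError, match="taxon index"):
            fill_attribute(store, "span")

    def test_unknown_attribute_rejected(self):
        with pytest.raises(KeyError):
            fill_attribute(make_store(STAR), "nope")


def _random_filled_store(seed, n_nodes=200, direction="both", barrier=False,
                         value_type="float"):
    rng = np.random.default_rng(seed)
    store = make_store(random_tree_nodes(rng, n_nodes))
    limit = None
    if barrier:
        internal = [t for t in store.taxa if store.children[t] and t != "1"]
        if internal:
            limit = {"clade": str(rng.choice(internal))}
    register(
        store,
        "trait",
        value_type=value_type,
        constraints={"enum": LEVELS} if value_type == "ordered_keyword" else {},
        summary_rules=["median"] if value_type == "float" else ["mode"],
        traverse=Traverse(direction=direction, limit=limit),
    )
    tips = [t for t in store.taxa if not store.children[t]]
    informative = rng.choice(tips, size=max(1, int(0.3 * len(tips))), replace=False)
    for t in informative:
        if value_type == "float":
            add_value(store, str(t), "trait", float(np.round(rng.lognormal(20, 1), 3)))
        else:
            add_value(store, str(t), "trait", str(rng.choice(LEVELS)))
    return store


def _assert_matches_oracle(store, attr="trait"):
    expected = naive_fill_expectation(store, attr)
    for tid, doc in store.taxa.items():
        slot = doc.attributes.get(attr)
        got = None
        if slot is not None and slot.estimate is not None:
            est = slot.estimate
            if est.provenance == "direct":
                got = (est.value, "direct", None)
            else:
                got = (est.value, est.provenance, est.source_taxon_id)
        want = expected.get(tid)
        if want and want[1] == "descendant":
            want = (want[0], "descendant", None)
        assert got == want, f"taxon {tid}: {got} != {want}"


@pytest.mark.parametrize("direction", ["up", "down", "both"])
@pytest.mark.parametrize("barrier", [False, True])
def test_fill_equals_recursive_oracle(direction, barrier):
    """Every estimate and provenance label matches a naive recursive oracle
    on random 200-node taxonomies with 30% informative tips."""
    for seed in range(12):
        store = _random_filled_store(seed, direction=direction, barrier=barrier)
        fill_attribute(store, "trait")
        _assert_matches_oracle(store)


def test_fill_keyword_mode_matches_oracle():
    for seed in range(5):
        store = _random_filled_store(seed, value_type="ordered_keyword")
        fill_attribute(store, "trait")
        _assert_matches_oracle(store)


def test_fill_idempotent_and_conserves_direct_values():
    store = _random_filled_store(3)
    direct_before = {
        t: copy.deepcopy(d.attributes["trait"])
        for t, d in store.taxa.items()
        if d.attributes.get("trait") and d.attributes["trait"].raw
    }
    first = fill_attribute(store, "trait")
    assert first > 0
    assert fill_attribute(store, "trait") == 0
    for t, slot in direct_before.items():
        after = store.taxa[t].attributes["trait"]
        assert after.raw == slot.raw and after.summary == slot.summary


def test_incremental_value_changes_only_root_path_and_descendants():
    """Adding one tip value only changes estimates reachable from that tip."""
    store = _random_filled_store(4)
    fill_attribute(store, "trait")
    before = {
        t: copy.deepcopy(d.attributes.get("trait")) for t, d in store.taxa.items()
    }
    bare_tips = [
        t
        for t in store.taxa
        if not store.children[t]
        and not (store.taxa[t].attributes.get("trait") and store.taxa[t].attributes["trait"].raw)
    ]
    tip = bare_tips[0]
    add_value(store, tip, "trait", 1.0e12)
    fill_attribute(store, "trait")
    root_path = {tip} | {a.taxon_id for a in store.taxa[tip].lineage}
    # nodes whose nearest informative source may route through the root path
    allowed = set(root_path)
    for t in root_path:
        allowed |= store.descendants(t)
    for t, slot in before.items():
        after = store.taxa[t].attributes.get("trait")
        if t not in allowed:
            assert after == slot, f"unrelated taxon {t} changed"


def test_provenance_soundness():
    """Ancestor estimates equal their source's stored value; descendant
    estimates are reproducible from the subtree's direct values alone."""
    store = _random_filled_store(5)
    fill_attribute(store, "trait")
    expected = naive_fill_expectation(store, "trait")
    for t, doc in store.taxa.items():
        slot = doc.attributes.get("trait")
        if not slot or not slot.estimate:
            continue
        est = slot.estimate
        if est.provenance == "ancestor":
            src = store.taxa[est.source_taxon_id].attributes["trait"].estimate
            assert src.provenance in ("direct", "descendant")
            assert est.value == src.value
            assert est.source_taxon_id in {a.taxon_id for a in doc.lineage}
        elif est.provenance == "descendant":
            assert expected[t][0] == est.value  # recomputed from subtree only


@pytest.mark.parametrize("stat, cmp", [("min", 1), ("max", -1)])
def test_monotone_statistics_bound_subtree(stat, cmp):
    """With ancestor-summary min (max), descendant estimates lie below
    (above) every direct value in their subtree."""
    rng = np.random.default_rng(9)
    store = make_store(random_tree_nodes(rng, 150))
    register(
        store,
        "trait",
        value_type="float",
        summary_rules=["median"],
        traverse=Traverse(direction="up", statistic=stat),
    )
    tips = [t for t in store.taxa if not store.children[t]]
    for t in rng.choice(tips, size=len(tips) // 2, replace=False):
        add_value(store, str(t), "trait", float(rng.normal(0, 10)))
    fill_attribute(store, "trait")
    for t, doc in store.taxa.items():
        slot = doc.attributes.get("trait")
        if not slot or not slot.estimate or slot.estimate.provenance != "descendant":
            continue
        subtree_direct = [
            store.taxa[d].attributes["trait"].summary.value
            for d in store.descendants(t)
            if store.taxa[d].attributes.get("trait") and store.taxa[d].attributes["trait"].raw
        ]
        for v in subtree_direct:
            assert cmp * (slot.estimate.value - v) <= 0


class TestFillAll:
    def test_only_eligible_attributes_filled(self):
        store = make_store(STAR)
        register(store, "gs", traverse=Traverse(direction="both"))
        register(store, "status", value_type="keyword", traverse=Traverse(direction="none"))
        add_value(store, "2", "gs", 1.0)
        add_value(store, "2", "status", "done")
        counts = fill_all(store)
        assert set(counts) == {"gs"}

    def test_rerun_writes_zero(self):
        store = make_store(STAR)
        register(store, "gs", traverse=Traverse(direction="both"))
        add_value(store, "2", "gs", 1.0)
        fill_all(store)
        assert fill_all(store) == {"gs": 0}
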