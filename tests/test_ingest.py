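"""YAML import specs, transforms, taxon matching and the indexing pass."""

import textwrap

import pytest
import yaml

from cladestore.ingest import (
    ExceptionRecord,
    ImportSpec,
    ImportSpecError,
    apply_transform,
    index_file,
    match_row_to_taxon,
    parse_import_spec,
)
from cladestore.query import format_results

from conftest import make_store, register

TAXA = [
    ("1", "1", "no rank", "root"),
    ("10", "1", "family", "Famone"),
    ("20", "1", "family", "Famtwo"),
    ("11", "10", "genus", "Genone"),
    ("21", "20", "genus", "Gentwo"),
    ("12", "11", "species", "Genone alpha"),
    ("13", "11", "species", "Shared name"),  # homonym pair across families
    ("22", "21", "species", "Shared name"),
    ("23", "21", "species", "Gentwo beta"),
]


@pytest.fixture
def store():
    s = make_store(TAXA)
    register(s, "genome_size", value_type="float", constraints={"min": 0})
    register(s, "chromosome_number", value_type="integer", constraints={"min": 1})
    return s


def write_pair(tmp_path, yaml_doc, tsv_text, name="src"):
    (tmp_path / f"{name}.tsv").write_text(textwrap.dedent(tsv_text))
    (tmp_path / f"{name}.yaml").write_text(yaml.safe_dump(yaml_doc))
    return tmp_path / f"{name}.yaml"


MINIMAL_YAML = {
    "file": {"path": "src.tsv", "delimiter": "\t"},
    "attributes": {"genome_size": {"type": "float", "summary": ["median"],
                                   "traverse": {"direction": "both"}}},
    "columns": {"size": {"attribute": "genome_size"}},
    "taxonomy": {"taxon_id": "taxon_id"},
    "source": {"name": "test", "date": "2022-11-16"},
}


class TestParseImportSpec:
    def test_minimal_spec_valid(self, tmp_path):
        path = write_pair(tmp_path, MINIMAL_YAML, "taxon_id\tsize\n12\t5.0\n")
        spec, defs = parse_import_spec(path)
        assert spec.delimiter == "\t" and spec.source_name == "test"
        assert [d.name for d in defs] == ["genome_size"]

    def test_undeclared_attribute_errors(self, tmp_path):
        doc = dict(MINIMAL_YAML, columns={"size": {"attribute": "mystery"}})
        path = write_pair(tmp_path, doc, "x\n")
        with pytest.raises(ImportSpecError, match="mystery"):
            parse_import_spec(path)

    def test_unknown_transform_errors(self, tmp_path):
        doc = dict(MINIMAL_YAML)
        doc["columns"] = {"size": {"attribute": "genome_size", "transform": {"frobnicate": 2}}}
        path = write_pair(tmp_path, doc, "x\n")
        with pytest.raises(ImportSpecError, match="frobnicate"):
            parse_import_spec(path)

    def test_missing_file_field_errors(self, tmp_path):
        doc = {k: v for k, v in MINIMAL_YAML.items() if k != "file"}
        path = write_pair(tmp_path, doc, "x\n")
        with pytest.raises(ImportSpecError, match="file"):
            parse_import_spec(path)

    def test_cvalue_spec_registers_pg_to_bp_transform(self, tmp_path):
        """A C-value source converts picograms to base pairs on one column."""
        doc = {
            "file": {"path": "src.tsv", "delimiter": "\t"},
            "attributes": {"genome_size": {"type": "float", "summary": ["median"],
                                           "units": "bp", "traverse": {"direction": "both"}}},
            "columns": {"c_value": {"attribute": "genome_size",
                                    "transform": {"multiply": 0.978e9}}},
            "taxonomy": {"scientific_name": "species", "family": "family"},
            "source": {"name": "cvalues", "date": "2020-01-01"},
        }
        path = write_pair(tmp_path, doc, "species\tfamily\tc_value\nGenone alpha\tFamone\t1.0\n")
        spec, _ = parse_import_spec(path)
        assert spec.attribute_columns["c_value"].transform == {"multiply": 0.978e9}

    def test_registry_conflict_is_hard_error(self, tmp_path, store):
        doc = dict(MINIMAL_YAML)
        doc["attributes"] = {"genome_size": {"type": "integer", "summary": ["median"]}}
        path = write_pair(tmp_path, doc, "x\n")
        with pytest.raises(ImportSpecError, match="conflict"):
            parse_import_spec(path, registry=store.attributes)

    def test_name_without_higher_rank_rejected(self, tmp_path):
        doc = dict(MINIMAL_YAML, taxonomy={"scientific_name": "species"})
        path = write_pair(tmp_path, doc, "x\n")
        with pytest.raises(ImportSpecError, match="higher rank"):
            parse_import_spec(path)


class TestApplyTransform:
    @pytest.mark.parametrize(
        "value, spec, expected",
        [
            (1.0, {"multiply": 0.978e9}, 9.78e8),
            (5, {"multiply": 1}, 5.0),
            (2, {"add": 3}, 5.0),
            ("MiXeD", {"lowercase": True}, "mixed"),
            ("MiXeD", {"uppercase": True}, "MIXED"),
            ("2020-11-30", {"date": True}, "2020-11-30"),
            ("30/11/2020", {"date": True}, "2020-11-30"),
        ],
    )
    def test_supported_transforms(self, value, spec, expected):
        out = apply_transform(value, spec)
        if isinstance(expected, float):
            assert out == pytest.approx(expected)
        else:
            assert out == expected

    def test_template_joins_row_columns(self):
        assert apply_transform("", {"template": "{genus} {species}"},
                               {"genus": "Genone", "species": "alpha"}) == "Genone alpha"

    def test_non_numeric_arithmetic_raises_value_error(self):
        with pytest.raises(ValueError):
            apply_transform("not-a-number", {"multiply": 2})


class TestMatchRow:
    def _spec(self, **opts):
        return ImportSpec(
            file_path="unused",
            taxonomy_columns={"taxon_id": "tid", "scientific_name": "name", "family": "fam"},
            **opts,
        )

    def test_taxon_id_wins_without_lookup(self, store):
        assert match_row_to_taxon({"tid": "23", "name": "ignored"}, store, self._spec()) == ("23", 1)

    def test_unique_name(self, store):
        assert match_row_to_taxon({"name": "Gentwo beta"}, store, self._spec()) == ("23", 2)

    def test_homonym_disambiguated_by_family(self, store):
        row = {"name": "Shared name", "fam": "Famtwo"}
        assert match_row_to_taxon(row, store, self._spec()) == ("22", 3)

    def test_homonym_without_rank_column_is_ambiguous(self, store):
        rec = match_row_to_taxon({"name": "Shared name"}, store, self._spec())
        assert isinstance(rec, ExceptionRecord) and rec.reason == "ambiguous-match"

    def test_fuzzy_only_when_allowed(self, store):
        row = {"name": "Gentwo betb"}
        rec = match_row_to_taxon(row, store, self._spec())
        assert isinstance(rec, ExceptionRecord)
        assert match_row_to_taxon(row, store, self._spec(allow_fuzzy=True)) == ("23", 5)

    def test_create_missing_taxon_anchored_at_genus(self, store):
        row = {"name": "Gentwo gamma", "fam": "Famtwo"}
        spec = self._spec(create_missing_taxa=True)
        tid, tier = match_row_to_taxon(row, store, spec)
        assert tier == 6 and store.taxa[tid].parent_id == "20"
        assert store.taxa[tid].scientific_name == "Gentwo gamma"


class TestIndexFile:
    def _pair(self, tmp_path, tsv):
        doc = {
            "file": {"path": "src.tsv", "delimiter": "\t"},
            "attributes": {
                "genome_size": {"type": "float", "summary": ["median"],
                                "traverse": {"direction": "both"}},
                "chromosome_number": {"type": "integer", "summary": ["mode"],
                                      "constraints": {"min": 1},
                                      "traverse": {"direction": "both"}},
            },
            "columns": {"size": {"attribute": "genome_size"},
                        "chroms": {"attribute": "chromosome_number"}},
            "taxonomy": {"taxon_id": "taxon_id"},
            "source": {"name": "test", "date": "2022-11-16"},
        }
        return write_pair(tmp_path, doc, tsv)

    def test_counts_and_raw_values(self, tmp_path):
        store = make_store(TAXA)
        path = self._pair(
            tmp_path,
            "taxon_id\tsize\tchroms\n12\t100.0\t4\n13\t200.0\t6\n23\t300.0\t8\n",
        )
        spec, defs = parse_import_spec(path)
        for d in defs:
            store.attributes[d.name] = d
        res = index_file(spec, store)
        assert (res.indexed, res.exceptions, res.raw_values) == (3, 0, 6)

    def test_reimport_is_idempotent(self, tmp_path):
        store = make_store(TAXA)
        path = self._pair(tmp_path, "taxon_id\tsize\tchroms\n12\t100.0\t4\n")
        spec, defs = parse_import_spec(path)
        for d in defs:
            store.attributes[d.name] = d
        index_file(spec, store)
        snapshot = [(rv.value, rv.source_name) for rv in store.taxa["12"].attributes["genome_size"].raw]
        res2 = index_file(spec, store)
        assert res2.raw_values == 0 and res2.indexed == 1
        assert [(rv.value, rv.source_name) for rv in store.taxa["12"].attributes["genome_size"].raw] == snapshot

    def test_constraint_violation_voids_cell_not_row(self, tmp_path):
        store = make_store(TAXA)
        path = self._pair(tmp_path, "taxon_id\tsize\tchroms\n12\t100.0\t-1\n")
        spec, defs = parse_import_spec(path)
        for d in defs:
            store.attributes[d.name] = d
        res = index_file(spec, store)
        assert res.indexed == 1 and res.raw_values == 1
        assert "chromosome_number" not in store.taxa["12"].attributes
        assert [r.reason for r in res.cell_exceptions] == ["constraint-violation"]

    def test_rows_in_equals_indexed_plus_exceptions(self, tmp_path):
        store = make_store(TAXA)
        path = self._pair(
            tmp_path,
            "taxon_id\tsize\tchroms\n12\t100.0\t4\nBAD\t1.0\t2\n13\tnot_a_number\tNA\n",
        )
        spec, defs = parse_import_spec(path)
        for d in defs:
            store.attributes[d.name] = d
        res = index_file(spec, store)
        assert res.indexed + res.exceptions == 3
        assert res.exceptions == 2  # unmatched row + row whose only cell is bad

    def test_exceptions_file_appends_reason(self, tmp_path):
        store = make_store(TAXA)
        path = self._pair(tmp_path, "taxon_id\tsize\tchroms\nBAD\t1.0\t2\n")
        spec, defs = parse_import_spec(path)
        for d in defs:
            store.attributes[d.name] = d
        exc = tmp_path / "exceptions.tsv"
        index_file(spec, store, exceptions_path=exc)
        lines = exc.read_text().strip().splitlines()
        assert "reason" in lines[0] and "no-taxon-match" in lines[1]

    def test_transform_applies_before_constraint_check(self, tmp_path):
        """A pre-transform value that violates constraints passes after scaling."""
        store = make_store(TAXA)
        doc = {
            "file": {"path": "src.tsv", "delimiter": "\t"},
            "attributes": {"genome_size": {"type": "float", "summary": ["median"],
                                           "constraints": {"min": 1e6},
                                           "traverse": {"direction": "both"}}},
            "columns": {"c_value": {"attribute": "genome_size",
                                    "transform": {"multiply": 0.978e9}}},
            "taxonomy": {"taxon_id": "taxon_id"},
            "source": {"name": "cv", "date": "2020-01-01"},
        }
        path = write_pair(tmp_path, doc, "taxon_id\tc_value\n12\t1.0\n")
        spec, defs = parse_import_spec(path)
        for d in defs:
            store.attributes[d.name] = d
        res = index_file(spec, store)
        assert res.raw_values == 1
        assert store.taxa["12"].attributes["genome_size"].raw[0].value == pytest.approx(9.78e8)

    def test_raw_mode_round_trip(self, tmp_path):
        """Raw-mode export reproduces the imported value multiset with sources."""
        store = make_store(TAXA)
        path = self._pair(
            tmp_path, "taxon_id\tsize\tchroms\n12\t100.0\t4\n23\t300.0\t8\n"
        )
        spec, defs = parse_import_spec(path)
        for d in defs:
            store.attributes[d.name] = d
        index_file(spec, store)
        docs = [store.taxa["12"], store.taxa["23"]]
        out = format_results(docs, "tsv", "raw")
        rows = [line.split("\t") for line in out.strip().splitlines()[1:]]
        got = sorted((r[0], r[3], r[4], r[6]) for r in rows)
        assert got == sorted(
            [
                ("12", "genome_size", "100", "test"),
                ("12", "chromosome_number", "4", "test"),
                ("23", "genome_size", "300", "test"),
                ("23", "chromosome_number", "8", "test"),
            ]
        )
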