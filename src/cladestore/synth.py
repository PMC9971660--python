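"""Synthetic fixture generator.

Emits everything the engine ingests, so the whole pipeline is testable
without downloads: a multi-rank backbone taxonomy in taxdump dialect
(with configurable homonym and synonym injection), per-attribute
TSV+YAML import pairs with configurable missingness and clade-level
effects, and an assembly table with span/N50/level fields.

The generated attributes emulate the data classes the engine is built
for: a genome-size-like log-normal trait, a chromosome-number-like
small integer, an ordered assembly-level keyword, a project target-list
attribute holding lists, and a sequencing-status milestone keyword.
Alongside each masked data table a ground-truth table (every species'
true value, and whether its family carries a shifted effect) is written
for parameter-recovery tests.

Everything is driven by one integer seed; identical seeds and specs
yield byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "AssemblyFixture",
    "AttributeFixture",
    "FixtureSpec",
    "synth_all",
    "synth_assemblies",
    "synth_attributes",
    "synth_taxonomy",
    "DEFAULT_RANKS",
]

DEFAULT_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

ASSEMBLY_LEVELS = ["complete genome", "chromosome", "scaffold", "contig"]
STATUS_LEVELS = [
    "insdc_open",
    "in_assembly",
    "data_generation",
    "sample_acquired",
    "sample_collected",
]
PROJECTS = ["AAA", "BBB", "CCC", "DDD", "EEE"]


@dataclass
class AttributeFixture:
    name: str
    value_type: str = "float"
    distribution: dict = field(default_factory=lambda: {"kind": "lognormal", "median": 1e9, "sigma": 0.3})
    missingness: float = 0.7
    clade_effect: Optional[dict] = None  # {"fraction": f, "multiplier": m} at family level
    traverse: dict = field(default_factory=lambda: {"direction": "both"})
    summary: list = field(default_factory=lambda: ["median"])
    enum: Optional[list] = None
    units: Optional[str] = None
    transform: Optional[dict] = None  # applied on import; truth holds post-transform values

    def __post_init__(self):
        if not 0 <= self.missingness <= 1:
            raise ValueError("missingness must be in [0, 1]")


@dataclass
class AssemblyFixture:
    fraction_with_assembly: float = 0.4
    mean_assemblies: float = 1.3
    span_median: float = 1e9
    span_sigma: float = 0.5
    scaffold_n50_median: float = 5e6
    scaffold_n50_sigma: float = 1.2
    contig_ratio_median: float = 8.0
    contig_ratio_sigma: float = 0.8


def _default_attributes() -> list:
    return [
        AttributeFixture(
            "genome_size",
            "float",
            {"kind": "lognormal", "median": 1.2e9, "sigma": 0.25},
            missingness=0.7,
            clade_effect={"fraction": 0.15, "multiplier": 8.0},
            units="bp",
        ),
        AttributeFixture(
            "chromosome_number",
            "integer",
            {"kind": "poisson", "lam": 11, "shift": 1},
            missingness=0.8,
            traverse={"direction": "both"},
            summary=["mode"],
        ),
        AttributeFixture(
            "sequencing_status",
            "ordered_keyword",
            {"kind": "choice", "labels": STATUS_LEVELS, "p": [0.1, 0.1, 0.2, 0.2, 0.4]},
            missingness=0.6,
            traverse={"direction": "none"},
            summary=["priority-by-enum"],
            enum=STATUS_LEVELS,
        ),
        AttributeFixture(
            "long_list",
            "list",
            {"kind": "projects", "mean": 1.4},
            missingness=0.5,
            traverse={"direction": "none"},
            summary=["list"],
        ),
    ]


@dataclass
class FixtureSpec:
    n_species: int = 1000
    ranks: tuple = DEFAULT_RANKS
    mean_group_sizes: dict = field(
        default_factory=lambda: {
            "genus": 3.0,      # species per genus
            "family": 3.0,     # genera per family
            "order": 3.0,      # families per order
            "class": 3.0,      # orders per class
            "phylum": 2.5,     # classes per phylum
            "kingdom": 3.0,    # phyla per kingdom
            "root": 2.0,       # kingdoms
        }
    )
    homonyms: int = 0
    synonyms: int = 0
    attributes: list = field(default_factory=_default_attributes)
    assemblies: Optional[AssemblyFixture] = field(default_factory=AssemblyFixture)

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


# ---------------------------------------------------------------------------
# taxonomy


def _partition(n: int, mean: float, rng: np.random.Generator) -> list[int]:
    """Split n items into groups of mean ~`mean` (each >= 1)."""
    sizes = []
    left = n
    while left > 0:
        s = int(rng.geometric(1.0 / max(mean, 1.0)))
        s = max(1, min(s, left))
        sizes.append(s)
        left -= s
    return sizes


def synth_taxonomy(spec: FixtureSpec, seed: int, out_dir) -> tuple[Path, Path]:
    """Write a valid single-root taxdump (nodes.dmp, names.dmp).

    Builds bottom-up: species are partitioned into genera, genera into
    families, and so on up the requested ranks.  Homonym injection
    renames `spec.homonyms` species pairs in different families to the
    same scientific name; synonym injection adds extra names.dmp rows
    with name class "synonym".
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ranks = list(spec.ranks)
    for required in ("family", "genus", "species"):
        if required not in ranks:
            raise ValueError(f"fixture ranks must include {required!r}")
    # nodes[rank] = list of (taxon_id, parent_id, name)
    next_id = [2]  # taxid 1 is the root

    def take_id() -> int:
        i = next_id[0]
        next_id[0] += 1
        return i

    # build from species upward: ids assigned per level, grouped next level up
    level_nodes: dict[str, list[dict]] = {r: [] for r in ranks}
    species = [
        {"id": 0, "name": "", "parent": 0} for _ in range(spec.n_species)
    ]
    level_nodes["species"] = species

    lower = species
    for rank in reversed(ranks[:-1]):
        mean = spec.mean_group_sizes.get(rank, 3.0)
        sizes = _partition(len(lower), mean, rng)
        groups = []
        idx = 0
        for gi, size in enumerate(sizes):
            node = {"id": 0, "name": "", "parent": 0, "members": lower[idx : idx + size]}
            groups.append(node)
            idx += size
        level_nodes[rank] = groups
        lower = groups

    # assign ids top-down so parents precede children (cosmetic only)
    for rank in ranks:
        for i, node in enumerate(level_nodes[rank]):
            node["id"] = take_id()
            node["name"] = f"{rank.capitalize()}{node['id']}"
    for rank in ranks[:-1]:
        for node in level_nodes[rank]:
            for child in node["members"]:
                child["parent"] = node["id"]
    for node in level_nodes[ranks[0]]:
        node["parent"] = 1

    # species get binomial-like names from their genus
    genus_of: dict[int, dict] = {}
    for genus in level_nodes["genus"]:
        for sp in genus["members"]:
            genus_of[sp["id"]] = genus
    for i, sp in enumerate(level_nodes["species"]):
        sp["name"] = f"{genus_of[sp['id']]['name']} sp{sp['id']}"

    # family of each species, for homonym placement
    family_of: dict[int, int] = {}
    for fam in level_nodes["family"]:
        stack = [(fam, m) for m in fam["members"]]
        while stack:
            f, node = stack.pop()
            if "members" in node:
                stack.extend((f, m) for m in node["members"])
            else:
                family_of[node["id"]] = f["id"]

    # homonyms: pairs of species in different families sharing one name
    sp_list = level_nodes["species"]
    if spec.homonyms:
        order = rng.permutation(len(sp_list))
        used: set[int] = set()
        made = 0
        for i in order:
            if made >= spec.homonyms:
                break
            a = sp_list[int(i)]
            if a["id"] in used:
                continue
            partner = next(
                (
                    b
                    for b in sp_list
                    if b["id"] not in used
                    and b["id"] != a["id"]
                    and family_of[b["id"]] != family_of[a["id"]]
                ),
                None,
            )
            if partner is None:
                continue
            partner["name"] = a["name"]
            used |= {a["id"], partner["id"]}
            made += 1

    names_rows: list[tuple[int, str, str]] = [(1, "root", "scientific name")]
    nodes_rows: list[tuple[int, int, str]] = [(1, 1, "no rank")]
    for rank in ranks:
        for node in level_nodes[rank]:
            nodes_rows.append((node["id"], node["parent"], rank))
            names_rows.append((node["id"], node["name"], "scientific name"))

    if spec.synonyms:
        all_nodes = [n for rank in ranks for n in level_nodes[rank]]
        picks = rng.choice(len(all_nodes), size=min(spec.synonyms, len(all_nodes)), replace=False)
        for i in sorted(int(p) for p in picks):
            node = all_nodes[i]
            names_rows.append((node["id"], f"Syn {node['name']}", "synonym"))

    nodes_path = out_dir / "nodes.dmp"
    names_path = out_dir / "names.dmp"
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for tid, parent, rank in sorted(nodes_rows):
            fh.write(f"{tid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for tid, name, cls_ in sorted(names_rows):
            fh.write(f"{tid}\t|\t{name}\t|\t\t|\t{cls_}\t|\n")
    return nodes_path, names_path


# ---------------------------------------------------------------------------
# attribute tables


def _species_and_families(store) -> list[tuple[str, str, str, str]]:
    """(taxon_id, name, family_id, family_name) for every species, id order."""
    from .taxonomy import sort_key

    out = []
    for tid in sorted(store.taxa, key=sort_key):
        doc = store.taxa[tid]
        if doc.rank != "species":
            continue
        fam = next((a for a in doc.lineage if a.rank == "family"), None)
        out.append(
            (tid, doc.scientific_name, fam.taxon_id if fam else "", fam.scientific_name if fam else "")
        )
    return out


def _draw(fixture: AttributeFixture, n: int, rng: np.random.Generator):
    d = fixture.distribution
    kind = d.get("kind", "lognormal")
    if kind == "lognormal":
        return np.exp(rng.normal(np.log(d["median"]), d["sigma"], size=n))
    if kind == "poisson":
        return rng.poisson(d["lam"], size=n) + d.get("shift", 0)
    if kind == "choice":
        return rng.choice(d["labels"], size=n, p=d.get("p"))
    if kind == "projects":
        # 1 + geometric project memberships drawn without replacement
        counts = np.minimum(rng.geometric(1.0 / d.get("mean", 1.4), size=n), len(PROJECTS))
        return [
            ",".join(sorted(rng.choice(PROJECTS, size=int(c), replace=False)))
            for c in counts
        ]
    raise ValueError(f"unknown distribution kind {kind!r}")


def synth_attributes(
    spec: FixtureSpec, store, seed: int, out_dir
) -> dict[str, dict[str, Path]]:
    """Write per-attribute TSV+YAML pairs plus ground-truth tables.

    Clade effects pick a deterministic fraction of families and multiply
    (numeric) values there, making descendant estimates statistically
    distinguishable; the truth table records each species' unmasked
    value and whether its family is shifted.
    """
    import yaml as _yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species = _species_and_families(store)
    n = len(species)
    families = sorted({fam_id for _, _, fam_id, _ in species if fam_id})
    paths: dict[str, dict[str, Path]] = {}

    for ai, fixture in enumerate(spec.attributes):
        rng = np.random.default_rng((seed, 101 + ai))
        if fixture.name in store.attributes:
            raise ValueError(f"attribute {fixture.name!r} already registered")
        values = _draw(fixture, n, rng)
        shifted: set[str] = set()
        if fixture.clade_effect:
            k = int(round(fixture.clade_effect["fraction"] * len(families)))
            picks = rng.choice(len(families), size=k, replace=False)
            shifted = {families[int(i)] for i in picks}
            mult = fixture.clade_effect["multiplier"]
            values = np.array(
                [
                    v * mult if fam in shifted else v
                    for v, (_, _, fam, _) in zip(values, species)
                ]
            )
        mask = rng.random(n) < fixture.missingness

        truth_path = out_dir / f"{fixture.name}.truth.tsv"
        with open(truth_path, "w", encoding="utf-8") as fh:
            fh.write("taxon_id\tfamily_id\tvalue\tshifted\tobserved\n")
            for (tid, _name, fam, _fname), v, m in zip(species, values, mask):
                fh.write(f"{tid}\t{fam}\t{v}\t{int(fam in shifted)}\t{int(not m)}\n")

        tsv_path = out_dir / f"{fixture.name}.tsv"
        with open(tsv_path, "w", encoding="utf-8") as fh:
            fh.write("taxon_id\tspecies\tfamily\tmeasurement\n")
            for (tid, name, _fam, fname), v, m in zip(species, values, mask):
                if m:
                    continue
                fh.write(f"{tid}\t{name}\t{fname}\t{v}\n")

        decl: dict = {
            "type": fixture.value_type,
            "summary": list(fixture.summary),
            "traverse": dict(fixture.traverse),
        }
        if fixture.enum:
            decl["constraints"] = {"enum": list(fixture.enum)}
        if fixture.units:
            decl["units"] = fixture.units
        column: dict = {"attribute": fixture.name}
        if fixture.transform:
            column["transform"] = dict(fixture.transform)
        doc = {
            "file": {"path": tsv_path.name, "delimiter": "\t"},
            "attributes": {fixture.name: decl},
            "columns": {"measurement": column},
            "taxonomy": {
                "taxon_id": "taxon_id",
                "scientific_name": "species",
                "family": "family",
            },
            "source": {"name": f"synthetic_{fixture.name}", "date": "2022-11-16"},
        }
        yaml_path = out_dir / f"{fixture.name}.yaml"
        yaml_path.write_text(_yaml.safe_dump(doc, sort_keys=True))
        paths[fixture.name] = {"tsv": tsv_path, "yaml": yaml_path, "truth": truth_path}
    return paths


def synth_assemblies(spec: FixtureSpec, store, seed: int, out_dir) -> dict[str, Path]:
    """Write an assembly-index TSV+YAML pair (span, N50s, level, date)."""
    import yaml as _yaml

    if spec.assemblies is None:
        raise ValueError("fixture spec has no assembly section")
    afix = spec.assemblies
    rng = np.random.default_rng((seed, 7))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species = _species_and_families(store)

    rows = []
    acc = 900_000
    for tid, name, _fam, fname in species:
        if rng.random() >= afix.fraction_with_assembly:
            continue
        n_asm = max(1, int(rng.geometric(1.0 / afix.mean_assemblies)))
        for _ in range(n_asm):
            acc += 1
            span = float(np.exp(rng.normal(np.log(afix.span_median), afix.span_sigma)))
            scaf = float(
                np.exp(rng.normal(np.log(afix.scaffold_n50_median), afix.scaffold_n50_sigma))
            )
            scaf = min(scaf, span)
            ratio = float(
                np.exp(rng.normal(np.log(afix.contig_ratio_median), afix.contig_ratio_sigma))
            )
            contig = scaf / max(ratio, 1.0)
            if scaf > 1e7:
                level = rng.choice(ASSEMBLY_LEVELS[:3], p=[0.05, 0.6, 0.35])
            else:
                level = rng.choice(ASSEMBLY_LEVELS[2:], p=[0.7, 0.3])
            day = int(rng.integers(0, 2800))
            date = (_dt.date(2015, 1, 1) + _dt.timedelta(days=day)).isoformat()
            rows.append(
                (f"GCA_{acc}.1", tid, name, round(span), round(contig), round(scaf), level, date)
            )

    tsv_path = out_dir / "assemblies.tsv"
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write(
            "accession\ttaxon_id\tspecies\tspan\tcontig_n50\tscaffold_n50\tlevel\trelease_date\n"
        )
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")

    doc = {
        "file": {"path": tsv_path.name, "delimiter": "\t"},
        "assembly": {"assembly_id": "accession"},
        "attributes": {
            "assembly_span": {
                "index": "assembly",
                "type": "integer",
                "summary": ["max"],
                "units": "bp",
            },
            "contig_n50": {"index": "assembly", "type": "integer", "summary": ["max"]},
            "scaffold_n50": {"index": "assembly", "type": "integer", "summary": ["max"]},
            "assembly_level": {
                "index": "assembly",
                "type": "ordered_keyword",
                "summary": ["priority-by-enum"],
                "constraints": {"enum": list(ASSEMBLY_LEVELS)},
            },
            "assembly_date": {"index": "assembly", "type": "date", "summary": ["min"]},
        },
        "columns": {
            "span": "assembly_span",
            "contig_n50": "contig_n50",
            "scaffold_n50": "scaffold_n50",
            "level": "assembly_level",
            "release_date": "assembly_date",
        },
        "taxonomy": {"taxon_id": "taxon_id", "scientific_name": "species"},
        "source": {"name": "synthetic_assemblies", "date": "2022-11-16"},
    }
    yaml_path = out_dir / "assemblies.yaml"
    yaml_path.write_text(_yaml.safe_dump(doc, sort_keys=True))
    return {"tsv": tsv_path, "yaml": yaml_path}


def synth_all(spec: FixtureSpec, seed: int, out_dir):
    """Generate taxonomy + attribute + assembly fixtures under out_dir.

    Returns (taxdump_dir, data_dir, loaded Store of the bare taxonomy).
    """
    from .taxonomy import load_taxdump

    out_dir = Path(out_dir)
    tax_dir = out_dir / "taxdump"
    data_dir = out_dir / "data"
    nodes, names = synth_taxonomy(spec, seed, tax_dir)
    store = load_taxdump(nodes, names)
    synth_attributes(spec, store, seed, data_dir)
    if spec.assemblies is not None:
        synth_assemblies(spec, store, seed, data_dir)
    return tax_dir, data_dir, store
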