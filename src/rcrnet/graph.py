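"""Typed signed causal knowledge graph ("KAM-lite").

The graph couples two edge layers over one set of typed biological entities:

* **causal edges** — signed cause-effect assertions (``increases`` = +1,
  ``decreases`` = -1) between entities, each backed by at least one literature
  evidence record (citation, quote, species, tissue);
* **non-causal edges** — unsigned form relationships connecting the different
  guises of one entity (a protein to its kinase activity, its phosphorylated
  form, a family to its members, a complex to its components).

Entities are fine-grained: the abundance of a protein, its enzymatic activity
and a site-modified form are distinct nodes, so a causal assertion can state
precisely *which* form of an entity drives an effect.  Feedback loops are
legal; the graph is a multigraph only in the limited sense that a pair of
nodes may carry both an increasing and a decreasing causal edge (each merged
over its evidences).

Serialization dialects
----------------------
``native-tsv``
    A single tab-separated file with a ``[nodes]`` section followed by an
    ``[edges]`` section.  One row per node; one row per *evidence* (causal
    edges with several evidences repeat the edge row).
``native-json``
    A single JSON document mirroring the in-memory model one-to-one.
``supplementary-table``
    Importer for a published nodes-edges-evidence spreadsheet (XLSX).  Column
    and relation names are matched against a tolerant alias table; rows whose
    relation cannot be mapped are reported, never guessed.
"""

from __future__ import annotations

import json
from collections import Counter, deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    ContractError,
    GraphParseError,
    ReferentialError,
    UnknownNodeError,
    VocabularyError,
)

ENTITY_CLASSES = frozenset(
    {
        "mRNA",
        "protein",
        "modified-protein",
        "activity",
        "complex",
        "protein-family",
        "biological-process",
        "proxy",
        "other",
    }
)

NONCAUSAL_RELATIONS = frozenset(
    {"has-activity", "has-modified-form", "has-member", "has-component"}
)

CAUSAL_RELATIONS = {"increases": +1, "decreases": -1}
SIGN_TO_RELATION = {+1: "increases", -1: "decreases"}

SPECIES = frozenset({"human", "mouse", "rat", "unspecified"})


@dataclass(frozen=True)
class Evidence:
    """One supporting line of evidence for a causal edge."""

    citation_id: str
    quote: str = ""
    species: str = "unspecified"
    tissue: str = ""

    def __post_init__(self):
        if self.species not in SPECIES:
            raise VocabularyError(
                f"unknown species {self.species!r}", field="species"
            )


@dataclass(frozen=True)
class EntityNode:
    """A typed biological entity (one *form* of an entity is one node)."""

    node_id: str
    label: str = ""
    entity_class: str = "other"
    base_entity: str | None = None
    modification: str | None = None
    activity_kind: str | None = None
    species_scope: frozenset[str] = frozenset()
    tags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.entity_class not in ENTITY_CLASSES:
            raise VocabularyError(
                f"unknown entity_class {self.entity_class!r}",
                field="entity_class",
            )
        if (self.entity_class == "modified-protein") != bool(self.modification):
            raise VocabularyError(
                "modification must be set exactly when entity_class is "
                f"'modified-protein' (node {self.node_id!r})",
                field="modification",
            )
        if (self.entity_class == "activity") != bool(self.activity_kind):
            raise VocabularyError(
                "activity_kind must be set exactly when entity_class is "
                f"'activity' (node {self.node_id!r})",
                field="activity_kind",
            )

    @property
    def gene_symbol(self) -> str:
        """Gene symbol this node measures/derives from (mRNA nodes)."""
        return self.base_entity or self.label or self.node_id


@dataclass
class CausalEdge:
    """A signed cause-effect assertion with accumulated evidence."""

    source: str
    target: str
    sign: int
    evidence: list[Evidence] = field(default_factory=list)

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ContractError(f"causal edge sign must be +-1, got {self.sign}")
        if self.source == self.target:
            raise ContractError(
                f"self-causation not allowed ({self.source!r})"
            )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.source, self.target, self.sign)


@dataclass(frozen=True)
class NonCausalEdge:
    """An unsigned form relationship between two entities."""

    source: str
    target: str
    relation: str

    def __post_init__(self):
        if self.relation not in NONCAUSAL_RELATIONS:
            raise VocabularyError(
                f"unknown non-causal relation {self.relation!r}",
                field="relation",
            )


@dataclass
class NetworkCensus:
    """Node/edge/citation counts for a graph (printable summary)."""

    class_counts: dict[str, int]
    total_nodes: int
    causal_edge_count: int
    noncausal_edge_count: int
    unique_citation_count: int

    @property
    def total_edges(self) -> int:
        return self.causal_edge_count + self.noncausal_edge_count

    def to_dict(self) -> dict:
        return {
            "total_nodes": self.total_nodes,
            "total_edges": self.total_edges,
            "causal_edges": self.causal_edge_count,
            "noncausal_edges": self.noncausal_edge_count,
            "unique_citations": self.unique_citation_count,
            "class_counts": dict(sorted(self.class_counts.items())),
        }


class CausalGraph:
    """Container for typed nodes plus signed causal and non-causal edges.

    Nodes are keyed by an opaque ``node_id`` (the native convention is a
    namespace-qualified label such as ``"HGNC:CDK2|kaof"``).  Causal edges are
    keyed by ``(source, target, sign)``: adding the same assertion again
    merges the evidence lists instead of duplicating the edge.
    """

    def __init__(self, name: str = "", species: str = "", provenance: str = ""):
        self.name = name
        self.species = species
        self.provenance = provenance
        self.nodes: dict[str, EntityNode] = {}
        self.causal_edges: dict[tuple[str, str, int], CausalEdge] = {}
        self.noncausal_edges: set[NonCausalEdge] = set()

    # -- construction -----------------------------------------------------

    def add_node(self, node: EntityNode) -> None:
        existing = self.nodes.get(node.node_id)
        if existing is not None and existing != node:
            raise ContractError(
                f"node id {node.node_id!r} redefined with different fields"
            )
        self.nodes[node.node_id] = node

    def add_causal_edge(
        self, source: str, target: str, sign: int,
        evidence: Evidence | Iterable[Evidence],
    ) -> CausalEdge:
        for endpoint in (source, target):
            if endpoint not in self.nodes:
                raise ReferentialError(
                    f"causal edge endpoint {endpoint!r} is not a declared node"
                )
        records = [evidence] if isinstance(evidence, Evidence) else list(evidence)
        if not records:
            raise ContractError("a causal edge requires at least one evidence")
        edge = self.causal_edges.get((source, target, sign))
        if edge is None:
            edge = CausalEdge(source, target, sign, [])
            self.causal_edges[edge.key] = edge
        for record in records:
            if record not in edge.evidence:
                edge.evidence.append(record)
        return edge

    def add_noncausal_edge(self, source: str, target: str, relation: str) -> None:
        for endpoint in (source, target):
            if endpoint not in self.nodes:
                raise ReferentialError(
                    f"non-causal edge endpoint {endpoint!r} is not a declared node"
                )
        self.noncausal_edges.add(NonCausalEdge(source, target, relation))

    def copy(self) -> "CausalGraph":
        out = CausalGraph(self.name, self.species, self.provenance)
        out.nodes = dict(self.nodes)
        out.causal_edges = {
            k: CausalEdge(e.source, e.target, e.sign, list(e.evidence))
            for k, e in self.causal_edges.items()
        }
        out.noncausal_edges = set(self.noncausal_edges)
        return out

    # -- queries ----------------------------------------------------------

    def node(self, node_id: str) -> EntityNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise UnknownNodeError(node_id) from None

    def out_edges(self, node_id: str) -> list[CausalEdge]:
        return [e for e in self.causal_edges.values() if e.source == node_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CausalGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and {k: (e.source, e.target, e.sign, tuple(e.evidence))
                 for k, e in self.causal_edges.items()}
            == {k: (e.source, e.target, e.sign, tuple(e.evidence))
                for k, e in other.causal_edges.items()}
            and self.noncausal_edges == other.noncausal_edges
        )

    def __len__(self) -> int:
        return len(self.nodes)

    def validate(self) -> None:
        """Re-check all referential invariants; raise on the first breach."""
        for edge in self.causal_edges.values():
            for endpoint in (edge.source, edge.target):
                if endpoint not in self.nodes:
                    raise ReferentialError(
                        f"dangling causal endpoint {endpoint!r}"
                    )
            if not edge.evidence:
                raise ContractError(
                    f"causal edge {edge.key} has no evidence"
                )
        for edge in self.noncausal_edges:
            for endpoint in (edge.source, edge.target):
                if endpoint not in self.nodes:
                    raise ReferentialError(
                        f"dangling non-causal endpoint {endpoint!r}"
                    )


# -- census ---------------------------------------------------------------


def census(graph: CausalGraph) -> NetworkCensus:
    """Tabulate node classes, edge layers, and distinct citations."""
    class_counts = Counter(n.entity_class for n in graph.nodes.values())
    citations = {
        ev.citation_id
        for edge in graph.causal_edges.values()
        for ev in edge.evidence
        if ev.citation_id
    }
    return NetworkCensus(
        class_counts=dict(class_counts),
        total_nodes=len(graph.nodes),
        causal_edge_count=len(graph.causal_edges),
        noncausal_edge_count=len(graph.noncausal_edges),
        unique_citation_count=len(citations),
    )


# -- downstream targets ---------------------------------------------------

AMBIGUOUS = 0


def downstream_mrna_targets(
    graph: CausalGraph, node_id: str, depth: int = 1
) -> dict[str, int]:
    """Signed map of mRNA-class genes reachable from ``node_id``.

    At depth 1 this is exactly the node's direct causal edges restricted to
    mRNA targets.  At depth *k* the implied sign of a gene is the product of
    edge signs along the path; a gene reachable with both a + and a - implied
    sign is flagged ambiguous (``0``).  The node's own gene symbol is never
    included (a node does not explain its own expression).

    Returns ``{gene_symbol: +1 | -1 | 0}``.
    """
    if depth < 1:
        raise ContractError("depth must be >= 1")
    origin = graph.node(node_id)

    adjacency: dict[str, list[tuple[str, int]]] = {}
    for edge in graph.causal_edges.values():
        adjacency.setdefault(edge.source, []).append((edge.target, edge.sign))

    # BFS over (node, implied sign) states: polynomial even with many paths.
    seen: set[tuple[str, int]] = set()
    frontier: deque[tuple[str, int, int]] = deque([(node_id, +1, 0)])
    signs: dict[str, set[int]] = {}
    while frontier:
        current, sign, dist = frontier.popleft()
        if dist >= depth:
            continue
        for nxt, edge_sign in adjacency.get(current, ()):
            implied = sign * edge_sign
            node = graph.nodes[nxt]
            if node.entity_class == "mRNA":
                signs.setdefault(node.gene_symbol, set()).add(implied)
            state = (nxt, implied)
            if state not in seen:
                seen.add(state)
                frontier.append((nxt, implied, dist + 1))

    signs.pop(origin.gene_symbol, None)
    return {
        gene: (next(iter(s)) if len(s) == 1 else AMBIGUOUS)
        for gene, s in signs.items()
    }


# -- subgraph by building-block tag ---------------------------------------


def subgraph_by_tag(graph: CausalGraph, tag: str) -> CausalGraph:
    """Induced subgraph on nodes carrying a building-block ``tag``.

    An empty result is legal only if the tag appears on no node *and* the
    tag is known to the graph; an entirely unknown tag raises.
    """
    all_tags = set().union(*(n.tags for n in graph.nodes.values()), set())
    tagged = {nid for nid, n in graph.nodes.items() if tag in n.tags}
    if not tagged and tag not in all_tags:
        raise UnknownNodeError(f"tag {tag!r} not present on any node")
    out = CausalGraph(f"{graph.name}[{tag}]", graph.species, graph.provenance)
    for nid in tagged:
        out.add_node(graph.nodes[nid])
    for edge in graph.causal_edges.values():
        if edge.source in tagged and edge.target in tagged:
            out.add_causal_edge(edge.source, edge.target, edge.sign, edge.evidence)
    for edge in graph.noncausal_edges:
        if edge.source in tagged and edge.target in tagged:
            out.add_noncausal_edge(edge.source, edge.target, edge.relation)
    return out


# -- orthology augmentation -----------------------------------------------


@dataclass
class AugmentationReport:
    """Bookkeeping from one orthology-augmentation pass."""

    n_translated: int = 0
    n_merged: int = 0
    n_skipped_unmapped: int = 0
    n_skipped_ambiguous: int = 0


def augment_with_orthologs(
    base: CausalGraph,
    donor: CausalGraph,
    ortholog_map: Iterable[tuple[str, str]] | Mapping[str, str],
    policy: str = "expand-all",
) -> tuple[CausalGraph, AugmentationReport]:
    """Translate the donor KAM's causal edges into the base KAM.

    ``ortholog_map`` pairs donor node ids with base node ids (many-to-many
    allowed).  Each donor causal edge whose endpoints both map is re-asserted
    between the mapped base nodes, keeping the donor-species evidence; an
    assertion already in the base merges evidences.  Edges with an unmapped
    endpoint are skipped and counted.  The operation is idempotent.

    ``policy`` controls many-to-many mappings: ``"expand-all"`` translates to
    every combination, ``"skip-ambiguous"`` skips edges touching a donor node
    with several base orthologs, ``"error"`` raises on such a node.
    """
    if policy not in {"expand-all", "skip-ambiguous", "error"}:
        raise ContractError(f"unknown orthology policy {policy!r}")
    pairs = (
        list(ortholog_map.items())
        if isinstance(ortholog_map, Mapping)
        else list(ortholog_map)
    )
    mapping: dict[str, list[str]] = {}
    for donor_id, base_id in pairs:
        if donor_id not in donor.nodes:
            raise ReferentialError(
                f"ortholog-map donor id {donor_id!r} not in donor graph"
            )
        if base_id not in base.nodes:
            raise ReferentialError(
                f"ortholog-map base id {base_id!r} not in base graph"
            )
        mapping.setdefault(donor_id, []).append(base_id)

    out = base.copy()
    report = AugmentationReport()
    for edge in sorted(donor.causal_edges.values(), key=lambda e: e.key):
        src_images = mapping.get(edge.source)
        tgt_images = mapping.get(edge.target)
        if not src_images or not tgt_images:
            report.n_skipped_unmapped += 1
            continue
        if len(src_images) > 1 or len(tgt_images) > 1:
            if policy == "error":
                raise ContractError(
                    f"ambiguous ortholog mapping for edge {edge.key}; "
                    "set policy='expand-all' or 'skip-ambiguous'"
                )
            if policy == "skip-ambiguous":
                report.n_skipped_ambiguous += 1
                continue
        for src in src_images:
            for tgt in tgt_images:
                if src == tgt:
                    continue
                existed = (src, tgt, edge.sign) in out.causal_edges
                out.add_causal_edge(src, tgt, edge.sign, edge.evidence)
                if existed:
                    report.n_merged += 1
                else:
                    report.n_translated += 1
    return out, report


# -- serialization: native dialects ---------------------------------------

_NODE_COLUMNS = [
    "node_id", "label", "entity_class", "base_entity",
    "modification", "activity_kind", "species_scope", "tags",
]
_EDGE_COLUMNS = [
    "source", "relation", "target", "sign",
    "citation", "species", "tissue", "quote",
]


def _node_row(node: EntityNode) -> list[str]:
    return [
        node.node_id,
        node.label,
        node.entity_class,
        node.base_entity or "",
        node.modification or "",
        node.activity_kind or "",
        ";".join(sorted(node.species_scope)),
        ";".join(sorted(node.tags)),
    ]


def _parse_node_row(values: dict[str, str], row: int) -> EntityNode:
    if not values.get("node_id"):
        raise GraphParseError("missing node_id", row=row, field="node_id")
    try:
        return EntityNode(
            node_id=values["node_id"],
            label=values.get("label", ""),
            entity_class=values.get("entity_class", "other"),
            base_entity=values.get("base_entity") or None,
            modification=values.get("modification") or None,
            activity_kind=values.get("activity_kind") or None,
            species_scope=frozenset(
                s for s in values.get("species_scope", "").split(";") if s
            ),
            tags=frozenset(t for t in values.get("tags", "").split(";") if t),
        )
    except VocabularyError as exc:
        raise VocabularyError(str(exc), row=row) from None


def _save_tsv(graph: CausalGraph, path: Path) -> None:
    lines = [
        "# rcrnet-graph v1",
        f"# name={graph.name}",
        f"# species={graph.species}",
        f"# provenance={graph.provenance}",
        "[nodes]",
        "\t".join(_NODE_COLUMNS),
    ]
    for node_id in sorted(graph.nodes):
        lines.append("\t".join(_node_row(graph.nodes[node_id])))
    lines.append("[edges]")
    lines.append("\t".join(_EDGE_COLUMNS))
    for key in sorted(graph.causal_edges):
        edge = graph.causal_edges[key]
        for ev in edge.evidence:
            lines.append("\t".join([
                edge.source, SIGN_TO_RELATION[edge.sign], edge.target,
                str(edge.sign), ev.citation_id, ev.species, ev.tissue,
                ev.quote.replace("\t", " ").replace("\n", " "),
            ]))
    for edge in sorted(graph.noncausal_edges,
                       key=lambda e: (e.source, e.relation, e.target)):
        lines.append("\t".join([
            edge.source, edge.relation, edge.target, "", "", "", "", "",
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _load_tsv(path: Path) -> CausalGraph:
    graph = CausalGraph()
    section = None
    header: list[str] = []
    pending_edges: list[tuple[int, dict[str, str]]] = []
    for lineno, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            for attr in ("name", "species", "provenance"):
                if body.startswith(f"{attr}="):
                    setattr(graph, attr, body[len(attr) + 1:])
            continue
        if line in ("[nodes]", "[edges]"):
            section = line[1:-1]
            header = []
            continue
        if section is None:
            raise GraphParseError(
                "content before any [nodes]/[edges] section", row=lineno
            )
        cells = line.split("\t")
        if not header:
            header = cells
            expected = _NODE_COLUMNS if section == "nodes" else _EDGE_COLUMNS
            if header != expected:
                raise GraphParseError(
                    f"bad {section} header {header!r}", row=lineno
                )
            continue
        if len(cells) > len(header):
            raise GraphParseError(
                f"{len(cells)} cells for {len(header)} columns", row=lineno
            )
        cells += [""] * (len(header) - len(cells))
        values = dict(zip(header, cells))
        if section == "nodes":
            graph.add_node(_parse_node_row(values, lineno))
        else:
            pending_edges.append((lineno, values))
    for lineno, values in pending_edges:
        _add_edge_record(graph, values, lineno)
    graph.validate()
    return graph


def _add_edge_record(graph: CausalGraph, values: dict[str, str], row: int) -> None:
    relation = values.get("relation", "")
    source, target = values.get("source", ""), values.get("target", "")
    if not source or not target:
        raise GraphParseError("edge with empty endpoint", row=row, field="source")
    if relation in CAUSAL_RELATIONS:
        sign = CAUSAL_RELATIONS[relation]
        declared = values.get("sign", "")
        if declared and int(declared) != sign:
            raise GraphParseError(
                f"sign column {declared} contradicts relation {relation!r}",
                row=row, field="sign",
            )
        evidence = Evidence(
            citation_id=values.get("citation", ""),
            quote=values.get("quote", ""),
            species=values.get("species") or "unspecified",
            tissue=values.get("tissue", ""),
        )
        try:
            graph.add_causal_edge(source, target, sign, evidence)
        except ReferentialError as exc:
            raise ReferentialError(str(exc), row=row) from None
    elif relation in NONCAUSAL_RELATIONS:
        try:
            graph.add_noncausal_edge(source, target, relation)
        except ReferentialError as exc:
            raise ReferentialError(str(exc), row=row) from None
    else:
        raise VocabularyError(
            f"unknown relation {relation!r}", row=row, field="relation"
        )


def _save_json(graph: CausalGraph, path: Path) -> None:
    doc = {
        "format": "rcrnet-graph",
        "version": 1,
        "metadata": {
            "name": graph.name,
            "species": graph.species,
            "provenance": graph.provenance,
        },
        "nodes": [
            {
                "node_id": n.node_id,
                "label": n.label,
                "entity_class": n.entity_class,
                "base_entity": n.base_entity,
                "modification": n.modification,
                "activity_kind": n.activity_kind,
                "species_scope": sorted(n.species_scope),
                "tags": sorted(n.tags),
            }
            for _, n in sorted(graph.nodes.items())
        ],
        "causal_edges": [
            {
                "source": e.source,
                "target": e.target,
                "sign": e.sign,
                "evidence": [
                    {
                        "citation_id": ev.citation_id,
                        "quote": ev.quote,
                        "species": ev.species,
                        "tissue": ev.tissue,
                    }
                    for ev in e.evidence
                ],
            }
            for _, e in sorted(graph.causal_edges.items())
        ],
        "noncausal_edges": [
            {"source": e.source, "target": e.target, "relation": e.relation}
            for e in sorted(
                graph.noncausal_edges,
                key=lambda e: (e.source, e.relation, e.target),
            )
        ],
    }
    path.write_text(
        json.dumps(doc, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def _load_json(path: Path) -> CausalGraph:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise GraphParseError(f"invalid JSON: {exc}") from None
    meta = doc.get("metadata", {})
    graph = CausalGraph(
        name=meta.get("name", ""),
        species=meta.get("species", ""),
        provenance=meta.get("provenance", ""),
    )
    for i, rec in enumerate(doc.get("nodes", [])):
        values = {
            k: ("" if rec.get(k) is None else rec.get(k))
            for k in ("node_id", "label", "entity_class", "base_entity",
                      "modification", "activity_kind")
        }
        values["species_scope"] = ";".join(rec.get("species_scope", []))
        values["tags"] = ";".join(rec.get("tags", []))
        graph.add_node(_parse_node_row(values, i))
    for i, rec in enumerate(doc.get("causal_edges", [])):
        evidence = [
            Evidence(
                citation_id=ev.get("citation_id", ""),
                quote=ev.get("quote", ""),
                species=ev.get("species", "unspecified"),
                tissue=ev.get("tissue", ""),
            )
            for ev in rec.get("evidence", [])
        ]
        if not evidence:
            raise GraphParseError("causal edge without evidence", row=i)
        graph.add_causal_edge(rec["source"], rec["target"], rec["sign"], evidence)
    for rec in doc.get("noncausal_edges", []):
        graph.add_noncausal_edge(rec["source"], rec["target"], rec["relation"])
    graph.validate()
    return graph


# -- supplementary-table importer ------------------------------------------

# Tolerant aliases for spreadsheet relation vocabularies (BEL-flavoured
# dialects differ in capitalisation and arrow shorthand).
RELATION_ALIASES: dict[str, object] = {
    "increases": +1, "directlyincreases": +1, "->": +1, "=>": +1,
    "decreases": -1, "directlydecreases": -1, "-|": -1, "=|": -1,
    "hasactivity": "has-activity", "has-activity": "has-activity",
    "actsin": "has-activity",
    "hasmodification": "has-modified-form",
    "has-modified-form": "has-modified-form",
    "hasmodifiedform": "has-modified-form",
    "hasmember": "has-member", "has-member": "has-member",
    "hascomponent": "has-component", "has-component": "has-component",
}

_CLASS_ALIASES = {
    "mrna": "mRNA", "rna": "mRNA", "gene": "mRNA",
    "protein": "protein", "proteinabundance": "protein",
    "phosphoprotein": "modified-protein", "modifiedprotein": "modified-protein",
    "modified-protein": "modified-protein",
    "activity": "activity", "kinaseactivity": "activity",
    "transcriptionalactivity": "activity",
    "complex": "complex", "proteincomplex": "complex",
    "family": "protein-family", "proteinfamily": "protein-family",
    "protein-family": "protein-family",
    "biologicalprocess": "biological-process",
    "biological-process": "biological-process", "process": "biological-process",
    "proxy": "proxy", "other": "other",
}


@dataclass
class ImportReport:
    """Rows the supplementary-table importer could not map."""

    unmapped_relations: Counter = field(default_factory=Counter)
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)


def load_supplementary_table(path: Path | str) -> tuple[CausalGraph, ImportReport]:
    """Import a published nodes-edges-evidence spreadsheet (XLSX).

    Expects a node sheet (columns including node id and class) and an edge
    sheet (source, relation, target, citation/PMID, optional species, tissue,
    evidence text).  Sheets and columns are located by fuzzy header matching;
    relation strings outside the alias table are reported, not guessed.
    """
    import openpyxl

    path = Path(path)
    book = openpyxl.load_workbook(path, read_only=True, data_only=True)
    report = ImportReport()
    graph = CausalGraph(name=path.stem, provenance=str(path))

    def norm(s):
        return str(s).strip().lower().replace("_", "").replace(" ", "") if s else ""

    def locate(headers, *cands):
        for cand in cands:
            for i, h in enumerate(headers):
                if norm(h) == cand or cand in norm(h):
                    return i
        return None

    node_rows: list[tuple[int, list]] = []
    edge_rows: list[tuple[int, list, list]] = []
    for sheet in book.worksheets:
        rows = sheet.iter_rows(values_only=True)
        try:
            headers = next(rows)
        except StopIteration:
            continue
        headers = list(headers or [])
        if locate(headers, "relation", "relationship") is not None:
            for i, row in enumerate(rows, start=2):
                edge_rows.append((i, headers, list(row)))
        elif locate(headers, "nodeid", "node", "label") is not None:
            for i, row in enumerate(rows, start=2):
                node_rows.append((i, headers, list(row)))  # type: ignore[arg-type]

    for lineno, headers, row in node_rows:  # type: ignore[misc]
        idx_id = locate(headers, "nodeid", "node", "label")
        idx_class = locate(headers, "class", "type")
        node_id = row[idx_id] if idx_id is not None else None
        if not node_id:
            report.rejected_rows.append((lineno, "empty node id"))
            continue
        raw_class = norm(row[idx_class]) if idx_class is not None else "other"
        entity_class = _CLASS_ALIASES.get(raw_class)
        if entity_class is None:
            report.rejected_rows.append(
                (lineno, f"unknown node class {raw_class!r}")
            )
            continue
        kwargs = {}
        if entity_class == "modified-protein":
            kwargs["modification"] = "unspecified"
        if entity_class == "activity":
            kwargs["activity_kind"] = "unspecified"
        graph.add_node(EntityNode(
            node_id=str(node_id), label=str(node_id),
            entity_class=entity_class, **kwargs,
        ))

    for lineno, headers, row in edge_rows:
        idx_src = locate(headers, "source", "subject", "from")
        idx_rel = locate(headers, "relation", "relationship")
        idx_tgt = locate(headers, "target", "object", "to")
        idx_cit = locate(headers, "pmid", "citation", "reference")
        idx_species = locate(headers, "species", "organism")
        idx_tissue = locate(headers, "tissue", "celltype", "context")
        idx_quote = locate(headers, "evidence", "quote", "text")
        src = str(row[idx_src]) if idx_src is not None and row[idx_src] else ""
        tgt = str(row[idx_tgt]) if idx_tgt is not None and row[idx_tgt] else ""
        rel_raw = row[idx_rel] if idx_rel is not None else None
        if not src or not tgt or rel_raw is None:
            report.rejected_rows.append((lineno, "incomplete edge row"))
            continue
        mapped = RELATION_ALIASES.get(norm(rel_raw))
        if mapped is None:
            report.unmapped_relations[str(rel_raw)] += 1
            report.rejected_rows.append(
                (lineno, f"unmapped relation {rel_raw!r}")
            )
            continue
        for endpoint in (src, tgt):
            if endpoint not in graph.nodes:
                graph.add_node(EntityNode(node_id=endpoint, label=endpoint))
        if isinstance(mapped, int):
            species = ""
            if idx_species is not None and row[idx_species]:
                species = norm(row[idx_species])
            graph.add_causal_edge(src, tgt, mapped, Evidence(
                citation_id=str(row[idx_cit]) if idx_cit is not None and row[idx_cit] else "",
                quote=str(row[idx_quote]) if idx_quote is not None and row[idx_quote] else "",
                species=species if species in SPECIES else "unspecified",
                tissue=str(row[idx_tissue]) if idx_tissue is not None and row[idx_tissue] else "",
            ))
        else:
            graph.add_noncausal_edge(src, tgt, mapped)
    return graph, report


# -- public load/save ------------------------------------------------------

DIALECTS = ("native-tsv", "native-json", "supplementary-table")


def load_graph(path: Path | str, dialect: str = "native-tsv") -> CausalGraph:
    """Load a :class:`CausalGraph` from ``path`` in the named dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native-tsv":
        return _load_tsv(path)
    if dialect == "native-json":
        return _load_json(path)
    if dialect == "supplementary-table":
        graph, _ = load_supplementary_table(path)
        return graph
    raise ContractError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def save_graph(graph: CausalGraph, path: Path | str,
               dialect: str = "native-tsv") -> Path:
    """Serialize ``graph`` so that ``load_graph(save_graph(g)) == g``."""
    path = Path(path)
    try:
        if dialect == "native-tsv":
            _save_tsv(graph, path)
        elif dialect == "native-json":
            _save_json(graph, path)
        else:
            raise ContractError(
                f"unknown dialect {dialect!r}; expected native-tsv or native-json"
            )
    except OSError as exc:
        raise OSError(f"cannot write graph to {path}: {exc}") from exc
    return path
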