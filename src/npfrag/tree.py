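"""Fragment trees: matched fragments linked by neutral losses.

The tree is rooted at the precursor ion; each matched fragment attaches
to the deepest (smallest) ancestor whose composition elementwise contains
it, and the edge is labeled with the composition and mass of the neutral
loss between them.  Complementary fragment pairs (two sides of one
cleavage) are cross-linked as sibling annotations.  Export formats: JSON
(schema shipped with the package), GraphML and DOT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import networkx as nx

from .chem import ElementComposition, monoisotopic_mass
from .errors import ConfigurationError
from .fragmenter import FragmentIon
from .scoring import PeakMatch

ROOT = "precursor"


@dataclass
class FragmentTree:
    graph: nx.DiGraph  # nodes: ids; edges parent->child with loss labels
    precursor: ElementComposition

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def _contains(a: ElementComposition, b: ElementComposition) -> bool:
    return all(x >= y for x, y in zip(a.counts, b.counts))


def build_tree(
    precursor: ElementComposition,
    matches: list[PeakMatch],
    tolerance: float = 0.02,
) -> FragmentTree:
    """Assemble matched fragments into a neutral-loss tree.

    Greedy deepest-parent rule: fragments are inserted by decreasing
    mass; each attaches to the already-inserted node with the smallest
    containing composition (ties by smallest loss mass), falling back to
    the precursor root.
    """
    g = nx.DiGraph()
    pre_mz = monoisotopic_mass(precursor)
    g.add_node(
        ROOT,
        mz=pre_mz,
        formula=precursor.formula(),
        kind="precursor",
        intensity=None,
    )
    nodes: list[tuple[str, ElementComposition, float]] = [(ROOT, precursor, pre_mz)]
    ordered = sorted(
        matches, key=lambda m: (-m.fragment.theoretical_mz, m.peak_index)
    )
    for k, match in enumerate(ordered):
        frag = match.fragment
        node_id = f"f{k}"
        g.add_node(
            node_id,
            mz=frag.theoretical_mz,
            formula=frag.composition.formula(),
            kind="fragment",
            intensity=match.intensity,
            depth=frag.depth,
            reconstruction=frag.via_reconstruction,
        )
        containing = [
            (pid, pcomp, pmz)
            for pid, pcomp, pmz in nodes
            if _contains(pcomp, frag.composition)
        ]
        if containing:
            # deepest parent = smallest containing mass; ties by node id
            pid, pcomp, pmz = min(containing, key=lambda t: (t[2], t[0]))
        else:
            pid, pcomp, pmz = nodes[0]
        try:
            loss = ElementComposition(
                tuple(a - b for a, b in zip(pcomp.counts, frag.composition.counts))
            )
            loss_formula = loss.formula()
        except Exception:
            loss_formula = "?"
        g.add_edge(
            pid,
            node_id,
            loss=loss_formula,
            loss_mass=round(pmz - frag.theoretical_mz, 6),
        )
        nodes.append((node_id, frag.composition, frag.theoretical_mz))

    # cross-link complementary pairs: fragment + sibling == precursor (±H)
    ids = [n for n in g.nodes if n != ROOT]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ca = ElementComposition.from_formula(g.nodes[a]["formula"])
            cb = ElementComposition.from_formula(g.nodes[b]["formula"])
            total = [x + y for x, y in zip(ca.counts, cb.counts)]
            diff = [abs(t - p) for t, p in zip(total, precursor.counts)]
            if sum(diff) <= 2 and all(
                d == 0 for k, d in enumerate(diff) if k != 1
            ):
                g.nodes[a].setdefault("complementary", []).append(b)
                g.nodes[b].setdefault("complementary", []).append(a)
    return FragmentTree(graph=g, precursor=precursor)


# ---------------------------------------------------------------------------
# Export


def tree_to_dict(tree: FragmentTree) -> dict:
    return {
        "precursor": tree.precursor.formula(),
        "nodes": [
            {"id": n, **{k: v for k, v in data.items()}}
            for n, data in sorted(tree.graph.nodes(data=True))
        ],
        "edges": [
            {"source": u, "target": v, **data}
            for u, v, data in sorted(tree.graph.edges(data=True))
        ],
    }


def tree_from_dict(doc: dict) -> FragmentTree:
    g = nx.DiGraph()
    for node in doc["nodes"]:
        node = dict(node)
        g.add_node(node.pop("id"), **node)
    for edge in doc["edges"]:
        edge = dict(edge)
        g.add_edge(edge.pop("source"), edge.pop("target"), **edge)
    return FragmentTree(
        graph=g, precursor=ElementComposition.from_formula(doc["precursor"])
    )


def export_tree(tree: FragmentTree, path, format: str = "json") -> None:
    """Serialize a tree as JSON, GraphML or DOT."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(tree_to_dict(tree), fh, indent=1, default=str)
    elif format == "graphml":
        g = nx.DiGraph()
        for n, data in tree.graph.nodes(data=True):
            g.add_node(
                n, **{k: str(v) for k, v in data.items() if v is not None}
            )
        for u, v, data in tree.graph.edges(data=True):
            g.add_edge(u, v, **{k: str(v) for k, v in data.items()})
        nx.write_graphml(g, path)
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write("digraph fragment_tree {\n")
            for n, data in sorted(tree.graph.nodes(data=True)):
                label = f"{data.get('formula', n)}\\n{data.get('mz', 0):.4f}"
                fh.write(f'  "{n}" [label="{label}"];\n')
            for u, v, data in sorted(tree.graph.edges(data=True)):
                fh.write(f'  "{u}" -> "{v}" [label="-{data.get("loss", "?")}"];\n')
            fh.write("}\n")
    else:
        raise ConfigurationError(f"unknown tree format {format!r}")


def import_tree(path) -> FragmentTree:
    with open(path) as fh:
        return tree_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# JSON schema validation (structural, no external dependency)


def tree_schema() -> dict:
    text = resources.files("npfrag.data").joinpath("tree_schema.json").read_text()
    return json.loads(text)


def validate_tree_document(doc: dict) -> list[str]:
    """Check a JSON tree document against the shipped schema.

    Returns a list of violations (empty when the document is valid).
    """
    schema = tree_schema()
    errors = []
    for key in schema["required"]:
        if key not in doc:
            errors.append(f"missing key {key!r}")
    if errors:
        return errors
    if not isinstance(doc["nodes"], list) or not doc["nodes"]:
        errors.append("nodes must be a non-empty list")
    node_ids = set()
    for node in doc.get("nodes", []):
        for key in schema["properties"]["nodes"]["items"]["required"]:
            if key not in node:
                errors.append(f"node missing {key!r}")
        if "id" in node:
            node_ids.add(node["id"])
    for edge in doc.get("edges", []):
        for key in schema["properties"]["edges"]["items"]["required"]:
            if key not in edge:
                errors.append(f"edge missing {key!r}")
        if edge.get("source") not in node_ids or edge.get("target") not in node_ids:
            errors.append("edge endpoints must be node ids")
    return errors
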