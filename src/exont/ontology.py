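"""Exon Ontology term DAG.

Terms describing protein features (domains, PTM sites, localization
signals, structural states, ...) are organised in a directed acyclic
graph of ``is_a`` links whose sinks are eight root classes of protein
features: catalytic, binding, receptor, transporter, localization,
structure, PTM and other.  The DAG is read from a minimal OBO subset
(``[Term]`` stanzas with ``id``, ``name`` and ``is_a`` tags) plus a
sidecar TSV mapping source-ontology root ids to the eight classes,
because merged ontologies assembled from several source trees (SO,
PSI-MOD, InterPro/GO) do not agree on a single root vocabulary.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

log = logging.getLogger(__name__)

#: The eight root classes of protein features.
ROOT_CLASSES = (
    "catalytic",
    "binding",
    "receptor",
    "transporter",
    "localization",
    "structure",
    "PTM",
    "other",
)


class OntologyError(ValueError):
    """Raised for structural defects in the term DAG."""


@dataclass
class TermNode:
    """A single ontology term.

    Parameters
    ----------
    term_id : str
        Opaque unique key, e.g. ``EXONT:0012``.
    name : str
        Human-readable label.
    parent_ids : list of str
        Direct ``is_a`` parents.  Empty for root-class nodes.
    root_class : str or None
        Which of the eight protein-feature classes the term resolves
        to; ``None`` until resolution.
    source : str
        Provenance label of the source ontology.
    multi_class : bool
        True when the term was reachable from more than one root class
        and was assigned the class of its nearest root.
    """

    term_id: str
    name: str
    parent_ids: list[str] = field(default_factory=list)
    root_class: str | None = None
    source: str = ""
    multi_class: bool = False


class OntologyTree:
    """Validated term DAG with root-class resolution.

    Use :func:`load_ontology` to build one from files; the constructor
    takes already-parsed :class:`TermNode` objects and validates.
    """

    def __init__(self, nodes: dict[str, TermNode], root_class_of: dict[str, str]):
        self.nodes = nodes
        #: term_id of each designated root node -> class name
        self.root_ids = dict(root_class_of)
        self._validate()
        self._resolve_root_classes()

    # -- construction -------------------------------------------------

    def _validate(self) -> None:
        for tid, node in self.nodes.items():
            for pid in node.parent_ids:
                if pid not in self.nodes:
                    raise OntologyError(
                        f"term {tid!r} has dangling parent {pid!r}"
                    )
        g = nx.DiGraph(
            (tid, pid) for tid, n in self.nodes.items() for pid in n.parent_ids
        )
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(a for a, _ in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyError(f"cycle in is_a links: {path}")

    def _resolve_root_classes(self) -> None:
        unknown = set(self.root_ids) - set(self.nodes)
        if unknown:
            raise OntologyError(f"root mapping names unknown terms: {sorted(unknown)}")
        for rid, cls in self.root_ids.items():
            if cls not in ROOT_CLASSES:
                raise OntologyError(f"unknown root class {cls!r} for {rid!r}")
            self.nodes[rid].root_class = cls
        for tid, node in self.nodes.items():
            if tid in self.root_ids:
                continue
            # nearest root by BFS level; ties broken by class order so
            # resolution is deterministic.
            hits: list[tuple[int, str]] = []
            seen = {tid}
            frontier, depth = [tid], 0
            while frontier and not hits:
                depth += 1
                nxt = []
                for t in frontier:
                    for pid in self.nodes[t].parent_ids:
                        if pid in seen:
                            continue
                        seen.add(pid)
                        if pid in self.root_ids:
                            hits.append((depth, self.root_ids[pid]))
                        nxt.append(pid)
                frontier = nxt
            reachable_classes = {
                self.root_ids[a] for a in self.ancestors(tid) if a in self.root_ids
            }
            if not reachable_classes:
                log.warning("term %s is not reachable from any root class", tid)
                continue
            if len(reachable_classes) > 1:
                node.multi_class = True
                log.warning(
                    "term %s reachable from classes %s; assigned nearest",
                    tid,
                    sorted(reachable_classes),
                )
            hits.sort(key=lambda dc: (dc[0], ROOT_CLASSES.index(dc[1])))
            node.root_class = hits[0][1]

    # -- queries ------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive ``is_a`` closure of *term_id*, excluding itself."""
        if term_id not in self.nodes:
            raise KeyError(f"unknown term {term_id!r}")
        out: set[str] = set()
        queue = deque(self.nodes[term_id].parent_ids)
        while queue:
            t = queue.popleft()
            if t in out:
                continue
            out.add(t)
            queue.extend(self.nodes[t].parent_ids)
        return out

    def root_class_of(self, term_id: str) -> str | None:
        return self.nodes[term_id].root_class

    def unresolved(self) -> list[str]:
        """Terms that could not be attached to any root class."""
        return sorted(
            t for t, n in self.nodes.items() if n.root_class is None
        )


def _read_root_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise OntologyError(f"bad root-map line: {line!r}")
        mapping[fields[0]] = fields[1]
    return mapping


def load_ontology(obo_path: str | Path, root_map_path: str | Path) -> OntologyTree:
    """Load and validate a term DAG.

    Parameters
    ----------
    obo_path : path
        OBO file restricted to ``[Term]`` stanzas with ``id``, ``name``,
        ``is_a`` (and ignored extras).
    root_map_path : path
        Two-column TSV ``source_root_id<TAB>class`` attaching designated
        root terms to the eight protein-feature classes.

    Raises
    ------
    OntologyError
        On cycles, dangling parents, or an invalid root map.
    """
    graph = obonet.read_obo(str(obo_path))
    nodes: dict[str, TermNode] = {}
    for tid, data in graph.nodes(data=True):
        if "name" not in data:
            # obonet materialises dangling is_a targets as bare nodes
            continue
        nodes[tid] = TermNode(
            term_id=tid,
            name=data["name"],
            parent_ids=list(data.get("is_a", [])),
            source=data.get("namespace", ""),
        )
    tree = OntologyTree(nodes, _read_root_map(root_map_path))
    bad = tree.unresolved()
    if bad:
        log.warning("%d terms unresolved to a root class: %s", len(bad), bad[:10])
    return tree
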