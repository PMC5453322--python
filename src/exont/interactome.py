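"""Protein-protein interaction partner lookup.

Given the genes bearing a tested exon list, report each gene's
interaction partners and the partners shared by two or more tested
genes — shared partners point at processes (e.g. autophagy regulators)
that coordinated splicing may converge on.  Interactions come from a
PSI-MITAB 2.5 file; only the two interactor-identifier columns and the
source-database column are consumed, since the network is used as a
partner list, not a weighted graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionEdge:
    """Undirected edge, stored with endpoints in lexicographic order."""

    gene_a: str
    gene_b: str
    source: str = ""

    @property
    def is_self(self) -> bool:
        return self.gene_a == self.gene_b


def _primary_id(column: str, id_map: dict[str, str] | None) -> str | None:
    """First identifier of a MITAB id column, mapped if a map is given."""
    first = column.split("|")[0].strip()
    if not first or first == "-":
        return None
    raw = first.split(":", 1)[1] if ":" in first else first
    raw = raw.strip('"')
    if not raw or raw == "-":
        return None
    if id_map is not None:
        return id_map.get(raw)
    return raw


def read_mitab(
    path: str | Path, id_map: dict[str, str] | None = None
) -> list[InteractionEdge]:
    """Read deduplicated undirected edges from PSI-MITAB 2.5.

    Rows whose identifiers cannot be resolved (or malformed rows) are
    skipped; the skip count is logged.
    """
    edges: dict[tuple[str, str], InteractionEdge] = {}
    skipped = 0
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if len(f) < 2:
            skipped += 1
            continue
        a = _primary_id(f[0], id_map)
        b = _primary_id(f[1], id_map)
        if a is None or b is None:
            skipped += 1
            continue
        source = f[12].split("|")[0] if len(f) > 12 else ""
        key = (min(a, b), max(a, b))
        if key not in edges:
            edge = InteractionEdge(*key, source=source)
            if edge.is_self:
                log.info("self-interaction kept and flagged: %s", a)
            edges[key] = edge
    if skipped:
        log.warning("%d MITAB rows skipped (malformed or unresolvable)", skipped)
    return [edges[k] for k in sorted(edges)]


def partners_of(
    edges: list[InteractionEdge], genes: set[str]
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Partner sets per query gene, plus partners shared by >=2 queries.

    A query gene is never its own partner unless a self-edge exists.
    """
    if not genes:
        raise ValueError("empty query gene set")
    partners: dict[str, set[str]] = {g: set() for g in sorted(genes)}
    for e in edges:
        if e.gene_a in genes:
            partners[e.gene_a].add(e.gene_b)
        if e.gene_b in genes:
            partners[e.gene_b].add(e.gene_a)
    shared: dict[str, set[str]] = {}
    seen: dict[str, set[str]] = {}
    for g, ps in partners.items():
        for p in ps:
            seen.setdefault(p, set()).add(g)
    for p, qs in seen.items():
        if len(qs) >= 2:
            shared[p] = qs
    return partners, shared
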