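"""KGML (KEGG Markup Language) pathway parsing.

Turns one KGML document into a :class:`~pathphylo.graph.PathwayGraph`
with a cross-species member-identifier namespace.  Only the structural
subset of KGML is consumed: ``<pathway>``, ``<entry id name type>``,
``<relation entry1 entry2>`` with ``<subtype>`` children, and
``<component>`` children of group entries.  Reactions and rendering
coordinates are ignored.

Cross-species identity of genes is the main reproducibility choice in
this pipeline and is therefore explicit: with no
:class:`NamespaceMap`, the entry's name tokens are used verbatim with
the species prefix stripped (``hsa:1234`` becomes ``1234``); with a
user-supplied map (e.g. a KEGG Orthology table) the mapped identifiers
are used instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Mapping

from lxml import etree

from .errors import MappingError, ParseError
from .graph import PathwayGraph

logger = logging.getLogger(__name__)

#: KGML entry types treated as gene-product nodes.  ``ortholog`` and
#: ``enzyme`` entries are gene-like placeholders in non-model organisms.
GENE_LIKE_TYPES = frozenset({"gene", "ortholog", "enzyme"})


@dataclass(frozen=True)
class KgmlEntry:
    """One ``<entry>`` element of a KGML document."""

    entry_id: int
    entry_type: str
    names: tuple[str, ...]
    component_ids: tuple[int, ...] = ()


@dataclass
class NamespaceMap:
    """Map from species-prefixed gene identifiers to cross-species member ids.

    ``strict`` application requires the map to cover every identifier it
    is asked about; otherwise unmapped identifiers pass through
    unchanged (after prefix stripping).
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "NamespaceMap":
        """Read a two-column TSV ``local_id<TAB>member_id``; '#' comments allowed."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                    )
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    def apply(self, identifiers: frozenset[str], strict: bool) -> frozenset[str]:
        missing = [i for i in identifiers if i not in self.mapping]
        if missing and strict:
            raise MappingError(
                "namespace map does not cover identifiers: "
                + ", ".join(sorted(missing))
            )
        return frozenset(
            self.mapping.get(i, _strip_prefix(i)) for i in identifiers
        )


def _strip_prefix(token: str) -> str:
    """Drop the KEGG database prefix (``hsa:1234`` -> ``1234``)."""
    _, _, rest = token.partition(":")
    return rest if rest else token


def _parse_document(document) -> etree._Element:
    if isinstance(document, (str, PathLike)) and not (
        isinstance(document, str) and document.lstrip().startswith("<")
    ):
        try:
            tree = etree.parse(str(document))
        except (etree.XMLSyntaxError, OSError) as exc:
            raise ParseError(f"cannot parse KGML document {document}: {exc}") from exc
        root = tree.getroot()
    else:
        data = document.encode() if isinstance(document, str) else document
        try:
            root = etree.fromstring(data)
        except etree.XMLSyntaxError as exc:
            raise ParseError(f"cannot parse KGML document: {exc}") from exc
    if root.tag != "pathway":
        raise ParseError(f"root element is <{root.tag}>, expected <pathway>")
    return root


def read_entries(root: etree._Element) -> dict[int, KgmlEntry]:
    entries: dict[int, KgmlEntry] = {}
    for el in root.iter("entry"):
        try:
            entry_id = int(el.get("id"))
        except (TypeError, ValueError):
            raise ParseError(
                f"<entry> with missing or non-integer id attribute: {etree.tostring(el, encoding=str)[:120]}"
            )
        entry_type = el.get("type")
        if entry_type is None:
            raise ParseError(f"<entry id={entry_id}> missing type attribute")
        if entry_id in entries:
            raise ParseError(f"duplicate entry id {entry_id}")
        names = tuple((el.get("name") or "").split())
        components = tuple(
            int(c.get("id")) for c in el.findall("component") if c.get("id")
        )
        if entry_type == "group" and not components:
            raise ParseError(f"group <entry id={entry_id}> has no components")
        entries[entry_id] = KgmlEntry(entry_id, entry_type, names, components)
    return entries


def parse_kgml(
    document,
    include_compounds: bool = False,
    namespace: NamespaceMap | None = None,
    strict: bool = True,
) -> PathwayGraph:
    """Parse a KGML document into a :class:`PathwayGraph`.

    Parameters
    ----------
    document:
        Path to a KGML file, or the XML text/bytes itself.
    include_compounds:
        Retain ``compound`` entries as nodes (default: genes only).
    namespace:
        Optional map to a cross-species member-identifier namespace.
    strict:
        If true, relations that reference unknown entries and namespace
        gaps are errors; otherwise they are skipped with a log message.

    Notes
    -----
    Group entries (protein complexes) are expanded: members receive a
    clique among themselves and inherit every relation that touched the
    group.  Repeated relations between one entry pair collapse to a
    single undirected edge; ``maplink`` relations and ``map`` entries
    are dropped.
    """
    root = _parse_document(document)
    species = root.get("org") or root.get("name") or "unknown"
    entries = read_entries(root)

    retained: dict[int, KgmlEntry] = {}
    groups: dict[int, tuple[int, ...]] = {}
    for e in entries.values():
        if e.entry_type in GENE_LIKE_TYPES:
            retained[e.entry_id] = e
        elif e.entry_type == "compound" and include_compounds:
            retained[e.entry_id] = e
        elif e.entry_type == "group":
            groups[e.entry_id] = e.component_ids

    def expand(entry_id: int) -> tuple[int, ...]:
        """Resolve an endpoint to retained node ids (groups -> members)."""
        if entry_id in retained:
            return (entry_id,)
        if entry_id in groups:
            out: list[int] = []
            for c in groups[entry_id]:
                out.extend(expand(c))
            return tuple(out)
        return ()

    nodes = []
    for e in retained.values():
        members = frozenset(e.names) or frozenset({f"entry{e.entry_id}"})
        if namespace is not None:
            members = namespace.apply(members, strict=strict)
        else:
            members = frozenset(_strip_prefix(t) for t in members)
        node_class = "gene" if e.entry_type in GENE_LIKE_TYPES else "compound"
        nodes.append((e.entry_id, members, node_class))

    edges: dict[frozenset[int], str | None] = {}

    def add_edge(u: int, v: int, subtype: str | None) -> None:
        if u == v:
            return
        key = frozenset((u, v))
        if key not in edges:
            edges[key] = subtype

    # clique among each group's members
    for comp_ids in groups.values():
        flat: list[int] = []
        for c in comp_ids:
            flat.extend(expand(c))
        for i, u in enumerate(flat):
            for v in flat[i + 1 :]:
                add_edge(u, v, "group")

    for rel in root.iter("relation"):
        if rel.get("type") == "maplink":
            continue
        try:
            e1, e2 = int(rel.get("entry1")), int(rel.get("entry2"))
        except (TypeError, ValueError):
            raise ParseError(
                f"<relation> with missing or non-integer endpoints: {etree.tostring(rel, encoding=str)[:120]}"
            )
        for endpoint in (e1, e2):
            if endpoint not in entries:
                if strict:
                    raise ParseError(
                        f"relation references unknown entry {endpoint}"
                    )
                logger.warning("skipping relation with unknown entry %d", endpoint)
                break
        else:
            subtypes = [s.get("name") for s in rel.findall("subtype") if s.get("name")]
            subtype = "+".join(subtypes) if subtypes else None
            for u in expand(e1):
                for v in expand(e2):
                    add_edge(u, v, subtype)

    return PathwayGraph.build(
        species, nodes, [(min(k), max(k), s) for k, s in edges.items()]
    )


def relabel_members(
    graph: PathwayGraph, namespace: NamespaceMap, strict: bool = True
) -> PathwayGraph:
    """Replace member_ids through ``namespace``; topology is unchanged.

    Nodes are never merged, even when two nodes map to the same member
    identifier.
    """
    g = graph.g.copy()
    missing: set[str] = set()
    for n in g.nodes:
        members = g.nodes[n]["member_ids"]
        if strict:
            missing |= {m for m in members if m not in namespace.mapping}
    if missing:
        raise MappingError(
            "namespace map does not cover identifiers: " + ", ".join(sorted(missing))
        )
    for n in g.nodes:
        members = g.nodes[n]["member_ids"]
        g.nodes[n]["member_ids"] = frozenset(
            namespace.mapping.get(m, m) for m in members
        )
    return PathwayGraph(graph.species_code, g)
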