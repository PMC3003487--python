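"""Readers and writers for the interchange formats curated networks travel in.

Supported formats:

* **SIF** — one ``source <relation> target`` line per link (a lone token
  declares an isolated node); the minimal Cytoscape edge-list dialect.
* **Attribute tables** — header TSV files attaching node identifiers
  (full name, EntrezGene, Unigene, Ensembl, UniProt) or edge curation data
  (references, PubMed IDs, curator, date).  Edge keys follow the classic
  Cytoscape convention ``"source (type) target"``.
* **XGMML** — the Cytoscape session-export XML dialect; bare documents and
  zip containers (session archives) are both accepted, view properties
  (coordinates, colors) are ignored.
* **GraphML** — full round-trip export including SBO ids and curation
  attributes, via networkx.

Dates are written as ``YYYY.MM.DD`` and parsed leniently
(``YYYY.MM.DD`` / ``YYYY-MM-DD`` / ``YYYY/MM/DD``).  All text I/O is UTF-8.
"""

from __future__ import annotations

import datetime
import io as _io
import os
import re
import zipfile
from dataclasses import dataclass, field
from typing import Optional, Union

import networkx as nx
from lxml import etree

from .errors import DanglingEndpointError, FormatError, UnknownLinkTypeError
from .model import (
    GeneNode,
    LinkType,
    Reference,
    RegLink,
    RegNetwork,
    build_network,
)

_DATE_FORMATS = ("%Y.%m.%d", "%Y-%m-%d", "%Y/%m/%d")


def parse_date(text: str) -> Optional[datetime.date]:
    """Lenient date parsing; returns None for blank/unparseable input."""
    text = (text or "").strip()
    if not text:
        return None
    for fmt in _DATE_FORMATS:
        try:
            return datetime.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    return None


def format_date(d: Optional[datetime.date]) -> str:
    return d.strftime("%Y.%m.%d") if d else ""


def _open_read(source):
    """Accept a path or a text file object; return (handle, should_close)."""
    if hasattr(source, "read"):
        return source, False
    return open(os.fspath(source), "r", encoding="utf-8"), True


# ---------------------------------------------------------------------------
# SIF
# ---------------------------------------------------------------------------

def read_sif(source, *, name: str = "") -> RegNetwork:
    """Parse a SIF edge list into a network.

    Nodes are auto-created in first-seen order; link order follows line
    order.  Lines with a single token declare isolated nodes; blank lines
    are skipped.  An unknown relation raises a FormatError naming the line.
    """
    handle, close = _open_read(source)
    try:
        symbols: dict = {}
        links: list = []

        def add_node(sym: str) -> None:
            if sym not in symbols:
                symbols[sym] = GeneNode(symbol=sym)

        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) == 1:
                add_node(parts[0])
                continue
            if len(parts) == 2:
                raise FormatError(
                    f"line {lineno}: expected 'source relation target', got {line!r}"
                )
            src, rel, *targets = parts
            try:
                lt = LinkType.from_name(rel)
            except UnknownLinkTypeError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            add_node(src)
            for tgt in targets:
                add_node(tgt)
                links.append(RegLink(source=src, target=tgt, link_type=lt))
        return build_network(symbols.values(), links, name=name)
    finally:
        if close:
            handle.close()


def write_sif(net: RegNetwork, dest=None) -> Optional[str]:
    """Serialize to SIF; returns the text when ``dest`` is None.

    Isolated nodes are written as single-token lines so the node set
    round-trips.
    """
    linked = set()
    lines = []
    for link in net.links:
        lt = link.link_type
        lines.append(f"{link.source}\t{lt.value}\t{link.target}")
        linked.add(link.source)
        linked.add(link.target)
    for sym in net.nodes:
        if sym not in linked:
            lines.append(sym)
    text = "\n".join(lines) + ("\n" if lines else "")
    if dest is None:
        return text
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(os.fspath(dest), "w", encoding="utf-8") as fh:
            fh.write(text)
    return None


# ---------------------------------------------------------------------------
# Attribute tables
# ---------------------------------------------------------------------------

@dataclass
class AttributeTable:
    """A Cytoscape-style node or edge attribute table.

    ``rows`` maps a key (node symbol, or ``"source (type) target"`` for
    edges) to a dict of attribute-name -> raw string value.
    """

    kind: str  # "node" | "edge"
    columns: list = field(default_factory=list)
    rows: dict = field(default_factory=dict)


def read_attribute_table(source, kind: str) -> AttributeTable:
    """Read a header TSV attribute table; values are kept verbatim."""
    if kind not in ("node", "edge"):
        raise ValueError(f"kind must be 'node' or 'edge', got {kind!r}")
    handle, close = _open_read(source)
    try:
        lines = [l.rstrip("\n") for l in handle]
    finally:
        if close:
            handle.close()
    lines = [l for l in lines if l.strip()]
    if not lines:
        return AttributeTable(kind=kind)
    header = [h.strip() for h in lines[0].split("\t")]
    if len(header) < 2 or any(not h for h in header):
        raise FormatError(f"malformed attribute-table header: {lines[0]!r}")
    table = AttributeTable(kind=kind, columns=header[1:])
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) > len(header):
            raise FormatError(f"line {lineno}: more cells than header columns")
        key = cells[0].strip()
        values = {}
        for name, cell in zip(header[1:], cells[1:]):
            values[name] = cell.strip()
        table.rows[key] = values
    return table


def _norm(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


_NODE_FIELDS = {
    "fullname": "full_name",
    "name": "full_name",
    "entrezgeneid": "entrez_id",
    "entrezid": "entrez_id",
    "entrezgene": "entrez_id",
    "unigeneid": "unigene_id",
    "unigene": "unigene_id",
    "ensemblid": "ensembl_id",
    "ensembl": "ensembl_id",
    "uniprot": "uniprot_id",
    "uniprotid": "uniprot_id",
}

_EDGE_KEY_RE = re.compile(r"^(?P<src>.+?)\s*\((?P<type>[^()]+)\)\s*(?P<tgt>.+)$")


def edge_key(link: RegLink) -> str:
    """The Cytoscape attribute-file key ``"source (type) target"``."""
    lt = link.link_type
    name = lt.value if isinstance(lt, LinkType) else str(lt)
    return f"{link.source} ({name}) {link.target}"


def attach_attributes(net: RegNetwork, table: AttributeTable) -> list:
    """Attach table values to a network in place.

    Returns the list of unmatched keys (rows that name no node/edge of the
    network); unmatched keys are reported, never fatal.
    """
    unmatched = []
    if table.kind == "node":
        for key, values in table.rows.items():
            node = net.nodes.get(key)
            if node is None:
                unmatched.append(key)
                continue
            for name, value in values.items():
                fld = _NODE_FIELDS.get(_norm(name))
                if fld is not None:
                    setattr(node, fld, value)
                else:
                    node.extra[name] = value
        return unmatched

    by_key: dict = {}
    for link in net.links:
        by_key.setdefault(edge_key(link), link)
        if not link.directed:  # interactions match either endpoint order
            rev = f"{link.target} ({link.link_type.value}) {link.source}"
            by_key.setdefault(rev, link)
    for key, values in table.rows.items():
        link = by_key.get(key)
        if link is None:
            unmatched.append(key)
            continue
        _apply_edge_attributes(link, values)
    return unmatched


def _apply_edge_attributes(link: RegLink, values: dict) -> None:
    pubmed_ids: list = []
    citations: list = []
    for name, value in values.items():
        n = _norm(name)
        if n in ("pubmedid", "pubmedids", "pubmed"):
            pubmed_ids = [p.strip() for p in value.split(";") if p.strip()]
        elif n in ("reference", "references", "citation"):
            citations = [c.strip() for c in value.split("|") if c.strip()]
        elif n == "addedby":
            link.added_by = value
        elif n == "addedon":
            link.added_on = parse_date(value)
    if pubmed_ids or citations:
        while len(citations) < len(pubmed_ids):
            citations.append("")
        while len(pubmed_ids) < len(citations):
            pubmed_ids.append("")
        link.references = tuple(
            Reference(p, c) for p, c in zip(pubmed_ids, citations)
        )


# ---------------------------------------------------------------------------
# XGMML
# ---------------------------------------------------------------------------

_XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def _localname(el) -> str:
    qname = etree.QName(el)
    return qname.localname


def _xgmml_atts(el) -> dict:
    atts = {}
    for child in el:
        if isinstance(child.tag, str) and _localname(child) == "att":
            name = child.get("name")
            if name is not None:
                atts[name] = child.get("value", "")
    return atts


def read_xgmml(source, *, name: str = "") -> RegNetwork:
    """Parse an XGMML document (or a zip session archive containing one).

    The edge type is taken from an ``att`` named ``interaction`` /
    ``interactiontype`` (case-insensitive), falling back to the
    ``"source (type) target"`` edge label.  Layout coordinates, colors and
    other view properties are ignored.
    """
    data = _read_bytes(source)
    if data[:2] == b"PK":  # zip container (session archive)
        data = _extract_xgmml_from_zip(data)
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not an XGMML/XML document: {exc}") from None
    graph = None
    for el in root.iter():
        if isinstance(el.tag, str) and _localname(el) == "graph":
            graph = el
            break
    if graph is None:
        raise FormatError("no <graph> element found in XGMML document")

    id_to_symbol: dict = {}
    nodes: dict = {}
    links: list = []
    for el in graph.iter():
        if not isinstance(el.tag, str):
            continue
        tag = _localname(el)
        if tag == "node":
            node_id = el.get("id") or el.get("label")
            label = el.get("label") or node_id
            if node_id is None:
                raise FormatError("XGMML node without id or label")
            id_to_symbol[node_id] = label
            node = GeneNode(symbol=label)
            for att, value in _xgmml_atts(el).items():
                fld = _NODE_FIELDS.get(_norm(att))
                if fld is not None:
                    setattr(node, fld, value)
                elif _norm(att) not in ("label", "canonicalname"):
                    node.extra[att] = value
            nodes[label] = node
        elif tag == "edge":
            src_id, tgt_id = el.get("source"), el.get("target")
            if src_id is None or tgt_id is None:
                raise FormatError("XGMML edge without source/target")
            for ref in (src_id, tgt_id):
                if ref not in id_to_symbol:
                    raise DanglingEndpointError(
                        f"XGMML edge references undeclared node id {ref!r}"
                    )
            atts = _xgmml_atts(el)
            type_name = None
            extra = {}
            for att, value in atts.items():
                if _norm(att) in ("interaction", "interactiontype", "linktype"):
                    type_name = value
                else:
                    extra[att] = value
            if type_name is None:
                label = el.get("label", "")
                m = _EDGE_KEY_RE.match(label)
                if m:
                    type_name = m.group("type")
            if type_name is None:
                raise FormatError(
                    f"XGMML edge {src_id}->{tgt_id} carries no interaction type"
                )
            try:
                lt = LinkType.from_name(type_name)
            except UnknownLinkTypeError as exc:
                raise FormatError(str(exc)) from None
            link = RegLink(
                source=id_to_symbol[src_id],
                target=id_to_symbol[tgt_id],
                link_type=lt,
            )
            _apply_edge_attributes(link, extra)
            links.append(link)
    net_name = name or graph.get("label", "")
    return build_network(nodes.values(), links, name=net_name)


def _read_bytes(source) -> bytes:
    if isinstance(source, bytes):
        return source
    if hasattr(source, "read"):
        data = source.read()
        return data.encode("utf-8") if isinstance(data, str) else data
    with open(os.fspath(source), "rb") as fh:
        return fh.read()


def _extract_xgmml_from_zip(data: bytes) -> bytes:
    """Scan a zip container for the first member that parses as XGMML."""
    with zipfile.ZipFile(_io.BytesIO(data)) as zf:
        names = sorted(
            zf.namelist(),
            key=lambda n: (not n.lower().endswith(".xgmml"), n),
        )
        for member in names:
            blob = zf.read(member)
            if b"<graph" in blob[:4096] or member.lower().endswith(".xgmml"):
                return blob
    raise FormatError("zip container holds no XGMML network document")


def write_xgmml(net: RegNetwork, dest=None) -> Optional[str]:
    """Serialize a network as a bare XGMML document."""
    nsmap = {None: _XGMML_NS}
    graph = etree.Element(
        f"{{{_XGMML_NS}}}graph",
        nsmap=nsmap,
        label=net.name or "network",
        directed="1",
    )
    ids = {sym: str(i) for i, sym in enumerate(net.nodes)}

    def att(parent, name, value, att_type="string"):
        etree.SubElement(
            parent, f"{{{_XGMML_NS}}}att", name=name, value=value, type=att_type
        )

    for sym, node in net.nodes.items():
        el = etree.SubElement(
            graph, f"{{{_XGMML_NS}}}node", id=ids[sym], label=sym
        )
        for name, value in (
            ("full name", node.full_name),
            ("EntrezGene ID", node.entrez_id),
            ("Unigene ID", node.unigene_id),
            ("Ensembl ID", node.ensembl_id),
            ("UniProt", node.uniprot_id),
        ):
            if value:
                att(el, name, value)
    for link in net.links:
        el = etree.SubElement(
            graph,
            f"{{{_XGMML_NS}}}edge",
            source=ids[link.source],
            target=ids[link.target],
            label=edge_key(link),
        )
        att(el, "interactiontype", link.link_type.value)
        att(el, "sbo id", link.link_type.sbo_id)
        if link.references:
            att(el, "Pubmed ID", ";".join(r.pubmed_id for r in link.references))
            if any(r.citation_text for r in link.references):
                att(
                    el,
                    "Reference",
                    "|".join(r.citation_text for r in link.references),
                )
        if link.added_by:
            att(el, "Added by", link.added_by)
        if link.added_on:
            att(el, "Added on", format_date(link.added_on))
    text = etree.tostring(
        graph, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")
    if dest is None:
        return text
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(os.fspath(dest), "w", encoding="utf-8") as fh:
            fh.write(text)
    return None


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def _to_multidigraph(net: RegNetwork) -> nx.MultiDiGraph:
    G = nx.MultiDiGraph(name=net.name or "network")
    for sym, node in net.nodes.items():
        G.add_node(
            sym,
            full_name=node.full_name,
            entrez_id=node.entrez_id,
            unigene_id=node.unigene_id,
            ensembl_id=node.ensembl_id,
            uniprot_id=node.uniprot_id,
        )
    for link in net.links:
        G.add_edge(
            link.source,
            link.target,
            link_type=link.link_type.value,
            sbo_id=link.link_type.sbo_id,
            pubmed_ids=";".join(r.pubmed_id for r in link.references),
            citations="|".join(r.citation_text for r in link.references),
            added_by=link.added_by,
            added_on=format_date(link.added_on),
        )
    return G


def export_graphml(net: RegNetwork, dest=None) -> Optional[str]:
    """Serialize to GraphML with full node identifier and curation attributes."""
    text = "\n".join(nx.generate_graphml(_to_multidigraph(net))) + "\n"
    if dest is None:
        return text
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(os.fspath(dest), "w", encoding="utf-8") as fh:
            fh.write(text)
    return None


def read_graphml(source, *, name: str = "") -> RegNetwork:
    """Parse GraphML written by :func:`export_graphml` (or compatible)."""
    try:
        if hasattr(source, "read"):
            data = source.read()
            G = nx.parse_graphml(data, force_multigraph=True)
        elif isinstance(source, str) and "<graphml" in source:
            G = nx.parse_graphml(source, force_multigraph=True)
        else:
            G = nx.read_graphml(os.fspath(source), force_multigraph=True)
    except Exception as exc:  # networkx raises a mixed bag of exceptions
        raise FormatError(f"not a GraphML document: {exc}") from None
    nodes = []
    for sym, data in G.nodes(data=True):
        nodes.append(
            GeneNode(
                symbol=str(sym),
                full_name=str(data.get("full_name", "")),
                entrez_id=str(data.get("entrez_id", "")),
                unigene_id=str(data.get("unigene_id", "")),
                ensembl_id=str(data.get("ensembl_id", "")),
                uniprot_id=str(data.get("uniprot_id", "")),
            )
        )
    links = []
    for src, tgt, data in G.edges(data=True):
        type_name = data.get("link_type") or data.get("interaction")
        if type_name is None and data.get("sbo_id"):
            lt = LinkType.from_sbo(str(data["sbo_id"]))
        else:
            if type_name is None:
                raise FormatError(f"GraphML edge {src}->{tgt} carries no link type")
            lt = LinkType.from_name(str(type_name))
        pubmed = [p for p in str(data.get("pubmed_ids", "")).split(";") if p]
        cites = str(data.get("citations", "")).split("|")
        refs = tuple(
            Reference(p, cites[i] if i < len(cites) else "")
            for i, p in enumerate(pubmed)
        )
        links.append(
            RegLink(
                source=str(src),
                target=str(tgt),
                link_type=lt,
                references=refs,
                added_by=str(data.get("added_by", "")),
                added_on=parse_date(str(data.get("added_on", ""))),
            )
        )
    return build_network(nodes, links, name=name or str(G.graph.get("name", "")))


# ---------------------------------------------------------------------------
# Format dispatch (CLI convenience)
# ---------------------------------------------------------------------------

_READERS = {"sif": read_sif, "xgmml": read_xgmml, "graphml": read_graphml}
_WRITERS = {"sif": write_sif, "xgmml": write_xgmml, "graphml": export_graphml}


def detect_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext in ("sif",):
        return "sif"
    if ext in ("xgmml", "xml", "cys"):
        return "xgmml"
    if ext in ("graphml",):
        return "graphml"
    raise FormatError(f"cannot detect network format from extension of {path!r}")


def read_network(path, fmt: Optional[str] = None) -> RegNetwork:
    fmt = fmt or detect_format(path)
    try:
        reader = _READERS[fmt]
    except KeyError:
        raise FormatError(f"unknown network format {fmt!r}") from None
    return reader(path)


def write_network(net: RegNetwork, path, fmt: Optional[str] = None) -> None:
    fmt = fmt or detect_format(path)
    try:
        writer = _WRITERS[fmt]
    except KeyError:
        raise FormatError(f"unknown network format {fmt!r}") from None
    writer(net, path)
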