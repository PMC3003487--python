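"""Typed data model for curated gene/protein regulation networks.

A curated network joins genes/proteins (one node per gene; the protein
product is not a separate node) by three kinds of binary links:

* ``stimulation`` — directed, SBO:0000170 (activity-flow "stimulation"),
* ``inhibition``  — directed, SBO:0000169,
* ``interaction`` — undirected, SBO:0000231.

Every link is a curation record: besides its endpoints and type it carries
literature references (PubMed IDs plus free-text citations), the curator's
initials and the date the record was added.  Node labels are MGI-style gene
symbols and are matched case-sensitively throughout.
"""

from __future__ import annotations

import datetime
import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Union

from .errors import (
    DanglingEndpointError,
    DuplicateLinkWarning,
    DuplicateNodeError,
    SelfLoopError,
    UnknownLinkTypeError,
    ValidationError,
)


class LinkType(enum.Enum):
    """The three mechanism types, with their fixed SBO activity-flow terms."""

    INTERACTION = "interaction"
    STIMULATION = "stimulation"
    INHIBITION = "inhibition"

    @property
    def sbo_id(self) -> str:
        return _SBO_IDS[self]

    @property
    def directed(self) -> bool:
        """Stimulation and inhibition carry a regulatory direction."""
        return self is not LinkType.INTERACTION

    @classmethod
    def from_name(cls, name: str) -> "LinkType":
        try:
            return cls(str(name).strip().lower())
        except ValueError:
            raise UnknownLinkTypeError(
                f"unknown link type {name!r}; expected one of "
                "'interaction', 'stimulation', 'inhibition'"
            ) from None

    @classmethod
    def from_sbo(cls, sbo_id: str) -> "LinkType":
        try:
            return _SBO_TO_TYPE[sbo_id.strip()]
        except KeyError:
            raise UnknownLinkTypeError(f"unknown SBO id {sbo_id!r}") from None


_SBO_IDS = {
    LinkType.STIMULATION: "SBO:0000170",
    LinkType.INHIBITION: "SBO:0000169",
    LinkType.INTERACTION: "SBO:0000231",
}
_SBO_TO_TYPE = {v: k for k, v in _SBO_IDS.items()}


class Reference(NamedTuple):
    """One supporting publication: PubMed ID plus optional citation text."""

    pubmed_id: str
    citation_text: str = ""


@dataclass
class GeneNode:
    """A gene and its protein product, labelled by its MGI-style symbol.

    All identifier fields are optional and may be empty strings; unknown
    extra attributes from attribute tables are kept verbatim in ``extra``.
    """

    symbol: str
    full_name: str = ""
    entrez_id: str = ""
    unigene_id: str = ""
    ensembl_id: str = ""
    uniprot_id: str = ""
    extra: dict = field(default_factory=dict)


@dataclass
class RegLink:
    """One curated mechanism between two genes.

    ``link_type`` may be a :class:`LinkType` or a raw string; valid strings
    are coerced, invalid ones are kept as-is so that
    :func:`validate_link_record` can report them as findings instead of
    raising.
    """

    source: str
    target: str
    link_type: Union[LinkType, str]
    references: tuple = ()
    added_by: str = ""
    added_on: Optional[datetime.date] = None

    def __post_init__(self) -> None:
        if isinstance(self.link_type, str):
            try:
                self.link_type = LinkType.from_name(self.link_type)
            except UnknownLinkTypeError:
                pass  # kept raw; surfaced by validate_link_record
        refs = []
        for ref in self.references:
            refs.append(ref if isinstance(ref, Reference) else Reference(*ref))
        self.references = tuple(refs)

    @property
    def directed(self) -> bool:
        lt = self.link_type
        return lt.directed if isinstance(lt, LinkType) else True


@dataclass(frozen=True)
class LinkKey:
    """Canonical identity of a link under configurable equivalence.

    For undirected keys ``(a, b)`` is stored in lexicographic order so that
    ``key(A, B) == key(B, A)``; ``link_type`` is ``None`` when type is
    ignored.
    """

    a: str
    b: str
    directed: bool
    link_type: Optional[LinkType] = None

    def sort_key(self) -> tuple:
        return (
            self.a,
            self.b,
            self.directed,
            self.link_type.value if self.link_type is not None else "",
        )

    def __str__(self) -> str:
        arrow = "->" if self.directed else "--"
        t = self.link_type.value if self.link_type else "*"
        return f"{self.a} {arrow} {self.b} [{t}]"


def canonical_link_key(
    link: RegLink, ignore_type: bool = False, ignore_direction: bool = False
) -> LinkKey:
    """Deterministic identity key for a link.

    Interactions always compare undirected; stimulations/inhibitions keep
    their direction unless ``ignore_direction`` is set.  With
    ``ignore_type`` the type field of the key is erased (direction-ness is
    still derived from the link's own type).
    """
    lt = link.link_type
    if not isinstance(lt, LinkType):
        lt = LinkType.from_name(str(lt))
    directed = lt.directed and not ignore_direction
    if directed:
        a, b = link.source, link.target
    else:
        a, b = sorted((link.source, link.target))
    return LinkKey(a, b, directed, None if ignore_type else lt)


@dataclass
class RegNetwork:
    """A set of gene nodes plus an ordered multiset of typed links."""

    nodes: dict
    links: list
    name: str = ""
    version: str = ""
    allow_self_loops: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def link_keys(
        self, ignore_type: bool = False, ignore_direction: bool = False
    ) -> list:
        return [
            canonical_link_key(l, ignore_type, ignore_direction) for l in self.links
        ]

    def distinct_link_keys(
        self, ignore_type: bool = False, ignore_direction: bool = False
    ) -> frozenset:
        return frozenset(self.link_keys(ignore_type, ignore_direction))


def build_network(
    nodes: Iterable[GeneNode],
    links: Iterable[RegLink],
    *,
    name: str = "",
    version: str = "",
    allow_self_loops: bool = False,
) -> RegNetwork:
    """Assemble and validate a :class:`RegNetwork`.

    Raises on dangling endpoints, duplicate node symbols and (by default)
    self-loops.  Exact-duplicate link records — same endpoints, direction
    and type — are merged into one link whose reference lists are unioned;
    a :class:`~signet.errors.DuplicateLinkWarning` is emitted per merge.
    """
    node_map: dict = {}
    for node in nodes:
        if not node.symbol:
            raise ValidationError("node with empty symbol")
        if node.symbol in node_map:
            raise DuplicateNodeError(f"duplicate node symbol {node.symbol!r}")
        node_map[node.symbol] = node

    merged: dict = {}
    ordered: list = []
    for link in links:
        for endpoint in (link.source, link.target):
            if endpoint not in node_map:
                raise DanglingEndpointError(
                    f"link {link.source!r}->{link.target!r}: endpoint "
                    f"{endpoint!r} is not a declared node"
                )
        if link.source == link.target and not allow_self_loops:
            raise SelfLoopError(
                f"self-loop on {link.source!r} (self-loops are off by default)"
            )
        if isinstance(link.link_type, LinkType):
            key = canonical_link_key(link)
            if key in merged:
                warnings.warn(
                    f"exact duplicate link {key}; merging reference lists",
                    DuplicateLinkWarning,
                    stacklevel=2,
                )
                kept = merged[key]
                seen = set(kept.references)
                extra = tuple(r for r in link.references if r not in seen)
                kept.references = kept.references + extra
                continue
            merged[key] = link
        ordered.append(link)

    return RegNetwork(
        nodes=node_map,
        links=ordered,
        name=name,
        version=version,
        allow_self_loops=allow_self_loops,
    )


@dataclass(frozen=True)
class SimpleGraph:
    """Undirected simple graph: the projection used for topology statistics.

    Edges are unordered symbol pairs stored as sorted tuples; no parallel
    edges, no self-loops.  Isolated nodes are retained.
    """

    nodes: frozenset
    edges: frozenset

    def adjacency(self) -> dict:
        adj = {n: set() for n in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj


def simple_projection(net: RegNetwork) -> SimpleGraph:
    """Collapse the typed multigraph to an undirected simple graph.

    Every unordered endpoint pair with at least one link of any type yields
    exactly one edge; self-loops are dropped; the full node set (including
    isolated nodes) is preserved.
    """
    edges = set()
    for link in net.links:
        if link.source == link.target:
            continue
        a, b = sorted((link.source, link.target))
        edges.add((a, b))
    return SimpleGraph(nodes=frozenset(net.nodes), edges=frozenset(edges))


@dataclass
class ValidationConfig:
    """Which curation-record rules :func:`validate_link_record` enforces."""

    require_references: bool = True
    require_curator: bool = True
    allow_self_loops: bool = False


@dataclass(frozen=True)
class Finding:
    """One machine-checkable curation finding (never an exception)."""

    code: str
    message: str
    level: str = "warning"


def validate_link_record(
    link: RegLink, rules: Optional[ValidationConfig] = None
) -> list:
    """Check one curation record against the assembly rules.

    Returns findings for: missing reference, non-digit PubMed ID, missing
    curator, unknown link type, self-loop.  The two remaining curation
    criteria — that the mechanism is *direct* and was described in the
    mouse model system — are properties of the cited literature and cannot
    be machine-checked; they are deliberately not inspected here.
    """
    rules = rules or ValidationConfig()
    findings = []
    if not isinstance(link.link_type, LinkType):
        findings.append(
            Finding("unknown-type", f"unknown link type {link.link_type!r}")
        )
    if rules.require_references and not link.references:
        findings.append(
            Finding(
                "missing-reference",
                f"link {link.source}->{link.target} has no literature reference",
            )
        )
    for ref in link.references:
        if ref.pubmed_id and not ref.pubmed_id.isdigit():
            findings.append(
                Finding("bad-pubmed-id", f"PubMed ID {ref.pubmed_id!r} is not a digit string")
            )
    if rules.require_curator and not link.added_by:
        findings.append(
            Finding("missing-curator", f"link {link.source}->{link.target} has no curator")
        )
    if link.source == link.target and not rules.allow_self_loops:
        findings.append(Finding("self-loop", f"self-loop on {link.source!r}"))
    return findings
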