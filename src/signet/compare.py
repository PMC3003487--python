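"""Network-to-network overlap and difference reporting.

Node overlap is exact symbol matching (both networks are assumed to use
the same symbol namespace).  Link overlap compares canonical link keys
under configurable identity semantics: by default both link type and
direction are ignored (unordered endpoint-pair match), the only
well-defined common denominator when comparing networks with differing
type vocabularies; stricter modes are available via the flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Tuple

from .model import RegNetwork


def _frac(shared: int, total: int) -> float:
    # A zero-link/zero-node network overlaps itself vacuously.
    return shared / total if total else 1.0


@dataclass(frozen=True)
class OverlapReport:
    """Shared counts and per-network fractions of a two-network comparison."""

    shared_links: int
    shared_nodes: int
    n_links_a: int
    n_links_b: int
    n_nodes_a: int
    n_nodes_b: int
    frac_links_of_a: float
    frac_links_of_b: float
    frac_nodes_of_a: float
    frac_nodes_of_b: float
    identity_options: Tuple[bool, bool]  # (ignore_type, ignore_direction)

    def percent(self, value: float) -> int:
        """Round a fraction to the nearest percent for reporting."""
        return round(value * 100)


def overlap(
    net_a: RegNetwork,
    net_b: RegNetwork,
    ignore_type: bool = True,
    ignore_direction: bool = True,
) -> OverlapReport:
    """Node and link overlap of two networks.

    Link counts are *distinct canonical keys* under the chosen identity
    options; fractions are computed against each network's own distinct
    key / node counts.
    """
    keys_a = net_a.distinct_link_keys(ignore_type, ignore_direction)
    keys_b = net_b.distinct_link_keys(ignore_type, ignore_direction)
    nodes_a, nodes_b = set(net_a.nodes), set(net_b.nodes)
    shared_links = len(keys_a & keys_b)
    shared_nodes = len(nodes_a & nodes_b)
    return OverlapReport(
        shared_links=shared_links,
        shared_nodes=shared_nodes,
        n_links_a=len(keys_a),
        n_links_b=len(keys_b),
        n_nodes_a=len(nodes_a),
        n_nodes_b=len(nodes_b),
        frac_links_of_a=_frac(shared_links, len(keys_a)),
        frac_links_of_b=_frac(shared_links, len(keys_b)),
        frac_nodes_of_a=_frac(shared_nodes, len(nodes_a)),
        frac_nodes_of_b=_frac(shared_nodes, len(nodes_b)),
        identity_options=(ignore_type, ignore_direction),
    )


def diff(
    net_a: RegNetwork,
    net_b: RegNetwork,
    ignore_type: bool = True,
    ignore_direction: bool = True,
) -> Tuple[FrozenSet, FrozenSet, FrozenSet]:
    """Partition both key sets into (only in A, only in B, shared)."""
    keys_a = net_a.distinct_link_keys(ignore_type, ignore_direction)
    keys_b = net_b.distinct_link_keys(ignore_type, ignore_direction)
    return keys_a - keys_b, keys_b - keys_a, keys_a & keys_b
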