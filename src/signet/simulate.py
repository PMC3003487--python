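"""Synthetic networks and two-condition expression data with known structure.

The network generator emulates the shape of a literature-curated
pluripotency network — by default 274 genes joined by 574 mixed-type links,
grown with preferential attachment so the simple projection has a
heavy-tailed degree distribution.  The expression generator emulates
two-condition log-intensity microarray data with replicates: every gene
gets Gaussian noise around a common baseline, and the endpoint genes of a
set of *planted* links are shifted between conditions (up for startups,
down for shutdowns) by a chosen effect size in noise-SD units, defining
ground truth for condensation recovery studies.

Every generator output is a pure function of its parameters including the
seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional

import numpy as np

from .condense import CondensedNetwork, ConditionPair
from .errors import ParameterError, SignetError
from .model import (
    GeneNode,
    LinkKey,
    LinkType,
    RegLink,
    RegNetwork,
    build_network,
    canonical_link_key,
)

_TYPE_ORDER = (LinkType.INTERACTION, LinkType.STIMULATION, LinkType.INHIBITION)

# Each unordered node pair supports 5 distinct links: one interaction plus
# both directions of stimulation and of inhibition.
_SLOTS_PER_PAIR = 5


@dataclass(frozen=True)
class NetworkGenParams:
    """Shape parameters for :func:`simulate_network`.

    Defaults emulate a curated pluripotency-scale network: 274 nodes,
    574 links, a 40/40/20 interaction/stimulation/inhibition mix, grown
    with preferential attachment.
    """

    n_nodes: int = 274
    n_links: int = 574
    type_probabilities: tuple = (0.40, 0.40, 0.20)
    attachment: str = "preferential"  # or "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 0 or self.n_links < 0:
            raise ParameterError("n_nodes and n_links must be non-negative")
        probs = self.type_probabilities
        if len(probs) != 3 or any(p < 0 for p in probs):
            raise ParameterError("type_probabilities must be 3 non-negative values")
        if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ParameterError("type_probabilities must sum to 1")
        if self.attachment not in ("uniform", "preferential"):
            raise ParameterError("attachment must be 'uniform' or 'preferential'")


def _symbol(i: int) -> str:
    return f"G{i:04d}"


def simulate_network(params: NetworkGenParams) -> RegNetwork:
    """Generate a typed network with exactly the requested counts.

    Links occupy distinct (pair, type, direction) slots — parallel links
    between a pair are allowed only when they differ in type or direction —
    with no self-loops.  Endpoints are drawn uniformly or with
    degree-proportional (degree + 1) weights; occupied slots are rejected
    and resampled, with a deterministic scan of the remaining free slots as
    a fallback near capacity.
    """
    n, m = params.n_nodes, params.n_links
    capacity = _SLOTS_PER_PAIR * n * (n - 1) // 2
    if m > capacity:
        raise ParameterError(
            f"{m} links do not fit: {n} nodes allow at most {capacity} distinct links"
        )
    rng = np.random.default_rng(params.seed)
    probs = np.asarray(params.type_probabilities, dtype=float)
    probs = probs / probs.sum()
    degrees = np.ones(n)
    used: set = set()
    links: list = []
    max_attempts = 50 * max(m, 1) + 1000
    attempts = 0
    while len(links) < m and attempts < max_attempts:
        attempts += 1
        if params.attachment == "preferential":
            w = degrees / degrees.sum()
            a, b = rng.choice(n, size=2, p=w)
        else:
            a, b = rng.integers(0, n, size=2)
        if a == b:
            continue
        lt = _TYPE_ORDER[rng.choice(3, p=probs)]
        if lt.directed:
            slot = (int(a), int(b), lt)
        else:
            slot = (min(int(a), int(b)), max(int(a), int(b)), lt)
        if slot in used:
            continue
        used.add(slot)
        links.append(
            RegLink(_symbol(int(a)), _symbol(int(b)), lt, added_by="synthetic")
        )
        degrees[a] += 1
        degrees[b] += 1
    if len(links) < m:
        _fill_remaining(links, used, n, m, rng, probs)
    nodes = [GeneNode(symbol=_symbol(i)) for i in range(n)]
    return build_network(
        nodes, links, name=f"synthetic-{params.seed}", version="synthetic"
    )


def _fill_remaining(links, used, n, m, rng, probs) -> None:
    """Deterministically fill the remaining slots when rejection stalls."""
    free = []
    for a in range(n):
        for b in range(a + 1, n):
            if (a, b, LinkType.INTERACTION) not in used:
                free.append((a, b, LinkType.INTERACTION))
            for lt in (LinkType.STIMULATION, LinkType.INHIBITION):
                for s, t in ((a, b), (b, a)):
                    if (s, t, lt) not in used:
                        free.append((s, t, lt))
    rng.shuffle(free)
    for a, b, lt in free[: m - len(links)]:
        used.add((a, b, lt) if lt.directed else (min(a, b), max(a, b), lt))
        links.append(RegLink(_symbol(a), _symbol(b), lt, added_by="synthetic"))


@dataclass(frozen=True)
class ExpressionGenParams:
    """Parameters for :func:`simulate_expression`.

    ``direction`` maps each planted link key to ``"startup"`` or
    ``"shutdown"``; ``planted_links`` is derived from it when omitted.
    ``effect_size`` is the condition-2 shift applied to both endpoint genes
    of a planted link, in units of ``noise_sd``.  Defaults are the study
    conditions of the recovery simulations: 3-SD effects, SD-1 noise on a
    baseline of 8 (log-intensity scale), 3 replicates per condition.
    """

    direction: Dict[LinkKey, str] = field(default_factory=dict)
    planted_links: Optional[FrozenSet[LinkKey]] = None
    effect_size: float = 3.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        for key, d in self.direction.items():
            if d not in ("startup", "shutdown"):
                raise ParameterError(f"direction for {key} must be startup/shutdown")
        if self.planted_links is None:
            object.__setattr__(self, "planted_links", frozenset(self.direction))
        elif set(self.planted_links) != set(self.direction):
            raise ParameterError("planted_links must equal the keys of direction")


def choose_planted(
    net: RegNetwork,
    n_planted: int,
    seed: int = 0,
    startup_fraction: float = 0.5,
) -> Dict[LinkKey, str]:
    """Pick planted links with directions such that no gene is pulled both ways.

    Links are drawn in random order and greedily assigned alternating
    startup/shutdown labels, skipping any link whose endpoint is already
    committed to the opposite direction.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(net.links))
    n_start = round(n_planted * startup_fraction)
    committed: Dict[str, str] = {}
    direction: Dict[LinkKey, str] = {}
    for idx in order:
        if len(direction) == n_planted:
            break
        link = net.links[int(idx)]
        key = canonical_link_key(link)
        if key in direction:
            continue
        label = "startup" if sum(d == "startup" for d in direction.values()) < n_start else "shutdown"
        ends = (link.source, link.target)
        if any(committed.get(g, label) != label for g in ends):
            # try the other label before giving up on this link
            other = "shutdown" if label == "startup" else "startup"
            want_other = (
                sum(d == other for d in direction.values())
                < (n_planted - n_start if other == "shutdown" else n_start)
            )
            if want_other and all(committed.get(g, other) == other for g in ends):
                label = other
            else:
                continue
        for g in ends:
            committed[g] = label
        direction[key] = label
    if len(direction) < n_planted:
        raise SignetError(
            f"could only plant {len(direction)} of {n_planted} requested links "
            "without direction conflicts"
        )
    return direction


def simulate_expression(
    net: RegNetwork, params: ExpressionGenParams
) -> ConditionPair:
    """Two-condition replicate expression for every gene of the network.

    Values are generated directly on the (log-intensity-like) analysis
    scale: ``baseline_mean + N(0, noise_sd)`` per replicate, with planted
    endpoint genes shifted by ``±effect_size * noise_sd`` in condition 2.
    The returned pair uses ``transform="raw"`` and plain scoring.  A gene
    touched by several same-direction planted links shifts once; links
    pulling a gene in both directions are an error.
    """
    net_keys = net.distinct_link_keys()
    missing = [k for k in params.direction if k not in net_keys]
    if missing:
        raise SignetError(
            "planted links absent from the network: "
            + ", ".join(str(k) for k in missing)
        )
    shift_sign: Dict[str, int] = {}
    conflicts = set()
    for key, d in params.direction.items():
        sign = 1 if d == "startup" else -1
        for gene in (key.a, key.b):
            if shift_sign.get(gene, sign) != sign:
                conflicts.add(gene)
            shift_sign[gene] = shift_sign.get(gene, sign)
    if conflicts:
        raise SignetError(
            "conflicting planted directions for gene(s): "
            + ", ".join(sorted(conflicts))
        )
    rng = np.random.default_rng(params.seed)
    reps = params.n_replicates
    values = {}
    for gene in sorted(net.nodes):
        noise = rng.normal(0.0, params.noise_sd, size=2 * reps)
        shift = shift_sign.get(gene, 0) * params.effect_size * params.noise_sd
        v1 = params.baseline_mean + noise[:reps]
        v2 = params.baseline_mean + shift + noise[reps:]
        values[gene] = (tuple(float(x) for x in v1), tuple(float(x) for x in v2))
    return ConditionPair(values=values, transform="raw", scoring_mode="plain")


def recovery_rate(
    condensed: CondensedNetwork, params: ExpressionGenParams
) -> float:
    """Fraction of planted links retained in the correct tail.

    Vacuously 1.0 (with a warning) when no links were planted.
    """
    if not params.direction:
        warnings.warn("no planted links; recovery rate is vacuously 1.0")
        return 1.0
    retained = {r.link_key: r.link_class for r in condensed.retained}
    correct = sum(
        1 for key, d in params.direction.items() if retained.get(key) == d
    )
    return correct / len(params.direction)
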