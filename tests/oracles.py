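"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (adjacency sets, BFS by
hand, binomial-coefficient sums) and deliberately shares no code path with
the package.
"""

from collections import deque
from math import comb


def bfs_distances(adj, start):
    """Shortest-path distances from ``start`` by plain breadth-first search."""
    dist = {start: 0}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for nb in adj[node]:
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return dist


def clustering_bruteforce(adj, node):
    """Count closed neighbor pairs directly."""
    nbrs = sorted(adj[node])
    k = len(nbrs)
    if k < 2:
        return 0.0
    closed = 0
    for i in range(k):
        for j in range(i + 1, k):
            if nbrs[j] in adj[nbrs[i]]:
                closed += 1
    return 2.0 * closed / (k * (k - 1))


def path_metrics_bruteforce(adj):
    """(total distance over connected unordered pairs, pair count, diameter)."""
    total = 0
    count = 0
    diameter = 0
    nodes = sorted(adj)
    for i, a in enumerate(nodes):
        dist = bfs_distances(adj, a)
        for b in nodes[i + 1 :]:
            if b in dist:
                total += dist[b]
                count += 1
                diameter = max(diameter, dist[b])
    return total, count, diameter


def n_components_bruteforce(adj):
    seen = set()
    n = 0
    for node in adj:
        if node not in seen:
            seen |= set(bfs_distances(adj, node))
            n += 1
    return n


def hypergeom_tail_bruteforce(k, K, n, N):
    """P(X >= k) as an explicit sum of draw counts over all outcomes."""
    denom = comb(N, n)
    num = 0
    for i in range(k, min(n, K) + 1):
        num += comb(K, i) * comb(N - K, n - i)
    return num / denom


def links_equal(l1, l2, ignore_type, ignore_direction):
    """Pairwise link equality, defined independently of LinkKey.

    Two links are equal when their (possibly erased) types match and their
    endpoints match under the direction policy: interactions are always
    unordered; directed types are unordered only when direction is ignored.
    """
    from signet.model import LinkType

    t1 = l1.link_type if not ignore_type else None
    t2 = l2.link_type if not ignore_type else None
    if t1 != t2:
        return False
    und1 = (l1.link_type is LinkType.INTERACTION) or ignore_direction
    und2 = (l2.link_type is LinkType.INTERACTION) or ignore_direction
    if und1 != und2:
        return False
    e1 = (l1.source, l1.target)
    e2 = (l2.source, l2.target)
    if und1:
        return set(e1) == set(e2)
    return e1 == e2


def network_adjacency(net):
    """Undirected simple adjacency built directly from the link records."""
    adj = {sym: set() for sym in net.nodes}
    for link in net.links:
        if link.source != link.target:
            adj[link.source].add(link.target)
            adj[link.target].add(link.source)
    return adj
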