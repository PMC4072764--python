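"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive (enumeration, recursion over plain
dicts) and shares no code path with the package implementation.
"""

from __future__ import annotations

import math
from itertools import combinations


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), by direct pmf summation."""
    total = math.comb(N, n)
    acc = 0
    for x in range(max(k, 0), min(n, K) + 1):
        if n - x <= N - K:
            acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def ease_bruteforce(k: int, n: int, K: int, N: int) -> float:
    """EASE: upper tail with the overlap decremented by one; k = 0 gives 1."""
    if k == 0:
        return 1.0
    return min(1.0, hypergeom_upper_tail(k - 1, n, K, N))


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg by the textbook step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


def ancestors_recursive(term: str, parents: dict[str, set[str]]) -> set[str]:
    """Term plus all ancestors, by plain recursion over the parent dict."""
    out = {term}
    for p in parents[term]:
        out |= ancestors_recursive(p, parents)
    return out


def resnik_bruteforce(t1: str, t2: str, parents: dict[str, set[str]],
                      ic: dict[str, float]) -> float:
    """Max finite IC over the exhaustive common-ancestor intersection."""
    common = ancestors_recursive(t1, parents) & ancestors_recursive(t2, parents)
    finite = [ic[t] for t in common if math.isfinite(ic[t])]
    return max(finite, default=0.0)


def ic_bruteforce(parents: dict[str, set[str]], root: str,
                  direct: dict[str, set[str]]) -> dict[str, float]:
    """IC by counting, per term, genes annotated to it or any descendant.

    ``direct`` maps gene -> direct term set; every gene counts towards the
    root regardless (forced root annotation).
    """
    genes_at: dict[str, set[str]] = {t: set() for t in parents}
    for gene, terms in direct.items():
        genes_at[root].add(gene)
        for t in terms:
            for anc in ancestors_recursive(t, parents):
                genes_at[anc].add(gene)
    root_n = len(genes_at[root])
    out = {}
    for t in parents:
        n = len(genes_at[t])
        out[t] = math.inf if n == 0 or root_n == 0 else -math.log(n / root_n)
    return out


def connectivity_bruteforce(n_nodes: int, edges: set[tuple[int, int]]):
    """(mean local clustering, #connected nodes, #components>=2, avg degree).

    Triangle counting per node and DFS component labelling over adjacency
    sets; isolated nodes are dropped first, mirroring induced-network
    semantics.
    """
    adj = {i: set() for i in range(n_nodes)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    connected = [i for i in adj if adj[i]]
    if not connected:
        return 0.0, 0, 0, 0.0
    cc_sum = 0.0
    for i in connected:
        nb = sorted(adj[i])
        if len(nb) < 2:
            continue
        links = sum(1 for a, b in combinations(nb, 2) if b in adj[a])
        cc_sum += 2.0 * links / (len(nb) * (len(nb) - 1))
    seen: set[int] = set()
    n_comp = 0
    for i in connected:
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        if len(comp) >= 2:
            n_comp += 1
    n_edges = len(edges)
    return (cc_sum / len(connected), len(connected), n_comp,
            2.0 * n_edges / len(connected))


def wilcoxon_exact_less(diffs: list[float]) -> float:
    """One-sided exact signed-rank p (alternative: median < 0).

    Enumerates all 2^n sign assignments of the ranked |differences|;
    requires distinct non-zero magnitudes.
    """
    mags = sorted(abs(d) for d in diffs)
    assert all(m > 0 for m in mags) and len(set(mags)) == len(mags)
    ranks = {m: r + 1 for r, m in enumerate(mags)}
    w_plus = sum(ranks[abs(d)] for d in diffs if d > 0)
    n = len(diffs)
    count = 0
    for mask in range(2 ** n):
        w = sum(r + 1 for r in range(n) if mask >> r & 1)
        if w <= w_plus:
            count += 1
    return count / 2 ** n


def project_bruteforce(human_edges, reverse: dict[str, set[str]]) -> set[tuple[str, str]]:
    """Expected projected fly pairs: all cross products minus self-pairs."""
    out = set()
    for h1, h2 in human_edges:
        if h1 == h2:
            continue
        for a in reverse.get(h1, set()):
            for b in reverse.get(h2, set()):
                if a != b:
                    out.add(tuple(sorted((a, b))))
    return out
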