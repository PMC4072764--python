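"""Connectivity of candidate gene sets against a Monte Carlo random-set null.

A candidate set's induced subgraph is summarised by three statistics —
mean local clustering coefficient, number of connected nodes (degree >= 1)
and average neighbours per connected node — plus the count of non-trivial
connected components.  The null distribution comes from repeatedly sampling
equally sized random gene sets from the screened universe and recomputing
the same statistics; the observed values are compared to the null with a
one-sided one-sample Wilcoxon signed-rank test (the null samples are
typically far from normal, which a Kolmogorov-Smirnov check makes explicit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from scipy import stats

#: the three statistics tested against the null
TESTED_STATS = ("clustering_coefficient", "n_connected_nodes", "avg_neighbors")


@dataclass(frozen=True)
class ConnectivityStats:
    clustering_coefficient: float
    n_connected_nodes: int
    n_components: int          # components with >= 2 nodes
    avg_neighbors: float

    def as_dict(self) -> dict[str, float]:
        return {
            "clustering_coefficient": self.clustering_coefficient,
            "n_connected_nodes": self.n_connected_nodes,
            "n_components": self.n_components,
            "avg_neighbors": self.avg_neighbors,
        }


@dataclass
class NullDistribution:
    """Per-statistic samples over Monte Carlo random gene sets."""

    samples: dict[str, np.ndarray]
    universe_size: int
    set_size: int
    seed: int

    @property
    def n_iter(self) -> int:
        return len(next(iter(self.samples.values())))


@dataclass(frozen=True)
class SignificanceResult:
    """Observed-vs-null comparison for one connectivity statistic.

    ``p`` is the one-sided one-sample Wilcoxon signed-rank p-value of the
    null samples against the observed value.  Because the observed value is
    itself one draw when there is no real module, the Wilcoxon p is
    anti-conservative as a set-level significance measure; ``p_empirical``
    is the calibrated permutation-style tail probability
    ``(1 + #{null >= observed}) / (n_iter + 1)``, uniform under the null.
    """

    fold_over_median: float    # nan when the null median is zero
    p: float
    p_empirical: float = 1.0
    degenerate: bool = False


def induced_network(candidates: set[str], network: nx.Graph) -> nx.Graph:
    """Subgraph induced by ``candidates`` with isolated candidates removed.

    Mirrors how interaction databases present gene-set networks: genes
    without any reported interaction inside the set simply do not appear
    as nodes.
    """
    sub = network.subgraph(candidates)
    connected = [n for n, d in sub.degree() if d >= 1]
    return nx.Graph(sub.subgraph(connected))


def connectivity_stats(network: nx.Graph) -> ConnectivityStats:
    """The three connectivity statistics plus the component count.

    The clustering coefficient is the mean Watts-Strogatz local coefficient
    over all nodes of the (isolate-free) graph, nodes of degree < 2
    contributing zero.  ``avg_neighbors`` is the mean degree over connected
    nodes, i.e. 2|E| / #connected.
    """
    degrees = dict(network.degree())
    connected = [n for n, d in degrees.items() if d >= 1]
    if not connected:
        return ConnectivityStats(0.0, 0, 0, 0.0)
    sub = network.subgraph(connected)
    cc = nx.average_clustering(sub)
    n_edges = sub.number_of_edges()
    n_components = sum(1 for comp in nx.connected_components(sub) if len(comp) >= 2)
    return ConnectivityStats(
        clustering_coefficient=cc,
        n_connected_nodes=len(connected),
        n_components=n_components,
        avg_neighbors=2.0 * n_edges / len(connected),
    )


def monte_carlo_null(
    universe: Sequence[str] | set[str],
    network: nx.Graph,
    set_size: int = 358,
    n_iter: int = 100,
    seed: int = 0,
) -> NullDistribution:
    """Null connectivity from random gene sets drawn from the universe.

    Each iterate samples ``set_size`` genes uniformly without replacement
    (from *all* supplied genes, not only those with interactions), builds
    the induced network and records every statistic.  Deterministic per seed.
    """
    pool = np.array(sorted(universe))
    if set_size > len(pool):
        raise ValueError(f"set_size {set_size} exceeds universe size {len(pool)}")
    rng = np.random.default_rng(seed)
    keys = ("clustering_coefficient", "n_connected_nodes", "n_components", "avg_neighbors")
    samples: dict[str, list[float]] = {k: [] for k in keys}
    for _ in range(n_iter):
        genes = set(rng.choice(pool, size=set_size, replace=False))
        st = connectivity_stats(induced_network(genes, network)).as_dict()
        for k in keys:
            samples[k].append(st[k])
    return NullDistribution(
        samples={k: np.asarray(v, dtype=float) for k, v in samples.items()},
        universe_size=len(pool),
        set_size=set_size,
        seed=seed,
    )


def wilcoxon_one_sample(values: np.ndarray, reference: float,
                        alternative: str = "less") -> tuple[float, bool]:
    """One-sample Wilcoxon signed-rank p-value of ``values`` vs a reference.

    ``alternative='less'`` tests whether values tend to fall *below* the
    reference.  Exact distribution for n <= 25 when differences are free of
    zeros and ties; otherwise the normal approximation with zero-dropping
    and tie-corrected variance.  Returns ``(p, degenerate)``; an all-zero
    difference vector is degenerate with p = 1.
    """
    d = np.asarray(values, dtype=float) - reference
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0, True
    exact_ok = nz.size <= 25 and d.size == nz.size and len(np.unique(np.abs(nz))) == nz.size
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative=alternative,
                         method=method, correction=(method == "approx"))
    return float(res.pvalue), False


def significance(
    observed: ConnectivityStats,
    null: NullDistribution,
    statistics: Sequence[str] = TESTED_STATS,
) -> dict[str, SignificanceResult]:
    """Fold-over-null-median and Wilcoxon p for each connectivity statistic.

    The one-sided alternative is that the observed set is *more* connected
    than random sets, i.e. the null values fall below the observed value.
    """
    obs = observed.as_dict()
    out: dict[str, SignificanceResult] = {}
    for key in statistics:
        sample = null.samples[key]
        med = float(np.median(sample))
        fold = obs[key] / med if med != 0 else math.nan
        p, degenerate = wilcoxon_one_sample(sample, obs[key], alternative="less")
        p_emp = (1.0 + np.count_nonzero(sample >= obs[key])) / (sample.size + 1.0)
        out[key] = SignificanceResult(fold_over_median=fold, p=p,
                                      p_empirical=float(p_emp), degenerate=degenerate)
    return out


def ks_normality(sample: Sequence[float]) -> tuple[float, bool]:
    """One-sample KS p-value against a normal fit to the sample.

    Returns ``(p, degenerate)``; a constant sample has no normal fit and is
    flagged degenerate with p = 0.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality check needs at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0, True
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.pvalue), False
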