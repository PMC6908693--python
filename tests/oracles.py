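"""Independent brute-force oracles shared by unit and acceptance tests.

Everything here is deliberately naive (full enumeration, textbook
formulas) and shares no code with the implementation it checks.
"""

import itertools

import networkx as nx
import numpy as np
from scipy.stats import spearmanr


def set_partitions(items):
    """All partitions of a list, via restricted-growth enumeration."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for k in range(len(partition)):
            yield partition[:k] + [[first] + partition[k]] + partition[k + 1 :]
        yield [[first]] + partition


def best_modularity_partition(graph: nx.Graph):
    """Exhaustive maximization of Newman modularity over all partitions."""
    nodes = list(graph.nodes)
    best_q, best = -np.inf, None
    for partition in set_partitions(nodes):
        q = nx.community.modularity(graph, [set(p) for p in partition])
        if q > best_q:
            best_q, best = q, partition
    return best_q, best


def spearman_brute_force_p(x, y):
    """Exact two-tailed permutation p for Spearman rho by full enumeration."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    rho_obs = spearmanr(x, y).statistic
    count = total = 0
    for perm in itertools.permutations(y):
        rho = spearmanr(x, perm).statistic
        total += 1
        count += abs(rho) >= abs(rho_obs) - 1e-12
    return rho_obs, count / total
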