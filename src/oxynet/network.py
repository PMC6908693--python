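"""Chemically annotated diatom co-variation networks.

Water-mass windows are detected from salinity persistence; within each
window, pairwise Spearman rank correlations between diatom taxa are
screened at |rho| >= 0.7 and p < 0.05 (exact permutation p for short
windows, t-approximation otherwise); significant pairs become signed
edges.  The positive-edge subgraph is partitioned into modules by
modularity maximization, edges are annotated with the mean per-cell
production of each oxylipin precursor class over their source window,
and module-wise enrichment is tested against a reshuffled null with
F-test-gated t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .errors import DataError
from .quant import PRECURSORS

log = logging.getLogger(__name__)

CLASS_COLUMNS = [f"{p}-derived" for p in PRECURSORS]
EXACT_P_MAX_N = 9  # full n! enumeration up to here
LOW_SUPPORT_N = 5  # edges from windows shorter than this are flagged


@dataclass
class WaterMassWindow:
    label: str
    weeks: list[str]
    salinity_mean: float
    salinity_half_range: float

    def __len__(self) -> int:
        return len(self.weeks)


def detect_water_masses(
    salinity: pd.Series, tolerance: float = 0.15, min_len: int = 3
) -> list[WaterMassWindow]:
    """Maximal runs of consecutive weeks with salinity spread <= 2*tolerance.

    Candidate intervals are scored greedily longest-first (ties: earliest);
    overlapping candidates are discarded, so the returned windows are
    disjoint.  Missing weeks break runs.
    """
    s = pd.Series(salinity).astype(float)
    if s.empty:
        raise DataError("empty salinity series")
    values = s.to_numpy()
    n = len(values)

    candidates = []  # (length, start, end) inclusive
    for i in range(n):
        if np.isnan(values[i]):
            continue
        lo = hi = values[i]
        for j in range(i + 1, n):
            if np.isnan(values[j]):
                break
            lo, hi = min(lo, values[j]), max(hi, values[j])
            if hi - lo > 2 * tolerance:
                break
            if j - i + 1 >= min_len:
                candidates.append((j - i + 1, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1]))

    taken = np.zeros(n, dtype=bool)
    windows = []
    for length, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        chunk = values[i : j + 1]
        windows.append((i, j, chunk))
    windows.sort(key=lambda w: w[0])
    return [
        WaterMassWindow(
            label=f"P{k + 1}",
            weeks=list(s.index[i : j + 1]),
            salinity_mean=float(chunk.mean()),
            salinity_half_range=float((chunk.max() - chunk.min()) / 2.0),
        )
        for k, (i, j, chunk) in enumerate(windows)
    ]


@dataclass
class EdgeRecord:
    taxa: tuple[str, str]  # sorted
    rho: float
    p: float
    sign: int  # +1 / -1
    periods: list[str]
    n_weeks: int
    low_support: bool = False
    annotations: dict[str, float] = field(default_factory=dict)


@lru_cache(maxsize=8)
def _perm_index(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))), dtype=np.int8)


def spearman_exact_p(r1: np.ndarray, r2: np.ndarray) -> tuple[float, float]:
    """Spearman rho and its exact two-tailed permutation p.

    Enumerates all n! orderings of one rank vector against the other;
    p = P(|rho_perm| >= |rho_obs|).  Midranks handle ties.
    """
    n = len(r1)
    z1 = (r1 - r1.mean())
    z2 = (r2 - r2.mean())
    denom = np.sqrt((z1 ** 2).sum() * (z2 ** 2).sum())
    if denom == 0:
        raise DataError("constant series in Spearman pair")
    rho = float(z1 @ z2 / denom)
    perms = _perm_index(n)
    rho_all = (z2[perms] @ z1) / denom
    p = float((np.abs(rho_all) >= abs(rho) - 1e-12).mean())
    return rho, p


def spearman_t_p(rho: float, n: int) -> float:
    """Two-tailed p from the t-approximation with df = n - 2."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    return float(2 * stats.t.sf(abs(t), n - 2))


def spearman_edges(
    abundance: pd.DataFrame,
    window: WaterMassWindow,
    rho_min: float = 0.7,
    alpha: float = 0.05,
    p_method: str = "t",
) -> list[EdgeRecord]:
    """Significant Spearman co-variations within one water-mass window.

    Taxa with all-zero abundance in the window are skipped; so are pairs
    with a constant member (rho undefined).  ``p_method`` selects the
    p-value: ``"t"`` (default) uses the t-approximation with df = n - 2,
    since an exact test cannot reach p < 0.05 from a 3-week window;
    ``"exact"`` enumerates all n! orderings (n <= 9); ``"auto"`` picks
    exact when feasible.  Edges from windows shorter than 5 weeks are
    flagged low-support regardless.
    """
    weeks = [w for w in window.weeks if w in abundance.columns]
    if len(weeks) < 3:
        raise DataError(f"window {window.label} has < 3 usable weeks")
    sub = abundance[weeks]
    active = sub.index[(sub > 0).any(axis=1)]
    sub = sub.loc[active]
    ranks = sub.rank(axis=1, method="average")
    n = len(weeks)
    if p_method not in ("t", "exact", "auto"):
        raise DataError(f"unknown p_method '{p_method}'")
    use_exact = (p_method == "exact") or (p_method == "auto" and n <= EXACT_P_MAX_N)
    if use_exact and n > EXACT_P_MAX_N:
        raise DataError(f"exact enumeration infeasible for n = {n}")

    edges: list[EdgeRecord] = []
    rank_arr = ranks.to_numpy()
    taxa = list(sub.index)
    for a, b in combinations(range(len(taxa)), 2):
        r1, r2 = rank_arr[a], rank_arr[b]
        if np.ptp(r1) == 0 or np.ptp(r2) == 0:
            log.info("skipping constant pair (%s, %s) in %s", taxa[a], taxa[b], window.label)
            continue
        if use_exact:
            rho, p = spearman_exact_p(r1, r2)
        else:
            z1, z2 = r1 - r1.mean(), r2 - r2.mean()
            rho = float(z1 @ z2 / np.sqrt((z1 ** 2).sum() * (z2 ** 2).sum()))
            p = spearman_t_p(rho, n)
        if abs(rho) >= rho_min and p < alpha:
            pair = tuple(sorted((taxa[a], taxa[b])))
            edges.append(
                EdgeRecord(
                    taxa=pair,
                    rho=rho,
                    p=p,
                    sign=1 if rho > 0 else -1,
                    periods=[window.label],
                    n_weeks=n,
                    low_support=n < LOW_SUPPORT_N,
                )
            )
    return edges


@dataclass
class CovariationNetwork:
    graph: nx.Graph  # nodes carry node_id; edges carry the EdgeRecord
    node_ids: dict[str, int]
    modules: dict[str, int | None] = field(default_factory=dict)
    modularity_q: float | None = None

    @property
    def edges(self) -> list[EdgeRecord]:
        return [d["record"] for _, _, d in self.graph.edges(data=True)]

    def degree_table(self) -> pd.DataFrame:
        rows = []
        for node in self.graph.nodes:
            pos = sum(1 for _, _, d in self.graph.edges(node, data=True) if d["record"].sign > 0)
            neg = sum(1 for _, _, d in self.graph.edges(node, data=True) if d["record"].sign < 0)
            rows.append((node, self.node_ids[node], pos, neg, pos + neg,
                         self.modules.get(node)))
        return pd.DataFrame(
            rows, columns=["taxon", "node_id", "positive_degree", "negative_degree",
                           "degree", "module"]
        ).set_index("taxon")


def build_network(edges: list[EdgeRecord], taxa: list[str]) -> CovariationNetwork:
    """Assemble the signed graph; duplicate pairs across periods merge.

    A pair significant in several windows becomes one edge keeping the
    strongest correlation (largest |rho|, smallest p) so the inclusion rule
    |rho| >= 0.7, p < 0.05 stays auditable; its chemical annotations later
    average across all source periods.  Isolated taxa stay in the node set
    (module-less).
    """
    taxa = list(taxa)
    known = set(taxa)
    g = nx.Graph()
    node_ids = {t: i + 1 for i, t in enumerate(taxa)}
    g.add_nodes_from(taxa)
    merged: dict[tuple[str, str], EdgeRecord] = {}
    for e in edges:
        if e.taxa[0] == e.taxa[1]:
            raise DataError(f"self-edge on {e.taxa[0]}")
        if not set(e.taxa) <= known:
            raise DataError(f"edge taxa {e.taxa} not in taxa list")
        if e.taxa in merged:
            prev = merged[e.taxa]
            strongest = e if abs(e.rho) > abs(prev.rho) else prev
            merged[e.taxa] = EdgeRecord(
                taxa=e.taxa,
                rho=strongest.rho,
                p=min(prev.p, e.p),
                sign=strongest.sign,
                periods=prev.periods + e.periods,
                n_weeks=max(prev.n_weeks, e.n_weeks),
                low_support=prev.low_support and e.low_support,
            )
        else:
            merged[e.taxa] = e
    for rec in merged.values():
        g.add_edge(*rec.taxa, record=rec)
    return CovariationNetwork(g, node_ids)


def _partition_modularity(g: nx.Graph, communities) -> float:
    return nx.community.modularity(g, communities)


def find_modules(
    network: CovariationNetwork, seed: int = 0, resolution: float = 1.0,
    restarts: int = 8,
) -> CovariationNetwork:
    """Louvain-style modularity maximization on the positive-edge subgraph.

    Runs several seeded Louvain restarts plus greedy agglomeration and
    keeps the best-Q partition.  Negative edges do not enter the
    modularity objective (it is ill-defined for them) but stay in the
    network for degree tallies and annotation.  Nodes outside the positive
    subgraph get no module label.
    """
    pos = nx.Graph()
    pos.add_edges_from(
        (u, v) for u, v, d in network.graph.edges(data=True) if d["record"].sign > 0
    )
    modules: dict[str, int | None] = {t: None for t in network.graph.nodes}
    if pos.number_of_edges() == 0:
        network.modules = modules
        network.modularity_q = 0.0
        return network

    best, best_q = None, -np.inf
    seeds = np.random.SeedSequence(seed).generate_state(restarts)
    for s in seeds:
        comms = nx.community.louvain_communities(pos, resolution=resolution, seed=int(s % (2**31)))
        q = _partition_modularity(pos, comms)
        if q > best_q + 1e-12:
            best, best_q = comms, q
    greedy = list(nx.community.greedy_modularity_communities(pos, resolution=resolution))
    q = _partition_modularity(pos, greedy)
    if q > best_q + 1e-12:
        best, best_q = greedy, q

    # deterministic labels: modules ordered by size then smallest node id
    ordered = sorted(best, key=lambda c: (-len(c), min(network.node_ids[t] for t in c)))
    for label, comm in enumerate(ordered):
        for t in comm:
            modules[t] = label
    network.modules = modules
    network.modularity_q = float(best_q)
    return network


def annotate_edges(
    edges: list[EdgeRecord],
    class_fg_per_cell: pd.DataFrame,
    windows: list[WaterMassWindow],
) -> list[EdgeRecord]:
    """Attach mean per-cell production of each precursor class to edges.

    For every source period of an edge, the mean fg/cell of each class
    over that window's weeks is computed (missing weeks skipped); an edge
    spanning several periods carries the across-period mean.
    """
    by_label = {w.label: w for w in windows}
    period_means: dict[str, dict[str, float]] = {}
    for label, w in by_label.items():
        weeks = [wk for wk in w.weeks if wk in class_fg_per_cell.index]
        sub = class_fg_per_cell.loc[weeks, CLASS_COLUMNS] if weeks else None
        period_means[label] = (
            {c: float(sub[c].mean()) for c in CLASS_COLUMNS} if sub is not None else {}
        )
    for e in edges:
        unknown = [p for p in e.periods if p not in by_label]
        if unknown:
            raise DataError(f"edge {e.taxa} references unknown period(s) {unknown}")
        per_period = [period_means[p] for p in e.periods]
        ann = {}
        for c in CLASS_COLUMNS:
            vals = [m[c] for m in per_period if c in m and np.isfinite(m[c])]
            ann[c] = float(np.mean(vals)) if vals else np.nan
        e.annotations = ann
    return edges


@dataclass
class NullTestResult:
    module: int
    class_label: str
    observed_mean: float
    null_mean: float
    t_stat: float
    df: float
    p: float
    f_test_p: float
    equal_variance: bool
    n_observed: int
    n_null: int
    reshuffles: int
    seed: int


def _intra_module_values(network: CovariationNetwork, class_label: str):
    """(module -> annotation values of its intra-module edges)."""
    out: dict[int, list[float]] = {}
    for u, v, d in network.graph.edges(data=True):
        mu, mv = network.modules.get(u), network.modules.get(v)
        if mu is None or mu != mv:
            continue
        val = d["record"].annotations.get(class_label, np.nan)
        if np.isfinite(val):
            out.setdefault(mu, []).append(val)
    return out


def variance_f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed F-test for variance equality."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb if va > vb else vb / va
    dfn = (len(a) - 1) if va > vb else (len(b) - 1)
    dfd = (len(b) - 1) if va > vb else (len(a) - 1)
    return float(min(1.0, 2 * stats.f.sf(f, dfn, dfd)))


def pooled_null_samples(
    network: CovariationNetwork,
    class_label: str,
    reshuffles: int = 1000,
    seed: int = 0,
) -> dict[int, list[np.ndarray]]:
    """Per-module null samples from reshuffled annotation networks.

    Each reshuffle permutes the intra-module edge annotations across
    modules (so every reshuffle conserves the annotation multiset exactly)
    and records the values landing in each module.  Modules with fewer
    than 2 intra-module edges are skipped.
    """
    per_module = _intra_module_values(network, class_label)
    eligible = {m: v for m, v in per_module.items() if len(v) >= 2}
    if len(eligible) < 2:
        raise DataError("need >= 2 modules with >= 2 intra-module edges")
    skipped = sorted(set(per_module) - set(eligible))
    if skipped:
        log.info("modules skipped in null test (<2 intra-module edges): %s", skipped)

    modules_sorted = sorted(eligible)
    all_values = np.concatenate([np.asarray(eligible[m], dtype=float) for m in modules_sorted])
    slices, start = {}, 0
    for m in modules_sorted:
        slices[m] = slice(start, start + len(eligible[m]))
        start += len(eligible[m])

    rng = np.random.default_rng(seed)
    pooled: dict[int, list[np.ndarray]] = {m: [] for m in modules_sorted}
    for _ in range(reshuffles):
        shuffled = rng.permutation(all_values)
        for m in modules_sorted:
            pooled[m].append(shuffled[slices[m]])
    return pooled


def null_module_test(
    network: CovariationNetwork,
    class_label: str,
    reshuffles: int = 1000,
    seed: int = 0,
) -> list[NullTestResult]:
    """Module-wise enrichment of a LOFA class against a reshuffled null.

    The observed sample for module m holds the class annotations of its
    intra-module edges (size n1).  Null networks permute all intra-module
    annotations across modules; the values landing in m are pooled over
    reshuffles and subsampled back to n1.  An F-test at alpha = 0.05
    decides between the pooled-variance t-test (df = n1 + n2 - 2) and
    Welch's test; p is two-tailed.
    """
    per_module = _intra_module_values(network, class_label)
    eligible = {m: v for m, v in per_module.items() if len(v) >= 2}
    pooled_null = pooled_null_samples(network, class_label, reshuffles, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    results = []
    for m in sorted(eligible):
        obs = np.asarray(eligible[m], dtype=float)
        null_pool = np.concatenate(pooled_null[m])
        null = rng.choice(null_pool, size=len(obs), replace=False)
        f_p = variance_f_test(obs, null)
        equal_var = f_p >= 0.05
        if np.var(obs) == 0 and np.var(null) == 0 and obs.mean() == null.mean():
            t_stat, p, df = 0.0, 1.0, len(obs) + len(null) - 2
        else:
            t_res = stats.ttest_ind(obs, null, equal_var=equal_var)
            t_stat, p = float(t_res.statistic), float(t_res.pvalue)
            df = (len(obs) + len(null) - 2) if equal_var else float(t_res.df)
        results.append(
            NullTestResult(
                module=m,
                class_label=class_label,
                observed_mean=float(obs.mean()),
                null_mean=float(null.mean()),
                t_stat=t_stat,
                df=float(df),
                p=p,
                f_test_p=f_p,
                equal_variance=equal_var,
                n_observed=len(obs),
                n_null=len(obs),
                reshuffles=reshuffles,
                seed=seed,
            )
        )
    return results


def audit_edges(network: CovariationNetwork, rho_min: float = 0.7, alpha: float = 0.05) -> bool:
    """Post-hoc check that every stored edge meets the inclusion rule."""
    return all(abs(e.rho) >= rho_min and e.p < alpha for e in network.edges)


def degree_summary(network: CovariationNetwork) -> dict[str, float]:
    """Average positive/negative degree over non-isolated nodes."""
    table = network.degree_table()
    active = table[table["degree"] > 0]
    if active.empty:
        return {"n_nodes": len(table), "n_connected": 0,
                "avg_positive_degree": 0.0, "avg_negative_degree": 0.0}
    return {
        "n_nodes": len(table),
        "n_connected": int(len(active)),
        "avg_positive_degree": float(active["positive_degree"].mean()),
        "avg_negative_degree": float(active["negative_degree"].mean()),
    }


def edge_list_frame(network: CovariationNetwork) -> pd.DataFrame:
    rows = []
    for e in network.edges:
        a, b = e.taxa
        rows.append(
            {
                "taxon_a": a,
                "taxon_b": b,
                "rho": e.rho,
                "p": e.p,
                "sign": e.sign,
                "period": "+".join(e.periods),
                "low_support": e.low_support,
                "htra_fgcell": e.annotations.get("HTrA-derived", np.nan),
                "epa_fgcell": e.annotations.get("EPA-derived", np.nan),
                "dha_fgcell": e.annotations.get("DHA-derived", np.nan),
                "module_a": network.modules.get(a),
                "module_b": network.modules.get(b),
            }
        )
    return pd.DataFrame(rows)


def write_graphml(network: CovariationNetwork, path) -> None:
    g = nx.Graph()
    for t in network.graph.nodes:
        g.add_node(
            t,
            node_id=network.node_ids[t],
            module=-1 if network.modules.get(t) is None else int(network.modules[t]),
        )
    for e in network.edges:
        g.add_edge(
            *e.taxa,
            rho=float(e.rho),
            p=float(e.p),
            sign=int(e.sign),
            period="+".join(e.periods),
        )
    nx.write_graphml(g, path)
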