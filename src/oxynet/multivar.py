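"""Community-composition statistics.

Dissimilarity (Bray-Curtis on raw counts, Jaccard on presence/absence),
rank-based one-way ANOSIM with a balanced design, SIMPER decomposition of
between-group dissimilarity, and non-metric multidimensional scaling.

The ANOSIM engine enumerates *all* distinct relabellings of the design
whenever there are no more of them than the requested permutation count,
in which case the reported p-value is exact; otherwise it falls back to
Monte Carlo sampling with the (1 + hits) / (N + 1) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, factorial, prod

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import smacof

from .errors import DataError


@dataclass
class DissimilarityMatrix:
    values: pd.DataFrame  # square, symmetric, zero diagonal, entries in [0, 1]
    metric: str

    @property
    def ids(self) -> pd.Index:
        return self.values.index

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(), checks=False)

    def subset(self, ids) -> "DissimilarityMatrix":
        return DissimilarityMatrix(self.values.loc[ids, ids], self.metric)


def _check_abundance(matrix: pd.DataFrame) -> None:
    if (matrix.to_numpy() < 0).any():
        raise DataError("abundance matrix contains negative entries")
    if matrix.shape[1] < 2:
        raise DataError("need >= 2 samples")


def bray_curtis(matrix: pd.DataFrame) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between samples (columns).

    d(j,k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik); a pair of all-zero
    samples is defined as identical (d = 0).
    """
    _check_abundance(matrix)
    x = matrix.to_numpy(dtype=float).T  # samples x taxa
    with np.errstate(invalid="ignore"):
        d = pdist(x, metric="braycurtis")
    d = np.nan_to_num(d, nan=0.0)  # all-zero pair -> 0
    return DissimilarityMatrix(
        pd.DataFrame(squareform(d), index=matrix.columns, columns=matrix.columns),
        "braycurtis",
    )


def jaccard(matrix: pd.DataFrame) -> DissimilarityMatrix:
    """Jaccard dissimilarity on presence/absence (binarized at > 0)."""
    _check_abundance(matrix)
    x = (matrix.to_numpy(dtype=float).T > 0)
    d = pdist(x, metric="jaccard")
    return DissimilarityMatrix(
        pd.DataFrame(squareform(d), index=matrix.columns, columns=matrix.columns),
        "jaccard",
    )


@dataclass
class AnosimResult:
    r: float
    p: float
    permutations: int
    method: str  # "exact" or "montecarlo"
    pairwise: dict = field(default_factory=dict)  # (g1, g2) -> AnosimResult


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    if within.all() or (~within).all():
        raise DataError("ANOSIM needs both within- and between-group pairs")
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (m / 2.0)


def _distinct_relabellings(counts: list[int]) -> int:
    n = sum(counts)
    return factorial(n) // prod(factorial(c) for c in counts)


def _enumerate_assignments(counts: np.ndarray) -> np.ndarray:
    """All distinct label vectors with the given group sizes (labels 0..k-1)."""
    n = int(counts.sum())
    out = []

    def rec(positions: tuple[int, ...], g: int, labels: np.ndarray):
        if g == len(counts) - 1:
            lab = labels.copy()
            lab[list(positions)] = g
            out.append(lab)
            return
        for chosen in combinations(positions, int(counts[g])):
            lab = labels.copy()
            lab[list(chosen)] = g
            rest = tuple(p for p in positions if p not in set(chosen))
            rec(rest, g + 1, lab)

    if len(counts) == 1:
        out.append(np.zeros(n, dtype=np.int64))
    else:
        rec(tuple(range(n)), 0, np.full(n, len(counts) - 1, dtype=np.int64))
    return np.asarray(out)


def _batch_r(ranks: np.ndarray, labels: np.ndarray, iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    """ANOSIM R for each row of a (K, n) label matrix, vectorised."""
    m = ranks.size
    same = labels[:, iu] == labels[:, ju]  # K x M
    n_within = same.sum(axis=1)
    total = ranks.sum()
    sum_within = same @ ranks
    rw = sum_within / n_within
    rb = (total - sum_within) / (m - n_within)
    return (rb - rw) / (m / 2.0)


def anosim(
    dist: DissimilarityMatrix,
    groups: pd.Series,
    permutations: int = 9999,
    seed: int = 0,
    pairwise: bool = False,
) -> AnosimResult:
    """One-way analysis of similarities on a distance matrix.

    All off-diagonal dissimilarities are ranked (midranks on ties);
    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2.  R near 0 means no separation, 1 complete separation.
    """
    groups = pd.Series(groups).reindex(dist.ids)
    if groups.isna().any():
        raise DataError("group labels missing for some samples")
    counts = groups.value_counts()
    if len(counts) < 2:
        raise DataError("ANOSIM needs >= 2 groups")
    if (counts < 2).any():
        raise DataError(f"singleton group(s): {counts[counts < 2].index.tolist()}")
    if permutations < 1:
        raise DataError("permutations must be >= 1")

    cond = dist.condensed()
    n = len(dist.ids)
    if np.allclose(cond, cond[0]):
        warnings.warn("constant distances; ANOSIM R = 0", stacklevel=2)
        return AnosimResult(0.0, 1.0, permutations, "degenerate")
    ranks = rankdata(cond)  # midranks
    iu, ju = np.triu_indices(n, k=1)
    codes = pd.Categorical(groups).codes.astype(np.int64)
    within = codes[iu] == codes[ju]
    r_obs = _anosim_r(ranks, within)

    group_sizes = [int(c) for c in counts.sort_index().values]
    n_exact = _distinct_relabellings(group_sizes)
    if n_exact <= permutations:
        labels = _enumerate_assignments(np.asarray(sorted(group_sizes)))
        r_all = _batch_r(ranks, labels, iu, ju)
        hits = int((r_all >= r_obs - 1e-12).sum())
        p = hits / n_exact
        method, n_perm = "exact", n_exact
    else:
        rng = np.random.default_rng(seed)
        perm = np.array([rng.permutation(codes) for _ in range(permutations)])
        r_all = _batch_r(ranks, perm, iu, ju)
        hits = int((r_all >= r_obs - 1e-12).sum())
        p = (1 + hits) / (permutations + 1)
        method, n_perm = "montecarlo", permutations

    result = AnosimResult(float(r_obs), float(p), n_perm, method)
    if pairwise:
        for g1, g2 in combinations(sorted(counts.index), 2):
            ids = groups.index[groups.isin([g1, g2])]
            sub = dist.subset(ids)
            result.pairwise[(g1, g2)] = anosim(
                sub, groups.loc[ids], permutations, seed, pairwise=False
            )
    return result


PAD_TAG = "__pad__"


def balance_groups(
    matrix: pd.DataFrame, groups: pd.Series
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Pad every group to the size of the largest with group-mean samples.

    The appended synthetic samples equal the group's taxon-wise mean (the
    "group means as missing observations" balancing device); their labels
    carry a ``__pad__`` marker so they can be excluded from SIMPER.
    Padding never changes a group's taxon-wise mean.
    """
    groups = pd.Series(groups).reindex(matrix.columns)
    if groups.isna().any():
        raise DataError("group labels missing for some samples")
    sizes = groups.value_counts()
    if (sizes < 1).any() or len(sizes) < 2:
        raise DataError("need >= 2 non-empty groups")
    target = int(sizes.max())
    out = matrix.copy()
    out_groups = groups.copy()
    padded: list[str] = []
    for g, size in sizes.items():
        if size == target:
            continue
        mean_col = matrix.loc[:, groups[groups == g].index].mean(axis=1)
        for k in range(target - int(size)):
            label = f"{g}{PAD_TAG}{k + 1}"
            out[label] = mean_col
            out_groups[label] = g
            padded.append(label)
    return out, out_groups, padded


@dataclass
class SimperResult:
    table: pd.DataFrame  # per-taxon average contribution / percent / cumulative
    groups: tuple[str, str]
    average_dissimilarity: float


def simper(matrix: pd.DataFrame, groups: pd.Series,
           pair: tuple[str, str] | None = None) -> SimperResult:
    """Per-taxon contributions to average between-group Bray-Curtis.

    For a between-group sample pair (j,k), taxon i contributes
    |x_ij - x_ik| / sum_s (x_sj + x_sk); contributions are averaged over
    all between-group pairs and expressed as percent of their sum (which
    equals the average between-group Bray-Curtis dissimilarity).
    """
    _check_abundance(matrix)
    groups = pd.Series(groups).reindex(matrix.columns)
    labels = sorted(groups.dropna().unique())
    if pair is None:
        if len(labels) != 2:
            raise DataError("simper needs exactly 2 groups or an explicit pair")
        pair = (labels[0], labels[1])
    a_ids = groups.index[groups == pair[0]]
    b_ids = groups.index[groups == pair[1]]
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise DataError(f"empty group in pair {pair}")
    xa = matrix[a_ids].to_numpy(dtype=float)
    xb = matrix[b_ids].to_numpy(dtype=float)
    contribs = np.zeros(matrix.shape[0])
    n_pairs = 0
    for j in range(xa.shape[1]):
        diff = np.abs(xa[:, [j]] - xb)  # taxa x |b|
        denom = (xa[:, [j]] + xb).sum(axis=0)
        ok = denom > 0
        contribs += np.where(ok, diff / np.where(ok, denom, 1.0), 0.0).sum(axis=1)
        n_pairs += xb.shape[1]
    contribs /= n_pairs
    avg_d = contribs.sum()
    percent = 100.0 * contribs / avg_d if avg_d > 0 else np.zeros_like(contribs)
    table = pd.DataFrame(
        {"contribution": contribs, "percent": percent}, index=matrix.index
    ).sort_values(["percent", "contribution"], ascending=False, kind="stable")
    # alphabetical tie-break for equal contributions
    table = table.sort_values("percent", ascending=False, kind="stable")
    table["cumulative_percent"] = table["percent"].cumsum()
    return SimperResult(table, pair, float(avg_d))


def simper_all(matrix: pd.DataFrame, groups: pd.Series) -> dict[tuple[str, str], SimperResult]:
    labels = sorted(pd.Series(groups).dropna().unique())
    return {
        (g1, g2): simper(matrix, groups, (g1, g2))
        for g1, g2 in combinations(labels, 2)
    }


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float  # Kruskal stress-1
    converged: bool
    restarts: int


def nmds(
    dist: DissimilarityMatrix,
    dims: int = 2,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1 over monotone disparities.

    Runs ``restarts`` random initializations and keeps the lowest-stress
    configuration; stress-1 = sqrt(sum (dhat - dstar)^2 / sum dhat^2) with
    dstar the isotonic regression of configuration distances on
    dissimilarity ranks.
    """
    if len(dist.ids) < 3:
        raise DataError("nMDS needs >= 3 samples")
    d = dist.values.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords, stress, n_iter = smacof(
            d,
            metric=False,
            n_components=dims,
            n_init=restarts,
            max_iter=max_iter,
            eps=tol,
            random_state=seed,
            normalized_stress=True,
            return_n_iter=True,
        )
    frame = pd.DataFrame(
        coords, index=dist.ids, columns=[f"nmds{k + 1}" for k in range(dims)]
    )
    return NmdsResult(frame, float(stress), bool(n_iter < max_iter), restarts)
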