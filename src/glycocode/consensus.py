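"""Subsampled consensus clustering.

Samples are repeatedly subsampled without replacement, partitioned with
PAM (partitioning around medoids, deterministic BUILD + SWAP) on the
1 - Pearson correlation distance, and co-clustering frequencies are
accumulated into a per-k consensus matrix.  The final partition cuts an
average-linkage tree on 1 - consensus, and k is selected from the
relative increase of the area under the consensus-CDF (delta-area rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .io import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "ConsensusRun",
    "median_center",
    "pearson_distance",
    "pam",
    "consensus_cluster",
    "select_k",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = v


@dataclass
class ConsensusRun:
    """Everything one consensus-clustering run produced, per candidate k."""

    ids: list[str]
    k_range: tuple[int, ...]
    consensus: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]
    cluster_consensus: dict[int, dict[int, float]]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    selected_k: int
    n_iterations: int
    subsample_fraction: float
    seed: int
    params: dict = field(default_factory=dict)


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median across samples (idempotent)."""
    if matrix.n_samples < 1:
        raise ValueError("need >= 1 sample")
    centred = matrix.values - np.median(matrix.values, axis=1, keepdims=True)
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), centred)


def pearson_distance(matrix: ExpressionMatrix) -> DistanceMatrix:
    """1 - Pearson correlation between sample columns (over genes)."""
    if matrix.n_genes < 2:
        raise ValueError("need >= 2 genes to correlate samples")
    values = matrix.values
    sd = values.std(axis=0)
    dead = np.where(sd == 0)[0]
    if dead.size:
        raise ValueError(
            f"zero-variance sample column(s): {[matrix.sample_ids[i] for i in dead[:5]]}"
        )
    r = np.corrcoef(values.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(list(matrix.sample_ids), d)


def pam(dist: DistanceMatrix | np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic PAM: greedy BUILD then best-improvement SWAP.

    Returns ``(labels, medoid_indices)``; labels index into the sorted
    medoid list.  All ties break toward the lowest index.
    """
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")

    # BUILD: first medoid minimises total distance, then max cost reduction
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        in_set = np.zeros(n, dtype=bool)
        in_set[medoids] = True
        reductions = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        reductions[in_set] = -np.inf
        best_c = int(np.argmax(reductions))
        medoids.append(best_c)
        nearest = np.minimum(nearest, d[:, best_c])

    # SWAP: repeat the best strictly improving medoid <-> non-medoid swap
    medoids = sorted(medoids)
    while True:
        med = np.array(medoids)
        dm = d[:, med]  # n x k
        if k > 1:
            order = np.argsort(dm, axis=1, kind="stable")
            near_j = order[:, 0]
            d1 = dm[np.arange(n), near_j]
            d2 = dm[np.arange(n), order[:, 1]]
        else:
            near_j = np.zeros(n, dtype=int)
            d1 = dm[:, 0]
            d2 = np.full(n, np.inf)
        current_cost = d1.sum()
        best = None  # (cost, m_pos, h)
        non_medoids = [h for h in range(n) if h not in set(medoids)]
        for m_pos in range(k):
            removed = near_j == m_pos
            base = np.where(removed, d2, d1)
            for h in non_medoids:
                cost = np.minimum(base, d[:, h]).sum()
                if cost < current_cost - 1e-12 and (best is None or cost < best[0] - 1e-12):
                    best = (cost, m_pos, h)
        if best is None:
            break
        _, m_pos, h = best
        medoids[m_pos] = h
        medoids = sorted(medoids)

    med = np.array(sorted(medoids))
    labels = np.argmin(d[:, med], axis=1)
    return labels, med


def _cdf_area(upper_entries: np.ndarray) -> float:
    """Area under the empirical CDF of consensus entries (step sum)."""
    xs = np.sort(upper_entries)
    m = xs.size
    if m < 2:
        return 0.0
    cdf_prev = np.arange(1, m + 1) / m  # CDF evaluated at each sorted value
    return float(np.sum(np.diff(xs) * cdf_prev[:-1]))


def consensus_cluster(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    n_iterations: int = 2000,
    subsample_fraction: float = 0.9,
    seed: int = 0,
    center: bool = True,
) -> ConsensusRun:
    """Consensus clustering of the samples of ``matrix``.

    Each iteration draws ``ceil(f * n)`` samples without replacement and
    runs PAM on their 1 - Pearson distance; consensus C(i, j) is the
    fraction of co-draws in which i and j co-clustered.  Per-iteration RNG
    streams are derived from ``(seed, k, iteration)`` so runs are
    reproducible and extending ``n_iterations`` keeps earlier iterations
    intact.
    """
    work = matrix if genes is None else matrix.subset_genes(genes)
    if center:
        work = median_center(work)
    n = work.n_samples
    k_range = tuple(sorted(k_range))
    if n < max(k_range) + 1:
        raise ValueError(f"need more samples than max(k_range) (n={n}, k={max(k_range)})")
    size = int(np.ceil(subsample_fraction * n))
    if size < max(k_range):
        raise ValueError("subsample smaller than the largest k")
    dist_full = pearson_distance(work).values

    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    cluster_consensus: dict[int, dict[int, float]] = {}
    for k in k_range:
        hits = np.zeros((n, n))
        draws = np.zeros((n, n))
        for h in range(n_iterations):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k, h)))
            chosen = np.sort(rng.choice(n, size=size, replace=False))
            sub = dist_full[np.ix_(chosen, chosen)]
            lab, _ = pam(sub, k)
            draws[np.ix_(chosen, chosen)] += 1.0
            same = lab[:, None] == lab[None, :]
            hits[np.ix_(chosen, chosen)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(draws > 0, hits / np.maximum(draws, 1), 0.0)
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
        consensus[k] = c

        link = sch.linkage(ssd.squareform(1.0 - c, checks=False), method="average")
        final = sch.fcluster(link, t=k, criterion="maxclust") - 1
        labels[k] = final
        cc: dict[int, float] = {}
        for cl in np.unique(final):
            members = np.where(final == cl)[0]
            if members.size > 1:
                block = c[np.ix_(members, members)]
                cc[int(cl)] = float(block[np.triu_indices(members.size, 1)].mean())
            else:
                cc[int(cl)] = 1.0
        cluster_consensus[k] = cc

    area = {k: _cdf_area(consensus[k][np.triu_indices(n, 1)]) for k in k_range}
    delta: dict[int, float] = {}
    for i, k in enumerate(k_range):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[k_range[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0

    run = ConsensusRun(
        ids=list(work.sample_ids),
        k_range=k_range,
        consensus=consensus,
        labels=labels,
        cluster_consensus=cluster_consensus,
        cdf_area=area,
        delta_area=delta,
        selected_k=0,
        n_iterations=n_iterations,
        subsample_fraction=subsample_fraction,
        seed=seed,
        params={"center": center},
    )
    run.selected_k = select_k(run)
    return run


def select_k(run: ConsensusRun, delta_min: float = 0.1) -> int:
    """Largest k whose delta-area is at least ``delta_min`` (fallback 2)."""
    if not run.k_range:
        raise ValueError("empty consensus run")
    chosen = run.k_range[0]
    for k in run.k_range:
        if k == run.k_range[0]:
            continue
        if run.delta_area[k] >= delta_min:
            chosen = k
    return int(chosen)
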