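"""Gene-set scoring.

* :func:`ss_enrichment` — single-sample enrichment in the GSVA style: a
  Gaussian-kernel cumulative gene-level statistic, per-sample gene
  ranking, and a weighted rank random-walk whose magnitude-difference
  extremum is the score.
* :func:`emt_score` — mesenchymal minus epithelial single-sample score.
* :func:`kruskal_wallis` — rank test of a score across clusters.
* :func:`gsea_two_class` — classic two-class GSEA with signal-to-noise
  ranking and phenotype-permutation null.
* :func:`module_score` — per-cell gene-set score against expression-bin
  matched control genes (single-cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "ScoreMatrix",
    "EnrichmentStats",
    "ss_enrichment",
    "emt_score",
    "kruskal_wallis",
    "gsea_two_class",
    "module_score",
]


@dataclass
class ScoreMatrix:
    """Gene-set x sample score block."""

    set_names: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValueError("score block does not match set/sample names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.set_names, columns=self.sample_ids)

    def row(self, name: str) -> np.ndarray:
        try:
            return self.values[self.set_names.index(name)]
        except ValueError:
            raise KeyError(name) from None


@dataclass
class EnrichmentStats:
    """Two-class GSEA results: per-set ES, NES, permutation p, BH q."""

    table: pd.DataFrame  # index set; columns es, nes, p, q, n_perm

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _kernel_statistic(values: np.ndarray) -> np.ndarray:
    """Gaussian-kernel cumulative statistic z_gi, gene-wise.

    z_gi = mean_j Phi((x_gi - x_gj) / h_g) with bandwidth h_g = s_g / 4
    (floored for constant genes); location-scale invariant per gene.
    """
    p, n = values.shape
    h = values.std(axis=1, ddof=1) / 4.0
    h = np.maximum(h, 1e-8)
    z = np.empty_like(values)
    for g in range(p):
        diff = (values[g][:, None] - values[g][None, :]) / h[g]
        z[g] = stats.norm.cdf(diff).mean(axis=1)
    return z


def _walk_es(order: np.ndarray, weights: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Magnitude-difference ES of the rank random-walk for one sample.

    ``order`` ranks genes best-first; ``weights`` are the rank weights
    d_g; ``in_set`` flags membership.
    """
    w = weights[order] ** tau
    members = in_set[order]
    denom_in = w[members].sum()
    p = order.size
    size = members.sum()
    step_in = np.where(members, w, 0.0)
    num = np.cumsum(step_in) / denom_in if denom_in > 0 else np.zeros(p)
    den = np.cumsum(~members) / (p - size)
    nu = num - den
    return float(max(nu.max(), 0.0) + min(nu.min(), 0.0))


def ss_enrichment(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    kernel: bool = True,
) -> ScoreMatrix:
    """Single-sample gene-set scores for every set in ``sets``.

    Per sample, genes are ordered by the kernel statistic (descending),
    weighted by the distance of their rank from the middle of the list
    (d = |p/2 - rank|), and walked: inside-set weighted steps up against
    uniform outside-set steps down.  The score is the magnitude
    difference of the walk's positive and negative extrema.
    """
    p = matrix.n_genes
    if p < 3:
        raise ValueError("need >= 3 genes")
    gene_set_members: dict[str, np.ndarray] = {}
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    for s in sets:
        inter = [g for g in s.members if g in gene_pos]
        if not inter:
            raise ValueError(f"gene set {s.name!r} has no genes in the matrix")
        if len(inter) >= p:
            raise ValueError(f"gene set {s.name!r} covers every gene in the matrix")
        flags = np.zeros(p, dtype=bool)
        flags[[gene_pos[g] for g in inter]] = True
        gene_set_members[s.name] = flags

    z = _kernel_statistic(matrix.values) if kernel else matrix.values
    scores = np.empty((len(gene_set_members), matrix.n_samples))
    for i in range(matrix.n_samples):
        order = np.argsort(-z[:, i], kind="stable")
        ranks = np.empty(p)
        ranks[order] = np.arange(1, p + 1)
        weights = np.abs(p / 2.0 - ranks)
        for si, flags in enumerate(gene_set_members.values()):
            scores[si, i] = _walk_es(order, weights, flags, tau)
    return ScoreMatrix(list(gene_set_members), list(matrix.sample_ids), scores)


def emt_score(
    scores: ScoreMatrix,
    epithelial_set: str = "EPITHELIAL",
    mesenchymal_set: str = "MESENCHYMAL",
) -> pd.Series:
    """EMT score = mesenchymal minus epithelial single-sample score.

    The sign convention puts mesenchymal-high (basal-like) samples high.
    """
    m = scores.row(mesenchymal_set)
    e = scores.row(epithelial_set)
    return pd.Series(m - e, index=scores.sample_ids, name="emt_score")


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across groups.

    Identical values in every group is not an error: H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    unique = np.unique(groups)
    if unique.size < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == g] for g in unique]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def _signal_to_noise(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Per-gene (mu1 - mu2) / (sigma1 + sigma2) with the canonical sigma floor."""
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    s1, s2 = x1.std(axis=1, ddof=1), x2.std(axis=1, ddof=1)
    s1 = np.maximum(s1, np.where(m1 != 0, 0.2 * np.abs(m1), 0.2))
    s2 = np.maximum(s2, np.where(m2 != 0, 0.2 * np.abs(m2), 0.2))
    return (m1 - m2) / (s1 + s2)


def _weighted_ks_es(metric: np.ndarray, in_set: np.ndarray) -> float:
    """Signed extremum of the weighted Kolmogorov-Smirnov running sum."""
    order = np.argsort(-metric, kind="stable")
    members = in_set[order]
    w = np.abs(metric[order])
    denom = w[members].sum()
    p = metric.size
    size = members.sum()
    if denom == 0:  # all member metrics zero: uniform steps
        num = np.cumsum(members) / size
    else:
        num = np.cumsum(np.where(members, w, 0.0)) / denom
    den = np.cumsum(~members) / (p - size)
    nu = num - den
    return float(nu[np.argmax(np.abs(nu))])


def gsea_two_class(
    matrix: ExpressionMatrix,
    labels: dict[str, str],
    sets: GeneSetCollection,
    contrast: tuple[str, str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentStats:
    """Two-class GSEA with phenotype-label permutation null.

    Genes are ranked by signal-to-noise; each set's ES is the extremum of
    the |metric|-weighted KS walk; NES normalises by the mean |null ES| of
    the same sign and p is the one-sided same-sign permutation tail.
    """
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError("need exactly two classes")
    if contrast is None:
        contrast = (groups[0], groups[1])
    idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    c1 = np.array([idx[s] for s, g in labels.items() if g == contrast[0]])
    c2 = np.array([idx[s] for s, g in labels.items() if g == contrast[1]])
    if c1.size < 3 or c2.size < 3:
        raise ValueError("each class needs >= 3 samples")
    values = matrix.values
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    members: dict[str, np.ndarray] = {}
    for s in sets:
        inter = [gene_pos[g] for g in s.members if g in gene_pos]
        if not inter:
            raise ValueError(f"gene set {s.name!r} has no genes in the matrix")
        if len(inter) >= matrix.n_genes:
            raise ValueError(f"gene set {s.name!r} covers every gene in the matrix")
        flags = np.zeros(matrix.n_genes, dtype=bool)
        flags[inter] = True
        members[s.name] = flags

    metric = _signal_to_noise(values[:, c1], values[:, c2])
    es = {name: _weighted_ks_es(metric, flags) for name, flags in members.items()}

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([c1, c2])
    null_es = {name: np.empty(n_perm) for name in members}
    for b in range(n_perm):
        perm = rng.permutation(pooled)
        pm = _signal_to_noise(values[:, perm[: c1.size]], values[:, perm[c1.size:]])
        for name, flags in members.items():
            null_es[name][b] = _weighted_ks_es(pm, flags)

    rows = []
    for name in members:
        observed = es[name]
        nulls = null_es[name]
        same = nulls[np.sign(nulls) == np.sign(observed)] if observed != 0 else nulls
        n_same = same.size
        p = (1.0 + np.sum(np.abs(same) >= abs(observed))) / (1.0 + n_same)
        mean_same = np.mean(np.abs(same)) if n_same else np.nan
        nes = observed / mean_same if n_same and mean_same > 0 else np.nan
        rows.append((name, observed, nes, p, n_perm))
    table = pd.DataFrame(rows, columns=["set", "es", "nes", "p", "n_perm"]).set_index("set")
    from .diffexp import bh_adjust

    table["q"] = bh_adjust(table["p"].to_numpy())
    return EnrichmentStats(table=table[["es", "nes", "p", "q", "n_perm"]])


def module_score(
    expression: np.ndarray,
    gene_ids: list[str],
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell module score: set mean minus bin-matched control mean.

    ``expression`` is cells x genes (normalised).  Genes are cut into
    ``n_bins`` equal-frequency bins of their across-cell mean; for each
    set gene, ``n_ctrl`` control genes are drawn (with replacement) from
    its bin and the score is the difference of means.
    """
    expression = np.asarray(expression, dtype=float)
    n_cells, n_genes = expression.shape
    if n_genes < n_bins:
        raise ValueError(f"need >= {n_bins} genes for {n_bins} expression bins")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    set_idx = [gene_pos[g] for g in gene_set.members if g in gene_pos]
    if not set_idx:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the matrix")

    means = expression.mean(axis=0)
    order = np.argsort(means, kind="stable")
    bins = np.empty(n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b

    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    for g in set_idx:
        pool = np.where(bins == bins[g])[0]
        ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=True))
    set_mean = expression[:, set_idx].mean(axis=1)
    ctrl_mean = expression[:, ctrl_idx].mean(axis=1)
    return set_mean - ctrl_mean
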