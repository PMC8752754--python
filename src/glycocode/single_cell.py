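"""Simplified single-cell pipeline and the tumour-macrophage circuit readout.

Counts are depth-normalised (log CP-scale), the mitochondrial fraction is
regressed out gene-wise, highly variable genes feed an exact-SVD PCA, and
cells are clustered on a pruned shared-nearest-neighbour graph with
Louvain modularity.  The endpoint is :func:`cross_compartment_corr`: per
patient, mean tumour-cell module scores of fucosylation programmes are
correlated (Spearman) against mean macrophage cytokine expression.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import anndata as ad
import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .io import GeneSetCollection
from .scoring import module_score

__all__ = [
    "CrossCorrResult",
    "normalize_log",
    "regress_covariate",
    "select_hvg",
    "pca_embed",
    "snn_louvain",
    "cross_compartment_corr",
    "run_sc_pipeline",
]


@dataclass
class CrossCorrResult:
    """Per (programme, cytokine) Spearman correlation across patients."""

    table: pd.DataFrame  # columns: program, cytokine, rho, p, n_patients

    def rho(self, program: str, cytokine: str) -> float:
        rows = self.table[(self.table["program"] == program) & (self.table["cytokine"] == cytokine)]
        if rows.empty:
            raise KeyError((program, cytokine))
        return float(rows["rho"].iloc[0])


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=float)


def normalize_log(counts, scale: float = 1e4) -> np.ndarray:
    """log(1 + scale * count / cell_total), cells x genes."""
    counts = _dense(counts)
    totals = counts.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(f"cells with zero total counts: {zero[:10].tolist()}")
    return np.log1p(scale * counts / totals[:, None])


def regress_covariate(normalized: np.ndarray, covariate) -> np.ndarray:
    """Gene-wise OLS removal of one per-cell covariate, means preserved."""
    y = np.asarray(normalized, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if y.shape[0] != c.size:
        raise ValueError("covariate length must equal the number of cells")
    if y.shape[0] < 3:
        raise ValueError("need >= 3 cells")
    if not np.all(np.isfinite(c)):
        raise ValueError("covariate must be finite")
    cc = c - c.mean()
    denom = (cc**2).sum()
    if denom == 0:
        warnings.warn("constant covariate; returning input unchanged", stacklevel=2)
        return y.copy()
    slope = (cc @ (y - y.mean(axis=0))) / denom  # per gene
    return y - cc[:, None] * slope[None, :]


def select_hvg(normalized: np.ndarray, gene_ids: list[str], n: int = 3000, n_bins: int = 20) -> list[str]:
    """Top-``n`` genes by mean-bin standardised dispersion.

    Genes are binned into ``n_bins`` equal-frequency bins of their mean;
    within each bin the variance is z-scored, and genes are ranked by
    that standardised dispersion (ties by gene id).
    """
    y = np.asarray(normalized, dtype=float)
    n_genes = y.shape[1]
    if n > n_genes:
        raise ValueError(f"requested {n} genes but matrix has {n_genes}")
    means = y.mean(axis=0)
    variances = y.var(axis=0)
    order = np.argsort(means, kind="stable")
    dispersion = np.zeros(n_genes)
    for chunk in np.array_split(order, min(n_bins, n_genes)):
        v = variances[chunk]
        sd = v.std()
        dispersion[chunk] = (v - v.mean()) / sd if sd > 0 else 0.0
    dispersion[variances == 0] = -np.inf  # constant genes are never variable
    ranked = sorted(range(n_genes), key=lambda g: (-dispersion[g], gene_ids[g]))
    return [gene_ids[g] for g in ranked[:n]]


def pca_embed(matrix: np.ndarray, n_comp: int = 10, scale: bool = False) -> np.ndarray:
    """Exact-SVD principal-component scores of cells x genes.

    Genes are centred (and optionally unit-scaled); the sign of each
    component is fixed so its largest-|loading| gene is positive.
    """
    y = np.asarray(matrix, dtype=float)
    if n_comp > min(y.shape):
        raise ValueError(f"n_comp={n_comp} exceeds min(cells, genes)={min(y.shape)}")
    y = y - y.mean(axis=0)
    if scale:
        sd = y.std(axis=0)
        y = y / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(y, full_matrices=False)
    scores = u[:, :n_comp] * s[:n_comp]
    loadings = vt[:n_comp]
    for j in range(n_comp):
        lead = np.argmax(np.abs(loadings[j]))
        if loadings[j, lead] < 0:
            scores[:, j] = -scores[:, j]
            loadings[j] = -loadings[j]
    return scores


def snn_louvain(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    prune: float = 1.0 / 15.0,
    seed: int = 0,
) -> np.ndarray:
    """Shared-nearest-neighbour graph + Louvain modularity clustering.

    kNN in Euclidean embedding space (the cell itself counts as a
    neighbour); SNN edge weights are the Jaccard similarity of neighbour
    sets, pruned below ``prune``; Louvain maximises resolution-scaled
    modularity with a seeded RNG.
    """
    x = np.asarray(embedding, dtype=float)
    n = x.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(x)
    _, neighbor_idx = nn.kneighbors(x)
    rows = np.repeat(np.arange(n), k_neighbors)
    adj = sp.csr_matrix(
        (np.ones(n * k_neighbors), (rows, neighbor_idx.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T  # pairwise neighbour-set intersections
    shared = sp.triu(shared.tocoo(), k=1)
    inter = shared.data
    jac = inter / (2 * k_neighbors - inter)
    keep = jac >= prune
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    weights = jac[keep].tolist()

    igraph.set_random_number_generator(random.Random(seed))
    graph = igraph.Graph(n=n, edges=edges, edge_attrs={"weight": weights})
    partition = graph.community_multilevel(weights="weight", resolution=resolution)
    return np.asarray(partition.membership, dtype=int)


def cross_compartment_corr(
    adata: ad.AnnData,
    program_sets: GeneSetCollection,
    cytokine_genes: list[str],
    tumour_label: str = "tumour",
    macrophage_label: str = "macrophage",
    cell_type_col: str = "cell_type",
    patient_col: str = "patient",
    layer: str = "normalized",
    method: str = "spearman",
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> CrossCorrResult:
    """Patient-level tumour-programme vs macrophage-cytokine correlation.

    For every patient with both compartments: the mean tumour-cell module
    score of each programme, and the mean normalised expression of each
    cytokine over that patient's macrophages; then a rank (Spearman)
    correlation across patients for every (programme, cytokine) pair.
    """
    expr = np.asarray(adata.layers[layer]) if layer in adata.layers else _dense(adata.X)
    gene_ids = list(adata.var_names)
    cell_types = adata.obs[cell_type_col].astype(str).to_numpy()
    patients = adata.obs[patient_col].astype(str).to_numpy()

    usable = []
    for patient in pd.unique(patients):
        mask = patients == patient
        if (cell_types[mask] == tumour_label).any() and (
            cell_types[mask] == macrophage_label
        ).any():
            usable.append(patient)
        else:
            warnings.warn(
                f"patient {patient!r} lacks a tumour or macrophage compartment; dropped",
                stacklevel=2,
            )
    if len(usable) < 3:
        raise ValueError(f"need >= 3 patients with both compartments (got {len(usable)})")

    scores = {
        s.name: module_score(expr, gene_ids, s, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        for s in program_sets
    }
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in cytokine_genes if g not in gene_pos]
    if missing:
        raise KeyError(f"cytokines not in matrix: {missing}")

    rows = []
    tumour_mask = cell_types == tumour_label
    mac_mask = cell_types == macrophage_label
    program_means = {
        name: np.array(
            [vals[(patients == p) & tumour_mask].mean() for p in usable]
        )
        for name, vals in scores.items()
    }
    cytokine_means = {
        cyt: np.array(
            [expr[(patients == p) & mac_mask, gene_pos[cyt]].mean() for p in usable]
        )
        for cyt in cytokine_genes
    }
    for name, pm in program_means.items():
        for cyt, cm in cytokine_means.items():
            if method == "spearman":
                rho, p = stats.spearmanr(pm, cm)
            else:
                rho, p = stats.pearsonr(pm, cm)
            rows.append(
                {
                    "program": name,
                    "cytokine": cyt,
                    "rho": float(rho),
                    "p": float(p),
                    "n_patients": len(usable),
                }
            )
    return CrossCorrResult(table=pd.DataFrame(rows))


def run_sc_pipeline(
    adata: ad.AnnData,
    n_hvg: int = 3000,
    n_comp: int = 10,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> ad.AnnData:
    """Normalise, regress mito fraction, HVG, PCA, SNN-Louvain; in place.

    Adds ``layers['normalized']`` / ``layers['residual']``,
    ``obsm['X_pca']`` and ``obs['cluster']``.
    """
    normalized = normalize_log(adata.X)
    adata.layers["normalized"] = normalized
    residual = regress_covariate(normalized, adata.obs["mito_fraction"].to_numpy())
    adata.layers["residual"] = residual
    n_hvg = min(n_hvg, adata.n_vars)
    hvgs = select_hvg(residual, list(adata.var_names), n=n_hvg)
    hvg_idx = [list(adata.var_names).index(g) for g in hvgs]
    embedding = pca_embed(residual[:, hvg_idx], n_comp=min(n_comp, len(hvg_idx), adata.n_obs))
    adata.obsm["X_pca"] = embedding
    adata.obs["cluster"] = pd.Categorical(
        snn_louvain(embedding, k_neighbors=k_neighbors, resolution=resolution, seed=seed).astype(str)
    )
    adata.uns["hvg"] = hvgs
    return adata
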