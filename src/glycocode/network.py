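"""Concordance network between subtype classification schemes.

Samples are classified under several schemes (consensus clustering on
each scheme's classifier genes, clusters named by their strongest
signature score); cross-scheme subtype pairs become candidate edges
scored by Jaccard overlap and an upper-tail hypergeometric test with BH
adjustment, and the significant-edge graph is meta-clustered with the
Markov cluster algorithm (MCL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .consensus import consensus_cluster
from .diffexp import bh_adjust
from .io import ExpressionMatrix, GeneSet, GeneSetCollection
from .scoring import ss_enrichment

__all__ = [
    "SchemeDefinition",
    "AssignmentTable",
    "ConcordanceNetwork",
    "classify_scheme",
    "jaccard",
    "hypergeom_overlap",
    "build_network",
    "mcl_cluster",
]


@dataclass
class SchemeDefinition:
    """A published-subtype classification scheme: name, subtypes, classifiers."""

    name: str
    subtypes: tuple[str, ...]
    classifier_sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        if len(self.subtypes) < 2:
            raise ValueError(f"scheme {self.name!r} needs >= 2 subtypes")
        if set(self.subtypes) != set(self.classifier_sets):
            raise ValueError(f"scheme {self.name!r}: classifier sets must match subtypes")

    def all_genes(self) -> list[str]:
        genes: dict[str, None] = {}
        for subtype in self.subtypes:
            for g in self.classifier_sets[subtype].members:
                genes[g] = None
        return list(genes)


@dataclass
class AssignmentTable:
    """sample id -> subtype name, for one or more schemes."""

    assignments: dict[str, dict[str, str]]  # scheme -> sample -> subtype

    def schemes(self) -> list[str]:
        return list(self.assignments)

    def members(self, scheme: str, subtype: str) -> set[str]:
        return {s for s, st in self.assignments[scheme].items() if st == subtype}

    def common_samples(self) -> set[str]:
        sets = [set(m) for m in self.assignments.values()]
        common = sets[0]
        for s in sets[1:]:
            common &= s
        return common


@dataclass
class ConcordanceNetwork:
    """Subtype nodes, tested cross-scheme edges, and MCL meta-clusters."""

    graph: nx.Graph
    edges: pd.DataFrame  # source, target, overlap, jaccard, p, q, significant
    meta_clusters: dict[str, int] = field(default_factory=dict)


def classify_scheme(
    matrix: ExpressionMatrix,
    scheme: SchemeDefinition,
    n_iterations: int = 250,
    subsample_fraction: float = 0.9,
    seed: int = 0,
) -> dict[str, str]:
    """Assign every sample of ``matrix`` to one subtype of ``scheme``.

    Consensus clustering on the union of the scheme's classifier genes
    with k = number of subtypes; each cluster is named after the subtype
    whose signature single-sample score has the highest cluster mean,
    resolving collisions greedily in descending score-gap order.
    """
    present = set(matrix.gene_ids)
    usable: dict[str, GeneSet] = {}
    for subtype in scheme.subtypes:
        s = scheme.classifier_sets[subtype]
        inter = [g for g in s.members if g in present]
        if len(inter) < max(1, int(np.ceil(0.5 * len(s.members)))):
            raise ValueError(
                f"scheme {scheme.name!r}: classifier set for {subtype!r} has "
                f"{len(inter)}/{len(s.members)} genes in the matrix (< 50%)"
            )
        usable[subtype] = GeneSet(s.name, s.description, tuple(inter))
    genes = [g for g in scheme.all_genes() if g in present]
    k = len(scheme.subtypes)
    run = consensus_cluster(
        matrix,
        genes=genes,
        k_range=(k,),
        n_iterations=n_iterations,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )
    labels = run.labels[k]

    signatures = GeneSetCollection()
    for subtype in scheme.subtypes:
        s = usable[subtype]
        signatures.add(GeneSet(subtype, s.description, s.members))
    scores = ss_enrichment(matrix, signatures)
    cluster_ids = sorted(set(labels))
    mean_score = np.zeros((len(scheme.subtypes), len(cluster_ids)))
    for si, subtype in enumerate(scheme.subtypes):
        row = scores.row(subtype)
        for ci, cl in enumerate(cluster_ids):
            mean_score[si, ci] = row[labels == cl].mean()

    # greedy naming in descending score-gap order
    names: dict[int, str] = {}
    free_subtypes = set(range(len(scheme.subtypes)))
    free_clusters = set(range(len(cluster_ids)))
    while free_clusters:
        best = None  # (gap, cluster, subtype)
        for ci in sorted(free_clusters):
            col = [(mean_score[si, ci], si) for si in sorted(free_subtypes)]
            col.sort(reverse=True)
            gap = col[0][0] - col[1][0] if len(col) > 1 else np.inf
            if best is None or gap > best[0]:
                best = (gap, ci, col[0][1])
        _, ci, si = best
        names[cluster_ids[ci]] = scheme.subtypes[si]
        free_clusters.remove(ci)
        free_subtypes.remove(si)
    return {sample: names[int(lab)] for sample, lab in zip(matrix.sample_ids, labels)}


def jaccard(a: set, b: set) -> float:
    """|A intersect B| / |A union B|; 0 when both are empty."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def hypergeom_overlap(x: int, n_a: int, n_b: int, n_total: int) -> float:
    """Upper-tail hypergeometric p of seeing >= x of nB marked items in nA draws."""
    if not (0 <= x <= min(n_a, n_b) <= n_total):
        raise ValueError(f"inconsistent counts: x={x}, nA={n_a}, nB={n_b}, N={n_total}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, n_total, n_b, n_a))


def build_network(assignments: AssignmentTable, alpha: float = 0.05, on_adjusted: bool = True) -> ConcordanceNetwork:
    """Jaccard/hypergeometric concordance network across schemes.

    One candidate edge per cross-scheme subtype pair over the common
    sample universe; BH adjustment across all candidate edges; an edge is
    significant when its (adjusted, by default) p falls below ``alpha``.
    """
    schemes = assignments.schemes()
    if len(schemes) < 2:
        raise ValueError("need >= 2 schemes")
    universe = assignments.common_samples()
    n_total = len(universe)
    if n_total == 0:
        raise ValueError("schemes share no samples")

    nodes: list[tuple[str, str, int]] = []
    node_members: dict[str, set[str]] = {}
    for scheme in schemes:
        for subtype in sorted(set(assignments.assignments[scheme].values())):
            members = assignments.members(scheme, subtype) & universe
            node = f"{scheme}:{subtype}"
            nodes.append((scheme, subtype, len(members)))
            node_members[node] = members

    rows = []
    for i, scheme_a in enumerate(schemes):
        for scheme_b in schemes[i + 1:]:
            for node_a, members_a in node_members.items():
                if not node_a.startswith(scheme_a + ":"):
                    continue
                for node_b, members_b in node_members.items():
                    if not node_b.startswith(scheme_b + ":"):
                        continue
                    overlap = len(members_a & members_b)
                    p = hypergeom_overlap(overlap, len(members_a), len(members_b), n_total)
                    rows.append(
                        {
                            "source": node_a,
                            "target": node_b,
                            "overlap": overlap,
                            "jaccard": jaccard(members_a, members_b),
                            "p": p,
                        }
                    )
    edges = pd.DataFrame(rows)
    edges["q"] = bh_adjust(edges["p"].to_numpy())
    edges["significant"] = (edges["q"] if on_adjusted else edges["p"]) < alpha

    graph = nx.Graph()
    for scheme, subtype, size in nodes:
        graph.add_node(f"{scheme}:{subtype}", scheme=scheme, subtype=subtype, size=size)
    for row in edges.itertuples(index=False):
        if row.significant:
            graph.add_edge(
                row.source,
                row.target,
                weight=row.jaccard,
                overlap=row.overlap,
                p=row.p,
                q=row.q,
            )
    meta = mcl_cluster(graph)
    return ConcordanceNetwork(graph=graph, edges=edges, meta_clusters=meta)


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune: float = 1e-8,
) -> dict[str, int]:
    """Markov clustering of a weighted graph into meta-clusters.

    Self-loops (weight 1) are added, the adjacency is column-normalised,
    and expansion (matrix power) alternates with inflation (elementwise
    power + renormalisation) until the matrix is stable.  Clusters are
    read off the attractor rows; every node lands in exactly one cluster.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError(f"negative edge weight on ({u}, {v})")
        m[index[u], index[v]] = w
        m[index[v], index[u]] = w
    np.fill_diagonal(m, 1.0)
    m = m / m.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        col_sums = inflated.sum(axis=0, keepdims=True)
        col_sums[col_sums == 0] = 1.0
        inflated = inflated / col_sums
        if np.max(np.abs(inflated - m)) < tol:
            m = inflated
            break
        m = inflated

    # attractors: rows with positive diagonal mass; merge overlapping supports
    attractors = [i for i in range(n) if m[i, i] > 1e-6]
    clusters: list[set[int]] = []
    for a in attractors:
        support = set(np.where(m[a] > 1e-6)[0]) | {a}
        merged = False
        for cluster in clusters:
            if cluster & support:
                cluster |= support
                merged = True
                break
        if not merged:
            clusters.append(support)
    # keep merging until stable (supports can chain)
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    assigned: dict[str, int] = {}
    for ci, cluster in enumerate(sorted(clusters, key=min)):
        for i in sorted(cluster):
            if nodes[i] not in assigned:
                assigned[nodes[i]] = ci
    next_id = len(clusters)
    for v in nodes:
        if v not in assigned:
            assigned[v] = next_id
            next_id += 1
    return assigned
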