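"""Empirical-Bayes moderated-t differential expression.

Implements the two designs the discovery analysis needs — unpaired
two-group and paired tumour/normal — with gene-wise variances shrunk
towards a common prior estimated from the data (Smyth-style moment
matching on log sample variances), Benjamini-Hochberg FDR adjustment,
the cross-cohort gene-panel rule (significant in at least ``min_cohorts``
datasets at a raw-p cut-off), and one-vs-rest cluster comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix, SampleMetadata

__all__ = [
    "DesignSpec",
    "DEResult",
    "PanelSelection",
    "moderated_t",
    "bh_adjust",
    "select_panel",
    "one_vs_rest_de",
    "design_from_metadata",
]


@dataclass
class DesignSpec:
    """Two-group comparison layout.

    ``groups`` maps each sample id to a group label; exactly two labels
    must occur and ``contrast`` orders them as (test, reference) so the
    fold change is test minus reference.  For a paired design ``pairs``
    maps each sample to a pair id, one test and one reference sample per
    pair.
    """

    kind: str  # "two_group_unpaired" | "paired"
    groups: dict[str, str]
    contrast: tuple[str, str]
    pairs: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("two_group_unpaired", "paired"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        labels = set(self.groups.values())
        if labels != set(self.contrast) or len(self.contrast) != 2:
            raise ValueError("groups must carry exactly the two contrast labels")
        if self.kind == "paired":
            if self.pairs is None:
                raise ValueError("paired design needs pair ids")
            by_pair: dict[str, list[str]] = {}
            for sample, pair in self.pairs.items():
                by_pair.setdefault(pair, []).append(sample)
            for pair, members in by_pair.items():
                got = sorted(self.groups[s] for s in members)
                if got != sorted(self.contrast):
                    raise ValueError(f"pair {pair!r} must have one sample per group (got {got})")


@dataclass
class DEResult:
    """Per-gene moderated-t table plus the shared shrinkage hyperparameters."""

    table: pd.DataFrame  # index gene; columns log2fc, s2, df, t, p, q
    prior_df: float  # d0, may be inf
    prior_var: float  # s0^2

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]


@dataclass
class PanelSelection:
    """Cross-cohort panel: per-gene per-cohort flags and the selection."""

    table: pd.DataFrame  # index gene; one bool column per cohort + n_significant, selected
    p_max: float
    min_cohorts: int

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma target must be positive")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from sample variances with common df.

    Works on ``e = log(s2) - digamma(df/2) + log(df/2)``: the mean of ``e``
    identifies s0^2 and the excess spread over trigamma(df/2) identifies
    d0.  A non-positive excess means no evidence of variance heterogeneity
    and returns d0 = inf (complete shrinkage to s0^2).
    """
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all genes have zero variance")
    if positive.size < s2.size:
        warnings.warn(
            f"{s2.size - positive.size} zero-variance genes excluded from prior estimation",
            stacklevel=2,
        )
    e = np.log(positive) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    if positive.size < 3:
        return np.inf, float(positive.mean())
    target = float(np.mean((e - e_mean) ** 2) * positive.size / (positive.size - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if target <= 0:  # no variance heterogeneity: complete shrinkage
        return np.inf, float(positive.mean())
    d0 = 2.0 * _trigamma_inverse(target)
    s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def moderated_t(
    matrix: ExpressionMatrix,
    design: DesignSpec,
    prior_df: float | None = None,
) -> DEResult:
    """Moderated t-test of every gene under the given two-group design.

    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary
    pooled/paired t exactly; inf shrinks every variance to the prior).
    """
    sample_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    missing = [s for s in design.groups if s not in sample_index]
    if missing:
        raise KeyError(f"design samples not in matrix: {missing[:5]}")
    values = matrix.values
    test_label, ref_label = design.contrast

    if design.kind == "two_group_unpaired":
        idx1 = [sample_index[s] for s, g in design.groups.items() if g == test_label]
        idx2 = [sample_index[s] for s, g in design.groups.items() if g == ref_label]
        n1, n2 = len(idx1), len(idx2)
        if n1 < 2 or n2 < 2:
            raise ValueError(f"each group needs >= 2 samples (got {n1} and {n2})")
        x1, x2 = values[:, idx1], values[:, idx2]
        beta = x1.mean(axis=1) - x2.mean(axis=1)
        ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
        df = float(n1 + n2 - 2)
        s2 = ss / df
        scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    else:
        assert design.pairs is not None
        by_pair: dict[str, dict[str, str]] = {}
        for sample, pair in design.pairs.items():
            by_pair.setdefault(pair, {})[design.groups[sample]] = sample
        pairs = sorted(by_pair)
        if len(pairs) < 2:
            raise ValueError("paired design needs >= 2 pairs")
        diffs = np.empty((values.shape[0], len(pairs)))
        for j, pair in enumerate(pairs):
            members = by_pair[pair]
            diffs[:, j] = (
                values[:, sample_index[members[test_label]]]
                - values[:, sample_index[members[ref_label]]]
            )
        n = len(pairs)
        beta = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        df = float(n - 1)
        scale = np.sqrt(1.0 / n)

    if np.all(s2 == 0):
        raise ValueError("all genes have zero variance")
    if prior_df is None:
        d0, s0 = estimate_prior(s2, df)
    elif np.isinf(prior_df):
        _, s0 = estimate_prior(s2, df)
        d0 = np.inf
    elif prior_df == 0:
        d0, s0 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0 = estimate_prior(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        total_df = np.inf
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        total_df = d0 + df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / (scale * np.sqrt(s2_post))
    zero_var = s2_post == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} genes with zero posterior variance; p set to 0 "
            "where the effect is non-zero",
            stacklevel=2,
        )
        t = np.where(zero_var & (beta == 0), 0.0, t)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.where(np.isnan(t), 1.0, p)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isinf(t), 0.0, p)

    table = pd.DataFrame(
        {
            "log2fc": beta,
            "s2": s2,
            "df": df,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    return DEResult(table=table, prior_df=float(d0), prior_var=float(s0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def select_panel(
    results: dict[str, DEResult],
    p_max: float = 0.01,
    min_cohorts: int = 2,
    use_adjusted: bool = False,
) -> PanelSelection:
    """Cross-cohort gene panel: p <= ``p_max`` in >= ``min_cohorts`` datasets.

    Gene universes may differ between cohorts; a gene is only counted in
    the cohorts that measured it.  ``use_adjusted`` switches the cut-off
    from raw to BH-adjusted p.
    """
    if not results:
        raise ValueError("no differential-expression results given")
    column = "q" if use_adjusted else "p"
    genes: dict[str, None] = {}
    for res in results.values():
        for g in res.table.index:
            genes[g] = None
    table = pd.DataFrame(index=pd.Index(list(genes), name="gene"))
    for cohort, res in results.items():
        flags = res.table[column] <= p_max
        table[cohort] = flags.reindex(table.index, fill_value=False)
    table["n_significant"] = table[list(results)].sum(axis=1).astype(int)
    table["selected"] = table["n_significant"] >= min_cohorts
    return PanelSelection(table=table, p_max=p_max, min_cohorts=min_cohorts)


def one_vs_rest_de(matrix: ExpressionMatrix, cluster_labels: dict[str, str]) -> dict[str, DEResult]:
    """Moderated t of each cluster against all remaining samples."""
    clusters = sorted(set(cluster_labels.values()))
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    counts = {c: sum(1 for v in cluster_labels.values() if v == c) for c in clusters}
    for c, n in counts.items():
        if n < 2:
            raise ValueError(f"cluster {c!r} has {n} samples, need >= 2")
    results: dict[str, DEResult] = {}
    for cluster in clusters:
        groups = {
            s: (cluster if lab == cluster else "rest") for s, lab in cluster_labels.items()
        }
        design = DesignSpec(
            kind="two_group_unpaired", groups=groups, contrast=(cluster, "rest")
        )
        sub = matrix.subset_samples([s for s in matrix.sample_ids if s in groups])
        results[cluster] = moderated_t(sub, design)
    return results


def design_from_metadata(metadata: list[SampleMetadata], paired: bool) -> DesignSpec:
    """Tumour-vs-normal design for one cohort's metadata."""
    if paired:
        with_pair = [m for m in metadata if m.pair_id is not None]
        return DesignSpec(
            kind="paired",
            groups={m.sample_id: m.condition for m in with_pair},
            contrast=("tumour", "normal"),
            pairs={m.sample_id: m.pair_id for m in with_pair},
        )
    return DesignSpec(
        kind="two_group_unpaired",
        groups={m.sample_id: m.condition for m in metadata},
        contrast=("tumour", "normal"),
    )
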