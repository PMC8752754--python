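"""Domain containers and plain-text readers/writers shared by every stage.

Bulk expression travels as :class:`ExpressionMatrix` (log-scale, genes x
samples), gene sets as :class:`GeneSetCollection` (GMT on disk), clinical
follow-up as :class:`ClinicalRecord` lists, and single-cell counts as
:class:`anndata.AnnData` built from a Matrix Market triplet plus
feature/barcode TSVs.  All loaders validate hard: a malformed file raises
instead of being silently repaired, because every downstream statistic
would inherit the repair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "ClinicalRecord",
    "GeneSet",
    "GeneSetCollection",
    "load_expression",
    "write_expression",
    "load_gmt",
    "write_gmt",
    "load_clinical",
    "write_clinical",
    "load_metadata",
    "write_metadata",
    "load_sc_counts",
]


@dataclass
class ExpressionMatrix:
    """Log-scale expression, rows = genes, columns = samples.

    Identifiers are case-sensitive and must be unique on both axes; the
    value block must be finite (no NaN / inf).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value block {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (order taken from the request, must exist)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])


@dataclass
class SampleMetadata:
    """Per-sample annotation: cohort, tumour/normal status, pairing, purity.

    ``pair_id`` is set only in paired cohorts and links exactly one tumour
    to one normal.  ``true_subtype`` is populated by the simulator only and
    carries the planted ground truth.
    """

    sample_id: str
    cohort_id: str
    condition: str
    pair_id: str | None = None
    purity: float | None = None
    true_subtype: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("tumour", "normal"):
            raise ValueError(f"condition must be 'tumour' or 'normal', got {self.condition!r}")
        if self.purity is not None and not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity must lie in [0, 1], got {self.purity}")


@dataclass
class ClinicalRecord:
    """Overall-survival follow-up: time in days, event 1 = death observed."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        self.time = float(self.time)
        if not self.time > 0:
            raise ValueError(f"survival time must be > 0 (sample {self.sample_id!r}: {self.time})")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1 (sample {self.sample_id!r}: {self.event})")
        self.event = int(self.event)


@dataclass
class GeneSet:
    """A named set of gene identifiers (members unique, at least one)."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(str(m) for m in self.members)
        if len(members) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(members)) != len(members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")
        self.members = members

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Ordered mapping of uniquely named gene sets (one GMT file)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene-set names: {dup}")

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self:
            raise ValueError(f"duplicate gene-set name: {gene_set.name!r}")
        self.sets.append(gene_set)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def load_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: no genes (file has a header but an empty body)")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    dup_cols = pd.Index(frame.columns)
    if dup_cols.duplicated().any():
        raise ValueError(f"{path}: duplicate sample id {dup_cols[dup_cols.duplicated()][0]!r}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                raise ValueError(
                    f"{path}: missing value at gene {frame.index[i]!r}, sample {col!r}"
                )
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {raw!r} at gene {frame.index[i]!r}, sample {col!r}"
                ) from None
    return ExpressionMatrix(list(frame.index), list(frame.columns), values)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def load_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member...).

    Duplicate members within one line are deduplicated with a warning;
    duplicate set names or lines with fewer than three fields are errors.
    """
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, description, *members = fields
            members = [m for m in members if m != ""]
            unique: list[str] = []
            seen: set[str] = set()
            for m in members:
                if m in seen:
                    continue
                seen.add(m)
                unique.append(m)
            if len(unique) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: gene set {name!r} has duplicate members; deduplicated",
                    stacklevel=2,
                )
            collection.add(GeneSet(name, description, tuple(unique)))
    if len(collection) == 0:
        raise ValueError(f"{path}: empty GMT file")
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for s in collection:
            handle.write("\t".join([s.name, s.description, *s.members]) + "\n")


def load_clinical(path) -> list[ClinicalRecord]:
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: clinical table needs columns {sorted(required)}")
    return [
        ClinicalRecord(str(row.sample_id), float(row.time), int(row.event))
        for row in frame.itertuples(index=False)
    ]


def write_clinical(records: list[ClinicalRecord], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def load_metadata(path) -> list[SampleMetadata]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pair_id": str})
    records = []
    for row in frame.itertuples(index=False):
        purity = getattr(row, "purity", None)
        if purity is not None and pd.isna(purity):
            purity = None
        pair = getattr(row, "pair_id", None)
        if pair is not None and pd.isna(pair):
            pair = None
        subtype = getattr(row, "true_subtype", None)
        if subtype is not None and pd.isna(subtype):
            subtype = None
        records.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                cohort_id=str(row.cohort_id),
                condition=str(row.condition),
                pair_id=pair,
                purity=None if purity is None else float(purity),
                true_subtype=subtype,
            )
        )
    _check_pairing(records)
    return records


def _check_pairing(records: list[SampleMetadata]) -> None:
    by_pair: dict[tuple[str, str], list[SampleMetadata]] = {}
    for r in records:
        if r.pair_id is not None:
            by_pair.setdefault((r.cohort_id, r.pair_id), []).append(r)
    for (cohort, pair), members in by_pair.items():
        conditions = sorted(m.condition for m in members)
        if conditions != ["normal", "tumour"]:
            raise ValueError(
                f"pair {pair!r} in cohort {cohort!r} must link exactly one tumour "
                f"to one normal (got {conditions})"
            )


def write_metadata(records: list[SampleMetadata], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "cohort_id": [r.cohort_id for r in records],
            "condition": [r.condition for r in records],
            "pair_id": [r.pair_id if r.pair_id is not None else "" for r in records],
            "purity": [r.purity if r.purity is not None else "" for r in records],
            "true_subtype": [r.true_subtype if r.true_subtype is not None else "" for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def load_sc_counts(matrix_path, features_path, barcodes_path) -> ad.AnnData:
    """Assemble an AnnData (cells x genes) from an MTX triplet trio.

    The Matrix Market file is genes x cells with 1-based indices, as written
    by the usual feature-barcode pipelines; features and barcodes are
    one-id-per-line TSVs.  Entries must be non-negative integers; indices
    out of the declared bounds are an error.
    """
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    try:
        mat = scipy.io.mmread(matrix_path)
    except ValueError as err:
        raise ValueError(f"{matrix_path}: malformed Matrix Market file ({err})") from err
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"{matrix_path}: matrix is {mat.shape[0]} x {mat.shape[1]} but there are "
            f"{len(features)} features and {len(barcodes)} barcodes"
        )
    if mat.nnz and mat.data.min() < 0:
        raise ValueError(f"{matrix_path}: negative count encountered")
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError(f"{matrix_path}: non-integer count encountered")
    counts = sp.csr_matrix(mat.T)  # cells x genes
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )
    return adata
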