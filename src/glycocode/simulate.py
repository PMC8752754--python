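"""Synthetic cohorts with the planted structure the pipeline is built to find.

Three generators:

* :func:`simulate_bulk` — four bulk expression cohorts (two paired
  tumour/normal, two unpaired) with three planted tumour subtypes: a
  fucosylation-program-high epithelial subtype, a basal subtype driven by
  LGALS1/MUC4/MUC16 plus mesenchymal genes, and a low-purity subtype whose
  tumour signal is attenuated by tumour content.  The generative model on
  log2 scale is ``x_gi = mu_g + purity_i * (a_g + sum_p L_gp *
  s_p(subtype_i)) * [tumour_i] + eps_gi`` with Gaussian noise: purity
  scales the whole tumour-specific signal, as bulk mixing of tumour and
  stroma does, and a stromal programme scales with ``1 - purity``, so
  low-purity samples share an attenuated tumour profile plus a strong
  stromal one and cluster together without any subtype-specific glycan
  signature.
* :func:`simulate_survival` — exponential overall-survival times whose
  hazard depends on the planted subtype, with administrative censoring.
* :func:`simulate_single_cell` — negative-binomial counts for tumour cells
  on an epithelial-mesenchymal continuum (four archetype profiles
  interpolated by a latent ``u``), macrophages whose cytokine programme is
  coupled to the patient-level tumour fucosylation (IL6 and CXCL8
  negatively, TGFB1 positively), and a third "other" stromal compartment.

Identical config + seed always reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import catalog
from .io import ClinicalRecord, ExpressionMatrix, SampleMetadata

__all__ = [
    "BulkSimConfig",
    "SurvSimConfig",
    "SCSimConfig",
    "simulate_bulk",
    "simulate_survival",
    "simulate_single_cell",
    "default_programs",
    "SUBTYPE_PROGRAMS",
]

SUBTYPES = ("fucosylated", "basal", "low_purity")

#: which expression programmes each planted subtype loads (purity-scaled)
SUBTYPE_PROGRAMS: dict[str, tuple[str, ...]] = {
    "fucosylated": ("fucosylation", "o_glycan", "epithelial"),
    "basal": ("basal", "mesenchymal"),
    "low_purity": (),
}


#: stromal genes expressed by the non-tumour compartment, scaling with 1 - purity
STROMAL = ("COL1A1", "COL3A1", "DCN", "PDGFRB", "ACTA2", "FAP", "THY1", "POSTN")


def default_programs() -> dict[str, tuple[str, ...]]:
    """Named gene programmes of the bulk generative model."""
    return {
        "fucosylation": tuple(dict.fromkeys(catalog.FUC_ALL + catalog.O_FUCOSYLATION)),
        "o_glycan": tuple(
            dict.fromkeys(catalog.O_GLYCAN_INITIATION + catalog.O_GLYCAN_EXTENSION)
        ),
        "basal": catalog.BASAL_MARKERS,
        "epithelial": catalog.EPITHELIAL,
        "mesenchymal": catalog.MESENCHYMAL,
    }


@dataclass
class BulkSimConfig:
    """Parameters of the bulk-cohort generator.

    ``program_effect`` is the log2 loading L of a programme gene in the
    subtypes that express it, multiplied by tumour purity; ``tumour_shift``
    is the tumour-vs-normal shift a_g shared by all programme genes (zero
    for background genes), which is what the cross-cohort panel rule must
    recover.  Cohort-specific baselines mu_g are redrawn per cohort so the
    at-least-two-datasets rule is a real constraint.
    """

    n_cohorts: int = 4
    paired: tuple[bool, ...] = (True, True, False, False)
    subtype_counts: dict[str, int] = field(
        default_factory=lambda: {"fucosylated": 30, "basal": 30, "low_purity": 20}
    )
    normals_per_cohort: int = 30
    programs: dict[str, tuple[str, ...]] = field(default_factory=default_programs)
    stromal_genes: tuple[str, ...] = STROMAL
    stromal_effect: float = 2.0
    n_background: int = 300
    program_effect: float = 2.0
    tumour_shift: float = 1.0
    noise_sd: float = 0.5
    purity_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "fucosylated": (8.0, 2.0),
            "basal": (8.0, 2.0),
            "low_purity": (2.0, 8.0),
        }
    )
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.paired) != self.n_cohorts:
            raise ValueError("paired flags must match n_cohorts")
        for name, count in self.subtype_counts.items():
            if name not in SUBTYPE_PROGRAMS:
                raise ValueError(f"unknown subtype {name!r}")
            if count < 2:
                raise ValueError(f"subtype {name!r} needs >= 2 tumours")
        if self.normals_per_cohort < 2:
            raise ValueError("need >= 2 normals per cohort")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not np.isfinite(self.program_effect) or not np.isfinite(self.tumour_shift):
            raise ValueError("effects must be finite")

    def gene_ids(self) -> list[str]:
        genes: dict[str, None] = {}
        for members in self.programs.values():
            for g in members:
                genes[g] = None
        for g in self.stromal_genes:
            genes[g] = None
        # remaining catalogue genes ride along with no planted effect, so
        # every glyco pathway is scorable downstream (null pathways stay null)
        for s in catalog.make_glyco_catalog():
            for g in s.members:
                genes.setdefault(g, None)
        for i in range(self.n_background):
            genes[f"BG{i + 1:04d}"] = None
        return list(genes)

    def program_genes(self) -> set[str]:
        """Tumour-cell programme genes (carry the tumour-vs-normal shift)."""
        return {g for members in self.programs.values() for g in members}

    def planted_de_genes(self) -> set[str]:
        """All genes with a planted tumour-vs-normal difference."""
        return self.program_genes() | set(self.stromal_genes)


@dataclass
class SurvSimConfig:
    """Exponential survival with subtype-specific hazard ratios."""

    baseline_rate: float = 1.0 / 600.0  # events per day
    hazard_ratios: dict[str, float] = field(
        default_factory=lambda: {"fucosylated": 1.0, "basal": 2.0, "low_purity": 1.4}
    )
    censor_time: float = 1825.0  # five years
    seed: int = 0

    def validate(self) -> None:
        if not self.baseline_rate > 0:
            raise ValueError("baseline rate must be > 0")
        for name, hr in self.hazard_ratios.items():
            if not hr > 0:
                raise ValueError(f"hazard ratio for {name!r} must be > 0")
        if not self.censor_time > 0:
            raise ValueError("censoring time must be > 0")


@dataclass
class SCSimConfig:
    """Parameters of the single-cell generator.

    Tumour cells carry a latent EMT position ``u`` in [0, 1] (patient mean
    Uniform(0.1, 0.9), Beta-distributed cells around it); four archetype
    profiles at anchors 0, 1/3, 2/3, 1 are interpolated by ``u``, with
    fucosylation/epithelial programmes loading on ``1 - u``.  Macrophage
    cytokine log-means are shifted by ``sign * coupling`` times the
    (centred) patient-level tumour fucosylation; at ``coupling = 0`` the
    circuit is switched off.
    """

    n_patients: int = 12
    cells_per_patient: int = 400
    cell_type_mix: dict[str, float] = field(
        default_factory=lambda: {"tumour": 0.5, "macrophage": 0.2, "other": 0.3}
    )
    emt_concentration: float = 10.0
    program_amp: float = 2.0  # natural-log amplitude of programme loadings
    dispersion: float = 0.3
    library_log_mean: float = float(np.log(2000.0))
    library_log_sd: float = 0.3
    coupling: float = 1.0
    cytokine_signs: dict[str, int] = field(
        default_factory=lambda: {"IL6": -1, "CXCL8": -1, "TGFB1": +1}
    )
    n_background: int = 150
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.cell_type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("cell-type proportions must sum to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_patients < 1 or self.cells_per_patient < 1:
            raise ValueError("need >= 1 patient and >= 1 cell per patient")


# ---------------------------------------------------------------------------
# bulk cohorts
# ---------------------------------------------------------------------------


def simulate_bulk(
    config: BulkSimConfig,
) -> list[tuple[ExpressionMatrix, list[SampleMetadata]]]:
    """Generate ``n_cohorts`` bulk cohorts with planted subtype structure."""
    config.validate()
    genes = config.gene_ids()
    n_genes = len(genes)
    program_genes = config.program_genes()
    # tumour-vs-normal shift: tumour-cell programme genes only
    a = np.array([config.tumour_shift if g in program_genes else 0.0 for g in genes])
    gene_index = {g: i for i, g in enumerate(genes)}
    # stromal loading, scaled by 1 - purity in every tumour sample
    stromal = np.zeros(n_genes)
    for g in config.stromal_genes:
        stromal[gene_index[g]] = config.stromal_effect
    # per-subtype loading vector over genes
    loadings = {}
    for subtype, prog_names in SUBTYPE_PROGRAMS.items():
        vec = np.zeros(n_genes)
        for p in prog_names:
            for g in config.programs[p]:
                vec[gene_index[g]] += config.program_effect
        loadings[subtype] = vec

    cohorts = []
    for c in range(config.n_cohorts):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(c,)))
        mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)

        tumour_subtypes: list[str] = []
        for subtype, count in config.subtype_counts.items():
            tumour_subtypes.extend([subtype] * count)
        n_tum = len(tumour_subtypes)
        n_norm = config.normals_per_cohort

        purity = np.empty(n_tum)
        for i, subtype in enumerate(tumour_subtypes):
            alpha, beta = config.purity_beta[subtype]
            purity[i] = rng.beta(alpha, beta)

        values = np.empty((n_genes, n_tum + n_norm))
        for i, subtype in enumerate(tumour_subtypes):
            values[:, i] = mu + purity[i] * (a + loadings[subtype]) + (1.0 - purity[i]) * stromal
        for j in range(n_norm):
            values[:, n_tum + j] = mu
        if config.noise_sd > 0:
            values += rng.normal(0.0, config.noise_sd, size=values.shape)

        cohort_id = f"cohort{c + 1}"
        sample_ids = [f"{cohort_id}_T{i + 1:03d}" for i in range(n_tum)] + [
            f"{cohort_id}_N{j + 1:03d}" for j in range(n_norm)
        ]

        # round-robin pairing across subtype blocks so pairs span subtypes
        pair_of_tumour: dict[int, str] = {}
        if config.paired[c]:
            blocks: list[list[int]] = []
            start = 0
            for subtype, count in config.subtype_counts.items():
                blocks.append(list(range(start, start + count)))
                start += count
            order: list[int] = []
            depth = 0
            while len(order) < n_tum:
                for block in blocks:
                    if depth < len(block):
                        order.append(block[depth])
                depth += 1
            for p, tumour_idx in enumerate(order[:n_norm]):
                pair_of_tumour[tumour_idx] = f"{cohort_id}_P{p + 1:03d}"

        metadata: list[SampleMetadata] = []
        for i, subtype in enumerate(tumour_subtypes):
            metadata.append(
                SampleMetadata(
                    sample_id=sample_ids[i],
                    cohort_id=cohort_id,
                    condition="tumour",
                    pair_id=pair_of_tumour.get(i),
                    purity=float(purity[i]),
                    true_subtype=subtype,
                )
            )
        pair_names = [pair_of_tumour[i] for i in sorted(pair_of_tumour)]
        for j in range(n_norm):
            metadata.append(
                SampleMetadata(
                    sample_id=sample_ids[n_tum + j],
                    cohort_id=cohort_id,
                    condition="normal",
                    pair_id=pair_names[j] if config.paired[c] and j < len(pair_names) else None,
                )
            )
        cohorts.append((ExpressionMatrix(genes, sample_ids, values), metadata))
    return cohorts


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def simulate_survival(
    metadata: list[SampleMetadata], config: SurvSimConfig
) -> list[ClinicalRecord]:
    """Exponential survival times for the tumour samples of ``metadata``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[ClinicalRecord] = []
    for sample in metadata:
        if sample.condition != "tumour":
            continue
        if sample.true_subtype is None:
            raise ValueError(f"sample {sample.sample_id!r} has no subtype label")
        if sample.true_subtype not in config.hazard_ratios:
            raise ValueError(f"unknown subtype {sample.true_subtype!r}")
        rate = config.baseline_rate * config.hazard_ratios[sample.true_subtype]
        t = rng.exponential(1.0 / rate)
        if t >= config.censor_time:
            records.append(ClinicalRecord(sample.sample_id, config.censor_time, 0))
        else:
            records.append(ClinicalRecord(sample.sample_id, t, 1))
    return records


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------

ANCHORS = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
MITO_GENES = ("MT-CO1", "MT-CO2", "MT-CO3", "MT-ND1", "MT-ND2", "MT-ND3", "MT-ATP6", "MT-CYB")
MACROPHAGE_MARKERS = ("CD68", "CD163", "CD209", "LYZ", "AIF1")
OTHER_MARKERS = ("COL1A1", "COL3A1", "DCN", "PDGFRB", "ACTA2")
ARCH_MARKERS = tuple(
    f"ARCH{k + 1}_M{m + 1}" for k in range(len(ANCHORS)) for m in range(5)
)


def _sc_gene_ids(config: SCSimConfig) -> list[str]:
    programs = default_programs()
    genes: dict[str, None] = {}
    for members in programs.values():
        for g in members:
            genes[g] = None
    for g in ARCH_MARKERS + MACROPHAGE_MARKERS + OTHER_MARKERS:
        genes[g] = None
    for g in config.cytokine_signs:
        genes[g] = None
    for g in MITO_GENES:
        genes[g] = None
    for i in range(config.n_background):
        genes[f"BG{i + 1:04d}"] = None
    return list(genes)


def _tent(u: float, k: int) -> float:
    """Piecewise-linear bump peaking at anchor k, zero at adjacent anchors."""
    width = ANCHORS[1] - ANCHORS[0]
    return float(max(0.0, 1.0 - abs(u - ANCHORS[k]) / width))


def simulate_single_cell(config: SCSimConfig) -> ad.AnnData:
    """Generate the synthetic single-cell dataset (cells x genes AnnData).

    ``obs`` carries patient id, cell type, the tumour archetype label, the
    latent EMT position ``u`` and the realised mitochondrial fraction;
    ``uns['patient_fucosylation']`` stores the patient-level latent
    fucosylation the macrophage cytokines were coupled to.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    programs = default_programs()
    genes = _sc_gene_ids(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # fixed per-simulation baseline log-rates
    eta0 = rng.normal(0.0, 0.5, size=n_genes)

    def indices(names) -> np.ndarray:
        return np.array([gene_index[g] for g in names if g in gene_index])

    idx = {
        "fucosylation": indices(programs["fucosylation"]),
        "o_glycan": indices(programs["o_glycan"]),
        "epithelial": indices(programs["epithelial"]),
        "mesenchymal": indices(programs["mesenchymal"]),
        "basal": indices(programs["basal"]),
        "macrophage": indices(MACROPHAGE_MARKERS),
        "other": indices(OTHER_MARKERS),
        "mito": indices(MITO_GENES),
    }
    arch_idx = [indices([f"ARCH{k + 1}_M{m + 1}" for m in range(5)]) for k in range(len(ANCHORS))]

    # patient-level latents
    patient_ids = [f"P{p + 1:02d}" for p in range(config.n_patients)]
    patient_mean_u = rng.uniform(0.1, 0.9, size=config.n_patients)

    # per-patient cell-type blocks (deterministic counts)
    mix = config.cell_type_mix
    n_tum = int(round(mix.get("tumour", 0.0) * config.cells_per_patient))
    n_mac = int(round(mix.get("macrophage", 0.0) * config.cells_per_patient))
    n_other = config.cells_per_patient - n_tum - n_mac

    amp = config.program_amp
    kappa = config.emt_concentration

    rows: list[np.ndarray] = []
    obs_patient: list[str] = []
    obs_type: list[str] = []
    obs_label: list[str] = []
    obs_u: list[float] = []
    patient_fuc: dict[str, float] = {}

    for p, patient in enumerate(patient_ids):
        m = patient_mean_u[p]
        u_cells = rng.beta(m * kappa, (1.0 - m) * kappa, size=n_tum)
        patient_fuc[patient] = float(1.0 - u_cells.mean()) if n_tum else 0.5
        f_centred = 2.0 * (patient_fuc[patient] - 0.5)

        etas: list[np.ndarray] = []
        for u in u_cells:
            eta = eta0.copy()
            eta[idx["fucosylation"]] += amp * (1.0 - u)
            eta[idx["o_glycan"]] += amp * (1.0 - u)
            eta[idx["epithelial"]] += amp * (1.0 - u)
            eta[idx["mesenchymal"]] += amp * u
            eta[idx["basal"]] += amp * u
            for k in range(len(ANCHORS)):
                eta[arch_idx[k]] += amp * _tent(float(u), k)
            etas.append(eta)
            obs_type.append("tumour")
            arch = int(np.argmin(np.abs(ANCHORS - u)))
            obs_label.append(f"tumour_arch{arch + 1}")
            obs_u.append(float(u))
        for _ in range(n_mac):
            eta = eta0.copy()
            eta[idx["macrophage"]] += amp
            for cyt, sign in config.cytokine_signs.items():
                eta[gene_index[cyt]] += 1.0 + sign * config.coupling * f_centred
            etas.append(eta)
            obs_type.append("macrophage")
            obs_label.append("macrophage")
            obs_u.append(np.nan)
        for _ in range(n_other):
            eta = eta0.copy()
            eta[idx["other"]] += amp
            etas.append(eta)
            obs_type.append("other")
            obs_label.append("other")
            obs_u.append(np.nan)
        obs_patient.extend([patient] * (n_tum + n_mac + n_other))

        block = np.vstack(etas)
        # per-cell mitochondrial load shifts, then convert to count means
        mito_shift = rng.normal(0.7, 0.5, size=block.shape[0])
        block[:, idx["mito"]] += mito_shift[:, None]
        rates = np.exp(block)
        probs = rates / rates.sum(axis=1, keepdims=True)
        if config.library_log_sd > 0:
            lib = rng.lognormal(config.library_log_mean, config.library_log_sd, size=block.shape[0])
        else:
            lib = np.full(block.shape[0], np.exp(config.library_log_mean))
        mean_counts = probs * lib[:, None]
        if config.dispersion == 0:
            counts = np.round(mean_counts)
        else:
            lam = rng.gamma(1.0 / config.dispersion, mean_counts * config.dispersion)
            counts = rng.poisson(lam).astype(float)
        rows.append(counts)

    counts = np.vstack(rows)
    barcodes = [f"{obs_patient[i]}_C{i + 1:05d}" for i in range(counts.shape[0])]
    mito_fraction = counts[:, idx["mito"]].sum(axis=1) / np.maximum(counts.sum(axis=1), 1.0)
    obs = pd.DataFrame(
        {
            "patient": pd.Categorical(obs_patient),
            "cell_type": pd.Categorical(obs_type),
            "label": pd.Categorical(obs_label),
            "emt_u": obs_u,
            "mito_fraction": mito_fraction,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["patient_fucosylation"] = patient_fuc
    return adata
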