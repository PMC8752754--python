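"""Catalogue contents and the three synthetic generators.

The generators are first-class code: determinism, noise-free limits,
boundary behaviour and the recoverability of the planted structure are
all asserted here (heavier end-to-end recovery lives in the acceptance
suite).
"""

import numpy as np
import pytest
from scipy import stats

from glycocode.catalog import make_glyco_catalog
from glycocode.io import GeneSetCollection, write_gmt, load_gmt
from glycocode.simulate import (
    BulkSimConfig,
    SCSimConfig,
    SurvSimConfig,
    simulate_bulk,
    simulate_single_cell,
    simulate_survival,
)
from glycocode.single_cell import normalize_log


class TestCatalog:
    def test_o_fucosylation_has_the_eight_machinery_genes(self, catalog):
        members = set(catalog["O_FUCOSYLATION"].members)
        assert members == {
            "LFNG", "MFNG", "RFNG", "B3GLCT", "B4GALT1", "ST6GAL1", "POFUT2", "POFUT1",
        }

    def test_fuc_all_is_union_of_synthesis_and_transferases(self, catalog):
        synthesis = set(catalog["FUC_SYNTHESIS"].members)
        transferases = set(catalog["FUC_TRANSFERASES"].members)
        assert synthesis == {"GMDS", "TSTA3"}
        assert transferases == {"FUT2", "FUT3", "FUT4", "FUT6"}
        assert set(catalog["FUC_ALL"].members) == synthesis | transferases
        assert len(catalog["FUC_ALL"]) == 6

    def test_unique_names_and_gmt_round_trip(self, catalog, tmp_path):
        names = catalog.names()
        assert len(names) == len(set(names))
        path = tmp_path / "cat.gmt"
        write_gmt(catalog, path)
        back = load_gmt(path)
        assert back.names() == names
        for s in catalog:
            assert back[s.name].members == s.members


class TestBulk:
    def test_same_seed_bit_identical(self):
        a = simulate_bulk(BulkSimConfig(seed=3))
        b = simulate_bulk(BulkSimConfig(seed=3))
        for (ma, _), (mb, _) in zip(a, b):
            np.testing.assert_array_equal(ma.values, mb.values)

    def test_noise_free_group_mean(self):
        """sigma = 0: subtype-A mean of a fucosylation gene is exactly
        mu_g + mean(purity) * (a_g + L_g)."""
        config = BulkSimConfig(seed=4, noise_sd=0.0, n_cohorts=1, paired=(False,))
        matrix, metadata = simulate_bulk(config)[0]
        gi = matrix.gene_ids.index("GMDS")
        a_samples = [m for m in metadata if m.true_subtype == "fucosylated"]
        idx = [matrix.sample_ids.index(m.sample_id) for m in a_samples]
        mean_purity = np.mean([m.purity for m in a_samples])
        normals = [matrix.sample_ids.index(m.sample_id) for m in metadata if m.condition == "normal"]
        mu = matrix.values[gi, normals[0]]  # noise-free normals sit at mu exactly
        expected = mu + mean_purity * (config.tumour_shift + config.program_effect)
        assert matrix.values[gi, idx].mean() == pytest.approx(expected, abs=1e-10)

    def test_low_purity_subtype_loads_no_tumour_programs(self):
        config = BulkSimConfig(seed=5, noise_sd=0.0, n_cohorts=1, paired=(False,))
        matrix, metadata = simulate_bulk(config)[0]
        gi = matrix.gene_ids.index("LGALS1")  # basal programme gene
        c_idx = [
            matrix.sample_ids.index(m.sample_id)
            for m in metadata
            if m.true_subtype == "low_purity"
        ]
        normals = [matrix.sample_ids.index(m.sample_id) for m in metadata if m.condition == "normal"]
        mu = matrix.values[gi, normals[0]]
        purities = [m.purity for m in metadata if m.true_subtype == "low_purity"]
        # only the purity-scaled tumour shift, no programme loading
        expected = mu + np.mean(purities) * config.tumour_shift
        assert matrix.values[gi, c_idx].mean() == pytest.approx(expected, abs=1e-10)

    def test_subtype_a_vs_b_separation_on_basal_gene(self):
        """Two-sample t on a basal programme gene separates A from B at
        alpha = 0.01 in nearly every replicate at default effect sizes."""
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            config = BulkSimConfig(seed=seed, n_cohorts=1, paired=(False,))
            matrix, metadata = simulate_bulk(config)[0]
            gi = matrix.gene_ids.index("MUC16")
            idx_a = [matrix.sample_ids.index(m.sample_id) for m in metadata if m.true_subtype == "fucosylated"]
            idx_b = [matrix.sample_ids.index(m.sample_id) for m in metadata if m.true_subtype == "basal"]
            _, p = stats.ttest_ind(matrix.values[gi, idx_b], matrix.values[gi, idx_a])
            hits += p <= 0.01
        assert hits >= int(0.95 * n_rep)

    def test_purity_ordering_planted(self, bulk_default):
        _, cohorts = bulk_default
        _, metadata = cohorts[0]
        low = [m.purity for m in metadata if m.true_subtype == "low_purity"]
        high = [m.purity for m in metadata if m.true_subtype in ("fucosylated", "basal")]
        assert np.mean(low) < np.mean(high)

    def test_paired_cohorts_link_one_tumour_to_one_normal(self, bulk_default):
        config, cohorts = bulk_default
        for (matrix, metadata), paired in zip(cohorts, config.paired):
            pairs: dict[str, list[str]] = {}
            for m in metadata:
                if m.pair_id:
                    pairs.setdefault(m.pair_id, []).append(m.condition)
            if paired:
                assert len(pairs) == config.normals_per_cohort
                assert all(sorted(v) == ["normal", "tumour"] for v in pairs.values())
                # pairs span all three subtypes (round-robin assignment)
                paired_subtypes = {
                    m.true_subtype for m in metadata if m.pair_id and m.condition == "tumour"
                }
                assert paired_subtypes == {"fucosylated", "basal", "low_purity"}
            else:
                assert not pairs

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            BulkSimConfig(subtype_counts={"fucosylated": 1, "basal": 30, "low_purity": 20}).validate()
        with pytest.raises(ValueError):
            BulkSimConfig(noise_sd=-1.0).validate()
        with pytest.raises(ValueError):
            BulkSimConfig(subtype_counts={"weird": 30, "basal": 30, "low_purity": 20}).validate()


class TestSurvival:
    def make_meta(self, seed=0):
        config = BulkSimConfig(seed=seed, n_cohorts=1, paired=(False,))
        return simulate_bulk(config)[0][1]

    def test_records_for_tumours_only_and_seeded(self):
        metadata = self.make_meta()
        config = SurvSimConfig(seed=9)
        a = simulate_survival(metadata, config)
        b = simulate_survival(metadata, config)
        assert a == b
        n_tumours = sum(1 for m in metadata if m.condition == "tumour")
        assert len(a) == n_tumours

    def test_censoring_boundary_all_censored(self):
        metadata = self.make_meta()
        records = simulate_survival(metadata, SurvSimConfig(seed=1, censor_time=1e-6))
        assert all(r.event == 0 for r in records)
        assert all(r.time == pytest.approx(1e-6) for r in records)

    def test_unknown_subtype_rejected(self):
        metadata = self.make_meta()
        config = SurvSimConfig(hazard_ratios={"fucosylated": 1.0})
        with pytest.raises(ValueError, match="unknown subtype|basal"):
            simulate_survival(metadata, config)

    def test_median_ratio_tracks_hazard_ratio(self):
        """HR 2 halves the exponential median: across-seed median of the
        basal/fucosylated empirical median ratio lies in [0.4, 0.65]."""
        config = BulkSimConfig(
            seed=0,
            n_cohorts=1,
            paired=(False,),
            subtype_counts={"fucosylated": 100, "basal": 100, "low_purity": 2},
        )
        metadata = simulate_bulk(config)[0][1]
        ratios = []
        for seed in range(100):
            records = simulate_survival(metadata, SurvSimConfig(seed=seed))
            by = {r.sample_id: r.time for r in records}
            basal = [by[m.sample_id] for m in metadata if m.true_subtype == "basal"]
            fuc = [by[m.sample_id] for m in metadata if m.true_subtype == "fucosylated"]
            ratios.append(np.median(basal) / np.median(fuc))
        assert 0.4 <= np.median(ratios) <= 0.65

    def test_null_hazard_gives_similar_medians(self):
        config = BulkSimConfig(
            seed=0, n_cohorts=1, paired=(False,),
            subtype_counts={"fucosylated": 200, "basal": 200, "low_purity": 2},
        )
        metadata = simulate_bulk(config)[0][1]
        hr1 = SurvSimConfig(seed=2, hazard_ratios={"fucosylated": 1.0, "basal": 1.0, "low_purity": 1.0})
        records = simulate_survival(metadata, hr1)
        by = {r.sample_id: r.time for r in records}
        basal = [by[m.sample_id] for m in metadata if m.true_subtype == "basal"]
        fuc = [by[m.sample_id] for m in metadata if m.true_subtype == "fucosylated"]
        assert np.median(basal) / np.median(fuc) == pytest.approx(1.0, abs=0.35)


class TestSingleCell:
    def test_same_seed_identical(self):
        a = simulate_single_cell(SCSimConfig(seed=2, n_patients=3, cells_per_patient=50))
        b = simulate_single_cell(SCSimConfig(seed=2, n_patients=3, cells_per_patient=50))
        np.testing.assert_array_equal(np.asarray(a.X.todense()), np.asarray(b.X.todense()))
        assert list(a.obs["label"]) == list(b.obs["label"])

    def test_noise_free_limit_counts_are_rounded_means(self):
        config = SCSimConfig(seed=3, n_patients=2, cells_per_patient=30,
                             dispersion=0.0, library_log_sd=0.0)
        adata = simulate_single_cell(config)
        counts = np.asarray(adata.X.todense())
        assert np.allclose(counts, np.round(counts))
        # fixed library: every cell total within rounding of the library size
        lib = np.exp(config.library_log_mean)
        assert np.all(np.abs(counts.sum(axis=1) - lib) < adata.n_vars)

    def test_fucosylation_loads_on_epithelial_end(self):
        """Mean fucosylation-gene expression is higher in u < 0.2 than in
        u > 0.8 tumour cells, every seed tried."""
        fuc = ["GMDS", "TSTA3", "FUT2", "FUT3", "FUT4", "FUT6"]
        for seed in range(5):
            adata = simulate_single_cell(SCSimConfig(seed=seed))
            norm = normalize_log(adata.X)
            cols = [list(adata.var_names).index(g) for g in fuc]
            u = adata.obs["emt_u"].to_numpy()
            tum = (adata.obs["cell_type"] == "tumour").to_numpy()
            lo = norm[np.ix_(tum & (u < 0.2), cols)].mean()
            hi = norm[np.ix_(tum & (u > 0.8), cols)].mean()
            assert lo > hi

    def test_metadata_complete(self, sc_default):
        obs = sc_default.obs
        assert set(obs["cell_type"]) == {"tumour", "macrophage", "other"}
        assert obs["mito_fraction"].between(0, 1).all()
        tum = obs["cell_type"] == "tumour"
        assert obs.loc[tum, "emt_u"].between(0, 1).all()
        assert obs.loc[tum, "label"].str.startswith("tumour_arch").all()
        counts = np.asarray(sc_default.X.todense())
        assert counts.min() >= 0
        assert np.allclose(counts, np.round(counts))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SCSimConfig(cell_type_mix={"tumour": 0.9, "macrophage": 0.3, "other": 0.3}).validate()
        with pytest.raises(ValueError, match="dispersion"):
            SCSimConfig(dispersion=-0.1).validate()
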