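"""Generator contracts: determinism, planted structure, moment checks."""

import numpy as np
import pandas as pd
import pytest

from sclcmet.synthetic_data import (
    SimConfig,
    make_annotation,
    simulate_bulk,
    simulate_peaks,
    simulate_sc,
    simulate_tma,
)


class TestConfigValidation:
    def test_empty_cohort_rejected(self):
        cfg = SimConfig(cohort_sizes={"never_met": 0, "met_primary": 5, "metastasis": 5})
        with pytest.raises(ValueError, match="empty cohort"):
            simulate_bulk(cfg)

    def test_compartment_mix_must_sum_to_one(self):
        cfg = SimConfig(compartment_mix={"epithelial": 0.5, "immune": 0.4})
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_cnv_segment_outside_genome_rejected(self):
        cfg = SimConfig(cnv_segments=[("chr1", 0, 500_000_000, 1.0)])
        with pytest.raises(ValueError, match="outside"):
            simulate_sc(cfg)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimConfig(nb_dispersion=0.0).validate()


class TestDeterminism:
    def test_bulk_bit_reproducible(self, small_cfg):
        b1, _, t1 = simulate_bulk(small_cfg)
        b2, _, t2 = simulate_bulk(small_cfg)
        pd.testing.assert_frame_equal(b1.counts, b2.counts)
        assert t1.planted_driver_ids == t2.planted_driver_ids

    def test_sc_bit_reproducible(self, small_cfg):
        a1, _, t1 = simulate_sc(small_cfg)
        a2, _, t2 = simulate_sc(small_cfg)
        assert (a1.X != a2.X).nnz == 0
        assert t1.malignant_cell_ids == t2.malignant_cell_ids

    def test_tma_and_peaks_reproducible(self, small_cfg):
        pd.testing.assert_frame_equal(simulate_tma(small_cfg), simulate_tma(small_cfg))
        p1, _, tr1 = simulate_peaks(small_cfg)
        p2, _, tr2 = simulate_peaks(small_cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(tr1, tr2)


class TestAnnotation:
    def test_flags_and_coordinates(self, small_cfg):
        anno = make_annotation(small_cfg)
        assert int(anno["is_tf"].sum()) == small_cfg.n_tf
        assert (anno["start"] < anno["end"]).all()
        assert (anno["symbol"] == "FOXA2").sum() == 1
        assert anno.loc[anno["symbol"] == "FOXA2", "is_tf"].all()

    def test_planted_structure_within_annotation(self, small_bulk):
        _, anno, truth = small_bulk
        assert anno.loc[truth.planted_driver_ids, "is_tf"].all()
        assert set(truth.foxa2_module_ids) <= set(anno.index)


class TestBulkGenerator:
    def test_counts_nonnegative_integers(self, small_bulk):
        bulk, _, _ = small_bulk
        vals = bulk.counts.to_numpy()
        assert (vals >= 0).all() and np.issubdtype(vals.dtype, np.integer)

    def test_nb_moment_relation(self):
        """Empirical variance across draws matches mu + alpha*mu^2 within 10%."""
        from sclcmet.synthetic_data import _nb_draw

        rng = np.random.default_rng(7)
        mu, alpha, n = 100.0, 0.2, 10_000
        draws = _nb_draw(rng, np.full(n, mu), alpha)
        expected = mu + alpha * mu**2
        assert draws.var() == pytest.approx(expected, rel=0.10)

    def test_null_effect_size_means_differ_only_by_noise(self, small_cfg):
        from dataclasses import replace

        cfg = replace(small_cfg, driver_log2fc=0.0)
        bulk, _, truth = simulate_bulk(cfg)
        meta = bulk.sample_meta
        drv = bulk.counts.loc[truth.planted_driver_ids]
        lib = bulk.counts.sum(axis=0)
        cpm = drv / lib * lib.mean()
        m_never = cpm.loc[:, meta == "never_met"].mean(axis=1)
        m_met = cpm.loc[:, meta == "metastasis"].mean(axis=1)
        ratio = np.log2(m_met / m_never)
        assert np.abs(ratio).max() < 0.5  # sampling noise only

    def test_planted_drivers_shifted_in_met_cohorts_only(self, small_bulk):
        bulk, _, truth = small_bulk
        meta = bulk.sample_meta
        lib = bulk.counts.sum(axis=0)
        cpm = bulk.counts.loc[truth.planted_driver_ids] / lib * lib.mean()
        m_never = cpm.loc[:, meta == "never_met"].mean(axis=1)
        for cohort in ("met_primary", "metastasis"):
            m = cpm.loc[:, meta == cohort].mean(axis=1)
            assert (np.log2(m / m_never) > 1.5).all()


class TestScGenerator:
    def test_sparsity_at_least_half(self, small_sc):
        adata, _, _ = small_sc
        assert 1.0 - adata.X.nnz / (adata.n_obs * adata.n_vars) >= 0.5

    def test_malignant_cells_are_epithelial(self, small_sc):
        adata, _, truth = small_sc
        mal = adata.obs.loc[truth.malignant_cell_ids]
        assert (mal["compartment_true"] == "epithelial").all()

    def test_foxa2_positive_fraction_binomial(self):
        """Planted 50% FOXA2+ fraction is observed at large cell count."""
        cfg = SimConfig(seed=5, n_patients_sc=10, cells_per_patient=1000)
        adata, _, truth = simulate_sc(cfg)
        mal = adata.obs_names.isin(truth.malignant_cell_ids)
        col = adata.var_names.get_loc(truth.foxa2_gene_id)
        raw = adata.X[:, col].toarray().ravel()
        assert (raw[mal] > 0).mean() == pytest.approx(0.5, abs=0.02)
        # planted positives have count > 0 by construction
        pos = adata.obs_names.isin(truth.foxa2_positive_cell_ids)
        assert (raw[pos] > 0).all()

    def test_null_module_effect_uncorrelated(self):
        """module_effect=0 leaves FOXA2 and module genes uncorrelated.

        Planted low-quality cells are excluded: their extreme shallow depth
        couples all genes positively, and they never reach analysis (QC
        removes them).
        """
        cfg = SimConfig(seed=9, n_patients_sc=10, cells_per_patient=1000,
                        module_effect=0.0)
        adata, _, truth = simulate_sc(cfg)
        keep = adata.obs_names.isin(truth.malignant_cell_ids) & ~adata.obs_names.isin(
            truth.low_quality_cell_ids
        )
        f = adata.X[:, adata.var_names.get_loc(truth.foxa2_gene_id)].toarray().ravel()[keep]
        for g in truth.foxa2_module_ids:
            x = adata.X[:, adata.var_names.get_loc(g)].toarray().ravel()[keep]
            if x.std() > 0:
                assert abs(np.corrcoef(x, f)[0, 1]) < 0.05

    def test_whole_chromosome_gain_raises_bin_signal(self):
        """A planted gain shows a positive mean log-ratio over its chromosome."""
        from sclcmet import sc_malignant as scm

        cfg = SimConfig(seed=3, n_genes=400, n_tf=40, n_planted_drivers=4,
                        n_patients_sc=2, cells_per_patient=500,
                        foxa2_module_size=6,
                        cnv_segments=[("chr1", 0, 120_000_000, 0.5)])
        adata, _, truth = simulate_sc(cfg)
        ad2 = scm.qc_filter(adata)
        scm.normalize_log1p(ad2)
        ref = ad2.obs_names[~ad2.obs_names.isin(truth.malignant_cell_ids)].tolist()
        prof = scm.cnv_signal(ad2, reference_cells=ref)
        mal = np.flatnonzero(ad2.obs_names.isin(truth.malignant_cell_ids))
        chr1 = prof.bins["chrom"] == "chr1"
        assert prof.matrix[np.ix_(mal, np.flatnonzero(chr1))].mean() > 0


class TestTmaGenerator:
    def test_percentages_sum_to_100(self, small_cfg):
        tma = simulate_tma(small_cfg)
        sums = tma[["pct_l0", "pct_l1", "pct_l2", "pct_l3"]].sum(axis=1)
        assert np.allclose(sums, 100.0)

    def test_h_score_consistent_with_percentages(self, small_cfg):
        tma = simulate_tma(small_cfg)
        recomputed = tma["pct_l1"] + 2 * tma["pct_l2"] + 3 * tma["pct_l3"]
        assert np.allclose(tma["h_score"], recomputed)

    def test_null_slope_recurrence_independent_of_score(self):
        """With slope 0 the cutpoint search is no better than chance."""
        from sclcmet.biomarker_survival import optimal_cutpoint

        metrics = []
        for seed in range(30):
            tma = simulate_tma(SimConfig(seed=seed, tma_n=60, tma_risk_slope=0.0))
            cut = optimal_cutpoint(tma["h_score"], tma["recurrence"])
            metrics.append(cut.metric)
        # best-of-many thresholds overfits slightly above 1, but stays far
        # below the perfect-separation value of 2
        assert 1.0 <= np.mean(metrics) < 1.5

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="tma_n"):
            simulate_tma(SimConfig(tma_n=3))


class TestPeakGenerator:
    def test_truth_matches_brute_force(self, small_cfg):
        peaks, anno, truth = simulate_peaks(small_cfg)
        # independent re-derivation for a subsample
        for pid, pk in peaks.sample(40, random_state=0).iterrows():
            mid = (pk["start"] + pk["end"]) // 2
            sub = anno[anno["chrom"] == pk["chrom"]]
            tss = np.where(sub["strand"] == "+", sub["start"], sub["end"] - 1)
            inside = sub[(sub["start"] < pk["end"]) & (sub["end"] > pk["start"])]
            if len(inside):
                assert truth.loc[pid, "relation"] == "intragenic"
                assert truth.loc[pid, "gene_id"] in set(inside["gene_id"])
            else:
                assert truth.loc[pid, "relation"] == "nearest_tss"
                assert truth.loc[pid, "distance"] == int(np.abs(tss - mid).min())

    def test_intervals_valid(self, small_cfg):
        peaks, _, _ = simulate_peaks(small_cfg)
        assert (peaks["start"] < peaks["end"]).all()
        assert ((peaks["summit"] >= peaks["start"]) & (peaks["summit"] < peaks["end"])).all()


class TestRoundTrip:
    def test_writers_produce_readable_text(self, tmp_path, small_cfg, small_bulk):
        from scipy.io import mmread

        from sclcmet.synthetic_data import (
            write_annotation, write_bulk, write_peaks, write_sc_mtx, write_tma,
        )
        from sclcmet.peak_tools import read_narrowpeak

        bulk, anno, truth = small_bulk
        write_bulk(bulk, tmp_path)
        back = pd.read_csv(tmp_path / "bulk_counts.tsv", sep="\t", index_col=0)
        assert back.shape == bulk.counts.shape

        write_annotation(anno, tmp_path / "anno.tsv")
        anno_back = pd.read_csv(tmp_path / "anno.tsv", sep="\t")
        assert list(anno_back.columns) == list(anno.columns)

        adata, _, _ = simulate_sc(small_cfg)
        write_sc_mtx(adata, tmp_path / "sc")
        m = mmread(tmp_path / "sc" / "matrix.mtx")
        assert m.shape == adata.shape

        peaks, _, _ = simulate_peaks(small_cfg)
        write_peaks(peaks, tmp_path / "peaks.narrowPeak")
        pk_back = read_narrowpeak(tmp_path / "peaks.narrowPeak")
        assert (pk_back["summit"].to_numpy() == peaks["summit"].to_numpy()).all()

        tma = simulate_tma(small_cfg)
        write_tma(tma, tmp_path / "tma.tsv")
        truth.to_json(tmp_path / "truth.json")
        assert (tmp_path / "truth.json").stat().st_size > 0
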