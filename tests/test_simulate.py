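import numpy as np
import pytest

from lcmseq.quantify import to_rpm
from lcmseq.simulate import (
    SimConfig,
    SimTruth,
    default_ercc_reference,
    gen_ct_plate,
    gen_ercc_counts,
    gen_exon_table,
    gen_fresh_vs_section,
    gen_granulosa_cohort,
    gen_oocyte_cohort,
    logistic_level,
)


class TestOocyteCohort:
    def test_determinism(self, fast_sim):
        m1, r1, t1 = gen_oocyte_cohort(fast_sim, 1)
        m2, r2, t2 = gen_oocyte_cohort(fast_sim, 1)
        np.testing.assert_array_equal(m1.counts, m2.counts)
        assert t1.observed_diameter_um == t2.observed_diameter_um

    def test_cohort_size_default(self):
        cfg = SimConfig(n_genes=1000, n_rising=50, n_falling=25,
                        n_oocyte_specific=50, seed=0)
        m, recs, truth = gen_oocyte_cohort(cfg, 1)
        assert m.n_cells == 44
        assert len(recs) == 44
        assert len(m.spike_ids) == 92

    def test_flat_degenerate_generator(self):
        cfg = SimConfig(
            n_genes=200, n_rising=0, n_falling=0, n_oocyte_specific=0,
            n_deg_neighboring=0, n_deg_nonneighboring=0,
            noise_sd=0.0, dropout=False, n_retarded=0, seed=0,
        )
        m, recs, truth = gen_oocyte_cohort(cfg, 0)
        # flat genes only, no noise: every cell has the same expected profile
        log2 = to_rpm(m, denominator_mode="genes").log2
        spread = log2.max(axis=1) - log2.min(axis=1)
        # only Poisson sampling separates cells
        assert np.median(spread) < 0.6
        assert all(k == 0 for k in truth.steepness)

    def test_planted_rising_gene_correlation(self, fast_sim):
        cfg = SimConfig(**{**fast_sim.__dict__, "n_retarded": 0})
        m, recs, truth = gen_oocyte_cohort(cfg, 2)
        log2 = to_rpm(m).log2
        d = np.array([r.diameter_um for r in recs])
        classes = np.array(truth.gene_classes)
        amp = np.array(truth.upper) - np.array(truth.lower)
        k = np.array(truth.steepness)
        lo = np.array(truth.lower)
        d0 = np.array(truth.inflection_um)
        # steep, high-amplitude, centrally inflected rising genes correlate
        # strongly with diameter
        strong = (
            (classes == "rising-sigmoid") & (amp > 4.5) & (k > 0.1)
            & (lo > 2.0) & (d0 > 35) & (d0 < 65)
        )
        rs = np.array([np.corrcoef(log2[i], d)[0, 1] for i in np.where(strong)[0]])
        assert strong.sum() >= 5
        assert np.median(rs) > 0.85

    def test_retarded_cells_use_effective_diameter(self, fast_sim):
        m, recs, truth = gen_oocyte_cohort(fast_sim, 3)
        obs = np.array(truth.observed_diameter_um)
        eff = np.array(truth.effective_diameter_um)
        ret = np.array(truth.retarded)
        assert ret.sum() == fast_sim.n_retarded
        np.testing.assert_allclose(obs[ret] - eff[ret], fast_sim.retardation_um)
        np.testing.assert_allclose(obs[~ret], eff[~ret])
        assert np.all(eff <= obs)

    def test_too_many_retarded_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_oocytes=4, n_retarded=5)

    def test_degenerate_diameter_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SimConfig(diameter_min_um=50, diameter_max_um=50)


class TestGranulosaCohort:
    def test_no_mixing_fraction_zero(self, fast_sim):
        cfg = SimConfig(**{**fast_sim.__dict__, "n_mixed": 0})
        m, recs, truth = gen_granulosa_cohort(cfg, 1)
        assert not any(truth.mixed)
        assert truth.mixing_fraction == 0.0

    def test_planted_offset_recovered(self, fast_sim):
        cfg = SimConfig(**{**fast_sim.__dict__, "dropout": False})
        m, recs, truth = gen_granulosa_cohort(cfg, 1)
        log2 = to_rpm(m).log2
        pos = np.array(truth.positions)
        idx = [m.gene_ids.index(g) for g in truth.deg_up_nonneighboring]
        mixed = np.array(truth.mixed)
        nn = (pos == "non_neighboring") & ~mixed
        nb = (pos == "neighboring") & ~mixed
        diff = log2[idx][:, nn].mean() - log2[idx][:, nb].mean()
        assert diff == pytest.approx(fast_sim.deg_offset_log2, abs=0.3)

    def test_mixed_cell_correlates_with_oocyte_mean(self, fast_sim):
        m, recs, truth = gen_granulosa_cohort(fast_sim, 2)
        log2 = to_rpm(m).log2
        ooc = np.array(truth.oocyte_mean_log2)
        cors = np.array([np.corrcoef(log2[:, i], ooc)[0, 1] for i in range(m.n_cells)])
        mixed = np.array(truth.mixed)
        assert cors[mixed].min() > cors[~mixed].max()

    def test_sporadic_genes_confined_to_neighboring(self, fast_sim):
        m, recs, truth = gen_granulosa_cohort(fast_sim, 3)
        log2 = to_rpm(m).log2
        pos = np.array(truth.positions)
        mixed = np.array(truth.mixed)
        idx = [m.gene_ids.index(g) for g in truth.deg_up_neighboring]
        non_neigh = log2[idx][:, (pos == "non_neighboring") & ~mixed]
        assert non_neigh.mean() < 1.0

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_granulosa=3, n_neighboring=3)


class TestFreshVsSection:
    def test_null_cohorts_exchangeable(self, fast_sim):
        cfg = SimConfig(**{**fast_sim.__dict__,
                           "n_detection_error_genes": 0, "n_bias_genes": 0})
        fresh, section, truth = gen_fresh_vs_section(cfg, 1)
        assert truth.detection_error_genes == []
        f = (fresh.counts > 0).mean()
        s = (section.counts > 0).mean()
        assert f == pytest.approx(s, abs=0.01)

    def test_planted_bias_recovered(self):
        cfg = SimConfig(n_genes=3000, n_rising=0, n_falling=0,
                        n_oocyte_specific=0, n_deg_neighboring=0,
                        n_deg_nonneighboring=0, n_bias_genes=100,
                        n_detection_error_genes=0, bias_shift_log2=-2.0,
                        artifact_level_range=(3.0, 6.0), dropout=False, seed=0)
        fresh, section, truth = gen_fresh_vs_section(cfg, 1)
        fl = to_rpm(fresh).log2
        sl = to_rpm(section).log2
        idx = [fresh.gene_ids.index(g) for g in truth.bias_genes]
        diff = sl[idx].mean() - fl[idx].mean()
        assert diff == pytest.approx(-2.0, abs=0.4)

    def test_planted_detection_gap(self):
        cfg = SimConfig(n_genes=3000, n_rising=0, n_falling=0,
                        n_oocyte_specific=0, n_deg_neighboring=0,
                        n_deg_nonneighboring=0, n_bias_genes=0,
                        n_detection_error_genes=50, detection_drop=0.4,
                        artifact_level_range=(4.5, 6.0),
                        n_section_cells=200, seed=0)
        fresh, section, truth = gen_fresh_vs_section(cfg, 1)
        idx = [fresh.gene_ids.index(g) for g in truth.detection_error_genes]
        gap = (fresh.counts[idx] > 0).mean() - (section.counts[idx] > 0).mean()
        assert gap == pytest.approx(0.4, abs=0.08)

    def test_artifact_overflow_rejected(self):
        with pytest.raises(ValueError):
            cfg = SimConfig(n_genes=100, n_rising=0, n_falling=0,
                            n_oocyte_specific=0, n_deg_neighboring=0,
                            n_deg_nonneighboring=0,
                            n_detection_error_genes=80, n_bias_genes=40)
            gen_fresh_vs_section(cfg, 0)


class TestErccGenerator:
    def test_expectation_mode_identity(self):
        import pandas as pd
        ref = pd.Series([4.0, 16.0, 64.0], index=["ERCC-1", "ERCC-2", "ERCC-3"])
        counts, truth = gen_ercc_counts(ref, 1.0, seed=0, scale=1.0, expectation=True)
        np.testing.assert_array_equal(counts, [4, 16, 64])

    def test_determinism(self):
        ref = default_ercc_reference(92)
        c1, _ = gen_ercc_counts(ref, 0.5, seed=11)
        c2, _ = gen_ercc_counts(ref, 0.5, seed=11)
        np.testing.assert_array_equal(c1, c2)

    def test_log_log_slope_near_one(self):
        ref = default_ercc_reference(92)
        counts, _ = gen_ercc_counts(ref, 1.0, seed=5)
        pos = counts > 0
        slope = np.polyfit(np.log2(ref.to_numpy()[pos]), np.log2(counts[pos]), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_bad_efficiency(self):
        ref = default_ercc_reference(5)
        with pytest.raises(ValueError):
            gen_ercc_counts(ref, 0.0)
        with pytest.raises(ValueError):
            gen_ercc_counts(ref, 0.5, scale=-1)


class TestCtPlate:
    def test_null_plate(self):
        ct, truth = gen_ct_plate(48, n_failures=0, seed=0)
        assert not any(truth.failed_wells)
        assert len(ct) == 48

    def test_planted_failures_are_maxima(self):
        hits = 0
        for s in range(20):
            ct, truth = gen_ct_plate(48, n_failures=8, failure_shift=8.0, seed=s)
            failed = np.array(truth.failed_wells)
            top8 = set(np.argsort(ct)[-8:])
            hits += top8 == set(np.where(failed)[0])
        assert hits >= 19

    def test_determinism(self):
        c1, _ = gen_ct_plate(24, seed=3)
        c2, _ = gen_ct_plate(24, seed=3)
        np.testing.assert_array_equal(c1, c2)

    def test_validation(self):
        with pytest.raises(ValueError):
            gen_ct_plate(2)
        with pytest.raises(ValueError):
            gen_ct_plate(10, n_failures=10)


class TestExonTable:
    def test_single_exon_genes(self):
        model, exon_m, junc_m, truth = gen_exon_table(
            n_genes=30, exons_per_gene_distribution=[1], seed=0
        )
        assert junc_m.n_features == 0
        for txs in model.transcripts.values():
            assert all(len(e) == 1 for e in txs.values())

    def test_uniform_high_coverage_saturates(self):
        from lcmseq.junctions import detectable_mask, exon_detection_rates, tmm_factors, tmm_values
        model, exon_m, _, _ = gen_exon_table(
            n_genes=50, seed=0, base_count=500.0, decay_half_life_exons=1e9
        )
        tmm = tmm_factors(exon_m.counts)
        mask = detectable_mask(tmm_values(exon_m.counts, tmm))
        rates = exon_detection_rates(mask, exon_m.feature_ids, model)
        assert rates.table["detection_rate"].min() == 1.0

    def test_decay_reduces_detection_with_exon_count(self):
        from lcmseq.junctions import detectable_mask, exon_detection_rates, tmm_factors, tmm_values
        model, exon_m, _, _ = gen_exon_table(n_genes=300, seed=1)
        tmm = tmm_factors(exon_m.counts)
        mask = detectable_mask(tmm_values(exon_m.counts, tmm))
        rates = exon_detection_rates(mask, exon_m.feature_ids, model)
        tab = rates.table
        few = tab[tab["n_exons"] <= 10]["detection_rate"].mean()
        many = tab[tab["n_exons"] > 20]["detection_rate"].mean()
        assert few > many

    def test_truth_records_expectations(self):
        _, exon_m, _, truth = gen_exon_table(n_genes=20, seed=0)
        assert set(truth.exon_expected_counts["exon"]) == set(exon_m.feature_ids)


class TestSimTruthIo:
    def test_json_round_trip(self, fast_sim, tmp_path):
        _, _, truth = gen_oocyte_cohort(fast_sim, 1)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = SimTruth.from_json(p)
        assert back == truth


def test_logistic_level_shape():
    d = np.array([20.0, 45.0, 80.0])
    lam = logistic_level(d, np.array(0.0), np.array(4.0), np.array(10.0), np.array(45.0))
    assert lam[0] == pytest.approx(0.0, abs=1e-6)
    assert lam[1] == pytest.approx(2.0)
    assert lam[2] == pytest.approx(4.0, abs=1e-6)
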