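import numpy as np
import pandas as pd
import pytest

from mirquiescent import (
    AnnotationConfig,
    CohortConfig,
    PlantedEffect,
    TargetConfig,
    colocalize_with_loci,
    delta_ct,
    detection_filter,
    dispersion_summary,
    generate_annotation,
    generate_cohort,
    generate_target_catalog,
    group_by_band,
    relative_expression,
)
from mirquiescent.errors import ConfigError


class TestCohortShape:
    def test_default_cohort_matches_study_design(self, default_cohort):
        ct, samples, _ = default_cohort
        assert len(ct.mirna_ids) == 321
        assert ct.values.shape == (322, 42)  # panel + U6 reference row
        assert len(samples.samples_in_group("control")) == 10
        assert len(samples.samples_in_condition("UC_quiescent")) == 8
        assert len(samples.samples_in_condition("CD_inflamed")) == 8

    def test_same_seed_is_byte_identical(self):
        a = generate_cohort(CohortConfig(seed=42))
        b = generate_cohort(CohortConfig(seed=42))
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[1].frame, b[1].frame)
        assert a[2].effects == b[2].effects

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(seed=1))
        b = generate_cohort(CohortConfig(seed=2))
        assert not a[0].values.equals(b[0].values)

    def test_zero_dispersion_no_effects_gives_flat_log_fold(self):
        cfg = CohortConfig(
            n_mirnas=20,
            dispersion_mean=0.0,
            dispersion_sd=0.0,
            control_noise_sd=0.0,
            detection_tail_fraction=0.0,
            planted_up=[],
            planted_down=[],
            seed=5,
        )
        ct, samples, _ = generate_cohort(cfg)
        rel = relative_expression(delta_ct(ct), samples)
        assert np.allclose(rel.log_fold.to_numpy(), 0.0, atol=1e-9)

    def test_detection_tail_is_censored(self, default_cohort):
        ct, samples, truth = default_cohort
        det = detection_filter(ct, samples)
        for cond in det.per_condition.columns:
            detected = det.detected_set(cond)
            assert not (detected & truth.undetectable)

    def test_planted_effect_shifts_measured_log_fold(self):
        cfg = CohortConfig(
            n_mirnas=30,
            detection_tail_fraction=0.0,
            planted_up=[PlantedEffect(0, "UC_quiescent", 15.0)],
            planted_down=[PlantedEffect(1, "UC_quiescent", -15.0)],
            seed=9,
        )
        ct, samples, truth = generate_cohort(cfg)
        rel = relative_expression(delta_ct(ct), samples)
        uc = samples.samples_in_condition("UC_quiescent")
        up_id, dn_id = cfg.mirna_ids()[0], cfg.mirna_ids()[1]
        assert rel.log_fold.loc[up_id, uc].mean() > 7
        assert rel.log_fold.loc[dn_id, uc].mean() < -7

    def test_invalid_planted_configs_rejected(self):
        with pytest.raises(ConfigError):
            generate_cohort(
                CohortConfig(planted_up=[PlantedEffect(400, "UC_quiescent", 10.0)])
            )
        with pytest.raises(ConfigError):
            generate_cohort(
                CohortConfig(planted_up=[PlantedEffect(0, "UC_sideways", 10.0)])
            )
        with pytest.raises(ConfigError):
            generate_cohort(
                CohortConfig(planted_up=[PlantedEffect(0, "UC_quiescent", -3.0)])
            )

    def test_inflamed_carryover(self):
        cfg = CohortConfig(
            n_mirnas=10,
            detection_tail_fraction=0.0,
            planted_up=[PlantedEffect(0, "CD_quiescent", 12.0)],
            planted_down=[],
            inflamed_extra_log_fold=2.0,
            seed=3,
        )
        _, _, truth = generate_cohort(cfg)
        mid = cfg.mirna_ids()[0]
        assert truth.effects[(mid, "CD_quiescent")] == 12.0
        assert truth.effects[(mid, "CD_inflamed")] == pytest.approx(14.0)


class TestDispersionCalibration:
    def test_pooled_sd_population_matches_targets(self, default_cohort, default_rel):
        """The generator's pooled per-miRNA SD population hits 6.3 ± 1.4."""
        rel, samples, det = default_rel
        disp = dispersion_summary(rel, samples, detection=det)
        assert abs(disp.mean_disp - 6.3) < 0.3
        assert abs(disp.sd_disp - 1.4) < 0.3

    def test_true_sigma_population_near_targets(self, default_cohort):
        _, _, truth = default_cohort
        sig = np.array(list(truth.sigma_log_fold.values()))
        assert abs(sig.mean() - 6.3) < 0.5  # pre-bias-correction target ≈ 6.42


class TestAnnotationGenerator:
    def test_planted_duplex_and_cluster_recovered(self):
        cfg = AnnotationConfig(n_duplexes=1, n_clusters=1, cluster_size=3, seed=2)
        annotation, _loci, truth = generate_annotation(cfg)
        groups = group_by_band(annotation)
        duplexes = [g for g in groups if g.category == "duplex"]
        clusters = [g for g in groups if g.category == "cluster"]
        assert len(duplexes) == 1 and len(clusters) == 1
        assert duplexes[0].gene_ids == sorted(truth.duplex_bands[0][2])
        assert clusters[0].gene_ids == sorted(truth.cluster_bands[0][2])

    def test_loci_overlap_truth(self):
        annotation, loci, truth = generate_annotation(AnnotationConfig(seed=6))
        table = colocalize_with_loci(annotation, loci, window_bp=0)
        assert set(table.gene_id) == truth.genes_in_loci

    def test_zero_loci_gives_no_overlap(self):
        cfg = AnnotationConfig(n_loci=0, n_genes_in_loci=0, seed=1)
        annotation, loci, _ = generate_annotation(cfg)
        assert colocalize_with_loci(annotation, loci).empty

    def test_seed_reproducibility(self):
        a = generate_annotation(AnnotationConfig(seed=4))
        b = generate_annotation(AnnotationConfig(seed=4))
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1].frame, b[1].frame)

    def test_capacity_exceeded_rejected(self):
        cfg = AnnotationConfig(
            n_singletons=100, chromosome_length=1_000_000, gene_spacing=500_000,
            n_chromosomes=1, n_loci=0, n_genes_in_loci=0,
        )
        with pytest.raises(ConfigError):
            generate_annotation(cfg)


class TestTargetGenerator:
    def test_catalog_has_no_duplicate_pairs(self):
        cat, _, _ = generate_target_catalog(TargetConfig(seed=1))
        assert not cat.pairs.duplicated(["mirna_id", "gene_id"]).any()

    def test_seed_reproducibility(self):
        a = generate_target_catalog(TargetConfig(seed=7))
        b = generate_target_catalog(TargetConfig(seed=7))
        pd.testing.assert_frame_equal(a[0].pairs, b[0].pairs)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_every_gene_annotated(self):
        _, proc, _ = generate_target_catalog(TargetConfig(n_genes=50, seed=2))
        assert proc.gene_id.nunique() == 50
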