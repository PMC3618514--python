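"""Synthetic cohort generator: phenotypes, BOLD, labels, FA."""

import numpy as np
import pandas as pd
import pytest

from traitconn import (
    SyntheticCohortConfig,
    build_connectivity,
    combined_trait_score,
    generate_bold,
    generate_fa,
    generate_label_volumes,
    generate_phenotypes,
    wavelet_correlation,
    modwt,
)


class TestPhenotypes:
    def test_cohort_size_and_schema(self):
        cfg = SyntheticCohortConfig(n_subjects=127, seed=1)
        ph = generate_phenotypes(cfg)
        assert len(ph) == 127
        assert set(ph.columns) == {
            "subject_id", "age", "gender", "verbal_iq", "performance_iq",
            "full_iq", "assq", "srs",
        }
        assert ph["age"].between(18, 65).all()
        assert ph["assq"].between(0, 39).all()
        assert ph["srs"].between(0, 195).all()
        assert set(ph["gender"]) <= {"female", "male"}

    def test_viq_piq_correlation_at_cohort_scale(self):
        ph = generate_phenotypes(SyntheticCohortConfig(n_subjects=127, seed=1))
        r = np.corrcoef(ph["verbal_iq"], ph["performance_iq"])[0, 1]
        assert 0.45 <= r <= 0.65

    def test_trait_iq_correlations_within_tolerance_at_cohort_scale(self):
        ph = generate_phenotypes(SyntheticCohortConfig(n_subjects=127, seed=1))
        r_assq = np.corrcoef(ph["verbal_iq"], ph["assq"])[0, 1]
        r_srs = np.corrcoef(ph["verbal_iq"], ph["srs"])[0, 1]
        assert r_assq == pytest.approx(-0.393, abs=0.1)
        assert r_srs == pytest.approx(-0.343, abs=0.1)

    def test_large_sample_converges_to_target_correlation(self):
        ph = generate_phenotypes(SyntheticCohortConfig(n_subjects=5000, seed=2))
        r = np.corrcoef(ph["verbal_iq"], ph["assq"])[0, 1]
        assert r == pytest.approx(-0.393, abs=0.03)

    def test_assq_right_skewed_srs_symmetric(self):
        ph = generate_phenotypes(SyntheticCohortConfig(n_subjects=5000, seed=3))
        from scipy import stats

        # ASSQ is strongly right-skewed; SRS is near-normal (mild right
        # skew from the floor at 0 is expected)
        assert stats.skew(ph["assq"]) > 1.5
        assert abs(stats.skew(ph["srs"])) < 0.5

    def test_seeded_runs_are_identical(self):
        cfg = SyntheticCohortConfig(n_subjects=127, seed=1)
        pd.testing.assert_frame_equal(generate_phenotypes(cfg), generate_phenotypes(cfg))

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(n_subjects=5)
        with pytest.raises(ValueError):
            SyntheticCohortConfig(n_subjects=0)


class TestBold:
    def test_shapes_and_determinism(self):
        cfg = SyntheticCohortConfig(n_subjects=12, n_regions=20, seed=4)
        ph = generate_phenotypes(cfg)
        bold = generate_bold(cfg, ph)
        assert bold.shape == (12, 20, 260)
        assert np.array_equal(bold, generate_bold(cfg, ph))

    def test_phenotype_count_mismatch_raises(self):
        cfg = SyntheticCohortConfig(n_subjects=12, n_regions=10, seed=4)
        ph = generate_phenotypes(cfg).iloc[:6]
        with pytest.raises(ValueError, match="does not match"):
            generate_bold(cfg, ph)

    def test_shared_community_signal_saturates_band3_correlation(self):
        # two regions in one community with no noise share nearly all their
        # band-3 variance
        cfg = SyntheticCohortConfig(
            n_subjects=10, n_regions=2, n_communities=1, noise_sd=0.0,
            effect_sizes={"hub_coupling": 0.0, "local_efficiency": 0.0, "fa": 0.0},
            long_range_fraction=0.0, seed=5,
        )
        ph = generate_phenotypes(cfg)
        bold = generate_bold(cfg, ph)
        r = wavelet_correlation(modwt(bold[0][0]), modwt(bold[0][1]), 3)
        assert r > 0.99

    def test_band3_concentration_of_coupling(self):
        cfg = SyntheticCohortConfig(n_subjects=10, n_regions=10, seed=6)
        ph = generate_phenotypes(cfg)
        bold = generate_bold(cfg, ph)
        # two same-community regions correlate more strongly in band 3 than
        # in band 1 (coupling is band-limited, noise is white)
        d0, d1 = modwt(bold[0][0]), modwt(bold[0][1])
        assert abs(wavelet_correlation(d0, d1, 3)) > abs(wavelet_correlation(d0, d1, 1))

    def test_null_effects_leave_networks_exchangeable(self):
        # with zero effect sizes the trait/hub-strength correlation is pure
        # sampling noise: the mean Fisher z over replicate cohorts must be
        # consistent with zero (each z ~ N(0, 1), so the mean of 5 has
        # SD 1/sqrt(5); 3-sigma bound)
        zs = []
        for seed in range(7, 12):
            cfg = SyntheticCohortConfig(
                n_subjects=24, n_regions=16, seed=seed,
                effect_sizes={"hub_coupling": 0.0, "local_efficiency": 0.0, "fa": 0.0},
            )
            ph = generate_phenotypes(cfg)
            bold = generate_bold(cfg, ph)
            trait = combined_trait_score(ph)
            hub_strength = []
            for s in range(cfg.n_subjects):
                _, net = build_connectivity(bold[s], tr=cfg.tr, level=3)
                hub_strength.append(net.w[cfg.hub_region].sum())
            r = np.corrcoef(trait, hub_strength)[0, 1]
            zs.append(np.arctanh(r) * np.sqrt(cfg.n_subjects - 3))
        assert abs(np.mean(zs)) < 3 / np.sqrt(len(zs))


class TestLabelVolumes:
    def test_every_region_owns_a_voxel_after_resolution(self):
        cfg = SyntheticCohortConfig(n_subjects=10, n_regions=30, seed=8)
        labels = generate_label_volumes(cfg)
        weights = labels.effective_weights()
        assert (weights.reshape(30, -1).sum(axis=1) > 0).all()

    def test_regions_overlap_before_resolution(self):
        cfg = SyntheticCohortConfig(n_subjects=10, n_regions=30, seed=8)
        labels = generate_label_volumes(cfg)
        above = (labels.probabilities > labels.threshold).sum(axis=0)
        assert (above > 1).any()

    def test_disjoint_regions_unchanged_by_resolution(self):
        probs = np.zeros((2, 2, 1, 1))
        probs[0, 0], probs[1, 1] = 0.8, 0.9
        from traitconn import LabelVolumeSet

        labels = LabelVolumeSet(probabilities=probs, region_names=["a", "b"])
        assert np.allclose(labels.effective_weights(), probs)

    def test_highest_probability_wins_overlap(self):
        probs = np.zeros((2, 1, 1, 1))
        probs[0, 0], probs[1, 0] = 0.6, 0.4
        from traitconn import LabelVolumeSet

        labels = LabelVolumeSet(probabilities=probs, region_names=["a", "b"])
        assert labels.assignment()[0, 0, 0] == 0

    def test_probability_tie_goes_to_lower_region_index(self):
        probs = np.full((2, 1, 1, 1), 0.5)
        from traitconn import LabelVolumeSet

        labels = LabelVolumeSet(probabilities=probs, region_names=["a", "b"])
        assert labels.assignment()[0, 0, 0] == 0

    def test_too_small_grid_raises(self):
        cfg = SyntheticCohortConfig(n_subjects=10, n_regions=30, grid_shape=(3, 3, 3), seed=8)
        with pytest.raises(ValueError, match="too small"):
            generate_label_volumes(cfg)


class TestFA:
    def test_zero_slope_leaves_fa_independent_of_trait(self):
        cfg = SyntheticCohortConfig(
            n_subjects=500, n_regions=20, seed=9,
            effect_sizes={"hub_coupling": 0.0, "local_efficiency": 0.0, "fa": 0.0},
        )
        ph = generate_phenotypes(cfg)
        fa = generate_fa(cfg, ph)
        trait = combined_trait_score(ph)
        corrs = [np.corrcoef(trait, fa.iloc[:, j])[0, 1] for j in range(20)]
        assert np.max(np.abs(corrs)) < 0.2

    def test_negative_slope_recovered_in_effect_regions(self):
        cfg = SyntheticCohortConfig(
            n_subjects=500, n_regions=20, seed=10,
            effect_sizes={"hub_coupling": 0.0, "local_efficiency": 0.0, "fa": -0.4},
        )
        ph = generate_phenotypes(cfg)
        fa = generate_fa(cfg, ph)
        trait = combined_trait_score(ph)
        for region in cfg.fa_effect_indices:
            r = np.corrcoef(trait, fa.iloc[:, region])[0, 1]
            assert r == pytest.approx(-0.4, abs=0.12)

    def test_fa_values_in_open_unit_interval(self):
        cfg = SyntheticCohortConfig(n_subjects=50, n_regions=15, seed=11)
        fa = generate_fa(cfg, generate_phenotypes(cfg))
        assert (fa > 0).all().all() and (fa < 1).all().all()

    def test_same_seed_gives_identical_tables(self):
        cfg = SyntheticCohortConfig(n_subjects=30, n_regions=10, seed=12)
        ph = generate_phenotypes(cfg)
        pd.testing.assert_frame_equal(generate_fa(cfg, ph), generate_fa(cfg, ph))
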