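"""Synthetic-cohort generator: planted structure and determinism."""

import numpy as np
import pytest
from scipy.stats import norm

from radscore.io import CLINICAL_VARIABLES, icc_2_1
from radscore.stats import auc_delong
from radscore.synthetic import (
    ConfigurationError,
    SimulationConfig,
    generate_clinical_table,
    generate_feature_table,
    generate_phantom_volume,
    generate_rater_replicates,
    inject_missingness,
)


class TestFeatureTable:
    def test_default_cohort_shapes_and_balance(self):
        cfg = SimulationConfig(seed=1)
        t, _ = generate_feature_table(cfg, "derivation")
        assert t.values.shape == (120, 107)
        assert int(t.labels.sum()) == 60
        v, _ = generate_feature_table(cfg, "validation")
        assert v.values.shape == (50, 107)
        assert int(v.labels.sum()) == 25

    def test_class_prefixes_and_counts(self):
        t, _ = generate_feature_table(SimulationConfig(seed=1))
        counts = {}
        for name in t.feature_names:
            counts[name.split("_")[0]] = counts.get(name.split("_")[0], 0) + 1
        assert counts == {"shape": 14, "firstorder": 18, "glcm": 24, "glrlm": 16,
                          "glszm": 16, "gldm": 14, "ngtdm": 5}

    def test_null_config_features_have_chance_auc(self):
        cfg = SimulationConfig(seed=2, n_derivation=2000, n_informative=0,
                               effect_sizes=(), n_redundant_pairs=0, n_zero_variance=0)
        t, _ = generate_feature_table(cfg, "derivation")
        devs = np.array([abs(auc_delong(t.values[f], t.labels)[0] - 0.5)
                         for f in t.feature_names])
        # per-feature AUC SE at 1000/1000 is ~0.013: the bulk must sit at
        # chance level, with only sampling-noise excursions beyond 0.03
        assert devs.mean() < 0.015
        assert (devs > 0.03).mean() < 0.10
        assert devs.max() < 0.06

    def test_single_effect_auc_matches_closed_form(self):
        # two unit-variance normals shifted by d have AUC Phi(d / sqrt 2);
        # cross-checked against a Monte-Carlo oracle
        d = 1.0
        oracle_rng = np.random.default_rng(7)
        a = oracle_rng.standard_normal((4000,))
        b = oracle_rng.standard_normal((4000,)) + d
        mc = (b[:, None] > a[None, :]).mean()
        closed = norm.cdf(d / np.sqrt(2))
        assert mc == pytest.approx(closed, abs=0.02)
        cfg = SimulationConfig(seed=3, n_derivation=5000, n_informative=1,
                               effect_sizes=(d,), n_redundant_pairs=0, n_zero_variance=0)
        t, truth = generate_feature_table(cfg, "derivation")
        auc, _, _ = auc_delong(t.values[truth.informative_feature_names[0]], t.labels)
        assert auc == pytest.approx(closed, abs=0.02)

    def test_redundant_pairs_strongly_correlated(self):
        t, truth = generate_feature_table(SimulationConfig(seed=4))
        for a, b in truth.redundant_pair_names:
            r = np.corrcoef(t.values[a], t.values[b])[0, 1]
            assert abs(r) >= 0.9

    def test_zero_variance_columns_constant(self):
        t, truth = generate_feature_table(SimulationConfig(seed=4))
        for name in truth.zero_variance_names:
            assert t.values[name].nunique() == 1

    def test_seed_determinism(self):
        a, _ = generate_feature_table(SimulationConfig(seed=5))
        b, _ = generate_feature_table(SimulationConfig(seed=5))
        assert a.values.equals(b.values)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_features=10,
                             feature_class_counts={"shape": 10},
                             n_informative=6, effect_sizes=(1,) * 6,
                             n_redundant_pairs=3, n_zero_variance=2).validate()


class TestRaterReplicates:
    def test_zero_noise_gives_identical_replicates(self):
        t, _ = generate_feature_table(SimulationConfig(seed=6))
        a, b = generate_rater_replicates(t, 0.0, seed=1)
        assert a.values.equals(b.values)
        name = next(n for n in t.feature_names if t.values[n].nunique() > 1)
        assert icc_2_1(np.column_stack([a.values[name], b.values[name]])) == pytest.approx(1.0)

    def test_noise_equal_to_signal_halves_icc(self):
        t, _ = generate_feature_table(SimulationConfig(seed=6))
        a, b = generate_rater_replicates(t, 1.0, seed=2)
        # shape-class features keep unit between-subject variance
        name = next(n for n in t.feature_names if n.startswith("shape")
                    and t.values[n].nunique() > 1)
        icc = icc_2_1(np.column_stack([a.values[name], b.values[name]]))
        assert icc == pytest.approx(0.5, abs=0.1)

    def test_same_seed_reproduces_replicates(self):
        t, _ = generate_feature_table(SimulationConfig(seed=6))
        a1, b1 = generate_rater_replicates(t, 0.3, seed=9)
        a2, b2 = generate_rater_replicates(t, 0.3, seed=9)
        assert a1.values.equals(a2.values) and b1.values.equals(b2.values)

    def test_negative_noise_rejected(self):
        t, _ = generate_feature_table(SimulationConfig(seed=6))
        with pytest.raises(ConfigurationError):
            generate_rater_replicates(t, -0.1, seed=0)


class TestClinicalTable:
    def test_column_set_is_the_24_standard_abbreviations(self):
        t = generate_clinical_table(SimulationConfig(seed=1))
        assert tuple(t.variables) == CLINICAL_VARIABLES

    def test_null_effects_yield_chance_level_flags(self):
        from radscore.clinical import screen_clinical

        cfg = SimulationConfig(seed=8, n_derivation=2000, clinical_effects={})
        t = generate_clinical_table(cfg)
        rep = screen_clinical(t, alpha=0.05)
        assert sum(rep.flagged.values()) <= 4  # Binom(24, .05): P(<=4) > .99

    def test_planted_effects_detected_at_cohort_scale(self):
        from radscore.clinical import screen_clinical

        cfg = SimulationConfig(seed=9)
        t = generate_clinical_table(cfg)
        rep = screen_clinical(t, alpha=0.05)
        planted = set(cfg.clinical_effects)
        assert len(planted & set(rep.flagged_variables)) >= 4

    def test_unknown_effect_variable_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(clinical_effects={"NotAVariable": 1.0}).validate()


class TestPhantom:
    def test_ellipsoid_mask_volume_matches_analytic(self):
        img, msk = generate_phantom_volume(
            shape=(60, 60, 40), mask_spec={"center": (30, 30, 20), "semiaxes": (18, 15, 12)},
            spacing=(1, 1, 1), seed=0)
        voxels = int(np.asanyarray(msk.dataobj).sum())
        analytic = 4 / 3 * np.pi * 18 * 15 * 12
        assert abs(voxels - analytic) / analytic < 0.02

    def test_spacing_recorded_in_header(self):
        img, msk = generate_phantom_volume(spacing=(1, 1, 5), seed=1)
        assert tuple(float(z) for z in img.header.get_zooms()) == (1.0, 1.0, 5.0)
        assert tuple(float(z) for z in msk.header.get_zooms()) == (1.0, 1.0, 5.0)

    def test_seed_determinism(self):
        a, _ = generate_phantom_volume(seed=2)
        b, _ = generate_phantom_volume(seed=2)
        assert np.array_equal(np.asanyarray(a.dataobj), np.asanyarray(b.dataobj))

    def test_oversized_mask_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            generate_phantom_volume(shape=(20, 20, 10),
                                    mask_spec={"center": (10, 10, 25), "semiaxes": (8, 8, 20)},
                                    spacing=(1, 1, 1), seed=0)


class TestMissingness:
    def test_rate_zero_is_identity(self):
        t = generate_clinical_table(SimulationConfig(seed=10))
        out = inject_missingness(t, 0.0, seed=1)
        assert out.data.equals(t.data)

    def test_missing_count_within_binomial_bounds(self):
        cfg = SimulationConfig(seed=11, n_derivation=500)
        t = generate_clinical_table(cfg)
        out = inject_missingness(t, 0.1, seed=2)
        n_cells = out.data.size
        missing = int(out.data.isna().sum().sum())
        mean, sd = 0.1 * n_cells, np.sqrt(n_cells * 0.1 * 0.9)
        assert abs(missing - mean) < 2.58 * sd  # 99% interval

    def test_rate_one_rejected(self):
        t = generate_clinical_table(SimulationConfig(seed=10))
        with pytest.raises(ConfigurationError):
            inject_missingness(t, 1.0, seed=0)
        # just below the boundary is still a valid rate
        inject_missingness(t, 0.999999, seed=0)
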