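"""Synthetic stand generator: mean structure, error model, calibration."""

import numpy as np
import pandas as pd
import pytest

from fircompat import synthetic
from fircompat.allocation import AllocationParams
from fircompat.published import (
    BIOMASS_SUMMARY,
    COMPONENTS,
    LIDAR_SUMMARY,
    SUSPECT_SUMMARY_ENTRIES,
)
from fircompat.records import TREE_COLUMNS, write_tree_csv
from fircompat.synthetic import (
    ConfigurationError,
    DbhHeightModel,
    GeneratorConfig,
    component_mean,
    default_config,
    generate_from_allocation,
    generate_stand,
    summarize_by_age_group,
    true_components,
)


class TestMeanStructure:
    def test_unit_covariates_return_group_scale(self):
        # at lh = lcd = 1 m the power terms collapse and the mean equals the
        # age-group scale coefficient of the generating allometry
        truth = synthetic.default_truth()
        assert component_mean(truth["trunk"], 1.0, 1.0, 1) == pytest.approx(0.2124)
        assert component_mean(truth["bark"], 1.0, 1.0, 5) == pytest.approx(0.1242)

    def test_zero_cv_reproduces_the_deterministic_means(self, noise_free_stand):
        df = noise_free_stand
        cfg = default_config()
        mu = true_components(cfg, df["lh"], df["lcd"], df["age_group"])
        for c in COMPONENTS:
            np.testing.assert_allclose(df[f"m_{c}"], mu[c], rtol=1e-12)

    def test_nonpositive_covariates_rejected(self):
        truth = synthetic.default_truth()
        with pytest.raises(ValueError):
            component_mean(truth["leaf"], 0.0, 1.0, 1)


class TestGenerateStand:
    def test_additivity_holds_for_every_record(self, small_stand):
        df = small_stand
        total = df["m_bark"] + df["m_trunk"] + df["m_branch"] + df["m_leaf"]
        assert np.all(df["m_total"].to_numpy() == total.to_numpy())

    def test_record_counts_and_schema(self, small_stand):
        assert list(small_stand.columns) == list(TREE_COLUMNS)
        counts = small_stand["age_group"].value_counts().to_dict()
        assert counts == {1: 718, 2: 441, 3: 346, 4: 314, 5: 181}

    def test_seeded_runs_are_identical_and_csv_byte_stable(self, tmp_path):
        cfg = default_config(n_per_age_group={g: 50 for g in range(1, 6)}, seed=42)
        a, b = generate_stand(cfg), generate_stand(cfg)
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_tree_csv(a, pa)
        write_tree_csv(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        small = {g: 30 for g in range(1, 6)}
        a = generate_stand(default_config(n_per_age_group=small, seed=1))
        b = generate_stand(default_config(n_per_age_group=small, seed=2))
        assert not np.allclose(a["lh"], b["lh"])

    def test_default_config_is_calibrated_to_the_study_envelope(self):
        df = generate_stand(default_config(seed=5))
        assert len(df) == 20836
        lh_lo = LIDAR_SUMMARY["lh"]["train"][1]
        lh_hi = LIDAR_SUMMARY["lh"]["train"][0]
        means = df.groupby("age_group")["lh"].mean()
        assert ((means > lh_lo) & (means < lh_hi)).all()
        # group-wise mean component biomass rises from young to mature, as
        # in the published (internally consistent) training means
        for c in COMPONENTS:
            m = df.groupby("age_group")[f"m_{c}"].mean()
            assert m[1] <= m[2] <= m[3] <= m[4]

    def test_error_cv_controls_scatter(self):
        small = {g: 300 for g in range(1, 6)}
        cfg0 = default_config(n_per_age_group=small,
                              error_cv={c: 1e-6 for c in COMPONENTS}, seed=9)
        df = generate_stand(cfg0)
        mu = true_components(cfg0, df["lh"], df["lcd"], df["age_group"])
        rel = np.abs(df["m_trunk"] - mu["trunk"]) / mu["trunk"]
        assert float(rel.max()) < 1e-4  # sup-norm shrinks with the CV


class TestConfigValidation:
    def test_non_psd_correlation_rejected(self):
        bad = np.array([[1, 0.9, 0.9, -0.9], [0.9, 1, 0.9, 0.9],
                        [0.9, 0.9, 1, 0.9], [-0.9, 0.9, 0.9, 1.0]])
        with pytest.raises(ConfigurationError):
            default_config(error_corr=bad).validate()

    def test_inverted_bounds_rejected(self):
        cov = synthetic.CovariateModel(lh_bounds=(30.0, 3.0))
        with pytest.raises(ConfigurationError):
            default_config(covariates=cov).validate()

    def test_asymmetric_correlation_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = 0.3
        with pytest.raises(ConfigurationError):
            default_config(error_corr=bad).validate()

    def test_dict_round_trip(self):
        cfg = default_config(seed=77)
        again = GeneratorConfig.from_dict(cfg.to_dict())
        assert again.to_dict() == cfg.to_dict()


class TestAllocationPath:
    def test_unit_ratios_give_equal_quarters(self):
        alloc = AllocationParams(1.0, 0.0, 0.0, 1.0, 1.0, 1.0)
        df = generate_from_allocation(40, alloc, seed=3)
        np.testing.assert_allclose(df["m_total"], 1.0)
        for c in COMPONENTS:
            np.testing.assert_allclose(df[f"m_{c}"], 0.25)

    def test_empty_request(self):
        df = generate_from_allocation(0, AllocationParams(1, 1, 1, 0.1, 0.1, 0.1))
        assert len(df) == 0

    def test_additivity_exact(self):
        alloc = AllocationParams(0.1, 2.0, 1.0, 0.2, 0.3, 0.1)
        df = generate_from_allocation(100, alloc, seed=4)
        total = df["m_bark"] + df["m_trunk"] + df["m_branch"] + df["m_leaf"]
        assert np.all(df["m_total"].to_numpy() == total.to_numpy())

    def test_impossible_bounds_exhaust_retries(self):
        model = DbhHeightModel(dbh_median=14.0, dbh_sigma_log=0.01,
                               dbh_bounds=(59.0, 60.0))
        with pytest.raises(RuntimeError):
            generate_from_allocation(
                10, AllocationParams(1, 1, 1, 0.1, 0.1, 0.1),
                model, seed=5, max_retries=5)


class TestSummary:
    def test_two_tree_hand_example(self):
        df = generate_stand(default_config(n_per_age_group={1: 2, 2: 0, 3: 0, 4: 0, 5: 0}))
        df.loc[:, "m_bark"] = [1.0, 3.0]
        out = summarize_by_age_group(df)
        row = out[(out.age_group == 1) & (out.component == "bark")].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(np.sqrt(2.0))

    def test_constant_records_have_zero_sd(self):
        df = generate_stand(default_config(n_per_age_group={1: 5, 2: 0, 3: 0, 4: 0, 5: 0}))
        for c in COMPONENTS + ("total",):
            df[f"m_{c}"] = 2.5
        out = summarize_by_age_group(df)
        assert (out["sd"] == 0).all()
        assert (out["max"] == out["min"]).all()
        assert (out["max"] == out["mean"]).all()

    def test_singleton_group_reports_undefined_sd(self):
        df = generate_stand(default_config(n_per_age_group={1: 1, 2: 0, 3: 0, 4: 0, 5: 0}))
        out = summarize_by_age_group(df)
        assert out["sd"].isna().all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_by_age_group(pd.DataFrame(columns=list(TREE_COLUMNS)))


def test_suspect_published_entries_are_flagged_not_fixed():
    # the flagged duplications really are present verbatim in the stored summary
    assert BIOMASS_SUMMARY[(3, "trunk")]["train"][2] == BIOMASS_SUMMARY[(3, "bark")]["train"][2]
    assert BIOMASS_SUMMARY[(5, "branch")]["train"][2] == BIOMASS_SUMMARY[(5, "leaf")]["train"][2]
    assert (3, "trunk", "train", "mean") in SUSPECT_SUMMARY_ENTRIES
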