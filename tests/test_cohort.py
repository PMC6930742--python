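"""Synthetic cohort generator: distributions, determinism, THI, IO."""

import io
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from tinnisel.cohort import (
    CohortConfig,
    RegionDistribution,
    ThiModel,
    attach_thi,
    generate_cohort,
)
from tinnisel.reference import SIGNAL_REGIONS, default_cohort_config
from tinnisel.tables import TableSchemaError, read_table, write_table

from conftest import small_signal_regions


class TestGenerateCohort:
    def test_reference_defaults_shape_and_groups(self):
        table = generate_cohort(default_cohort_config(seed=0))
        assert table.n_patients == 46
        assert table.n_controls == 56
        assert len(table.region_names) == 61
        assert table.provenance == "synthetic"

    def test_patient_mean_matches_printed_statistics_within_3_se(self):
        table = generate_cohort(default_cohort_config(seed=5))
        region = "R_hypothalamus_5_-5_-11"
        sample_mean = table.patients()[region].mean()
        se = 45.5 / np.sqrt(46)
        assert abs(sample_mean - 349.0) < 3 * se

    def test_large_sample_recovers_config_parameters(self):
        config = replace(default_cohort_config(seed=9), n_patients=2000,
                         n_controls=2000)
        table = generate_cohort(config)
        pat = table.patients()
        ctl = table.data[table.data["group"] == "control"]
        for reg in SIGNAL_REGIONS:
            got_mean = pat[reg.region_name].mean()
            got_sd = pat[reg.region_name].std()
            assert abs(got_mean - reg.mean_patient) / reg.mean_patient < 0.02
            assert abs(got_sd - reg.sd_patient) / reg.sd_patient < 0.05
            got_c = ctl[reg.region_name].mean()
            assert abs(got_c - reg.mean_control) / reg.mean_control < 0.02

    def test_zero_effect_scale_removes_group_differences(self, tiny_config):
        # two-sample t at alpha = 0.001 over replicated null cohorts
        # should reject at about the nominal rate
        config = replace(tiny_config, effect_scale=0.0, n_patients=30,
                         n_controls=30)
        n_tests = rejections = 0
        for seed in range(100):
            table = generate_cohort(replace(config, seed=seed))
            vols = table.volumes
            labels = table.labels.astype(bool)
            _, p = stats.ttest_ind(vols[labels], vols[~labels], axis=0)
            rejections += int((p < 0.001).sum())
            n_tests += vols.shape[1]
        assert rejections / n_tests < 0.005

    def test_determinism_byte_identical_csv(self):
        config = default_cohort_config(seed=123)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_table(generate_cohort(config), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_scaling_all_means_and_sds_scales_volumes(self, tiny_config):
        factor = 3.0
        scaled_regions = tuple(
            RegionDistribution(
                r.region_name,
                factor * r.mean_patient,
                factor * r.sd_patient,
                factor * r.mean_control,
                factor * r.sd_control,
            )
            for r in tiny_config.signal_regions
        )
        lo, hi = tiny_config.null_mean_range
        scaled = replace(
            tiny_config,
            signal_regions=scaled_regions,
            null_mean_range=(factor * lo, factor * hi),
        )
        base = generate_cohort(tiny_config)
        big = generate_cohort(scaled)
        np.testing.assert_allclose(
            big.volumes, factor * base.volumes, rtol=1e-12
        )

    def test_exchangeable_correlation_between_regions(self):
        config = replace(
            default_cohort_config(seed=21), n_patients=3000, n_controls=10,
            correlation=0.5,
        )
        table = generate_cohort(config)
        pat = table.patients()
        a = pat[SIGNAL_REGIONS[0].region_name]
        b = pat[SIGNAL_REGIONS[3].region_name]
        assert stats.pearsonr(a, b)[0] == pytest.approx(0.5, abs=0.06)

    def test_invalid_configs_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="positive-definite"):
            replace(tiny_config, correlation=1.0)
        with pytest.raises(ValueError, match="SDs must be positive"):
            RegionDistribution("bad", 100.0, 0.0, 100.0, 5.0)
        with pytest.raises(ValueError, match="at least 10"):
            replace(tiny_config, n_patients=2, n_controls=2)

    def test_volumes_floored_at_physical_minimum(self):
        config = CohortConfig(
            n_patients=30,
            n_controls=30,
            signal_regions=(RegionDistribution("tiny", 2.0, 5.0, 2.0, 5.0),),
            n_null_regions=1,
            null_mean_range=(2.0, 3.0),
            null_cv=2.0,
            thi_model=None,
            seed=0,
        )
        table = generate_cohort(config)
        assert table.volumes.min() >= 1.0


class TestAttachThi:
    def test_scores_even_and_in_range_controls_unscored(self, tiny_config):
        table = generate_cohort(tiny_config)
        pat_thi = table.patients()["thi"].to_numpy()
        assert np.isfinite(pat_thi).all()
        assert ((pat_thi >= 0) & (pat_thi <= 100)).all()
        assert (pat_thi % 2 == 0).all()
        controls = table.data[table.data["group"] == "control"]
        assert controls["thi"].isna().all()

    def test_zero_target_r_gives_near_zero_correlation(self):
        config = replace(
            default_cohort_config(seed=3), n_patients=500, n_controls=10,
            thi_model=ThiModel(band_weights=(0, 0, 1, 0, 0)),
        )
        table = generate_cohort(config)
        pat = table.patients()
        r = stats.pearsonr(
            pat["thi"], pat["R_hypothalamus_5_-5_-11"]
        )[0]
        assert abs(r) < 2.0 / np.sqrt(len(pat))

    def test_target_r_recovered_in_focus_band(self):
        model = ThiModel(
            region="R_hypothalamus_5_-5_-11",
            band="moderate",
            target_r=0.8,
            band_weights=(0, 0, 1, 0, 0),
        )
        config = replace(
            default_cohort_config(seed=17), n_patients=500, n_controls=10,
            thi_model=model,
        )
        table = generate_cohort(config)
        pat = table.patients()
        r = stats.pearsonr(pat["thi"], pat["R_hypothalamus_5_-5_-11"])[0]
        assert 0.75 <= r <= 0.85

    def test_unknown_region_and_bad_r_rejected(self, tiny_config):
        table = generate_cohort(tiny_config)
        with pytest.raises(KeyError, match="nope"):
            attach_thi(
                table,
                ThiModel(region="nope", band="mild", target_r=0.5),
                seed=0,
            )
        with pytest.raises(ValueError, match=r"\|r\| < 1"):
            ThiModel(region="sig_0", band="mild", target_r=1.0)


class TestTableIO:
    def test_round_trip_is_exact(self, tiny_config, tmp_path):
        table = generate_cohort(tiny_config)
        path = tmp_path / "t.csv"
        write_table(table, path)
        back = read_table(path)
        assert back.equals(table)
        np.testing.assert_array_equal(back.volumes, table.volumes)

    def test_duplicate_subject_id_names_the_id(self, tiny_config, tmp_path):
        table = generate_cohort(tiny_config)
        df = table.data.copy()
        df.loc[1, "subject_id"] = df.loc[0, "subject_id"]
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(TableSchemaError, match="TP001"):
            read_table(path)

    def test_missing_group_column_lists_missing(self, tiny_config, tmp_path):
        table = generate_cohort(tiny_config)
        df = table.data.drop(columns=["group"])
        path = tmp_path / "nogroup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(TableSchemaError, match=r"missing.*group"):
            read_table(path)

    def test_non_numeric_volume_rejected(self, tiny_config, tmp_path):
        table = generate_cohort(tiny_config)
        df = table.data.copy()
        df["sig_0"] = df["sig_0"].astype(object)
        df.loc[0, "sig_0"] = "abc"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(TableSchemaError, match="sig_0"):
            read_table(path)


def test_small_signal_regions_helper_orders_groups():
    regions = small_signal_regions(2)
    assert all(r.mean_control > r.mean_patient for r in regions)
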