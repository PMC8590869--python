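from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsi.features import (PROV_ABSENT, PROV_FORWARD_FILLED, PROV_IMPUTED,
                          PROV_MASKED, PROV_MEASURED, PopulationStats,
                          StayObservations, build_feature_matrix,
                          compute_population_stats, hr_sbp_available,
                          merge_blood_pressure, snapshot)
from hsi.registry import default_registry


def obs_frame(rows):
    return pd.DataFrame(rows, columns=["stay_id", "variable", "time", "value"])


@pytest.fixture()
def stats():
    s = PopulationStats()
    for name in default_registry().names:
        s.means[name] = 1.0
        s.samples[name] = [1.0, 2.0]
    s.means["heart_rate"] = 80.0
    s.means["systolic_bp"] = 120.0
    s.means["lactate"] = 1.5
    return s


def make_snapshot(rows, t, stats, mode="all", age=50.0):
    registry = default_registry()
    so = StayObservations(obs_frame(rows), registry)
    return snapshot(so, stats, t, stay_id="s1", age=age, mode=mode,
                    registry=registry)


BASE_ROWS = [("s1", "heart_rate", 1.0, 90.0), ("s1", "systolic_bp", 1.0, 110.0)]


class TestMergeBloodPressure:
    def test_invasive_priority(self):
        obs = obs_frame([("s1", "systolic_bp_invasive", 5.0, 90.0),
                         ("s1", "systolic_bp_noninvasive", 5.0, 100.0)])
        merged = merge_blood_pressure(obs)
        assert list(merged["variable"]) == ["systolic_bp"]
        assert merged["value"].iloc[0] == 90.0

    def test_noninvasive_passthrough(self):
        obs = obs_frame([("s1", "systolic_bp_noninvasive", 5.0, 100.0)])
        merged = merge_blood_pressure(obs)
        assert list(merged["variable"]) == ["systolic_bp"]
        assert merged["value"].iloc[0] == 100.0

    def test_different_time_bins_both_kept(self):
        obs = obs_frame([("s1", "systolic_bp_invasive", 5.0, 90.0),
                         ("s1", "systolic_bp_noninvasive", 5.5, 100.0)])
        merged = merge_blood_pressure(obs)
        assert len(merged) == 2
        assert set(merged["variable"]) == {"systolic_bp"}

    def test_empty_input(self):
        merged = merge_blood_pressure(obs_frame([]))
        assert merged.empty

    def test_plain_variables_untouched(self):
        obs = obs_frame(BASE_ROWS)
        merged = merge_blood_pressure(obs)
        assert len(merged) == 2


class TestSnapshot:
    def test_forward_fill_at_exact_limit(self, stats):
        fv = make_snapshot(BASE_ROWS, 3.0, stats)
        assert fv.valid
        assert fv.provenance["heart_rate"] == PROV_FORWARD_FILLED
        assert fv.values["heart_rate"] == 90.0

    def test_forward_fill_past_limit_invalidates(self, stats):
        fv = make_snapshot(BASE_ROWS, 3.01, stats)
        assert not fv.valid
        assert fv.provenance["heart_rate"] == PROV_IMPUTED

    def test_measurement_at_query_time_is_measured(self, stats):
        fv = make_snapshot(BASE_ROWS, 1.0, stats)
        assert fv.provenance["heart_rate"] == PROV_MEASURED

    def test_fio2_imputed_to_room_air(self, stats):
        fv = make_snapshot(BASE_ROWS, 1.0, stats)
        assert fv.values["fio2"] == 0.21
        assert fv.provenance["fio2"] == PROV_IMPUTED

    def test_mawp_pip_left_absent(self, stats):
        fv = make_snapshot(BASE_ROWS, 1.0, stats)
        for name in ("mawp", "pip"):
            assert math.isnan(fv.values[name])
            assert fv.provenance[name] == PROV_ABSENT

    def test_lab_fill_limit_is_26h(self, stats):
        rows = BASE_ROWS + [("s1", "lactate", 1.0, 9.9),
                            ("s1", "heart_rate", 27.0, 90.0),
                            ("s1", "systolic_bp", 27.0, 110.0)]
        at_limit = make_snapshot(rows, 27.0, stats)
        assert at_limit.values["lactate"] == 9.9
        rows2 = [("s1", "lactate", 1.0, 9.9),
                 ("s1", "heart_rate", 27.5, 90.0),
                 ("s1", "systolic_bp", 27.5, 110.0)]
        past = make_snapshot(rows2, 27.5, stats)
        assert past.provenance["lactate"] == PROV_IMPUTED
        assert past.values["lactate"] == stats.means["lactate"]

    def test_shock_index_identity(self, stats):
        fv = make_snapshot(BASE_ROWS, 1.0, stats)
        assert fv.values["shock_index"] == fv.values["heart_rate"] / \
            fv.values["systolic_bp"]

    def test_age_from_metadata(self, stats):
        fv = make_snapshot(BASE_ROWS, 1.0, stats, age=73.0)
        assert fv.values["age"] == 73.0
        assert fv.provenance["age"] == PROV_MEASURED

    def test_causality_future_values_ignored(self, stats):
        rows = BASE_ROWS + [("s1", "lactate", 5.0, 9.9)]
        fv = make_snapshot(rows, 2.0, stats)
        assert fv.values["lactate"] == stats.means["lactate"]

    def test_unknown_variable_rejected(self, stats):
        with pytest.raises(ValueError, match="unknown variable"):
            make_snapshot([("s1", "chakra", 1.0, 7.0)], 2.0, stats)

    def test_unknown_mode_rejected(self, stats):
        with pytest.raises(ValueError, match="mode"):
            make_snapshot(BASE_ROWS, 1.0, stats, mode="turbo")


class TestOperatingModes:
    def test_all_mode_has_33_variables(self):
        registry = default_registry()
        assert len(registry.mode_variables("all")) == 33
        assert len(registry) == 33

    def test_basic_mode_masks_lactate(self, stats):
        rows = BASE_ROWS + [("s1", "lactate", 0.5, 9.9)]
        fv = make_snapshot(rows, 1.0, stats, mode="basic")
        assert fv.values["lactate"] == stats.means["lactate"]
        assert fv.provenance["lactate"] == PROV_MASKED

    def test_basic_vent_cannot_create_data(self, stats):
        fv = make_snapshot(BASE_ROWS, 1.0, stats, mode="basic+ventilation")
        assert math.isnan(fv.values["mawp"])
        assert math.isnan(fv.values["pip"])

    def test_mode_nesting(self, stats):
        registry = default_registry()
        basic = registry.mode_variables("basic")
        labs = registry.mode_variables("basic+labs")
        everything = registry.mode_variables("all")
        assert basic <= labs <= everything
        assert basic <= registry.mode_variables("basic+ventilation") | basic

    def test_idempotence(self, stats):
        a = make_snapshot(BASE_ROWS, 2.5, stats)
        b = make_snapshot(BASE_ROWS, 2.5, stats)
        assert a.values == b.values and a.provenance == b.provenance


class TestPopulationStats:
    def test_means_from_raw_values_only(self):
        obs = obs_frame([("s1", "lactate", 0.0, 1.0),
                         ("s1", "lactate", 1.0, 3.0)])
        stays = pd.DataFrame({"stay_id": ["s1"], "age": [60]})
        stats = compute_population_stats(obs, stays)
        assert stats.means["lactate"] == 2.0
        assert stats.means["age"] == 60.0

    def test_roundtrip(self, tmp_path):
        obs = obs_frame([("s1", "heart_rate", 0.0, 80.0),
                         ("s1", "systolic_bp", 0.0, 120.0)])
        stays = pd.DataFrame({"stay_id": ["s1"], "age": [60]})
        stats = compute_population_stats(obs, stays)
        stats.save(tmp_path / "stats.json")
        loaded = PopulationStats.load(tmp_path / "stats.json")
        assert loaded.means == stats.means
        assert loaded.samples == stats.samples

    def test_shock_index_mean_derived(self):
        obs = obs_frame([("s1", "heart_rate", 0.0, 80.0),
                         ("s1", "systolic_bp", 0.0, 120.0)])
        stays = pd.DataFrame({"stay_id": ["s1"], "age": [60]})
        stats = compute_population_stats(obs, stays)
        assert stats.means["shock_index"] == pytest.approx(80.0 / 120.0)


class TestBatchMatrix:
    def test_matches_single_snapshots(self, small_cohort, registry):
        stays = small_cohort["stays"]
        observations = small_cohort["observations"]
        stats = compute_population_stats(observations, stays, registry)
        queries = pd.DataFrame({"stay_id": stays["stay_id"].head(5),
                                "time": [8.0, 9.0, 10.0, 11.0, 12.0]})
        mat = build_feature_matrix(observations, stays, stats, queries,
                                   registry=registry)
        assert len(mat) == 5
        row = mat.iloc[0]
        sid = row["stay_id"]
        so = StayObservations(
            observations[observations["stay_id"] == sid], registry)
        age = float(stays.set_index("stay_id").loc[sid, "age"])
        fv = snapshot(so, stats, row["time"], stay_id=sid, age=age,
                      registry=registry)
        for name in registry.names:
            got, want = row[name], fv.values[name]
            assert (math.isnan(got) and math.isnan(want)) or got == want

    def test_mode_nesting_on_cohort(self, small_cohort, registry):
        """Measured-variable sets nest: basic <= basic+labs <= all."""
        stays = small_cohort["stays"]
        observations = small_cohort["observations"]
        stats = compute_population_stats(observations, stays, registry)
        queries = pd.DataFrame({"stay_id": stays["stay_id"].head(20),
                                "time": np.linspace(7, 15, 20)})
        mats = {m: build_feature_matrix(observations, stays, stats, queries,
                                        mode=m, registry=registry)
                for m in ("basic", "basic+labs", "all")}
        live = {m: (mats[m][[f"{n}_prov" for n in registry.names]]
                    .isin([PROV_MEASURED, PROV_FORWARD_FILLED]))
                for m in mats}
        assert (~live["basic"].to_numpy() | live["basic+labs"].to_numpy()).all()
        assert (~live["basic+labs"].to_numpy() | live["all"].to_numpy()).all()


@settings(max_examples=50, deadline=None)
@given(st.floats(0.0, 30.0), st.floats(0.0, 40.0))
def test_causality_property(obs_time, query_time):
    """snapshot(t) never uses a measurement newer than t."""
    stats = PopulationStats(means={n: 1.0 for n in default_registry().names})
    rows = [("s1", "heart_rate", obs_time, 123.0),
            ("s1", "systolic_bp", obs_time, 99.0)]
    fv = make_snapshot(rows, query_time, stats)
    if query_time < obs_time:
        assert not fv.valid
        assert fv.values["heart_rate"] != 123.0
    elif query_time - obs_time <= 2.0:
        assert fv.values["heart_rate"] == 123.0
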