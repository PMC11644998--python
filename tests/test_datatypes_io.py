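"""Domain-type invariants and the delimited-text dialects."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tibload.config import config_from_dict
from tibload.datatypes import (
    InsoleSeries,
    LoadStimulusSeries,
    ParticipantMeta,
    TrackerMinuteTable,
)
from tibload.errors import ConfigError, FormatError, ValidationError
from tibload.io import (
    load_config,
    read_cohort_dir,
    read_insole,
    read_meta,
    read_participant_dir,
    read_tracker,
    write_insole,
    write_meta,
    write_participant_dir,
    write_tracker,
)

RATE = 25.0


class TestInsoleSeries:
    def test_three_row_file_round_trip(self, tmp_path, toy_meta, tiny_insole):
        p = tmp_path / "insole.csv"
        write_insole(tiny_insole, p)
        back = read_insole(p, toy_meta)
        assert len(back) == 3
        np.testing.assert_array_equal(back.t, tiny_insole.t)
        np.testing.assert_array_equal(back.force, tiny_insole.force)

    def test_write_read_write_is_byte_stable(self, tmp_path, toy_meta, tiny_insole):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_insole(tiny_insole, p1)
        write_insole(read_insole(p1, toy_meta), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_wrong_column_name_is_format_error(self, tmp_path, toy_meta):
        p = tmp_path / "bad.csv"
        p.write_text("t_s,force_n,cop_mm\n0.0,700.0,150.0\n")
        with pytest.raises(FormatError, match="cop_m"):
            read_insole(p, toy_meta)

    def test_non_monotone_time_names_offending_row(self, tmp_path, toy_meta):
        p = tmp_path / "bad.csv"
        p.write_text("t_s,force_n,cop_m\n0.0,0.0,0.1\n0.08,700.0,0.1\n0.04,0.0,0.1\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_insole(p, toy_meta)

    def test_negative_force_rejected(self):
        with pytest.raises(ValidationError):
            InsoleSeries(t=np.array([0.0]), force=np.array([-1.0]), cop=np.array([0.1]))

    def test_off_grid_time_rejected(self):
        with pytest.raises(ValidationError):
            InsoleSeries(
                t=np.array([0.0, 0.05]), force=np.zeros(2), cop=np.full(2, 0.1)
            )

    def test_gaps_on_grid_allowed(self):
        s = InsoleSeries(
            t=np.array([0.0, 0.04, 1.0]), force=np.zeros(3), cop=np.full(3, 0.1)
        )
        assert len(s) == 3

    def test_unloaded_cop_carried_forward_on_read(self, tmp_path, toy_meta):
        p = tmp_path / "cf.csv"
        p.write_text(
            "t_s,force_n,cop_m\n0.0,0.0,0.9\n0.04,700.0,0.15\n0.08,0.0,0.9\n"
        )
        back = read_insole(p, toy_meta, noise_floor_n=1.0)
        # leading unloaded sample backfills, trailing carries forward;
        # the out-of-range 0.9 values never survive on unloaded rows
        np.testing.assert_allclose(back.cop, [0.15, 0.15, 0.15])


@given(
    n_minutes=st.integers(min_value=1, max_value=3),
    seed=st.integers(min_value=0, max_value=50),
)
def test_insole_round_trip_property(tmp_path_factory, n_minutes, seed):
    """Write/read preserves generated series exactly (values already canonical)."""
    rng = np.random.default_rng(seed)
    n = int(n_minutes * 60 * RATE)
    force = np.clip(rng.normal(300, 400, n), 0, None)
    force[force < 1.0] = 0.0
    cop = np.clip(rng.normal(0.15, 0.05, n), 0.0, 0.26)
    # canonical form: unloaded rows already carry the last loaded CoP
    from tibload.io import carry_forward_cop

    cop = carry_forward_cop(force, cop, 1.0)
    series = InsoleSeries(t=np.arange(n) / RATE, force=force, cop=cop)
    meta = ParticipantMeta("RT", 70.0, 0.12)
    p = tmp_path_factory.mktemp("rt") / "s.csv"
    write_insole(series, p)
    back = read_insole(p, meta)
    np.testing.assert_array_equal(back.t, series.t)
    np.testing.assert_array_equal(back.force, series.force)
    np.testing.assert_array_equal(back.cop, series.cop)


class TestTrackerTable:
    def valid_text(self):
        return (
            "minute_start_s,activity_time_s,step_count,activity_level,scaled_steps,scaled_activity\n"
            "0.0,30.0,60,6.0,360.0,180.0\n"
            "60.0,0.0,0,0.0,0.0,0.0\n"
        )

    def test_round_trip(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(self.valid_text())
        table = read_tracker(p)
        p2 = tmp_path / "t2.csv"
        write_tracker(table, p2)
        assert read_tracker(p2).step_count.tolist() == [60, 0]

    def test_header_only_file_is_empty_table(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(self.valid_text().splitlines()[0] + "\n")
        assert len(read_tracker(p)) == 0

    @pytest.mark.parametrize(
        "mutation,pattern",
        [
            (("30.0", "61.0"), "activity_time"),  # out of [0, 60]
            (("60,6.0,360.0", "60,6.0,999.0"), "scaled_steps"),
            (("60.0,0.0,0", "90.0,0.0,0"), "minute_start"),  # breaks the 60 s grid
            (("0,0.0,0.0,0.0", "-3,0.0,0.0,0.0"), "step_count"),
        ],
    )
    def test_mutated_fixture_raises_typed_error(self, tmp_path, mutation, pattern):
        old, new = mutation
        text = self.valid_text().replace(old, new)
        assert text != self.valid_text(), "mutation must change the fixture"
        p = tmp_path / "m.csv"
        p.write_text(text)
        with pytest.raises(ValidationError, match=pattern):
            read_tracker(p)


class TestMeta:
    def test_round_trip(self, tmp_path, toy_meta):
        p = tmp_path / "meta.yaml"
        write_meta(toy_meta, p)
        back = read_meta(p)
        assert back == toy_meta

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "meta.yaml"
        p.write_text(
            "participant_id: X\nbody_mass_kg: 70\nankle_offset_x_m: 0.1\n"
            "achilles_moment_arm_r_m: 0.05\ninsole_length_m: 0.26\nshoe_size: 42\n"
        )
        with pytest.raises(FormatError, match="shoe_size"):
            read_meta(p)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValidationError):
            ParticipantMeta("X", 70.0, ankle_offset_x=0.3, insole_length=0.26)


class TestLoadStimulusSeries:
    def test_negative_ls_rejected(self):
        with pytest.raises(ValidationError):
            LoadStimulusSeries(np.array([0.0]), np.array([-1.0]), np.array(["insole"]))

    def test_unknown_source_rejected(self):
        with pytest.raises(ValidationError, match="source"):
            LoadStimulusSeries(np.array([0.0]), np.array([1.0]), np.array(["oracle"]))


class TestConfig:
    def test_empty_config_gives_documented_defaults(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("")
        cfg = load_config(p)
        assert cfg.m == 4.0
        assert cfg.achilles_moment_arm_r == 0.05
        assert cfg.sample_rate == 25.0
        assert cfg.minute_s == 60.0
        assert cfg.window_start_min == 30
        assert cfg.window_increment_min == 5
        assert cfg.bin_width_pct == 5.0

    def test_unknown_key_listed(self):
        with pytest.raises(ConfigError, match="bogus_knob"):
            config_from_dict({"bogus_knob": 1})

    def test_unknown_cohort_key_listed(self):
        with pytest.raises(ConfigError, match="n_legs"):
            config_from_dict({"cohort": {"n_legs": 2}})

    def test_negative_window_increment_rejected(self):
        with pytest.raises(ConfigError):
            config_from_dict({"window_increment_min": -5})

    def test_values_propagate(self):
        cfg = config_from_dict({"m": 4, "cohort": {"n_participants": 4}})
        assert cfg.m == 4.0
        assert cfg.cohort.n_participants == 4


class TestParticipantDirs:
    def test_cohort_directory_round_trip(self, tmp_path, small_cohort, small_config):
        root = tmp_path / "cohort"
        for day in small_cohort:
            write_participant_dir(day, root / day.participant_id)
        back = read_cohort_dir(
            root, small_config.noise_floor_n, small_config.sample_rate
        )
        assert [d.participant_id for d in back] == [d.participant_id for d in small_cohort]
        for da, db in zip(small_cohort, back):
            np.testing.assert_array_equal(da.insole.force, db.insole.force)
            np.testing.assert_array_equal(da.tracker.step_count, db.tracker.step_count)
            assert db.ground_truth is None

    def test_ground_truth_files_written(self, tmp_path, small_cohort):
        day = small_cohort[0]
        d = tmp_path / "p"
        write_participant_dir(day, d)
        assert (d / "ground_truth.csv").exists()
        assert (d / "schedule.csv").exists()
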