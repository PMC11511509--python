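"""File dialects, stomp synchronization, manifold resampling."""
import numpy as np
import pytest

from spinekin.dataio import (
    ImuStream,
    MarkerStream,
    read_imu_csv,
    read_markers,
    read_trc,
    resample_imu,
    resample_markers,
    sync_imus,
    write_imu_csv,
    write_markers_csv,
    write_trc,
)
from spinekin.errors import (
    AmbiguousSyncError,
    DataFormatError,
    SyncFailureError,
)
from spinekin.synthetic import NoiseModel, render_imu, render_omc

from conftest import default_scenario


@pytest.fixture(scope="module")
def cal_truth():
    from spinekin.synthetic import truth_trajectories

    return truth_trajectories(default_scenario(movements=("F",)))["cal"]


class TestImuCsv:
    def test_write_read_write_is_byte_identical(self, cal_truth, tmp_path):
        stream = render_imu(cal_truth, NoiseModel(), rng=np.random.default_rng(0))["T1T2"]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_imu_csv(stream, p1)
        back = read_imu_csv(p1)
        write_imu_csv(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_minimal_fixture_roundtrip(self, tmp_path):
        s = ImuStream(
            t=np.array([0.0, 0.016, 0.032]),
            quat_wxyz=np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0.0]]),
            accel=np.zeros((3, 3)), gyro=np.zeros((3, 3)), mag=np.zeros((3, 3)),
        )
        p = tmp_path / "s.csv"
        write_imu_csv(s, p)
        back = read_imu_csv(p)
        assert len(back.t) == 3
        assert np.allclose(back.quat_wxyz, s.quat_wxyz)

    def test_non_unit_quaternion_renormalized_with_log(self, tmp_path, caplog):
        p = tmp_path / "q.csv"
        p.write_text(
            "# spinekin-imu-v1\n# units: ...\n"
            "t,qw,qx,qy,qz,ax,ay,az,gx,gy,gz,mx,my,mz\n"
            "0,0.98,0,0,0,0,0,9.81,0,0,0,20,0,40\n"
            "0.016,1,0,0,0,0,0,9.81,0,0,0,20,0,40\n"
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="spinekin.dataio"):
            s = read_imu_csv(p)
        assert np.allclose(np.linalg.norm(s.quat_wxyz, axis=1), 1.0)
        assert any("renormalized 1" in r.getMessage() for r in caplog.records)

    def test_timestamp_regression_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "# spinekin-imu-v1\n# units: ...\n"
            "t,qw,qx,qy,qz,ax,ay,az,gx,gy,gz,mx,my,mz\n"
            + "0.1,1,0,0,0,0,0,9.81,0,0,0,20,0,40\n"
            + "0.05,1,0,0,0,0,0,9.81,0,0,0,20,0,40\n"
        )
        with pytest.raises(DataFormatError, match="regression"):
            read_imu_csv(p)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "# spinekin-imu-v1\n# units: ...\n"
            "t,qw,qx,qy,qz,ax,ay,az,gx,gy,gz,mx,my,mz\n"
            "0,1,0,0,0,0,0,9.81,0,0,0,20,0,40\n"
            "0.016,oops,0,0,0,0,0,9.81,0,0,0,20,0,40\n"
        )
        with pytest.raises(DataFormatError, match="line 5"):
            read_imu_csv(p)


class TestMarkerFiles:
    def test_trc_roundtrip_byte_identical(self, cal_truth, tmp_path, config):
        streams = render_omc(cal_truth, NoiseModel(), rng=np.random.default_rng(1))
        d1, d2 = tmp_path / "one", tmp_path / "two"
        d1.mkdir(), d2.mkdir()
        p1, p2 = d1 / "markers.trc", d2 / "markers.trc"
        write_trc(streams, p1, config.marker_labels)
        back = read_trc(p1, config.marker_labels)
        write_trc(back, p2, config.marker_labels)
        assert p1.read_bytes() == p2.read_bytes()

    def test_occlusion_survives_roundtrip(self, cal_truth, tmp_path, config):
        streams = render_omc(cal_truth, NoiseModel.noise_free(),
                             occlusions=[("L5S1", 1.0, 2.0)])
        p = tmp_path / "o.trc"
        write_trc(streams, p, config.marker_labels)
        back = read_trc(p, config.marker_labels)
        assert np.array_equal(back["L5S1"].visible, streams["L5S1"].visible)

    def test_zero_filled_block_becomes_gap(self, tmp_path, config):
        streams = {
            s: MarkerStream(
                t=np.arange(4) / 120.0,
                points=np.tile(np.array([[0, 0, 0], [40, 0, 0], [0, 40, 0.0]]),
                               (4, 1, 1)) + 10.0,
                visible=np.ones((4, 3), bool),
            )
            for s in config.marker_labels
        }
        streams["T1T2"].points[2] = 0.0  # zero-filled occlusion convention
        p = tmp_path / "z.csv"
        write_markers_csv(streams, p, config.marker_labels)
        back = read_markers(p, marker_labels=config.marker_labels)
        assert not back["T1T2"].visible[2].any()
        assert back["T1T2"].visible[[0, 1, 3]].all()

    def test_unknown_labels_listed(self, tmp_path, config):
        p = tmp_path / "u.csv"
        p.write_text("t,BOGUS_x,BOGUS_y,BOGUS_z\n0.0,1,2,3\n")
        with pytest.raises(DataFormatError, match="BOGUS"):
            read_markers(p, marker_labels=config.marker_labels)

    def test_missing_cluster_dropped_not_fatal(self, cal_truth, tmp_path, config):
        streams = render_omc(cal_truth, NoiseModel.noise_free())
        del streams["T12L1"]
        labels = {k: v for k, v in config.marker_labels.items() if k != "T12L1"}
        p = tmp_path / "m.trc"
        write_trc(streams, p, labels)
        back = read_trc(p, config.marker_labels)
        assert "T12L1" not in back
        assert set(back) == {"T1T2", "L5S1", "FEMUR"}


class TestSync:
    def test_known_offsets_recovered_within_one_sample(self, cal_truth):
        offsets = {"T1T2": 0.0, "T12L1": 0.12, "L5S1": -0.07, "FEMUR": 0.3}
        streams = render_imu(cal_truth, NoiseModel(),
                             rng=np.random.default_rng(3), clock_offsets=offsets)
        est = sync_imus(streams)
        for s, true_rel in offsets.items():
            assert abs(est[s] - true_rel) <= 0.016 + 1e-9

    def test_flat_acceleration_fails(self):
        s = ImuStream(t=np.arange(100) / 62.5,
                      quat_wxyz=np.tile([1, 0, 0, 0.0], (100, 1)),
                      accel=np.tile([0, 0, 9.81], (100, 1)),
                      gyro=np.zeros((100, 3)), mag=np.zeros((100, 3)))
        with pytest.raises(SyncFailureError):
            sync_imus({"T1T2": s})

    def test_two_comparable_spikes_ambiguous(self):
        accel = np.tile([0, 0, 9.81], (200, 1)).astype(float)
        accel[50, 2] += 60.0
        accel[150, 2] += 58.0
        s = ImuStream(t=np.arange(200) / 62.5,
                      quat_wxyz=np.tile([1, 0, 0, 0.0], (200, 1)),
                      accel=accel, gyro=np.zeros((200, 3)), mag=np.zeros((200, 3)))
        with pytest.raises(AmbiguousSyncError):
            sync_imus({"T1T2": s})


class TestResample:
    def test_constant_stream_stays_constant(self):
        s = ImuStream(t=np.arange(50) / 62.5,
                      quat_wxyz=np.tile([0.5, 0.5, 0.5, 0.5], (50, 1)),
                      accel=np.tile([1.0, 2.0, 3.0], (50, 1)),
                      gyro=np.zeros((50, 3)), mag=np.zeros((50, 3)))
        out = resample_imu(s, np.linspace(0, 0.7, 97))
        assert np.allclose(np.abs(out.quat_wxyz @ np.array([0.5, 0.5, 0.5, 0.5])), 1.0)
        assert np.allclose(out.accel, [1.0, 2.0, 3.0])

    def test_constant_rate_rotation_interpolates_on_geodesic(self):
        from scipy.spatial.transform import Rotation

        t = np.arange(0, 1.0, 1 / 62.5)
        ang = np.radians(90) * t  # constant angular velocity about z
        rot = Rotation.from_rotvec(np.outer(ang, [0, 0, 1]))
        s = ImuStream(t=t, quat_wxyz=rot.as_quat(scalar_first=True),
                      accel=np.zeros((t.size, 3)), gyro=np.zeros((t.size, 3)),
                      mag=np.zeros((t.size, 3)))
        tt = np.linspace(0.01, 0.9, 200)
        out = resample_imu(s, tt)
        expect = Rotation.from_rotvec(
            np.outer(np.radians(90) * tt, [0, 0, 1])).as_quat(scalar_first=True)
        dot = np.abs(np.sum(out.quat_wxyz * expect, axis=1))
        assert np.degrees(2 * np.arccos(np.clip(dot, -1, 1))).max() < 1e-5

    def test_wide_gap_preserved(self):
        t = np.arange(30) / 120.0
        pts = np.tile(np.array([[0, 0, 0], [40, 0, 0], [0, 40, 0.0]]), (30, 1, 1))
        vis = np.ones((30, 3), bool)
        pts[8:22] = np.nan  # ~0.12 s gap -> exceeds max_gap 0.05
        vis[8:22] = False
        s = MarkerStream(t=t, points=pts, visible=vis)
        out = resample_markers(s, t, max_gap_s=0.05)
        assert not out.visible[10:20].any()
        assert out.visible[:5].all() and out.visible[25:].all()
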