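"""Track ingestion, velocity maps, overlays and the synthetic generator."""

import io

import numpy as np
import pandas as pd
import pytest

from aceodep.core import ConfigError
from aceodep.velocimetry import (
    load_tracks,
    make_synthetic_tracks,
    overlay,
    velocity_map,
    write_pgm,
    write_tracks,
)


def canonical_csv(rows):
    buf = io.StringIO()
    pd.DataFrame(rows, columns=["track_id", "t_s", "x_um", "y_um"]).to_csv(buf, index=False)
    buf.seek(0)
    return buf


class TestLoadTracks:
    def test_trackmate_frames_at_60_fps_with_1um_pixels(self):
        """A 3-point track recorded at 60 fps with 1 um pixels lands at
        t = {0, 1/60, 2/60} s in meters."""
        buf = io.StringIO(
            "TRACK_ID,FRAME,POSITION_X,POSITION_Y\n"
            "0,0,10,5\n0,1,12,5\n0,2,14,5\n"
        )
        t = load_tracks(buf, pixel_size=1e-6, frame_interval=1 / 60)
        np.testing.assert_allclose(t.data["t"], [0, 1 / 60, 2 / 60])
        np.testing.assert_allclose(t.data["x"], [10e-6, 12e-6, 14e-6])

    def test_trackmate_extra_header_rows_tolerated(self):
        buf = io.StringIO(
            "TRACK_ID,POSITION_X,POSITION_Y,POSITION_T\n"
            "Track ID,X,Y,T\n"
            "Track ID,(pixel),(pixel),(s)\n"
            "1,10,5,0.0\n1,12,6,0.1\n"
        )
        t = load_tracks(buf)
        assert t.n_tracks == 1
        assert len(t.data) == 2

    def test_empty_file_rejected(self):
        with pytest.raises((ConfigError, Exception)):
            load_tracks(io.StringIO(""))

    def test_single_point_tracks_dropped(self):
        t = load_tracks(canonical_csv([(0, 0.0, 1.0, 1.0)]))
        assert t.n_tracks == 0

    def test_missing_columns_listed(self):
        buf = io.StringIO("a,b\n1,2\n")
        with pytest.raises(ConfigError, match="required columns"):
            load_tracks(buf)

    def test_non_monotone_time_names_track(self):
        rows = [(3, 0.0, 0, 0), (3, 0.2, 1, 0), (3, 0.1, 2, 0)]
        with pytest.raises(ConfigError, match="track 3"):
            load_tracks(canonical_csv(rows))

    def test_roundtrip_canonical_dialect_identity(self):
        table = make_synthetic_tracks("rotation", {"omega": 2.0, "radii": [40e-6, 80e-6]})
        buf = io.StringIO()
        write_tracks(table, buf)
        first = buf.getvalue()
        buf.seek(0)
        again = load_tracks(buf)
        buf2 = io.StringIO()
        write_tracks(again, buf2)
        assert buf2.getvalue() == first  # bit-exact round trip


class TestVelocityMap:
    def test_constant_speed_track_reports_exact_speed(self):
        s0 = 100e-6
        table = make_synthetic_tracks("constant", {"speed": s0, "n_tracks": 1, "n_frames": 20})
        vm = velocity_map(table, bin_size=5e-6)
        populated = vm.mean_speed[vm.counts > 0]
        np.testing.assert_allclose(populated, s0, rtol=1e-12)

    def test_solid_body_rotation_recovers_omega_r(self):
        """32 samples per revolution: chord-vs-arc bias ~ (2 pi/32)^2/24 << 5%."""
        omega = 2.0
        radii = [50e-6, 100e-6, 150e-6]
        fps = 32 * omega / (2 * np.pi)
        table = make_synthetic_tracks(
            "rotation", {"omega": omega, "radii": radii, "n_frames": 33, "fps": fps}
        )
        vm = velocity_map(table, bin_size=10e-6)
        gx, gy = np.meshgrid(vm.bin_x, vm.bin_y, indexing="xy")
        rad = np.hypot(gx, gy)
        ok = vm.counts > 0
        rel = np.abs(vm.mean_speed[ok] - omega * rad[ok]) / (omega * rad[ok])
        assert np.median(rel) < 0.05

    def test_interleaving_tracks_leaves_map_unchanged(self):
        """Row order between tracks is irrelevant (TrackMate exports group by
        spot, not by track); within-track time order is preserved."""
        table = make_synthetic_tracks("rotation", {"omega": 1.0, "radii": [60e-6, 90e-6]})
        vm1 = velocity_map(table, 10e-6)
        shuffled = (
            table.data.assign(_row=table.data.groupby("track_id").cumcount())
            .sort_values(["_row", "track_id"], kind="stable")
            .drop(columns="_row")
        )
        buf = io.StringIO()
        pd.DataFrame(
            {
                "track_id": shuffled["track_id"],
                "t_s": shuffled["t"],
                "x_um": shuffled["x"] * 1e6,
                "y_um": shuffled["y"] * 1e6,
            }
        ).to_csv(buf, index=False)
        buf.seek(0)
        vm2 = velocity_map(load_tracks(buf), 10e-6)
        np.testing.assert_allclose(vm1.mean_speed, vm2.mean_speed, rtol=1e-9, equal_nan=True)

    def test_oversized_bin_rejected(self):
        table = make_synthetic_tracks("constant", {"speed": 1e-4, "n_frames": 5})
        with pytest.raises(ConfigError, match="bin_size"):
            velocity_map(table, bin_size=1.0)

    def test_simulator_tracks_reproduce_flow_speed_field(self, baseline_fields):
        """Seeding tracers in the solved baseline flow and pushing them
        through the velocity-map pipeline recovers the solver's own speed
        field within 10% (L2, over well-sampled bins)."""
        flow = baseline_fields.flow
        xs = np.linspace(20e-6, 280e-6, 12)
        ys = np.linspace(20e-6, 140e-6, 7)
        seeds = np.array([(x, y) for x in xs for y in ys])
        table = make_synthetic_tracks(
            "from_flowfield", {"flow": flow, "seeds": seeds, "n_frames": 40, "fps": 60.0}
        )
        vm = velocity_map(table, bin_size=20e-6)
        from aceodep.tracing import BilinearSampler

        # reference: the solver's own speed sampled at the same segment
        # midpoints and binned identically
        samp = BilinearSampler(flow.x, flow.y, np.hypot(flow.u, flow.v))
        mids, refs = [], []
        for _, grp in table.data.groupby("track_id"):
            xy = grp[["x", "y"]].to_numpy()
            m = (xy[1:] + xy[:-1]) / 2
            mids.append(m)
            refs.append(samp(m)[0])
        mids_arr = np.concatenate(mids)
        refs_arr = np.concatenate(refs)
        x0, y0 = mids_arr[:, 0].min(), mids_arr[:, 1].min()
        ex = np.linspace(x0, x0 + vm.bin_x.size * 20e-6, vm.bin_x.size + 1)
        ey = np.linspace(y0, y0 + vm.bin_y.size * 20e-6, vm.bin_y.size + 1)
        cnt, _, _ = np.histogram2d(mids_arr[:, 1], mids_arr[:, 0], bins=(ey, ex))
        ssum, _, _ = np.histogram2d(mids_arr[:, 1], mids_arr[:, 0], bins=(ey, ex),
                                    weights=refs_arr)
        ok = (cnt >= 5) & (vm.counts >= 5)
        ref_mean = ssum[ok] / cnt[ok]
        est = vm.mean_speed[ok]
        assert np.linalg.norm(est - ref_mean) / np.linalg.norm(ref_mean) < 0.10


class TestOverlay:
    def test_straight_track_marks_a_line(self):
        table = make_synthetic_tracks(
            "constant", {"speed": 100e-6, "n_tracks": 1, "n_frames": 10, "direction": 0.0}
        )
        img = overlay(table, extent=(0, 20e-6, -5e-6, 5e-6), shape=(11, 50))
        rows_hit = np.unique(np.nonzero(img)[0])
        assert rows_hit.size == 1  # horizontal motion -> single pixel row

    def test_mirror_symmetric_tracks_give_mirror_raster(self):
        # two vertical tracks at mirror-symmetric pixel centers (2 um pixels)
        rows = []
        for f in range(10):
            y = 10e-6 + f * 8e-6
            rows.append((0, f / 60, 11e-6, y))
            rows.append((1, f / 60, 89e-6, y))
        buf = io.StringIO()
        df = pd.DataFrame(rows, columns=["track_id", "t_s", "x", "y"])
        pd.DataFrame(
            {"track_id": df.track_id, "t_s": df.t_s, "x_um": df.x * 1e6, "y_um": df.y * 1e6}
        ).to_csv(buf, index=False)
        buf.seek(0)
        table = load_tracks(buf)
        img = overlay(table, extent=(0, 100e-6, 0, 100e-6), shape=(50, 50))
        np.testing.assert_array_equal(img, img[:, ::-1])

    def test_baseline_tracks_show_closed_vortex_loops(self, baseline_fields):
        """Tracer overlays of the simulated baseline flow show connected
        high-density curves (the vortices)."""
        flow = baseline_fields.flow
        seeds = np.array([[60e-6, 80e-6], [240e-6, 80e-6]])
        table = make_synthetic_tracks(
            "from_flowfield", {"flow": flow, "seeds": seeds, "n_frames": 600, "fps": 60.0}
        )
        img = overlay(table, extent=(0, 300e-6, 0, 160e-6), shape=(80, 150))
        assert (img > 0).sum() > 100  # extended curve, not a blob

    def test_pgm_writer_plain_text(self, tmp_path):
        img = np.array([[0, 1], [2, 3]])
        p = tmp_path / "img.pgm"
        write_pgm(img, p)
        text = p.read_text()
        assert text.startswith("P2\n2 2\n3\n")


class TestSyntheticTracks:
    def test_constant_pattern_displacement_per_frame(self):
        """100 um/s at 60 fps -> 1.667 um per frame."""
        table = make_synthetic_tracks(
            "constant", {"speed": 100e-6, "n_tracks": 1, "n_frames": 10, "fps": 60.0}
        )
        d = np.diff(table.data["x"].to_numpy())
        np.testing.assert_allclose(d, 100e-6 / 60.0, rtol=1e-12)

    def test_seed_changes_jitter_not_mean_field(self):
        p = {"omega": 2.0, "radii": [100e-6], "jitter": 0.5e-6, "n_frames": 64, "fps": 20.0}
        t1 = make_synthetic_tracks("rotation", p, seed=1)
        t2 = make_synthetic_tracks("rotation", p, seed=2)
        assert not np.allclose(t1.data["x"], t2.data["x"])
        v1 = velocity_map(t1, 50e-6)
        v2 = velocity_map(t2, 50e-6)
        m1 = np.nanmean(v1.mean_speed)
        m2 = np.nanmean(v2.mean_speed)
        assert abs(m1 - m2) / m1 < 0.2
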