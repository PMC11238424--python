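"""Segmentation, linking, and kinematic statistics."""

import itertools

import numpy as np
import pytest

from bactglass import rodsim, trackkin
from bactglass.orientfield import nematic_diff
from bactglass.trackkin import CellTrack, Detection


def _det(points, angles=None, lengths=None):
    points = np.atleast_2d(np.asarray(points, float))
    n = len(points)
    return Detection(
        centroids=points,
        angles=np.zeros(n) if angles is None else np.asarray(angles, float),
        lengths=np.full(n, 3.0) if lengths is None else np.asarray(lengths, float),
    )


def exhaustive_links(detections, max_disp):
    """Frame-pair minimum-cost assignment by brute-force enumeration."""
    links = set()
    for f in range(len(detections) - 1):
        a = detections[f].centroids
        b = detections[f + 1].centroids
        na, nb = len(a), len(b)
        best_cost, best_assign = np.inf, ()
        k = min(na, nb)
        for rows in itertools.permutations(range(na), k):
            for cols in itertools.permutations(range(nb), k):
                cost, assign = 0.0, []
                for r, c in zip(rows, cols):
                    d2 = np.sum((a[r] - b[c]) ** 2)
                    if d2 <= max_disp**2:
                        cost += d2
                        assign.append((r, c))
                # unassigned links carry no cost; fewer links never beats
                # more links at equal cost under squared-distance minimality,
                # so compare (negative link count, cost)
                key = (-len(assign), cost)
                if key < (-len(best_assign), best_cost):
                    best_cost, best_assign = cost, tuple(assign)
        links |= {(f, r, c) for r, c in best_assign}
    return links


def links_of_tracks(tracks):
    out = set()
    for tr in tracks:
        for i in range(len(tr.frames) - 1):
            if tr.frames[i + 1] == tr.frames[i] + 1:
                out.add((int(tr.frames[i]), tuple(tr.centroids[i]),
                         tuple(tr.centroids[i + 1])))
    return out


class TestLinking:
    def test_stationary_particles_one_track_each(self):
        pts = np.array([[0.0, 0.0], [5.0, 1.0], [-3.0, 4.0]])
        dets = [_det(pts) for _ in range(5)]
        tracks = trackkin.link_tracks(dets, max_disp_um=1.0)
        assert len(tracks) == 3
        for tr in tracks:
            assert len(tr.frames) == 5
            assert np.allclose(np.diff(tr.centroids, axis=0), 0.0)

    def test_jumps_beyond_cutoff_terminate_tracks_instead_of_linking(self):
        """An exchange landing near (but beyond cutoff of) the other
        particle's position must not be cross-linked."""
        dets = [
            _det([[0.0, 0.0], [4.0, 0.0]]),
            _det([[4.0, 1.0], [0.0, 1.0]]),
        ]
        tracks = trackkin.link_tracks(dets, max_disp_um=0.5, min_length=1)
        assert len(tracks) == 4
        assert all(len(tr.frames) == 1 for tr in tracks)

    def test_matches_bruteforce_assignment_oracle(self, rng):
        """5 particles, 4 frames, random small steps: optimal linking."""
        pts = rng.uniform(-5, 5, (5, 2))
        dets = []
        for f in range(4):
            pts = pts + rng.normal(0, 0.3, pts.shape)
            order = rng.permutation(5)
            dets.append(_det(pts[order]))
        tracks = trackkin.link_tracks(dets, max_disp_um=2.0, min_length=1)
        oracle = exhaustive_links(dets, 2.0)
        oracle_pts = {
            (f, tuple(dets[f].centroids[r]), tuple(dets[f + 1].centroids[c]))
            for f, r, c in oracle
        }
        assert links_of_tracks(tracks) == oracle_pts

    def test_gap_bridging(self):
        p = [0.0, 0.0]
        dets = [_det([p]), _det(np.empty((0, 2))), _det([[0.2, 0.0]])]
        no_gap = trackkin.link_tracks(dets, max_disp_um=1.0, max_gap=0,
                                      min_length=1)
        with_gap = trackkin.link_tracks(dets, max_disp_um=1.0, max_gap=1,
                                        min_length=1)
        assert max(len(t.frames) for t in no_gap) == 1
        assert max(len(t.frames) for t in with_gap) == 2

    def test_detection_order_invariance(self, rng):
        pts = rng.uniform(-5, 5, (6, 2))
        steps = [pts + rng.normal(0, 0.1, pts.shape) for _ in range(3)]
        dets_a = [_det(s) for s in steps]
        dets_b = [_det(s[rng.permutation(len(s))]) for s in steps]
        ta = trackkin.link_tracks(dets_a, 1.0)
        tb = trackkin.link_tracks(dets_b, 1.0)
        key = lambda tr: tuple(map(tuple, np.round(tr.centroids, 9)))
        assert sorted(map(key, ta)) == sorted(map(key, tb))

    def test_ground_truth_identities_recovered(self, medium_movie):
        """True tracks reproduced when steps are well below the cutoff."""
        _, _, gt, _ = medium_movie
        df = gt["tracks"]
        frames = sorted(df["frame"].unique())
        dets = []
        for f in frames:
            sub = df[df["frame"] == f].sort_values("track_id")
            dets.append(_det(sub[["x_um", "y_um"]].values,
                             sub["angle_rad"].values,
                             sub["length_um"].values))
        tracks = trackkin.link_tracks(dets, max_disp_um=0.8)
        assert len(tracks) == df["track_id"].nunique()
        for tr in tracks:
            assert len(tr.frames) == len(frames)


class TestSegmentation:
    def test_blank_frame_returns_no_cells(self):
        frame = np.full((64, 64), 0.8)
        det = trackkin.segment_cells(frame, 0.1724, threshold=0.5)
        assert det.n_cells == 0

    def test_dilute_frame_accuracy(self, dilute_scene):
        """Isolated rods: centroid within 0.5 px, angle within 3 deg."""
        ensembles, stack, _, optics = dilute_scene
        ens = ensembles[0]
        det = trackkin.segment_cells(stack.frames[0], optics.pixel_size)
        H, W = optics.shape
        half_w = W / 2 * optics.pixel_size
        fully_inside = np.all(np.abs(ens.positions) < half_w - 3.0, axis=1)
        for i in np.nonzero(fully_inside)[0]:
            j = np.argmin(np.hypot(*(det.centroids - ens.positions[i]).T))
            pos_err = np.hypot(*(det.centroids[j] - ens.positions[i]))
            ang_err = abs(nematic_diff(det.angles[j], ens.angles[i]))
            assert pos_err < 0.5 * optics.pixel_size
            assert np.degrees(ang_err) < 3.0

    def test_two_parallel_touching_rods_split(self):
        """Constructed fixture: two parallel rods with a faint seam."""
        optics = rodsim.OpticsParams(
            shape=(64, 64), blur_sigma=0.1, noise_amplitude=0.002, noise_seed=0
        )
        gap = 1.0 + 2.5 * optics.pixel_size
        ens = rodsim.RodEnsemble(
            positions=[[0.0, -gap / 2], [0.0, gap / 2]],
            angles=[0.0, 0.0], lengths=[4.0, 4.0], width=1.0,
            speeds=[0.0, 0.0], well_radius=8.0, time=0.0,
        )
        stack = rodsim.render_frames([ens], optics)
        det = trackkin.segment_cells(stack.frames[0], optics.pixel_size)
        assert det.n_cells == 2
        for a in det.angles:
            assert np.degrees(abs(nematic_diff(a, 0.0))) < 5.0


class TestDisplacementOrientationHistogram:
    def _straight_track(self, angle, n=11, step=0.5):
        t = np.arange(n)
        direction = np.array([np.cos(angle), np.sin(angle)])
        return CellTrack(
            track_id=0, frames=t, times=t * 1.0,
            centroids=np.outer(t * step, direction),
            angles=np.full(n, nematic_diff(angle, 0.0)),
            lengths=np.full(n, 3.0),
        )

    def test_axis_aligned_motion_fills_first_bin(self):
        tracks = [self._straight_track(0.4)]
        edges, prob, _ = trackkin.displacement_orientation_histogram(tracks)
        assert prob[0] == pytest.approx(1.0)

    def test_isotropic_displacements_give_flat_histogram(self, rng):
        tracks = []
        n = 10_000
        for i in range(n // 10):
            pts = np.cumsum(rng.normal(0, 0.5, (11, 2)), axis=0)
            tracks.append(CellTrack(
                track_id=i, frames=np.arange(11), times=np.arange(11.0),
                centroids=pts,
                angles=rng.uniform(-np.pi / 2, np.pi / 2, 11),
                lengths=np.full(11, 3.0),
            ))
        edges, prob, _ = trackkin.displacement_orientation_histogram(
            tracks, bins=9
        )
        n_samples = sum(len(t.frames) - 1 for t in tracks)
        tol = 4 * np.sqrt((1 / 9) * (8 / 9) / n_samples)
        assert np.all(np.abs(prob - 1 / 9) < tol)

    def test_self_propelled_rods_move_along_their_axis(self, medium_movie):
        """Ground-truth tracks of axis-propelled rods: mass at small angles."""
        _, _, gt, _ = medium_movie
        df = gt["tracks"]
        tracks = []
        for tid, sub in df.groupby("track_id"):
            sub = sub.sort_values("frame")
            tracks.append(CellTrack(
                track_id=tid, frames=sub["frame"].values,
                times=sub["t_s"].values,
                centroids=sub[["x_um", "y_um"]].values,
                angles=sub["angle_rad"].values,
                lengths=sub["length_um"].values,
            ))
        edges, prob, _ = trackkin.displacement_orientation_histogram(
            tracks, lag_frames=2, bins=4
        )
        assert np.all(np.diff(prob) <= 0)
        assert prob[0] > 0.5


class TestVelocityCorrelation:
    def _translating_tracks(self, v, n_cells=6, n_frames=5, rng=None):
        rng = rng or np.random.default_rng(3)
        base = rng.uniform(-5, 5, (n_cells, 2))
        tracks = []
        for i in range(n_cells):
            t = np.arange(n_frames)
            tracks.append(CellTrack(
                track_id=i, frames=t, times=t * 0.1,
                centroids=base[i] + np.outer(t * 0.1, v),
                angles=np.zeros(n_frames), lengths=np.full(n_frames, 3.0),
            ))
        return tracks

    def test_rigid_translation_gives_v_squared_everywhere(self):
        v = np.array([1.5, -2.0])
        tracks = self._translating_tracks(v)
        vc = trackkin.velocity_correlation(tracks, lag_frames=1, bin_um=1.0)
        assert np.allclose(vc.corr, v @ v, rtol=1e-9)
        assert np.all(vc.n_pairs >= 1)

    def test_independent_velocities_average_to_zero(self, rng):
        tracks = []
        n_frames = 40
        for i in range(30):
            steps = rng.normal(0, 0.2, (n_frames, 2))
            tracks.append(CellTrack(
                track_id=i, frames=np.arange(n_frames),
                times=np.arange(n_frames) * 1.0,
                centroids=rng.uniform(-3, 3, 2) + np.cumsum(steps, axis=0) * 0.01,
                angles=np.zeros(n_frames), lengths=np.full(n_frames, 3.0),
            ))
        vc = trackkin.velocity_correlation(tracks, lag_frames=1, bin_um=2.0)
        assert np.all(np.abs(vc.corr) <= 3 * vc.stderr + 1e-12)

    def test_three_cell_hand_oracle(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        vel = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 1.0]])
        tracks = [
            CellTrack(
                track_id=i, frames=np.array([0, 1]), times=np.array([0.0, 1.0]),
                centroids=np.stack([pos[i], pos[i] + vel[i]]),
                angles=np.zeros(2), lengths=np.full(2, 3.0),
            )
            for i in range(3)
        ]
        vc = trackkin.velocity_correlation(tracks, lag_frames=1, bin_um=1.0)
        # pairs: (0,1) r=1, dot=0; (0,2) r=2, dot=-1; (1,2) r=sqrt(5), dot=1
        by_bin = dict(zip(np.round(vc.r_bins, 6), vc.corr))
        assert by_bin[1.5] == pytest.approx(0.0)
        assert by_bin[2.5] == pytest.approx(
            (-1.0 + 1.0) / 2
        )  # r=2 and r=sqrt(5)~2.24 share the [2,3) bin
        assert vc.n_pairs.sum() == 3

    def test_rigid_rotation_closed_form(self, rng):
        """v_i . v_j of rotation about the origin equals w^2 (r_i . r_j)."""
        omega = 0.01
        base = rng.uniform(-4, 4, (5, 2))
        n_frames = 3
        tracks = []
        for i in range(5):
            pts = []
            for f in range(n_frames):
                a = omega * f
                R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
                pts.append(R @ base[i])
            tracks.append(CellTrack(
                track_id=i, frames=np.arange(n_frames),
                times=np.arange(n_frames) * 1.0,
                centroids=np.stack(pts), angles=np.zeros(n_frames),
                lengths=np.full(n_frames, 3.0),
            ))
        vc = trackkin.velocity_correlation(tracks, lag_frames=1, bin_um=50.0)
        expected = []
        for i in range(5):
            for j in range(i + 1, 5):
                expected.append(omega**2 * (base[i] @ base[j]))
        # all pairs fall in the single wide bin for both reference frames
        assert vc.corr[0] == pytest.approx(np.mean(expected), rel=1e-3)

    def test_no_concurrent_pairs_warns(self):
        t1 = CellTrack(0, np.array([0, 1]), np.array([0.0, 1.0]),
                       np.zeros((2, 2)), np.zeros(2), np.full(2, 3.0))
        t2 = CellTrack(1, np.array([5, 6]), np.array([5.0, 6.0]),
                       np.zeros((2, 2)), np.zeros(2), np.full(2, 3.0))
        with pytest.warns(RuntimeWarning):
            vc = trackkin.velocity_correlation([t1, t2], lag_frames=1)
        assert vc.r_bins.size == 0


def test_cage_escape_flagging():
    t = np.arange(0.0, 10.0, 0.5)
    x = np.where(t < 5, 0.05 * t, 0.05 * 5 + 3.0 * (t - 5))
    track = CellTrack(
        track_id=0, frames=np.arange(len(t)), times=t,
        centroids=np.stack([x, np.zeros_like(x)], axis=-1),
        angles=np.zeros_like(t), lengths=np.full(len(t), 3.0),
    )
    events = trackkin.cage_escape_events(track, window_s=2.0, cell_width_um=1.0)
    assert len(events) == 1
    assert events[0][0] > 5.0
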