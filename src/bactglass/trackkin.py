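"""Per-cell kinematics: segmentation, linking, and motion statistics.

Cells are segmented classically (intensity threshold from the fuzzy c-means
clustering, morphological opening, distance-transform watershed to split
touching rods, second-moment ellipse per component) and linked frame to
frame by minimum-total-squared-displacement assignment with a hard per-link
cutoff — the standard nearest-neighbor linking strategy for colloidal
tracking. On the resulting tracks, the module computes the two motion
statistics of interest for active rods: the distribution of the angle
between a cell's displacement and its body axis (axis-aligned propulsion
shows up as mass near 0°), and the pair velocity correlation ⟨v_i · v_j⟩
versus cell-cell distance (collective motion shows up as a positive
short-range plateau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.measure import regionprops, label as sk_label
from skimage.morphology import disk
from skimage.segmentation import watershed

from .imgprep import fuzzy_cmeans_1d
from .orientfield import nematic_diff
from .stack import ImageStack

__all__ = [
    "Detection",
    "CellTrack",
    "VelocityCorrelation",
    "segment_cells",
    "segment_stack",
    "link_tracks",
    "tracks_to_dataframe",
    "displacement_orientation_histogram",
    "velocity_correlation",
    "cage_escape_events",
]


@dataclass
class Detection:
    """Cells found in one frame (parallel arrays)."""

    centroids: np.ndarray  # (N, 2) physical (x, y), μm, y-up, frame center origin
    angles: np.ndarray  # (N,) nematic axis, rad
    lengths: np.ndarray  # (N,) major-axis length, μm
    labels: np.ndarray = None  # (H, W) label image, optional

    @property
    def n_cells(self) -> int:
        return len(self.centroids)


@dataclass
class CellTrack:
    """One linked trajectory."""

    track_id: int
    frames: np.ndarray  # strictly increasing frame indices
    times: np.ndarray  # s
    centroids: np.ndarray  # (n, 2) μm
    angles: np.ndarray  # rad, nematic
    lengths: np.ndarray  # μm

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")


def _px_to_physical(rows, cols, shape, pixel_size):
    """Pixel (row, col) centroids -> physical (x, y), y-up, origin at center."""
    H, W = shape
    x = (np.asarray(cols) + 0.5 - W / 2) * pixel_size
    y = (H / 2 - (np.asarray(rows) + 0.5)) * pixel_size
    return np.stack([x, y], axis=-1)


def segment_cells(
    frame: np.ndarray,
    pixel_size: float,
    threshold: float | None = None,
    min_area_px: int = 4,
    opening_radius: int = 1,
    split_touching: bool = True,
) -> Detection:
    """Segment dark rods in one pre-processed frame.

    ``threshold`` defaults to the fuzzy-c-means darker-class midpoint of the
    frame's own histogram. Merged blobs are split by a watershed on the
    distance transform, seeded with one marker per distance core. Each
    component's centroid, nematic axis angle and major-axis length come
    from its second-moment ellipse; components below ``min_area_px`` are
    discarded.
    """
    f = np.asarray(frame, float)
    if threshold is None:
        try:
            centers, _ = fuzzy_cmeans_1d(f.ravel())
            threshold = 0.5 * (centers[0] + centers[1])
        except (ValueError, RuntimeError):
            return Detection(np.empty((0, 2)), np.empty(0), np.empty(0))
    binary = f < threshold
    if opening_radius > 0:
        binary = ndimage.binary_opening(binary, structure=disk(opening_radius))
    if not binary.any():
        return Detection(np.empty((0, 2)), np.empty(0), np.empty(0),
                         labels=np.zeros(f.shape, int))
    if split_touching:
        # markers: per-component cores where the (smoothed) distance
        # transform exceeds 60% of that component's maximum. A rod's whole
        # ridge stays one marker (no fragmentation), while blobs with
        # separate cores joined by a thin neck get one marker per core.
        comp = sk_label(binary)
        dist = ndimage.gaussian_filter(
            ndimage.distance_transform_edt(binary), 1.0
        )
        comp_max = ndimage.maximum(dist, comp, np.arange(comp.max() + 1))
        core = binary & (dist >= 0.6 * comp_max[comp])
        markers = sk_label(core, connectivity=2)
        if markers.any():
            labels = watershed(-dist, markers, mask=binary)
        else:
            labels = comp
    else:
        labels = sk_label(binary)
    rows, cols, angs, lens = [], [], [], []
    for rp in regionprops(labels):
        if rp.area < min_area_px:
            continue
        r0, c0 = rp.centroid
        rows.append(r0)
        cols.append(c0)
        # regionprops measures the angle from the row axis; the major-axis
        # direction is (dcol, drow) = (-sin o, -cos o), which in the
        # physical y-up frame is the angle o + pi/2 from +x
        angs.append(nematic_diff(rp.orientation + np.pi / 2, 0.0))
        lens.append(rp.axis_major_length * pixel_size)
    if not rows:
        return Detection(np.empty((0, 2)), np.empty(0), np.empty(0), labels=labels)
    return Detection(
        centroids=_px_to_physical(rows, cols, f.shape, pixel_size),
        angles=np.asarray(angs),
        lengths=np.asarray(lens),
        labels=labels,
    )


def segment_stack(stack: ImageStack, **kwargs) -> list[Detection]:
    """Segment every frame of a movie with a shared threshold."""
    if "threshold" not in kwargs:
        centers, _ = fuzzy_cmeans_1d(stack.frames[0].ravel())
        kwargs["threshold"] = 0.5 * (centers[0] + centers[1])
    return [
        segment_cells(f, stack.pixel_size, **kwargs) for f in stack.frames
    ]


def link_tracks(
    detections: list[Detection],
    max_disp_um: float,
    max_gap: int = 0,
    frame_interval: float = 1.0,
    min_length: int = 2,
) -> list[CellTrack]:
    """Link per-frame detections into trajectories.

    Frame-to-frame global assignment minimizing total squared displacement
    (Hungarian algorithm) with a hard per-link cutoff ``max_disp_um``:
    candidate links longer than the cutoff are never made, and a detection
    left unmatched starts a new track. Track heads stay eligible for
    ``max_gap`` missed frames before being closed. Deterministic; an
    ambiguous optimum resolves to the lowest-index pairing.
    """
    if len(detections) < 2:
        raise ValueError("need detections from at least 2 frames")
    tracks_data: list[dict] = []
    active: list[dict] = []  # each: {data index, last frame, last position}
    BIG = 1e12

    def start(fidx, det, i):
        tracks_data.append(
            {"frames": [fidx], "cent": [det.centroids[i]],
             "ang": [det.angles[i]], "len": [det.lengths[i]]}
        )
        active.append(
            {"idx": len(tracks_data) - 1, "frame": fidx, "pos": det.centroids[i]}
        )

    for i in range(detections[0].n_cells):
        start(0, detections[0], i)
    for fidx in range(1, len(detections)):
        det = detections[fidx]
        # drop stale heads
        active = [a for a in active if fidx - a["frame"] <= max_gap + 1]
        n_a, n_d = len(active), det.n_cells
        if n_a and n_d:
            apos = np.stack([a["pos"] for a in active])
            cost = np.sum(
                (apos[:, None, :] - det.centroids[None, :, :]) ** 2, axis=-1
            )
            cost = np.where(cost <= max_disp_um**2, cost, BIG)
            rows, cols = optimize.linear_sum_assignment(cost)
            matched_det = set()
            kept = []
            for r, c in zip(rows, cols):
                if cost[r, c] >= BIG:
                    kept.append(active[r])
                    continue
                a = active[r]
                td = tracks_data[a["idx"]]
                td["frames"].append(fidx)
                td["cent"].append(det.centroids[c])
                td["ang"].append(det.angles[c])
                td["len"].append(det.lengths[c])
                a["frame"] = fidx
                a["pos"] = det.centroids[c]
                kept.append(a)
                matched_det.add(c)
            unmatched_active = [active[r] for r in range(n_a) if r not in set(rows)]
            active = kept + unmatched_active
            for c in range(n_d):
                if c not in matched_det:
                    start(fidx, det, c)
        else:
            for c in range(n_d):
                start(fidx, det, c)
    out = []
    tid = 0
    for td in tracks_data:
        if len(td["frames"]) < min_length:
            continue
        frames = np.asarray(td["frames"])
        out.append(
            CellTrack(
                track_id=tid,
                frames=frames,
                times=frames * frame_interval,
                centroids=np.stack(td["cent"]),
                angles=np.asarray(td["ang"]),
                lengths=np.asarray(td["len"]),
            )
        )
        tid += 1
    return out


def tracks_to_dataframe(tracks: list[CellTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for k in range(len(tr.frames)):
            rows.append(
                (tr.track_id, int(tr.frames[k]), tr.times[k],
                 tr.centroids[k, 0], tr.centroids[k, 1],
                 tr.angles[k], tr.lengths[k])
            )
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "t_s", "x_um", "y_um",
                       "angle_rad", "length_um"]
    )


def displacement_orientation_histogram(
    tracks: list[CellTrack],
    lag_frames: int = 1,
    bins: int = 9,
    min_disp_um: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Distribution of the angle between displacement and body axis.

    For each cell and reference frame with both endpoints tracked, the
    angle between the displacement over ``lag_frames`` and the cell's
    nematic axis (nematic mean of the two endpoint axes), folded into
    [0°, 90°]. Displacements below ``min_disp_um`` are excluded (counted).
    Returns ``(bin_edges_deg, probability, n_excluded)``.
    """
    angles = []
    n_excluded = 0
    for tr in tracks:
        fr = tr.frames
        pos_by_frame = {f: i for i, f in enumerate(fr)}
        for f in fr:
            j = pos_by_frame.get(f + lag_frames)
            if j is None:
                continue
            i = pos_by_frame[f]
            disp = tr.centroids[j] - tr.centroids[i]
            norm = np.hypot(*disp)
            if norm <= min_disp_um:
                n_excluded += 1
                continue
            axis = tr.angles[i] + 0.5 * nematic_diff(tr.angles[j], tr.angles[i])
            disp_ang = np.arctan2(disp[1], disp[0])
            dang = np.abs(nematic_diff(disp_ang, axis))
            angles.append(np.degrees(dang))
    edges = np.linspace(0, 90, bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    total = counts.sum()
    prob = counts / total if total else counts.astype(float)
    return edges, prob, n_excluded


@dataclass
class VelocityCorrelation:
    """Binned pair velocity correlation ⟨v_i · v_j⟩ vs distance."""

    r_bins: np.ndarray  # bin centers, μm
    corr: np.ndarray  # (μm/s)²
    stderr: np.ndarray
    n_pairs: np.ndarray


def velocity_correlation(
    tracks: list[CellTrack],
    lag_frames: int = 2,
    bin_um: float = 0.5,
    r_max: float | None = None,
) -> VelocityCorrelation:
    """⟨v_i · v_j⟩ binned by instantaneous pair distance.

    Velocities are centroid displacements over ``lag_frames`` divided by
    the elapsed time; for every pair of concurrently tracked cells the dot
    product enters the bin of their distance at the reference frame. The
    standard error treats all pairs as independent.
    """
    samples: list[tuple[float, float]] = []  # (r, v_i . v_j)
    per_frame: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for tr in tracks:
        index = {f: i for i, f in enumerate(tr.frames)}
        for f in tr.frames:
            j = index.get(f + lag_frames)
            if j is None:
                continue
            i = index[f]
            dt = tr.times[j] - tr.times[i]
            v = (tr.centroids[j] - tr.centroids[i]) / dt
            per_frame.setdefault(int(f), []).append((tr.centroids[i], v))
    for f, items in per_frame.items():
        if len(items) < 2:
            continue
        pos = np.stack([p for p, _ in items])
        vel = np.stack([v for _, v in items])
        iu, ju = np.triu_indices(len(items), k=1)
        r = np.hypot(*(pos[iu] - pos[ju]).T)
        dots = np.einsum("ij,ij->i", vel[iu], vel[ju])
        samples.extend(zip(r, dots))
    if not samples:
        warnings.warn("no concurrent track pairs; empty velocity correlation",
                      RuntimeWarning)
        return VelocityCorrelation(*(np.empty(0),) * 4)
    r, dots = np.array(samples).T
    if r_max is None:
        r_max = r.max() + 1e-9
    nbins = max(1, int(np.ceil(r_max / bin_um)))
    idx = np.minimum((r / bin_um).astype(int), nbins - 1)
    n = np.bincount(idx, minlength=nbins)
    s = np.bincount(idx, weights=dots, minlength=nbins)
    s2 = np.bincount(idx, weights=dots**2, minlength=nbins)
    good = n >= 1
    mean = s[good] / n[good]
    var = s2[good] / n[good] - mean**2
    stderr = np.sqrt(np.clip(var, 0, None) / n[good])
    centers = (np.arange(nbins) + 0.5) * bin_um
    return VelocityCorrelation(
        r_bins=centers[good], corr=mean, stderr=stderr, n_pairs=n[good]
    )


def cage_escape_events(
    track: CellTrack, window_s: float = 2.0, cell_width_um: float = 1.0
) -> list[tuple[float, float]]:
    """Flag cage-escape episodes on one trajectory.

    An escape is a time at which the displacement accumulated over the
    trailing ``window_s`` exceeds two cell widths; consecutive flagged
    times merge into (start, end) intervals. A descriptive utility for
    inspecting glassy trajectories, not a headline statistic.
    """
    t = track.times
    flagged = np.zeros(len(t), bool)
    for i in range(len(t)):
        j = np.searchsorted(t, t[i] - window_s)
        disp = np.hypot(*(track.centroids[i] - track.centroids[j]))
        flagged[i] = disp > 2 * cell_width_um
    events = []
    i = 0
    while i < len(t):
        if flagged[i]:
            j = i
            while j + 1 < len(t) and flagged[j + 1]:
                j += 1
            events.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1
    return events
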