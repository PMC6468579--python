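"""Detection of diffraction-limited puncta and frame-to-frame linking.

Detection is Laplacian-of-Gaussian blob finding: local maxima of the
scale-normalized negated LoG response above a response threshold, refined to
subpixel positions by an intensity-weighted centroid in a window of side
2*ceil(2*sigma)+1 around each maximum.

Linking is greedy mutual-nearest assignment: candidate (track, detection)
pairs within the displacement gate are linked in ascending order of
distance, which links mutually nearest pairs first. Gap closing re-links a
track to a detection up to ``max_gap`` missed frames later, with the gate
scaled by the gap length. Unmatched detections seed new tracks. This is
adequate at the sparse punctum densities of interest; on small problems it
attains the exhaustively-enumerated optimal assignment (see tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

__all__ = [
    "Detection",
    "Track",
    "TrackSet",
    "detect_puncta",
    "link_tracks",
    "filter_tracks",
]


@dataclass(frozen=True)
class Detection:
    """One punctum in one frame: subpixel (row, col) centroid in px."""

    frame_index: int
    centroid: tuple[float, float]
    intensity: float = 0.0


@dataclass
class Track:
    """Time-ordered detections of one punctum within one cell."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)
    cell_id: str = ""
    associated_truth: bool | None = None  # ground-truth label (synthetic data)

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame_index for d in self.detections], dtype=int)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (row, col) centroids in px."""
        return np.array([d.centroid for d in self.detections], dtype=float)

    def displacement_vectors(self) -> np.ndarray:
        """Inter-frame displacement vectors (n-1, 2), px."""
        return np.diff(self.points, axis=0)

    def displacement_magnitudes(self) -> np.ndarray:
        d = self.displacement_vectors()
        return np.hypot(d[:, 0], d[:, 1])

    def validate(self) -> None:
        f = self.frames
        if len(f) and np.any(np.diff(f) <= 0):
            raise ValueError("frame indices must be strictly increasing")


@dataclass
class TrackSet:
    """All tracks of one cell, with imaging metadata."""

    tracks: list[Track]
    pixel_size: float
    n_frames: int

    def __post_init__(self):
        ids = [t.track_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise ValueError("track_ids must be unique")

    def __len__(self) -> int:
        return len(self.tracks)


def detect_puncta(frame: np.ndarray, log_sigma_px: float = 1.6,
                  min_response: float = 1.0) -> list[Detection]:
    """LoG blob detection with subpixel centroid refinement.

    Returns detections with frame_index 0; callers tracking a stack reindex
    them. ``min_response`` is a threshold on the scale-normalized response
    sigma^2 * (-LoG), which for a Gaussian spot of amplitude A and matched
    sigma peaks at ~A/2.
    """
    if log_sigma_px <= 0:
        raise ValueError("log_sigma_px must be positive")
    img = np.asarray(frame, dtype=float)
    resp = -(log_sigma_px ** 2) * ndi.gaussian_laplace(img, log_sigma_px)
    peaks = peak_local_max(resp, min_distance=int(np.ceil(log_sigma_px)),
                           threshold_abs=min_response, exclude_border=False)
    half = int(np.ceil(2 * log_sigma_px))
    out: list[Detection] = []
    for r, c in peaks:
        r0, r1 = max(0, r - half), min(img.shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(img.shape[1], c + half + 1)
        win = img[r0:r1, c0:c1]
        w = win - win.min()
        tot = w.sum()
        if tot == 0:
            cen = (float(r), float(c))
        else:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            cen = (float((rr * w).sum() / tot), float((cc * w).sum() / tot))
        out.append(Detection(0, cen, intensity=float(img[r, c])))
    out.sort(key=lambda d: d.centroid)
    return out


def detect_stack(stack: np.ndarray, log_sigma_px: float = 1.6,
                 min_response: float = 1.0) -> list[list[Detection]]:
    """Run :func:`detect_puncta` on every frame of a (t, rows, cols) stack."""
    per_frame = []
    for f, frame in enumerate(stack):
        dets = [Detection(f, d.centroid, d.intensity)
                for d in detect_puncta(frame, log_sigma_px, min_response)]
        per_frame.append(dets)
    return per_frame


def _link_cost(p: tuple[float, float], q: tuple[float, float]) -> float:
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def link_tracks(detections_per_frame: list[list[Detection]],
                max_disp_px: float = 5.0, max_gap: int = 1,
                pixel_size: float = 1.0, cell_id: str = "") -> TrackSet:
    """Link per-frame detections into trajectories.

    ``detections_per_frame[f]`` holds the detections of frame f (may be
    empty). Links farther than ``max_disp_px`` per frame step are rejected;
    a track missing from up to ``max_gap`` consecutive frames may be
    re-linked with the gate scaled by the gap length.
    """
    n_frames = len(detections_per_frame)
    tracks: list[Track] = []
    # active: list of track indices; last point/frame read from the track
    active: list[int] = []
    next_id = 0
    for f in range(n_frames):
        dets = sorted(detections_per_frame[f], key=lambda d: d.centroid)
        # candidate links (cost, active-slot, detection-slot)
        cands = []
        for ai, ti in enumerate(active):
            last = tracks[ti].detections[-1]
            gap = f - last.frame_index
            if gap > max_gap + 1:
                continue
            for di, det in enumerate(dets):
                cost = _link_cost(last.centroid, det.centroid)
                if cost <= max_disp_px * gap:
                    cands.append((cost, ai, di))
        cands.sort()
        used_a: set[int] = set()
        used_d: set[int] = set()
        for cost, ai, di in cands:
            if ai in used_a or di in used_d:
                continue
            tracks[active[ai]].detections.append(dets[di])
            used_a.add(ai)
            used_d.add(di)
        for di, det in enumerate(dets):
            if di not in used_d:
                tracks.append(Track(next_id, [det], cell_id=cell_id))
                active.append(len(tracks) - 1)
                next_id += 1
        # retire tracks whose gap can no longer be closed
        active = [ti for ti in active
                  if f - tracks[ti].detections[-1].frame_index <= max_gap]
    for t in tracks:
        t.validate()
    return TrackSet(tracks, pixel_size=pixel_size, n_frames=n_frames)


def filter_tracks(ts: TrackSet, min_length: int = 3) -> TrackSet:
    """Drop tracks shorter than ``min_length`` detections (flicker removal)."""
    kept = [t for t in ts.tracks if len(t) >= min_length]
    return TrackSet(kept, pixel_size=ts.pixel_size, n_frames=ts.n_frames)
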