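"""Synthetic data with known ground truth for every pipeline stage.

Four generators emulate the experimental inputs:

* **Cells** — a single connected cytoplasm containing an ER-like tubular
  network (random spanning tree over scattered nodes, drawn as 2–4 px wide
  tubules) and elongated mitochondria (random ellipses, aspect ratio 2–6).
  Diffraction-limited puncta are seeded organelle-associated with
  probability ``p_assoc`` (within ``assoc_radius`` nm of the target
  organelle) or uniformly in the cytoplasm, then moved frame to frame:
  associated puncta ride their organelle's rigid jitter with a small
  non-cumulative wobble (a tethered contact), free puncta diffuse with a
  reflected Gaussian random walk. Frames are rendered with a Gaussian PSF
  and Poisson + Gaussian noise.
* **Immunogold fields** — fixed-area images with elliptical mitochondrial
  outlines and Poisson-distributed gold clusters, each associated (placed
  within the association rule's reach of an outline) with a controllable
  probability.
* **Fraction profiles** — two cofractionation profiles sharing a latent
  gradient profile, mixed with independent noise so that the population
  Pearson correlation equals ``target_r``.
* **Association studies** — per-cell observed/randomized fraction pairs at
  a prescribed effect size, for power and null-calibration experiments.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse.csgraph import minimum_spanning_tree
from shapely import affinity
from shapely.geometry import Point, Polygon, box

from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .immunogold import GoldCluster, GoldImage
from .io import ImageStack
from .segmentation import Mask, point_to_mask_distances
from .tracking import Detection, Track, TrackSet

__all__ = [
    "SyntheticCellParams",
    "SyntheticCell",
    "GoldFieldParams",
    "FractionProfileParams",
    "FractionProfile",
    "generate_cell_geometry",
    "simulate_puncta_tracks",
    "render_timelapse",
    "simulate_cell",
    "generate_gold_field",
    "generate_fraction_profiles",
    "simulate_association_study",
]


@dataclass(frozen=True)
class SyntheticCellParams:
    """Ground-truth parameters of one synthetic cell time-lapse.

    Lengths are in nm; the image grid is ``image_shape`` pixels of
    ``pixel_size`` nm (default 80 nm/px, typical confocal sampling with a
    63x/1.4 NA objective).
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 80.0          # nm/px
    n_frames: int = 10
    n_puncta: int = 30
    p_assoc: float = 0.45             # probability a punctum is seeded associated
    assoc_radius: float = 100.0       # nm; placement distance for associated puncta
    assoc_organelle: str = "er"       # "er" | "mito": association target
    diffusion_step_sd: float = 40.0   # nm/frame, free-punctum random walk
    organelle_motion_sd: float = 20.0  # nm/frame, rigid organelle jitter
    residual_motion_sd: float = 10.0  # nm/frame, wobble of tethered puncta
    psf_sigma: float = 120.0          # nm
    noise_poisson_scale: float = 1.0  # photons per intensity unit (0 = off)
    noise_gaussian_sd: float = 2.0    # intensity units (0 = off)
    n_mito: int = 24                  # mitochondria count in the geometry
    er_nodes: int = 1050              # ER tubule junction count (density knob)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_assoc <= 1.0:
            raise ValueError("p_assoc must be in [0, 1]")
        for name in ("pixel_size", "assoc_radius", "psf_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("diffusion_step_sd", "organelle_motion_sd",
                     "residual_motion_sd", "noise_poisson_scale",
                     "noise_gaussian_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.assoc_organelle not in ("er", "mito"):
            raise ValueError("assoc_organelle must be 'er' or 'mito'")


@dataclass
class SyntheticCell:
    """Geometry, ground-truth tracks, per-frame masks and rendered stack."""

    params: SyntheticCellParams
    cytoplasm_mask: Mask
    er_mask: Mask
    mito_mask: Mask
    er_masks: list[Mask] | None = None    # per frame, rigid jitter applied
    mito_masks: list[Mask] | None = None
    truth_tracks: TrackSet | None = None
    stack: ImageStack | None = None


@dataclass(frozen=True)
class GoldFieldParams:
    """Parameters of a synthetic immunogold field experiment."""

    image_area: float = 11.125        # µm² per image
    n_images: int = 41
    cluster_density: float = 0.8      # clusters/µm²
    assoc_fraction: float = 0.6       # probability a cluster is associated
    mito_region_count: int = 6
    mito_region_area_fraction: float = 0.15
    assoc_distance_um: float = 0.03   # reach of the association rule
    seed: int = 0

    def __post_init__(self):
        if self.image_area <= 0:
            raise ValueError("image_area must be positive")
        if not 0.0 <= self.assoc_fraction <= 1.0:
            raise ValueError("assoc_fraction must be in [0, 1]")


@dataclass(frozen=True)
class FractionProfileParams:
    """Parameters for a pair of correlated cofractionation profiles.

    12 fractions by default (24 collected fractions probed pairwise as 12
    lanes). ``target_r`` is the population Pearson correlation of the two
    profiles; with ``noise_sd`` = 0 the profiles share the latent gradient
    exactly and |r| collapses to 1.
    """

    n_fractions: int = 12
    target_r: float = 0.633
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_fractions < 3:
            raise ValueError("need at least 3 fractions")
        if not -1.0 <= self.target_r <= 1.0:
            raise ValueError("|target_r| must be <= 1")


@dataclass(frozen=True)
class FractionProfile:
    marker: str
    values: tuple[float, ...]


# ---------------------------------------------------------------------------
# cell geometry


def _cytoplasm(shape, rng) -> np.ndarray:
    h, w = shape
    mask = np.zeros(shape, bool)
    rr, cc = draw_ellipse(h / 2, w / 2, 0.42 * h, 0.40 * w,
                          shape=shape, rotation=rng.uniform(0, np.pi))
    mask[rr, cc] = True
    return mask


def _er_network(cyto: np.ndarray, n_nodes: int, rng) -> np.ndarray:
    """Random spanning tree over scattered nodes, drawn as 2–4 px tubules.

    The node count sets the network density; the default emulates a dense
    perinuclear ER whose 100 nm neighborhood covers roughly half the
    cytoplasm, the chance level reported for ER proximity in live cells.
    """
    interior = ndi.binary_erosion(cyto, structure=disk(4))
    coords = np.argwhere(interior)
    idx = rng.choice(len(coords), size=min(n_nodes, len(coords)), replace=False)
    nodes = coords[idx]
    d = np.linalg.norm(nodes[:, None] - nodes[None], axis=-1)
    mst = minimum_spanning_tree(d).toarray()
    er = np.zeros_like(cyto)
    for i, j in zip(*np.nonzero(mst)):
        rr, cc = draw_line(*nodes[i], *nodes[j])
        er[rr, cc] = True
    er = ndi.binary_dilation(er, structure=disk(1))
    return er & cyto


def _mitochondria(cyto: np.ndarray, n_mito: int, rng) -> np.ndarray:
    """Disjoint elongated ellipses (aspect 2–6) inside the cytoplasm."""
    mito = np.zeros_like(cyto)
    interior = ndi.binary_erosion(cyto, structure=disk(3))
    coords = np.argwhere(interior)
    placed = 0
    attempts = 0
    blocked = ndi.binary_dilation(mito, structure=disk(2))
    while placed < n_mito and attempts < 200 * max(n_mito, 1):
        attempts += 1
        r, c = coords[rng.integers(len(coords))]
        b = rng.uniform(2.5, 4.0)           # semi-minor, px
        a = b * rng.uniform(2.0, 6.0)       # semi-major, px
        rr, cc = draw_ellipse(r, c, a, b, shape=cyto.shape,
                              rotation=rng.uniform(0, np.pi))
        cand = np.zeros_like(cyto)
        cand[rr, cc] = True
        cand &= cyto
        if not cand.any() or (cand & blocked).any():
            continue
        mito |= cand
        blocked = ndi.binary_dilation(mito, structure=disk(2))
        placed += 1
    return mito


def generate_cell_geometry(params: SyntheticCellParams) -> SyntheticCell:
    """Build cytoplasm, ER and mitochondria masks (no tracks, no rendering)."""
    h, w = params.image_shape
    if h < 64 or w < 64:
        raise ValueError("image_shape must be at least 64 px per side")
    rng = np.random.default_rng(params.seed)
    cyto = _cytoplasm(params.image_shape, rng)
    er = _er_network(cyto, params.er_nodes, rng)
    mito = _mitochondria(cyto, params.n_mito, rng)
    px = params.pixel_size
    return SyntheticCell(
        params=params,
        cytoplasm_mask=Mask(cyto, px),
        er_mask=Mask(er, px, frame_index=0),
        mito_mask=Mask(mito, px, frame_index=0),
    )


# ---------------------------------------------------------------------------
# punctum trajectories


def _shift_mask(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(mask)
    h, w = mask.shape
    rs = slice(max(dr, 0), min(h + dr, h))
    cs = slice(max(dc, 0), min(w + dc, w))
    rs0 = slice(max(-dr, 0), min(h - dr, h))
    cs0 = slice(max(-dc, 0), min(w - dc, w))
    out[rs, cs] = mask[rs0, cs0]
    return out


def _inside(mask: np.ndarray, p: np.ndarray) -> bool:
    r, c = int(round(p[0])), int(round(p[1]))
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        return False
    return bool(mask[r, c])


def simulate_puncta_tracks(cell: SyntheticCell,
                           params: SyntheticCellParams) -> TrackSet:
    """Seed puncta and simulate their frame-to-frame motion.

    Fills ``cell.er_masks``/``cell.mito_masks`` with per-frame rigid-jitter
    masks and ``cell.truth_tracks`` with the ground-truth trajectories.
    """
    rng = np.random.default_rng(params.seed + 1)
    px = params.pixel_size
    cyto = cell.cytoplasm_mask.pixels
    target0 = (cell.er_mask if params.assoc_organelle == "er"
               else cell.mito_mask)
    if params.p_assoc > 0 and target0.is_empty():
        raise ValueError("p_assoc > 0 requires a nonempty target organelle "
                         f"mask ({params.assoc_organelle})")

    # rigid jitter of each organelle: integer pixel offsets per frame so the
    # tethered puncta and the shifted masks stay in exact register
    sd_px = params.organelle_motion_sd / px
    offsets = {}
    for name in ("er", "mito"):
        cum = np.cumsum(rng.normal(0.0, sd_px, size=(params.n_frames, 2)),
                        axis=0)
        cum[0] = 0.0
        offsets[name] = np.rint(cum).astype(int)
    er_frames = [_shift_mask(cell.er_mask.pixels, *offsets["er"][t]) & cyto
                 for t in range(params.n_frames)]
    mito_frames = [_shift_mask(cell.mito_mask.pixels, *offsets["mito"][t]) & cyto
                   for t in range(params.n_frames)]
    cell.er_masks = [Mask(m, px, frame_index=t)
                     for t, m in enumerate(er_frames)]
    cell.mito_masks = [Mask(m, px, frame_index=t)
                       for t, m in enumerate(mito_frames)]
    target_offsets = offsets[params.assoc_organelle]

    cyto_coords = np.argwhere(cyto)
    if not len(cyto_coords):
        raise ValueError("empty cytoplasm mask")
    # placement domain for associated seeding: pixels within assoc_radius
    if not target0.is_empty():
        dt_px = ndi.distance_transform_edt(~target0.pixels)
        near = (dt_px * px <= params.assoc_radius) & cyto
        near_coords = np.argwhere(near)
    else:
        near_coords = np.empty((0, 2), int)

    diff_sd = params.diffusion_step_sd / px
    wob_sd = params.residual_motion_sd / px
    tracks: list[Track] = []
    for i in range(params.n_puncta):
        assoc = bool(rng.random() < params.p_assoc)
        # frame-0 placement, rejection sampled to satisfy the exact distance
        for _ in range(1000):
            pool = near_coords if assoc else cyto_coords
            p0 = pool[rng.integers(len(pool))] + rng.uniform(-0.5, 0.5, 2)
            if not _inside(cyto, p0):
                continue
            if assoc:
                d0 = point_to_mask_distances(p0[None], target0)[0]
                if d0 > params.assoc_radius:
                    continue
            break
        pts = [p0]
        for t in range(1, params.n_frames):
            prev = pts[-1]
            if assoc:
                anchor = p0 + target_offsets[t]
                cand = anchor + rng.normal(0.0, wob_sd, 2)
                if not _inside(cyto, cand):
                    cand = anchor if _inside(cyto, anchor) else prev
            else:
                step = rng.normal(0.0, diff_sd, 2)
                cand = prev + step
                if not _inside(cyto, cand):
                    cand = prev - step       # reflect the step
                    if not _inside(cyto, cand):
                        cand = prev
            pts.append(cand)
        dets = [Detection(t, (float(p[0]), float(p[1]))) for t, p in
                enumerate(pts)]
        tracks.append(Track(i, dets, cell_id=f"cell{params.seed}",
                            associated_truth=assoc))
    ts = TrackSet(tracks, pixel_size=px, n_frames=params.n_frames)
    cell.truth_tracks = ts
    return ts


# ---------------------------------------------------------------------------
# rendering

_SPOT_AMPLITUDE = 150.0
_ORGANELLE_AMPLITUDE = 120.0
_BACKGROUND = 10.0


def render_timelapse(cell: SyntheticCell, tracks: TrackSet,
                     params: SyntheticCellParams) -> ImageStack:
    """Render the four-channel stack (puncta, ER, mito, membrane).

    Puncta are Gaussian spots of sd ``psf_sigma``; organelle channels are
    their masks at fixed amplitude lightly blurred; the membrane channel is
    the cytoplasm outline. Poisson noise (photon scale
    ``noise_poisson_scale``) is applied first, then Gaussian read noise.
    """
    rng = np.random.default_rng(params.seed + 2)
    h, w = params.image_shape
    px = params.pixel_size
    sigma = params.psf_sigma / px
    half = int(np.ceil(4 * sigma))
    per_track = {t.track_id: {d.frame_index: d.centroid for d in t.detections}
                 for t in tracks.tracks}

    ring = cell.cytoplasm_mask.pixels & ~ndi.binary_erosion(
        cell.cytoplasm_mask.pixels, structure=disk(2))
    frames = np.empty((params.n_frames, 4, h, w), np.float32)
    for t in range(params.n_frames):
        puncta = np.full((h, w), _BACKGROUND)
        for tid, by_frame in per_track.items():
            if t not in by_frame:
                continue
            r0, c0 = by_frame[t]
            ri, ci = int(round(r0)), int(round(c0))
            rs = slice(max(0, ri - half), min(h, ri + half + 1))
            cs = slice(max(0, ci - half), min(w, ci + half + 1))
            rr, cc = np.mgrid[rs, cs]
            puncta[rs, cs] += _SPOT_AMPLITUDE * np.exp(
                -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma ** 2))
        er_m = (cell.er_masks[t].pixels if cell.er_masks
                else cell.er_mask.pixels)
        mito_m = (cell.mito_masks[t].pixels if cell.mito_masks
                  else cell.mito_mask.pixels)
        er_img = _BACKGROUND + _ORGANELLE_AMPLITUDE * ndi.gaussian_filter(
            er_m.astype(float), 0.8)
        mito_img = _BACKGROUND + _ORGANELLE_AMPLITUDE * ndi.gaussian_filter(
            mito_m.astype(float), 0.8)
        mem_img = _BACKGROUND + _ORGANELLE_AMPLITUDE * ring
        for c, img in enumerate((puncta, er_img, mito_img, mem_img)):
            if params.noise_poisson_scale > 0:
                img = rng.poisson(
                    img * params.noise_poisson_scale
                ) / params.noise_poisson_scale
            if params.noise_gaussian_sd > 0:
                img = img + rng.normal(0.0, params.noise_gaussian_sd,
                                       size=img.shape)
            frames[t, c] = img
    stack = ImageStack(frames, pixel_size=px)
    cell.stack = stack
    return stack


def simulate_cell(params: SyntheticCellParams) -> SyntheticCell:
    """Geometry + trajectories + rendering in one call."""
    cell = generate_cell_geometry(params)
    tracks = simulate_puncta_tracks(cell, params)
    render_timelapse(cell, tracks, params)
    return cell


# ---------------------------------------------------------------------------
# immunogold fields


def _sample_in_polygon(poly: Polygon, bounds, rng, max_tries=10000):
    minx, miny, maxx, maxy = poly.bounds
    minx, miny = max(minx, bounds[0]), max(miny, bounds[1])
    maxx, maxy = min(maxx, bounds[2]), min(maxy, bounds[3])
    for _ in range(max_tries):
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if poly.contains(p):
            return p
    raise RuntimeError("polygon sampling failed")


def generate_gold_field(params: GoldFieldParams) -> list[GoldImage]:
    """Synthetic fixed-area EM images with ground-truth association labels."""
    if params.assoc_fraction > 0 and params.mito_region_count == 0:
        raise ValueError("assoc_fraction > 0 requires mitochondrial regions")
    rng = np.random.default_rng(params.seed)
    side = float(np.sqrt(params.image_area))
    frame = box(0, 0, side, side)
    images = []
    for i in range(params.n_images):
        regions: list[Polygon] = []
        if params.mito_region_count:
            area_each = (params.mito_region_area_fraction * params.image_area
                         / params.mito_region_count)
            for _ in range(params.mito_region_count):
                for _ in range(500):
                    aspect = rng.uniform(1.5, 4.0)
                    b = np.sqrt(area_each / (np.pi * aspect))
                    a = aspect * b
                    ell = Point(rng.uniform(a, side - a),
                                rng.uniform(a, side - a)).buffer(1.0, 64)
                    ell = affinity.scale(ell, a, b)
                    ell = affinity.rotate(ell, rng.uniform(0, 180))
                    if not frame.contains(ell):
                        continue
                    gap = 2 * params.assoc_distance_um
                    if all(ell.distance(r) > gap for r in regions):
                        regions.append(ell)
                        break
        n_clusters = rng.poisson(params.cluster_density * params.image_area)
        clusters = []
        reach = [r.buffer(params.assoc_distance_um) for r in regions]
        for k in range(n_clusters):
            assoc = bool(rng.random() < params.assoc_fraction)
            if assoc:
                poly = reach[rng.integers(len(reach))]
                p = _sample_in_polygon(poly.intersection(frame),
                                       (0, 0, side, side), rng)
            else:
                for _ in range(10000):
                    p = Point(rng.uniform(0, side), rng.uniform(0, side))
                    if all(rp.distance(p) > 0 for rp in reach):
                        break
            clusters.append(GoldCluster(k, float(p.x), float(p.y),
                                        associated=assoc))
        images.append(GoldImage(f"img{i:03d}", "antibody",
                                params.image_area, clusters,
                                regions if regions else None))
    return images


# ---------------------------------------------------------------------------
# fraction profiles


def generate_fraction_profiles(
        params: FractionProfileParams,
        markers: tuple[str, str] = ("poi", "marker"),
) -> tuple[FractionProfile, FractionProfile]:
    """Two gradient profiles with population Pearson correlation target_r.

    The second profile mixes the first's latent gradient z with independent
    noise w of sd ``noise_sd``: y = a*z + w, with the mixing weight
    a = r*noise_sd/sqrt(1-r^2) solving corr(z, y) = r. With noise_sd = 0
    the latent profile is shared exactly and |r| degenerates to 1.
    """
    rng = np.random.default_rng(params.seed)
    n, r = params.n_fractions, params.target_r
    z = rng.normal(size=n)
    w = rng.normal(0.0, params.noise_sd, size=n)
    if abs(r) == 1.0 or params.noise_sd == 0:
        y = np.sign(r) * z if r != 0 else w
    else:
        a = r * params.noise_sd / np.sqrt(1.0 - r * r)
        y = a * z + w
    baseline = 10.0
    return (FractionProfile(markers[0], tuple(baseline + z)),
            FractionProfile(markers[1], tuple(baseline + y)))


# ---------------------------------------------------------------------------
# paper-scale association studies


def simulate_association_study(n_cells: int = 13,
                               mean_observed: float = 0.7082,
                               mean_randomized: float = 0.4695,
                               between_cell_sd: float = 0.20,
                               within_pair_sd: float = 0.065,
                               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (observed, randomized) fraction pairs at a prescribed effect.

    A shared per-cell random effect makes the two fractions strongly
    correlated, so the SD of the paired differences (``within_pair_sd``)
    can be far smaller than the between-cell SD, as in real per-cell
    association data. Fractions are clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    se = within_pair_sd / np.sqrt(2.0)
    su2 = between_cell_sd ** 2 - se ** 2
    if su2 < 0:
        raise ValueError("between_cell_sd must exceed within_pair_sd/sqrt(2)")
    u = rng.normal(0.0, np.sqrt(su2), n_cells)
    obs = np.clip(mean_observed + u + rng.normal(0.0, se, n_cells), 0.0, 1.0)
    rand = np.clip(mean_randomized + u + rng.normal(0.0, se, n_cells), 0.0, 1.0)
    return obs, rand
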