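"""Immunogold cluster density and mitochondria-association quantification.

Electron-microscopy images of fixed area carry point annotations for
silver-enhanced gold clusters (each cluster reduced to its centroid) and
mitochondrial outlines (polygons in µm, or a binary mask with a µm/px
scale). A cluster is "directly associated" with mitochondria when it lies
inside an outline or within ``assoc_distance`` (default 0.03 µm) of its
boundary, acknowledging that silver-enhanced gold can sit tens of
nanometers from the epitope.

Per-group quantification reports cluster density (mean ± SEM of per-image
clusters/µm²) and the pooled association fraction. When images carry
pre-annotated association flags and no outlines, the flags are used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "GoldCluster",
    "GoldImage",
    "GoldQuantResult",
    "classify_association",
    "quantify_group",
    "polygons_from_frame",
]


@dataclass(frozen=True)
class GoldCluster:
    cluster_id: int
    x_um: float
    y_um: float
    associated: bool | None = None  # annotation or ground truth; None = unknown


@dataclass
class GoldImage:
    """One fixed-area EM image with its point and region annotations."""

    image_id: str
    group: str  # e.g. "antibody" | "control"
    area_um2: float = 11.125
    clusters: list[GoldCluster] = field(default_factory=list)
    mito_regions: list[Polygon] | None = None

    def __post_init__(self):
        if self.area_um2 <= 0:
            raise ValueError("image area must be positive (µm²)")


@dataclass(frozen=True)
class GoldQuantResult:
    group: str
    n_images: int
    n_clusters: int
    density_mean: float  # clusters/µm², mean of per-image densities
    density_sem: float
    n_associated: int
    association_fraction: float | None  # None when no clusters


def classify_association(point_um: tuple[float, float],
                         mito_regions: list[Polygon] | None,
                         assoc_distance_um: float = 0.03) -> bool:
    """True iff the point lies inside a region or within ``assoc_distance_um``
    of a region boundary. Empty/absent region set -> False."""
    if not mito_regions:
        return False
    p = Point(point_um)
    return any(poly.distance(p) <= assoc_distance_um for poly in mito_regions)


def quantify_group(images: list[GoldImage],
                   assoc_distance_um: float = 0.03) -> GoldQuantResult:
    """Density and association statistics for one group of EM images.

    Association of each cluster is decided geometrically from the image's
    mitochondrial outlines when present; otherwise the cluster's annotated
    flag is used (clusters with neither contribute as unassociated).
    """
    if not images:
        raise ValueError("need at least one image")
    groups = {im.group for im in images}
    if len(groups) > 1:
        raise ValueError(f"mixed groups in one quantification: {groups}")
    densities = []
    n_clusters = 0
    n_assoc = 0
    for im in images:
        densities.append(len(im.clusters) / im.area_um2)
        n_clusters += len(im.clusters)
        for cl in im.clusters:
            if im.mito_regions is not None:
                assoc = classify_association((cl.x_um, cl.y_um),
                                             im.mito_regions, assoc_distance_um)
            else:
                assoc = bool(cl.associated)
            n_assoc += assoc
    densities = np.asarray(densities)
    n = len(images)
    sem = float(densities.std(ddof=1) / sqrt(n)) if n > 1 else 0.0
    frac = n_assoc / n_clusters if n_clusters else None
    return GoldQuantResult(group=groups.pop(), n_images=n,
                           n_clusters=n_clusters,
                           density_mean=float(densities.mean()),
                           density_sem=sem, n_associated=n_assoc,
                           association_fraction=frac)


def polygons_from_frame(df: pd.DataFrame) -> dict[str, list[Polygon]]:
    """Build per-image polygon lists from a vertex table with columns
    image_id, region_id, vertex_index, x_um, y_um."""
    out: dict[str, list[Polygon]] = {}
    for (img, _), g in df.groupby(["image_id", "region_id"], sort=True):
        g = g.sort_values("vertex_index")
        poly = Polygon(zip(g["x_um"], g["y_um"]))
        out.setdefault(str(img), []).append(poly)
    return out


def clusters_to_frame(images: list[GoldImage]) -> pd.DataFrame:
    rows = []
    for im in images:
        for cl in im.clusters:
            rows.append({"image_id": im.image_id, "group": im.group,
                         "cluster_id": cl.cluster_id, "x_um": cl.x_um,
                         "y_um": cl.y_um, "associated": cl.associated})
    return pd.DataFrame(rows, columns=["image_id", "group", "cluster_id",
                                       "x_um", "y_um", "associated"])


def images_from_frames(clusters: pd.DataFrame,
                       regions: pd.DataFrame | None = None,
                       area_um2: float = 11.125) -> list[GoldImage]:
    """Assemble GoldImage records from annotation tables (CSV layouts)."""
    polys = polygons_from_frame(regions) if regions is not None else {}
    images = []
    for (img, grp), g in clusters.groupby(["image_id", "group"], sort=True):
        cls = [GoldCluster(int(r.cluster_id), float(r.x_um), float(r.y_um),
                           None if pd.isna(r.associated) else bool(r.associated))
               for r in g.itertuples()]
        images.append(GoldImage(str(img), str(grp), area_um2, cls,
                                polys.get(str(img))))
    return images
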