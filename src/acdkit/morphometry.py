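"""Label-image morphometrics and rule-based cluster calling.

Measurements follow the field's scoring conventions for the cotyledon
epidermis: cell areas in um^2 (area is used in place of volume, epidermal
cell height being nearly uniform), "small cells" strictly below 120 um^2,
a small-cell cluster being four or more small cells in mutual contact
(4-connected pixel adjacency, i.e. a shared wall), and stomatal
clustering scored as the percentage of stomata in direct contact with
another stoma.  Spacing-division geometry is summarised by the acute
angle between the stomatal pore axis and the new division plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SMALL_CELL_THRESHOLD_UM2",
    "MIN_CLUSTER_SIZE",
    "ClusterReport",
    "StomatalClusterCount",
    "SizeAsymmetry",
    "measure_cells",
    "build_adjacency",
    "find_small_cell_clusters",
    "count_stomatal_clusters",
    "spacing_angle",
    "cumulative_angle_curve",
    "size_asymmetry",
    "nuclear_offset",
]

SMALL_CELL_THRESHOLD_UM2 = 120.0
MIN_CLUSTER_SIZE = 4


def measure_cells(label_image, pixel_size_um: float,
                  small_threshold_um2: float = SMALL_CELL_THRESHOLD_UM2,
                  types: Optional[Mapping] = None) -> pd.DataFrame:
    """Per-cell morphometrics of a label image.

    Area is pixel count times pixel_size_um**2; ``is_small`` uses a strict
    ``<`` comparison against the threshold.  ``types`` optionally maps
    cell_id to a cell-type annotation (default ``unknown``).  Cells whose
    pixels touch the image border are flagged.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    labels = np.asarray(label_image)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    px_area = pixel_size_um ** 2

    border = np.zeros_like(labels, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_ids = set(np.unique(labels[border]))

    counts = np.bincount(labels.ravel(), minlength=int(ids.max()) + 1)
    crow = ndimage.mean(np.indices(labels.shape)[0], labels=labels, index=ids)
    ccol = ndimage.mean(np.indices(labels.shape)[1], labels=labels, index=ids)

    areas = counts[ids] * px_area
    df = pd.DataFrame({
        "cell_id": ids,
        "area_um2": areas,
        "centroid_x_um": (np.asarray(ccol) + 0.5) * pixel_size_um,
        "centroid_y_um": (np.asarray(crow) + 0.5) * pixel_size_um,
        "is_small": areas < small_threshold_um2,
        "touches_border": [int(i) in border_ids for i in ids],
    })
    df["type"] = [types.get(i, "unknown") if types is not None else "unknown"
                  for i in ids]
    return df


def build_adjacency(label_image) -> nx.Graph:
    """Cell contact graph: edge (a, b) iff the labels share a 4-adjacent
    pixel pair (corner-only touching is not contact).  Background 0 is
    excluded; every nonzero label is a node even if isolated."""
    labels = np.asarray(label_image)
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in np.unique(labels) if i > 0)
    for a, b in ((labels[:, :-1], labels[:, 1:]),
                 (labels[:-1, :], labels[1:, :])):
        diff = (a != b) & (a > 0) & (b > 0)
        if diff.any():
            pairs = np.unique(np.stack([a[diff], b[diff]]), axis=1)
            g.add_edges_from((int(x), int(y)) for x, y in pairs.T)
    return g


@dataclass
class ClusterReport:
    """Small-cell clusters of one field: components of >= min size among
    small cells in contact, plus the fraction of small cells clustered."""

    clusters: List[Set[int]]
    n_small: int
    n_small_in_clusters: int
    fraction_in_clusters: float
    min_cluster_size: int = MIN_CLUSTER_SIZE


def find_small_cell_clusters(morphologies: pd.DataFrame, adjacency: nx.Graph,
                             min_cluster_size: int = MIN_CLUSTER_SIZE
                             ) -> ClusterReport:
    """Call small-cell clusters: connected components of the contact graph
    induced by small cells, keeping components of size >= min_cluster_size.

    The clustered fraction is n_small_in_clusters / n_small (0 when there
    are no small cells).  Clusters are returned sorted by smallest member
    id for deterministic output.
    """
    small_ids = set(int(i) for i in
                    morphologies.loc[morphologies["is_small"], "cell_id"])
    sub = adjacency.subgraph(small_ids)
    components = [set(c) for c in nx.connected_components(sub)]
    # isolated small cells absent from the graph still count toward n_small
    in_graph = set().union(*components) if components else set()
    components += [{i} for i in sorted(small_ids - in_graph)]
    clusters = sorted((c for c in components if len(c) >= min_cluster_size),
                      key=min)
    n_small = len(small_ids)
    n_in = sum(len(c) for c in clusters)
    frac = n_in / n_small if n_small else 0.0
    return ClusterReport(clusters=clusters, n_small=n_small,
                         n_small_in_clusters=n_in, fraction_in_clusters=frac,
                         min_cluster_size=min_cluster_size)


@dataclass
class StomatalClusterCount:
    n_stomata: int
    n_in_contact: int
    percent_clustered: Optional[float]


def count_stomatal_clusters(morphologies: pd.DataFrame,
                            adjacency: nx.Graph) -> StomatalClusterCount:
    """Percentage of stomata in direct contact with at least one other
    stoma.  Undefined (None) when the field has no stomata."""
    stomata = set(int(i) for i in
                  morphologies.loc[morphologies["type"] == "stoma", "cell_id"])
    n_in = sum(1 for s in stomata
               if s in adjacency
               and any(nb in stomata for nb in adjacency.neighbors(s)))
    n = len(stomata)
    pct = 100.0 * n_in / n if n else None
    return StomatalClusterCount(n_stomata=n, n_in_contact=n_in,
                                percent_clustered=pct)


def spacing_angle(pore_axis_deg: float, plane_axis_deg: float) -> float:
    """Acute angle between two undirected axes, in [0, 90] degrees."""
    d = abs(pore_axis_deg - plane_axis_deg) % 180.0
    return float(min(d, 180.0 - d))


def cumulative_angle_curve(alphas: Sequence[float]) -> np.ndarray:
    """Cumulative frequency of spacing angles evaluated at 0..90 degrees.

    Returns a length-91 monotone nondecreasing array ending at 1.0.
    """
    a = np.asarray(alphas, dtype=float)
    if a.size == 0:
        raise ValueError("cumulative_angle_curve requires at least one angle")
    if np.any((a < 0) | (a > 90)):
        raise ValueError("spacing angles must lie in [0, 90]")
    grid = np.arange(91)
    return (a[None, :] <= grid[:, None]).mean(axis=1)


@dataclass
class SizeAsymmetry:
    """Daughter-size asymmetry of one asymmetric division.

    ``ratio`` is meristemoid area / SLGC area, fate following the crescent
    (the crescent-bearing daughter is the SLGC).  ``reversed`` is True iff
    the crescent-bearing daughter is strictly smaller than its sister;
    None when the crescent annotation is missing (the ratio is then
    computed with the smaller daughter as the meristemoid).
    """

    division_id: object
    meristemoid_area_um2: float
    slgc_area_um2: float
    ratio: float
    reversed: Optional[bool]


def size_asymmetry(division_id, daughter_areas: Mapping,
                   crescent_daughter_id=None) -> SizeAsymmetry:
    """Size asymmetry of one division from its two daughters' areas
    (measured in the first frame after cytokinesis)."""
    items = list(daughter_areas.items())
    if len(items) != 2:
        raise ValueError("exactly two daughters required")
    (id1, a1), (id2, a2) = items
    if a1 <= 0 or a2 <= 0:
        raise ValueError("daughter areas must be positive")
    if crescent_daughter_id is None:
        mer_area, slgc_area = sorted([a1, a2])
        rev = None
    else:
        if crescent_daughter_id not in (id1, id2):
            raise ValueError("crescent_daughter_id is not one of the daughters")
        crescent_area = a1 if crescent_daughter_id == id1 else a2
        sister_area = a2 if crescent_daughter_id == id1 else a1
        slgc_area, mer_area = crescent_area, sister_area
        rev = bool(crescent_area < sister_area)
    return SizeAsymmetry(division_id=division_id,
                         meristemoid_area_um2=float(mer_area),
                         slgc_area_um2=float(slgc_area),
                         ratio=float(mer_area / slgc_area),
                         reversed=rev)


def nuclear_offset(cell, nucleus_xy) -> float:
    """Normalized pre-division nuclear offset in [0, 1).

    ``offset = |nucleus - centroid| / r_dir`` where ``r_dir`` is the
    distance from the cell centroid to the cell boundary along the
    centroid-to-nucleus ray: 0 for a centred nucleus, approaching 1 for a
    fully cortical one.  ``cell`` is either a shapely Polygon (in the same
    coordinates as ``nucleus_xy``) or a boolean mask (with ``nucleus_xy``
    in (col, row) pixel coordinates).  Raises if the nucleus lies outside
    the cell.
    """
    import shapely.geometry as sg

    nucleus = np.asarray(nucleus_xy, dtype=float)
    if isinstance(cell, sg.Polygon):
        if not cell.covers(sg.Point(nucleus)):
            raise ValueError("nucleus centroid lies outside the cell")
        centroid = np.array([cell.centroid.x, cell.centroid.y])
        disp = nucleus - centroid
        dist = float(np.hypot(*disp))
        if dist == 0.0:
            return 0.0
        direction = disp / dist
        span = 2.0 * max(cell.bounds[2] - cell.bounds[0],
                         cell.bounds[3] - cell.bounds[1])
        ray = sg.LineString([centroid, centroid + direction * span])
        hit = ray.intersection(cell.exterior)
        if hit.is_empty:
            raise ValueError("ray does not reach the cell boundary")
        pts = ([hit] if isinstance(hit, sg.Point)
               else [g for g in getattr(hit, "geoms", [hit])])
        coords = []
        for g in pts:
            coords.extend(np.asarray(g.coords))
        dists = [float(np.hypot(x - centroid[0], y - centroid[1]))
                 for x, y in coords]
        r_dir = min(d for d in dists if d > 1e-9)
        return dist / r_dir

    mask = np.asarray(cell, dtype=bool)
    col, row = float(nucleus[0]), float(nucleus[1])
    ri, ci = int(round(row)), int(round(col))
    if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]) or not mask[ri, ci]:
        raise ValueError("nucleus centroid lies outside the cell")
    crow, ccol = ndimage.center_of_mass(mask)
    disp = np.array([col - ccol, row - crow])
    dist = float(np.hypot(*disp))
    if dist == 0.0:
        return 0.0
    direction = disp / dist
    step = 0.2
    t = 0.0
    limit = 2.0 * max(mask.shape)
    r_dir = None
    while t < limit:
        t += step
        x = ccol + direction[0] * t
        y = crow + direction[1] * t
        rr, cc = int(round(y)), int(round(x))
        if not (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]) or not mask[rr, cc]:
            r_dir = t - step / 2.0
            break
    if r_dir is None:
        raise ValueError("ray never left the cell mask")
    return dist / r_dir
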