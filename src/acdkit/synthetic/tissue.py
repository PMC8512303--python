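"""Synthetic epidermis generator with known ground truth.

Emulates a segmented cotyledon epidermis: an integer label image in which
every pixel belongs to one cell, built as a power diagram (additively
weighted Voronoi tessellation) over jittered lattice seed points.  Small
cells (area below the 120 um^2 threshold) are produced by shrinking
individual lattice cells with a power weight calibrated against the
rendered image; planted small-cell clusters are produced by splitting one
lattice site into a tight ring of sub-seeds, so the members are well
below the threshold and mutually in contact.  Stomata are type
annotations chosen on the rendered contact graph: planted stomatal pairs
are adjacent normal cells, all other stomata are kept out of contact.

Ground truth (type, size class, cluster membership, stomatal pair
membership) is returned per cell and verified against the rendered image
before returning, so every planted structure is recoverable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

SMALL_CELL_THRESHOLD_UM2 = 120.0


class TissueSpecError(ValueError):
    """Raised for infeasible or inconsistent tissue parameterizations."""


@dataclass
class TissueSpec:
    """Parameters of a synthetic epidermis field.

    Lengths are in micrometres.  ``small_cell_fraction`` is the fraction
    of cells rendered as isolated small cells (strictly below 120 um^2);
    members of ``planted_clusters`` are small in addition to that
    fraction.  ``planted_clusters`` is a list of (cluster_size, count)
    with cluster_size >= 4.  ``stomata_fraction`` cells are annotated as
    stomata; ``planted_stomatal_pairs`` of them are placed in adjacent
    pairs, the rest kept out of mutual contact.
    """

    field_width_um: float = 388.0
    field_height_um: float = 388.0
    pixel_size_um: float = 1.0
    n_cells: int = 450
    small_cell_fraction: float = 0.0
    small_area_range_um2: Tuple[float, float] = (50.0, 100.0)
    normal_area_range_um2: Tuple[float, float] = (150.0, 700.0)
    planted_clusters: Sequence[Tuple[int, int]] = field(default_factory=list)
    stomata_fraction: float = 0.0
    planted_stomatal_pairs: int = 0
    seed: int = 0

    def __post_init__(self):
        if min(self.field_width_um, self.field_height_um, self.pixel_size_um) <= 0:
            raise TissueSpecError("field dimensions and pixel size must be positive")
        if self.n_cells < 4:
            raise TissueSpecError("n_cells must be at least 4")
        if not 0.0 <= self.small_cell_fraction <= 1.0:
            raise TissueSpecError("small_cell_fraction must be in [0, 1]")
        if not 0.0 <= self.stomata_fraction <= 1.0:
            raise TissueSpecError("stomata_fraction must be in [0, 1]")
        if self.small_cell_fraction + self.stomata_fraction > 1.0:
            raise TissueSpecError("small_cell_fraction + stomata_fraction must be <= 1")
        lo, hi = self.small_area_range_um2
        if not (0 < lo <= hi < SMALL_CELL_THRESHOLD_UM2):
            raise TissueSpecError(
                "small_area_range_um2 must lie strictly below "
                f"{SMALL_CELL_THRESHOLD_UM2} um^2")
        nlo, nhi = self.normal_area_range_um2
        if not (SMALL_CELL_THRESHOLD_UM2 <= nlo <= nhi):
            raise TissueSpecError(
                "normal_area_range_um2 must lie at or above "
                f"{SMALL_CELL_THRESHOLD_UM2} um^2")
        for k, c in self.planted_clusters:
            if k < 4:
                raise TissueSpecError("planted cluster size must be >= 4")
            if c < 0:
                raise TissueSpecError("planted cluster count must be >= 0")
        if self.planted_stomatal_pairs < 0:
            raise TissueSpecError("planted_stomatal_pairs must be >= 0")


def _grid_dims(n_sites: int, width: float, height: float) -> Tuple[int, int]:
    nx = max(2, int(round(np.sqrt(n_sites * width / height))))
    ny = max(2, int(np.ceil(n_sites / nx)))
    while nx * ny < n_sites:
        ny += 1
    return nx, ny


def _adjacent_label_pairs(labels):
    """Set of 4-adjacent label pairs (a < b) in a label image."""
    pairs = set()
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        diff = a != b
        u = np.unique(np.stack([a[diff], b[diff]]), axis=1)
        for x, y in u.T:
            pairs.add((int(min(x, y)), int(max(x, y))))
    return pairs


def generate_epidermis(spec: TissueSpec):
    """Render a synthetic epidermis field.

    Returns ``(label_image, cell_table)``.  ``label_image`` is an int32
    array in which every pixel carries a cell label >= 1.  ``cell_table``
    has one row per cell with columns ``cell_id, type, area_um2,
    centroid_x_um, centroid_y_um, is_small, cluster_id, stomatal_pair_id``
    (``cluster_id``/``stomatal_pair_id`` are 0 outside planted
    structures).  Deterministic for a fixed spec and seed.
    """
    rng = np.random.default_rng(spec.seed)

    n_clusters = sum(c for _, c in spec.planted_clusters)
    n_scatter = int(round(spec.small_cell_fraction * spec.n_cells))
    n_stoma = max(int(round(spec.stomata_fraction * spec.n_cells)),
                  2 * spec.planted_stomatal_pairs)

    extra = sum((k - 1) * c for k, c in spec.planted_clusters)
    n_sites = spec.n_cells - extra
    if n_sites < n_clusters + n_scatter + n_stoma + 4:
        raise TissueSpecError(
            "requested clusters/small cells/stomata exceed available cells")

    nx, ny = _grid_dims(n_sites, spec.field_width_um, spec.field_height_um)
    sx = spec.field_width_um / nx
    sy = spec.field_height_um / ny
    site_area = sx * sy
    if site_area < 160.0:
        raise TissueSpecError(
            f"mean cell area {site_area:.0f} um^2 too small to guarantee "
            "normal cells above the 120 um^2 threshold; reduce n_cells")
    for k, c in spec.planted_clusters:
        if c > 0 and site_area / k > 110.0:
            raise TissueSpecError(
                f"cluster of {k} sub-cells in a {site_area:.0f} um^2 site "
                "would exceed the small-cell threshold; increase n_cells")

    n_slots = nx * ny
    order = rng.permutation(n_slots)
    taken = np.zeros(n_slots, dtype=bool)

    # small-cell structures need geometric isolation: placing them on the
    # even-index subgrid guarantees lattice Chebyshev distance >= 2 between
    # any two of them (the rare jitter-induced contact through a dropped
    # site is repaired after rendering)
    even_sites = [s for s in order
                  if (s % nx) % 2 == 0 and (s // nx) % 2 == 0]
    if n_clusters + n_scatter > len(even_sites):
        raise TissueSpecError(
            "field too crowded to isolate the requested small-cell structures")
    cluster_sites = even_sites[:n_clusters]
    scatter_sites = even_sites[n_clusters:n_clusters + n_scatter]
    taken[cluster_sites] = True
    taken[scatter_sites] = True

    # drop surplus plain sites (keeps the exact requested cell count); never
    # next to a planted cluster, whose ring geometry must stay intact
    surplus = n_slots - n_sites
    dropped = np.zeros(n_slots, dtype=bool)
    if surplus > 0:
        protected = set()
        for s in cluster_sites:
            ax, ay = s % nx, s // nx
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    bx, by = ax + dx, ay + dy
                    if 0 <= bx < nx and 0 <= by < ny:
                        protected.add(by * nx + bx)
        n_dropped = 0
        for s in order[::-1]:
            if n_dropped == surplus:
                break
            if taken[s] or dropped[s] or s in protected:
                continue
            dropped[s] = True
            n_dropped += 1
        if n_dropped < surplus:
            raise TissueSpecError("could not reconcile n_cells with lattice size")

    cluster_site_map = {}
    ci = 0
    for k, c in spec.planted_clusters:
        for _ in range(c):
            cluster_site_map[cluster_sites[ci]] = (ci + 1, k)
            ci += 1
    scatter_set = set(scatter_sites)

    jitter = 0.15
    s_min = min(sx, sy)
    L = np.sqrt(site_area)
    lo, hi = spec.small_area_range_um2

    seeds_xy: List[Tuple[float, float]] = []
    weights: List[float] = []
    targets: List[float] = []        # per-seed target area; nan = uncontrolled
    groups: List[int] = []           # weight-control group; -1 = uncontrolled
    cluster_ids: List[int] = []
    small_truth: List[bool] = []
    next_group = 0
    for s in range(n_slots):
        if dropped[s]:
            continue
        gx, gy = s % nx, s // nx
        cx = (gx + 0.5) * sx + rng.uniform(-jitter, jitter) * sx
        cy = (gy + 0.5) * sy + rng.uniform(-jitter, jitter) * sy
        if s in cluster_site_map:
            cid, k = cluster_site_map[s]
            phase = rng.uniform(0, 2 * np.pi)
            r = 0.20 * s_min
            t_c = float(np.clip(0.8 * site_area / k, lo, 0.95 * hi))
            # all sub-seeds of one cluster share a single control weight:
            # per-cell weights are unstable at ring-scale mutual distances
            for j in range(k):
                ang = phase + 2 * np.pi * j / k
                seeds_xy.append((cx + r * np.cos(ang), cy + r * np.sin(ang)))
                weights.append(0.0)
                targets.append(t_c)
                groups.append(next_group)
                cluster_ids.append(cid)
                small_truth.append(True)
            next_group += 1
        elif s in scatter_set:
            target = float(rng.uniform(lo, hi))
            seeds_xy.append((cx, cy))
            weights.append(L * (L - np.sqrt(target)))
            targets.append(target)
            groups.append(next_group)
            next_group += 1
            cluster_ids.append(0)
            small_truth.append(True)
        else:
            seeds_xy.append((cx, cy))
            weights.append(0.0)
            targets.append(np.nan)
            groups.append(-1)
            cluster_ids.append(0)
            small_truth.append(False)

    seeds_xy = np.asarray(seeds_xy)
    weights = np.asarray(weights, dtype=float)
    targets = np.asarray(targets)
    groups = np.asarray(groups)
    cluster_ids = np.asarray(cluster_ids)
    small_truth = np.asarray(small_truth)
    n_seeds = len(seeds_xy)
    assert n_seeds == spec.n_cells

    w_px = max(2, int(round(spec.field_width_um / spec.pixel_size_um)))
    h_px = max(2, int(round(spec.field_height_um / spec.pixel_size_um)))
    xs = (np.arange(w_px) + 0.5) * spec.pixel_size_um
    ys = (np.arange(h_px) + 0.5) * spec.pixel_size_um
    gxx, gyy = np.meshgrid(xs, ys)
    pix = np.column_stack([gxx.ravel(), gyy.ravel()])

    tree = cKDTree(seeds_xy)
    k_query = min(n_seeds, 16)
    dist, idx = tree.query(pix, k=k_query)
    if k_query == 1:
        dist, idx = dist[:, None], idx[:, None]
    dist2 = dist ** 2
    px_area = spec.pixel_size_um ** 2
    rowidx = np.arange(len(pix))

    group_members = {g: np.nonzero(groups == g)[0]
                     for g in np.unique(groups) if g >= 0}

    def render():
        """Relabel, calibrating controlled cell areas to their targets.

        One shared weight per control group (a scatter small cell, or all
        sub-seeds of one planted cluster together); the update also pushes
        the group's worst member safely below the small-cell threshold.
        """
        controlled = ~np.isnan(targets)
        winner = counts = None
        for _ in range(25):
            power = dist2 + weights[idx]
            winner = idx[rowidx, np.argmin(power, axis=1)]
            counts = np.bincount(winner, minlength=n_seeds)
            areas_now = counts * px_area
            small_ok = np.all(areas_now[controlled]
                              <= 0.96 * SMALL_CELL_THRESHOLD_UM2)
            normal_ok = np.all(areas_now[~controlled]
                               >= 1.04 * SMALL_CELL_THRESHOLD_UM2)
            if small_ok and normal_ok and np.all(counts > 0):
                break
            for g, members in group_members.items():
                err = float(np.mean(areas_now[members] - targets[members]))
                worst = float(np.max(areas_now[members])
                              - 0.9 * SMALL_CELL_THRESHOLD_UM2)
                err = max(err, worst)
                weights[members] = max(weights[members][0] + 0.8 * err, 0.0)
        return winner.reshape(h_px, w_px) + 1, counts * px_area

    labels, areas = render()

    # repair rare jitter-induced contacts between unrelated small cells by
    # demoting the offending isolated small cell back to a normal cell
    for _ in range(3):
        contacts = sorted(_adjacent_label_pairs(labels))
        bad = []
        for a, b in contacts:
            ia, ib = a - 1, b - 1
            if small_truth[ia] and small_truth[ib] and cluster_ids[ia] != cluster_ids[ib]:
                bad.append((ia, ib))
        if not bad:
            break
        for ia, ib in bad:
            victim = ia if cluster_ids[ia] == 0 else ib
            if cluster_ids[victim] != 0:
                raise RuntimeError("synthetic tissue: planted clusters collided")
            small_truth[victim] = False
            targets[victim] = np.nan
            weights[victim] = 0.0
        labels, areas = render()
    else:
        raise RuntimeError("synthetic tissue: small-cell isolation unrepairable")

    # stomata are annotations on normal cells, chosen on the rendered
    # contact graph so planted pairs touch and all other stomata do not
    contacts = sorted(_adjacent_label_pairs(labels))
    neighbours = {i: set() for i in range(1, n_seeds + 1)}
    for a, b in contacts:
        neighbours[a].add(b)
        neighbours[b].add(a)
    normal_ids = [i + 1 for i in range(n_seeds) if not small_truth[i]]
    stoma_pair_id = np.zeros(n_seeds, dtype=int)
    is_stoma = np.zeros(n_seeds, dtype=bool)

    def stoma_free(cid):
        return not is_stoma[cid - 1] and not any(
            is_stoma[nb - 1] for nb in neighbours[cid])

    pair_edges = [(a, b) for a, b in contacts
                  if not small_truth[a - 1] and not small_truth[b - 1]]
    rng.shuffle(pair_edges)
    placed_pairs = 0
    for a, b in pair_edges:
        if placed_pairs == spec.planted_stomatal_pairs:
            break
        if stoma_free(a) and stoma_free(b):
            placed_pairs += 1
            is_stoma[a - 1] = is_stoma[b - 1] = True
            stoma_pair_id[a - 1] = stoma_pair_id[b - 1] = placed_pairs
    if placed_pairs < spec.planted_stomatal_pairs:
        raise TissueSpecError("field too crowded to place planted stomatal pairs")
    iso_order = rng.permutation(normal_ids)
    n_iso = n_stoma - 2 * spec.planted_stomatal_pairs
    placed_iso = 0
    for cid in iso_order:
        if placed_iso == n_iso:
            break
        if stoma_free(cid):
            is_stoma[cid - 1] = True
            placed_iso += 1
    if placed_iso < n_iso:
        raise TissueSpecError("field too crowded to place isolated stomata")

    types = np.where(is_stoma, "stoma",
                     np.where(small_truth, "meristemoid", "pavement"))
    cell_table = pd.DataFrame({
        "cell_id": np.arange(1, n_seeds + 1),
        "type": types,
        "area_um2": areas,
        "centroid_x_um": seeds_xy[:, 0],
        "centroid_y_um": seeds_xy[:, 1],
        "is_small": small_truth,
        "cluster_id": cluster_ids,
        "stomatal_pair_id": stoma_pair_id,
    })

    _verify_ground_truth(labels, cell_table)
    return labels, cell_table


def _verify_ground_truth(labels, cell_table):
    """Assert the rendered image honours the planted size/contact contract."""
    small = cell_table["is_small"].to_numpy()
    areas = cell_table["area_um2"].to_numpy()
    if np.any(areas[small] >= SMALL_CELL_THRESHOLD_UM2):
        raise RuntimeError("synthetic tissue: a planted small cell rendered >= 120 um^2")
    if np.any(areas[~small] < SMALL_CELL_THRESHOLD_UM2):
        raise RuntimeError("synthetic tissue: a normal cell rendered < 120 um^2")
    if np.any(areas <= 0):
        raise RuntimeError("synthetic tissue: a seed rendered with zero area")

    pairs = _adjacent_label_pairs(labels)
    ids = cell_table["cell_id"].to_numpy()
    cluster_of = dict(zip(ids, cell_table["cluster_id"]))
    small_of = dict(zip(ids, small))
    for a, b in pairs:
        if small_of[a] and small_of[b] and cluster_of[a] != cluster_of[b]:
            raise RuntimeError("synthetic tissue: unrelated small cells in contact")
    # each planted cluster connected under 4-adjacency
    for cid in sorted(set(cell_table["cluster_id"]) - {0}):
        members = set(ids[cell_table["cluster_id"] == cid])
        seen = {min(members)}
        frontier = [min(members)]
        while frontier:
            cur = frontier.pop()
            for a, b in pairs:
                other = b if a == cur else (a if b == cur else None)
                if other in members and other not in seen:
                    seen.add(other)
                    frontier.append(other)
        if seen != members:
            raise RuntimeError("synthetic tissue: planted cluster not connected")
    # planted stomatal pairs adjacent; other stomata isolated from stomata
    stoma = set(ids[cell_table["type"] == "stoma"])
    pair_of = dict(zip(ids, cell_table["stomatal_pair_id"]))
    stoma_contacts = {s: 0 for s in stoma}
    for a, b in pairs:
        if a in stoma and b in stoma:
            if pair_of[a] != pair_of[b] or pair_of[a] == 0:
                raise RuntimeError("synthetic tissue: unplanned stomatal contact")
            stoma_contacts[a] += 1
            stoma_contacts[b] += 1
    for s in stoma:
        if pair_of[s] > 0 and stoma_contacts[s] == 0:
            raise RuntimeError("synthetic tissue: planted stomatal pair not in contact")
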