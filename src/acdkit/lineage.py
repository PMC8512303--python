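"""Lineage traces of stomatal-lineage cells and division classification.

A lineage trace is a forest: cells are nodes, divisions are internal
events linking a mother to exactly two daughters.  Divisions are
classified by the mother's history: an *entry* division initiates a
lineage (mother has no recorded parent division); subsequent asymmetric
divisions are *amplifying* when the mother was born as the smaller sister
(a meristemoid) and *spacing* when she was the larger sister (an SLGC);
divisions of GMC-fated mothers are the symmetric guard-cell divisions.
Ties in sister size are resolved by the crescent annotation (the
crescent-bearing daughter takes the SLGC identity), else the class is
``ambiguous``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "LineageTable",
    "LineageError",
    "ClusterOrigin",
    "classify_divisions",
    "cell_cycle_lengths",
    "classify_cluster_origin",
    "pair_outcomes",
]

CELL_COLUMNS = ["cell_id", "parent_division_id", "birth_time_min",
                "end_time_min", "fate", "birth_area_um2"]
DIVISION_COLUMNS = ["division_id", "mother_id", "daughter1_id", "daughter2_id",
                    "time_min", "plane_axis_deg", "crescent_daughter_id"]


class LineageError(ValueError):
    pass


@dataclass
class LineageTable:
    """Cells and divisions of one tracked field.

    ``cells``: cell_id, parent_division_id (NaN for founders),
    birth_time_min, end_time_min, fate, birth_area_um2.
    ``divisions``: division_id, mother_id, daughter1_id, daughter2_id,
    time_min, plane_axis_deg (optional), crescent_daughter_id (optional).
    """

    cells: pd.DataFrame
    divisions: pd.DataFrame

    def __post_init__(self):
        cells = self.cells.copy()
        divs = self.divisions.copy()
        for col in CELL_COLUMNS:
            if col not in cells.columns:
                if col in ("birth_area_um2",):
                    cells[col] = np.nan
                else:
                    raise LineageError(f"cells table missing column {col!r}")
        for col in DIVISION_COLUMNS:
            if col not in divs.columns:
                if col in ("plane_axis_deg", "crescent_daughter_id"):
                    divs[col] = np.nan
                else:
                    raise LineageError(f"divisions table missing column {col!r}")
        if cells["cell_id"].duplicated().any():
            raise LineageError("duplicate cell_id")
        if divs["division_id"].duplicated().any():
            raise LineageError("duplicate division_id")
        daughters = pd.concat([divs["daughter1_id"], divs["daughter2_id"]])
        if daughters.duplicated().any():
            raise LineageError("a cell appears as daughter of two divisions")
        known = set(cells["cell_id"])
        for col in ("mother_id", "daughter1_id", "daughter2_id"):
            missing = set(divs[col]) - known
            if missing:
                raise LineageError(f"{col} references unknown cells {sorted(missing)[:5]}")
        # daughters are born at the division time; divisions never precede
        # their mother's birth (this also rules out cycles in the forest)
        div_time = dict(zip(divs["division_id"], divs["time_min"]))
        birth = dict(zip(cells["cell_id"], cells["birth_time_min"]))
        for _, d in divs.iterrows():
            for daughter in (d["daughter1_id"], d["daughter2_id"]):
                if not np.isclose(birth[daughter], d["time_min"]):
                    raise LineageError(
                        f"daughter {daughter!r} birth time does not match "
                        f"division {d['division_id']!r} time")
            if d["time_min"] < birth[d["mother_id"]]:
                raise LineageError(
                    f"division {d['division_id']!r} precedes mother's birth")
        parent_by_daughter = {}
        for _, d in divs.iterrows():
            parent_by_daughter[d["daughter1_id"]] = d["division_id"]
            parent_by_daughter[d["daughter2_id"]] = d["division_id"]
        declared = dict(zip(cells["cell_id"], cells["parent_division_id"]))
        for cid, pdiv in declared.items():
            actual = parent_by_daughter.get(cid)
            if pd.isna(pdiv):
                if actual is not None:
                    raise LineageError(f"cell {cid!r} has undeclared parent division")
            elif actual != pdiv:
                raise LineageError(f"cell {cid!r} parent division mismatch")
        self.cells = cells
        self.divisions = divs
        self._parent_div = {cid: (None if pd.isna(p) else p)
                            for cid, p in declared.items()}
        self._div_by_id = {d["division_id"]: d for _, d in divs.iterrows()}
        self._divs_by_mother = {}
        for _, d in divs.iterrows():
            self._divs_by_mother.setdefault(d["mother_id"], []).append(d)

    # -- accessors ---------------------------------------------------------
    def parent_division(self, cell_id):
        """Division record that produced ``cell_id``, or None for founders."""
        div_id = self._parent_div.get(cell_id)
        if div_id is None:
            return None
        return self._div_by_id[div_id]

    def sister(self, cell_id):
        d = self.parent_division(cell_id)
        if d is None:
            return None
        return d["daughter2_id"] if d["daughter1_id"] == cell_id else d["daughter1_id"]

    def divisions_of(self, cell_id):
        """Divisions in which ``cell_id`` is the mother."""
        return self._divs_by_mother.get(cell_id, [])

    def ancestor_divisions(self, cell_id):
        """Chain of (division_id, daughter_on_path) from ``cell_id`` up to its root."""
        chain = []
        cur = cell_id
        while True:
            d = self.parent_division(cur)
            if d is None:
                return chain
            chain.append((d["division_id"], cur))
            cur = d["mother_id"]

    # -- serialisation -----------------------------------------------------
    def to_csv(self, cells_path, divisions_path):
        self.cells.to_csv(cells_path, index=False)
        self.divisions.to_csv(divisions_path, index=False)

    @classmethod
    def from_csv(cls, cells_path, divisions_path):
        return cls(cells=pd.read_csv(cells_path),
                   divisions=pd.read_csv(divisions_path))

    def to_json(self, path):
        doc = {"cells": self.cells.to_dict(orient="records"),
               "divisions": self.divisions.to_dict(orient="records")}
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True,
                                         default=_json_default))

    @classmethod
    def from_json(cls, path):
        doc = json.loads(Path(path).read_text())
        return cls(cells=pd.DataFrame(doc["cells"]),
                   divisions=pd.DataFrame(doc["divisions"]))


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


def _areas_from(table: LineageTable, morphologies) -> Mapping:
    if morphologies is None:
        return dict(zip(table.cells["cell_id"], table.cells["birth_area_um2"]))
    if isinstance(morphologies, pd.DataFrame):
        col = "birth_area_um2" if "birth_area_um2" in morphologies else "area_um2"
        return dict(zip(morphologies["cell_id"], morphologies[col]))
    return dict(morphologies)


def classify_divisions(table: LineageTable, morphologies=None) -> pd.DataFrame:
    """Classify every division as entry/amplifying/spacing/gmc_symmetric/ambiguous.

    ``morphologies`` maps cell_id to area in the first frame after the
    cell's birth; by default the ``birth_area_um2`` column of the cells
    table is used.  Mothers whose own birth sizes are unavailable (and
    untied sizes unresolvable by the crescent annotation) yield
    ``ambiguous`` with a warning.
    """
    areas = _areas_from(table, morphologies)
    fate = dict(zip(table.cells["cell_id"], table.cells["fate"]))
    rows = []
    for _, d in table.divisions.iterrows():
        mother = d["mother_id"]
        if str(fate.get(mother, "")).upper() == "GMC":
            cls = "gmc_symmetric"
        else:
            parent = table.parent_division(mother)
            if parent is None:
                cls = "entry"
            else:
                sister = table.sister(mother)
                a_m = areas.get(mother, np.nan)
                a_s = areas.get(sister, np.nan)
                if np.isnan(a_m) or np.isnan(a_s):
                    warnings.warn(
                        f"division {d['division_id']!r}: missing birth area for "
                        "mother or sister; classified ambiguous")
                    cls = "ambiguous"
                elif a_m < a_s:
                    cls = "amplifying"
                elif a_m > a_s:
                    cls = "spacing"
                else:
                    crescent = parent.get("crescent_daughter_id", np.nan)
                    if pd.isna(crescent):
                        cls = "ambiguous"
                    elif crescent == mother:
                        cls = "spacing"       # crescent-bearing sister is the SLGC
                    else:
                        cls = "amplifying"
        rows.append({"division_id": d["division_id"], "division_class": cls})
    return pd.DataFrame(rows)


def cell_cycle_lengths(table: LineageTable, classes: Optional[pd.DataFrame] = None):
    """Cell-cycle length (birth to own division, minutes) per dividing cell.

    Returns ``(lengths, n_censored)``: one row per observed division with
    the mother's cycle length and the division's class; cells that never
    divide within the window are excluded from the table and counted as
    right-censored.
    """
    if classes is None:
        classes = classify_divisions(table)
    cls_of = dict(zip(classes["division_id"], classes["division_class"]))
    birth = dict(zip(table.cells["cell_id"], table.cells["birth_time_min"]))
    rows = []
    for _, d in table.divisions.iterrows():
        length = d["time_min"] - birth[d["mother_id"]]
        if length < 0:
            raise LineageError(
                f"negative cycle length for division {d['division_id']!r}")
        rows.append({"cell_id": d["mother_id"], "division_id": d["division_id"],
                     "division_class": cls_of[d["division_id"]],
                     "cycle_min": float(length)})
    mothers = set(table.divisions["mother_id"])
    n_censored = int((~table.cells["cell_id"].isin(mothers)).sum())
    return pd.DataFrame(rows, columns=["cell_id", "division_id",
                                       "division_class", "cycle_min"]), n_censored


@dataclass
class ClusterOrigin:
    """Developmental origin of one stomatal cluster."""

    origin: str  # 'fate_error' | 'spacing_error' | 'unresolvable'
    evidence: Optional[object] = None  # division_id supporting the call


def classify_cluster_origin(cluster_cell_ids: Iterable, table: LineageTable,
                            adjacency=None,
                            classes: Optional[pd.DataFrame] = None) -> ClusterOrigin:
    """Classify a stomatal cluster as a fate error or a spacing error.

    *Fate error*: two clustered stomata descend from the two sisters of a
    single division, each sister becoming a stoma directly (at most one
    intervening symmetric GMC division).  *Spacing error*: otherwise, a
    spacing division occurs in the history of a clustered stoma (the
    misplaced division that created the adjacency).  Stomata missing from
    the trace, or histories fitting neither rule, are ``unresolvable``.
    """
    ids = list(cluster_cell_ids)
    known = set(table.cells["cell_id"])
    if any(c not in known for c in ids):
        return ClusterOrigin(origin="unresolvable")
    if classes is None:
        classes = classify_divisions(table)
    cls_of = dict(zip(classes["division_id"], classes["division_class"]))

    chains = {c: table.ancestor_divisions(c) for c in ids}

    def steps_to(div_id, cell):
        """Divisions on the path strictly between ``div_id``'s daughter and ``cell``."""
        chain = chains[cell]
        for i, (d, _daughter) in enumerate(chain):
            if d == div_id:
                return [d2 for d2, _ in chain[:i]]
        return None

    for i, c1 in enumerate(ids):
        anc1 = {d for d, _ in chains[c1]}
        for c2 in ids[i + 1:]:
            common = [d for d, _ in chains[c2] if d in anc1]
            if not common:
                continue
            mrca = common[0]
            d1 = dict(chains[c1])[mrca]
            d2 = dict(chains[c2])[mrca]
            if d1 == d2:
                continue  # same daughter branch: not a sister pair
            ok = True
            for cell in (c1, c2):
                between = steps_to(mrca, cell)
                if len(between) > 1 or any(
                        cls_of.get(d) != "gmc_symmetric" for d in between):
                    ok = False
            if ok:
                return ClusterOrigin(origin="fate_error", evidence=mrca)

    for c in ids:
        for d, _ in chains[c]:
            if cls_of.get(d) == "spacing":
                return ClusterOrigin(origin="spacing_error", evidence=d)
    return ClusterOrigin(origin="unresolvable")


def pair_outcomes(table: LineageTable, classes: Optional[pd.DataFrame] = None,
                  lost_fate: str = "lost",
                  division_classes=("entry", "amplifying", "spacing")):
    """Sister-pair division outcomes for every tracked asymmetric division.

    For each asymmetric division (class entry, amplifying or spacing) the
    smaller daughter is the meristemoid and the larger the SLGC (ties
    resolved by the crescent annotation, which marks the SLGC).  ``amp``
    records whether the meristemoid underwent a subsequent asymmetric
    division within the window (a symmetric GMC division does not count);
    ``spa`` whether the SLGC divided.  Pairs with a daughter that left the
    field (fate equal to ``lost_fate``) are excluded and counted.

    Returns ``(pairs, n_excluded)``; ``pairs`` also carries ``slgc_fate``
    so callers can compute denominators that exclude SLGCs that
    differentiated into pavement cells.
    """
    if classes is None:
        classes = classify_divisions(table)
    cls_of = dict(zip(classes["division_id"], classes["division_class"]))
    areas = _areas_from(table, None)
    fate = dict(zip(table.cells["cell_id"], table.cells["fate"]))

    rows = []
    n_excluded = 0
    for _, d in table.divisions.iterrows():
        if cls_of[d["division_id"]] not in division_classes:
            continue
        d1, d2 = d["daughter1_id"], d["daughter2_id"]
        a1, a2 = areas.get(d1, np.nan), areas.get(d2, np.nan)
        crescent = d.get("crescent_daughter_id", np.nan)
        if not np.isnan(a1) and not np.isnan(a2) and a1 != a2:
            meristemoid, slgc = (d1, d2) if a1 < a2 else (d2, d1)
        elif not pd.isna(crescent):
            slgc = crescent
            meristemoid = d2 if crescent == d1 else d1
        else:
            continue  # cannot orient the pair
        if fate.get(meristemoid) == lost_fate or fate.get(slgc) == lost_fate:
            n_excluded += 1
            continue
        amp = any(cls_of[dd["division_id"]] != "gmc_symmetric"
                  for dd in table.divisions_of(meristemoid))
        spa = len(table.divisions_of(slgc)) > 0
        rows.append({"pair_id": d["division_id"], "amp": bool(amp),
                     "spa": bool(spa), "slgc_fate": fate.get(slgc)})
    return pd.DataFrame(rows, columns=["pair_id", "amp", "spa",
                                       "slgc_fate"]), n_excluded
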