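"""Synthetic 48-h lineage traces with known division classes.

Each founder protodermal cell undergoes an entry division producing a
smaller meristemoid and a larger SLGC (which carries the polarity
crescent).  Whether the meristemoid then amplifies and/or the SLGC
performs a spacing division is drawn from the coupled 2x2 distribution of
:mod:`acdkit.synthetic.pairs`, so an odds ratio of 1 builds lineages in
which the two sister behaviours are exactly independent.  Meristemoids
that do not amplify may transition to GMC and divide symmetrically.
Smaller daughters cycle faster than larger ones by a configurable factor
(the stomatal lineage's inverted size/cycle relationship).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from ..lineage import LineageTable
from .pairs import joint_table_from_or


class LineageSimSpecError(ValueError):
    pass


@dataclass
class LineageSimSpec:
    n_founders: int = 100
    window_min: float = 2880.0          # 48 h observation window
    entry_time_range: Tuple[float, float] = (60.0, 600.0)
    slgc_cycle_min: float = 900.0       # spacing-division cycle scale
    cycle_ratio: float = 0.7            # meristemoid cycle / SLGC cycle
    cycle_sd_frac: float = 0.08         # lognormal sigma of cycle lengths
    p_amp: float = 0.5
    p_spa: float = 0.3
    coupling_or: float = 1.0
    p_gmc: float = 0.6                  # non-amplifying meristemoid -> GMC
    daughter_ratio: float = 0.5         # meristemoid/SLGC birth area
    founder_area_um2: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 1:
            raise LineageSimSpecError("n_founders must be >= 1")
        if not 0 < self.cycle_ratio <= 1:
            raise LineageSimSpecError("cycle_ratio must be in (0, 1]")
        if not 0 < self.daughter_ratio < 1:
            raise LineageSimSpecError("daughter_ratio must be in (0, 1)")
        joint_table_from_or(self.p_amp, self.p_spa, self.coupling_or)
        t_lo, t_hi = self.entry_time_range
        if not 0 <= t_lo <= t_hi:
            raise LineageSimSpecError("invalid entry_time_range")
        if t_hi + 2.0 * self.slgc_cycle_min > self.window_min:
            raise LineageSimSpecError(
                "window too short: second-round divisions could be censored")


@dataclass
class LineageTruth:
    """Ground truth accompanying a generated lineage forest."""

    divisions: pd.DataFrame   # division_id, class_truth
    pairs: pd.DataFrame       # founder entry pairs: division_id, amp, spa


def generate_lineage(spec: LineageSimSpec):
    """Build a lineage forest with ground-truth division classes.

    Returns ``(table, truth)``.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    cells = []
    divisions = []
    truth_divs = []
    truth_pairs = []
    W = spec.window_min

    def lognorm(scale):
        return float(scale * rng.lognormal(0.0, spec.cycle_sd_frac))

    next_cell = 1
    next_div = 1

    def add_cell(parent_div, birth, fate, area):
        nonlocal next_cell
        cid = next_cell
        next_cell += 1
        cells.append({"cell_id": cid, "parent_division_id": parent_div,
                      "birth_time_min": birth, "end_time_min": W,
                      "fate": fate, "birth_area_um2": area})
        return cid

    def add_division(mother, t, areas, crescent_idx, cls, fates):
        nonlocal next_div
        did = next_div
        next_div += 1
        d_ids = [add_cell(did, t, fates[i], areas[i]) for i in range(2)]
        divisions.append({"division_id": did, "mother_id": mother,
                          "daughter1_id": d_ids[0], "daughter2_id": d_ids[1],
                          "time_min": t,
                          "plane_axis_deg": float(rng.uniform(0, 180)),
                          "crescent_daughter_id": (d_ids[crescent_idx]
                                                   if crescent_idx is not None
                                                   else np.nan)})
        truth_divs.append({"division_id": did, "class_truth": cls})
        return did, d_ids

    p11, p10, p01, p00 = joint_table_from_or(spec.p_amp, spec.p_spa,
                                             spec.coupling_or)
    for _ in range(spec.n_founders):
        founder = add_cell(np.nan, 0.0, "protodermal", spec.founder_area_um2)
        t_entry = float(rng.uniform(*spec.entry_time_range))
        a_slgc = float(rng.uniform(0.8, 1.2)) * spec.founder_area_um2
        a_mer = spec.daughter_ratio * a_slgc
        # daughter order randomised so classification cannot rely on it
        if rng.random() < 0.5:
            areas, crescent_idx = (a_mer, a_slgc), 1
            fates, mer_pos, slgc_pos = ["meristemoid", "SLGC"], 0, 1
        else:
            areas, crescent_idx = (a_slgc, a_mer), 0
            fates, mer_pos, slgc_pos = ["SLGC", "meristemoid"], 1, 0
        entry_id, d_ids = add_division(founder, t_entry, areas, crescent_idx,
                                       "entry", fates)
        mer, slgc = d_ids[mer_pos], d_ids[slgc_pos]

        cat = int(rng.choice(4, p=[p11, p10, p01, p00]))
        amp, spa = cat <= 1, cat in (0, 2)

        if amp:
            t_amp = t_entry + lognorm(spec.cycle_ratio * spec.slgc_cycle_min)
            larger = 0.9 * a_mer
            smaller = spec.daughter_ratio * larger
            add_division(mer, t_amp, (smaller, larger), 1, "amplifying",
                         ["meristemoid", "SLGC"])
        elif rng.random() < spec.p_gmc:
            # meristemoid matures into a GMC and divides symmetrically
            cells[mer - 1]["fate"] = "GMC"
            t_gmc = t_entry + lognorm(1.1 * spec.cycle_ratio * spec.slgc_cycle_min)
            half = 0.5 * a_mer
            add_division(mer, t_gmc, (half, half), None, "gmc_symmetric",
                         ["guard", "guard"])
        if spa:
            t_spa = t_entry + lognorm(spec.slgc_cycle_min)
            larger = 0.9 * a_slgc
            smaller = spec.daughter_ratio * larger
            add_division(slgc, t_spa, (smaller, larger), 1, "spacing",
                         ["meristemoid", "SLGC"])
        else:
            cells[slgc - 1]["fate"] = "pavement"
        truth_pairs.append({"division_id": entry_id, "amp": bool(amp),
                            "spa": bool(spa)})

    table = LineageTable(cells=pd.DataFrame(cells),
                         divisions=pd.DataFrame(divisions))
    truth = LineageTruth(divisions=pd.DataFrame(truth_divs),
                         pairs=pd.DataFrame(truth_pairs))
    return table, truth
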