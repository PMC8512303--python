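"""Synthetic spacing-division geometries.

Each record emulates one measured SLGC spacing division: the stomatal pore
axis of the neighbouring stoma, the axis of the new division plane, the
spacing angle alpha between them (0-90 degrees), the two daughter areas,
and which daughter inherits the polarity crescent.  In a "normal" division
the larger daughter (future SLGC) carries the crescent; with probability
``reversal_prob`` the crescent instead lands in the smaller daughter
("reversed" size asymmetry).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def generate_division_geometries(n: int, angle_concentration: float = 0.0,
                                 reversal_prob: float = 0.0,
                                 size_ratio_params=(0.5, 0.12),
                                 seed: int = 0) -> pd.DataFrame:
    """Sample ``n`` division geometries with ground-truth labels.

    ``angle_concentration`` >= 0 biases spacing angles toward 0 degrees via
    alpha = 90 * U**(1 + c); c = 0 gives angles uniform on [0, 90].
    ``size_ratio_params = (mean, sd)`` set the smaller/larger daughter area
    ratio, clipped to [0.2, 0.95] so the size ordering is always strict.
    Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= reversal_prob <= 1.0:
        raise ValueError("reversal_prob must be in [0, 1]")
    if angle_concentration < 0:
        raise ValueError("angle_concentration must be >= 0")
    mean_ratio, sd_ratio = size_ratio_params
    rng = np.random.default_rng(seed)

    pore = rng.uniform(0.0, 180.0, size=n)
    alpha = 90.0 * rng.random(n) ** (1.0 + angle_concentration)
    sign = rng.choice([-1.0, 1.0], size=n)
    plane = (pore + sign * alpha) % 180.0

    large = rng.uniform(150.0, 320.0, size=n)
    ratio = np.clip(rng.normal(mean_ratio, sd_ratio, size=n), 0.2, 0.95)
    small = ratio * large
    reversed_truth = rng.random(n) < reversal_prob
    crescent_area = np.where(reversed_truth, small, large)
    sister_area = np.where(reversed_truth, large, small)

    return pd.DataFrame({
        "division_id": np.arange(1, n + 1),
        "pore_axis_deg": pore,
        "plane_axis_deg": plane,
        "alpha_truth_deg": alpha,
        "crescent_daughter_area_um2": crescent_area,
        "sister_area_um2": sister_area,
        "reversed_truth": reversed_truth,
    })
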