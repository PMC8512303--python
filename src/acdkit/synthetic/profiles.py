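"""Synthetic cortical intensity profiles with known Gaussian parameters."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from ..polarity import AngularProfile, crescent_model


class ProfileSpecError(ValueError):
    pass


@dataclass
class ProfileSpec:
    """Ground-truth parameters of a synthetic crescent profile.

    The noiseless profile is ``baseline + amplitude * exp(-d(theta, mu)^2 /
    (2 sigma^2))`` with ``d`` the wrapped angular distance; Gaussian noise
    of s.d. ``noise_sd`` is added independently per bin and the result is
    clipped at zero (intensities are nonnegative).
    """

    sigma_deg: float = 30.0
    mu_deg: float = 180.0
    amplitude: float = 100.0
    baseline: float = 10.0
    noise_sd: float = 0.0
    n_bins: int = 360
    seed: int = 0

    def __post_init__(self):
        if self.sigma_deg <= 0:
            raise ProfileSpecError("sigma_deg must be > 0")
        if self.amplitude < 0:
            raise ProfileSpecError("amplitude must be >= 0")
        if not 0 <= self.mu_deg < 360:
            raise ProfileSpecError("mu_deg must be in [0, 360)")
        if self.noise_sd < 0:
            raise ProfileSpecError("noise_sd must be >= 0")
        if self.n_bins < 36:
            raise ProfileSpecError("n_bins must be >= 36")


def bin_centres(n_bins: int) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) * 360.0 / n_bins


def noiseless_profile(spec: ProfileSpec) -> np.ndarray:
    return crescent_model(bin_centres(spec.n_bins), spec.mu_deg, spec.sigma_deg,
                          spec.amplitude, spec.baseline)


def generate_profiles(spec: ProfileSpec, n_cells: int = 1
                      ) -> Tuple[List[AngularProfile], pd.DataFrame]:
    """Generate ``n_cells`` profiles sharing the spec's ground truth.

    Returns (profiles, truth) where ``truth`` holds one row per cell with
    the generating parameters.  Deterministic for a fixed spec.
    """
    if n_cells < 1:
        raise ProfileSpecError("n_cells must be >= 1")
    rng = np.random.default_rng(spec.seed)
    theta = bin_centres(spec.n_bins)
    clean = noiseless_profile(spec)
    profiles = []
    for i in range(n_cells):
        y = clean.copy()
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_bins)
        y = np.clip(y, 0.0, None)
        profiles.append(AngularProfile(theta_deg=theta, intensity=y, cell_id=i + 1))
    truth = pd.DataFrame({
        "cell_id": np.arange(1, n_cells + 1),
        "sigma_deg": spec.sigma_deg,
        "mu_deg": spec.mu_deg,
        "amplitude": spec.amplitude,
        "baseline": spec.baseline,
    })
    return profiles, truth


def paint_crescent_disk(spec: ProfileSpec, radius_px: int = 40, pad_px: int = 6,
                        cell_id: int = 1):
    """Paint a crescent onto the boundary of a disk-shaped cell.

    Returns ``(label_image, intensity_image)``: a single disk cell labelled
    ``cell_id`` on background 0, with the crescent model evaluated at each
    boundary pixel's centroid angle.  Used for end-to-end tests of profile
    extraction from images.
    """
    size = 2 * (radius_px + pad_px) + 1
    c = radius_px + pad_px
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    mask = r2 <= radius_px ** 2
    labels = np.where(mask, cell_id, 0).astype(np.int32)

    theta = np.degrees(np.arctan2(yy - c, xx - c)) % 360.0
    intensity = np.zeros((size, size), dtype=float)
    vals = crescent_model(theta, spec.mu_deg, spec.sigma_deg,
                          spec.amplitude, spec.baseline)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
    # a thin cortical shell carries the signal, as membrane markers do
    shell = mask & (r2 >= (radius_px - 2) ** 2)
    intensity[shell] = np.clip(vals[shell], 0.0, None)
    return labels, intensity
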