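"""Synthetic polarity time-lapse series around a cell division.

Time is expressed in frames; the cytokinesis frame (cell plate formation,
time 00:00) sits between ``n_frames_before`` pre-division frames and
``n_frames_after`` post-division frames.  Three expression variants are
emulated:

- ``full``: polarized for several frames before cytokinesis and for many
  hours after it (persistent crescent);
- ``pre``: polarized before division only, with the signal degraded within
  at most one frame after cytokinesis;
- ``post``: polarity first appears at cytokinesis or one frame earlier and
  persists afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

from ..polarity import AngularProfile
from .profiles import ProfileSpec, bin_centres, noiseless_profile

UNPOLARIZED_SIGMA_DEG = 180.0


class TimelapseSpecError(ValueError):
    pass


@dataclass
class TimelapseSpec:
    """Parameters of a synthetic polarity time course.

    ``onset_frames_before_division`` is the number of frames before
    cytokinesis at which polarity appears; ``offset_frames_after_division``
    the number of frames after cytokinesis during which it persists.  For
    ``variant='pre'`` the offset must be <= 1 (rapid post-division
    degradation); for ``variant='post'`` the onset must be <= 1 (signal at
    cytokinesis or one frame earlier).
    """

    frame_interval_min: float = 40.0
    n_frames_before: int = 8
    n_frames_after: int = 12
    variant: str = "full"
    onset_frames_before_division: int = 5
    offset_frames_after_division: int = 10
    polar_sigma_deg: float = 30.0
    amplitude: float = 100.0
    baseline: float = 10.0
    noise_sd: float = 2.0
    n_bins: int = 72
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval_min <= 0:
            raise TimelapseSpecError("frame_interval_min must be > 0")
        if self.variant not in ("full", "pre", "post"):
            raise TimelapseSpecError("variant must be one of full|pre|post")
        if self.variant == "pre" and self.offset_frames_after_division > 1:
            raise TimelapseSpecError(
                "variant='pre' requires offset_frames_after_division <= 1")
        if self.variant == "post" and self.onset_frames_before_division > 1:
            raise TimelapseSpecError(
                "variant='post' requires onset_frames_before_division <= 1")
        if self.onset_frames_before_division > self.n_frames_before:
            raise TimelapseSpecError("onset exceeds pre-division frames")
        if self.offset_frames_after_division > self.n_frames_after:
            raise TimelapseSpecError("offset exceeds post-division frames")


@dataclass
class TimelapseSeries:
    """Generated series: one profile per frame plus per-frame ground truth."""

    profiles: List[AngularProfile]
    cytokinesis_frame: int
    frame_interval_min: float
    truth: pd.DataFrame = field(repr=False)


def generate_timelapse(spec: TimelapseSpec) -> TimelapseSeries:
    """Generate the per-frame profile series for one tracked division.

    Frames inside the variant's polarity window carry a crescent of s.d.
    ``polar_sigma_deg``; frames outside are flat (amplitude 0) plus noise.
    Ground truth records the generating sigma per frame
    (``UNPOLARIZED_SIGMA_DEG`` outside the window).
    """
    rng = np.random.default_rng(spec.seed)
    cyto = spec.n_frames_before
    n_frames = spec.n_frames_before + 1 + spec.n_frames_after
    start = cyto - spec.onset_frames_before_division
    stop = cyto + spec.offset_frames_after_division  # inclusive

    theta = bin_centres(spec.n_bins)
    mu = float(rng.uniform(0, 360))
    profiles = []
    truth_rows = []
    for f in range(n_frames):
        polar = start <= f <= stop
        sigma = spec.polar_sigma_deg if polar else UNPOLARIZED_SIGMA_DEG
        amp = spec.amplitude if polar else 0.0
        base = ProfileSpec(sigma_deg=spec.polar_sigma_deg, mu_deg=mu,
                           amplitude=amp, baseline=spec.baseline,
                           n_bins=spec.n_bins)
        y = noiseless_profile(base)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_bins)
        profiles.append(AngularProfile(theta_deg=theta,
                                       intensity=np.clip(y, 0.0, None),
                                       cell_id=1, frame_index=f))
        truth_rows.append({"frame_index": f, "polarized_truth": polar,
                           "sigma_truth_deg": sigma, "mu_truth_deg": mu})
    return TimelapseSeries(profiles=profiles, cytokinesis_frame=cyto,
                           frame_interval_min=spec.frame_interval_min,
                           truth=pd.DataFrame(truth_rows))
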