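"""Sister-cell division-coordination statistics and test conventions.

For tracked sister pairs from asymmetric divisions, Obs[AMP] is the
fraction of meristemoids that underwent an amplifying division, Obs[SPA]
the fraction of sister SLGCs that underwent a spacing division, and
Obs[SPA+AMP] the fraction of pairs in which both occurred.  Under
independence the expected joint frequency is Exp[SPA+AMP] =
Obs[SPA] * Obs[AMP]; a deficit (Obs below Exp) indicates competition or
inhibition between sisters.  A permutation test (shuffling the SLGC
outcomes across pairs) provides an inferential check on the deficit; the
underlying study compares Obs with Exp descriptively, so the test is an
optional extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoordinationStats",
    "BonferroniThreshold",
    "GroupComparison",
    "coordination_stats",
    "coordination_permutation_test",
    "bonferroni_threshold",
    "compare_groups",
]


def _to_bool_arrays(pairs):
    if len(pairs) == 0:
        raise ValueError("no sister pairs provided")
    if isinstance(pairs, pd.DataFrame):
        amp = pairs["amp"].to_numpy(dtype=bool)
        spa = pairs["spa"].to_numpy(dtype=bool)
    else:
        arr = np.asarray(pairs, dtype=bool)
        amp, spa = arr[:, 0], arr[:, 1]
    if len(amp) == 0:
        raise ValueError("no sister pairs provided")
    return amp, spa


@dataclass
class CoordinationStats:
    """Observed and expected sister-pair division frequencies."""

    obs_spa: float
    obs_amp: float
    obs_both: float
    exp_both: float
    deficit: float          # obs_both - exp_both; negative = suppression
    n_pairs: int
    p_perm: Optional[float] = None

    def summary(self) -> str:
        lines = [
            f"Sister-pair division coordination (n = {self.n_pairs} pairs)",
            "-----------------------------------------------------------",
            f"Obs[SPA]      (SLGC spacing division)        : {self.obs_spa:7.4f}",
            f"Obs[AMP]      (meristemoid amplifying div.)  : {self.obs_amp:7.4f}",
            f"Obs[SPA+AMP]  (both observed)                : {self.obs_both:7.4f}",
            f"Exp[SPA+AMP]  (independence: Obs*Obs)        : {self.exp_both:7.4f}",
            f"deficit Obs - Exp                            : {self.deficit:+7.4f}",
        ]
        if self.p_perm is not None:
            lines.append(
                f"permutation p-value (two-sided)              : {self.p_perm:7.4f}")
        return "\n".join(lines)


def coordination_stats(pairs) -> CoordinationStats:
    """Compute Obs[SPA], Obs[AMP], Obs[SPA+AMP] and Exp[SPA+AMP].

    ``pairs`` is a DataFrame with boolean ``amp``/``spa`` columns or an
    (n, 2) boolean array.  ``exp_both`` is exactly obs_spa * obs_amp.
    """
    amp, spa = _to_bool_arrays(pairs)
    n = len(amp)
    obs_amp = amp.mean()
    obs_spa = spa.mean()
    obs_both = (amp & spa).mean()
    exp_both = obs_spa * obs_amp
    return CoordinationStats(obs_spa=float(obs_spa), obs_amp=float(obs_amp),
                             obs_both=float(obs_both), exp_both=float(exp_both),
                             deficit=float(obs_both - exp_both), n_pairs=n)


def coordination_permutation_test(pairs, n_perm: int = 999,
                                  seed: int = 0) -> float:
    """Two-sided permutation p-value for the coordination deficit.

    The null is built by permuting the ``spa`` outcomes across pairs,
    which preserves both marginals and makes the deficit zero in
    expectation; p = (1 + #{|deficit_perm| >= |deficit_obs|}) /
    (n_perm + 1).  Degenerate columns (all-true or all-false) carry no
    information and return p = 1 with a warning.  Deterministic per seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    amp, spa = _to_bool_arrays(pairs)
    n = len(amp)
    if amp.all() or (~amp).all() or spa.all() or (~spa).all():
        warnings.warn("degenerate outcome column; permutation test uninformative")
        return 1.0
    rng = np.random.default_rng(seed)
    k_obs = int((amp & spa).sum())
    expected = n * amp.mean() * spa.mean()

    perm = rng.permuted(np.tile(spa, (n_perm, 1)), axis=1)
    k_perm = (perm & amp[None, :]).sum(axis=1)
    hits = np.abs(k_perm - expected) >= abs(k_obs - expected) - 1e-9
    return float((1 + hits.sum()) / (n_perm + 1))


class BonferroniThreshold(NamedTuple):
    """Bonferroni-corrected p-value threshold, exact and at the reporting
    convention of 3 decimal places."""

    exact: float
    rounded: float


def bonferroni_threshold(alpha: float, m_comparisons: int) -> BonferroniThreshold:
    """Corrected per-comparison threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    exact = alpha / m_comparisons
    return BonferroniThreshold(exact=exact, rounded=round(exact, 3))


@dataclass
class GroupComparison:
    p_value: float
    statistic: float
    method: str
    n_a: int
    n_b: int
    degenerate: bool = False


def compare_groups(sample_a, sample_b, method: str = "mann_whitney"
                   ) -> GroupComparison:
    """Two-sided two-sample comparison (Mann-Whitney U or Student's t).

    Identical constant samples are flagged degenerate with p = 1 by
    convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if method not in ("mann_whitney", "t_test"):
        raise ValueError("method must be 'mann_whitney' or 't_test'")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        warnings.warn("identical constant samples; p-value set to 1")
        return GroupComparison(p_value=1.0, statistic=np.nan, method=method,
                               n_a=a.size, n_b=b.size, degenerate=True)
    if method == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        res = stats.ttest_ind(a, b)
    return GroupComparison(p_value=float(res.pvalue),
                           statistic=float(res.statistic), method=method,
                           n_a=a.size, n_b=b.size)
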