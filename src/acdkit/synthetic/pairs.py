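"""Coupled sister-pair outcome simulator.

Each tracked asymmetric division yields a sister pair: the meristemoid may
undergo an amplifying division (``amp``) and the SLGC a spacing division
(``spa``).  The pair of Bernoulli outcomes is parameterized by the two
marginal probabilities plus an odds ratio: odds ratio 1 is exact
independence (the null under which Exp[SPA+AMP] = Obs[SPA] * Obs[AMP]);
odds ratios below 1 emulate mutual suppression between sisters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd


class PairSimSpecError(ValueError):
    pass


@dataclass
class PairSimSpec:
    n_pairs: int = 500
    p_amp: float = 0.5
    p_spa: float = 0.3
    coupling_or: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise PairSimSpecError("n_pairs must be >= 1")
        for name in ("p_amp", "p_spa"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise PairSimSpecError(f"{name} must be in [0, 1]")
        if self.coupling_or <= 0:
            raise PairSimSpecError("coupling_or must be > 0")
        joint_table_from_or(self.p_amp, self.p_spa, self.coupling_or)


def joint_table_from_or(p_amp: float, p_spa: float, odds_ratio: float
                        ) -> Tuple[float, float, float, float]:
    """Analytic 2x2 joint distribution from marginals and odds ratio.

    Returns ``(p11, p10, p01, p00)`` where the first index is ``amp`` and
    the second ``spa``.  The joint cell solves Plackett's quadratic
    ``psi = (p11 p00) / (p10 p01)``; the root yielding a valid probability
    table is returned.  Raises ``PairSimSpecError`` if the combination is
    infeasible.
    """
    p1, p2, psi = float(p_amp), float(p_spa), float(odds_ratio)
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0) or psi == 1.0:
        p11 = p1 * p2
    else:
        a = psi - 1.0
        s = 1.0 + (p1 + p2) * a
        disc = s * s - 4.0 * psi * a * p1 * p2
        if disc < 0:
            raise PairSimSpecError("no real solution for this odds ratio")
        root = np.sqrt(disc)
        candidates = [(s - root) / (2 * a), (s + root) / (2 * a)]
        p11 = None
        for cand in candidates:
            cells = (cand, p1 - cand, p2 - cand, 1.0 - p1 - p2 + cand)
            if all(-1e-12 <= c <= 1.0 + 1e-12 for c in cells):
                p11 = min(max(cand, 0.0), 1.0)
                break
        if p11 is None:
            raise PairSimSpecError(
                f"marginals ({p1}, {p2}) with odds ratio {psi} do not form "
                "a valid 2x2 probability table")
    cells = (p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11)
    if any(c < -1e-12 for c in cells):
        raise PairSimSpecError(
            f"marginals ({p1}, {p2}) with odds ratio {psi} do not form "
            "a valid 2x2 probability table")
    return tuple(max(c, 0.0) for c in cells)


def generate_sister_pairs(spec: PairSimSpec) -> pd.DataFrame:
    """Sample sister-pair outcomes from the coupled 2x2 distribution.

    Returns a DataFrame with columns ``pair_id, amp, spa`` (booleans).
    Deterministic for a fixed spec.
    """
    p11, p10, p01, p00 = joint_table_from_or(spec.p_amp, spec.p_spa,
                                             spec.coupling_or)
    rng = np.random.default_rng(spec.seed)
    cat = rng.choice(4, size=spec.n_pairs, p=[p11, p10, p01, p00])
    amp = cat <= 1
    spa = (cat == 0) | (cat == 2)
    return pd.DataFrame({
        "pair_id": np.arange(1, spec.n_pairs + 1),
        "amp": amp,
        "spa": spa,
    })
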