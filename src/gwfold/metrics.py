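"""Evaluation metrics: distance-matrix RMSD, relative improvement, speed-up,
and the closed-form least-squares trend line used for length scaling plots.

The structural metric is the superposition-free dRMSD: the root mean square
difference of all intra-structure pairwise Euclidean distances over the
n(n-1)/2 residue pairs.  Being a function of distance matrices only, it is
invariant to rigid motion of either structure and needs no unit of
reference frame alignment; lattice conformations (lattice units) are
compared against native alpha-carbon coordinates (angstroms) directly,
with an optional uniform scale factor for the lattice side.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import pdist


class TrendLine(NamedTuple):
    slope: float
    intercept: float


def rmsd(observed: Sequence, native: Sequence, scale: float = 1.0) -> float:
    """Distance-matrix RMSD between two equal-length coordinate sets.

    ``scale`` multiplies the observed coordinates (off by default), for
    mapping lattice units onto angstroms when desired.
    """
    obs = np.asarray(observed, dtype=float) * scale
    nat = np.asarray(native, dtype=float)
    if obs.shape != nat.shape or obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be n x 3, "
                         f"got {obs.shape} and {nat.shape}")
    if len(obs) < 2:
        raise ValueError("need at least 2 points")
    d_obs = pdist(obs)
    d_nat = pdist(nat)
    return float(np.sqrt(np.mean((d_obs - d_nat) ** 2)))


def relative_improvement(target_energy: float, reference_energy: float) -> float:
    """Relative improvement (percent) of a target over a reference energy.

    R.I. = (E_t - E_r) / E_r x 100.  With negative (favourable) energies a
    more negative target gives a positive improvement.
    """
    if reference_energy == 0:
        raise ValueError("reference energy must be nonzero")
    return (target_energy - reference_energy) / reference_energy * 100.0


def speedup(reference_avg_evals: float, target_avg_evals: float) -> float:
    """Ratio of reference to target objective-evaluation counts."""
    if reference_avg_evals <= 0 or target_avg_evals <= 0:
        raise ValueError("evaluation counts must be positive")
    return reference_avg_evals / target_avg_evals


def trend_fit(points: Sequence[tuple[float, float]]) -> TrendLine:
    """Ordinary least-squares line y = m x + c by the closed forms

    m = (n sum(xy) - sum(x) sum(y)) / (n sum(x^2) - sum(x)^2),
    c = (sum(y) - m sum(x)) / n.
    """
    pts = list(points)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    denom = n * np.sum(x * x) - np.sum(x) ** 2
    if denom == 0:
        raise ValueError("degenerate fit: all x values equal")
    m = (n * np.sum(x * y) - np.sum(x) * np.sum(y)) / denom
    c = (np.sum(y) - m * np.sum(x)) / n
    return TrendLine(float(m), float(c))
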