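"""Path collective variables S (progress) and Z (distance from the path).

A binding route is described by an ordered ladder of reference
conformations X_1 ... X_N. For a query frame with dissimilarities
D_i = MSD(frame, X_i) after superposition, the progress variable is the
exponentially weighted average index

    s = sum_i i * exp(-lambda * D_i) / sum_i exp(-lambda * D_i)

and the orthogonal off-path distance is

    z = -(1 / lambda) * ln sum_i exp(-lambda * D_i).

Indices start at 1, so s spans [1, N]. lambda sets how sharply the nearest
reference dominates; it should scale as the inverse of the typical
consecutive reference dissimilarity. Both sums are evaluated with a
max-shift (log-sum-exp) so that arbitrarily large lambda*D never overflows
or underflows.

Unit convention: reference dissimilarities are MSD in nm^2 and lambda in
nm^-2 (coordinates on disk are Angstrom; the conversion 1 A^2 = 0.01 nm^2
is applied internally and logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .geometry import Frame, SelectionPair, Trajectory, kabsch_superpose

__all__ = [
    "PathDefinition",
    "compute_s_z",
    "compute_s_z_from_d",
    "select_equidistant_centers",
    "z_fraction_below",
    "A2_TO_NM2",
]

logger = logging.getLogger(__name__)

A2_TO_NM2 = 0.01


@dataclass
class PathDefinition:
    """An ordered reference-frame ladder defining the S/Z variables.

    Parameters
    ----------
    references : ordered reference conformations (a :class:`Trajectory` or
        list of :class:`Frame`), at least two.
    lam : exponential sharpness, nm^-2.
    selection : align/measure atom sets used for the MSD dissimilarity.
    """

    references: object
    lam: float
    selection: SelectionPair

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.n_references < 2:
            raise ValueError("a path needs at least 2 reference frames")

    @property
    def n_references(self) -> int:
        return len(self.references)

    def _reference(self, i: int) -> Frame:
        refs = self.references
        return refs.frame(i) if isinstance(refs, Trajectory) else refs[i]

    def dissimilarities(self, frame: Frame) -> np.ndarray:
        """MSD (nm^2) of the query frame to every reference, after superposition."""
        sel = self.selection
        out = np.empty(self.n_references)
        for i in range(self.n_references):
            ref = self._reference(i)
            _, _, aligned = kabsch_superpose(frame, ref, sel.align_set)
            diff = aligned.coords[sel.measure_set] - ref.coords[sel.measure_set]
            out[i] = np.mean(np.sum(diff * diff, axis=1)) * A2_TO_NM2
        return out

    def spacing_cv(self) -> float:
        """Coefficient of variation of consecutive reference dissimilarities.

        The S definition assumes an approximately equidistant ladder; this
        diagnostic reports how far the supplied references deviate from
        that.
        """
        d = np.array(
            [
                self.dissimilarities(self._reference(i))[i + 1]
                for i in range(self.n_references - 1)
            ]
        )
        return float(d.std() / d.mean()) if d.mean() > 0 else 0.0


def compute_s_z_from_d(D: np.ndarray, lam: float) -> tuple[float, float]:
    """Evaluate S and Z from precomputed dissimilarities.

    Stable for exponents up to at least 1e4: the weights are formed as
    ``exp(-lam * D_i + shift)`` via log-sum-exp, so only relative
    dissimilarities matter numerically.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 1 or D.size < 2:
        raise ValueError("need a vector of at least 2 dissimilarities")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    idx = np.arange(1, D.size + 1, dtype=float)
    a = -lam * D
    shift = a.max()
    w = np.exp(a - shift)
    s = float((idx * w).sum() / w.sum())
    z = float(-(logsumexp(a)) / lam)
    return s, z


def compute_s_z(frame: Frame, path: PathDefinition) -> tuple[float, float]:
    """S (dimensionless, in [1, N]) and Z (nm^2) of a frame on a path."""
    return compute_s_z_from_d(path.dissimilarities(frame), path.lam)


def select_equidistant_centers(s_values: np.ndarray, n_centers: int) -> np.ndarray:
    """Pick candidate indices whose s-values best match a uniform grid.

    Greedy: for each node of the ideal uniform grid over
    [min(s), max(s)], take the unused candidate closest to it (subject to
    the chosen s-values being strictly increasing; ties go to the lowest
    candidate index). Returns candidate indices ordered by increasing s.
    """
    s_values = np.asarray(s_values, dtype=float)
    n = s_values.size
    if not 2 <= n_centers <= n:
        raise ValueError("need 2 <= n_centers <= n_candidates")
    order = np.lexsort((np.arange(n), s_values))  # by s, lowest index on ties
    s_sorted = s_values[order]
    grid = np.linspace(s_sorted[0], s_sorted[-1], n_centers)
    chosen: list[int] = []
    lo = 0  # strictly increasing: candidates before lo are spent
    for gi, g in enumerate(grid):
        hi = n - (n_centers - gi - 1)  # leave room for the remaining nodes
        block = s_sorted[lo:hi]
        j = lo + int(np.argmin(np.abs(block - g)))
        chosen.append(j)
        lo = j + 1
    return np.array([order[j] for j in chosen], dtype=int)


def z_fraction_below(z_values: np.ndarray, bound: float) -> float:
    """Fraction of samples with Z below ``bound`` (same units as Z).

    A sampling diagnostic: along a well-resolved route the off-path
    distance should stay small for most frames.
    """
    z_values = np.asarray(z_values, dtype=float)
    if z_values.size == 0:
        raise ValueError("empty z series")
    return float(np.mean(z_values < bound))
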