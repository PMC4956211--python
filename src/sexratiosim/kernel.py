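"""Inverse-distance movement kernel on a bounded N x N lattice.

For a source cell i the probability of relocating to cell j is
proportional to 1/d_ij, where d_ij is the Euclidean distance between cell
centres on the integer lattice. The source cell itself is excluded
(staying put happens only through the movement-probability Bernoulli
draw, not through the destination draw). Edges are physical boundaries:
there is no wrap-around, so border cells simply have fewer nearby
destinations and correspondingly flatter kernels.
"""

from __future__ import annotations

import functools

import numpy as np

__all__ = ["DistanceKernel", "build_distance_kernel"]


class DistanceKernel:
    """Row-stochastic destination distributions for every source cell.

    Cells are indexed flat, row-major, 0-based: cell ``(r, c)`` (1-based
    grid coordinates) maps to ``(r - 1) * N + (c - 1)``.

    Attributes
    ----------
    N : int
        Grid resolution.
    probs : ndarray of shape (N**2, N**2)
        ``probs[i, j]`` is the probability a mover at i relocates to j;
        each row sums to 1 and the diagonal is 0.
    """

    def __init__(self, N: int, probs: np.ndarray):
        self.N = int(N)
        self.probs = probs
        # Flattened per-row CDF with row offsets: row i occupies the value
        # range (i, i + 1], so the whole array is globally sorted and a
        # single searchsorted performs an exact per-row inverse-CDF draw.
        cum = np.cumsum(probs, axis=1)
        cum[:, -1] = 1.0
        self._flat_cdf = (cum + np.arange(probs.shape[0])[:, None]).ravel()

    @property
    def n_cells(self) -> int:
        return self.N * self.N

    def draw_destinations(self, source_cells: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one destination cell per source cell (exact inverse CDF)."""
        src = np.asarray(source_cells, dtype=np.int64)
        u = rng.random(src.shape[0])
        idx = np.searchsorted(self._flat_cdf, src + u, side="right")
        return idx - src * self.n_cells


@functools.lru_cache(maxsize=2)
def build_distance_kernel(N: int) -> DistanceKernel:
    """Build (and cache) the 1/d kernel for an N x N grid.

    Raises
    ------
    ValueError
        If ``N == 1`` (a single cell has no destination: movement is
        impossible on a degenerate domain) or ``N < 1``.
    """
    if N < 1:
        raise ValueError("grid resolution must be a positive integer")
    if N == 1:
        raise ValueError("degenerate 1x1 domain: no destination cell exists")
    cells = np.arange(N * N)
    r, c = np.divmod(cells, N)
    d = np.hypot(r[:, None] - r[None, :], c[:, None] - c[None, :])
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    probs = w / w.sum(axis=1, keepdims=True)
    return DistanceKernel(N, probs)
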