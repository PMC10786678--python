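"""Pairwise distance fluctuations from a normal-mode set.

The quantity minimized within a quasi-rigid domain is the variance of
the inter-residue distance,

    σ_ij² = Σ_k λ_k⁻¹ [(u_k^(i) − u_k^(j)) · d̂_ij]²      (anisotropic)
    σ_ij² = 3 Σ_k λ_k⁻¹ (u_{k,i} − u_{k,j})²             (GNM)

i.e. the first-order fluctuation of the scalar distance along the
equilibrium direction, up to the global scale k_BT/γ.  σ² is evaluated
on a sparse neighborhood pair set (default twice the model cutoff)
rather than all N² pairs; the downstream spectral clustering operates
on exactly that sparse graph.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy.spatial import cKDTree

from .modes import ModeSet
from .structure_io import Structure

logger = logging.getLogger(__name__)

__all__ = ["PairFluctuations", "pair_list", "distance_fluctuation_matrix"]


@dataclass
class PairFluctuations:
    """Mean-square distance fluctuations on a sparse pair set.

    ``pairs`` is (P, 2) with i < j; ``sigma2`` per-pair values in Å² up
    to the global scale; every pair lies within ``neighborhood_radius``
    unless it was force-included (e.g. backbone springs beyond cutoff).
    """

    pairs: np.ndarray
    sigma2: np.ndarray
    neighborhood_radius: float
    n_nodes: int


def pair_list(structure: Structure, radius: float) -> np.ndarray:
    """All residue pairs within ``radius`` Å, as an (P, 2) array, i < j.

    Uses a k-d tree; identical to the all-pairs O(N²) definition.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(structure.coords)
    pairs = sorted(tuple(sorted(p)) for p in tree.query_pairs(radius))
    return np.array(pairs, dtype=np.intp).reshape(-1, 2)


def distance_fluctuation_matrix(
    modes: ModeSet,
    structure: Structure,
    pairs: np.ndarray,
    neighborhood_radius: float = np.inf,
) -> PairFluctuations:
    """Evaluate σ_ij² for every pair in ``pairs``.

    Negative values from floating-point cancellation are clipped to 0
    (and logged if below −1e−10).
    """
    coords = structure.coords
    n = coords.shape[0]
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    i, j = pairs[:, 0], pairs[:, 1]
    inv = 1.0 / modes.eigenvalues

    if modes.is_anisotropic:
        if modes.eigenvectors.shape[0] != 3 * n:
            raise ValueError("mode vectors and structure size disagree")
        d = coords[j] - coords[i]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-8):
            raise ValueError("degenerate geometry: pair with zero separation")
        dh = d / r[:, None]
        u = modes.eigenvectors.reshape(n, 3, -1)
        # projected relative displacement per pair and mode: (P, K)
        proj = np.einsum("pdk,pd->pk", u[i] - u[j], dh, optimize=True)
        sigma2 = (proj**2) @ inv
    else:
        if modes.eigenvectors.shape[0] != n:
            raise ValueError("mode vectors and structure size disagree")
        du = modes.eigenvectors[i] - modes.eigenvectors[j]
        sigma2 = 3.0 * ((du**2) @ inv)

    if np.any(sigma2 < -1e-10):
        logger.warning("clipping %d negative sigma2 values", int((sigma2 < -1e-10).sum()))
    sigma2 = np.clip(sigma2, 0.0, None)
    return PairFluctuations(
        pairs=pairs, sigma2=sigma2, neighborhood_radius=float(neighborhood_radius), n_nodes=n
    )
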