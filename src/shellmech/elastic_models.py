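"""Elastic network construction and stiffness-matrix assembly.

Residues are point masses on alpha-carbons connected by Hookean springs
within a distance cutoff r_c.  Four model variants are supported:

``anm``
    Anisotropic network model.  The potential is
    V = 1/2 Σ_edges γ_ij (|r_i − r_j| − |d_ij|)², whose exact Hessian at
    equilibrium has off-diagonal 3×3 blocks H_ij = −γ_ij d̂_ij d̂_ijᵀ.
    Default cutoff 15 Å.
``gnm``
    Gaussian network model; the N×N Kirchhoff (connectivity Laplacian)
    matrix Γ.  Default cutoff 7.5 Å.
``uenm``
    Unified (generalized anisotropic) model: a convex mixture
    f·H_anm + (1−f)·(Γ ⊗ I₃) that penalizes both distance changes and
    isotropic relative displacement.  Default cutoff 7.5 Å, f = 0.5.
``bbenm``
    Backbone-enhanced ANM: sequence-adjacent residues of the same chain
    are connected regardless of distance and their spring constant is
    multiplied by β ≥ 1.  Default cutoff 7.5 Å, β = 10.

Spring constants are uniform (γ = 1) by default; the physical scale is
recovered downstream by B-factor calibration and cancels in correlation
and clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure_io import Structure

__all__ = [
    "NetworkModel",
    "StiffnessMatrix",
    "DisconnectedNetworkError",
    "DEFAULT_CUTOFF",
    "build_network",
    "anm_hessian",
    "gnm_kirchhoff",
    "uenm_hessian",
    "bbenm_hessian",
    "build_stiffness",
    "potential_energy",
]

MODEL_KINDS = ("anm", "gnm", "uenm", "bbenm")

#: default cutoff radii in Å per model kind
DEFAULT_CUTOFF = {"anm": 15.0, "gnm": 7.5, "uenm": 7.5, "bbenm": 7.5}


class DisconnectedNetworkError(Exception):
    """The contact network splits into several components."""

    def __init__(self, sizes):
        self.component_sizes = sorted(sizes, reverse=True)
        super().__init__(
            f"elastic network is disconnected: component sizes {self.component_sizes}"
        )


@dataclass
class NetworkModel:
    """Residue-level elastic network.

    ``edges`` is an (E, 2) integer array with i < j; ``gammas`` the per-edge
    spring constants (γ units); ``bonded_mask`` flags sequence-adjacent
    same-chain pairs.  Non-bonded edges always satisfy the cutoff; for
    ``bbenm`` bonded edges may exceed it.
    """

    coords: np.ndarray
    edges: np.ndarray
    gammas: np.ndarray
    bonded_mask: np.ndarray
    model_kind: str
    cutoff: float

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


@dataclass
class StiffnessMatrix:
    """Sparse symmetric stiffness matrix.

    3N×3N for anisotropic models, N×N for GNM.  ``n_rigid_expected`` is
    the analytic count of zero modes: 6 (anm/bbenm, or uenm at f = 1),
    3 (uenm with f < 1 — the isotropic term penalizes rotations), or
    1 (gnm).
    """

    matrix: sp.csr_array
    model_kind: str
    n_sites: int
    n_rigid_expected: int

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    @property
    def is_anisotropic(self) -> bool:
        return self.model_kind != "gnm"


def _sequence_bonded_pairs(structure: Structure) -> set[tuple[int, int]]:
    pairs = set()
    for i in range(len(structure) - 1):
        a, b = structure.residues[i], structure.residues[i + 1]
        if a.chain_id == b.chain_id:
            pairs.add((i, i + 1))
    return pairs


def build_network(
    structure: Structure,
    model_kind: str = "uenm",
    cutoff: float | None = None,
    gamma: float = 1.0,
    on_disconnected: str = "error",
) -> NetworkModel:
    """Build the elastic network of a coarse-grained structure.

    Edges connect all residue pairs within ``cutoff`` (found with a k-d
    tree; identical to the all-pairs definition).  For ``bbenm``,
    sequence-adjacent same-chain pairs are added regardless of distance
    and flagged bonded.

    Parameters
    ----------
    on_disconnected : {"error", "largest"}
        A disconnected network is a hard error by default; ``"largest"``
        is not supported here (the caller must subset the structure) and
        is reserved for the CLI front-end.

    Raises
    ------
    DisconnectedNetworkError
        If the resulting graph is not connected.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")
    if cutoff is None:
        cutoff = DEFAULT_CUTOFF[model_kind]
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = structure.coords
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 residues to build a network")

    tree = cKDTree(coords)
    pairs = {tuple(sorted(p)) for p in tree.query_pairs(cutoff)}

    bonded = _sequence_bonded_pairs(structure)
    if model_kind == "bbenm":
        pairs |= bonded  # backbone springs exist even beyond the cutoff

    edges = np.array(sorted(pairs), dtype=np.intp).reshape(-1, 2)
    bonded_mask = np.array([tuple(e) in bonded for e in edges], dtype=bool)
    gammas = np.full(edges.shape[0], float(gamma))

    adj = sp.coo_array(
        (np.ones(2 * len(edges)), (np.r_[edges[:, 0], edges[:, 1]],
                                   np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    )
    n_comp, comp = connected_components(adj.tocsr(), directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp).tolist()
        raise DisconnectedNetworkError(sizes)

    return NetworkModel(
        coords=coords,
        edges=edges,
        gammas=gammas,
        bonded_mask=bonded_mask,
        model_kind=model_kind,
        cutoff=float(cutoff),
    )


def _effective_gammas(network: NetworkModel, beta: float) -> np.ndarray:
    g = network.gammas.copy()
    if beta != 1.0:
        g[network.bonded_mask] *= beta
    return g


def _anisotropic_hessian(
    network: NetworkModel, f: float, gammas: np.ndarray
) -> sp.csr_array:
    """Assemble 3N×3N blocks −γ [ f d̂d̂ᵀ + (1−f) I₃ ], diagonal closing rows."""
    coords = network.coords
    n = network.n_nodes
    i, j = network.edges[:, 0], network.edges[:, 1]
    d = coords[j] - coords[i]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-8):
        raise ValueError("degenerate geometry: coincident connected nodes")
    dh = d / r[:, None]

    blocks = f * dh[:, :, None] * dh[:, None, :] + (1.0 - f) * np.eye(3)[None]
    blocks *= gammas[:, None, None]  # (E, 3, 3), the positive block k_ij

    diag = np.zeros((n, 3, 3))
    np.add.at(diag, i, blocks)
    np.add.at(diag, j, blocks)

    e = len(i)
    a, b = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    a, b = a.ravel(), b.ravel()
    rows = np.concatenate([
        (3 * i[:, None] + a[None]).ravel(),
        (3 * j[:, None] + a[None]).ravel(),
        (3 * np.arange(n)[:, None] + a[None]).ravel(),
    ])
    cols = np.concatenate([
        (3 * j[:, None] + b[None]).ravel(),
        (3 * i[:, None] + b[None]).ravel(),
        (3 * np.arange(n)[:, None] + b[None]).ravel(),
    ])
    vals = np.concatenate([
        -blocks.reshape(e, 9).ravel(),
        -np.transpose(blocks, (0, 2, 1)).reshape(e, 9).ravel(),
        diag.reshape(n, 9).ravel(),
    ])
    h = sp.coo_array((vals, (rows, cols)), shape=(3 * n, 3 * n)).tocsr()
    h.eliminate_zeros()
    return h


def anm_hessian(network: NetworkModel) -> StiffnessMatrix:
    """Anisotropic network model Hessian.

    Exact second derivative at equilibrium of the pairwise-distance
    potential; six zero modes (rigid translations and rotations).
    """
    h = _anisotropic_hessian(network, f=1.0, gammas=network.gammas)
    return StiffnessMatrix(h, "anm", network.n_nodes, n_rigid_expected=6)


def gnm_kirchhoff(network: NetworkModel) -> StiffnessMatrix:
    """Gaussian network model Kirchhoff matrix Γ (rows sum to zero)."""
    n = network.n_nodes
    i, j = network.edges[:, 0], network.edges[:, 1]
    g = network.gammas
    deg = np.zeros(n)
    np.add.at(deg, i, g)
    np.add.at(deg, j, g)
    rows = np.concatenate([i, j, np.arange(n)])
    cols = np.concatenate([j, i, np.arange(n)])
    vals = np.concatenate([-g, -g, deg])
    mat = sp.coo_array((vals, (rows, cols)), shape=(n, n)).tocsr()
    return StiffnessMatrix(mat, "gnm", n, n_rigid_expected=1)


def uenm_hessian(network: NetworkModel, f: float = 0.5) -> StiffnessMatrix:
    """Unified model Hessian: f·H_anm + (1−f)·(Γ ⊗ I₃).

    Positive semidefinite for all f in [0, 1]; for f < 1 only the three
    translations are zero modes.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"mixing weight f must lie in [0, 1], got {f}")
    h = _anisotropic_hessian(network, f=f, gammas=network.gammas)
    n_rigid = 6 if f == 1.0 else 3
    return StiffnessMatrix(h, "uenm", network.n_nodes, n_rigid_expected=n_rigid)


def bbenm_hessian(network: NetworkModel, beta: float = 10.0) -> StiffnessMatrix:
    """Backbone-enhanced ANM Hessian: γ multiplied by β on bonded edges."""
    if beta < 1.0:
        raise ValueError(f"backbone enhancement beta must be >= 1, got {beta}")
    g = _effective_gammas(network, beta)
    h = _anisotropic_hessian(network, f=1.0, gammas=g)
    return StiffnessMatrix(h, "bbenm", network.n_nodes, n_rigid_expected=6)


def build_stiffness(
    network: NetworkModel, f: float = 0.5, beta: float = 10.0
) -> StiffnessMatrix:
    """Dispatch to the stiffness builder matching ``network.model_kind``."""
    kind = network.model_kind
    if kind == "anm":
        return anm_hessian(network)
    if kind == "gnm":
        return gnm_kirchhoff(network)
    if kind == "uenm":
        return uenm_hessian(network, f=f)
    if kind == "bbenm":
        return bbenm_hessian(network, beta=beta)
    raise ValueError(f"unknown model kind {kind!r}")


def potential_energy(
    network: NetworkModel, displaced_coords: np.ndarray, beta: float = 1.0
) -> float:
    """Harmonic pairwise-distance energy at displaced coordinates.

    Returns 1/2 Σ_edges γ_eff (|r'_i − r'_j| − |d_ij|)² in γ·Å², with
    γ_eff including the backbone enhancement ``beta`` on bonded edges.
    Serves as the independent energy function whose numerical Hessian
    the anisotropic builders must reproduce.
    """
    x = np.asarray(displaced_coords, float)
    if x.shape != network.coords.shape:
        raise ValueError("displaced coordinates shape mismatch")
    i, j = network.edges[:, 0], network.edges[:, 1]
    g = _effective_gammas(network, beta)
    r0 = np.linalg.norm(network.coords[j] - network.coords[i], axis=1)
    r = np.linalg.norm(x[j] - x[i], axis=1)
    return 0.5 * float(np.sum(g * (r - r0) ** 2))
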