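"""Synthetic structures with known mechanical ground truth.

Real capsids are large downloads; these generators produce desk-scale
stand-ins whose mechanics are known by construction, so every pipeline
stage can be exercised and validated offline.

``make_hinged_toy`` builds several compact residue blobs ("domains")
arranged on a ring and touching their neighbors through a small contact
patch.  Within a domain residues sit on a jittered cubic lattice at
~3.8 Å spacing (the CA–CA scale), so the default 7.5 Å cutoff connects
each domain densely while the inter-domain interface carries only a few
springs — quasi-rigid domains by construction.  A stiffness ratio can
additionally soften the interface springs.

``make_spherical_shell`` places quasi-uniform points on a sphere
(Fibonacci lattice plus jitter), a closed-shell topology stand-in.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_array
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .elastic_models import NetworkModel
from .structure_io import Residue, Structure, structure_to_pdb

__all__ = [
    "PlantedStructure",
    "make_hinged_toy",
    "make_spherical_shell",
    "make_pdb_fixture_text",
    "planted_gammas",
]

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass
class PlantedStructure:
    """A synthetic structure with known domain labels and spring strengths."""

    structure: Structure
    true_labels: np.ndarray
    gamma_intra: float
    gamma_inter: float
    description: str

    @property
    def n_domains(self) -> int:
        return int(self.true_labels.max()) + 1


def _blob(m: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """``m`` points nearest the origin of a cubic lattice, jittered."""
    half = int(np.ceil((3 * m / (4 * np.pi)) ** (1 / 3))) + 2
    ax = np.arange(-half, half + 1) * spacing
    grid = np.array(np.meshgrid(ax, ax, ax, indexing="ij")).reshape(3, -1).T
    order = np.argsort(np.linalg.norm(grid, axis=1), kind="stable")
    pts = grid[order[:m]]
    return pts + rng.normal(0.0, 0.25, pts.shape)


def _chains_structure(
    coords: np.ndarray, chain_of: np.ndarray, description: str
) -> Structure:
    residues = []
    counters: dict[str, int] = {}
    for pt, ci in zip(coords, chain_of):
        chain = _CHAIN_IDS[int(ci) % len(_CHAIN_IDS)]
        counters[chain] = counters.get(chain, 0) + 1
        residues.append(
            Residue(
                chain_id=chain,
                residue_number=counters[chain],
                insertion_code="",
                residue_name="ALA",
                coord=pt,
                bfactor=1.0,
            )
        )
    return Structure(residues=residues, source_id=description, title=description)


def _connected_at(coords: np.ndarray, cutoff: float) -> bool:
    pairs = cKDTree(coords).query_pairs(cutoff)
    if not pairs:
        return coords.shape[0] == 1
    arr = np.array(sorted(pairs))
    n = coords.shape[0]
    adj = coo_array(
        (np.ones(2 * len(arr)), (np.r_[arr[:, 0], arr[:, 1]], np.r_[arr[:, 1], arr[:, 0]])),
        shape=(n, n),
    )
    n_comp, _ = connected_components(adj.tocsr(), directed=False)
    return n_comp == 1


def make_hinged_toy(
    n_domains: int,
    residues_per_domain: int,
    stiffness_ratio: float = 100.0,
    seed: int = 0,
    cutoff: float = 7.5,
    spacing: float = 3.8,
    gap: float = 3.0,
) -> PlantedStructure:
    """Ring of compact residue blobs joined by narrow contact patches.

    Each domain occupies its own chain.  Intra-domain springs get
    ``gamma_intra`` = 1; inter-domain springs 1/``stiffness_ratio``
    (apply via :func:`planted_gammas`).  ``stiffness_ratio`` = 1 leaves
    no mechanical signal beyond the interface geometry itself.
    """
    if n_domains < 2:
        raise ValueError("need at least 2 domains")
    if residues_per_domain < 8:
        raise ValueError("need at least 8 residues per domain")
    if stiffness_ratio < 1:
        raise ValueError("stiffness_ratio must be >= 1")

    blob_radius = spacing * (3 * residues_per_domain / (4 * np.pi)) ** (1 / 3)
    # the surface gap keeps the interface narrow: wide enough to carry a
    # few springs at the default cutoff, narrow enough that domains stay
    # quasi-rigid relative to the hinge
    chord = 2 * blob_radius + gap
    ring_r = chord / (2 * np.sin(np.pi / n_domains))

    for attempt in range(25):
        rng = np.random.default_rng([seed, attempt])
        parts = []
        for d in range(n_domains):
            pts = _blob(residues_per_domain, spacing, rng)
            pts = pts @ Rotation.random(random_state=np.random.RandomState(
                (seed * 97 + attempt * 13 + d) % 2**31)).as_matrix().T
            # irregular placement breaks the ring symmetry so no two
            # interfaces are mechanically equivalent
            ang = 2 * np.pi * d / n_domains + rng.uniform(-0.1, 0.1) * 2 * np.pi / n_domains
            rad = ring_r * (1.0 + rng.uniform(0.0, 0.08))
            center = rad * np.array([np.cos(ang), np.sin(ang), 0.0])
            parts.append(pts + center)
        coords = np.vstack(parts)
        labels = np.repeat(np.arange(n_domains), residues_per_domain)

        ok = all(_connected_at(p, cutoff) for p in parts) and _connected_at(coords, cutoff)
        # domains must touch but not interpenetrate
        min_inter = min(
            cdist(parts[d], parts[(d + 1) % n_domains]).min() for d in range(n_domains)
        )
        if ok and min_inter > 2.8:
            break
    else:
        raise RuntimeError("could not generate a collision-free hinged toy")

    structure = _chains_structure(
        coords, labels, f"hinged_toy_d{n_domains}_m{residues_per_domain}_s{seed}"
    )
    return PlantedStructure(
        structure=structure,
        true_labels=labels,
        gamma_intra=1.0,
        gamma_inter=1.0 / stiffness_ratio,
        description=structure.source_id,
    )


def planted_gammas(network: NetworkModel, planted: PlantedStructure) -> None:
    """Assign intra/inter-domain spring constants to a built network in place."""
    lab = planted.true_labels
    i, j = network.edges[:, 0], network.edges[:, 1]
    same = lab[i] == lab[j]
    network.gammas = np.where(same, planted.gamma_intra, planted.gamma_inter)


def make_spherical_shell(n_points: int, radius: float, seed: int = 0) -> Structure:
    """Quasi-uniform jittered Fibonacci lattice on a sphere of given radius."""
    if n_points < 60:
        raise ValueError("need at least 60 points for a shell")
    rng = np.random.default_rng(seed)
    k = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    rho = np.sqrt(1.0 - z**2)
    pts = radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    pts += rng.normal(0.0, 0.2, pts.shape)
    chain_of = k // 5000  # keep author residue numbers within PDB column limits
    return _chains_structure(pts, chain_of, f"spherical_shell_n{n_points}_s{seed}")


def make_pdb_fixture_text(structure: Structure, b_factors=None) -> str:
    """Minimal CA-only PDB text for a fixture; round-trips through parsing."""
    return structure_to_pdb(structure, b_factors)
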