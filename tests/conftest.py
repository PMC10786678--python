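"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest

from shellmech.structure_io import Residue, Structure


def structure_from_coords(coords, chain_ids=None, bfactors=None) -> Structure:
    """Wrap bare coordinates in a Structure (single chain by default)."""
    coords = np.asarray(coords, float)
    n = len(coords)
    if chain_ids is None:
        chain_ids = ["A"] * n
    if bfactors is None:
        bfactors = np.ones(n)
    counters: dict[str, int] = {}
    residues = []
    for pt, ch, b in zip(coords, chain_ids, bfactors):
        counters[ch] = counters.get(ch, 0) + 1
        residues.append(
            Residue(ch, counters[ch], "", "GLY", np.asarray(pt, float), float(b))
        )
    return Structure(residues=residues, source_id="synthetic")


def random_structure(n: int, box: float, seed: int) -> Structure:
    """Uniform random points in a cubic box (synthetic stand-in geometry)."""
    rng = np.random.default_rng(seed)
    return structure_from_coords(rng.uniform(0.0, box, (n, 3)))


def random_connected_structure(n: int, seed: int, cutoff: float = 7.5) -> Structure:
    """Random points dense enough that the cutoff network is connected.

    Density targets ~14 neighbors per site; deterministic seed bumping
    skips the rare draw that still disconnects.
    """
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import coo_array
    from scipy.spatial import cKDTree

    box = (n / 0.008) ** (1.0 / 3.0)
    for bump in range(20):
        s = random_structure(n, box, seed + 1000 * bump)
        pairs = np.array(sorted(cKDTree(s.coords).query_pairs(cutoff)))
        if len(pairs) == 0:
            continue
        adj = coo_array(
            (np.ones(2 * len(pairs)),
             (np.r_[pairs[:, 0], pairs[:, 1]], np.r_[pairs[:, 1], pairs[:, 0]])),
            shape=(n, n),
        )
        if connected_components(adj.tocsr(), directed=False)[0] == 1:
            return s
    raise RuntimeError("no connected random structure found")


def fd_hessian_entries(energy, x0, entries, h=1e-5):
    """Central-difference second derivatives of ``energy`` at x0.

    ``entries`` is an iterable of flat index pairs (a, b); returns the
    4-point-formula estimate for each.  Independent of any analytic
    Hessian code path.
    """
    x0 = np.asarray(x0, float).ravel()
    out = np.empty(len(entries))
    for m, (a, b) in enumerate(entries):
        if a == b:
            xp = x0.copy(); xp[a] += h
            xm = x0.copy(); xm[a] -= h
            out[m] = (energy(xp) - 2.0 * energy(x0) + energy(xm)) / h**2
        else:
            xpp = x0.copy(); xpp[a] += h; xpp[b] += h
            xpm = x0.copy(); xpm[a] += h; xpm[b] -= h
            xmp = x0.copy(); xmp[a] -= h; xmp[b] += h
            xmm = x0.copy(); xmm[a] -= h; xmm[b] -= h
            out[m] = (energy(xpp) - energy(xpm) - energy(xmp) + energy(xmm)) / (4.0 * h**2)
    return out


def fd_check_hessian(energy, hessian, coords, rng, n_zero_probes=50, h=1e-5):
    """Max |FD − analytic| over the sparsity pattern plus random zero probes,
    relative to the largest analytic entry."""
    hd = hessian.tocoo()
    mask = hd.row <= hd.col
    entries = list(zip(hd.row[mask].tolist(), hd.col[mask].tolist()))
    dim = hessian.shape[0]
    stored = set(entries)
    probes = 0
    while probes < n_zero_probes:
        a, b = int(rng.integers(dim)), int(rng.integers(dim))
        if a <= b and (a, b) not in stored:
            entries.append((a, b))
            probes += 1
    fd = fd_hessian_entries(energy, coords, entries, h=h)
    analytic = np.array([hessian[a, b] for a, b in entries])
    scale = np.abs(analytic).max()
    return np.abs(fd - analytic).max() / scale


@pytest.fixture(scope="session")
def three_ca_pdb_text() -> str:
    return (
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
        "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 20.00           C\n"
        "ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00 30.00           C\n"
        "END\n"
    )


@pytest.fixture(scope="session")
def three_ca_cif_text() -> str:
    return """\
data_synthetic
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.auth_atom_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . ALA A 1 1 ? 0.000 0.000 0.000 1.00 10.00 1 ALA A CA 1
ATOM 2 C CA . GLY A 1 2 ? 3.800 0.000 0.000 1.00 20.00 2 GLY A CA 1
ATOM 3 C CA . SER A 1 3 ? 7.600 0.000 0.000 1.00 30.00 3 SER A CA 1
"""
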