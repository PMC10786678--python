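"""Low-frequency normal modes, mean-square fluctuations, B-factor QC.

The stiffness matrix is singular by construction (rigid-body motions),
so the smallest nonrigid eigenpairs are obtained with a sparse
shift-invert Lanczos solve targeted just below zero.  Rigid modes are
identified by a relative eigenvalue threshold *and* verified against the
analytic count for the model kind — a silent off-by-one here corrupts
everything downstream.

B-factors follow B_i = (8π²/3)⟨Δr_i²⟩; the fitted scale maps the
model's unit-γ fluctuations onto experiment and implies a physical
spring constant at fixed temperature (293 K).  Correlation and
clustering are invariant to this scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla
from scipy import stats

from .elastic_models import StiffnessMatrix

__all__ = [
    "ModeSet",
    "BfactorFit",
    "RigidModeCountError",
    "compute_modes",
    "mean_square_fluctuations",
    "fit_bfactors",
    "mode_convergence_profile",
]

#: Boltzmann constant times 293 K, kcal/mol
KBT_293K = 0.0019872041 * 293.0


class RigidModeCountError(Exception):
    """The number of near-zero eigenvalues differs from the analytic count."""


@dataclass
class ModeSet:
    """Nonrigid eigenpairs of a stiffness matrix.

    ``eigenvalues`` are ascending and strictly above the rigid threshold;
    ``eigenvectors`` columns are orthonormal (length 3N anisotropic, N
    for GNM) with sign fixed so the first nonzero component is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_rigid_discarded: int
    model_kind: str
    n_requested: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def is_anisotropic(self) -> bool:
        return self.model_kind != "gnm"

    def truncated(self, n: int) -> "ModeSet":
        """The lowest ``n`` modes as a new ModeSet."""
        if not 1 <= n <= self.n_modes:
            raise ValueError(f"cannot truncate {self.n_modes} modes to {n}")
        return ModeSet(
            self.eigenvalues[:n],
            self.eigenvectors[:, :n],
            self.n_rigid_discarded,
            self.model_kind,
            n,
        )


@dataclass
class BfactorFit:
    """Least-squares calibration of predicted MSF against experiment."""

    predicted_msf: np.ndarray
    scale_c: float
    gamma_fitted: float
    cc: float

    @property
    def predicted_bfactors(self) -> np.ndarray:
        return self.scale_c * self.predicted_msf


def _fix_signs(vecs: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip each column so its first nonzero component is positive."""
    out = vecs.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        nz = np.nonzero(np.abs(col) > tol)[0]
        if nz.size and col[nz[0]] < 0:
            out[:, k] = -col
    return out


def compute_modes(
    matrix: StiffnessMatrix,
    n_modes: int = 200,
    rigid_tol: float = 1e-8,
) -> ModeSet:
    """Solve for the ``n_modes`` smallest nonrigid eigenpairs.

    Requests ``n_modes`` plus the expected rigid count from a sparse
    shift-invert solve near zero (dense for very small problems),
    discards eigenvalues below ``rigid_tol`` times a Gershgorin-style
    estimate of the largest eigenvalue, and errors if the discarded
    count differs from the analytic expectation.

    Raises
    ------
    RigidModeCountError
        Collinear or otherwise degenerate geometry changes the zero-mode
        census.
    ValueError
        n_modes plus the rigid count exceeds the matrix dimension.
    """
    a = matrix.matrix
    dim = a.shape[0]
    r_expected = matrix.n_rigid_expected
    k = n_modes + r_expected
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if k > dim:
        raise ValueError(
            f"n_modes={n_modes} plus {r_expected} rigid modes exceeds dimension {dim}"
        )
    lam_max_est = float(a.diagonal().max())
    if k >= dim - 1:
        # ARPACK requires k < dim-1; tiny systems fall back to dense
        w, v = np.linalg.eigh(a.toarray())
        w, v = w[:k], v[:, :k]
    else:
        rng = np.random.default_rng(0)  # deterministic Lanczos start
        v0 = rng.uniform(-1.0, 1.0, dim)
        try:
            w, v = spla.eigsh(a, k=k, sigma=-1e-6 * lam_max_est, which="LM", v0=v0)
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(
                "eigensolver did not converge; raise the iteration cap (maxiter) "
                "or reduce n_modes"
            ) from exc
    order = np.argsort(w)
    w, v = w[order], v[:, order]

    thresh = rigid_tol * lam_max_est
    rigid = w < thresh
    n_rigid = int(np.count_nonzero(rigid))
    if n_rigid != r_expected:
        raise RigidModeCountError(
            f"found {n_rigid} near-zero eigenvalues, expected {r_expected} for "
            f"{matrix.model_kind}; the structure may be collinear or the network "
            f"marginally connected"
        )
    if not np.all(rigid[:n_rigid]) or np.any(rigid[n_rigid:]):
        raise RigidModeCountError("rigid modes are not the lowest eigenvalues")

    w, v = w[n_rigid:], v[:, n_rigid:]
    v = _fix_signs(v)
    return ModeSet(
        eigenvalues=w,
        eigenvectors=v,
        n_rigid_discarded=n_rigid,
        model_kind=matrix.model_kind,
        n_requested=n_modes,
    )


def mean_square_fluctuations(modes: ModeSet) -> np.ndarray:
    """Per-residue MSF ⟨Δr_i²⟩ in Å² up to the global scale k_BT/γ.

    Anisotropic: MSF_i = Σ_k λ_k⁻¹ ‖u_k^(i)‖² over the 3-vector of mode
    k at residue i.  GNM: MSF_i = 3 Σ_k λ_k⁻¹ u_{k,i}².
    """
    inv = 1.0 / modes.eigenvalues
    if modes.is_anisotropic:
        n = modes.eigenvectors.shape[0] // 3
        u2 = modes.eigenvectors.reshape(n, 3, -1) ** 2
        return u2.sum(axis=1) @ inv
    return 3.0 * (modes.eigenvectors**2 @ inv)


def fit_bfactors(msf: np.ndarray, b_exp: np.ndarray) -> BfactorFit:
    """Calibrate predicted MSF to experimental B-factors.

    The scale minimizes Σ (B_exp − c·MSF)², hence
    c = Σ MSF·B_exp / Σ MSF²; the Pearson correlation cc is the quality
    metric; gamma_fitted = (8π²/3)·k_BT/c at 293 K, kcal/(mol·Å²).
    """
    msf = np.asarray(msf, float)
    b_exp = np.asarray(b_exp, float)
    if msf.shape != b_exp.shape or msf.ndim != 1 or len(msf) < 3:
        raise ValueError("msf and b_exp must be equal-length vectors of length >= 3")
    if np.ptp(b_exp) == 0 or np.ptp(msf) == 0:
        raise ValueError(
            "correlation undefined: zero variance in B-factors or predictions"
        )
    scale_c = float(msf @ b_exp / (msf @ msf))
    cc = float(stats.pearsonr(msf, b_exp).statistic)
    gamma_fitted = (8.0 * np.pi**2 / 3.0) * KBT_293K / scale_c
    return BfactorFit(predicted_msf=msf, scale_c=scale_c, gamma_fitted=gamma_fitted, cc=cc)


def mode_convergence_profile(
    matrix: StiffnessMatrix,
    n_list: list[int],
    b_exp: np.ndarray,
    rigid_tol: float = 1e-8,
) -> list[tuple[int, float]]:
    """Correlation coefficient as a function of retained mode count.

    One eigensolve at max(n_list) is truncated for each entry, which is
    exactly equivalent to fresh smaller solves.
    """
    n_list = sorted(set(int(n) for n in n_list))
    if n_list[0] < 1:
        raise ValueError("mode counts must be >= 1")
    full = compute_modes(matrix, n_modes=n_list[-1], rigid_tol=rigid_tol)
    out = []
    for n in n_list:
        msf = mean_square_fluctuations(full.truncated(n))
        out.append((n, fit_bfactors(msf, b_exp).cc))
    return out
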