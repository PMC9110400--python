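"""Mean-field homogenization of the coral skeletal wall.

Two schemes:

* a self-consistent scheme (SCS) for the pristine polycrystal — randomly
  oriented transversely isotropic aragonite needles (aspect ratio ``a``)
  plus spherical organic-filled nano-pores of volume fraction ``phi_np``
  treated as voids; each inclusion is embedded in the yet-unknown effective
  medium, which is isotropised every iteration, and
* a Mori-Tanaka scheme for acidification damage — spherical dissolution
  voids of volume fraction ``phi_oa`` in the converged polycrystal matrix.

Both operate on Mandel 6x6 matrices; results are reported as isotropic
engineering constants (E, nu, k, mu) in GPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inclusion import InclusionSpec, hill_tensor
from .tensor import (
    ElasticTensor,
    isotropic_project,
    rotation_matrix_zyz,
    rotation_operator,
)

__all__ = [
    "CrystalPhase",
    "OrientationGrid",
    "PolycrystalState",
    "enforce_transverse_isotropy",
    "self_consistent_stiffness",
    "mori_tanaka_porous",
    "stiffness_porosity_sweep",
    "concentration_bracket",
]


def enforce_transverse_isotropy(C: ElasticTensor) -> ElasticTensor:
    """Symmetrise an orthorhombic stiffness into transverse isotropy about e3.

    Paired constants are arithmetically averaged:
    C11' = C22' = mean(C11, C22), C13' = C23' = mean(C31, C23),
    C44' = C55' = mean(C44, C55), C12' = C12, C33' = C33,
    and the in-plane shear is closed by C66' = (C11' - C12')/2.
    """
    V = C.voigt
    c11 = 0.5 * (V[0, 0] + V[1, 1])
    c13 = 0.5 * (V[0, 2] + V[1, 2])
    c44 = 0.5 * (V[3, 3] + V[4, 4])
    c12 = V[0, 1]
    c33 = V[2, 2]
    c66 = 0.5 * (c11 - c12)
    out = np.zeros((6, 6))
    out[0, 0] = out[1, 1] = c11
    out[2, 2] = c33
    out[0, 1] = out[1, 0] = c12
    out[0, 2] = out[2, 0] = out[1, 2] = out[2, 1] = c13
    out[3, 3] = out[4, 4] = c44
    out[5, 5] = c66
    ti = ElasticTensor.from_voigt(out, "transverse_isotropic", C.units)
    if not ti.is_positive_definite():
        raise ValueError("transverse-isotropy enforcement lost positive definiteness")
    return ti


def _check_transverse_isotropy(V: np.ndarray, tol: float = 1e-9) -> bool:
    scale = np.abs(V).max()
    return (
        abs(V[0, 0] - V[1, 1]) <= tol * scale
        and abs(V[0, 2] - V[1, 2]) <= tol * scale
        and abs(V[3, 3] - V[4, 4]) <= tol * scale
        and abs(V[5, 5] - 0.5 * (V[0, 0] - V[0, 1])) <= tol * scale
    )


@dataclass
class CrystalPhase:
    """Transversely isotropic aragonite needle phase with nano-porosity."""

    S_Arag: ElasticTensor
    aspect_ratio: float = 10.0
    phi_np: float = 0.039

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi_np < 1.0):
            raise ValueError("phi_np must lie in [0, 1)")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect ratio must be >= 1")
        if not _check_transverse_isotropy(self.S_Arag.voigt):
            raise ValueError(
                "crystal stiffness must be transversely isotropic about e3; "
                "apply enforce_transverse_isotropy first"
            )

    @property
    def inclusion(self) -> InclusionSpec:
        return InclusionSpec("prolate_spheroid", self.aspect_ratio)


@dataclass(frozen=True)
class OrientationGrid:
    """Quadrature over needle orientations on the unit sphere.

    ``theta``/``weight`` integrate f(theta) against sin(theta)/2 dtheta
    (weights sum to 1); ``n_phi`` azimuth nodes carry uniform weight 1/n_phi.
    """

    theta: np.ndarray
    weight: np.ndarray
    n_phi: int = 8

    @classmethod
    def gauss_legendre(cls, n_theta: int = 64, n_phi: int = 8) -> "OrientationGrid":
        x, w = np.polynomial.legendre.leggauss(n_theta)
        return cls(theta=np.arccos(x), weight=w / 2.0, n_phi=n_phi)

    def __post_init__(self) -> None:
        if abs(self.weight.sum() - 1.0) > 1e-10:
            raise ValueError("orientation weights must sum to 1")


@dataclass
class PolycrystalState:
    """Converged self-consistent polycrystal."""

    S_CS: ElasticTensor
    E_poly: float
    nu_poly: float
    k_poly: float
    mu_poly: float
    convergence_residual: float
    n_iterations: int
    quadrature_spec: OrientationGrid = field(repr=False, default=None)
    residual_history: list = field(repr=False, default_factory=list)


def _orientation_rotations(grid: OrientationGrid) -> tuple[np.ndarray, np.ndarray]:
    """6x6 rotation operators and weights for all (theta, phi) nodes."""
    phis = 2.0 * np.pi * np.arange(grid.n_phi) / grid.n_phi
    ops, wts = [], []
    for th, w in zip(grid.theta, grid.weight):
        for ph in phis:
            ops.append(rotation_operator(rotation_matrix_zyz(ph, th, 0.0)))
            wts.append(w / grid.n_phi)
    return np.array(ops), np.array(wts)


def self_consistent_stiffness(
    phase: CrystalPhase,
    grid: OrientationGrid | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> PolycrystalState:
    """Fixed point of the self-consistent polycrystal estimate.

    The orientation-averaged needle term (volume fraction 1 - phi_np, prolate
    Hill tensor) and the spherical nano-pore void term (fraction phi_np) are
    assembled each iteration around the current isotropised effective medium.
    """
    if grid is None:
        grid = OrientationGrid.gauss_legendre()
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    S_A = phase.S_Arag.matrix
    ops, wts = _orientation_rotations(grid)
    S_rot = np.einsum("nij,jk,nlk->nil", ops, S_A, ops)

    # initial guess: isotropic projection of the Voigt orientation average
    voigt_mean = np.einsum("n,nij->ij", wts, S_rot)
    S_cs, _, _, _, _ = isotropic_project(voigt_mean)

    I6 = np.eye(6)
    phi = phase.phi_np
    history: list[float] = []
    residual = np.inf
    for it in range(1, max_iter + 1):
        iso_et = ElasticTensor(S_cs, "isotropic")
        P0 = hill_tensor(iso_et, phase.inclusion)
        P_sph = hill_tensor(iso_et, InclusionSpec("sphere", 1.0))
        P_rot = np.einsum("nij,jk,nlk->nil", ops, P0, ops)
        A = np.linalg.inv(I6 + np.einsum("nij,njk->nik", P_rot, S_rot - S_cs))
        num = (1.0 - phi) * np.einsum("n,nij,njk->ik", wts, S_rot, A)
        den = (1.0 - phi) * np.einsum("n,nij->ij", wts, A)
        if phi > 0:
            den = den + phi * np.linalg.inv(I6 - P_sph @ S_cs)
        S_new = num @ np.linalg.inv(den)
        S_new, E, nu, k, mu = isotropic_project(0.5 * (S_new + S_new.T))
        residual = np.linalg.norm(S_new - S_cs) / np.linalg.norm(S_cs)
        history.append(residual)
        S_cs = S_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"self-consistent scheme did not converge in {max_iter} iterations; "
            f"residual history tail: {history[-5:]}"
        )
    S_iso, E, nu, k, mu = isotropic_project(S_cs)
    out = ElasticTensor(S_iso, "isotropic")
    if not out.is_positive_definite():
        raise RuntimeError(
            "effective stiffness lost positive definiteness (porosity beyond "
            "the self-consistent percolation threshold)"
        )
    return PolycrystalState(out, E, nu, k, mu, residual, it, grid, history)


def concentration_bracket(
    phase: CrystalPhase, S_CS: ElasticTensor, grid: OrientationGrid | None = None
) -> np.ndarray:
    """The bracketed normaliser of the stress-concentration relation:

    D = (1 - phi_np) <A(theta, phi)> + phi_np (II - P_sph S_CS)^{-1},
    A = (II + P_ndl (S_Arag - S_CS))^{-1}, averaged over orientations.
    """
    if grid is None:
        grid = OrientationGrid.gauss_legendre()
    ops, wts = _orientation_rotations(grid)
    S_rot = np.einsum("nij,jk,nlk->nil", ops, phase.S_Arag.matrix, ops)
    S_cs = S_CS.matrix
    P0 = hill_tensor(S_CS, phase.inclusion)
    P_rot = np.einsum("nij,jk,nlk->nil", ops, P0, ops)
    I6 = np.eye(6)
    A = np.linalg.inv(I6 + np.einsum("nij,njk->nik", P_rot, S_rot - S_cs))
    D = (1.0 - phase.phi_np) * np.einsum("n,nij->ij", wts, A)
    if phase.phi_np > 0:
        P_sph = hill_tensor(S_CS, InclusionSpec("sphere", 1.0))
        D = D + phase.phi_np * np.linalg.inv(I6 - P_sph @ S_cs)
    return D


def mori_tanaka_porous(S_CS: ElasticTensor, phi_oa: float) -> ElasticTensor:
    """Mori-Tanaka degradation of the skeleton by spherical dissolution voids.

    S_OA = (1-phi) S_CS : [ (1-phi) II + phi (II - P_sph S_CS)^{-1} ]^{-1};
    exact void limit (pore stiffness zero).
    """
    if not (0.0 <= phi_oa < 1.0):
        raise ValueError("phi_oa must lie in [0, 1)")
    if phi_oa == 0.0:
        return ElasticTensor(S_CS.matrix.copy(), "isotropic", S_CS.units)
    S = S_CS.matrix
    I6 = np.eye(6)
    A_pore = np.linalg.inv(I6 - hill_tensor(S_CS, InclusionSpec("sphere", 1.0)) @ S)
    S_oa = (1.0 - phi_oa) * S @ np.linalg.inv((1.0 - phi_oa) * I6 + phi_oa * A_pore)
    S_iso, _, _, _, _ = isotropic_project(0.5 * (S_oa + S_oa.T))
    return ElasticTensor(S_iso, "isotropic", S_CS.units)


def stiffness_porosity_sweep(
    phase: CrystalPhase,
    phis: np.ndarray,
    mode: str = "phi_np",
    grid: OrientationGrid | None = None,
) -> pd.DataFrame:
    """Sweep porosity and report (phi, E, nu) in GPa.

    mode 'phi_np' varies the intrinsic nano-porosity inside the
    self-consistent scheme; mode 'phi_oa' holds phi_np fixed and varies
    acidification porosity in the Mori-Tanaka scheme.
    """
    phis = np.asarray(phis, dtype=float)
    if np.any(phis < 0) or np.any(phis > 0.9):
        raise ValueError("porosities must lie in [0, 0.9]")
    rows = []
    if mode == "phi_np":
        for p in phis:
            ph = CrystalPhase(phase.S_Arag, phase.aspect_ratio, float(p))
            st = self_consistent_stiffness(ph, grid)
            rows.append((p, st.E_poly, st.nu_poly))
    elif mode == "phi_oa":
        base = self_consistent_stiffness(phase, grid)
        for p in phis:
            S_oa = mori_tanaka_porous(base.S_CS, float(p))
            _, E, nu, _, _ = isotropic_project(S_oa.matrix)
            rows.append((p, E, nu))
    else:
        raise ValueError("mode must be 'phi_np' or 'phi_oa'")
    return pd.DataFrame(rows, columns=["phi", "E_GPa", "nu"])
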