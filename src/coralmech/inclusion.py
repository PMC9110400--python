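"""Eshelby and Hill tensors for spheroidal inclusions in an isotropic matrix.

Closed-form solutions for a prolate spheroid (needle, aspect ratio a >= 1,
symmetry axis along e3) and the sphere limit.  The effective matrix of the
self-consistent scheme is isotropised every iteration, so the isotropic-matrix
forms are exact within that scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor import (
    ElasticTensor,
    ISO_J,
    ISO_K,
    isotropic_project,
    tensor4_to_mandel,
)

__all__ = ["InclusionSpec", "eshelby_tensor", "hill_tensor"]

# switch to the sphere branch when the spheroid formulas become 0/0
_SPHERE_GUARD = 1e-6


@dataclass(frozen=True)
class InclusionSpec:
    """Shape of an ellipsoidal inclusion.

    aspect_ratio is long/short axis; the long axis is e3 (callers rotate).
    """

    shape: str = "prolate_spheroid"
    aspect_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("prolate_spheroid", "sphere"):
            raise ValueError(f"unknown inclusion shape {self.shape!r}")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect ratio must be >= 1")
        if self.shape == "sphere" and abs(self.aspect_ratio - 1.0) > _SPHERE_GUARD:
            raise ValueError("a sphere must have aspect ratio 1")


def _eshelby_sphere(nu: float) -> np.ndarray:
    """Spherical Eshelby tensor: alpha J + beta K (isotropic)."""
    alpha = (1.0 + nu) / (3.0 * (1.0 - nu))
    beta = 2.0 * (4.0 - 5.0 * nu) / (15.0 * (1.0 - nu))
    return alpha * ISO_J + beta * ISO_K


def _eshelby_prolate(nu: float, a: float) -> np.ndarray:
    """Prolate-spheroid Eshelby tensor, symmetry axis e3, aspect ratio a > 1."""
    a2 = a * a
    e = a2 - 1.0
    # shape integral g(a); g -> 2/3 as a -> 1, g -> 0 as a -> inf
    g = a / e ** 1.5 * (a * np.sqrt(e) - np.arccosh(a))
    q = 1.0 / (4.0 * (1.0 - nu))
    nu2 = 1.0 - 2.0 * nu

    S1111 = 1.5 * q * a2 / e + q * (nu2 - 9.0 / (4.0 * e)) * g
    S3333 = 2.0 * q * (nu2 + (3.0 * a2 - 1.0) / e - (nu2 + 3.0 * a2 / e) * g)
    S1122 = q * (a2 / (2.0 * e) - (nu2 + 0.75 / e) * g)
    S1133 = -2.0 * q * a2 / e + q * (3.0 * a2 / e - nu2) * g
    S3311 = -2.0 * q * (nu2 + 1.0 / e) + 2.0 * q * (nu2 + 1.5 / e) * g
    S1212 = q * (a2 / (2.0 * e) + (nu2 - 0.75 / e) * g)
    S1313 = q * (nu2 - (a2 + 1.0) / e - 0.5 * (nu2 - 3.0 * (a2 + 1.0) / e) * g)

    T = np.zeros((3, 3, 3, 3))

    def put(i, j, k, l, val):
        for a_, b_ in ((i, j), (j, i)):
            for c_, d_ in ((k, l), (l, k)):
                T[a_, b_, c_, d_] = val

    put(0, 0, 0, 0, S1111)
    put(1, 1, 1, 1, S1111)
    put(2, 2, 2, 2, S3333)
    put(0, 0, 1, 1, S1122)
    put(1, 1, 0, 0, S1122)
    put(0, 0, 2, 2, S1133)
    put(1, 1, 2, 2, S1133)
    put(2, 2, 0, 0, S3311)
    put(2, 2, 1, 1, S3311)
    put(0, 1, 0, 1, S1212)
    put(0, 2, 0, 2, S1313)
    put(1, 2, 1, 2, S1313)
    return tensor4_to_mandel(T)


def eshelby_tensor(nu_matrix: float, spec: InclusionSpec) -> np.ndarray:
    """Eshelby tensor R (Mandel 6x6, unitless) for the inclusion in an
    isotropic matrix with Poisson ratio nu_matrix.

    The spheroid long axis is e3; rotate the result for other orientations.
    """
    if not 0.0 < nu_matrix < 0.5:
        raise ValueError("matrix Poisson ratio must lie in (0, 0.5)")
    a = spec.aspect_ratio
    if spec.shape == "sphere" or abs(a - 1.0) < _SPHERE_GUARD:
        return _eshelby_sphere(nu_matrix)
    return _eshelby_prolate(nu_matrix, a)


def hill_tensor(S_matrix: ElasticTensor, spec: InclusionSpec) -> np.ndarray:
    """Hill (polarisation) tensor P = R : S_matrix^{-1} (Mandel, 1/GPa).

    The matrix must be isotropic and positive definite; the closed forms do
    not apply to anisotropic media.
    """
    M = S_matrix.matrix if isinstance(S_matrix, ElasticTensor) else np.asarray(S_matrix)
    iso, _, nu, k, mu = isotropic_project(M)
    if np.linalg.norm(M - iso) > 1e-8 * np.linalg.norm(M):
        raise ValueError("hill_tensor requires an isotropic matrix stiffness")
    R = eshelby_tensor(nu, spec)
    S_inv = ISO_J / (3.0 * k) + ISO_K / (2.0 * mu)
    P = R @ S_inv
    return 0.5 * (P + P.T)
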