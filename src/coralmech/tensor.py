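"""Fourth-order tensor algebra in an orthonormal (Mandel) 6-vector basis.

All internal computation uses the Mandel convention, in which a symmetric
second-order tensor S maps to the 6-vector

    [S11, S22, S33, sqrt(2) S23, sqrt(2) S13, sqrt(2) S12]

and a minor-symmetric fourth-order tensor maps to a 6x6 matrix such that
matrix-vector products equal double contractions and matrix inversion equals
tensor inversion.  The engineering (Voigt) convention is supported as an I/O
dialect only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MANDEL_SCALE",
    "ElasticTensor",
    "sym2_to_mandel",
    "mandel_to_sym2",
    "voigt_stiffness_to_mandel",
    "mandel_to_voigt_stiffness",
    "voigt_compliance_to_mandel",
    "mandel_to_voigt_compliance",
    "mandel_to_tensor4",
    "tensor4_to_mandel",
    "identity_tensors",
    "sym_dyad",
    "ISO_J",
    "ISO_K",
    "rotation_matrix_zyz",
    "direction_n",
    "direction_t",
    "rotation_operator",
    "rotate_mandel",
    "isotropic_project",
    "isotropic_stiffness",
    "engineering_constants",
]

#: scale factors turning tensor components into Mandel components
MANDEL_SCALE = np.array([1.0, 1.0, 1.0, np.sqrt(2.0), np.sqrt(2.0), np.sqrt(2.0)])

# index pairs of the Voigt ordering (11, 22, 33, 23, 13, 12)
_VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))


def sym2_to_mandel(S: np.ndarray) -> np.ndarray:
    """Map a symmetric 3x3 tensor to its Mandel 6-vector."""
    S = np.asarray(S, dtype=float)
    return np.array(
        [S[0, 0], S[1, 1], S[2, 2],
         np.sqrt(2) * S[1, 2], np.sqrt(2) * S[0, 2], np.sqrt(2) * S[0, 1]]
    )


def mandel_to_sym2(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`sym2_to_mandel`."""
    v = np.asarray(v, dtype=float)
    s = 1.0 / np.sqrt(2.0)
    return np.array(
        [
            [v[0], s * v[5], s * v[4]],
            [s * v[5], v[1], s * v[3]],
            [s * v[4], s * v[3], v[2]],
        ]
    )


def voigt_stiffness_to_mandel(C: np.ndarray) -> np.ndarray:
    """Voigt stiffness matrix (engineering shear strains) -> Mandel matrix."""
    C = np.asarray(C, dtype=float)
    return C * np.outer(MANDEL_SCALE, MANDEL_SCALE)


def mandel_to_voigt_stiffness(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    return C / np.outer(MANDEL_SCALE, MANDEL_SCALE)


def voigt_compliance_to_mandel(S: np.ndarray) -> np.ndarray:
    """Voigt engineering compliance (gamma = 2*eps shear rows) -> Mandel."""
    S = np.asarray(S, dtype=float)
    # engineering compliance carries factors 2 (mixed rows) and 4 (shear-shear)
    # relative to tensor components; Mandel carries sqrt(2) and 2
    g = MANDEL_SCALE / np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
    return S * np.outer(g, g)


def mandel_to_voigt_compliance(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    return S * np.outer(MANDEL_SCALE, MANDEL_SCALE)


def mandel_to_tensor4(M: np.ndarray) -> np.ndarray:
    """Expand a Mandel 6x6 matrix into the full 3x3x3x3 component array."""
    M = np.asarray(M, dtype=float)
    T = np.zeros((3, 3, 3, 3))
    for I, (i, j) in enumerate(_VOIGT_PAIRS):
        for J, (k, l) in enumerate(_VOIGT_PAIRS):
            val = M[I, J] / (MANDEL_SCALE[I] * MANDEL_SCALE[J])
            for a, b in ((i, j), (j, i)):
                for c, d in ((k, l), (l, k)):
                    T[a, b, c, d] = val
    return T


def tensor4_to_mandel(T: np.ndarray) -> np.ndarray:
    """Contract a minor-symmetric 3x3x3x3 array to its Mandel 6x6 matrix."""
    T = np.asarray(T, dtype=float)
    M = np.zeros((6, 6))
    for I, (i, j) in enumerate(_VOIGT_PAIRS):
        for J, (k, l) in enumerate(_VOIGT_PAIRS):
            M[I, J] = T[i, j, k, l] * MANDEL_SCALE[I] * MANDEL_SCALE[J]
    return M


# ---------------------------------------------------------------------------
# special tensors
# ---------------------------------------------------------------------------

_I6 = np.eye(6)
_IDENTITY2 = sym2_to_mandel(np.eye(3))
#: volumetric projector J = (I x I)/3
ISO_J = np.outer(_IDENTITY2, _IDENTITY2) / 3.0
#: deviatoric projector K = II - J
ISO_K = _I6 - ISO_J


def sym_dyad(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Symmetrised dyadic product (A ob B)_ijkl = (A_ik B_jl + A_il B_jk)/2.

    Input are symmetric 3x3 tensors; output is the Mandel 6x6 matrix.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    T = 0.5 * (
        np.einsum("ik,jl->ijkl", A, B) + np.einsum("il,jk->ijkl", A, B)
    )
    # symmetrise the first index pair as well (needed when A != B)
    T = 0.5 * (T + np.transpose(T, (1, 0, 2, 3)))
    return tensor4_to_mandel(T)


def identity_tensors() -> tuple[np.ndarray, np.ndarray, object]:
    """Return (symmetric identity II, dyad IxI, sym-dyad constructor).

    All as Mandel 6x6 matrices; II_ijkl = (d_ik d_jl + d_il d_jk)/2.
    """
    return _I6.copy(), np.outer(_IDENTITY2, _IDENTITY2), sym_dyad


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

def rotation_matrix_zyz(phi: float, theta: float, psi: float = 0.0) -> np.ndarray:
    """Intrinsic Z-Y-Z Euler rotation: Rz(phi) @ Ry(theta) @ Rz(psi).

    Maps the crystal 3-axis onto n(phi, theta) =
    (sin th cos ph, sin th sin ph, cos th); psi is spin about n.
    """
    if not np.all(np.isfinite([phi, theta, psi])):
        raise ValueError("rotation angles must be finite")
    cf, sf = np.cos(phi), np.sin(phi)
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(psi), np.sin(psi)
    Rz1 = np.array([[cf, -sf, 0], [sf, cf, 0], [0, 0, 1]])
    Ry = np.array([[ct, 0, st], [0, 1, 0], [-st, 0, ct]])
    Rz2 = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]])
    return Rz1 @ Ry @ Rz2


def direction_n(phi: float, theta: float) -> np.ndarray:
    """Needle long-axis unit vector n(phi, theta)."""
    return np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def direction_t(phi: float, theta: float, psi: float) -> np.ndarray:
    """Unit vector orthogonal to n, spun by psi about n."""
    return rotation_matrix_zyz(phi, theta, psi) @ np.array([1.0, 0.0, 0.0])


# Mandel basis matrices E_I, used to assemble the 6x6 rotation operator
_E_BASIS = [mandel_to_sym2(row) for row in np.eye(6)]


def rotation_operator(R: np.ndarray) -> np.ndarray:
    """6x6 orthogonal operator Q with (R S R^T) = Q @ mandel(S).

    Rotating a stiffness: C' = Q @ C @ Q.T.
    """
    Q = np.empty((6, 6))
    for J, EJ in enumerate(_E_BASIS):
        rotated = sym2_to_mandel(R @ EJ @ R.T)
        Q[:, J] = rotated
    return Q


def rotate_mandel(M: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Rotate a Mandel 6x6 fourth-order tensor by the 3x3 rotation R."""
    Q = rotation_operator(R)
    return Q @ M @ Q.T


# ---------------------------------------------------------------------------
# isotropic algebra
# ---------------------------------------------------------------------------

def isotropic_stiffness(k: float, mu: float) -> np.ndarray:
    """Mandel stiffness of an isotropic solid with bulk k and shear mu."""
    return 3.0 * k * ISO_J + 2.0 * mu * ISO_K


def engineering_constants(k: float, mu: float) -> tuple[float, float]:
    """(E, nu) from bulk and shear moduli."""
    E = 9.0 * k * mu / (3.0 * k + mu)
    nu = (3.0 * k - 2.0 * mu) / (2.0 * (3.0 * k + mu))
    return E, nu


def isotropic_project(M: np.ndarray) -> tuple[np.ndarray, float, float, float, float]:
    """Project a Mandel stiffness onto the isotropic subspace.

    Returns (isotropic Mandel matrix, E, nu, k, mu).  The projection is
    orthogonal in the Frobenius inner product: 3k = <M, J>, 2mu = <M, K>/5.
    """
    M = np.asarray(M, dtype=float)
    k = float(np.tensordot(M, ISO_J)) / 3.0
    mu = float(np.tensordot(M, ISO_K)) / 10.0
    if k <= 0 or mu <= 0:
        raise ValueError("projection target is not positive definite")
    E, nu = engineering_constants(k, mu)
    return isotropic_stiffness(k, mu), E, nu, k, mu


# ---------------------------------------------------------------------------
# ElasticTensor container
# ---------------------------------------------------------------------------

_SYMMETRY_CLASSES = ("triclinic", "orthorhombic", "transverse_isotropic", "isotropic")


@dataclass
class ElasticTensor:
    """A minor/major-symmetric stiffness or compliance tensor.

    The matrix is stored in the Mandel basis; use the ``voigt`` property or
    :meth:`from_voigt` for the engineering dialect.  Units are GPa for
    stiffness, 1/GPa for compliance (tracked as a tag only).
    """

    matrix: np.ndarray
    symmetry_class: str = "triclinic"
    units: str = "GPa"
    basis_tag: str = field(default="mandel")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (6, 6):
            raise ValueError("expected a 6x6 matrix")
        if self.symmetry_class not in _SYMMETRY_CLASSES:
            raise ValueError(f"unknown symmetry class {self.symmetry_class!r}")
        rel = np.linalg.norm(self.matrix - self.matrix.T) / max(
            np.linalg.norm(self.matrix), 1e-300
        )
        if rel > 1e-10:
            raise ValueError("matrix is not symmetric")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)
        if self.basis_tag != "mandel":
            raise ValueError("internal storage must be Mandel; convert on input")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_voigt(
        cls, C_voigt: np.ndarray, symmetry_class: str = "triclinic", units: str = "GPa"
    ) -> "ElasticTensor":
        return cls(voigt_stiffness_to_mandel(C_voigt), symmetry_class, units)

    @classmethod
    def isotropic(cls, E: float, nu: float, units: str = "GPa") -> "ElasticTensor":
        k = E / (3.0 * (1.0 - 2.0 * nu))
        mu = E / (2.0 * (1.0 + nu))
        return cls(isotropic_stiffness(k, mu), "isotropic", units)

    # -- views -------------------------------------------------------------
    @property
    def voigt(self) -> np.ndarray:
        return mandel_to_voigt_stiffness(self.matrix)

    @property
    def tensor4(self) -> np.ndarray:
        return mandel_to_tensor4(self.matrix)

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix)

    def is_positive_definite(self) -> bool:
        return bool(np.all(self.eigenvalues() > 0))

    # -- algebra -----------------------------------------------------------
    def inv(self) -> "ElasticTensor":
        units = "1/GPa" if self.units == "GPa" else "GPa"
        return ElasticTensor(np.linalg.inv(self.matrix), self.symmetry_class, units)

    def rotate(self, phi: float, theta: float, psi: float = 0.0) -> "ElasticTensor":
        """Rotate by intrinsic Z-Y-Z Euler angles (crystal 3-axis -> n)."""
        R = rotation_matrix_zyz(phi, theta, psi)
        out = rotate_mandel(self.matrix, R)
        trivial = np.allclose(R, np.eye(3), atol=1e-15)
        cls = self.symmetry_class if (trivial or self.symmetry_class == "isotropic") \
            else "triclinic"
        return ElasticTensor(out, cls, self.units)

    def contract(self, other: "np.ndarray | ElasticTensor") -> np.ndarray:
        """Double contraction with a 6x6 Mandel matrix or 6-vector."""
        rhs = other.matrix if isinstance(other, ElasticTensor) else np.asarray(other)
        return self.matrix @ rhs

    # -- I/O ---------------------------------------------------------------
    def to_json(self, path: str | Path, basis: str = "voigt") -> None:
        if basis == "voigt":
            mat = self.voigt
        elif basis == "mandel":
            mat = self.matrix
        else:
            raise ValueError("basis must be 'voigt' or 'mandel'")
        payload = {
            "basis": basis,
            "units": self.units,
            "symmetry_class": self.symmetry_class,
            "matrix": mat.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ElasticTensor":
        payload = json.loads(Path(path).read_text())
        mat = np.asarray(payload["matrix"], dtype=float)
        basis = payload.get("basis", "voigt")
        if basis == "voigt":
            mat = voigt_stiffness_to_mandel(mat)
        elif basis != "mandel":
            raise ValueError(f"unknown basis {basis!r}")
        return cls(
            mat,
            payload.get("symmetry_class", "triclinic"),
            payload.get("units", "GPa"),
        )
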