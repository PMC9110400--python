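"""Independent brute-force oracles used to cross-check the library.

Everything here works on full 3x3x3x3 component arrays with explicit index
loops or einsum contractions — deliberately avoiding the library's Mandel
fast paths — so that agreement is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np

VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))
_SCALE = np.array([1.0, 1.0, 1.0, np.sqrt(2), np.sqrt(2), np.sqrt(2)])


def mandel_to_t4(M: np.ndarray) -> np.ndarray:
    T = np.zeros((3, 3, 3, 3))
    for I, (i, j) in enumerate(VOIGT_PAIRS):
        for J, (k, l) in enumerate(VOIGT_PAIRS):
            v = M[I, J] / (_SCALE[I] * _SCALE[J])
            T[i, j, k, l] = T[j, i, k, l] = T[i, j, l, k] = T[j, i, l, k] = v
    return T


def t4_to_mandel(T: np.ndarray) -> np.ndarray:
    M = np.zeros((6, 6))
    for I, (i, j) in enumerate(VOIGT_PAIRS):
        for J, (k, l) in enumerate(VOIGT_PAIRS):
            M[I, J] = T[i, j, k, l] * _SCALE[I] * _SCALE[J]
    return M


def double_contract_t4(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """C_ijkl = A_ijmn B_mnkl by explicit loops."""
    C = np.zeros((3, 3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    s = 0.0
                    for m in range(3):
                        for n in range(3):
                            s += A[i, j, m, n] * B[m, n, k, l]
                    C[i, j, k, l] = s
    return C


def apply_t4(A: np.ndarray, S: np.ndarray) -> np.ndarray:
    """(A : S)_ij for a symmetric second-order S."""
    return np.einsum("ijkl,kl->ij", A, S)


def invert_t4(T: np.ndarray) -> np.ndarray:
    """Inverse on the space of symmetric second-order tensors via a
    least-squares solve on the 9x9 flattening."""
    I4 = np.zeros((3, 3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    I4[i, j, k, l] = 0.5 * (
                        (i == k) * (j == l) + (i == l) * (j == k)
                    )
    X = np.linalg.lstsq(T.reshape(9, 9), I4.reshape(9, 9), rcond=None)[0]
    return X.reshape(3, 3, 3, 3)


def rotate_t4(T: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Bond transformation by direct index contraction."""
    return np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, T)


def random_sym6(rng: np.random.Generator) -> np.ndarray:
    """Random symmetric positive-definite Mandel matrix."""
    A = rng.normal(size=(6, 6))
    return A @ A.T + 6.0 * np.eye(6)


def hill_quadrature(
    C_t4: np.ndarray, semi_axes: tuple[float, float, float],
    n_theta: int = 128, n_phi: int = 128,
) -> np.ndarray:
    """Hill polarisation tensor of an ellipsoid by angular quadrature of the
    Green-operator integrand over the unit sphere (full tensor, 3x3x3x3)."""
    a1, a2, a3 = semi_axes
    x, w = np.polynomial.legendre.leggauss(n_theta)
    phis = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    P = np.zeros((3, 3, 3, 3))
    for ct, wt in zip(x, w):
        st = np.sqrt(1 - ct * ct)
        for ph in phis:
            xi = np.array([st * np.cos(ph), st * np.sin(ph), ct])
            K = np.einsum("ijkl,j,l->ik", C_t4, xi, xi)
            N = np.linalg.inv(K)
            H = 0.25 * (
                np.einsum("ik,j,l->ijkl", N, xi, xi)
                + np.einsum("jk,i,l->ijkl", N, xi, xi)
                + np.einsum("il,j,k->ijkl", N, xi, xi)
                + np.einsum("jl,i,k->ijkl", N, xi, xi)
            )
            rho = (a1 ** 2 * xi[0] ** 2 + a2 ** 2 * xi[1] ** 2
                   + a3 ** 2 * xi[2] ** 2) ** 1.5
            P += wt * (2 * np.pi / n_phi) * H * (a1 * a2 * a3) / rho
    return P / (4 * np.pi)


def mt_void_scalar(k: float, mu: float, phi: float) -> tuple[float, float]:
    """Scalar Mori-Tanaka spherical-void formulas for (k_eff, mu_eff)."""
    nu = (3 * k - 2 * mu) / (2 * (3 * k + mu))
    alpha = (1 + nu) / (3 * (1 - nu))
    beta = 2 * (4 - 5 * nu) / (15 * (1 - nu))
    k_eff = (1 - phi) * k / ((1 - phi) + phi / (1 - alpha))
    mu_eff = (1 - phi) * mu / ((1 - phi) + phi / (1 - beta))
    return k_eff, mu_eff


def dilute_void_young(E: float, nu: float, phi: float) -> float:
    """Dilute spherical-void estimate of the degraded Young modulus."""
    k = E / (3 * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    alpha = (1 + nu) / (3 * (1 - nu))
    beta = 2 * (4 - 5 * nu) / (15 * (1 - nu))
    k_d = k * (1 - phi / (1 - alpha))
    mu_d = mu * (1 - phi / (1 - beta))
    return 9 * k_d * mu_d / (3 * k_d + mu_d)
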