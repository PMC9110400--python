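"""Interfacial strength upscaling and the porosity-dependent yield surface.

The polycrystal's elastic limit is set by Mohr-Coulomb decohesion of the most
adversely loaded aragonite needle: the needle-average stress follows from the
stress concentration tensor B(phi, theta), its normal/tangential tractions
are maximised over needle orientation (theta) and tangent spin (psi), and the
macroscopic strength is the interfacial tensile strength divided by that
maximal traction combination.  The resulting uniaxial tensile/compressive
strengths parameterise a pressure-sensitive conic (Drucker-Prager-type)
yield surface whose quadric coefficients degrade with acidification porosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .homogenize import CrystalPhase, concentration_bracket, OrientationGrid
from .inclusion import hill_tensor
from .tensor import (
    ElasticTensor,
    ISO_J,
    ISO_K,
    direction_n,
    direction_t,
    mandel_to_sym2,
    rotation_matrix_zyz,
    rotation_operator,
    sym2_to_mandel,
    sym_dyad,
)

__all__ = [
    "InterfaceStrength",
    "StrengthResult",
    "YieldSurface",
    "concentration_tensor",
    "needle_traction",
    "polycrystal_strength",
    "build_yield_surface",
    "strength_porosity_sweep",
]

#: angular increments of the orientation search
DEFAULT_D_THETA = np.pi / 128
DEFAULT_D_PSI = np.pi / 32


@dataclass(frozen=True)
class InterfaceStrength:
    """Interfacial tensile/shear strength of the needle boundary, MPa."""

    sigma_ut: float
    sigma_us: float

    def __post_init__(self) -> None:
        if self.sigma_ut <= 0 or self.sigma_us <= 0:
            raise ValueError("interfacial strengths must be positive")

    @property
    def beta(self) -> float:
        """Tensile-to-shear interfacial strength ratio."""
        return self.sigma_ut / self.sigma_us


@dataclass
class StrengthResult:
    """Polycrystal uniaxial elastic limits (positive magnitudes, MPa)."""

    sigma_ut: float
    sigma_uc: float
    critical_tension: tuple[float, float]
    critical_compression: tuple[float, float]
    d_theta: float = DEFAULT_D_THETA
    d_psi: float = DEFAULT_D_PSI


def concentration_tensor(
    theta: float,
    phase: CrystalPhase,
    S_CS: ElasticTensor,
    grid: OrientationGrid | None = None,
    _bracket_inv: np.ndarray | None = None,
) -> np.ndarray:
    """Stress concentration tensor B(0, theta) of a needle at polar angle
    theta (azimuth fixed to 0 by axisymmetry), Mandel 6x6, unitless.

    sigma_needle = B : Sigma_macro.  The bracketed normaliser (orientation
    average plus nano-pore term) can be precomputed and passed in.
    """
    S_cs = S_CS.matrix
    if _bracket_inv is None:
        _bracket_inv = np.linalg.inv(concentration_bracket(phase, S_CS, grid))
    Q = rotation_operator(rotation_matrix_zyz(0.0, theta, 0.0))
    S_rot = Q @ phase.S_Arag.matrix @ Q.T
    P_rot = Q @ hill_tensor(S_CS, phase.inclusion) @ Q.T
    A = np.linalg.inv(np.eye(6) + P_rot @ (S_rot - S_cs))
    return S_rot @ A @ _bracket_inv @ np.linalg.inv(S_cs)


def needle_traction(
    B: np.ndarray, S_hat: np.ndarray, theta: float, psi: float
) -> tuple[float, float]:
    """Normal and tangential traction on the needle interface.

    S_hat is a unit-Frobenius-norm macroscopic stress direction (3x3
    symmetric); returns (sigma_nn, sigma_nt) = (n.sigma.n, n.sigma.t) with
    n = n(0, theta) and t spun by psi about n.
    """
    S_hat = np.asarray(S_hat, dtype=float)
    if abs(np.linalg.norm(S_hat) - 1.0) > 1e-8:
        raise ValueError("S_hat must have unit Frobenius norm")
    sigma = mandel_to_sym2(B @ sym2_to_mandel(S_hat))
    n = direction_n(0.0, theta)
    t = direction_t(0.0, theta, psi)
    return float(n @ sigma @ n), float(n @ sigma @ t)


def _traction_extremes(
    B: np.ndarray, S_hat: np.ndarray, psis: np.ndarray, theta: float
) -> tuple[float, float]:
    """max over psi of sigma_nn + beta|sigma_nt| needs only (sigma_nn,
    max |sigma_nt|); returns those for one theta."""
    sigma = mandel_to_sym2(B @ sym2_to_mandel(S_hat))
    n = direction_n(0.0, theta)
    nn = float(n @ sigma @ n)
    nts = [abs(n @ sigma @ direction_t(0.0, theta, p)) for p in psis]
    return nn, max(nts)


def polycrystal_strength(
    phase: CrystalPhase,
    S_CS: ElasticTensor,
    iface: InterfaceStrength,
    d_theta: float = DEFAULT_D_THETA,
    d_psi: float = DEFAULT_D_PSI,
    grid: OrientationGrid | None = None,
    polish: bool = True,
) -> StrengthResult:
    """Uniaxial tensile and compressive elastic limits of the polycrystal.

    For loading +/- e3 x e3 the Mohr-Coulomb traction combination
    g(theta, psi) = sigma_nn + beta |sigma_nt| is maximised over the needle
    orientation grid (optionally polished by bounded local refinement); the
    strength is sigma_int_ut / max g.
    """
    beta = iface.beta
    bracket_inv = np.linalg.inv(concentration_bracket(phase, S_CS, grid))
    thetas = np.arange(0.0, np.pi, d_theta)
    psis = np.arange(0.0, 2.0 * np.pi, d_psi)

    e3 = np.zeros((3, 3))
    e3[2, 2] = 1.0

    results = {}
    for label, S_hat in (("tension", e3), ("compression", -e3)):
        B_cache = {}

        def g_of(theta: float) -> tuple[float, float]:
            B = concentration_tensor(
                theta, phase, S_CS, _bracket_inv=bracket_inv
            )
            sigma = mandel_to_sym2(B @ sym2_to_mandel(S_hat))
            n = direction_n(0.0, theta)
            nn = float(n @ sigma @ n)
            # psi-grid maximum of |sigma_nt|
            best_psi, best_nt = 0.0, -np.inf
            for p in psis:
                nt = abs(n @ sigma @ direction_t(0.0, theta, p))
                if nt > best_nt:
                    best_nt, best_psi = nt, p
            return nn + beta * best_nt, best_psi

        g_vals = np.empty_like(thetas)
        psi_stars = np.empty_like(thetas)
        for i, th in enumerate(thetas):
            g_vals[i], psi_stars[i] = g_of(th)
        i_max = int(np.argmax(g_vals))
        g_max, th_star, psi_star = g_vals[i_max], thetas[i_max], psi_stars[i_max]

        if polish:
            lo = max(th_star - d_theta, 0.0)
            hi = min(th_star + d_theta, np.pi)
            res = minimize_scalar(
                lambda th: -g_of(th)[0], bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > g_max:
                g_max, th_star = -res.fun, float(res.x)
                psi_star = g_of(th_star)[1]
        if g_max <= 0:
            raise RuntimeError(
                f"no failing needle orientation under {label}; inputs inconsistent"
            )
        results[label] = (iface.sigma_ut / g_max, th_star, psi_star)

    return StrengthResult(
        sigma_ut=results["tension"][0],
        sigma_uc=results["compression"][0],
        critical_tension=results["tension"][1:],
        critical_compression=results["compression"][1:],
        d_theta=d_theta,
        d_psi=d_psi,
    )


# ---------------------------------------------------------------------------
# quadric yield surface
# ---------------------------------------------------------------------------


@dataclass
class YieldSurface:
    """Porosity-dependent conic yield criterion.

    Y(S) = sqrt(S : FF : S) + F : S - 1, with quadric tensor FF (1/MPa^2),
    linear tensor F (1/MPa), cohesion h (MPa) and friction coefficient T.
    At phi_oa = 0 the criterion is a Drucker-Prager cone through the
    uniaxial tension/compression points used to build it.
    """

    phi_oa: float
    h: float
    T: float
    FF: np.ndarray = field(repr=False)
    F: np.ndarray = field(repr=False)

    def evaluate(self, stress: np.ndarray) -> float:
        """Y at a 3x3 symmetric stress (MPa); negative inside the surface."""
        s = sym2_to_mandel(np.asarray(stress, dtype=float))
        quad = float(s @ self.FF @ s)
        return float(np.sqrt(max(quad, 0.0)) + self.F @ s - 1.0)

    def gradient(self, stress: np.ndarray) -> np.ndarray:
        """dY/dS as a Mandel 6-vector (1/MPa)."""
        s = sym2_to_mandel(np.asarray(stress, dtype=float))
        quad = float(s @ self.FF @ s)
        g = self.F.copy()
        if quad > 1e-30:
            g = g + (self.FF @ s) / np.sqrt(quad)
        return g

    def uniaxial_strength(self, sense: str = "tension") -> float:
        """Positive magnitude solving Y(+/- s e3 x e3) = 0."""
        sgn = 1.0 if sense == "tension" else -1.0
        e3 = np.zeros((3, 3))
        e3[2, 2] = sgn

        def f(s: float) -> float:
            return self.evaluate(s * e3)

        hi = 10.0
        while f(hi) < 0 and hi < 1e9:
            hi *= 2.0
        if f(hi) < 0:
            raise RuntimeError("yield surface unbounded along this axis")
        return float(brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-12))


def build_yield_surface(
    sigma_ut: float, sigma_uc: float, phi_oa: float = 0.0
) -> YieldSurface:
    """Quadric yield surface from pristine uniaxial strengths (MPa).

    h = (2/3) ut*uc/(uc - ut); T = sqrt(6) (uc - ut)/(uc + ut);
    FF = (1 + 2 phi/3)/((1-phi)^2 h^2 T^2) II
         - (1/3 + phi/18)/((1-phi)^2 h^2 T^2) I x I;
    F = I / (3 (1-phi) h).
    """
    if not (0.0 < sigma_ut < sigma_uc):
        raise ValueError("need 0 < sigma_ut < sigma_uc")
    if not (0.0 <= phi_oa < 1.0):
        raise ValueError("phi_oa must lie in [0, 1)")
    h = (2.0 / 3.0) * sigma_ut * sigma_uc / (sigma_uc - sigma_ut)
    T = np.sqrt(6.0) * (sigma_uc - sigma_ut) / (sigma_uc + sigma_ut)
    I2 = np.eye(3)
    denom = (1.0 - phi_oa) ** 2 * h ** 2 * T ** 2
    FF = (1.0 + 2.0 * phi_oa / 3.0) / denom * sym_dyad(I2, I2) \
        - (1.0 / 3.0 + phi_oa / 18.0) / denom * (3.0 * ISO_J)
    F = sym2_to_mandel(I2) / (3.0 * (1.0 - phi_oa) * h)
    return YieldSurface(phi_oa=phi_oa, h=h, T=T, FF=FF, F=F)


def strength_porosity_sweep(
    sigma_ut: float, sigma_uc: float, phis: np.ndarray
) -> pd.DataFrame:
    """Uniaxial strengths vs acidification porosity from the yield surface.

    The baseline strengths embed the intrinsic nano-porosity; phi here is the
    acidification porosity only.
    """
    rows = []
    for p in np.asarray(phis, dtype=float):
        ys = build_yield_surface(sigma_ut, sigma_uc, float(p))
        rows.append((p, ys.uniaxial_strength("tension"),
                     ys.uniaxial_strength("compression")))
    return pd.DataFrame(rows, columns=["phi_oa", "sigma_ut_MPa", "sigma_uc_MPa"])
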