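"""Strain-driven elasto-viscoplastic material point on the conic yield surface.

A desk-scale constitutive driver for the degraded skeleton material
(stiffness from the Mori-Tanaka scheme, strength from the quadric yield
criterion): elastic predictor, backward-Euler return mapping with associative
flow, and a Perzyna-type viscous overstress Y^m / eta governing the plastic
multiplier rate.  eta -> 0 recovers rate-independent plasticity, which is
what every verification check uses; the viscous branch is a documented
regularisation, not a calibrated law.

Stresses are in MPa and strains unitless throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .strength import YieldSurface
from .tensor import ElasticTensor, mandel_to_sym2, sym2_to_mandel

__all__ = ["Material", "MaterialState", "integrate_step", "uniaxial_stress_driver"]

_YTOL = 1e-8


@dataclass(frozen=True)
class Material:
    """Elastic stiffness (Mandel 6x6, MPa) + yield surface at one phi_oa."""

    stiffness: np.ndarray
    surface: YieldSurface

    @classmethod
    def from_gpa(cls, S_OA: ElasticTensor, surface: YieldSurface) -> "Material":
        return cls(S_OA.matrix * 1.0e3, surface)


@dataclass
class MaterialState:
    """Strain/stress state of one material point (Mandel 6-vectors)."""

    material: Material
    strain: np.ndarray = field(default_factory=lambda: np.zeros(6))
    plastic_strain: np.ndarray = field(default_factory=lambda: np.zeros(6))
    kappa: float = 0.0  # accumulated plastic multiplier

    @property
    def stress(self) -> np.ndarray:
        return self.material.stiffness @ (self.strain - self.plastic_strain)

    @property
    def stress_tensor(self) -> np.ndarray:
        return mandel_to_sym2(self.stress)


def _surface_value(ys: YieldSurface, s: np.ndarray) -> float:
    quad = float(s @ ys.FF @ s)
    return float(np.sqrt(max(quad, 0.0)) + ys.F @ s - 1.0)


def _surface_grad(ys: YieldSurface, s: np.ndarray) -> np.ndarray:
    quad = float(s @ ys.FF @ s)
    g = ys.F.copy()
    if quad > 1e-30:
        g = g + (ys.FF @ s) / np.sqrt(quad)
    return g


def integrate_step(
    state: MaterialState,
    d_strain: np.ndarray,
    dt: float = 1.0,
    eta: float = 0.0,
    m: float = 1.0,
) -> MaterialState:
    """Advance the state by a total-strain increment (3x3 symmetric or
    Mandel 6-vector).

    Elastic predictor / plastic corrector: if the trial stress violates the
    yield criterion, the stress returns along the surface normal
    (associative flow); with eta > 0 the plastic multiplier follows the
    Perzyna rate dkappa/dt = <Y>^m / eta, leaving a viscous overstress.
    """
    d = np.asarray(d_strain, dtype=float)
    if d.shape == (3, 3):
        d = sym2_to_mandel(d)
    if dt <= 0.0:
        raise ValueError("time increment must be positive")
    C = state.material.stiffness
    ys = state.material.surface
    strain = state.strain + d
    s_trial = C @ (strain - state.plastic_strain)
    if _surface_value(ys, s_trial) <= _YTOL:
        return replace(state, strain=strain)

    E_scale = float(np.linalg.norm(C)) / 6.0

    def residual(x: np.ndarray) -> np.ndarray:
        s, dlam = x[:6], x[6]
        r = np.empty(7)
        n = _surface_grad(ys, s)
        r[:6] = s - s_trial + dlam * (C @ n)
        Yv = _surface_value(ys, s)
        if eta == 0.0:
            r[6] = Yv * E_scale * 1e-3
        else:
            r[6] = (dlam - dt * max(Yv, 0.0) ** m / eta) * E_scale
        return r

    if eta == 0.0:
        # start from the trial stress scaled toward the surface
        scale = 1.0 / (1.0 + max(_surface_value(ys, s_trial), 0.0))
        x0 = np.concatenate([s_trial * scale, [1e-8]])
    else:
        dlam0 = dt * max(_surface_value(ys, s_trial), 0.0) ** m / eta
        x0 = np.concatenate([s_trial, [dlam0]])
    sol = root(residual, x0, method="hybr", tol=1e-12)
    if not sol.success or (eta == 0.0 and abs(_surface_value(ys, sol.x[:6])) > 1e-6):
        sol = _apex_return(ys, C, s_trial, dt, eta, m)
        if sol is None:
            raise RuntimeError(
                f"return mapping failed: {getattr(sol, 'message', 'apex fallback')}"
            )
    s_new, dlam = sol.x[:6], float(sol.x[6])
    # eps_p += C^{-1}(s_trial - s_new)
    plastic = state.plastic_strain + np.linalg.solve(C, s_trial - s_new)
    return MaterialState(
        material=state.material,
        strain=strain,
        plastic_strain=plastic,
        kappa=state.kappa + dlam,
    )


class _ApexSolution:
    def __init__(self, x):
        self.x = x
        self.success = True


def _apex_return(ys, C, s_trial, dt, eta, m):
    """Purely volumetric return to the cone apex (phi_oa = 0 surfaces only).

    The apex sits at the hydrostatic tension point F : S = 1, i.e.
    S = h I; used when the smooth normal return cannot converge.
    """
    if ys.phi_oa > 1e-12:
        return None
    h = ys.h
    s_apex = sym2_to_mandel(h * np.eye(3))
    d_el = np.linalg.solve(C, s_trial - s_apex)
    dlam = float(np.linalg.norm(d_el))
    return _ApexSolution(np.concatenate([s_apex, [dlam]]))


def uniaxial_stress_driver(
    material: Material,
    strain_max: float,
    n_steps: int = 200,
    sense: str = "compression",
    dt: float = 1.0,
    eta: float = 0.0,
    m: float = 1.0,
    unload_steps: int = 0,
) -> pd.DataFrame:
    """Strain-controlled uniaxial-stress test along e3.

    The axial strain is ramped to +/- strain_max; at each step the (equal)
    lateral strains are iterated so the lateral stresses vanish.  With
    ``unload_steps`` > 0 the ramp reverses afterwards at the same increment.
    Returns a table of (strain_33, stress_33 [MPa], kappa); the limit stress
    is the extreme of the stress column.
    """
    sgn = -1.0 if sense == "compression" else 1.0
    d_ax = sgn * strain_max / n_steps
    state = MaterialState(material)
    rows = [(0.0, 0.0, 0.0)]
    # elastic guess for the lateral contraction ratio
    Cinv = np.linalg.inv(material.stiffness)
    nu_eff = -Cinv[0, 2] / Cinv[2, 2]

    lat_prev = -nu_eff * d_ax
    increments = [d_ax] * n_steps + [-d_ax] * unload_steps
    for d_ax_i in increments:

        def axial_step(d_lat: float) -> MaterialState:
            d = np.zeros(6)
            d[0] = d[1] = d_lat
            d[2] = d_ax_i
            return integrate_step(state, d, dt=dt, eta=eta, m=m)

        def lateral_stress(d_lat: float) -> float:
            return float(axial_step(d_lat).stress[0])

        # bracket around the previous lateral increment
        lo, hi = lat_prev - 5 * abs(d_ax) - 1e-9, lat_prev + 5 * abs(d_ax) + 1e-9
        flo, fhi = lateral_stress(lo), lateral_stress(hi)
        tries = 0
        while flo * fhi > 0 and tries < 8:
            lo, hi = lo - 5 * abs(d_ax), hi + 5 * abs(d_ax)
            flo, fhi = lateral_stress(lo), lateral_stress(hi)
            tries += 1
        if flo * fhi > 0:
            raise RuntimeError("lateral-stress iteration failed to bracket zero")
        d_lat = brentq(lateral_stress, lo, hi, xtol=1e-14)
        state = axial_step(d_lat)
        lat_prev = d_lat
        rows.append((float(state.strain[2]), float(state.stress[2]), state.kappa))
    return pd.DataFrame(rows, columns=["strain_33", "stress_33_MPa", "kappa"])
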