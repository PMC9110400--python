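"""Hollow-cantilever idealisation of a coral branch under current drag.

A branch is modelled as a hollow circular cantilever: a quadratic drag line
load from the sea current bends it, hydrostatic pressure superposes a mean
stress, and acidification enters twice — through the degraded wall material
(stiffness + yield surface at a given dissolution porosity) and through
uniform erosion of the outer wall (thinning).  Euler-Bernoulli closed forms
give tip deflection and extreme-fibre stress; the yield criterion turns the
stress state into a utilisation number (failure at >= 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .strength import YieldSurface
from .tensor import ElasticTensor, isotropic_project

__all__ = ["BeamSpec", "FlowLoad", "BeamResponse", "beam_response",
           "critical_velocity", "compliance_grid"]

#: sea-water density, kg/m^3
SEAWATER_DENSITY = 1027.0


@dataclass(frozen=True)
class BeamSpec:
    """Hollow-cantilever branch geometry (mm) and wall material.

    The thinning depth erodes the outer surface only (the inner radius is
    untouched), mirroring dissolution of the exposed periphery.
    """

    outer_radius: float
    wall_thickness: float
    length: float
    material_stiffness: ElasticTensor  # GPa, isotropic (degraded skeleton)
    yield_surface: YieldSurface  # MPa
    thinning: float = 0.0

    def __post_init__(self) -> None:
        if self.wall_thickness - self.thinning <= 0:
            raise ValueError("thinning exceeds the wall thickness")
        if self.length <= self.outer_radius:
            raise ValueError("length must exceed the outer radius")
        if self.outer_radius <= self.wall_thickness:
            raise ValueError("wall thicker than the outer radius")

    @property
    def r_outer_eff(self) -> float:
        return self.outer_radius - self.thinning

    @property
    def r_inner(self) -> float:
        return self.outer_radius - self.wall_thickness

    @property
    def second_moment(self) -> float:
        """Annulus second moment of area, mm^4."""
        return math.pi / 4.0 * (self.r_outer_eff ** 4 - self.r_inner ** 4)

    @property
    def young_modulus(self) -> float:
        """E of the wall material, GPa."""
        _, E, _, _, _ = isotropic_project(self.material_stiffness.matrix)
        return E


@dataclass(frozen=True)
class FlowLoad:
    """Uniform current perpendicular to the branch axis."""

    speed: float  # m/s
    density: float = SEAWATER_DENSITY  # kg/m^3
    drag_coefficient: float = 1.0  # circular cylinder
    hydrostatic_pressure: float = 0.0  # MPa, superposed mean stress

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("current speed must be non-negative")

    def line_load(self, diameter_mm: float) -> float:
        """Drag line load w = 1/2 rho C_d D v^2, N/mm."""
        D = diameter_mm * 1e-3
        return 0.5 * self.density * self.drag_coefficient * D * self.speed ** 2 * 1e-3


@dataclass
class BeamResponse:
    tip_deflection: float  # mm
    max_bending_stress: float  # MPa
    utilisation: float  # >= 1 means failure
    line_load: float  # N/mm


def beam_response(spec: BeamSpec, load: FlowLoad) -> BeamResponse:
    """Cantilever response to drag + hydrostatic loading.

    delta_tip = w L^4 / (8 E I); sigma_b = (w L^2 / 2) * R_out / I at the
    root; the extreme-fibre stress state diag(-p, -p, sigma_b - p) is fed to
    the yield surface, and utilisation = Y + 1 so failure <=> >= 1.
    """
    if spec.wall_thickness / spec.outer_radius > 0.5:
        pass  # thick-walled: closed forms remain usable, accuracy degrades
    w = load.line_load(2.0 * spec.r_outer_eff)  # N/mm
    L = spec.length
    E = spec.young_modulus * 1e3  # MPa = N/mm^2
    I = spec.second_moment
    delta = w * L ** 4 / (8.0 * E * I)
    M = w * L ** 2 / 2.0  # N*mm
    sigma_b = M * spec.r_outer_eff / I  # MPa
    p = load.hydrostatic_pressure
    stress = np.diag([-p, -p, sigma_b - p])
    utilisation = spec.yield_surface.evaluate(stress) + 1.0
    return BeamResponse(delta, sigma_b, utilisation, w)


def critical_velocity(
    spec: BeamSpec, load: FlowLoad | None = None, cap: float = 30.0
) -> float:
    """Smallest current speed (m/s) at which the root extreme fibre yields.

    Returns inf when no failure occurs below the speed cap.
    """
    base = load or FlowLoad(0.0)

    def util(v: float) -> float:
        lv = FlowLoad(v, base.density, base.drag_coefficient,
                      base.hydrostatic_pressure)
        return beam_response(spec, lv).utilisation - 1.0

    if util(cap) < 0:
        return math.inf
    return float(brentq(util, 0.0, cap, xtol=1e-10))


def compliance_grid(
    material_factory,
    outer_radius: float,
    wall_thickness: float,
    length: float,
    load: FlowLoad,
    phi_values=(0.0, 0.15, 0.3),
    thinning_fractions=(0.0, 1.0 / 3.0, 2.0 / 3.0),
) -> pd.DataFrame:
    """Deflection of the damaged branch normalised on the pristine case.

    ``material_factory(phi_oa) -> (ElasticTensor, YieldSurface)`` supplies
    the degraded wall material; thinning fractions are applied to the wall
    thickness.  The grid emulates the combined porosity x erosion damage
    matrix: compliance must grow monotonically along both axes.
    """
    rows = []
    ref = None
    for phi in phi_values:
        S_oa, ys = material_factory(phi)
        for f in thinning_fractions:
            spec = BeamSpec(outer_radius, wall_thickness, length,
                            S_oa, ys, thinning=f * wall_thickness * 0.999)
            resp = beam_response(spec, load)
            if ref is None:
                ref = resp.tip_deflection
            rows.append((phi, f, resp.tip_deflection,
                         resp.tip_deflection / ref, resp.utilisation))
    return pd.DataFrame(
        rows, columns=["phi_oa", "thinning_fraction", "deflection_mm",
                       "normalised_compliance", "utilisation"]
    )
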