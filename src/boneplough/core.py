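"""Closed-form force laws for ploughing cortical bone with a conical diamond tip.

The tool is modelled as a rigid cone pressed into and dragged across the bone
surface.  Normal force is described three ways — an elastic (Sneddon) conical
contact law, a yield-limited law, a depth-integrated yield law — plus an
empirical power law in indented volume that is actually calibrated from
experiments.  The tangential (ploughing) force follows the normal force through
an orientation-dependent ploughing coefficient: cortical bone is built from
axially oriented osteons, so its shear strength depends on the angle between
the cutting direction and the osteon long axis, modelled as a sinusoid.

Unit system: forces in N, lengths in mm, stresses in MPa (= N/mm²), volumes in
mm³.  Angles at the API boundary are degrees; the sinusoid argument
``C3·θ + θ0`` is evaluated in radians (C3 carries radian-per-degree units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "ToolGeometry",
    "BoneMaterial",
    "IndentationState",
    "NormalForceModel",
    "AnisotropyModel",
    "ForcePrediction",
    "indentation_volume",
    "elastic_normal_force",
    "yield_normal_force",
    "integrated_normal_force",
    "empirical_normal_force",
    "shear_stress",
    "physical_tangential_force",
    "ploughing_coefficient",
    "tangential_force",
]

CONVENTIONS = ("canonical", "literal")


@dataclass(frozen=True)
class ToolGeometry:
    """Geometry of the single-point diamond tool (SPDT).

    Parameters
    ----------
    cone_angle : float
        Full included angle of the diamond tip, degrees.
    phi : float
        Angle between the cone side and the workpiece plane, degrees.  For a
        90° cone, phi = 45° and tan(phi) = 1.
    tip_diameter : float
        Diamond tip diameter, mm.
    shank_diameter, bit_diameter, length : float
        Descriptive shank/bit dimensions, mm; not used in any force law.
    """

    cone_angle: float = 90.0
    phi: float = 45.0
    tip_diameter: float = 2.0
    shank_diameter: float = 9.7
    bit_diameter: float = 11.0
    length: float = 47.0

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 90.0:
            raise ValueError(f"phi must be in (0, 90) degrees, got {self.phi}")
        if self.tip_diameter <= 0:
            raise ValueError("tip_diameter must be positive")

    @property
    def tan_phi(self) -> float:
        return math.tan(math.radians(self.phi))


@dataclass(frozen=True)
class BoneMaterial:
    """Mechanical properties of cortical bone.

    Defaults describe bovine cortical bone: Young's modulus mid-range of the
    reported 10–22 GPa, yield strength at the upper compressive-strength bound,
    and inherent shear strength 3 MPa.

    Parameters
    ----------
    E : float
        Elastic modulus, MPa.
    delta_s : float
        Yield strength, MPa.
    tau_s : float
        Inherent shear strength, MPa.
    properties : dict
        Optional extra property ranges (tensile/compressive strength, density,
        Poisson ratio, ...), units as documented by the data source.
    """

    E: float = 15000.0
    delta_s: float = 150.0
    tau_s: float = 3.0
    properties: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("E", "delta_s", "tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class NormalForceModel:
    """Empirical normal-force power law Fz = C·V^α.

    C is the prefactor (N·mm⁻³ᵅ) and α the dimensionless exponent.  The
    calibrated values for bovine cortical bone are C = 707.53, α = 0.39.
    """

    C: float
    alpha: float
    r_squared: float | None = None
    fit_metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not 0.0 < self.alpha < 3.0:
            raise ValueError(f"alpha must be in (0, 3), got {self.alpha}")
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class AnisotropyModel:
    """Orientation dependence of the ploughing coefficient.

    Canonical form: ``f_p(θ) = C1 + C2·sin(C3·θ + θ0_rad)`` where θ is the
    cutting angle in degrees (angle between feed direction and the osteon long
    axis), C3 converts degrees to radians of sinusoid phase, and θ0 is a phase
    offset carried in degrees.  ``fp0`` records the ploughing coefficient at
    the reference angle θ0.

    ``convention`` selects the operative form: "canonical" evaluates the
    sinusoid directly; "literal" additionally multiplies by fp0 (an alternate
    published form, retained for transparency — it double-counts the reference
    level and does not reproduce the measured coefficients).
    """

    fp0: float
    C1: float
    C2: float
    C3: float
    theta0: float = 0.0
    convention: str = "canonical"

    def __post_init__(self) -> None:
        if self.fp0 <= 0:
            raise ValueError("fp0 must be positive")
        if self.C2 < 0:
            raise ValueError("C2 must be nonnegative (sign convention)")
        if self.C3 <= 0:
            raise ValueError("C3 must be positive")
        if self.convention not in CONVENTIONS:
            raise ValueError(
                f"unknown convention {self.convention!r}; expected one of {CONVENTIONS}"
            )

    def argument(self, theta: float) -> float:
        """Sinusoid phase C3·θ + θ0, in radians, for θ in degrees."""
        return self.C3 * theta + math.radians(self.theta0)


@dataclass(frozen=True)
class IndentationState:
    """Deterministic indentation geometry at depth h for a given tool.

    h: depth (uncut chip thickness), mm; V: indented cone-segment volume, mm³;
    A: horizontal projected contact area entering the yield law, mm²;
    A_p: forward (tool advance direction) projected area, mm²;
    d: indentation diameter at the surface, mm.
    """

    h: float
    V: float
    A: float
    A_p: float
    d: float

    @classmethod
    def from_depth(cls, h: float, tool: ToolGeometry) -> "IndentationState":
        if h < 0:
            raise ValueError(f"depth h must be nonnegative, got {h}")
        t = tool.tan_phi
        return cls(
            h=h,
            V=math.pi * h**3 / (3.0 * t**2),
            A=math.pi * h**2 / (8.0 * t**2),
            A_p=h**2 / t,
            d=2.0 * h / t,
        )


@dataclass(frozen=True)
class ForcePrediction:
    """A joint normal/tangential force prediction.

    Invariant: ``Fp == fp * Fz`` to machine precision.
    """

    Fz: float
    Fp: float
    fp: float
    provenance: dict[str, Any] = field(default_factory=dict)


def indentation_volume(h: float, tool: ToolGeometry = ToolGeometry()) -> float:
    """Volume of the cone segment pressed below the surface, mm³.

    V = π·h³/(3·tan²φ); for the 90° cone (φ = 45°) this reduces to π·h³/3.
    """
    if h < 0:
        raise ValueError(f"depth h must be nonnegative, got {h}")
    return math.pi * h**3 / (3.0 * tool.tan_phi**2)


def elastic_normal_force(
    h: float, mat: BoneMaterial, tool: ToolGeometry = ToolGeometry()
) -> float:
    """Elastic conical-contact normal force (Sneddon): Fz = (2/π)·E·h²·tanφ."""
    if h < 0:
        raise ValueError(f"depth h must be nonnegative, got {h}")
    return (2.0 / math.pi) * mat.E * h**2 * tool.tan_phi


def contact_stiffness_force(
    A: float, mat: BoneMaterial, tool: ToolGeometry = ToolGeometry()
) -> float:
    """Normal force expressed through contact area: Fz = (tanφ/2)·E·A.

    A derivation step only; not used by the calibration pipeline.
    """
    if A < 0:
        raise ValueError("area A must be nonnegative")
    return 0.5 * tool.tan_phi * mat.E * A


def yield_normal_force(
    h: float, mat: BoneMaterial, tool: ToolGeometry = ToolGeometry()
) -> float:
    """Yield-limited normal force: Fz = δs·A with A = π·h²/(8·tan²φ)."""
    if h < 0:
        raise ValueError(f"depth h must be nonnegative, got {h}")
    return mat.delta_s * math.pi * h**2 / (8.0 * tool.tan_phi**2)


def integrated_normal_force(
    h: float, mat: BoneMaterial, tool: ToolGeometry = ToolGeometry()
) -> float:
    """Depth-integrated yield force: Fz = ∫₀ʰ δs·A(h') dh' = π·δs·h³/(24·tan²φ).

    Identically equal to δs·V/(8·tan²φ) with V the indented cone volume.
    """
    if h < 0:
        raise ValueError(f"depth h must be nonnegative, got {h}")
    return math.pi * mat.delta_s * h**3 / (24.0 * tool.tan_phi**2)


def empirical_normal_force(V: float, model: NormalForceModel) -> float:
    """Calibrated power law Fz = C·V^α (monotone, concave for α < 1)."""
    if V < 0:
        raise ValueError(f"volume V must be nonnegative, got {V}")
    return model.C * V**model.alpha


def shear_stress(theta: float, model: AnisotropyModel, mat: BoneMaterial) -> float:
    """Orientation-dependent shear stress τp(θ) = τs·(C1 + C2·sin(C3·θ + θ0))."""
    return mat.tau_s * (model.C1 + model.C2 * math.sin(model.argument(theta)))


def physical_tangential_force(
    h: float,
    theta: float,
    model: AnisotropyModel,
    mat: BoneMaterial,
    tool: ToolGeometry = ToolGeometry(),
) -> float:
    """Tangential force from the forward projected area: Fp = (h²/tanφ)·τp(θ)."""
    if h < 0:
        raise ValueError(f"depth h must be nonnegative, got {h}")
    return (h**2 / tool.tan_phi) * shear_stress(theta, model, mat)


def ploughing_coefficient(theta: float, model: AnisotropyModel) -> float:
    """Ploughing coefficient f_p(θ) = Fp/Fz at cutting angle θ (degrees).

    Under the default "canonical" convention returns
    ``C1 + C2·sin(C3·θ + θ0)``; under "literal" the result is additionally
    multiplied by fp0.
    """
    base = model.C1 + model.C2 * math.sin(model.argument(theta))
    if model.convention == "canonical":
        return base
    if model.convention == "literal":
        return model.fp0 * base
    raise ValueError(f"unknown convention {model.convention!r}")  # pragma: no cover


def tangential_force(
    V: float,
    theta: float,
    nmodel: NormalForceModel,
    amodel: AnisotropyModel,
    legacy_prefactor: bool = False,
) -> ForcePrediction:
    """Predict normal and tangential forces at indented volume V and angle θ.

    Default: Fp = f_p(θ)·Fz with Fz = C·V^α, so the prediction satisfies
    Fp = fp·Fz exactly.  With ``legacy_prefactor=True`` the alternate published
    closed form Fp = fp0·C·(C1 + C2·sin(C3·θ + θ0))·V^α is evaluated instead
    (its fp is then fp0·(C1 + C2·sin(...)), i.e. the "literal" convention).
    """
    Fz = empirical_normal_force(V, nmodel)
    if legacy_prefactor:
        fp = amodel.fp0 * (amodel.C1 + amodel.C2 * math.sin(amodel.argument(theta)))
    else:
        fp = ploughing_coefficient(theta, amodel)
    return ForcePrediction(
        Fz=Fz,
        Fp=fp * Fz,
        fp=fp,
        provenance={
            "normal_force": {"C": nmodel.C, "alpha": nmodel.alpha},
            "anisotropy": {
                "fp0": amodel.fp0,
                "C1": amodel.C1,
                "C2": amodel.C2,
                "C3": amodel.C3,
                "theta0_deg": amodel.theta0,
                "convention": amodel.convention,
            },
            "legacy_prefactor": legacy_prefactor,
            "theta_deg": theta,
            "V_mm3": V,
        },
    )
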