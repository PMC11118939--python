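"""Constitutive cards for every tissue of the lumbar-segment model.

The segment mixes five material classes: orthotropic elastic bone
(trabecular core), orthotropic elastoplastic bone (cortical shell, von
Mises yield at 64 MPa), isotropic elastic tissue (endplates, posterior
block, nucleus pulposus), a Neo-Hookean annulus ground substance, and
tension-only ligaments.  The trabecular longitudinal modulus follows the
density power law E_zz = 4730 * rho^1.56 MPa (rho in g/cm^3), with the
transverse moduli a fixed tenth of the longitudinal one.

Units: N-mm-MPa internally; densities accepted in g/cm^3 or kg/m^3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Tuple

import numpy as np

__all__ = [
    "DensityCard",
    "OrthotropicElastic",
    "IsotropicElastic",
    "PlasticityCard",
    "NeoHookean",
    "LigamentCard",
    "FibreLayerCard",
    "MaterialLibrary",
    "density_to_modulus",
    "transverse_from_longitudinal",
    "neo_hookean_from_linear",
    "default_material_library",
    "LIGAMENT_MODULI",
    "LIGAMENT_AREAS",
]

#: Young's moduli of the six ligament groups [MPa].
LIGAMENT_MODULI: Dict[str, float] = {
    "ALL": 20.0, "PLL": 20.0, "CL": 33.0, "LF": 19.0, "ISS": 12.0, "SSL": 12.0,
}

#: Default ligament cross-section areas [mm^2] (literature-style placeholders;
#: the source model does not state them).
LIGAMENT_AREAS: Dict[str, float] = {
    "ALL": 40.0, "PLL": 20.0, "CL": 36.0, "LF": 40.0, "ISS": 35.0, "SSL": 25.0,
}

#: Uniaxial yield stress of the cortical shell [MPa].
CORTICAL_YIELD = 64.0


@dataclass(frozen=True)
class DensityCard:
    """Volumetric bone density.

    ``rho`` is stored in g/cm^3; pass ``source_units='kg/m^3'`` to convert
    (divide by 1000) on construction.
    """

    rho: float
    source_units: str = "g/cm^3"

    def __post_init__(self):
        if self.source_units == "kg/m^3":
            object.__setattr__(self, "rho", self.rho / 1000.0)
            object.__setattr__(self, "source_units", "g/cm^3")
        elif self.source_units != "g/cm^3":
            raise ValueError(f"unknown density units {self.source_units!r}")
        if not (0.05 <= self.rho <= 2.5):
            raise ValueError(f"density {self.rho} g/cm^3 outside [0.05, 2.5]")


@dataclass(frozen=True)
class OrthotropicElastic:
    """Engineering constants of an orthotropic elastic solid [MPa]."""

    E_xx: float
    E_yy: float
    E_zz: float
    G_xy: float
    G_yz: float
    G_xz: float
    nu_xy: float
    nu_yz: float
    nu_xz: float

    def __post_init__(self):
        for name in ("E_xx", "E_yy", "E_zz", "G_xy", "G_yz", "G_xz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # fail early on a thermodynamically inadmissible card
        np.linalg.cholesky(self.stiffness())

    def compliance(self) -> np.ndarray:
        """6x6 compliance in Voigt order (11, 22, 33, 12, 23, 13).

        The Poisson ratios coupling a transverse direction to the stiff
        longitudinal (z) one are taken as major ratios (referred to E_zz):
        pairing them with the soft transverse moduli instead would make
        the published trabecular cards thermodynamically inadmissible.
        """
        Ex, Ey, Ez = self.E_xx, self.E_yy, self.E_zz
        S = np.zeros((6, 6))
        S[0, 0], S[1, 1], S[2, 2] = 1 / Ex, 1 / Ey, 1 / Ez
        S[0, 1] = S[1, 0] = -self.nu_xy / max(Ex, Ey)
        S[1, 2] = S[2, 1] = -self.nu_yz / max(Ey, Ez)
        S[0, 2] = S[2, 0] = -self.nu_xz / max(Ex, Ez)
        S[3, 3], S[4, 4], S[5, 5] = 1 / self.G_xy, 1 / self.G_yz, 1 / self.G_xz
        return S

    def stiffness(self) -> np.ndarray:
        """6x6 stiffness (inverse of compliance), symmetric positive definite."""
        C = np.linalg.inv(self.compliance())
        return 0.5 * (C + C.T)


@dataclass(frozen=True)
class IsotropicElastic:
    """Isotropic elastic card; ``nu`` up to 0.4999 (near-incompressible)."""

    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError("nu must lie in (-1, 0.5)")

    @property
    def shear_modulus(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def bulk_modulus(self) -> float:
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))

    def stiffness(self) -> np.ndarray:
        lam = self.bulk_modulus - 2.0 * self.shear_modulus / 3.0
        G = self.shear_modulus
        C = np.zeros((6, 6))
        C[:3, :3] = lam
        C[np.arange(3), np.arange(3)] += 2 * G
        C[np.arange(3, 6), np.arange(3, 6)] = G
        return C


@dataclass(frozen=True)
class PlasticityCard:
    """von Mises yield with linear isotropic hardening."""

    yield_stress: float = CORTICAL_YIELD
    hardening_modulus: float = 0.05 * 8000.0  # 5% of cortical E_zz

    def __post_init__(self):
        if self.yield_stress <= 0:
            raise ValueError("yield stress must be positive")
        if self.hardening_modulus < 0:
            raise ValueError("hardening modulus must be non-negative")


@dataclass(frozen=True)
class NeoHookean:
    """Neo-Hookean coefficients with their linear-elastic provenance.

    W = C10 (I1_bar - 3) + (1/D) (J - 1)^2, so mu0 = 2*C10 and K0 = 2/D.
    """

    C10: float
    D: float
    mu0: float
    K0: float
    E: float
    nu: float

    def __post_init__(self):
        if self.C10 <= 0 or self.D <= 0:
            raise ValueError("C10 and D must be positive")


@dataclass(frozen=True)
class LigamentCard:
    """Tension-only uniaxial ligament group."""

    group: str
    E: float
    nu: float = 0.3
    area: float = 30.0
    tension_only: bool = True

    def __post_init__(self):
        if self.group not in LIGAMENT_MODULI:
            raise ValueError(f"unknown ligament group {self.group!r}")
        if self.E != LIGAMENT_MODULI[self.group]:
            raise ValueError(
                f"{self.group} modulus {self.E} != {LIGAMENT_MODULI[self.group]}")
        if self.area <= 0:
            raise ValueError("ligament area must be positive")


@dataclass(frozen=True)
class FibreLayerCard:
    """Annulus fibre membranes: external / internal layer moduli [MPa]."""

    E_external: float = 500.0
    E_internal: float = 300.0
    thickness_external: float = 0.75
    thickness_internal: float = 0.75
    angles_deg: Tuple[float, float] = (30.0, -30.0)


@dataclass
class MaterialLibrary:
    """Map component label -> constitutive card for one degeneration grade."""

    grade: int
    cortical: OrthotropicElastic
    cortical_plasticity: PlasticityCard
    trabecular: OrthotropicElastic
    endplate: IsotropicElastic
    posterior: IsotropicElastic
    nucleus: IsotropicElastic
    annulus: NeoHookean
    fibres: FibreLayerCard
    ligaments: Dict[str, LigamentCard] = field(default_factory=dict)

    def card_for(self, element_set: str):
        """Resolve a mesh element-set name to its card."""
        for prefix, card in (
            ("cortical", self.cortical), ("trabecular", self.trabecular),
            ("endplate", self.endplate), ("posterior", self.posterior),
            ("nucleus", self.nucleus), ("annulus", self.annulus),
            ("fibre", self.fibres),
        ):
            if element_set.startswith(prefix):
                return card
        if element_set.startswith("ligament_"):
            return self.ligaments[element_set.split("_")[1]]
        raise KeyError(element_set)

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), **kw)


def density_to_modulus(rho: DensityCard | float) -> float:
    """Longitudinal trabecular modulus E_zz [MPa] from density [g/cm^3].

    Power law E = 4.730 * rho^1.56 GPa, returned in MPa.
    """
    r = rho.rho if isinstance(rho, DensityCard) else float(rho)
    if r <= 0:
        raise ValueError("density must be positive")
    return 4730.0 * r ** 1.56


def transverse_from_longitudinal(E_zz: float) -> Tuple[float, float]:
    """Transverse trabecular moduli: E_xx = E_yy = 0.1 * E_zz."""
    if E_zz <= 0:
        raise ValueError("E_zz must be positive")
    return 0.1 * E_zz, 0.1 * E_zz


def neo_hookean_from_linear(E: float, nu: float) -> NeoHookean:
    """Neo-Hookean (C10, D) from small-strain (E, nu).

    mu0 = E / (2 (1 + nu)); K0 = E / (3 (1 - 2 nu)); C10 = mu0 / 2; D = 2 / K0.

    The bulk relation uses the standard (1 - 2 nu) denominator: it is the
    unique form that reproduces both published (C10, D) pairs of the annulus
    cards, whereas a (1 + 2 nu) denominator does not.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if not (0.0 <= nu < 0.5):
        raise ValueError("nu must lie in [0, 0.5); D is undefined at nu = 0.5")
    mu0 = E / (2.0 * (1.0 + nu))
    K0 = E / (3.0 * (1.0 - 2.0 * nu))
    return NeoHookean(C10=mu0 / 2.0, D=2.0 / K0, mu0=mu0, K0=K0, E=E, nu=nu)


# Table-derived shear moduli / Poisson ratios of trabecular bone at the two
# reference densities; shear scales linearly with E_zz in between.
_TRAB_REF = {
    0.3: dict(G_xy=27.8, G_yz=48.2, G_xz=48.2),
    0.1: dict(G_xy=5.0, G_yz=8.7, G_xz=8.7),
}
_TRAB_NU = dict(nu_xy=0.3, nu_yz=0.2, nu_xz=0.2)

CORTICAL = OrthotropicElastic(
    E_xx=2667.0, E_yy=2667.0, E_zz=8000.0,
    G_xy=1026.0, G_yz=1539.0, G_xz=1539.0, **_TRAB_NU)


def trabecular_card(rho_g_cm3: float) -> OrthotropicElastic:
    """Trabecular orthotropic card at a given density."""
    E_zz = density_to_modulus(rho_g_cm3)
    E_xx, E_yy = transverse_from_longitudinal(E_zz)
    for ref_rho, G in _TRAB_REF.items():
        if abs(rho_g_cm3 - ref_rho) < 1e-9:
            return OrthotropicElastic(E_xx=E_xx, E_yy=E_yy, E_zz=E_zz,
                                      **G, **_TRAB_NU)
    scale = E_zz / density_to_modulus(0.3)
    G = {k: v * scale for k, v in _TRAB_REF[0.3].items()}
    return OrthotropicElastic(E_xx=E_xx, E_yy=E_yy, E_zz=E_zz, **G, **_TRAB_NU)


def default_material_library(grade) -> MaterialLibrary:
    """Full material library for one of the five degeneration grades.

    Accepts a grade number 1..5 or a ``GradeSpec``.
    """
    from .grading import grade_spec, GradeSpec  # cycle-free: grading imports nothing here at module level

    spec = grade if isinstance(grade, GradeSpec) else grade_spec(int(grade))
    nuc_E, nuc_nu = spec.nucleus
    ann_E, ann_nu = spec.annulus_linear
    return MaterialLibrary(
        grade=spec.grade,
        cortical=CORTICAL,
        cortical_plasticity=PlasticityCard(),
        trabecular=trabecular_card(spec.trabecular_density / 1000.0),
        endplate=IsotropicElastic(E=50.0, nu=0.4),
        posterior=IsotropicElastic(E=3500.0, nu=0.25),
        nucleus=IsotropicElastic(E=nuc_E, nu=nuc_nu),
        annulus=neo_hookean_from_linear(ann_E, ann_nu),
        fibres=FibreLayerCard(),
        ligaments={g: LigamentCard(group=g, E=E, area=LIGAMENT_AREAS[g])
                   for g, E in LIGAMENT_MODULI.items()},
    )
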