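"""Tissue material table and isotropic elastic-constant conversions.

Each material is described by its engineering constants — Young's modulus
``E`` (Pa), Poisson's ratio ``sigma`` and density ``rho`` (kg/m^3) — from
which the plane-strain stiffness constants, the longitudinal (P-wave)
velocity and the acoustic impedance are derived:

    lambda = E*sigma / ((1+sigma)*(1-2*sigma))
    mu     = E / (2*(1+sigma))
    c11    = lambda + 2*mu          (C22 = C11 for an isotropic medium)
    c12    = lambda
    c33    = mu
    c_l    = sqrt(c11 / rho)
    z      = rho * c_l

The built-in table carries the five tissues of the rat-tibia model (skin,
fat, muscle, bone marrow, cortical bone).  The printed fat row is
internally inconsistent: its stated density (1940 kg/m^3) cannot reproduce
its stated velocity and impedance, which both imply a density near
940 kg/m^3.  The row is kept verbatim but flagged; a reconciled variant
with rho = 940 is available and is the default for wave simulations so
that impedance contrasts (which govern interface reflections) match the
published impedance column.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "TissueProperties",
    "longitudinal_velocity",
    "acoustic_impedance",
    "stiffness_constants",
    "builtin_table",
    "consistency_report",
    "materials_from_yaml",
    "materials_to_yaml",
    "IMPEDANCE_PRINT_SCALE",
]

#: The published table prints impedance as Z / 1e5 (kg m^-2 s^-1).
IMPEDANCE_PRINT_SCALE = 1e5


def _check_engineering_constants(E: float, sigma: float, rho: float) -> None:
    if not (E > 0):
        raise ValueError(f"Young's modulus must be positive, got {E!r}")
    if not (rho > 0):
        raise ValueError(f"density must be positive, got {rho!r}")
    if not (0.0 <= sigma < 0.5):
        raise ValueError(f"Poisson's ratio must lie in [0, 0.5), got {sigma!r}")


def stiffness_constants(E: float, sigma: float) -> tuple[float, float, float]:
    """Plane-strain stiffness constants (c11, c12, c33) in Pa.

    c11 = lambda + 2*mu, c12 = lambda, c33 = mu for an isotropic solid.
    """
    if not (E > 0):
        raise ValueError(f"Young's modulus must be positive, got {E!r}")
    if not (0.0 <= sigma < 0.5):
        raise ValueError(f"Poisson's ratio must lie in [0, 0.5), got {sigma!r}")
    lam = E * sigma / ((1.0 + sigma) * (1.0 - 2.0 * sigma))
    mu = E / (2.0 * (1.0 + sigma))
    return (lam + 2.0 * mu, lam, mu)


def longitudinal_velocity(E: float, sigma: float, rho: float) -> float:
    """Bulk P-wave speed sqrt(E*(1-sigma) / (rho*(1+sigma)*(1-2*sigma))) in m/s."""
    _check_engineering_constants(E, sigma, rho)
    c11, _, _ = stiffness_constants(E, sigma)
    return math.sqrt(c11 / rho)


def acoustic_impedance(rho: float, c_l: float) -> float:
    """Characteristic acoustic impedance rho * c_l in kg m^-2 s^-1."""
    if rho < 0 or c_l < 0:
        raise ValueError("density and velocity must be non-negative")
    return rho * c_l


def impedance_printed(z: float) -> float:
    """Impedance on the published display scale (Z / 1e5)."""
    return z / IMPEDANCE_PRINT_SCALE


@dataclass(frozen=True)
class TissueProperties:
    """One material's elastic description with derived wave constants.

    Derived fields (``c11``, ``c12``, ``c33``, ``c_l``, ``z``) are computed
    from ``(E, sigma, rho)`` at construction and always self-consistent.
    ``printed_c_l`` / ``printed_z`` optionally carry published reference
    values; ``flags`` records any inconsistency between the two.
    """

    name: str
    E: float  # Young's modulus, Pa
    sigma: float  # Poisson's ratio
    rho: float  # density, kg/m^3
    c11: float = field(init=False)
    c12: float = field(init=False)
    c33: float = field(init=False)
    c_l: float = field(init=False)  # longitudinal velocity, m/s
    z: float = field(init=False)  # acoustic impedance, kg m^-2 s^-1
    printed_c_l: float | None = None
    printed_z: float | None = None  # on the x1e5 display scale
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_engineering_constants(self.E, self.sigma, self.rho)
        c11, c12, c33 = stiffness_constants(self.E, self.sigma)
        object.__setattr__(self, "c11", c11)
        object.__setattr__(self, "c12", c12)
        object.__setattr__(self, "c33", c33)
        object.__setattr__(self, "c_l", math.sqrt(c11 / self.rho))
        object.__setattr__(self, "z", self.rho * self.c_l)

    @property
    def z_printed(self) -> float:
        return impedance_printed(self.z)

    @property
    def consistent(self) -> bool:
        """True when derived velocity/impedance reproduce any printed values."""
        ok = True
        if self.printed_c_l is not None:
            ok &= abs(self.c_l - self.printed_c_l) <= 0.05
        if self.printed_z is not None:
            ok &= abs(self.z_printed - self.printed_z) <= 0.01
        return ok


# Published rat-tibia tissue table: (name, E in GPa, sigma, rho, printed C_l, printed Z).
_TABLE_ROWS = [
    ("skin", 0.000035, 0.499998, 1050.0, 1666.67, 17.50),
    ("fat", 0.000035, 0.499997, 1940.0, 1462.84, 13.75),
    ("muscle", 0.000012, 0.4999993, 1040.0, 1657.48, 17.24),
    ("bone marrow", 0.002, 0.49985, 1020.0, 1476.32, 15.06),
    ("cortical bone", 15.0, 0.37, 1970.0, 3669.74, 72.29),
]

#: Density implied by the fat row's printed velocity and impedance
#: (13.75e5 / 1462.84 = 940 kg/m^3); the printed 1940 reproduces neither.
FAT_RECONCILED_RHO = 940.0


def _fat_reconciled_modulus(sigma: float, rho: float, c_l: float) -> float:
    # E such that the plane-strain P-wave speed equals the target c_l
    return c_l * c_l * rho * (1.0 + sigma) * (1.0 - 2.0 * sigma) / (1.0 - sigma)


def builtin_table(variant: str = "verbatim") -> list[TissueProperties]:
    """The five-tissue material table.

    variant="verbatim" returns the published rows unchanged (the fat row is
    flagged inconsistent).  variant="reconciled" replaces the fat density
    with 940 kg/m^3 and rescales its modulus so the derived velocity and
    impedance match the published 1462.84 m/s and 13.75 (x1e5); all other
    rows are identical in both variants.
    """
    if variant not in ("verbatim", "reconciled"):
        raise ValueError(f"unknown table variant {variant!r}")
    out: list[TissueProperties] = []
    for name, e_gpa, sigma, rho, p_cl, p_z in _TABLE_ROWS:
        E = e_gpa * 1e9
        flags: tuple[str, ...] = ()
        if name == "fat":
            if variant == "reconciled":
                rho = FAT_RECONCILED_RHO
                E = _fat_reconciled_modulus(sigma, rho, p_cl)
                flags = ("density-reconciled",)
            else:
                flags = ("inconsistent-printed-row",)
        out.append(
            TissueProperties(
                name=name, E=E, sigma=sigma, rho=rho,
                printed_c_l=p_cl, printed_z=p_z, flags=flags,
            )
        )
    return out


def consistency_report(table: list[TissueProperties] | None = None) -> list[dict]:
    """Check each row's derived velocity/impedance against its printed values."""
    if table is None:
        table = builtin_table("verbatim")
    report = []
    for t in table:
        report.append(
            {
                "name": t.name,
                "derived_c_l": t.c_l,
                "printed_c_l": t.printed_c_l,
                "derived_z_printed": t.z_printed,
                "printed_z": t.printed_z,
                "consistent": t.consistent,
            }
        )
    return report


def materials_to_yaml(table: list[TissueProperties]) -> str:
    """Serialize materials as a YAML list of (name, E_GPa, sigma, rho)."""
    rows = [
        {"name": t.name, "E_GPa": t.E / 1e9, "sigma": t.sigma, "rho": t.rho}
        for t in table
    ]
    return yaml.safe_dump({"materials": rows}, sort_keys=False)


def materials_from_yaml(text: str | io.TextIOBase) -> list[TissueProperties]:
    """Load custom materials from YAML produced by :func:`materials_to_yaml`."""
    doc = yaml.safe_load(text)
    rows = doc["materials"] if isinstance(doc, dict) else doc
    return [
        TissueProperties(
            name=r["name"], E=float(r["E_GPa"]) * 1e9,
            sigma=float(r["sigma"]), rho=float(r["rho"]),
        )
        for r in rows
    ]


def material_map(variant: str = "verbatim") -> dict[str, TissueProperties]:
    """Table as a name-keyed dict."""
    return {t.name: t for t in builtin_table(variant)}


def from_velocity(name: str, c_l: float, rho: float, sigma: float = 0.4999) -> TissueProperties:
    """Construct a material with a prescribed P-wave speed.

    Convenience for test media (e.g. a 1500 m/s water-like solid): solves
    for the Young's modulus that yields ``c_l`` at the given density and
    Poisson's ratio.
    """
    E = _fat_reconciled_modulus(sigma, rho, c_l)
    return TissueProperties(name=name, E=E, sigma=sigma, rho=rho)
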