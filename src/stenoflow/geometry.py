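"""Stenosis geometry, blood properties and geometry-derived model coefficients.

The reduced-order pressure-drop models treat a stenosed artery segment as an
axially varying circular tube: an unobstructed vessel of diameter ``D0``
narrowing to a throat diameter ``Ds`` over a lesion of length ``Ls``.  All
model coefficients that depend only on the lumen — the effective length
``La``, the Young viscous coefficient ``Kv``, the Womersley number ``alpha``,
the integral viscous resistance ``Rvc`` and inertance ``Lu`` — live here.

All quantities are SI internally (metres, Pa·s, kg/m³).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "FluidProperties",
    "BLOOD",
    "StenosisGeometry",
    "RadiusProfile",
    "TABLE_FIXTURES",
    "make_fixture",
    "effective_length",
    "kv_young",
    "womersley",
    "kv_itu",
    "make_profile",
    "viscous_resistance",
    "inertance",
    "poiseuille_resistance",
]

LesionType = Literal["axisymmetric", "eccentric"]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood model.

    Parameters
    ----------
    density:
        Mass density ρ in kg/m³.
    dynamic_viscosity:
        Dynamic viscosity μ in Pa·s.
    """

    density: float = 1060.0
    dynamic_viscosity: float = 3.5e-3

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.dynamic_viscosity <= 0:
            raise ValueError("dynamic viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """ν = μ/ρ in m²/s."""
        return self.dynamic_viscosity / self.density


#: Standard blood properties (ρ = 1060 kg/m³, μ = 3.5 mPa·s).  These
#: reproduce the expected Womersley scales: α ≈ 14 for an aortic-calibre
#: vessel (D0 ≈ 5 cm, f = 1 Hz) and α ≈ 1.1 for a coronary calibre (4 mm).
BLOOD = FluidProperties()


@dataclass(frozen=True)
class StenosisGeometry:
    """An idealised stenosed vessel segment with a circular lumen.

    ``eccentricity`` is the fractional offset of the throat lumen centre from
    the vessel axis.  The reduced-order models are area-based, so eccentricity
    is carried as metadata (it does not change any coefficient), but it lets
    downstream reports distinguish eccentric lesions.
    """

    D0: float
    Ds: float
    Ls: float
    lesion_type: LesionType = "axisymmetric"
    eccentricity: float = 0.0
    upstream_length: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.Ds <= self.D0:
            raise ValueError(f"require 0 < Ds <= D0, got Ds={self.Ds}, D0={self.D0}")
        if self.Ls <= 0:
            raise ValueError("Ls must be positive")
        if self.lesion_type not in ("axisymmetric", "eccentric"):
            raise ValueError(f"unknown lesion type {self.lesion_type!r}")
        if self.lesion_type == "axisymmetric" and self.eccentricity != 0.0:
            raise ValueError("axisymmetric lesions must have zero eccentricity")
        if self.upstream_length is None:
            object.__setattr__(self, "upstream_length", 4.0 * self.D0)

    @classmethod
    def from_severity(
        cls,
        D0: float,
        severity: float,
        Ls: float,
        **kwargs,
    ) -> "StenosisGeometry":
        """Build a geometry from the diameter severity S_D = 1 − Ds/D0."""
        if not 0 < severity < 1:
            raise ValueError(f"severity must lie in (0, 1), got {severity}")
        return cls(D0=D0, Ds=D0 * (1.0 - severity), Ls=Ls, **kwargs)

    # -- derived quantities -------------------------------------------------
    @property
    def R0(self) -> float:
        return self.D0 / 2.0

    @property
    def Rs(self) -> float:
        return self.Ds / 2.0

    @property
    def A0(self) -> float:
        """Unobstructed cross-sectional area π D0²/4."""
        return math.pi * self.D0**2 / 4.0

    @property
    def As(self) -> float:
        """Throat cross-sectional area π Ds²/4."""
        return math.pi * self.Ds**2 / 4.0

    @property
    def severity(self) -> float:
        """Diameter severity S_D = 1 − Ds/D0."""
        return 1.0 - self.Ds / self.D0

    @property
    def area_severity(self) -> float:
        """Area severity 1 − As/A0."""
        return 1.0 - self.As / self.A0

    def with_severity(self, severity: float) -> "StenosisGeometry":
        if not 0 < severity < 1:
            raise ValueError(f"severity must lie in (0, 1), got {severity}")
        return replace(self, Ds=self.D0 * (1.0 - severity))

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        """Config-block form with explicit cm units."""
        return {
            "name": self.name,
            "D0_cm": self.D0 * 100.0,
            "Ds_cm": self.Ds * 100.0,
            "Ls_cm": self.Ls * 100.0,
            "lesion_type": self.lesion_type,
            "eccentricity": self.eccentricity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StenosisGeometry":
        D0 = float(d["D0_cm"]) / 100.0
        if "Ds_cm" in d:
            Ds = float(d["Ds_cm"]) / 100.0
        elif "S_D" in d:
            Ds = D0 * (1.0 - float(d["S_D"]))
        else:
            raise KeyError("need either 'Ds_cm' or 'S_D'")
        return cls(
            D0=D0,
            Ds=Ds,
            Ls=float(d["Ls_cm"]) / 100.0,
            lesion_type=d.get("lesion_type", "axisymmetric"),
            eccentricity=float(d.get("eccentricity", 0.0)),
            name=str(d.get("name", "")),
        )


#: Benchmark lesion families: (Ls, D0) in metres plus lesion type.  They span
#: aortic (G1, G3), carotid (G2) and coronary (G4) calibres; G3 is the G1
#: lesion stretched to Ls/D = 8 and G4 is eccentric.
TABLE_FIXTURES: dict[str, dict] = {
    "G1": {"Ls": 0.10, "D0": 0.0508, "lesion_type": "axisymmetric"},
    "G2": {"Ls": 0.01, "D0": 0.00508, "lesion_type": "axisymmetric"},
    "G3": {"Ls": 0.40, "D0": 0.0508, "lesion_type": "axisymmetric"},
    "G4": {"Ls": 0.014, "D0": 0.004, "lesion_type": "eccentric", "eccentricity": 0.5},
}


def make_fixture(name: str, severity: float) -> StenosisGeometry:
    """Build one of the benchmark geometries G1–G4 at a given S_D."""
    try:
        spec = TABLE_FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {sorted(TABLE_FIXTURES)}"
        ) from None
    return StenosisGeometry.from_severity(
        D0=spec["D0"],
        severity=severity,
        Ls=spec["Ls"],
        lesion_type=spec["lesion_type"],
        eccentricity=spec.get("eccentricity", 0.0),
        name=name,
    )


def effective_length(geom: StenosisGeometry) -> float:
    """Effective lesion length La = 0.83·Ls + 1.64·Ds (m).

    Empirical correction of the geometric stenosis length that accounts for
    pressure recovery beyond the throat; used in place of Ls inside the
    viscous coefficient and as the turbulence integral length scale.
    """
    return 0.83 * geom.Ls + 1.64 * geom.Ds


def kv_young(geom: StenosisGeometry) -> float:
    """Young viscous coefficient Kv = 32·(La/D0)·(A0/As)² (dimensionless)."""
    if geom.As <= 0:
        raise ZeroDivisionError("singular geometry: throat area is zero")
    return 32.0 * (effective_length(geom) / geom.D0) * (geom.A0 / geom.As) ** 2


def womersley(geom: StenosisGeometry, fluid: FluidProperties, f: float) -> float:
    """Womersley number α = R0·sqrt(ρ·f/μ) with cyclic frequency f in Hz."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    return geom.R0 * math.sqrt(fluid.density * f / fluid.dynamic_viscosity)


def kv_itu(geom: StenosisGeometry, alpha: float) -> float:
    """Itu viscous correction Kv = 1 + 0.053·(As/A0)·α²."""
    return 1.0 + 0.053 * (geom.As / geom.A0) * alpha**2


# ---------------------------------------------------------------------------
# Radius profiles and the integral coefficients Rvc, Lu
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadiusProfile:
    """Lumen radius R(x) along the lesion, x ∈ [0, Ls].

    ``radius`` is a vectorised callable.  The shape tag records how the
    profile was built; Rvc and Lu depend on it, so it is propagated to
    outputs.
    """

    Ls: float
    radius: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    shape: str = "custom-sampled"

    def __call__(self, x) -> np.ndarray:
        return np.asarray(self.radius(np.asarray(x, dtype=float)))

    @classmethod
    def from_samples(cls, x: np.ndarray, r: np.ndarray) -> "RadiusProfile":
        """Monotone-cubic interpolation of a sampled (x, R) profile."""
        x = np.asarray(x, dtype=float)
        r = np.asarray(r, dtype=float)
        if x.ndim != 1 or x.size < 2 or np.any(np.diff(x) <= 0):
            raise ValueError("x samples must be strictly increasing, length >= 2")
        if np.any(r <= 0):
            raise ValueError("radius samples must be positive")
        interp = PchipInterpolator(x - x[0], r)
        return cls(Ls=float(x[-1] - x[0]), radius=interp, shape="custom-sampled")

    @classmethod
    def from_csv(cls, path) -> "RadiusProfile":
        """Read a two-column CSV (x_m, R_m) with strictly increasing x."""
        rows = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().startswith(("#", "x")):
                    continue
                rows.append((float(row[0]), float(row[1])))
        if len(rows) < 2:
            raise ValueError(f"profile file {path} has fewer than 2 samples")
        arr = np.array(rows)
        return cls.from_samples(arr[:, 0], arr[:, 1])


def make_profile(geom: StenosisGeometry, shape: str = "cosine") -> RadiusProfile:
    """Analytic lumen profile with R(0)=R(Ls)=R0 and minimum Rs at Ls/2.

    ``cosine``:  R(x) = R0 − (R0 − Rs)·(1 − cos 2πx/Ls)/2 (smooth bump).
    ``conical``: linear taper R0 → Rs → R0 with the kink at mid-lesion.
    """
    R0, Rs, Ls = geom.R0, geom.Rs, geom.Ls
    if shape == "cosine":

        def radius(x):
            return R0 - (R0 - Rs) * (1.0 - np.cos(2.0 * np.pi * x / Ls)) / 2.0

    elif shape == "conical":

        def radius(x):
            return R0 - (R0 - Rs) * (1.0 - np.abs(2.0 * x / Ls - 1.0))

    else:
        raise ValueError(f"unknown profile shape {shape!r}")
    return RadiusProfile(Ls=Ls, radius=radius, shape=shape)


def _kernel_integral(profile: RadiusProfile, power: int, rtol: float) -> float:
    """∫ R(x)^(−power) dx by composite Simpson with step-halving control."""
    n = 1000  # intervals; 1001 nodes at the first level
    last = None
    for _ in range(8):
        x = np.linspace(0.0, profile.Ls, n + 1)
        r = profile(x)
        if np.any(r <= 0):
            raise ValueError("radius profile must be positive everywhere")
        val = _simpson(r**-power, x)
        if last is not None and abs(val - last) <= rtol * abs(val):
            return val
        last = val
        n *= 2
    return last


def _simpson(y: np.ndarray, x: np.ndarray) -> float:
    from scipy.integrate import simpson

    return float(simpson(y, x=x))


def viscous_resistance(
    profile: RadiusProfile, fluid: FluidProperties, rtol: float = 1e-8
) -> float:
    """Integral viscous resistance Rvc = (8μ/π)·∫ R(x)⁻⁴ dx (Pa·s/m³).

    Reduces to the Poiseuille resistance 8μLs/(πR0⁴) for a uniform tube.
    """
    return (
        8.0 * fluid.dynamic_viscosity / math.pi * _kernel_integral(profile, 4, rtol)
    )


def inertance(
    profile: RadiusProfile, fluid: FluidProperties, rtol: float = 1e-8
) -> float:
    """Blood inertance Lu = (ρ/π)·∫ R(x)⁻² dx (Pa·s²/m³)."""
    return fluid.density / math.pi * _kernel_integral(profile, 2, rtol)


def poiseuille_resistance(fluid: FluidProperties, length: float, radius: float) -> float:
    """Fully developed laminar resistance 8μL/(πR⁴) of a uniform tube."""
    return 8.0 * fluid.dynamic_viscosity * length / (math.pi * radius**4)
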