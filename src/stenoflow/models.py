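"""Reduced-order trans-stenotic pressure-drop models.

Three algebraic pressure–flow relations are evaluated term by term over one
cycle of a periodic inlet waveform:

* **Young–Tsai** — Δp = (4μKv/πD0³)·Q + (Ktρ/2A0²)(A0/As−1)²·Q|Q|
  + (ρKuL/A0)·dQ/dt, with Kv = 32(La/D0)(A0/As)², Kt = 1.52, Ku = 1.2.
* **Itu** — Δp = Kv·Rvc·Q + (ρKt/2A0²)(A0/As−1)²·Q|Q| + Ku·Lu·dQ/dt
  + Kc·Rvc·Q̄, with Kv = 1 + 0.053(As/A0)α², Kc = 0.0018α², and the
  integral coefficients Rvc, Lu taken along the lumen profile.  The final
  "continuous" component is constant in time and accounts for the phase lag
  between flow and pressure.
* **Proposed** — Δp = (μKv/2πR0³)·Q + Cε·t_ref·Q³/(La·A0³) + (ρKuL/A0)·dQ/dt.
  The cubic term replaces the empirical Q|Q| closure with a turbulent
  kinetic-energy dissipation estimate ε = Cε·u³/ℓ integrated over the lesion
  volume, with integral length scale ℓ = La and an implicit unit-period time
  factor t_ref (the closure assumes a 1 s cycle).  Its prefactor
  Cε = 2·Cm·ν·(1/As − 1/A0)²·S_D/ρ carries the geometry dependence that the
  fixed constant Kt cannot, and vanishes with the stenosis.

The linear (viscous) term of the proposed model is algebraically identical to
the Young–Tsai viscous term: μKv/(2πR0³) = 4μKv/(πD0³).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

from .geometry import (
    FluidProperties,
    RadiusProfile,
    StenosisGeometry,
    effective_length,
    inertance,
    kv_itu,
    kv_young,
    make_profile,
    poiseuille_resistance,
    viscous_resistance,
    womersley,
)
from .waveforms import FlowWaveform

__all__ = [
    "KT_DEFAULT",
    "KU_DEFAULT",
    "CM_DEFAULT",
    "TREF_DEFAULT",
    "CEPSILON_FORMS",
    "PressureDropSeries",
    "cepsilon",
    "young_tsai_dp",
    "itu_dp",
    "proposed_dp",
    "steady_simplification",
    "term_contributions",
]

KT_DEFAULT = 1.52  # empirical turbulence coefficient (Young/Itu)
KU_DEFAULT = 1.2  # empirical inertial coefficient
CM_DEFAULT = 1.0  # dimensional constant in Cε, kg²·s/m⁴
TREF_DEFAULT = 1.0  # unit-period time factor of the dissipation closure, s

#: Admissible readings of the Cε severity factor.  "severity-scaled" is the
#: default (see :func:`cepsilon`); the other two divide or multiply by the
#: full ρ·S_D product.
CEPSILON_FORMS = ("severity-scaled", "severity-divided", "severity-multiplied")

TERM_NAMES = ("viscous", "turbulence", "inertial", "continuous")


@dataclass
class PressureDropSeries:
    """Δp(t) for one model over one cycle, with its per-term breakdown."""

    model: str
    time: np.ndarray
    terms: dict[str, np.ndarray]
    period: float
    coefficients: dict = field(default_factory=dict)

    @property
    def dp(self) -> np.ndarray:
        """Total Δp(t) = sum of the term series (Pa)."""
        return sum(self.terms.values())

    def cycle_mean(self, y: np.ndarray | None = None) -> float:
        y = self.dp if y is None else y
        return float(simpson(y, x=self.time)) / self.period

    @property
    def mean_dp(self) -> float:
        """Cycle-averaged Δp̄ (Pa)."""
        return self.cycle_mean()

    @property
    def mean_abs_dp(self) -> float:
        return self.cycle_mean(np.abs(self.dp))

    def term_means(self, absolute: bool = True) -> dict[str, float]:
        return {
            k: self.cycle_mean(np.abs(v) if absolute else v)
            for k, v in self.terms.items()
        }

    def contributions(self, metric: str = "mean-abs") -> dict[str, float]:
        """Fractional share of each term in the total pressure drop.

        ``mean-abs``      — cycle-average of |term| over the sum of cycle
                            averages of |terms| (default).
        ``at-mean-flow``  — each term evaluated at the steady operating point
                            Q = Q̄, dQ/dt = 0 (the inertial share is zero by
                            construction); this is the point metric used for
                            per-term bar charts at the average velocity.
        """
        if metric == "mean-abs":
            means = self.term_means(absolute=True)
        elif metric == "at-mean-flow":
            means = {k: abs(v) for k, v in self.coefficients["at_mean_flow"].items()}
        else:
            raise ValueError(f"unknown contribution metric {metric!r}")
        total = sum(means.values())
        if total == 0.0:
            return {k: 0.0 for k in means}
        return {k: v / total for k, v in means.items()}

    def to_frame(self, **extra):
        """Tidy per-sample table (t, Q, dQdt, dp_total, per-term columns)."""
        import pandas as pd

        data = {"t": self.time}
        if "flow" in self.coefficients:
            data["Q"] = self.coefficients["flow"]["Q"]
            data["dQdt"] = self.coefficients["flow"]["dQdt"]
        data["dp_total"] = self.dp
        for name in TERM_NAMES:
            data[f"dp_{name}"] = self.terms.get(name, np.zeros_like(self.time))
        df = pd.DataFrame(data)
        df["model"] = self.model
        for k, v in extra.items():
            df[k] = v
        return df


def cepsilon(
    geom: StenosisGeometry,
    fluid: FluidProperties,
    cm: float = CM_DEFAULT,
    form: str = "severity-scaled",
) -> float:
    """Turbulence-dissipation prefactor Cε (kg/m³ in the default form).

    The geometric factor 2·Cm·ν·(1/As − 1/A0)² is combined with the diameter
    severity S_D and the density:

    * ``severity-scaled`` (default): Cε = 2·Cm·ν·(1/As − 1/A0)²·S_D / ρ —
      the severity scales the dissipation up, and dividing by ρ alone leaves
      Cε with density units, the only dimensionally coherent closure of the
      cubic pressure term.
    * ``severity-divided``:   Cε = 2·Cm·ν·(1/As − 1/A0)² / (ρ·S_D)
    * ``severity-multiplied``: Cε = 2·Cm·ν·(1/As − 1/A0)²·ρ·S_D

    Returns 0 exactly when As = A0 (no stenosis, by continuity).
    """
    if form not in CEPSILON_FORMS:
        raise ValueError(f"unknown Cε form {form!r}; choose from {CEPSILON_FORMS}")
    s = geom.severity
    if s == 0.0:
        return 0.0
    base = 2.0 * cm * fluid.kinematic_viscosity * (1.0 / geom.As - 1.0 / geom.A0) ** 2
    if form == "severity-scaled":
        return base * s / fluid.density
    if form == "severity-divided":
        return base / (fluid.density * s)
    return base * fluid.density * s


def _inertial_L(geom: StenosisGeometry, inertial_length: str) -> float:
    if inertial_length == "effective":
        return effective_length(geom)
    if inertial_length == "stenosis":
        return geom.Ls
    raise ValueError(f"unknown inertial length convention {inertial_length!r}")


def _check_open(geom: StenosisGeometry) -> None:
    if geom.As <= 0:
        raise ZeroDivisionError("singular geometry: throat area is zero")


def _series(
    model: str,
    w: FlowWaveform,
    terms_of_q,  # callable (Q, dQdt, Qbar) -> dict of arrays
    coefficients: dict,
    samples_per_cycle: int | None,
) -> PressureDropSeries:
    t = w.time_grid(samples_per_cycle)
    q = w.q(t)
    dq = w.dqdt(t)
    qbar = w.mean_flow
    terms = terms_of_q(q, dq, qbar)
    coefficients = dict(coefficients)
    coefficients["flow"] = {"Q": q, "dQdt": dq, "Qbar": qbar}
    # steady operating point Q = Q̄, dQ/dt = 0, for the point metric
    pt = terms_of_q(np.array([qbar]), np.array([0.0]), qbar)
    coefficients["at_mean_flow"] = {k: float(v[0]) for k, v in pt.items()}
    return PressureDropSeries(
        model=model,
        time=t,
        terms=terms,
        period=w.period,
        coefficients=coefficients,
    )


def young_tsai_dp(
    geom: StenosisGeometry,
    fluid: FluidProperties,
    w: FlowWaveform,
    kt: float = KT_DEFAULT,
    ku: float = KU_DEFAULT,
    inertial_length: str = "effective",
    include_upstream: bool = False,
    samples_per_cycle: int | None = None,
) -> PressureDropSeries:
    """Young–Tsai pressure drop over one cycle."""
    _check_open(geom)
    kv = kv_young(geom)
    cv = 4.0 * fluid.dynamic_viscosity * kv / (np.pi * geom.D0**3)
    if include_upstream:
        cv += poiseuille_resistance(fluid, geom.upstream_length, geom.R0)
    ctq = kt * fluid.density / (2.0 * geom.A0**2) * (geom.A0 / geom.As - 1.0) ** 2
    L = _inertial_L(geom, inertial_length)
    ci = fluid.density * ku * L / geom.A0

    def terms(q, dq, qbar):
        return {
            "viscous": cv * q,
            "turbulence": ctq * q * np.abs(q),
            "inertial": ci * dq,
        }

    coeffs = {
        "Kv": kv, "Kt": kt, "Ku": ku, "L": L, "La": effective_length(geom),
        "include_upstream": include_upstream,
    }
    return _series("young_tsai", w, terms, coeffs, samples_per_cycle)


def itu_dp(
    geom: StenosisGeometry,
    fluid: FluidProperties,
    w: FlowWaveform,
    profile: RadiusProfile | None = None,
    kt: float = KT_DEFAULT,
    ku: float = KU_DEFAULT,
    include_continuous: bool = True,
    include_upstream: bool = False,
    samples_per_cycle: int | None = None,
) -> PressureDropSeries:
    """Itu pressure drop over one cycle (four terms, cosine profile default).

    The Womersley number uses the waveform's cyclic frequency f = 1/T.
    """
    _check_open(geom)
    if profile is None:
        profile = make_profile(geom, "cosine")
    f = 1.0 / w.period
    alpha = womersley(geom, fluid, f)
    kv = kv_itu(geom, alpha)
    kc = 0.0018 * alpha**2
    rvc = viscous_resistance(profile, fluid)
    lu = inertance(profile, fluid)
    cv = kv * rvc
    if include_upstream:
        cv += poiseuille_resistance(fluid, geom.upstream_length, geom.R0)
    ctq = kt * fluid.density / (2.0 * geom.A0**2) * (geom.A0 / geom.As - 1.0) ** 2
    ci = ku * lu

    def terms(q, dq, qbar):
        out = {
            "viscous": cv * q,
            "turbulence": ctq * q * np.abs(q),
            "inertial": ci * dq,
        }
        if include_continuous:
            out["continuous"] = np.full_like(q, kc * rvc * qbar)
        return out

    coeffs = {
        "Kv": kv, "Kt": kt, "Ku": ku, "Kc": kc, "alpha": alpha,
        "Rvc": rvc, "Lu": lu, "profile": profile.shape,
        "include_continuous": include_continuous,
        "include_upstream": include_upstream,
    }
    return _series("itu", w, terms, coeffs, samples_per_cycle)


def proposed_dp(
    geom: StenosisGeometry,
    fluid: FluidProperties,
    w: FlowWaveform,
    ku: float = KU_DEFAULT,
    cm: float = CM_DEFAULT,
    cepsilon_form: str = "severity-scaled",
    t_ref: float = TREF_DEFAULT,
    inertial_length: str = "effective",
    include_upstream: bool = False,
    samples_per_cycle: int | None = None,
) -> PressureDropSeries:
    """Pressure drop from the cubic turbulence-dissipation model.

    The closure assumes a unit (1 s) cycle; a waveform with a different
    period is accepted with a warning since the dissipation term's implicit
    time factor ``t_ref`` stays at 1 s.
    """
    _check_open(geom)
    if abs(w.period - 1.0) > 1e-9:
        warnings.warn(
            "the cubic dissipation closure assumes a 1 s cycle; results for "
            f"period {w.period} s keep t_ref = {t_ref} s",
            stacklevel=2,
        )
    kv = kv_young(geom)
    la = effective_length(geom)
    cv = fluid.dynamic_viscosity * kv / (2.0 * np.pi * geom.R0**3)
    if include_upstream:
        cv += poiseuille_resistance(fluid, geom.upstream_length, geom.R0)
    ce = cepsilon(geom, fluid, cm=cm, form=cepsilon_form)
    ct = ce * t_ref / (la * geom.A0**3)
    L = _inertial_L(geom, inertial_length)
    ci = fluid.density * ku * L / geom.A0

    def terms(q, dq, qbar):
        return {
            "viscous": cv * q,
            "turbulence": ct * q**3,
            "inertial": ci * dq,
        }

    coeffs = {
        "Kv": kv, "Ku": ku, "Cm": cm, "Ceps": ce, "cepsilon_form": cepsilon_form,
        "t_ref": t_ref, "La": la, "L": L, "include_upstream": include_upstream,
    }
    return _series("proposed", w, terms, coeffs, samples_per_cycle)


def steady_simplification(
    geom: StenosisGeometry,
    fluid: FluidProperties,
    cm: float = CM_DEFAULT,
    cepsilon_form: str = "severity-scaled",
    t_ref: float = TREF_DEFAULT,
) -> tuple[float, float]:
    """Steady two-coefficient form Δp(Q) = A·Q + B·Q³ of the proposed model.

    A = μKv/(2πR0³); B = Cε·t_ref/(La·A0³).  For cycle-mean FFR work the
    dynamic model at Q = Q̄ with dQ/dt = 0 reduces exactly to this.
    """
    _check_open(geom)
    a = fluid.dynamic_viscosity * kv_young(geom) / (2.0 * np.pi * geom.R0**3)
    ce = cepsilon(geom, fluid, cm=cm, form=cepsilon_form)
    b = ce * t_ref / (effective_length(geom) * geom.A0**3)
    return a, b


def term_contributions(
    series: PressureDropSeries, metric: str = "mean-abs"
) -> dict[str, float]:
    """Module-level alias of :meth:`PressureDropSeries.contributions`."""
    return series.contributions(metric=metric)
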