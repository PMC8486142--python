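"""Periodic inlet waveforms: velocity/flow signals, derivatives, cycle stats.

Two generators mirror the study conditions:

* :func:`bc1` — the analytic sinusoid u(t) = u0 + A·sin(2πft);
* :func:`bc2_synthetic` — a deterministic physiological pulse (pedestal plus
  a Hann-shaped systolic ejection) standing in for a measured inlet trace.

A waveform carries the vessel inlet area so mean velocity u(t) and volume
flow rate Q(t) = u(t)·A0 are interchangeable.  Derivatives are analytic where
the generator provides them and 4th-order periodic central differences for
sampled data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import simpson

__all__ = ["FlowWaveform", "bc1", "bc2_synthetic", "from_samples", "cycle_stats"]


@dataclass(frozen=True)
class FlowWaveform:
    """A periodic inlet condition.

    ``velocity`` maps time (s, any real value — evaluation wraps by the
    period) to cross-section mean velocity (m/s).  ``velocity_derivative`` is
    the analytic du/dt when available; otherwise finite differences are used.
    """

    period: float
    area: float
    velocity: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    velocity_derivative: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False
    )
    samples_per_cycle: int = 1000
    label: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.samples_per_cycle < 16:
            raise ValueError("samples_per_cycle too small")

    # -- evaluation ---------------------------------------------------------
    def u(self, t) -> np.ndarray:
        return np.asarray(self.velocity(np.asarray(t, dtype=float)))

    def q(self, t) -> np.ndarray:
        """Volume flow rate Q(t) = u(t)·A0 (m³/s)."""
        return self.u(t) * self.area

    def dudt(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.velocity_derivative is not None:
            return np.asarray(self.velocity_derivative(t))
        # 4th-order central difference; periodicity makes the stencil exact
        # to wrap around cycle boundaries.
        h = self.period / (8.0 * self.samples_per_cycle)
        return (
            -self.u(t + 2 * h) + 8 * self.u(t + h) - 8 * self.u(t - h) + self.u(t - 2 * h)
        ) / (12.0 * h)

    def dqdt(self, t) -> np.ndarray:
        """dQ/dt (m³/s²)."""
        return self.dudt(t) * self.area

    # -- cycle statistics ---------------------------------------------------
    def time_grid(self, samples_per_cycle: int | None = None) -> np.ndarray:
        """One full period, endpoint inclusive (odd node count for Simpson)."""
        n = samples_per_cycle or self.samples_per_cycle
        return np.linspace(0.0, self.period, n + 1)

    @property
    def mean_flow(self) -> float:
        """Cycle-mean flow rate Q̄ over exactly one period (m³/s)."""
        t = self.time_grid()
        return float(simpson(self.q(t), x=t)) / self.period

    def stats(self) -> dict[str, float]:
        """{Q̄, max|Q|, mean|dQ/dt|} over one period."""
        t = self.time_grid()
        q = self.q(t)
        dq = self.dqdt(t)
        return {
            "mean_flow": float(simpson(q, x=t)) / self.period,
            "max_abs_flow": float(np.max(np.abs(q))),
            "mean_abs_dqdt": float(simpson(np.abs(dq), x=t)) / self.period,
        }

    # -- scaling / IO -------------------------------------------------------
    def scaled(self, factor: float) -> "FlowWaveform":
        """Pointwise velocity scaling (area unchanged)."""
        base_u, base_du = self.velocity, self.velocity_derivative
        return FlowWaveform(
            period=self.period,
            area=self.area,
            velocity=lambda t: factor * base_u(t),
            velocity_derivative=(
                None if base_du is None else (lambda t: factor * base_du(t))
            ),
            samples_per_cycle=self.samples_per_cycle,
            label=self.label,
            params={**self.params, "scaled_by": factor},
        )

    def to_csv(self, path, quantity: str = "u") -> None:
        """Write one period as two-column CSV, last sample exclusive."""
        t = self.time_grid()[:-1]
        y = self.u(t) if quantity == "u" else self.q(t)
        header = "t_s,u_m_per_s" if quantity == "u" else "t_s,Q_m3_per_s"
        np.savetxt(path, np.column_stack([t, y]), delimiter=",", header=header,
                   comments="")


def cycle_stats(w: FlowWaveform) -> dict[str, float]:
    """Module-level alias of :meth:`FlowWaveform.stats`."""
    return w.stats()


def bc1(
    u0: float,
    amplitude: float,
    f: float = 1.0,
    area: float = 1.0,
    samples_per_cycle: int = 1000,
) -> FlowWaveform:
    """Sinusoidal inlet u(t) = u0 + A·sin(2πft) with analytic derivative."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    if amplitude >= u0:
        warnings.warn(
            "amplitude >= mean velocity: the inlet flow reverses during the cycle",
            stacklevel=2,
        )
    two_pi_f = 2.0 * np.pi * f
    return FlowWaveform(
        period=1.0 / f,
        area=area,
        velocity=lambda t: u0 + amplitude * np.sin(two_pi_f * t),
        velocity_derivative=lambda t: amplitude * two_pi_f * np.cos(two_pi_f * t),
        samples_per_cycle=samples_per_cycle,
        label="BC1",
        params={"u0": u0, "amplitude": amplitude, "f": f},
    )


def bc2_synthetic(
    mean_u: float,
    area: float = 1.0,
    period: float = 1.0,
    peak_factor: float = 1.6,
    systole_fraction: float = 0.35,
    systole_center: float = 0.2,
    harmonics: Sequence[tuple[float, float]] | None = None,
    samples_per_cycle: int = 1000,
) -> FlowWaveform:
    """Deterministic physiological inlet pulse with exactly the given mean.

    Default form: a diastolic pedestal plus a Hann (cos²) systolic ejection
    wave of width ``systole_fraction``·T centred at ``systole_center``·T.
    The peak/mean velocity ratio is ``peak_factor`` (default 1.6, which keeps
    the peak inlet Reynolds number within the pulsatile regime studied — the
    same ≤500 band as the sinusoidal condition at both vessel scales).  The
    shape is C¹ and the derivative is analytic.

    Alternatively pass ``harmonics`` — up to 6 pairs (a_k, b_k) — for a
    Fourier pulse s(τ) = 1 + Σ a_k cos(2πkτ) + b_k sin(2πkτ); the mean is
    normalised to ``mean_u`` by construction.
    """
    if mean_u <= 0:
        raise ValueError("mean velocity must be positive")

    if harmonics is not None:
        if len(harmonics) > 6:
            raise ValueError("at most 6 harmonics")
        coeffs = [(float(a), float(b)) for a, b in harmonics]

        def shape(tau):
            s = np.ones_like(tau)
            for k, (a, b) in enumerate(coeffs, start=1):
                s = s + a * np.cos(2 * np.pi * k * tau) + b * np.sin(2 * np.pi * k * tau)
            return s

        def dshape(tau):
            ds = np.zeros_like(tau)
            for k, (a, b) in enumerate(coeffs, start=1):
                w = 2 * np.pi * k
                ds = ds + w * (-a * np.sin(w * tau) + b * np.cos(w * tau))
            return ds

        params = {"mean_u": mean_u, "period": period, "harmonics": coeffs}
    else:
        if not 1.0 < peak_factor:
            raise ValueError("peak_factor must exceed 1")
        if not 0 < systole_fraction < 1:
            raise ValueError("systole_fraction must lie in (0, 1)")
        w = systole_fraction
        b = (peak_factor - 1.0) / (1.0 - w / 2.0)  # bump height
        a = 1.0 - b * w / 2.0  # pedestal; exact unit mean
        if a <= 0:
            raise ValueError("peak_factor too large for this systole_fraction")
        c = systole_center

        def shape(tau):
            d = (tau - c + 0.5) % 1.0 - 0.5  # periodic distance to the peak
            return np.where(
                np.abs(d) < w / 2.0, a + b * np.cos(np.pi * d / w) ** 2, a
            )

        def dshape(tau):
            d = (tau - c + 0.5) % 1.0 - 0.5
            return np.where(
                np.abs(d) < w / 2.0,
                -b * np.pi / w * np.sin(2.0 * np.pi * d / w),
                0.0,
            )

        params = {
            "mean_u": mean_u,
            "period": period,
            "peak_factor": peak_factor,
            "systole_fraction": w,
            "systole_center": c,
        }

    return FlowWaveform(
        period=period,
        area=area,
        velocity=lambda t: mean_u * shape(np.asarray(t) / period),
        velocity_derivative=lambda t: mean_u / period * dshape(np.asarray(t) / period),
        samples_per_cycle=samples_per_cycle,
        label="BC2",
        params=params,
    )


def from_samples(
    t: np.ndarray,
    values: np.ndarray,
    area: float,
    quantity: str = "u",
    period: float | None = None,
) -> FlowWaveform:
    """Waveform from one sampled period (uniform grid, last sample exclusive).

    Evaluation uses trigonometric (FFT) interpolation, so the derivative is
    spectral; for the smooth periodic signals used here this is at least as
    accurate as 4th-order differences.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size < 8:
        raise ValueError("need at least 8 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-8):
        raise ValueError("samples must be uniformly spaced")
    T = period if period is not None else float(t[-1] - t[0] + dt[0])
    u = values / area if quantity.lower().startswith("q") else values

    n = u.size
    coef = np.fft.rfft(u) / n
    k = np.arange(coef.size)

    def velocity(tt):
        tt = np.asarray(tt, dtype=float)
        phase = np.exp(2j * np.pi * np.outer(tt - t[0], k) / T)
        weights = np.where(k == 0, 1.0, 2.0)
        return np.real(phase @ (weights * coef))

    def velocity_derivative(tt):
        tt = np.asarray(tt, dtype=float)
        phase = np.exp(2j * np.pi * np.outer(tt - t[0], k) / T)
        weights = np.where(k == 0, 1.0, 2.0) * (2j * np.pi * k / T)
        return np.real(phase @ (weights * coef))

    return FlowWaveform(
        period=T,
        area=area,
        velocity=lambda tt: velocity(tt).reshape(np.shape(tt)),
        velocity_derivative=lambda tt: velocity_derivative(tt).reshape(np.shape(tt)),
        samples_per_cycle=max(1000, n),
        label="sampled",
        params={"n_samples": n},
    )


def read_csv(path, area: float) -> FlowWaveform:
    """Read a two-column CSV (t_s, u_m_per_s) or (t_s, Q_m3_per_s)."""
    import csv as _csv

    ts, ys, quantity = [], [], "u"
    with open(path, newline="") as fh:
        for row in _csv.reader(fh):
            if not row:
                continue
            if row[0].strip().lower().startswith("t"):
                if len(row) > 1 and row[1].strip().lower().startswith("q"):
                    quantity = "q"
                continue
            ts.append(float(row[0]))
            ys.append(float(row[1]))
    return from_samples(np.array(ts), np.array(ys), area=area, quantity=quantity)
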