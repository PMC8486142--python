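"""Parameter-sweep orchestration over geometries, severities, inlets, models.

The default manifest mirrors the benchmark study grid: lesion families G1–G4
at diameter severities 50–90%, a sinusoidal (BC1) and a physiological (BC2)
inlet per scale — the long lesion G3 runs under BC1 only — and all three
pressure-drop models.  Every output row carries the complete coefficient set
used, so any number in the table can be audited offline.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .ffr import DEFAULT_REFERENCE_PRESSURE, classification_agreement, classify, ffr as compute_ffr
from .geometry import BLOOD, FluidProperties, make_fixture, make_profile
from .models import (
    PressureDropSeries,
    itu_dp,
    proposed_dp,
    young_tsai_dp,
)
from .waveforms import FlowWaveform, bc1, bc2_synthetic

__all__ = ["SweepManifest", "default_manifest", "run_sweep",
           "report_contributions", "compare_with_reference"]

log = logging.getLogger("stenoflow")

#: BC1 mean inlet velocities (m/s) per benchmark geometry; the sinusoid
#: amplitude is half the mean in both printed conditions, and BC2 matches
#: the mean at each scale.
MEAN_VELOCITY = {"G1": 0.02, "G2": 0.2, "G3": 0.02, "G4": 0.2}

MODEL_FUNCS = {
    "young_tsai": young_tsai_dp,
    "itu": itu_dp,
    "proposed": proposed_dp,
}

COEFF_COLUMNS = ("Kv", "Kt", "Ku", "Kc", "Ceps", "L", "La", "Rvc", "Lu", "alpha")


@dataclass
class SweepManifest:
    """Complete, serialisable description of a sweep run."""

    geometries: list[str] = field(
        default_factory=lambda: ["G1", "G2", "G3", "G4"]
    )
    severities: list[float] = field(
        default_factory=lambda: [0.5, 0.6, 0.7, 0.8, 0.9]
    )
    bcs: list[str] = field(default_factory=lambda: ["BC1", "BC2"])
    models: list[str] = field(
        default_factory=lambda: ["young_tsai", "itu", "proposed"]
    )
    #: geometries restricted to a subset of the BCs
    bc_restrictions: dict = field(default_factory=lambda: {"G3": ["BC1"]})
    mean_velocity_m_per_s: dict = field(default_factory=lambda: dict(MEAN_VELOCITY))
    density_kg_per_m3: float = BLOOD.density
    viscosity_pa_s: float = BLOOD.dynamic_viscosity
    reference_pressure_pa: float = DEFAULT_REFERENCE_PRESSURE
    samples_per_cycle: int = 1000
    profile_shape: str = "cosine"
    cepsilon_form: str = "severity-scaled"
    inertial_length: str = "effective"
    contribution_metric: str = "mean-abs"
    bc2_peak_factor: float = 1.6

    @property
    def fluid(self) -> FluidProperties:
        return FluidProperties(self.density_kg_per_m3, self.viscosity_pa_s)

    def waveform(self, bc: str, geometry: str, area: float) -> FlowWaveform:
        mean_u = self.mean_velocity_m_per_s[geometry]
        if bc == "BC1":
            return bc1(mean_u, mean_u / 2.0, f=1.0, area=area,
                       samples_per_cycle=self.samples_per_cycle)
        if bc == "BC2":
            return bc2_synthetic(mean_u, area=area, period=1.0,
                                 peak_factor=self.bc2_peak_factor,
                                 samples_per_cycle=self.samples_per_cycle)
        if bc == "steady":
            return bc1(mean_u, 0.0, f=1.0, area=area,
                       samples_per_cycle=self.samples_per_cycle)
        raise ValueError(f"unknown boundary condition {bc!r}")

    def cases(self):
        for g in self.geometries:
            allowed = self.bc_restrictions.get(g, self.bcs)
            for s in self.severities:
                for bc in self.bcs:
                    if bc not in allowed:
                        continue
                    yield g, s, bc

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SweepManifest":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls(**data)


def default_manifest() -> SweepManifest:
    return SweepManifest()


def _evaluate(
    manifest: SweepManifest, geometry: str, severity: float, bc: str, model: str
) -> tuple[PressureDropSeries, dict]:
    geom = make_fixture(geometry, severity)
    fluid = manifest.fluid
    w = manifest.waveform(bc, geometry, geom.A0)
    fn = MODEL_FUNCS[model]
    kwargs: dict = {"samples_per_cycle": manifest.samples_per_cycle}
    if model == "itu":
        kwargs["profile"] = make_profile(geom, manifest.profile_shape)
    if model in ("young_tsai", "proposed"):
        kwargs["inertial_length"] = manifest.inertial_length
    if model == "proposed":
        kwargs["cepsilon_form"] = manifest.cepsilon_form
    series = fn(geom, fluid, w, **kwargs)
    return series, {"geom": geom, "waveform": w}


def run_sweep(manifest: SweepManifest | None = None) -> pd.DataFrame:
    """One row per (geometry, severity, bc, model); deterministic.

    Invalid combinations are reported in the row's ``error`` column and the
    sweep continues.
    """
    manifest = manifest or default_manifest()
    log.info(
        "sweep options: cepsilon_form=%s inertial_length=%s "
        "contribution_metric=%s profile=%s",
        manifest.cepsilon_form, manifest.inertial_length,
        manifest.contribution_metric, manifest.profile_shape,
    )
    rows = []
    for geometry, severity, bc in manifest.cases():
        for model in manifest.models:
            row: dict = {
                "geometry": geometry, "S_D": severity, "bc": bc, "model": model,
                "error": "",
            }
            try:
                series, ctx = _evaluate(manifest, geometry, severity, bc, model)
                res = compute_ffr(series.mean_dp, manifest.reference_pressure_pa)
                contrib = series.contributions(manifest.contribution_metric)
                row.update(
                    {
                        "dp_mean_pa": series.mean_dp,
                        "ffr": res.value,
                        "ffr_class": res.category,
                        "ffr_in_range": res.in_range,
                        "Qbar_m3_per_s": series.coefficients["flow"]["Qbar"],
                    }
                )
                for term in ("viscous", "turbulence", "inertial", "continuous"):
                    row[f"frac_{term}"] = contrib.get(term, 0.0)
                    row[f"mean_abs_{term}_pa"] = series.term_means().get(term, 0.0)
                for c in COEFF_COLUMNS:
                    row[c] = series.coefficients.get(c, np.nan)
            except Exception as exc:  # keep sweeping, report per-row
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def report_contributions(
    table: pd.DataFrame, severities: list[float] | float = 0.6
) -> pd.DataFrame:
    """Per-model stacked term fractions at the requested severities."""
    if np.isscalar(severities):
        severities = [float(severities)]
    cols = ["geometry", "S_D", "bc", "model"] + [
        f"frac_{t}" for t in ("viscous", "turbulence", "inertial", "continuous")
    ]
    mask = table["S_D"].isin(severities) & (table["error"] == "")
    return table.loc[mask, cols].reset_index(drop=True)


def compare_with_reference(
    table: pd.DataFrame, reference: pd.DataFrame, model: str = "proposed"
) -> float:
    """Classification error rate of a model against a reference table.

    ``reference`` carries (geometry, S_D, bc) keys plus either an
    ``ffr_reference`` or a ``class_reference`` column (e.g. external CFD).
    """
    sub = table[(table["model"] == model) & (table["error"] == "")]
    merged = sub.merge(reference, on=["geometry", "S_D", "bc"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping cases between results and reference")
    if "class_reference" in merged:
        ref = merged["class_reference"]
    elif "ffr_reference" in merged:
        ref = merged["ffr_reference"].map(classify)
    else:
        raise KeyError("reference needs 'ffr_reference' or 'class_reference'")
    return classification_agreement(merged["ffr_class"], ref)
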