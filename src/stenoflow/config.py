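"""Phantom, flow, injection, acquisition and transport-model configuration.

Every physical constant of the bench experiment lives here as a dataclass
default: a 50 cm PVC hose of 10 mm inner diameter with a 4 mm long stenotic
segment (2/4/6 mm inner diameter, i.e. 80/60/40 % diameter stenosis), a
solenoid valve producing an 800 ms cycle (500 ms open at 25 ml/s, 300 ms
closed), a 20 ml contrast bolus injected over 1 s through a sheath 15 cm
proximal to the stenosis, and flat-detector acquisition at 30 frames/s for
at least 10 s.  All of them can be overridden programmatically or through a
YAML config file (see :func:`ExperimentConfig.from_yaml`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "PhantomGeometry",
    "FlowProgram",
    "InjectionProtocol",
    "AcquisitionSettings",
    "TransportModel",
    "ExperimentConfig",
    "GRADE_TO_DIAMETER",
]

#: Diameter stenosis grade (%) -> stenotic inner diameter (mm) for the
#: four bench models (no stenosis = full 10 mm lumen).
GRADE_TO_DIAMETER = {0: 10.0, 40: 6.0, 60: 4.0, 80: 2.0}


@dataclass
class PhantomGeometry:
    """Straight tube with a short concentric stenosis at the axial origin.

    The axial coordinate is in mm with its origin at the stenosis centre
    and flow in +x; the contrast sheath sits at ``injection_offset``
    (negative = proximal).
    """

    tube_length: float = 500.0
    inner_diameter: float = 10.0
    wall_thickness: float = 2.0
    stenosis_inner_diameter: float = 10.0
    stenosis_length: float = 4.0
    stenosis_center: float = 0.0
    injection_offset: float = -150.0

    def __post_init__(self) -> None:
        if not 0.0 < self.stenosis_inner_diameter <= self.inner_diameter:
            raise ValueError(
                "stenosis_inner_diameter must be in (0, inner_diameter]; "
                "a fully occluded tube is not modelled"
            )
        if self.stenosis_length <= 0:
            raise ValueError("stenosis_length must be positive")
        if self.injection_offset >= self.stenosis_center - self.stenosis_length / 2:
            raise ValueError("injection site must lie proximal to the stenosis")
        if self.tube_length <= 0:
            raise ValueError("tube_length must be positive")

    @property
    def grade_pct(self) -> float:
        """Diameter stenosis grade in percent (80/60/40/0 for the bench models)."""
        return 100.0 * (1.0 - self.stenosis_inner_diameter / self.inner_diameter)

    @property
    def lumen_area(self) -> float:
        """Nominal lumen cross-section in mm^2."""
        return np.pi * (self.inner_diameter / 2.0) ** 2

    @property
    def stenosis_area(self) -> float:
        """Stenotic lumen cross-section in mm^2."""
        return np.pi * (self.stenosis_inner_diameter / 2.0) ** 2

    def radius_at(self, x: np.ndarray) -> np.ndarray:
        """Local lumen radius (mm) at axial positions ``x`` (mm)."""
        x = np.asarray(x, dtype=float)
        r = np.full(x.shape, self.inner_diameter / 2.0)
        half = self.stenosis_length / 2.0
        inside = np.abs(x - self.stenosis_center) < half
        r[inside] = self.stenosis_inner_diameter / 2.0
        return r

    @classmethod
    def for_grade(cls, grade_pct: int, **overrides) -> "PhantomGeometry":
        """Geometry of one of the four bench models (grade 0/40/60/80 %)."""
        try:
            d = GRADE_TO_DIAMETER[int(grade_pct)]
        except KeyError:
            raise ValueError(f"unknown stenosis grade {grade_pct!r}; expected 0/40/60/80")
        return cls(stenosis_inner_diameter=d, **overrides)


@dataclass
class FlowProgram:
    """Square-wave pulsatile flow produced by the solenoid valve.

    ``open_phase_flow`` is the regulated flow with no stenosis in line;
    placing a stenotic hose behind the valve reduces the delivered flow.
    The reduction is modelled as an orifice-type quadratic resistance:

        Q_delivered = Q_open / (1 + k * ((A0/As)**2 - 1))

    with ``k = resistance_coeff``, A0 the nominal and As the stenotic lumen
    area, so the nonstenotic model is unaffected (As = A0).
    """

    open_phase_flow: float = 25.0  # ml/s while the valve is open
    cycle_duration: float = 0.8  # s
    open_duration: float = 0.5  # s
    closed_duration: float = 0.3  # s
    resistance_coeff: float = 0.002  # dimensionless orifice-resistance constant

    def __post_init__(self) -> None:
        if abs(self.open_duration + self.closed_duration - self.cycle_duration) > 1e-9:
            raise ValueError("open_duration + closed_duration must equal cycle_duration")
        if self.open_phase_flow <= 0:
            raise ValueError("open_phase_flow must be positive")
        if self.resistance_coeff < 0:
            raise ValueError("resistance_coeff must be non-negative")

    def reduction_factor(self, geometry: PhantomGeometry) -> float:
        """Flow scale factor for a given stenosis (1.0 for no stenosis)."""
        ratio = (geometry.lumen_area / geometry.stenosis_area) ** 2
        return 1.0 / (1.0 + self.resistance_coeff * (ratio - 1.0))

    def valve_flow(self, t: float, geometry: PhantomGeometry) -> float:
        """Valve-driven flow (ml/s) at time ``t`` (open/closed square wave)."""
        phase = t % self.cycle_duration
        q = self.open_phase_flow if phase < self.open_duration else 0.0
        return q * self.reduction_factor(geometry)


@dataclass
class InjectionProtocol:
    """Contrast bolus delivered by the power injector.

    ``contrast_attenuation_coefficient`` converts projected contrast path
    length into detector gray value: gray = coefficient * integral of the
    contrast volume fraction along the X-ray path (mm of equivalent pure
    contrast).  Gray values are arbitrary units; 500/mm keeps the peak of
    a default run in comfortable 16-bit range.
    """

    volume: float = 20.0  # ml
    duration: float = 1.0  # s
    start_time: float = 0.5  # s after acquisition start
    contrast_attenuation_coefficient: float = 500.0  # gray value per mm pure contrast

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("volume must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def rate(self) -> float:
        """Injection rate in ml/s."""
        return self.volume / self.duration


@dataclass
class AcquisitionSettings:
    """Detector geometry, frame rate and noise model.

    ``noise_sd`` is the SD of additive Gaussian detector noise in gray
    values; ``None`` selects 2 % of the peak noise-free on-axis pixel value
    of the run (small enough not to disturb the 5 % bolus trigger, large
    enough to give replicate scatter).
    """

    frame_rate: float = 30.0  # frames/s
    duration: float = 12.0  # s (>= 10 s at defaults)
    pixel_size: float = 0.2  # mm
    noise_sd: float | None = None  # gray values; None = 2 % of peak (auto)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def timestamps(self) -> np.ndarray:
        n = int(round(self.duration * self.frame_rate))
        return np.arange(n) / self.frame_rate


@dataclass
class TransportModel:
    """Numerical and closure parameters of the 1D bolus transport model.

    The closures stand in for 3D effects the 1D scheme cannot resolve:

    * ``dispersion``: baseline axial dispersion (shear/pulsatility mixing).
    * ``mixing_dispersion_factor`` over ``mixing_length`` downstream of the
      stenosis: enhanced mixing where the poststenotic jet collapses.
    * recirculation retention: downstream of the jet-collapse point
      (``storage_offset`` .. ``storage_offset + storage_length`` behind the
      distal shoulder) tracer is exchanged into a stagnant recirculation
      pocket at a rate of ``storage_rate_scale`` x (relative diameter
      step)**``storage_severity_exponent`` per second and
      released back at ``storage_release_rate``; the nonstenotic model has
      no pocket.  Trapped tracer stays visible to the detector.
    * poststenotic jet: over ``jet_length`` mm behind the distal shoulder
      the stream is still a narrow fast jet, so the local transport
      velocity is Q/A_jet with A_jet widening linearly from the stenotic
      to the full lumen area (tracer spends less time per mm there).
    * ``injection_adds_flow``: the 20 ml/s injector flow displaces water
      and transiently accelerates everything downstream of the sheath tip
      (incompressible fluid); disable to model a massless tracer source.
    """

    dx: float = 1.0  # axial grid, mm
    cfl: float = 0.5  # advective Courant number bound
    dispersion: float = 100.0  # mm^2/s baseline axial dispersion
    mixing_dispersion_factor: float = 10.0  # dispersion multiplier in mixing zone
    mixing_length: float = 30.0  # mm downstream of the distal shoulder
    storage_offset: float = 15.0  # mm behind distal shoulder where pocket starts
    storage_length: float = 27.0  # mm axial extent of recirculation pocket
    storage_rate_scale: float = 22.0  # 1/s at a full-diameter step (severity 1)
    storage_severity_exponent: float = 2.5  # trapping ~ severity**exponent
    storage_release_rate: float = 0.12  # 1/s release back into the stream
    jet_length: float = 12.0  # mm over which the poststenotic jet widens back
    injection_adds_flow: bool = True

    def __post_init__(self) -> None:
        if self.dx <= 0 or not 0 < self.cfl <= 1:
            raise ValueError("dx must be positive and 0 < cfl <= 1")
        if self.dispersion < 0 or self.mixing_dispersion_factor < 0:
            raise ValueError("dispersion terms must be non-negative")
        if min(self.storage_rate_scale, self.storage_release_rate) < 0:
            raise ValueError("storage rates must be non-negative")


@dataclass
class ExperimentConfig:
    """Full bench experiment: grades x replicates plus analysis settings."""

    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    flow: FlowProgram = field(default_factory=FlowProgram)
    injection: InjectionProtocol = field(default_factory=InjectionProtocol)
    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    transport: TransportModel = field(default_factory=TransportModel)
    grades: Sequence[int] = (0, 40, 60, 80)
    n_replicates: int = 3
    integration_windows: Sequence[float] = (1.0, 3.0, 5.0, 7.0)
    roi_sizes: Sequence[float] = (10.0, 8.0, 6.0, 4.0)
    arrival_threshold: float = 0.05
    smoothing_sd: float = 0.0  # s; > 0 emulates clinical-software curve smoothing
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grades"] = list(self.grades)
        d["integration_windows"] = list(self.integration_windows)
        d["roi_sizes"] = list(self.roi_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, typ in [
            ("geometry", PhantomGeometry),
            ("flow", FlowProgram),
            ("injection", InjectionProtocol),
            ("acquisition", AcquisitionSettings),
            ("transport", TransportModel),
        ]:
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
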