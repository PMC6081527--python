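"""Projection of a simulated concentration field into fluoroscopic frames.

Subtracted (DSA-style) convention: the water-filled blank is already zero,
contrast increases the gray value, and gray is linear in the contrast path
length through the lumen.  For each pixel column the tracer volume
fraction is spread laterally according to a profile:

* ``parabolic`` (default): contrast rides the faster core of laminar pipe
  flow, so the volume concentration falls off as 1 - (rho/r)^2 — the
  projection is proportional to (r^2 - y^2)^(3/2);
* ``chord``: contrast uniformly mixed over the cross-section — projection
  proportional to the chord length 2*sqrt(r^2 - y^2);
* ``flat``: equal projected gray across the lumen width (a control without
  any lateral structure).

All profiles conserve the projected total, so full-width region means are
identical between them; only sub-lumen ROIs tell them apart.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .config import (
    AcquisitionSettings,
    FlowProgram,
    InjectionProtocol,
    PhantomGeometry,
    TransportModel,
)
from .transport import ConcentrationField, simulate_transport

__all__ = ["ImageSeries", "project_to_images", "generate_replicates", "LATERAL_PROFILES"]

LATERAL_PROFILES = ("parabolic", "chord", "flat")

#: replicate-to-replicate jitter of the injection start (s); one valve
#: cycle wide, so the bolus phase relative to the valve differs per run
INJECTION_JITTER = 0.4


@dataclass
class ImageSeries:
    """Timestamped stack of 2D gray-value frames of one simulated run."""

    timestamps: np.ndarray  # (nframes,) s, uniformly spaced
    frames: np.ndarray  # (nframes, ny, nx) uint16 gray values
    pixel_size: float  # mm
    origin: tuple[float, float]  # (x, y) mm of the outer corner of pixel [0, 0]
    geometry: PhantomGeometry
    meta: dict = field(default_factory=dict)

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.timestamps[1] - self.timestamps[0])

    def x_to_col(self, x_mm: float) -> int:
        return int(np.floor((x_mm - self.origin[0]) / self.pixel_size))

    def y_to_row(self, y_mm: float) -> int:
        return int(np.floor((y_mm - self.origin[1]) / self.pixel_size))


def _lateral_profile(mode: str, y: np.ndarray, r_col: np.ndarray) -> np.ndarray:
    """Projected path per unit volume fraction, shape (ny, ncols).

    For every mode the integral over y equals the lumen area, so a column
    of pixels always sums to (attenuation x tracer per axial length).
    """
    h2 = r_col[None, :] ** 2 - y[:, None] ** 2
    inside = h2 > 0.0
    h2 = np.where(inside, h2, 0.0)
    if mode == "parabolic":
        prof = (8.0 / 3.0) * h2**1.5 / r_col[None, :] ** 2
    elif mode == "chord":
        prof = 2.0 * np.sqrt(h2)
    elif mode == "flat":
        prof = np.where(inside, np.pi * r_col[None, :] / 2.0, 0.0)
    else:
        raise ValueError(f"unknown lateral profile {mode!r}; expected one of {LATERAL_PROFILES}")
    return prof


def project_to_images(
    fieldc: ConcentrationField,
    geometry: PhantomGeometry,
    acq: AcquisitionSettings,
    attenuation: float | None = None,
    lateral_profile: str = "parabolic",
    rng: np.random.Generator | None = None,
    meta: dict | None = None,
) -> ImageSeries:
    """Render an image series from a concentration field.

    ``attenuation`` is the gray value per mm of equivalent pure-contrast
    path (default: the :class:`InjectionProtocol` default).  Noise is
    additive zero-mean Gaussian with SD ``acq.noise_sd`` (``None`` = 2 %
    of the run's peak noise-free pixel), clipped at zero, quantized to
    16-bit.
    """
    if geometry.inner_diameter / acq.pixel_size < 4:
        raise ValueError(
            "pixel grid too coarse to resolve the lumen: fewer than 4 pixels "
            f"across the {geometry.inner_diameter} mm diameter at "
            f"{acq.pixel_size} mm/pixel"
        )
    if attenuation is None:
        attenuation = InjectionProtocol().contrast_attenuation_coefficient
    times = acq.timestamps()
    conc = fieldc.sample(times)  # (nframes, ncells) mm^3/mm, raises if span too short

    px = acq.pixel_size
    nx = int(round(geometry.tube_length / px))
    height = geometry.inner_diameter + 2.0 * geometry.wall_thickness
    ny = int(round(height / px))
    origin = (-geometry.tube_length / 2.0, -height / 2.0)
    x_cols = origin[0] + (np.arange(nx) + 0.5) * px
    y_rows = origin[1] + (np.arange(ny) + 0.5) * px

    r_col = geometry.radius_at(x_cols)
    area_col = np.pi * r_col**2
    prof = _lateral_profile(lateral_profile, y_rows, r_col).astype(np.float64)

    # linear interpolation of the 1 mm transport grid onto pixel columns
    grid = fieldc.axial_grid
    idx = np.clip(np.searchsorted(grid, x_cols) - 1, 0, len(grid) - 2)
    w = np.clip((x_cols - grid[idx]) / (grid[idx + 1] - grid[idx]), 0.0, 1.0)
    phi = ((1.0 - w) * conc[:, idx] + w * conc[:, idx + 1]) / area_col  # volume fraction

    noise_sd = acq.noise_sd
    if noise_sd is None:
        peak = attenuation * float((phi * prof.max(axis=0)).max()) if phi.size else 0.0
        noise_sd = 0.02 * peak
    if rng is None:
        rng = np.random.default_rng(acq.seed)

    frames = np.empty((len(times), ny, nx), dtype=np.uint16)
    for k in range(len(times)):
        img = attenuation * phi[k][None, :] * prof
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        np.clip(np.rint(img, out=img), 0.0, 65535.0, out=img)
        frames[k] = img.astype(np.uint16)

    full_meta = {
        "frame_rate": acq.frame_rate,
        "noise_sd": float(noise_sd),
        "attenuation": float(attenuation),
        "lateral_profile": lateral_profile,
        "grade_pct": geometry.grade_pct,
        "geometry": dataclasses.asdict(geometry),
    }
    full_meta.update(meta or {})
    return ImageSeries(
        timestamps=times,
        frames=frames,
        pixel_size=px,
        origin=origin,
        geometry=geometry,
        meta=full_meta,
    )


def generate_replicates(
    geometry: PhantomGeometry,
    flow: FlowProgram,
    injection: InjectionProtocol,
    acq: AcquisitionSettings,
    n_replicates: int,
    base_seed: int,
    model: TransportModel | None = None,
    jitter: bool = True,
    lateral_profile: str = "parabolic",
) -> list[ImageSeries]:
    """Simulate ``n_replicates`` independent runs of one stenosis model.

    Replicates differ in the detector-noise realization and in a seeded
    jitter of the injection start, uniform within one valve cycle
    (±0.4 s), emulating the uncontrolled phase between power injector and
    solenoid valve in repeated bench runs.  Deterministic per
    ``base_seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    model = model or TransportModel()
    out: list[ImageSeries] = []
    for rep, child in enumerate(np.random.SeedSequence(base_seed).spawn(n_replicates)):
        rng = np.random.default_rng(child)
        shift = float(rng.uniform(-INJECTION_JITTER, INJECTION_JITTER)) if jitter else 0.0
        inj = replace(injection, start_time=injection.start_time + shift)
        fieldc = simulate_transport(
            geometry, flow, inj, duration=acq.duration, model=model,
            output_times=acq.timestamps(),
        )
        series = project_to_images(
            fieldc, geometry, acq,
            attenuation=injection.contrast_attenuation_coefficient,
            lateral_profile=lateral_profile, rng=rng,
            meta={"replicate": rep, "base_seed": int(base_seed),
                  "injection_start": inj.start_time},
        )
        out.append(series)
    return out
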