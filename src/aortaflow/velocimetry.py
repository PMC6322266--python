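"""Phase-to-velocity conversion and cycle-integrated net flow.

The phase pixel value of a through-plane PC acquisition encodes signed
velocity up to the VENC limit.  Two decoding conventions ("dialects") are
provided:

``phase-linear`` (default)
    v = P * VENC / P_max, the conventional linear mapping from the signed
    integer phase value to cm/s, with P_max the full-scale phase value.

``magnitude-scaled``
    v = P * M * ASF with ASF = 10*pi*R / VENC, where M is the raw magnitude
    pixel and R the reconstruction scale from the header, a convention in
    which velocity is proportional to the magnitude value (as in
    magnitude-masked phase reconstructions).  It yields calibrated cm/s only
    when the magnitude/scale product is itself calibrated, and round-trips
    exactly against the phantom's matching encoder.

Net flow integrates the masked velocity field over the cycle:

    NetFlow = sum_n sum_i S[n,i] * V[n,i] * a * dt     [mL]

with S the binary valve mask, a the pixel area in cm^2 and dt the frame
interval in s.  Signed velocities are retained, so regurgitant (negative)
flow subtracts from the total.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import AlignmentError, PCSeries, SegmentationMap

__all__ = [
    "DIALECTS",
    "DEFAULT_DIALECT",
    "PHASE_FULL_SCALE",
    "VelocityMap",
    "FlowResult",
    "amplitude_scale_factor",
    "to_velocity",
    "encode_phase",
    "net_flow",
]

DIALECTS = ("phase-linear", "magnitude-scaled")
DEFAULT_DIALECT = "phase-linear"

#: Full-scale signed phase pixel value for the phase-linear dialect
#: (12-bit style encoding: P = +/-4096 maps to +/-VENC).
PHASE_FULL_SCALE = 4096.0


@dataclass(frozen=True)
class VelocityMap:
    """Per-frame signed through-plane velocity in cm/s."""

    velocity: np.ndarray  # (n_frames, H, W)
    dialect: str
    source: PCSeries | None = None

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]


@dataclass(frozen=True)
class FlowResult:
    """Per-frame flow increments and cycle-integrated net flow, in mL.

    ``net_flow == per_frame_flow.sum() == forward_flow + backward_flow``
    with ``forward_flow`` the sum of positive increments and
    ``backward_flow`` (<= 0) the sum of negative ones.
    """

    per_frame_flow: np.ndarray
    frame_interval: float

    @property
    def net_flow(self) -> float:
        return float(self.per_frame_flow.sum())

    @property
    def forward_flow(self) -> float:
        return float(self.per_frame_flow[self.per_frame_flow > 0].sum())

    @property
    def backward_flow(self) -> float:
        return float(self.per_frame_flow[self.per_frame_flow < 0].sum())

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "net_flow_ml": self.net_flow,
            "forward_flow_ml": self.forward_flow,
            "backward_flow_ml": self.backward_flow,
            "frame_interval_s": self.frame_interval,
            "per_frame_flow_ml": [float(v) for v in self.per_frame_flow],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame_index", "time_s", "flow_ml"])
            for n, v in enumerate(self.per_frame_flow):
                writer.writerow([n, n * self.frame_interval, float(v)])
        return path


def amplitude_scale_factor(recon_scale: float, venc: float) -> float:
    """ASF = 10 * pi * R / VENC (cm/s per phase-magnitude product unit)."""
    if not recon_scale > 0 or not venc > 0:
        raise ValueError(
            f"recon_scale and venc must be positive, got R={recon_scale}, VENC={venc}"
        )
    return 10.0 * math.pi * recon_scale / venc


def to_velocity(series: PCSeries, dialect: str = DEFAULT_DIALECT) -> VelocityMap:
    """Convert raw phase pixels to a signed velocity map in cm/s."""
    if dialect == "phase-linear":
        vel = series.phase * (series.venc / PHASE_FULL_SCALE)
    elif dialect == "magnitude-scaled":
        asf = amplitude_scale_factor(series.recon_scale, series.venc)
        vel = series.phase * series.magnitude * asf
    else:
        raise ValueError(f"unknown velocity dialect {dialect!r}; expected one of {DIALECTS}")
    peak = float(np.abs(vel).max()) if vel.size else 0.0
    if peak > series.venc * (1.0 + 1e-6):
        warnings.warn(
            f"decoded |velocity| {peak:.1f} cm/s exceeds VENC {series.venc:.1f}; "
            "no anti-aliasing correction is applied",
            RuntimeWarning,
            stacklevel=2,
        )
    return VelocityMap(velocity=vel, dialect=dialect, source=series)


def encode_phase(
    velocity: np.ndarray,
    magnitude: np.ndarray,
    venc: float,
    recon_scale: float,
    dialect: str = DEFAULT_DIALECT,
) -> np.ndarray:
    """Inverse of :func:`to_velocity`: raw phase values for a velocity field.

    Returns unrounded float phase values; integer quantization happens only
    when the series is written to DICOM.  For the magnitude-scaled dialect,
    pixels with zero magnitude get zero phase (their velocity is undefined
    under that decoding).
    """
    if dialect == "phase-linear":
        return velocity * (PHASE_FULL_SCALE / venc)
    if dialect == "magnitude-scaled":
        asf = amplitude_scale_factor(recon_scale, venc)
        with np.errstate(divide="ignore", invalid="ignore"):
            phase = np.where(magnitude > 0, velocity / (magnitude * asf), 0.0)
        return phase
    raise ValueError(f"unknown velocity dialect {dialect!r}; expected one of {DIALECTS}")


def net_flow(
    vel: VelocityMap,
    seg: SegmentationMap,
    series: PCSeries,
) -> FlowResult:
    """Integrate masked velocities into per-frame and cycle net flow (mL).

    cm/s * cm^2 * s = cm^3 = mL, so no further unit factor is needed.
    """
    if vel.velocity.shape != seg.masks.shape or seg.masks.shape != series.magnitude.shape:
        raise AlignmentError(
            f"shape mismatch: velocity {vel.velocity.shape}, mask {seg.masks.shape}, "
            f"series {series.magnitude.shape}"
        )
    increments = (
        (vel.velocity * seg.masks).sum(axis=(1, 2))
        * series.pixel_area
        * series.frame_interval
    )
    return FlowResult(per_frame_flow=increments, frame_interval=series.frame_interval)
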