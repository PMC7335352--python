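"""Geometry and unit conventions shared by every analysis stage.

All positions are measured along the kymograph spatial axis with the
chromium barrier (tether point) at coordinate 0 and values increasing
toward the free DNA end / pedestal.  Pixels are converted to micrometres
with the microscope's calibrated pixel size, and micrometre quantities
are converted to base pairs by assuming the full DNA contour length is
uniformly mapped onto the mean measured end-to-end extension of the
tethered molecules.  The bp conversion is therefore geometry-dependent:
each tether mode (single-tethered, U-shaped, double-tethered) carries
its own mean extension.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, asdict
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

#: camera pixel size through the 60x objective, μm per pixel
DEFAULT_PIXEL_SIZE_UM = 0.267
#: acquisition frame interval, s
DEFAULT_FRAME_INTERVAL_S = 5.0
#: lambda-phage DNA contour length, bp
LAMBDA_CONTOUR_BP = 48_502
#: mean end-to-end extensions by substrate, μm
EXTENSION_NAKED_UM = 10.75
EXTENSION_NUCLEOSOME_UM = 9.11
EXTENSION_U_SHAPED_UM = 9.54
EXTENSION_DOUBLE_TETHER_UM = 8.0


class TetherMode(str, enum.Enum):
    SINGLE = "single"
    U_SHAPED = "u_shaped"
    DOUBLE = "double"


@dataclass(frozen=True)
class CurtainGeometry:
    """Per-experiment imaging geometry and DNA substrate description.

    Parameters
    ----------
    pixel_size_um:
        Length of one camera pixel in the sample plane (μm).
    frame_interval_s:
        Time between consecutive kymograph frames (s).
    contour_bp:
        DNA contour length in base pairs.
    extension_um:
        Mean end-to-end extension of the flow-stretched DNA (μm); the
        bp↔μm mapping assumes the contour is spread uniformly over it.
        Flow-stretched DNA sits well below its crystallographic contour
        length, so no upper bound is enforced.
    tether_mode:
        How the DNA is anchored: ``single`` (one biotinylated end, free
        end extended by flow), ``u_shaped`` (both ends on the bilayer)
        or ``double`` (barrier-to-pedestal).
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    contour_bp: float = LAMBDA_CONTOUR_BP
    extension_um: float = EXTENSION_NAKED_UM
    tether_mode: TetherMode = TetherMode.SINGLE

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "frame_interval_s", "contour_bp", "extension_um"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        object.__setattr__(self, "tether_mode", TetherMode(self.tether_mode))

    @property
    def bp_per_um(self) -> float:
        return self.contour_bp / self.extension_um

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tether_mode"] = self.tether_mode.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CurtainGeometry":
        return cls(**{k: d[k] for k in (
            "pixel_size_um", "frame_interval_s", "contour_bp",
            "extension_um", "tether_mode") if k in d})


def _check_finite(x: ArrayLike) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    return arr


def px_to_um(x_px: ArrayLike, geometry: CurtainGeometry) -> ArrayLike:
    """Convert pixel distances (or velocities per frame basis) to μm."""
    out = _check_finite(x_px) * geometry.pixel_size_um
    return float(out) if np.isscalar(x_px) or out.ndim == 0 else out


def um_to_px(x_um: ArrayLike, geometry: CurtainGeometry) -> ArrayLike:
    out = _check_finite(x_um) / geometry.pixel_size_um
    return float(out) if np.isscalar(x_um) or out.ndim == 0 else out


def um_to_bp(x_um: ArrayLike, geometry: CurtainGeometry) -> ArrayLike:
    """Convert a μm quantity (distance or rate) to bp units.

    Applies the uniform-mapping assumption: ``contour_bp`` base pairs
    span ``extension_um`` micrometres, so the same factor converts
    distances (μm → bp) and velocities (μm/s → bp/s).
    """
    out = _check_finite(x_um) * geometry.bp_per_um
    return float(out) if np.isscalar(x_um) or out.ndim == 0 else out


def bp_to_um(x_bp: ArrayLike, geometry: CurtainGeometry) -> ArrayLike:
    out = _check_finite(x_bp) / geometry.bp_per_um
    return float(out) if np.isscalar(x_bp) or out.ndim == 0 else out


def frames_to_s(n_frames: ArrayLike, geometry: CurtainGeometry) -> ArrayLike:
    out = _check_finite(n_frames) * geometry.frame_interval_s
    return float(out) if np.isscalar(n_frames) or out.ndim == 0 else out


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures for report output."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
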