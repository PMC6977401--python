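"""Acquisition protocol geometry and timing.

The scanning protocol raster-scans a square field: at each of ``n_y`` slow-axis
positions a set of ``n_repeats`` overlapping B-scans of ``n_x`` A-scans is
acquired, each A-scan being one spectrum of ``n_spectral`` pixels.  The repeat
(oversampling) axis is what the angiographic differential analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator


class AcquisitionProtocol(BaseModel):
    """Scan geometry and timing of one volumetric acquisition.

    Defaults describe the full-scale in vivo protocol: 300 B-scan positions,
    300 A-scans per B-scan, sixfold oversampling, 2048 spectral pixels,
    1.1 x 1.1 mm lateral field and a 2.12 mm axial range in air.
    """

    model_config = {"frozen": True}

    n_y: int = Field(300, ge=1, description="slow-axis (B-scan) positions")
    n_x: int = Field(300, ge=1, description="A-scans per B-scan")
    n_repeats: int = Field(6, ge=1, description="B-scan oversampling factor")
    n_spectral: int = Field(2048, ge=2, description="spectral pixels per A-scan")
    t_acq_us: float = Field(18.0, gt=0, description="acquisition time per A-scan (us)")
    t_rep_us: float = Field(20.0, gt=0, description="repetition time per A-scan (us)")
    x_range_mm: float = Field(1.1, gt=0)
    y_range_mm: float = Field(1.1, gt=0)
    z_range_air_mm: float = Field(2.12, gt=0)

    @model_validator(mode="after")
    def _check_timing(self) -> "AcquisitionProtocol":
        if self.t_rep_us < self.t_acq_us:
            raise ValueError(
                f"repetition time ({self.t_rep_us} us) must be >= acquisition "
                f"time ({self.t_acq_us} us)"
            )
        return self

    # -- derived geometry ---------------------------------------------------

    @property
    def n_depth(self) -> int:
        """Depth pixels retained after FFT (positive-frequency half)."""
        return self.n_spectral // 2

    @property
    def dz_air_um(self) -> float:
        """Axial pixel pitch in air (um per depth pixel)."""
        return self.z_range_air_mm * 1e3 / self.n_depth

    @property
    def dx_um(self) -> float:
        return self.x_range_mm * 1e3 / self.n_x

    @property
    def dy_um(self) -> float:
        return self.y_range_mm * 1e3 / self.n_y

    @property
    def n_bscans(self) -> int:
        return self.n_y * self.n_repeats


@dataclass(frozen=True)
class TimingReport:
    per_bscan_s: float
    total_scan_s: float
    timestamps_s: np.ndarray  # one per B-scan, acquisition order (y major, repeat minor)


def protocol_timing(protocol: AcquisitionProtocol) -> TimingReport:
    """Timing of one volumetric acquisition.

    Total sample scanning time is the product of B-scan positions, oversampling
    factor, A-scans per B-scan and the per-A-scan acquisition time (the
    full-scale protocol gives 9.7 s).  B-scan timestamps are spaced by the
    per-B-scan time so that the last B-scan ends at the total scanning time.
    """
    per_bscan = protocol.n_x * protocol.t_acq_us * 1e-6
    total = protocol.n_y * protocol.n_repeats * per_bscan
    timestamps = np.arange(protocol.n_bscans) * per_bscan
    return TimingReport(per_bscan_s=per_bscan, total_scan_s=total, timestamps_s=timestamps)
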