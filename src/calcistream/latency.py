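"""Closed-loop latency budget model for real-time miniscope decoding.

The end-to-end feedback latency of a closed-loop imaging system is the sum
of three delays that accrue sequentially between photons hitting the sensor
and a TTL pulse leaving the decoder:

* light-gathering delay ``tau_L`` — the sensor integrates photons over one
  frame interval, which is equivalent to convolving the true fluorescence
  signal with a boxcar of width ``I`` and therefore delays it by ``I / 2``;
* frame transmission delay ``tau_T`` — pixels are streamed serially, one per
  pixel-clock cycle, until the last pixel of the imaging subwindow arrives;
* image processing delay ``tau_I`` — a fixed image-pipeline latency plus a
  per-output-unit cost of evaluating the linear decoder.

All internal values are kept at full precision; rounding to 0.1 ms happens
only in :meth:`LatencyReport.rounded`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "LatencyParams",
    "LatencyReport",
    "pixels_per_frame",
    "latency_budget",
    "feedback_latency_bound",
]

#: Fixed image-pipeline (FPGA) latency in ms, y-intercept of the measured
#: linear fit of processing delay against decoder output-unit count.
DEFAULT_FPGA_INTERCEPT_MS = 0.888

#: Incremental decoder cost per output unit in ms (47.3 microseconds).
DEFAULT_ARM_SLOPE_MS = 0.0473

#: Pixel clock period of the 608x608 miniscope sensor, in nanoseconds.
V4_PIXEL_CLOCK_NS = 60.24

#: A/D conversion overhead subtracted from the frame interval to obtain the
#: exposure time, in ms.
ADC_OVERHEAD_MS = 1.0


@dataclass(frozen=True)
class LatencyParams:
    """Parameters of the latency model.

    Parameters
    ----------
    frame_interval_ms:
        Frame interval ``I`` in milliseconds (50 ms at 20 Hz).
    sensor_width, sensor_height:
        Full sensor dimensions ``W`` x ``H`` in pixels.
    bottom_row, right_col:
        1-based row/column of the bottom-right corner of the imaging
        subwindow on the sensor.  Transmission of a frame is complete once
        this pixel has arrived, so only ``P = W * (B - 1) + R`` pixels count
        toward the transmission delay.
    pixel_clock_ns:
        Serial pixel clock period ``C`` in nanoseconds.
    n_output_units:
        Number of decoder output units ``M``.
    """

    frame_interval_ms: float = 50.0
    sensor_width: int = 608
    sensor_height: int = 608
    bottom_row: int = 560
    right_col: int = 560
    pixel_clock_ns: float = V4_PIXEL_CLOCK_NS
    n_output_units: int = 12
    fpga_intercept_ms: float = DEFAULT_FPGA_INTERCEPT_MS
    arm_slope_ms: float = DEFAULT_ARM_SLOPE_MS

    def __post_init__(self) -> None:
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        if self.pixel_clock_ns <= 0:
            raise ValueError("pixel_clock_ns must be positive")
        if not 1 <= self.bottom_row <= self.sensor_height:
            raise ValueError(
                f"bottom_row {self.bottom_row} outside 1..{self.sensor_height}"
            )
        if not 1 <= self.right_col <= self.sensor_width:
            raise ValueError(
                f"right_col {self.right_col} outside 1..{self.sensor_width}"
            )
        if self.n_output_units < 0:
            raise ValueError("n_output_units must be non-negative")

    @classmethod
    def centered_subwindow(
        cls,
        sensor_width: int = 608,
        sensor_height: int = 608,
        subwindow: int = 512,
        **kwargs,
    ) -> "LatencyParams":
        """Params for a ``subwindow`` x ``subwindow`` region centered on the
        sensor, using the 1-based corner convention ``B = H/2 + s/2``."""
        return cls(
            sensor_width=sensor_width,
            sensor_height=sensor_height,
            bottom_row=sensor_height // 2 + subwindow // 2,
            right_col=sensor_width // 2 + subwindow // 2,
            **kwargs,
        )


@dataclass(frozen=True)
class LatencyReport:
    """Latency budget, all delays in milliseconds."""

    tau_L: float
    tau_T: float
    tau_I: float
    P: int
    exposure_ms: float

    @property
    def tau_F(self) -> float:
        """Total feedback latency: the three delays accrue sequentially."""
        return self.tau_L + self.tau_T + self.tau_I

    def rounded(self, ndigits: int = 1) -> dict:
        """Presentation values rounded to ``ndigits`` decimals of a ms."""
        return {
            "tau_L_ms": round(self.tau_L, ndigits),
            "tau_T_ms": round(self.tau_T, ndigits),
            "tau_I_ms": round(self.tau_I, ndigits),
            "tau_F_ms": round(self.tau_F, ndigits),
            "exposure_ms": round(self.exposure_ms, ndigits),
            "pixels_per_frame": self.P,
        }


def pixels_per_frame(sensor_width: int, bottom_row: int, right_col: int) -> int:
    """Effective number of pixels transmitted before a frame is usable.

    Pixels stream in raster order; the frame can be processed once the
    bottom-right pixel of the imaging subwindow (1-based row ``bottom_row``,
    column ``right_col``) has arrived, after ``W * (B - 1) + R`` pixels.
    """
    if bottom_row < 1 or right_col < 1 or right_col > sensor_width:
        raise ValueError("bottom_row/right_col out of range for sensor")
    return sensor_width * (bottom_row - 1) + right_col


def latency_budget(params: LatencyParams) -> LatencyReport:
    """Evaluate the three-component latency budget.

    ``tau_L = I / 2`` (boxcar light integration), ``tau_T = P * C`` (serial
    pixel transmission), ``tau_I = intercept + slope * M`` (image pipeline
    plus decoder).  The exposure time is ``I - 1`` ms, one A/D-conversion
    overhead short of the frame interval.
    """
    P = pixels_per_frame(params.sensor_width, params.bottom_row, params.right_col)
    if params.bottom_row > params.sensor_height:
        raise ValueError("bottom_row exceeds sensor height")
    tau_L = params.frame_interval_ms / 2.0
    tau_T = P * params.pixel_clock_ns * 1e-6  # ns -> ms
    tau_I = params.fpga_intercept_ms + params.arm_slope_ms * params.n_output_units
    exposure = params.frame_interval_ms - ADC_OVERHEAD_MS
    return LatencyReport(tau_L=tau_L, tau_T=tau_T, tau_I=tau_I, P=P, exposure_ms=exposure)


#: Upper bound on the image-processing delay over its observed
#: distribution, ms; used for worst-case feedback budgets.
TAU_I_MAX_MS = 2.5


def feedback_latency_bound(params: LatencyParams, tau_I_max_ms: float = TAU_I_MAX_MS) -> float:
    """Worst-case feedback latency ``tau_L + tau_T + max(tau_I)`` in ms.

    The processing delay varies frame to frame; the closed-loop guarantee
    uses its distribution maximum (2.5 ms by default) rather than the mean
    model, so TTL output is emitted before the next frame finishes
    arriving.
    """
    report = latency_budget(params)
    return report.tau_L + report.tau_T + tau_I_max_ms
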